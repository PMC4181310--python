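"""Published field summaries used as inputs to the replication.

The original field study (radio-collared neonates captured at <=24 h in
Minnesota, South Dakota and California, 2001-2009) released only summary
statistics, not per-animal records.  The per-site / per-year mean new-hoof
growths below, with their sample sizes, are the published inputs from which
the reported age-estimate means can be recomputed exactly (the age
calibrations are linear, so the mean estimate equals the calibration applied
to the weighted mean hoof growth).  They also seed the cohort simulator's
default site structure.
"""

from __future__ import annotations

from .age_models import MULE_DEER, PRONGHORN, WHITE_TAILED_DEER

__all__ = [
    "SITE_HOOF_MEANS",
    "SAMPLE_SIZES",
    "weighted_mean_hoof",
    "max_observed_hoof",
]

# (site/year label, mean new-hoof growth mm, n animals)
SITE_HOOF_MEANS: dict[str, list[tuple[str, float, int]]] = {
    WHITE_TAILED_DEER: [
        ("Redwood-Renville MN", 2.70, 17),
        ("Lincoln-Pipestone MN", 1.98, 6),
        ("Brookings SD", 1.92, 12),
        ("Edmunds-Faulk SD", 1.98, 36),
    ],
    MULE_DEER: [
        ("CA 2006", 3.61, 19),
        ("CA 2007", 3.81, 18),
        ("CA 2008", 4.05, 24),
    ],
    PRONGHORN: [
        ("SD 2002", 2.32, 21),
        ("SD 2003", 2.39, 12),
        ("SD 2004", 3.99, 1),
        ("SD 2005", 1.86, 3),
    ],
}

# Known-age neonates entering the survival analyses, per species.
SAMPLE_SIZES = {WHITE_TAILED_DEER: 71, MULE_DEER: 61, PRONGHORN: 37}


def weighted_mean_hoof(species: str) -> float:
    """Sample-size-weighted mean of the published site/year hoof means (mm)."""
    rows = SITE_HOOF_MEANS[species]
    total_n = sum(n for _, _, n in rows)
    return sum(mean * n for _, mean, n in rows) / total_n


def max_observed_hoof(species: str) -> float:
    """Largest published site/year mean hoof growth (mm)."""
    return max(mean for _, mean, _ in SITE_HOOF_MEANS[species])
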