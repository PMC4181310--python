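"""Known-fate interval survival models with group-equality constraints.

For radio-tagged animals whose status is known at every occasion (detection
probability 1), the likelihood of a staggered-entry encounter-history set is
a product of simple binomials: each animal-occasion at risk survives its
occasion with probability ``S`` or dies.  Survival is modelled on the logit
scale with one parameter per *cell*, a (group, time-block) combination:

* group structure — cohorts (known-age and per-calibration) pooled
  according to an equality spec such as ``"KA=B=S,H=HS"``;
* time structure — ``constant`` (one block), ``weekly`` (week blocks) or
  ``daily`` (one block per day).

``K = n_groups * n_time_blocks`` counts structural parameters, matching the
Program MARK convention even when some cells have no exposure.  Cells where
the maximum-likelihood estimate lies on the boundary (zero deaths, or all
deaths) are flagged and their logit clamped at +/-15 rather than diverging.

The module follows the statsmodels Model/Results idiom:
:class:`KnownFateModel` holds the design, ``.fit()`` returns a
:class:`KnownFateResults` carrying estimates, covariance, AICc, deviance
(relative to the saturated cohort-by-occasion model) and cumulative
survival with delta-method uncertainty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, log_expit, logit

from .encounter import DIED, EncounterHistory, OccasionMap, make_occasion_map

__all__ = [
    "GroupStructure",
    "parse_group_spec",
    "enumerate_partitions",
    "singleton_structure",
    "pooled_structure",
    "KnownFateModel",
    "KnownFateResults",
    "CumulativeSurvival",
    "FitError",
    "neg2_log_likelihood",
    "aicc",
]

_Z95 = 1.959963984540054
_BETA_CLAMP = 15.0

TIME_STRUCTURES = ("constant", "weekly", "daily")


class FitError(RuntimeError):
    """Raised when the optimizer fails to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


# ---------------------------------------------------------------------------
# Group structures (set partitions of the cohort labels)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupStructure:
    """A partition of cohort labels into shared-survival groups."""

    cohorts: tuple[str, ...]
    groups: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        flat = [c for g in self.groups for c in g]
        if sorted(flat) != sorted(self.cohorts):
            raise ValueError(
                f"groups {self.groups} are not a partition of cohorts {self.cohorts}"
            )

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def partition(self) -> dict[str, int]:
        """Cohort label -> 1-based group id."""
        return {c: i for i, g in enumerate(self.groups, start=1) for c in g}

    @property
    def spec_string(self) -> str:
        return ",".join("=".join(g) for g in self.groups)

    @property
    def display(self) -> str:
        return "{" + ", ".join(" = ".join(g) for g in self.groups) + "}"


def singleton_structure(cohorts: Sequence[str]) -> GroupStructure:
    """Every cohort its own group (the most general structure)."""
    cohorts = tuple(cohorts)
    return GroupStructure(cohorts=cohorts, groups=tuple((c,) for c in cohorts))


def pooled_structure(cohorts: Sequence[str]) -> GroupStructure:
    """All cohorts share one survival parameter."""
    cohorts = tuple(cohorts)
    return GroupStructure(cohorts=cohorts, groups=(cohorts,))


def parse_group_spec(spec: str, cohorts: Sequence[str]) -> GroupStructure:
    """Parse an equality spec like ``"KA=B=S,H=HS"`` (braces and whitespace
    tolerated) over the given cohort labels.

    Every cohort must appear exactly once; ``=`` joins cohorts within a
    group and ``,`` separates groups.
    """
    cohorts = tuple(cohorts)
    known = set(cohorts)
    cleaned = spec.strip().strip("{}")
    seen: set[str] = set()
    groups: list[tuple[str, ...]] = []
    for part in cleaned.split(","):
        members = []
        for tok in part.split("="):
            tok = tok.strip()
            if not tok:
                raise ValueError(f"empty label in group spec {spec!r}")
            if tok not in known:
                raise ValueError(
                    f"unknown cohort {tok!r} at position {spec.find(tok)} "
                    f"in spec {spec!r}; known cohorts: {sorted(known)}"
                )
            if tok in seen:
                raise ValueError(f"duplicate cohort {tok!r} in spec {spec!r}")
            seen.add(tok)
            members.append(tok)
        groups.append(tuple(members))
    missing = known - seen
    if missing:
        raise ValueError(f"spec {spec!r} omits cohorts {sorted(missing)}")
    return GroupStructure(cohorts=cohorts, groups=tuple(groups))


def enumerate_partitions(cohorts: Sequence[str]) -> list[GroupStructure]:
    """All set partitions of the cohort labels (Bell-number count)."""
    cohorts = tuple(cohorts)
    if not 1 <= len(cohorts) <= 6:
        raise ValueError("partition enumeration supports 1..6 cohorts")

    def _partitions(items: tuple[str, ...]):
        if not items:
            yield ()
            return
        first, rest = items[0], items[1:]
        for part in _partitions(rest):
            # first joins each existing block, or opens a new one
            for i in range(len(part)):
                yield part[:i] + ((first,) + part[i],) + part[i + 1 :]
            yield ((first,),) + part

    structures = []
    for part in _partitions(cohorts):
        # canonical order: blocks sorted by first appearance in cohort order
        order = {c: i for i, c in enumerate(cohorts)}
        blocks = tuple(
            tuple(sorted(b, key=order.get))
            for b in sorted(part, key=lambda b: min(order[c] for c in b))
        )
        structures.append(GroupStructure(cohorts=cohorts, groups=blocks))
    return structures


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

def _time_blocks(occasion_map: OccasionMap, time_structure: str) -> list[tuple[int, ...]]:
    """Occasion indices (1-based) composing each time block."""
    n = occasion_map.n_occasions
    if time_structure == "constant":
        return [tuple(range(1, n + 1))]
    if time_structure == "daily":
        if any(occasion_map.block_length(i) != 1 for i in range(1, n + 1)):
            raise ValueError("daily time structure requires a daily occasion map")
        return [(i,) for i in range(1, n + 1)]
    if time_structure == "weekly":
        if occasion_map.resolution == "weekly":
            return [(i,) for i in range(1, n + 1)]
        weekly = make_occasion_map(occasion_map.horizon, "weekly")
        blocks: dict[int, list[int]] = {}
        for occ in range(1, n + 1):
            day = occasion_map.blocks[occ - 1][0]
            blocks.setdefault(weekly.block_of(day), []).append(occ)
        return [tuple(blocks[b]) for b in sorted(blocks)]
    raise ValueError(f"time_structure must be one of {TIME_STRUCTURES}, got {time_structure!r}")


class KnownFateModel:
    """Known-fate survival model for staggered-entry encounter histories.

    Parameters
    ----------
    histories : sequence of EncounterHistory
        Histories sharing one occasion structure.
    occasion_map : OccasionMap
        The occasion structure the histories were built on.
    groups : GroupStructure, str, or None
        Equality constraints over cohort labels; a string is parsed with
        :func:`parse_group_spec`; ``None`` gives every cohort its own group.
    time_structure : {"constant", "weekly", "daily"}
        How survival varies over occasions within a group.
    """

    def __init__(
        self,
        histories: Sequence[EncounterHistory],
        occasion_map: OccasionMap,
        groups: "GroupStructure | str | None" = None,
        time_structure: str = "constant",
    ):
        if not histories:
            raise ValueError("no encounter histories supplied")
        if any(h.n_occasions != occasion_map.n_occasions for h in histories):
            raise ValueError("histories do not match the occasion map")
        self.histories = list(histories)
        self.occasion_map = occasion_map
        self.time_structure = time_structure

        present: list[str] = []
        for h in self.histories:
            if h.cohort_label not in present:
                present.append(h.cohort_label)

        if groups is None:
            structure = singleton_structure(present)
        elif isinstance(groups, str):
            structure = parse_group_spec(groups, present)
        else:
            structure = groups
            empty = [c for c in structure.cohorts if c not in present]
            if empty:
                warnings.warn(
                    f"cohorts with zero animals dropped from the design: {empty}",
                    stacklevel=2,
                )
                kept = tuple(c for c in structure.cohorts if c in present)
                new_groups = tuple(
                    tuple(c for c in g if c in present) for g in structure.groups
                )
                structure = GroupStructure(
                    cohorts=kept, groups=tuple(g for g in new_groups if g)
                )
            stray = set(present) - set(structure.cohorts)
            if stray:
                raise ValueError(f"histories carry cohorts outside the structure: {sorted(stray)}")
        self.groups = structure

        self.time_block_occasions = _time_blocks(occasion_map, time_structure)
        self.n_time_blocks = len(self.time_block_occasions)
        self.n_groups = structure.n_groups
        self.K = self.n_groups * self.n_time_blocks

        # occasion (0-based) -> time-block index (0-based)
        occ_block = np.empty(occasion_map.n_occasions, dtype=int)
        for b, occs in enumerate(self.time_block_occasions):
            for occ in occs:
                occ_block[occ - 1] = b
        self._occ_block = occ_block

        part = structure.partition
        exposures = np.zeros((self.n_groups, self.n_time_blocks))
        deaths = np.zeros_like(exposures)
        for h in self.histories:
            g = part[h.cohort_label] - 1
            counts = np.bincount(
                occ_block[h.entry_occasion - 1 : h.exit_occasion],
                minlength=self.n_time_blocks,
            )
            exposures[g] += counts
            if h.fate == DIED:
                deaths[g, occ_block[h.exit_occasion - 1]] += 1
        self.exposures = exposures.ravel()
        self.deaths = deaths.ravel()
        self.survivals = self.exposures - self.deaths
        self.n_eff = float(self.exposures.sum())

    # -- likelihood ---------------------------------------------------------

    def neg2_log_likelihood(self, beta: np.ndarray) -> float:
        """-2 log L for a full-length parameter vector (one beta per cell);
        empty cells contribute nothing."""
        beta = np.asarray(beta, dtype=float)
        if beta.shape != (self.K,):
            raise ValueError(f"beta must have length K={self.K}, got {beta.shape}")
        mask = self.exposures > 0
        ll = np.sum(
            self.survivals[mask] * log_expit(beta[mask])
            + self.deaths[mask] * log_expit(-beta[mask])
        )
        return float(-2.0 * ll)

    def _saturated_neg2loglik(self) -> float:
        """-2 log L of the saturated cohort-by-occasion model (closed form:
        each cell fitted at deaths/exposures); the deviance reference."""
        agg: dict[tuple[str, int], np.ndarray] = {}
        for h in self.histories:
            for occ in range(h.entry_occasion, h.exit_occasion + 1):
                key = (h.cohort_label, occ)
                cell = agg.setdefault(key, np.zeros(2))  # [exposures, deaths]
                cell[0] += 1
                if h.fate == DIED and occ == h.exit_occasion:
                    cell[1] += 1
        total = 0.0
        for n_c, d_c in agg.values():
            s_c = n_c - d_c
            if s_c > 0:
                total += s_c * np.log(s_c / n_c)
            if d_c > 0:
                total += d_c * np.log(d_c / n_c)
        return float(-2.0 * total)

    # -- fitting ------------------------------------------------------------

    def fit(self, maxiter: int = 500) -> "KnownFateResults":
        """Maximise the likelihood; returns a :class:`KnownFateResults`.

        Optimisation starts every beta at the logit of the overall empirical
        survival; boundary cells (no deaths, or no survivors) are clamped at
        +/-15 on the logit scale and flagged.
        """
        empty = self.exposures == 0
        boundary = ~empty & ((self.deaths == 0) | (self.survivals == 0))
        free = ~empty & ~boundary

        beta = np.full(self.K, np.nan)
        beta[boundary & (self.deaths == 0)] = _BETA_CLAMP
        beta[boundary & (self.survivals == 0)] = -_BETA_CLAMP

        # boundary cells contribute exactly zero log-likelihood at their
        # limiting MLE (S = 0 or 1); the clamp is a reporting device only
        neg2 = 0.0
        if free.any():
            p0 = np.clip(self.survivals.sum() / self.exposures.sum(), 1e-6, 1 - 1e-6)
            x0 = np.full(free.sum(), logit(p0))
            n_f, s_f, d_f = self.exposures[free], self.survivals[free], self.deaths[free]

            def objective(x):
                val = -2.0 * np.sum(s_f * log_expit(x) + d_f * log_expit(-x))
                grad = 2.0 * (n_f * expit(x) - s_f)
                return val, grad

            res = optimize.minimize(
                objective,
                x0,
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": maxiter, "ftol": 1e-14, "gtol": 1e-10},
            )
            if not res.success:
                raise FitError(f"optimizer failed: {res.message}", diagnostics=res)
            beta[free] = res.x
            neg2 = float(res.fun)

        # information-based variances; empty cells have none
        S = expit(beta)
        var_beta = np.full(self.K, np.nan)
        nonempty = ~empty
        var_beta[nonempty] = 1.0 / (
            self.exposures[nonempty] * S[nonempty] * (1 - S[nonempty])
        )

        if self.n_eff > self.K + 1:
            aicc_value = aicc(neg2, self.K, self.n_eff)
        else:
            aicc_value = np.nan
        deviance = neg2 - self._saturated_neg2loglik()

        return KnownFateResults(
            model=self,
            params=beta,
            var_params=var_beta,
            neg2loglik=neg2,
            aicc=aicc_value,
            deviance=deviance,
            boundary=boundary,
            empty=empty,
        )


def neg2_log_likelihood(design: KnownFateModel, beta: np.ndarray) -> float:
    """Functional alias for :meth:`KnownFateModel.neg2_log_likelihood`."""
    return design.neg2_log_likelihood(beta)


def aicc(neg2loglik: float, K: int, n_eff: float) -> float:
    """Akaike's Information Criterion with small-sample correction.

    ``n_eff`` is the effective sample size (total animal-occasion exposures
    for known-fate data) and must exceed ``K + 1``.
    """
    if n_eff <= K + 1:
        raise ValueError(f"AICc undefined: n_eff ({n_eff}) must exceed K+1 ({K + 1})")
    return neg2loglik + 2 * K + 2 * K * (K + 1) / (n_eff - K - 1)


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CumulativeSurvival:
    estimate: float
    se: float
    ci_low: float
    ci_high: float


class KnownFateResults:
    """Fitted known-fate model: estimates, uncertainty and diagnostics."""

    def __init__(self, model, params, var_params, neg2loglik, aicc, deviance, boundary, empty):
        self.model = model
        self.params = params
        self.var_params = var_params
        self.bse = np.sqrt(var_params)
        self.neg2loglik = neg2loglik
        self.aicc = aicc
        self.deviance = deviance
        self.boundary = boundary
        self.empty = empty
        self.K = model.K
        self.n_eff = model.n_eff

    # -- parameter-scale summaries ------------------------------------------

    def cov_params(self) -> np.ndarray:
        """Covariance of the logit-scale parameters (diagonal: cells are
        likelihood-separable)."""
        return np.diag(self.var_params)

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        """Normal-theory intervals on the logit scale, shape (K, 2)."""
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        half = z * self.bse
        return np.column_stack([self.params - half, self.params + half])

    def beta_ci_overlaps_zero(self, alpha: float = 0.05) -> np.ndarray:
        """Flag per beta: does the 95% CI include zero?  (Used to screen
        weakly supported competing models.)  Empty cells flag False."""
        ci = self.conf_int(alpha)
        with np.errstate(invalid="ignore"):
            return (ci[:, 0] <= 0) & (0 <= ci[:, 1])

    @property
    def interval_survival(self) -> np.ndarray:
        """Per-cell per-occasion survival probabilities."""
        return expit(self.params)

    @property
    def interval_survival_se(self) -> np.ndarray:
        S = self.interval_survival
        with np.errstate(invalid="ignore"):
            return np.sqrt(S * (1 - S) / self.exposures_safe)

    @property
    def exposures_safe(self) -> np.ndarray:
        return np.where(self.model.exposures > 0, self.model.exposures, np.nan)

    def cell_table(self) -> pd.DataFrame:
        """One row per (group, time block) cell."""
        m = self.model
        rows = []
        for g in range(m.n_groups):
            for b in range(m.n_time_blocks):
                j = g * m.n_time_blocks + b
                rows.append(
                    {
                        "group": g + 1,
                        "group_cohorts": "=".join(m.groups.groups[g]),
                        "time_block": b + 1,
                        "n_occasions": len(m.time_block_occasions[b]),
                        "exposures": m.exposures[j],
                        "deaths": m.deaths[j],
                        "survival": self.interval_survival[j],
                        "se": self.interval_survival_se[j],
                        "boundary": bool(self.boundary[j]),
                    }
                )
        return pd.DataFrame(rows)

    # -- cumulative survival -------------------------------------------------

    def _group_index(self, cohort: str | None) -> int:
        m = self.model
        if cohort is None:
            if m.n_groups != 1:
                raise ValueError("multiple groups; specify a cohort label")
            return 0
        part = m.groups.partition
        if cohort not in part:
            raise KeyError(
                f"unknown cohort {cohort!r}; known: {sorted(part)}"
            )
        return part[cohort] - 1

    def cumulative_survival(
        self, cohort: str | None = None, through_occasion: int | None = None
    ) -> CumulativeSurvival:
        """Probability of surviving occasions 1..through_occasion for the
        group containing ``cohort`` (delta-method SE; CI on the logit scale,
        back-transformed).

        The estimate is the product over time blocks of the block survival
        raised to the number of covered occasions.  Cells with zero exposure
        cannot be estimated and are skipped with a warning.
        """
        m = self.model
        g = self._group_index(cohort)
        through = through_occasion or m.occasion_map.n_occasions
        S = self.interval_survival
        log_T = 0.0
        var_log_T = 0.0
        for b, occs in enumerate(m.time_block_occasions):
            mlen = sum(1 for occ in occs if occ <= through)
            if mlen == 0:
                continue
            j = g * m.n_time_blocks + b
            if self.empty[j]:
                warnings.warn(
                    f"group {g + 1} has no exposure in time block {b + 1}; "
                    "skipped in the cumulative product",
                    stacklevel=2,
                )
                continue
            log_T += mlen * np.log(S[j])
            var_S = S[j] * (1 - S[j]) / m.exposures[j]
            var_log_T += (mlen / S[j]) ** 2 * var_S
        T = float(np.exp(log_T))
        se = float(T * np.sqrt(var_log_T))
        if se == 0 or T in (0.0, 1.0):
            lo = hi = T
        else:
            se_logit = se / (T * (1 - T))
            lo = float(expit(logit(T) - _Z95 * se_logit))
            hi = float(expit(logit(T) + _Z95 * se_logit))
        return CumulativeSurvival(estimate=T, se=se, ci_low=lo, ci_high=hi)

    def survival_curve(self, cohort: str | None = None) -> pd.DataFrame:
        """Cumulative survival after each occasion (for plotting)."""
        m = self.model
        rows = []
        for occ in range(1, m.occasion_map.n_occasions + 1):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cs = self.cumulative_survival(cohort, through_occasion=occ)
            rows.append(
                {
                    "occasion": occ,
                    "day_end": m.occasion_map.blocks[occ - 1][1],
                    "estimate": cs.estimate,
                    "se": cs.se,
                    "ci_low": cs.ci_low,
                    "ci_high": cs.ci_high,
                }
            )
        return pd.DataFrame(rows)

    def plot_survival(self, ax=None, cohorts: Sequence[str] | None = None):
        """Step plot of cumulative survival per group with 95% bands."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.model
        if cohorts is None:
            cohorts = [g[0] for g in m.groups.groups]
        for cohort in cohorts:
            curve = self.survival_curve(cohort)
            label = "=".join(m.groups.groups[self._group_index(cohort)])
            ax.step(curve["day_end"], curve["estimate"], where="post", label=label)
            ax.fill_between(
                curve["day_end"], curve["ci_low"], curve["ci_high"],
                step="post", alpha=0.2,
            )
        ax.set_xlabel("age (days)")
        ax.set_ylabel("cumulative survival")
        ax.set_ylim(0, 1.02)
        ax.legend()
        return ax

    # -- reporting -----------------------------------------------------------

    @property
    def model_label(self) -> str:
        return f"{self.model.groups.display} {self.model.time_structure}"

    def summary(self) -> str:
        m = self.model
        lines = [
            "Known-fate survival model",
            "=" * 60,
            f"model:          {m.groups.display}",
            f"time structure: {m.time_structure}",
            f"occasions:      {m.occasion_map.n_occasions} "
            f"({m.occasion_map.resolution}, horizon {m.occasion_map.horizon} d)",
            f"histories:      {len(m.histories)}",
            f"K: {self.K}   n_eff: {self.n_eff:.0f}   -2lnL: {self.neg2loglik:.2f}",
            f"AICc: {self.aicc:.2f}   deviance: {self.deviance:.2f}",
            "-" * 60,
        ]
        table = self.cell_table()
        lines.append(table.to_string(index=False, float_format=lambda x: f"{x:.4f}"))
        lines.append("-" * 60)
        for g, members in enumerate(m.groups.groups, start=1):
            cs = self.cumulative_survival(members[0])
            lines.append(
                f"cumulative survival {{{ ' = '.join(members) }}}: "
                f"{cs.estimate:.3f} (SE {cs.se:.3f}, "
                f"95% CI {cs.ci_low:.3f}-{cs.ci_high:.3f})"
            )
        return "\n".join(lines)


def beta_ci_overlaps_zero(results: KnownFateResults, alpha: float = 0.05) -> np.ndarray:
    """Functional alias for :meth:`KnownFateResults.beta_ci_overlaps_zero`."""
    return results.beta_ci_overlaps_zero(alpha)
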