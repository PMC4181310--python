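"""Model ranking by AICc and CONTRAST-style survival comparisons.

Ranking uses Akaike weights, ``w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2)``
with ``delta_i = AICc_i - min AICc``; models within 2 AICc of the best are
flagged as viable alternatives.

Survival contrasts follow the Program CONTRAST chi-square procedure for
independent estimates: for two groups,

    chi2 = (S1 - S2)^2 / (SE1^2 + SE2^2),  df = 1,

and for k groups the quadratic form of the pairwise-difference contrast
matrix against the diagonal variance matrix, df = k - 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .known_fate import KnownFateResults

__all__ = ["ContrastResult", "akaike_weights", "rank_models", "contrast_chi2", "contrast_table"]


@dataclass(frozen=True)
class ContrastResult:
    chi2: float
    df: int
    p_value: float


def akaike_weights(aicc_values: Sequence[float]) -> np.ndarray:
    """Akaike weights from AICc values (or, equivalently, from deltas)."""
    a = np.asarray(aicc_values, dtype=float)
    if a.size == 0:
        raise ValueError("no AICc values")
    rel = np.exp(-(a - a.min()) / 2.0)
    return rel / rel.sum()


def rank_models(fits: Sequence[KnownFateResults]) -> pd.DataFrame:
    """Rank fitted models (all on the same data) ascending by AICc.

    Returns a table with model spec, time structure, AICc, delta AICc,
    Akaike weight, viable flag (delta < 2), K and deviance; sort is stable
    under ties.
    """
    if not fits:
        raise ValueError("no fitted models to rank")
    rows = pd.DataFrame(
        {
            "model": [f.model.groups.display for f in fits],
            "time_structure": [f.model.time_structure for f in fits],
            "aicc": [f.aicc for f in fits],
            "K": [f.K for f in fits],
            "deviance": [f.deviance for f in fits],
        }
    )
    rows["delta_aicc"] = rows["aicc"] - rows["aicc"].min()
    rows["weight"] = akaike_weights(rows["aicc"].to_numpy())
    rows["viable"] = rows["delta_aicc"] < 2.0
    rows = rows.sort_values("aicc", kind="stable").reset_index(drop=True)
    return rows[["model", "time_structure", "aicc", "delta_aicc", "weight", "viable", "K", "deviance"]]


def contrast_chi2(estimates: Sequence[float], ses: Sequence[float]) -> ContrastResult:
    """Chi-square test for differences among k independent survival
    estimates with standard errors."""
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    if est.size < 2:
        raise ValueError("need at least two estimates to contrast")
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")
    k = est.size
    if k == 2:
        chi2 = float((est[0] - est[1]) ** 2 / (se[0] ** 2 + se[1] ** 2))
        df = 1
    else:
        C = np.zeros((k - 1, k))
        for i in range(k - 1):
            C[i, i], C[i, i + 1] = 1.0, -1.0
        d = C @ est
        V = C @ np.diag(se**2) @ C.T
        chi2 = float(d @ np.linalg.solve(V, d))
        df = k - 1
    return ContrastResult(chi2=chi2, df=df, p_value=float(stats.chi2.sf(chi2, df)))


def contrast_table(
    labels: Sequence[str], estimates: Sequence[float], ses: Sequence[float]
) -> pd.DataFrame:
    """All pairwise two-group contrasts, one row per pair."""
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            r = contrast_chi2([estimates[i], estimates[j]], [ses[i], ses[j]])
            rows.append(
                {
                    "group_1": labels[i],
                    "group_2": labels[j],
                    "estimate_1": estimates[i],
                    "estimate_2": estimates[j],
                    "se_1": ses[i],
                    "se_2": ses[j],
                    "chi2": r.chi2,
                    "df": r.df,
                    "p_value": r.p_value,
                }
            )
    return pd.DataFrame(rows)
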