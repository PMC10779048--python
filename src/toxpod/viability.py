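"""Trypan-blue viability metrics and many-to-one significance testing.

In the trypan blue exclusion assay, live cells exclude the dye ("white")
while dead cells stain ("blue").  Two endpoints are derived per sample:
percent viability (white / total) and percent viable cell density (viable
cells per cm² relative to the time-matched medium control).  Percent
viability enters statistics after an arcsine transform of the proportion;
densities after a square-root transform.  Exposed groups are compared to the
time-matched control with Dunnett's many-to-one procedure within each
timepoint.
"""

from __future__ import annotations

import math
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "percent_viability",
    "arcsine_transform",
    "percent_viable_cell_density",
    "dunnett_many_to_one",
]


def percent_viability(white: float, blue: float) -> float:
    """Percent of dye-excluding (live) cells: 100·white/(white+blue)."""
    if white < 0 or blue < 0:
        raise ValueError("counts must be >= 0")
    total = white + blue
    if total == 0:
        raise ValueError("percent viability undefined for zero total count")
    return 100.0 * white / total


def arcsine_transform(pv: float, sqrt: bool = False) -> float:
    """Arcsine-normalize a percent viability: arcsin(pv/100), in radians.

    With ``sqrt=True`` the classical variance-stabilizing
    arcsin(sqrt(pv/100)) is used instead.
    """
    if not 0.0 <= pv <= 100.0:
        raise ValueError("percent viability must lie in [0, 100]")
    p = pv / 100.0
    return math.asin(math.sqrt(p) if sqrt else p)


def percent_viable_cell_density(
    sample_density: float, control_density: float
) -> float:
    """Viable-cell density of a sample as a percent of the control density."""
    if control_density <= 0:
        raise ValueError("control density must be positive")
    if sample_density < 0:
        raise ValueError("sample density must be >= 0")
    return 100.0 * sample_density / control_density


def dunnett_many_to_one(
    data: pd.DataFrame,
    control_label: str,
    value_col: str = "value",
    condition_col: str = "condition",
    timepoint_col: str = "timepoint",
    alternative: Literal["two-sided", "less", "greater"] = "two-sided",
    seed: int = 0,
) -> pd.DataFrame:
    """Dunnett's test of every exposure against its time-matched control.

    Within each timepoint, all groups labelled other than ``control_label``
    are compared against the control with familywise adjustment based on the
    equicorrelated multivariate-t distribution of the Dunnett statistics.
    Returns a frame with columns ``timepoint, condition, statistic, p_raw,
    p_adj, n``; ``p_raw`` is the unadjusted per-comparison t-test p computed
    from the same pooled-variance statistic.

    Parameters
    ----------
    data:
        Long-format table of (already transformed) per-replicate values.
    control_label:
        Value of ``condition_col`` identifying the medium control.
    seed:
        Seed for the multivariate-t integration, making adjusted p-values
        reproducible.
    """
    rows = []
    for tp, sub in data.groupby(timepoint_col, sort=True):
        groups = {
            cond: np.asarray(g[value_col], dtype=float)
            for cond, g in sub.groupby(condition_col, sort=True)
        }
        if control_label not in groups:
            raise ValueError(
                f"control group {control_label!r} missing at timepoint {tp!r}"
            )
        control = groups.pop(control_label)
        if not groups:
            continue
        if len(control) < 2 or any(len(v) < 2 for v in groups.values()):
            raise ValueError("each group needs >= 2 replicates")
        labels = sorted(groups)
        samples = [groups[lab] for lab in labels]
        res = stats.dunnett(
            *samples,
            control=control,
            alternative=alternative,
            rng=np.random.default_rng(seed),
        )
        # residual df of the pooled one-way layout used by the statistic
        n_total = len(control) + sum(len(s) for s in samples)
        df_resid = n_total - (len(samples) + 1)
        for lab, t_stat, p_adj, s in zip(
            labels, np.atleast_1d(res.statistic), np.atleast_1d(res.pvalue), samples
        ):
            if alternative == "two-sided":
                p_raw = 2.0 * stats.t.sf(abs(t_stat), df_resid)
            elif alternative == "less":
                p_raw = stats.t.cdf(t_stat, df_resid)
            else:
                p_raw = stats.t.sf(t_stat, df_resid)
            rows.append(
                {
                    "timepoint": tp,
                    "condition": lab,
                    "statistic": float(t_stat),
                    "p_raw": float(p_raw),
                    "p_adj": float(min(1.0, p_adj)),
                    "n": len(s),
                }
            )
    return pd.DataFrame(rows)
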