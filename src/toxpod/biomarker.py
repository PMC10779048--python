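"""Weighted biomarker-gene ranking within a focal pathway.

Genes of a commonly enriched ("hub") stress pathway are ranked by

    score = (mean |fold change| over samples where the gene is a DEG)
          + 100 · (number of those samples with |fold change| > 5),

so a moderate fold change recurring across many samples outranks an extreme
fold change seen once.  Scores are computed only over samples in which the
pathway itself is significantly enriched.  The top-k genes form the
candidate biomarker panel.  Pathway coverage (DEGs in the set / set size)
per sample is correlated against percent viable cell density with
Spearman's rank correlation to link transcriptional burden to apical
toxicity.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from toxpod.enrichment import GeneSet

__all__ = [
    "GeneScore",
    "weighted_gene_scores",
    "top_k_panel",
    "coverage_viability_correlation",
]

HIGH_FC_THRESHOLD = 5.0
HIGH_FC_WEIGHT = 100.0


class GeneScore(NamedTuple):
    gene: str
    avg_fc: float
    n_high: int
    score: float


def weighted_gene_scores(
    deg_tables: dict[str, pd.DataFrame],
    pathway: GeneSet,
    enriched_samples: set[str] | list[str],
    use_absolute: bool = True,
) -> pd.DataFrame:
    """Score pathway-member genes across enriched samples.

    Parameters
    ----------
    deg_tables:
        Per-sample DEG tables (columns ``gene, fc, is_deg``).
    enriched_samples:
        Samples in which the pathway is significantly enriched; only these
        contribute.  Genes that are a DEG in none of them are omitted.
    use_absolute:
        Average |fc| (default).  With False the signed fold changes are
        averaged, letting opposite-direction responses cancel.

    Returns a DataFrame ``gene, avg_fc, n_high, score`` sorted by descending
    score with alphabetical tie-break.
    """
    enriched = [s for s in enriched_samples if s in deg_tables]
    rows = []
    members = pathway.members
    per_gene: dict[str, list[float]] = {}
    for sample in enriched:
        table = deg_tables[sample]
        hits = table[table["is_deg"] & table["gene"].isin(members)]
        for gene, fc in zip(hits["gene"], hits["fc"]):
            per_gene.setdefault(gene, []).append(float(fc))
    for gene, fcs in per_gene.items():
        vals = [abs(f) for f in fcs] if use_absolute else fcs
        avg = float(np.mean(vals))
        n_high = int(sum(abs(f) > HIGH_FC_THRESHOLD for f in fcs))
        rows.append(
            GeneScore(gene, avg, n_high, avg + HIGH_FC_WEIGHT * n_high)._asdict()
        )
    df = pd.DataFrame(rows, columns=["gene", "avg_fc", "n_high", "score"])
    return df.sort_values(
        ["score", "gene"], ascending=[False, True]
    ).reset_index(drop=True)


def top_k_panel(scores: pd.DataFrame, k: int = 10) -> list[str]:
    """The min(k, n) highest-scoring genes, ties broken alphabetically."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = scores.sort_values(["score", "gene"], ascending=[False, True])
    return list(ordered["gene"].head(k))


def coverage_viability_correlation(
    coverage: list[float] | np.ndarray,
    pvcd: list[float] | np.ndarray,
    seed: int = 0,
) -> tuple[float, float]:
    """Spearman correlation of pathway coverage with viable-cell density.

    Uses midranks for ties.  The p-value comes from exact enumeration of
    pairings for n <= 9 and from the t approximation otherwise.  Returns
    (rho, p).
    """
    x = np.asarray(coverage, dtype=float)
    y = np.asarray(pvcd, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("coverage and pvcd must be equal-length vectors")
    n = len(x)
    if n < 4:
        raise ValueError("need >= 4 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant vector")
    rho, p_t = stats.spearmanr(x, y)
    if n <= 9:
        return float(rho), _exact_pairing_p(x, y, float(rho))
    return float(rho), float(p_t)


def _exact_pairing_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact Spearman p by enumerating all pairings of y with x."""
    import itertools

    rx = stats.rankdata(x) - (len(x) + 1) / 2
    ry = stats.rankdata(y) - (len(y) + 1) / 2
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    perms = np.array(list(itertools.permutations(range(len(y)))))
    rhos = (ry[perms] @ rx) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))
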