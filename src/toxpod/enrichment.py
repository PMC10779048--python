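"""Directional over-representation analysis of DEG lists against gene sets.

Enrichment p-values are one-sided hypergeometric upper-tail probabilities of
the observed DEG/pathway overlap against the measured-gene universe.  A
pathway is significantly enriched when −log10 p > 1.3 (p < 0.05) and at
least 3 of its members are DEGs.  Directionality is summarized by the
activation z-score over direction-annotated DEG members,

    z = (N_concordant − N_discordant) / sqrt(N_concordant + N_discordant),

with z ≥ 2 called "activated" and z ≤ −2 "inactivated".  Oversized DEG lists
(> 8000) are split into a low (1.5 ≤ |fc| < 2) and a high (|fc| ≥ 2)
fold-change list that are enriched separately; a pathway enriched by either
list counts once for that sample when ranking commonly enriched pathways.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "EnrichmentResult",
    "hypergeom_upper_tail",
    "enrich",
    "activation_z",
    "split_deg_list",
    "rank_common_pathways",
    "enrich_all",
]

SIGNIFICANCE_NEG_LOG10_P = 1.3
MIN_DEGS = 3
ACTIVATION_Z = 2.0
SPLIT_CAP = 8000


@dataclass(frozen=True)
class GeneSet:
    """A named gene set with optional per-member expected direction (±1)."""

    name: str
    members: frozenset[str]
    directions: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if len(self.members) < 3:
            raise ValueError(f"gene set {self.name!r} needs >= 3 members")
        extra = set(self.directions) - self.members
        if extra:
            raise ValueError(f"direction annotations outside set: {sorted(extra)}")
        bad = {s for s in self.directions.values()} - {-1, 1}
        if bad:
            raise ValueError("direction signs must be +1 or -1")


@dataclass
class GeneSetCollection:
    """Ordered collection of gene sets, keyed by name."""

    sets: dict[str, GeneSet]

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __len__(self) -> int:
        return len(self.sets)

    @property
    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class EnrichmentResult:
    """Per (sample, pathway) enrichment outcome."""

    sample: str
    pathway: str
    n_deg: int
    p: float
    z: float | None
    coverage: float
    significant: bool
    state: str  # activated | inactivated | indeterminate
    sublist: str = "all"  # all | low | high (fold-change split lists)

    @property
    def row_label(self) -> str:
        """Label distinguishing split sublists, e.g. for z-score matrices."""
        return self.sample if self.sublist == "all" else f"{self.sample}|{self.sublist}"

    @staticmethod
    def classify(z: float | None) -> str:
        if z is None:
            return "indeterminate"
        if z >= ACTIVATION_Z:
            return "activated"
        if z <= -ACTIVATION_Z:
            return "inactivated"
        return "indeterminate"


def hypergeom_upper_tail(k: int, m: int, n_set: int, n_draw: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(M=m, K=n_set, N=n_draw)."""
    p = float(stats.hypergeom.sf(k - 1, m, n_set, n_draw))
    return min(1.0, max(0.0, p))


def _deg_genes(degs: pd.DataFrame) -> pd.DataFrame:
    if "is_deg" in degs.columns:
        return degs[degs["is_deg"]]
    return degs


def enrich(
    degs: pd.DataFrame,
    gene_set: GeneSet,
    background: set[str] | list[str],
    sample: str = "",
) -> EnrichmentResult:
    """Hypergeometric over-representation of a DEG list in one gene set.

    ``degs`` is a DEG table (rows with ``is_deg`` True are the DEG list);
    ``background`` the measured-gene universe.  p is the exact upper-tail
    probability of observing at least the seen overlap.
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background universe")
    members = gene_set.members & bg
    if gene_set.members - bg:
        raise ValueError(
            f"gene set {gene_set.name!r} has members outside the background"
        )
    deg_table = _deg_genes(degs)
    deg_genes = set(deg_table["gene"]) & bg
    if deg_genes != set(deg_table["gene"]):
        raise ValueError("DEG genes must be a subset of the background")
    overlap = deg_genes & members
    k = len(overlap)
    p = hypergeom_upper_tail(k, len(bg), len(members), len(deg_genes))
    coverage = k / len(gene_set.members)
    significant = (-np.log10(p) > SIGNIFICANCE_NEG_LOG10_P) and (k >= MIN_DEGS)
    z = activation_z(degs, gene_set)
    return EnrichmentResult(
        sample=sample,
        pathway=gene_set.name,
        n_deg=k,
        p=p,
        z=z,
        coverage=coverage,
        significant=bool(significant),
        state=EnrichmentResult.classify(z),
    )


def activation_z(degs: pd.DataFrame, gene_set: GeneSet) -> float | None:
    """Directional concordance z over annotated DEG members, or None.

    Concordant = the DEG's fold-change sign matches the set's expected sign
    for that gene.  Returns None when no direction-annotated member is a DEG
    (the pathway then carries no z-score).
    """
    if not gene_set.directions:
        return None
    deg_table = _deg_genes(degs)
    fc = dict(zip(deg_table["gene"], deg_table["fc"]))
    n_conc = n_disc = 0
    for gene, expected in gene_set.directions.items():
        if gene not in fc:
            continue
        if np.sign(fc[gene]) == expected:
            n_conc += 1
        else:
            n_disc += 1
    total = n_conc + n_disc
    if total == 0:
        return None
    return (n_conc - n_disc) / np.sqrt(total)


def split_deg_list(degs: pd.DataFrame, cap: int = SPLIT_CAP) -> dict[str, pd.DataFrame]:
    """Split an oversized DEG list into low/high fold-change sublists.

    If the DEG list has at most ``cap`` entries it is returned unchanged
    under the key ``"all"``; otherwise two disjoint tables partitioning the
    input are returned: ``"low"`` with 1.5 <= |fc| < 2 and ``"high"`` with
    |fc| >= 2.
    """
    deg_table = _deg_genes(degs)
    if len(deg_table) <= cap:
        return {"all": degs}
    abs_fc = deg_table["fc"].abs()
    return {
        "low": deg_table[abs_fc < 2.0].copy(),
        "high": deg_table[abs_fc >= 2.0].copy(),
    }


def rank_common_pathways(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Rank pathways by the number of unique samples showing enrichment.

    Split sublists of one sample must share its sample label, so a pathway
    enriched by both the low and high list of a sample counts once.  Output
    is sorted by descending sample count with alphabetical tie-break.
    """
    seen: dict[str, set[str]] = {}
    for r in results:
        if r.significant:
            seen.setdefault(r.pathway, set()).add(r.sample)
    rows = [
        {"pathway": name, "n_samples_enriched": len(samples)}
        for name, samples in seen.items()
    ]
    df = pd.DataFrame(rows, columns=["pathway", "n_samples_enriched"])
    return df.sort_values(
        ["n_samples_enriched", "pathway"], ascending=[False, True]
    ).reset_index(drop=True)


def enrich_all(
    deg_tables: dict[str, pd.DataFrame],
    collection: GeneSetCollection,
    background: set[str] | list[str],
    cap: int = SPLIT_CAP,
) -> list[EnrichmentResult]:
    """Enrich every sample's DEG table against every set in a collection.

    Oversized DEG lists are split per :func:`split_deg_list`; sublist
    results keep the parent sample label so downstream ranking counts
    samples uniquely.
    """
    results: list[EnrichmentResult] = []
    for sample, table in deg_tables.items():
        for label, sub in split_deg_list(table, cap=cap).items():
            for gene_set in collection:
                res = enrich(sub, gene_set, background, sample=sample)
                res.sublist = label
                results.append(res)
    return results
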