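"""End-to-end orchestration of the dose-response analysis pipeline.

Stages: (synthetic data generation) → differential expression → pathway
enrichment and common-pathway ranking → z-score clustering → biomarker
panel and coverage-viability correlation → benchmark concentration
modeling (transcriptomic tPODs and viability BMCs) → potency ranking.
All stage thresholds default to the study's standard settings (DEG |fc| ≥
1.5 and adjusted p < 0.05, enrichment −log10 p > 1.3 with ≥ 3 DEGs,
activation |z| ≥ 2, split cap 8000, Williams 100 permutations, BMR 1 SD,
BMCU/BMCL gate 40, lack-of-fit gate 0.1, tPOD rank 25, hybrid extra-risk
level 0.5).  A single global seed deterministically derives every stage
seed via ``numpy.random.SeedSequence(seed).generate_state``, so reruns with
identical configuration are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from toxpod import io
from toxpod.biomarker import coverage_viability_correlation, top_k_panel, \
    weighted_gene_scores
from toxpod.bmc import (
    BMCResult, DoseResponseSeries, collapse_and_tpod, filter_gene_bmcs,
    model_and_bmc, potency_rank, prefilter_probes, viability_bmc,
)
from toxpod.clustering import build_zscore_matrix, cluster_samples
from toxpod.degs import ExpressionMatrix, call_degs, differential_stats
from toxpod.dose_metrics import metal_mass_conc, ssa_conc
from toxpod.enrichment import enrich_all, rank_common_pathways
from toxpod.synthetic import (
    ExposureDesign, GroundTruth, default_design, default_truth,
    simulate_expression, simulate_viability,
)
from toxpod.viability import dunnett_many_to_one, percent_viability, \
    arcsine_transform

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]

_STAGES = ("truth", "expression", "viability", "deg", "enrich", "cluster",
           "panel", "bmc")


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    In ``synthetic`` mode the generator parameters apply; in ``user-data``
    mode the four input paths are required.  Threshold defaults are the
    study-standard values listed in the module docstring.
    """

    mode: str = "synthetic"
    seed: int = 0
    outdir: str = "toxpod_out"

    # user-data inputs
    matrix_path: str | None = None
    design_path: str | None = None
    gmt_path: str | None = None
    directions_path: str | None = None
    trypan_path: str | None = None

    # synthetic generator
    n_genes: int = 500
    n_sets: int = 10
    hub_size: int = 198
    noise_sd: float = 0.25
    replicates: int = 4
    concentrations: tuple[float, ...] = (5.0, 10.0, 25.0, 50.0)
    timepoints: tuple[int, ...] = (2, 24, 48)

    # thresholds (study-standard defaults)
    fc_cut: float = 1.5
    p_cut: float = 0.05
    neg_log10_p: float = 1.3
    min_degs: int = 3
    z_cut: float = 2.0
    split_cap: int = 8000
    deg_n_perm: int = 1000
    williams_n_perm: int = 100
    bmr_k: float = 1.0
    ratio_gate: float = 40.0
    fit_p_gate: float = 0.1
    tpod_rank: int = 25
    hybrid_level: float = 0.5
    hybrid_tail_p0: float = 0.01
    cluster_k: int = 4
    panel_k: int = 10
    n_boot: int = 60
    dose_metric: str = "metal"  # compound | metal | ssa
    bmc_timepoints: tuple[int, ...] | None = None

    def validate(self) -> None:
        if self.mode not in {"synthetic", "user-data"}:
            raise ValueError("mode must be 'synthetic' or 'user-data'")
        if self.mode == "user-data":
            for name in ("matrix_path", "design_path", "gmt_path",
                         "trypan_path"):
                if getattr(self, name) is None:
                    raise ValueError(f"user-data mode requires {name}")
        if self.dose_metric not in {"compound", "metal", "ssa"}:
            raise ValueError("dose_metric must be compound, metal or ssa")


@dataclass
class RunReport:
    """Per-stage record counts, seeds and the output-file manifest."""

    counts: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    manifest: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    tpods: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True, default=str)


def derive_stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds from one global seed.

    Stage i receives SeedSequence(seed).generate_state(n)[i] mod 2**31, in
    the fixed stage order, so any stage can be rerun reproducibly.
    """
    state = np.random.SeedSequence(seed).generate_state(len(_STAGES))
    return {name: int(s % (2**31)) for name, s in zip(_STAGES, state)}


def _dose_in_metric(conc: float, compound, metric: str) -> float:
    if metric == "compound" or compound is None:
        return conc
    if metric == "metal":
        return metal_mass_conc(conc, compound.oxide_formula)
    if metric == "ssa":
        if compound.ssa is None:
            raise ValueError(f"no SSA available for {compound.label}")
        return ssa_conc(conc, compound.ssa)
    raise ValueError(metric)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage and write all artifacts under ``config.outdir``.

    Returns the run report (also written as ``run_report.json``).  Rerunning
    with an identical configuration and seed reproduces byte-identical
    output files.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = derive_stage_seeds(config.seed)
    report = RunReport(seeds=seeds)

    def emit(path: Path) -> None:
        report.manifest.append(str(path.relative_to(outdir)))

    # ---- inputs -----------------------------------------------------------
    if config.mode == "synthetic":
        design = default_design(
            concentrations=tuple(config.concentrations),
            timepoints=tuple(config.timepoints),
            replicates=config.replicates,
        )
        truth = default_truth(
            design, n_genes=config.n_genes, n_sets=config.n_sets,
            hub_size=config.hub_size, noise_sd=config.noise_sd,
            seed=seeds["truth"],
        )
        matrix = simulate_expression(design, truth, seed=seeds["expression"])
        trypan = simulate_viability(design, truth, seed=seeds["viability"])
        gene_sets = truth.gene_sets
        io.write_expression(matrix, outdir / "expression.tsv",
                            outdir / "design.tsv")
        io.write_gene_sets(gene_sets, outdir / "gene_sets.gmt",
                           outdir / "gene_set_directions.tsv")
        io.write_trypan(trypan, outdir / "trypan.tsv")
        for name in ("expression.tsv", "design.tsv", "gene_sets.gmt",
                     "gene_set_directions.tsv", "trypan.tsv"):
            emit(outdir / name)
        compounds = {c.label: c for c in design.compounds}
        timepoints = list(design.timepoints)
    else:
        for name in ("matrix_path", "design_path", "gmt_path", "trypan_path"):
            p = getattr(config, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} does not exist: {p}")
        matrix = io.read_expression(config.matrix_path, config.design_path)
        gene_sets = io.read_gene_sets(config.gmt_path, config.directions_path)
        trypan = io.read_trypan(config.trypan_path)
        design = None
        compounds = {}
        timepoints = sorted(matrix.design["timepoint"].unique())

    # ---- viability metrics ------------------------------------------------
    trypan = trypan.copy()
    trypan["percent_viability"] = [
        percent_viability(w, b)
        for w, b in zip(trypan["white_count"], trypan["blue_count"])
    ]
    trypan["arcsine_viability"] = [
        arcsine_transform(v) for v in trypan["percent_viability"]
    ]
    ctrl_density = (
        trypan[trypan["concentration"] == 0]
        .groupby("timepoint")["density_viable"].mean()
    )
    trypan["pvcd"] = [
        100.0 * row.density_viable / ctrl_density[row.timepoint]
        for row in trypan.itertuples()
    ]
    viab_stats = dunnett_many_to_one(
        trypan.assign(
            condition=[
                f"{c}@{k:g}" for c, k in zip(trypan["compound"],
                                             trypan["concentration"])
            ],
            value=np.sqrt(trypan["density_viable"]),
        ),
        control_label="control@0",
        seed=seeds["viability"],
    )
    io.write_trypan(trypan, outdir / "viability_metrics.tsv")
    viab_stats.to_csv(outdir / "viability_dunnett.tsv", sep="\t", index=False)
    emit(outdir / "viability_metrics.tsv")
    emit(outdir / "viability_dunnett.tsv")
    report.counts["viability_samples"] = len(trypan)

    # ---- differential expression -----------------------------------------
    deg_dir = outdir / "deg"
    deg_dir.mkdir(exist_ok=True)
    deg_tables: dict[str, pd.DataFrame] = {}
    conditions = [
        c for c in matrix.design["condition"].unique()
        if not c.startswith("control@")
    ]
    for cond in sorted(conditions):
        tp = cond.rsplit("@", 1)[-1]
        control = f"control@{tp}"
        stats_df = differential_stats(
            matrix, cond, control, n_perm=config.deg_n_perm,
            seed=seeds["deg"],
        )
        table = call_degs(stats_df, fc_cut=config.fc_cut, p_cut=config.p_cut)
        deg_tables[cond] = table
        path = deg_dir / f"{cond.replace('/', '_')}.tsv"
        table.to_csv(path, sep="\t", index=False)
        emit(path)
    report.counts["deg_conditions"] = len(deg_tables)
    report.counts["total_degs"] = int(
        sum(t["is_deg"].sum() for t in deg_tables.values())
    )

    # ---- enrichment -------------------------------------------------------
    background = set(matrix.genes)
    results = enrich_all(deg_tables, gene_sets, background,
                         cap=config.split_cap)
    enr_df = pd.DataFrame(
        [
            {"sample": r.sample, "sublist": r.sublist, "pathway": r.pathway,
             "n_deg": r.n_deg, "p": r.p,
             "z": np.nan if r.z is None else r.z,
             "coverage": r.coverage, "significant": r.significant,
             "state": r.state}
            for r in results
        ]
    )
    enr_df.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    emit(outdir / "enrichment.tsv")
    common = rank_common_pathways(results)
    common.to_csv(outdir / "common_pathways.tsv", sep="\t", index=False)
    emit(outdir / "common_pathways.tsv")
    report.counts["enrichment_results"] = len(results)
    report.counts["significant_enrichments"] = int(enr_df["significant"].sum())

    # ---- clustering -------------------------------------------------------
    zmat = build_zscore_matrix(results)
    zmat.values.to_csv(outdir / "zscore_matrix.tsv", sep="\t")
    emit(outdir / "zscore_matrix.tsv")
    try:
        tree, labels, excluded = cluster_samples(zmat, k=config.cluster_k)
        (outdir / "dendrogram.nwk").write_text(tree.to_newick() + "\n",
                                               encoding="utf-8")
        labels.to_csv(outdir / "cluster_labels.tsv", sep="\t",
                      header=["cluster"])
        emit(outdir / "dendrogram.nwk")
        emit(outdir / "cluster_labels.tsv")
        if excluded:
            report.warnings.append(
                f"samples with all-zero z profiles excluded from clustering: "
                f"{excluded}"
            )
    except ValueError as exc:
        report.warnings.append(f"clustering skipped: {exc}")

    # ---- biomarker panel --------------------------------------------------
    if len(common) and common["n_samples_enriched"].iloc[0] > 0:
        focal_name = common["pathway"].iloc[0]
        focal = gene_sets[focal_name]
        enriched_samples = {
            r.sample for r in results if r.significant and r.pathway == focal_name
        }
        scores = weighted_gene_scores(deg_tables, focal, enriched_samples)
        panel = top_k_panel(scores, k=config.panel_k)
        scores.insert(0, "rank", np.arange(1, len(scores) + 1))
        scores.to_csv(outdir / "biomarker_scores.tsv", sep="\t", index=False)
        emit(outdir / "biomarker_scores.tsv")
        report.counts["panel"] = panel

        # coverage vs viable-cell density over enriched samples
        cov, pv = [], []
        pvcd_by_cond = (
            trypan.assign(
                condition=[
                    f"{c}@{k:g}@{int(t)}h"
                    for c, k, t in zip(trypan["compound"],
                                       trypan["concentration"],
                                       trypan["timepoint"])
                ]
            ).groupby("condition")["pvcd"].mean()
        )
        for r in results:
            if r.pathway == focal_name and r.significant \
                    and r.sublist in ("all", "low") \
                    and r.sample in pvcd_by_cond.index:
                cov.append(r.coverage)
                pv.append(float(pvcd_by_cond[r.sample]))
        if len(cov) >= 4 and len(set(cov)) > 1 and len(set(pv)) > 1:
            rho, p = coverage_viability_correlation(cov, pv,
                                                   seed=seeds["panel"])
            corr = {"pathway": focal_name, "n_samples": len(cov),
                    "spearman_rho": rho, "p": p}
        else:
            corr = {"pathway": focal_name, "n_samples": len(cov),
                    "spearman_rho": None, "p": None}
            report.warnings.append("too few paired samples for the "
                                   "coverage-viability correlation")
        (outdir / "coverage_viability.json").write_text(
            json.dumps(corr, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        emit(outdir / "coverage_viability.json")

    # ---- benchmark concentration modeling ---------------------------------
    bmc_tps = list(config.bmc_timepoints or timepoints)
    bmc_dir = outdir / "bmc"
    bmc_dir.mkdir(exist_ok=True)
    tpod_results: dict[str, BMCResult] = {}
    viability_results: list[BMCResult] = []
    labels_by_compound = (
        compounds
        if compounds
        else {
            c: None
            for c in matrix.design["compound"].unique()
            if c != "control"
        }
    )
    for tp in bmc_tps:
        for label, comp in sorted(labels_by_compound.items()):
            sel = matrix.design[
                ((matrix.design["compound"] == label)
                 | (matrix.design["compound"] == "control"))
                & (matrix.design["timepoint"] == tp)
            ]
            if sel.empty:
                continue
            samples = list(sel.index)
            doses_c = sel["concentration"].to_numpy(dtype=float)
            doses = np.array(
                [_dose_in_metric(d, comp, config.dose_metric) if d > 0 else 0.0
                 for d in doses_c]
            )
            values = matrix.values[samples]
            pre = prefilter_probes(
                values, doses, fc_min=config.fc_cut, p_max=0.05,
                n_perm=config.williams_n_perm, seed=seeds["bmc"],
            )
            kept = pre[pre["keep"]]["probe"].tolist()
            rows = []
            for i, probe in enumerate(kept):
                series = DoseResponseSeries(
                    doses, values.loc[probe].to_numpy(dtype=float),
                    endpoint=str(probe), units=config.dose_metric,
                )
                res = model_and_bmc(series, bmr_k=config.bmr_k,
                                    n_boot=config.n_boot,
                                    seed=seeds["bmc"] + i)
                if res is None:
                    continue
                rows.append(
                    {"probe": probe, "gene": probe, "bmc": res.bmc,
                     "bmcl": res.bmcl, "bmcu": res.bmcu,
                     "model": res.model.model, "fit_p": res.model.fit_p}
                )
            per_probe = pd.DataFrame(
                rows, columns=["probe", "gene", "bmc", "bmcl", "bmcu",
                               "model", "fit_p"]
            )
            stem = f"{label}_{tp}h"
            per_probe.to_csv(bmc_dir / f"{stem}_probes.tsv", sep="\t",
                             index=False)
            emit(bmc_dir / f"{stem}_probes.tsv")
            max_dose = float(doses.max())
            filtered = filter_gene_bmcs(per_probe, max_dose=max_dose)
            tpod = collapse_and_tpod(filtered, condition=stem,
                                     rank=config.tpod_rank)
            tpod.gene_bmcs.to_csv(bmc_dir / f"{stem}_genes.tsv", sep="\t",
                                  index=False)
            emit(bmc_dir / f"{stem}_genes.tsv")
            if tpod.tpod is not None:
                row = tpod.gene_bmcs.iloc[config.tpod_rank - 1]
                tpod_results[stem] = BMCResult(
                    bmc=tpod.tpod, bmcl=float(row["bmcl"]),
                    bmcu=float(row["bmcu"]),
                    bmr_spec={"type": "sd_multiple", "k": config.bmr_k},
                    units=config.dose_metric, label=stem,
                )
            report.tpods[stem] = {
                "tpod": tpod.tpod, "n_genes_passing": tpod.n_genes_passing,
                "reason": tpod.reason,
            }

            # viability BMC for the same compound/timepoint
            vsel = trypan[
                ((trypan["compound"] == label)
                 | (trypan["compound"] == "control"))
                & (trypan["timepoint"] == tp)
            ]
            vdoses = np.array(
                [_dose_in_metric(d, comp, config.dose_metric) if d > 0 else 0.0
                 for d in vsel["concentration"]]
            )
            try:
                vseries = DoseResponseSeries(
                    vdoses, vsel["density_viable"].to_numpy(dtype=float),
                    endpoint=stem, units=config.dose_metric,
                )
                vres = viability_bmc(
                    vseries, level=config.hybrid_level,
                    tail_p0=config.hybrid_tail_p0, seed=seeds["bmc"],
                    n_boot=config.n_boot, label=stem,
                )
                if vres is not None:
                    viability_results.append(vres)
            except ValueError as exc:
                report.warnings.append(f"viability BMC {stem}: {exc}")

    tpod_json = {
        k: {"tpod": v["tpod"], "n_genes_passing": v["n_genes_passing"]}
        for k, v in report.tpods.items()
    }
    (bmc_dir / "tpods.json").write_text(
        json.dumps(tpod_json, indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    emit(bmc_dir / "tpods.json")

    # ---- potency ranking --------------------------------------------------
    chains = {}
    if len(tpod_results) >= 2:
        chains["transcriptomic"] = potency_rank(
            list(tpod_results.values())
        ).chain
    if len(viability_results) >= 2:
        chains["viability"] = potency_rank(viability_results).chain
    (outdir / "potency.txt").write_text(
        "".join(f"{k}: {v}\n" for k, v in sorted(chains.items())),
        encoding="utf-8",
    )
    emit(outdir / "potency.txt")

    (outdir / "run_report.json").write_text(report.to_json() + "\n",
                                            encoding="utf-8")
    return report
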