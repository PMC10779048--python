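"""Synthetic experiment generator: determinism and programmed structure."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from toxpod.degs import call_degs, differential_stats
from toxpod.synthetic import (
    Compound, ExposureDesign, default_design, default_truth,
    generate_gene_sets, simulate_experiment, simulate_expression,
    simulate_viability,
)


@pytest.fixture(scope="module")
def design():
    return default_design(timepoints=(24,), replicates=4)


@pytest.fixture(scope="module")
def truth(design):
    return default_truth(design, n_genes=150, n_sets=5, hub_size=30, seed=3)


def test_gene_set_parameter_echo():
    coll = generate_gene_sets(100, 1, (10, 10), overlap_fraction=0.0,
                              direction_fraction=1.0, seed=7)
    (s,) = list(coll)
    assert len(s.members) == 10
    assert set(s.directions) == set(s.members)
    assert set(v for v in s.directions.values()) <= {-1, 1}


def test_gene_sets_disjoint_when_overlap_zero():
    coll = generate_gene_sets(200, 5, (10, 20), overlap_fraction=0.0, seed=1)
    sets = [s.members for s in coll]
    for a, b in itertools.combinations(sets, 2):
        assert not (a & b)


def test_gene_sets_overlap_fraction_creates_sharing():
    coll = generate_gene_sets(100, 4, (10, 20), overlap_fraction=0.5, seed=2)
    sets = [s.members for s in coll]
    assert any(a & b for a, b in itertools.combinations(sets, 2))


def test_gene_sets_determinism_and_validation():
    a = generate_gene_sets(100, 3, (5, 10), seed=9)
    b = generate_gene_sets(100, 3, (5, 10), seed=9)
    assert a.names == b.names
    for name in a.names:
        assert a[name].members == b[name].members
        assert a[name].directions == b[name].directions
    with pytest.raises(ValueError, match="size_range"):
        generate_gene_sets(10, 1, (5, 50))


def test_design_validation():
    with pytest.raises(ValueError, match="increasing"):
        Compound("X", "Zn", "NP", "ZnO", (5.0, 2.0, 10.0))
    with pytest.raises(ValueError, match=">= 3"):
        Compound("X", "Zn", "NP", "ZnO", (5.0, 10.0))
    with pytest.raises(ValueError, match="replicates"):
        ExposureDesign(default_design().compounds, replicates=1)


def test_expression_matches_programmed_hill_mean(design):
    """Empirical mean over many replicates sits within 3 SE of the
    programmed Hill response at the tested dose."""
    comp = design.compounds[0]  # theta 0.95
    truth = default_truth(design, n_genes=40, n_sets=2, hub_size=10, seed=5)
    # pin one hub gene's parameters for an analytic expectation
    g = truth.genes.index[truth.genes["in_hub"]][0]
    truth.genes.loc[g, ["emax_log2", "ac50", "hill_slope", "direction"]] = \
        [3.0, 10.0, 2.0, 1]
    big = ExposureDesign(design.compounds, timepoints=(24,), replicates=1000)
    matrix = simulate_expression(big, truth, seed=1)
    cond = big.condition_label(comp, 10.0, 24)
    vals = matrix.values.loc[g, matrix.samples_of(cond)]
    programmed = 1 * 3.0 * comp.theta * 10.0**2 / (10.0**2 + 10.0**2) * 1.0
    se = truth.noise_sd / np.sqrt(len(vals))
    assert abs(vals.mean() - programmed) < 3 * se


def test_controls_have_zero_programmed_effect(design, truth):
    matrix = simulate_expression(design, truth, seed=2)
    ctrl = matrix.values[matrix.samples_of("control@24h")]
    assert abs(ctrl.mean().mean()) < 0.05
    assert np.isfinite(matrix.values.to_numpy()).all()


def test_null_truth_produces_no_degs(design):
    truth = default_truth(design, n_genes=80, n_sets=3, hub_size=10, seed=6)
    truth.genes["emax_log2"] = 0.0
    matrix = simulate_expression(design, truth, seed=3)
    comp = design.compounds[0]
    cond = design.condition_label(comp, comp.max_dose, 24)
    out = call_degs(differential_stats(matrix, cond, "control@24h",
                                       n_perm=150, seed=0))
    assert out["is_deg"].mean() <= 0.05


def test_expression_determinism(design, truth):
    a = simulate_expression(design, truth, seed=4)
    b = simulate_expression(design, truth, seed=4)
    pd.testing.assert_frame_equal(a.values, b.values)
    c = simulate_expression(design, truth, seed=5)
    assert not a.values.equals(c.values)


def test_viability_baseline_and_ec50(design, truth):
    """Live fraction is f0 at dose 0 and f0/2 at the effective ec50."""
    vp = truth.viability[design.compounds[0].label]
    assert vp.live_fraction(0.0) == pytest.approx(vp.f0)
    assert vp.live_fraction(vp.ec50) == pytest.approx(vp.f0 / 2)


def test_viability_binomial_mean_matches_programmed_fraction(design, truth):
    big = ExposureDesign(design.compounds, timepoints=(24,), replicates=600)
    table = simulate_viability(big, truth, seed=7)
    comp = design.compounds[1]
    vp = truth.viability[comp.label]
    d = comp.concentrations[1]
    sub = table[(table["compound"] == comp.label)
                & (table["concentration"] == d)]
    frac = sub["white_count"] / (sub["white_count"] + sub["blue_count"])
    expected = vp.live_fraction(d * truth.time_scaling[24])
    se = frac.std(ddof=1) / np.sqrt(len(frac))
    assert abs(frac.mean() - expected) < 3 * se


def test_viability_determinism(design, truth):
    a = simulate_viability(design, truth, seed=8)
    b = simulate_viability(design, truth, seed=8)
    pd.testing.assert_frame_equal(a, b)


def test_programmed_coverage_and_viability_rank_anticorrelated(design, truth):
    """On the noise-free truth, hub coverage rises and viability falls in
    exact rank-opposition across the latent-toxicity ordering."""
    coverage = [truth.programmed_hub_coverage(c) for c in design.compounds]
    decline = [truth.programmed_viability_decline(c) for c in design.compounds]
    thetas = [c.theta for c in design.compounds]
    assert len(set(coverage)) == len(coverage)
    rho_cov = stats.spearmanr(thetas, coverage).statistic
    rho_dec = stats.spearmanr(thetas, decline).statistic
    assert rho_cov == pytest.approx(1.0)
    assert rho_dec == pytest.approx(1.0)
    # viability itself (f0 - decline) is therefore perfectly anti-ranked
    assert stats.spearmanr(coverage, decline).statistic == pytest.approx(1.0)


def test_experiment_bundle_determinism(design):
    a = simulate_experiment(design=design, seed=21, n_genes=60, n_sets=3,
                            hub_size=12)
    b = simulate_experiment(design=design, seed=21, n_genes=60, n_sets=3,
                            hub_size=12)
    pd.testing.assert_frame_equal(a.expression.values, b.expression.values)
    pd.testing.assert_frame_equal(a.viability, b.viability)
    assert a.gene_sets.names == b.gene_sets.names
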