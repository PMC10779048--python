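"""Williams trend, dose-response fitting, BMC/tPOD and potency ranking."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from toxpod.bmc import (
    BMCResult, DoseResponseSeries, ModelFit, bmc_from_fit, collapse_and_tpod,
    filter_gene_bmcs, fit_all_models, hybrid_bmc_from_fit, model_and_bmc,
    pava, potency_rank, prefilter_probes, select_best, viability_bmc,
    williams_trend,
)


def series(doses, y, **kw):
    return DoseResponseSeries(np.asarray(doses, float), np.asarray(y, float), **kw)


def brute_force_isotonic(y, w, increasing=True):
    """Tiny quadratic-program oracle: enumerate level partitions."""
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    n = len(y)
    best, best_cost = None, np.inf
    # enumerate all ways of splitting 0..n into contiguous blocks
    for mask in range(1 << (n - 1)):
        cuts = [0] + [i + 1 for i in range(n - 1) if mask >> i & 1] + [n]
        fit = np.empty(n)
        for a, b in zip(cuts[:-1], cuts[1:]):
            fit[a:b] = np.average(y[a:b], weights=w[a:b])
        block_means = [fit[a] for a in cuts[:-1]]
        if increasing and any(np.diff(block_means) < 0):
            continue
        if not increasing and any(np.diff(block_means) > 0):
            continue
        cost = (w * (y - fit) ** 2).sum()
        if cost < best_cost - 1e-12:
            best, best_cost = fit, cost
    return best


def test_pava_amalgamation_example():
    assert np.allclose(pava([3, 1, 2], [1, 1, 1]), [2, 2, 2])


def test_pava_matches_brute_force_qp():
    rng = np.random.default_rng(2)
    for _ in range(25):
        n = int(rng.integers(2, 6))
        y = rng.normal(size=n)
        w = rng.integers(1, 5, size=n).astype(float)
        for increasing in (True, False):
            got = pava(y, w, increasing)
            exp = brute_force_isotonic(y, w, increasing)
            assert np.allclose(got, exp, atol=1e-9)


def test_williams_minimal_p_on_strong_monotone_signal():
    rng = np.random.default_rng(0)
    doses = np.repeat([0, 1, 2, 4], 4)
    y = np.repeat([0, 1, 2, 3], 4) + rng.normal(0, 1e-3, 16)
    res = williams_trend(series(doses, y), n_perm=100, seed=1)
    assert res.p == pytest.approx(1 / 101)
    assert res.direction == 1


def test_williams_statistic_shift_invariant():
    rng = np.random.default_rng(1)
    doses = np.repeat([0, 1, 2, 4], 3)
    y = rng.normal(0, 1, 12)
    a = williams_trend(series(doses, y), n_perm=100, seed=5)
    b = williams_trend(series(doses, y + 100.0), n_perm=100, seed=5)
    assert a.statistic == pytest.approx(b.statistic, rel=1e-9)
    assert a.p == b.p


def test_williams_detects_decreasing_trend():
    doses = np.repeat([0, 1, 2, 4], 4)
    y = np.repeat([10, 9, 8, 6], 4) + np.random.default_rng(3).normal(0, 0.05, 16)
    res = williams_trend(series(doses, y), n_perm=100, seed=2)
    assert res.direction == -1
    assert res.p == pytest.approx(1 / 101)


def test_williams_type_one_error_near_nominal():
    """Null rejection rate at alpha 0.05 stays near nominal (scaled run)."""
    rng = np.random.default_rng(11)
    doses = np.repeat([0, 1, 2, 4], 3)
    hits = 0
    n_series = 300
    for i in range(n_series):
        y = rng.normal(0, 1, len(doses))
        res = williams_trend(series(doses, y), n_perm=100, seed=i)
        hits += res.p < 0.05
    rate = hits / n_series
    assert abs(rate - 5 / 101) < 0.03


def test_prefilter_gates():
    doses = np.repeat([0, 1, 2, 4], 4)
    rng = np.random.default_rng(4)
    flat = rng.normal(0, 0.1, 16)
    weak = np.repeat([0, 0.1, 0.3, 0.45], 4) + rng.normal(0, 0.05, 16)  # fc 1.37
    strong = np.repeat([0, 0.5, 1.0, 1.6], 4) + rng.normal(0, 0.05, 16)
    values = pd.DataFrame([flat, weak, strong],
                          index=["flat", "weak", "strong"])
    out = prefilter_probes(values, doses, n_perm=100, seed=0)
    keep = dict(zip(out["probe"], out["keep"]))
    assert not keep["flat"]
    assert not keep["weak"]   # trend present but fold change below 1.5
    assert keep["strong"]


def make_fit(model, params, sigma, doses=(0.0, 100.0), direction=1):
    d = np.asarray(doses, float)
    return ModelFit(model=model, params=np.asarray(params, float), sigma=sigma,
                    doses=d, responses=np.zeros_like(d), direction=direction)


def test_bmc_closed_forms():
    lin = make_fit("linear", [0.0, 2.0], sigma=1.0)
    assert bmc_from_fit(lin, ci=False).bmc == pytest.approx(0.5, rel=1e-6)
    hill = make_fit("hill", [0.0, 4.0, 25.0, 2.0], sigma=0.2)
    expected = 25.0 * math.sqrt(0.2 / 3.8)
    assert bmc_from_fit(hill, ci=False).bmc == pytest.approx(expected, rel=1e-6)


def test_bmc_doubles_with_sigma_for_linear_model():
    a = bmc_from_fit(make_fit("linear", [0.0, 2.0], 1.0), ci=False).bmc
    b = bmc_from_fit(make_fit("linear", [0.0, 2.0], 2.0), ci=False).bmc
    assert b == pytest.approx(2 * a, rel=1e-9)


def test_flat_model_bmc_undefined():
    flat = make_fit("linear", [5.0, 0.0], sigma=1.0)
    res = bmc_from_fit(flat, ci=False)
    assert not res.defined and math.isnan(res.bmc)


def test_fit_recovers_linear_and_prefers_hill_for_hill_data():
    rng = np.random.default_rng(6)
    doses = np.repeat([0, 12.5, 25, 50, 100], 4).astype(float)
    y_lin = 1.0 + 0.05 * doses + rng.normal(0, 1.0, len(doses))
    fits = fit_all_models(series(doses, y_lin), seed=0)
    lin = next(f for f in fits if f.model == "linear")
    assert lin.params[1] == pytest.approx(0.05, abs=0.02)
    assert lin.fit_p > 0.1

    mu = 4.0 * doses**2 / (25.0**2 + doses**2)
    y_hill = mu + rng.normal(0, 0.2, len(doses))
    fits = fit_all_models(series(doses, y_hill), seed=0)
    by_name = {f.model: f for f in fits}
    assert by_name["hill"].aic < by_name["linear"].aic


def test_constant_data_leaves_bmc_undefined():
    doses = np.repeat([0, 1, 2, 4], 3).astype(float)
    y = np.full(len(doses), 3.0)
    fits = fit_all_models(series(doses, y), seed=0)
    lin = next(f for f in fits if f.model == "linear")
    assert abs(lin.params[1]) < 1e-6
    assert not bmc_from_fit(lin, ci=False).defined


def test_select_best_ordering_and_interval_rule():
    doses = np.repeat([0, 1, 2, 4, 8], 3).astype(float)
    f1 = make_fit("linear", [0.0, 1.0], 1.0, doses)
    f1.aic, f1.converged = 100.0, True
    f2 = make_fit("poly2", [0.0, 1.0, 0.0], 1.0, doses)
    f2.aic, f2.converged = 103.0, True
    assert select_best([f2, f1]).model == "linear"
    # lowest-AIC fit without a finite interval is passed over
    bmcs = {
        "linear": BMCResult(1.0, math.nan, math.nan, {}, f1),
        "poly2": BMCResult(1.2, 0.8, 2.0, {}, f2),
    }
    assert select_best([f1, f2], bmcs).model == "poly2"
    # AIC tie -> fewer parameters
    f2.aic = 100.0
    assert select_best([f2, f1]).model == "linear"


def test_saturated_fits_excluded():
    doses = np.repeat([0, 1, 2, 4], 3).astype(float)
    f = make_fit("hill", [0, 1, 1, 1], 1.0, doses)
    f.saturated = True
    assert select_best([f]) is None


@pytest.mark.parametrize(
    "row,kept",
    [
        ({"bmc": 5.0, "bmcl": 1.0, "bmcu": 45.0, "fit_p": 0.5}, False),  # ratio 45
        ({"bmc": 120.0, "bmcl": 80.0, "bmcu": 200.0, "fit_p": 0.5}, False),  # > max dose
        ({"bmc": 5.0, "bmcl": 2.0, "bmcu": 10.0, "fit_p": 0.05}, False),  # lack of fit
        ({"bmc": 5.0, "bmcl": 2.0, "bmcu": 10.0, "fit_p": 0.5}, True),
    ],
)
def test_filter_gene_bmcs_gates(row, kept):
    df = pd.DataFrame([{"probe": "p1", "gene": "g1", **row}])
    out = filter_gene_bmcs(df, max_dose=100.0)
    assert (len(out) == 1) is kept


def test_filter_drops_unannotated_probes():
    df = pd.DataFrame(
        [{"probe": "p1", "gene": None, "bmc": 5.0, "bmcl": 2.0, "bmcu": 10.0,
          "fit_p": 0.5},
         {"probe": "p2", "gene": "", "bmc": 5.0, "bmcl": 2.0, "bmcu": 10.0,
          "fit_p": 0.5}]
    )
    assert len(filter_gene_bmcs(df, 100.0)) == 0


def test_probe_median_collapse():
    df = pd.DataFrame(
        [{"probe": f"p{i}", "gene": "g1", "bmc": b, "bmcl": b / 2,
          "bmcu": b * 2, "fit_p": 0.5} for i, b in enumerate([2.0, 4.0, 9.0])]
    )
    res = collapse_and_tpod(df, rank=1)
    assert res.gene_bmcs["bmc"].iloc[0] == pytest.approx(4.0)
    assert res.gene_bmcs["n_probes"].iloc[0] == 3


def test_tpod_rank_selection_and_failure():
    def table(n):
        return pd.DataFrame(
            [{"probe": f"p{i}", "gene": f"g{i:02d}", "bmc": float(i + 1),
              "bmcl": i + 0.5, "bmcu": i + 2.0, "fit_p": 0.5}
             for i in range(n)]
        )
    res = collapse_and_tpod(table(30))
    assert res.tpod == pytest.approx(25.0)
    assert res.n_genes_passing == 30
    res = collapse_and_tpod(table(24))
    assert res.tpod is None
    assert "24" in res.reason


def test_hybrid_closed_form_linear_case():
    fit = make_fit("linear", [1000.0, -20.0], sigma=100.0, direction=-1)
    bmc = hybrid_bmc_from_fit(fit, level=0.5, tail_p0=0.01)
    z = stats.norm.ppf(0.99) + stats.norm.ppf(0.505)
    assert bmc == pytest.approx(z * 100.0 / 20.0, rel=1e-6)


def test_hybrid_flat_undefined():
    fit = make_fit("linear", [1000.0, 0.0], sigma=100.0, direction=-1)
    assert hybrid_bmc_from_fit(fit, 0.5, 0.01) is None


def test_viability_bmc_interval_covers_known_truth():
    """Bootstrap 95% CIs cover the programmed hybrid BMC in most seeded
    replicates (scaled-down coverage simulation)."""
    doses = np.repeat([0, 5, 10, 25, 50], 4).astype(float)
    z = stats.norm.ppf(0.99) + stats.norm.ppf(0.505)
    true_bmc = z * 25.0 / 15.0
    n_runs, covered, rel_errs = 30, 0, []
    for i in range(n_runs):
        rng = np.random.default_rng(100 + i)
        y = 1000.0 - 15.0 * doses + rng.normal(0, 25.0, len(doses))
        res = viability_bmc(series(doses, y), seed=i, n_boot=80,
                            models=("linear", "poly2", "power", "hill"))
        assert res is not None
        covered += res.bmcl <= true_bmc <= res.bmcu
        rel_errs.append(abs(res.bmc - true_bmc) / true_bmc)
        assert res.bmcl <= res.bmc <= res.bmcu
    assert covered / n_runs >= 0.75
    assert np.median(rel_errs) <= 0.5


def test_potency_rank_chains_and_equivalence():
    def r(label, bmc, lo, hi):
        return BMCResult(bmc, lo, hi, {}, label=label)
    rank = potency_rank([r("C", 3.5, 3.0, 4.0), r("A", 1.5, 1.0, 2.0),
                         r("B", 2.5, 1.8, 3.2)])
    assert rank.chain == "A ~ B ~ C"
    assert rank.equivalent("A", "B") and not rank.equivalent("A", "C")
    rank2 = potency_rank([r("A", 1.5, 1.0, 2.0), r("B", 3.5, 3.0, 4.0)])
    assert rank2.chain == "A > B"
    with pytest.raises(ValueError, match="mixed"):
        potency_rank([BMCResult(1, 0.5, 2, {}, units="ug/mL", label="A"),
                      BMCResult(1, 0.5, 2, {}, units="cm2/mL", label="B")])


def test_series_validation():
    with pytest.raises(ValueError, match="dose groups"):
        series([0, 0, 1, 1], [1, 2, 3, 4])
    with pytest.raises(ValueError, match="replicates"):
        series([0, 0, 1, 1, 2, 2, 4], [1, 2, 3, 4, 5, 6, 7])
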