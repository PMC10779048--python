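import numpy as np
import pandas as pd
import pytest

from toxpod.degs import ExpressionMatrix
from toxpod.pipeline import PipelineConfig, run_pipeline
from toxpod.synthetic import default_design, default_truth, simulate_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """A compact seeded synthetic experiment shared by read-only tests."""
    design = default_design(timepoints=(24,), replicates=4)
    truth = default_truth(design, n_genes=120, n_sets=5, hub_size=30, seed=11)
    return simulate_experiment(design=design, truth=truth, seed=11)


def two_group_matrix(rng, n_genes=50, n_rep=4, shift=None):
    """Null (or shifted) two-condition expression matrix for DEG tests."""
    samples = [f"a_r{i}" for i in range(n_rep)] + [f"b_r{i}" for i in range(n_rep)]
    values = rng.normal(0.0, 0.25, size=(n_genes, 2 * n_rep))
    if shift is not None:
        values[: len(shift), :n_rep] += np.asarray(shift)[:, None]
    genes = [f"g{i:03d}" for i in range(n_genes)]
    design = pd.DataFrame(
        {"condition": ["a"] * n_rep + ["b"] * n_rep,
         "replicate": list(range(n_rep)) * 2},
        index=pd.Index(samples, name="sample"),
    )
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        design=design,
    )


@pytest.fixture(scope="session")
def e2e_run(tmp_path_factory):
    """One scaled end-to-end pipeline run on the synthetic fixture.

    Sized for a single CPU: 4 compounds x 4 doses x 2 timepoints with a
    60-gene hub inside a 300-gene universe; BMC modeling on the 24 h
    timepoint in compound mass units (the unit in which the latent-toxicity
    ordering is programmed).
    """
    outdir = tmp_path_factory.mktemp("e2e") / "run"
    config = PipelineConfig(
        mode="synthetic", seed=7, outdir=str(outdir),
        n_genes=300, n_sets=8, hub_size=60, replicates=4,
        timepoints=(24, 48), bmc_timepoints=(24,),
        deg_n_perm=500, dose_metric="compound", n_boot=60,
    )
    report = run_pipeline(config)
    return config, report
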