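import numpy as np
import pandas as pd
import pytest

from mced.methylome import CpGCountTable
from mced.pipeline import PipelineConfig, run_pipeline
from mced.simcohort import DEFAULT_AGE_SEX, SimConfig


def make_table(C, T, chroms=None, samples=None):
    """Small CpGCountTable helper for unit tests."""
    C = np.atleast_2d(np.asarray(C))
    T = np.atleast_2d(np.asarray(T))
    n_sites, n_samples = C.shape
    if chroms is None:
        chroms = ["chr1"] * n_sites
    sites = pd.DataFrame({
        "chrom": chroms,
        "pos0": np.arange(n_sites) * 100,
        "strand": "+",
    })
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    return CpGCountTable(sites, C, T, samples)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run on the default synthetic cohort (seed 1), with
    artifacts written; shared across acceptance and integration tests."""
    outdir = tmp_path_factory.mktemp("pipeline_run")
    cfg = PipelineConfig(seed=1)
    cfg.sim.seed = 1
    result = run_pipeline(cfg, outdir=outdir)
    return {"cfg": cfg, "outdir": outdir, "result": result}


def null_sim_config(seed: int) -> SimConfig:
    """Zero-effect cohort with exchangeable demographics (constant age,
    balanced sex) for null-safety checks."""
    flat = {k: (60.0, 0.0, 0.5) for k in DEFAULT_AGE_SEX}
    return SimConfig(
        seed=seed, n_healthy=100, n_per_cancer_per_stage=4, n_cpg_sites=6000,
        dmr_effect=0.0, cnv_segment_effect=0.0, frag_tumor_mode=166,
        age_sex_model=flat, healthy_young_frac=0.0,
    )
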