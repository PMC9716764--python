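import pathlib
import sys

import pytest

sys.path.insert(0, str(pathlib.Path(__file__).parent))  # make oracles importable

from actcomp import CohortConfig, generate_cohort, run_pipeline


@pytest.fixture(scope="session")
def cohort10(tmp_path_factory):
    """Small synthetic cohort under default study conditions."""
    d = tmp_path_factory.mktemp("cohort10")
    cfg = CohortConfig(n_girls=10, seed=202)
    return cfg, generate_cohort(cfg, d)


@pytest.fixture(scope="session")
def run10(cohort10):
    cfg, res = cohort10
    out = run_pipeline(res.out_dir, res.out_dir / "out")
    return cfg, res, out


@pytest.fixture(scope="session")
def cohort200(tmp_path_factory):
    """Recovery-scale cohort: 200 girls, effect size 3, jitter sd 0.02."""
    d = tmp_path_factory.mktemp("cohort200")
    cfg = CohortConfig(n_girls=200, seed=2018)
    return cfg, generate_cohort(cfg, d)


@pytest.fixture(scope="session")
def run200(cohort200):
    cfg, res = cohort200
    out = run_pipeline(res.out_dir, res.out_dir / "out")
    return cfg, res, out
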