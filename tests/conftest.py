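import numpy as np
import pytest

from vitamr import AnalysisConfig, make_fixtures, run_analysis
from vitamr.harmonize import HarmonizedPair

FIXTURE_SEED = 11


def make_pairs(bx, by, sx=None, sy=None, eaf=0.3):
    """Build harmonized pairs from effect arrays (defaults: tight exposure SEs)."""
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    sx = np.full_like(bx, 0.01) if sx is None else np.asarray(sx, dtype=float)
    sy = np.full_like(by, 0.05) if sy is None else np.asarray(sy, dtype=float)
    return [
        HarmonizedPair(
            variant_id=f"rs{i:04d}", effect_allele="A", other_allele="G",
            beta_exposure=float(bx[i]), se_exposure=float(sx[i]),
            beta_outcome=float(by[i]), se_outcome=float(sy[i]),
            eaf_exposure=eaf, eaf_outcome=eaf, action="none", status="kept",
        )
        for i in range(len(bx))
    ]


def random_instance(rng, j):
    """A random MR problem: exposure/outcome effects with heterogeneous SEs."""
    bx = rng.uniform(0.02, 0.12, j) * rng.choice([-1.0, 1.0], j)
    sx = rng.uniform(0.002, 0.01, j)
    sy = rng.uniform(0.01, 0.08, j)
    by = rng.normal(0.1 * bx, sy)
    return make_pairs(bx, by, sx, sy)


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    paths = make_fixtures(out, seed=FIXTURE_SEED)
    return paths


@pytest.fixture(scope="session")
def fixture_run(fixture_bundle):
    config = AnalysisConfig.from_yaml(fixture_bundle["config"])
    return run_analysis(config)
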