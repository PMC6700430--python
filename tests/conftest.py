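import numpy as np
import pandas as pd
import pytest

from coatrophy import (
    SimConfig,
    default_schema,
    generate_cohort,
    normalize_to_icv,
    reference_stats,
    robust_z,
    run_consensus_analysis,
    subtract_z,
)

DEFAULT_SEED = 7


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def small_config():
    """A quick cohort for unit tests (not the default study conditions)."""
    return SimConfig(n_cn=25, n_mci=40, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config, schema):
    return generate_cohort(small_config, schema)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """Full pipeline on the default synthetic study conditions."""
    outdir = tmp_path_factory.mktemp("default_run")
    moduleset, manifest = run_consensus_analysis(
        {"simulate": {"seed": DEFAULT_SEED}}, outdir=outdir
    )
    return moduleset, manifest, outdir


@pytest.fixture(scope="session")
def z_matrices(schema):
    """Baseline and subtracted robust-Z matrices of the default cohort."""
    baseline, m36, clinical = generate_cohort(SimConfig(seed=DEFAULT_SEED), schema)
    base_pct = normalize_to_icv(baseline)
    m36_pct = normalize_to_icv(m36)
    z_base = robust_z(base_pct, reference_stats(base_pct))
    z_m36 = robust_z(m36_pct, reference_stats(m36_pct))
    z_sub = subtract_z(z_m36, z_base)
    return {"baseline": z_base, "m36": z_m36, "subtracted": z_sub,
            "clinical": clinical}


def random_symmetric_adjacency(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Random valid soft-thresholded adjacency for oracle tests."""
    s = rng.uniform(-1, 1, size=(n, n))
    s = (s + s.T) / 2
    a = ((1 + s) / 2) ** 6
    np.fill_diagonal(a, 1.0)
    cols = [f"f{i}" for i in range(n)]
    return pd.DataFrame(a, index=cols, columns=cols)
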