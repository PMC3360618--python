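import numpy as np
import pytest

from morphoqtl import pipeline, simulate as sim


@pytest.fixture(scope="session")
def f2_dataset():
    """One seeded F2-mapping dataset under the default study conditions."""
    return sim.generate_dataset(sim.f2_cross_config(seed=42))


@pytest.fixture(scope="session")
def f2_coeffs(f2_dataset):
    """Symmetrized Fourier coefficient matrix of the seeded dataset."""
    mat, aligned, fit = pipeline.coefficient_matrix(f2_dataset.outlines)
    groups = f2_dataset.design.set_index("id")["group"].reindex(mat.index)
    return mat, groups, aligned, fit


@pytest.fixture(scope="session")
def f2_replicates():
    """Fifty independent F2-mapping replicates (scan + threshold each)."""
    reps = []
    for s in range(50):
        ds = sim.generate_dataset(sim.f2_cross_config(seed=1000 + s))
        reps.append(pipeline.f2_scan(ds, n_perm=400, perm_seed=s))
    return reps


@pytest.fixture(scope="session")
def congenic_replicates():
    """Thirty congenic/bicongenic replicates: (coefficient matrix, groups)."""
    out = []
    for s in range(30):
        ds = sim.generate_dataset(sim.congenic_config(seed=2000 + s))
        mat, _, _ = pipeline.coefficient_matrix(ds.outlines)
        groups = ds.design.set_index("id")["group"].reindex(mat.index)
        out.append((mat, groups))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(7)
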