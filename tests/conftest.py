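import numpy as np
import pytest

from bmdtox.datasets import BenchmarkResponse, QuantalDataset, builtin_fixture


@pytest.fixture(scope="session")
def cystic():
    return builtin_fixture("cystic_focal_degeneration")


@pytest.fixture(scope="session")
def bmr10():
    return BenchmarkResponse("extra_risk", 0.10)


@pytest.fixture
def random_quantal_datasets():
    """Seeded random-but-valid quantal datasets for property checks."""

    def make(n_datasets=6, seed=1234):
        rng = np.random.default_rng(seed)
        out = []
        for i in range(n_datasets):
            n_groups = rng.integers(3, 6)
            doses = np.sort(rng.uniform(0.5, 60.0, n_groups - 1))
            doses = np.concatenate([[0.0], doses])
            n = int(rng.integers(20, 80))
            # monotone-ish truth with noise
            p = np.clip(0.05 + 0.6 * doses / doses.max() + rng.normal(0, 0.05, n_groups), 0.01, 0.95)
            x = rng.binomial(n, p)
            # ensure some dose response so a BMD exists
            x[-1] = max(x[-1], x[0] + max(3, n // 10))
            x = np.minimum(x, n)
            out.append(
                QuantalDataset(f"rand_{i}", tuple((float(d), n, int(xi)) for d, xi in zip(doses, x)))
            )
        return out

    return make
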