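import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from mitopop import Alignment


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def small_alignment():
    return Alignment(
        ids=("a", "b", "c", "d"),
        seqs=("ACGTACGT", "ACGTACGA", "ACGTACGT", "ACCTACGA"),
    )


def random_alignment(rng, n, L, alphabet="ACGT"):
    mat = rng.choice(list(alphabet), size=(n, L))
    return Alignment(
        ids=tuple(f"s{i}" for i in range(n)),
        seqs=tuple("".join(row) for row in mat),
    )
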