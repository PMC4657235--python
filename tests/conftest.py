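import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def gonnet():
    from flankalign.seqio import load_gonnet250

    return load_gonnet250()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def toy_matrix():
    """A small symmetric matrix over a 4-letter sub-alphabet (match 4)."""
    from flankalign.seqio import SubstitutionMatrix

    import numpy as np

    alpha = "ARND"
    m = np.full((4, 4), -2.0)
    np.fill_diagonal(m, 4.0)
    return SubstitutionMatrix(alpha, m)


def random_protein(rng, n, alphabet="ARNDCQEGHILKMFPSTWYV"):
    return "".join(rng.choice(list(alphabet), size=n))
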