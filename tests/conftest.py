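import numpy as np
import pytest

from macetools import load_instrument
from macetools.rasch import ResponseMatrix


@pytest.fixture(scope="session")
def defn():
    return load_instrument()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_rasch_data(rng, difficulties, n, theta_mean=0.0, theta_sd=1.5,
                    items=None):
    """Model-conforming binary responses from a known bank."""
    b = np.asarray(difficulties, dtype=float)
    theta = rng.normal(theta_mean, theta_sd, n)
    p = 1.0 / (1.0 + np.exp(-(theta[:, None] - b[None, :])))
    x = (rng.random((n, b.size)) < p).astype(float)
    items = items if items is not None else list(range(b.size))
    return ResponseMatrix([f"p{i}" for i in range(n)], items, x), theta


@pytest.fixture(scope="session")
def construct_responses(defn):
    """Factory: construct-level endorsements -> raw 52-item response dict."""

    def build(endorsed_by_subscale):
        resp = {}
        for name, sub in defn.subscales.items():
            endorsed = set(endorsed_by_subscale.get(name, ()))
            for item in sub.item_ids:
                on = item in endorsed
                if item in sub.reverse_ids:
                    resp[item] = 0 if on else 1
                else:
                    resp[item] = 1 if on else 0
        return resp

    return build
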