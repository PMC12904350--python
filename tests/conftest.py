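import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy.special import expit
from scipy.stats import norm

from irtcat import Item, ItemBank

settings.register_profile(
    "irtcat",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("irtcat")


@pytest.fixture
def toy_bank() -> ItemBank:
    """Five hand-picked items spanning difficulty, with varied a and c."""
    return ItemBank(
        [
            Item("t1", a=1.0, b=-1.5, c=0.15, content_domain="easy"),
            Item("t2", a=1.8, b=-0.5, c=0.20),
            Item("t3", a=1.2, b=0.0, c=0.10),
            Item("t4", a=2.2, b=0.6, c=0.25),
            Item("t5", a=0.8, b=1.8, c=0.18, content_domain="hard"),
        ]
    )


def random_items(rng: np.random.Generator, n: int) -> list[Item]:
    """Random valid 3PL items for property checks."""
    a = rng.uniform(0.5, 3.0, n)
    b = rng.uniform(-3.0, 3.0, n)
    c = rng.uniform(0.0, 0.35, n)
    return [Item(f"r{k}", a=float(a[k]), b=float(b[k]), c=float(c[k])) for k in range(n)]


def dense_eap_sd(items, responses, theta_min=-4.0, theta_max=4.0, n_points=10001,
                 prior_mean=0.0, prior_sd=1.0):
    """Independent dense-grid trapezoid oracle for EAP theta and posterior SD.

    Computes the posterior density directly from the 3PL closed form and
    integrates with the trapezoid rule; shares no code with the package's
    quadrature path.
    """
    x = np.linspace(theta_min, theta_max, n_points)
    f = norm.pdf(x, prior_mean, prior_sd)
    for item, r in zip(items, responses):
        p = item.c + (1.0 - item.c) * expit(item.a * (x - item.b))
        f = f * (p if r == 1 else 1.0 - p)
    z = np.trapezoid(f, x)
    eap = np.trapezoid(x * f, x) / z
    sd = np.sqrt(np.trapezoid((x - eap) ** 2 * f, x) / z)
    return float(eap), float(sd)
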