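import random

import pytest


def random_instance(rng: random.Random, max_n: int = 12):
    """Random two-group instance spanning untied, light-tie and heavy-tie regimes."""
    n_total = rng.randint(2, max_n)
    m = rng.randint(1, n_total - 1)
    regime = rng.choice(["untied", "light", "heavy"])
    if regime == "untied":
        vals = rng.sample(range(1000), n_total)
    elif regime == "light":
        vals = [rng.randint(1, max(2, n_total)) for _ in range(n_total)]
    else:
        vals = [rng.randint(1, 3) for _ in range(n_total)]
    return vals[:m], vals[m:]


@pytest.fixture
def seeded_rng():
    return random.Random(20260921)
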