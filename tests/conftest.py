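import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def random_newick(rng: np.random.Generator, n_leaves: int,
                  min_bl: float = 0.01, max_bl: float = 1.0) -> str:
    """Random rooted binary tree by sequential random joins."""
    parts = [f"L{i}" for i in range(n_leaves)]
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        b = parts.pop(j)
        a = parts.pop(i)
        bl_a = rng.uniform(min_bl, max_bl)
        bl_b = rng.uniform(min_bl, max_bl)
        parts.append(f"({a}:{bl_a:.6f},{b}:{bl_b:.6f})")
    return parts[0] + ";"
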