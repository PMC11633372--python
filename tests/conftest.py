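from __future__ import annotations

import numpy as np
import pytest

from causalmaps import CausalMap, Polarity, worked_example_fixtures


@pytest.fixture(scope="session")
def fixtures() -> dict[str, CausalMap]:
    return worked_example_fixtures()


@pytest.fixture
def chain3(fixtures):
    return fixtures["chain3"]


@pytest.fixture
def clustering_toy(fixtures):
    return fixtures["clustering_toy"]


def random_map(
    seed: int,
    n: int | None = None,
    p: float | None = None,
    *,
    acyclic: bool = False,
    p_unspecified: float = 0.0,
) -> CausalMap:
    """Small Erdos-Renyi-style signed digraph for oracle comparisons.

    Deliberately built by direct edge draws (not via the package's own
    generator) so oracle tests do not depend on generator correctness.
    With ``acyclic`` only forward edges i < j are drawn (a random DAG).
    """
    rng = np.random.default_rng(seed)
    if n is None:
        n = int(rng.integers(5, 26))
    if p is None:
        p = 2.5 / n
    labels = [f"v{i:02d}" for i in range(n)]
    cmap = CausalMap(f"random(seed={seed})")
    for v in labels:
        cmap.add_node(v)
    for i in range(n):
        for j in range(n):
            if i == j or (acyclic and i >= j):
                continue
            if rng.random() < p:
                r = rng.random()
                if r < p_unspecified:
                    pol = Polarity.UNSPECIFIED
                elif rng.random() < 0.7:
                    pol = Polarity.POSITIVE
                else:
                    pol = Polarity.NEGATIVE
                cmap.add_edge(labels[i], labels[j], pol)
    return cmap
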