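import numpy as np
import pytest

import fuzzysig as fs


@pytest.fixture(scope="session")
def toy9_model():
    return fs.toy9()


@pytest.fixture(scope="session")
def chain3():
    """S -> A -> B (activations), S stimulated, A/B measured, truth h=0.5."""
    model = fs.LogicModel.from_edges(
        ["S", "A", "B"],
        [("S", "A", 1, 1), ("A", "B", 1, 1)],
        fs.HillParams(p=2, h=0.5),
        {"S": "stimulated", "A": "measured", "B": "measured"},
    )
    return model


@pytest.fixture(scope="session")
def chain3_panel(chain3):
    conds = [{"S": v} for v in (0.0, 0.25, 0.5, 0.75, 1.0)]
    dataset, flags = fs.make_steady_state_panel(chain3, conds, noise_sd=0.0, seed=0)
    assert all(flags)
    return dataset


def dtw_path_oracle(y, z):
    """Exhaustive enumeration of all admissible warping paths.

    Independent of the dynamic program: recursively walks every monotone,
    continuous, endpoint-pinned path and returns the minimum of
    (total cost, path length) normalized as cost / length.
    """
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    best = [None]

    def walk(i, j, cost, length):
        cost = cost + (y[i] - z[j]) ** 2
        length += 1
        if i == len(y) - 1 and j == len(z) - 1:
            key = (cost, length)
            if best[0] is None or key < best[0]:
                best[0] = key
            return
        if i + 1 < len(y) and j + 1 < len(z):
            walk(i + 1, j + 1, cost, length)
        if i + 1 < len(y):
            walk(i + 1, j, cost, length)
        if j + 1 < len(z):
            walk(i, j + 1, cost, length)

    walk(0, 0, 0.0, 0)
    cost, length = best[0]
    return cost / length
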