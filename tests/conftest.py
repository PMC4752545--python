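from __future__ import annotations

import numpy as np
import pytest

from xfroc.dataset import SENTINEL, ScoredDataset


def build_dataset(
    nl_normal, ll, weights, nl_abnormal=None, rating_bounds=None, n_cells=(1, 1, 1)
) -> ScoredDataset:
    """Assemble a single-cell (or replicated) ScoredDataset from rating lists.

    ``nl_normal``/``nl_abnormal``: per-case lists of NL ratings; ``ll``:
    per-abnormal-case lists of per-lesion ratings (may contain -inf);
    ``weights``: matching per-lesion weights.  The same cell data is tiled
    over the ``n_cells = (I1, I2, J)`` design.
    """
    K1, K2 = len(nl_normal), len(ll)
    nl_abnormal = nl_abnormal if nl_abnormal is not None else [[] for _ in range(K2)]
    all_nl = list(nl_normal) + list(nl_abnormal)
    M = max(1, max((len(v) for v in all_nl), default=0))
    L = max(1, max((len(v) for v in ll), default=0))
    nl = np.full((*n_cells, K1 + K2, M), SENTINEL)
    ll_arr = np.full((*n_cells, K2, L), SENTINEL)
    w = np.zeros((K2, L))
    for k, marks in enumerate(all_nl):
        nl[..., k, : len(marks)] = sorted(marks, reverse=True)
    for a in range(K2):
        ll_arr[..., a, : len(ll[a])] = ll[a]
        w[a, : len(weights[a])] = weights[a]
    case_ids = tuple(f"N{k}" for k in range(K1)) + tuple(f"A{a}" for a in range(K2))
    return ScoredDataset(
        nl=nl, ll=ll_arr, lesion_weights=w, case_ids=case_ids,
        n_normal=K1, rating_bounds=rating_bounds,
    )


def random_small_dataset(rng: np.random.Generator) -> tuple:
    """A random tiny single-cell dataset plus its list-form mirror for oracles.

    Ratings are small integers so exact ties occur often, exercising the 0.5
    branch of the kernel; lesions and NL slots are unmarked with nontrivial
    probability.
    """
    K1 = int(rng.integers(1, 6))
    K2 = int(rng.integers(1, 6))
    nl_normal, nl_abnormal, ll, weights = [], [], [], []
    for _ in range(K1):
        nl_normal.append(list(rng.integers(1, 8, size=rng.integers(0, 4))))
    for _ in range(K2):
        nl_abnormal.append(list(rng.integers(1, 8, size=rng.integers(0, 3))))
        n_les = int(rng.integers(1, 4))
        ll.append(
            [float(rng.integers(1, 8)) if rng.random() < 0.7 else SENTINEL
             for _ in range(n_les)]
        )
        weights.append([1.0 / n_les] * n_les)
    ds = build_dataset(nl_normal, ll, weights, nl_abnormal)
    return ds, nl_normal, nl_abnormal, ll, weights


@pytest.fixture(scope="session")
def phantom_truth():
    from xfroc.simulate import make_phantom_truth

    return make_phantom_truth(seed=0)


@pytest.fixture(scope="session")
def study_scale_dataset():
    """One simulated dataset at the full study design (4 x 2 x 11, 34 + 34)."""
    from xfroc.simulate import SimConfig, simulate_froc

    return simulate_froc(SimConfig(seed=1))
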