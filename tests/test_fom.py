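import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xfroc.dataset import SENTINEL
from xfroc.fom import (
    UndefinedFomError,
    fom_matrix,
    inferred_roc_fom,
    jackknife,
    psi,
    wafroc_fom,
)

import _oracles
from conftest import build_dataset, random_small_dataset

INF = float("inf")


@pytest.mark.parametrize(
    "a,b,expected",
    [(5, 3, 1.0), (2, 7, 0.0), (4, 4, 0.5), (-INF, -INF, 0.5),
     (3, -INF, 1.0), (-INF, 3, 0.0)],
)
def test_psi_kernel(a, b, expected):
    assert psi(a, b) == expected


def test_wafroc_four_case_example():
    """2 normals (highest NL 3, unmarked) x 2 one-lesion abnormals (LL 5, unmarked).

    Pairs: psi(5,3)=1, psi(5,-inf)=1, psi(-inf,3)=0, psi(-inf,-inf)=0.5,
    so theta = 2.5/4 = 0.625; identical for the inferred ROC since the
    abnormal cases carry no NLs.
    """
    nl_normal = [[3.0], []]
    ll = [[5.0], [SENTINEL]]
    weights = [[1.0], [1.0]]
    assert wafroc_fom(
        np.array([[3.0], [SENTINEL]]), np.array(ll), np.array(weights)
    ) == pytest.approx(0.625)
    ds = build_dataset(nl_normal, ll, weights)
    fm = fom_matrix(ds, "wafroc")
    assert fm.values[0, 0, 0] == pytest.approx(0.625)
    assert fom_matrix(ds, "roc").values[0, 0, 0] == pytest.approx(0.625)
    assert _oracles.brute_wafroc(nl_normal, ll, weights) == pytest.approx(0.625)


def test_perfect_observer_scores_one():
    ds = build_dataset([[2.0], [1.0]], [[9.0], [8.0]], [[1.0], [1.0]])
    assert fom_matrix(ds, "wafroc").values[0, 0, 0] == 1.0
    assert fom_matrix(ds, "roc").values[0, 0, 0] == 1.0


def test_silent_observer_scores_half():
    """An observer who marks nothing scores 0.5 under the tie convention."""
    ds = build_dataset([[], []], [[SENTINEL], [SENTINEL]], [[1.0], [1.0]])
    assert fom_matrix(ds, "wafroc").values[0, 0, 0] == 0.5
    assert fom_matrix(ds, "roc").values[0, 0, 0] == 0.5


def test_fom_requires_both_case_classes():
    with pytest.raises(UndefinedFomError):
        wafroc_fom(np.empty((0, 1)), np.array([[5.0]]), np.array([[1.0]]))
    with pytest.raises(UndefinedFomError):
        inferred_roc_fom(np.full((2, 1), SENTINEL), np.empty((0, 1)), 2)


def test_foms_match_brute_force_on_random_small_datasets():
    """Exact agreement with pair-enumeration oracles over 300 random datasets."""
    rng = np.random.default_rng(2024)
    for _ in range(300):
        ds, nl_n, nl_a, ll, w = random_small_dataset(rng)
        got_w = fom_matrix(ds, "wafroc").values[0, 0, 0]
        got_r = fom_matrix(ds, "roc").values[0, 0, 0]
        assert got_w == pytest.approx(_oracles.brute_wafroc(nl_n, ll, w), abs=1e-12)
        assert got_r == pytest.approx(
            _oracles.brute_inferred_roc(nl_n + nl_a, ll, len(nl_n)), abs=1e-12
        )


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), scale=st.floats(0.1, 5.0), shift=st.floats(-3, 3))
def test_foms_invariant_under_monotone_transforms(seed, scale, shift):
    """Both FOMs depend only on rating order, not on the rating scale."""
    rng = np.random.default_rng(seed)
    ds, *_ = random_small_dataset(rng)
    base_w = fom_matrix(ds, "wafroc").values
    base_r = fom_matrix(ds, "roc").values

    def transform(arr):
        out = arr.copy()
        finite = np.isfinite(out)
        out[finite] = scale * out[finite] + shift  # strictly increasing
        return out

    ds.nl, ds.ll = transform(ds.nl), transform(ds.ll)
    ds.rating_bounds = None
    np.testing.assert_allclose(fom_matrix(ds, "wafroc").values, base_w, atol=1e-12)
    np.testing.assert_allclose(fom_matrix(ds, "roc").values, base_r, atol=1e-12)


def test_extra_nl_never_increases_and_higher_ll_never_decreases():
    rng = np.random.default_rng(11)
    for _ in range(25):
        ds, nl_n, nl_a, ll, w = random_small_dataset(rng)
        base_w = fom_matrix(ds, "wafroc").values[0, 0, 0]
        base_r = fom_matrix(ds, "roc").values[0, 0, 0]

        # add a high NL mark on normal case 0
        nl_n2 = [list(v) for v in nl_n]
        nl_n2[0] = nl_n2[0] + [9.0]
        ds2 = build_dataset(nl_n2, ll, w, nl_a)
        assert fom_matrix(ds2, "wafroc").values[0, 0, 0] <= base_w + 1e-12
        assert fom_matrix(ds2, "roc").values[0, 0, 0] <= base_r + 1e-12

        # raise the first lesion's rating
        ll2 = [list(v) for v in ll]
        ll2[0][0] = 10.0
        ds3 = build_dataset(nl_n, ll2, w, nl_a)
        assert fom_matrix(ds3, "wafroc").values[0, 0, 0] >= base_w - 1e-12


def test_fom_matrix_shape_and_locality(study_scale_dataset):
    fm = fom_matrix(study_scale_dataset, "wafroc")
    assert fm.values.shape == (4, 2, 11)
    assert ((fm.values >= 0) & (fm.values <= 1)).all()
    # perturb one cell: only that cell's theta changes
    ds = study_scale_dataset
    original = ds.ll[1, 0, 3].copy()
    ds.ll[1, 0, 3] = np.where(np.isfinite(ds.ll[1, 0, 3]), 10.0, SENTINEL)
    fm2 = fom_matrix(ds, "wafroc")
    ds.ll[1, 0, 3] = original
    changed = ~np.isclose(fm.values, fm2.values)
    assert changed[1, 0, 3] or np.allclose(fm.values[1, 0, 3], fm2.values[1, 0, 3])
    changed[1, 0, 3] = False
    assert not changed.any()


def test_jackknife_loo_example_and_identities():
    """Deleting the unmarked normal case from the 4-case example gives 0.5."""
    nl_normal = [[3.0], []]
    ll = [[5.0], [SENTINEL]]
    weights = [[1.0], [1.0]]
    ds = build_dataset(nl_normal, ll, weights)
    jk = jackknife(ds, "wafroc")
    # deleting normal case 1 (unmarked) leaves pairs psi(5,3)=1, psi(-inf,3)=0
    assert jk.loo[0, 0, 0, 1] == pytest.approx(0.5)
    # deleting normal case 0 leaves psi(5,-inf)=1, psi(-inf,-inf)=0.5
    assert jk.loo[0, 0, 0, 0] == pytest.approx(0.75)
    # pseudovalue identity: mean(Y) = K*theta - (K-1)*mean(theta_loo)
    K = jk.n_cases
    np.testing.assert_allclose(
        jk.pseudovalues.mean(axis=-1),
        K * jk.theta - (K - 1) * jk.loo.mean(axis=-1),
    )


def test_jackknife_matches_deleting_cases_explicitly():
    """LOO values agree with recomputing the FOM on the reduced dataset."""
    rng = np.random.default_rng(3)
    for fom_type in ("wafroc", "roc"):
        for _ in range(10):
            while True:
                ds, nl_n, nl_a, ll, w = random_small_dataset(rng)
                if len(nl_n) >= 2 and len(ll) >= 2:
                    break
            jk = jackknife(ds, fom_type)
            K1 = len(nl_n)
            for k in range(K1 + len(ll)):
                if k < K1:
                    nn = nl_n[:k] + nl_n[k + 1:]
                    expected = (
                        _oracles.brute_wafroc(nn, ll, w)
                        if fom_type == "wafroc"
                        else _oracles.brute_inferred_roc(nn + nl_a, ll, K1 - 1)
                    )
                else:
                    a = k - K1
                    la, wa = ll[:a] + ll[a + 1:], w[:a] + w[a + 1:]
                    na = nl_a[:a] + nl_a[a + 1:]
                    expected = (
                        _oracles.brute_wafroc(nl_n, la, wa)
                        if fom_type == "wafroc"
                        else _oracles.brute_inferred_roc(nl_n + na, la, K1)
                    )
                assert jk.loo[0, 0, 0, k] == pytest.approx(expected, abs=1e-12)


def test_jackknife_requires_two_cases_per_class():
    ds = build_dataset([[3.0]], [[5.0], [4.0]], [[1.0], [1.0]])
    with pytest.raises(UndefinedFomError):
        jackknife(ds, "wafroc")
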