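import numpy as np
import pytest

from xfroc.fom import fom_matrix
from xfroc.simulate import (
    PHANTOM_LESION_COUNTS,
    SimConfig,
    make_phantom_truth,
    null_rejection_rate,
    simulate_froc,
)


def small_cfg(**kw):
    base = dict(n_factor1=2, n_factor2=2, n_readers=3,
                n_normal=10, n_abnormal=10, seed=0)
    base.update(kw)
    return SimConfig(**base)


def test_same_seed_reproduces_identical_dataset():
    a, b = simulate_froc(small_cfg()), simulate_froc(small_cfg())
    assert np.array_equal(a.nl, b.nl) and np.array_equal(a.ll, b.ll)
    c = simulate_froc(small_cfg(seed=1))
    assert not (np.array_equal(a.nl, c.nl) and np.array_equal(a.ll, c.ll))


def test_perfect_separation_yields_fom_one():
    """nu=1, lambda=0, huge mu: every lesion outrates every (absent) NL."""
    cfg = small_cfg(lesion_hit_prob=1.0, nl_rate=0.0, detectability=50.0,
                    rating_model="continuous")
    fm = fom_matrix(simulate_froc(cfg), "wafroc")
    np.testing.assert_allclose(fm.values, 1.0)


def test_equal_detectability_gives_no_systematic_cell_differences():
    """Null config: mean FOM difference between cells is within 3 MC SE of 0."""
    diffs = []
    for seed in range(60):
        fm = fom_matrix(simulate_froc(small_cfg(seed=seed, n_readers=2)), "wafroc")
        diffs.append(fm.values[0].mean() - fm.values[1].mean())
    diffs = np.asarray(diffs)
    se = diffs.std(ddof=1) / np.sqrt(len(diffs))
    assert abs(diffs.mean()) < 3 * se + 1e-12


def test_increasing_detectability_increases_wafroc():
    """Monotonicity of the generator in mu, averaged over seeds."""
    def mean_fom(mu):
        vals = [
            fom_matrix(
                simulate_froc(small_cfg(detectability=mu, seed=s,
                                        rating_model="continuous")),
                "wafroc",
            ).values.mean()
            for s in range(15)
        ]
        return float(np.mean(vals))

    assert mean_fom(0.5) < mean_fom(1.5) < mean_fom(3.0)


def test_power_ordering_with_effect_size():
    """A large factor-1 effect is detected more often than a small one."""
    def detections(delta, n_reps=25):
        hits = 0
        for seed in range(n_reps):
            mu = np.array([[0.8, 0.8], [0.8 + delta, 0.8 + delta]])
            cfg = SimConfig(n_factor1=2, n_factor2=2, n_readers=8,
                            n_normal=25, n_abnormal=25,
                            detectability=mu, seed=seed)
            from xfroc.crossed import crossed_modality_analysis

            res = crossed_modality_analysis(simulate_froc(cfg))
            hits += res.factor1_analysis.p < 0.025
        return hits

    assert detections(0.8) > detections(0.2)


def test_stream_splitting_isolates_dimensions():
    """Adding a reader leaves the existing readers' draws untouched."""
    a = simulate_froc(small_cfg(n_readers=2))
    b = simulate_froc(small_cfg(n_readers=3))
    assert np.array_equal(a.ll, b.ll[:, :, :2])
    # NL slot count can grow with the extra reader; compare finite sets per case
    M = min(a.nl.shape[-1], b.nl.shape[-1])
    assert np.array_equal(a.nl[..., :M], b.nl[:, :, :2, :, :M])


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        simulate_froc(small_cfg(lesion_hit_prob=1.5))
    with pytest.raises(ValueError):
        simulate_froc(small_cfg(nl_rate=-1.0))
    with pytest.raises(ValueError):
        simulate_froc(small_cfg(detectability=np.zeros((3, 3))))


class TestPhantomTruth:
    """The fixture reproduces the published nodule distribution exactly."""

    def test_totals_and_margins(self, phantom_truth):
        lesions = phantom_truth.lesions
        assert len(lesions) == 46
        assert len(phantom_truth.normal_ids) == 34
        assert len(phantom_truth.abnormal_ids) == 34
        assert sum(l.side == "right" for l in lesions) == 25
        assert sum(l.side == "left" for l in lesions) == 21
        levels = [sum(l.level == z for l in lesions) for z in ("upper", "mid", "lower")]
        assert levels == [8, 26, 12]
        depths = [sum(l.depth == d for l in lesions)
                  for d in ("anterior", "posterior", "central")]
        assert depths == [8, 25, 13]
        assert sum(l.peripheral for l in lesions) == 18

    def test_zone_cell_counts_exact_every_run(self):
        from xfroc.simulate import _ZONE_COUNTS

        for seed in (0, 1, 99):
            truth = make_phantom_truth(seed)
            for (level, depth, side), expected in _ZONE_COUNTS.items():
                got = sum(
                    l.level == level and l.depth == depth and l.side == side
                    for l in truth.lesions
                )
                assert got == expected, (level, depth, side)
            assert sum(l.peripheral for l in truth.lesions) == 18

    def test_lesion_counts_per_case(self, phantom_truth):
        counts = sorted(
            phantom_truth.n_lesions(c) for c in phantom_truth.abnormal_ids
        )
        assert counts == sorted(PHANTOM_LESION_COUNTS)
        mean = np.mean(counts)
        assert round(float(mean), 2) == 1.35
        assert round(float(np.std(counts, ddof=1)), 2) == 0.54

    def test_sizes_densities_and_geometry(self, phantom_truth):
        for l in phantom_truth.lesions:
            assert l.diameter_mm in (5.0, 8.0, 10.0, 12.0)
            assert l.density_hu in (100.0, -630.0, -800.0)
            assert 0 <= l.x <= 512 and 0 <= l.y <= 512
            # coordinates consistent with the side label (right lung on image left)
            assert (l.x < 256) == (l.side == "right")
        assert phantom_truth.validate() == []

    def test_lesions_on_same_case_are_separated(self, phantom_truth):
        import math

        for case in phantom_truth.abnormal_ids:
            lesions = phantom_truth.lesions_for(case)
            for i in range(len(lesions)):
                for j in range(i + 1, len(lesions)):
                    d = math.hypot(lesions[i].x - lesions[j].x,
                                   lesions[i].y - lesions[j].y)
                    assert d > 40.0  # unambiguous with the 20 px radius


def test_null_rejection_rate_limits_and_validation():
    cfg = small_cfg(n_readers=3, n_normal=8, n_abnormal=8)
    tiny_alpha = null_rejection_rate(cfg, n_reps=5, overall_alpha=1e-9)
    assert tiny_alpha.rate == 0.0
    with pytest.raises(ValueError):
        null_rejection_rate(
            small_cfg(detectability=np.array([[1.0, 2.0], [1.0, 1.0]])), n_reps=2
        )
    r = null_rejection_rate(cfg, n_reps=10)
    assert 0.0 <= r.ci_low <= r.rate <= r.ci_high <= 1.0
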