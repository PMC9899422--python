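"""Manifold geometry: Cover oracle, LP separability, mean-field analysis."""

import numpy as np
import pytest

from speechmanifold import (
    ActivationSet,
    DegenerateDataError,
    InsufficientDataError,
    InvalidInputError,
    ManifoldSet,
    cover_fraction,
    empirical_capacity,
    is_linearly_separable,
    mft_analysis,
    participation_ratio,
    prepare_manifolds,
    separable_fraction,
)


def _singletons(P, N, rng):
    return ManifoldSet(manifolds=rng.standard_normal((P, 1, N)), class_ids=list(range(P)))


class TestCoverFraction:
    @pytest.mark.parametrize(
        "P,n,expected",
        [(3, 2, 0.75), (4, 2, 0.5), (5, 5, 1.0), (8, 1, 2 / 256), (6, 3, 2 * 16 / 64)],
    )
    def test_closed_form_values(self, P, n, expected):
        assert cover_fraction(P, n) == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_dimension(self):
        for P in range(2, 9):
            fracs = [cover_fraction(P, n) for n in range(1, P + 1)]
            assert all(b >= a for a, b in zip(fracs, fracs[1:]))
            assert fracs[-1] == 1.0


class TestLinearSeparability:
    def test_centered_xor_is_not_separable(self):
        pos = np.array([[1.0, 1.0], [-1.0, -1.0]])
        neg = np.array([[1.0, -1.0], [-1.0, 1.0]])
        assert is_linearly_separable(pos, neg) is False

    def test_opposite_points_are_separable(self):
        assert is_linearly_separable(np.array([[1.0, 0.0]]), np.array([[-1.0, 0.0]])) is True

    def test_shared_point_is_infeasible(self):
        p = np.array([[0.3, 0.7]])
        assert is_linearly_separable(p, p) is False

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            is_linearly_separable(np.ones((2, 3)), np.ones((2, 2)))


class TestSeparableFraction:
    def test_four_points_in_two_dims_half_separable(self, rng):
        # Cover: C(4,2)/2^4 = 0.5 expected over random dichotomies
        fracs = [
            separable_fraction(_singletons(4, 12, rng), 2, 200, seed=s) for s in range(5)
        ]
        assert abs(np.mean(fracs) - 0.5) < 0.1

    def test_saturates_when_dims_exceed_points(self, rng):
        ms = _singletons(5, 10, rng)
        assert separable_fraction(ms, 6, 50, seed=1) == 1.0

    def test_single_dichotomy_is_binary(self, rng):
        f = separable_fraction(_singletons(4, 8, rng), 2, 1, seed=2)
        assert f in (0.0, 1.0)

    def test_too_few_manifolds_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            separable_fraction(_singletons(1, 5, rng), 1, 10, seed=0)


class TestEmpiricalCapacity:
    def test_duplicated_points_leave_capacity_unchanged(self, rng):
        base = rng.standard_normal((16, 1, 60))
        singles = ManifoldSet(manifolds=base, class_ids=list(range(16)))
        dupes = ManifoldSet(
            manifolds=np.repeat(base, 5, axis=1), class_ids=list(range(16))
        )
        a = empirical_capacity(singles, n_dichotomies=100, seed=3)
        b = empirical_capacity(dupes, n_dichotomies=100, seed=3)
        assert abs(a.alpha - b.alpha) <= 0.2

    def test_bisection_brackets_the_crossing(self, rng):
        est = empirical_capacity(_singletons(12, 40, rng), n_dichotomies=100, seed=4)
        curve = dict(est.curve)
        assert curve[est.n_star] >= 0.5
        if est.n_star - 1 in curve:
            assert curve[est.n_star - 1] < 0.5

    def test_unreachable_target_raises_with_curve(self, rng):
        ms = _singletons(6, 8, rng)
        from speechmanifold import OutOfRangeError

        with pytest.raises(OutOfRangeError) as exc:
            empirical_capacity(ms, f_target=1.1, n_dichotomies=20, seed=0)
        assert exc.value.curve  # observed curve attached


class TestPrepareManifolds:
    def _acts(self, rng, P=4, m=8, N=30):
        feats = [rng.standard_normal((m, N)) + 2.0 * rng.standard_normal(N) for _ in range(P)]
        return ActivationSet(layers={"L": feats}, class_ids=list(range(P)))

    def test_global_mean_removed(self, rng):
        ms = prepare_manifolds(self._acts(rng), M=5, N_proj=30, seed=0)
        flat = ms.manifolds.reshape(-1, ms.N)
        scale = np.abs(flat).max()
        assert np.all(np.abs(flat.mean(axis=0)) < 1e-8 * max(scale, 1.0))

    def test_projection_preserves_pairwise_distances(self, rng):
        feats = [rng.standard_normal((6, 1000)) for _ in range(5)]
        acts = ActivationSet(layers={"L": feats}, class_ids=list(range(5)))
        full = prepare_manifolds(acts, M=6, N_proj=1000, seed=1)
        proj = prepare_manifolds(acts, M=6, N_proj=200, seed=1)
        a = full.manifolds.reshape(-1, 1000)
        b = proj.manifolds.reshape(-1, 200)
        da = np.linalg.norm(a[:, None] - a[None, :], axis=-1)
        db = np.linalg.norm(b[:, None] - b[None, :], axis=-1)
        off = ~np.eye(len(a), dtype=bool)
        rel = np.abs(db[off] - da[off]) / da[off]
        assert np.mean(rel <= 0.25) >= 0.99

    def test_insufficient_exemplars_rejected(self, rng):
        with pytest.raises(InsufficientDataError):
            prepare_manifolds(self._acts(rng, m=3), M=5, N_proj=30, seed=0)

    def test_multi_layer_set_needs_layer_id(self, rng):
        acts = ActivationSet(
            layers={"A": [rng.standard_normal((4, 10))] * 2,
                    "B": [rng.standard_normal((4, 10))] * 2},
            class_ids=[0, 1],
        )
        with pytest.raises(InvalidInputError):
            prepare_manifolds(acts, M=3, N_proj=10, seed=0)
        ms = prepare_manifolds(acts, M=3, N_proj=10, seed=0, layer_id="B")
        assert ms.layer_id == "B"


class TestMeanFieldAnalysis:
    def test_wider_manifolds_lower_capacity_higher_dimension(self, rng):
        centers = rng.standard_normal((8, 1, 40)) * 3.0
        spread = rng.standard_normal((8, 12, 40))
        narrow = ManifoldSet(manifolds=centers + 0.3 * spread, class_ids=list(range(8)))
        wide = ManifoldSet(manifolds=centers + 3.0 * spread, class_ids=list(range(8)))
        rn = mft_analysis(narrow, n_gaussian_samples=200, seed=5)
        rw = mft_analysis(wide, n_gaussian_samples=200, seed=5)
        assert rw.alpha < rn.alpha
        assert rw.dimension > rn.dimension

    def test_noise_feature_padding_leaves_capacity_load_stable(self, rng):
        # capacity is a per-dimension load: doubling N with pure-noise
        # features must not halve or double it
        X = rng.standard_normal((6, 10, 50)) + 2 * rng.standard_normal((6, 1, 50))
        pad = 0.1 * rng.standard_normal((6, 10, 50))
        ms = ManifoldSet(manifolds=X, class_ids=list(range(6)))
        padded = ManifoldSet(
            manifolds=np.concatenate([X, pad], axis=2), class_ids=list(range(6))
        )
        a = mft_analysis(ms, n_gaussian_samples=200, seed=6).alpha
        b = mft_analysis(padded, n_gaussian_samples=200, seed=6).alpha
        assert 2 / 3 < b / a < 3 / 2

    def test_coincident_point_manifolds_rejected(self):
        X = np.zeros((2, 3, 10))
        X[0] += 1.0
        X[1] += 1.0  # both manifolds collapse onto the same point
        ms = ManifoldSet(manifolds=X, class_ids=[0, 1])
        from speechmanifold import DegenerateGeometryError

        with pytest.raises(DegenerateGeometryError):
            mft_analysis(ms, seed=0)

    def test_agrees_with_empirical_capacity_on_balls(self, rng):
        # small-ball benchmark: the two routes (mean-field theory vs LP
        # simulation) must agree within 15%
        centers = 4.0 * rng.standard_normal((20, 1, 100))
        ms = ManifoldSet(
            manifolds=centers + 0.4 * rng.standard_normal((20, 8, 100)),
            class_ids=list(range(20)),
        )
        a_mft = mft_analysis(ms, n_gaussian_samples=300, seed=7).alpha
        a_sim = empirical_capacity(ms, n_dichotomies=150, seed=7).alpha
        assert abs(a_mft - a_sim) / a_sim < 0.15


class TestParticipationRatio:
    def test_single_direction_gives_one(self, rng):
        pts = np.outer(rng.standard_normal(50), np.ones(6))
        assert participation_ratio(pts) == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_gaussian_matches_dimension(self, rng):
        pts = rng.standard_normal((10000, 5))
        assert participation_ratio(pts) == pytest.approx(5.0, rel=0.05)

    def test_identical_points_rejected(self):
        with pytest.raises(DegenerateDataError):
            participation_ratio(np.ones((10, 4)))
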