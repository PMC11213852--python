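"""Fuzzy c-means, Xie-Beni, selection and consensus."""

import itertools
import subprocess
import textwrap

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ltc_subtyper.fuzzy import (
    FuzzyPartition,
    consensus_fcm,
    fcm_fit,
    hard_assign,
    select_c,
    xie_beni,
)


def _blobs(rng, centers, n_per, spread=0.15):
    pts = [c + spread * rng.standard_normal((n_per, len(c))) for c in np.atleast_2d(centers)]
    return np.vstack(pts)


class TestFcmFit:
    def test_single_cluster_is_mean(self, rng):
        X = rng.standard_normal((20, 3))
        part = fcm_fit(X, 1, seed=0)
        assert np.allclose(part.membership, 1.0)
        assert np.allclose(part.centers[0], X.mean(axis=0), atol=1e-8)
        assert np.isclose(part.objective, ((X - X.mean(0)) ** 2).sum(), rtol=1e-6)

    def test_point_at_center_gets_crisp_membership(self):
        X = np.array([[0.0], [0.0], [10.0], [10.0], [5.0]])
        part = fcm_fit(X, 2, seed=1)
        # the points sitting exactly on a converged center are crisp
        d = np.abs(X - part.centers.T.ravel()[None, :])
        on_center = np.isclose(d.min(axis=1), 0.0)
        assert np.allclose(part.membership[on_center].max(axis=1), 1.0)

    def test_two_blob_centers_near_means(self):
        X = np.array([0.0, 0.1, 0.2, 10.0, 10.1, 10.2])[:, None]
        part = fcm_fit(X, 2, m=2.0, seed=0)
        got = np.sort(part.centers.ravel())
        assert np.abs(got - np.array([0.1, 10.1])).max() < 0.05

    def test_membership_rows_sum_to_one(self, rng):
        X = rng.standard_normal((40, 2))
        part = fcm_fit(X, 4, seed=2)
        assert np.allclose(part.membership.sum(axis=1), 1.0, atol=1e-9)

    def test_objective_consistent_with_fields(self, rng):
        X = rng.standard_normal((30, 2))
        part = fcm_fit(X, 3, seed=5)
        d2 = ((X[:, None, :] - part.centers[None]) ** 2).sum(-1)
        J = (part.membership**part.m * d2).sum()
        assert np.isclose(J, part.objective, rtol=1e-6)

    def test_c_greater_than_n_rejected(self):
        with pytest.raises(ValueError):
            fcm_fit(np.zeros((3, 1)), 4)

    def test_matches_exhaustive_partition_oracle(self, rng):
        """n<=8 two-cluster instances: FCM hard labels equal the minimum
        within-cluster-SSE 2-partition found by enumeration."""
        for trial in range(5):
            c1 = rng.uniform(-1, 0)
            X = np.sort(
                np.r_[c1 + 0.05 * rng.standard_normal(4), c1 + 6 + 0.05 * rng.standard_normal(4)]
            )[:, None]
            best, best_sse = None, np.inf
            for assign in itertools.product([0, 1], repeat=len(X)):
                assign = np.array(assign)
                if assign.min() == assign.max():
                    continue
                sse = sum(
                    ((X[assign == k] - X[assign == k].mean(0)) ** 2).sum()
                    for k in (0, 1)
                )
                if sse < best_sse:
                    best, best_sse = assign, sse
            labels = hard_assign(fcm_fit(X, 2, seed=trial)) - 1
            agree = (labels == best).mean()
            assert agree in (0.0, 1.0)  # equal up to label swap


class TestAgainstReferenceImplementation:
    def test_centers_match_e1071_cmeans(self, rng, tmp_path):
        """Independent oracle: R's e1071::cmeans on a two-blob instance."""
        X = _blobs(rng, [[0, 0], [5, 5]], 25)
        np.savetxt(tmp_path / "x.csv", X, delimiter=",")
        script = textwrap.dedent(
            """
            x <- as.matrix(read.csv("{path}", header=FALSE))
            set.seed(1)
            fit <- e1071::cmeans(x, centers=2, m=2)
            cat(sprintf("%.6f", fit$centers[order(fit$centers[,1]),]))
            """
        ).format(path=tmp_path / "x.csv")
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        ref = np.array([float(v) for v in out.stdout.split()]).reshape(2, 2, order="F")
        part = fcm_fit(X, 2, m=2.0, seed=0)
        ours = part.centers[np.argsort(part.centers[:, 0])]
        assert np.abs(ours - ref).max() < 0.05


class TestXieBeni:
    def test_crisp_points_at_centers_zero(self):
        X = np.array([[0.0], [1.0]])
        part = FuzzyPartition(
            membership=np.eye(2),
            centers=np.array([[0.0], [1.0]]),
            objective=0.0,
            m=2.0,
            seed=0,
            n_iterations=1,
            converged=True,
        )
        assert xie_beni(X, part) == 0.0

    def test_hand_expanded_double_sum(self):
        X = np.array([0.0, 1.0, 3.0, 4.0])[:, None]
        u = np.array([[0.8, 0.2], [0.7, 0.3], [0.3, 0.7], [0.2, 0.8]])
        v = np.array([[0.5], [3.5]])
        part = FuzzyPartition(u, v, 0.0, 2.0, 0, 1, True)
        # numerator: sum_i sum_k u_ik^2 d_ik^2 expanded by hand = 2.67
        assert np.isclose(xie_beni(X, part), 2.67 / (4 * 9.0), atol=1e-12)

    def test_coincident_centers_infinite(self):
        X = np.array([[0.0], [1.0]])
        part = FuzzyPartition(
            np.full((2, 2), 0.5), np.zeros((2, 1)), 0.0, 2.0, 0, 1, True
        )
        with pytest.warns(UserWarning):
            assert xie_beni(X, part) == np.inf


class TestSelectC:
    def test_single_candidate(self, rng):
        X = _blobs(rng, [[0, 0], [5, 5]], 10)
        report = select_c(X, c_candidates=[4], runs_per_c=2, seed=0)
        assert report.chosen_c == 4

    def test_tie_goes_to_smaller_c(self, monkeypatch):
        import ltc_subtyper.fuzzy as fz

        monkeypatch.setattr(fz, "xie_beni", lambda X, p: 1.0)
        X = np.random.default_rng(0).standard_normal((30, 2))
        report = fz.select_c(X, c_candidates=[2, 3, 4], runs_per_c=1, seed=0)
        assert report.chosen_c == 2

    def test_recovers_planted_count_small(self, rng):
        centers = 6 * np.array(
            [[0, 0], [1, 0], [0, 1], [1, 1], [2, 0.5]], dtype=float
        )
        X = _blobs(rng, centers, 30)
        report = select_c(X, c_candidates=range(2, 9), runs_per_c=4, seed=1)
        assert report.chosen_c == 5


class TestConsensus:
    def test_single_run_equals_fit(self, rng):
        X = rng.standard_normal((30, 2))
        part = consensus_fcm(X, 3, n_runs=1, seed=4)
        single = fcm_fit(X, 3, seed=4)
        assert np.allclose(part.membership, single.membership, atol=1e-12)

    def test_well_separated_memberships_near_crisp(self, rng):
        X = _blobs(rng, [[0, 0], [8, 8]], 20, spread=0.1)
        part = consensus_fcm(X, 2, n_runs=20, seed=0)
        assert part.membership.max(axis=1).min() >= 0.99

    def test_rows_sum_to_one_after_averaging(self, rng):
        X = rng.standard_normal((50, 3))
        part = consensus_fcm(X, 4, n_runs=10, seed=2)
        assert np.allclose(part.membership.sum(axis=1), 1.0, atol=1e-9)

    def test_deterministic_given_seed(self, rng):
        X = rng.standard_normal((40, 2))
        a = consensus_fcm(X, 3, n_runs=5, seed=9)
        b = consensus_fcm(X, 3, n_runs=5, seed=9)
        assert np.array_equal(a.membership, b.membership)
        assert np.array_equal(a.centers, b.centers)


class TestHardAssign:
    def test_argmax_and_tie_rule(self):
        u = np.array([[0.2, 0.7, 0.1], [0.5, 0.5, 0.0]])
        part = FuzzyPartition(u, np.zeros((3, 1)), 0.0, 2.0, 0, 1, True)
        assert list(hard_assign(part)) == [2, 1]

    def test_crisp_partition_roundtrip(self, rng):
        u = np.eye(4)[rng.integers(0, 4, size=12)]
        part = FuzzyPartition(u, np.zeros((4, 1)), 0.0, 2.0, 0, 1, True)
        labels = hard_assign(part)
        assert np.array_equal(np.eye(4)[labels - 1], u)


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_membership_normalization_property(seed):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((20, 2))
    part = fcm_fit(X, 3, seed=seed)
    assert np.allclose(part.membership.sum(axis=1), 1.0, atol=1e-9)
    assert part.membership.min() >= 0.0 and part.membership.max() <= 1.0
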