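from itertools import permutations

import numpy as np
import pytest

from oceandecay.matrixstats import anosim, mantel, mrm, partial_mantel
from oceandecay.pairwise import PairwiseMatrix

from conftest import random_distance_matrix


def pearson(a, b):
    return float(np.corrcoef(a, b)[0, 1])


def exhaustive_mantel_p(X: PairwiseMatrix, Y: PairwiseMatrix) -> float:
    """One-tailed Mantel p by full enumeration of station permutations."""
    n = X.n
    iu = np.triu_indices(n, k=1)
    x = X.values[iu]
    r_obs = pearson(x, Y.values[iu])
    hits = 0
    total = 0
    for perm in permutations(range(n)):
        yp = Y.values[np.ix_(perm, perm)][iu]
        if pearson(x, yp) >= r_obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


class TestMantel:
    def test_self_correlation_is_one(self):
        X = random_distance_matrix(6, np.random.default_rng(0))
        res = mantel(X, X, n_perm=99, seed=1)
        assert res.r == pytest.approx(1.0)

    def test_constant_matrix_rejected(self):
        n = 5
        C = PairwiseMatrix(np.ones((n, n)) - np.eye(n), [f"s{i}" for i in range(n)])
        X = random_distance_matrix(n, np.random.default_rng(0))
        with pytest.raises(ValueError, match="constant"):
            mantel(X, C, n_perm=9)

    def test_seeded_runs_bit_reproducible(self):
        rng = np.random.default_rng(2)
        X, Y = random_distance_matrix(7, rng), random_distance_matrix(7, rng)
        r1 = mantel(X, Y, n_perm=199, seed=42)
        r2 = mantel(X, Y, n_perm=199, seed=42)
        assert (r1.r, r1.p) == (r2.r, r2.p)

    def test_p_agrees_with_exhaustive_enumeration(self):
        """Sampled permutation p matches the 120-permutation oracle (n=5)."""
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            X, Y = random_distance_matrix(5, rng), random_distance_matrix(5, rng)
            p_exact = exhaustive_mantel_p(X, Y)
            res = mantel(X, Y, n_perm=9999, seed=7)
            assert res.p == pytest.approx(p_exact, abs=0.01)

    def test_station_relabeling_invariance(self):
        rng = np.random.default_rng(3)
        X, Y = random_distance_matrix(8, rng), random_distance_matrix(8, rng)
        perm = rng.permutation(8)
        Xp = PairwiseMatrix(X.values[np.ix_(perm, perm)], X.labels)
        Yp = PairwiseMatrix(Y.values[np.ix_(perm, perm)], Y.labels)
        assert mantel(Xp, Yp, n_perm=1, seed=0).r == pytest.approx(
            mantel(X, Y, n_perm=1, seed=0).r
        )

    def test_matches_scikit_bio(self):
        """Observed statistic agrees with the scikit-bio implementation."""
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(4)
        X, Y = random_distance_matrix(10, rng), random_distance_matrix(10, rng)
        ours = mantel(X, Y, n_perm=999, seed=0)
        theirs_r, theirs_p, _ = skbio_distance.mantel(
            skbio_distance.DistanceMatrix(X.values, X.labels),
            skbio_distance.DistanceMatrix(Y.values, Y.labels),
            method="pearson",
            permutations=999,
            alternative="greater",
        )
        assert ours.r == pytest.approx(theirs_r, abs=1e-12)
        assert ours.p == pytest.approx(theirs_p, abs=0.05)


class TestPartialMantel:
    def test_reduces_to_plain_mantel_when_controls_orthogonal(self):
        # construct X, Y, Z with X,Y correlated and Z numerically orthogonal
        rng = np.random.default_rng(5)
        n = 12
        m = n * (n - 1) // 2
        labels = [f"s{i}" for i in range(n)]
        base = rng.normal(size=m)
        X = PairwiseMatrix.from_condensed(np.abs(base + 0.5 * rng.normal(size=m)), labels)
        Y = PairwiseMatrix.from_condensed(np.abs(base + 0.5 * rng.normal(size=m)), labels)
        xv, yv = X.condensed(), Y.condensed()
        # residualize z against the joint span of (1, x, y): exact orthogonality
        A = np.column_stack([np.ones(m), xv, yv])
        z = rng.normal(size=m)
        beta, *_ = np.linalg.lstsq(A, z, rcond=None)
        zc = z - A @ beta
        Z = PairwiseMatrix.from_condensed(zc - zc.min() + 0.1, labels)
        r_plain = mantel(X, Y, n_perm=1, seed=0).r
        r_part = partial_mantel(X, Y, Z, n_perm=1, seed=0).r
        assert r_part == pytest.approx(r_plain, abs=1e-9)

    def test_matches_residual_regression_oracle(self):
        """Closed-form partial r equals correlation of OLS residuals."""
        rng = np.random.default_rng(6)
        X = random_distance_matrix(9, rng)
        Y = random_distance_matrix(9, rng)
        Z = random_distance_matrix(9, rng)
        x, y, z = X.condensed(), Y.condensed(), Z.condensed()

        def residualize(v, w):
            A = np.column_stack([np.ones_like(w), w])
            beta, *_ = np.linalg.lstsq(A, v, rcond=None)
            return v - A @ beta

        oracle = pearson(residualize(x, z), residualize(y, z))
        res = partial_mantel(X, Y, Z, n_perm=9, seed=0)
        assert res.r == pytest.approx(oracle, abs=1e-12)

    def test_degenerate_control_rejected(self):
        rng = np.random.default_rng(7)
        X = random_distance_matrix(6, rng)
        Y = random_distance_matrix(6, rng)
        with pytest.raises(ValueError, match="degenerate"):
            partial_mantel(X, Y, X, n_perm=9)  # r_xz = 1


class TestMRM:
    def test_exact_linear_response(self):
        rng = np.random.default_rng(8)
        P1 = random_distance_matrix(7, rng)
        resp = PairwiseMatrix(2.0 * P1.values + 3.0, P1.labels)
        resp.values[np.diag_indices(7)] = 0.0
        res = mrm(resp, {"p1": P1}, n_perm=49, seed=0)
        assert res.coefficients["p1"] == pytest.approx(2.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_single_predictor_r2_equals_mantel_r_squared(self):
        rng = np.random.default_rng(9)
        X, Y = random_distance_matrix(8, rng), random_distance_matrix(8, rng)
        r = mantel(X, Y, n_perm=1, seed=0).r
        res = mrm(X, {"y": Y}, n_perm=1, seed=0)
        assert res.r_squared == pytest.approx(r**2, abs=1e-12)

    def test_collinear_predictors_rejected(self):
        rng = np.random.default_rng(10)
        P1 = random_distance_matrix(6, rng)
        P2 = PairwiseMatrix(2.0 * P1.values, P1.labels)
        resp = random_distance_matrix(6, rng)
        with pytest.raises(ValueError, match="collinear|rank"):
            mrm(resp, {"a": P1, "b": P2}, n_perm=9)

    def test_r2_p_agrees_with_exhaustive_enumeration(self):
        """Permutation p for R² matches full 120-permutation enumeration."""
        rng = np.random.default_rng(11)
        resp = random_distance_matrix(5, rng)
        pred = random_distance_matrix(5, rng)
        n = 5
        iu = np.triu_indices(n, k=1)
        x = pred.values[iu]
        A = np.column_stack([np.ones_like(x), x])

        def r2(yv):
            beta, *_ = np.linalg.lstsq(A, yv, rcond=None)
            resid = yv - A @ beta
            return 1 - resid @ resid / np.sum((yv - yv.mean()) ** 2)

        r2_obs = r2(resp.values[iu])
        hits = sum(
            r2(resp.values[np.ix_(p, p)][iu]) >= r2_obs - 1e-12
            for p in permutations(range(n))
        )
        p_exact = hits / 120
        res = mrm(resp, {"x": pred}, n_perm=9999, seed=3)
        assert res.r_squared_p == pytest.approx(p_exact, abs=0.01)


class TestAnosim:
    def separable(self, n_per=3, within=0.1, between=0.9):
        n = 2 * n_per
        D = np.full((n, n), between)
        D[:n_per, :n_per] = within
        D[n_per:, n_per:] = within
        np.fill_diagonal(D, 0.0)
        labels = [f"s{i}" for i in range(n)]
        return (
            PairwiseMatrix(D, labels),
            ["g1"] * n_per + ["g2"] * n_per,
        )

    def test_maximal_separation_gives_R_one(self):
        dissim, groups = self.separable()
        res = anosim(dissim, groups, n_perm=99, seed=0)
        assert res.R == pytest.approx(1.0)

    def test_singleton_group_rejected(self):
        dissim, _ = self.separable()
        with pytest.raises(ValueError, match="singleton"):
            anosim(dissim, ["a"] + ["b"] * 5, n_perm=9)

    def test_null_mean_R_near_zero(self):
        rng = np.random.default_rng(12)
        vals = []
        for _ in range(60):
            D = random_distance_matrix(10, rng)
            labels = rng.permutation(["a"] * 5 + ["b"] * 5)
            vals.append(anosim(D, labels, n_perm=1, seed=0).R)
        assert abs(np.mean(vals)) < 0.05

    def test_p_agrees_with_exhaustive_label_assignments(self):
        """p matches enumeration of all 20 balanced 2x3 assignments."""
        from itertools import combinations

        rng = np.random.default_rng(13)
        D = random_distance_matrix(6, rng)
        groups = ["a", "a", "a", "b", "b", "b"]
        res_obs = anosim(D, groups, n_perm=1, seed=0)
        stats = []
        for combo in combinations(range(6), 3):
            lab = np.array(["b"] * 6)
            lab[list(combo)] = "a"
            stats.append(anosim(D, lab, n_perm=1, seed=0).R)
        p_exact = np.mean([s >= res_obs.R - 1e-12 for s in stats])
        res = anosim(D, groups, n_perm=9999, seed=5)
        assert res.p == pytest.approx(p_exact, abs=0.01)

    def test_matches_scikit_bio(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(14)
        D = random_distance_matrix(9, rng)
        groups = ["a"] * 4 + ["b"] * 5
        ours = anosim(D, groups, n_perm=99, seed=0)
        theirs = skbio_distance.anosim(
            skbio_distance.DistanceMatrix(D.values, D.labels),
            grouping=list(groups),
            permutations=99,
        )
        assert ours.R == pytest.approx(theirs["test statistic"], abs=1e-12)
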