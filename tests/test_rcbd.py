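"""RCBD ANOVA/ANCOVA, polynomial contrasts, Duncan's test, pooled SEM."""

import numpy as np
import pytest

from proreq.rcbd import (
    DesignError,
    ancova_rcbd,
    duncan_mrt,
    lsd_threshold,
    orthogonal_poly_coefficients,
    polynomial_contrasts,
    pooled_sem,
    rcbd_anova,
)

CP_LEVELS = {"T1": 5.4, "T2": 6.6, "T3": 8.5, "T4": 10.5}


def random_design(rng, n_blocks=4, n_treat=4):
    blocks = np.repeat([f"b{i}" for i in range(n_blocks)], n_treat)
    treats = np.tile([f"t{j}" for j in range(n_treat)], n_blocks)
    y = rng.normal(10, 2, size=n_blocks * n_treat)
    return y, blocks, treats


def projection_ss(y, groups_list):
    """Brute-force sequential SS via explicit projection matrices."""
    n = len(y)
    y = np.asarray(y, float)

    def proj(X):
        return X @ np.linalg.pinv(X.T @ X) @ X.T

    def dummies(codes):
        levels = list(dict.fromkeys(codes))
        return np.column_stack([(np.asarray(codes) == l).astype(float) for l in levels])

    Xs = [np.ones((n, 1))]
    rss = []
    for g in groups_list:
        Xs.append(np.column_stack([Xs[-1], dummies(g)]))
    for X in Xs:
        P = proj(X)
        r = y - P @ y
        rss.append(float(r @ r))
    return [rss[i] - rss[i + 1] for i in range(len(groups_list))] + [rss[-1]]


class TestRcbdAnova:
    def test_constant_response_all_zero_ss(self):
        y = np.full(8, 5.0)
        res = rcbd_anova(y, ["b1"] * 4 + ["b2"] * 4, ["t1", "t2", "t3", "t4"] * 2)
        assert res.term("treatment").ss == pytest.approx(0.0, abs=1e-18)
        assert res.term("treatment").f is None  # F undefined at zero MSE

    def test_hand_computed_two_by_two(self):
        res = rcbd_anova([10, 12, 20, 22], ["b1", "b1", "b2", "b2"], ["t1", "t2", "t1", "t2"])
        assert res.term("block").ss == pytest.approx(100.0)
        assert res.term("treatment").ss == pytest.approx(4.0)
        assert res.term("error").ss == pytest.approx(0.0, abs=1e-18)

    def test_matches_projection_matrix_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            nb = rng.integers(2, 6)
            nt = rng.integers(2, 6)
            y, blocks, treats = random_design(rng, nb, nt)
            res = rcbd_anova(y, blocks, treats)
            ss_b, ss_t, ss_e = projection_ss(y, [blocks, treats])
            assert res.term("block").ss == pytest.approx(ss_b, abs=1e-10, rel=1e-10)
            assert res.term("treatment").ss == pytest.approx(ss_t, abs=1e-10, rel=1e-10)
            assert res.term("error").ss == pytest.approx(ss_e, abs=1e-10, rel=1e-10)

    def test_ss_decomposition_and_df_sum(self):
        rng = np.random.default_rng(2)
        y, blocks, treats = random_design(rng)
        res = rcbd_anova(y, blocks, treats)
        total = float(((y - y.mean()) ** 2).sum())
        assert res.ss_total == pytest.approx(total, rel=1e-10)
        assert sum(t.df for t in res.terms) == len(y) - 1

    def test_incomplete_design_rejected(self):
        with pytest.raises(DesignError, match="missing"):
            rcbd_anova([1, 2, 3], ["b1", "b1", "b2"], ["t1", "t2", "t1"])

    def test_too_few_levels_rejected(self):
        with pytest.raises(DesignError):
            rcbd_anova([1, 2], ["b1", "b1"], ["t1", "t2"])


class TestAncova:
    def test_constant_covariate_reduces_to_anova(self):
        rng = np.random.default_rng(3)
        y, blocks, treats = random_design(rng)
        plain = rcbd_anova(y, blocks, treats)
        adj = ancova_rcbd(y, blocks, treats, np.full(len(y), 7.0))
        assert adj.term("treatment").ss == pytest.approx(plain.term("treatment").ss)
        assert adj.treatment_means == plain.treatment_means

    def test_perfect_covariate_removes_error(self):
        rng = np.random.default_rng(4)
        y, blocks, treats = random_design(rng)
        res = ancova_rcbd(y, blocks, treats, y)
        assert res.term("error").ss == pytest.approx(0.0, abs=1e-16)

    def test_known_slope_recovered(self):
        rng = np.random.default_rng(5)
        slope_true = 2.5
        recovered = []
        for _ in range(50):
            _, blocks, treats = random_design(rng)
            x = rng.normal(0, 1, 16)
            treat_eff = {f"t{j}": j * 1.0 for j in range(4)}
            y = 10 + x * slope_true + np.array([treat_eff[t] for t in treats])
            y += rng.normal(0, 0.5, 16)
            res = ancova_rcbd(y, blocks, treats, x)
            recovered.append(res.covariate_slope)
        assert np.mean(recovered) == pytest.approx(slope_true, abs=0.05)

    def test_adjusted_means_move_toward_common_covariate(self):
        rng = np.random.default_rng(6)
        _, blocks, treats = random_design(rng)
        x = np.where(np.asarray(treats) == "t0", 2.0, 0.0) + rng.normal(0, 0.2, 16)
        y = 5 + 3 * x + rng.normal(0, 0.1, 16)
        res = ancova_rcbd(y, blocks, treats, x)
        # t0 has the inflated covariate, so its adjusted mean drops
        assert res.adjusted_treatment_means["t0"] < res.treatment_means["t0"]

    def test_collinear_covariate_rejected(self):
        _, blocks, treats = random_design(np.random.default_rng(7))
        x = (np.asarray(treats) == "t0").astype(float)
        with pytest.raises(ValueError, match="collinear"):
            ancova_rcbd(np.arange(16.0), blocks, treats, x)


class TestPolynomialContrasts:
    def test_equally_spaced_matches_classical_tables(self):
        C = orthogonal_poly_coefficients([1, 2, 3, 4])
        lin = C[0] / C[0][-1] * 3
        quad = C[1] / C[1][-1]
        assert lin == pytest.approx([-3, -1, 1, 3])
        assert quad == pytest.approx([1, -1, -1, 1])

    def test_unequal_cp_levels_are_orthogonal(self):
        C = orthogonal_poly_coefficients([5.4, 6.6, 8.5, 10.5])
        assert C[0] @ C[1] == pytest.approx(0.0, abs=1e-12)
        assert C[0].sum() == pytest.approx(0.0, abs=1e-12)
        assert C[1].sum() == pytest.approx(0.0, abs=1e-12)

    def test_collinear_means_have_zero_quadratic(self):
        levels = [5.4, 6.6, 8.5, 10.5]
        means = 1.0 + 0.3 * np.asarray(levels)
        res = polynomial_contrasts(levels, means, mse=0.5, n_per_mean=4, error_df=9)
        assert res["quadratic"]["estimate"] == pytest.approx(0.0, abs=1e-12)
        assert res["linear"]["p"] < 0.01

    def test_contrast_ss_sums_to_treatment_ss(self):
        # full polynomial set decomposes SS(treatment) on balanced data
        rng = np.random.default_rng(8)
        y, blocks, treats = random_design(rng)
        res = rcbd_anova(y, blocks, treats)
        means = [res.treatment_means[t] for t in ["t0", "t1", "t2", "t3"]]
        full = polynomial_contrasts(
            [5.4, 6.6, 8.5, 10.5], means, res.mse, res.n_per_mean, res.error_df,
            orders=("linear", "quadratic", "cubic"),
        )
        total = sum(v["ss"] for v in full.values())
        assert total == pytest.approx(res.term("treatment").ss, rel=1e-9)

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            orthogonal_poly_coefficients([1, 2], max_order=2)

    def test_null_rejection_rate_near_alpha(self):
        # no treatment effect: the linear-contrast test should reject at alpha
        rng = np.random.default_rng(9)
        alpha, n_rep = 0.05, 2000
        levels = [5.4, 6.6, 8.5, 10.5]
        rejections = 0
        for _ in range(n_rep):
            y, blocks, treats = random_design(rng)
            res = rcbd_anova(y, blocks, treats, treatment_levels=dict(zip(["t0", "t1", "t2", "t3"], levels)))
            if res.contrast_p["linear"] < alpha:
                rejections += 1
        rate = rejections / n_rep
        se = np.sqrt(alpha * (1 - alpha) / n_rep)
        assert abs(rate - alpha) <= 3 * se


class TestDuncan:
    def test_adg_letter_pattern(self):
        # printed group means with MSE reconstructed from the pooled SEM
        means = {"T1": -0.05, "T2": 0.16, "T3": 0.29, "T4": 0.51}
        letters = duncan_mrt(means, mse=4 * 0.05**2, n_per_mean=4, error_df=9)
        assert letters == {"T1": "c", "T2": "b", "T3": "b", "T4": "a"}

    def test_equal_means_share_letter(self):
        letters = duncan_mrt({"a": 1.0, "b": 1.0, "c": 1.0}, 0.5, 4, 9)
        assert len(set(letters.values())) == 1

    def test_far_separated_means_distinct(self):
        letters = duncan_mrt({"lo": 0.0, "hi": 100.0}, 0.01, 4, 9)
        assert letters["hi"] == "a" and letters["lo"] == "b"

    def test_shift_invariance(self):
        means = {"T1": -0.05, "T2": 0.16, "T3": 0.29, "T4": 0.51}
        shifted = {k: v + 17.3 for k, v in means.items()}
        assert duncan_mrt(means, 0.01, 4, 9) == duncan_mrt(shifted, 0.01, 4, 9)

    def test_scale_equivariance(self):
        means = {"T1": -0.05, "T2": 0.16, "T3": 0.29, "T4": 0.51}
        scaled = {k: 10 * v for k, v in means.items()}
        assert duncan_mrt(means, 0.01, 4, 9) == duncan_mrt(scaled, 100 * 0.01, 4, 9)

    def test_rejects_nonpositive_mse(self):
        with pytest.raises(ValueError):
            duncan_mrt({"a": 1, "b": 2}, 0.0, 4, 9)


class TestPooledSem:
    @pytest.mark.parametrize("mse, n, sem", [(0.01, 4, 0.05), (0, 5, 0), (4, 1, 2)])
    def test_values(self, mse, n, sem):
        assert pooled_sem(mse, n) == pytest.approx(sem)

    def test_lsd_is_positive_and_grows_with_mse(self):
        assert lsd_threshold(0.04, 4, 9) > lsd_threshold(0.01, 4, 9) > 0
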