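"""Surrogate shuffling, mixed models, LRT, Holm, partial correlations."""

import itertools
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_segment
from qrentrain import inference
from qrentrain.errors import DegenerateModelError, ValidationError
from qrentrain.inference import (
    MixedFitHandle,
    fit_random_intercept_model,
    holm_adjust,
    likelihood_ratio_test,
    partial_correlations,
    shuffle_pairs,
)
from qrentrain.io_formats import Role
from qrentrain.scoring import QAPair


def make_pairs(dyad, n, offset=0):
    pairs = []
    for i in range(n):
        q = make_segment(f"{dyad}q{i}", dyad, f"{dyad}a", Role.QUESTION,
                         offset + 2000 * i, offset + 2000 * i + 500)
        r = make_segment(f"{dyad}r{i}", dyad, f"{dyad}b", Role.RESPONSE,
                         offset + 2000 * i + 600, offset + 2000 * i + 1500)
        pairs.append(QAPair(f"{dyad}q{i}+{dyad}r{i}", q, r, dyad))
    return pairs


class TestShufflePairs:
    def test_two_pairs_have_unique_derangement(self):
        out = shuffle_pairs(make_pairs("d1", 2), seed=0)
        assert sorted(p.pair_id for p in out) == ["d1q0+d1r1", "d1q1+d1r0"]

    def test_no_fixed_points_exhaustive_small(self):
        for n in (2, 3, 4):
            pairs = make_pairs("d1", n)
            for seed in range(50):
                for p in shuffle_pairs(pairs, seed):
                    q_idx = p.question.segment_id[-1]
                    r_idx = p.response.segment_id[-1]
                    assert q_idx != r_idx

    def test_never_crosses_dyads(self):
        pairs = make_pairs("d1", 3) + make_pairs("d2", 3)
        for seed in range(20):
            for p in shuffle_pairs(pairs, seed):
                assert p.question.dyad_id == p.response.dyad_id == p.dyad_id

    def test_three_pair_derangements_equifrequent(self):
        """S3 has exactly two derangements; both appear ~50:50."""
        pairs = make_pairs("d1", 3)
        rng = np.random.default_rng(42)
        counts = {}
        n = 4000
        for _ in range(n):
            out = shuffle_pairs(pairs, rng)
            key = tuple(p.response.segment_id for p in out)
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 2
        for c in counts.values():
            # 3-sigma binomial band around 1/2
            assert abs(c - n / 2) < 3 * np.sqrt(n * 0.25)

    def test_single_pair_dyad_excluded(self, caplog):
        pairs = make_pairs("d1", 1) + make_pairs("d2", 2)
        out = shuffle_pairs(pairs, seed=0)
        assert {p.dyad_id for p in out} == {"d2"}

    def test_deterministic_under_seed(self):
        pairs = make_pairs("d1", 5)
        a = [p.pair_id for p in shuffle_pairs(pairs, seed=7)]
        b = [p.pair_id for p in shuffle_pairs(pairs, seed=7)]
        assert a == b


class TestHolm:
    def test_hand_computed_families(self):
        assert holm_adjust([0.01, 0.04]) == pytest.approx([0.02, 0.04])
        # two kinematic tests with raw p .022 and .038 both adjust to .044
        assert holm_adjust([0.022, 0.038]) == pytest.approx([0.044, 0.044])
        assert holm_adjust([0.038, 0.022]) == pytest.approx([0.044, 0.044])

    def test_single_p_unchanged(self):
        assert holm_adjust([0.3]) == pytest.approx([0.3])

    def test_monotone_and_never_below_raw(self, rng):
        for _ in range(50):
            p = rng.random(rng.integers(1, 8))
            adj = holm_adjust(p)
            assert (adj >= p - 1e-15).all()
            order = np.argsort(p)
            assert (np.diff(adj[order]) >= -1e-15).all()
            assert (adj <= 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            holm_adjust([0.2, 1.4])


def simulate_grouped(rng, n_groups=12, per_group=8, beta=0.0, tau=1.0,
                     sigma=1.0):
    rows = []
    for g in range(n_groups):
        u = rng.normal(0, tau)
        x = rng.normal(0, 1, per_group)
        y = 1.0 + beta * x + u + rng.normal(0, sigma, per_group)
        for xi, yi in zip(x, y):
            rows.append({"y": yi, "x": xi, "group": f"g{g}"})
    return pd.DataFrame(rows)


class TestMixedModel:
    def test_null_model_loglik_finite(self, rng):
        df = simulate_grouped(rng)
        h = fit_random_intercept_model(df, "y", None)
        assert np.isfinite(h.llf)
        assert h.fixed_effect is None

    def test_beta_recovered_within_2se_mostly(self):
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(30):
            df = simulate_grouped(rng, beta=0.7)
            h = fit_random_intercept_model(df, "y", "x")
            if abs(h.beta - 0.7) <= 2 * h.se:
                hits += 1
        assert hits >= 26

    def test_null_data_gives_small_t_in_distribution(self):
        rng = np.random.default_rng(4)
        ts = []
        for _ in range(30):
            df = simulate_grouped(rng, beta=0.0)
            ts.append(fit_random_intercept_model(df, "y", "x").t)
        assert np.mean(np.abs(ts)) < 1.5
        assert np.max(np.abs(ts)) < 4.5

    def test_zero_variance_predictor_flagged(self, rng):
        df = simulate_grouped(rng)
        df["x"] = 2.0
        with pytest.raises(DegenerateModelError):
            fit_random_intercept_model(df, "y", "x")

    def test_nonfinite_dependent_rejected(self, rng):
        df = simulate_grouped(rng)
        df.loc[0, "y"] = np.inf
        with pytest.raises(ValidationError):
            fit_random_intercept_model(df, "y", None)

    def test_matches_lme4_reference_fit(self, tmp_path):
        """Independent oracle: lme4's ML fit on the same small dataset."""
        rng = np.random.default_rng(11)
        df = simulate_grouped(rng, n_groups=10, per_group=6, beta=0.5)
        h = fit_random_intercept_model(df, "y", "x")
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = (
            "suppressMessages(library(lme4));"
            f"d <- read.csv('{csv}');"
            "m <- lmer(y ~ x + (1|group), data=d, REML=FALSE);"
            "cat(sprintf('%.6f %.6f', as.numeric(logLik(m)), fixef(m)[2]))"
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        llf_r, beta_r = map(float, out.stdout.split())
        assert h.llf == pytest.approx(llf_r, abs=1e-3)
        assert h.beta == pytest.approx(beta_r, abs=1e-4)


class TestLRT:
    def handle(self, llf, n_params, beta=0.0, se=1.0):
        return MixedFitHandle(llf=llf, n_params=n_params, n_obs=100,
                              dependent="y", fixed_effect="x", beta=beta,
                              se=se, t=beta / se)

    def test_identical_models_give_chi2_zero_p_one(self):
        r = likelihood_ratio_test(self.handle(-50.0, 3),
                                  self.handle(-50.0, 4))
        assert r.chi2 == 0.0
        assert r.p_raw == 1.0

    def test_chi2_384_df1_p_005(self):
        r = likelihood_ratio_test(self.handle(-50.0, 3),
                                  self.handle(-50.0 + 3.84 / 2, 4))
        assert r.p_raw == pytest.approx(0.0500, abs=5e-4)

    def test_non_nested_rejected(self):
        a = self.handle(-50.0, 4)
        b = self.handle(-49.0, 4)
        with pytest.raises(DegenerateModelError):
            likelihood_ratio_test(a, b)

    def test_type_i_error_near_nominal(self):
        """Null simulations reject at ~alpha (binomial band check)."""
        rng = np.random.default_rng(5)
        n_rep, rej = 150, 0
        for _ in range(n_rep):
            df = simulate_grouped(rng, n_groups=10, per_group=6, beta=0.0)
            null = fit_random_intercept_model(df, "y", None)
            full = fit_random_intercept_model(df, "y", "x")
            if likelihood_ratio_test(null, full).p_raw < 0.05:
                rej += 1
        band = 3 * np.sqrt(n_rep * 0.05 * 0.95)
        assert abs(rej - 0.05 * n_rep) <= band

    def test_chi2_invariant_to_affine_rescaling(self, rng):
        df = simulate_grouped(rng, beta=0.4)

        def lrt(frame):
            null = fit_random_intercept_model(frame, "y", None)
            full = fit_random_intercept_model(frame, "y", "x")
            return likelihood_ratio_test(null, full).chi2

        base = lrt(df)
        scaled = df.assign(y=3.5 * df.y - 11.0)
        assert lrt(scaled) == pytest.approx(base, abs=1e-4)


class TestPartialCorrelations:
    def frame(self, data):
        return pd.DataFrame(data, columns=["head_distance", "hand_distance",
                                           "f0_diff"])

    def test_independent_variables_near_zero(self, rng):
        df = self.frame(rng.normal(size=(4000, 3)))
        net = partial_correlations(df)
        off = net.partial_r[~np.eye(3, dtype=bool)]
        assert np.abs(off).max() < 0.06

    def test_matches_precision_matrix_closed_form(self, rng):
        cov = np.array([[1.0, 0.6, 0.3],
                        [0.6, 1.0, 0.5],
                        [0.3, 0.5, 1.0]])
        df = self.frame(rng.multivariate_normal(np.zeros(3), cov, 20000))
        net = partial_correlations(df)
        prec = np.linalg.inv(cov)
        for a, b in itertools.combinations(range(3), 2):
            expected = -prec[a, b] / np.sqrt(prec[a, a] * prec[b, b])
            assert net.partial_r[a, b] == pytest.approx(expected, abs=0.03)

    def test_matches_pingouin(self, rng):
        import pingouin

        df = self.frame(rng.normal(size=(500, 3)))
        df["head_distance"] += 0.5 * df["f0_diff"]
        net = partial_correlations(df)
        ref = pingouin.partial_corr(df, x="head_distance",
                                    y="hand_distance", covar="f0_diff")
        assert net.partial_r[0, 1] == pytest.approx(float(ref["r"].iloc[0]),
                                                    abs=1e-10)

    def test_uncorrelated_control_reduces_to_plain_r(self, rng):
        x = rng.normal(size=5000)
        y = 0.5 * x + rng.normal(size=5000)
        z = rng.normal(size=5000)  # independent of both
        df = self.frame(np.column_stack([x, y, z]))
        net = partial_correlations(df)
        plain = np.corrcoef(x, y)[0, 1]
        assert net.partial_r[0, 1] == pytest.approx(plain, abs=0.05)

    def test_degenerate_control_flagged(self):
        x = np.arange(10.0)
        df = self.frame(np.column_stack([x, x[::-1], x]))  # z == x exactly
        with pytest.raises(DegenerateModelError):
            partial_correlations(df)
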