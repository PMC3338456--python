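import math

import numpy as np
import pandas as pd
import pytest

from meadowsem.sem import (
    SEMData,
    SEMParams,
    SEMSpec,
    SEMStructureError,
    destandardize,
    log_likelihood,
    log_posterior,
    prepare_sem_data,
    sample_posterior,
    significance_flags,
    standardize,
)
from meadowsem.synthetic import StudyDesign, TrueParams, simulate


def single_row_data():
    return SEMData(
        W=np.array([0.5]), CP=np.array([0.3]), TP=np.array([-0.2]),
        ADF=np.array([0.1]), P=np.array([0.4]), U=np.array([-0.1]),
        O=np.array([1]),
        meadow_idx=np.array([0]), allot_idx=np.array([0]), year_idx=np.array([0]),
        n_meadow=1, n_allot=1, n_year=1,
    )


def unit_params(n=1):
    return SEMParams(
        lam_tp=0.0, lam_adf=0.0,
        sigma_cp=1.0, sigma_tp=1.0, sigma_adf=1.0,
        gamma_wq=0.0, gamma_wp=0.0, sigma_q=1.0, sigma_p=1.0, rho_qp=0.0,
        beta_qu=0.0, beta_pu=0.0, sigma_u=1.0,
        sigma_meadow=1.0, sigma_allotment=1.0, sigma_year=1.0,
        alpha=0.0, beta_wo=0.0, beta_uo=0.0,
        Q=np.full(n, 0.2), u_meadow=np.zeros(1), u_allotment=np.zeros(1),
        u_year=np.zeros(1),
    )


class TestStandardize:
    def test_symmetric_triple(self):
        out, rec = standardize(pd.DataFrame({"a": [2.0, 4.0, 6.0]}))
        assert out["a"].tolist() == pytest.approx([-1.0, 0.0, 1.0])
        assert rec.means["a"] == 4.0 and rec.sds["a"] == 2.0

    def test_idempotence(self, rng):
        x = rng.normal(size=50)
        x = (x - x.mean()) / x.std(ddof=1)
        out, _ = standardize(pd.DataFrame({"a": x}))
        assert out["a"].to_numpy() == pytest.approx(x, abs=1e-12)

    def test_roundtrip(self, rng):
        df = pd.DataFrame({"a": rng.normal(3, 2, 40), "b": rng.uniform(0, 9, 40)})
        out, rec = standardize(df)
        back = destandardize(out, rec)
        assert back["a"].to_numpy() == pytest.approx(df["a"].to_numpy(), abs=1e-10)
        assert back["b"].to_numpy() == pytest.approx(df["b"].to_numpy(), abs=1e-10)

    def test_zero_variance_names_column(self):
        with pytest.raises(ValueError, match="badcol"):
            standardize(pd.DataFrame({"badcol": [1.0, 1.0, 1.0]}))


class TestSpec:
    def test_cycle_rejected(self):
        with pytest.raises(SEMStructureError, match="acyclic"):
            SEMSpec(edges=(("W", "Q"), ("Q", "U"), ("U", "W")))

    def test_unknown_node_rejected(self):
        with pytest.raises(SEMStructureError):
            SEMSpec(edges=(("W", "Z"),))

    def test_from_dict(self):
        spec = SEMSpec.from_dict({"season": "late", "edges": [["W", "Q"], ["W", "O"]]})
        assert spec.season == "late"
        assert ("W", "O") in spec.edges

    def test_from_yaml(self, tmp_path):
        path = tmp_path / "spec.yaml"
        path.write_text("season: early\nfixed_loading: cp\n")
        spec = SEMSpec.from_yaml(path)
        assert spec.season == "early"
        assert spec.edges == SEMSpec().edges


class TestLogPosterior:
    def test_single_row_hand_sum(self):
        data = single_row_data()
        params = unit_params()

        def lognorm(x, mu, sd):
            return -0.5 * math.log(2 * math.pi) - math.log(sd) - 0.5 * ((x - mu) / sd) ** 2

        hand = 0.0
        hand += lognorm(0.3, 0.2, 1)  # CP | Q, fixed loading 1
        hand += lognorm(-0.2, 0.0, 1) + lognorm(0.1, 0.0, 1)  # TP, ADF
        hand += lognorm(0.2, 0.0, 1) + lognorm(0.4, 0.0, 1)  # (Q, P) | W, rho=0
        hand += lognorm(-0.1, 0.0, 1)  # U
        hand += math.log(0.5)  # occupancy at logit 0
        hand += 3 * lognorm(0.0, 0.0, 1)  # random intercepts
        hand += 9 * lognorm(0.0, 0.0, 10.0)  # coefficient priors
        hand += 9 * (0.5 * math.log(2 / math.pi) - 0.5)  # half-normal(0,1) at sd=1
        hand += math.log(0.5)  # uniform(-1,1) prior on rho
        assert log_posterior(SEMSpec(), params, data) == pytest.approx(hand, abs=1e-10)

    def test_doubling_rows_doubles_loglik(self, rng):
        n = 6
        data = SEMData(
            W=rng.normal(size=n), CP=rng.normal(size=n), TP=rng.normal(size=n),
            ADF=rng.normal(size=n), P=rng.normal(size=n), U=rng.normal(size=n),
            O=rng.integers(0, 2, n),
            meadow_idx=np.zeros(n, int), allot_idx=np.zeros(n, int),
            year_idx=np.zeros(n, int), n_meadow=1, n_allot=1, n_year=1,
        )
        doubled = SEMData(
            W=np.r_[data.W, data.W], CP=np.r_[data.CP, data.CP],
            TP=np.r_[data.TP, data.TP], ADF=np.r_[data.ADF, data.ADF],
            P=np.r_[data.P, data.P], U=np.r_[data.U, data.U],
            O=np.r_[data.O, data.O],
            meadow_idx=np.zeros(2 * n, int), allot_idx=np.zeros(2 * n, int),
            year_idx=np.zeros(2 * n, int), n_meadow=1, n_allot=1, n_year=1,
        )
        p1 = unit_params(n)
        p2 = unit_params(2 * n)
        assert log_likelihood(p2, doubled) == pytest.approx(
            2 * log_likelihood(p1, data), abs=1e-10
        )

    def test_nonpositive_sd_rejected_before_evaluation(self):
        params = unit_params()
        params.sigma_q = 0.0
        with pytest.raises(ValueError, match="sigma_q"):
            log_posterior(SEMSpec(), params, single_row_data())

    def test_dimension_mismatch(self):
        params = unit_params()
        params.Q = np.zeros(3)
        with pytest.raises(SEMStructureError):
            log_posterior(SEMSpec(), params, single_row_data())

    def test_sign_symmetry_broken_only_by_fixed_loading(self, rng):
        n = 8
        data = SEMData(
            W=rng.normal(size=n), CP=rng.normal(size=n), TP=rng.normal(size=n),
            ADF=rng.normal(size=n), P=rng.normal(size=n), U=rng.normal(size=n),
            O=rng.integers(0, 2, n),
            meadow_idx=np.zeros(n, int), allot_idx=np.zeros(n, int),
            year_idx=np.zeros(n, int), n_meadow=1, n_allot=1, n_year=1,
        )
        p = unit_params(n)
        p.lam_tp, p.lam_adf = 0.8, -0.6
        p.gamma_wq, p.beta_qu, p.rho_qp = -0.5, 0.4, 0.2
        p.Q = rng.normal(size=n)
        base = log_likelihood(p, data)

        flipped = unit_params(n)
        flipped.lam_tp, flipped.lam_adf = -0.8, 0.6
        flipped.gamma_wq, flipped.beta_qu, flipped.rho_qp = 0.5, -0.4, -0.2
        flipped.Q = -p.Q
        flipped.lam_cp = -1.0  # flipping the fixed loading restores symmetry
        assert log_likelihood(flipped, data) == pytest.approx(base, abs=1e-10)

        flipped.lam_cp = 1.0  # the fixed loading breaks the symmetry
        assert log_likelihood(flipped, data) != pytest.approx(base, abs=1e-6)


class TestPrepare:
    def test_prepare_columns_and_groups(self, default_dataset):
        _, my, _ = default_dataset
        data = prepare_sem_data(my, "early")
        assert data.n == len(my)
        assert data.n_meadow == 24 and data.n_allot == 3 and data.n_year == 2
        for arr in (data.W, data.CP, data.TP, data.ADF, data.P, data.U):
            assert arr.mean() == pytest.approx(0.0, abs=1e-10)
            assert arr.std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_missing_column_rejected(self, default_dataset):
        _, my, _ = default_dataset
        with pytest.raises(SEMStructureError, match="missing"):
            prepare_sem_data(my.drop(columns=["cp_mid"]), "mid")


class TestSampler:
    def test_determinism(self, default_dataset):
        _, my, _ = default_dataset
        data = prepare_sem_data(my, "mid")
        kw = dict(n_chains=2, n_iter=150, burn_in=50, seed=99)
        s1 = sample_posterior(SEMSpec(), data, **kw)
        s2 = sample_posterior(SEMSpec(), data, **kw)
        for name in s1.params:
            np.testing.assert_array_equal(s1.params[name], s2.params[name])
        np.testing.assert_array_equal(s1.lp, s2.lp)

    def test_arg_validation(self, default_dataset):
        _, my, _ = default_dataset
        data = prepare_sem_data(my, "mid")
        with pytest.raises(ValueError):
            sample_posterior(SEMSpec(), data, n_chains=1)
        with pytest.raises(ValueError):
            sample_posterior(SEMSpec(), data, n_iter=100, burn_in=100)

    def test_cached_lp_matches_independent_evaluation(self, sem_fit):
        data, samples = sem_fit
        from meadowsem.pipeline import _state_at

        for it in (1200, 1700, 2300):
            state = _state_at(samples, 0, it)
            assert log_posterior(SEMSpec(), state, data) == pytest.approx(
                samples.lp[0, it], abs=1e-8
            )

    def test_conjugate_closed_form_gamma_wp(self, sem_fit):
        # plug-in conjugate posterior mean for the wetness->productivity
        # path: N(0,100) prior, Gaussian likelihood, rho ~ 0 in the
        # generating process
        data, samples = sem_fit
        draws = samples.flat("gamma_wp")
        sigma_p = float(samples.flat("sigma_p").mean())
        closed = float(data.W @ data.P) / (
            float(data.W @ data.W) + sigma_p**2 / 100.0
        )
        assert abs(draws.mean() - closed) < 3 * draws.std()

    def test_conjugate_closed_form_gamma_wq_tight_indicators(self):
        # with nearly noiseless indicators the latent is pinned to CP and
        # the quality path posterior has the conjugate regression form
        design = StudyDesign(years=(2007, 2008))
        params = TrueParams(sigma_cp=0.02, sigma_tp=0.02, sigma_adf=0.02)
        _, my, _ = simulate(design, params, seed=21)
        data = prepare_sem_data(my, "mid")
        samples = sample_posterior(
            SEMSpec(), data, n_chains=2, n_iter=2000, burn_in=800, seed=3
        )
        draws = samples.flat("gamma_wq")
        sigma_q = float(samples.flat("sigma_q").mean())
        closed = float(data.W @ data.CP) / (
            float(data.W @ data.W) + sigma_q**2 / 100.0
        )
        assert abs(draws.mean() - closed) < 3 * draws.std()

    def test_recovery_rmse_decreases_with_sample_size(self):
        from meadowsem.synthetic import implied_standardized_truth

        truth = implied_standardized_truth(TrueParams(), "mid", n_meadows=4000)
        check = ("gamma_wq", "gamma_wp", "beta_qu", "beta_pu", "beta_wo")
        rmse = {}
        for n_meadows in (24, 96, 384):
            errs = []
            for seed in range(3):
                design = StudyDesign(
                    n_allotments=3,
                    meadows_per_allotment=(n_meadows // 3,) * 3,
                    years=(2007, 2008),
                )
                _, my, _ = simulate(design, TrueParams(), seed=1000 + seed)
                data = prepare_sem_data(my, "mid")
                samples = sample_posterior(
                    SEMSpec(), data, n_chains=2, n_iter=1200, burn_in=500,
                    seed=seed,
                )
                errs.extend(
                    float(samples.flat(name).mean()) - truth[name] for name in check
                )
            rmse[n_meadows] = float(np.sqrt(np.mean(np.square(errs))))
        assert rmse[384] < rmse[96] < rmse[24]


class TestSignificanceFlags:
    def test_degenerate_positive_mass(self):
        flags = significance_flags({"x": np.ones(1000)}, names=["x"])
        assert flags["x"] == "**"

    def test_symmetric_draws_ns(self):
        draws = np.r_[np.linspace(-1, 1, 1001)]
        assert significance_flags({"x": draws}, names=["x"])["x"] == "NS"

    def test_normal_quantile_check(self):
        draws = np.random.default_rng(8).normal(0.2, 0.1, 200_000)
        # analytic 95% interval (0.004, 0.396) excludes zero
        assert significance_flags({"x": draws}, names=["x"])["x"] == "**"

    def test_star_band(self):
        # mass placed so 90% CI excludes 0 but 95% does not
        rng = np.random.default_rng(5)
        draws = rng.normal(0.165, 0.1, 400_000)
        assert significance_flags({"x": draws}, names=["x"])["x"] == "*"

    def test_samples_export_frame(self, sem_fit):
        _, samples = sem_fit
        frame = samples.to_frame()
        assert len(frame) == samples.n_chains * samples.n_iter
        assert {"chain", "iteration", "gamma_wq", "lp"} <= set(frame.columns)

    def test_posterior_fit_flags(self, sem_fit):
        _, samples = sem_fit
        flags = significance_flags(samples)
        assert flags["gamma_wq"] == "**"
        assert flags["gamma_wp"] == "**"
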