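"""Unit tests of the RAM path-model engine."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from riclpm import (
    PathModel,
    SampleMoments,
    baseline_fit,
    fit_indices,
    fit_ml,
    implied_moments,
    model_df,
)
from riclpm.sem_core import sample_moments


def ar1_chain(b="b", q="q", v1="v1", n_waves=4, means=0.0):
    """Univariate AR(1) chain over observed nodes y1..y4."""
    nodes = tuple(f"y{i}" for i in range(1, n_waves + 1))
    paths = tuple((f"y{i}", f"y{i+1}", b) for i in range(1, n_waves))
    covs = ((nodes[0], nodes[0], v1),) + tuple(
        (nodes[i], nodes[i], q) for i in range(1, n_waves)
    )
    mean_entries = tuple((nd, means) for nd in nodes)
    return PathModel(
        nodes=nodes, latent=frozenset(), paths=paths, covs=covs,
        means=mean_entries, selection=nodes,
    )


class TestImpliedMoments:
    def test_identity_case(self):
        """No paths: sigma = diag of the variances, mu = the means."""
        model = PathModel(
            nodes=("x", "y"), latent=frozenset(), paths=(),
            covs=(("x", "x", "vx"), ("y", "y", "vy")),
            means=(("x", "mx"), ("y", "my")), selection=("x", "y"),
        )
        mp = implied_moments(model, {"vx": 2.0, "vy": 5.0, "mx": 1.0, "my": -3.0})
        np.testing.assert_allclose(mp.sigma, np.diag([2.0, 5.0]))
        np.testing.assert_allclose(mp.mu, [1.0, -3.0])

    def test_ar1_closed_form(self):
        """Stationary AR(1): cov(t, t+k) = b^k var, var = q/(1-b^2)."""
        b, q = 0.6, 1.0
        v1 = q / (1 - b**2)
        mp = implied_moments(ar1_chain(), {"b": b, "q": q, "v1": v1})
        for i in range(4):
            for j in range(4):
                assert mp.sigma[i, j] == pytest.approx(b ** abs(i - j) * v1)

    def test_ar1_monte_carlo(self):
        """Implied AR(1) moments agree with simulated chains."""
        b, q, v1 = 0.5, 2.0, 3.0
        n = 200_000
        rng = np.random.default_rng(42)
        y = np.empty((n, 4))
        y[:, 0] = rng.normal(0, np.sqrt(v1), n)
        for t in range(3):
            y[:, t + 1] = b * y[:, t] + rng.normal(0, np.sqrt(q), n)
        mp = implied_moments(ar1_chain(), {"b": b, "q": q, "v1": v1})
        emp = np.cov(y, rowvar=False)
        mc_se = np.sqrt(
            (np.outer(np.diag(mp.sigma), np.diag(mp.sigma)) + mp.sigma**2) / n
        )
        assert (np.abs(emp - mp.sigma) < 3 * mc_se).all()

    def test_missing_label_raises_with_name(self):
        with pytest.raises(KeyError, match="v1"):
            implied_moments(ar1_chain(), {"b": 0.5, "q": 1.0})

    def test_cyclic_model_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            PathModel(
                nodes=("a", "b"), latent=frozenset(),
                paths=(("a", "b", "p"), ("b", "a", "r")),
                covs=(("a", "a", 1.0), ("b", "b", 1.0)),
                means=(), selection=("a", "b"),
            )


class TestModelDf:
    def test_saturated_model_zero_df(self):
        nodes = ("x", "y", "z")
        covs = tuple(
            (a, b, f"c_{a}{b}") for i, a in enumerate(nodes) for b in nodes[i:]
        )
        means = tuple((n, f"m_{n}") for n in nodes)
        model = PathModel(nodes=nodes, latent=frozenset(), paths=(),
                          covs=covs, means=means, selection=nodes)
        assert model_df(model) == 0

    def test_overparameterized_warns(self):
        model = PathModel(
            nodes=("x",), latent=frozenset(), paths=(),
            covs=(("x", "x", "v"),),
            means=(("x", "m1"),), selection=("x",),
        )
        # 1 observed -> 2 moments; add a redundant free path label via a
        # second latent to exceed the moment count
        model = PathModel(
            nodes=("x", "f"), latent=frozenset({"f"}),
            paths=(("f", "x", "l"),),
            covs=(("x", "x", "v"), ("f", "f", "vf")),
            means=(("x", "m1"),), selection=("x",),
        )
        with pytest.warns(UserWarning, match="over-parameterized"):
            assert model_df(model) == -2

    def test_df_equals_brute_force_label_count(self, riclpm_model, ri_ar_model):
        for model in (riclpm_model, ri_ar_model):
            labels = {
                v
                for group in (model.paths, model.covs)
                for *_, v in group
                if isinstance(v, str)
            } | {v for _, v in model.means if isinstance(v, str)}
            p = len(model.selection)
            assert model_df(model) == p * (p + 3) // 2 - len(labels)


class TestFitMl:
    def test_saturated_fit_reproduces_sample(self):
        rng = np.random.default_rng(0)
        x = rng.multivariate_normal([1, 2], [[2, 0.5], [0.5, 1]], size=400)
        df = pd.DataFrame(x, columns=["x", "y"])
        model = PathModel(
            nodes=("x", "y"), latent=frozenset(), paths=(),
            covs=(("x", "x", "vx"), ("y", "y", "vy"), ("x", "y", "cxy")),
            means=(("x", "mx"), ("y", "my")), selection=("x", "y"),
        )
        fit = fit_ml(model, df)
        sm = sample_moments(df)
        assert fit.statistic == pytest.approx(0.0, abs=1e-6)
        assert fit.df == 0
        est = fit.estimates
        assert est["vx"] == pytest.approx(sm.cov[0, 0], rel=1e-4)
        assert est["cxy"] == pytest.approx(sm.cov[0, 1], rel=1e-3)
        assert est["mx"] == pytest.approx(sm.mean[0], rel=1e-4)

    def test_ar1_parameter_recovery(self):
        b, q, v1 = 0.5, 1.0, 4.0
        rng = np.random.default_rng(7)
        n = 2000
        y = np.empty((n, 4))
        y[:, 0] = rng.normal(0, np.sqrt(v1), n)
        for t in range(3):
            y[:, t + 1] = b * y[:, t] + rng.normal(0, np.sqrt(q), n)
        fit = fit_ml(ar1_chain(means="mu"), pd.DataFrame(y, columns=[f"y{i}" for i in range(1, 5)]))
        assert fit.converged
        for lab, true in (("b", b), ("q", q), ("v1", v1)):
            row = fit.params.loc[lab]
            assert abs(row["estimate"] - true) < 3 * row["se"]

    def test_sample_too_small_rejected(self):
        df = pd.DataFrame(np.eye(3), columns=["y1", "y2", "y3"])
        with pytest.raises(ValueError, match="exceed"):
            fit_ml(ar1_chain(n_waves=3), df)


class TestBaselineAndIndices:
    def test_diagonal_sample_gives_zero_baseline(self):
        sm = SampleMoments(mean=np.zeros(3), cov=np.diag([1.0, 2.0, 3.0]), n=50)
        T_b, df_b = baseline_fit(sm)
        assert T_b == pytest.approx(0.0, abs=1e-12)
        assert df_b == 3 * 6 // 2 - 2 * 3

    def test_baseline_df_for_eight_variables(self):
        sm = SampleMoments(mean=np.zeros(8), cov=np.eye(8), n=100)
        _, df_b = baseline_fit(sm)
        assert df_b == 28  # 8*11/2 - 2*8

    def test_baseline_dominates_fitted_model(self, truth):
        from riclpm import build_riclpm, generate_latent_panel

        model = build_riclpm()
        panel = generate_latent_panel(truth, 400, seed=5)
        fit = fit_ml(model, panel[list(model.selection)])
        assert fit.baseline_statistic >= fit.statistic

    def test_perfect_fit_gives_cfi_one(self):
        fi = fit_indices(T=12.0, df=12, T_b=300.0, df_b=28)
        assert fi.cfi == 1.0

    def test_no_improvement_gives_cfi_zero(self):
        fi = fit_indices(T=300.0, df=28, T_b=300.0, df_b=28)
        assert fi.cfi == 0.0

    @pytest.mark.parametrize("T,df,T_b,df_b", [
        (44.646, 12, 320.0, 28),
        (27.541, 20, 150.0, 28),
        (5.0, 10, 80.0, 28),
    ])
    def test_indices_match_independent_transcription(self, T, df, T_b, df_b):
        """Second, independent transcription of the CFI/TLI formulas."""
        fi = fit_indices(T, df, T_b, df_b)
        cfi_oracle = 1 - max(T - df, 0) / max(T_b - df_b, T - df, 0)
        tli_oracle = ((T_b / df_b) - (T / df)) / ((T_b / df_b) - 1)
        assert fi.cfi == pytest.approx(cfi_oracle)
        assert fi.tli_raw == pytest.approx(tli_oracle)

    def test_zero_model_df_flags_undefined(self):
        fi = fit_indices(T=0.0, df=0, T_b=10.0, df_b=5)
        assert fi.cfi is None and fi.tli is None

    def test_zero_baseline_df_rejected(self):
        with pytest.raises(ValueError):
            fit_indices(1.0, 1, 1.0, 0)


class TestStandardize:
    def test_ar1_unit_variances_standardized_equals_unstandardized(self):
        """Stationary unit variances: standardized coefficient = b."""
        b = 0.5
        rng = np.random.default_rng(3)
        n = 5000
        y = np.empty((n, 4))
        y[:, 0] = rng.normal(0, 1, n)
        for t in range(3):
            y[:, t + 1] = b * y[:, t] + rng.normal(0, np.sqrt(1 - b**2), n)
        fit = fit_ml(ar1_chain(means="mu"),
                     pd.DataFrame(y, columns=[f"y{i}" for i in range(1, 5)]))
        free = fit.paths[fit.paths["free"]]
        for _, row in free.iterrows():
            assert row["std"] == pytest.approx(row["estimate"], abs=0.05)
            assert row["std"] == pytest.approx(b, abs=0.06)

    def test_sign_preserved(self, truth):
        from riclpm import build_riclpm, generate_latent_panel

        model = build_riclpm()
        panel = generate_latent_panel(truth, 500, seed=21)
        fit = fit_ml(model, panel[list(model.selection)])
        free = fit.paths[fit.paths["free"]]
        assert (np.sign(free["std"]) == np.sign(free["estimate"])).all()


def test_pathmodel_json_roundtrip(riclpm_model):
    restored = PathModel.from_json(riclpm_model.to_json())
    assert restored == riclpm_model
    assert restored.free_labels() == riclpm_model.free_labels()


def test_likelihood_ratio_coherence(truth):
    """A constrained model never fits better than the model nesting it."""
    from riclpm import RiclpmOptions, build_riclpm, generate_latent_panel

    panel = generate_latent_panel(truth, 600, seed=9)
    full = build_riclpm(RiclpmOptions())
    constrained = build_riclpm(RiclpmOptions(cross_lags=False))
    cols = list(full.selection)
    T_full = fit_ml(full, panel[cols]).statistic
    T_con = fit_ml(constrained, panel[cols]).statistic
    assert T_con >= T_full - 1e-6
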