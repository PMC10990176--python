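"""Builders for the two competing panel models and effect-size labelling.

Both models describe 2 processes (TSK kinesiophobia total and total physical
activity in minutes/day) observed at 4 waves (weeks 1, 3, 6, 12 after
hospital discharge), 8 observed variables in all.

``build_riclpm`` constructs the random-intercept cross-lagged panel model:
each observed score is decomposed into a grand mean, a stable between-person
random intercept (loadings fixed to 1), and a fluctuating within-person
component; the within components carry autoregressive and cross-lagged paths
between consecutive waves.  With the default free-parameter inventory
(random-intercept variances + covariance, wave-1 within (co)variances, 4
lagged paths and 2 residual variances per transition, residual covariances
fixed to 0, 8 means) the model has 32 free parameters and 12 degrees of
freedom.  Freeing the dynamic residual covariances (the textbook variant)
is available as a switch and costs 3 df.

``build_ri_ar`` constructs the alternative trait + state model: kinesiophobia
is a pure random intercept (trait) with free per-wave residual variances and
no autoregression, physical activity is an observed AR(1) chain with no
random intercept, and a free concurrent TSK-residual<->PA covariance at each
wave lets any association show up.  24 free parameters, 20 degrees of
freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sem_core import PathModel, FitResult, SampleMoments, fit_ml, model_df
from .missing_data import ImputationSet, rubin_pool

__all__ = [
    "RiclpmOptions",
    "WAVE_WEEKS",
    "OBSERVED_ORDER",
    "build_riclpm",
    "build_ri_ar",
    "effect_size_label",
    "fit_panel",
    "PanelFit",
]

WAVE_WEEKS = (1, 3, 6, 12)
OBSERVED_ORDER = tuple(f"tsk_wk{w}" for w in WAVE_WEEKS) + tuple(
    f"pa_wk{w}" for w in WAVE_WEEKS
)


@dataclass(frozen=True)
class RiclpmOptions:
    """Switches for the model builders.

    cross_lags
        Include the 6 cross-lagged paths (RI-CLPM only).
    dynamic_residual_covariances
        Free the within-wave residual covariance at waves 2-4 (RI-CLPM
        only); fixed to 0 under defaults.
    ri_covariance
        Free the covariance between the two random intercepts (RI-CLPM) /
        keep the 4 concurrent covariances (alternative model).
    """

    n_waves: int = 4
    cross_lags: bool = True
    dynamic_residual_covariances: bool = False
    ri_covariance: bool = True
    wave_weeks: tuple[int, ...] = WAVE_WEEKS

    def __post_init__(self):
        if self.n_waves < 2:
            raise ValueError("need at least 2 waves")
        if len(self.wave_weeks) < self.n_waves:
            object.__setattr__(
                self, "wave_weeks", tuple(range(1, self.n_waves + 1))
            )


def build_riclpm(opts: RiclpmOptions = RiclpmOptions()) -> PathModel:
    """Random-intercept cross-lagged panel model as a PathModel."""
    W = opts.wave_weeks[: opts.n_waves]
    obs = [f"tsk_wk{w}" for w in W] + [f"pa_wk{w}" for w in W]
    within = [f"w_tsk_wk{w}" for w in W] + [f"w_pa_wk{w}" for w in W]
    latents = ["ri_tsk", "ri_pa"] + within
    nodes = tuple(obs + latents)

    paths: list[tuple[str, str, float | str]] = []
    covs: list[tuple[str, str, float | str]] = []
    means: list[tuple[str, float | str]] = []

    for w in W:
        # measurement: observed = 1*RI + 1*within, no measurement error
        paths.append(("ri_tsk", f"tsk_wk{w}", 1.0))
        paths.append((f"w_tsk_wk{w}", f"tsk_wk{w}", 1.0))
        paths.append(("ri_pa", f"pa_wk{w}", 1.0))
        paths.append((f"w_pa_wk{w}", f"pa_wk{w}", 1.0))
        means.append((f"tsk_wk{w}", f"mu_tsk_wk{w}"))
        means.append((f"pa_wk{w}", f"mu_pa_wk{w}"))

    covs.append(("ri_tsk", "ri_tsk", "var_ri_tsk"))
    covs.append(("ri_pa", "ri_pa", "var_ri_pa"))
    if opts.ri_covariance:
        covs.append(("ri_tsk", "ri_pa", "cov_ri"))
    else:
        covs.append(("ri_tsk", "ri_pa", 0.0))

    w1 = W[0]
    covs.append((f"w_tsk_wk{w1}", f"w_tsk_wk{w1}", f"var_w_tsk_wk{w1}"))
    covs.append((f"w_pa_wk{w1}", f"w_pa_wk{w1}", f"var_w_pa_wk{w1}"))
    covs.append((f"w_tsk_wk{w1}", f"w_pa_wk{w1}", f"cov_w_wk{w1}"))

    for prev, nxt in zip(W[:-1], W[1:]):
        paths.append((f"w_tsk_wk{prev}", f"w_tsk_wk{nxt}", f"a_tsk_wk{nxt}"))
        paths.append((f"w_pa_wk{prev}", f"w_pa_wk{nxt}", f"a_pa_wk{nxt}"))
        if opts.cross_lags:
            paths.append((f"w_pa_wk{prev}", f"w_tsk_wk{nxt}", f"c_pa_tsk_wk{nxt}"))
            paths.append((f"w_tsk_wk{prev}", f"w_pa_wk{nxt}", f"c_tsk_pa_wk{nxt}"))
        covs.append((f"w_tsk_wk{nxt}", f"w_tsk_wk{nxt}", f"rvar_tsk_wk{nxt}"))
        covs.append((f"w_pa_wk{nxt}", f"w_pa_wk{nxt}", f"rvar_pa_wk{nxt}"))
        covs.append(
            (f"w_tsk_wk{nxt}", f"w_pa_wk{nxt}",
             f"rcov_wk{nxt}" if opts.dynamic_residual_covariances else 0.0)
        )

    return PathModel(
        nodes=nodes,
        latent=frozenset(latents),
        paths=tuple(paths),
        covs=tuple(covs),
        means=tuple(means),
        selection=tuple(obs),
    )


def build_ri_ar(opts: RiclpmOptions = RiclpmOptions()) -> PathModel:
    """Trait-kinesiophobia + autoregressive-PA alternative model."""
    W = opts.wave_weeks[: opts.n_waves]
    obs = [f"tsk_wk{w}" for w in W] + [f"pa_wk{w}" for w in W]
    nodes = tuple(obs + ["ri_tsk"])

    paths: list[tuple[str, str, float | str]] = []
    covs: list[tuple[str, str, float | str]] = []
    means: list[tuple[str, float | str]] = []

    covs.append(("ri_tsk", "ri_tsk", "var_ri_tsk"))
    for w in W:
        paths.append(("ri_tsk", f"tsk_wk{w}", 1.0))
        covs.append((f"tsk_wk{w}", f"tsk_wk{w}", f"rvar_tsk_wk{w}"))
        means.append((f"tsk_wk{w}", f"mu_tsk_wk{w}"))
        means.append((f"pa_wk{w}", f"mu_pa_wk{w}"))
        if opts.ri_covariance:
            # concurrent association between the TSK residual and PA
            covs.append((f"tsk_wk{w}", f"pa_wk{w}", f"cov_tsk_pa_wk{w}"))

    w1 = W[0]
    covs.append((f"pa_wk{w1}", f"pa_wk{w1}", f"var_pa_wk{w1}"))
    for prev, nxt in zip(W[:-1], W[1:]):
        paths.append((f"pa_wk{prev}", f"pa_wk{nxt}", f"a_pa_wk{nxt}"))
        covs.append((f"pa_wk{nxt}", f"pa_wk{nxt}", f"rvar_pa_wk{nxt}"))

    return PathModel(
        nodes=nodes,
        latent=frozenset({"ri_tsk"}),
        paths=tuple(paths),
        covs=tuple(covs),
        means=tuple(means),
        selection=tuple(obs),
    )


def effect_size_label(beta: float) -> str:
    """Label a standardized beta: small < 0.30 <= moderate < 0.50 <= large.

    Applied to the absolute value.  The conventional printed bands leave a
    gap between 0.29 and 0.30; [0, 0.30) is assigned to "small" so the three
    labels partition the line.
    """
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    b = abs(beta)
    if b < 0.30:
        return "small"
    if b < 0.50:
        return "moderate"
    return "large"


@dataclass
class PanelFit:
    """Report for one fitted panel model, shaped like a lagged-effects table.

    With multiple imputation the coefficient table pools estimates and SEs
    by Rubin's rules; the chi-square and fit indices are reported as the
    across-imputation mean with the across-imputation standard deviation
    (no consensus pooling rule exists for ML fit statistics, and the report
    labels them accordingly).
    """

    table: pd.DataFrame
    statistic: float
    statistic_spread: float
    df: int
    pvalue: float
    cfi: float
    tli: float
    n: int
    m: int  # imputations pooled (1 = single fit)
    fits: list[FitResult] = field(default_factory=list, repr=False)
    n_failed: int = 0
    n_nonconverged: int = 0

    def to_markdown(self) -> str:
        lines = [self.table.to_string(index=False), ""]
        spread = f" (SD over imputations {self.statistic_spread:.3f})" if self.m > 1 else ""
        lines.append(f"Chi Square = {self.statistic:.3f}{spread}  P = {self.pvalue:.4g}")
        lines.append(f"CFI = {self.cfi:.2f}")
        lines.append(f"TLI = {self.tli:.2f}")
        lines.append(f"DF = {self.df}")
        return "\n".join(lines)


def _report_rows(fit: FitResult, model: PathModel) -> pd.DataFrame:
    """Free structural paths, grouped by dependent variable."""
    paths = fit.paths
    free = paths[paths["free"]].copy()
    # dependent blocks ordered as the model declares targets
    order = {t: i for i, (s, t, v) in enumerate(model.paths)}
    free["order"] = [order[t] for t in free["target"]]
    free = free.sort_values(["order"]).drop(columns="order")
    free["est_over_se"] = free["estimate"] / free["se"]
    from scipy import stats as _st

    free["p"] = 2 * _st.norm.sf(np.abs(free["est_over_se"]))
    free["effect_size"] = [
        effect_size_label(b) if np.isfinite(b) else ""
        for b in free["std"]
    ]
    cols = [
        "target", "source", "estimate", "se", "est_over_se", "p",
        "std", "std_se", "std_ci_low", "std_ci_high", "effect_size",
    ]
    return free[cols].reset_index(drop=True)


def fit_panel(
    model: PathModel,
    panel: pd.DataFrame,
    mi: ImputationSet | None = None,
    *,
    seed: int = 0,
) -> PanelFit:
    """Fit a panel model to the 8-column wave panel, optionally over an
    imputation set with Rubin pooling of coefficient rows."""
    cols = list(model.selection)
    if mi is None:
        fit = fit_ml(model, panel[cols], seed=seed)
        table = _report_rows(fit, model)
        return PanelFit(
            table=table,
            statistic=fit.statistic,
            statistic_spread=0.0,
            df=fit.df,
            pvalue=fit.pvalue,
            cfi=fit.cfi,
            tli=fit.tli,
            n=fit.n,
            m=1,
            fits=[fit],
        )

    fits: list[FitResult] = []
    n_failed = 0
    n_nonconverged = 0
    for i, completed in enumerate(mi.tables):
        try:
            # boundary solutions do not recover under jittered restarts,
            # so per-imputation fits keep the restart budget small
            f = fit_ml(model, completed[cols], seed=seed + i, max_restarts=1)
        except Exception:
            n_failed += 1
            continue
        if not f.converged:
            # kept in the pool (estimates are admissible boundary solutions)
            # but counted, so reports can flag them
            n_nonconverged += 1
        fits.append(f)
    if len(fits) < 2:
        raise RuntimeError(
            f"fewer than 2 imputation fits completed ({n_failed} failures)"
        )

    tables = [_report_rows(f, model) for f in fits]
    base = tables[0]
    rows = []
    for idx in range(len(base)):
        pooled = rubin_pool(
            np.array([t.loc[idx, "estimate"] for t in tables]),
            np.array([t.loc[idx, "se"] for t in tables]) ** 2,
        )
        std_pool = rubin_pool(
            np.array([t.loc[idx, "std"] for t in tables]),
            np.array([t.loc[idx, "std_se"] for t in tables]) ** 2,
        )
        row = dict(base.loc[idx, ["target", "source"]])
        row.update(
            estimate=pooled.estimate, se=pooled.se,
            est_over_se=pooled.estimate / pooled.se, p=pooled.pvalue,
            std=std_pool.estimate, std_se=std_pool.se,
            std_ci_low=std_pool.ci_low, std_ci_high=std_pool.ci_high,
            effect_size=(effect_size_label(std_pool.estimate)
                         if np.isfinite(std_pool.estimate) else ""),
        )
        rows.append(row)
    table = pd.DataFrame(rows)

    Ts = np.array([f.statistic for f in fits])
    return PanelFit(
        table=table,
        statistic=float(Ts.mean()),
        statistic_spread=float(Ts.std(ddof=1)),
        df=fits[0].df,
        pvalue=float(np.mean([f.pvalue for f in fits])),
        cfi=float(np.mean([f.cfi for f in fits])),
        tli=float(np.mean([f.tli for f in fits])),
        n=fits[0].n,
        m=len(fits),
        fits=fits,
        n_failed=n_failed,
        n_nonconverged=n_nonconverged,
    )
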