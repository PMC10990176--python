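"""Seeded synthetic cohorts with the dependence structure the analysis assumes.

The generator emulates a cohort of cardiac patients followed for 12 weeks
after hospital discharge: a random-intercept cross-lagged panel (RI-CLPM)
truth for kinesiophobia (TSK total, 13-52) and total physical activity
(minutes/day) at 4 waves; 13-item questionnaire tables whose items sum to
the generated totals; epoch-level accelerometer streams whose MET-category
minutes aggregate back to the panel targets; wave-level questionnaire
missingness and epoch-level accelerometer missingness, both
missing-completely-at-random; and the eligibility/exclusion flow ending in
the analysis sample.

The latent truth is a linear state-space model per patient i:

    y_it = grand_mean_t + b_i + w_it
    w_i,t+1 = B_t w_it + e_i,t+1,   e ~ N(0, Q_t)

with b_i the 2-vector of random intercepts and w the within-person
component (2 processes).  Disturbances are multivariate normal, matching
the downstream maximum-likelihood estimator.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .measures import Cutpoints

__all__ = [
    "TruthParams",
    "CohortConfig",
    "CohortDataset",
    "default_truth",
    "generate_latent_panel",
    "truth_to_riclpm_values",
    "disaggregate_tsk_items",
    "generate_met_day",
    "impose_missingness",
    "apply_cohort_flow",
    "generate_cohort",
    "write_cohort",
]

WAVE_WEEKS = (1, 3, 6, 12)
PROCESSES = ("tsk", "pa")

#: Per-wave (light, moderate, heavy) activity shares used to split total PA,
#: proportional to the published per-category medians at each wave.
_CATEGORY_MEDIANS = np.array(
    [
        [54.14, 24.34, 0.43],
        [82.86, 39.21, 0.57],
        [84.04, 35.50, 0.83],
        [81.34, 40.15, 1.15],
    ]
)
_CATEGORY_SHARES = _CATEGORY_MEDIANS / _CATEGORY_MEDIANS.sum(axis=1, keepdims=True)


def _check_psd(mat: np.ndarray, name: str, strict: bool) -> None:
    mat = np.asarray(mat, float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(mat, mat.T):
        raise ValueError(f"{name} must be symmetric")
    eig = np.linalg.eigvalsh(mat).min()
    if strict and eig <= 0:
        raise ValueError(f"{name} is not positive definite (min eigenvalue {eig:.3g})")
    if not strict and eig < -1e-10:
        raise ValueError(f"{name} is not positive semidefinite (min eigenvalue {eig:.3g})")


@dataclass(frozen=True)
class TruthParams:
    """Generating parameters of the latent panel truth.

    Process order is (tsk, pa) throughout.  ``lagged_coefs[t]`` is the 2x2
    transition matrix from wave t to wave t+1 with rows = outcome, columns =
    predictor: diagonal entries are autoregressive, off-diagonal
    cross-lagged.
    """

    grand_means: np.ndarray          # (2, n_waves)
    ri_variances: tuple[float, float]
    ri_covariance: float
    wave1_within_cov: np.ndarray     # (2, 2)
    lagged_coefs: tuple[np.ndarray, ...]       # n_waves-1 matrices (2, 2)
    residual_variances: tuple[tuple[float, float], ...]
    residual_covariances: tuple[float, ...] = ()

    def __post_init__(self):
        gm = np.asarray(self.grand_means, float)
        if gm.shape[0] != 2:
            raise ValueError("grand_means must have 2 rows (tsk, pa)")
        n_waves = gm.shape[1]
        object.__setattr__(self, "grand_means", gm)
        if len(self.lagged_coefs) != n_waves - 1:
            raise ValueError("need one lagged_coefs matrix per transition")
        if len(self.residual_variances) != n_waves - 1:
            raise ValueError("need residual variances per transition")
        rc = self.residual_covariances or tuple(0.0 for _ in range(n_waves - 1))
        if len(rc) != n_waves - 1:
            raise ValueError("need one residual covariance per transition")
        object.__setattr__(self, "residual_covariances", tuple(float(c) for c in rc))
        object.__setattr__(
            self, "lagged_coefs", tuple(np.asarray(b, float) for b in self.lagged_coefs)
        )
        if any(v < 0 for v in self.ri_variances):
            raise ValueError("random-intercept variances must be nonnegative")
        _check_psd(self.ri_matrix, "random-intercept covariance block", strict=False)
        _check_psd(np.asarray(self.wave1_within_cov, float),
                   "wave-1 within covariance", strict=True)
        for t, q in enumerate(self.residual_matrices):
            if self.residual_variances[t][0] <= 0 or self.residual_variances[t][1] <= 0:
                raise ValueError(f"residual variances of transition {t + 1} must be positive")
            _check_psd(q, f"residual covariance block of transition {t + 1}",
                       strict=True)

    @property
    def n_waves(self) -> int:
        return self.grand_means.shape[1]

    @property
    def ri_matrix(self) -> np.ndarray:
        v1, v2 = self.ri_variances
        return np.array([[v1, self.ri_covariance], [self.ri_covariance, v2]])

    @property
    def residual_matrices(self) -> tuple[np.ndarray, ...]:
        out = []
        for (q1, q2), c in zip(self.residual_variances, self.residual_covariances):
            out.append(np.array([[q1, c], [c, q2]]))
        return tuple(out)


def default_truth(wave_weeks: tuple[int, ...] = WAVE_WEEKS) -> TruthParams:
    """Default generating truth matched to the published cohort.

    Grand means take the published medians (TSK 27.43 falling to 25.00, with
    the two unprinted waves interpolated; total PA 82.09 / 127.50 / 127.00 /
    123.85 min/day).  Variances are spread-matched (SD ~ IQR/1.349) and
    split between the random intercept and the within component in rough
    agreement with the published standardized loadings.  Lagged coefficients
    are the published standardized estimates converted to the unstandardized
    scale under stationary within variances; residual variances are then
    chosen to keep the within variances stationary.
    """
    tsk_means = np.array([27.43, 26.6, 25.8, 25.0])
    pa_means = np.array([82.09, 127.50, 127.00, 123.85])

    var_tsk = (7.28 / 1.349) ** 2          # ~29, from the TSK IQR
    var_pa = (53.98 / 1.349) ** 2          # ~1600, from the total-PA IQR
    ri_tsk, within_tsk = 0.5 * var_tsk, 0.5 * var_tsk
    ri_pa, within_pa = 0.4 * var_pa, 0.6 * var_pa

    sd = np.array([np.sqrt(within_tsk), np.sqrt(within_pa)])
    betas = [
        np.array([[0.53, 0.12], [0.09, 0.52]]),
        np.array([[0.61, 0.15], [0.09, 0.67]]),
        np.array([[0.53, -0.04], [-0.01, 0.65]]),
    ]
    lagged = []
    resid = []
    var_vec = np.array([within_tsk, within_pa])
    for beta in betas:
        b = beta * np.outer(sd, 1.0 / sd)   # b_ij = beta_ij * sd_i / sd_j
        lagged.append(b)
        implied = b @ np.diag(var_vec) @ b.T
        q = np.maximum(var_vec - np.diag(implied), 0.05 * var_vec)
        resid.append((float(q[0]), float(q[1])))

    return TruthParams(
        grand_means=np.vstack([tsk_means, pa_means]),
        ri_variances=(ri_tsk, ri_pa),
        ri_covariance=0.0,
        wave1_within_cov=np.diag([within_tsk, within_pa]),
        lagged_coefs=tuple(lagged),
        residual_variances=tuple(resid),
    )


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level configuration: flow counts, waves, wear protocol, rates."""

    n_assessed: int = 188
    n_died: int = 2
    n_questionnaire_completers: int = 149
    n_no_accelerometer: int = 33
    n_waves: int = 4
    wave_weeks: tuple[int, ...] = WAVE_WEEKS
    wear_days: int = 90
    epoch_minutes: float = 1.0
    tsk_wave_missing_rates: tuple[float, ...] = (0.228, 0.248, 0.282, 0.362)
    epoch_missing_rate: float = 0.144
    seed: int = 0

    def __post_init__(self):
        c = self
        if not (
            c.n_assessed >= c.n_questionnaire_completers
            >= c.n_questionnaire_completers - c.n_no_accelerometer >= 0
        ):
            raise ValueError("inconsistent cohort flow counts")
        if c.n_died < 0 or c.n_assessed - c.n_died < c.n_questionnaire_completers:
            raise ValueError("deaths exceed the assessed-minus-completers margin")
        rates = tuple(c.tsk_wave_missing_rates) + (c.epoch_missing_rate,)
        if any(not 0 <= r <= 1 for r in rates):
            raise ValueError("missingness rates must lie in [0, 1]")
        if len(c.tsk_wave_missing_rates) != c.n_waves:
            raise ValueError("need one TSK missing rate per wave")
        if c.epoch_minutes <= 0 or c.wear_days < 1:
            raise ValueError("wear protocol must be positive")

    @classmethod
    def desk(cls, **overrides) -> "CohortConfig":
        """Fast preset: 14-day wear period, everything else at defaults."""
        overrides.setdefault("wear_days", 14)
        return cls(**overrides)

    @property
    def n_analysis(self) -> int:
        return self.n_questionnaire_completers - self.n_no_accelerometer


@dataclass
class CohortDataset:
    """One generated cohort: exclusion ledger, wave panel, items, epochs."""

    flow: dict
    panel: pd.DataFrame          # long: patient_id, wave, week, tsk_total,
    #                              tsk_missing, pa_light/moderate/heavy/total
    items: pd.DataFrame          # patient_id, wave, item_1..item_13
    epochs: pd.DataFrame | None  # patient_id, timestamp, met

    def to_wide(self) -> pd.DataFrame:
        """8-column wide panel (tsk_wk*, pa_wk*) with NaN for missing."""
        p = self.panel.copy()
        p.loc[p["tsk_missing"], "tsk_total"] = np.nan
        wide_tsk = p.pivot(index="patient_id", columns="week", values="tsk_total")
        wide_pa = p.pivot(index="patient_id", columns="week", values="pa_total")
        out = pd.DataFrame(index=wide_tsk.index)
        for w in sorted(wide_tsk.columns):
            out[f"tsk_wk{w}"] = wide_tsk[w]
        for w in sorted(wide_pa.columns):
            out[f"pa_wk{w}"] = wide_pa[w]
        return out


def generate_latent_panel(truth: TruthParams, n: int, seed: int) -> pd.DataFrame:
    """Draw n patients from the latent truth.

    Returns per-patient between-components (``b_tsk``, ``b_pa``),
    within-components (``w_tsk_wk*``, ``w_pa_wk*``) and observed values
    (``tsk_wk*``, ``pa_wk*``) with observed = grand mean + between + within.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    waves = WAVE_WEEKS[: truth.n_waves]

    b = rng.multivariate_normal(
        np.zeros(2), truth.ri_matrix, size=n, method="svd"
    )
    w = np.empty((n, truth.n_waves, 2))
    w[:, 0, :] = rng.multivariate_normal(
        np.zeros(2), np.asarray(truth.wave1_within_cov, float), size=n, method="svd"
    )
    for t, (B, Q) in enumerate(zip(truth.lagged_coefs, truth.residual_matrices)):
        e = rng.multivariate_normal(np.zeros(2), Q, size=n, method="svd")
        w[:, t + 1, :] = w[:, t, :] @ B.T + e

    out = {"b_tsk": b[:, 0], "b_pa": b[:, 1]}
    for j, week in enumerate(waves):
        out[f"w_tsk_wk{week}"] = w[:, j, 0]
        out[f"w_pa_wk{week}"] = w[:, j, 1]
    for j, week in enumerate(waves):
        out[f"tsk_wk{week}"] = truth.grand_means[0, j] + b[:, 0] + w[:, j, 0]
        out[f"pa_wk{week}"] = truth.grand_means[1, j] + b[:, 1] + w[:, j, 1]
    return pd.DataFrame(out)


def truth_to_riclpm_values(truth: TruthParams) -> dict[str, float]:
    """Map TruthParams onto the free labels of the default RI-CLPM builder."""
    waves = WAVE_WEEKS[: truth.n_waves]
    vals: dict[str, float] = {
        "var_ri_tsk": truth.ri_variances[0],
        "var_ri_pa": truth.ri_variances[1],
        "cov_ri": truth.ri_covariance,
        f"var_w_tsk_wk{waves[0]}": float(truth.wave1_within_cov[0][0]),
        f"var_w_pa_wk{waves[0]}": float(truth.wave1_within_cov[1][1]),
        f"cov_w_wk{waves[0]}": float(np.asarray(truth.wave1_within_cov)[0, 1]),
    }
    for j, week in enumerate(waves):
        vals[f"mu_tsk_wk{week}"] = float(truth.grand_means[0, j])
        vals[f"mu_pa_wk{week}"] = float(truth.grand_means[1, j])
    for t, nxt in enumerate(waves[1:]):
        B = truth.lagged_coefs[t]
        vals[f"a_tsk_wk{nxt}"] = float(B[0, 0])
        vals[f"c_pa_tsk_wk{nxt}"] = float(B[0, 1])
        vals[f"c_tsk_pa_wk{nxt}"] = float(B[1, 0])
        vals[f"a_pa_wk{nxt}"] = float(B[1, 1])
        vals[f"rvar_tsk_wk{nxt}"] = float(truth.residual_variances[t][0])
        vals[f"rvar_pa_wk{nxt}"] = float(truth.residual_variances[t][1])
        vals[f"rcov_wk{nxt}"] = float(truth.residual_covariances[t])
    return vals


def disaggregate_tsk_items(total: int, seed) -> np.ndarray:
    """Split a TSK total into 13 item scores in 1..4 summing to it.

    The excess over the floor (13 ones) is allocated one point at a time to
    a uniformly chosen item with headroom; ``seed`` may be an int or a
    numpy Generator.
    """
    total = int(total)
    if not 13 <= total <= 52:
        raise ValueError(f"TSK total out of range 13..52: {total}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    items = np.ones(13, dtype=int)
    for _ in range(total - 13):
        open_items = np.flatnonzero(items < 4)
        items[open_items[rng.integers(len(open_items))]] += 1
    return items


def generate_met_day(
    target_minutes: tuple[float, float, float],
    config: CohortConfig,
    seed,
    date="2021-01-01",
    cuts: Cutpoints = Cutpoints(),
) -> pd.DataFrame:
    """One day of epoch records hitting (light, moderate, heavy) targets.

    Targets are quantized to the epoch grid (rounded to the nearest whole
    epoch), so aggregating the output recovers them exactly at epoch
    resolution.  Non-active epochs carry MET values at or below the
    sedentary cut; active epochs draw MET values inside their category's
    interval.
    """
    light, moderate, heavy = (float(t) for t in target_minutes)
    if min(light, moderate, heavy) < 0:
        raise ValueError("activity targets must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    em = config.epoch_minutes
    n_epochs = int(round(24 * 60 / em))
    counts = [int(round(t / em)) for t in (light, moderate, heavy)]
    if sum(counts) > n_epochs:
        raise ValueError(
            f"activity targets ({light}+{moderate}+{heavy} min) exceed the "
            f"{24 * 60:.0f}-minute day"
        )
    n_sed = n_epochs - sum(counts)
    eps = 1e-6
    met = np.concatenate(
        [
            rng.uniform(cuts.sedentary_max + eps, cuts.light_max - eps, counts[0]),
            rng.uniform(cuts.light_max, cuts.moderate_max, counts[1]),
            rng.uniform(cuts.moderate_max + eps, 12.0, counts[2]),
            rng.uniform(0.9, cuts.sedentary_max, n_sed),
        ]
    )
    order = rng.permutation(n_epochs)
    met = met[order]
    start = pd.Timestamp(date)
    timestamps = start + pd.to_timedelta(np.arange(n_epochs) * em, unit="m")
    return pd.DataFrame({"timestamp": timestamps, "met": met})


def apply_cohort_flow(config: CohortConfig) -> dict:
    """Exclusion ledger from assessment to the analysis sample."""
    n_not_completed = config.n_assessed - config.n_died - config.n_questionnaire_completers
    if n_not_completed < 0:
        raise ValueError("flow counts inconsistent: completers exceed survivors")
    final = config.n_questionnaire_completers - config.n_no_accelerometer
    ledger = {
        "assessed_for_eligibility": config.n_assessed,
        "died": config.n_died,
        "did_not_complete_questionnaires": n_not_completed,
        "questionnaire_completers": config.n_questionnaire_completers,
        "did_not_wear_accelerometer": config.n_no_accelerometer,
        "analysis_sample": final,
        "empty_analysis_set": final == 0,
    }
    if final == 0:
        warnings.warn("cohort flow leaves an empty analysis set", UserWarning)
    return ledger


def impose_missingness(
    dataset: CohortDataset, config: CohortConfig, seed: int
) -> CohortDataset:
    """MCAR deletion: wave-level TSK records and individual epochs.

    Each wave-level TSK record is deleted independently with its wave's
    rate (the corresponding item rows are dropped: the questionnaire was
    never returned); each epoch is deleted independently with the epoch
    rate.  The mask is stored in the panel, never silently dropped.
    """
    rng = np.random.default_rng(seed)
    panel = dataset.panel.copy()
    for wave, rate in zip(range(1, config.n_waves + 1), config.tsk_wave_missing_rates):
        rows = panel.index[panel["wave"] == wave]
        drop = rng.random(len(rows)) < rate
        panel.loc[rows[drop], "tsk_missing"] = True
        panel.loc[rows[drop], "tsk_total"] = np.nan
    missing_keys = set(
        map(tuple, panel.loc[panel["tsk_missing"], ["patient_id", "wave"]].to_numpy())
    )
    items = dataset.items[
        ~dataset.items[["patient_id", "wave"]].apply(tuple, axis=1).isin(missing_keys)
    ].reset_index(drop=True)
    epochs = dataset.epochs
    if epochs is not None and config.epoch_missing_rate > 0:
        keep = rng.random(len(epochs)) >= config.epoch_missing_rate
        epochs = epochs[keep].reset_index(drop=True)
    return CohortDataset(flow=dataset.flow, panel=panel, items=items, epochs=epochs)


def generate_cohort(
    truth: TruthParams | None = None,
    config: CohortConfig = CohortConfig(),
    *,
    include_epochs: bool = False,
    cuts: Cutpoints = Cutpoints(),
    apply_missingness: bool = True,
) -> CohortDataset:
    """Full synthetic cohort: flow, panel, items and (optionally) epochs.

    Identical (truth, config) including the config seed give bit-identical
    datasets.  TSK totals are generated continuously, then rounded and
    clamped to 13..52 before item disaggregation; PA totals are floored at
    zero (both documented as part of the synthetic measurement model).
    """
    truth = truth if truth is not None else default_truth()
    flow = apply_cohort_flow(config)
    n = flow["analysis_sample"]
    if n == 0:
        raise ValueError("cohort flow leaves no analysis patients")

    root = np.random.default_rng(config.seed)
    s_latent, s_items, s_split, s_epochs, s_missing = root.integers(
        0, 2**31 - 1, size=5
    )
    latent = generate_latent_panel(truth, n, int(s_latent))
    waves = WAVE_WEEKS[: truth.n_waves]

    item_rng = np.random.default_rng(int(s_items))
    split_rng = np.random.default_rng(int(s_split))

    panel_rows, item_rows = [], []
    pa_cat = np.empty((n, len(waves), 3))
    for j, week in enumerate(waves):
        tsk = np.clip(np.round(latent[f"tsk_wk{week}"]), 13, 52).astype(int)
        pa_total = np.clip(latent[f"pa_wk{week}"].to_numpy(), 0.0, 1200.0)
        shares = split_rng.dirichlet(_CATEGORY_SHARES[j] * 60.0, size=n)
        pa_cat[:, j, :] = shares * pa_total[:, None]
        for i in range(n):
            panel_rows.append(
                {
                    "patient_id": i + 1,
                    "wave": j + 1,
                    "week": week,
                    "tsk_total": float(tsk[i]),
                    "tsk_missing": False,
                    "pa_light": pa_cat[i, j, 0],
                    "pa_moderate": pa_cat[i, j, 1],
                    "pa_heavy": pa_cat[i, j, 2],
                    "pa_total": float(pa_total[i]),
                }
            )
            items = disaggregate_tsk_items(int(tsk[i]), item_rng)
            item_rows.append(
                {"patient_id": i + 1, "wave": j + 1,
                 **{f"item_{k + 1}": int(v) for k, v in enumerate(items)}}
            )
    panel = pd.DataFrame(panel_rows).sort_values(["patient_id", "wave"]).reset_index(drop=True)
    items = pd.DataFrame(item_rows)

    epochs = None
    if include_epochs:
        epochs = _generate_epoch_streams(
            pa_cat, waves, config, cuts, np.random.default_rng(int(s_epochs))
        )

    dataset = CohortDataset(flow=flow, panel=panel, items=items, epochs=epochs)
    if apply_missingness:
        dataset = impose_missingness(dataset, config, int(s_missing))
    return dataset


def _generate_epoch_streams(pa_cat, waves, config, cuts, rng) -> pd.DataFrame:
    """Daily epoch streams; day targets interpolate the wave targets by week."""
    n = pa_cat.shape[0]
    n_weeks = max(1, config.wear_days // 7)
    week_grid = np.arange(1, n_weeks + 1)
    frames = []
    base = pd.Timestamp("2021-01-01")
    for i in range(n):
        weekly = np.column_stack(
            [np.interp(week_grid, waves, pa_cat[i, :, c]) for c in range(3)]
        )
        per_patient = []
        for day in range(config.wear_days):
            week_idx = min(day // 7, n_weeks - 1)
            targets = tuple(weekly[week_idx])
            date = base + pd.Timedelta(days=day)
            day_df = generate_met_day(targets, config, rng, date=date, cuts=cuts)
            per_patient.append(day_df)
        patient = pd.concat(per_patient, ignore_index=True)
        patient.insert(0, "patient_id", i + 1)
        frames.append(patient)
    return pd.concat(frames, ignore_index=True)


def write_cohort(dataset: CohortDataset, directory) -> dict[str, str]:
    """Write the cohort as plain-text artifacts (CSV + JSON ledger)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {}
    panel = dataset.panel.copy()
    panel.to_csv(d / "panel.csv", index=False)
    paths["panel"] = str(d / "panel.csv")
    dataset.items.to_csv(d / "items.csv", index=False)
    paths["items"] = str(d / "items.csv")
    if dataset.epochs is not None:
        ep = dataset.epochs.copy()
        ep["timestamp"] = pd.to_datetime(ep["timestamp"]).dt.strftime(
            "%Y-%m-%dT%H:%M:%S"
        )
        ep.to_csv(d / "epochs.csv", index=False)
        paths["epochs"] = str(d / "epochs.csv")
    (d / "flow.json").write_text(json.dumps(dataset.flow, indent=1))
    paths["flow"] = str(d / "flow.json")
    return paths
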