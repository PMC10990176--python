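"""Missing-data machinery: Little's MCAR test, FCS multiple imputation,
Rubin pooling.

Little's test compares the observed-variable means of each missingness
pattern against the EM-estimated grand mean, weighting by the EM covariance:

    d^2 = sum_j n_j (ybar_j - mu_j)' Sigma_j^{-1} (ybar_j - mu_j)

restricted to the variables observed in pattern j, referred to chi-square on
``sum_j p_j - p`` degrees of freedom.  Under missing-completely-at-random
the statistic is asymptotically chi-square; a small p-value signals that
missingness depends on the data.

``fcs_impute`` is full-conditional-specification (chained-equations)
multiple imputation with a Bayesian normal linear regression kernel: each
incomplete variable is regressed on all others, the residual variance and
coefficients are drawn from their posterior under a noninformative prior,
and missing cells are replaced by posterior-predictive draws; the chain
cycles a fixed number of iterations per imputation.

``rubin_pool`` combines per-imputation estimates by Rubin's rules with the
small-sample degrees of freedom.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MissingTable",
    "ImputationSet",
    "LittleResult",
    "PooledEstimate",
    "littles_mcar",
    "fcs_impute",
    "rubin_pool",
]


@dataclass
class MissingTable:
    """Rectangular numeric table with an explicit missingness mask.

    ``mask`` is True where the value is missing.  Variables that are
    entirely missing are excluded on construction, with a warning.
    """

    data: pd.DataFrame
    mask: pd.DataFrame

    def __post_init__(self):
        if self.data.shape != self.mask.shape:
            raise ValueError("mask shape must equal table shape")
        if list(self.data.columns) != list(self.mask.columns):
            raise ValueError("mask columns must match table columns")
        all_missing = [c for c in self.data.columns if self.mask[c].all()]
        if all_missing:
            warnings.warn(
                f"excluding entirely missing variable(s): {all_missing}",
                UserWarning,
            )
            self.data = self.data.drop(columns=all_missing)
            self.mask = self.mask.drop(columns=all_missing)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "MissingTable":
        """Build from a DataFrame using NaN as the missingness indicator."""
        num = df.astype(float)
        return cls(data=num, mask=num.isna())

    @property
    def values(self) -> np.ndarray:
        x = self.data.to_numpy(float).copy()
        x[self.mask.to_numpy(bool)] = np.nan
        return x

    def to_csv(self, data_path, mask_path) -> None:
        self.data.to_csv(data_path, index=False)
        self.mask.to_csv(mask_path, index=False)

    @classmethod
    def read_csv(cls, data_path, mask_path) -> "MissingTable":
        data = pd.read_csv(data_path)
        mask = pd.read_csv(mask_path).astype(bool)
        return cls(data=data, mask=mask)


@dataclass
class ImputationSet:
    """m completed copies of a partially missing table.

    Completed tables agree with the original on every observed cell.
    """

    tables: list[pd.DataFrame]
    mask: pd.DataFrame
    m: int
    iterations: int
    seed: int

    def write(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for i, t in enumerate(self.tables, start=1):
            t.to_csv(d / f"imputation_{i:03d}.csv", index=False)
        self.mask.to_csv(d / "mask.csv", index=False)
        (d / "manifest.json").write_text(
            json.dumps(
                {"m": self.m, "iterations": self.iterations, "seed": self.seed},
                indent=1,
            )
        )

    @classmethod
    def read(cls, directory) -> "ImputationSet":
        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        tables = [
            pd.read_csv(p) for p in sorted(d.glob("imputation_*.csv"))
        ]
        mask = pd.read_csv(d / "mask.csv").astype(bool)
        return cls(tables=tables, mask=mask, **manifest)


# ---------------------------------------------------------------------------
# EM for the multivariate-normal mean/covariance with missing data
# ---------------------------------------------------------------------------

def _em_norm(
    x: np.ndarray, max_iter: int = 500, tol: float = 1e-8, ridge: float = 1e-10
) -> tuple[np.ndarray, np.ndarray, bool, int]:
    """EM estimates of (mu, Sigma) from rows with NaN missing values.

    Convergence when the observed-data log-likelihood changes by less than
    ``tol`` (or after ``max_iter`` sweeps).  Near-singular observed blocks
    are ridge-regularized with a warning.
    """
    n, p = x.shape
    miss = np.isnan(x)
    keep = ~miss.all(axis=1)
    x, miss = x[keep], miss[keep]
    n = len(x)

    mu = np.nanmean(x, axis=0)
    filled = np.where(miss, mu, x)
    sigma = np.cov(filled, rowvar=False, ddof=0)
    sigma += ridge * np.eye(p) * max(np.trace(sigma) / p, 1.0)

    patterns: dict[bytes, np.ndarray] = {}
    for key in np.unique(miss, axis=0):
        rows = np.flatnonzero((miss == key).all(axis=1))
        patterns[key.tobytes()] = (key, rows)

    last_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        sum_x = np.zeros(p)
        sum_xx = np.zeros((p, p))
        ll = 0.0
        for key, (pat, rows) in patterns.items():
            o = np.flatnonzero(~pat)
            mrows = np.flatnonzero(pat)
            xo = x[np.ix_(rows, o)]
            soo = sigma[np.ix_(o, o)]
            try:
                soo_inv = np.linalg.inv(soo)
            except np.linalg.LinAlgError:
                warnings.warn("singular pattern covariance; ridge applied")
                soo = soo + 1e-6 * np.trace(soo) / len(o) * np.eye(len(o))
                soo_inv = np.linalg.inv(soo)
            dev = xo - mu[o]
            sign, logdet = np.linalg.slogdet(soo)
            ll += -0.5 * (
                len(rows) * (len(o) * np.log(2 * np.pi) + logdet)
                + np.einsum("ij,jk,ik->", dev, soo_inv, dev)
            )
            xhat = np.empty((len(rows), p))
            xhat[:, o] = xo
            if len(mrows):
                smo = sigma[np.ix_(mrows, o)]
                beta = smo @ soo_inv
                cond_mean = mu[mrows] + dev @ beta.T
                xhat[:, mrows] = cond_mean
                cond_cov = sigma[np.ix_(mrows, mrows)] - beta @ smo.T
            sum_x += xhat.sum(axis=0)
            cross = xhat.T @ xhat
            if len(mrows):
                cross[np.ix_(mrows, mrows)] += len(rows) * cond_cov
            sum_xx += cross
        mu = sum_x / n
        sigma = sum_xx / n - np.outer(mu, mu)
        sigma = 0.5 * (sigma + sigma.T)
        if abs(ll - last_ll) < tol:
            converged = True
            break
        last_ll = ll
    return mu, sigma, converged, it


@dataclass(frozen=True)
class LittleResult:
    statistic: float
    df: int
    pvalue: float
    n_patterns: int
    defined: bool
    em_converged: bool


def littles_mcar(data: MissingTable | pd.DataFrame) -> LittleResult:
    """Little's chi-square test of missing-completely-at-random.

    With a single missingness pattern (complete data) the test is undefined:
    statistic 0, df 0, flagged.
    """
    if isinstance(data, pd.DataFrame):
        data = MissingTable.from_dataframe(data)
    x = data.values
    miss = np.isnan(x)
    keep = ~miss.all(axis=1)
    x, miss = x[keep], miss[keep]
    p = x.shape[1]

    pats = np.unique(miss, axis=0)
    if len(pats) < 2 and miss.sum() == 0:
        return LittleResult(0.0, 0, float("nan"), 1, False, True)

    mu, sigma, em_ok, _ = _em_norm(x)
    d2 = 0.0
    df = 0
    for pat in pats:
        rows = (miss == pat).all(axis=1)
        o = np.flatnonzero(~pat)
        if len(o) == 0:
            continue
        nj = int(rows.sum())
        ybar = x[np.ix_(np.flatnonzero(rows), o)].mean(axis=0)
        soo = sigma[np.ix_(o, o)]
        try:
            soo_inv = np.linalg.inv(soo)
        except np.linalg.LinAlgError:
            warnings.warn("singular pattern covariance in test; ridge applied")
            soo = soo + 1e-6 * np.trace(soo) / len(o) * np.eye(len(o))
            soo_inv = np.linalg.inv(soo)
        dev = ybar - mu[o]
        d2 += nj * dev @ soo_inv @ dev
        df += len(o)
    df -= p
    if df <= 0:
        return LittleResult(float(d2), max(df, 0), float("nan"),
                            len(pats), False, em_ok)
    return LittleResult(
        float(d2), df, float(stats.chi2.sf(d2, df)), len(pats), True, em_ok
    )


# ---------------------------------------------------------------------------
# FCS multiple imputation
# ---------------------------------------------------------------------------

def _bayes_norm_draw(y, X, X_mis, rng, ridge=1e-8):
    """Posterior-predictive draw for the normal linear kernel."""
    n, k = X.shape
    xtx = X.T @ X + ridge * np.eye(k)
    xtx_inv = np.linalg.inv(xtx)
    beta_hat = xtx_inv @ X.T @ y
    resid = y - X @ beta_hat
    dof = max(n - k, 1)
    sigma2 = resid @ resid / stats.chi2.rvs(dof, random_state=rng)
    beta = beta_hat + np.linalg.cholesky(
        0.5 * (xtx_inv + xtx_inv.T) * sigma2 + ridge * np.eye(k)
    ) @ rng.standard_normal(k)
    return X_mis @ beta + rng.standard_normal(len(X_mis)) * np.sqrt(sigma2)


def fcs_impute(
    data: MissingTable | pd.DataFrame,
    m: int = 20,
    iterations: int = 10,
    seed: int = 0,
) -> ImputationSet:
    """Chained-equations multiple imputation, Bayesian normal kernel.

    Each of the ``m`` imputations runs an independent chain (seeded from
    ``seed``), cycling ``iterations`` times over the incomplete variables.
    Observed cells are never altered.  Non-numeric columns are rejected.
    """
    if m < 2:
        raise ValueError("m must be at least 2")
    if isinstance(data, pd.DataFrame):
        bad = [c for c in data.columns
               if not np.issubdtype(data[c].dtype, np.number)]
        if bad:
            raise TypeError(f"non-numeric column(s) {bad}: categorical "
                            "imputation is out of scope")
        data = MissingTable.from_dataframe(data)
    x0 = data.values
    n, p = x0.shape
    mask = np.isnan(x0)
    incomplete = [j for j in range(p) if mask[:, j].any()]

    root = np.random.default_rng(seed)
    chains = root.spawn(m)
    tables = []
    col_means = np.nanmean(x0, axis=0)
    for chain in chains:
        x = np.where(mask, col_means, x0)
        # start missing cells at random observed draws, mice-style
        for j in incomplete:
            obs_vals = x0[~mask[:, j], j]
            x[mask[:, j], j] = chain.choice(obs_vals, size=mask[:, j].sum())
        for _ in range(iterations):
            for j in incomplete:
                obs = ~mask[:, j]
                others = [k for k in range(p) if k != j]
                X = np.column_stack([np.ones(n), x[:, others]])
                x[mask[:, j], j] = _bayes_norm_draw(
                    x0[obs, j], X[obs], X[mask[:, j]], chain
                )
        out = data.data.copy().astype(float)
        out[:] = np.where(mask, x, x0)
        tables.append(out)
    return ImputationSet(
        tables=tables, mask=data.mask.copy(), m=m, iterations=iterations, seed=seed
    )


# ---------------------------------------------------------------------------
# Rubin's rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PooledEstimate:
    estimate: float
    se: float
    df: float
    ci_low: float
    ci_high: float
    pvalue: float
    within: float
    between: float


def rubin_pool(estimates, variances, alpha: float = 0.05) -> PooledEstimate:
    """Pool m point estimates and their squared SEs by Rubin's rules.

    Total variance ``T = Wbar + (1 + 1/m) B``; the small-sample degrees of
    freedom ``(m-1)(1 + Wbar / ((1+1/m)B))^2`` give a t-based interval
    (normal when the between-imputation variance is zero).
    """
    est = np.asarray(estimates, float)
    var = np.asarray(variances, float)
    m = len(est)
    if m < 2:
        raise ValueError("need at least 2 imputations to pool")
    if (var < 0).any():
        raise ValueError("variances must be nonnegative")
    qbar = est.mean()
    wbar = var.mean()
    b = est.var(ddof=1)
    total = wbar + (1 + 1 / m) * b
    se = np.sqrt(total)
    if b > 0:
        df = (m - 1) * (1 + wbar / ((1 + 1 / m) * b)) ** 2
        crit = stats.t.ppf(1 - alpha / 2, df)
        pvalue = 2 * stats.t.sf(abs(qbar) / se, df) if se > 0 else float("nan")
    else:
        df = float("inf")
        crit = stats.norm.ppf(1 - alpha / 2)
        pvalue = 2 * stats.norm.sf(abs(qbar) / se) if se > 0 else float("nan")
    return PooledEstimate(
        estimate=float(qbar), se=float(se), df=float(df),
        ci_low=float(qbar - crit * se), ci_high=float(qbar + crit * se),
        pvalue=float(pvalue), within=float(wbar), between=float(b),
    )
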