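"""Path-model (SEM) engine in the reticular action model (RAM) formulation.

A :class:`PathModel` is a declarative description of a recursive structural
equation model: named nodes (latent or observed), directed paths, symmetric
(co)variance entries and intercepts, each either fixed to a number or free
under a string label (label reuse expresses equality constraints).

Implied first and second moments over the observed selection follow from the
RAM identity: with ``A`` the directed coefficient matrix, ``S`` the symmetric
exogenous covariance matrix, ``M`` the intercept vector and ``F`` the
selection matrix,

    total = (I - A)^-1
    Sigma = F total S total' F'
    mu    = F total M

Maximum-likelihood estimation minimizes the Wishart discrepancy

    F_ML = ln|Sigma| - ln|S_obs| + tr(S_obs Sigma^-1) - p
           + (xbar - mu)' Sigma^-1 (xbar - mu)

with ``T = (n - 1) F_ML`` referred to a chi-square distribution on
``df = p(p+3)/2 - (number of distinct free labels)`` degrees of freedom
(mean structure always counted).  An ``n`` multiplier can be selected for
software conventions that use it.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "PathModel",
    "MomentPair",
    "SampleMoments",
    "FitIndices",
    "FitResult",
    "implied_moments",
    "model_df",
    "fit_ml",
    "baseline_fit",
    "fit_indices",
    "standardize",
    "sample_moments",
]

Value = float | str  # fixed number or free label


@dataclass(frozen=True)
class PathModel:
    """Declarative recursive path model.

    Parameters
    ----------
    nodes
        All node names, in a fixed order.
    latent
        Subset of ``nodes`` flagged latent.
    paths
        ``(source, target, value)`` directed coefficient entries.
    covs
        ``(a, b, value)`` symmetric (co)variance entries; ``a == b`` is a
        variance.
    means
        ``(node, value)`` intercept entries.  Nodes without an entry have
        intercept fixed at 0.
    selection
        Ordered observed nodes defining the row/column order of the implied
        moments.
    """

    nodes: tuple[str, ...]
    latent: frozenset[str]
    paths: tuple[tuple[str, str, Value], ...]
    covs: tuple[tuple[str, str, Value], ...]
    means: tuple[tuple[str, Value], ...]
    selection: tuple[str, ...]

    def __post_init__(self) -> None:
        known = set(self.nodes)
        if len(self.nodes) != len(known):
            raise ValueError("duplicate node names")
        for src, tgt, _ in self.paths:
            if src not in known or tgt not in known:
                raise ValueError(f"path {src}->{tgt} references unknown node")
        for a, b, _ in self.covs:
            if a not in known or b not in known:
                raise ValueError(f"covariance ({a},{b}) references unknown node")
        for node, _ in self.means:
            if node not in known:
                raise ValueError(f"mean entry references unknown node {node!r}")
        for node in self.selection:
            if node in self.latent:
                raise ValueError(f"latent node {node!r} cannot be observed")
            if node not in known:
                raise ValueError(f"selection references unknown node {node!r}")
        if self._has_cycle():
            raise ValueError("directed-path graph has a cycle; model must be recursive")

    def _has_cycle(self) -> bool:
        children: dict[str, list[str]] = {n: [] for n in self.nodes}
        for src, tgt, _ in self.paths:
            children[src].append(tgt)
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(n: str) -> bool:
            if state.get(n) == 0:
                return True
            if state.get(n) == 1:
                return False
            state[n] = 0
            if any(visit(c) for c in children[n]):
                return True
            state[n] = 1
            return False

        return any(visit(n) for n in self.nodes)

    def free_labels(self) -> tuple[str, ...]:
        """Distinct free labels in order of first appearance."""
        seen: dict[str, None] = {}
        for *_, v in self.paths:
            if isinstance(v, str):
                seen.setdefault(v)
        for *_, v in self.covs:
            if isinstance(v, str):
                seen.setdefault(v)
        for _, v in self.means:
            if isinstance(v, str):
                seen.setdefault(v)
        return tuple(seen)

    # -- serialization ---------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "nodes": list(self.nodes),
                "latent": sorted(self.latent),
                "paths": [list(p) for p in self.paths],
                "covs": [list(c) for c in self.covs],
                "means": [list(m) for m in self.means],
                "selection": list(self.selection),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "PathModel":
        d = json.loads(text)
        return cls(
            nodes=tuple(d["nodes"]),
            latent=frozenset(d["latent"]),
            paths=tuple((s, t, v) for s, t, v in d["paths"]),
            covs=tuple((a, b, v) for a, b, v in d["covs"]),
            means=tuple((n, v) for n, v in d["means"]),
            selection=tuple(d["selection"]),
        )


@dataclass(frozen=True)
class MomentPair:
    """Implied mean vector and covariance matrix over the observed selection."""

    mu: np.ndarray
    sigma: np.ndarray
    names: tuple[str, ...]


@dataclass(frozen=True)
class SampleMoments:
    """Observed sample mean, covariance (unbiased, divisor n-1) and size."""

    mean: np.ndarray
    cov: np.ndarray
    n: int
    names: tuple[str, ...] = ()


class CompiledModel:
    """Index-array compilation of a PathModel for fast matrix assembly."""

    def __init__(self, model: PathModel):
        self.model = model
        self.labels = model.free_labels()
        self.k = len(self.labels)
        idx = {n: i for i, n in enumerate(model.nodes)}
        lab = {l: i for i, l in enumerate(self.labels)}
        self.n_nodes = len(model.nodes)
        self.sel_idx = np.array([idx[n] for n in model.selection], dtype=int)

        def split(entries, rows, cols):
            fr, fc, fv, pr, pc, pk = [], [], [], [], [], []
            for r, c, v in entries:
                if isinstance(v, str):
                    pr.append(rows(r, c)), pc.append(cols(r, c)), pk.append(lab[v])
                else:
                    fr.append(rows(r, c)), fc.append(cols(r, c)), fv.append(float(v))
            return (
                np.array(fr, int), np.array(fc, int), np.array(fv, float),
                np.array(pr, int), np.array(pc, int), np.array(pk, int),
            )

        # A[target, source] = coefficient
        self._a = split(model.paths, lambda s, t: idx[t], lambda s, t: idx[s])
        self._s = split(model.covs, lambda a, b: idx[a], lambda a, b: idx[b])
        m_entries = [(n, n, v) for n, v in model.means]
        self._m = split(m_entries, lambda a, b: idx[a], lambda a, b: idx[b])

    def matrices(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        n = self.n_nodes
        A = np.zeros((n, n))
        S = np.zeros((n, n))
        M = np.zeros(n)
        fr, fc, fv, pr, pc, pk = self._a
        A[fr, fc] = fv
        A[pr, pc] = theta[pk]
        fr, fc, fv, pr, pc, pk = self._s
        S[fr, fc] = fv
        S[pr, pc] = theta[pk]
        S = S + S.T - np.diag(np.diag(S))
        fr, fc, fv, pr, pc, pk = self._m
        M[fr] = fv
        M[pr] = theta[pk]
        return A, S, M

    def implied_full(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Moments over ALL nodes (latent included)."""
        A, S, M = self.matrices(theta)
        total = np.linalg.inv(np.eye(self.n_nodes) - A)
        cov = total @ S @ total.T
        mean = total @ M
        return mean, cov

    def implied(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mean, cov = self.implied_full(theta)
        s = self.sel_idx
        return mean[s], cov[np.ix_(s, s)]

    def theta_from(self, values: Mapping[str, float]) -> np.ndarray:
        missing = [l for l in self.labels if l not in values]
        if missing:
            raise KeyError(f"no value supplied for free label(s): {missing}")
        return np.array([values[l] for l in self.labels], float)


def implied_moments(model: PathModel, values: Mapping[str, float]) -> MomentPair:
    """Model-implied mean and covariance over the observed selection.

    ``values`` assigns a number to every free label; a missing label raises
    ``KeyError`` naming it.
    """
    comp = CompiledModel(model)
    mu, sigma = comp.implied(comp.theta_from(values))
    return MomentPair(mu=mu, sigma=sigma, names=model.selection)


def model_df(model: PathModel) -> int:
    """Degrees of freedom: sample-moment count minus free-parameter count.

    The mean structure is always counted, so with p observed variables there
    are p(p+3)/2 sample moments.
    """
    p = len(model.selection)
    df = p * (p + 3) // 2 - len(model.free_labels())
    if df < 0:
        warnings.warn(
            f"model is over-parameterized: df = {df} < 0", UserWarning, stacklevel=2
        )
    return df


def sample_moments(
    data: pd.DataFrame, columns: Sequence[str] | None = None
) -> SampleMoments:
    """Complete-row sample mean and unbiased covariance of a data table."""
    df = data[list(columns)] if columns is not None else data
    df = df.dropna()
    n = len(df)
    if n < 2:
        raise ValueError("need at least 2 complete rows for sample moments")
    x = df.to_numpy(float)
    return SampleMoments(
        mean=x.mean(axis=0), cov=np.cov(x, rowvar=False, ddof=1),
        n=n, names=tuple(df.columns),
    )


def _coerce_sample(sample, selection: tuple[str, ...]) -> SampleMoments:
    if isinstance(sample, SampleMoments):
        if sample.names and tuple(sample.names) != selection:
            order = [sample.names.index(n) for n in selection]
            return SampleMoments(
                mean=sample.mean[order],
                cov=sample.cov[np.ix_(order, order)],
                n=sample.n,
                names=selection,
            )
        return sample
    if isinstance(sample, pd.DataFrame):
        return sample_moments(sample, selection)
    raise TypeError("sample must be SampleMoments or a DataFrame of raw complete data")


def _discrepancy(mu, sigma, m, S) -> float:
    """F_ML; +inf when the implied covariance is not positive definite."""
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        return np.inf
    logdet_sigma = 2.0 * np.sum(np.log(np.diag(chol)))
    sign, logdet_s = np.linalg.slogdet(S)
    p = len(m)
    inv = np.linalg.inv(sigma)
    d = m - mu
    return float(
        logdet_sigma - logdet_s + np.trace(S @ inv) - p + d @ inv @ d
    )


@dataclass(frozen=True)
class FitIndices:
    cfi: float | None
    tli: float | None
    cfi_raw: float | None
    tli_raw: float | None


@dataclass
class FitResult:
    """Everything a fitted path model reports.

    ``params`` has one row per free label (estimate, se); ``paths`` one row
    per directed path with unstandardized and standardized coefficients and
    delta-method 95% CIs on the standardized scale.
    """

    model: PathModel
    params: pd.DataFrame
    paths: pd.DataFrame
    loglik: float
    statistic: float  # chi-square T
    df: int
    pvalue: float
    baseline_statistic: float
    baseline_df: int
    cfi: float | None
    tli: float | None
    cfi_raw: float | None
    tli_raw: float | None
    n: int
    converged: bool
    n_restarts: int
    grad_norm: float
    vcov: np.ndarray = field(repr=False, default=None)

    @property
    def estimates(self) -> dict[str, float]:
        return dict(zip(self.params.index, self.params["estimate"]))

    def to_json(self) -> str:
        return json.dumps(
            {
                "params": self.params.reset_index().to_dict(orient="records"),
                "paths": self.paths.to_dict(orient="records"),
                "loglik": self.loglik,
                "chi_square": self.statistic,
                "df": self.df,
                "p": self.pvalue,
                "cfi": self.cfi,
                "tli": self.tli,
                "cfi_raw": self.cfi_raw,
                "tli_raw": self.tli_raw,
                "n": self.n,
                "converged": self.converged,
            },
            indent=1,
            default=float,
        )


def _start_values(comp: CompiledModel, sm: SampleMoments) -> np.ndarray:
    """Documented start-value rule.

    Free means start at the matching observed mean (0 for latents); free
    paths and covariances start at 0; each free variance loading on an
    observed node receives an equal share of that node's sample variance
    (a latent variance serving several indicators gets the average share).
    """
    model = comp.model
    obs_idx = {n: i for i, n in enumerate(model.selection)}
    theta = np.zeros(comp.k)
    lab_pos = {l: i for i, l in enumerate(comp.labels)}

    # free means
    for node, v in model.means:
        if isinstance(v, str):
            theta[lab_pos[v]] = sm.mean[obs_idx[node]] if node in obs_idx else 0.0

    # variance slots per observed node: own free diag + latent parents
    # (through fixed paths) whose own diag is free
    var_label: dict[str, str] = {}
    for a, b, v in model.covs:
        if a == b and isinstance(v, str):
            var_label[a] = v

    parents: dict[str, list[str]] = {n: [] for n in model.nodes}
    for src, tgt, _ in model.paths:
        parents[tgt].append(src)

    def variance_sources(node: str, seen: frozenset[str]) -> list[str]:
        """Labels of free variances feeding this node through paths."""
        out = []
        if node in var_label:
            out.append(var_label[node])
        for p in parents[node]:
            if p not in seen:
                out.extend(variance_sources(p, seen | {p}))
        return out

    shares: dict[str, list[float]] = {}
    for node in model.selection:
        srcs = variance_sources(node, frozenset({node}))
        if not srcs:
            continue
        share = sm.cov[obs_idx[node], obs_idx[node]] / len(srcs)
        for l in srcs:
            shares.setdefault(l, []).append(share)
    for l, vals in shares.items():
        theta[lab_pos[l]] = float(np.mean(vals))
    # any free variance not reaching an observed node: start at 1
    for node, l in var_label.items():
        if l not in shares and theta[lab_pos[l]] == 0.0:
            theta[lab_pos[l]] = 1.0
    return theta


def fit_ml(
    model: PathModel,
    sample,
    *,
    seed: int = 0,
    max_restarts: int = 5,
    gtol: float = 1e-6,
    chi_square_multiplier: str = "n-1",
) -> FitResult:
    """Maximum-likelihood fit of a path model to sample moments or raw data.

    ``sample`` is either :class:`SampleMoments` or a DataFrame whose complete
    rows provide them.  Quasi-Newton (BFGS) minimization in a scaled
    parameter space starts from documented start values; on non-convergence
    up to ``max_restarts`` seeded, jittered restarts are attempted.  Standard
    errors come from the inverse numerical Hessian of ``(n-1) F / 2``.
    """
    if chi_square_multiplier not in ("n-1", "n"):
        raise ValueError("chi_square_multiplier must be 'n-1' or 'n'")
    comp = CompiledModel(model)
    sm = _coerce_sample(sample, model.selection)
    p = len(model.selection)
    if sm.n <= p:
        raise ValueError(f"sample size {sm.n} must exceed number of variables {p}")
    if np.linalg.eigvalsh(sm.cov).min() <= 0:
        raise ValueError("sample covariance matrix is not positive definite")

    m, S, n = sm.mean, sm.cov, sm.n
    mult = (n - 1) if chi_square_multiplier == "n-1" else n

    theta0 = _start_values(comp, sm)
    scale = np.maximum(np.abs(theta0), 1.0)

    def f_scaled(x: np.ndarray) -> float:
        mu, sigma = comp.implied(x * scale)
        val = _discrepancy(mu, sigma, m, S)
        return val if np.isfinite(val) else 1e10

    # variances are kept nonnegative: unconstrained quasi-Newton can diverge
    # along the Heywood ridge where a latent variance trades off against
    # another and goes unboundedly negative
    variance_labels = {
        v for a, b, v in model.covs if a == b and isinstance(v, str)
    }
    bounds = [
        (0.0, None) if lab in variance_labels else (None, None)
        for lab in comp.labels
    ]

    lower = np.array([b[0] if b[0] is not None else -np.inf for b in bounds])

    def projected_gnorm(res) -> float:
        at_bound = res.x <= lower + 1e-12
        proj = np.asarray(res.jac, float).copy()
        proj[at_bound & (proj > 0)] = 0.0  # KKT at an active lower bound
        return float(np.linalg.norm(proj, ord=np.inf))

    rng = np.random.default_rng(seed)
    best = None
    converged = False
    attempt = 0
    x0 = theta0 / scale
    while attempt <= max_restarts:
        res = optimize.minimize(
            f_scaled, x0, method="BFGS", jac="3-point",
            options={"gtol": gtol, "maxiter": 2000},
        )
        gnorm = float(np.linalg.norm(res.jac, ord=np.inf))
        if gnorm >= 10 * gtol:
            # stalled — typically an improper (Heywood) solution where a
            # variance dives negative; retry under the variance bounds.
            # Such fits usually remain flagged: boundary solutions are
            # reported as non-converged rather than chased.
            res_b = optimize.minimize(
                f_scaled, x0, method="L-BFGS-B",
                jac="3-point", bounds=bounds,
                options={"gtol": gtol, "ftol": 1e-14, "maxiter": 500},
            )
            gnorm_b = projected_gnorm(res_b)
            if res_b.fun <= res.fun or not np.all(res.x >= lower - 1e-12):
                res, gnorm = res_b, gnorm_b
        if best is None or res.fun < best[0].fun:
            best = (res, gnorm)
        if gnorm < 10 * gtol:
            converged = True
            best = (res, gnorm)
            break
        attempt += 1
        jitter = rng.normal(0.0, 0.1, size=comp.k)
        x0 = np.maximum(theta0 / scale * (1.0 + jitter) + 0.01 * jitter, lower)

    res, gnorm = best
    theta = res.x * scale
    F = float(res.fun)
    T = mult * F
    df = model_df(model)
    pvalue = float(stats.chi2.sf(T, df)) if df > 0 else float("nan")

    # log-likelihood of the complete-data sample at the fitted moments
    mu, sigma = comp.implied(theta)
    sign, logdet = np.linalg.slogdet(sigma)
    inv = np.linalg.inv(sigma)
    d = m - mu
    quad = (n - 1) * np.trace(S @ inv) + n * d @ inv @ d
    loglik = -0.5 * (n * (p * math.log(2 * math.pi) + logdet) + quad)

    # SEs from inverse numerical Hessian of (n-1) F / 2 in raw space;
    # a variance estimated on its boundary is held fixed there (its own SE
    # is undefined and the remaining SEs are conditional on the constraint)
    at_bound = np.array(
        [lo == 0.0 and abs(t) <= 1e-8 * s
         for t, s, lo in zip(theta, scale,
                             (b[0] for b in bounds))]
    )
    vcov, se = _hessian_vcov(comp, theta, m, S, mult, at_bound=at_bound)

    params = pd.DataFrame(
        {"estimate": theta, "se": se}, index=pd.Index(comp.labels, name="label")
    )

    Tb, dfb = baseline_fit(sm, chi_square_multiplier=chi_square_multiplier)
    fi = fit_indices(T, df, Tb, dfb)

    result = FitResult(
        model=model,
        params=params,
        paths=pd.DataFrame(),
        loglik=float(loglik),
        statistic=T,
        df=df,
        pvalue=pvalue,
        baseline_statistic=Tb,
        baseline_df=dfb,
        cfi=fi.cfi,
        tli=fi.tli,
        cfi_raw=fi.cfi_raw,
        tli_raw=fi.tli_raw,
        n=n,
        converged=converged,
        n_restarts=attempt,
        grad_norm=gnorm,
        vcov=vcov,
    )
    result.paths = standardize(model, result)
    return result


def _hessian_vcov(comp, theta, m, S, mult, at_bound=None):
    """Central-difference Hessian of mult*F/2; eigenvalue-clipped inverse.

    Parameters at an active boundary are excluded (their SE is undefined;
    the rest are conditional on the constraint).
    """
    k = len(theta)

    def f(t):
        mu, sigma = comp.implied(t)
        v = _discrepancy(mu, sigma, m, S)
        return (v if np.isfinite(v) else 1e10) * mult / 2.0

    h = 1e-4 * np.maximum(np.abs(theta), 1.0)
    H = np.zeros((k, k))
    f0 = f(theta)
    for i in range(k):
        for j in range(i, k):
            if i == j:
                tp = theta.copy(); tp[i] += h[i]
                tm = theta.copy(); tm[i] -= h[i]
                H[i, i] = (f(tp) - 2 * f0 + f(tm)) / h[i] ** 2
            else:
                tpp = theta.copy(); tpp[i] += h[i]; tpp[j] += h[j]
                tpm = theta.copy(); tpm[i] += h[i]; tpm[j] -= h[j]
                tmp = theta.copy(); tmp[i] -= h[i]; tmp[j] += h[j]
                tmm = theta.copy(); tmm[i] -= h[i]; tmm[j] -= h[j]
                H[i, j] = H[j, i] = (f(tpp) - f(tpm) - f(tmp) + f(tmm)) / (
                    4 * h[i] * h[j]
                )
    free = (
        np.ones(k, bool) if at_bound is None else ~np.asarray(at_bound, bool)
    )
    Hf = 0.5 * (H + H.T)[np.ix_(free, free)]
    eigval, eigvec = np.linalg.eigh(Hf)
    floor = 1e-10 * max(float(np.abs(eigval).max()), 1.0)
    eigval = np.maximum(eigval, floor)
    vcov_f = (eigvec / eigval) @ eigvec.T
    vcov = np.zeros((k, k))
    vcov[np.ix_(free, free)] = vcov_f
    se = np.sqrt(np.diag(vcov))
    se[~free] = np.nan
    return vcov, se


def baseline_fit(
    sample, *, selection: tuple[str, ...] | None = None,
    chi_square_multiplier: str = "n-1",
) -> tuple[float, int]:
    """Chi-square and df of the independence baseline (diagonal covariance).

    The baseline frees every variance and mean and fixes all covariances to
    zero, so its ML solution is closed-form: implied covariance = diag(S),
    implied means = sample means.
    """
    if isinstance(sample, pd.DataFrame):
        sm = sample_moments(sample, selection)
    else:
        sm = sample
    S = sm.cov
    p = S.shape[0]
    sign, logdet_s = np.linalg.slogdet(S)
    F = float(np.sum(np.log(np.diag(S))) - logdet_s)
    mult = (sm.n - 1) if chi_square_multiplier == "n-1" else sm.n
    Tb = mult * F
    dfb = p * (p + 3) // 2 - 2 * p
    return Tb, dfb


def fit_indices(T: float, df: int, T_b: float, df_b: int) -> FitIndices:
    """Comparative fit index (CFI) and Tucker-Lewis index (TLI).

    Raw (untruncated) values are reported alongside the conventional
    truncated ones.  ``df = 0`` yields undefined (None) indices.
    """
    if df_b <= 0:
        raise ValueError("baseline df must be positive")
    if df == 0:
        return FitIndices(None, None, None, None)
    num = max(T - df, 0.0)
    den = max(T_b - df_b, T - df, 0.0)
    cfi = 1.0 if den == 0 else 1.0 - num / den
    cfi_raw = float("nan") if T_b == df_b else 1.0 - (T - df) / (T_b - df_b)
    denom = T_b / df_b - 1.0
    tli_raw = float("nan") if denom == 0 else (T_b / df_b - T / df) / denom
    tli = min(max(tli_raw, 0.0), 1.0) if math.isfinite(tli_raw) else tli_raw
    return FitIndices(cfi=cfi, tli=tli, cfi_raw=cfi_raw, tli_raw=tli_raw)


def standardize(model: PathModel, fit: FitResult, z: float = 1.959964) -> pd.DataFrame:
    """Standardized path coefficients with delta-method 95% CIs.

    Each coefficient is multiplied by implied SD(source)/SD(target), with
    SDs taken from the implied moments extended to latent nodes.  CIs are
    delta-method on the standardized scale: free coefficients propagate the
    full parameter covariance; fully fixed coefficients may still get a CI
    through the variances they depend on.
    """
    comp = CompiledModel(model)
    theta = comp.theta_from(fit.estimates)
    node_pos = {n: i for i, n in enumerate(model.nodes)}

    def std_values(t: np.ndarray) -> np.ndarray:
        A, S, M = comp.matrices(t)
        total = np.linalg.inv(np.eye(comp.n_nodes) - A)
        cov = total @ S @ total.T
        sd = np.sqrt(np.maximum(np.diag(cov), 0.0))
        out = np.empty(len(model.paths))
        for i, (src, tgt, v) in enumerate(model.paths):
            coef = t[comp.labels.index(v)] if isinstance(v, str) else float(v)
            st, sS = sd[node_pos[src]], sd[node_pos[tgt]]
            out[i] = coef * st / sS if sS > 0 else np.nan
        return out

    base = std_values(theta)
    # numeric Jacobian of standardized values wrt free parameters
    k = comp.k
    J = np.zeros((len(model.paths), k))
    h = 1e-5 * np.maximum(np.abs(theta), 1.0)
    for j in range(k):
        tp = theta.copy(); tp[j] += h[j]
        tm = theta.copy(); tm[j] -= h[j]
        J[:, j] = (std_values(tp) - std_values(tm)) / (2 * h[j])
    if fit.vcov is not None:
        var = np.einsum("ij,jk,ik->i", J, fit.vcov, J)
        var[var < 0] = np.nan
        se_std = np.sqrt(var)
    else:
        se_std = np.full(len(model.paths), np.nan)

    rows = []
    labels = dict(zip(fit.params.index, zip(fit.params["estimate"], fit.params["se"])))
    for i, (src, tgt, v) in enumerate(model.paths):
        if isinstance(v, str):
            est, se = labels[v]
            free, label = True, v
        else:
            est, se, free, label = float(v), np.nan, False, ""
        rows.append(
            {
                "source": src,
                "target": tgt,
                "label": label,
                "free": free,
                "estimate": est,
                "se": se,
                "std": base[i],
                "std_se": se_std[i],
                "std_ci_low": base[i] - z * se_std[i],
                "std_ci_high": base[i] + z * se_std[i],
            }
        )
    return pd.DataFrame(rows)
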