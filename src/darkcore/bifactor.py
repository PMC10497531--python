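"""Normal-theory maximum-likelihood estimation of the orthogonal bifactor model.

The model for the p x p covariance matrix is

    Sigma(theta) = Lambda Psi Lambda' + Theta,

where Lambda (p x (1+T)) has the bifactor pattern — every item loads on the
general factor (column 0) and on exactly one scale-specific factor — Psi is
diagonal (all factors orthogonal, variances free) and Theta is diagonal
(residual variances). Each factor is given a scale by fixing one marker
loading to 1: the first item overall for the general factor and the first
item of each scale for its specific factor. The free-parameter count is
therefore (p-1) + (p-T) + p + (T+1).

Estimation minimizes the ML discrepancy

    F_ML = ln|Sigma| + tr(S Sigma^{-1}) - ln|S| - p

with an analytic gradient under L-BFGS-B; residual and factor variances are
bounded below (a fraction of the item variance) so Sigma stays positive
definite throughout, which keeps tens of thousands of unsupervised subset
fits from derailing on Heywood cases.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, eigh
from scipy.stats import chi2 as chi2_dist
from scipy.stats import ncx2

__all__ = [
    "ScaleMap",
    "ModelSpec",
    "ParameterVector",
    "FitOptions",
    "BifactorFit",
    "sample_covariance",
    "implied_sigma",
    "fml",
    "fml_gradient",
    "degrees_of_freedom",
    "fit",
    "fit_indices",
    "population_parameters",
]


@dataclass(frozen=True)
class ScaleMap:
    """Ordered assignment of item columns to trait scales."""

    item_ids: tuple[str, ...]
    item_scale: tuple[str, ...]
    reverse_coded: tuple[bool, ...] = None

    def __post_init__(self):
        item_ids = tuple(self.item_ids)
        item_scale = tuple(self.item_scale)
        rev = self.reverse_coded
        rev = tuple(bool(r) for r in rev) if rev is not None else tuple([False] * len(item_ids))
        object.__setattr__(self, "item_ids", item_ids)
        object.__setattr__(self, "item_scale", item_scale)
        object.__setattr__(self, "reverse_coded", rev)
        if len(item_ids) != len(item_scale) or len(item_ids) != len(rev):
            raise ValueError("item_ids, item_scale and reverse_coded must have equal length")
        if len(set(item_ids)) != len(item_ids):
            dup = [i for i in item_ids if item_ids.count(i) > 1][0]
            raise ValueError(f"duplicate item id {dup!r} in scale map")
        counts = pd.Series(item_scale).value_counts()
        small = counts[counts < 2]
        if len(small):
            raise ValueError(f"every scale needs >= 2 items; offending: {list(small.index)}")

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    @property
    def scale_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.item_scale:
            seen.setdefault(s)
        return list(seen)

    @property
    def n_scales(self) -> int:
        return len(self.scale_names)

    def scale_indices(self, scale: str) -> np.ndarray:
        idx = np.flatnonzero(np.asarray(self.item_scale, dtype=object) == scale)
        if idx.size == 0:
            raise KeyError(f"unknown scale {scale!r}")
        return idx

    def subset(self, scales) -> "ScaleMap":
        """Scale map restricted to the given scales, preserving item order."""
        scales = set(scales)
        unknown = scales - set(self.scale_names)
        if unknown:
            raise KeyError(f"unknown scales: {sorted(unknown)}")
        keep = [i for i, s in enumerate(self.item_scale) if s in scales]
        return ScaleMap(
            item_ids=tuple(self.item_ids[i] for i in keep),
            item_scale=tuple(self.item_scale[i] for i in keep),
            reverse_coded=tuple(self.reverse_coded[i] for i in keep),
        )

    @classmethod
    def from_population(cls, model) -> "ScaleMap":
        return cls(item_ids=tuple(model.item_ids), item_scale=tuple(model.item_scale))


@dataclass(frozen=True)
class ModelSpec:
    """Bifactor model specification with marker-variable identification.

    The general factor's marker is the first item overall; each specific
    factor's marker is the first item of its scale. Factor covariances are
    fixed to 0, factor variances and residual variances are free; no mean
    structure.
    """

    scale_map: ScaleMap

    @property
    def p(self) -> int:
        return self.scale_map.n_items

    @property
    def T(self) -> int:
        return self.scale_map.n_scales

    @property
    def item_scale_index(self) -> np.ndarray:
        """For every item, the index (0..T-1) of its scale."""
        order = {s: t for t, s in enumerate(self.scale_map.scale_names)}
        return np.array([order[s] for s in self.scale_map.item_scale])

    @property
    def scale_markers(self) -> np.ndarray:
        """First item of each scale (markers of the specific factors)."""
        idx = self.item_scale_index
        return np.array([np.flatnonzero(idx == t)[0] for t in range(self.T)])

    @property
    def n_free_parameters(self) -> int:
        p, T = self.p, self.T
        return (p - 1) + (p - T) + p + (T + 1)


@dataclass(frozen=True)
class ParameterVector:
    """Full parameter arrays (markers included at their fixed value 1)."""

    lam_g: np.ndarray  # p general loadings, lam_g[0] == 1
    lam_s: np.ndarray  # p specific loadings, markers == 1
    theta: np.ndarray  # p residual variances
    psi: np.ndarray  # T+1 factor variances, psi[0] = general

    def __post_init__(self):
        for name in ("lam_g", "lam_s", "theta", "psi"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))

    def to_free(self, spec: ModelSpec) -> np.ndarray:
        mask_s = np.ones(spec.p, dtype=bool)
        mask_s[spec.scale_markers] = False
        return np.concatenate([self.lam_g[1:], self.lam_s[mask_s], self.theta, self.psi])

    @classmethod
    def from_free(cls, x: np.ndarray, spec: ModelSpec) -> "ParameterVector":
        p, T = spec.p, spec.T
        lam_g = np.empty(p)
        lam_g[0] = 1.0
        lam_g[1:] = x[: p - 1]
        lam_s = np.empty(p)
        mask_s = np.ones(p, dtype=bool)
        mask_s[spec.scale_markers] = False
        lam_s[~mask_s] = 1.0
        lam_s[mask_s] = x[p - 1 : p - 1 + p - T]
        theta = x[p - 1 + p - T : p - 1 + 2 * p - T]
        psi = x[p - 1 + 2 * p - T :]
        return cls(lam_g=lam_g, lam_s=lam_s, theta=theta, psi=psi)

    def loading_matrix(self, spec: ModelSpec) -> np.ndarray:
        lam = np.zeros((spec.p, spec.T + 1))
        lam[:, 0] = self.lam_g
        lam[np.arange(spec.p), spec.item_scale_index + 1] = self.lam_s
        return lam


@dataclass(frozen=True)
class FitOptions:
    """Optimizer controls. ``chi2_n`` selects the chi-square convention
    (``"n"``: chi2 = N * F_ML, the default of covariance-ML software when the
    biased sample covariance is analyzed; ``"n-1"`` available)."""

    max_restarts: int = 5
    jitter_sd: float = 0.2
    maxiter: int = 10_000
    gtol: float = 1e-9
    ftol: float = 1e-14
    gtol_accept: float = 1e-5
    variance_floor: float = 1e-4
    chi2_n: str = "n"
    seed: int = 0

    def __post_init__(self):
        if self.chi2_n not in ("n", "n-1"):
            raise ValueError("chi2_n must be 'n' or 'n-1'")


@dataclass
class BifactorFit:
    """Estimation result: parameters, discrepancy and global fit indices."""

    params: ParameterVector
    spec: ModelSpec
    f_ml: float
    chi_square: float
    df: int
    p_value: float
    rmsea: float
    rmsea_ci90: tuple[float, float]
    srmr: float
    converged: bool
    n_iterations: int
    n_restarts: int
    n: int
    heywood: bool
    gradient_norm: float
    options: FitOptions = field(default=None, repr=False)

    def to_json(self) -> str:
        d = {
            "lam_g": self.params.lam_g.tolist(),
            "lam_s": self.params.lam_s.tolist(),
            "theta": self.params.theta.tolist(),
            "psi": self.params.psi.tolist(),
            "item_ids": list(self.spec.scale_map.item_ids),
            "item_scale": list(self.spec.scale_map.item_scale),
            "f_ml": self.f_ml,
            "chi_square": self.chi_square,
            "df": self.df,
            "p_value": self.p_value,
            "rmsea": self.rmsea,
            "rmsea_ci90": list(self.rmsea_ci90),
            "srmr": self.srmr,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "n_restarts": self.n_restarts,
            "n": self.n,
            "heywood": self.heywood,
            "gradient_norm": self.gradient_norm,
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, s: str) -> "BifactorFit":
        d = json.loads(s)
        spec = ModelSpec(ScaleMap(item_ids=tuple(d["item_ids"]), item_scale=tuple(d["item_scale"])))
        params = ParameterVector(
            lam_g=np.array(d["lam_g"]),
            lam_s=np.array(d["lam_s"]),
            theta=np.array(d["theta"]),
            psi=np.array(d["psi"]),
        )
        return cls(
            params=params,
            spec=spec,
            f_ml=d["f_ml"],
            chi_square=d["chi_square"],
            df=d["df"],
            p_value=d["p_value"],
            rmsea=d["rmsea"],
            rmsea_ci90=tuple(d["rmsea_ci90"]),
            srmr=d["srmr"],
            converged=d["converged"],
            n_iterations=d["n_iterations"],
            n_restarts=d["n_restarts"],
            n=d["n"],
            heywood=d["heywood"],
            gradient_norm=d["gradient_norm"],
        )


# ---------------------------------------------------------------------------
# covariance algebra
# ---------------------------------------------------------------------------


def sample_covariance(X) -> np.ndarray:
    """Biased (divide-by-N) sample covariance of the columns of X."""
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        A = X.to_numpy(dtype=float)
    else:
        A = np.asarray(X, dtype=float)
        names = [str(i) for i in range(A.shape[1])]
    if A.ndim != 2 or A.shape[0] < 2:
        raise ValueError("X must be a 2-D matrix with N >= 2 rows")
    sd = A.std(axis=0)
    if np.any(sd == 0):
        bad = names[int(np.flatnonzero(sd == 0)[0])]
        raise ValueError(f"constant column {bad!r}: covariance is degenerate")
    Ac = A - A.mean(axis=0)
    S = Ac.T @ Ac / A.shape[0]
    return (S + S.T) / 2.0


def implied_sigma(params: ParameterVector, spec: ModelSpec) -> np.ndarray:
    """Sigma(theta) = Lambda Psi Lambda' + Theta in the bifactor pattern."""
    lam = params.loading_matrix(spec)
    sigma = (lam * params.psi) @ lam.T + np.diag(params.theta)
    return (sigma + sigma.T) / 2.0


def fml(S: np.ndarray, Sigma: np.ndarray) -> float:
    """ML discrepancy ln|Sigma| + tr(S Sigma^-1) - ln|S| - p.

    Returns ``inf`` when Sigma is not positive definite (sentinel for the
    optimizer); raises if S itself is singular. Tiny negative round-off is
    clipped to 0.
    """
    S = np.asarray(S, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    p = S.shape[0]
    sign, logdet_s = np.linalg.slogdet(S)
    if sign <= 0 or not np.isfinite(logdet_s):
        raise ValueError("sample covariance is singular; F_ML undefined")
    try:
        c, low = cho_factor(Sigma, lower=True, check_finite=False)
    except np.linalg.LinAlgError:
        return np.inf
    if np.any(np.diag(c) <= 0):
        return np.inf
    logdet_sigma = 2.0 * np.sum(np.log(np.diag(c)))
    sigma_inv_s = cho_solve((c, low), S, check_finite=False)
    val = logdet_sigma + np.trace(sigma_inv_s) - logdet_s - p
    return max(0.0, float(val))


def fml_gradient(params: ParameterVector, spec: ModelSpec, S: np.ndarray) -> np.ndarray:
    """Analytic gradient of F_ML w.r.t. the free parameter vector.

    With G = Sigma^-1 (Sigma - S) Sigma^-1: dF/dLambda = 2 G Lambda Psi,
    dF/dPsi_k = (Lambda' G Lambda)_kk, dF/dTheta_i = G_ii.
    """
    sigma = implied_sigma(params, spec)
    c, low = cho_factor(sigma, lower=True, check_finite=False)
    p = spec.p
    sigma_inv = cho_solve((c, low), np.eye(p), check_finite=False)
    G = sigma_inv - sigma_inv @ S @ sigma_inv
    G = (G + G.T) / 2.0
    lam = params.loading_matrix(spec)
    d_lam = 2.0 * (G @ lam) * params.psi
    d_psi = np.einsum("ik,ij,jk->k", lam, G, lam)
    d_theta = np.diag(G).copy()

    mask_s = np.ones(p, dtype=bool)
    mask_s[spec.scale_markers] = False
    g_lam_g = d_lam[1:, 0]
    g_lam_s = d_lam[np.arange(p), spec.item_scale_index + 1][mask_s]
    return np.concatenate([g_lam_g, g_lam_s, d_theta, d_psi])


def degrees_of_freedom(spec: ModelSpec) -> int:
    """p(p+1)/2 distinct moments minus the free-parameter count."""
    p = spec.p
    return p * (p + 1) // 2 - spec.n_free_parameters


# ---------------------------------------------------------------------------
# fit indices
# ---------------------------------------------------------------------------


def _ncp_bound(chi_square: float, df: int, prob: float) -> float:
    """Noncentrality lambda with ncx2(df, lambda).cdf(chi_square) == prob, or 0."""
    if chi2_dist.cdf(chi_square, df) < prob:
        return 0.0
    hi = max(chi_square - df, 1.0)
    while ncx2.cdf(chi_square, df, hi) > prob:
        hi *= 2.0
        if hi > 1e12:
            return hi
    return optimize.brentq(lambda lam: ncx2.cdf(chi_square, df, lam) - prob, 0.0, hi, xtol=1e-10)


def fit_indices(chi_square: float, df: int, n: int, S: np.ndarray, Sigma_hat: np.ndarray):
    """RMSEA (with 90% CI from the noncentral chi-square), SRMR and p-value.

    RMSEA = sqrt(max(0, (chi2 - df) / (df * n))); the CI endpoints invert the
    noncentral chi-square tail probabilities 0.95 / 0.05 at the observed
    statistic. SRMR is the root mean square of correlation-metric residuals
    over the p(p+1)/2 unique elements including the diagonal.
    """
    if df <= 0:
        raise ValueError("RMSEA undefined for df <= 0")
    if n <= 1:
        raise ValueError("n must exceed 1")
    rmsea = float(np.sqrt(max(0.0, (chi_square - df) / (df * n))))
    lam_lo = _ncp_bound(chi_square, df, 0.95)
    lam_hi = _ncp_bound(chi_square, df, 0.05)
    ci = (float(np.sqrt(lam_lo / (df * n))), float(np.sqrt(lam_hi / (df * n))))

    d_s = np.sqrt(np.diag(S))
    d_m = np.sqrt(np.diag(Sigma_hat))
    r_s = S / np.outer(d_s, d_s)
    r_m = Sigma_hat / np.outer(d_m, d_m)
    iu = np.triu_indices(S.shape[0])
    srmr = float(np.sqrt(np.mean((r_s[iu] - r_m[iu]) ** 2)))

    p_value = float(chi2_dist.sf(chi_square, df))
    return rmsea, ci, srmr, p_value


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------


def _start_values(S: np.ndarray, spec: ModelSpec) -> ParameterVector:
    """Principal-axis start: first component scaled to the marker metric;
    specific loadings 0.3, residuals half the item variance, factor variances
    from the marker items."""
    p = spec.p
    w, v = eigh(S, subset_by_index=(p - 1, p - 1))
    a = np.sqrt(max(w[-1], 1e-8)) * v[:, -1]
    if a.sum() < 0:
        a = -a
    a0 = a[0]
    if abs(a0) < 0.05 * np.sqrt(S[0, 0]):
        a0 = 0.5 * np.sqrt(S[0, 0])
    lam_g = a / a0
    lam_g[0] = 1.0
    lam_s = np.full(p, 0.3)
    lam_s[spec.scale_markers] = 1.0
    theta = 0.5 * np.diag(S).copy()
    psi = np.empty(spec.T + 1)
    psi[0] = a0**2
    psi[1:] = 0.25 * np.diag(S)[spec.scale_markers]
    return ParameterVector(lam_g=lam_g, lam_s=lam_s, theta=theta, psi=psi)


def _bounds(S: np.ndarray, spec: ModelSpec, floor: float):
    p, T = spec.p, spec.T
    var = np.diag(S)
    lo = np.full(spec.n_free_parameters, -np.inf)
    hi = np.full(spec.n_free_parameters, np.inf)
    off = (p - 1) + (p - T)
    lo[off : off + p] = floor * var
    lo[off + p] = floor * var[0]
    lo[off + p + 1 :] = floor * var[spec.scale_markers]
    return np.stack([lo, hi], axis=1)


def fit(S: np.ndarray, n: int, spec: ModelSpec, options: FitOptions | None = None) -> BifactorFit:
    """Fit the bifactor model to a sample covariance matrix by ML.

    Minimizes F_ML with L-BFGS-B and the analytic gradient; on failure
    restarts with multiplicative lognormal jitter (sd ``options.jitter_sd``)
    of the starting values, keeping the best solution across attempts.
    Non-convergence is reported via ``converged=False``, never silently
    dropped. chi2 = n * F_ML (or (n-1) * F_ML via options), p-value from the
    central chi-square upper tail.
    """
    options = options or FitOptions()
    S = np.asarray(S, dtype=float)
    p = spec.p
    if S.shape != (p, p):
        raise ValueError(f"covariance is {S.shape}, spec expects ({p}, {p})")
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("covariance matrix is not symmetric")
    eigmin = eigh(S, eigvals_only=True, subset_by_index=(0, 0))[0]
    if eigmin <= 0:
        warnings.warn("sample covariance is not positive definite", stacklevel=2)
    if n < p:
        warnings.warn(f"sample size n={n} below item count p={p}", stacklevel=2)

    sign, logdet_s = np.linalg.slogdet(S)
    if sign <= 0:
        raise ValueError("singular sample covariance; cannot evaluate F_ML")

    bounds = _bounds(S, spec, options.variance_floor)
    x0 = _start_values(S, spec).to_free(spec)
    x0 = np.clip(x0, bounds[:, 0], bounds[:, 1])

    def objective(x):
        params = ParameterVector.from_free(x, spec)
        sigma = implied_sigma(params, spec)
        try:
            c, low = cho_factor(sigma, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return 1e10, np.zeros_like(x)
        logdet_sigma = 2.0 * np.sum(np.log(np.diag(c)))
        sigma_inv = cho_solve((c, low), np.eye(p), check_finite=False)
        f = logdet_sigma + np.sum(sigma_inv * S) - logdet_s - p
        G = sigma_inv - sigma_inv @ S @ sigma_inv
        G = (G + G.T) / 2.0
        lam = params.loading_matrix(spec)
        d_lam = 2.0 * (G @ lam) * params.psi
        d_psi = np.einsum("ik,ij,jk->k", lam, G, lam)
        mask_s = np.ones(p, dtype=bool)
        mask_s[spec.scale_markers] = False
        grad = np.concatenate(
            [
                d_lam[1:, 0],
                d_lam[np.arange(p), spec.item_scale_index + 1][mask_s],
                np.diag(G),
                d_psi,
            ]
        )
        return f, grad

    best = None
    n_restarts_used = 0
    rng = np.random.default_rng(options.seed)
    for attempt in range(options.max_restarts + 1):
        if attempt == 0:
            x_init = x0
        else:
            n_restarts_used += 1
            jitter = rng.lognormal(mean=0.0, sigma=options.jitter_sd, size=x0.size)
            x_init = np.clip(x0 * jitter, bounds[:, 0], bounds[:, 1])
        res = optimize.minimize(
            objective,
            x_init,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={
                "maxiter": options.maxiter,
                "maxfun": 5 * options.maxiter,
                "gtol": options.gtol,
                "ftol": options.ftol,
                "maxcor": 30,
            },
        )
        # the line search may stall at machine precision with the projected
        # gradient already negligible; that still counts as converged
        grad_ok = np.isfinite(res.fun) and np.max(np.abs(res.jac)) < options.gtol_accept
        ok = (bool(res.success) or grad_ok) and np.isfinite(res.fun)
        if best is None or (np.isfinite(res.fun) and res.fun < best[0].fun):
            best = (res, ok)
        if ok:
            break

    res, converged = best
    params = ParameterVector.from_free(res.x, spec)
    f_val = max(0.0, float(res.fun))
    n_eff = n if options.chi2_n == "n" else n - 1
    chi_square = n_eff * f_val
    df = degrees_of_freedom(spec)
    sigma_hat = implied_sigma(params, spec)
    if df > 0:
        rmsea, ci, srmr, p_value = fit_indices(chi_square, df, n_eff, S, sigma_hat)
    else:
        rmsea, ci, srmr, p_value = 0.0, (0.0, 0.0), 0.0, 1.0

    floor_hit = np.any(np.isclose(params.theta, bounds[(p - 1) + (p - spec.T) : (p - 1) + (p - spec.T) + p, 0])) or np.any(
        np.isclose(params.psi, bounds[-(spec.T + 1) :, 0])
    )
    return BifactorFit(
        params=params,
        spec=spec,
        f_ml=f_val,
        chi_square=float(chi_square),
        df=int(df),
        p_value=p_value,
        rmsea=rmsea,
        rmsea_ci90=ci,
        srmr=srmr,
        converged=bool(converged),
        n_iterations=int(res.nit),
        n_restarts=n_restarts_used,
        n=int(n),
        heywood=bool(floor_hit),
        gradient_norm=float(np.max(np.abs(res.jac))),
        options=options,
    )


def population_parameters(model, spec: ModelSpec | None = None) -> ParameterVector:
    """True parameters of a population model re-expressed in the marker metric.

    The simulator works on the standardized metric (unit factor variances);
    the fitted model fixes marker loadings to 1 instead, so loadings divide
    by their marker and factor variances become the squared marker loading.
    """
    if spec is None:
        spec = ModelSpec(ScaleMap.from_population(model))
    lam_g = model.general_loadings.astype(float)
    lam_s = model.specific_loadings.astype(float)
    theta = 1.0 - lam_g**2 - lam_s**2
    psi = np.empty(spec.T + 1)
    psi[0] = lam_g[0] ** 2
    markers = spec.scale_markers
    psi[1:] = lam_s[markers] ** 2
    lam_g = lam_g / lam_g[0]
    out_s = lam_s.copy()
    for t, m in enumerate(markers):
        idx = spec.scale_map.scale_indices(spec.scale_map.scale_names[t])
        out_s[idx] = lam_s[idx] / lam_s[m]
    return ParameterVector(lam_g=lam_g, lam_s=out_s, theta=theta, psi=psi)


def subset_seed(global_seed: int, subset) -> int:
    """Deterministic per-subset seed: CRC32 of the sorted trait names mixed
    with the global seed, kept below 2^31."""
    key = ",".join(sorted(subset)).encode()
    return (zlib.crc32(key) ^ (global_seed * 2654435761)) & 0x7FFFFFFF
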