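"""Crossed random-intercept linear mixed models, estimated from scratch.

The model is

    y_i = x_i' beta + gamma_{k[i]} + alpha_{j[i]} + delta_{t[i]} + eps_i

with mutually uncorrelated Gaussian random intercepts for individual (k),
individual-by-indicator (j) and individual-by-wave (t) cells, so the total
phenotypic variance decomposes into trait, indicator, state and residual
components.  A genotype covariate x can additionally moderate any random
term through an extra random effect xi scaled by x (entries of that term's
design block equal x_i instead of 1), so carriers of the risk genotype have
inflated variance at that level -- an indirect gene-environment-interaction
test.

Estimation maximizes the REML (or ML) criterion profiled over the residual
variance and the fixed effects.  Writing theta_t = sd_t / sd_resid and D the
per-column scaling of the stacked sparse random-effects design Z, the
profiled criterion uses the penalized-least-squares system

    M = D Z'Z D + I,      S = X'X - (D Z'X)' M^{-1} (D Z'X),

with log|V|-type terms obtained from sparse LU factors of M, so a single
evaluation costs one sparse factorization regardless of the number of
individuals.  The criterion is optimized over log-theta by L-BFGS-B with
seeded random restarts; profile-likelihood intervals invert the chi-square(1)
deviance cutoff on the non-profiled criterion.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
from scipy import optimize, stats
from scipy.sparse.linalg import splu

logger = logging.getLogger("sociovar")

#: Grouping factors the engine knows, in canonical order.
RANDOM_TERMS = ("individual", "individual_indicator", "individual_wave")

#: Relative-SD threshold below which a variance is reported as a boundary zero.
BOUNDARY_THETA = np.exp(-12.0)

_ETA_BOUNDS = (-13.0, 8.0)


class ConvergenceError(RuntimeError):
    """Optimizer failed; carries the best parameters found."""

    def __init__(self, msg, best_eta=None):
        super().__init__(msg)
        self.best_eta = best_eta


# ---------------------------------------------------------------------------
# model specification and design construction


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model description.

    ``fixed_terms`` name covariate columns ("intercept", "age", "gender",
    "wave", or any genotype covariate such as "risk_score" /
    "rs2254298_risk").  ``random_terms`` are drawn from
    :data:`RANDOM_TERMS`.  Each ``gxe_terms`` entry is a
    ``(genotype_covariate, random_term)`` pair adding a variance component
    for the covariate-scaled deviation at that level.  Random effects never
    covary across terms.
    """

    fixed_terms: tuple[str, ...] = ("intercept", "age", "gender", "wave")
    random_terms: tuple[str, ...] = RANDOM_TERMS
    gxe_terms: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        if len(set(self.random_terms)) != len(self.random_terms):
            raise ValueError("random_terms must be distinct")
        for t in self.random_terms:
            if t not in RANDOM_TERMS:
                raise ValueError(f"unknown random term {t!r}")
        for cov, t in self.gxe_terms:
            if t not in self.random_terms:
                raise ValueError(f"gxe term {cov!r} x {t!r}: {t!r} not in random_terms")

    @property
    def block_names(self) -> tuple[str, ...]:
        return tuple(self.random_terms) + tuple(
            f"gxe_{cov}_{term}" for cov, term in self.gxe_terms
        )


@dataclass
class DesignMatrices:
    """Fixed and random design matrices for one model fit."""

    X: np.ndarray
    y: np.ndarray
    Z_blocks: list
    block_names: list[str]
    fixed_names: list[str]
    n_individuals: int
    n_dropped: int
    row_meta: pd.DataFrame


def _group_codes(df: pd.DataFrame, term: str) -> np.ndarray:
    if term == "individual":
        keys = df["individual_id"]
    elif term == "individual_indicator":
        keys = pd.MultiIndex.from_arrays([df["individual_id"], df["indicator"]])
    elif term == "individual_wave":
        keys = pd.MultiIndex.from_arrays([df["individual_id"], df["wave_year"]])
    else:  # pragma: no cover - guarded by ModelSpec
        raise ValueError(f"unknown random term {term!r}")
    codes, _ = pd.factorize(keys, sort=True)
    return codes


def _indicator_block(codes: np.ndarray, values: np.ndarray | None = None) -> sp.csr_matrix:
    n = len(codes)
    q = int(codes.max()) + 1 if n else 0
    data = np.ones(n) if values is None else np.asarray(values, dtype=float)
    return sp.csr_matrix((data, (np.arange(n), codes)), shape=(n, q))


def build_design(
    observations: pd.DataFrame,
    genotypes: pd.DataFrame | None,
    spec: ModelSpec,
    response: str = "score_std",
) -> DesignMatrices:
    """Assemble X, y and the sparse random-effect blocks for ``spec``.

    The wave covariate is coded as years since the earliest observed wave.
    Rows with a missing response or any missing required covariate are
    dropped (available-case analysis) with a logged count.  Collinear fixed
    columns are dropped with a warning.
    """
    df = observations.copy()
    df["wave"] = df["wave_year"] - df["wave_year"].min()
    df["intercept"] = 1.0

    geno_covs = {cov for cov, _ in spec.gxe_terms}
    geno_covs |= {t for t in spec.fixed_terms if t not in df.columns}
    if geno_covs:
        if genotypes is None:
            raise ValueError(
                f"model requests genotype covariates {sorted(geno_covs)} but no "
                "genotype table was supplied"
            )
        missing_cols = geno_covs - set(genotypes.columns)
        if missing_cols:
            raise ValueError(f"genotype table lacks columns {sorted(missing_cols)}")
        df = df.merge(
            genotypes[["individual_id", *sorted(geno_covs)]], on="individual_id", how="left"
        )

    required = list(dict.fromkeys([response, *spec.fixed_terms, *(c for c, _ in spec.gxe_terms)]))
    keep = df[required].notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "build_design: dropped %d of %d rows with missing response/covariates",
            n_dropped,
            len(df),
        )
    df = df.loc[keep].reset_index(drop=True)
    if not len(df):
        raise ValueError("no complete observations left after listwise deletion")

    X = df[list(spec.fixed_terms)].to_numpy(dtype=float)
    fixed_names = list(spec.fixed_terms)
    # drop collinear columns via pivoted QR
    _, R, piv = sla.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        dropped = [fixed_names[i] for i in sorted(piv[rank:])]
        warnings.warn(f"dropping collinear fixed-effect columns: {dropped}")
        keep_idx = sorted(piv[:rank])
        X = X[:, keep_idx]
        fixed_names = [fixed_names[i] for i in keep_idx]

    y = df[response].to_numpy(dtype=float)

    term_codes = {t: _group_codes(df, t) for t in spec.random_terms}
    Z_blocks = [_indicator_block(term_codes[t]) for t in spec.random_terms]
    for cov, term in spec.gxe_terms:
        Z_blocks.append(_indicator_block(term_codes[term], df[cov].to_numpy(dtype=float)))

    return DesignMatrices(
        X=X,
        y=y,
        Z_blocks=Z_blocks,
        block_names=list(spec.block_names),
        fixed_names=fixed_names,
        n_individuals=int(df["individual_id"].nunique()),
        n_dropped=n_dropped,
        row_meta=df[["individual_id", "indicator", "wave_year"]],
    )


# ---------------------------------------------------------------------------
# profiled criterion


class _Workspace:
    """Cross-product matrices precomputed once per design."""

    def __init__(self, design: DesignMatrices):
        X, y = design.X, design.y
        Z = sp.hstack([b.tocsr() for b in design.Z_blocks], format="csr")
        self.ZtZ = (Z.T @ Z).tocsr()
        self.ZtX = np.asarray((Z.T @ X))
        self.Zty = np.asarray(Z.T @ y).ravel()
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.n, self.p = X.shape
        self.q = Z.shape[1]
        sizes = [b.shape[1] for b in design.Z_blocks]
        self.col_block = np.repeat(np.arange(len(sizes)), sizes)
        self.n_blocks = len(sizes)
        self.block_names = design.block_names
        self._eye = sp.eye(self.q, format="csr")

    def solve_system(self, theta: np.ndarray):
        """Factorize M = D Z'Z D + I and return the pieces of the criterion."""
        d = np.asarray(theta, dtype=float)[self.col_block]
        D = sp.diags(d)
        M = (D @ self.ZtZ @ D + self._eye).tocsc()
        lu = splu(
            M,
            permc_spec="MMD_AT_PLUS_A",
            diag_pivot_thresh=0.0,
            options={"SymmetricMode": True},
        )
        logdet_M = float(np.log(np.abs(lu.U.diagonal())).sum())
        cZX = d[:, None] * self.ZtX
        czy = d * self.Zty
        MiZX = lu.solve(cZX)
        Mizy = lu.solve(czy)
        S = self.XtX - cZX.T @ MiZX
        rhs = self.Xty - MiZX.T @ czy
        cS = sla.cho_factor(S)
        beta = sla.cho_solve(cS, rhs)
        logdet_S = 2.0 * float(np.log(np.diag(cS[0])).sum())
        b = Mizy - MiZX @ beta
        r2 = self.yty - czy @ b - self.Xty @ beta
        r2 = max(float(r2), 1e-300)
        return {
            "logdet_M": logdet_M,
            "logdet_S": logdet_S,
            "beta": beta,
            "b": b,
            "r2": r2,
            "cS": cS,
        }

    def profiled_neg2ll(self, theta: np.ndarray, reml: bool = True) -> float:
        """-2 log-likelihood profiled over beta and the residual variance."""
        parts = self.solve_system(theta)
        nu = self.n - self.p if reml else self.n
        sigma2 = parts["r2"] / nu
        val = parts["logdet_M"] + nu * (1.0 + np.log(2.0 * np.pi * sigma2))
        if reml:
            val += parts["logdet_S"]
        return float(val)

    def neg2ll(self, theta: np.ndarray, sigma2: float, reml: bool = True) -> float:
        """-2 log-likelihood at explicit variance parameters (beta profiled)."""
        parts = self.solve_system(theta)
        nu = self.n - self.p if reml else self.n
        val = (
            parts["logdet_M"]
            + nu * np.log(2.0 * np.pi * sigma2)
            + parts["r2"] / sigma2
        )
        if reml:
            val += parts["logdet_S"]
        return float(val)


# ---------------------------------------------------------------------------
# results containers


def _round_half_away(x: float, decimals: int) -> float:
    f = 10.0**decimals
    return float(np.sign(x) * np.floor(np.abs(x) * f + 0.5) / f)


@dataclass
class VarianceComponents:
    """Estimated variances with shares of the summed model variance."""

    variances: dict[str, float]
    boundary: dict[str, bool] = field(default_factory=dict)
    intervals: dict[str, tuple[float, float]] = field(default_factory=dict)

    def shares(self, decimals: int | None = None) -> dict[str, float]:
        return variance_shares(self, decimals=decimals)

    def as_frame(self, decimals: int = 1) -> pd.DataFrame:
        shares = self.shares()
        rows = []
        for name, v in self.variances.items():
            rows.append(
                {
                    "component": name,
                    "var": v,
                    "sd": np.sqrt(v),
                    "var_pct": _round_half_away(shares[name], decimals),
                }
            )
        return pd.DataFrame(rows)


def variance_shares(components, decimals: int | None = None) -> dict[str, float]:
    """Percentage share of each component in the summed model variance.

    Shares are taken over exactly the components present in the fitted model
    (including any genotype-moderated terms) and rounded half-away-from-zero
    when ``decimals`` is given.
    """
    var = components.variances if isinstance(components, VarianceComponents) else dict(components)
    total = float(sum(var.values()))
    if any(v < 0 for v in var.values()):
        raise ValueError("variance components must be nonnegative")
    if total <= 0:
        raise ZeroDivisionError("all variance components are zero; shares undefined")
    shares = {k: 100.0 * v / total for k, v in var.items()}
    if decimals is not None:
        shares = {k: _round_half_away(s, decimals) for k, s in shares.items()}
    return shares


@dataclass
class FitResult:
    """Fixed effects, variance components and fit metadata for one model."""

    betas: pd.DataFrame
    components: VarianceComponents
    loglik: float
    criterion: str
    aic: float | None
    converged: bool
    n_obs: int
    n_individuals: int
    n_params: int
    spec: ModelSpec
    data_digest: str
    _ws: _Workspace | None = field(default=None, repr=False)
    _theta: np.ndarray | None = field(default=None, repr=False)
    _sigma2: float | None = field(default=None, repr=False)
    _design: "DesignMatrices | None" = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "criterion": self.criterion,
            "loglik": self.loglik,
            "aic": self.aic,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "n_individuals": self.n_individuals,
            "n_params": self.n_params,
            "fixed_effects": self.betas.to_dict(orient="records"),
            "variance_components": self.components.variances,
            "variance_shares": self.components.shares(),
            "boundary": self.components.boundary,
            "intervals": {k: list(v) for k, v in self.components.intervals.items()},
            "spec": {
                "fixed_terms": list(self.spec.fixed_terms),
                "random_terms": list(self.spec.random_terms),
                "gxe_terms": [list(t) for t in self.spec.gxe_terms],
            },
        }


def _digest(y: np.ndarray) -> str:
    # identifies the observation set (not the design): AIC is comparable
    # across specs exactly when the response rows coincide
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(np.round(y, 10)).tobytes())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# fitting


def _optimize_theta(ws: _Workspace, reml: bool, n_restarts: int, seed: int):
    """Minimize the profiled criterion over eta = log(theta)."""
    k = ws.n_blocks
    rng = np.random.default_rng(seed)
    starts = [np.zeros(k)]
    starts += [rng.uniform(-2.0, 1.0, size=k) for _ in range(max(0, n_restarts - 1))]
    obj = lambda e: ws.profiled_neg2ll(np.exp(e), reml=reml)  # noqa: E731
    best = None
    any_success = False
    for eta0 in starts:
        res = optimize.minimize(
            obj,
            eta0,
            method="L-BFGS-B",
            bounds=[_ETA_BOUNDS] * k,
            # eps sized so finite-difference steps dominate criterion round-off
            options={"maxiter": 200, "ftol": 1e-11, "gtol": 1e-6, "eps": 1e-5},
        )
        if res.success:
            any_success = True
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError("optimizer produced no finite criterion value")
    # derivative-free polish: sharpens the quasi-Newton solution (whose line
    # search can stall on round-off noise near the optimum) to ~1e-9 in eta
    polish = optimize.minimize(
        obj,
        best.x,
        method="Nelder-Mead",
        options={"maxiter": 500, "xatol": 1e-9, "fatol": 1e-11},
    )
    if polish.fun <= best.fun + 1e-9:
        best = polish
        any_success = any_success or polish.success
    if not any_success:
        raise ConvergenceError(
            f"no restart converged (best criterion {best.fun:.6g})", best_eta=best.x
        )
    best.x = np.clip(best.x, _ETA_BOUNDS[0], _ETA_BOUNDS[1])
    return best


def fit(
    design: DesignMatrices,
    spec: ModelSpec | None = None,
    criterion: str = "reml",
    n_restarts: int = 3,
    seed: int = 0,
) -> FitResult:
    """Fit the mixed model by REML (default) or ML.

    Variance parameters are estimated by maximizing the criterion profiled
    over log-SD-ratio parameters; fixed effects are the GLS solution at the
    optimum, with large-sample normal p-values.  Variances whose relative SD
    falls below ``exp(-12)`` are reported as boundary zeros.  AIC
    (``-2 * ML loglik + 2 * n_params``) is attached to ML fits only.
    """
    if criterion not in ("reml", "ml"):
        raise ValueError("criterion must be 'reml' or 'ml'")
    spec = spec or ModelSpec(
        fixed_terms=tuple(design.fixed_names),
        random_terms=tuple(n for n in design.block_names if n in RANDOM_TERMS),
    )
    reml = criterion == "reml"
    ws = _Workspace(design)
    n_params = ws.p + ws.n_blocks + 1
    if ws.n < n_params:
        raise ValueError(f"n_obs={ws.n} smaller than parameter count {n_params}")

    if np.var(design.y) == 0.0:
        # degenerate input: a constant response carries no variance to split
        return _degenerate_fit(design, spec, criterion, ws, n_params)

    best = _optimize_theta(ws, reml, n_restarts, seed)
    theta = np.exp(best.x)
    parts = ws.solve_system(theta)
    nu = ws.n - ws.p if reml else ws.n
    sigma2 = parts["r2"] / nu

    boundary = {name: bool(t < BOUNDARY_THETA) for name, t in zip(ws.block_names, theta)}
    variances = {
        name: (0.0 if boundary[name] else float(t**2 * sigma2))
        for name, t in zip(ws.block_names, theta)
    }
    variances["residual"] = float(sigma2)
    boundary["residual"] = False

    se = np.sqrt(np.diag(sigma2 * sla.cho_solve(parts["cS"], np.eye(ws.p))))
    z = parts["beta"] / se
    betas = pd.DataFrame(
        {
            "term": design.fixed_names,
            "estimate": parts["beta"],
            "se": se,
            "p_value": 2.0 * stats.norm.sf(np.abs(z)),
        }
    )
    loglik = -0.5 * best.fun
    aic = (-2.0 * loglik + 2.0 * n_params) if criterion == "ml" else None
    return FitResult(
        betas=betas,
        components=VarianceComponents(variances, boundary=boundary),
        loglik=float(loglik),
        criterion=criterion,
        aic=aic,
        converged=True,
        n_obs=ws.n,
        n_individuals=design.n_individuals,
        n_params=n_params,
        spec=spec,
        data_digest=_digest(design.y),
        _ws=ws,
        _theta=theta,
        _sigma2=float(sigma2),
        _design=design,
    )


def _degenerate_fit(design, spec, criterion, ws, n_params) -> FitResult:
    beta = np.zeros(ws.p)
    names = list(design.fixed_names)
    if "intercept" in names:
        beta[names.index("intercept")] = design.y[0]
    variances = {name: 0.0 for name in ws.block_names}
    variances["residual"] = 0.0
    boundary = {name: True for name in variances}
    betas = pd.DataFrame(
        {"term": names, "estimate": beta, "se": np.zeros(ws.p), "p_value": np.ones(ws.p)}
    )
    return FitResult(
        betas=betas,
        components=VarianceComponents(variances, boundary=boundary),
        loglik=np.inf,
        criterion=criterion,
        aic=None,
        converged=True,
        n_obs=ws.n,
        n_individuals=design.n_individuals,
        n_params=n_params,
        spec=spec,
        data_digest=_digest(design.y),
        _ws=ws,
        _theta=np.zeros(ws.n_blocks),
        _sigma2=0.0,
    )


# ---------------------------------------------------------------------------
# profile-likelihood confidence intervals


def _profile_deviance_fn(fit_result: FitResult, component: str, reml: bool):
    """Return f(v) = min over nuisance parameters of the non-profiled criterion
    with the named component's variance fixed at v."""
    ws = fit_result._ws
    theta_hat = np.maximum(fit_result._theta, 1e-8)
    sigma2_hat = fit_result._sigma2
    names = list(ws.block_names)
    opts = {"maxiter": 100, "ftol": 1e-9, "eps": 1e-5}
    if component == "residual":
        free0 = np.log(theta_hat)

        def dev(v: float) -> float:
            if v <= 0:
                return np.inf
            # theta must be rescaled so component SDs stay fixed as sigma moves
            def obj(eta):
                return ws.neg2ll(np.exp(eta), v, reml=reml)

            res = optimize.minimize(
                obj, np.log(theta_hat * np.sqrt(sigma2_hat / v)), method="L-BFGS-B",
                bounds=[_ETA_BOUNDS] * len(free0), options=opts,
            )
            return float(res.fun)

        return dev

    if component not in names:
        raise KeyError(f"unknown component {component!r}; have {names + ['residual']}")
    ci = names.index(component)
    others = [i for i in range(len(names)) if i != ci]

    def dev(v: float) -> float:
        if v < 0:
            return np.inf

        def obj(params):
            log_sigma2 = params[-1]
            sigma2 = np.exp(log_sigma2)
            theta = np.empty(len(names))
            theta[others] = np.exp(params[:-1])
            theta[ci] = np.sqrt(v / sigma2)
            return ws.neg2ll(theta, sigma2, reml=reml)

        x0 = np.concatenate([np.log(theta_hat[others]), [np.log(sigma2_hat)]])
        res = optimize.minimize(
            obj, x0, method="L-BFGS-B",
            bounds=[_ETA_BOUNDS] * len(others) + [(-30.0, 10.0)],
            options=opts,
        )
        return float(res.fun)

    return dev


def profile_ci(
    fit_result: FitResult,
    component: str,
    level: float = 0.95,
    method: str = "profile",
    n_boot: int = 200,
    seed: int = 0,
) -> tuple[float, float]:
    """Confidence interval for one variance component.

    ``method='profile'`` (default) finds where the profiled REML deviance
    rises by the chi-square(1) quantile above its minimum, truncating the
    lower bound at zero.  ``method='boot'`` is a parametric-bootstrap
    percentile interval.
    """
    if fit_result._ws is None:
        raise ValueError("fit result does not carry its workspace; refit in-process")
    if not fit_result.converged:
        raise ValueError("profile_ci requires a converged fit")
    if method == "boot":
        return _bootstrap_ci(fit_result, component, level, n_boot, seed)
    if method != "profile":
        raise ValueError("method must be 'profile' or 'boot'")

    reml = fit_result.criterion == "reml"
    ws = fit_result._ws
    v_hat = fit_result.components.variances[component]
    dev = _profile_deviance_fn(fit_result, component, reml)
    dev_min = ws.neg2ll(fit_result._theta, fit_result._sigma2, reml=reml)
    cutoff = dev_min + stats.chi2.ppf(level, 1)

    scale = v_hat if v_hat > 0 else fit_result._sigma2 * 0.01

    def g(v):
        return dev(v) - cutoff

    xtol = max(scale, 1e-8) * 1e-4

    # lower bound (variance is bounded below by zero)
    if component != "residual" and g(0.0) <= 0:
        lo = 0.0
    else:
        left, right = None, max(v_hat, scale)
        v = right * 0.5
        for _ in range(40):
            if g(v) > 0:
                left = v
                break
            right = v
            v *= 0.4
            if component == "residual" and v < scale * 1e-8:
                break
        if left is None:
            warnings.warn(f"{component}: lower profile bound did not bracket; truncated at 0")
            lo = 0.0
        else:
            lo = float(optimize.brentq(g, left, right, xtol=xtol, rtol=1e-5))
    # upper bound
    v = max(v_hat, scale) * 1.5
    left, right = max(v_hat, 0.0), None
    for _ in range(60):
        if g(v) > 0:
            right = v
            break
        left = v
        v *= 1.6
    if right is None:
        warnings.warn(f"{component}: upper profile bound did not bracket; one-sided interval")
        hi = np.inf
    else:
        hi = float(optimize.brentq(g, left, right, xtol=xtol, rtol=1e-5))
    return (lo, hi)


def _bootstrap_ci(fit_result, component, level, n_boot, seed):
    """Percentile interval from parametric-bootstrap refits."""
    design = fit_result._design
    if design is None:
        raise ValueError("bootstrap CI requires the fit's design matrices")
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n_boot):
        y_star = simulate_from_fit(fit_result, design, rng)
        d_star = DesignMatrices(
            X=design.X, y=y_star, Z_blocks=design.Z_blocks,
            block_names=design.block_names, fixed_names=design.fixed_names,
            n_individuals=design.n_individuals, n_dropped=0, row_meta=design.row_meta,
        )
        r = fit(d_star, fit_result.spec, criterion=fit_result.criterion,
                n_restarts=1, seed=int(rng.integers(2**31 - 1)))
        draws.append(r.components.variances[component])
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [a, 1.0 - a])
    return (max(0.0, float(lo)), float(hi))


def simulate_from_fit(fit_result: FitResult, design: DesignMatrices, rng) -> np.ndarray:
    """Draw a response vector from the fitted model (parametric bootstrap)."""
    names = list(fit_result._ws.block_names)
    y = design.X @ fit_result.betas["estimate"].to_numpy()
    for name, Z in zip(names, design.Z_blocks):
        v = fit_result.components.variances[name]
        if v > 0:
            # gxe blocks carry the covariate in their entries; the latent draw
            # itself is unit-scaled by sd
            u = rng.normal(0.0, np.sqrt(v), size=Z.shape[1])
            y = y + Z @ u
    y = y + rng.normal(0.0, np.sqrt(fit_result.components.variances["residual"]), size=len(y))
    return y


# ---------------------------------------------------------------------------
# model comparison and higher-level fits


def compare_aic(fit_a: FitResult, fit_b: FitResult):
    """Return (preferred spec, AIC difference a-b); requires ML fits on identical data."""
    for f in (fit_a, fit_b):
        if f.criterion != "ml" or f.aic is None:
            raise ValueError("compare_aic requires ML fits with AIC")
    if fit_a.n_obs != fit_b.n_obs or fit_a.data_digest != fit_b.data_digest:
        raise ValueError("fits are on different observation sets; AIC incomparable")
    delta = fit_a.aic - fit_b.aic
    return (fit_a.spec if delta <= 0 else fit_b.spec), float(delta)


def fit_gxe_models(
    observations: pd.DataFrame,
    genotypes: pd.DataFrame,
    covariates: tuple[str, ...] | None = None,
    base_fixed: tuple[str, ...] = ("intercept", "age", "gender", "wave"),
    criterion: str = "reml",
    min_defined: float = 0.9,
    n_restarts: int = 3,
    seed: int = 0,
) -> dict[str, FitResult]:
    """Fit a genotype-moderated variance model per genotype covariate.

    For the cumulative risk score and each single-SNP risk flag, the model
    adds the covariate as a fixed effect plus one variance-moderation term at
    each of the three base grouping factors.  Individuals lacking the
    covariate are dropped (logged); a covariate must be defined for at least
    ``min_defined`` of the individuals and must vary, otherwise the
    moderation terms are skipped with a warning.
    """
    from .genotypes import SNP_IDS

    if covariates is None:
        covariates = ("risk_score", *(f"{s}_risk" for s in SNP_IDS))
    results: dict[str, FitResult] = {}
    ids = observations["individual_id"].unique()
    for cov in covariates:
        defined = genotypes.loc[genotypes[cov].notna(), "individual_id"]
        frac = np.isin(ids, defined).mean()
        if frac < min_defined:
            logger.warning(
                "covariate %s defined for only %.1f%% of individuals (< %.0f%%); skipping",
                cov, 100 * frac, 100 * min_defined,
            )
            continue
        values = genotypes.loc[genotypes["individual_id"].isin(ids), cov].dropna()
        if values.nunique() < 2:
            warnings.warn(f"covariate {cov} is degenerate (single value); gxe terms skipped")
            spec = ModelSpec(fixed_terms=(*base_fixed, cov))
        else:
            spec = ModelSpec(
                fixed_terms=(*base_fixed, cov),
                gxe_terms=tuple((cov, t) for t in RANDOM_TERMS),
            )
        design = build_design(observations, genotypes, spec)
        results[cov] = fit(design, spec, criterion=criterion, n_restarts=n_restarts, seed=seed)
    return results


@dataclass
class AssociationResult:
    """Per-indicator genotype association test (sum-to-zero group coding)."""

    snp: str
    indicator: str
    risk_label: str
    nonrisk_label: str
    deviations: dict[str, tuple[float, float]]  # group -> (estimate, se)
    f_value: float
    p_value: float
    ddf: int
    n_obs: int
    warnings: list[str]


def test_indicator_association(
    observations: pd.DataFrame,
    genotypes: pd.DataFrame,
    snp: str,
    indicator: str,
    n_restarts: int = 2,
    seed: int = 0,
) -> AssociationResult:
    """Test one SNP against one indicator's longitudinal standardized scores.

    Fits an individual-random-intercept model with age, gender and wave
    covariates plus a sum-to-zero contrast between the risk and non-risk
    genotype groups; reports the two group deviations (which sum to zero), a
    1-numerator-df Wald F for the contrast with residual denominator df
    ``n_obs - rank(X)``, and its p-value.
    """
    from .genotypes import SNPS

    sub = observations.loc[observations["indicator"] == indicator].copy()
    flag_col = f"{snp}_risk"
    sub = sub.merge(genotypes[["individual_id", flag_col]], on="individual_id", how="left")
    sub["geno_contrast"] = np.where(
        sub[flag_col].isna(), np.nan, np.where(sub[flag_col] > 0, 1.0, -1.0)
    )
    spec = ModelSpec(
        fixed_terms=("intercept", "age", "gender", "wave", "geno_contrast"),
        random_terms=("individual",),
    )
    design = build_design(sub, None, spec)
    res = fit(design, spec, n_restarts=n_restarts, seed=seed)
    row = res.betas.set_index("term").loc["geno_contrast"]
    beta, se = float(row["estimate"]), float(row["se"])
    ddf = design.X.shape[0] - design.X.shape[1]
    f_val = (beta / se) ** 2
    p = float(stats.f.sf(f_val, 1, ddf))

    warns: list[str] = []
    per_group = (
        sub.dropna(subset=["geno_contrast"]).groupby(flag_col)["individual_id"].nunique()
    )
    for grp, n_ind in per_group.items():
        if n_ind < 10:
            warns.append(f"genotype group {int(grp)} has only {n_ind} individuals")
    d = SNPS[snp]
    risk_label = "/".join(sorted(d.risk_genotypes))
    non_risk = sorted(
        {"".join(sorted((a, b))) for a in d.alleles for b in d.alleles} - set(d.risk_genotypes)
    )
    return AssociationResult(
        snp=snp,
        indicator=indicator,
        risk_label=risk_label,
        nonrisk_label="/".join(non_risk),
        deviations={risk_label: (beta, se), "/".join(non_risk): (-beta, se)},
        f_value=float(f_val),
        p_value=p,
        ddf=int(ddf),
        n_obs=int(design.X.shape[0]),
        warnings=warns,
    )
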