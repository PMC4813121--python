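"""Binomial GLMM with two crossed random intercepts, fitted by Laplace.

The movement indicator of every (individual x window) record is modelled as

    y ~ Bernoulli(p),   logit(p) = X beta + s_ind u[ind] + s_rep u[rep]

with spherical random effects u ~ N(0, I) and standard deviations
``s_ind = sigma_ind``, ``s_rep = sigma_rep``.  The marginal likelihood is
approximated by a Laplace expansion around the joint mode of the random
effects: an inner penalized Newton iteration (penalized IRLS) finds the mode
of (beta, u) for fixed variance parameters, and an outer Nelder-Mead search
maximizes the Laplace-approximate profile likelihood over the two standard
deviations.  The crossed structure is exploited directly — the individual
block of the Hessian is diagonal, the replicate block is small, and a Schur
complement reduces every Newton solve to a dense system of size
(n_fixed + n_replicates).

On top of the fitter sit the model-building and selection tools of the
analysis: variance-inflation-factor screening, likelihood-ratio tests,
backward-stepwise fixed-effect selection under the marginality rule (a main
effect stays whenever one of its interactions stays), a boundary-corrected
LRT for the random intercepts, the penalized-residual dispersion diagnostic,
and a random-walk Metropolis sampler for approximate Bayesian intervals.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit
from scipy.stats import chi2 as chi2_dist

logger = logging.getLogger(__name__)

Z975 = 1.959963984540054

MAIN_TERMS = (
    "time", "time2", "local_density", "neighboring_density", "sex",
    "local_sex_ratio", "neighboring_sex_ratio", "bulb_age",
)
INTERACTION_TERMS = (
    "local_density:neighboring_density",
    "local_density:local_sex_ratio",
    "local_density:neighboring_sex_ratio",
    "neighboring_density:local_sex_ratio",
    "neighboring_density:neighboring_sex_ratio",
    "sex:local_sex_ratio",
    "sex:neighboring_sex_ratio",
)


class DegenerateDataError(ValueError):
    """Response is constant or completely separated."""


@dataclass(frozen=True)
class ModelSpec:
    """Ordered fixed-effect term list plus random grouping factors."""

    fixed: tuple[str, ...]
    random: tuple[str, ...] = ("individual", "replicate")

    def __post_init__(self) -> None:
        if len(set(self.fixed)) != len(self.fixed):
            raise ValueError("duplicated term in spec")
        self.validate_marginality()

    def validate_marginality(self) -> None:
        for term in self.fixed:
            for parent in term_parents(term):
                if parent not in self.fixed:
                    raise ValueError(
                        f"interaction {term!r} without its main effect "
                        f"{parent!r} violates marginality"
                    )

    def drop(self, term: str) -> "ModelSpec":
        if term not in self.fixed:
            raise ValueError(f"term {term!r} not in spec")
        return replace(self, fixed=tuple(t for t in self.fixed if t != term))

    def drop_random(self, group: str) -> "ModelSpec":
        return replace(self, random=tuple(g for g in self.random if g != group))

    def is_nested_in(self, other: "ModelSpec") -> bool:
        return set(self.fixed) <= set(other.fixed) and \
            set(self.random) <= set(other.random)


def term_parents(term: str) -> tuple[str, ...]:
    return tuple(term.split(":")) if ":" in term else ()


GLOBAL_SPEC = ModelSpec(fixed=MAIN_TERMS + INTERACTION_TERMS)
#: the retained model after backward selection in the original analysis
FINAL_SPEC = ModelSpec(fixed=(
    "time", "time2", "local_density", "neighboring_density", "sex",
    "local_sex_ratio", "neighboring_sex_ratio",
    "local_density:neighboring_density",
    "local_density:local_sex_ratio",
    "neighboring_density:local_sex_ratio",
    "neighboring_density:neighboring_sex_ratio",
    "sex:local_sex_ratio",
))

_GROUP_COLUMN = {"individual": "tag_id", "replicate": "replicate_id"}


# ---------------------------------------------------------------------------
# model matrix
# ---------------------------------------------------------------------------

def _base_columns(windows: pd.DataFrame) -> dict[str, np.ndarray]:
    def col(name):
        if name not in windows.columns:
            raise KeyError(f"window table missing column {name!r}")
        return windows[name].to_numpy()

    t = np.asarray(col("time_min"), dtype=float)
    sex = windows["sex"]
    male = (sex == "M").to_numpy(dtype=float) if sex.dtype == object \
        else sex.to_numpy(dtype=float)
    return {
        "time": t,
        "time2": t * t,
        "local_density": np.asarray(col("local_density"), dtype=float),
        "neighboring_density": np.asarray(col("neighboring_density"), dtype=float),
        "sex": male,
        "local_sex_ratio": np.asarray(col("local_sex_ratio"), dtype=float),
        "neighboring_sex_ratio": np.asarray(col("neighboring_sex_ratio"),
                                            dtype=float),
        "bulb_age": np.asarray(col("bulb_age"), dtype=float),
    }


def build_model_matrix(
    windows: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray, list[str], dict[str, np.ndarray]]:
    """Response vector, fixed design (intercept first), term names, groupings.

    Sex is coded female=0 / male=1; interactions are element-wise products;
    the deterministic column order follows ``spec.fixed``.
    """
    if "y" not in windows.columns:
        raise KeyError("window table missing column 'y'")
    y = windows["y"].to_numpy(dtype=float)
    base = _base_columns(windows)
    cols = [np.ones(len(windows))]
    names = ["intercept"]
    for term in spec.fixed:
        parents = term_parents(term)
        if parents:
            a, b = parents
            cols.append(base[a] * base[b])
        else:
            if term not in base:
                raise KeyError(f"unknown term {term!r}")
            cols.append(base[term])
        names.append(term)
    X = np.column_stack(cols)
    groups = {}
    for g in spec.random:
        codes, _ = pd.factorize(windows[_GROUP_COLUMN[g]], sort=True)
        groups[g] = codes.astype(np.int64)
    return y, X, names, groups


# ---------------------------------------------------------------------------
# collinearity screening
# ---------------------------------------------------------------------------

def compute_vif(X: np.ndarray, names: list[str],
                warn_above: float = 3.0) -> dict[str, float]:
    """Variance inflation factors, VIF_j = 1 / (1 - R^2_j).

    Each non-intercept column is regressed on all the others (intercept
    included).  An exactly collinear column is reported as ``inf`` with a
    warning rather than raising.
    """
    vif: dict[str, float] = {}
    n, p = X.shape
    for j in range(p):
        if names[j] == "intercept":
            continue
        xj = X[:, j]
        others = np.delete(X, j, axis=1)
        beta, _, _, _ = np.linalg.lstsq(others, xj, rcond=None)
        resid = xj - others @ beta
        ss_tot = float(np.sum((xj - xj.mean()) ** 2))
        ss_res = float(np.sum(resid ** 2))
        if ss_tot <= 0:
            raise ValueError(f"column {names[j]!r} is constant")
        r2 = 1.0 - ss_res / ss_tot
        if r2 >= 1.0 - 1e-12:
            warnings.warn(f"column {names[j]!r} is exactly collinear; VIF=inf")
            vif[names[j]] = math.inf
        else:
            vif[names[j]] = 1.0 / (1.0 - r2)
    flagged = {k: v for k, v in vif.items() if v > warn_above}
    if flagged:
        logger.info("VIF above %.1f: %s", warn_above,
                    {k: round(v, 2) for k, v in flagged.items()})
    return vif


# ---------------------------------------------------------------------------
# Laplace machinery
# ---------------------------------------------------------------------------

def _robust_solve(K: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Cholesky solve with adaptive ridge, falling back to least squares."""
    scale = max(float(np.trace(K)) / K.shape[0], 1e-30)
    for jitter in (0.0, 1e-10, 1e-7, 1e-4):
        try:
            Kj = K if jitter == 0.0 else K + jitter * scale * np.eye(K.shape[0])
            return cho_solve(cho_factor(Kj, lower=True), rhs)
        except np.linalg.LinAlgError:
            continue
    return np.linalg.lstsq(K, rhs, rcond=None)[0]


class _LaplaceLogit:
    """Penalized-Newton / Laplace engine for 0, 1 or 2 crossed intercepts."""

    def __init__(self, y: np.ndarray, X: np.ndarray,
                 codes: list[np.ndarray], sizes: list[int],
                 offset: np.ndarray | None = None):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.n, self.p = self.X.shape
        self.offset = np.zeros(self.n) if offset is None \
            else np.asarray(offset, dtype=float)
        self.codes = codes
        self.sizes = sizes
        self.nf = len(codes)
        # warm state reused across outer evaluations
        p0 = float(np.clip(self.y.mean(), 1e-6, 1 - 1e-6))
        self.beta = np.zeros(self.p)
        self.beta[0] = math.log(p0 / (1 - p0))
        self.us = [np.zeros(q) for q in sizes]

    # -- linear predictor and penalized log-likelihood ---------------------
    def eta(self, beta, us, s):
        e = self.X @ beta + self.offset
        for k in range(self.nf):
            e = e + s[k] * us[k][self.codes[k]]
        return e

    def h(self, beta, us, s):
        e = self.eta(beta, us, s)
        ll = float(np.sum(self.y * e - np.logaddexp(0.0, e)))
        pen = 0.5 * sum(float(u @ u) for u in us)
        return ll - pen

    # -- one Newton solve ---------------------------------------------------
    def _newton_step(self, beta, us, s, w, r):
        X, p = self.X, self.p
        g_b = X.T @ r
        Hbb = (X * w[:, None]).T @ X
        if self.nf == 0:
            db = _robust_solve(Hbb, g_b)
            return db, [], float(np.abs(g_b).max())
        g1c, q1, s1 = self.codes[0], self.sizes[0], s[0]
        g_1 = s1 * np.bincount(g1c, weights=r, minlength=q1) - us[0]
        d1 = s1 ** 2 * np.bincount(g1c, weights=w, minlength=q1) + 1.0
        Hb1 = s1 * np.stack(
            [np.bincount(g1c, weights=w * X[:, j], minlength=q1)
             for j in range(p)]
        )
        inv_d1 = 1.0 / d1
        B1 = Hb1 * inv_d1
        grad_max = max(float(np.abs(g_b).max()), float(np.abs(g_1).max()))
        if self.nf == 1:
            db = _robust_solve(Hbb - B1 @ Hb1.T, g_b - B1 @ g_1)
            du1 = inv_d1 * (g_1 - Hb1.T @ db)
            return db, [du1], grad_max
        g2c, q2, s2 = self.codes[1], self.sizes[1], s[1]
        g_2 = s2 * np.bincount(g2c, weights=r, minlength=q2) - us[1]
        d2 = s2 ** 2 * np.bincount(g2c, weights=w, minlength=q2) + 1.0
        Hb2 = s2 * np.stack(
            [np.bincount(g2c, weights=w * X[:, j], minlength=q2)
             for j in range(p)]
        )
        C = s1 * s2 * sp.coo_matrix(
            (w, (g1c, g2c)), shape=(q1, q2)
        ).toarray()
        grad_max = max(grad_max, float(np.abs(g_2).max()))
        Cd = C * inv_d1[:, None]
        S_bb = Hbb - B1 @ Hb1.T
        S_b2 = Hb2 - B1 @ C
        S_22 = np.diag(d2) - Cd.T @ C
        K = np.block([[S_bb, S_b2], [S_b2.T, S_22]])
        rhs = np.concatenate([g_b - B1 @ g_1, g_2 - Cd.T @ g_1])
        sol = _robust_solve(K, rhs)
        db, du2 = sol[:p], sol[p:]
        du1 = inv_d1 * (g_1 - Hb1.T @ db - C @ du2)
        return db, [du1, du2], grad_max

    def pirls(self, s, tol: float = 1e-8, max_iter: int = 50):
        """Joint (beta, u) mode for fixed standard deviations ``s``."""
        beta = self.beta.copy()
        us = [u.copy() for u in self.us]
        h_cur = self.h(beta, us, s)
        converged = False
        for _ in range(max_iter):
            e = self.eta(beta, us, s)
            mu = expit(e)
            w = np.clip(mu * (1.0 - mu), 1e-10, None)
            r = self.y - mu
            db, dus, grad_max = self._newton_step(beta, us, s, w, r)
            if grad_max < tol * (1.0 + abs(h_cur)):
                converged = True
                break
            step = 1.0
            for _ in range(30):
                beta_t = beta + step * db
                us_t = [u + step * du for u, du in zip(us, dus)]
                h_new = self.h(beta_t, us_t, s)
                if h_new >= h_cur - 1e-12:
                    break
                step *= 0.5
            if abs(h_new - h_cur) < 1e-12 * (1.0 + abs(h_cur)) and step == 1.0:
                beta, us, h_cur = beta_t, us_t, h_new
                converged = True
                break
            beta, us, h_cur = beta_t, us_t, h_new
        self.beta, self.us = beta, [u.copy() for u in us]
        return beta, us, h_cur, converged

    def _logdet_uu(self, beta, us, s):
        """log det of the random-effect block of the penalized Hessian."""
        if self.nf == 0:
            return 0.0
        e = self.eta(beta, us, s)
        mu = expit(e)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        g1c, q1, s1 = self.codes[0], self.sizes[0], s[0]
        d1 = s1 ** 2 * np.bincount(g1c, weights=w, minlength=q1) + 1.0
        if self.nf == 1:
            return float(np.sum(np.log(d1)))
        g2c, q2, s2 = self.codes[1], self.sizes[1], s[1]
        d2 = s2 ** 2 * np.bincount(g2c, weights=w, minlength=q2) + 1.0
        C = s1 * s2 * sp.coo_matrix((w, (g1c, g2c)),
                                    shape=(q1, q2)).toarray()
        S_22 = np.diag(d2) - (C / d1[:, None]).T @ C
        sign, ld2 = np.linalg.slogdet(S_22)
        if sign <= 0:
            raise np.linalg.LinAlgError("non-PD random-effect Hessian")
        return float(np.sum(np.log(d1))) + float(ld2)

    def laplace_loglik(self, s, tol: float = 1e-8):
        beta, us, h_val, conv = self.pirls(s, tol=tol)
        ll = h_val - 0.5 * self._logdet_uu(beta, us, s)
        return ll, conv

    def cov_beta(self, s):
        """Conditional (on sigma) Wald covariance of the fixed effects."""
        beta, us = self.beta, self.us
        e = self.eta(beta, us, s)
        mu = expit(e)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        X, p = self.X, self.p
        Hbb = (X * w[:, None]).T @ X
        if self.nf == 0:
            return np.linalg.inv(Hbb)
        g1c, q1, s1 = self.codes[0], self.sizes[0], s[0]
        d1 = s1 ** 2 * np.bincount(g1c, weights=w, minlength=q1) + 1.0
        Hb1 = s1 * np.stack(
            [np.bincount(g1c, weights=w * X[:, j], minlength=q1)
             for j in range(p)]
        )
        B1 = Hb1 / d1
        S_bb = Hbb - B1 @ Hb1.T
        if self.nf == 1:
            return np.linalg.inv(S_bb)
        g2c, q2, s2 = self.codes[1], self.sizes[1], s[1]
        d2 = s2 ** 2 * np.bincount(g2c, weights=w, minlength=q2) + 1.0
        Hb2 = s2 * np.stack(
            [np.bincount(g2c, weights=w * X[:, j], minlength=q2)
             for j in range(p)]
        )
        C = s1 * s2 * sp.coo_matrix((w, (g1c, g2c)),
                                    shape=(q1, q2)).toarray()
        Cd = C / d1[:, None]
        S_b2 = Hb2 - B1 @ C
        S_22 = np.diag(d2) - Cd.T @ C
        return np.linalg.inv(S_bb - S_b2 @ np.linalg.solve(S_22, S_b2.T))


# ---------------------------------------------------------------------------
# fit result
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    sigma2: dict[str, float]
    loglik: float
    converged: bool
    n_obs: int
    n_groups: dict[str, int]
    mu: np.ndarray = field(repr=False)
    u_modes: dict[str, np.ndarray] = field(repr=False)
    response: np.ndarray = field(repr=False)

    @property
    def beta_dict(self) -> dict[str, float]:
        return dict(zip(self.terms, map(float, self.beta)))

    @property
    def ci_dict(self) -> dict[str, tuple[float, float]]:
        return {t: (float(lo), float(hi))
                for t, lo, hi in zip(self.terms, self.ci_low, self.ci_high)}

    def n_parameters(self) -> int:
        return len(self.terms) + len(self.sigma2)

    def to_json_dict(self) -> dict:
        return {
            "terms": list(self.terms),
            "estimates": {t: float(b) for t, b in zip(self.terms, self.beta)},
            "se": {t: float(v) for t, v in zip(self.terms, self.se)},
            "ci95": {t: [float(lo), float(hi)] for t, lo, hi in
                     zip(self.terms, self.ci_low, self.ci_high)},
            "variance_components": {k: float(v) for k, v in self.sigma2.items()},
            "loglik": float(self.loglik),
            "converged": bool(self.converged),
            "dispersion": float(dispersion(self)),
            "n_obs": int(self.n_obs),
            "n_groups": {k: int(v) for k, v in self.n_groups.items()},
        }


def fit_glmm(
    y: np.ndarray,
    X: np.ndarray,
    groups: dict[str, np.ndarray],
    terms: list[str] | None = None,
    offset: np.ndarray | None = None,
    start: dict | None = None,
    inner_tol: float = 1e-8,
    outer_xatol: float = 1e-5,
    outer_fatol: float = 1e-8,
    max_outer: int = 500,
    refine_beta: bool = True,
    refine_maxiter: int = 300,
    fix_sigma: dict[str, float] | None = None,
) -> FitResult:
    """Maximize the Laplace-approximate likelihood of the crossed GLMM.

    ``groups`` maps grouping-factor names to integer code arrays (0..q-1);
    pass an empty dict for an ordinary logistic regression.  ``offset`` is a
    fixed, known addition to the linear predictor (used e.g. to anchor an
    aliased term).  ``fix_sigma`` pins the named standard deviations instead
    of estimating them (all grouping factors must be covered).  ``start`` may supply ``{"sigma": {name: sd}}`` warm
    starts.  Wald 95% intervals come from the sigma-conditional Hessian at
    the optimum.

    Fitting proceeds in two stages.  First a Nelder-Mead search over the two
    standard deviations with (beta, u) jointly mode-optimized by penalized
    IRLS (the fast profile).  Then, with ``refine_beta=True``, a quasi-Newton
    polish of the full Laplace objective over (beta, sigma) jointly — the
    fixed effects then maximize the approximate marginal likelihood
    *including* the log-determinant's dependence on beta, matching the
    reference Laplace implementations for this model class.  The polish
    costs a few times the profile stage; ``refine_beta=False`` keeps the
    profile optimum (useful inside large selection loops, where likelihood
    *differences* are insensitive to the criterion variant).
    """
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("empty response")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("response must be 0/1")
    if y.min() == y.max():
        raise DegenerateDataError(
            f"response is constant (all {int(y[0])}): model is degenerate"
        )
    names = list(groups)
    for g in names:
        if len(np.unique(groups[g])) < 2:
            raise ValueError(f"grouping factor {g!r} needs >= 2 levels")
    codes = [np.asarray(groups[g], dtype=np.int64) for g in names]
    sizes = [int(c.max()) + 1 for c in codes]
    engine = _LaplaceLogit(y, X, codes, sizes, offset=offset)
    term_names = terms if terms is not None else \
        [f"x{j}" for j in range(X.shape[1])]

    if engine.nf == 0:
        beta, us, h_val, conv = engine.pirls(np.zeros(0), tol=inner_tol)
        sig_opt = np.zeros(0)
        loglik = h_val
        outer_ok = True
    elif fix_sigma is not None and set(fix_sigma) >= set(names):
        # variance components pinned: no outer search
        sig_opt = np.array([abs(float(fix_sigma[g])) for g in names])
        loglik, conv = engine.laplace_loglik(sig_opt, tol=inner_tol)
        outer_ok = True
        beta, us = engine.beta, engine.us
    else:
        start_sig = np.full(engine.nf, 0.5)
        if start and "sigma" in start:
            start_sig = np.array(
                [abs(float(start["sigma"].get(g, 0.5))) for g in names])
            start_sig = np.maximum(start_sig, 0.02)
        from scipy.optimize import minimize

        def nll(sv):
            s = np.abs(sv)
            ll, _ = engine.laplace_loglik(s, tol=inner_tol)
            return -ll

        res = minimize(
            nll, start_sig, method="Nelder-Mead",
            options={"xatol": outer_xatol, "fatol": outer_fatol,
                     "maxfev": max_outer},
        )
        sig_opt = np.abs(res.x)
        loglik, conv = engine.laplace_loglik(sig_opt, tol=inner_tol)
        outer_ok = bool(res.success)
        beta, us = engine.beta, engine.us
        if refine_beta:
            cov0 = engine.cov_beta(sig_opt)
            scale = np.sqrt(np.clip(np.diag(cov0), 1e-16, None))
            s_scale = np.maximum(0.1 * np.maximum(sig_opt, 0.1), 1e-3)
            beta0, sig0 = beta.copy(), sig_opt.copy()

            def nll_joint(z):
                b = beta0 + z[:engine.p] * scale
                sv = np.abs(sig0 + z[engine.p:] * s_scale)
                return -_laplace_ll_fixed_beta(engine, b, sv)

            from scipy.optimize import minimize as _minimize
            res2 = _minimize(
                nll_joint, np.zeros(engine.p + engine.nf), method="BFGS",
                options={"maxiter": refine_maxiter, "gtol": 3e-5,
                         "eps": 1e-5},
            )
            if -res2.fun >= loglik - 1e-9:
                beta = beta0 + res2.x[:engine.p] * scale
                sig_opt = np.abs(sig0 + res2.x[engine.p:] * s_scale)
                # re-solve the random-effect mode at the accepted optimum
                loglik = float(_laplace_ll_fixed_beta(engine, beta, sig_opt))
                engine.beta = beta.copy()
                us = engine.us
            else:  # polish failed to improve; keep the profile optimum
                engine.pirls(sig_opt, tol=inner_tol)
                beta, us = engine.beta, engine.us

    cov = engine.cov_beta(sig_opt)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    converged = bool(conv and outer_ok and np.all(np.abs(beta) < 40))
    if not converged:
        logger.warning("GLMM fit flagged non-converged "
                       "(inner=%s, outer=%s, max|beta|=%.2f)",
                       conv, outer_ok, float(np.abs(beta).max()))
    mu = expit(engine.eta(beta, us, sig_opt))
    return FitResult(
        terms=term_names,
        beta=beta.copy(),
        se=se,
        ci_low=beta - Z975 * se,
        ci_high=beta + Z975 * se,
        sigma2={g: float(s ** 2) for g, s in zip(names, sig_opt)},
        loglik=float(loglik),
        converged=converged,
        n_obs=int(y.size),
        n_groups=dict(zip(names, sizes)),
        mu=mu,
        u_modes={g: u.copy() for g, u in zip(names, us)},
        response=y.copy(),
    )


def fit_windows(windows: pd.DataFrame, spec: ModelSpec,
                anchors: dict[str, float] | None = None,
                **fit_kwargs) -> FitResult:
    """Build the model matrix from a window table and fit the GLMM.

    ``anchors`` maps term names to fixed coefficient values: each anchored
    term is removed from the free parameters and enters the linear
    predictor as a known offset.  This resolves exact aliasing among
    terms — in a two-patch system with coherent snapshot covariates,
    density x sex-ratio products reproduce patch male counts, making
    {local_density, neighboring_density, local_density:local_sex_ratio,
    neighboring_density:neighboring_sex_ratio} exactly collinear — at the
    cost of not validating the anchored direction.
    """
    if anchors:
        unknown = set(anchors) - set(spec.fixed)
        if unknown:
            raise ValueError(f"anchor term(s) not in spec: {sorted(unknown)}")
        y, X, names, groups = build_model_matrix(windows, spec)
        offset = np.zeros(len(y))
        keep = []
        for j, nm in enumerate(names):
            if nm in anchors:
                offset += anchors[nm] * X[:, j]
            else:
                keep.append(j)
        X = X[:, keep]
        names = [names[j] for j in keep]
        return fit_glmm(y, X, groups, terms=names, offset=offset,
                        **fit_kwargs)
    y, X, names, groups = build_model_matrix(windows, spec)
    return fit_glmm(y, X, groups, terms=names, **fit_kwargs)


# ---------------------------------------------------------------------------
# likelihood-ratio machinery
# ---------------------------------------------------------------------------

def lrt(fit_full: FitResult, fit_reduced: FitResult) -> tuple[float, int, float]:
    """chi2 = 2 (ll_full - ll_reduced) clipped at 0, df, p."""
    full_terms = set(fit_full.terms) | set(fit_full.sigma2)
    red_terms = set(fit_reduced.terms) | set(fit_reduced.sigma2)
    if not red_terms <= full_terms:
        raise ValueError("models are not nested")
    df = fit_full.n_parameters() - fit_reduced.n_parameters()
    if df <= 0:
        raise ValueError("reduced model has no fewer parameters")
    chi2 = max(0.0, 2.0 * (fit_full.loglik - fit_reduced.loglik))
    p = float(chi2_dist.sf(chi2, df))
    return chi2, df, p


@dataclass
class SelectionStep:
    phase: str  # 'interactions' or 'mains'
    term: str
    chi2: float
    df: int
    p: float
    removed: bool


@dataclass
class SelectionTrace:
    steps: list[SelectionStep]
    final_spec: ModelSpec
    final_fit: FitResult

    def removed_terms(self) -> list[str]:
        return [s.term for s in self.steps if s.removed]

    def to_json_dict(self) -> dict:
        return {
            "steps": [
                {"phase": s.phase, "term": s.term, "chi2": float(s.chi2),
                 "df": int(s.df), "p": float(s.p), "removed": bool(s.removed)}
                for s in self.steps
            ],
            "final_terms": list(self.final_spec.fixed),
            "final_fit": self.final_fit.to_json_dict(),
        }


def backward_select(
    windows: pd.DataFrame,
    spec: ModelSpec = GLOBAL_SPEC,
    alpha: float = 0.05,
    anchors: dict[str, float] | None = None,
    **fit_kwargs,
) -> SelectionTrace:
    """Backward-stepwise LRT selection of fixed effects.

    Phase 1 removes interactions one at a time — at each round the candidate
    with the largest LRT p-value (ties broken toward the later position in
    the term list) is dropped if p > alpha.  Phase 2 does the same for main
    effects, except that a main effect participating in a retained
    interaction is kept regardless of its own p-value (marginality).
    Random intercepts are refitted at every step.  Anchored terms (fixed
    known coefficients entering as offsets) are never removal candidates
    and lock their main effects like any retained interaction.
    """
    anchors = anchors or {}
    current = spec
    fit_cur = fit_windows(windows, current, anchors=anchors, **fit_kwargs)
    steps: list[SelectionStep] = []

    def candidate_stats(cands):
        stats = []
        warm = {"sigma": {g: math.sqrt(v)
                          for g, v in fit_cur.sigma2.items()}}
        for term in cands:
            fit_red = fit_windows(windows, current.drop(term),
                                  anchors=anchors, start=warm, **fit_kwargs)
            chi2, df, p = lrt(fit_cur, fit_red)
            stats.append((term, chi2, df, p, fit_red))
        return stats

    for phase, pool in (("interactions", INTERACTION_TERMS),
                        ("mains", MAIN_TERMS)):
        while True:
            if phase == "interactions":
                cands = [t for t in current.fixed
                         if t in pool and t not in anchors]
            else:
                # parents of every retained interaction stay, anchored ones
                # included (the anchored term is still part of the model)
                locked = {p_ for t in current.fixed
                          for p_ in term_parents(t)}
                cands = [t for t in current.fixed
                         if t in pool and t not in locked
                         and t not in anchors]
            if not cands:
                break
            stats = candidate_stats(cands)
            # highest p first; ties -> later position in the term list
            order = {t: i for i, t in enumerate(current.fixed)}
            term, chi2, df, p, fit_red = max(
                stats, key=lambda s: (s[3], order[s[0]]))
            if p > alpha:
                steps.append(SelectionStep(phase, term, chi2, df, p, True))
                current = current.drop(term)
                fit_cur = fit_red
            else:
                for term_k, chi2_k, df_k, p_k, _ in stats:
                    steps.append(
                        SelectionStep(phase, term_k, chi2_k, df_k, p_k, False))
                break
    logger.info("backward selection removed %s", [s.term for s in steps
                                                  if s.removed])
    return SelectionTrace(steps=steps, final_spec=current, final_fit=fit_cur)


def random_effect_lrt(
    windows: pd.DataFrame,
    spec: ModelSpec,
    boundary_correction: bool = True,
    **fit_kwargs,
) -> dict[str, tuple[float, float]]:
    """LRT for each random intercept: full model vs model without it.

    The null sigma^2 = 0 sits on the boundary of the parameter space, so by
    default the p-value is halved (50:50 mixture of chi2_0 and chi2_1).
    """
    if not spec.random:
        raise ValueError("spec has no random terms to test")
    fit_full = fit_windows(windows, spec, **fit_kwargs)
    out = {}
    for g in spec.random:
        reduced = spec.drop_random(g)
        if reduced.random:
            fit_red = fit_windows(windows, reduced, **fit_kwargs)
        else:
            y, X, names, _ = build_model_matrix(windows, reduced)
            fit_red = fit_glmm(y, X, {}, terms=names)
        chi2, _, _ = lrt(fit_full, fit_red)
        p = float(chi2_dist.sf(chi2, 1))
        if boundary_correction:
            p *= 0.5
        out[g] = (chi2, p)
    return out


def dispersion(fit: FitResult) -> float:
    """sqrt of the penalized residual sum of squares over n.

    PRSS = sum of squared Pearson residuals at the fitted values plus the
    random-effect quadratic penalty |u|^2 at the (spherical) modes.  Under a
    correctly specified binomial model the statistic sits near 1; it is a
    diagnostic only.
    """
    var = np.clip(fit.mu * (1.0 - fit.mu), 1e-10, None)
    pearson2 = float(np.sum((fit.response - fit.mu) ** 2 / var))
    penalty = sum(float(u @ u) for u in fit.u_modes.values())
    return math.sqrt((pearson2 + penalty) / fit.n_obs)


# ---------------------------------------------------------------------------
# approximate Bayesian intervals
# ---------------------------------------------------------------------------

def mcmc_fit(
    windows: pd.DataFrame,
    spec: ModelSpec,
    n_draws: int = 1500,
    n_burn: int = 500,
    chains: int = 2,
    seed: int = 0,
    prior_sd_beta: float = 10.0,
    prior_sd_sigma: float = 5.0,
) -> dict:
    """Random-walk Metropolis over (beta, sigma) for credible intervals.

    The target is the Laplace-approximate marginal posterior: the random
    effects are integrated out by the same Laplace expansion the frequentist
    path uses (with the fixed effects held at their proposed values), under
    weakly informative priors beta ~ N(0, prior_sd_beta^2) and
    sigma ~ half-N(0, prior_sd_sigma^2).  Chains are flagged when the
    split-R-hat of any parameter exceeds 1.05.
    """
    y, X, names, groups = build_model_matrix(windows, spec)
    map_fit = fit_glmm(y, X, groups, terms=names)
    gnames = list(groups)
    codes = [np.asarray(groups[g], dtype=np.int64) for g in gnames]
    sizes = [int(c.max()) + 1 for c in codes]
    engine = _LaplaceLogit(y, X, codes, sizes)
    p = X.shape[1]
    nf = len(gnames)

    def logpost(theta):
        beta = theta[:p]
        s = np.abs(theta[p:])
        # profile the random effects at their mode for this (beta, s):
        # reuse the joint-PIRLS engine but penalize deviations of beta by
        # fixing it: run u-only Newton via a huge prior is overkill; instead
        # evaluate the joint h at the u-mode found with beta fixed.
        ll = _laplace_ll_fixed_beta(engine, beta, s)
        lp = -0.5 * float(beta @ beta) / prior_sd_beta ** 2
        lp += -0.5 * float(s @ s) / prior_sd_sigma ** 2
        return ll + lp

    sd0 = np.array([math.sqrt(map_fit.sigma2[g]) for g in gnames])
    x0 = np.concatenate([map_fit.beta, np.maximum(sd0, 0.05)])
    prop_sd = np.concatenate(
        [np.maximum(map_fit.se, 1e-4), np.full(nf, 0.05)])
    prop_sd *= 2.4 / math.sqrt(len(x0))

    rng_root = np.random.SeedSequence(seed)
    all_draws = []
    for ch_seq in rng_root.spawn(chains):
        rng = np.random.default_rng(ch_seq)
        x = x0 + 0.1 * prop_sd * rng.standard_normal(len(x0))
        lp_x = logpost(x)
        draws = np.empty((n_draws, len(x0)))
        n_acc = 0
        for it in range(n_burn + n_draws):
            prop = x + prop_sd * rng.standard_normal(len(x0))
            lp_p = logpost(prop)
            if math.log(rng.random()) < lp_p - lp_x:
                x, lp_x = prop, lp_p
                n_acc += 1
            if it >= n_burn:
                draws[it - n_burn] = x
        draws[:, p:] = np.abs(draws[:, p:])
        all_draws.append(draws)
        logger.info("MCMC chain acceptance %.2f", n_acc / (n_burn + n_draws))

    stacked = np.concatenate(all_draws)
    rhat = _split_rhat(all_draws)
    if np.any(rhat > 1.05):
        warnings.warn(
            f"MCMC chains may not have mixed: max split-R-hat "
            f"{float(rhat.max()):.3f} > 1.05"
        )
    pnames = names + [f"sigma_{g}" for g in gnames]
    q = np.percentile(stacked, [2.5, 97.5], axis=0)
    return {
        "terms": names,
        "mean": {nm: float(m) for nm, m in zip(pnames, stacked.mean(axis=0))},
        "ci_low": {nm: float(v) for nm, v in zip(pnames, q[0])},
        "ci_high": {nm: float(v) for nm, v in zip(pnames, q[1])},
        "sigma2_mean": {
            g: float(np.mean(stacked[:, p + k] ** 2))
            for k, g in enumerate(gnames)
        },
        "rhat": {nm: float(v) for nm, v in zip(pnames, rhat)},
        "n_draws": int(stacked.shape[0]),
    }


def _laplace_ll_fixed_beta(engine: _LaplaceLogit, beta: np.ndarray,
                           s: np.ndarray) -> float:
    """Laplace marginal log-likelihood with the fixed effects held fixed.

    Newton iteration over the random effects only (diagonal individual
    block, Schur complement for the replicate block), with step halving on
    the penalized objective.
    """
    offset = engine.X @ beta + engine.offset
    y = engine.y
    if engine.nf == 0:
        return float(np.sum(y * offset - np.logaddexp(0.0, offset)))
    us = [u.copy() for u in engine.us]

    def h_of(us_):
        e = offset.copy()
        for k in range(engine.nf):
            e = e + s[k] * us_[k][engine.codes[k]]
        ll = float(np.sum(y * e - np.logaddexp(0.0, e)))
        return ll - 0.5 * sum(float(u @ u) for u in us_), e

    h_cur, e = h_of(us)
    for _ in range(100):
        mu = expit(e)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        r = y - mu
        g1c, q1, s1 = engine.codes[0], engine.sizes[0], s[0]
        g_1 = s1 * np.bincount(g1c, weights=r, minlength=q1) - us[0]
        d1 = s1 ** 2 * np.bincount(g1c, weights=w, minlength=q1) + 1.0
        if engine.nf == 1:
            dus = [g_1 / d1]
            grad_max = float(np.abs(g_1).max())
        else:
            g2c, q2, s2 = engine.codes[1], engine.sizes[1], s[1]
            g_2 = s2 * np.bincount(g2c, weights=r, minlength=q2) - us[1]
            d2 = s2 ** 2 * np.bincount(g2c, weights=w, minlength=q2) + 1.0
            C = s1 * s2 * sp.coo_matrix((w, (g1c, g2c)),
                                        shape=(q1, q2)).toarray()
            Cd = C / d1[:, None]
            S_22 = np.diag(d2) - Cd.T @ C
            du2 = _robust_solve(S_22, g_2 - Cd.T @ g_1)
            dus = [(g_1 - C @ du2) / d1, du2]
            grad_max = max(float(np.abs(g_1).max()), float(np.abs(g_2).max()))
        if grad_max < 1e-9 * (1.0 + abs(h_cur)):
            break
        step = 1.0
        for _ in range(30):
            us_t = [u + step * du for u, du in zip(us, dus)]
            h_new, e_new = h_of(us_t)
            if h_new >= h_cur - 1e-12:
                break
            step *= 0.5
        us, h_cur, e = us_t, h_new, e_new
    engine.us = [u.copy() for u in us]
    return h_cur - 0.5 * engine._logdet_uu(beta, us, s)


def _split_rhat(chain_draws: list[np.ndarray]) -> np.ndarray:
    """Split-R-hat per parameter from a list of (n, d) chain arrays."""
    halves = []
    for d in chain_draws:
        n = d.shape[0] // 2
        halves.extend([d[:n], d[n:2 * n]])
    arr = np.stack(halves)  # (m, n, d)
    m, n, _ = arr.shape
    chain_means = arr.mean(axis=1)
    chain_vars = arr.var(axis=1, ddof=1)
    W = chain_vars.mean(axis=0)
    B = n * chain_means.var(axis=0, ddof=1)
    var_plus = (n - 1) / n * W + B / n
    with np.errstate(invalid="ignore", divide="ignore"):
        rhat = np.sqrt(var_plus / W)
    return np.where(W > 0, rhat, 1.0)
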