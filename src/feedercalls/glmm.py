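"""Random-intercept GLMMs for the playback responses, by approximate ML.

Three response models are supported, matching the experiment's analysis plan:
a Gamma GLMM (log link) for discovery latency, and Poisson GLMMs (log link)
for the two unique-visitor counts. Fixed effects are time of day (PM relative
to AM), treatment (playback relative to silent control), trial order as a
numeric main effect, and optionally their time-of-day x treatment
interaction; a Gaussian random intercept per experimental site absorbs
repeated trials at the same location.

The marginal likelihood integrates the site intercept out by adaptive
Gauss-Hermite quadrature (one node = the Laplace approximation): for each
site the integrand is re-centred at its conditional mode and re-scaled by the
conditional curvature before applying the quadrature rule. The quadrature-
approximated deviance is minimised by quasi-Newton iterations using
Fisher-identity gradients (posterior-weighted score sums); standard errors
come from the observed information (numerical Hessian of the marginal
deviance) at the optimum. Wald z statistics with two-tailed normal p-values
are reported, with no degrees-of-freedom correction.

Censored latencies enter as the censoring value itself (60 min), exactly as
in the analysis being re-implemented; a proper censored likelihood is a
possible extension, deliberately off by default.

With the random-intercept variance pinned to zero the marginal likelihood is
the ordinary GLM likelihood, which is then solved exactly by Newton scoring —
this pinned path doubles as the initialiser for the mixed fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import brentq, minimize
from scipy.special import digamma, gammaln, logsumexp
from scipy.stats import norm

__all__ = [
    "FitResult",
    "InteractionSelection",
    "RESPONSE_FAMILY",
    "build_design",
    "fit_glmm",
    "fit_playback_model",
    "select_interaction",
    "species_subset",
]


class DesignError(ValueError):
    """The trial records cannot support the requested design matrix."""


class FitError(RuntimeError):
    """The optimiser failed in a way that yields no usable estimates."""


RESPONSE_FAMILY = {
    "latency": "gamma",
    "initial_recruitment": "poisson",
    "total_birds": "poisson",
}

_RESPONSE_COLUMN = {
    "latency": "latency_min",
    "initial_recruitment": "initial_recruitment",
    "total_birds": "total_birds",
}


# ---------------------------------------------------------------------------
# family log-densities on the log-link scale (eta = log mean)
# ---------------------------------------------------------------------------

def _poisson_logf(y: np.ndarray, eta: np.ndarray) -> np.ndarray:
    return y * eta - np.exp(eta) - gammaln(y + 1.0)


def _poisson_d1(y: np.ndarray, eta: np.ndarray) -> np.ndarray:
    return y - np.exp(eta)


def _poisson_d2(y: np.ndarray, eta: np.ndarray) -> np.ndarray:
    return -np.exp(eta)


def _gamma_logf(y: np.ndarray, eta: np.ndarray, k: float) -> np.ndarray:
    return (k * np.log(k) - gammaln(k) + (k - 1.0) * np.log(y)
            - k * eta - k * y * np.exp(-eta))


def _gamma_d1(y: np.ndarray, eta: np.ndarray, k: float) -> np.ndarray:
    return k * (y * np.exp(-eta) - 1.0)


def _gamma_d2(y: np.ndarray, eta: np.ndarray, k: float) -> np.ndarray:
    return -k * y * np.exp(-eta)


def _gamma_dlogf_dk(y: np.ndarray, eta: np.ndarray, k: float) -> np.ndarray:
    return np.log(k) + 1.0 - digamma(k) + np.log(y) - eta - y * np.exp(-eta)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Fixed-effect table plus variance components from one model fit."""

    response: str
    family: str
    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    re_variance: float
    shape: float | None
    loglik: float
    converged: bool
    n_obs: int
    n_groups: int
    n_quadrature: int
    message: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.terms,
            "coefficient": self.coef,
            "se": self.se,
            "z": self.z,
            "p": self.p,
        })

    def term(self, name: str) -> dict[str, float]:
        i = self.terms.index(name)
        return {"coefficient": float(self.coef[i]), "se": float(self.se[i]),
                "z": float(self.z[i]), "p": float(self.p[i])}

    def summary(self) -> dict:
        return {
            "response": self.response,
            "family": self.family,
            "terms": [
                {"term": t, "coefficient": float(c), "se": float(s),
                 "z": float(zz), "p": float(pp)}
                for t, c, s, zz, pp in zip(self.terms, self.coef, self.se, self.z, self.p)
            ],
            "random_intercept_variance": float(self.re_variance),
            "gamma_shape": None if self.shape is None else float(self.shape),
            "loglik": float(self.loglik),
            "converged": bool(self.converged),
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
        }


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

def build_design(
    records: pd.DataFrame,
    response: str,
    interaction: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str], list[str]]:
    """Model matrices for one response.

    Reference levels are AM and CONTROL, so the reported coefficients are
    PM-versus-AM and playback-versus-control; trial order enters as a numeric
    main effect. Count responses drop trials with missing counts listwise;
    the latency response uses every trial with censored values entered as the
    censoring limit. Returns ``(X, y, group_codes, terms, group_labels)``.
    """
    if response not in _RESPONSE_COLUMN:
        raise DesignError(f"unknown response {response!r}; "
                          f"expected one of {sorted(_RESPONSE_COLUMN)}")
    col = _RESPONSE_COLUMN[response]
    df = records.dropna(subset=[col]).copy()
    if len(df) == 0:
        raise DesignError(f"no usable trials for response {response!r}")
    if df["site_id"].nunique() < 2:
        raise DesignError("need trials from at least 2 sites")

    pm = (df["time_of_day"] == "PM").to_numpy(dtype=float)
    pb = (df["treatment"] == "PLAYBACK").to_numpy(dtype=float)
    order = df["order"].to_numpy(dtype=float)
    for name, v in (("time_of_day", pm), ("treatment", pb), ("order", order)):
        if np.unique(v).size < 2:
            raise DesignError(f"term {name!r} has a single level in these records")

    cols = [np.ones(len(df)), pm, pb, order]
    terms = ["intercept", "time_of_day", "treatment", "order"]
    if interaction:
        cols.append(pm * pb)
        terms.append("time_of_day:treatment")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError("design matrix is rank deficient")

    y = df[col].to_numpy(dtype=float)
    labels, codes = np.unique(df["site_id"].to_numpy(), return_inverse=True)
    return X, y, codes, terms, list(labels)


# ---------------------------------------------------------------------------
# plain GLM (variance pinned to zero) by Newton scoring
# ---------------------------------------------------------------------------

def _glm_newton(X: np.ndarray, y: np.ndarray, family: str,
                max_iter: int = 200, tol: float = 1e-12) -> np.ndarray:
    """Exact ML coefficients of the log-link GLM by damped Newton iterations.

    For the Gamma family the shape parameter factors out of the score, so the
    coefficient solution does not depend on it.
    """
    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = np.log(max(y.mean(), 1e-8))
    for _ in range(max_iter):
        eta = X @ beta
        if family == "poisson":
            d1, d2 = _poisson_d1(y, eta), _poisson_d2(y, eta)
            hess = X.T @ (d2[:, None] * X)
        else:
            # Fisher scoring: the Gamma expected information -k X'X is
            # constant, so the step never degenerates on an overshoot
            d1 = _gamma_d1(y, eta, 1.0)
            hess = -(X.T @ X)
        score = X.T @ d1
        try:
            step = np.linalg.solve(hess, -score)
        except np.linalg.LinAlgError as exc:
            raise FitError("singular Hessian in GLM iterations") from exc
        # damped update: halve until the log-likelihood does not decrease
        ll_old = _family_loglik(y, eta, family, 1.0)
        scale = 1.0
        for _ in range(40):
            cand = beta + scale * step
            if _family_loglik(y, X @ cand, family, 1.0) >= ll_old - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        if np.max(np.abs(scale * step)) < tol:
            break
    return beta


def _family_loglik(y: np.ndarray, eta: np.ndarray, family: str, k: float) -> float:
    if family == "poisson":
        return float(_poisson_logf(y, eta).sum())
    return float(_gamma_logf(y, eta, k).sum())


def _gamma_shape_mle(y: np.ndarray, eta: np.ndarray) -> float:
    """ML shape given the fitted means: solves log k - psi(k) = -1 - C."""
    r = np.log(y) - eta - y * np.exp(-eta)
    target = -1.0 - float(np.mean(r))
    if target <= 0:  # perfect fit; shape unbounded above
        return 1e6
    f = lambda k: np.log(k) - digamma(k) - target
    return float(brentq(f, 1e-8, 1e8, xtol=1e-12, rtol=1e-14))


def _fit_glm(X: np.ndarray, y: np.ndarray, family: str) -> tuple[np.ndarray, float, float]:
    """Pinned-variance fit: coefficients, ML shape (1 for Poisson), loglik."""
    beta = _glm_newton(X, y, family)
    eta = X @ beta
    if family == "gamma":
        k = _gamma_shape_mle(y, eta)
    else:
        k = 1.0
    return beta, k, _family_loglik(y, eta, family, k)


# ---------------------------------------------------------------------------
# marginal likelihood by adaptive Gauss-Hermite quadrature
# ---------------------------------------------------------------------------

def _site_mode(y: np.ndarray, eta_fixed: np.ndarray, sigma2: float,
               family: str, k: float) -> tuple[float, float]:
    """Conditional mode and curvature of the integrand for one site."""
    b = 0.0

    def l_prime(b_: float) -> tuple[float, float]:
        eta = eta_fixed + b_
        if family == "poisson":
            d1, d2 = _poisson_d1(y, eta), _poisson_d2(y, eta)
        else:
            d1, d2 = _gamma_d1(y, eta, k), _gamma_d2(y, eta, k)
        return float(d1.sum() - b_ / sigma2), float(d2.sum() - 1.0 / sigma2)

    for _ in range(100):
        g, h = l_prime(b)
        step = -g / h
        step = float(np.clip(step, -2.0, 2.0))
        b += step
        if abs(step) < 1e-12:
            break
    _, h = l_prime(b)
    return b, h


def _marginal_nll_and_grad(
    theta: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    codes: np.ndarray,
    family: str,
    nodes: np.ndarray,
    weights: np.ndarray,
    n_groups: int,
) -> tuple[float, np.ndarray]:
    """Negative marginal log-likelihood and its Fisher-identity gradient.

    The gradient is the posterior-weighted score evaluated on the adaptive
    quadrature nodes; with enough nodes the quadrature is effectively exact,
    so this matches the gradient of the exact marginal likelihood.
    """
    p = X.shape[1]
    beta = theta[:p]
    sigma = float(np.exp(theta[p]))
    sigma2 = max(sigma * sigma, 1e-12)
    k = float(np.exp(theta[p + 1])) if family == "gamma" else 1.0

    eta_all = X @ beta
    log_wk = np.log(weights)
    z2 = nodes * nodes

    ll = 0.0
    g_beta = np.zeros(p)
    g_logsigma = 0.0
    g_logk = 0.0

    for i in range(n_groups):
        sel = codes == i
        yi = y[sel]
        Xi = X[sel]
        ef = eta_all[sel]

        bhat, h = _site_mode(yi, ef, sigma2, family, k)
        tau = 1.0 / np.sqrt(-h)
        b_nodes = bhat + np.sqrt(2.0) * tau * nodes  # (K,)
        eta = ef[:, None] + b_nodes[None, :]         # (n_i, K)

        if family == "poisson":
            logf = _poisson_logf(yi[:, None], eta)
            d1 = _poisson_d1(yi[:, None], eta)
        else:
            logf = _gamma_logf(yi[:, None], eta, k)
            d1 = _gamma_d1(yi[:, None], eta, k)

        log_prior = -0.5 * np.log(2.0 * np.pi * sigma2) - b_nodes**2 / (2.0 * sigma2)
        log_integrand = logf.sum(axis=0) + log_prior
        log_terms = log_wk + z2 + log_integrand
        li = np.log(np.sqrt(2.0) * tau) + logsumexp(log_terms)
        ll += li

        omega = np.exp(log_terms - logsumexp(log_terms))  # posterior node weights
        g_beta += Xi.T @ (d1 @ omega)
        g_logsigma += float(omega @ (b_nodes**2 / sigma2 - 1.0))
        if family == "gamma":
            dk = _gamma_dlogf_dk(yi[:, None], eta, k).sum(axis=0)
            g_logk += k * float(omega @ dk)

    grad = np.concatenate([g_beta, [g_logsigma]])
    if family == "gamma":
        grad = np.concatenate([grad, [g_logk]])
    return -ll, -grad


def fit_glmm(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    family: str,
    n_quadrature: int = 15,
    var_fixed: float | None = None,
    terms: Sequence[str] | None = None,
    response: str = "",
) -> FitResult:
    """Fit a log-link GLMM with one Gaussian random intercept.

    ``groups`` holds integer site codes. ``var_fixed=0`` pins the random
    intercept variance to zero, reducing the model to an ordinary GLM solved
    exactly by Newton scoring. Otherwise the marginal likelihood is maximised
    by L-BFGS-B over (coefficients, log sigma[, log shape]) with adaptive
    Gauss-Hermite quadrature (``n_quadrature`` nodes; 1 node = Laplace).
    Non-convergence is flagged on the result, never silent.
    """
    if family not in ("poisson", "gamma"):
        raise ValueError(f"family must be 'poisson' or 'gamma', got {family!r}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    codes = np.asarray(groups)
    if codes.dtype.kind not in "iu":
        _, codes = np.unique(codes, return_inverse=True)
    n_groups = int(codes.max()) + 1 if len(codes) else 0
    p = X.shape[1]
    terms = list(terms) if terms is not None else [f"x{i}" for i in range(p)]

    if var_fixed is not None and var_fixed != 0.0:
        raise ValueError("var_fixed supports only 0 (the GLM reduction)")

    if var_fixed == 0.0:
        beta, k, ll = _fit_glm(X, y, family)
        eta = X @ beta
        if family == "poisson":
            info = X.T @ (np.exp(eta)[:, None] * X)
        else:
            info = k * (X.T @ X)
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
        z = beta / se
        return FitResult(response, family, terms, beta, se, z, 2.0 * norm.sf(np.abs(z)),
                         0.0, k if family == "gamma" else None, ll, True,
                         len(y), n_groups, 0, "variance pinned to 0: exact GLM fit")

    nodes, weights = hermgauss(n_quadrature)

    beta0, k0, _ = _fit_glm(X, y, family)
    theta0 = np.concatenate([beta0, [np.log(0.3)]])
    if family == "gamma":
        theta0 = np.concatenate([theta0, [np.log(max(min(k0, 1e3), 1e-3))]])

    bounds = [(None, None)] * p + [(np.log(1e-6), np.log(1e3))]
    if family == "gamma":
        bounds.append((np.log(1e-4), np.log(1e6)))

    args = (X, y, codes, family, nodes, weights, n_groups)
    if n_quadrature >= 5:
        fun, jac = _marginal_nll_and_grad, True
    else:
        # with very few nodes the Fisher-identity gradient is a poor gradient
        # of the quadrature objective (it ignores the adaptive rescaling), so
        # optimise the objective itself by finite differences
        fun, jac = (lambda t, *a: _marginal_nll_and_grad(t, *a)[0]), None
    res = minimize(
        fun, theta0, jac=jac, args=args,
        method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    theta = res.x
    nll, grad = _marginal_nll_and_grad(theta, X, y, codes, family, nodes, weights, n_groups)
    converged = bool(res.success) or float(np.max(np.abs(grad))) < 1e-3
    message = res.message if isinstance(res.message, str) else str(res.message)

    from statsmodels.tools.numdiff import approx_hess

    def nll_only(t: np.ndarray) -> float:
        return _marginal_nll_and_grad(t, X, y, codes, family, nodes, weights, n_groups)[0]

    H = approx_hess(theta, nll_only)
    try:
        cov = np.linalg.inv(H)
        diag = np.diag(cov)
        if np.any(diag[:p] <= 0):
            raise np.linalg.LinAlgError("non-positive variance")
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
        diag = np.abs(np.diag(cov))
        converged = False
        message += "; observed information not positive definite"

    beta = theta[:p]
    se = np.sqrt(diag[:p])
    z = beta / se
    sigma = float(np.exp(theta[p]))
    shape = float(np.exp(theta[p + 1])) if family == "gamma" else None
    return FitResult(response, family, terms, beta, se, z, 2.0 * norm.sf(np.abs(z)),
                     sigma * sigma, shape, -nll, converged, len(y), n_groups,
                     n_quadrature, message)


def fit_playback_model(
    records: pd.DataFrame,
    response: str,
    interaction: bool = False,
    n_quadrature: int = 15,
    var_fixed: float | None = None,
) -> FitResult:
    """Build the design for one response and fit its GLMM."""
    X, y, codes, terms, _ = build_design(records, response, interaction=interaction)
    family = RESPONSE_FAMILY[response]
    return fit_glmm(X, y, codes, family, n_quadrature=n_quadrature,
                    var_fixed=var_fixed, terms=terms, response=response)


# ---------------------------------------------------------------------------
# interaction selection and species subsets
# ---------------------------------------------------------------------------

@dataclass
class InteractionSelection:
    """Trace of the interaction-dropping rule for one response."""

    full: FitResult
    reduced: FitResult | None
    chosen: FitResult = field(init=False)
    interaction_p: float = field(init=False)
    kept_interaction: bool = field(init=False)

    def __post_init__(self) -> None:
        self.interaction_p = self.full.term("time_of_day:treatment")["p"]
        self.kept_interaction = self.reduced is None
        self.chosen = self.full if self.reduced is None else self.reduced

    def summary(self) -> dict:
        return {
            "interaction_p": self.interaction_p,
            "kept_interaction": self.kept_interaction,
            "full": self.full.summary(),
            "reduced": None if self.reduced is None else self.reduced.summary(),
        }


def select_interaction(
    records: pd.DataFrame,
    response: str,
    alpha: float = 0.05,
    n_quadrature: int = 15,
) -> InteractionSelection:
    """Fit with the time-of-day x treatment interaction; drop it if p >= alpha.

    A p-value exactly at the threshold removes the interaction (the rule keeps
    it only when strictly significant). Both fits are retained in the trace.
    """
    full = fit_playback_model(records, response, interaction=True,
                              n_quadrature=n_quadrature)
    p_int = full.term("time_of_day:treatment")["p"]
    reduced = None
    if p_int >= alpha:
        reduced = fit_playback_model(records, response, interaction=False,
                                     n_quadrature=n_quadrature)
    return InteractionSelection(full=full, reduced=reduced)


def species_subset(
    records_by_species: Mapping[str, pd.DataFrame],
    response: str,
    alpha: float = 0.05,
    n_quadrature: int = 15,
    min_trials: int = 12,
) -> dict[str, InteractionSelection | None]:
    """Run the same model pipeline on each species' records.

    Empty subsets are skipped with a warning; sparse subsets (fewer usable
    trials than ``min_trials`` — the scarce-species case) are flagged with a
    warning but still fitted. A subset whose design cannot be built is skipped
    rather than failed.
    """
    out: dict[str, InteractionSelection | None] = {}
    col = _RESPONSE_COLUMN[response]
    for species, records in records_by_species.items():
        usable = records.dropna(subset=[col])
        if len(usable) == 0:
            warnings.warn(f"species {species}: no usable trials, skipped", stacklevel=2)
            out[species] = None
            continue
        if len(usable) < min_trials:
            warnings.warn(f"species {species}: sparse subset "
                          f"({len(usable)} trials) — estimates may be unstable",
                          stacklevel=2)
        try:
            out[species] = select_interaction(records, response, alpha=alpha,
                                              n_quadrature=n_quadrature)
        except DesignError as exc:
            warnings.warn(f"species {species}: {exc}; skipped", stacklevel=2)
            out[species] = None
    return out
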