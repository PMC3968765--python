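"""Random-effects logistic models for item-level accuracy.

Implements the model family used for the accuracy analyses:

    y_ij ~ Bernoulli(logit^{-1}(x_ij' beta + z_ij' u_i)),   u_i ~ N(0, D)

with subject-level random effects (intercept, powered item position,
novelty) and fixed effects built from the WMC composite, ordinal item
position raised to a Box-Tidwell power lambda, item novelty, and
rule-token counts raised to a power gamma.  A random-intercept-only
model is integrated by adaptive Gauss-Hermite quadrature; models with
multi-dimensional (diagonal) random effects use the Laplace
approximation.  Model comparison uses BIC with n equal to the total
observation count.

Coefficients are reported on the raw predictor scale (matching the
conventional tabulation of such fits); internally the design columns
are standardized for optimizer conditioning and the estimates mapped
back, which is an exact reparametrization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
import statsmodels.api as sm

__all__ = [
    "ItemProfile",
    "GlmmSpec",
    "GlmmFit",
    "make_profiles",
    "white_nonlinearity_test",
    "box_tidwell",
    "fit_glmm",
    "compare_bic",
    "simulate_from_model",
    "MODEL_TERMS",
]

FIXED_TERMS = ("intercept", "wmc", "position", "wmc:position", "novelty", "tokens", "wmc:tokens")
RANDOM_TERMS = ("intercept", "position", "novelty")

#: Fixed/random term sets of the standard model ladder.
MODEL_TERMS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "1": (("intercept", "wmc", "position", "wmc:position"), ("intercept",)),
    "2": (("intercept", "wmc", "position", "wmc:position"), ("intercept", "position")),
    "3": (
        ("intercept", "wmc", "position", "wmc:position"),
        ("intercept", "position", "novelty"),
    ),
    "4": (("intercept", "wmc", "position", "wmc:position", "novelty"), ("intercept",)),
    "tokens": (("intercept", "wmc", "tokens", "wmc:tokens"), ("intercept",)),
}


@dataclass(frozen=True)
class ItemProfile:
    """Metadata for one item: serial position, novelty flag, token count."""

    position: int
    novelty: int
    tokens: float | None = None


def make_profiles(
    n_items: int = 36,
    novelty_items: tuple[int, ...] = (2, 10, 14, 16, 18, 21, 25, 28, 30, 31, 35),
    token_counts: np.ndarray | None = None,
) -> pd.DataFrame:
    """Item metadata table with columns item, position, novelty, tokens."""
    pos = np.arange(1, n_items + 1)
    nov = np.isin(pos, novelty_items).astype(int)
    tok = np.full(n_items, np.nan) if token_counts is None else np.asarray(token_counts, float)
    return pd.DataFrame({"item": pos, "position": pos, "novelty": nov, "tokens": tok})


@dataclass(frozen=True)
class GlmmSpec:
    """Which fixed and random terms enter the model, plus the exponents."""

    fixed_terms: tuple[str, ...] = MODEL_TERMS["1"][0]
    random_terms: tuple[str, ...] = MODEL_TERMS["1"][1]
    lambda_: float = 1.704
    gamma: float = 2.32

    def __post_init__(self) -> None:
        if "intercept" not in self.fixed_terms:
            raise ValueError("intercept must be among the fixed terms")
        for t in self.fixed_terms:
            if t not in FIXED_TERMS:
                raise ValueError(f"unknown fixed term {t!r}")
        for t in self.random_terms:
            if t not in RANDOM_TERMS:
                raise ValueError(f"unknown random term {t!r}")
        for inter, main in (("wmc:position", ("wmc", "position")), ("wmc:tokens", ("wmc", "tokens"))):
            if inter in self.fixed_terms and any(m not in self.fixed_terms for m in main):
                raise ValueError(f"{inter} requires both main effects")
        if self.lambda_ <= 0 or self.gamma <= 0:
            raise ValueError("lambda and gamma must be positive")


@dataclass
class GlmmFit:
    """Estimated mixed logistic model."""

    coefficients: dict[str, float]
    std_errors: dict[str, float]
    random_sd: dict[str, float]
    loglik: float
    bic: float
    df: int
    n_obs: int
    converged: bool
    boundary: bool = False
    spec: GlmmSpec | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# diagnostic screens


def white_nonlinearity_test(x: np.ndarray, y: np.ndarray) -> tuple[float, int, float]:
    """Likelihood-ratio screen for a non-linear logit relationship.

    Compares logistic(y ~ x) against logistic(y ~ x + x^2 + x^3) with
    the added polynomial terms standardized; the statistic is chi-square
    with 2 degrees of freedom under the linear null.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0:
        raise ValueError("predictor is constant")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("responses must be binary")
    xs = (x - x.mean()) / x.std()
    base = np.column_stack([np.ones_like(xs), xs])
    aug_terms = np.column_stack([xs**2, xs**3])
    aug_terms = (aug_terms - aug_terms.mean(axis=0)) / aug_terms.std(axis=0)
    aug = np.column_stack([base, aug_terms])
    try:
        ll0 = sm.Logit(y, base).fit(disp=0, maxiter=200).llf
        ll1 = sm.Logit(y, aug).fit(disp=0, maxiter=200).llf
    except Exception as exc:  # perfect separation and friends
        raise RuntimeError(f"White screen unavailable: {exc}") from exc
    chi2 = max(0.0, 2.0 * (ll1 - ll0))
    p = float(stats.chi2.sf(chi2, 2))
    return float(chi2), 2, p


def box_tidwell(
    x: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-3,
    max_iter: int = 20,
    lambda0: float = 1.0,
) -> tuple[float, bool]:
    """Power-transformation exponent linearizing x in the logit.

    At each step the main coefficient ``beta`` comes from the base fit
    logistic(y ~ x^lam) and the auxiliary coefficient ``delta`` from the
    augmented fit logistic(y ~ x^lam + x^lam * ln x); the first-order
    expansion of x^lam in lam gives the update ``lam <- lam + delta /
    beta`` (taking ``beta`` from the base fit avoids the near-collinear
    augmented design destabilizing the ratio).  Iteration stops when the
    update falls below ``tol``.  Returns (lambda_hat, converged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x <= 0):
        raise ValueError("Box-Tidwell requires a strictly positive predictor")
    lnx = np.log(x)
    lam = float(lambda0)
    ones = np.ones_like(x)
    for _ in range(max_iter):
        xl = x**lam
        s1 = xl.std() or 1.0
        aux = xl * lnx
        s2 = aux.std() or 1.0
        base = sm.Logit(y, np.column_stack([ones, xl / s1])).fit(disp=0, maxiter=200)
        augm = sm.Logit(
            y, np.column_stack([ones, xl / s1, aux / s2])
        ).fit(disp=0, maxiter=200)
        beta = base.params[1] / s1
        delta = augm.params[2] / s2
        if beta == 0:
            return lam, False
        step = float(np.clip(delta / beta, -2.0, 2.0))
        lam_new = lam + step
        if lam_new <= 0:
            lam_new = lam / 2.0
        if abs(lam_new - lam) < tol:
            return float(lam_new), True
        lam = lam_new
    return float(lam), False


# ---------------------------------------------------------------------------
# design construction

_TERM_LABELS = {
    "intercept": "intercept",
    "wmc": "wmc",
    "position": "position^lambda",
    "wmc:position": "wmc:position^lambda",
    "novelty": "novelty",
    "tokens": "tokens^gamma",
    "wmc:tokens": "wmc:tokens^gamma",
}


def _build_design(
    responses: pd.DataFrame,
    profiles: pd.DataFrame,
    covariate: np.ndarray,
    spec: GlmmSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str], np.ndarray]:
    """Rectangular (subject x item) response array plus design matrices.

    Returns (y, X_fixed, Z_random, fixed_labels, subject_index) where y
    is n_subjects x n_items and X/Z are n_items x p arrays replicated
    across subjects except for the WMC column, handled separately.
    """
    df = responses.merge(profiles, on="item", how="left")
    if df[["subject", "item", "y"]].isna().any().any():
        raise ValueError("responses must be complete cases")
    pivot = df.pivot(index="subject", columns="item", values="y")
    if pivot.isna().any().any():
        raise ValueError("responses must be balanced (every subject x item cell)")
    items = pivot.columns.to_numpy()
    prof = profiles.set_index("item").loc[items]
    y = pivot.to_numpy(dtype=float)
    n_subj = y.shape[0]
    covariate = np.asarray(covariate, dtype=float)
    if len(covariate) != n_subj:
        raise ValueError("covariate length must equal the number of subjects")

    psi = prof["position"].to_numpy(dtype=float) ** spec.lambda_
    nov = prof["novelty"].to_numpy(dtype=float)
    tok = prof["tokens"].to_numpy(dtype=float)
    if ("tokens" in spec.fixed_terms or "wmc:tokens" in spec.fixed_terms) and np.isnan(
        tok
    ).any():
        raise ValueError("token counts required for token terms")
    tokg = tok**spec.gamma

    item_parts = {
        "intercept": np.ones_like(psi),
        "position": psi,
        "novelty": nov,
        "tokens": tokg,
    }
    # fixed design as n_subj x n_items x p
    cols = []
    labels = []
    for term in spec.fixed_terms:
        labels.append(_TERM_LABELS[term])
        if term == "wmc":
            cols.append(np.repeat(covariate[:, None], len(items), axis=1))
        elif term.startswith("wmc:"):
            part = item_parts[term.split(":")[1]]
            cols.append(covariate[:, None] * part[None, :])
        else:
            cols.append(np.repeat(item_parts[term][None, :], n_subj, axis=0))
    X = np.stack(cols, axis=2)
    Z = np.stack([item_parts[t] for t in spec.random_terms], axis=1)  # items x q
    return y, X, Z, labels, pivot.index.to_numpy()


# ---------------------------------------------------------------------------
# marginal likelihood machinery


def _subject_loglik_agh(
    eta: np.ndarray, y: np.ndarray, sd: float, nodes: np.ndarray, wts: np.ndarray
) -> np.ndarray:
    """Per-subject marginal log-likelihood, random intercept, adaptive GH.

    eta, y: n_subj x n_items arrays.  The quadrature grid is recentered
    at each subject's posterior mode with curvature-matched scaling.
    """
    if sd < 1e-8:
        return _bernoulli_loglik(eta, y)
    var = sd**2
    u = np.zeros(eta.shape[0])
    for _ in range(25):  # Newton mode-finding, vectorized over subjects
        p = special.expit(eta + u[:, None])
        g = (y - p).sum(axis=1) - u / var
        h = (p * (1 - p)).sum(axis=1) + 1.0 / var
        step = g / h
        u += step
        if np.max(np.abs(step)) < 1e-9:
            break
    p = special.expit(eta + u[:, None])
    h = (p * (1 - p)).sum(axis=1) + 1.0 / var
    scale = 1.0 / np.sqrt(h)
    # integrand log f(u) = sum_j [y eta - log(1+e^eta)] + log phi(u; 0, var)
    pts = u[:, None] + scale[:, None] * nodes[None, :]  # n_subj x K
    etau = eta[:, :, None] + pts[:, None, :]
    ll = (y[:, :, None] * etau - np.logaddexp(0.0, etau)).sum(axis=1)
    ll += -0.5 * pts**2 / var - 0.5 * np.log(2 * np.pi * var)
    # AGH weights: w_k * exp(t_k^2 / 2) for probabilists' nodes, times scale
    log_int = (
        special.logsumexp(ll + 0.5 * nodes[None, :] ** 2 + np.log(wts)[None, :], axis=1)
        + np.log(scale)
        + 0.5 * np.log(2 * np.pi)
    )
    return log_int


def _bernoulli_loglik(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    return (y * eta - np.logaddexp(0.0, eta)).sum(axis=1)


def _subject_loglik_laplace(
    eta: np.ndarray, y: np.ndarray, Z: np.ndarray, sds: np.ndarray
) -> np.ndarray:
    """Laplace-approximate marginal log-likelihood, diagonal random effects.

    eta: n_subj x n_items, Z: n_items x q, sds: length-q random-effect SDs.
    """
    n_subj = eta.shape[0]
    q = Z.shape[1]
    var = np.maximum(sds, 1e-6) ** 2
    u = np.zeros((n_subj, q))
    eye = np.eye(q)
    for _ in range(50):
        lin = eta + u @ Z.T
        p = special.expit(lin)
        g = (y - p) @ Z - u / var[None, :]
        w = p * (1 - p)
        # Hessian per subject: Z' diag(w_i) Z + D^{-1}
        H = np.einsum("ij,jk,jl->ikl", w, Z, Z) + eye * (1.0 / var)
        step = np.linalg.solve(H, g[:, :, None])[:, :, 0]
        u += step
        if np.max(np.abs(step)) < 1e-9:
            break
    lin = eta + u @ Z.T
    p = special.expit(lin)
    w = p * (1 - p)
    H = np.einsum("ij,jk,jl->ikl", w, Z, Z) + eye * (1.0 / var)
    f = (y * lin - np.logaddexp(0.0, lin)).sum(axis=1)
    f += -0.5 * (u**2 / var[None, :]).sum(axis=1) - 0.5 * np.log(2 * np.pi * var).sum()
    sign, logdet = np.linalg.slogdet(H / (2 * np.pi))
    return f - 0.5 * logdet


def fit_glmm(
    responses: pd.DataFrame,
    profiles: pd.DataFrame,
    covariate: np.ndarray,
    spec: GlmmSpec | None = None,
    n_quad: int = 15,
    fix_random_sd: float | None = None,
) -> GlmmFit:
    """Maximum marginal likelihood fit of the mixed logistic model.

    ``responses`` is long-format with columns subject, item, y (0/1);
    ``profiles`` carries item, position, novelty and optionally tokens;
    ``covariate`` is the per-subject WMC composite aligned with the
    sorted subject labels.  ``fix_random_sd`` pins every random-effect
    SD at a constant instead of estimating it (0 reduces the model to a
    plain logistic regression, which is the oracle used in tests).
    """
    if spec is None:
        spec = GlmmSpec()
    y, X, Z, labels, _ = _build_design(responses, profiles, covariate, spec)
    n_subj, n_items, p = X.shape
    n_obs = y.size
    q = Z.shape[1]
    intercept_only_random = spec.random_terms == ("intercept",)

    # standardize non-intercept fixed columns (exact reparametrization)
    Xf = X.reshape(-1, p)
    mu = Xf.mean(axis=0)
    sd = Xf.std(axis=0)
    mu[0], sd[0] = 0.0, 1.0  # leave the intercept column alone
    sd[sd == 0] = 1.0
    Xs = ((Xf - mu) / sd).reshape(n_subj, n_items, p)

    nodes, wts = np.polynomial.hermite_e.hermegauss(n_quad)
    wts = wts / wts.sum()

    glm = sm.Logit(y.reshape(-1), Xs.reshape(-1, p)).fit(disp=0, maxiter=200)
    estimate_sds = fix_random_sd is None
    n_var = q if estimate_sds else 0
    fixed_sds = None if estimate_sds else np.full(q, float(fix_random_sd))

    def unpack(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        beta = theta[:p]
        sds = np.exp(theta[p:]) if estimate_sds else fixed_sds
        return beta, sds

    def negll(theta: np.ndarray) -> float:
        beta, sds = unpack(theta)
        eta = Xs @ beta
        if np.all(sds < 1e-8):
            ll = _bernoulli_loglik(eta, y)
        elif intercept_only_random:
            ll = _subject_loglik_agh(eta, y, sds[0], nodes, wts)
        else:
            ll = _subject_loglik_laplace(eta, y, Z, sds)
        return -float(ll.sum())

    theta0 = np.concatenate([glm.params, np.log(np.full(n_var, 0.3))])
    res = optimize.minimize(
        negll,
        theta0,
        method="L-BFGS-B",
        bounds=[(None, None)] * p + [(-7.0, 3.0)] * n_var,
        options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-7},
    )
    theta = res.x
    loglik = -res.fun
    _, sds_hat = unpack(theta)
    boundary = bool(estimate_sds and np.any(theta[p:] <= -6.5))

    # observed-information standard errors in the standardized basis
    try:
        hess = _numerical_hessian(negll, theta)
        cov = np.linalg.inv(hess)
        se_std = np.sqrt(np.maximum(np.diag(cov)[:p], 0.0))
    except np.linalg.LinAlgError:
        se_std = np.full(p, np.nan)

    # back-transform to the raw predictor scale
    beta_std = theta[:p]
    beta_raw = beta_std / sd
    beta_raw[0] = beta_std[0] - np.sum(beta_std[1:] * mu[1:] / sd[1:])
    se_raw = se_std / sd
    if not np.isnan(se_std[0]):
        # delta method for the intercept under the linear back-map
        jac = np.zeros(p)
        jac[0] = 1.0
        jac[1:] = -mu[1:] / sd[1:]
        se_raw[0] = float(np.sqrt(jac @ cov[:p, :p] @ jac))

    df = p + n_var
    bic = -2.0 * loglik + df * np.log(n_obs)
    return GlmmFit(
        coefficients=dict(zip(labels, beta_raw)),
        std_errors=dict(zip(labels, se_raw)),
        random_sd={t: float(s) for t, s in zip(spec.random_terms, sds_hat)},
        loglik=float(loglik),
        bic=float(bic),
        df=df,
        n_obs=n_obs,
        converged=bool(res.success),
        boundary=boundary,
        spec=spec,
    )


def _numerical_hessian(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    n = len(x)
    h = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            xi = x.copy()
            xi[i] += eps
            xi[j] += eps
            fpp = f(xi)
            xi = x.copy()
            xi[i] += eps
            xi[j] -= eps
            fpm = f(xi)
            xi = x.copy()
            xi[i] -= eps
            xi[j] += eps
            fmp = f(xi)
            xi = x.copy()
            xi[i] -= eps
            xi[j] -= eps
            fmm = f(xi)
            h[i, j] = h[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps**2)
    del f0
    return h


def compare_bic(fits: list[GlmmFit]) -> tuple[GlmmFit, list[GlmmFit]]:
    """Best fit by BIC (ties toward fewer parameters) plus full ranking."""
    if not fits:
        raise ValueError("no fits to compare")
    n_obs = {f.n_obs for f in fits}
    if len(n_obs) != 1:
        raise ValueError("fits were not computed on identical data (n_obs differ)")
    ranking = sorted(fits, key=lambda f: (f.bic, f.df))
    return ranking[0], ranking


def simulate_from_model(
    spec: GlmmSpec,
    coefficients: dict[str, float],
    random_sd: dict[str, float],
    covariate: np.ndarray,
    profiles: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw long-format binary responses from a fully specified model.

    Coefficients are on the raw predictor scale, keyed by the term
    labels (``intercept``, ``wmc``, ``position^lambda``, ...).
    """
    covariate = np.asarray(covariate, dtype=float)
    n_subj = len(covariate)
    items = profiles["item"].to_numpy()
    n_items = len(items)
    dummy = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(1, n_subj + 1), n_items),
            "item": np.tile(items, n_subj),
            "y": 0.0,
        }
    )
    _, X, Z, labels, _ = _build_design(dummy, profiles, covariate, spec)
    missing = [l for l in labels if l not in coefficients]
    if missing:
        raise ValueError(f"missing coefficients for terms: {missing}")
    beta = np.array([coefficients[l] for l in labels])
    sds = np.array([float(random_sd.get(t, 0.0)) for t in spec.random_terms])
    if np.any(sds < 0):
        raise ValueError("random-effect SDs must be >= 0")
    u = rng.standard_normal((n_subj, Z.shape[1])) * sds[None, :]
    eta = X @ beta + u @ Z.T
    yy = (rng.random((n_subj, n_items)) < special.expit(eta)).astype(int)
    dummy["y"] = yy.reshape(-1)
    return dummy
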