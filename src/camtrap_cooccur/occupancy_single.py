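"""Single-season, single-species occupancy models.

The model is the classic zero-inflated detection model: a site is occupied
with probability psi (logit-linear in site covariates) and, if occupied,
detected on occasion t with probability p_t (logit-linear in occasion
covariates such as the grazing-season flag).  The site likelihood
marginalizes the latent occupancy state:

    L_i = psi_i * prod_t p_it^y_it (1 - p_it)^(1 - y_it)
          + (1 - psi_i) * I(all observed y_it = 0)

with NA occasions dropped from the product.  Model selection uses AICc,
delta-AICc equivalence (<= 2) and Akaike weights.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from statsmodels.tools.numdiff import approx_fprime, approx_hess

from camtrap_cooccur.data_model import DetectionHistory

_GRAD_TOL = 0.05      # max |gradient| on the nll scale for the converged flag
_OPT_OPTIONS = {"maxiter": 2000, "maxfun": 20000, "ftol": 1e-11, "gtol": 1e-7}
_BOUNDARY_LOGIT = 10  # |logit| beyond this flags a boundary estimate


@dataclass(frozen=True)
class OccModelSpec:
    """A candidate model: covariates on occupancy and on detection."""

    psi_covariates: tuple[str, ...] = ()
    p_covariates: tuple[str, ...] = ("Time",)

    def label(self) -> str:
        p = ", ".join(self.p_covariates) or "."
        psi = ", ".join(self.psi_covariates) or "."
        return f"P ({p}). Psi ({psi})"


@dataclass
class OccFit:
    """A fitted single-species occupancy model."""

    spec: OccModelSpec
    beta_psi: np.ndarray          # intercept first
    beta_p: np.ndarray            # intercept first
    se_psi: np.ndarray
    se_p: np.ndarray
    logLik: float
    K: int
    n_sites: int
    converged: bool
    boundary: bool = False
    seed: int | None = None

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([self.beta_psi, self.beta_p])


@dataclass
class ModelRanking:
    """AICc ranking of a candidate set."""

    table: pd.DataFrame           # Model, K, logLik, AICc, dAICc, weight
    fits: list[OccFit] = field(default_factory=list)

    @property
    def equivalence_set(self) -> pd.DataFrame:
        return self.table[self.table["dAICc"] <= 2.0]

    @property
    def best(self) -> OccFit:
        return self.fits[int(self.table.index[0])]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _log_sigmoid(x: np.ndarray) -> np.ndarray:
    return -np.logaddexp(0.0, -x)


def nll_single(
    params: np.ndarray,
    y: np.ndarray,
    psi_design: np.ndarray,
    p_design: np.ndarray,
) -> float:
    """Negative log-likelihood of the single-species occupancy model.

    Parameters
    ----------
    params
        Concatenated ``(beta_psi, beta_p)``; logit links.
    y
        Sites x occasions matrix in {0, 1, NaN}.
    psi_design
        Sites x k_psi design (intercept column included).
    p_design
        Occasions x k_p design shared across sites, or a per-site
        sites x occasions x k_p array.

    All-NA sites contribute zero.
    """
    params = np.asarray(params, dtype=float)
    if not np.all(np.isfinite(params)):
        raise ValueError("non-finite parameters")
    k_psi = psi_design.shape[1]
    b_psi, b_p = params[:k_psi], params[k_psi:]

    eta_psi = psi_design @ b_psi                      # (n,)
    if p_design.ndim == 2:
        eta_p = np.broadcast_to(p_design @ b_p, y.shape)  # (n, T)
    else:
        eta_p = np.einsum("ntk,k->nt", p_design, b_p)

    obs = ~np.isnan(y)
    yy = np.where(obs, y, 0.0)
    # log detection likelihood given occupied
    ll_det = np.where(obs, yy * _log_sigmoid(eta_p) + (1 - yy) * _log_sigmoid(-eta_p), 0.0)
    ld1 = ll_det.sum(axis=1)
    never = (np.where(obs, yy, 0.0).sum(axis=1) == 0) & obs.any(axis=1)
    all_na = ~obs.any(axis=1)

    log_psi = _log_sigmoid(eta_psi)
    log_1mpsi = _log_sigmoid(-eta_psi)
    # occupied branch always; unoccupied branch only when no detections
    with np.errstate(divide="ignore"):
        branch0 = np.where(never, log_1mpsi, -np.inf)
    site_ll = np.logaddexp(log_psi + ld1, branch0)
    site_ll = np.where(all_na, 0.0, site_ll)
    return float(-site_ll.sum())


def brute_force_nll_single(params, y, psi_design, p_design) -> float:
    """Independent oracle: explicit sum over the latent state z in {0, 1}."""
    params = np.asarray(params, dtype=float)
    k_psi = psi_design.shape[1]
    b_psi, b_p = params[:k_psi], params[k_psi:]
    n, T = y.shape
    total = 0.0
    for i in range(n):
        psi = 1 / (1 + np.exp(-(psi_design[i] @ b_psi)))
        lik = 0.0
        for z in (0, 1):
            term = psi if z == 1 else 1 - psi
            for t in range(T):
                if np.isnan(y[i, t]):
                    continue
                if p_design.ndim == 2:
                    p = 1 / (1 + np.exp(-(p_design[t] @ b_p)))
                else:
                    p = 1 / (1 + np.exp(-(p_design[i, t] @ b_p)))
                pd_ = z * p
                term *= pd_ if y[i, t] == 1 else 1 - pd_
            lik += term
        if np.isnan(y[i]).all():
            continue
        total -= np.log(lik)
    return float(total)


def _build_designs(
    spec: OccModelSpec,
    history: DetectionHistory,
    site_design: pd.DataFrame,
    occasion_covariates: pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    y = history.matrix.to_numpy(dtype=float)
    n, T = y.shape
    psi_X = np.ones((n, 1 + len(spec.psi_covariates)))
    for j, cov in enumerate(spec.psi_covariates):
        psi_X[:, 1 + j] = site_design.loc[history.matrix.index, cov].to_numpy()
    p_X = np.ones((T, 1 + len(spec.p_covariates)))
    for j, cov in enumerate(spec.p_covariates):
        p_X[:, 1 + j] = occasion_covariates[cov].to_numpy()
    return y, psi_X, p_X


def fit_single(
    spec: OccModelSpec,
    history: DetectionHistory,
    site_design: pd.DataFrame,
    occasion_covariates: pd.DataFrame,
    n_starts: int = 5,
    seed: int | None = None,
) -> OccFit:
    """Fit one candidate model by maximum likelihood.

    Quasi-Newton (L-BFGS-B) from ``n_starts`` jittered initializations;
    the best optimum is kept.  Standard errors come from the inverse of the
    numerically estimated Hessian at the MLE.  Boundary estimates
    (|logit| > 10 for the implied psi or p at the sample mean design) are
    flagged, not clamped.
    """
    y, psi_X, p_X = _build_designs(spec, history, site_design, occasion_covariates)
    obs = ~np.isnan(y)
    if np.nansum(y) == 0:
        raise ValueError(
            "species never detected; exclude it from the analysis rather than fitting"
        )
    k = psi_X.shape[1] + p_X.shape[1]
    rng = np.random.default_rng(seed)

    def objective(th):
        try:
            return nll_single(th, y, psi_X, p_X)
        except (ValueError, FloatingPointError):
            return np.inf

    best = None
    for s in range(n_starts):
        x0 = np.zeros(k) if s == 0 else rng.normal(scale=1.0, size=k)
        res = minimize(objective, x0, method="L-BFGS-B", options=_OPT_OPTIONS)
        if best is None or res.fun < best.fun:
            best = res

    theta = best.x
    grad = approx_fprime(theta, objective, centered=True)
    converged = bool(best.success and np.max(np.abs(grad)) < _GRAD_TOL)

    hess = approx_hess(theta, objective)
    se = np.full(k, np.nan)
    try:
        cov = np.linalg.inv(hess)
        d = np.diag(cov)
        se = np.where(d > 0, np.sqrt(np.abs(d)), np.nan)
    except np.linalg.LinAlgError:
        pass

    k_psi = psi_X.shape[1]
    eta_psi = psi_X @ theta[:k_psi]
    eta_p = p_X @ theta[k_psi:]
    boundary = bool(
        np.max(np.abs(eta_psi)) > _BOUNDARY_LOGIT or np.max(np.abs(eta_p)) > _BOUNDARY_LOGIT
    )
    n_sites = int(obs.any(axis=1).sum())
    return OccFit(
        spec=spec,
        beta_psi=theta[:k_psi],
        beta_p=theta[k_psi:],
        se_psi=se[:k_psi],
        se_p=se[k_psi:],
        logLik=-float(best.fun),
        K=k,
        n_sites=n_sites,
        converged=converged,
        boundary=boundary,
        seed=seed,
    )


def aicc(logLik: float, K: int, n: int) -> float:
    """Akaike information criterion with the small-sample correction.

    AICc = -2 logLik + 2K + 2K(K+1)/(n - K - 1), undefined for n <= K + 1.
    ``n`` is the number of sites entering the model.
    """
    if n <= K + 1:
        raise ValueError(f"AICc undefined for n={n} <= K+1={K + 1}")
    return -2.0 * logLik + 2.0 * K + 2.0 * K * (K + 1) / (n - K - 1)


def akaike_weights(delta: np.ndarray) -> np.ndarray:
    """Akaike weights from delta-AICc values: w_i ∝ exp(-Δ_i / 2)."""
    delta = np.asarray(delta, dtype=float)
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def rank_models(fits: list[OccFit], n: int | None = None) -> ModelRanking:
    """Rank fitted models by AICc; attach delta-AICc and Akaike weights."""
    if not fits:
        raise ValueError("need at least one fit")
    if n is None:
        n = fits[0].n_sites
    rows = []
    for f in fits:
        rows.append(
            {
                "Model": f.spec.label(),
                "K": f.K,
                "logLik": f.logLik,
                "AICc": aicc(f.logLik, f.K, n),
                "converged": f.converged,
            }
        )
    table = pd.DataFrame(rows)
    table["dAICc"] = table["AICc"] - table["AICc"].min()
    table["weight"] = akaike_weights(table["dAICc"].to_numpy())
    order = table.sort_values("AICc").index
    return ModelRanking(table=table.loc[order], fits=fits)


def all_subsets(
    candidate_covariates: list[str],
    p_covariates: tuple[str, ...] = ("Time",),
    max_candidates: int = 10,
) -> list[OccModelSpec]:
    """All-subsets candidate set: every subset of occupancy covariates
    crossed with the fixed detection structure (2^k models)."""
    if len(candidate_covariates) > max_candidates:
        raise ValueError(
            f"{len(candidate_covariates)} candidates exceed the {max_candidates}-"
            "covariate enumeration limit; restrict the candidate list"
        )
    specs = []
    for r in range(len(candidate_covariates) + 1):
        for combo in itertools.combinations(candidate_covariates, r):
            specs.append(OccModelSpec(psi_covariates=combo, p_covariates=tuple(p_covariates)))
    return specs


def write_ranking(ranking: ModelRanking, path) -> None:
    """Write the AICc ranking table (Model, K, logLik, AICc, dAICc, weight)."""
    cols = ["Model", "K", "logLik", "AICc", "dAICc", "weight"]
    ranking.table[cols].to_csv(path, index=False)
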