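"""Multi-species occupancy with pairwise interactions.

Joint occupancy of S species at a site follows a multivariate Bernoulli
distribution parameterized with log-linear natural parameters: first-order
terms f_i(x) = x' beta_i (one per species, covariate-dependent) and
second-order pairwise intercepts f_ij (constant).  The probability of a
presence vector z in {0,1}^S is

    psi(z | x) ∝ exp( sum_i f_i(x) z_i + sum_{i<j} f_ij z_i z_j ),

normalized over all 2^S states; third- and higher-order terms are fixed at
zero.  f_ij > 0 implies co-occurrence beyond what covariates explain, and
f_ij < 0 implies avoidance.  Detection is imperfect: given the latent state,
species s is detected on occasion t with probability z_s * p_st (logit-
linear in occasion covariates), and the site likelihood marginalizes the
2^S latent states exactly.

Derived summaries: conditional occupancy curves, odds ratios for the
presence of another species (ORsp) and for a covariate step (ORh), and the
relative-importance table of |log OR| values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import norm
from statsmodels.tools.numdiff import approx_fprime, approx_hess

from camtrap_cooccur.data_model import DetectionHistory
from camtrap_cooccur.occupancy_single import _GRAD_TOL, _OPT_OPTIONS, _log_sigmoid


@dataclass
class NaturalParams:
    """Natural parameters of the multivariate-Bernoulli occupancy layer."""

    beta: list[np.ndarray]      # per-species coefficients, intercept first
    gamma: np.ndarray           # S x S symmetric matrix of pairwise intercepts

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        if not np.allclose(self.gamma, self.gamma.T):
            raise ValueError("gamma must be symmetric")

    @property
    def n_species(self) -> int:
        return len(self.beta)


@dataclass
class MultiOccFit:
    """A fitted multi-species occupancy model."""

    species: list[str]
    psi_covariates: dict[str, tuple[str, ...]]
    natural_params: NaturalParams
    detection: dict[str, np.ndarray]       # per-species (intercept, Time, ...)
    p_covariates: tuple[str, ...]
    params: np.ndarray
    se: np.ndarray
    param_names: list[str]
    logLik: float
    K: int
    n_sites: int
    converged: bool

    def summary(self) -> pd.DataFrame:
        """Tidy Wald table: component, covariate, estimate, SE, z, p."""
        z = self.params / self.se
        p = 2 * norm.sf(np.abs(z))
        return pd.DataFrame(
            {
                "term": self.param_names,
                "estimate": self.params,
                "SE": self.se,
                "z": z,
                "p": p,
            }
        )


def state_matrix(n_species: int) -> np.ndarray:
    """All 2^S presence vectors; row index encodes the state bit pattern."""
    states = np.array(
        [[(i >> s) & 1 for s in range(n_species)] for i in range(2 ** n_species)],
        dtype=float,
    )
    return states


def _pair_index(n_species: int) -> list[tuple[int, int]]:
    return list(itertools.combinations(range(n_species), 2))


def _log_joint_unnorm(f: np.ndarray, gamma: np.ndarray, states: np.ndarray) -> np.ndarray:
    """Unnormalized log psi for each site (rows of f) and state.

    f : (n, S) first-order natural parameters; gamma : (S, S) symmetric.
    Returns (n, 2^S).
    """
    pair_term = np.array(
        [sum(gamma[i, j] * z[i] * z[j] for i, j in _pair_index(f.shape[1]))
         for z in states]
    )
    return f @ states.T + pair_term


def joint_psi(params: NaturalParams, x: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Joint occupancy distribution at one covariate point.

    Parameters
    ----------
    params
        Natural parameters.
    x
        Per-species covariate rows (each including the intercept entry),
        matching the lengths of ``params.beta``.

    Returns
    -------
    (states, probs): the 2^S presence vectors and their probabilities,
    which are non-negative and sum to one.
    """
    S = params.n_species
    if S < 2:
        raise ValueError("need at least two species")
    f = np.array([[np.dot(np.atleast_1d(x[s]), params.beta[s]) for s in range(S)]])
    states = state_matrix(S)
    logu = _log_joint_unnorm(f, params.gamma, states)[0]
    logp = logu - logsumexp(logu)
    return states, np.exp(logp)


def nll_multi(
    params_vec: np.ndarray,
    ys: np.ndarray,
    psi_designs: list[np.ndarray],
    p_design: np.ndarray,
) -> float:
    """Negative log-likelihood of the multi-species occupancy model.

    Parameters
    ----------
    params_vec
        Packed vector: per-species occupancy coefficients, then the pairwise
        interaction intercepts (combination order), then per-species
        detection coefficients.
    ys
        (S, n, T) detection histories in {0, 1, NaN}; NA masks must agree
        across species (they depend only on deployment).
    psi_designs
        Per-species site design matrices (n x k_s, intercept included).
    p_design
        Occasions x k_p detection design shared across sites and species.

    The site likelihood sums psi(z | x_i) times the detection likelihood of
    each species under its latent state over all 2^S states.
    """
    params_vec = np.asarray(params_vec, dtype=float)
    if not np.all(np.isfinite(params_vec)):
        raise ValueError("non-finite parameters")
    S, n, T = ys.shape
    if len(psi_designs) != S:
        raise ValueError("one psi design per species required")
    for s in range(1, S):
        if not np.array_equal(np.isnan(ys[s]), np.isnan(ys[0])):
            raise ValueError("misaligned histories: NA patterns differ across species")

    beta, gamma, beta_p = unpack_params(
        params_vec, [X.shape[1] for X in psi_designs], S, p_design.shape[1]
    )

    f = np.column_stack([psi_designs[s] @ beta[s] for s in range(S)])  # (n, S)
    states = state_matrix(S)
    logpsi = _log_joint_unnorm(f, gamma, states)
    logpsi -= logsumexp(logpsi, axis=1, keepdims=True)                 # (n, 2^S)

    obs = ~np.isnan(ys[0])                                             # (n, T)
    ld1 = np.empty((S, n))
    ld0 = np.empty((S, n))
    for s in range(S):
        eta = p_design @ beta_p[s]                                     # (T,)
        yy = np.where(obs, ys[s], 0.0)
        ll = np.where(obs, yy * _log_sigmoid(eta) + (1 - yy) * _log_sigmoid(-eta), 0.0)
        ld1[s] = ll.sum(axis=1)
        detected = yy.sum(axis=1) > 0
        # a detection forces z_s = 1: the z_s = 0 branch gets a log-likelihood
        # so low it underflows to zero inside logsumexp (a finite stand-in for
        # -inf keeps 0 * (-inf) = NaN out of the matmul)
        ld0[s] = np.where(detected, -1e30, 0.0)

    # detection log-likelihood of each state: sum_s z_s ld1 + (1-z_s) ld0
    det_ll = states @ ld1 + (1 - states) @ ld0                         # (2^S, n)
    site_ll = logsumexp(logpsi + det_ll.T, axis=1)
    site_ll = np.where(obs.any(axis=1), site_ll, 0.0)
    return float(-site_ll.sum())


def brute_force_nll_multi(params_vec, ys, psi_designs, p_design) -> float:
    """Independent oracle: explicit loops over sites, 2^S states, species,
    occasions."""
    S, n, T = ys.shape
    beta, gamma, beta_p = unpack_params(
        np.asarray(params_vec, float), [X.shape[1] for X in psi_designs], S,
        p_design.shape[1],
    )
    pairs = _pair_index(S)
    total = 0.0
    for i in range(n):
        if np.isnan(ys[:, i, :]).all():
            continue
        f = [psi_designs[s][i] @ beta[s] for s in range(S)]
        weights = []
        for state in itertools.product((0, 1), repeat=S):
            e = sum(f[s] * state[s] for s in range(S))
            e += sum(gamma[a, b] * state[a] * state[b] for a, b in pairs)
            weights.append(np.exp(e))
        weights = np.array(weights) / np.sum(weights)
        lik = 0.0
        for w, state in zip(weights, itertools.product((0, 1), repeat=S)):
            term = w
            for s in range(S):
                p = 1 / (1 + np.exp(-(p_design @ beta_p[s])))
                for t in range(T):
                    if np.isnan(ys[s, i, t]):
                        continue
                    pd_ = state[s] * p[t]
                    term *= pd_ if ys[s, i, t] == 1 else 1 - pd_
            lik += term
        total -= np.log(lik)
    return float(total)


def pack_params(beta: list[np.ndarray], gamma: np.ndarray, beta_p: list[np.ndarray]) -> np.ndarray:
    S = len(beta)
    gam = [gamma[i, j] for i, j in _pair_index(S)]
    return np.concatenate([*beta, gam, *beta_p])


def unpack_params(
    vec: np.ndarray, k_psi: list[int], S: int, k_p: int
) -> tuple[list[np.ndarray], np.ndarray, list[np.ndarray]]:
    beta = []
    pos = 0
    for k in k_psi:
        beta.append(vec[pos:pos + k])
        pos += k
    gamma = np.zeros((S, S))
    for (i, j) in _pair_index(S):
        gamma[i, j] = gamma[j, i] = vec[pos]
        pos += 1
    beta_p = []
    for _ in range(S):
        beta_p.append(vec[pos:pos + k_p])
        pos += k_p
    return beta, gamma, beta_p


def fit_multi(
    psi_covariates: dict[str, tuple[str, ...] | list[str]],
    histories: dict[str, DetectionHistory],
    site_design: pd.DataFrame,
    occasion_covariates: pd.DataFrame,
    p_covariates: tuple[str, ...] = ("Time",),
    n_starts: int = 5,
    seed: int | None = None,
) -> MultiOccFit:
    """Fit the interaction model by maximum likelihood.

    Per-species occupancy covariates are fixed in advance (two-step
    procedure: the winners of the single-species AICc ranking).  Interaction
    terms are intercept-only.  Wald standard errors come from the inverse of
    the numerical Hessian at the MLE; non-convergence after all starts is
    flagged on the returned fit, never raised.
    """
    species = list(psi_covariates)
    S = len(species)
    idx = histories[species[0]].matrix.index
    ys = np.stack([histories[sp].matrix.to_numpy(dtype=float) for sp in species])
    T = ys.shape[2]

    psi_designs = []
    for sp in species:
        covs = tuple(psi_covariates[sp])
        X = np.ones((len(idx), 1 + len(covs)))
        for j, cov in enumerate(covs):
            X[:, 1 + j] = site_design.loc[idx, cov].to_numpy()
        psi_designs.append(X)
    p_X = np.ones((T, 1 + len(p_covariates)))
    for j, cov in enumerate(p_covariates):
        p_X[:, 1 + j] = occasion_covariates[cov].to_numpy()

    k = sum(X.shape[1] for X in psi_designs) + S * (S - 1) // 2 + S * p_X.shape[1]
    rng = np.random.default_rng(seed)

    def objective(th):
        try:
            return nll_multi(th, ys, psi_designs, p_X)
        except (ValueError, FloatingPointError):
            return np.inf

    best = None
    for s in range(n_starts):
        x0 = np.zeros(k) if s == 0 else rng.normal(scale=0.5, size=k)
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

    beta, gamma, beta_p = unpack_params(theta, [X.shape[1] for X in psi_designs], S,
                                        p_X.shape[1])
    names: list[str] = []
    for sp in species:
        names.append(f"{sp}:Intercept")
        names.extend(f"{sp}:{c}" for c in psi_covariates[sp])
    for i, j in _pair_index(S):
        names.append(f"{species[i]}:{species[j]}:Intercept")
    for sp in species:
        names.append(f"{sp}:p:Intercept")
        names.extend(f"{sp}:p:{c}" for c in p_covariates)

    return MultiOccFit(
        species=species,
        psi_covariates={sp: tuple(psi_covariates[sp]) for sp in species},
        natural_params=NaturalParams(beta=beta, gamma=gamma),
        detection={sp: beta_p[s] for s, sp in enumerate(species)},
        p_covariates=tuple(p_covariates),
        params=theta,
        se=se,
        param_names=names,
        logLik=-float(best.fun),
        K=k,
        n_sites=int((~np.isnan(ys[0])).any(axis=1).sum()),
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Derived summaries

def _x_rows(fit: MultiOccFit, x: dict[str, float] | None) -> list[np.ndarray]:
    """Per-species covariate rows at a baseline point (default: all zeros on
    the standardized scale)."""
    x = x or {}
    rows = []
    for sp in fit.species:
        covs = fit.psi_covariates[sp]
        rows.append(np.array([1.0] + [x.get(c, 0.0) for c in covs]))
    return rows


def conditional_occupancy(
    params: NaturalParams,
    focal: int,
    given: int,
    given_value: int,
    x: list[np.ndarray],
) -> float:
    """Pr(z_focal = 1 | z_given = given_value, x) from the joint distribution."""
    if focal == given:
        raise ValueError("focal and conditioning species must differ")
    states, probs = joint_psi(params, x)
    cond = probs[states[:, given] == given_value]
    cond_states = states[states[:, given] == given_value]
    denom = cond.sum()
    if denom <= 0:
        raise ValueError("conditioning event has probability zero")
    return float(cond[cond_states[:, focal] == 1].sum() / denom)


def conditional_occupancy_curve(
    fit: MultiOccFit,
    focal: str,
    given: str,
    covariate: str,
    grid: np.ndarray,
) -> pd.DataFrame:
    """Conditional occupancy of ``focal`` vs a covariate, with the
    conditioning species present and absent."""
    fi, gi = fit.species.index(focal), fit.species.index(given)
    rows = []
    for v in grid:
        x = _x_rows(fit, {covariate: float(v)})
        rows.append(
            {
                covariate: v,
                "present": conditional_occupancy(fit.natural_params, fi, gi, 1, x),
                "absent": conditional_occupancy(fit.natural_params, fi, gi, 0, x),
            }
        )
    return pd.DataFrame(rows)


def or_sp(
    params: NaturalParams,
    focal: int,
    partner: int | None = None,
    x: list[np.ndarray] | None = None,
    mode: str = "pairwise",
) -> float:
    """Log odds ratio for the presence of other species.

    ``pairwise`` (default): toggle one partner species between present and
    absent, marginalizing the remaining species; for S = 2 this equals the
    interaction intercept f_12 exactly.  ``all_others``: toggle every
    non-focal species together (z_others all 1 vs all 0).
    Covariates are held at ``x`` (default: intercept-only baseline).
    """
    S = params.n_species
    if x is None:  # intercept-only baseline (covariates at 0, standardized scale)
        x = [np.concatenate([[1.0], np.zeros(len(b) - 1)]) for b in params.beta]
    states, probs = joint_psi(params, x)

    def logit_focal(mask_species: list[int], mask_value: int) -> float:
        sel = np.all(states[:, mask_species] == mask_value, axis=1)
        p_sel = probs[sel]
        s_sel = states[sel]
        pr = p_sel[s_sel[:, focal] == 1].sum() / p_sel.sum()
        return np.log(pr) - np.log1p(-pr)

    if mode == "pairwise":
        if partner is None:
            raise ValueError("pairwise mode requires a partner species")
        return float(logit_focal([partner], 1) - logit_focal([partner], 0))
    if mode == "all_others":
        others = [s for s in range(S) if s != focal]
        return float(logit_focal(others, 1) - logit_focal(others, 0))
    raise ValueError(f"unknown mode {mode!r}")


def or_h(
    fit: MultiOccFit,
    focal: str,
    h: str,
    dx: float = 1.0,
    x: dict[str, float] | None = None,
) -> float:
    """Log odds ratio of focal-species occupancy for a covariate step.

    Computed as the change in logit Pr(z_focal = 1 | all others absent) when
    covariate ``h`` moves by ``dx`` from baseline ``x``; with all other
    species absent this reduces to beta_{focal,h} * dx.
    """
    if not np.isfinite(dx):
        raise ValueError("dx must be finite")
    if h not in fit.psi_covariates[focal]:
        raise ValueError(f"covariate {h!r} not in the {focal} occupancy model")
    fi = fit.species.index(focal)
    others = [s for s in range(len(fit.species)) if s != fi]
    x = dict(x or {})

    def logit_at(xv: dict[str, float]) -> float:
        states, probs = joint_psi(fit.natural_params, _x_rows(fit, xv))
        sel = np.all(states[:, others] == 0, axis=1)
        pr = probs[sel][states[sel][:, fi] == 1].sum() / probs[sel].sum()
        return np.log(pr) - np.log1p(-pr)

    x1 = dict(x)
    x1[h] = x.get(h, 0.0) + dx
    return float(logit_at(x1) - logit_at(x))


def importance_table(
    fit: MultiOccFit,
    x: dict[str, float] | None = None,
    dx: float = 1.0,
    mode: str = "pairwise",
) -> pd.DataFrame:
    """Relative importance of interactions and covariates per species.

    Rows are |log ORsp| for each partner species and |log ORh| for each
    covariate in the focal species' occupancy model; columns are focal
    species.  Larger values mean stronger influence on occupancy odds.
    """
    all_covs = sorted({c for covs in fit.psi_covariates.values() for c in covs})
    rows = fit.species + all_covs
    out = pd.DataFrame(np.nan, index=rows, columns=fit.species)
    x_rows = _x_rows(fit, x)
    for fi, focal in enumerate(fit.species):
        for pi, partner in enumerate(fit.species):
            if partner == focal:
                continue
            out.loc[partner, focal] = abs(
                or_sp(fit.natural_params, fi, pi, x_rows, mode=mode)
            )
        for cov in fit.psi_covariates[focal]:
            out.loc[cov, focal] = abs(or_h(fit, focal, cov, dx=dx, x=x))
    return out


def write_fit_summary(fit: MultiOccFit, path) -> None:
    fit.summary().to_csv(path, index=False)


def write_importance(table: pd.DataFrame, path) -> None:
    table.to_csv(path, na_rep="")
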