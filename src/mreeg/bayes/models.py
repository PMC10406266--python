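"""Hierarchical Bayesian models for comparing artifact-reduction methods.

Four model families cover the evaluation analyses:

* :func:`fit_two_level_model` -- varying-intercept / varying-slope normal
  regression: ``y ~ Normal(x . beta_participant, sigma_method)`` with
  participant coefficient vectors drawn from ``MultiNormal(beta, Sigma)``,
  ``Sigma`` decomposed into an SD vector and a correlation matrix Omega
  (LKJ prior).  Sampled by NUTS in non-centered form by default.
* :func:`fit_effect_size_model` -- the same structure with one residual SD
  per participant and method, partially pooled on the log scale toward the
  method-level SD; reports standardized within-participant effect sizes.
* :func:`fit_single_level_model` -- ordinary normal linear regression for
  across-participant summaries.
* :func:`robust_correlation` -- bivariate Student-t correlation, robust to
  outliers.

Priors follow the weakly-informative defaults in :class:`PriorConfig`:
Normal(0, 10) regression coefficients, half-Cauchy(2.5) standard
deviations, Gamma(2, 0.1) degrees of freedom, LKJ(2) correlations.
Diagnostics (rank-normalized split R-hat, bulk/tail ESS, MCSE) come from
ArviZ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np

from . import autodiff as ad
from .autodiff import Var, backward, exp, gammaln, gather, log, log1p, reshape, \
    solve_lower, sqrt, square, tanh, vsum
from .nuts import sample_nuts
from ..core_io import log as _log


# ---------------------------------------------------------------------------
# configuration and containers
# ---------------------------------------------------------------------------

@dataclass
class PriorConfig:
    beta_sd: float = 10.0  # Normal(0, sd) on regression coefficients
    sd_scale: float = 2.5  # half-Cauchy scale on standard deviations
    corr_mean_sd: float = 100.0  # Normal(0, sd) on robust-correlation means
    df_alpha: float = 2.0  # Gamma(alpha, beta) on Student-t dof
    df_beta: float = 0.1
    lkj_eta: float = 2.0  # LKJ shape on the coefficient correlation matrix

    def __post_init__(self) -> None:
        for v in (self.beta_sd, self.sd_scale, self.corr_mean_sd,
                  self.df_alpha, self.df_beta, self.lkj_eta):
            if v <= 0:
                raise ValueError("all prior scales must be positive")


@dataclass
class ModelSpec:
    """Design for the two-level model.

    ``y``: outcome vector; ``X``: (n, p) design matrix; ``participant_idx``
    and ``method_idx``: per-row group indices (0-based, contiguous);
    ``residual_structure``: one of {"per_method",
    "per_method_per_participant_pooled", "single"}.
    """

    y: np.ndarray
    X: np.ndarray
    participant_idx: np.ndarray
    method_idx: np.ndarray
    residual_structure: str = "per_method"

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.participant_idx = np.asarray(self.participant_idx, dtype=int)
        self.method_idx = np.asarray(self.method_idx, dtype=int)
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("design matrix is rank deficient")
        for idx, name in ((self.participant_idx, "participant"),
                          (self.method_idx, "method")):
            u = np.unique(idx)
            if not np.array_equal(u, np.arange(u.size)):
                raise ValueError(f"{name} indices must be contiguous from 0")

    @property
    def n_participants(self) -> int:
        return int(self.participant_idx.max()) + 1

    @property
    def n_methods(self) -> int:
        return int(self.method_idx.max()) + 1


@dataclass
class PosteriorSamples:
    """Named MCMC draws in (chains, draws, ...) layout."""

    draws: dict[str, np.ndarray]
    divergences: int = 0
    n_draws_total: int = 0

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    def flat(self, name: str) -> np.ndarray:
        if name not in self.draws:
            raise KeyError(f"unknown parameter {name!r}")
        arr = self.draws[name]
        return arr.reshape(arr.shape[0] * arr.shape[1], *arr.shape[2:])

    def namespace(self) -> dict[str, np.ndarray]:
        return {k: self.flat(k) for k in self.draws}


@dataclass
class Diagnostics:
    rhat: dict[str, np.ndarray]
    ess_bulk: dict[str, np.ndarray]
    ess_tail: dict[str, np.ndarray]
    mcse: dict[str, np.ndarray]
    max_rhat: float
    min_ess_bulk: float
    min_ess_tail: float
    divergence_rate: float = 0.0
    converged: bool = True


# ---------------------------------------------------------------------------
# log-density building blocks
# ---------------------------------------------------------------------------

def _errstate_wrap(fn):
    """Silence numpy warnings inside a log-posterior (out-of-support points
    return -inf and are rejected by the sampler)."""
    def wrapped(theta):
        with np.errstate(all="ignore"):
            return fn(theta)
    return wrapped


def _normal_lp(v: Var, sd: float) -> Var:
    return -0.5 * vsum(square(v)) / sd**2


def _half_cauchy_lp(log_s: Var, scale: float) -> Var:
    """half-Cauchy(0, scale) on s = exp(log_s), including the log-Jacobian."""
    s = exp(log_s)
    return vsum(-log1p(square(s / scale)) + log_s)


def _lkj_structure(p: int) -> dict:
    """Constant index/scatter matrices for the vectorized CPC -> Cholesky map.

    For entry e = (i, j), ``l_ij = c_e * exp(0.5 * cum_e)`` with
    ``cum_e = sum_{k<j} log(1 - c_ik^2)`` (a strictly-prior-in-row partial
    sum), and the diagonal is ``l_ii = exp(0.5 * row_sum_i)``.  Both partial
    sums are linear maps of ``g = log(1 - c^2)``, so the whole transform
    vectorizes into a few matrix products.
    """
    q = p * (p - 1) // 2
    entries = [(i, j) for i in range(1, p) for j in range(i)]
    A = np.zeros((q, q))  # cum over same-row earlier entries
    B = np.zeros((p - 1, q))  # full row sums, rows 1..p-1
    M_off = np.zeros((p * p, q))
    M_diag = np.zeros((p * p, p - 1))
    for e, (i, j) in enumerate(entries):
        M_off[i * p + j, e] = 1.0
        B[i - 1, e] = 1.0
        for e2, (i2, j2) in enumerate(entries):
            if i2 == i and j2 < j:
                A[e, e2] = 1.0
    base = np.zeros(p * p)
    base[0] = 1.0  # L[0, 0] = 1
    for i in range(1, p):
        M_diag[i * p + i, i - 1] = 1.0
    return dict(A=A, B=B, M_off=M_off, M_diag=M_diag, base=base, q=q)


def _lkj_cholesky(y: Var, p: int, eta: float, S: dict | None = None):
    """Map unconstrained y (p(p-1)/2,) to the Cholesky factor of a
    correlation matrix via canonical partial correlations (vectorized).

    Returns (L, lp, log_diag_sum) where lp holds the LKJ(eta) log-density
    plus the transform's log-Jacobian and log_diag_sum the sum of log
    diagonal entries (needed for the centered parameterization).
    """
    if p == 1:
        return Var(np.ones((1, 1))), Var(0.0), Var(0.0)
    S = S or _lkj_structure(p)
    c = tanh(y)
    g = log1p(-square(c))  # (q,)
    cum = S["A"] @ g  # Var via __rmatmul__
    log_diag = 0.5 * (S["B"] @ g)  # (p-1,)
    l_off = c * exp(0.5 * cum)
    L_flat = S["M_off"] @ l_off + S["M_diag"] @ exp(log_diag) + S["base"]
    L = reshape(L_flat, (p, p))
    density_coeffs = np.array([p - i + 2.0 * eta - 3.0 for i in range(1, p)])
    lp = vsum(g) + 0.5 * vsum(cum) + vsum(density_coeffs * log_diag)
    return L, lp, vsum(log_diag)


def _lkj_cholesky_np(y: np.ndarray, p: int) -> np.ndarray:
    """Pure-numpy version of the CPC -> Cholesky map (for draw unpacking)."""
    c = np.tanh(y)
    L = np.zeros((p, p))
    L[0, 0] = 1.0
    idx = 0
    for i in range(1, p):
        rem = 1.0
        for j in range(i):
            L[i, j] = c[idx] * np.sqrt(rem)
            rem *= 1.0 - c[idx] ** 2
            idx += 1
        L[i, i] = np.sqrt(rem)
    return L


class _Packer:
    """Pack/unpack named blocks of the unconstrained parameter vector."""

    def __init__(self, blocks: list[tuple[str, tuple]]):
        self.blocks = blocks
        self.slices = {}
        self.shapes = {}
        pos = 0
        for name, shape in blocks:
            size = int(np.prod(shape)) if shape else 1
            self.slices[name] = slice(pos, pos + size)
            self.shapes[name] = shape
            pos += size
        self.dim = pos

    def unpack(self, theta: np.ndarray) -> dict[str, Var]:
        out = {}
        for name, shape in self.blocks:
            v = theta[self.slices[name]]
            out[name] = Var(v.reshape(shape) if shape else v)
        return out

    def unpack_np(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        return {name: theta[self.slices[name]].reshape(shape or (1,))
                for name, shape in self.blocks}

    def grad(self, params: dict[str, Var]) -> np.ndarray:
        g = np.zeros(self.dim)
        for name, _ in self.blocks:
            g[self.slices[name]] = np.ravel(params[name].grad)
        return g


# ---------------------------------------------------------------------------
# two-level varying-intercept / varying-slope model
# ---------------------------------------------------------------------------

def _two_level_logp_manual(spec: ModelSpec, priors: PriorConfig,
                           pooled_sd: bool = False):
    """Hand-derived gradient of the non-centered two-level log-posterior
    (hot path; equality with the autodiff version is asserted in the test
    suite).  ``pooled_sd`` switches the residual structure to one SD per
    participant and method, partially pooled toward the method SD."""
    yd, X = spec.y, spec.X
    pidx, midx = spec.participant_idx, spec.method_idx
    n, p = X.shape
    J, M = spec.n_participants, spec.n_methods
    q = p * (p - 1) // 2
    S = _lkj_structure(p) if p > 1 else None
    entries = [(i, j) for i in range(1, p) for j in range(i)]
    rows_e = np.array([i for i, _ in entries], dtype=int)
    cols_e = np.array([j for _, j in entries], dtype=int)
    count_m = np.bincount(midx, minlength=M).astype(float)
    coeffs = np.array([p - i + 2.0 * priors.lkj_eta - 3.0 for i in range(1, p)])
    sc2 = priors.sd_scale**2

    blocks = [("beta", (p,)), ("b_raw", (J, p)), ("log_tau", (p,)),
              ("y_corr", (q,)), ("log_sigma", (M,))]
    if pooled_sd:
        blocks += [("eps_sigma", (J, M)), ("log_kappa", ())]
    packer = _Packer(blocks)
    sl = packer.slices

    def logp_grad(theta: np.ndarray):
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            return _logp_grad_inner(theta)

    def _logp_grad_inner(theta: np.ndarray):
        beta = theta[sl["beta"]]
        Z = theta[sl["b_raw"]].reshape(J, p)
        lt = theta[sl["log_tau"]]
        y = theta[sl["y_corr"]]
        ls = theta[sl["log_sigma"]]
        tau, sigma = np.exp(lt), np.exp(ls)

        # correlation Cholesky from canonical partial correlations
        if q:
            c = np.tanh(y)
            g = np.log1p(-c**2)
            cum = S["A"] @ g
            ld = 0.5 * (S["B"] @ g)  # log diag, rows 1..p-1
            l_off = c * np.exp(0.5 * cum)
            L = np.zeros((p, p))
            L[0, 0] = 1.0
            L[rows_e, cols_e] = l_off
            L[np.arange(1, p), np.arange(1, p)] = np.exp(ld)
        else:
            L = np.ones((1, 1))
        U = Z @ L.T
        b = beta + U * tau
        brow = b[pidx]
        mu = np.einsum("ij,ij->i", X, brow)
        if pooled_sd:
            eps = theta[sl["eps_sigma"]].reshape(J, M)
            lk = theta[sl["log_kappa"]]
            kappa = np.exp(lk)
            log_sig_jm = ls[None, :] + kappa * eps
            log_sig_row = log_sig_jm[pidx, midx]
            s_row = np.exp(log_sig_row)
        else:
            s_row = sigma[midx]
        r = (yd - mu) / s_row

        lp = (-0.5 * np.sum((beta / priors.beta_sd)**2)
              - 0.5 * np.sum(Z**2)
              + np.sum(-np.log1p(tau**2 / sc2) + lt)
              + np.sum(-np.log1p(sigma**2 / sc2) + ls)
              - 0.5 * np.sum(r**2))
        if pooled_sd:
            lp += (-np.sum(log_sig_row) - 0.5 * np.sum(eps**2)
                   + float(np.sum(-np.log1p(kappa**2 / sc2) + lk)))
        else:
            lp -= float(count_m @ ls)
        if q:
            lp += np.sum(g) + 0.5 * np.sum(cum) + float(coeffs @ ld)

        # backward pass
        d_mu = r / s_row
        d_brow = d_mu[:, None] * X
        d_b = np.zeros((J, p))
        np.add.at(d_b, pidx, d_brow)
        d_beta = d_b.sum(axis=0) - beta / priors.beta_sd**2
        d_U = d_b * tau
        d_tau = (d_b * U).sum(axis=0)
        d_Z = d_U @ L - Z
        d_lt = tau * d_tau - 2.0 * (tau**2 / sc2) / (1.0 + tau**2 / sc2) + 1.0
        grad = np.zeros(packer.dim)
        if pooled_sd:
            # d lp / d log sigma_row = r^2 - 1, scattered to (j, m)
            D = np.zeros((J, M))
            np.add.at(D, (pidx, midx), r**2 - 1.0)
            d_ls = D.sum(axis=0) - 2.0 * (sigma**2 / sc2) / (1.0 + sigma**2 / sc2) + 1.0
            grad[sl["eps_sigma"]] = (kappa * D - eps).ravel()
            grad[sl["log_kappa"]] = (kappa * np.sum(eps * D)
                                     - 2.0 * (kappa**2 / sc2) / (1.0 + kappa**2 / sc2) + 1.0)
        else:
            d_ls = (np.bincount(midx, weights=r**2, minlength=M) - count_m
                    - 2.0 * (sigma**2 / sc2) / (1.0 + sigma**2 / sc2) + 1.0)
        grad[sl["beta"]] = d_beta
        grad[sl["b_raw"]] = d_Z.ravel()
        grad[sl["log_tau"]] = d_lt
        grad[sl["log_sigma"]] = d_ls
        if q:
            d_L = d_U.T @ Z
            d_ld = d_L[np.arange(1, p), np.arange(1, p)] * np.exp(ld) + coeffs
            d_l_off = d_L[rows_e, cols_e]
            d_cum = np.full(q, 0.5) + 0.5 * d_l_off * l_off
            d_c = d_l_off * np.exp(0.5 * cum)
            d_g = 1.0 + 0.5 * (S["B"].T @ d_ld) + S["A"].T @ d_cum
            d_c += d_g * (-2.0 * c / (1.0 - c**2))
            grad[sl["y_corr"]] = d_c * (1.0 - c**2)
        if not np.isfinite(lp):
            return -np.inf, np.zeros(packer.dim)
        return float(lp), np.nan_to_num(grad)

    return packer, logp_grad


def _two_level_logp_factory(spec: ModelSpec, priors: PriorConfig, centered: bool,
                            pooled_sd: bool, force_autodiff: bool = False):
    if not centered and not force_autodiff:
        return _two_level_logp_manual(spec, priors, pooled_sd)
    return _two_level_logp_autodiff(spec, priors, centered, pooled_sd)


def _two_level_logp_autodiff(spec: ModelSpec, priors: PriorConfig, centered: bool,
                             pooled_sd: bool):
    y, X = spec.y, spec.X
    pidx, midx = spec.participant_idx, spec.method_idx
    n, p = X.shape
    J, M = spec.n_participants, spec.n_methods
    q = p * (p - 1) // 2

    blocks = [("beta", (p,)),
              ("b_raw", (J, p)),
              ("log_tau", (p,)),
              ("y_corr", (q,)),
              ("log_sigma", (M,))]
    if pooled_sd:
        blocks += [("eps_sigma", (J, M)), ("log_kappa", ())]
    packer = _Packer(blocks)
    lkj_S = _lkj_structure(p) if p > 1 else None

    def logp_grad(theta: np.ndarray):
        P = packer.unpack(theta)
        beta, b_raw = P["beta"], P["b_raw"]
        log_tau, y_corr, log_sigma = P["log_tau"], P["y_corr"], P["log_sigma"]
        tau = exp(log_tau)
        L, lkj_lp, log_diag_sum = _lkj_cholesky(y_corr, p, priors.lkj_eta, lkj_S)
        lp = _normal_lp(beta, priors.beta_sd) + lkj_lp
        lp = lp + _half_cauchy_lp(log_tau, priors.sd_scale)
        lp = lp + _half_cauchy_lp(log_sigma, priors.sd_scale)
        if centered:
            b = b_raw
            A = reshape(tau, (p, 1)) * L
            z = solve_lower(A, (b - beta).T)
            lp = lp - 0.5 * vsum(square(z)) - float(J) * (vsum(log_tau) + log_diag_sum)
        else:
            b = beta + (b_raw @ L.T) * tau
            lp = lp - 0.5 * vsum(square(b_raw))
        mu = vsum(gather(b, pidx) * X, axis=1)
        if pooled_sd:
            eps, log_kappa = P["eps_sigma"], P["log_kappa"]
            kappa = exp(log_kappa)
            lp = lp + _half_cauchy_lp(log_kappa, priors.sd_scale)
            lp = lp - 0.5 * vsum(square(eps))
            log_sig_jm = log_sigma + kappa * eps  # (J, M) broadcast over rows
            log_sig_row = log_sig_jm[(pidx, midx)]
        else:
            log_sig_row = gather(log_sigma, midx)
        sig_row = exp(log_sig_row)
        resid = (y - mu) / sig_row
        lp = lp - vsum(log_sig_row) - 0.5 * vsum(square(resid))
        backward(lp)
        if not np.isfinite(lp.value):
            return -np.inf, np.zeros(packer.dim)
        return float(np.asarray(lp.value).sum()), np.nan_to_num(packer.grad(P))

    def logp_grad_safe(theta: np.ndarray):
        with np.errstate(all="ignore"):
            return logp_grad(theta)

    return packer, logp_grad_safe


def _unpack_two_level_draws(all_draws: np.ndarray, packer: _Packer, spec: ModelSpec,
                            centered: bool, pooled_sd: bool,
                            effect_cols: np.ndarray | None = None) -> dict[str, np.ndarray]:
    C, D, _ = all_draws.shape
    p, J, M = spec.X.shape[1], spec.n_participants, spec.n_methods
    q = p * (p - 1) // 2
    out = {
        "beta": np.zeros((C, D, p)),
        "beta_participant": np.zeros((C, D, J, p)),
        "sd_participant": np.zeros((C, D, p)),
        "sigma_method": np.zeros((C, D, M)),
    }
    if q:
        out["omega"] = np.zeros((C, D, q))
    if pooled_sd:
        out["sigma_participant_method"] = np.zeros((C, D, J, M))
        if effect_cols is not None:
            out["effect_size"] = np.zeros((C, D, M))
    tril = np.tril_indices(p, k=-1)
    for c in range(C):
        for d in range(D):
            P = packer.unpack_np(all_draws[c, d])
            beta = P["beta"]
            tau = np.exp(P["log_tau"])
            L = _lkj_cholesky_np(P["y_corr"], p)
            if centered:
                b = P["b_raw"].reshape(J, p)
            else:
                b = beta + (P["b_raw"].reshape(J, p) @ L.T) * tau
            sigma = np.exp(P["log_sigma"])
            out["beta"][c, d] = beta
            out["beta_participant"][c, d] = b
            out["sd_participant"][c, d] = tau
            out["sigma_method"][c, d] = sigma
            if q:
                omega = L @ L.T
                out["omega"][c, d] = omega[tril]
            if pooled_sd:
                kappa = np.exp(P["log_kappa"])
                sig_jm = np.exp(np.log(sigma)[None, :]
                                + kappa * P["eps_sigma"].reshape(J, M))
                out["sigma_participant_method"][c, d] = sig_jm
                if effect_cols is not None:
                    d_jm = b[:, effect_cols] / sig_jm  # (J, M)
                    out["effect_size"][c, d] = d_jm.mean(axis=0)
    return out


def fit_two_level_model(spec: ModelSpec, priors: PriorConfig | None = None,
                        chains: int = 4, warmup: int = 1000, draws: int = 1000,
                        seed: int = 0, centered: bool = False,
                        target_accept: float = 0.85,
                        compute_diag: bool = True,
                        max_treedepth: int = 10,
                        _effect_cols: np.ndarray | None = None,
                        ) -> tuple[PosteriorSamples, Diagnostics]:
    """Fit the two-level varying-intercept / varying-slope normal model.

    Returns posterior draws for the group coefficients ``beta``, the
    per-participant coefficients, the coefficient SD vector and correlation
    entries, and the per-method residual SDs, together with convergence
    diagnostics.  A divergence rate above 1% or any R-hat above 1.01 flags
    the result as non-converged (it is returned, not discarded).
    """
    priors = priors or PriorConfig()
    if spec.n_participants < 2:
        raise ValueError("at least 2 participants are required")
    counts = np.bincount(spec.participant_idx)
    if counts.min() < 2:
        raise ValueError("every participant needs at least 2 rows")
    pooled = spec.residual_structure == "per_method_per_participant_pooled"
    packer, logp_grad = _two_level_logp_factory(spec, priors, centered, pooled)
    rng = np.random.default_rng(seed)
    x0s = 0.1 * rng.standard_normal((chains, packer.dim))
    raw, stats, _ = sample_nuts(logp_grad, x0s, warmup, draws, seed,
                                target_accept=target_accept,
                                max_treedepth=max_treedepth)
    named = _unpack_two_level_draws(raw, packer, spec, centered, pooled, _effect_cols)
    n_div = sum(s.divergences for s in stats)
    samples = PosteriorSamples(named, n_div, chains * draws)
    if not compute_diag:
        diag = Diagnostics({}, {}, {}, {}, float("nan"), float("nan"), float("nan"),
                           n_div / (chains * draws), True)
        return samples, diag
    diag = compute_diagnostics(samples)
    diag.divergence_rate = n_div / (chains * draws)
    diag.converged = diag.divergence_rate <= 0.01 and diag.max_rhat <= 1.01
    if not diag.converged:
        _log.warning("two-level fit flagged non-converged: rhat=%.3f, div rate=%.3f",
                     diag.max_rhat, diag.divergence_rate)
    return samples, diag


def fit_effect_size_model(spec: ModelSpec, effect_cols: np.ndarray,
                          priors: PriorConfig | None = None, chains: int = 4,
                          warmup: int = 1000, draws: int = 1000, seed: int = 0,
                          target_accept: float = 0.85, max_treedepth: int = 10,
                          ) -> tuple[PosteriorSamples, Diagnostics]:
    """Two-level model with one residual SD per participant and method,
    partially pooled (on the log scale) toward the method-level SD.

    ``effect_cols[m]`` names the design column whose participant coefficient
    is the contralateral-minus-ipsilateral difference under method ``m``;
    the reported ``effect_size`` draws are the participant average of that
    coefficient divided by the participant-by-method residual SD.
    """
    spec = ModelSpec(spec.y, spec.X, spec.participant_idx, spec.method_idx,
                     "per_method_per_participant_pooled")
    return fit_two_level_model(spec, priors, chains, warmup, draws, seed,
                               centered=False, target_accept=target_accept,
                               max_treedepth=max_treedepth,
                               _effect_cols=np.asarray(effect_cols, dtype=int))


# ---------------------------------------------------------------------------
# single-level regression
# ---------------------------------------------------------------------------

def fit_single_level_model(y: np.ndarray, X: np.ndarray,
                           priors: PriorConfig | None = None, chains: int = 4,
                           warmup: int = 1000, draws: int = 1000, seed: int = 0,
                           ) -> tuple[PosteriorSamples, Diagnostics]:
    """Single-level normal linear regression ``y ~ Normal(X beta, sigma)``."""
    priors = priors or PriorConfig()
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than predictors ({p})")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    packer = _Packer([("beta", (p,)), ("log_sigma", ())])

    def logp_grad(theta):
        P = packer.unpack(theta)
        beta, log_sigma = P["beta"], P["log_sigma"]
        sigma = exp(log_sigma)
        mu = X @ beta if p > 1 else vsum(X * beta, axis=1)
        resid = (y - mu) / sigma
        lp = _normal_lp(beta, priors.beta_sd) + _half_cauchy_lp(log_sigma, priors.sd_scale)
        lp = lp - float(n) * log_sigma - 0.5 * vsum(square(resid))
        backward(lp)
        if not np.isfinite(lp.value):
            return -np.inf, np.zeros(packer.dim)
        return float(np.asarray(lp.value).sum()), np.nan_to_num(packer.grad(P))

    logp_grad = _errstate_wrap(logp_grad)
    rng = np.random.default_rng(seed)
    x0s = 0.1 * rng.standard_normal((chains, packer.dim))
    raw, stats, _ = sample_nuts(logp_grad, x0s, warmup, draws, seed)
    C, D = chains, draws
    named = {"beta": raw[:, :, packer.slices["beta"]].reshape(C, D, p),
             "sigma": np.exp(raw[:, :, packer.slices["log_sigma"]]).reshape(C, D)}
    n_div = sum(s.divergences for s in stats)
    samples = PosteriorSamples(named, n_div, C * D)
    diag = compute_diagnostics(samples)
    diag.divergence_rate = n_div / (C * D)
    diag.converged = diag.divergence_rate <= 0.01 and diag.max_rhat <= 1.01
    return samples, diag


# ---------------------------------------------------------------------------
# robust correlation
# ---------------------------------------------------------------------------

def _robust_logp_manual(data: np.ndarray, priors: PriorConfig, packer: "_Packer"):
    """Hand-derived gradient of the bivariate Student-t log-posterior
    (verified against the autodiff version in the test suite)."""
    from scipy.special import digamma, gammaln as sp_gammaln
    n = data.shape[0]
    xs, ys = data[:, 0], data[:, 1]
    sl = packer.slices
    sc2 = priors.sd_scale**2

    def logp_grad(theta: np.ndarray):
        mu = theta[sl["mu"]]
        ls = theta[sl["log_s"]]
        u = float(theta[sl["u_rho"]][0])
        lnu = float(theta[sl["log_nu"]][0])
        s = np.exp(ls)
        rho = np.tanh(u)
        nu = np.exp(lnu)
        omr2 = 1.0 - rho**2
        z1 = (xs - mu[0]) / s[0]
        z2 = (ys - mu[1]) / s[1]
        qf = (z1**2 - 2.0 * rho * z1 * z2 + z2**2) / omr2

        lp = (-0.5 * np.sum((mu / priors.corr_mean_sd) ** 2)
              + np.sum(-np.log1p(s**2 / sc2) + ls)
              + np.log(omr2)  # uniform(-1, 1) prior via tanh Jacobian
              + priors.df_alpha * lnu - priors.df_beta * nu
              + n * (sp_gammaln((nu + 2.0) / 2.0) - sp_gammaln(nu / 2.0)
                     - np.log(nu) - ls[0] - ls[1] - 0.5 * np.log(omr2))
              - 0.5 * (nu + 2.0) * np.sum(np.log1p(qf / nu)))
        if not np.isfinite(lp):
            return -np.inf, np.zeros(packer.dim)

        d_q = -0.5 * (nu + 2.0) / (nu + qf)  # dlp/dq_i
        dq_dz1 = 2.0 * (z1 - rho * z2) / omr2
        dq_dz2 = 2.0 * (z2 - rho * z1) / omr2
        d_mu = np.array([np.sum(d_q * dq_dz1) * (-1.0 / s[0]),
                         np.sum(d_q * dq_dz2) * (-1.0 / s[1])])
        d_mu -= mu / priors.corr_mean_sd**2
        d_ls = np.array([np.sum(d_q * dq_dz1 * (-z1)),
                         np.sum(d_q * dq_dz2 * (-z2))])
        d_ls += -2.0 * (s**2 / sc2) / (1.0 + s**2 / sc2) + 1.0 - n
        dq_drho = (-2.0 * z1 * z2 + 2.0 * rho * qf) / omr2
        d_rho = (np.sum(d_q * dq_drho)
                 - 2.0 * rho / omr2  # prior/Jacobian term
                 + n * rho / omr2)
        d_u = d_rho * omr2
        dlog1p_dnu = -qf / (nu * (nu + qf))
        d_nu = (priors.df_alpha / nu - priors.df_beta
                + n * (0.5 * digamma((nu + 2.0) / 2.0)
                       - 0.5 * digamma(nu / 2.0) - 1.0 / nu)
                - 0.5 * np.sum(np.log1p(qf / nu))
                - 0.5 * (nu + 2.0) * np.sum(dlog1p_dnu))
        d_lnu = d_nu * nu
        # the prior alpha*lnu term's derivative w.r.t. lnu is alpha directly;
        # it was folded in above as (alpha/nu)*nu, which is identical
        grad = np.zeros(packer.dim)
        grad[sl["mu"]] = d_mu
        grad[sl["log_s"]] = d_ls
        grad[sl["u_rho"]] = d_u
        grad[sl["log_nu"]] = d_lnu
        return float(lp), np.nan_to_num(grad)

    return _errstate_wrap(logp_grad)


def robust_correlation(x: np.ndarray, y: np.ndarray,
                       priors: PriorConfig | None = None, chains: int = 4,
                       warmup: int = 1000, draws: int = 1000, seed: int = 0,
                       max_treedepth: int = 10, force_autodiff: bool = False,
                       ) -> tuple[PosteriorSamples, Diagnostics]:
    """Posterior of the correlation coefficient of a bivariate Student-t.

    The pair (x, y) is modelled as bivariate-t with mean vector (vague
    normal priors), per-axis scales (half-Cauchy), correlation rho
    (uniform(-1, 1)) and degrees of freedom nu ~ Gamma(2, 0.1); the heavy
    tails make rho robust to gross outliers.  Returns draws of ``rho``.
    """
    priors = priors or PriorConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 10:
        raise ValueError("x and y must be equal-length series of at least 10 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input vector; correlation undefined")
    data = np.column_stack([x, y])
    packer = _Packer([("mu", (2,)), ("log_s", (2,)), ("u_rho", ()), ("log_nu", ())])
    logp_grad = (_robust_logp_manual(data, priors, packer) if not force_autodiff
                 else _robust_logp_autodiff(data, priors, packer))
    rng = np.random.default_rng(seed)
    x0s = 0.1 * rng.standard_normal((chains, packer.dim))
    raw, stats, _ = sample_nuts(logp_grad, x0s, warmup, draws, seed,
                                max_treedepth=max_treedepth)
    C, D = chains, draws
    named = {
        "rho": np.tanh(raw[:, :, packer.slices["u_rho"]]).reshape(C, D),
        "mu": raw[:, :, packer.slices["mu"]].reshape(C, D, 2),
        "scale": np.exp(raw[:, :, packer.slices["log_s"]]).reshape(C, D, 2),
        "nu": np.exp(raw[:, :, packer.slices["log_nu"]]).reshape(C, D),
    }
    n_div = sum(s.divergences for s in stats)
    samples = PosteriorSamples(named, n_div, C * D)
    diag = compute_diagnostics(samples)
    diag.divergence_rate = n_div / (C * D)
    diag.converged = diag.divergence_rate <= 0.01 and diag.max_rhat <= 1.01
    return samples, diag


def _robust_logp_autodiff(data: np.ndarray, priors: PriorConfig, packer: "_Packer"):
    n = data.shape[0]

    def logp_grad(theta):
        P = packer.unpack(theta)
        mu, log_s, u_rho, log_nu = P["mu"], P["log_s"], P["u_rho"], P["log_nu"]
        s = exp(log_s)
        rho = tanh(u_rho)
        nu = exp(log_nu)
        one_m_r2 = 1.0 - square(rho)
        d = data - mu  # (n, 2) broadcast
        d1, d2 = d[:, 0], d[:, 1]
        z1, z2 = d1 / s[0:1], d2 / s[1:2]
        qf = (square(z1) - 2.0 * rho * z1 * z2 + square(z2)) / one_m_r2
        lp = _normal_lp(mu, priors.corr_mean_sd) + _half_cauchy_lp(log_s, priors.sd_scale)
        # uniform(-1, 1) prior on rho via the tanh transform Jacobian
        lp = lp + vsum(log(one_m_r2))
        # Gamma(alpha, rate beta) on nu, plus log-Jacobian of exp
        lp = lp + priors.df_alpha * log_nu - priors.df_beta * nu
        lp = lp + float(n) * (gammaln((nu + 2.0) / 2.0) - gammaln(nu / 2.0)
                              - log(nu) - vsum(log_s) - 0.5 * log(one_m_r2))
        lp = lp - ((nu + 2.0) / 2.0) * vsum(log1p(qf / nu))
        backward(lp)
        if not np.isfinite(lp.value):
            return -np.inf, np.zeros(packer.dim)
        return float(np.asarray(lp.value).sum()), np.nan_to_num(packer.grad(P))

    return _errstate_wrap(logp_grad)


# ---------------------------------------------------------------------------
# posterior utilities
# ---------------------------------------------------------------------------

def posterior_probability(samples: PosteriorSamples, contrast, direction: str = ">") -> float:
    """Fraction of draws for which the contrast satisfies the inequality.

    ``contrast`` is either a callable receiving the flattened-draw namespace
    or a string expression over parameter names (e.g.
    ``"beta[:, 2] - beta[:, 1]"``).
    """
    ns = samples.namespace()
    if callable(contrast):
        vals = np.asarray(contrast(ns))
    else:
        try:
            vals = np.asarray(eval(contrast, {"np": np, "__builtins__": {}}, ns))
        except NameError as e:
            raise KeyError(f"unknown parameter in contrast: {e}") from e
    if direction == ">":
        return float(np.mean(vals > 0))
    if direction == "<":
        return float(np.mean(vals < 0))
    raise ValueError("direction must be '>' or '<'")


def summarize_posterior(samples: PosteriorSamples, parameter: str,
                        index: tuple | int | None = None) -> dict:
    """Median and equal-tailed 66% / 95% intervals of one parameter."""
    v = samples.flat(parameter)
    if index is not None:
        v = v[(slice(None),) + (index if isinstance(index, tuple) else (index,))]
    v = np.ravel(np.asarray(v, dtype=float)) if v.ndim == 1 else v.reshape(v.shape[0], -1)
    if v.ndim > 1:
        raise ValueError("select a scalar component with `index`")
    return {
        "median": float(np.quantile(v, 0.5)),
        "interval_66": (float(np.quantile(v, 0.17)), float(np.quantile(v, 0.83))),
        "interval_95": (float(np.quantile(v, 0.025)), float(np.quantile(v, 0.975))),
    }


def compute_diagnostics(samples: PosteriorSamples) -> Diagnostics:
    """Rank-normalized split R-hat, bulk/tail ESS and MCSE per parameter.

    Constant parameters yield NaN diagnostics (reported as such, excluded
    from the max/min aggregates).
    """
    first = next(iter(samples.draws.values()))
    if first.shape[0] < 2:
        raise ValueError("diagnostics require at least 2 chains")
    if first.shape[1] < 100:
        raise ValueError("diagnostics require at least 100 draws per chain")
    rhat, ess_b, ess_t, mcse = {}, {}, {}, {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.from_dict(posterior=samples.draws)
        r = az.rhat(idata, method="rank")
        eb = az.ess(idata, method="bulk")
        et = az.ess(idata, method="tail")
        mc = az.mcse(idata, method="mean")
    for name in samples.draws:
        rhat[name] = np.asarray(r[name])
        ess_b[name] = np.asarray(eb[name])
        ess_t[name] = np.asarray(et[name])
        mcse[name] = np.asarray(mc[name])
    all_r = np.concatenate([np.ravel(v) for v in rhat.values()])
    all_eb = np.concatenate([np.ravel(v) for v in ess_b.values()])
    all_et = np.concatenate([np.ravel(v) for v in ess_t.values()])
    return Diagnostics(
        rhat=rhat, ess_bulk=ess_b, ess_tail=ess_t, mcse=mcse,
        max_rhat=float(np.nanmax(all_r)) if np.any(np.isfinite(all_r)) else float("nan"),
        min_ess_bulk=float(np.nanmin(all_eb)) if np.any(np.isfinite(all_eb)) else float("nan"),
        min_ess_tail=float(np.nanmin(all_et)) if np.any(np.isfinite(all_et)) else float("nan"),
    )


# ---------------------------------------------------------------------------
# generative simulator (parameter-recovery and calibration studies)
# ---------------------------------------------------------------------------

def simulate_two_level_dataset(n_participants: int = 8, n_blocks: int = 20,
                               n_methods: int = 5, seed: int = 0,
                               beta: np.ndarray | None = None,
                               tau: float | np.ndarray = 0.5,
                               sigma: float | np.ndarray = 1.0,
                               ) -> tuple[ModelSpec, dict]:
    """Draw a dataset from the two-level model's own generative process.

    Each participant contributes ``n_blocks`` rows cycling through the
    methods; the design is one-hot in method.  Group coefficients default
    to an order-1 spread.  Returns the :class:`ModelSpec` and the true
    parameters.
    """
    rng = np.random.default_rng(seed)
    M = n_methods
    beta = np.asarray(beta, dtype=float) if beta is not None \
        else np.linspace(0.5, 1.5, M)
    tau = np.broadcast_to(np.asarray(tau, dtype=float), (M,)).copy()
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), (M,)).copy()
    b = beta[None, :] + tau[None, :] * rng.standard_normal((n_participants, M))
    rows_y, rows_X, pidx, midx = [], [], [], []
    for j in range(n_participants):
        for k in range(n_blocks):
            m = k % M
            x = np.zeros(M)
            x[m] = 1.0
            rows_X.append(x)
            rows_y.append(b[j, m] + sigma[m] * rng.standard_normal())
            pidx.append(j)
            midx.append(m)
    spec = ModelSpec(np.array(rows_y), np.array(rows_X), np.array(pidx), np.array(midx))
    return spec, {"beta": beta, "tau": tau, "sigma": sigma, "b": b}
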