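"""No-U-Turn Hamiltonian Monte Carlo with dual-averaging step-size and
diagonal mass-matrix adaptation.

A compact implementation of the standard recursion (doubling trajectory
with slice acceptance), sufficient for the moderate-dimension hierarchical
posteriors fitted here.  Divergent transitions (energy error > 1000) are
recorded per draw so downstream code can flag non-convergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

MAX_TREEDEPTH = 10
DIVERGENCE_THRESHOLD = 1000.0


@dataclass
class ChainStats:
    divergences: int = 0
    step_size: float = 0.0
    mean_accept: float = 0.0
    max_treedepth_hits: int = 0


def _leapfrog(logp_grad, x, r, eps, inv_mass):
    lp, grad = logp_grad(x)
    r = r + 0.5 * eps * grad
    x = x + eps * inv_mass * r
    lp, grad = logp_grad(x)
    r = r + 0.5 * eps * grad
    return x, r, lp, grad


def _hamiltonian(lp, r, inv_mass):
    return lp - 0.5 * np.sum(inv_mass * r**2)


def _find_initial_step(logp_grad, x0, inv_mass, rng):
    eps = 1.0
    lp0, _ = logp_grad(x0)
    r0 = rng.standard_normal(x0.size) / np.sqrt(inv_mass)
    h0 = _hamiltonian(lp0, r0, inv_mass)
    x, r, lp, _ = _leapfrog(logp_grad, x0, r0, eps, inv_mass)
    h = _hamiltonian(lp, r, inv_mass)
    if not np.isfinite(h):
        accept = 0.0
    else:
        accept = np.exp(min(h - h0, 50.0))
    direction = 1 if accept > 0.5 else -1
    for _ in range(50):
        eps *= 2.0**direction
        x, r, lp, _ = _leapfrog(logp_grad, x0, r0, eps, inv_mass)
        h = _hamiltonian(lp, r, inv_mass)
        accept = np.exp(min(h - h0, 50.0)) if np.isfinite(h) else 0.0
        if (direction == 1 and accept <= 0.5) or (direction == -1 and accept >= 0.5):
            break
    return max(eps, 1e-8)


class _Tree:
    """State carried through the NUTS doubling recursion."""

    __slots__ = ("rng", "logp_grad", "inv_mass", "eps", "logu", "h0",
                 "n_accept_sum", "n_accept_count", "diverged")

    def __init__(self, rng, logp_grad, inv_mass, eps, logu, h0):
        self.rng, self.logp_grad = rng, logp_grad
        self.inv_mass, self.eps, self.logu, self.h0 = inv_mass, eps, logu, h0
        self.n_accept_sum = 0.0
        self.n_accept_count = 0
        self.diverged = False

    def build(self, x, r, v, j):
        if j == 0:
            x1, r1, lp1, _ = _leapfrog(self.logp_grad, x, r, v * self.eps, self.inv_mass)
            h1 = _hamiltonian(lp1, r1, self.inv_mass)
            n1 = int(self.logu <= h1)
            s1 = int(np.isfinite(h1) and self.logu < h1 + DIVERGENCE_THRESHOLD)
            if not s1:
                self.diverged = True
            self.n_accept_sum += min(1.0, np.exp(min(h1 - self.h0, 0.0))) \
                if np.isfinite(h1) else 0.0
            self.n_accept_count += 1
            return x1, r1, x1, r1, x1, n1, s1
        xm, rm, xp, rp, xc, n1, s1 = self.build(x, r, v, j - 1)
        if s1:
            if v == -1:
                xm, rm, _, _, xc2, n2, s2 = self.build(xm, rm, v, j - 1)
            else:
                _, _, xp, rp, xc2, n2, s2 = self.build(xp, rp, v, j - 1)
            if n2 > 0 and self.rng.random() < n2 / max(n1 + n2, 1):
                xc = xc2
            n1 += n2
            s1 = s2 * s1 * int(self._no_uturn(xm, rm, xp, rp))
        return xm, rm, xp, rp, xc, n1, s1

    def _no_uturn(self, xm, rm, xp, rp):
        dx = xp - xm
        return (dx @ (self.inv_mass * rm) >= 0) and (dx @ (self.inv_mass * rp) >= 0)


def nuts_chain(logp_grad: Callable, x0: np.ndarray, n_warmup: int, n_draws: int,
               seed: int, target_accept: float = 0.8,
               max_treedepth: int = MAX_TREEDEPTH) -> tuple[np.ndarray, ChainStats, np.ndarray]:
    """Run one NUTS chain; returns (draws, stats, divergence flags per draw)."""
    rng = np.random.default_rng(seed)
    dim = x0.size
    x = x0.astype(float).copy()
    inv_mass = np.ones(dim)
    eps = _find_initial_step(logp_grad, x, inv_mass, rng)

    # dual averaging state
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    # Stan-style expanding covariance-adaptation windows: an initial
    # step-size-only buffer, doubling variance windows, and a terminal
    # step-size buffer; the mass matrix and dual averaging restart at the
    # end of each variance window.
    init_buf, term_buf, first_win = 75, 50, 25
    window_ends: list[int] = []
    if n_warmup >= init_buf + first_win + term_buf:
        pos, width = init_buf, first_win
        while pos + width < n_warmup - term_buf:
            if pos + 3 * width >= n_warmup - term_buf:
                width = n_warmup - term_buf - pos
            window_ends.append(pos + width)
            pos += width
            width *= 2
        var_start = init_buf
    elif n_warmup >= 40:
        window_ends = [int(0.75 * n_warmup)]
        var_start = n_warmup // 4
    else:
        var_start = 0
    mass_buf: list[np.ndarray] = []

    draws = np.zeros((n_draws, dim))
    div_flags = np.zeros(n_draws, dtype=bool)
    stats = ChainStats()
    accepts = []
    adapt_count = 0

    for it in range(n_warmup + n_draws):
        warming = it < n_warmup
        r0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        lp, _ = logp_grad(x)
        h0 = _hamiltonian(lp, r0, inv_mass)
        logu = h0 + np.log(rng.random())
        tree = _Tree(rng, logp_grad, inv_mass, eps, logu, h0)
        xm, rm, xp, rp = x, r0, x, r0
        xc, n, s, j = x, 1, 1, 0
        while s == 1 and j < max_treedepth:
            v = -1 if rng.random() < 0.5 else 1
            if v == -1:
                xm, rm, _, _, xc2, n2, s2 = tree.build(xm, rm, v, j)
            else:
                _, _, xp, rp, xc2, n2, s2 = tree.build(xp, rp, v, j)
            if s2 == 1 and n2 > 0 and rng.random() < min(1.0, n2 / n):
                xc = xc2
            n += n2
            s = s2 * int(tree._no_uturn(xm, rm, xp, rp))
            j += 1
        if j >= max_treedepth:
            stats.max_treedepth_hits += 1
        x = xc
        accept_stat = tree.n_accept_sum / max(tree.n_accept_count, 1)

        if warming:
            adapt_count += 1
            frac = 1.0 / (adapt_count + t0)
            h_bar = (1 - frac) * h_bar + frac * (target_accept - accept_stat)
            log_eps = mu - np.sqrt(adapt_count) / gamma * h_bar
            w = adapt_count ** (-kappa)
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            if window_ends and it >= var_start:
                mass_buf.append(x.copy())
            if window_ends and it + 1 == window_ends[0]:
                if len(mass_buf) >= 10:
                    buf = np.array(mass_buf)
                    w_n = buf.shape[0]
                    # regularized variance estimate (Stan's shrinkage)
                    var = np.var(buf, axis=0, ddof=1)
                    var = (w_n / (w_n + 5.0)) * var + 1e-3 * (5.0 / (w_n + 5.0))
                    inv_mass = np.maximum(var, 1e-10)
                    eps = float(np.exp(log_eps_bar)) if log_eps_bar != 0 else eps
                    mu = np.log(10.0 * eps)
                    h_bar, log_eps_bar, adapt_count = 0.0, 0.0, 0
                mass_buf = []
                window_ends.pop(0)
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar)) if log_eps_bar != 0.0 else eps
        else:
            k = it - n_warmup
            draws[k] = x
            div_flags[k] = tree.diverged
            if tree.diverged:
                stats.divergences += 1
            accepts.append(accept_stat)

    stats.step_size = eps
    stats.mean_accept = float(np.mean(accepts)) if accepts else 0.0
    return draws, stats, div_flags


def sample_nuts(logp_grad: Callable, x0s: np.ndarray, n_warmup: int, n_draws: int,
                seed: int, target_accept: float = 0.8,
                max_treedepth: int = MAX_TREEDEPTH):
    """Run several chains (x0s: chains x dim); returns draws
    (chains, n_draws, dim), per-chain stats, and divergence flags."""
    chains = x0s.shape[0]
    all_draws = np.zeros((chains, n_draws, x0s.shape[1]))
    all_stats = []
    all_div = np.zeros((chains, n_draws), dtype=bool)
    for c in range(chains):
        d, st, dv = nuts_chain(logp_grad, x0s[c], n_warmup, n_draws,
                               seed + 1000 * c + 1, target_accept, max_treedepth)
        all_draws[c] = d
        all_stats.append(st)
        all_div[c] = dv
    return all_draws, all_stats, all_div
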