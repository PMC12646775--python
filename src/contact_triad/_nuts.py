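"""No-U-Turn sampler over a user-supplied log-density and gradient.

A self-contained dynamic Hamiltonian Monte Carlo implementation in the style
of Stan's adaptive sampler: multinomial trajectory sampling with the
no-U-turn termination criterion, dual-averaging step-size adaptation toward a
target acceptance statistic, and diagonal mass-matrix estimation over
expanding warmup windows.  Both hierarchical models in this package sample on
fully unconstrained parameterizations (non-centred random effects, log scale
for SDs), so the target density is smooth everywhere and a diagonal metric
suffices.

The only interface is :func:`sample_nuts`; models supply
``logp_grad(theta) -> (float, ndarray)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["sample_nuts", "NutsStats"]

_DIVERGENCE = 1000.0  # energy error treated as a divergent transition


@dataclass
class NutsStats:
    """Per-chain sampler diagnostics."""

    step_size: np.ndarray          # final step size per chain
    inv_mass: np.ndarray           # (chains, dim) diagonal inverse metric
    divergences: np.ndarray        # post-warmup divergent transitions per chain
    mean_accept: np.ndarray        # post-warmup mean acceptance statistic
    max_treedepth_hits: np.ndarray


class _Tree:
    __slots__ = ("theta_m", "r_m", "grad_m", "theta_p", "r_p", "grad_p",
                 "theta", "logp", "grad", "log_w", "sum_acc", "n_leaves",
                 "diverged", "turned")

    def __init__(self, theta_m, r_m, grad_m, theta_p, r_p, grad_p,
                 theta, logp, grad, log_w, sum_acc, n_leaves, diverged, turned):
        self.theta_m, self.r_m, self.grad_m = theta_m, r_m, grad_m
        self.theta_p, self.r_p, self.grad_p = theta_p, r_p, grad_p
        self.theta, self.logp, self.grad = theta, logp, grad
        self.log_w, self.sum_acc, self.n_leaves = log_w, sum_acc, n_leaves
        self.diverged, self.turned = diverged, turned


def _uturn(theta_m, theta_p, r_m, r_p, v) -> bool:
    d = theta_p - theta_m
    return (d @ (v * r_m)) < 0.0 or (d @ (v * r_p)) < 0.0


def _leapfrog(logp_grad, theta, r, grad, eps, v):
    r_half = r + 0.5 * eps * grad
    theta_new = theta + eps * v * r_half
    logp_new, grad_new = logp_grad(theta_new)
    r_new = r_half + 0.5 * eps * grad_new
    return theta_new, r_new, logp_new, grad_new


def _build_tree(logp_grad, theta, r, grad, direction, depth, eps, v, h0, rng):
    if depth == 0:
        theta1, r1, logp1, grad1 = _leapfrog(
            logp_grad, theta, r, grad, direction * eps, v)
        h = logp1 - 0.5 * np.sum(v * r1 * r1)
        dh = h - h0
        finite = math.isfinite(dh)
        diverged = (not finite) or dh < -_DIVERGENCE
        log_w = -math.inf if diverged else dh
        acc = min(1.0, math.exp(min(0.0, dh))) if finite else 0.0
        return _Tree(theta1, r1, grad1, theta1, r1, grad1,
                     theta1, logp1, grad1, log_w, acc, 1, diverged, False)

    inner = _build_tree(logp_grad, theta, r, grad, direction, depth - 1,
                        eps, v, h0, rng)
    if inner.diverged or inner.turned:
        return inner
    if direction == 1:
        outer = _build_tree(logp_grad, inner.theta_p, inner.r_p, inner.grad_p,
                            direction, depth - 1, eps, v, h0, rng)
        theta_m, r_m, grad_m = inner.theta_m, inner.r_m, inner.grad_m
        theta_p, r_p, grad_p = outer.theta_p, outer.r_p, outer.grad_p
    else:
        outer = _build_tree(logp_grad, inner.theta_m, inner.r_m, inner.grad_m,
                            direction, depth - 1, eps, v, h0, rng)
        theta_m, r_m, grad_m = outer.theta_m, outer.r_m, outer.grad_m
        theta_p, r_p, grad_p = inner.theta_p, inner.r_p, inner.grad_p

    log_w = np.logaddexp(inner.log_w, outer.log_w)
    # multinomial sampling among the subtrees, proportional to their weights
    take_outer = (outer.log_w > -math.inf
                  and math.log(rng.random() + 1e-300) < outer.log_w - log_w)
    src = outer if take_outer else inner
    turned = (outer.turned or
              _uturn(theta_m, theta_p, r_m, r_p, v))
    return _Tree(theta_m, r_m, grad_m, theta_p, r_p, grad_p,
                 src.theta, src.logp, src.grad, log_w,
                 inner.sum_acc + outer.sum_acc,
                 inner.n_leaves + outer.n_leaves,
                 outer.diverged, turned)


def _nuts_transition(logp_grad, theta, logp, grad, eps, v, rng, max_depth):
    dim = theta.shape[0]
    r0 = rng.standard_normal(dim) / np.sqrt(v)
    h0 = logp - 0.5 * np.sum(v * r0 * r0)
    theta_m = theta_p = theta
    r_m = r_p = r0
    grad_m = grad_p = grad
    prop_theta, prop_logp, prop_grad = theta, logp, grad
    log_w = 0.0
    sum_acc, n_leaves = 0.0, 0
    diverged = False
    depth = 0
    while depth < max_depth:
        direction = 1 if rng.random() < 0.5 else -1
        if direction == 1:
            sub = _build_tree(logp_grad, theta_p, r_p, grad_p, 1, depth,
                              eps, v, h0, rng)
            theta_p, r_p, grad_p = sub.theta_p, sub.r_p, sub.grad_p
        else:
            sub = _build_tree(logp_grad, theta_m, r_m, grad_m, -1, depth,
                              eps, v, h0, rng)
            theta_m, r_m, grad_m = sub.theta_m, sub.r_m, sub.grad_m
        sum_acc += sub.sum_acc
        n_leaves += sub.n_leaves
        if sub.diverged:
            diverged = True
            break
        if not sub.turned:
            # biased progressive sampling: favour the fresh subtree
            if math.log(rng.random() + 1e-300) < sub.log_w - log_w:
                prop_theta, prop_logp, prop_grad = sub.theta, sub.logp, sub.grad
        log_w = np.logaddexp(log_w, sub.log_w)
        if sub.turned or _uturn(theta_m, theta_p, r_m, r_p, v):
            break
        depth += 1
    accept_stat = sum_acc / max(n_leaves, 1)
    return prop_theta, prop_logp, prop_grad, accept_stat, diverged, depth


def _find_initial_step(logp_grad, theta, logp, grad, v, rng) -> float:
    eps = 1.0
    r = rng.standard_normal(theta.shape[0]) / np.sqrt(v)
    h0 = logp - 0.5 * np.sum(v * r * r)
    _, r1, logp1, _ = _leapfrog(logp_grad, theta, r, grad, eps, v)
    h1 = logp1 - 0.5 * np.sum(v * r1 * r1)
    dh = h1 - h0 if math.isfinite(h1) else -math.inf
    direction = 1 if dh > math.log(0.5) else -1
    for _ in range(100):
        eps *= 2.0 ** direction
        _, r1, logp1, _ = _leapfrog(logp_grad, theta, r, grad, eps, v)
        h1 = logp1 - 0.5 * np.sum(v * r1 * r1)
        dh = h1 - h0 if math.isfinite(h1) else -math.inf
        if (direction == 1 and dh <= math.log(0.5)) or \
           (direction == -1 and dh >= math.log(0.5)):
            break
    return eps


def _mass_windows(warmup: int) -> list[tuple[int, int]]:
    """(start, end) half-open variance-estimation windows within warmup."""
    if warmup < 40:
        return []
    init_buf = max(1, int(0.15 * warmup))
    term_buf = max(1, int(0.10 * warmup))
    start, end = init_buf, warmup - term_buf
    width = max(10, (end - start) // 8)
    windows = []
    while start < end:
        stop = start + width
        if end - stop < width:  # absorb the remainder into the last window
            stop = end
        windows.append((start, stop))
        start = stop
        width *= 2
    return windows


def sample_nuts(
    logp_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    init: np.ndarray,
    *,
    chains: int = 4,
    iterations: int = 2000,
    warmup: int = 1000,
    seed: int = 0,
    max_treedepth: int = 10,
    target_accept: float = 0.8,
    init_jitter: float = 0.5,
) -> tuple[np.ndarray, NutsStats]:
    """Draw from a log-density with NUTS; returns post-warmup draws.

    Parameters mirror the usual MCMC configuration: ``iterations`` is the
    total per chain including ``warmup`` (discarded).  Each chain uses an
    independent deterministic random stream derived from ``seed``, so reruns
    are bit-identical.  Returns ``(draws, stats)`` with draws of shape
    ``(chains, iterations - warmup, dim)``.
    """
    if warmup >= iterations:
        raise ValueError("warmup must be smaller than iterations")
    if chains < 1:
        raise ValueError("need at least one chain")
    init = np.asarray(init, dtype=float)
    dim = init.shape[0]
    kept = iterations - warmup
    draws = np.empty((chains, kept, dim))
    stats = NutsStats(
        step_size=np.empty(chains),
        inv_mass=np.empty((chains, dim)),
        divergences=np.zeros(chains, dtype=int),
        mean_accept=np.zeros(chains),
        max_treedepth_hits=np.zeros(chains, dtype=int),
    )
    windows = _mass_windows(warmup)

    for chain in range(chains):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(chain,)))
        theta = init + init_jitter * rng.uniform(-1.0, 1.0, dim)
        logp, grad = logp_grad(theta)
        if not math.isfinite(logp):
            raise ValueError("log density not finite at the initial point")
        v = np.ones(dim)  # diagonal inverse metric (posterior variance est.)

        eps = _find_initial_step(logp_grad, theta, logp, grad, v, rng)
        mu = math.log(10.0 * eps)
        log_eps_bar, h_bar, adapt_t = 0.0, 0.0, 0
        gamma, t0, kappa = 0.05, 10.0, 0.75

        welford_n = 0
        welford_mean = np.zeros(dim)
        welford_m2 = np.zeros(dim)
        window_idx = 0

        acc_sum, acc_n = 0.0, 0
        for it in range(iterations):
            theta, logp, grad, accept, diverged, depth = _nuts_transition(
                logp_grad, theta, logp, grad, eps, v, rng, max_treedepth)
            if it < warmup:
                adapt_t += 1
                h_bar = ((1.0 - 1.0 / (adapt_t + t0)) * h_bar
                         + (target_accept - accept) / (adapt_t + t0))
                log_eps = mu - math.sqrt(adapt_t) / gamma * h_bar
                eta = adapt_t ** (-kappa)
                log_eps_bar = eta * log_eps + (1.0 - eta) * log_eps_bar
                eps = math.exp(log_eps)
                if window_idx < len(windows):
                    w_start, w_end = windows[window_idx]
                    if w_start <= it < w_end:
                        welford_n += 1
                        delta = theta - welford_mean
                        welford_mean += delta / welford_n
                        welford_m2 += delta * (theta - welford_mean)
                    if it == w_end - 1 and welford_n > 1:
                        var = welford_m2 / (welford_n - 1)
                        n = welford_n
                        v = (n / (n + 5.0)) * var + 1e-3 * (5.0 / (n + 5.0))
                        v = np.maximum(v, 1e-10)
                        # restart step-size adaptation under the new metric
                        eps = _find_initial_step(logp_grad, theta, logp, grad, v, rng)
                        mu = math.log(10.0 * eps)
                        log_eps_bar, h_bar, adapt_t = 0.0, 0.0, 0
                        welford_n = 0
                        welford_mean[:] = 0.0
                        welford_m2[:] = 0.0
                        window_idx += 1
                if it == warmup - 1:
                    eps = math.exp(log_eps_bar) if adapt_t > 0 else eps
            else:
                draws[chain, it - warmup] = theta
                acc_sum += accept
                acc_n += 1
                if diverged:
                    stats.divergences[chain] += 1
                if depth >= max_treedepth:
                    stats.max_treedepth_hits[chain] += 1

        stats.step_size[chain] = eps
        stats.inv_mass[chain] = v
        stats.mean_accept[chain] = acc_sum / max(acc_n, 1)
    return draws, stats
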