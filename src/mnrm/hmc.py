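"""No-U-Turn sampler (NUTS) with warmup adaptation.

Multinomial NUTS: each iteration doubles a leapfrog trajectory until the
path makes a U-turn or diverges, then samples a point from the trajectory
with weights proportional to the joint density.  Trajectory lengths adapt
to the local geometry, which matters here: the posterior of a latent-trait
model with a free trait scale has long, curved ridges that fixed-length
HMC traverses too slowly.

Warmup adapts the step size by dual averaging (target acceptance 0.8) and
a diagonal mass matrix from the sample variance of a mid-warmup window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["HMCDiagnostics", "nuts_sample"]

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]

_DIVERGENCE = 1000.0  # energy error treated as divergent


@dataclass
class HMCDiagnostics:
    accept_rate: float
    step_size: float
    divergences: int
    mean_tree_depth: float


class _Tree:
    """A balanced subtree of the NUTS trajectory."""

    __slots__ = (
        "x_minus", "p_minus", "g_minus", "x_plus", "p_plus", "g_plus",
        "proposal", "lp_proposal", "g_proposal", "logw", "sum_accept",
        "n_steps", "turning", "diverging",
    )


def _leapfrog(logp_grad, x, p, grad, eps, inv_mass):
    p = p + 0.5 * eps * grad
    x = x + eps * p * inv_mass
    lp, grad = logp_grad(x)
    p = p + 0.5 * eps * grad
    return x, p, lp, grad


def _uturn(x_plus, x_minus, p_plus, p_minus, inv_mass) -> bool:
    dx = x_plus - x_minus
    return (dx @ (p_minus * inv_mass)) < 0 or (dx @ (p_plus * inv_mass)) < 0


def _build_tree(logp_grad, x, p, grad, depth, direction, eps, inv_mass, h0, rng):
    if depth == 0:
        x1, p1, lp1, g1 = _leapfrog(logp_grad, x, p, grad, direction * eps, inv_mass)
        t = _Tree()
        t.x_minus = t.x_plus = x1
        t.p_minus = t.p_plus = p1
        t.g_minus = t.g_plus = g1
        t.proposal, t.lp_proposal, t.g_proposal = x1, lp1, g1
        if np.isfinite(lp1):
            h1 = -lp1 + 0.5 * float(p1 @ (p1 * inv_mass))
            dh = h1 - h0
        else:
            dh = np.inf
        t.diverging = not np.isfinite(dh) or dh > _DIVERGENCE
        t.logw = -dh if not t.diverging else -np.inf
        t.sum_accept = float(np.exp(min(0.0, -dh))) if np.isfinite(dh) else 0.0
        t.n_steps = 1
        t.turning = False
        return t

    first = _build_tree(logp_grad, x, p, grad, depth - 1, direction, eps, inv_mass, h0, rng)
    if first.diverging or first.turning:
        return first
    if direction == 1:
        second = _build_tree(
            logp_grad, first.x_plus, first.p_plus, first.g_plus,
            depth - 1, direction, eps, inv_mass, h0, rng,
        )
        first.x_plus, first.p_plus, first.g_plus = (
            second.x_plus, second.p_plus, second.g_plus,
        )
    else:
        second = _build_tree(
            logp_grad, first.x_minus, first.p_minus, first.g_minus,
            depth - 1, direction, eps, inv_mass, h0, rng,
        )
        first.x_minus, first.p_minus, first.g_minus = (
            second.x_minus, second.p_minus, second.g_minus,
        )
    first.sum_accept += second.sum_accept
    first.n_steps += second.n_steps
    first.diverging = second.diverging
    if not second.diverging:
        total = np.logaddexp(first.logw, second.logw)
        if np.isfinite(second.logw) and np.log(rng.random()) < second.logw - total:
            first.proposal = second.proposal
            first.lp_proposal = second.lp_proposal
            first.g_proposal = second.g_proposal
        first.logw = total
        first.turning = second.turning or _uturn(
            first.x_plus, first.x_minus, first.p_plus, first.p_minus, inv_mass
        )
    return first


def _find_initial_step(logp_grad, x, lp, grad, inv_mass, rng) -> float:
    """Double/halve the step until the one-step acceptance crosses 0.5."""
    eps = 0.1
    p = rng.standard_normal(x.shape) / np.sqrt(inv_mass)
    h0 = -lp + 0.5 * float(p @ (p * inv_mass))

    def delta_h(eps):
        _, p1, lp1, _ = _leapfrog(logp_grad, x, p, grad, eps, inv_mass)
        if not np.isfinite(lp1):
            return np.inf
        return (-lp1 + 0.5 * float(p1 @ (p1 * inv_mass))) - h0

    direction = 1 if -delta_h(eps) > np.log(0.5) else -1
    for _ in range(30):
        eps *= 2.0**direction
        ratio = -delta_h(eps)
        if (direction == 1 and ratio <= np.log(0.5)) or (
            direction == -1 and ratio >= np.log(0.5)
        ):
            break
    return min(eps, 1.0)


def nuts_sample(
    logp_grad: LogpGrad,
    x0: np.ndarray,
    n_iterations: int,
    warmup: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    max_tree_depth: int = 9,
) -> tuple[np.ndarray, HMCDiagnostics]:
    """Run one NUTS chain; returns post-warmup draws (n_iterations - warmup, dim)."""
    x = np.array(x0, dtype=float)
    dim = x.size
    inv_mass = np.ones(dim)
    lp, grad = logp_grad(x)
    if not np.isfinite(lp):
        raise ValueError("non-finite log density at the initial point")

    eps = _find_initial_step(logp_grad, x, lp, grad, inv_mass, rng)
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = np.log(eps), 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    da_iter = 0

    w_lo, w_hi = int(0.25 * warmup), int(0.7 * warmup)
    window: list[np.ndarray] = []

    kept = np.empty((n_iterations - warmup, dim))
    sum_accept_stat = 0.0
    divergences = 0
    total_depth = 0

    for it in range(n_iterations):
        p = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = -lp + 0.5 * float(p @ (p * inv_mass))

        tree = _Tree()
        tree.x_minus = tree.x_plus = x
        tree.p_minus = tree.p_plus = p
        tree.g_minus = tree.g_plus = grad
        tree.proposal, tree.lp_proposal, tree.g_proposal = x, lp, grad
        tree.logw = 0.0
        tree.sum_accept, tree.n_steps = 0.0, 0
        tree.turning = tree.diverging = False

        depth = 0
        while depth < max_tree_depth:
            direction = 1 if rng.random() < 0.5 else -1
            if direction == 1:
                sub = _build_tree(logp_grad, tree.x_plus, tree.p_plus, tree.g_plus,
                                  depth, 1, eps, inv_mass, h0, rng)
            else:
                sub = _build_tree(logp_grad, tree.x_minus, tree.p_minus, tree.g_minus,
                                  depth, -1, eps, inv_mass, h0, rng)
            tree.sum_accept += sub.sum_accept
            tree.n_steps += sub.n_steps
            if sub.diverging:
                divergences += it >= warmup
                break
            if not sub.turning:
                # biased progressive sampling favours the new subtree
                if np.isfinite(sub.logw) and np.log(rng.random()) < sub.logw - tree.logw:
                    tree.proposal = sub.proposal
                    tree.lp_proposal = sub.lp_proposal
                    tree.g_proposal = sub.g_proposal
            if direction == 1:
                tree.x_plus, tree.p_plus, tree.g_plus = sub.x_plus, sub.p_plus, sub.g_plus
            else:
                tree.x_minus, tree.p_minus, tree.g_minus = (
                    sub.x_minus, sub.p_minus, sub.g_minus,
                )
            if sub.turning:
                break
            tree.logw = np.logaddexp(tree.logw, sub.logw)
            if _uturn(tree.x_plus, tree.x_minus, tree.p_plus, tree.p_minus, inv_mass):
                break
            depth += 1

        x, lp, grad = tree.proposal, tree.lp_proposal, tree.g_proposal
        accept_stat = tree.sum_accept / max(tree.n_steps, 1)
        total_depth += depth

        if it < warmup:
            da_iter += 1
            frac = 1.0 / (da_iter + t0)
            h_bar = (1 - frac) * h_bar + frac * (target_accept - accept_stat)
            log_eps = mu - np.sqrt(da_iter) / gamma * h_bar
            w = da_iter ** (-kappa)
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            if w_lo <= it < w_hi:
                window.append(x.copy())
            if it == w_hi - 1 and len(window) >= 10:
                var = np.var(np.asarray(window), axis=0, ddof=1)
                floor = max(1e-6, float(np.median(var)) * 1e-3)
                inv_mass = np.maximum(var, floor)
                window.clear()
                mu = np.log(10.0 * eps)
                log_eps_bar, h_bar, da_iter = np.log(eps), 0.0, 0
            if it == warmup - 1 and da_iter > 0:
                eps = float(np.exp(log_eps_bar))
        else:
            kept[it - warmup] = x
            sum_accept_stat += accept_stat

    n_kept = max(1, n_iterations - warmup)
    return kept, HMCDiagnostics(
        accept_rate=sum_accept_stat / n_kept,
        step_size=eps,
        divergences=divergences,
        mean_tree_depth=total_depth / n_iterations,
    )
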