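"""A self-contained No-U-Turn sampler on an unconstrained parameter space.

Multinomial NUTS (tree doubling with multinomial selection among leapfrog
states), dual-averaging step-size adaptation, and windowed diagonal
mass-matrix adaptation.  The model is supplied as a single callable
``logp_and_grad(q) -> (float, ndarray)``; non-finite log densities are
treated as divergent leaves, so models may simply return ``-inf`` outside
their support.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["NUTSChain", "sample_nuts"]

#: Energy-error threshold beyond which a leapfrog trajectory is declared divergent.
DIVERGENCE_THRESHOLD = 1000.0


@dataclass
class NUTSChain:
    """Draws and per-iteration sampler statistics for one chain."""

    draws: np.ndarray  # (n_draws, dim), post-warmup only
    divergent: np.ndarray  # (n_draws,) bool
    tree_depth: np.ndarray  # (n_draws,) int
    accept_stat: np.ndarray  # (n_draws,) float
    energy: np.ndarray  # (n_draws,) float
    step_size: float
    inv_mass: np.ndarray


class _Tree:
    """One subtree built by recursive doubling."""

    __slots__ = (
        "q_minus", "p_minus", "g_minus", "q_plus", "p_plus", "g_plus",
        "q_prop", "g_prop", "logp_prop", "log_sum_w", "sum_accept",
        "n_leapfrog", "divergent", "turning",
    )


def _leapfrog(logp_and_grad, q, p, grad, eps, inv_mass):
    p = p + 0.5 * eps * grad
    q = q + eps * inv_mass * p
    logp, grad = logp_and_grad(q)
    if not np.isfinite(logp):
        return q, p, grad, -np.inf
    p = p + 0.5 * eps * grad
    return q, p, grad, logp


def _kinetic(p, inv_mass):
    # overflowing momenta yield inf kinetic energy -> -inf log weight,
    # which the tree builder already treats as a divergent leaf
    with np.errstate(over="ignore"):
        return 0.5 * float(np.dot(p, inv_mass * p))


def _is_turning(q_minus, q_plus, p_minus, p_plus, inv_mass):
    dq = q_plus - q_minus
    return (np.dot(dq, inv_mass * p_minus) < 0) or (np.dot(dq, inv_mass * p_plus) < 0)


def _build_tree(logp_and_grad, q, p, grad, direction, depth, eps, h0, inv_mass, rng):
    tree = _Tree()
    if depth == 0:
        q1, p1, g1, logp1 = _leapfrog(logp_and_grad, q, p, grad, direction * eps, inv_mass)
        h1 = logp1 - _kinetic(p1, inv_mass) if np.isfinite(logp1) else -np.inf
        log_w = h1 - h0
        tree.q_minus = tree.q_plus = tree.q_prop = q1
        tree.p_minus = tree.p_plus = p1
        tree.g_minus = tree.g_plus = tree.g_prop = g1
        tree.logp_prop = logp1
        tree.log_sum_w = log_w
        tree.sum_accept = min(1.0, np.exp(min(log_w, 0.0))) if np.isfinite(log_w) else 0.0
        tree.n_leapfrog = 1
        tree.divergent = (not np.isfinite(log_w)) or (log_w < -DIVERGENCE_THRESHOLD)
        tree.turning = False
        return tree

    first = _build_tree(logp_and_grad, q, p, grad, direction, depth - 1, eps, h0, inv_mass, rng)
    if first.divergent or first.turning:
        return first
    if direction == 1:
        second = _build_tree(
            logp_and_grad, first.q_plus, first.p_plus, first.g_plus,
            direction, depth - 1, eps, h0, inv_mass, rng,
        )
        first.q_plus, first.p_plus, first.g_plus = second.q_plus, second.p_plus, second.g_plus
    else:
        second = _build_tree(
            logp_and_grad, first.q_minus, first.p_minus, first.g_minus,
            direction, depth - 1, eps, h0, inv_mass, rng,
        )
        first.q_minus, first.p_minus, first.g_minus = second.q_minus, second.p_minus, second.g_minus

    first.n_leapfrog += second.n_leapfrog
    first.sum_accept += second.sum_accept
    first.divergent = second.divergent
    log_total = np.logaddexp(first.log_sum_w, second.log_sum_w)
    # Multinomial selection between the two subtrees' proposals.
    if np.isfinite(second.log_sum_w) and np.log(rng.uniform()) < second.log_sum_w - log_total:
        first.q_prop = second.q_prop
        first.g_prop = second.g_prop
        first.logp_prop = second.logp_prop
    first.log_sum_w = log_total
    first.turning = second.turning or _is_turning(
        first.q_minus, first.q_plus, first.p_minus, first.p_plus, inv_mass
    )
    return first


def _find_initial_step(logp_and_grad, q, grad, logp, inv_mass, rng):
    eps = 1.0
    p = rng.standard_normal(q.size) / np.sqrt(inv_mass)
    h0 = logp - _kinetic(p, inv_mass)
    _, p1, _, logp1 = _leapfrog(logp_and_grad, q, p, grad, eps, inv_mass)
    h1 = logp1 - _kinetic(p1, inv_mass) if np.isfinite(logp1) else -np.inf
    direction = 1 if (h1 - h0) > np.log(0.5) else -1
    for _ in range(50):
        eps *= 2.0**direction
        _, p1, _, logp1 = _leapfrog(logp_and_grad, q, p, grad, eps, inv_mass)
        h1 = logp1 - _kinetic(p1, inv_mass) if np.isfinite(logp1) else -np.inf
        if direction == 1 and (h1 - h0) <= np.log(0.5):
            break
        if direction == -1 and (h1 - h0) > np.log(0.5):
            break
    return max(eps, 1e-7)


def _adaptation_windows(n_warmup):
    """Stan-style warmup schedule: fast start, doubling slow windows, fast end."""
    init_buffer, term_buffer, base_window = 75, 50, 25
    if n_warmup < init_buffer + term_buffer + base_window:
        init_buffer = max(1, int(0.15 * n_warmup))
        term_buffer = max(1, int(0.10 * n_warmup))
        base_window = max(1, n_warmup - init_buffer - term_buffer)
    ends = []
    start = init_buffer
    size = base_window
    while start < n_warmup - term_buffer:
        end = start + size
        if end + 2 * size > n_warmup - term_buffer:
            end = n_warmup - term_buffer
        ends.append(end)
        start = end
        size *= 2
    return init_buffer, ends


def sample_nuts(
    logp_and_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    q0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.9,
    max_treedepth: int = 10,
) -> NUTSChain:
    """Run one NUTS chain and return post-warmup draws with statistics."""
    q = np.asarray(q0, dtype=float).copy()
    dim = q.size
    logp, grad = logp_and_grad(q)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log density")

    inv_mass = np.ones(dim)
    eps = _find_initial_step(logp_and_grad, q, grad, logp, inv_mass, rng)

    # Dual averaging state (Hoffman & Gelman 2014 defaults).
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    da_gamma, da_t0, da_kappa = 0.05, 10.0, 0.75
    da_count = 0

    init_buffer, window_ends = _adaptation_windows(n_warmup)
    welford_n = 0
    welford_mean = np.zeros(dim)
    welford_m2 = np.zeros(dim)

    total = n_warmup + n_draws
    draws = np.empty((n_draws, dim))
    divergent = np.zeros(n_draws, dtype=bool)
    tree_depth = np.zeros(n_draws, dtype=np.int64)
    accept_stat = np.zeros(n_draws)
    energy = np.zeros(n_draws)

    for it in range(total):
        warmup = it < n_warmup
        p = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = logp - _kinetic(p, inv_mass)
        q_minus = q_plus = q
        p_minus = p_plus = p
        g_minus = g_plus = grad
        q_prop, g_prop, logp_prop = q, grad, logp
        log_sum_w = 0.0
        sum_accept, n_leapfrog = 0.0, 0
        diverged = False
        depth = 0
        while depth < max_treedepth:
            direction = 1 if rng.uniform() < 0.5 else -1
            if direction == 1:
                tree = _build_tree(
                    logp_and_grad, q_plus, p_plus, g_plus, 1, depth, eps, h0, inv_mass, rng
                )
                q_plus, p_plus, g_plus = tree.q_plus, tree.p_plus, tree.g_plus
            else:
                tree = _build_tree(
                    logp_and_grad, q_minus, p_minus, g_minus, -1, depth, eps, h0, inv_mass, rng
                )
                q_minus, p_minus, g_minus = tree.q_minus, tree.p_minus, tree.g_minus
            sum_accept += tree.sum_accept
            n_leapfrog += tree.n_leapfrog
            if tree.divergent:
                diverged = True
                break
            if tree.turning:
                break
            # Biased progressive sampling: favour the newly built subtree.
            if np.log(rng.uniform()) < tree.log_sum_w - log_sum_w:
                q_prop, g_prop, logp_prop = tree.q_prop, tree.g_prop, tree.logp_prop
            log_sum_w = np.logaddexp(log_sum_w, tree.log_sum_w)
            depth += 1
            if _is_turning(q_minus, q_plus, p_minus, p_plus, inv_mass):
                break

        q, grad, logp = q_prop, g_prop, logp_prop
        accept_prob = sum_accept / max(n_leapfrog, 1)

        if warmup:
            da_count += 1
            frac = 1.0 / (da_count + da_t0)
            h_bar = (1 - frac) * h_bar + frac * (target_accept - accept_prob)
            log_eps = mu - np.sqrt(da_count) / da_gamma * h_bar
            weight = da_count**-da_kappa
            log_eps_bar = weight * log_eps + (1 - weight) * log_eps_bar
            eps = float(np.exp(log_eps))

            if it >= init_buffer and (not window_ends or it < window_ends[-1]):
                welford_n += 1
                delta = q - welford_mean
                welford_mean += delta / welford_n
                welford_m2 += delta * (q - welford_mean)
            if window_ends and it + 1 == window_ends[0]:
                window_ends.pop(0)
                if welford_n > 4:
                    var = welford_m2 / (welford_n - 1)
                    inv_mass = (
                        welford_n / (welford_n + 5.0) * var
                        + 1e-3 * 5.0 / (welford_n + 5.0)
                    )
                welford_n = 0
                welford_mean[:] = 0.0
                welford_m2[:] = 0.0
                # Re-initialise step-size search around the current value.
                eps = _find_initial_step(logp_and_grad, q, grad, logp, inv_mass, rng)
                mu = np.log(10.0 * eps)
                log_eps_bar, h_bar, da_count = 0.0, 0.0, 0
            if it + 1 == n_warmup:
                eps = float(np.exp(log_eps_bar))
        else:
            idx = it - n_warmup
            draws[idx] = q
            divergent[idx] = diverged
            tree_depth[idx] = depth
            accept_stat[idx] = accept_prob
            energy[idx] = -(h0)

    return NUTSChain(
        draws=draws,
        divergent=divergent,
        tree_depth=tree_depth,
        accept_stat=accept_stat,
        energy=energy,
        step_size=eps,
        inv_mass=inv_mass,
    )
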