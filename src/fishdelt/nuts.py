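"""No-U-Turn Hamiltonian Monte Carlo on an unconstrained parameter space.

A self-contained NUTS implementation driven by a single callable that
returns the log target density and its gradient. One transition simulates
Hamiltonian dynamics with the leapfrog integrator, doubling the trajectory
until it makes a U-turn (or diverges), and slice-samples a point from the
set of visited states. Warmup adapts the step size by dual averaging
toward a target acceptance statistic and the diagonal mass matrix from
the sample variance over expanding warmup windows, mirroring the usual
windowed scheme.

The implementation is deterministic given a :class:`numpy.random.Generator`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_MAX_ENERGY_ERROR = 1000.0  # divergence threshold on the Hamiltonian error


@dataclass
class ChainResult:
    """Draws and sampler diagnostics for one chain."""

    draws: np.ndarray            # (n_draws, dim)
    divergences: int
    divergent: np.ndarray        # (n_draws,) bool, post-warmup transitions only
    step_size: float
    inv_mass: np.ndarray
    accept_mean: float
    treedepths: np.ndarray       # (n_draws,)


class _Tree:
    """State carried through recursive trajectory doubling."""

    __slots__ = (
        "x_minus", "p_minus", "g_minus", "x_plus", "p_plus", "g_plus",
        "x_prop", "lp_prop", "g_prop", "n_valid", "keep_going",
        "alpha_sum", "n_alpha", "diverged",
    )


def _kinetic(p: np.ndarray, inv_mass: np.ndarray) -> float:
    return 0.5 * float(np.dot(inv_mass * p, p))


def _leapfrog(logp_grad, x, p, grad, eps, inv_mass):
    p_half = p + 0.5 * eps * grad
    x_new = x + eps * (inv_mass * p_half)
    lp_new, grad_new = logp_grad(x_new)
    p_new = p_half + 0.5 * eps * grad_new
    return x_new, p_new, lp_new, grad_new


def _no_uturn(x_plus, p_plus, x_minus, p_minus, inv_mass) -> bool:
    dx = x_plus - x_minus
    return (np.dot(dx, inv_mass * p_minus) >= 0.0) and (np.dot(dx, inv_mass * p_plus) >= 0.0)


def _build_tree(logp_grad, x, p, grad, log_u, direction, depth, eps, inv_mass, h0, rng) -> _Tree:
    t = _Tree()
    if depth == 0:
        x1, p1, lp1, g1 = _leapfrog(logp_grad, x, p, grad, direction * eps, inv_mass)
        h1 = lp1 - _kinetic(p1, inv_mass) if np.isfinite(lp1) else -np.inf
        t.x_minus = t.x_plus = t.x_prop = x1
        t.p_minus = t.p_plus = p1
        t.g_minus = t.g_plus = t.g_prop = g1
        t.lp_prop = lp1
        t.n_valid = int(log_u <= h1)
        t.diverged = (h1 - log_u) < -_MAX_ENERGY_ERROR or not np.isfinite(h1)
        t.keep_going = not t.diverged
        t.alpha_sum = min(1.0, float(np.exp(min(h1 - h0, 0.0)))) if np.isfinite(h1) else 0.0
        t.n_alpha = 1
        return t

    first = _build_tree(logp_grad, x, p, grad, log_u, direction, depth - 1, eps, inv_mass, h0, rng)
    if not first.keep_going:
        return first
    if direction == -1:
        second = _build_tree(
            logp_grad, first.x_minus, first.p_minus, first.g_minus,
            log_u, direction, depth - 1, eps, inv_mass, h0, rng,
        )
        first.x_minus, first.p_minus, first.g_minus = second.x_minus, second.p_minus, second.g_minus
    else:
        second = _build_tree(
            logp_grad, first.x_plus, first.p_plus, first.g_plus,
            log_u, direction, depth - 1, eps, inv_mass, h0, rng,
        )
        first.x_plus, first.p_plus, first.g_plus = second.x_plus, second.p_plus, second.g_plus

    total = first.n_valid + second.n_valid
    if second.n_valid > 0 and rng.random() < second.n_valid / max(total, 1):
        first.x_prop, first.lp_prop, first.g_prop = second.x_prop, second.lp_prop, second.g_prop
    first.n_valid = total
    first.alpha_sum += second.alpha_sum
    first.n_alpha += second.n_alpha
    first.diverged = first.diverged or second.diverged
    first.keep_going = (
        second.keep_going
        and not first.diverged
        and _no_uturn(first.x_plus, first.p_plus, first.x_minus, first.p_minus, inv_mass)
    )
    return first


def _transition(logp_grad, x, lp, grad, eps, inv_mass, max_depth, rng):
    """One NUTS transition. Returns (x, lp, grad, accept_stat, depth, diverged)."""
    p0 = rng.standard_normal(x.shape[0]) / np.sqrt(inv_mass)
    h0 = lp - _kinetic(p0, inv_mass)
    log_u = h0 + np.log(rng.random())

    t = _Tree()
    t.x_minus = t.x_plus = x
    t.p_minus = t.p_plus = p0
    t.g_minus = t.g_plus = grad
    x_cur, lp_cur, g_cur = x, lp, grad
    n_valid = 1
    depth = 0
    diverged = False
    alpha_sum, n_alpha = 0.0, 0
    keep_going = True
    while keep_going and depth < max_depth:
        direction = 1 if rng.random() < 0.5 else -1
        if direction == -1:
            sub = _build_tree(logp_grad, t.x_minus, t.p_minus, t.g_minus, log_u,
                              direction, depth, eps, inv_mass, h0, rng)
            t.x_minus, t.p_minus, t.g_minus = sub.x_minus, sub.p_minus, sub.g_minus
        else:
            sub = _build_tree(logp_grad, t.x_plus, t.p_plus, t.g_plus, log_u,
                              direction, depth, eps, inv_mass, h0, rng)
            t.x_plus, t.p_plus, t.g_plus = sub.x_plus, sub.p_plus, sub.g_plus
        if sub.keep_going and sub.n_valid > 0 and rng.random() < sub.n_valid / n_valid:
            x_cur, lp_cur, g_cur = sub.x_prop, sub.lp_prop, sub.g_prop
        n_valid += sub.n_valid
        alpha_sum += sub.alpha_sum
        n_alpha += sub.n_alpha
        diverged = diverged or sub.diverged
        keep_going = (
            sub.keep_going
            and _no_uturn(t.x_plus, t.p_plus, t.x_minus, t.p_minus, inv_mass)
        )
        depth += 1
    accept = alpha_sum / max(n_alpha, 1)
    return x_cur, lp_cur, g_cur, accept, depth, diverged


def _find_initial_step(logp_grad, x, lp, grad, inv_mass, rng) -> float:
    """Heuristic: scale eps by 2 until the one-step acceptance crosses 1/2."""
    eps = 1.0
    p = rng.standard_normal(x.shape[0]) / np.sqrt(inv_mass)
    h0 = lp - _kinetic(p, inv_mass)
    _, p1, lp1, _ = _leapfrog(logp_grad, x, p, grad, eps, inv_mass)
    h1 = lp1 - _kinetic(p1, inv_mass) if np.isfinite(lp1) else -np.inf
    direction = 1 if (h1 - h0) > np.log(0.5) else -1
    for _ in range(100):
        eps *= 2.0**direction
        _, p1, lp1, _ = _leapfrog(logp_grad, x, p, grad, eps, inv_mass)
        h1 = lp1 - _kinetic(p1, inv_mass) if np.isfinite(lp1) else -np.inf
        if direction == 1 and (h1 - h0) <= np.log(0.5):
            break
        if direction == -1 and (h1 - h0) >= np.log(0.5):
            break
    return eps


class _DualAveraging:
    """Nesterov dual averaging of log step size toward a target acceptance."""

    def __init__(self, eps0: float, target: float, gamma=0.05, t0=10.0, kappa=0.75):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.gamma, self.t0, self.kappa = gamma, t0, kappa
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 0

    def update(self, accept: float) -> float:
        self.count += 1
        m = self.count
        w = 1.0 / (m + self.t0)
        self.h_bar = (1.0 - w) * self.h_bar + w * (self.target - accept)
        self.log_eps = self.mu - np.sqrt(m) / self.gamma * self.h_bar
        step = m**-self.kappa
        self.log_eps_bar = step * self.log_eps + (1.0 - step) * self.log_eps_bar
        return float(np.exp(self.log_eps))

    @property
    def adapted(self) -> float:
        return float(np.exp(self.log_eps_bar))


def _adaptation_schedule(n_warmup: int) -> tuple[int, int, list[int]]:
    """(init_buffer, term_buffer, metric-window end iterations)."""
    if n_warmup < 20:
        return n_warmup, 0, []
    init = min(75, max(10, int(0.15 * n_warmup)))
    term = min(50, max(5, int(0.10 * n_warmup)))
    ends = []
    size = max(25, int(0.08 * n_warmup))
    pos = init
    while pos + size < n_warmup - term:
        pos += size
        ends.append(pos)
        size *= 2
    if not ends:
        ends = [n_warmup - term] if n_warmup - term > init else []
    elif ends[-1] != n_warmup - term:
        ends[-1] = n_warmup - term
    return init, term, ends


def sample_chain(
    logp_grad,
    x0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.95,
    max_treedepth: int = 10,
) -> ChainResult:
    """Run one NUTS chain and return post-warmup draws plus diagnostics."""
    x = np.asarray(x0, dtype=float).copy()
    lp, grad = logp_grad(x)
    if not np.isfinite(lp):
        raise ValueError("non-finite log density at the initial point")
    dim = x.shape[0]
    inv_mass = np.ones(dim)

    eps = _find_initial_step(logp_grad, x, lp, grad, inv_mass, rng)
    da = _DualAveraging(eps, target_accept)

    init_buf, term_buf, window_ends = _adaptation_schedule(n_warmup)
    window_ends_set = set(window_ends)
    window_buffer: list[np.ndarray] = []

    accepts = []
    for it in range(n_warmup):
        x, lp, grad, accept, _, _ = _transition(
            logp_grad, x, lp, grad, eps, inv_mass, max_treedepth, rng
        )
        eps = da.update(accept)
        in_window = init_buf <= it < n_warmup - term_buf and window_ends
        if in_window:
            window_buffer.append(x.copy())
        if (it + 1) in window_ends_set and len(window_buffer) >= 5:
            w = np.asarray(window_buffer)
            n = w.shape[0]
            var = w.var(axis=0, ddof=1)
            inv_mass = (n / (n + 5.0)) * var + 1e-3 * (5.0 / (n + 5.0))
            inv_mass = np.maximum(inv_mass, 1e-10)
            window_buffer = []
            # restart step-size adaptation around the current step
            eps = _find_initial_step(logp_grad, x, lp, grad, inv_mass, rng)
            da = _DualAveraging(eps, target_accept)

    if n_warmup > 0:
        eps = da.adapted

    draws = np.empty((n_draws, dim))
    divergent = np.zeros(n_draws, dtype=bool)
    depths = np.zeros(n_draws, dtype=np.int16)
    for it in range(n_draws):
        x, lp, grad, accept, depth, div = _transition(
            logp_grad, x, lp, grad, eps, inv_mass, max_treedepth, rng
        )
        draws[it] = x
        divergent[it] = div
        depths[it] = depth
        accepts.append(accept)

    return ChainResult(
        draws=draws,
        divergences=int(divergent.sum()),
        divergent=divergent,
        step_size=float(eps),
        inv_mass=inv_mass,
        accept_mean=float(np.mean(accepts)) if accepts else 0.0,
        treedepths=depths,
    )
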