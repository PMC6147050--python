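"""No-U-Turn Hamiltonian Monte Carlo sampler.

A self-contained NUTS implementation (slice-sampling variant with doubling,
dynamic termination on the U-turn criterion) with dual-averaging step-size
adaptation and windowed diagonal mass-matrix estimation during warmup. The
target is supplied as a callable returning the log density and its gradient
on an unconstrained parameter vector.

Divergences are transitions whose simulated Hamiltonian error exceeds
``DELTA_MAX``; post-warmup divergences are counted and reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DELTA_MAX = 1000.0  # energy error admitting a point into the slice


@dataclass
class SampleStats:
    """Per-chain sampling diagnostics."""

    divergences: int
    step_size: float
    mean_accept: float
    max_treedepth_hits: int
    inv_mass: np.ndarray


class _DualAveraging:
    """Nesterov dual averaging of log step size (Stan defaults)."""

    def __init__(self, eps0: float, target: float):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 0
        self.gamma, self.t0, self.kappa = 0.05, 10.0, 0.75

    def update(self, accept_prob: float) -> float:
        self.count += 1
        m = self.count
        eta = 1.0 / (m + self.t0)
        self.h_bar = (1 - eta) * self.h_bar + eta * (self.target - accept_prob)
        self.log_eps = self.mu - np.sqrt(m) / self.gamma * self.h_bar
        w = m ** (-self.kappa)
        self.log_eps_bar = w * self.log_eps + (1 - w) * self.log_eps_bar
        return np.exp(self.log_eps)

    def restart(self, eps0: float) -> None:
        self.mu = np.log(10.0 * eps0)
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 0

    @property
    def adapted(self) -> float:
        return float(np.exp(self.log_eps_bar))


class _Welford:
    """Streaming mean/variance for mass-matrix estimation."""

    def __init__(self, dim: int):
        self.n = 0
        self.mean = np.zeros(dim)
        self.m2 = np.zeros(dim)

    def push(self, x: np.ndarray) -> None:
        self.n += 1
        d = x - self.mean
        self.mean += d / self.n
        self.m2 += d * (x - self.mean)

    def variance(self) -> np.ndarray:
        if self.n < 2:
            return np.ones_like(self.mean)
        var = self.m2 / (self.n - 1)
        # regularize toward unit scale as Stan does for small windows
        return (self.n / (self.n + 5.0)) * var + (5.0 / (self.n + 5.0)) * 1e-3


def _adaptation_windows(warmup: int):
    """(init step-size phase, list of mass windows, terminal step-size phase)."""
    if warmup < 40:
        return warmup, [], 0
    init = min(75, int(0.15 * warmup))
    term = min(50, int(0.1 * warmup))
    middle = warmup - init - term
    windows = []
    w = 25
    pos = 0
    while pos < middle:
        if pos + w >= middle or pos + 3 * w >= middle:
            windows.append(middle - pos)
            break
        windows.append(w)
        pos += w
        w *= 2
    return init, windows, term


def nuts(
    logp_grad,
    theta0: np.ndarray,
    n_samples: int,
    warmup: int,
    rng: np.random.Generator,
    target_accept: float = 0.9,
    max_treedepth: int = 10,
    adapt_mass: bool = True,
) -> tuple[np.ndarray, SampleStats]:
    """Run one NUTS chain.

    Returns ``(draws, stats)`` with ``draws`` of shape ``(n_samples, dim)``
    containing the post-warmup states.
    """
    theta = np.array(theta0, dtype=float)
    dim = theta.size
    lp, grad = logp_grad(theta)
    if not np.isfinite(lp):
        raise ValueError("log density not finite at the initial point")

    inv_mass = np.ones(dim)
    eps = _find_reasonable_epsilon(logp_grad, theta, lp, grad, inv_mass, rng)
    da = _DualAveraging(eps, target_accept)

    init, windows, term = _adaptation_windows(warmup)
    window_ends = []
    pos = init
    for w in windows:
        pos += w
        window_ends.append(pos)
    welford = _Welford(dim) if adapt_mass else None

    draws = np.empty((n_samples, dim))
    divergences = 0
    depth_hits = 0
    accept_sum = 0.0
    n_kept = 0

    total = warmup + n_samples
    for it in range(total):
        adapting = it < warmup
        theta, lp, grad, alpha, n_alpha, diverged, hit_depth = _transition(
            logp_grad, theta, lp, grad, eps, inv_mass, rng, max_treedepth
        )
        if adapting:
            eps = da.update(alpha / n_alpha)
            if welford is not None and it >= init and (not window_ends or it < window_ends[-1]):
                welford.push(theta)
            if window_ends and it + 1 == window_ends[0]:
                inv_mass = welford.variance()
                welford = _Welford(dim)
                window_ends.pop(0)
                # fresh step size for the new metric
                eps = _find_reasonable_epsilon(logp_grad, theta, lp, grad, inv_mass, rng)
                da.restart(eps)
            if it + 1 == warmup:
                eps = da.adapted
        else:
            if diverged:
                divergences += 1
            if hit_depth:
                depth_hits += 1
            accept_sum += alpha / n_alpha
            draws[n_kept] = theta
            n_kept += 1

    stats = SampleStats(
        divergences=divergences,
        step_size=float(eps),
        mean_accept=accept_sum / max(n_samples, 1),
        max_treedepth_hits=depth_hits,
        inv_mass=inv_mass,
    )
    return draws, stats


def _kinetic(r: np.ndarray, inv_mass: np.ndarray) -> float:
    return 0.5 * float(np.dot(r * inv_mass, r))


def _leapfrog(logp_grad, theta, r, grad, eps, inv_mass):
    r = r + 0.5 * eps * grad
    theta = theta + eps * inv_mass * r
    lp, grad = logp_grad(theta)
    r = r + 0.5 * eps * grad
    return theta, r, lp, grad


def _find_reasonable_epsilon(logp_grad, theta, lp, grad, inv_mass, rng) -> float:
    """Heuristic initial step size (Hoffman & Gelman)."""
    eps = 1.0
    r = rng.standard_normal(theta.size) / np.sqrt(inv_mass)
    joint0 = lp - _kinetic(r, inv_mass)
    _, r1, lp1, _ = _leapfrog(logp_grad, theta, r, grad, eps, inv_mass)
    joint1 = lp1 - _kinetic(r1, inv_mass)
    if not np.isfinite(joint1):
        joint1 = -np.inf
    direction = 1.0 if (joint1 - joint0) > np.log(0.5) else -1.0
    for _ in range(60):
        eps *= 2.0**direction
        _, r1, lp1, _ = _leapfrog(logp_grad, theta, r, grad, eps, inv_mass)
        joint1 = lp1 - _kinetic(r1, inv_mass)
        if not np.isfinite(joint1):
            joint1 = -np.inf
        if direction * (joint1 - joint0) <= direction * np.log(0.5):
            break
    return max(eps, 1e-10)


def _transition(logp_grad, theta, lp, grad, eps, inv_mass, rng, max_treedepth):
    """One NUTS transition (Algorithm 6, slice variant)."""
    r0 = rng.standard_normal(theta.size) / np.sqrt(inv_mass)
    joint0 = lp - _kinetic(r0, inv_mass)
    logu = joint0 - rng.exponential(1.0)

    theta_minus = theta_plus = theta
    r_minus = r_plus = r0
    grad_minus = grad_plus = grad
    theta_new, lp_new, grad_new = theta, lp, grad
    n = 1
    s = True
    diverged = False
    alpha_sum = 0.0
    n_alpha = 0
    depth = 0

    while s and depth < max_treedepth:
        v = 1 if rng.random() < 0.5 else -1
        if v == -1:
            (theta_minus, r_minus, grad_minus, _, _, _,
             theta1, lp1, grad1, n1, s1, a1, na1, div1) = _build_tree(
                logp_grad, theta_minus, r_minus, grad_minus, logu, v, depth,
                eps, inv_mass, joint0, rng)
        else:
            (_, _, _, theta_plus, r_plus, grad_plus,
             theta1, lp1, grad1, n1, s1, a1, na1, div1) = _build_tree(
                logp_grad, theta_plus, r_plus, grad_plus, logu, v, depth,
                eps, inv_mass, joint0, rng)
        diverged = diverged or div1
        if s1 and n1 > 0 and rng.random() < n1 / max(n, 1):
            theta_new, lp_new, grad_new = theta1, lp1, grad1
        n += n1
        alpha_sum += a1
        n_alpha += na1
        s = s1 and _no_uturn(theta_minus, theta_plus, r_minus, r_plus, inv_mass)
        depth += 1

    return theta_new, lp_new, grad_new, alpha_sum, max(n_alpha, 1), diverged, depth >= max_treedepth


def _no_uturn(theta_minus, theta_plus, r_minus, r_plus, inv_mass) -> bool:
    dtheta = theta_plus - theta_minus
    return (np.dot(dtheta, inv_mass * r_minus) >= 0) and (
        np.dot(dtheta, inv_mass * r_plus) >= 0
    )


def _build_tree(logp_grad, theta, r, grad, logu, v, depth, eps, inv_mass, joint0, rng):
    """Recursive doubling; returns edge states plus a proposal from the subtree."""
    if depth == 0:
        theta1, r1, lp1, grad1 = _leapfrog(logp_grad, theta, r, grad, v * eps, inv_mass)
        joint1 = lp1 - _kinetic(r1, inv_mass)
        if not np.isfinite(joint1):
            joint1 = -np.inf
        n1 = int(logu <= joint1)
        diverged = (joint1 - logu) < -DELTA_MAX
        s1 = not diverged
        alpha = min(1.0, float(np.exp(min(joint1 - joint0, 0.0))))
        return (theta1, r1, grad1, theta1, r1, grad1,
                theta1, lp1, grad1, n1, s1, alpha, 1, diverged)

    (theta_minus, r_minus, grad_minus, theta_plus, r_plus, grad_plus,
     theta1, lp1, grad1, n1, s1, a1, na1, div1) = _build_tree(
        logp_grad, theta, r, grad, logu, v, depth - 1, eps, inv_mass, joint0, rng)
    if s1:
        if v == -1:
            (theta_minus, r_minus, grad_minus, _, _, _,
             theta2, lp2, grad2, n2, s2, a2, na2, div2) = _build_tree(
                logp_grad, theta_minus, r_minus, grad_minus, logu, v, depth - 1,
                eps, inv_mass, joint0, rng)
        else:
            (_, _, _, theta_plus, r_plus, grad_plus,
             theta2, lp2, grad2, n2, s2, a2, na2, div2) = _build_tree(
                logp_grad, theta_plus, r_plus, grad_plus, logu, v, depth - 1,
                eps, inv_mass, joint0, rng)
        if n2 > 0 and rng.random() < n2 / max(n1 + n2, 1):
            theta1, lp1, grad1 = theta2, lp2, grad2
        n1 += n2
        a1 += a2
        na1 += na2
        s1 = s2 and _no_uturn(theta_minus, theta_plus, r_minus, r_plus, inv_mass)
        div1 = div1 or div2
    return (theta_minus, r_minus, grad_minus, theta_plus, r_plus, grad_plus,
            theta1, lp1, grad1, n1, s1, a1, na1, div1)
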