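"""Independent brute-force oracles used by the test suite.

Deliberately naive (loops, direct definitions, closed forms) and kept
separate from the implementation paths they validate.
"""

from __future__ import annotations

import math

import numpy as np


def sampen_bruteforce(x, m: int, r: float) -> float:
    """Sample entropy by direct template counting (triple loop).

    Richman–Moorman: B = #{(i, j), i != j} of m-length template pairs with
    Chebyshev distance <= r, A the same for length m+1, both over the first
    n - m starting indices; SampEn = -ln(A/B).
    """
    x = list(map(float, x))
    n = len(x)
    nt = n - m
    a = b = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    if b == 0:
        raise ValueError("no m-length matches")
    if a == 0:
        return float("inf")
    return -math.log(a / b)


def ami_bruteforce(x, lag: int, n_bins: int) -> float:
    """Average mutual information (nats) by explicit bin counting."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    lo, hi = x.min(), x.max()
    width = (hi - lo) / n_bins

    def bin_of(v):
        b = int((v - lo) / width)
        return min(b, n_bins - 1)

    npairs = n - lag
    joint = [[0] * n_bins for _ in range(n_bins)]
    for i in range(npairs):
        joint[bin_of(x[i])][bin_of(x[i + lag])] += 1
    px = [sum(row) for row in joint]
    py = [sum(joint[i][j] for i in range(n_bins)) for j in range(n_bins)]
    ami = 0.0
    for i in range(n_bins):
        for j in range(n_bins):
            c = joint[i][j]
            if c:
                p = c / npairs
                ami += p * math.log(p * npairs * npairs / (px[i] * py[j]))
    return ami


def autocorr_direct(x, k: int) -> float:
    """Unbiased mean-removed variance-normalized autocorrelation at lag k."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    xc = x - x.mean()
    var = float(np.mean(xc**2))
    s = 0.0
    for i in range(n - k):
        s += xc[i] * xc[i + k]
    return s / (n - k) / var


def fnn_bruteforce(x, dim: int, lag: int, rtol=15.0, atol=2.0) -> float:
    """False-nearest-neighbor fraction by all-pairs search (no KD-tree)."""
    x = np.asarray(x, dtype=float)
    n_next = len(x) - dim * lag
    emb = np.array([[x[i + k * lag] for k in range(dim)] for i in range(n_next)])
    nxt = np.array([x[i + dim * lag] for i in range(n_next)])
    size = float(np.std(x))
    false = 0
    for i in range(n_next):
        best, bd = -1, np.inf
        for j in range(n_next):
            if j == i:
                continue
            d = float(np.linalg.norm(emb[i] - emb[j]))
            if d < bd:
                bd, best = d, j
        extra = abs(nxt[i] - nxt[best])
        d1 = math.hypot(bd, extra)
        if (extra / bd if bd > 0 else math.inf) > rtol or d1 > atol * size:
            false += 1
    return false / n_next


# ---------------------------------------------------------------------------
# Lorenz / Benettin


def _lorenz_rhs(s, sigma, rho, beta):
    x, y, z = s
    return np.array([sigma * (y - x), x * (rho - z) - y, x * y - beta * z])


def lorenz_series(
    n: int, dt: float = 0.01, sigma=10.0, rho=28.0, beta=8.0 / 3.0,
    x0=(1.0, 1.0, 1.0), transient: int = 3000,
) -> np.ndarray:
    """x-coordinate of an RK4-integrated Lorenz trajectory."""
    s = np.array(x0, dtype=float)
    out = np.empty(n)
    for i in range(n + transient):
        k1 = _lorenz_rhs(s, sigma, rho, beta)
        k2 = _lorenz_rhs(s + dt / 2 * k1, sigma, rho, beta)
        k3 = _lorenz_rhs(s + dt / 2 * k2, sigma, rho, beta)
        k4 = _lorenz_rhs(s + dt * k3, sigma, rho, beta)
        s = s + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        if i >= transient:
            out[i - transient] = s[0]
    return out


def benettin_lyapunov(
    n: int = 40000, dt: float = 0.01, sigma=10.0, rho=28.0, beta=8.0 / 3.0,
) -> float:
    """Largest Lyapunov exponent by tangent-space integration with
    renormalization (Benettin); independent of any delay embedding."""

    def jac(s):
        x, y, z = s
        return np.array([[-sigma, sigma, 0.0], [rho - z, -1.0, -x], [y, x, -beta]])

    s = np.array([1.0, 1.0, 1.0])
    v = np.array([1.0, 0.0, 0.0])
    acc, cnt = 0.0, 0
    for i in range(n):
        k1 = _lorenz_rhs(s, sigma, rho, beta)
        k2 = _lorenz_rhs(s + dt / 2 * k1, sigma, rho, beta)
        k3 = _lorenz_rhs(s + dt / 2 * k2, sigma, rho, beta)
        k4 = _lorenz_rhs(s + dt * k3, sigma, rho, beta)
        j1 = jac(s) @ v
        j2 = jac(s + dt / 2 * k1) @ (v + dt / 2 * j1)
        j3 = jac(s + dt / 2 * k2) @ (v + dt / 2 * j2)
        j4 = jac(s + dt * k3) @ (v + dt * j3)
        s = s + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        v = v + dt / 6 * (j1 + 2 * j2 + 2 * j3 + j4)
        nv = float(np.linalg.norm(v))
        if i > 2000:  # discard transient alignment
            acc += math.log(nv)
            cnt += 1
        v /= nv
    return acc / (cnt * dt)


def minjerk_ldlj_closed_form() -> float:
    """LDLJ of a single minimum-jerk stroke by symbolic integration.

    a(tau) = 60 tau - 180 tau^2 + 120 tau^3 on unit displacement/duration;
    LDLJ = -ln( (T / a_peak^2) * int j^2 dt ), invariant to displacement and
    duration, evaluated exactly with sympy.
    """
    import sympy as sp

    tau = sp.symbols("tau")
    a = 60 * tau - 180 * tau**2 + 120 * tau**3
    j = sp.diff(a, tau)
    int_j2 = sp.integrate(j**2, (tau, 0, 1))
    crit = sp.solve(sp.diff(a, tau), tau)
    a_peak = max(abs(a.subs(tau, c)) for c in crit + [sp.Integer(0), sp.Integer(1)])
    dlj = int_j2 / a_peak**2
    return float(-sp.log(dlj))
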