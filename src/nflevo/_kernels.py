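"""Numba kernels for forward-Euler integration of within-host dynamics.

State vector order is (P, R, A, I, U, D); interaction coefficients
arrive in the edge order of :data:`nflevo.genotypes.EDGES`:
(R,P), (A,R), (I,A), (U,A), (D,A), (R,U), (I,D), (P,I).

All kernels clamp every concentration to [0, 1] after each Euler step
and use plain IEEE double arithmetic (no fastmath) so results are
bit-reproducible and agree with the pure-Python scalar integrator.
"""

from __future__ import annotations

import numpy as np
from numba import njit

P, R, A, I, U, D = 0, 1, 2, 3, 4, 5
E_RP, E_AR, E_IA, E_UA, E_DA, E_RU, E_ID, E_PI = 0, 1, 2, 3, 4, 5, 6, 7


@njit(cache=True)
def _term(mu, yj, yi):
    """Sign-dependent saturating interaction term of one incoming edge."""
    if mu > 0.0:
        return mu * yj * (1.0 - yi)
    if mu < 0.0:
        return mu * yj * yi
    return 0.0


@njit(cache=True)
def _euler_step(y, mu, phi, pi, dt, force_ip):
    """Advance one individual's 6-species state by one clamped Euler step."""
    mu_pi = mu[E_PI]
    if force_ip and mu_pi < 0.0:
        mu_pi = -mu_pi
    dP = -mu_pi * y[I] * y[P] + pi * y[P] * (1.0 - y[P])
    dR = -phi[0] * y[R] + _term(mu[E_RP], y[P], y[R]) + _term(mu[E_RU], y[U], y[R])
    dA = -phi[1] * y[A] + _term(mu[E_AR], y[R], y[A])
    dI = -phi[2] * y[I] + _term(mu[E_IA], y[A], y[I]) + _term(mu[E_ID], y[D], y[I])
    dU = -phi[3] * y[U] + _term(mu[E_UA], y[A], y[U])
    dD = -phi[4] * y[D] + _term(mu[E_DA], y[A], y[D])
    y[P] += dt * dP
    y[R] += dt * dR
    y[A] += dt * dA
    y[I] += dt * dI
    y[U] += dt * dU
    y[D] += dt * dD
    for s in range(6):
        if y[s] < 0.0:
            y[s] = 0.0
        elif y[s] > 1.0:
            y[s] = 1.0


@njit(cache=True)
def trajectories(mu, phi, pi, P0, infected, n_steps, dt, force_ip):
    """Full trajectories for a batch of individuals.

    mu: (m, 8); phi: (m, 5); pi, P0: (m,); infected: (m,) bool.
    Returns (m, n_steps + 1, 6) including the initial state.
    """
    m = mu.shape[0]
    out = np.zeros((m, n_steps + 1, 6))
    for k in range(m):
        y = np.zeros(6)
        if infected[k]:
            y[P] = P0[k]
        out[k, 0] = y
        for step in range(n_steps):
            _euler_step(y, mu[k], phi[k], pi[k], dt, force_ip)
            out[k, step + 1] = y
    return out


@njit(cache=True)
def time_averages(mu, phi, pi, P0, n_steps, dt, force_ip):
    """Lifetime means of P and I for a batch of infected individuals.

    mu: (m, 8); phi: (5,); pi, P0 scalar.  Returns (m, 2) columns
    (P_bar, I_bar), each the mean over the stored grid of n_steps + 1
    points, matching the full-trajectory kernel exactly.
    """
    m = mu.shape[0]
    out = np.empty((m, 2))
    for k in range(m):
        y = np.zeros(6)
        y[P] = P0
        sP = y[P]
        sI = y[I]
        for step in range(n_steps):
            _euler_step(y, mu[k], phi, pi, dt, force_ip)
            sP += y[P]
            sI += y[I]
        out[k, 0] = sP / (n_steps + 1)
        out[k, 1] = sI / (n_steps + 1)
    return out
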