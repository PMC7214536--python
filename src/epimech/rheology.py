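"""Viscoelastic rest-length remodelling.

Each vertex segment's viscoelastic branch carries a dynamic rest length L
obeying

    (1/L) dL/dt = γ ((l − L)/L − ε_c)

so L remodels until the strain (l − L)/L reaches the intrinsic
contractility ε_c; for ε_c = 0 the branch responds like a Maxwell fluid.
Time discretisation uses a θ-weighted scheme that is second-order accurate
and unconditionally stable at θ = 1/2, and — crucially — is linear in
L_{n+1}, so the update can be substituted symbolically into the equilibrium
residual (`rest_affine` in :func:`epimech.mechanics.assemble`), keeping the
Newton solve fully implicit.
"""

from __future__ import annotations

import numpy as np

__all__ = ["rest_length_rate", "theta_update", "rest_affine_coefficients"]


class RestLengthStabilityError(ArithmeticError):
    """The θ-scheme denominator is non-positive (pathological Δt·γ)."""


def rest_length_rate(l, L, gamma: float, eps_c: float):
    """dL/dt = γ (l − L(1 + ε_c)); zero exactly when (l−L)/L = ε_c."""
    L = np.asarray(L, dtype=float)
    if np.any(L <= 0):
        raise ValueError("rest length must be positive")
    return gamma * (np.asarray(l, dtype=float) - L * (1.0 + eps_c))


def rest_affine_coefficients(l_n, L_n, dt: float, theta: float, gamma: float, eps_c: float):
    """Coefficients (a, c) of the implicit update L_{n+1} = a + c·l_{n+1}.

    Rearranging the θ-weighted discretisation,

        L_{n+1} [1 + Δtγθ(1+ε_c)] = L_n [1 − Δtγ(1−θ)(1+ε_c)] + Δtγ l_{n+θ}

    with l_{n+θ} = (1−θ) l_n + θ l_{n+1}.
    """
    eps_c = np.asarray(eps_c, dtype=float)
    den = 1.0 + dt * gamma * theta * (1.0 + eps_c)
    if np.any(den <= 0.0):
        raise RestLengthStabilityError(
            f"theta-scheme denominator {np.min(den):.3g} <= 0"
        )
    l_n = np.asarray(l_n, dtype=float)
    L_n = np.asarray(L_n, dtype=float)
    a = (
        L_n * (1.0 - dt * gamma * (1.0 - theta) * (1.0 + eps_c))
        + dt * gamma * (1.0 - theta) * l_n
    ) / den
    c = np.broadcast_to(dt * gamma * theta / den, a.shape).copy()
    return a, c


def theta_update(l_n, l_np1, L_n, dt: float, theta: float, gamma: float, eps_c: float):
    """Advance the rest length one step; unique root of the linear relation."""
    L_n = np.asarray(L_n, dtype=float)
    if np.any(L_n <= 0):
        raise ValueError("rest length must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    a, c = rest_affine_coefficients(l_n, L_n, dt, theta, gamma, eps_c)
    return a + c * np.asarray(l_np1, dtype=float)
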