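"""Shared stiff-ODE driver.

BDF with an explicit small first step: scipy's automatic initial-step
heuristic can abort immediately on states that mix particle counts (~1e12)
with milligram amounts, and LSODA's dense output occasionally emits
non-monotone step sequences on short intervals.
"""

from __future__ import annotations

from scipy.integrate import solve_ivp


def solve_stiff(rhs, t_span, y0, *, args=(), events=None, rtol=1e-8, atol=1e-12,
                first_step=None, jac_sparsity=None):
    span = t_span[1] - t_span[0]
    if first_step is None:
        first_step = max(min(1e-6 * span, span / 2), 1e-12)
    sol = solve_ivp(rhs, t_span, y0, method="BDF", args=args, events=events,
                    dense_output=True, rtol=rtol, atol=atol, first_step=first_step,
                    jac_sparsity=jac_sparsity)
    if not sol.success:
        sol = solve_ivp(rhs, t_span, y0, method="Radau", args=args, events=events,
                        dense_output=True, rtol=rtol, atol=atol, first_step=first_step)
    return sol


def probe_sparsity(rhs, y_examples, args=()):
    """Structural Jacobian sparsity by finite differences at probe states.

    Probe states should exercise every regime branch (e.g. sub- and
    supersaturated) so that clamp-gated couplings are captured.
    """
    import numpy as np

    mask = None
    for y in y_examples:
        y = np.asarray(y, dtype=float)
        f0 = rhs(0.0, y, *args)
        J = np.zeros((y.size, y.size), dtype=bool)
        for j in range(y.size):
            dy = y.copy()
            h = max(abs(y[j]) * 1e-6, 1e-9)
            dy[j] += h
            J[:, j] = np.abs(rhs(0.0, dy, *args) - f0) > 0
        mask = J if mask is None else (mask | J)
    mask |= np.eye(mask.shape[0], dtype=bool)
    return mask
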