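"""Compiled adaptive Runge-Kutta integration for the model bank.

Nested sampling spends essentially all of its time solving small ODE
systems, one solve per likelihood evaluation, so the right-hand sides and
the integrator are compiled with numba.  The integrator is an embedded
Dormand-Prince 5(4) pair with proportional step-size control; steps are
clamped so every requested output time is hit exactly (no dense-output
interpolation error enters the likelihood).

A solve *fails* — returning ``ok = False`` instead of raising — when the
step count budget is exhausted, the state leaves a large finite bound, or
anything becomes non-finite.  Callers map failure to a log-likelihood of
``-inf``, which the sampler treats as an excluded region of parameter
space.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["dp45_solve", "MAX_STEPS_DEFAULT", "STATE_BOUND_DEFAULT"]

MAX_STEPS_DEFAULT = 20_000
STATE_BOUND_DEFAULT = 1e8

# Dormand-Prince (RK45) Butcher tableau
_C = np.array([0.0, 1 / 5, 3 / 10, 4 / 5, 8 / 9, 1.0, 1.0])
_A = np.zeros((7, 7))
_A[1, 0] = 1 / 5
_A[2, :2] = (3 / 40, 9 / 40)
_A[3, :3] = (44 / 45, -56 / 15, 32 / 9)
_A[4, :4] = (19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729)
_A[5, :5] = (9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656)
_A[6, :6] = (35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84)
_B5 = np.array([35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84, 0.0])
_B4 = np.array(
    [5179 / 57600, 0.0, 7571 / 16695, 393 / 640, -92097 / 339200, 187 / 2100, 1 / 40]
)
_E = _B5 - _B4  # local error weights


@njit(cache=True)
def _dp45_core(rhs, params, y0, t_eval, rtol, atol, max_steps, y_bound, A, C, B5, E):
    n = y0.shape[0]
    m = t_eval.shape[0]
    out = np.empty((m, n))
    y = y0.copy()
    t = t_eval[0]
    out[0] = y
    k = np.empty((7, n))
    ytmp = np.empty(n)
    # initial step: a small fraction of the full span
    span = t_eval[m - 1] - t
    if span <= 0.0:
        for j in range(1, m):
            out[j] = y
        return out, True
    h = span / 100.0
    hmax = span / 4.0
    nsteps = 0
    idx = 1
    rhs(t, y, params, k[0])
    while idx < m:
        if nsteps >= max_steps:
            return out, False
        t_next = t_eval[idx]
        hit = False
        if t + h >= t_next:
            h = t_next - t
            hit = True
        # seven stages (FSAL: k[6] becomes next k[0] on acceptance)
        for s in range(1, 7):
            for i in range(n):
                acc = 0.0
                for q in range(s):
                    acc += A[s, q] * k[q, i]
                ytmp[i] = y[i] + h * acc
            rhs(t + C[s] * h, ytmp, params, k[s])
        # 5th order solution and embedded error estimate
        errnorm = 0.0
        ok_vals = True
        for i in range(n):
            acc5 = 0.0
            erri = 0.0
            for q in range(7):
                acc5 += B5[q] * k[q, i]
                erri += E[q] * k[q, i]
            ynew_i = y[i] + h * acc5
            ytmp[i] = ynew_i
            if not np.isfinite(ynew_i) or abs(ynew_i) > y_bound:
                ok_vals = False
            sc = atol + rtol * max(abs(y[i]), abs(ynew_i))
            e = h * erri / sc
            errnorm += e * e
        errnorm = np.sqrt(errnorm / n)
        nsteps += 1
        if ok_vals and errnorm <= 1.0:
            t = t + h
            y[:] = ytmp
            k[0] = k[6]
            if hit:
                out[idx] = y
                idx += 1
            fac = 5.0
            if errnorm > 1e-10:
                fac = 0.9 * errnorm ** (-0.2)
                if fac > 5.0:
                    fac = 5.0
            h = h * fac
            if h > hmax:
                h = hmax
        else:
            if not ok_vals:
                h = h * 0.1
            else:
                fac = 0.9 * errnorm ** (-0.2)
                if fac < 0.1:
                    fac = 0.1
                h = h * fac
            if h < 1e-14 * span or not np.isfinite(h):
                return out, False
    return out, True


def dp45_solve(
    rhs,
    params: np.ndarray,
    y0: np.ndarray,
    t_eval: np.ndarray,
    rtol: float = 1e-6,
    atol: float = 1e-8,
    max_steps: int = MAX_STEPS_DEFAULT,
    y_bound: float = STATE_BOUND_DEFAULT,
):
    """Integrate ``rhs`` from ``t_eval[0]`` hitting every time in ``t_eval``.

    Parameters
    ----------
    rhs
        numba-compiled ``rhs(t, y, params, dy)`` writing derivatives into
        ``dy``.
    params
        Kinetic-parameter array handed through to ``rhs``.
    y0
        Initial state at ``t_eval[0]``.
    t_eval
        Non-decreasing output times; the first entry is the initial time.

    Returns
    -------
    (states, ok)
        ``states`` has shape ``(len(t_eval), len(y0))``; ``ok`` is False
        on failure, in which case ``states`` is only partially filled.
    """
    y0 = np.ascontiguousarray(y0, dtype=np.float64)
    t_eval = np.ascontiguousarray(t_eval, dtype=np.float64)
    params = np.ascontiguousarray(params, dtype=np.float64)
    if np.any(np.diff(t_eval) < 0):
        raise ValueError("t_eval must be non-decreasing")
    if not np.all(np.isfinite(y0)) or not np.all(np.isfinite(params)):
        return np.full((len(t_eval), len(y0)), np.nan), False
    return _dp45_core(
        rhs, params, y0, t_eval, rtol, atol, max_steps, y_bound, _A, _C, _B5, _E
    )
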