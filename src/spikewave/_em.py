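"""Fixed-step Euler-Maruyama stepping kernel.

The inner loop is compiled with numba when available (it dominates the
runtime of the basin and stimulation scans, which integrate tens of
thousands of short trajectories); the pure-Python definition is the
reference semantics and is used unchanged if compilation is
unavailable.

Parameter packing order for the kernel:
    [c1..c9, tau_py, tau_in, tau_tc, tau_re, h_py, h_in, h_tc, h_re,
     ln_epsilon, a_lin, b_lin]
plus a flag selecting linear (1) or sigmoid (0) thalamic activation.
"""

from __future__ import annotations

import math

import numpy as np

from .model import ModelParameters


def pack_params(p: ModelParameters) -> np.ndarray:
    return np.array(
        [
            p.c1, p.c2, p.c3, p.c4, p.c5, p.c6, p.c7, p.c8, p.c9,
            p.tau_py, p.tau_in, p.tau_tc, p.tau_re,
            p.h_py, p.h_in, p.h_tc, p.h_re,
            math.log(p.epsilon), p.a_lin, p.b_lin,
        ],
        dtype=np.float64,
    )


def _sig(u, ln_eps):
    z = u * ln_eps
    if z >= 0.0:
        return 1.0 / (1.0 + math.exp(-z))
    e = math.exp(z)
    return e / (1.0 + e)


def _em_path(x0, pv, linear, dt, dw, thin, out):
    """March len(dw) EM steps from x0; write every `thin`-th state to out.

    dw holds the pre-scaled Gaussian increments (sd * sqrt(dt) * xi)
    added to the TC component. out must have shape (len(dw)//thin + 1, 4).
    Returns 0 on success, or the 1-based step index at which the state
    became non-finite.
    """
    py = x0[0]
    inh = x0[1]
    tc = x0[2]
    re = x0[3]
    ln_eps = pv[17]
    a = pv[18]
    b = pv[19]
    out[0, 0] = py
    out[0, 1] = inh
    out[0, 2] = tc
    out[0, 3] = re
    j = 1
    for i in range(dw.shape[0]):
        f_py = _sig(py, ln_eps)
        f_in = _sig(inh, ln_eps)
        f_tc = _sig(tc, ln_eps)
        if linear:
            s_tc = a * tc + b
            s_re = a * re + b
        else:
            s_tc = f_tc
            s_re = _sig(re, ln_eps)
        d_py = pv[9] * (pv[13] - py + pv[0] * f_py - pv[2] * f_in + pv[8] * f_tc)
        d_in = pv[10] * (pv[14] - inh + pv[1] * f_py)
        d_tc = pv[11] * (pv[15] - tc + pv[6] * f_py - pv[5] * s_re)
        d_re = pv[12] * (pv[16] - re + pv[7] * f_py + pv[4] * s_tc - pv[3] * s_re)
        py += dt * d_py
        inh += dt * d_in
        tc += dt * d_tc + dw[i]
        re += dt * d_re
        if not (math.isfinite(py) and math.isfinite(inh)
                and math.isfinite(tc) and math.isfinite(re)):
            return i + 1
        if (i + 1) % thin == 0:
            out[j, 0] = py
            out[j, 1] = inh
            out[j, 2] = tc
            out[j, 3] = re
            j += 1
    return 0


try:  # compile when numba is present; fall back to the pure-Python loop
    from numba import njit

    _sig = njit(cache=True, fastmath=False)(_sig)
    em_path = njit(cache=True, fastmath=False)(_em_path)
except ImportError:  # pragma: no cover - exercised only without numba
    em_path = _em_path
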