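"""Fixed-step explicit Euler kernel for the within-culture infection ODEs.

Compiled with numba for speed: a 20-time-unit culture phase at the default
step of 0.001 is 20,000 steps, and burst-size sweeps integrate tens of
thousands of such phases.  The kernel advances free phage P[i], infected
cells I[i, j] and uninfected cells C[j] in place and reports a status code
instead of raising, so the Python wrapper can attach context.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: status codes returned by :func:`euler_advance`
OK = 0
NEGATIVE = 1  # a density undershot 0 beyond the clamp tolerance
NONFINITE = 2  # a density became NaN or infinite

#: relative clamp tolerance: undershoots smaller than this fraction of the
#: total density are treated as roundoff and clamped to zero
CLAMP_REL = 1e-12


@njit(cache=False)
def euler_advance(P, I, C, b, lam, k, r, dt, nsteps):  # pragma: no cover - jitted
    """Advance the culture state by ``nsteps`` Euler steps of size ``dt``.

    Arrays are modified in place.  Returns ``(status, step_index)`` where
    ``status`` is OK, NEGATIVE or NONFINITE and ``step_index`` locates the
    first offending step (or -1 on success).
    """
    nP = P.shape[0]
    nH = C.shape[0]
    dP = np.empty(nP)
    dI = np.empty((nP, nH))
    dC = np.empty(nH)
    for s in range(nsteps):
        for i in range(nP):
            dP[i] = 0.0
        for j in range(nH):
            dC[j] = r[j] * C[j]
            for i in range(nP):
                ads = k[i, j] * P[i] * C[j]
                dP[i] += b[i, j] * lam[i, j] * I[i, j] - ads
                dI[i, j] = ads - lam[i, j] * I[i, j]
                dC[j] -= ads
        total = 0.0
        for i in range(nP):
            P[i] += dt * dP[i]
            total += P[i]
            for j in range(nH):
                I[i, j] += dt * dI[i, j]
                total += I[i, j]
        for j in range(nH):
            C[j] += dt * dC[j]
            total += C[j]
        if not np.isfinite(total):
            return NONFINITE, s
        tol = CLAMP_REL * abs(total)
        for i in range(nP):
            if P[i] < 0.0:
                if -P[i] <= tol:
                    P[i] = 0.0
                else:
                    return NEGATIVE, s
            for j in range(nH):
                if I[i, j] < 0.0:
                    if -I[i, j] <= tol:
                        I[i, j] = 0.0
                    else:
                        return NEGATIVE, s
        for j in range(nH):
            if C[j] < 0.0:
                if -C[j] <= tol:
                    C[j] = 0.0
                else:
                    return NEGATIVE, s
    return OK, -1
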