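"""Small central-difference derivative helpers.

Used for the 2-D inner (per-subject) Newton steps of the Laplace
approximation and for the outer-problem Hessian behind relative standard
errors.  Step sizes are relative where the point is away from zero.
"""

from __future__ import annotations

import numpy as np


def gradient(f, x, h=1e-5):
    """Central-difference gradient of scalar ``f`` at 1-D point ``x``."""
    x = np.asarray(x, float)
    g = np.zeros_like(x)
    for i in range(len(x)):
        hi = h * max(1.0, abs(x[i]))
        xp = x.copy()
        xm = x.copy()
        xp[i] += hi
        xm[i] -= hi
        g[i] = (f(xp) - f(xm)) / (2 * hi)
    return g


def hessian(f, x, h=1e-4):
    """Central-difference Hessian of scalar ``f`` at 1-D point ``x``."""
    x = np.asarray(x, float)
    n = len(x)
    H = np.zeros((n, n))
    steps = np.array([h * max(1.0, abs(xi)) for xi in x])
    f0 = f(x)
    for i in range(n):
        xp = x.copy()
        xm = x.copy()
        xp[i] += steps[i]
        xm[i] -= steps[i]
        H[i, i] = (f(xp) - 2 * f0 + f(xm)) / steps[i] ** 2
    for i in range(n):
        for j in range(i + 1, n):
            xpp = x.copy()
            xpm = x.copy()
            xmp = x.copy()
            xmm = x.copy()
            xpp[[i, j]] += [steps[i], steps[j]]
            xpm[i] += steps[i]
            xpm[j] -= steps[j]
            xmp[i] -= steps[i]
            xmp[j] += steps[j]
            xmm[[i, j]] -= [steps[i], steps[j]]
            H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (
                4 * steps[i] * steps[j]
            )
    return H
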