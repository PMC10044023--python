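"""Independent numerical oracles for the closed-form PK computations.

``grid_concentrations`` advances the one-compartment ODE on a uniform
1e-3 h grid with an exact per-step update (the infusion rate is constant
within a step when dose times are grid-aligned), giving a dense reference
curve without using the superposition/segment machinery under test.  AUC is
then composite-trapezoid on that grid and time-above-MIC a grid count.
``ode_concentrations`` integrates the differential equation directly with
an adaptive Runge-Kutta solver as a fully independent cross-check.
"""

import numpy as np
from scipy.integrate import solve_ivp


def grid_concentrations(ip, regimen, t_end, dt=1e-3):
    """Dense concentrations on [0, t_end] by exact stepwise advance."""
    n = int(round(t_end / dt))
    rate = np.zeros(n)
    for d in regimen.doses:
        i0 = int(round(d.time / dt))
        i1 = int(round((d.time + d.duration) / dt))
        rate[i0:min(i1, n)] += d.rate
    ke = ip.cl / ip.v
    decay = np.exp(-ke * dt)
    gain = (1.0 - decay) / ip.cl
    c = np.empty(n + 1)
    c[0] = 0.0
    for i in range(n):
        c[i + 1] = c[i] * decay + rate[i] * gain
    return np.arange(n + 1) * dt, c


def grid_auc(times, conc, t0, t1):
    """Composite trapezoid over the grid window [t0, t1]."""
    m = (times >= t0 - 1e-12) & (times <= t1 + 1e-12)
    return float(np.trapezoid(conc[m], times[m]))


def grid_time_above(times, conc, mic, t0, t1):
    """Measure of {C > mic} from the dense grid, with linear interpolation
    of the crossing position inside each straddled cell."""
    dt = times[1] - times[0]
    m = (times >= t0 - 1e-12) & (times <= t1 + 1e-12)
    c = conc[m]
    above = c > mic
    both = above[:-1] & above[1:]
    total = float(both.sum()) * dt
    crossing = above[:-1] != above[1:]
    if crossing.any():
        c0 = c[:-1][crossing]
        c1 = c[1:][crossing]
        frac = np.abs((c0 - mic) / (c0 - c1))  # portion of the cell above
        up = ~above[:-1][crossing]  # rising crossing: above part at the end
        total += float(np.where(up, 1 - frac, frac).sum()) * dt
    return total


def grid_concentrations_batch(ips, regimens, t_end, dt=1e-3):
    """Vectorised stepwise advance for many (subject, regimen) instances.

    Returns ``times, conc`` with ``conc`` of shape (n_instances, n_steps+1).
    Dose times and durations must be multiples of ``dt``.
    """
    n = int(round(t_end / dt))
    n_inst = len(ips)
    rate = np.zeros((n_inst, n))
    ke = np.empty(n_inst)
    inv_cl = np.empty(n_inst)
    for j, (ip, reg) in enumerate(zip(ips, regimens)):
        for d in reg.doses:
            i0 = int(round(d.time / dt))
            i1 = int(round((d.time + d.duration) / dt))
            rate[j, i0:min(i1, n)] += d.rate
        ke[j] = ip.cl / ip.v
        inv_cl[j] = 1.0 / ip.cl
    decay = np.exp(-ke * dt)
    gain = (1.0 - decay) * inv_cl
    conc = np.empty((n_inst, n + 1))
    conc[:, 0] = 0.0
    c = np.zeros(n_inst)
    for i in range(n):
        c = c * decay + rate[:, i] * gain
        conc[:, i + 1] = c
    return np.arange(n + 1) * dt, conc


def ode_concentrations(ip, regimen, t_eval):
    """Adaptive RK integration of dC/dt = input/V - ke*C, piecewise in the
    infusion breakpoints so the discontinuous input is handled exactly."""
    ke = ip.cl / ip.v
    bps = sorted({d.time for d in regimen.doses}
                 | {d.time + d.duration for d in regimen.doses}
                 | {0.0, float(max(t_eval)) + 1e-9})

    def rate_at(t):
        return sum(d.rate for d in regimen.doses if d.time <= t < d.time + d.duration)

    t_eval = np.asarray(t_eval, float)
    out = np.empty_like(t_eval)
    c0 = 0.0
    for lo, hi in zip(bps[:-1], bps[1:]):
        r = rate_at(0.5 * (lo + hi))

        def rhs(t, y, r=r):
            return [r / ip.v - ke * y[0]]

        inside = (t_eval >= lo) & (t_eval < hi)
        pts = np.sort(t_eval[inside])
        sol = solve_ivp(rhs, (lo, hi), [c0], t_eval=np.unique(np.r_[pts, hi]),
                        rtol=1e-11, atol=1e-12, method="DOP853")
        for t in t_eval[inside]:
            out[np.isclose(t_eval, t) & inside] = sol.y[0][
                np.argmin(np.abs(sol.t - t))
            ]
        c0 = sol.y[0][-1]
    return out
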