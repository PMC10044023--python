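"""Vectorised one-compartment infusion kinetics.

Two access patterns back the estimation and Monte Carlo layers:

* :func:`conc_padded` — concentrations at arbitrary observation times for many
  subjects with heterogeneous (zero-padded) dose schedules; used by the
  mixed-effects likelihood, where each subject contributes a handful of
  sampled concentrations.
* :func:`time_above_mic_shared` / :func:`auc_shared` — exact time-above-MIC
  and AUC for a *shared* regimen evaluated across an array of (CL, V) draws;
  used by the Monte Carlo PTA engine where thousands of virtual subjects
  receive the same exact-interval schedule.

Both reuse the closed-form segment representation of
:class:`~ceftazpk.pk_model.ConcentrationProfile`: with a common elimination
rate constant per subject, concentration between infusion breakpoints is
``A + E * exp(-ke * dt)`` and all queries are analytic.
"""

from __future__ import annotations

import numpy as np

from .pk_model import Regimen


def conc_padded(times, dose_start, dose_dur, dose_rate, cl, v):
    """Concentrations for padded per-subject dose schedules.

    Parameters
    ----------
    times : (S, T) observation times in hours (NaN allowed for padding).
    dose_start, dose_dur, dose_rate : (S, D) schedules; pad with rate 0.
    cl, v : (S,) individual clearance (L/h) and volume (L).

    Returns
    -------
    (S, T) concentrations in mg/L (NaN where ``times`` is NaN).
    """
    times = np.asarray(times, float)
    cl = np.asarray(cl, float)[:, None, None]
    v = np.asarray(v, float)[:, None, None]
    ke = cl / v
    ts = np.asarray(dose_start, float)[:, None, :]
    dur = np.asarray(dose_dur, float)[:, None, :]
    rate = np.asarray(dose_rate, float)[:, None, :]
    t = times[:, :, None]

    el = t - ts  # time since infusion start
    with np.errstate(invalid="ignore"):
        during = (el >= 0) & (el < dur)
        after = el >= dur
        # during infusion: (R/CL)(1 - e^{-ke*el}); after: value at end decayed
        c_dur = (rate / cl) * (-np.expm1(-ke * np.where(during, el, 0.0)))
        c_aft = (
            (rate / cl)
            * (-np.expm1(-ke * dur))
            * np.exp(-ke * np.where(after, el - dur, 0.0))
        )
        contrib = np.where(during, c_dur, 0.0) + np.where(after, c_aft, 0.0)
    return contrib.sum(axis=2)


def _shared_segments(regimen: Regimen):
    """Breakpoints, per-segment active rate sums for a shared regimen."""
    starts = np.array([d.time for d in regimen.doses])
    ends = np.array([d.end for d in regimen.doses])
    rates = np.array([d.rate for d in regimen.doses])
    bp = np.unique(np.concatenate([starts, ends]))
    active = (starts[None, :] <= bp[:, None]) & (bp[:, None] < ends[None, :])
    rate_sum = active @ rates
    return bp, rate_sum


def _segment_coeffs(regimen: Regimen, cl, v):
    """Per-segment (A, E) arrays of shape (K, N) plus breakpoints for N subjects."""
    cl = np.asarray(cl, float)
    v = np.asarray(v, float)
    ke = cl / v
    bp, rate_sum = _shared_segments(regimen)
    K = len(bp)
    A = rate_sum[:, None] / cl[None, :]
    E = np.empty((K, len(cl)))
    c = np.zeros(len(cl))
    for k in range(K):
        E[k] = c - A[k]
        if k + 1 < K:
            c = A[k] + E[k] * np.exp(-ke * (bp[k + 1] - bp[k]))
    return bp, A, E, ke


def time_above_mic_shared(cl, v, regimen: Regimen, mic: float, t_start: float, t_end: float):
    """Hours with C(t) > mic over [t_start, t_end] for each (cl, v) pair."""
    if mic < 0:
        raise ValueError("mic must be non-negative")
    if not t_start < t_end:
        raise ValueError("t_start must be < t_end")
    bp, A, E, ke = _segment_coeffs(regimen, cl, v)
    total = np.zeros_like(ke)
    for k in range(len(bp)):
        seg_lo = bp[k]
        seg_hi = bp[k + 1] if k + 1 < len(bp) else np.inf
        lo = max(t_start, seg_lo)
        hi = min(t_end, seg_hi)
        if hi <= lo:
            continue
        tau0 = lo - seg_lo
        tau1 = hi - seg_lo
        c0 = A[k] + E[k] * np.exp(-ke * tau0)
        c1 = A[k] + (E[k] * np.exp(-ke * tau1) if np.isfinite(tau1) else 0.0)
        above0 = c0 > mic
        above1 = c1 > mic
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = (mic - A[k]) / E[k]
            tau_x = np.where(ratio > 0, -np.log(np.where(ratio > 0, ratio, 1.0)) / ke, tau0)
        tau_x = np.clip(tau_x, tau0, tau1 if np.isfinite(tau1) else tau0 + 1e12)
        seg_time = np.where(
            above0 & above1,
            tau1 - tau0,
            np.where(
                above0 & ~above1,
                tau_x - tau0,
                np.where(~above0 & above1, tau1 - tau_x, 0.0),
            ),
        )
        total += seg_time
    return total


def auc_shared(cl, v, regimen: Regimen, t_start: float, t_end: float):
    """Exact AUC (mg*h/L) over [t_start, t_end] for each (cl, v) pair."""
    if not t_start < t_end:
        raise ValueError("t_start must be < t_end")
    bp, A, E, ke = _segment_coeffs(regimen, cl, v)
    total = np.zeros_like(ke)
    for k in range(len(bp)):
        seg_lo = bp[k]
        seg_hi = bp[k + 1] if k + 1 < len(bp) else np.inf
        lo = max(t_start, seg_lo)
        hi = min(t_end, seg_hi)
        if hi <= lo:
            continue
        tau0 = lo - seg_lo
        tau1 = hi - seg_lo
        e1 = np.exp(-ke * tau1) if np.isfinite(tau1) else 0.0
        total += A[k] * (tau1 - tau0) + (E[k] / ke) * (np.exp(-ke * tau0) - e1)
    return total
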