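"""Model-qualification diagnostics: prediction-corrected VPC and GOF tables.

The prediction-corrected visual predictive check (pcVPC) normalises each
observation (and each simulated observation) by the ratio of its bin's
median population prediction to its own population prediction, removing
covariate- and dose-driven heterogeneity before comparing percentiles.
Bins are quantile-based on time after the most recent dose; sparse bins
(fewer than 5 observations) are merged with a neighbour.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset_io import Dataset
from .estimation import _Bundle, _inner_laplace, model_components, _OMEGA_MIN, _SIGMA_MIN

__all__ = ["VPCResult", "pc_vpc", "gof_tables", "time_after_dose"]


def time_after_dose(ds: Dataset) -> pd.Series:
    """Hours since the most recent dose start, per observation row."""
    ev = ds.events
    out = pd.Series(np.nan, index=ev.index)
    for sid, grp in ev.groupby("ID", sort=False):
        dose_times = grp.loc[grp["EVID"] == 1, "TIME"].to_numpy(float)
        obs = grp[grp["EVID"] == 0]
        for idx, row in obs.iterrows():
            past = dose_times[dose_times <= row["TIME"]]
            out[idx] = row["TIME"] - past.max() if len(past) else np.nan
    return out[ev["EVID"] == 0]


@dataclass
class VPCResult:
    bin_edges: np.ndarray
    bin_mid: np.ndarray
    observed: pd.DataFrame  # per bin: p5, p50, p95 of prediction-corrected obs
    bands: dict  # percentile -> (lo, hi) arrays: 95% CI across simulations
    n_sim: int

    def n_bins(self) -> int:
        return len(self.bin_mid)

    def coverage(self) -> float:
        """Fraction of (bin, percentile) cells with the observed curve inside
        its simulated 95% band."""
        inside = total = 0
        for pct in (5, 50, 95):
            lo, hi = self.bands[pct]
            obs = self.observed[f"p{pct}"].to_numpy()
            ok = (obs >= lo) & (obs <= hi)
            inside += int(ok.sum())
            total += len(ok)
        return inside / total


def _merge_sparse_bins(edges, tad, min_per_bin=5):
    edges = list(edges)
    while len(edges) > 2:
        counts, _ = np.histogram(tad, bins=edges)
        if counts.min() >= min_per_bin:
            break
        k = int(np.argmin(counts))
        drop = k + 1 if k < len(counts) - 1 else k
        edges.pop(drop)
    counts, _ = np.histogram(tad, bins=edges)
    if (counts == 0).any():
        raise ValueError(f"empty VPC bin after merging; edges {edges}")
    return np.asarray(edges)


def pc_vpc(
    ds: Dataset,
    pop,
    n_sim: int = 1000,
    seed: int = 0,
    bins: int = 6,
    min_per_bin: int = 5,
) -> VPCResult:
    """Prediction-corrected VPC of a fitted model on a dataset.

    ``pop`` is a converged :class:`~ceftazpk.estimation.FitResult` or a
    :class:`~ceftazpk.pk_model.PopulationParameters`.  Deterministic under
    ``seed``.
    """
    if n_sim < 500:
        warnings.warn("VPC bands from fewer than 500 simulated replicates",
                      stacklevel=2)
    spec, theta_cl, theta_v, gammas, betas, w1, w2, sg = model_components(pop)
    bundle = _Bundle(ds, spec)
    rng = np.random.default_rng(seed)

    tv = bundle.typical_cl(theta_cl, gammas, betas)
    pred = bundle.conc(tv, np.full_like(tv, theta_v))  # population prediction
    mask = bundle.mask
    y = bundle.y[mask]
    pred_flat = np.maximum(pred[mask], 1e-9)
    tad_all = time_after_dose(ds)
    # align TAD with the bundle's (subject-major, time-sorted) layout
    obs_df = ds.observations()
    obs_df = obs_df[np.isfinite(obs_df["DV"].to_numpy(float))]
    tad = np.concatenate(
        [tad_all.loc[obs_df.index[obs_df["ID"] == sid]].to_numpy(float)
         for sid in bundle.ids]
    )

    qs = np.linspace(0, 1, bins + 1)
    edges = np.unique(np.quantile(tad, qs))
    edges[0] -= 1e-9
    edges[-1] += 1e-9
    edges = _merge_sparse_bins(edges, tad, min_per_bin)
    bin_idx = np.clip(np.searchsorted(edges, tad, side="right") - 1, 0,
                      len(edges) - 2)

    # prediction correction: scale by bin-median PRED / individual PRED
    bin_median_pred = np.array(
        [np.median(pred_flat[bin_idx == b]) for b in range(len(edges) - 1)]
    )
    correction = bin_median_pred[bin_idx] / pred_flat
    y_pc = y * correction

    S, T = bundle.mask.shape
    eta = rng.normal(0.0, 1.0, size=(n_sim, S, 2)) * np.array([w1, w2])
    cl = tv[None, :] * np.exp(eta[:, :, 0])
    v = theta_v * np.exp(eta[:, :, 1])
    f = bundle.conc(cl, v)  # (n_sim, S, T)
    eps = rng.normal(0.0, 1.0, size=f.shape)
    ysim = f * (1.0 + sg * eps)
    ysim = np.maximum(ysim, 0.0)[:, mask] * correction[None, :]

    pcts = (5, 50, 95)
    obs_rows = {}
    bands = {}
    nb = len(edges) - 1
    for pct in pcts:
        obs_rows[f"p{pct}"] = np.array(
            [np.percentile(y_pc[bin_idx == b], pct) for b in range(nb)]
        )
        sim_pct = np.stack(
            [np.percentile(ysim[:, bin_idx == b], pct, axis=1) for b in range(nb)],
            axis=1,
        )  # (n_sim, nb)
        bands[pct] = (
            np.percentile(sim_pct, 2.5, axis=0),
            np.percentile(sim_pct, 97.5, axis=0),
        )
    mids = 0.5 * (edges[:-1] + edges[1:])
    return VPCResult(
        bin_edges=np.asarray(edges), bin_mid=mids,
        observed=pd.DataFrame(obs_rows), bands=bands, n_sim=n_sim,
    )


def gof_tables(ds: Dataset, pop) -> dict:
    """Observed-vs-predicted and residual summaries.

    Returns a per-observation table (population prediction PRED, individual
    prediction IPRED from the empirical Bayes modes, residuals, individual
    weighted residuals and a conditional weighted residual approximation)
    plus scalar summaries (bias and RMSE on the log scale, identity-line
    correlation).
    """
    spec, theta_cl, theta_v, gammas, betas, w1, w2, sg = model_components(pop)
    bundle = _Bundle(ds, spec)
    tv = bundle.typical_cl(theta_cl, gammas, betas)
    omega2 = np.array([max(w1, _OMEGA_MIN) ** 2, max(w2, _OMEGA_MIN) ** 2])
    sg_eff = max(sg, _SIGMA_MIN)
    _, eta_hat, _ = _inner_laplace(
        bundle, tv, theta_v, omega2, sg_eff, np.zeros((len(bundle.ids), 2))
    )
    pred = bundle.conc(tv, np.full_like(tv, theta_v))
    ipred = bundle.conc(tv * np.exp(eta_hat[:, 0]), theta_v * np.exp(eta_hat[:, 1]))

    # FOCE-style conditional weighted residuals: linearise f in eta at the mode
    h = 1e-4
    S, T = bundle.mask.shape
    G_all = np.empty((S, T, 2))
    for k in range(2):
        ep = eta_hat.copy()
        em = eta_hat.copy()
        ep[:, k] += h
        em[:, k] -= h
        fp = bundle.conc(tv * np.exp(ep[:, 0]), theta_v * np.exp(ep[:, 1]))
        fm = bundle.conc(tv * np.exp(em[:, 0]), theta_v * np.exp(em[:, 1]))
        G_all[:, :, k] = (fp - fm) / (2 * h)

    rows = []
    for s, sid in enumerate(bundle.ids):
        m = bundle.mask[s]
        if not m.any():
            continue
        yobs = bundle.y[s, m]
        f_hat = np.maximum(ipred[s, m], 1e-9)
        G = G_all[s][m]
        cov = G @ np.diag(omega2) @ G.T + np.diag((sg_eff * f_hat) ** 2)
        resid = yobs - f_hat + G @ eta_hat[s]
        try:
            L = np.linalg.cholesky(cov)
            cwres = np.linalg.solve(L, resid)
        except np.linalg.LinAlgError:
            cwres = resid / np.sqrt(np.diag(cov))
        times = bundle.times[s, m]
        for j in range(m.sum()):
            rows.append({
                "ID": sid, "TIME": times[j], "DV": yobs[j],
                "PRED": pred[s, m][j], "IPRED": f_hat[j],
                "RES": yobs[j] - pred[s, m][j],
                "IWRES": (yobs[j] - f_hat[j]) / (sg_eff * f_hat[j]),
                "CWRES": cwres[j],
            })
    table = pd.DataFrame(rows)
    logr = np.log(np.maximum(table["DV"], 1e-9) / np.maximum(table["IPRED"], 1e-9))
    summary = {
        "bias_log": float(logr.mean()),
        "rmse_log": float(np.sqrt((logr**2).mean())),
        "corr_obs_pred": float(np.corrcoef(table["DV"], table["PRED"])[0, 1]),
        "corr_obs_ipred": float(np.corrcoef(table["DV"], table["IPRED"])[0, 1]),
        "n_obs": int(len(table)),
    }
    return {"observations": table, "summary": summary}
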