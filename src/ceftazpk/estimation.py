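"""Nonlinear mixed-effects estimation of the population PK model.

The marginal likelihood is approximated by the Laplace method: for each
subject the joint negative log-density of observations and random effects is
minimised over the 2-D random-effect vector (an inner Newton problem, run
batched across subjects), and the curvature at the mode supplies the
Gaussian-integral correction.  The outer problem — fixed effects, covariate
coefficients, variance components — is solved with a derivative-free
Nelder-Mead search over a log-transformed parameter vector.

Covariates enter clearance the way the final model does: continuous
covariates as power functions normalised to a reference value (the dataset
median by default) and binary covariates as multiplicative factors.
Covariate selection runs a univariate likelihood-ratio screen followed by a
multivariate backward elimination at a stricter significance level.

Relative standard errors come from a finite-difference Hessian of the
objective at the optimum; eta shrinkage is 1 - SD(EBE)/omega.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import _numdiff
from .dataset_io import Dataset, renal_group
from .pk_model import PopulationParameters

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "FitResult",
    "CovariateStepReport",
    "fit",
    "covariate_step",
    "empirical_bayes",
    "bootstrap",
]

_LOG2PI = math.log(2.0 * math.pi)
_OMEGA_MIN, _OMEGA_MAX = 1e-8, 5.0
_SIGMA_MIN, _SIGMA_MAX = 1e-8, 2.0
#: smooth lower floors for *freely estimated* variance components; they
#: close the degenerate sigma -> 0 likelihood valley (0.5% is well below
#: the assay's reported precision).  Fixed values bypass the floors.
_FREE_SIGMA_FLOOR = 0.005
_FREE_OMEGA_FLOOR = 1e-3
_F_FLOOR = 1e-6  # mg/L floor for model predictions inside the likelihood


@dataclass(frozen=True)
class ModelSpec:
    """Structure of the covariate model on clearance."""

    continuous_cl: tuple = ()
    binary_cl: tuple = ()
    refs: dict | None = None  # reference values; dataset medians when None

    def with_candidate(self, name: str, kind: str) -> "ModelSpec":
        if kind == "continuous":
            return replace(self, continuous_cl=self.continuous_cl + (name,))
        return replace(self, binary_cl=self.binary_cl + (name,))

    def without(self, name: str) -> "ModelSpec":
        return replace(
            self,
            continuous_cl=tuple(c for c in self.continuous_cl if c != name),
            binary_cl=tuple(c for c in self.binary_cl if c != name),
        )

    @property
    def covariates(self) -> tuple:
        return self.continuous_cl + self.binary_cl


FINAL_MODEL_SPEC = ModelSpec(continuous_cl=("EGFR_CKDEPI",), binary_cl=("ABX",))


@dataclass
class FitResult:
    """Laplace-fit output: estimates, precision and diagnostics."""

    theta_cl: float
    theta_v: float
    gammas: dict
    betas: dict
    omega_cl: float
    omega_v: float
    sigma_prop: float
    refs: dict
    ofv: float
    converged: bool
    message: str
    n_subjects: int
    n_obs: int
    rse_percent: dict = field(default_factory=dict)
    shrinkage_percent: dict = field(default_factory=dict)
    etas: pd.DataFrame | None = None
    n_evaluations: int = 0

    @property
    def iiv_cl_percent_cv(self) -> float:
        return 100.0 * self.omega_cl

    @property
    def iiv_v_percent_cv(self) -> float:
        return 100.0 * self.omega_v

    def estimates(self) -> dict:
        out = {"theta_cl": self.theta_cl, "theta_v": self.theta_v,
               "omega_cl": self.omega_cl, "omega_v": self.omega_v,
               "sigma_prop": self.sigma_prop}
        out.update({f"gamma_{k}": v for k, v in self.gammas.items()})
        out.update({f"beta_{k}": v for k, v in self.betas.items()})
        return out

    def to_population_parameters(self) -> PopulationParameters:
        """Map a final-structure fit (eGFR power + antibiotic factor) onto
        :class:`PopulationParameters`; raises for other covariate structures."""
        if set(self.gammas) - {"EGFR_CKDEPI"} or set(self.betas) - {"ABX"}:
            raise ValueError("fit does not have the final-model covariate structure")
        return PopulationParameters(
            theta_cl=self.theta_cl,
            theta_v=self.theta_v,
            gamma_egfr=self.gammas.get("EGFR_CKDEPI", 0.0),
            theta_abx=self.betas.get("ABX", 1.0),
            egfr_ref=self.refs.get("EGFR_CKDEPI", 76.86),
            omega_cl=self.omega_cl,
            omega_v=self.omega_v,
            sigma_prop=self.sigma_prop,
        )


# ----------------------------------------------------------------------
# data bundle: padded arrays for vectorised likelihood evaluation
# ----------------------------------------------------------------------

class _Bundle:
    def __init__(self, ds: Dataset, spec: ModelSpec):
        obs = ds.observations()
        obs = obs[np.isfinite(obs["DV"].to_numpy(float))]
        doses = ds.doses()
        ids = ds.subject_ids
        S = len(ids)
        T = max((obs["ID"] == sid).sum() for sid in ids) if len(obs) else 1
        T = max(T, 1)
        D = max((doses["ID"] == sid).sum() for sid in ids)

        self.ids = ids
        self.times = np.full((S, T), np.nan)
        self.y = np.full((S, T), np.nan)
        self.mask = np.zeros((S, T), bool)
        self.dose_start = np.zeros((S, D))
        self.dose_dur = np.full((S, D), 1.0)
        self.dose_rate = np.zeros((S, D))

        needed = list(spec.continuous_cl + spec.binary_cl)
        cov = ds.events.groupby("ID", sort=False)[needed].first() if needed else None
        self.refs = dict(spec.refs or {})
        for name in spec.continuous_cl:
            self.refs.setdefault(name, float(cov[name].median()))
        self.cont = {
            name: cov[name].to_numpy(float) / self.refs[name]
            for name in spec.continuous_cl
        }
        self.flags = {name: cov[name].to_numpy(float) for name in spec.binary_cl}

        for s, sid in enumerate(ids):
            o = obs[obs["ID"] == sid]
            k = len(o)
            self.times[s, :k] = o["TIME"].to_numpy(float)
            self.y[s, :k] = o["DV"].to_numpy(float)
            self.mask[s, :k] = True
            d = doses[doses["ID"] == sid]
            kd = len(d)
            self.dose_start[s, :kd] = d["TIME"].to_numpy(float)
            self.dose_dur[s, :kd] = d["DUR"].to_numpy(float)
            self.dose_rate[s, :kd] = (d["AMT"] / d["DUR"]).to_numpy(float)

        self.n_obs = int(self.mask.sum())
        self._t = np.where(self.mask, self.times, 0.0)[..., None]  # (S,T,1)
        self._y = np.where(self.mask, self.y, 1.0)

    def typical_cl(self, theta_cl, gammas: dict, betas: dict):
        tv = np.full(len(self.ids), theta_cl)
        for name, g in gammas.items():
            tv = tv * self.cont[name] ** g
        for name, b in betas.items():
            tv = tv * b ** self.flags[name]
        return tv

    def conc(self, cl, v):
        """Concentrations at observation times; cl, v shape (..., S)."""
        ke = (cl / v)[..., None, None]
        clx = cl[..., None, None]
        ts = self.dose_start[..., :, None, :]  # broadcast over leading dims
        dur = self.dose_dur[..., :, None, :]
        rate = self.dose_rate[..., :, None, :]
        el = self._t - ts  # (...,S,T,D)
        during = (el >= 0) & (el < dur)
        after = el >= dur
        c_dur = (rate / clx) * (-np.expm1(-ke * np.where(during, el, 0.0)))
        c_aft = (
            (rate / clx)
            * (-np.expm1(-ke * dur))
            * np.exp(-ke * np.where(after, el - dur, 0.0))
        )
        return (np.where(during, c_dur, 0.0) + np.where(after, c_aft, 0.0)).sum(-1)


def _joint_nll(bundle: _Bundle, tv_cl, theta_v, omega2, sigma, eta):
    """Per-subject negative log joint density; eta shape (..., S, 2)."""
    cl = tv_cl * np.exp(eta[..., 0])
    v = theta_v * np.exp(eta[..., 1])
    f = np.maximum(bundle.conc(cl, v), _F_FLOOR)
    res = (bundle._y - f) / (sigma * f)
    data_terms = np.where(bundle.mask, _LOG2PI + 2 * np.log(sigma * f) + res**2, 0.0)
    prior = (eta**2 / omega2).sum(-1) + np.log(omega2).sum() + 2 * _LOG2PI
    return 0.5 * (data_terms.sum(-1) + prior)


_STENCIL = np.array(
    [[0, 0], [1, 0], [-1, 0], [0, 1], [0, -1], [1, 1], [1, -1], [-1, 1], [-1, -1]],
    dtype=float,
)


def _inner_laplace(bundle, tv_cl, theta_v, omega2, sigma, eta0,
                   max_iter=40, tol=1e-7, h=1e-4):
    """Batched per-subject Newton minimisation of the joint density.

    Returns (nll at mode, eta mode, Hessian at mode), each batched over
    subjects.  Gradient/Hessian via a 9-point central-difference stencil.
    """
    eta = eta0.copy()
    S = eta.shape[0]
    H = np.tile(np.eye(2), (S, 1, 1))
    for _ in range(max_iter):
        pts = eta[None, :, :] + h * _STENCIL[:, None, :]  # (9,S,2)
        vals = _joint_nll(bundle, tv_cl, theta_v, omega2, sigma, pts)  # (9,S)
        l0 = vals[0]
        g = np.stack(
            [(vals[1] - vals[2]) / (2 * h), (vals[3] - vals[4]) / (2 * h)], axis=1
        )
        h11 = (vals[1] - 2 * l0 + vals[2]) / h**2
        h22 = (vals[3] - 2 * l0 + vals[4]) / h**2
        h12 = (vals[5] - vals[6] - vals[7] + vals[8]) / (4 * h**2)
        H = np.empty((S, 2, 2))
        H[:, 0, 0], H[:, 1, 1] = h11, h22
        H[:, 0, 1] = H[:, 1, 0] = h12
        # eigenvalue floor keeps the Newton direction a descent direction
        tr = h11 + h22
        det = h11 * h22 - h12**2
        disc = np.sqrt(np.maximum(tr**2 / 4 - det, 0.0))
        min_eig = tr / 2 - disc
        lam = np.maximum(1e-6 - min_eig, 0.0)
        Hreg = H + lam[:, None, None] * np.eye(2)
        det_r = Hreg[:, 0, 0] * Hreg[:, 1, 1] - Hreg[:, 0, 1] ** 2
        step = np.empty((S, 2))
        with np.errstate(divide="ignore", invalid="ignore"):
            step[:, 0] = -(Hreg[:, 1, 1] * g[:, 0] - Hreg[:, 0, 1] * g[:, 1]) / det_r
            step[:, 1] = -(Hreg[:, 0, 0] * g[:, 1] - Hreg[:, 0, 1] * g[:, 0]) / det_r
        step = np.nan_to_num(step, nan=0.0, posinf=0.0, neginf=0.0)
        norm = np.linalg.norm(step, axis=1)
        step *= np.minimum(1.0, 4.0 / np.maximum(norm, 1e-300))[:, None]

        # per-subject backtracking
        alpha = np.ones(S)
        improved = np.zeros(S, bool)
        for _bt in range(8):
            trial = eta + alpha[:, None] * step
            l_try = _joint_nll(bundle, tv_cl, theta_v, omega2, sigma, trial)
            better = l_try < l0 - 1e-12
            newly = better & ~improved
            eta[newly] = trial[newly]
            improved |= better
            if improved.all():
                break
            alpha[~improved] *= 0.5
        if np.abs(g).max() < tol or not improved.any():
            break
    # curvature at the final mode (stencil re-evaluated once more)
    pts = eta[None, :, :] + h * _STENCIL[:, None, :]
    vals = _joint_nll(bundle, tv_cl, theta_v, omega2, sigma, pts)
    H = np.empty((S, 2, 2))
    H[:, 0, 0] = (vals[1] - 2 * vals[0] + vals[2]) / h**2
    H[:, 1, 1] = (vals[3] - 2 * vals[0] + vals[4]) / h**2
    H[:, 0, 1] = H[:, 1, 0] = (vals[5] - vals[6] - vals[7] + vals[8]) / (4 * h**2)
    return vals[0], eta, H


def _ofv_from_inner(l_mode, H, eig_floor=1e-6):
    # eigenvalues of the 2x2 curvature, floored: an indefinite Hessian means
    # the inner mode is a ridge point and must not be rewarded with a
    # vanishing determinant
    h11, h22, h12 = H[:, 0, 0], H[:, 1, 1], H[:, 0, 1]
    tr = h11 + h22
    det = h11 * h22 - h12**2
    disc = np.sqrt(np.maximum(tr**2 / 4 - det, 0.0))
    lam1 = np.maximum(tr / 2 - disc, eig_floor)
    lam2 = np.maximum(tr / 2 + disc, eig_floor)
    return float(np.sum(2 * l_mode + np.log(lam1 * lam2) - 2 * _LOG2PI))


# ----------------------------------------------------------------------
# outer problem
# ----------------------------------------------------------------------

class _ParamMap:
    """Maps the outer optimiser vector onto named parameters.

    Positive parameters are log-transformed; covariate exponents (gammas)
    stay on the natural scale.  Parameters named in ``fix`` are excluded
    from the vector and injected at their fixed value on decode.
    """

    def __init__(self, spec: ModelSpec, fix: dict | None = None):
        self.spec = spec
        self.fix = dict(fix or {})
        self.names = (
            ["theta_cl", "theta_v"]
            + [f"gamma_{c}" for c in spec.continuous_cl]
            + [f"beta_{b}" for b in spec.binary_cl]
            + ["omega_cl", "omega_v", "sigma_prop"]
        )
        self.free = [n for n in self.names if n not in self.fix]

    @staticmethod
    def _floor(name: str) -> float:
        if name == "sigma_prop":
            return _FREE_SIGMA_FLOOR
        if name.startswith("omega_"):
            return _FREE_OMEGA_FLOOR
        return 0.0

    def _is_log(self, name: str) -> bool:
        return not name.startswith("gamma_")

    def encode(self, init: dict) -> np.ndarray:
        out = []
        for n in self.free:
            v = init.get(n, 0.1 if n.startswith("gamma_")
                         else 1.0 if n.startswith("beta_") else None)
            if v is None:
                raise KeyError(f"no initial value for {n}")
            out.append(math.log(max(v - self._floor(n), 1e-8))
                       if self._is_log(n) else v)
        return np.array(out)

    def decode(self, x) -> dict:
        vals = dict(self.fix)
        for n, xi in zip(self.free, x):
            vals[n] = (self._floor(n) + math.exp(xi)) if self._is_log(n) else float(xi)
        for n in ("omega_cl", "omega_v"):
            vals[n] = float(np.clip(vals[n], 0.0, _OMEGA_MAX))
        vals["sigma_prop"] = float(np.clip(vals["sigma_prop"], 0.0, _SIGMA_MAX))
        gammas = {c: vals[f"gamma_{c}"] for c in self.spec.continuous_cl}
        betas = {b: vals[f"beta_{b}"] for b in self.spec.binary_cl}
        return (vals["theta_cl"], vals["theta_v"], gammas, betas,
                vals["omega_cl"], vals["omega_v"], vals["sigma_prop"])


DEFAULT_INITIALS = {
    "theta_cl": 4.5, "theta_v": 22.0,
    "omega_cl": 0.3, "omega_v": 0.4, "sigma_prop": 0.2,
}


def fit(
    ds: Dataset,
    spec: ModelSpec = FINAL_MODEL_SPEC,
    initials: dict | None = None,
    fix: dict | None = None,
    max_iter: int = 1500,
    compute_rse: bool = True,
    xatol: float = 1e-4,
    fatol: float = 1e-4,
    restarts: int = 0,
) -> FitResult:
    """Laplace fit of the population model on a (cleaned) dataset.

    Deterministic given the data, initials and optimiser settings.  ``fix``
    pins named parameters (e.g. ``{"omega_cl": 0.0}``) outside the search —
    an omega of zero holds that random effect at zero, reducing the
    objective to a pooled regression criterion.  ``restarts`` re-launches
    the simplex from the incumbent optimum (useful on near-degenerate
    likelihoods).  Returns a :class:`FitResult` whose ``converged`` flag
    reflects the outer optimiser; non-convergence is reported explicitly,
    never silently.
    """
    init = dict(DEFAULT_INITIALS)
    if initials:
        init.update(initials)
    pm = _ParamMap(spec, fix)
    bundle = _Bundle(ds, spec)
    eta_cache = {"eta": np.zeros((len(bundle.ids), 2))}
    n_eval = [0]

    def ofv(x):
        n_eval[0] += 1
        theta_cl, theta_v, gammas, betas, w1, w2, sg = pm.decode(x)
        tv = bundle.typical_cl(theta_cl, gammas, betas)
        omega2 = np.array([max(w1, 1e-10) ** 2, max(w2, 1e-10) ** 2])
        l_mode, eta, H = _inner_laplace(bundle, tv, theta_v, omega2,
                                        max(sg, 1e-10), eta_cache["eta"])
        eta_cache["eta"] = eta
        return _ofv_from_inner(l_mode, H)

    x0 = pm.encode(init)
    with np.errstate(over="ignore", invalid="ignore"):
        res = optimize.minimize(
            ofv, x0, method="Nelder-Mead",
            options={"maxiter": max_iter, "xatol": xatol, "fatol": fatol,
                     "adaptive": True},
        )
        for _ in range(restarts):
            res2 = optimize.minimize(
                ofv, res.x, method="Nelder-Mead",
                options={"maxiter": max_iter, "xatol": xatol, "fatol": fatol,
                         "adaptive": True},
            )
            if res2.fun < res.fun:
                res = res2
        converged = bool(res.success)
        message = str(res.message)
        if not converged:
            # the simplex can fail its function-spread test indefinitely when
            # a subject's joint density is multimodal (e.g. around a BLQ
            # datum) even though the estimates are stationary; verify
            # stationarity with one restart before declaring failure
            res3 = optimize.minimize(
                ofv, res.x, method="Nelder-Mead",
                options={"maxiter": max_iter, "xatol": xatol, "fatol": fatol,
                         "adaptive": True},
            )
            moved = float(np.max(np.abs(res3.x - res.x)))
            if abs(res3.fun - res.fun) < 0.5 and moved < 0.02:
                converged = True
                message = "stationary under restart (simplex criterion not met)"
            if res3.fun < res.fun:
                res = res3
        if res.success:
            converged, message = True, str(res.message)

    theta_cl, theta_v, gammas, betas, w1, w2, sg = pm.decode(res.x)

    # EBEs and shrinkage at the optimum
    tv = bundle.typical_cl(theta_cl, gammas, betas)
    omega2 = np.array([max(w1, 1e-10) ** 2, max(w2, 1e-10) ** 2])
    _, eta_hat, _ = _inner_laplace(bundle, tv, theta_v, omega2,
                                   max(sg, 1e-10), eta_cache["eta"])
    etas = pd.DataFrame(
        {"ID": bundle.ids, "ETA_CL": eta_hat[:, 0], "ETA_V": eta_hat[:, 1],
         "CL": tv * np.exp(eta_hat[:, 0]), "V": theta_v * np.exp(eta_hat[:, 1])}
    )
    shrink = {
        "eta_cl": float(np.clip(100 * (1 - eta_hat[:, 0].std(ddof=1) / w1), 0, 100))
        if w1 > 0 else 100.0,
        "eta_v": float(np.clip(100 * (1 - eta_hat[:, 1].std(ddof=1) / w2), 0, 100))
        if w2 > 0 else 100.0,
    }

    result = FitResult(
        theta_cl=theta_cl, theta_v=theta_v, gammas=gammas, betas=betas,
        omega_cl=w1, omega_v=w2, sigma_prop=sg, refs=dict(bundle.refs),
        ofv=float(res.fun), converged=converged, message=message,
        n_subjects=len(bundle.ids), n_obs=bundle.n_obs,
        shrinkage_percent=shrink, etas=etas, n_evaluations=n_eval[0],
    )
    if not converged:
        logger.warning("fit did not converge: %s", message)

    if compute_rse and converged:
        try:
            H = _numdiff.hessian(ofv, res.x, h=1e-3)
            cov = 2.0 * np.linalg.inv(H)
            se_x = np.sqrt(np.maximum(np.diag(cov), 0.0))
            # parameters are log-transformed (gammas excepted), so SE on the
            # natural scale is |param| * SE(log param); RSE% is then 100*SE_x
            vals = result.estimates()
            rse = {}
            for name, sx, xv in zip(pm.free, se_x, res.x):
                if name.startswith("gamma_"):
                    rse[name] = 100.0 * sx / abs(vals[name]) if vals[name] else np.inf
                else:
                    rse[name] = 100.0 * sx  # delta method on the log scale
            result.rse_percent = rse
        except np.linalg.LinAlgError:
            logger.warning("RSE Hessian singular; RSEs unavailable")
    return result


# ----------------------------------------------------------------------
# covariate selection
# ----------------------------------------------------------------------

#: the tested covariate list: renal-function markers, body size, age,
#: ethnicity (coded caucasian vs other), ward flags, fever, co-antibiotics
DEFAULT_CANDIDATES = (
    ("SCR", "continuous"),
    ("EGFR_CKDEPI", "continuous"),
    ("EGFR_MDRD", "continuous"),
    ("EGFR_CG", "continuous"),
    ("BMI", "continuous"),
    ("AGE", "continuous"),
    ("ETHNICITY_CAUC", "binary"),
    ("WARD_ORTHO", "binary"),
    ("WARD_HEMA", "binary"),
    ("FEVER", "binary"),
    ("ABX", "binary"),
)

#: mutually collinear renal-function markers: at most one may be retained
RENAL_COLLINEAR = ("SCR", "EGFR_CKDEPI", "EGFR_MDRD", "EGFR_CG")


@dataclass
class CovariateStepReport:
    univariate: pd.DataFrame
    multivariate: pd.DataFrame
    retained: tuple
    final_spec: ModelSpec
    final_fit: FitResult
    iiv_cl_trajectory: list  # %CV of IIV on CL: base, then after each inclusion


def _prepare_candidates(ds: Dataset, candidates):
    """Materialise derived candidate columns (ethnicity dummy)."""
    ev = ds.events
    if any(n == "ETHNICITY_CAUC" for n, _ in candidates) and "ETHNICITY_CAUC" not in ev:
        ev = ev.copy()
        ev["ETHNICITY_CAUC"] = (
            ev.get("ETHNICITY", "caucasian").astype(str).str.lower().eq("caucasian").astype(int)
        )
        ds = Dataset(ev, ds.lloq, ds.uloq)
    return ds


def covariate_step(
    ds: Dataset,
    base_fit: FitResult,
    candidates=DEFAULT_CANDIDATES,
    base_spec: ModelSpec = ModelSpec(),
    p_univariate: float = 0.05,
    p_multivariate: float = 0.01,
    fit_kwargs: dict | None = None,
) -> CovariateStepReport:
    """Univariate likelihood-ratio screen, then multivariate backward elimination.

    Screening keeps candidates with a drop in objective of at least
    ``chi2(1 - p_univariate, 1 df)`` (3.84 at p<0.05); the multivariate step
    retains covariates whose removal from the joint model raises the
    objective by at least ``chi2(1 - p_multivariate, 1 df)`` (6.63 at
    p<0.01).  Only the best of the mutually collinear renal-function markers
    may enter the multivariate model.
    """
    if not base_fit.converged:
        raise ValueError("base fit did not converge")
    fkw = dict(compute_rse=False)
    fkw.update(fit_kwargs or {})
    ds = _prepare_candidates(ds, candidates)
    crit_uni = stats.chi2.ppf(1 - p_univariate, 1)
    crit_multi = stats.chi2.ppf(1 - p_multivariate, 1)
    base_init = {k: v for k, v in base_fit.estimates().items()
                 if not k.startswith(("gamma_", "beta_"))}

    uni_rows = []
    passers = {}
    for name, kind in candidates:
        spec_c = base_spec.with_candidate(name, kind)
        f = fit(ds, spec_c, initials=base_init, **fkw)
        d_ofv = base_fit.ofv - f.ofv
        p = float(stats.chi2.sf(max(d_ofv, 0.0), 1))
        passed = f.converged and d_ofv >= crit_uni
        uni_rows.append({"candidate": name, "kind": kind, "delta_ofv": d_ofv,
                         "p_value": p, "passed": bool(passed)})
        if passed:
            passers[name] = (kind, d_ofv)
    univariate = pd.DataFrame(uni_rows)

    # collinearity: keep only the best renal-function marker
    renal_passers = [n for n in passers if n in RENAL_COLLINEAR]
    if len(renal_passers) > 1:
        best = max(renal_passers, key=lambda n: passers[n][1])
        for n in renal_passers:
            if n != best:
                warnings.warn(
                    f"collinear renal markers: dropping {n} in favour of {best}",
                    stacklevel=2,
                )
                del passers[n]

    # multivariate backward elimination among the screened candidates
    current = dict(passers)
    multi_rows = []
    iiv_traj = [base_fit.iiv_cl_percent_cv]

    def fit_spec(names):
        spec_m = base_spec
        for n in names:
            spec_m = spec_m.with_candidate(n, current[n][0])
        return fit(ds, spec_m, initials=base_init, **fkw), spec_m

    full_fit, full_spec = (base_fit, base_spec) if not current else fit_spec(list(current))
    while current:
        worst_name, worst_d = None, np.inf
        for name in list(current):
            others = [n for n in current if n != name]
            red_fit, _ = (base_fit, base_spec) if not others else fit_spec(others)
            d_ofv = red_fit.ofv - full_fit.ofv  # rise on removal
            multi_rows.append({"candidate": name, "delta_ofv": d_ofv,
                               "p_value": float(stats.chi2.sf(max(d_ofv, 0.0), 1)),
                               "retained": bool(d_ofv >= crit_multi)})
            if d_ofv < worst_d:
                worst_name, worst_d = name, d_ofv
        if worst_d >= crit_multi:
            break
        del current[worst_name]
        full_fit, full_spec = (base_fit, base_spec) if not current else fit_spec(list(current))

    # IIV trajectory: refit adding retained covariates in decreasing delta-OFV
    order = sorted(current, key=lambda n: -current[n][1])
    spec_t = base_spec
    for n in order:
        spec_t = spec_t.with_candidate(n, current[n][0])
        f_t, _ = fit_spec([m for m in order[: order.index(n) + 1]])
        iiv_traj.append(f_t.iiv_cl_percent_cv)

    multivariate = pd.DataFrame(multi_rows) if multi_rows else pd.DataFrame(
        columns=["candidate", "delta_ofv", "p_value", "retained"]
    )
    final_fit, final_spec = (base_fit, base_spec) if not current else fit_spec(list(current))
    return CovariateStepReport(
        univariate=univariate, multivariate=multivariate,
        retained=tuple(order), final_spec=final_spec, final_fit=final_fit,
        iiv_cl_trajectory=iiv_traj,
    )


# ----------------------------------------------------------------------
# empirical Bayes estimates
# ----------------------------------------------------------------------

def model_components(pop):
    """Normalise a :class:`FitResult` or :class:`PopulationParameters` into
    ``(spec, theta_cl, theta_v, gammas, betas, omega_cl, omega_v, sigma)``."""
    if isinstance(pop, FitResult):
        spec = ModelSpec(
            continuous_cl=tuple(pop.gammas), binary_cl=tuple(pop.betas), refs=pop.refs
        )
        return (spec, pop.theta_cl, pop.theta_v, pop.gammas, pop.betas,
                pop.omega_cl, pop.omega_v, pop.sigma_prop)
    spec = ModelSpec(
        continuous_cl=("EGFR_CKDEPI",), binary_cl=("ABX",),
        refs={"EGFR_CKDEPI": pop.egfr_ref},
    )
    return (spec, pop.theta_cl, pop.theta_v, {"EGFR_CKDEPI": pop.gamma_egfr},
            {"ABX": pop.theta_abx}, pop.omega_cl, pop.omega_v, pop.sigma_prop)


def empirical_bayes(ds: Dataset, pop) -> pd.DataFrame:
    """Per-subject MAP random effects and individual CL/V.

    ``pop`` may be a :class:`PopulationParameters` (final-model structure) or
    a :class:`FitResult`.  Subjects without observations sit at the prior
    mode (eta = 0, typical values).
    """
    spec, theta_cl, theta_v, gammas, betas, w1, w2, sg = model_components(pop)
    bundle = _Bundle(ds, spec)
    tv = bundle.typical_cl(theta_cl, gammas, betas)
    # an omega of zero pins that random effect at the prior mode exactly
    omega2 = np.array([w1**2 if w1 > 0 else 1e-12, w2**2 if w2 > 0 else 1e-12])
    _, eta, _ = _inner_laplace(bundle, tv, theta_v, omega2, max(sg, _SIGMA_MIN),
                               np.zeros((len(bundle.ids), 2)))
    if w1 == 0:
        eta[:, 0] = 0.0
    if w2 == 0:
        eta[:, 1] = 0.0
    return pd.DataFrame(
        {"ID": bundle.ids, "ETA_CL": eta[:, 0], "ETA_V": eta[:, 1],
         "CL": tv * np.exp(eta[:, 0]), "V": theta_v * np.exp(eta[:, 1])}
    )


# ----------------------------------------------------------------------
# bootstrap
# ----------------------------------------------------------------------

def bootstrap(
    ds: Dataset,
    spec: ModelSpec = FINAL_MODEL_SPEC,
    n_replicates: int = 1000,
    seed: int = 0,
    initials: dict | None = None,
    stratify: bool = True,
    fit_kwargs: dict | None = None,
) -> dict:
    """Nonparametric bootstrap: resample subjects with replacement and refit.

    Resampling is stratified by renal-function group so each replicate keeps
    the study's group sizes.  Returns replicate medians and percentile 95%
    CIs per parameter plus the failure count; more than 20 % failed
    replicates triggers a hard warning.
    """
    rng = np.random.default_rng(seed)
    fkw = dict(compute_rse=False)
    fkw.update(fit_kwargs or {})
    cov = ds.covariates()
    groups = cov["EGFR_CKDEPI"].map(renal_group)
    strata = (
        [list(groups.index[groups == g]) for g in ("I", "II", "III")
         if (groups == g).any()]
        if stratify
        else [list(cov.index)]
    )

    rows = []
    failures = 0
    for _rep in range(n_replicates):
        sampled = []
        for stratum in strata:
            idx = rng.integers(0, len(stratum), size=len(stratum))
            sampled.extend(stratum[i] for i in idx)
        frames = []
        for new_id, sid in enumerate(sampled, start=1):
            sub = ds.events[ds.events["ID"] == sid].copy()
            sub["ID"] = new_id
            frames.append(sub)
        rep_ds = Dataset(pd.concat(frames, ignore_index=True), ds.lloq, ds.uloq)
        try:
            f = fit(rep_ds, spec, initials=initials, **fkw)
        except Exception:  # numerical failure counts as a failed replicate
            failures += 1
            continue
        if not f.converged:
            failures += 1
            continue
        rows.append(f.estimates())

    est = pd.DataFrame(rows)
    summary = {}
    for colname in est.columns:
        vals = est[colname].to_numpy(float)
        summary[colname] = {
            "median": float(np.median(vals)),
            "ci95_low": float(np.percentile(vals, 2.5)),
            "ci95_high": float(np.percentile(vals, 97.5)),
        }
    out = {
        "n_replicates": n_replicates,
        "n_failed": failures,
        "parameters": summary,
        "replicates": est,
    }
    if n_replicates and failures / n_replicates > 0.2:
        warnings.warn(
            f"bootstrap: {failures}/{n_replicates} replicates failed to converge",
            stacklevel=2,
        )
    return out
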