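"""Single-season site-occupancy models with accessibility covariates.

The likelihood is the standard zero-inflated detection-history mixture: with
station occupancy probability psi_s and per-occasion detection probability
p_s (both logit-linear in raw-unit covariates),

    L_s = psi_s * prod_o p_s^y_so (1 - p_s)^(1 - y_so)
          + (1 - psi_s) * 1{no detection at s},

products running over occasions with effort (camera-failure occasions drop
out of the product). Model selection uses AICc with the station count as the
effective sample size; candidate models are all combinations of occupancy
covariates {RR, ST, H} with detection constant or a function of camera
spacing DC.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

from .data import DetectionMatrix, Station, ValidationError, station_covariates

log = logging.getLogger("camtrap")

PSI_COVARIATES = ("RR", "ST", "H")
P_COVARIATES = ("DC",)


@dataclass(frozen=True)
class OccModelSpec:
    """One candidate model: occupancy and detection covariate subsets."""

    species: str
    psi_covariates: tuple[str, ...] = ()
    p_covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not set(self.psi_covariates) <= set(PSI_COVARIATES):
            raise ValidationError(f"unknown occupancy covariates {self.psi_covariates}")
        if not set(self.p_covariates) <= set(P_COVARIATES):
            raise ValidationError(f"unknown detection covariates {self.p_covariates}")

    @property
    def n_params(self) -> int:
        return 2 + len(self.psi_covariates) + len(self.p_covariates)

    @property
    def label(self) -> str:
        psi = "+".join(self.psi_covariates) if self.psi_covariates else "."
        p = "+".join(self.p_covariates) if self.p_covariates else "."
        return f"psi({psi})p({p})"


@dataclass
class OccupancyFit:
    """MLE fit of one occupancy model."""

    spec: OccModelSpec
    params: np.ndarray  # logit-scale coefficients, psi block then p block
    se: np.ndarray
    cov: np.ndarray
    loglik: float
    converged: bool
    psi_hat: np.ndarray  # per station
    p_hat: np.ndarray
    param_names: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.spec.n_params

    def coef(self, name: str) -> float:
        return float(self.params[self.param_names.index(name)])

    def coef_se(self, name: str) -> float:
        return float(self.se[self.param_names.index(name)])


def design_matrices(
    spec: OccModelSpec, stations: Sequence[Station]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Raw-unit design matrices (intercept first) and parameter names."""
    cov = station_covariates(stations)
    n = len(stations)
    Xpsi = np.column_stack(
        [np.ones(n)] + [cov[c] for c in spec.psi_covariates]
    )
    Xp = np.column_stack([np.ones(n)] + [cov[c] for c in spec.p_covariates])
    names = (
        ["psi_intercept"]
        + [f"psi_{c}" for c in spec.psi_covariates]
        + ["p_intercept"]
        + [f"p_{c}" for c in spec.p_covariates]
    )
    return Xpsi, Xp, names


def occ_loglik(
    params: np.ndarray,
    y: np.ndarray,
    Xpsi: np.ndarray,
    Xp: np.ndarray,
) -> float:
    """Log-likelihood of the detection histories.

    ``y`` is station x occasion in {0, 1, NaN}; NaN occasions contribute
    nothing. An all-missing station contributes exactly 0.
    """
    params = np.asarray(params, dtype=float)
    if not np.all(np.isfinite(params)):
        raise ValidationError("non-finite parameters")
    kpsi = Xpsi.shape[1]
    eta_psi = Xpsi @ params[:kpsi]
    eta_p = Xp @ params[kpsi:]
    psi = expit(eta_psi)
    p = np.clip(expit(eta_p), 1e-300, 1.0 - 1e-16)  # keep logs finite
    obs = ~np.isnan(y)
    y0 = np.where(obs, y, 0.0)
    with np.errstate(divide="ignore"):
        logp = np.log(p)
        log1p_ = np.log1p(-p)
    # conditional log-prob of the history given presence
    ll_hist = np.sum(
        np.where(obs, y0 * logp[:, None] + (1 - y0) * log1p_[:, None], 0.0), axis=1
    )
    detected = (y0 * obs).sum(axis=1) > 0
    with np.errstate(divide="ignore"):
        term1 = np.log(psi) + ll_hist
        term0 = np.where(detected, -np.inf, np.log1p(-psi))
    ll = np.logaddexp(term1, term0)
    return float(ll.sum())


def _naive_start(y: np.ndarray, kpsi: int, kp: int) -> np.ndarray:
    obs = ~np.isnan(y)
    det_station = np.nansum(y, axis=1) > 0
    naive_psi = np.clip(det_station.mean(), 0.05, 0.95)
    occ_rows = det_station
    if occ_rows.any():
        naive_p = np.clip(
            np.nansum(y[occ_rows]) / max(1, obs[occ_rows].sum()), 0.05, 0.95
        )
    else:
        naive_p = 0.2
    start = np.zeros(kpsi + kp)
    start[0] = np.log(naive_psi / (1 - naive_psi))
    start[kpsi] = np.log(naive_p / (1 - naive_p))
    return start


def _numeric_hessian(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    n = x.size
    H = np.zeros((n, n))
    h = eps * np.maximum(1.0, np.abs(x))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


def fit_occupancy(
    spec: OccModelSpec,
    data: DetectionMatrix,
    stations: Sequence[Station],
    extra_starts: int = 2,
) -> OccupancyFit:
    """Maximum-likelihood fit by multi-start quasi-Newton on the logit scale.

    Starts at zero and at naive-occupancy-informed values (plus a couple of
    small perturbations); standard errors come from the inverse observed
    information at the optimum. Covariates enter in raw units, so the
    coefficients are directly comparable to untransformed published estimates.
    """
    if data.n_detections == 0:
        raise ValidationError(
            f"{spec.species}: no detections; occupancy is not estimable "
            "(handle as a naive zero)"
        )
    Xpsi, Xp, names = design_matrices(spec, stations)
    y = data.y
    nll = lambda th: -occ_loglik(th, y, Xpsi, Xp)

    starts = [np.zeros(spec.n_params), _naive_start(y, Xpsi.shape[1], Xp.shape[1])]
    rng = np.random.default_rng(12345)
    for _ in range(extra_starts):
        starts.append(starts[1] + rng.normal(0, 0.5, size=spec.n_params))

    best = None
    for s0 in starts:
        res = optimize.minimize(
            nll, s0, method="L-BFGS-B",
            options=dict(maxiter=500, ftol=1e-12, gtol=1e-8),
        )
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    converged = bool(best.success) and np.all(np.isfinite(best.x))
    H = _numeric_hessian(nll, best.x)
    try:
        cov = np.linalg.pinv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        if not np.all(np.isfinite(se)):
            converged = False
    except np.linalg.LinAlgError:
        cov = np.full((spec.n_params, spec.n_params), np.nan)
        se = np.full(spec.n_params, np.nan)
        converged = False
    kpsi = Xpsi.shape[1]
    psi_hat = expit(Xpsi @ best.x[:kpsi])
    p_hat = expit(Xp @ best.x[kpsi:])
    if not converged:
        log.warning("%s %s: fit flagged non-converged", spec.species, spec.label)
    return OccupancyFit(
        spec=spec,
        params=best.x,
        se=se,
        cov=cov,
        loglik=-float(best.fun),
        converged=converged,
        psi_hat=psi_hat,
        p_hat=p_hat,
        param_names=names,
    )


def enumerate_model_set(species: str, strict_15: bool = False) -> list[OccModelSpec]:
    """All occupancy x detection covariate combinations (8 x 2 = 16 models).

    ``strict_15`` drops the saturated psi(RR+ST+H)p(DC) model, yielding a
    15-model set; which of the 16 combinations the original analysis omitted
    is not documented, so neither mode is asserted as its intent.
    """
    specs = []
    for r in range(len(PSI_COVARIATES) + 1):
        for psi_sub in itertools.combinations(PSI_COVARIATES, r):
            for p_sub in ((), ("DC",)):
                specs.append(OccModelSpec(species, psi_sub, p_sub))
    if strict_15:
        specs = [
            s for s in specs
            if not (len(s.psi_covariates) == 3 and len(s.p_covariates) == 1)
        ]
    return specs


def aicc(loglik: float, k: int, n: int) -> float:
    if n <= k + 1:
        raise ValidationError(f"AICc undefined: n={n} <= K+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def rank_aicc(fits: Sequence[OccupancyFit], n: int) -> pd.DataFrame:
    """AICc ranking table with delta-AICc and Akaike weights.

    Non-converged fits are excluded (and logged). Ties break by smaller K,
    then by model label.
    """
    usable = [f for f in fits if f.converged]
    dropped = [f for f in fits if not f.converged]
    for f in dropped:
        log.warning("excluding non-converged fit %s", f.spec.label)
    if not usable:
        raise ValidationError("no converged fits to rank")
    rows = [
        dict(
            model=f.spec.label, species=f.spec.species, K=f.k,
            loglik=f.loglik, AICc=aicc(f.loglik, f.k, n),
        )
        for f in usable
    ]
    df = pd.DataFrame(rows).sort_values(
        ["AICc", "K", "model"], kind="mergesort"
    ).reset_index(drop=True)
    df["delta_AICc"] = df["AICc"] - df["AICc"].iloc[0]
    w = np.exp(-0.5 * df["delta_AICc"].to_numpy())
    df["weight"] = w / w.sum()
    return df


def site_psi(
    fit: OccupancyFit, stations: Sequence[Station]
) -> pd.DataFrame:
    """Per-site mean of station occupancy estimates with delta-method SE.

    The station predictions are unconditional covariate predictions
    (not conditioned on the observed histories).
    """
    if not fit.converged:
        raise ValidationError("site_psi requires a converged fit")
    Xpsi, _, _ = design_matrices(fit.spec, stations)
    kpsi = Xpsi.shape[1]
    psi = expit(Xpsi @ fit.params[:kpsi])
    sites = [s.site for s in stations]
    rows = []
    for site in dict.fromkeys(sites):
        idx = np.array([i for i, s in enumerate(sites) if s == site])
        if idx.size == 0:
            log.warning("site %s has no stations; omitted", site)
            continue
        mean_psi = float(psi[idx].mean())
        # gradient of the site mean wrt the psi-block coefficients
        grad = np.zeros(fit.params.size)
        grad[:kpsi] = (psi[idx] * (1 - psi[idx])) @ Xpsi[idx] / idx.size
        var = float(grad @ fit.cov @ grad)
        rows.append(
            dict(site=site, n_stations=int(idx.size), psi=mean_psi,
                 se=float(np.sqrt(max(var, 0.0))))
        )
    return pd.DataFrame(rows)


def fit_species(
    species: str,
    data: DetectionMatrix,
    stations: Sequence[Station],
    strict_15: bool = False,
    n_effective: int | None = None,
) -> tuple[pd.DataFrame, OccupancyFit]:
    """Fit the full model set for one species and return (ranking, best fit)."""
    n = n_effective if n_effective is not None else len(stations)
    fits = []
    for spec in enumerate_model_set(species, strict_15=strict_15):
        try:
            fits.append(fit_occupancy(spec, data, stations))
        except ValidationError:
            raise
    table = rank_aicc(fits, n=n)
    best_label = table["model"].iloc[0]
    best = next(f for f in fits if f.spec.label == best_label)
    return table, best
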