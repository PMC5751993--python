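"""Bayesian spatially explicit capture-recapture with data augmentation.

Model
-----
Activity centres s_i live on a discrete state space: a regular grid of
potential centres (default one per km²) covering the trap-array envelope
buffered by 15 km, each centre carrying a binary habitat-suitability flag.
The observed n individuals are augmented with all-zero capture histories up
to M = multiplier * n; inclusion indicators z_i ~ Bernoulli(psi_aug) with
psi_aug ~ Uniform(0, 1) make the population size N_super = sum z_i a derived
quantity with a Uniform(0, M) prior.

Detection is a per-trap, per-occasion Bernoulli with half-normal encounter
rate: p(d) = 1 - exp(-lambda0 * exp(-d² / (2 sigma²))). sigma and lambda0
get diffuse uniform priors on wide positive ranges and are updated by
random-walk Metropolis on the log scale with adaptation (20-40% acceptance)
during burn-in only; centres move by uniform proposals over grid neighbours
(with the neighbourhood-size Hastings correction); z and psi_aug are Gibbs
steps. Density is N_super per 100 km² of suitable state space, per draw.

Convergence is judged by the Geweke z-statistic (|z| < 1.6) on the thinned
post-burn-in chains; the runner can escalate the iteration count on failure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .data import CaptureMatrix, RunConfig, Station, ValidationError

log = logging.getLogger("camtrap")

GEWEKE_THRESHOLD = 1.6


@dataclass
class StateSpace:
    """Discrete grid of potential activity centres."""

    centers: np.ndarray  # (K, 2) km
    suitable: np.ndarray  # (K,) bool
    resolution: float  # centres per km²
    buffer: float  # km

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.suitable = np.asarray(self.suitable, dtype=bool)
        if self.suitable.sum() == 0:
            raise ValidationError("state space has no suitable centres")

    @property
    def n_centers(self) -> int:
        return int(self.centers.shape[0])

    @property
    def suitable_area(self) -> float:
        """km² of suitable habitat (each centre represents 1/resolution km²)."""
        return float(self.suitable.sum() / self.resolution)


def build_state_space(
    traps: np.ndarray | list[Station],
    buffer: float = 15.0,
    resolution: float = 1.0,
    suitability_mask=None,
    mode: str = "rectangle",
) -> StateSpace:
    """Regular centre grid covering the buffered trap-array envelope.

    ``mode='rectangle'`` buffers the axis-aligned bounding box (deterministic
    centre count); ``mode='hull'`` clips the same grid to the buffered convex
    hull of the traps. Every trap lies at least ``buffer`` from the state
    space edge by construction.
    """
    if resolution <= 0:
        raise ValidationError("resolution must be > 0")
    xy = (
        np.array([[t.x, t.y] for t in traps])
        if len(traps) and isinstance(traps[0], Station)
        else np.asarray(traps, dtype=float)
    )
    if xy.shape[0] < 2:
        raise ValidationError("need >= 2 traps")
    spacing = 1.0 / np.sqrt(resolution)
    x0, x1 = xy[:, 0].min() - buffer, xy[:, 0].max() + buffer
    y0, y1 = xy[:, 1].min() - buffer, xy[:, 1].max() + buffer
    nx = max(1, int(round((x1 - x0) / spacing)))
    ny = max(1, int(round((y1 - y0) / spacing)))
    gx = x0 + (np.arange(nx) + 0.5) * (x1 - x0) / nx
    gy = y0 + (np.arange(ny) + 0.5) * (y1 - y0) / ny
    GX, GY = np.meshgrid(gx, gy)
    centers = np.column_stack([GX.ravel(), GY.ravel()])
    if mode == "hull":
        from shapely.geometry import MultiPoint, Point

        hull = MultiPoint([tuple(p) for p in xy]).convex_hull.buffer(buffer)
        keep = np.array([hull.contains(Point(*c)) for c in centers])
        centers = centers[keep]
    suitable = (
        np.ones(centers.shape[0], dtype=bool)
        if suitability_mask is None
        else np.asarray(suitability_mask, dtype=bool)
    )
    if suitable.shape[0] != centers.shape[0]:
        raise ValidationError("suitability mask length mismatch")
    return StateSpace(centers=centers, suitable=suitable, resolution=resolution, buffer=buffer)


def encounter_prob(d, lambda0: float, sigma: float):
    """Per-occasion capture probability at centre-trap distance d (km)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0) or lambda0 <= 0 or sigma <= 0:
        raise ValidationError("require d >= 0, lambda0 > 0, sigma > 0")
    return 1.0 - np.exp(-lambda0 * np.exp(-(d**2) / (2.0 * sigma**2)))


@dataclass
class SecrPosterior:
    """Thinned post-burn-in draws and diagnostics."""

    sigma: np.ndarray
    lambda0: np.ndarray
    psi_aug: np.ndarray
    n_super: np.ndarray
    density: np.ndarray  # individuals / 100 km² suitable
    acceptance: dict[str, float]
    geweke: dict[str, float]
    iterations: int
    m_aug: int
    converged: bool = False

    def summary(self) -> dict[str, dict[str, float]]:
        out = {}
        for name in ("sigma", "lambda0", "psi_aug", "n_super", "density"):
            x = getattr(self, name)
            lo, hi = np.percentile(x, [2.5, 97.5])
            out[name] = dict(
                mean=float(x.mean()), sd=float(x.std(ddof=1)),
                q2_5=float(lo), q97_5=float(hi),
                geweke_z=self.geweke.get(name, np.nan),
            )
        return out


def _spectral_var(x: np.ndarray) -> float:
    """Newey-West estimate of the spectral density at frequency zero."""
    x = np.asarray(x, dtype=float)
    n = x.size
    xc = x - x.mean()
    lags = min(n - 1, int(np.floor(4 * (n / 100.0) ** (2.0 / 9.0))) + 1)
    s = xc @ xc / n
    for k in range(1, lags + 1):
        w = 1.0 - k / (lags + 1.0)
        s += 2.0 * w * (xc[k:] @ xc[:-k]) / n
    return float(max(s, 0.0))


def geweke_z(chain: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z: early vs late segment means over spectral SEs."""
    chain = np.asarray(chain, dtype=float)
    n = chain.size
    if n < 100:
        raise ValidationError("chain too short for the Geweke diagnostic (< 100)")
    if np.ptp(chain) == 0 or np.std(chain) < 1e-12 * max(1.0, abs(chain.mean())):
        raise ValidationError("degenerate (near-constant) chain")
    a = chain[: int(first * n)]
    b = chain[n - int(last * n):]
    va = _spectral_var(a) / a.size
    vb = _spectral_var(b) / b.size
    denom = np.sqrt(va + vb)
    if denom == 0:
        raise ValidationError("degenerate chain segments")
    return float((a.mean() - b.mean()) / denom)


def _neighbor_table(centers: np.ndarray, radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Padded neighbour-index table and neighbour counts for centre moves."""
    tree = cKDTree(centers)
    lists = tree.query_ball_point(centers, r=radius)
    lists = [[j for j in lst if j != i] for i, lst in enumerate(lists)]
    counts = np.array([len(l) for l in lists], dtype=int)
    if counts.min() == 0:
        raise ValidationError("isolated state-space centre; increase proposal radius")
    table = np.zeros((centers.shape[0], counts.max()), dtype=int)
    for i, lst in enumerate(lists):
        table[i, : len(lst)] = lst
        table[i, len(lst):] = lst[0] if lst else i  # padding never drawn
    return table, counts


def run_secr_mcmc(
    capture: CaptureMatrix,
    traps: np.ndarray | list[Station],
    state_space: StateSpace,
    config: RunConfig | None = None,
    rng: np.random.Generator | None = None,
    iterations: int | None = None,
    escalate: bool = False,
    sigma_range: tuple[float, float] = (0.05, 30.0),
    lambda0_range: tuple[float, float] = (1e-4, 5.0),
    proposal_radius: float = 3.5,
) -> SecrPosterior:
    """Metropolis-within-Gibbs sampler for the augmented SECR model.

    ``capture.Y`` gives per-individual, per-trap counts of trap-occasion
    detections out of ``capture.occasions`` occasions. With ``escalate=True``
    the run restarts with doubled iterations (up to ``config.mcmc_max_iters``)
    until every monitored chain passes the Geweke check.
    """
    config = config or RunConfig()
    rng = rng or config.rng_for("secr")
    n_obs = capture.n_individuals
    if n_obs < 1:
        raise ValidationError("need >= 1 observed individual")
    trap_xy = (
        np.array([[t.x, t.y] for t in traps])
        if len(traps) and isinstance(traps[0], Station)
        else np.asarray(traps, dtype=float)
    )
    J = trap_xy.shape[0]
    K = capture.occasions
    Y = capture.Y.astype(float)  # (n_obs, J)
    # warn when sigma is weakly identified
    multi_trap = np.sum((Y > 0).sum(axis=1) >= 2)
    if multi_trap == 0:
        log.warning(
            "no individual recaptured at distinct traps: sigma weakly "
            "identified; interpret the posterior with caution"
        )
    M = config.aug_multiplier * n_obs
    Y_aug = np.vstack([Y, np.zeros((M - n_obs, J))])  # (M, J)
    captured = np.zeros(M, dtype=bool)
    captured[:n_obs] = True

    suit_idx = np.flatnonzero(state_space.suitable)
    centers = state_space.centers
    D2 = (
        (centers[:, None, 0] - trap_xy[None, :, 0]) ** 2
        + (centers[:, None, 1] - trap_xy[None, :, 1]) ** 2
    )  # (Kc, J)
    nb_table, nb_counts = _neighbor_table(centers, proposal_radius)
    area = state_space.suitable_area

    iters = iterations or config.mcmc_iters
    while True:
        post = _run_chain(
            rng, Y_aug, captured, D2, nb_table, nb_counts, suit_idx, K, M,
            n_obs, area, iters, config, sigma_range, lambda0_range,
        )
        if not escalate or post.converged or iters >= config.mcmc_max_iters:
            if escalate and not post.converged:
                log.warning(
                    "SECR chains failed the Geweke check at %d iterations; "
                    "reporting the non-converged posterior", iters
                )
            return post
        iters = min(iters * 2, config.mcmc_max_iters)
        log.info("escalating SECR iterations to %d", iters)


def _loglik_rows(Y_aug, active, center_idx, D2, K, lambda0, sigma):
    """Bernoulli log-likelihood per active individual at its centre."""
    d2 = D2[center_idx[active]]  # (n_active, J)
    p = 1.0 - np.exp(-lambda0 * np.exp(-d2 / (2.0 * sigma**2)))
    p = np.clip(p, 1e-300, 1 - 1e-12)
    y = Y_aug[active]
    return np.sum(y * np.log(p) + (K - y) * np.log1p(-p), axis=1)


def _run_chain(
    rng, Y_aug, captured, D2, nb_table, nb_counts, suit_idx, K, M, n_obs,
    area, iterations, config, sigma_range, lambda0_range,
):
    burn = int(config.burnin_frac * iterations)
    thin = config.thin
    Kc = D2.shape[0]

    # initial state: captured individuals at their mean capture location
    center_idx = rng.choice(suit_idx, size=M)
    trap_weight = Y_aug[:n_obs] / Y_aug[:n_obs].sum(axis=1, keepdims=True)
    # nearest suitable centre to each captured individual's centroid
    mean_d2 = trap_weight @ D2[suit_idx].T  # (n_obs, n_suitable)
    center_idx[:n_obs] = suit_idx[np.argmin(mean_d2, axis=1)]
    z = captured.copy()
    z[n_obs:] = rng.random(M - n_obs) < 0.5
    sigma = float(np.sqrt(np.median(D2)) / 3)
    sigma = float(np.clip(sigma, *sigma_range))
    lambda0 = 0.1
    psi = max(0.5, (z.sum() + 1) / (M + 2))
    step_sigma, step_lam = 0.1, 0.2

    keep = max(1, (iterations - burn) // thin)
    out = {k: np.empty(keep) for k in ("sigma", "lambda0", "psi_aug", "n_super", "density")}
    acc = {"sigma": 0, "lambda0": 0, "centers": 0.0}
    n_param_updates = 0
    n_center_updates = 0
    kept = 0

    active = captured | z
    ll = _loglik_rows(Y_aug, active, center_idx, D2, K, lambda0, sigma)

    for it in range(iterations):
        # --- sigma / lambda0 random-walk on log scale ---------------------
        for name in ("sigma", "lambda0"):
            cur = sigma if name == "sigma" else lambda0
            step = step_sigma if name == "sigma" else step_lam
            prop = float(np.exp(np.log(cur) + step * rng.normal()))
            lo, hi = sigma_range if name == "sigma" else lambda0_range
            n_param_updates += 1
            if not lo <= prop <= hi:
                continue
            s_p = prop if name == "sigma" else sigma
            l_p = prop if name == "lambda0" else lambda0
            ll_prop = _loglik_rows(Y_aug, active, center_idx, D2, K, l_p, s_p)
            # log-scale RW on a uniform prior: Jacobian term log(prop/cur)
            log_r = ll_prop.sum() - ll.sum() + np.log(prop / cur)
            if np.log(rng.random()) < log_r:
                if name == "sigma":
                    sigma = prop
                else:
                    lambda0 = prop
                ll = ll_prop
                acc[name] += 1
        # --- psi (Gibbs, Beta-Bernoulli conjugacy) -----------------------
        nz = int(z.sum())
        psi = rng.beta(1 + nz, 1 + M - nz)
        # --- z for augmented individuals (Gibbs) -------------------------
        d2_aug = D2[center_idx[n_obs:]]
        p_aug = 1.0 - np.exp(-lambda0 * np.exp(-d2_aug / (2.0 * sigma**2)))
        log_q0 = K * np.log1p(-np.clip(p_aug, 0, 1 - 1e-12)).sum(axis=1)
        w1 = psi * np.exp(log_q0)
        z[n_obs:] = rng.random(M - n_obs) < w1 / (w1 + (1 - psi))
        active = captured | z
        ll = _loglik_rows(Y_aug, active, center_idx, D2, K, lambda0, sigma)
        # --- centre moves -------------------------------------------------
        # z=0 individuals: Gibbs draw from the uniform prior
        inactive = ~active
        if inactive.any():
            center_idx[inactive] = rng.choice(suit_idx, size=int(inactive.sum()))
        # active individuals: neighbour-uniform MH with Hastings correction
        act_idx = np.flatnonzero(active)
        cur_c = center_idx[act_idx]
        pick = (rng.random(act_idx.size) * nb_counts[cur_c]).astype(int)
        prop_c = nb_table[cur_c, pick]
        ok = np.isin(prop_c, suit_idx, assume_unique=False) if suit_idx.size != Kc else np.ones(act_idx.size, bool)
        d2p = D2[prop_c]
        pp = 1.0 - np.exp(-lambda0 * np.exp(-d2p / (2.0 * sigma**2)))
        pp = np.clip(pp, 1e-300, 1 - 1e-12)
        yact = Y_aug[act_idx]
        ll_prop = np.sum(yact * np.log(pp) + (K - yact) * np.log1p(-pp), axis=1)
        log_r = ll_prop - ll + np.log(nb_counts[cur_c] / nb_counts[prop_c])
        accept = ok & (np.log(rng.random(act_idx.size)) < log_r)
        center_idx[act_idx[accept]] = prop_c[accept]
        ll = np.where(accept, ll_prop, ll)
        acc["centers"] += accept.mean()
        n_center_updates += 1
        # --- adapt step sizes during burn-in only ------------------------
        if it < burn and it > 0 and it % 100 == 0:
            for name in ("sigma", "lambda0"):
                rate = acc[name] / max(1, n_param_updates / 2)
                factor = 1.15 if rate > 0.4 else (0.87 if rate < 0.2 else 1.0)
                if name == "sigma":
                    step_sigma = float(np.clip(step_sigma * factor, 1e-3, 2.0))
                else:
                    step_lam = float(np.clip(step_lam * factor, 1e-3, 2.0))
        # --- record -------------------------------------------------------
        if it >= burn and (it - burn) % thin == 0 and kept < keep:
            n_super = int(z.sum())
            out["sigma"][kept] = sigma
            out["lambda0"][kept] = lambda0
            out["psi_aug"][kept] = psi
            out["n_super"][kept] = n_super
            out["density"][kept] = n_super / area * 100.0
            kept += 1

    for k in out:
        out[k] = out[k][:kept]
    geweke = {}
    converged = True
    for name, chain in out.items():
        if name == "density":
            continue
        try:
            gz = geweke_z(chain)
        except ValidationError:
            gz = np.nan
        geweke[name] = gz
        if not (np.isfinite(gz) and abs(gz) < GEWEKE_THRESHOLD):
            converged = False
    geweke["density"] = geweke.get("n_super", np.nan)
    return SecrPosterior(
        sigma=out["sigma"],
        lambda0=out["lambda0"],
        psi_aug=out["psi_aug"],
        n_super=out["n_super"],
        density=out["density"],
        acceptance=dict(
            sigma=acc["sigma"] / max(1, n_param_updates / 2),
            lambda0=acc["lambda0"] / max(1, n_param_updates / 2),
            centers=acc["centers"] / max(1, n_center_updates),
        ),
        geweke=geweke,
        iterations=iterations,
        m_aug=M,
        converged=converged,
    )


def summarize_density(
    posterior: SecrPosterior, state_space: StateSpace
) -> dict[str, float]:
    """Posterior mean, SD and central 95% interval of density (/100 km²)."""
    if posterior.density.size == 0:
        raise ValidationError("empty posterior")
    d = posterior.n_super / state_space.suitable_area * 100.0
    lo, hi = np.percentile(d, [2.5, 97.5])
    return dict(
        mean=float(d.mean()),
        sd=float(d.std(ddof=1)) if d.size > 1 else 0.0,
        q2_5=float(lo),
        q97_5=float(hi),
    )
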