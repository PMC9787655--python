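"""Metropolis-within-Gibbs sampler for the integrated SCR-movement model.

The posterior couples, for every augmented individual, a latent daily
trajectory, an inclusion indicator z, a reproductive state (fixed by stratum),
and a latent litter size, with the movement, detection and telemetry
parameters.  One sweep applies, in a fixed order:

1. ``update_params``  - conjugate Gibbs draws for the inclusion
   probabilities (Beta) and litter-size probabilities (Dirichlet), Gibbs
   refresh of latent litter sizes, then adaptive random-walk Metropolis for
   the movement and detection parameters (log scale for standard deviations,
   natural scale with support rejection for the persistence parameters).
2. ``update_location`` - single-site Metropolis on each daily location of
   detected individuals (local target: the two or three movement transitions
   that involve s_t, the encounter term and any telemetry terms at t).
3. ``update_initial_cell`` - an independence proposal for the first location
   drawn from the initial distribution itself, so the initial terms cancel in
   the acceptance ratio.
4. ``update_trajectory_block`` - the full-trajectory move for augmented,
   never-detected individuals: propose an entire trajectory from the movement
   prior; the prior proposal cancels every movement term, leaving exactly the
   ratio of non-detection likelihoods (and acceptance 1 for z = 0).
5. ``update_z`` - exact two-point Gibbs draw of each undetected individual's
   inclusion indicator.

Trajectories of z = 0 individuals are retained and refreshed from the prior,
which is what makes the z update conjugate.  Every kernel's acceptance ratio
equals the corresponding difference of :meth:`Sampler.joint_logdensity`
(plus proposal terms); the test suite audits this identity directly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
from scipy.special import betaln, expit, gammaln

try:  # optional JIT for the innermost encounter-likelihood loop
    from numba import njit

    @njit(cache=True)
    def _enc_ll_core(d2, log_eff, B, y, a0, a1, a2, sd2):
        n, T, J = d2.shape
        out = np.zeros((n, T))
        for i in range(n):
            for t in range(T):
                shift = a2 * B[i, t]
                mx = 0.0
                for j in range(J):
                    le = log_eff[t, j]
                    if le == -np.inf:
                        continue
                    e = a0 + a1 * le + shift - d2[i, t, j] / (2.0 * sd2)
                    if e > mx:
                        mx = e
                tot = np.exp(-mx)
                for j in range(J):
                    le = log_eff[t, j]
                    if le == -np.inf:
                        continue
                    tot += np.exp(
                        a0 + a1 * le + shift - d2[i, t, j] / (2.0 * sd2) - mx
                    )
                denom = mx + np.log(tot)
                yy = y[i, t]
                if yy < J:
                    out[i, t] = (
                        a0
                        + a1 * log_eff[t, yy]
                        + shift
                        - d2[i, t, yy] / (2.0 * sd2)
                        - denom
                    )
                else:
                    out[i, t] = -denom
        return out

except Exception:  # pragma: no cover - numba not installed
    _enc_ll_core = None

from . import movement as mv
from .landscape import PotentialSurface, StateSpace, SurveyRegion
from .observation import EncounterData, TelemetryData

__all__ = [
    "Priors",
    "ModelConfig",
    "Theta",
    "MCMCState",
    "Sampler",
    "behavioural_flags",
]


# ---------------------------------------------------------------------------
# priors and configuration


@dataclass(frozen=True)
class Priors:
    """Prior hyperparameters.

    Defaults are the deliberately vague choices of the motivating analysis:
    N(0, sd 10) for detection coefficients, Gamma(0.01, rate 0.01) for the
    standard deviations, Beta(1, 1) for persistence and inclusion
    probabilities, Dirichlet(1, 1, 1) for litter-size probabilities and
    N(50, sd 1) for the habitat-potential coefficient.
    """

    alpha_sd: float = 10.0
    sigma_shape: float = 0.01
    sigma_rate: float = 0.01
    sigma_det_shape: float = 0.01
    sigma_det_rate: float = 0.01
    gamma_a: float = 1.0
    gamma_b: float = 1.0
    psi_a: float = 1.0
    psi_b: float = 1.0
    omega_conc: tuple = (1.0, 1.0, 1.0)
    delta_mean: float = 50.0
    delta_sd: float = 1.0

    # hand-coded log-pdfs: these sit inside the MCMC inner loop
    def lp_alpha(self, a: float) -> float:
        sd = self.alpha_sd
        return -0.9189385332046727 - np.log(sd) - 0.5 * (a / sd) ** 2

    @staticmethod
    def _lp_gamma_dist(x: float, shape: float, rate: float) -> float:
        if x <= 0:
            return -np.inf
        return (
            shape * np.log(rate)
            - gammaln(shape)
            + (shape - 1.0) * np.log(x)
            - rate * x
        )

    @staticmethod
    def _lp_beta_dist(x: float, a: float, b: float) -> float:
        if not 0.0 <= x <= 1.0:
            return -np.inf
        term = 0.0
        if a != 1.0:
            term += (a - 1.0) * (np.log(x) if x > 0 else -np.inf)
        if b != 1.0:
            term += (b - 1.0) * (np.log1p(-x) if x < 1 else -np.inf)
        return term - betaln(a, b)

    def lp_sigma(self, s: float) -> float:
        return self._lp_gamma_dist(s, self.sigma_shape, self.sigma_rate)

    def lp_sigma_det(self, s: float) -> float:
        return self._lp_gamma_dist(s, self.sigma_det_shape, self.sigma_det_rate)

    def lp_gamma(self, g: float) -> float:
        return self._lp_beta_dist(g, self.gamma_a, self.gamma_b)

    def lp_psi(self, p: float) -> float:
        return self._lp_beta_dist(p, self.psi_a, self.psi_b)

    def lp_omega(self, w: np.ndarray) -> float:
        conc = np.asarray(self.omega_conc, dtype=float)
        w = np.asarray(w, dtype=float)
        if np.any(w <= 0):
            return -np.inf
        return float(
            gammaln(conc.sum())
            - gammaln(conc).sum()
            + ((conc - 1.0) * np.log(w)).sum()
        )

    def lp_delta(self, d: float) -> float:
        sd = self.delta_sd
        return (
            -0.9189385332046727
            - np.log(sd)
            - 0.5 * ((d - self.delta_mean) / sd) ** 2
        )


@dataclass
class ModelConfig:
    """Structural and sampler configuration.

    ``m_per_state`` gives the *total* augmented-population size per
    reproductive state (observed individuals included); the defaults are the
    case-study values.  ``delta`` fixes the habitat-potential coefficient
    (case-study mode, where it is not estimable); set ``delta=None`` to
    sample it under its informative normal prior.
    """

    movement_model: str = "crw"
    priors: Priors = field(default_factory=Priors)
    m_per_state: Mapping[int, int] = field(
        default_factory=lambda: {1: 803, 2: 480, 3: 317}
    )
    class_of_state: Mapping[int, str] = field(
        default_factory=lambda: {1: "male", 2: "female", 3: "female"}
    )
    delta: Optional[float] = 50.0
    target_accept: float = 0.35
    adapt: bool = True
    # Metropolis repetitions of the parameter block per sweep; the scalar
    # parameters are far cheaper to update than the latent trajectories, so
    # extra repetitions buy effective sample size almost for free
    param_repeats: int = 5
    store_trajectories: bool = True
    trajectory_thin: int = 5
    init: Mapping[str, float] = field(
        default_factory=lambda: {
            "sigma": 10.0,
            "gamma": 0.5,
            "alpha0": -5.0,
            "alpha1": 1.0,
            "alpha2": 0.0,
            "sigma_det": 5.0,
            "psi": 0.3,
        }
    )


# ---------------------------------------------------------------------------
# latent state


@dataclass
class Theta:
    """Parameter vector.  ``sigma``/``gamma`` are per-movement-class,
    ``psi`` per reproductive stratum."""

    sigma: np.ndarray
    gamma: np.ndarray
    delta: float
    alpha0: float
    alpha1: float
    alpha2: float
    sigma_det: float
    psi: np.ndarray
    omega: np.ndarray

    def copy(self) -> "Theta":
        return Theta(
            sigma=self.sigma.copy(),
            gamma=self.gamma.copy(),
            delta=self.delta,
            alpha0=self.alpha0,
            alpha1=self.alpha1,
            alpha2=self.alpha2,
            sigma_det=self.sigma_det,
            psi=self.psi.copy(),
            omega=self.omega.copy(),
        )


@dataclass
class MCMCState:
    """Complete latent state: trajectories ``s`` (M, T, 2), inclusion
    indicators ``z``, litter sizes ``n`` (0 outside state 3) and ``theta``."""

    s: np.ndarray
    z: np.ndarray
    n: np.ndarray
    theta: Theta

    def copy(self) -> "MCMCState":
        return MCMCState(
            s=self.s.copy(), z=self.z.copy(), n=self.n.copy(), theta=self.theta.copy()
        )


def behavioural_flags(
    y: np.ndarray, n_traps: int, surveyed: np.ndarray
) -> np.ndarray:
    """Behavioural-response flags implied by encounter histories: 1 on the
    first surveyed occasion strictly after an individual's first capture."""
    y = np.asarray(y)
    n, T = y.shape
    det = y < n_traps
    B = np.zeros((n, T), dtype=np.int8)
    # next surveyed occasion strictly after t (T = none)
    nxt = np.full(T + 1, T, dtype=int)
    for t in range(T - 1, -1, -1):
        nxt[t] = t + 1 if (t + 1 < T and surveyed[t + 1]) else nxt[t + 1]
    for i in np.flatnonzero(det.any(axis=1)):
        t0 = int(det[i].argmax())
        t1 = nxt[t0]
        if t1 < T:
            B[i, t1] = 1
    return B


# ---------------------------------------------------------------------------
# model data (internal)


class _ModelData:
    """Validated, array-ready view of one dataset for the sampler."""

    def __init__(
        self,
        encounters: EncounterData,
        telemetry: Optional[TelemetryData],
        state_space: StateSpace,
        region: SurveyRegion,
        potential: PotentialSurface,
        config: ModelConfig,
    ):
        self.config = config
        self.state_space = state_space
        self.region = region
        self.potential = potential
        enc = encounters
        self.n_obs = enc.n_individuals
        self.T = enc.n_occasions
        self.J = enc.n_traps
        if region.n_traps != self.J:
            raise ValueError("survey region and effort disagree on trap count")
        self.effort = enc.effort
        with np.errstate(divide="ignore"):
            self.log_eff = np.log(self.effort)
        self.surveyed = self.effort.sum(axis=1) > 0
        pos = self.effort > 0
        self.mean_log_effort = float(self.log_eff[pos].mean()) if pos.any() else 1.0
        self.trap_centroids = region.centroids

        # roster: observed individuals first, then augmentation per stratum
        self.strata = sorted(config.m_per_state)
        if not np.isin(enc.state, self.strata).all():
            raise ValueError("encounter states outside configured strata")
        states = [enc.state]
        for r in self.strata:
            n_obs_r = int((enc.state == r).sum())
            n_aug = config.m_per_state[r] - n_obs_r
            if n_aug < 0:
                raise ValueError(
                    f"m_per_state[{r}] smaller than the number of observed "
                    f"state-{r} individuals"
                )
            states.append(np.full(n_aug, r, dtype=np.int64))
        self.state = np.concatenate(states)
        self.M = len(self.state)
        self.stratum_idx = np.searchsorted(self.strata, self.state)
        self.n_strata = len(self.strata)

        labels = sorted({config.class_of_state[r] for r in self.strata})
        self.class_labels = labels
        lab_of = {r: labels.index(config.class_of_state[r]) for r in self.strata}
        self.class_idx = np.array([lab_of[r] for r in self.state], dtype=np.intp)
        self.n_classes = len(labels)

        self.litter_obs = np.zeros(self.M, dtype=np.int64)
        self.litter_obs[: self.n_obs] = enc.litter
        self.observed = np.zeros(self.M, dtype=bool)
        self.observed[: self.n_obs] = True

        y_full = np.full((self.M, self.T), self.J, dtype=np.int64)
        y_full[: self.n_obs] = enc.y
        self.set_observations(y_full)

        # telemetry, grouped per occasion
        tel = telemetry if telemetry is not None else TelemetryData.empty()
        if tel.n_fixes and tel.individual.max(initial=-1) >= self.n_obs:
            raise ValueError("telemetry references unknown individuals")
        if tel.n_fixes and tel.occasion.max(initial=0) >= self.T:
            raise ValueError("telemetry references unknown occasions")
        self.fix_ind = tel.individual
        self.fix_occ = tel.occasion
        self.fix_u = tel.u
        cov = tel.covariances()
        self.fix_ecov = cov  # None, or (n_fixes, 2, 2) with zeros for GPS
        self.n_fixes = tel.n_fixes
        self.tagged = np.zeros(self.M, dtype=bool)
        if self.n_fixes:
            self.tagged[np.unique(self.fix_ind)] = True
        self._fixes_at_t = [
            np.flatnonzero(self.fix_occ == t) for t in range(self.T)
        ]

    def set_observations(self, y_full: np.ndarray) -> None:
        """Install encounter histories (all M rows) and derive masks.

        Used at construction and by the prior-invariance (Geweke) harness,
        where the data are re-simulated each iteration.
        """
        self.y_full = y_full
        self.detected = (y_full < self.J).any(axis=1)
        self.det_rows = np.flatnonzero(self.detected)
        self.undet_rows = np.flatnonzero(~self.detected)
        self.B_full = behavioural_flags(y_full, self.J, self.surveyed)


# ---------------------------------------------------------------------------
# the sampler


class Sampler:
    """Metropolis-within-Gibbs kernels over one :class:`_ModelData`.

    Set ``record_proposals = True`` to append per-proposal diagnostics
    (proposed values, log acceptance ratios, decisions) to
    ``proposal_log`` - used by the acceptance-ratio audit tests.
    """

    def __init__(
        self,
        data: _ModelData,
        rng: np.random.Generator,
        state: Optional[MCMCState] = None,
    ):
        self.data = data
        self.config = data.config
        self.rng = rng
        self.adapting = False
        self._adapt_step = 1
        self.record_proposals = False
        self.proposal_log: list[dict] = []
        d = data
        self.scales = {
            "sigma": np.full(d.n_classes, 0.15),
            "gamma": np.full(d.n_classes, 0.10),
            "delta": 0.3,
            "alpha0": 0.5,
            "alpha1": 0.2,
            "alpha2": 0.5,
            "sigma_det": 0.08,
            "alpha_ridge": 1.0,
            "loc": np.full(d.M, 5.0),
        }
        self._loc_acc = np.zeros(d.M)
        self._loc_try = np.zeros(d.M)
        self.state = state if state is not None else self.initial_state()
        lp = self.joint_logdensity()
        if not np.isfinite(lp):
            raise RuntimeError(
                f"non-finite joint log-density at initialization ({lp}); "
                "check data/state consistency"
            )

    # -- initialization ----------------------------------------------------

    def _interp_observed_path(self, i: int) -> np.ndarray:
        """Linear interpolation through an observed individual's known
        points (trap centroids of detections, telemetry fixes), snapped to
        ice at occasion 1."""
        d = self.data
        occ: list[float] = []
        pts: list[np.ndarray] = []
        det_t = np.flatnonzero(d.y_full[i] < d.J)
        for t in det_t:
            occ.append(t)
            pts.append(d.trap_centroids[d.y_full[i, t]])
        if d.n_fixes:
            for k in np.flatnonzero(d.fix_ind == i):
                occ.append(float(d.fix_occ[k]))
                pts.append(d.fix_u[k])
        order = np.argsort(occ)
        occ_a = np.asarray(occ, dtype=float)[order]
        pts_a = np.asarray(pts, dtype=float)[order]
        ts = np.arange(d.T, dtype=float)
        s = np.column_stack(
            [np.interp(ts, occ_a, pts_a[:, 0]), np.interp(ts, occ_a, pts_a[:, 1])]
        )
        # jitter identical consecutive points slightly and clamp to extent
        xmin, xmax, ymin, ymax = d.state_space.extent
        eps = 1e-6 * d.state_space.resolution_km
        s[:, 0] = np.clip(s[:, 0], xmin, xmax - eps)
        s[:, 1] = np.clip(s[:, 1], ymin, ymax - eps)
        return s

    def _snap_to_ice(self, p: np.ndarray) -> np.ndarray:
        """Move a first-occasion location to the nearest ice-cell centroid if
        it starts in a zero-probability cell."""
        d = self.data
        row, col = d.state_space.cell_rowcol(p)
        if d.state_space.ice[row, col]:
            return p
        ice_rc = np.argwhere(d.state_space.ice == 1)
        cent = (ice_rc[:, ::-1] + 0.5) * d.state_space.resolution_km
        return cent[np.argmin(((cent - p) ** 2).sum(axis=1))]

    def initial_state(self) -> MCMCState:
        d, cfg, rng = self.data, self.config, self.rng
        init = cfg.init
        theta = Theta(
            sigma=np.full(d.n_classes, float(init["sigma"])),
            gamma=np.full(
                d.n_classes,
                float(init["gamma"]) if cfg.movement_model == "crw" else 0.0,
            ),
            delta=float(
                cfg.delta if cfg.delta is not None else cfg.priors.delta_mean
            ),
            alpha0=float(init["alpha0"]),
            alpha1=float(init["alpha1"]),
            alpha2=float(init["alpha2"]),
            sigma_det=float(init["sigma_det"]),
            psi=np.full(d.n_strata, float(init["psi"])),
            omega=np.ones(3) / 3.0,
        )
        sig = theta.sigma[d.class_idx]
        gam = theta.gamma[d.class_idx]
        s, _ = mv.simulate_paths(
            d.state_space, d.potential, sig, gam, theta.delta, d.T, rng
        )
        for i in d.det_rows:
            path = self._interp_observed_path(int(i))
            path[0] = self._snap_to_ice(path[0])
            s[i] = path
        z = np.zeros(d.M, dtype=np.int8)
        z[d.det_rows] = 1
        z[d.undet_rows] = (rng.random(len(d.undet_rows)) < theta.psi[
            d.stratum_idx[d.undet_rows]
        ]).astype(np.int8)
        n = np.zeros(d.M, dtype=np.int64)
        mothers = d.state == 3
        n[mothers] = rng.choice(3, size=int(mothers.sum()), p=theta.omega) + 1
        n[d.observed & mothers] = d.litter_obs[d.observed & mothers]
        self.scales["loc"] = np.full(d.M, 0.5 * float(init["sigma"]))
        return MCMCState(s=s, z=z, n=n, theta=theta)

    # -- likelihood components --------------------------------------------

    def _sig_gam(self, theta: Theta, rows: np.ndarray):
        ci = self.data.class_idx[rows]
        return theta.sigma[ci], theta.gamma[ci]

    def movement_ll(
        self, s: np.ndarray, rows: np.ndarray, theta: Theta
    ) -> np.ndarray:
        """Per-individual movement log-density for ``rows``."""
        sig, gam = self._sig_gam(theta, rows)
        return mv.path_logdensity(
            s[rows], sig, gam, theta.delta, self.data.state_space, self.data.potential
        )

    def _enc_ll_matrix(
        self, s: np.ndarray, rows: np.ndarray, theta: Theta, d2: np.ndarray = None
    ) -> np.ndarray:
        """(len(rows), T) encounter log-likelihood terms log xi_{y_it}."""
        d = self.data
        if d2 is None:
            d2 = ((s[:, :, None, :] - d.trap_centroids) ** 2).sum(axis=-1)
        if _enc_ll_core is not None:
            return _enc_ll_core(
                np.ascontiguousarray(d2),
                d.log_eff,
                np.ascontiguousarray(d.B_full[rows]),
                np.ascontiguousarray(d.y_full[rows]),
                theta.alpha0,
                theta.alpha1,
                theta.alpha2,
                theta.sigma_det**2,
            )
        eta = (
            theta.alpha0
            + theta.alpha1 * d.log_eff[None]
            + theta.alpha2 * d.B_full[rows, :, None]
            - d2 / (2.0 * theta.sigma_det**2)
        )
        eta = np.where(np.isneginf(d.log_eff[None]), -np.inf, eta)
        m = np.maximum(eta.max(axis=-1), 0.0)
        with np.errstate(invalid="ignore"):
            ex = np.exp(eta - m[..., None])
        ex = np.where(np.isneginf(eta), 0.0, ex)
        denom = m + np.log(np.exp(-m) + ex.sum(axis=-1))  # (n, T)
        y = d.y_full[rows]
        out = -denom
        hit = y < d.J
        ii, tt = np.nonzero(hit)
        out[ii, tt] = eta[ii, tt, y[ii, tt]] - denom[ii, tt]
        return out

    def encounter_ll(
        self,
        s: np.ndarray,
        rows: np.ndarray,
        theta: Theta,
        per_row: bool = False,
        d2: np.ndarray = None,
    ):
        ll = self._enc_ll_matrix(s[rows], rows, theta, d2=d2).sum(axis=1)
        return ll if per_row else float(ll.sum())

    def _enc_ll_col(
        self, s_col: np.ndarray, rows: np.ndarray, t: int, theta: Theta
    ) -> np.ndarray:
        """Encounter log-likelihood of occasion ``t`` only, for candidate
        locations ``s_col`` (len(rows), 2)."""
        d = self.data
        if not d.surveyed[t]:
            return np.zeros(len(rows))
        d2 = ((s_col[:, None, :] - d.trap_centroids) ** 2).sum(axis=-1)
        eta = (
            theta.alpha0
            + theta.alpha1 * d.log_eff[t][None]
            + theta.alpha2 * d.B_full[rows, t, None]
            - d2 / (2.0 * theta.sigma_det**2)
        )
        eta = np.where(np.isneginf(d.log_eff[t][None]), -np.inf, eta)
        m = np.maximum(eta.max(axis=-1), 0.0)
        with np.errstate(invalid="ignore"):
            ex = np.exp(eta - m[..., None])
        ex = np.where(np.isneginf(eta), 0.0, ex)
        denom = m + np.log(np.exp(-m) + ex.sum(axis=-1))
        y = d.y_full[rows, t]
        out = -denom
        hit = y < d.J
        out[hit] = eta[hit, y[hit]] - denom[hit]
        return out

    def telemetry_ll(
        self, s: np.ndarray, theta: Theta, fixes: Optional[np.ndarray] = None
    ) -> float:
        """Telemetry log-likelihood; ``fixes`` restricts to a subset."""
        d = self.data
        if d.n_fixes == 0:
            return 0.0
        k = np.arange(d.n_fixes) if fixes is None else fixes
        if len(k) == 0:
            return 0.0
        resid = d.fix_u[k] - s[d.fix_ind[k], d.fix_occ[k]]
        v = theta.sigma_det**2
        if d.fix_ecov is None:
            return float(
                (-np.log(2.0 * np.pi * v) - (resid**2).sum(axis=1) / (2.0 * v)).sum()
            )
        cov = d.fix_ecov[k].copy()
        cov[:, 0, 0] += v
        cov[:, 1, 1] += v
        det = cov[:, 0, 0] * cov[:, 1, 1] - cov[:, 0, 1] ** 2
        quad = (
            cov[:, 1, 1] * resid[:, 0] ** 2
            - 2.0 * cov[:, 0, 1] * resid[:, 0] * resid[:, 1]
            + cov[:, 0, 0] * resid[:, 1] ** 2
        ) / det
        return float(
            (-np.log(2.0 * np.pi) - 0.5 * np.log(det) - 0.5 * quad).sum()
        )

    def _tel_ll_at(
        self, s_col: np.ndarray, rows: np.ndarray, t: int, theta: Theta
    ) -> np.ndarray:
        """Per-row telemetry log-likelihood of fixes at occasion ``t`` with
        candidate daily locations ``s_col``."""
        d = self.data
        out = np.zeros(len(rows))
        ks = d._fixes_at_t[t] if d.n_fixes else np.empty(0, dtype=int)
        if len(ks) == 0:
            return out
        pos_lookup = np.full(d.M, -1)
        pos_lookup[rows] = np.arange(len(rows))
        p_idx = pos_lookup[d.fix_ind[ks]]
        keep = p_idx >= 0
        if not keep.any():
            return out
        ks = ks[keep]
        p_idx = p_idx[keep]
        resid = d.fix_u[ks] - s_col[p_idx]
        v = theta.sigma_det**2
        if d.fix_ecov is None:
            lp = -np.log(2.0 * np.pi * v) - (resid**2).sum(axis=1) / (2.0 * v)
        else:
            cov = d.fix_ecov[ks].copy()
            cov[:, 0, 0] += v
            cov[:, 1, 1] += v
            det = cov[:, 0, 0] * cov[:, 1, 1] - cov[:, 0, 1] ** 2
            quad = (
                cov[:, 1, 1] * resid[:, 0] ** 2
                - 2.0 * cov[:, 0, 1] * resid[:, 0] * resid[:, 1]
                + cov[:, 0, 0] * resid[:, 1] ** 2
            ) / det
            lp = -np.log(2.0 * np.pi) - 0.5 * np.log(det) - 0.5 * quad
        np.add.at(out, p_idx, lp)
        return out

    def _window_steps(
        self, s_rows: np.ndarray, rows: np.ndarray, lo: int, hi: int, theta: Theta
    ) -> np.ndarray:
        """Per-step log-densities of transitions lo..hi-1 on the slice
        ``s_rows[:, lo:hi+1]``.  Transition ``lo`` is evaluated
        persistence-free (as if first), so callers only consume transitions
        ``> lo`` unless ``lo == 0``."""
        sig, gam = self._sig_gam(theta, rows)
        _, steps = mv.path_logdensity(
            s_rows[:, lo : hi + 1],
            sig,
            gam,
            theta.delta,
            self.data.state_space,
            self.data.potential,
            per_step=True,
        )
        return steps

    def _trans_lp(
        self, s_rows: np.ndarray, rows: np.ndarray, k: int, theta: Theta
    ) -> np.ndarray:
        """Log-density of transition k -> k+1 for the given rows (trajectory
        slices ``s_rows`` of shape (len(rows), T, 2))."""
        sig, gam = self._sig_gam(theta, rows)
        lo = max(k - 1, 0)
        _, steps = mv.path_logdensity(
            s_rows[:, lo : k + 2],
            sig,
            gam,
            theta.delta,
            self.data.state_space,
            self.data.potential,
            per_step=True,
        )
        return steps[:, k - lo]

    def _init_lp(self, s1: np.ndarray) -> np.ndarray:
        """Initial-location log-density (cell categorical x uniform)."""
        d = self.data
        out = np.full(len(s1), -np.inf)
        ok = d.state_space.contains(s1)
        if ok.any():
            g = d.state_space.cell_index(s1[ok])
            with np.errstate(divide="ignore"):
                out[ok] = np.log(d.state_space.pi[g]) - 2.0 * np.log(
                    d.state_space.resolution_km
                )
        return out

    # -- joint density -----------------------------------------------------

    def joint_logdensity(self, state: Optional[MCMCState] = None) -> float:
        """Full joint log-density of latent state, data and priors.

        Components: movement prior of every trajectory (z = 0 included, as
        those trajectories are retained), encounter likelihood of included
        individuals, telemetry likelihood, inclusion and litter pmfs, and the
        parameter priors.  Raises on NaN with component attribution.
        """
        st = self.state if state is None else state
        d, pr = self.data, self.config.priors
        th = st.theta
        all_rows = np.arange(d.M)
        comp = {}
        comp["movement"] = float(self.movement_ll(st.s, all_rows, th).sum())
        zr = np.flatnonzero(st.z == 1)
        comp["encounter"] = self.encounter_ll(st.s, zr, th)
        comp["telemetry"] = self.telemetry_ll(st.s, th)
        psi_i = th.psi[d.stratum_idx]
        with np.errstate(divide="ignore"):
            comp["inclusion"] = float(
                np.where(st.z == 1, np.log(psi_i), np.log1p(-psi_i)).sum()
            )
        mothers = d.state == 3
        with np.errstate(divide="ignore"):
            comp["litter"] = float(np.log(th.omega[st.n[mothers] - 1]).sum())
        lp_prior = (
            pr.lp_alpha(th.alpha0)
            + pr.lp_alpha(th.alpha1)
            + pr.lp_alpha(th.alpha2)
            + pr.lp_sigma_det(th.sigma_det)
            + sum(pr.lp_sigma(s) for s in th.sigma)
            + sum(pr.lp_psi(p) for p in th.psi)
            + pr.lp_omega(th.omega)
        )
        if self.config.movement_model == "crw":
            lp_prior += sum(pr.lp_gamma(g) for g in th.gamma)
        if self.config.delta is None:
            lp_prior += pr.lp_delta(th.delta)
        comp["prior"] = float(lp_prior)
        for name, v in comp.items():
            if np.isnan(v):
                raise FloatingPointError(f"NaN in joint log-density component {name!r}")
        return float(sum(comp.values()))

    # -- Gibbs kernels -----------------------------------------------------

    def update_z(self, rows: Optional[np.ndarray] = None) -> None:
        """Exact Gibbs draw of inclusion indicators for undetected
        individuals: odds(z=1) = psi_r * P(all non-detections | s) / (1-psi)."""
        d, st = self.data, self.state
        rows = d.undet_rows if rows is None else np.asarray(rows)
        if np.any(d.detected[rows]):
            raise ValueError("update_z applies only to never-detected individuals")
        if len(rows) == 0:
            return
        nd_ll = self.encounter_ll(st.s, rows, st.theta, per_row=True)
        psi = st.theta.psi[d.stratum_idx[rows]]
        with np.errstate(divide="ignore"):
            logit = np.log(psi) - np.log1p(-psi) + nd_ll
        p1 = expit(logit)
        st.z[rows] = (self.rng.random(len(rows)) < p1).astype(np.int8)
        if self.record_proposals:
            self.proposal_log.append(
                {"kernel": "z", "rows": rows, "p1": p1, "new": st.z[rows].copy()}
            )

    def update_litters(self) -> None:
        """Gibbs refresh of latent litter sizes (state-3, unobserved):
        their full conditional is the litter-size categorical itself."""
        d, st = self.data, self.state
        rows = np.flatnonzero((d.state == 3) & ~d.observed)
        if len(rows):
            st.n[rows] = (
                self.rng.choice(3, size=len(rows), p=st.theta.omega / st.theta.omega.sum())
                + 1
            )

    def _gibbs_psi(self) -> None:
        d, st, pr = self.data, self.state, self.config.priors
        for r_pos in range(d.n_strata):
            in_r = d.stratum_idx == r_pos
            k = int(st.z[in_r].sum())
            m = int(in_r.sum())
            st.theta.psi[r_pos] = self.rng.beta(pr.psi_a + k, pr.psi_b + m - k)

    def _gibbs_omega(self) -> None:
        d, st, pr = self.data, self.state, self.config.priors
        mothers = d.state == 3
        counts = np.bincount(st.n[mothers] - 1, minlength=3) if mothers.any() else np.zeros(3)
        conc = np.asarray(pr.omega_conc, dtype=float) + counts
        st.theta.omega = self.rng.dirichlet(conc)

    # -- Metropolis kernels ------------------------------------------------

    def _mh_scalar(self, name, cur, prop, delta_lp, setter) -> bool:
        accept = np.log(self.rng.random()) < delta_lp
        if accept:
            setter(prop)
        if self.record_proposals:
            self.proposal_log.append(
                {
                    "kernel": name,
                    "current": cur,
                    "proposed": prop,
                    "log_accept_ratio": float(delta_lp),
                    "accepted": bool(accept),
                }
            )
        if self.adapting:
            a = min(1.0, np.exp(min(delta_lp, 0.0)))
            rate = self._adapt_step ** -0.6
            self.scales[name] = np.asarray(self.scales[name], dtype=float)
            if np.ndim(self.scales[name]) == 0:
                self.scales[name] = float(
                    self.scales[name] * np.exp(rate * (a - self.config.target_accept))
                )
        return bool(accept)

    def _mh_class_param(
        self, name: str, c: int, rows_obs: np.ndarray, ll_cur: float
    ) -> float:
        """Adaptive RW Metropolis for sigma_c (log scale) or gamma_c
        (natural scale, support-rejecting), proposed *jointly* with fresh
        prior trajectories for the class's excluded (z = 0) phantom
        individuals.

        Retained phantom trajectories otherwise dominate the
        movement-parameter conditional (they are prior draws at the current
        value), freezing the chain.  Proposing them from the prior at the
        candidate parameter cancels their terms in the acceptance ratio
        exactly - they carry no likelihood - which is equivalent to
        integrating them out.  The ratio then involves only the movement
        terms of data-bearing rows (detected or currently included).

        ``ll_cur`` is the current movement log-likelihood over those
        data-bearing class rows; the updated value is returned for reuse.
        """
        d, st, pr = self.data, self.state, self.config.priors
        th = st.theta
        scale = float(np.asarray(self.scales[name])[c])
        cur = float(getattr(th, name)[c])
        if name == "sigma":
            prop = float(np.exp(np.log(cur) + scale * self.rng.standard_normal()))
            prior_diff = pr.lp_sigma(prop) - pr.lp_sigma(cur) + np.log(prop) - np.log(cur)
        else:
            prop = float(cur + scale * self.rng.standard_normal())
            if not 0.0 <= prop <= 1.0:
                self._log_and_adapt_class(name, c, cur, prop, -np.inf, False)
                return ll_cur
            prior_diff = pr.lp_gamma(prop) - pr.lp_gamma(cur)
        th_new = th.copy()
        getattr(th_new, name)[c] = prop
        ll_new = float(self.movement_ll(st.s, rows_obs, th_new).sum())
        rows_u = d.undet_rows[
            (d.class_idx[d.undet_rows] == c) & (st.z[d.undet_rows] == 0)
        ]
        delta_lp = ll_new - ll_cur + prior_diff
        accept = np.log(self.rng.random()) < delta_lp
        s_prop = None
        if accept:
            getattr(th, name)[c] = prop
            if len(rows_u):
                # the phantom trajectories cancel from the ratio, so their
                # proposal draw is deferred until the move is accepted
                sig_u, gam_u = self._sig_gam(th_new, rows_u)
                s_prop, _ = mv.simulate_paths(
                    d.state_space, d.potential, sig_u, gam_u, th_new.delta, d.T, self.rng
                )
                st.s[rows_u] = s_prop
        self._log_and_adapt_class(name, c, cur, prop, delta_lp, accept, s_prop, rows_u)
        return ll_new if accept else ll_cur

    def _log_and_adapt_class(
        self, name, c, cur, prop, delta_lp, accept, s_prop=None, rows_u=None
    ):
        if self.record_proposals:
            self.proposal_log.append(
                {
                    "kernel": name,
                    "class": c,
                    "current": cur,
                    "proposed": prop,
                    "log_accept_ratio": float(delta_lp),
                    "accepted": bool(accept),
                    "trajectory_proposal": s_prop,
                    "trajectory_rows": rows_u,
                }
            )
        if self.adapting:
            a = 0.0 if np.isneginf(delta_lp) else min(1.0, np.exp(min(delta_lp, 0.0)))
            rate = self._adapt_step ** -0.6
            self.scales[name][c] *= np.exp(rate * (a - self.config.target_accept))

    def update_params(self) -> None:
        """Parameter block: conjugate psi/omega/litter Gibbs draws, then
        random-walk Metropolis for movement and detection parameters."""
        d, st, pr = self.data, self.state, self.config.priors
        self._gibbs_psi()
        self._gibbs_omega()
        self.update_litters()
        th = st.theta
        # the latent locations are fixed within this block, so the trap
        # distance matrix of included individuals is shared by all proposals
        zrows = np.flatnonzero(st.z == 1)
        d2_z = ((st.s[zrows][:, :, None, :] - d.trap_centroids) ** 2).sum(axis=-1)
        for _rep in range(max(1, self.config.param_repeats)):
            data_rows = np.flatnonzero(d.detected | (st.z == 1))
            for c in range(d.n_classes):
                rows_c = data_rows[d.class_idx[data_rows] == c]
                ll_cur = float(self.movement_ll(st.s, rows_c, th).sum())
                ll_cur = self._mh_class_param("sigma", c, rows_c, ll_cur)
                if self.config.movement_model == "crw":
                    self._mh_class_param("gamma", c, rows_c, ll_cur)
            if self.config.delta is None:
                # same joint parameter + phantom-trajectory move as the
                # class parameters, over all classes at once
                cur = th.delta
                prop = cur + self.scales["delta"] * self.rng.standard_normal()
                th_new = th.copy()
                th_new.delta = prop
                dlp = (
                    float(self.movement_ll(st.s, data_rows, th_new).sum())
                    - float(self.movement_ll(st.s, data_rows, th).sum())
                    + pr.lp_delta(prop)
                    - pr.lp_delta(cur)
                )
                rows_u = d.undet_rows[st.z[d.undet_rows] == 0]

                def _set_delta(v, rows_u=rows_u):
                    th.delta = v
                    if len(rows_u):
                        sig_u, gam_u = self._sig_gam(th, rows_u)
                        s_prop, _ = mv.simulate_paths(
                            d.state_space, d.potential, sig_u, gam_u, v, d.T, self.rng
                        )
                        st.s[rows_u] = s_prop

                self._mh_scalar("delta", cur, prop, dlp, _set_delta)
            enc_cur = self.encounter_ll(st.s, zrows, th, d2=d2_z)
            for name in ("alpha0", "alpha1", "alpha2"):
                cur = getattr(th, name)
                prop = cur + float(np.asarray(self.scales[name])) * self.rng.standard_normal()
                th_new = th.copy()
                setattr(th_new, name, prop)
                enc_new = self.encounter_ll(st.s, zrows, th_new, d2=d2_z)
                dlp = enc_new - enc_cur + pr.lp_alpha(prop) - pr.lp_alpha(cur)
                if self._mh_scalar(
                    name, cur, prop, dlp, lambda v, n=name: setattr(th, n, v)
                ):
                    enc_cur = enc_new
            # joint move along the weakly identified (alpha0, alpha1) ridge:
            # raising the intercept while lowering the effort slope leaves the
            # logit at mean log-effort unchanged, so coordinate-wise proposals
            # crawl; this direction is where the posterior is wide
            eps = float(np.asarray(self.scales["alpha_ridge"])) * self.rng.standard_normal()
            prop_pair = (th.alpha0 + eps, th.alpha1 - eps / d.mean_log_effort)
            th_new = th.copy()
            th_new.alpha0, th_new.alpha1 = prop_pair
            enc_new = self.encounter_ll(st.s, zrows, th_new, d2=d2_z)
            dlp = (
                enc_new
                - enc_cur
                + pr.lp_alpha(prop_pair[0])
                - pr.lp_alpha(th.alpha0)
                + pr.lp_alpha(prop_pair[1])
                - pr.lp_alpha(th.alpha1)
            )

            def _set_pair(v, th=th):
                th.alpha0, th.alpha1 = v

            if self._mh_scalar(
                "alpha_ridge", (th.alpha0, th.alpha1), prop_pair, dlp, _set_pair
            ):
                enc_cur = enc_new
            cur = th.sigma_det
            prop = float(
                np.exp(
                    np.log(cur)
                    + float(np.asarray(self.scales["sigma_det"]))
                    * self.rng.standard_normal()
                )
            )
            th_new = th.copy()
            th_new.sigma_det = prop
            dlp = (
                self.encounter_ll(st.s, zrows, th_new, d2=d2_z)
                - enc_cur
                + self.telemetry_ll(st.s, th_new)
                - self.telemetry_ll(st.s, th)
                + pr.lp_sigma_det(prop)
                - pr.lp_sigma_det(cur)
                + np.log(prop)
                - np.log(cur)
            )
            self._mh_scalar(
                "sigma_det", cur, prop, dlp, lambda v: setattr(th, "sigma_det", v)
            )

    def update_location(
        self, t: Optional[int] = None, rows: Optional[np.ndarray] = None
    ) -> None:
        """Single-site Metropolis on daily locations of detected (or included)
        individuals.  The local target collects every term of the joint that
        involves s_t: the transitions into and out of occasion t (including
        the t+1 -> t+2 transition whose correlated-walk mean contains s_t),
        the initial-distribution term at t = 0, the encounter term and any
        telemetry fixes at t.

        With ``t=None`` all occasions are scanned in three interleaved
        passes: sites three or more occasions apart share no factor of the
        target, so each pass proposes its sites simultaneously and decides
        them independently from two whole-path density evaluations.
        """
        d, st = self.data, self.state
        if t is None:
            for color in range(min(3, d.T)):
                self._update_location_sites(
                    np.arange(color, d.T, 3), rows
                )
            return
        rows = d.det_rows if rows is None else np.asarray(rows)
        if len(rows) == 0:
            return
        th = st.theta
        s_rows = st.s[rows]
        prop_col = s_rows[:, t] + self.scales["loc"][
            rows, None
        ] * self.rng.standard_normal((len(rows), 2))
        inside = d.state_space.contains(prop_col)
        s_new = s_rows.copy()
        s_new[:, t] = prop_col
        # every transition whose density involves s_t (the t+1 -> t+2 mean
        # contains s_t through the persistence term)
        ks = [k for k in (t - 1, t, t + 1) if 0 <= k <= d.T - 2]
        lo = max(t - 2, 0)
        hi = min(t + 2, d.T - 1)
        idx = [k - lo for k in ks]
        steps_new = self._window_steps(s_new, rows, lo, hi, th)
        steps_old = self._window_steps(s_rows, rows, lo, hi, th)
        dlp = steps_new[:, idx].sum(axis=1) - steps_old[:, idx].sum(axis=1)
        if t == 0:
            dlp += self._init_lp(prop_col) - self._init_lp(s_rows[:, 0])
        zmask = st.z[rows] == 1
        enc = self._enc_ll_col(prop_col, rows, t, th) - self._enc_ll_col(
            s_rows[:, t], rows, t, th
        )
        dlp += np.where(zmask, enc, 0.0)
        dlp += self._tel_ll_at(prop_col, rows, t, th) - self._tel_ll_at(
            s_rows[:, t], rows, t, th
        )
        dlp = np.where(inside, dlp, -np.inf)
        accept = np.log(self.rng.random(len(rows))) < dlp
        st.s[rows[accept], t] = prop_col[accept]
        self._loc_try[rows] += 1
        self._loc_acc[rows] += accept
        if self.record_proposals:
            self.proposal_log.append(
                {
                    "kernel": "location",
                    "t": t,
                    "rows": rows,
                    "proposed": prop_col,
                    "log_accept_ratio": dlp,
                    "accepted": accept,
                }
            )

    def _update_location_sites(
        self, sites: np.ndarray, rows: Optional[np.ndarray] = None
    ) -> None:
        """Simultaneous single-site moves at mutually non-interacting
        occasions (pairwise >= 3 apart)."""
        d, st = self.data, self.state
        rows = d.det_rows if rows is None else np.asarray(rows)
        if len(rows) == 0 or len(sites) == 0:
            return
        th = st.theta
        s_rows = st.s[rows]
        prop = s_rows[:, sites] + self.scales["loc"][
            rows, None, None
        ] * self.rng.standard_normal((len(rows), len(sites), 2))
        inside = d.state_space.contains(prop)  # (n, S)
        s_new = s_rows.copy()
        s_new[:, sites] = np.where(inside[..., None], prop, s_rows[:, sites])
        init_new, steps_new = mv.path_logdensity(
            s_new,
            *self._sig_gam(th, rows),
            th.delta,
            d.state_space,
            d.potential,
            per_step=True,
        )
        init_old, steps_old = mv.path_logdensity(
            s_rows,
            *self._sig_gam(th, rows),
            th.delta,
            d.state_space,
            d.potential,
            per_step=True,
        )
        dstep = steps_new - steps_old
        zmask = st.z[rows] == 1
        for j, t in enumerate(sites):
            ks = [k for k in (t - 1, t, t + 1) if 0 <= k <= d.T - 2]
            dlp = dstep[:, ks].sum(axis=1)
            if t == 0:
                dlp = dlp + init_new - init_old
            enc = self._enc_ll_col(prop[:, j], rows, t, th) - self._enc_ll_col(
                s_rows[:, t], rows, t, th
            )
            dlp += np.where(zmask, enc, 0.0)
            dlp += self._tel_ll_at(prop[:, j], rows, t, th) - self._tel_ll_at(
                s_rows[:, t], rows, t, th
            )
            dlp = np.where(inside[:, j], dlp, -np.inf)
            accept = np.log(self.rng.random(len(rows))) < dlp
            st.s[rows[accept], t] = prop[accept, j]
            self._loc_try[rows] += 1
            self._loc_acc[rows] += accept

    def _adapt_locations(self) -> None:
        tried = self._loc_try > 0
        if not tried.any():
            return
        rate = self._adapt_step ** -0.6
        acc = np.where(tried, self._loc_acc / np.maximum(self._loc_try, 1), 0.0)
        self.scales["loc"][tried] *= np.exp(
            rate * (acc[tried] - self.config.target_accept)
        )
        self._loc_acc[:] = 0.0
        self._loc_try[:] = 0.0

    def update_initial_cell(self, rows: Optional[np.ndarray] = None) -> None:
        """Joint (g, s_1) Metropolis move with an independence proposal from
        the initial distribution itself; the initial terms cancel, leaving the
        outgoing movement transitions and occasion-1 observation terms."""
        d, st = self.data, self.state
        rows = np.arange(d.M) if rows is None else np.asarray(rows)
        if len(rows) == 0:
            return
        th = st.theta
        _, prop = mv.sample_initials(len(rows), d.state_space, self.rng)
        s_rows = st.s[rows]
        s_new = s_rows.copy()
        s_new[:, 0] = prop
        hi = min(2, d.T - 1)  # s_1 enters transitions 0 and (via persistence) 1
        steps_new = self._window_steps(s_new, rows, 0, hi, th)
        steps_old = self._window_steps(s_rows, rows, 0, hi, th)
        dlp = (steps_new - steps_old).sum(axis=1)
        zmask = st.z[rows] == 1
        enc = self._enc_ll_col(prop, rows, 0, th) - self._enc_ll_col(
            s_rows[:, 0], rows, 0, th
        )
        dlp += np.where(zmask, enc, 0.0)
        dlp += self._tel_ll_at(prop, rows, 0, th) - self._tel_ll_at(
            s_rows[:, 0], rows, 0, th
        )
        accept = np.log(self.rng.random(len(rows))) < dlp
        st.s[rows[accept], 0] = prop[accept]
        if self.record_proposals:
            self.proposal_log.append(
                {
                    "kernel": "initial_cell",
                    "rows": rows,
                    "proposed": prop,
                    "log_accept_ratio": dlp,
                    "accepted": accept,
                }
            )

    def update_trajectory_block(self, rows: Optional[np.ndarray] = None) -> None:
        """Full-trajectory proposal from the movement prior for augmented,
        never-detected individuals.  The prior proposal cancels all movement
        terms, so the acceptance ratio is exactly the ratio of non-detection
        likelihoods (and 1 when z = 0 or no effort was expended)."""
        d, st = self.data, self.state
        rows = d.undet_rows if rows is None else np.asarray(rows)
        if np.any(d.detected[rows]):
            raise ValueError(
                "update_trajectory_block applies only to never-detected "
                "individuals; detected individuals use update_location"
            )
        if len(rows) == 0:
            return
        th = st.theta
        sig, gam = self._sig_gam(th, rows)
        s_prop, _ = mv.simulate_paths(
            d.state_space, d.potential, sig, gam, th.delta, d.T, self.rng
        )
        nd_old = self.encounter_ll(st.s, rows, th, per_row=True)
        nd_new = self._enc_ll_matrix(s_prop, rows, th).sum(axis=1)
        dlp = np.where(st.z[rows] == 1, nd_new - nd_old, 0.0)
        accept = np.log(self.rng.random(len(rows))) < dlp
        st.s[rows[accept]] = s_prop[accept]
        if self.record_proposals:
            self.proposal_log.append(
                {
                    "kernel": "trajectory_block",
                    "rows": rows,
                    "proposed": s_prop,
                    "log_accept_ratio": dlp,
                    "accepted": accept,
                }
            )

    # -- sweep -------------------------------------------------------------

    def sweep(self) -> None:
        """One full scan in the documented fixed order."""
        self.update_params()
        self.update_location()
        self.update_initial_cell()
        self.update_trajectory_block()
        self.update_z()
        if self.adapting:
            self._adapt_locations()
            self._adapt_step += 1
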