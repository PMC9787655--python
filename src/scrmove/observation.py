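"""Search-encounter detection and telemetry observation models.

Detection: each surveyed grid cell acts as an effective trap.  On occasion t
an individual at latent location ``s`` is recorded in trap cell j (or not at
all) as a categorical draw with probabilities from a multinomial logit of
survey effort, an immediate behavioural response, and a half-normal distance
kernel:

    eta_j  = alpha0 + alpha1 * log(x_tj) + alpha2 * B_it - d_j^2 / (2 sigma_det^2)
    xi_j   = exp(eta_j) / (1 + sum_k exp(eta_k)),   xi_{J+1} = 1 / (1 + sum_k ...)

Cells with zero effort have ``eta = -inf`` (detection probability exactly 0).

Telemetry: a fix ``u`` within occasion t is bivariate normal around ``s_t``
with the shared within-occasion scale ``sigma_det``.  Argos fixes add an
error-ellipse covariance; because every layer is Gaussian the latent true fix
location is marginalized analytically, giving
``u ~ N(s_t, sigma_det^2 I + Sigma_ellipse)``.

``sigma_det`` is shared between the detection kernel and the telemetry model:
it measures within-occasion movement around the daily average location.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "DetectionParams",
    "EncounterData",
    "TelemetryData",
    "ARGOS_AXIS_SCALE",
    "detection_probs",
    "detection_logits",
    "simulate_encounter",
    "encounter_loglik",
    "argos_covariance",
    "telemetry_loglik",
]

_LOG_2PI = float(np.log(2.0 * np.pi))

#: Default conversion from Argos error-ellipse semi-axes to Gaussian standard
#: deviations (half-normal convention of the Argos error literature).
ARGOS_AXIS_SCALE = 1.0 / np.sqrt(2.0)


@dataclass(frozen=True)
class DetectionParams:
    """Logit-scale detection parameters and the shared within-occasion scale.

    alpha0: intercept; alpha1: log-effort slope; alpha2: additive shift on the
    first survey after capture (behavioural response); sigma_det: km.
    """

    alpha0: float
    alpha1: float
    alpha2: float = 0.0
    sigma_det: float = 5.0

    def __post_init__(self):
        if not self.sigma_det > 0:
            raise ValueError("sigma_det must be positive")


def detection_logits(
    s: np.ndarray,
    effort_row: np.ndarray,
    B: np.ndarray,
    params: DetectionParams,
    trap_centroids: np.ndarray,
) -> np.ndarray:
    """Multinomial logits ``eta`` (..., J) for locations ``s`` (..., 2).

    Zero-effort cells get ``-inf``; negative effort raises.
    """
    effort_row = np.asarray(effort_row, dtype=float)
    if np.any(effort_row < 0):
        raise ValueError("survey effort must be non-negative")
    s = np.asarray(s, dtype=float)
    d2 = ((s[..., None, :] - trap_centroids) ** 2).sum(axis=-1)  # (..., J)
    with np.errstate(divide="ignore"):
        log_eff = np.log(effort_row)
    B = np.asarray(B, dtype=float)
    eta = (
        params.alpha0
        + params.alpha1 * log_eff
        + params.alpha2 * B[..., None]
        - d2 / (2.0 * params.sigma_det**2)
    )
    return np.where(np.isneginf(log_eff), -np.inf, eta)


def _log_denom(eta: np.ndarray) -> np.ndarray:
    """log(1 + sum_j exp(eta_j)) along the last axis, stably."""
    m = np.maximum(eta.max(axis=-1), 0.0)
    with np.errstate(invalid="ignore"):
        expd = np.exp(eta - m[..., None])
    expd = np.where(np.isneginf(eta), 0.0, expd)  # -inf - -inf guards
    return m + np.log(np.exp(-m) + expd.sum(axis=-1))


def detection_probs(
    s: np.ndarray,
    effort_row: np.ndarray,
    B: np.ndarray,
    params: DetectionParams,
    trap_centroids: np.ndarray,
) -> np.ndarray:
    """Detection probability vector ``xi`` of length J+1 (last entry =
    non-detection).  Sums to one; zero-effort cells carry exactly zero mass.

    Broadcasts over leading axes of ``s``/``B``.
    """
    eta = detection_logits(s, effort_row, B, params, trap_centroids)
    denom = _log_denom(eta)
    with np.errstate(invalid="ignore"):
        xi_traps = np.exp(eta - denom[..., None])
    xi_traps = np.where(np.isneginf(eta), 0.0, xi_traps)
    xi_none = np.exp(-denom)
    return np.concatenate([xi_traps, xi_none[..., None]], axis=-1)


def simulate_encounter(xi: np.ndarray, rng: np.random.Generator) -> int:
    """One categorical encounter draw; returns the 0-based trap index, or J
    (the last index) for non-detection."""
    xi = np.asarray(xi, dtype=float)
    if xi.ndim != 1 or not np.isclose(xi.sum(), 1.0, atol=1e-8) or (xi < 0).any():
        raise ValueError("xi must be a probability vector")
    return int(rng.choice(len(xi), p=xi / xi.sum()))


def encounter_loglik(y: int, xi: np.ndarray) -> float:
    """Log-probability of one encounter outcome: ``log xi[y]``.

    ``y`` is a 0-based index into ``xi`` (so ``y = J`` means non-detection);
    out-of-range values raise.  Pointing at a zero-probability (e.g.
    zero-effort) cell yields ``-inf``.
    """
    xi = np.asarray(xi, dtype=float)
    if not 0 <= y < len(xi):
        raise ValueError(f"encounter outcome {y} out of range [0, {len(xi) - 1}]")
    with np.errstate(divide="ignore"):
        return float(np.log(xi[y]))


def simulate_encounter_histories(
    s: np.ndarray,
    z: np.ndarray,
    params: DetectionParams,
    effort: np.ndarray,
    trap_centroids: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Sequentially simulate encounter histories for a population.

    Occasions are visited in order because the behavioural-response flag of
    occasion t (1 on the first surveyed occasion after an individual's first
    capture) depends on the capture history before t.  Individuals with
    ``z = 0`` are never detected.

    Returns ``(y, B)``: (n, T) arrays of 0-based trap indices (J = not
    detected) and behavioural flags.
    """
    s = np.asarray(s, dtype=float)
    n, T, _ = s.shape
    J = effort.shape[1]
    surveyed = effort.sum(axis=1) > 0
    nxt = np.full(T + 1, T, dtype=int)  # next surveyed occasion strictly after t
    for t in range(T - 1, -1, -1):
        nxt[t] = t + 1 if (t + 1 < T and surveyed[t + 1]) else nxt[t + 1]
    y = np.full((n, T), J, dtype=np.int64)
    B = np.zeros((n, T), dtype=np.int8)
    captured = np.zeros(n, dtype=bool)
    for t in range(T):
        if not surveyed[t]:
            continue
        xi = detection_probs(s[:, t], effort[t], B[:, t], params, trap_centroids)
        u = rng.random(n)
        draw = (u[:, None] > np.cumsum(xi, axis=1)).sum(axis=1)
        y[:, t] = np.where(np.asarray(z) == 1, draw, J)
        newly = (y[:, t] < J) & ~captured
        captured |= newly
        t1 = nxt[t]
        if t1 < T:
            B[newly, t1] = 1
    return y, B


# ---------------------------------------------------------------------------
# telemetry


def fixes_to_occasions(
    times_days: np.ndarray,
    n_occasions: int,
    rng: Optional[np.random.Generator] = None,
    max_per_day: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Attach continuously timestamped fixes to daily occasions.

    A fix at time tau (days since the start of occasion 1) attaches to
    occasion t when ``t - 1 < tau <= t`` (1-based), i.e. 0-based occasion
    ``ceil(tau) - 1``; fixes outside the study window are dropped.  If more
    than ``max_per_day`` fixes land on one occasion the surplus is removed
    by uniform thinning with ``rng`` (the run seed).

    Returns ``(keep_index, occasion)`` for the retained fixes.
    """
    t = np.asarray(times_days, dtype=float)
    occ = np.ceil(t).astype(np.int64) - 1
    occ[t <= 0] = 0
    inside = (t > 0) & (occ < n_occasions) | (t == 0)
    idx = np.flatnonzero(inside)
    occ = occ[idx]
    if max_per_day and len(idx):
        if rng is None:
            rng = np.random.default_rng(0)
        keep = []
        for o in np.unique(occ):
            members = idx[occ == o]
            if len(members) > max_per_day:
                members = np.sort(
                    rng.choice(members, size=max_per_day, replace=False)
                )
            keep.append(members)
        idx = np.concatenate(keep)
        idx.sort()
        occ = np.ceil(np.maximum(t[idx], 0.0)).astype(np.int64) - 1
        occ[t[idx] <= 0] = 0
    return idx, occ


def argos_covariance(
    semi_major_km: float,
    semi_minor_km: float,
    orientation: float,
    axis_scale: float = ARGOS_AXIS_SCALE,
) -> np.ndarray:
    """Observation covariance from an Argos error ellipse.

    ``R(orientation) diag((c a)^2, (c b)^2) R(orientation)^T`` with axis-to-SD
    factor ``c = axis_scale`` (1/sqrt(2) by default, per the half-normal
    ellipse convention; configurable because tags report error ellipses, not
    1-SD ellipses).  ``orientation`` is the angle of the semi-major axis in
    radians.
    """
    if not (semi_major_km >= semi_minor_km > 0):
        raise ValueError("require semi_major >= semi_minor > 0")
    c, s = np.cos(orientation), np.sin(orientation)
    R = np.array([[c, -s], [s, c]])
    D = np.diag(
        [(axis_scale * semi_major_km) ** 2, (axis_scale * semi_minor_km) ** 2]
    )
    return R @ D @ R.T


def _bvn_logpdf(resid: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Log-density of centered bivariate normals; ``resid`` (..., 2),
    ``cov`` (..., 2, 2)."""
    a = cov[..., 0, 0]
    b = cov[..., 0, 1]
    d = cov[..., 1, 1]
    det = a * d - b * b
    if np.any(det <= 0):
        raise np.linalg.LinAlgError("singular telemetry covariance")
    x, y = resid[..., 0], resid[..., 1]
    quad = (d * x * x - 2.0 * b * x * y + a * y * y) / det
    return -_LOG_2PI - 0.5 * np.log(det) - 0.5 * quad


def telemetry_loglik(
    u: np.ndarray,
    s: np.ndarray,
    sigma_det: float,
    ellipse_cov: Optional[np.ndarray] = None,
) -> float:
    """Log-likelihood of one telemetry fix ``u`` given the daily location.

    GPS (no ellipse): ``N(u; s, sigma_det^2 I)``.  Argos: the latent true fix
    location is integrated out analytically, giving
    ``N(u; s, sigma_det^2 I + ellipse_cov)``.
    """
    resid = np.asarray(u, float) - np.asarray(s, float)
    cov = np.eye(2) * sigma_det**2
    if ellipse_cov is not None:
        cov = cov + np.asarray(ellipse_cov, float)
    return float(_bvn_logpdf(resid, cov))


# ---------------------------------------------------------------------------
# data containers

NOT_DETECTED = -1  # sentinel used in interchange tables; arrays use index J


@dataclass
class EncounterData:
    """Spatial encounter histories and survey effort.

    Attributes
    ----------
    y : (n, T) int array
        0-based trap-cell index of detection, or ``J`` for "not detected".
    effort : (T, J) float array
        Km searched per occasion x trap cell.
    B : (n, T) int array
        Behavioural-response flags: 1 on the first survey after an
        individual's first capture, else 0.
    state : (n,) int array
        Reproductive state per individual (1 = male, 2 = female without
        offspring, 3 = female with offspring).
    litter : (n,) int array
        Observed litter size for state-3 individuals (1-3); 0 elsewhere.
    """

    y: np.ndarray
    effort: np.ndarray
    B: np.ndarray
    state: np.ndarray
    litter: Optional[np.ndarray] = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=np.int64)
        self.effort = np.asarray(self.effort, dtype=float)
        self.B = np.asarray(self.B, dtype=np.int8)
        self.state = np.asarray(self.state, dtype=np.int64)
        n, T = self.y.shape
        Te, J = self.effort.shape
        if Te != T:
            raise ValueError("effort and y disagree on the number of occasions")
        if self.B.shape != (n, T):
            raise ValueError("B must match y in shape")
        if self.litter is None:
            self.litter = np.zeros(n, dtype=np.int64)
        self.litter = np.asarray(self.litter, dtype=np.int64)
        if np.any(self.effort < 0):
            raise ValueError("survey effort must be non-negative")
        if self.y.min(initial=0) < 0 or self.y.max(initial=0) > J:
            raise ValueError("encounter values must lie in 0..J")
        det = self.y < J
        rows, occ = np.nonzero(det)
        if np.any(self.effort[occ, self.y[rows, occ]] <= 0):
            raise ValueError("detection recorded in a zero-effort cell-day")
        if np.any((self.litter < 0) | (self.litter > 3)):
            raise ValueError("litter sizes must be in 0..3")

    @property
    def n_individuals(self) -> int:
        return self.y.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.y.shape[1]

    @property
    def n_traps(self) -> int:
        return self.effort.shape[1]

    @property
    def detected(self) -> np.ndarray:
        """(n,) bool: individual has at least one detection."""
        return (self.y < self.n_traps).any(axis=1)

    @property
    def first_capture_occasion(self) -> np.ndarray:
        """(n,) first occasion of detection, or T for never-detected."""
        det = self.y < self.n_traps
        first = np.where(det.any(axis=1), det.argmax(axis=1), self.n_occasions)
        return first


@dataclass
class TelemetryData:
    """Telemetry fixes keyed to individuals and occasions.

    ``individual`` indexes rows of the companion :class:`EncounterData`;
    ``occasion`` is the 0-based occasion the fix attaches to (at most 4 fixes
    per individual-occasion).  ``ellipse`` holds per-fix
    (semi-major km, semi-minor km, orientation rad) for Argos fixes and NaN
    rows for GPS fixes.
    """

    individual: np.ndarray
    occasion: np.ndarray
    u: np.ndarray
    ellipse: Optional[np.ndarray] = None
    axis_scale: float = ARGOS_AXIS_SCALE

    def __post_init__(self):
        self.individual = np.asarray(self.individual, dtype=np.int64)
        self.occasion = np.asarray(self.occasion, dtype=np.int64)
        self.u = np.asarray(self.u, dtype=float).reshape(-1, 2)
        n = len(self.u)
        if self.individual.shape != (n,) or self.occasion.shape != (n,):
            raise ValueError("telemetry arrays must have one row per fix")
        if self.ellipse is not None:
            self.ellipse = np.asarray(self.ellipse, dtype=float).reshape(n, 3)
            present = ~np.isnan(self.ellipse).any(axis=1)
            e = self.ellipse[present]
            if np.any(~(e[:, 0] >= e[:, 1]) | ~(e[:, 1] > 0)):
                raise ValueError("ellipse axes must satisfy semi_major >= semi_minor > 0")
        if n:
            pair = self.individual * (self.occasion.max() + 1) + self.occasion
            _, counts = np.unique(pair, return_counts=True)
            if counts.max(initial=0) > 4:
                raise ValueError("at most 4 telemetry fixes per individual-occasion")

    @property
    def n_fixes(self) -> int:
        return len(self.u)

    @property
    def is_argos(self) -> np.ndarray:
        if self.ellipse is None:
            return np.zeros(self.n_fixes, dtype=bool)
        return ~np.isnan(self.ellipse).any(axis=1)

    def covariances(self) -> Optional[np.ndarray]:
        """(n_fixes, 2, 2) ellipse covariances (zero matrix for GPS fixes)."""
        if self.ellipse is None or not self.is_argos.any():
            return None
        cov = np.zeros((self.n_fixes, 2, 2))
        for k in np.flatnonzero(self.is_argos):
            a, b, th = self.ellipse[k]
            cov[k] = argos_covariance(a, b, th, self.axis_scale)
        return cov

    @classmethod
    def empty(cls) -> "TelemetryData":
        return cls(
            individual=np.empty(0, dtype=np.int64),
            occasion=np.empty(0, dtype=np.int64),
            u=np.empty((0, 2)),
        )
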