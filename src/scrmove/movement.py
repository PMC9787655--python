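"""Initial-location model and daily movement kernels.

Two continuous-space movement processes describe how an individual's average
daily location ``s_t`` evolves:

* bivariate normal random walk (``bvn_rw``):
      s_{t+1} ~ N( s_t + delta * grad_c(s_t),  sigma^2 I )
* correlated random walk (``crw``) with directional persistence gamma:
      s_{t+1} ~ N( s_t + gamma (s_t - s_{t-1}) + delta * grad_c(s_t),  sigma^2 I )

``grad_c`` is the (signed) gradient of the distance-to-ice potential surface,
so positive ``delta`` drifts individuals toward sea ice.  With ``gamma = 0``
the correlated walk reduces exactly to the plain random walk; the first
transition of a correlated walk (no previous displacement) also uses the
plain-random-walk mean.

Step densities are plain bivariate normals.  Simulation keeps locations
inside the rectangular state-space extent (each coordinate is an exact draw
from a one-dimensional truncated normal), and inference assigns ``-inf``
density to locations outside the extent, but no truncation normalizer is
applied: the movement law is the unbounded Gaussian kernel of the original
model, with the extent acting as a hard support constraint.  The state space
is meant to extend far beyond the data, so boundary truncation is a rare
event; including the state-dependent normalizer instead would make
boundary-hugging trajectories with outward means degenerate attractors of
the posterior.

Movement parameters are keyed by an arbitrary class label (sex in the polar
bear study) so that classes can differ in step scale and persistence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Union

import numpy as np
from scipy.special import ndtr

from .landscape import PotentialSurface, StateSpace

__all__ = [
    "MovementParams",
    "Trajectory",
    "sample_initial",
    "sample_initials",
    "step_mean",
    "simulate_trajectory",
    "simulate_paths",
    "trajectory_logdensity",
    "path_logdensity",
    "TrajectoryEscapeError",
]

MODELS = ("bvn_rw", "crw")

_LOG_2PI = float(np.log(2.0 * np.pi))


class TrajectoryEscapeError(RuntimeError):
    """A trajectory could not be kept inside the state space."""


def _resolve(value: Union[float, Mapping], class_id) -> float:
    if isinstance(value, Mapping):
        if class_id is None:
            raise ValueError("class_id required for class-keyed parameters")
        return float(value[class_id])
    return float(value)


@dataclass(frozen=True)
class MovementParams:
    """Movement-kernel parameters.

    ``sigma`` (km/day step standard deviation) and ``gamma`` (directional
    persistence in [0, 1]) may be scalars or mappings keyed by movement-class
    label.  ``delta`` scales the habitat-potential drift.  For the plain
    random walk ``gamma`` is ignored (treated as zero).
    """

    model: str = "crw"
    sigma: Union[float, Mapping] = 15.0
    gamma: Union[float, Mapping] = 0.0
    delta: float = 0.0

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        for v in (
            self.sigma.values() if isinstance(self.sigma, Mapping) else [self.sigma]
        ):
            if not v > 0:
                raise ValueError("sigma must be positive")
        for v in (
            self.gamma.values() if isinstance(self.gamma, Mapping) else [self.gamma]
        ):
            if not 0 <= v <= 1:
                raise ValueError("gamma must be in [0, 1]")

    def sigma_for(self, class_id=None) -> float:
        return _resolve(self.sigma, class_id)

    def gamma_for(self, class_id=None) -> float:
        if self.model == "bvn_rw":
            return 0.0
        return _resolve(self.gamma, class_id)


@dataclass(frozen=True)
class Trajectory:
    """A single individual's latent daily locations.

    ``g1`` is the row-major index of the initial habitat cell, ``s`` the
    (T, 2) array of daily locations in km.
    """

    g1: int
    s: np.ndarray
    class_id: Optional[str] = None

    def __post_init__(self):
        s = np.atleast_2d(np.asarray(self.s, dtype=float))
        if s.ndim != 2 or s.shape[1] != 2 or s.shape[0] < 1:
            raise ValueError("s must be a (T, 2) array with T >= 1")
        object.__setattr__(self, "s", s)

    @property
    def T(self) -> int:
        return self.s.shape[0]


# ---------------------------------------------------------------------------
# initial locations


def sample_initials(
    n: int, state_space: StateSpace, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized initial draw: cells from the ice-uniform categorical
    distribution, locations uniform within the drawn cell.

    Returns ``(g1, s1)`` with shapes (n,) and (n, 2).
    """
    g = rng.choice(state_space.n_cells, size=n, p=state_space.pi)
    origin = state_space.cell_origin(g)
    s1 = origin + rng.random((n, 2)) * state_space.resolution_km
    return g, s1


def sample_initial(
    state_space: StateSpace, rng: np.random.Generator
) -> tuple[int, np.ndarray]:
    """Single draw of ``(g1, s1)`` from the initial-location model."""
    g, s1 = sample_initials(1, state_space, rng)
    return int(g[0]), s1[0]


# ---------------------------------------------------------------------------
# step means and drift


def _drift(points: np.ndarray, potential: PotentialSurface, delta: float) -> np.ndarray:
    if delta == 0.0:
        return np.zeros(np.shape(points))
    row, col = potential.state_space.cell_rowcol(points)
    return delta * potential.grad[row, col]


def step_mean(
    s_t: np.ndarray,
    s_prev: Optional[np.ndarray],
    params: MovementParams,
    potential: PotentialSurface,
    class_id=None,
) -> np.ndarray:
    """Conditional mean of the next location given the current (and, for the
    correlated walk, previous) location.

    A correlated walk with no previous location (the first transition) falls
    back to the plain-random-walk mean.
    """
    s_t = np.asarray(s_t, dtype=float)
    mean = s_t + _drift(s_t, potential, params.delta)
    if params.model == "crw" and s_prev is not None:
        mean = mean + params.gamma_for(class_id) * (s_t - np.asarray(s_prev, float))
    return mean


# ---------------------------------------------------------------------------
# simulation


def _truncated_step(
    mean: np.ndarray,
    sigma: np.ndarray,
    state_space: StateSpace,
    rng: np.random.Generator,
) -> np.ndarray:
    """Exact draw from N(mean_i, sigma_i^2 I) truncated to the rectangular
    extent.

    The truncated kernel factorizes over the two axes, so each coordinate is
    an inverse-CDF draw from a one-dimensional truncated normal - the same
    law rejection sampling targets, but with deterministic cost even when the
    mean lies far outside the extent (strong drift or persistence).  If the
    truncation mass underflows entirely the draw collapses to the nearest
    boundary, which the Metropolis acceptance step then evaluates honestly.
    """
    from scipy.special import ndtri

    xmin, xmax, ymin, ymax = state_space.extent
    # fast path: a plain Gaussian draw is indistinguishable from the
    # truncated one when every mean sits > 8 sigma inside the boundary
    pad = 8.0 * sigma
    far = (
        (mean[:, 0] > xmin + pad)
        & (mean[:, 0] < xmax - pad)
        & (mean[:, 1] > ymin + pad)
        & (mean[:, 1] < ymax - pad)
    )
    z = rng.standard_normal(mean.shape)
    out = mean + sigma[:, None] * z
    if not far.all():
        u = ndtr(z[~far])  # reuse the uniforms behind the Gaussian draws
        m = mean[~far]
        sg = sigma[~far]
        for dim, (lo, hi) in enumerate(((xmin, xmax), (ymin, ymax))):
            a = ndtr((lo - m[:, dim]) / sg)
            b = ndtr((hi - m[:, dim]) / sg)
            p = np.clip(a + u[:, dim] * (b - a), 1e-300, 1.0 - 1e-16)
            out[np.flatnonzero(~far), dim] = m[:, dim] + sg * ndtri(p)
    np.clip(out[:, 0], xmin, np.nextafter(xmax, -np.inf), out=out[:, 0])
    np.clip(out[:, 1], ymin, np.nextafter(ymax, -np.inf), out=out[:, 1])
    return out


def simulate_paths(
    state_space: StateSpace,
    potential: PotentialSurface,
    sigma: np.ndarray,
    gamma: np.ndarray,
    delta: float,
    T: int,
    rng: np.random.Generator,
    s1: Optional[np.ndarray] = None,
    g1: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate ``n`` trajectories at once (the workhorse behind both the
    public simulator and the block trajectory proposal of the sampler).

    ``sigma`` and ``gamma`` are per-individual arrays; ``gamma`` is zero for
    plain-random-walk individuals.  Returns ``(s, g1)`` with ``s`` of shape
    (n, T, 2).
    """
    sigma = np.atleast_1d(np.asarray(sigma, dtype=float))
    gamma = np.broadcast_to(np.asarray(gamma, dtype=float), sigma.shape)
    n = len(sigma)
    if T < 1:
        raise ValueError("T must be >= 1")
    if s1 is None:
        g1, s1 = sample_initials(n, state_space, rng)
    else:
        s1 = np.asarray(s1, dtype=float).reshape(n, 2)
        if g1 is None:
            g1 = state_space.cell_index(s1)
    s = np.empty((n, T, 2))
    s[:, 0] = s1
    for t in range(T - 1):
        mean = s[:, t] + _drift(s[:, t], potential, delta)
        if t > 0:
            mean = mean + gamma[:, None] * (s[:, t] - s[:, t - 1])
        s[:, t + 1] = _truncated_step(mean, sigma, state_space, rng)
    return s, np.asarray(g1)


def simulate_trajectory(
    state_space: StateSpace,
    potential: PotentialSurface,
    params: MovementParams,
    T: int,
    rng: np.random.Generator,
    s1: Optional[np.ndarray] = None,
    class_id=None,
) -> Trajectory:
    """Simulate one trajectory of length ``T`` from the movement model,
    truncated to the state-space extent."""
    sig = np.array([params.sigma_for(class_id)])
    gam = np.array([params.gamma_for(class_id)])
    s1_arr = None if s1 is None else np.asarray(s1, float).reshape(1, 2)
    s, g1 = simulate_paths(
        state_space, potential, sig, gam, params.delta, T, rng, s1=s1_arr
    )
    return Trajectory(g1=int(g1[0]), s=s[0], class_id=class_id)


# ---------------------------------------------------------------------------
# exact log-density


try:  # optional JIT of the per-step density loop
    from numba import njit

    @njit(cache=True)
    def _path_core(s, sigma, gamma, delta, grad, pi, res, ncols, xmax, ymax):
        n, T, _ = s.shape
        initial = np.empty(n)
        steps = np.zeros((n, max(T - 1, 0)))
        log2pi = 1.8378770664093453
        for i in range(n):
            ok = True
            for t in range(T):
                x, y = s[i, t, 0], s[i, t, 1]
                if not (0.0 <= x < xmax and 0.0 <= y < ymax):
                    ok = False
                    break
            if not ok:
                initial[i] = -np.inf
                for t in range(T - 1):
                    steps[i, t] = -np.inf
                continue
            col = int(s[i, 0, 0] / res)
            row = int(s[i, 0, 1] / res)
            p = pi[row * ncols + col]
            initial[i] = (np.log(p) if p > 0 else -np.inf) - 2.0 * np.log(res)
            sg = sigma[i]
            gm = gamma[i]
            base = -log2pi - 2.0 * np.log(sg)
            inv2v = 1.0 / (2.0 * sg * sg)
            for t in range(T - 1):
                cx, cy = s[i, t, 0], s[i, t, 1]
                mx, my = cx, cy
                if delta != 0.0:
                    col = int(cx / res)
                    row = int(cy / res)
                    mx += delta * grad[row, col, 0]
                    my += delta * grad[row, col, 1]
                if t > 0:
                    mx += gm * (cx - s[i, t - 1, 0])
                    my += gm * (cy - s[i, t - 1, 1])
                rx = s[i, t + 1, 0] - mx
                ry = s[i, t + 1, 1] - my
                steps[i, t] = base - (rx * rx + ry * ry) * inv2v
        return initial, steps

except Exception:  # pragma: no cover
    _path_core = None


def path_logdensity(
    s: np.ndarray,
    sigma: np.ndarray,
    gamma: np.ndarray,
    delta: float,
    state_space: StateSpace,
    potential: PotentialSurface,
    per_step: bool = False,
):
    """Joint log-density of ``n`` trajectories under the movement model.

    Parameters
    ----------
    s : (n, T, 2)
        Trajectories.
    sigma, gamma : (n,)
        Per-individual step scale and persistence (gamma = 0 for the plain
        random walk).
    per_step : bool
        If True, return ``(initial, steps)`` where ``initial`` is (n,) and
        ``steps`` is (n, T-1); otherwise return the (n,) totals.

    Trajectories with any location outside the extent, or starting in a cell
    with zero initial probability, have density ``-inf`` (returned, not
    raised).
    """
    s = np.asarray(s, dtype=float)
    n, T, _ = s.shape
    sigma = np.asarray(sigma, dtype=float)
    gamma = np.broadcast_to(np.asarray(gamma, dtype=float), sigma.shape)

    if _path_core is not None:
        _, xmax, _, ymax = state_space.extent
        initial, steps = _path_core(
            np.ascontiguousarray(s),
            np.ascontiguousarray(sigma),
            np.ascontiguousarray(gamma),
            float(delta),
            potential.grad,
            state_space.pi,
            state_space.resolution_km,
            state_space.ncols,
            xmax,
            ymax,
        )
        if per_step:
            return initial, steps
        return initial + steps.sum(axis=1)

    valid = state_space.contains(s).all(axis=1)  # (n,)
    initial = np.full(n, -np.inf)
    steps = np.zeros((n, max(T - 1, 0)))
    if valid.any():
        v = np.flatnonzero(valid)
        sv = s[v]
        g1 = state_space.cell_index(sv[:, 0])
        with np.errstate(divide="ignore"):
            init_v = np.log(state_space.pi[g1]) - 2.0 * np.log(
                state_space.resolution_km
            )
        initial[v] = init_v
        if T > 1:
            cur = sv[:, :-1]  # (nv, T-1, 2)
            mean = cur + _drift(cur.reshape(-1, 2), potential, delta).reshape(cur.shape)
            if T > 2:
                disp = sv[:, 1:-1] - sv[:, :-2]
                mean[:, 1:] += gamma[v, None, None] * disp
            resid = sv[:, 1:] - mean
            sig = sigma[v, None]
            lp = (
                -_LOG_2PI
                - 2.0 * np.log(sig)
                - (resid**2).sum(axis=-1) / (2.0 * sig**2)
            )
            steps[v] = lp
    steps[~valid] = -np.inf
    if per_step:
        return initial, steps
    return initial + steps.sum(axis=1)


def trajectory_logdensity(
    traj: Trajectory,
    params: MovementParams,
    state_space: StateSpace,
    potential: PotentialSurface,
) -> float:
    """Exact log-density of one trajectory: initial cell (ice-uniform
    categorical), uniform position within the cell, and the product of
    bivariate-normal step densities (``-inf`` outside the extent)."""
    sig = np.array([params.sigma_for(traj.class_id)])
    gam = np.array([params.gamma_for(traj.class_id)])
    return float(
        path_logdensity(
            traj.s[None], sig, gam, params.delta, state_space, potential
        )[0]
    )
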