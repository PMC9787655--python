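"""Derived abundance quantities under data augmentation.

The augmented population holds M individuals per reproductive stratum, each
with an inclusion indicator z_i.  Given a posterior draw of trajectories and
inclusion indicators, abundance in the surveyed region A follows by counting:

* daily abundance        N_At   = sum_i z_i * w_it,  w_it = 1{s_it in A}
* cumulative abundance   N*_At  = sum_i z_i * max(w_i,1:t)
* dependent offspring    N_cubs = sum_i z_i * 1{r_i = 3} * n_i

N*_AT at the final occasion is the superpopulation: the number of distinct
individuals that used A at any time during the study.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .landscape import SurveyRegion

__all__ = [
    "AbundanceSeries",
    "in_region",
    "daily_abundance",
    "cumulative_abundance",
    "cub_total",
    "expected_litter_size",
    "abundance_series",
    "density_surface",
]


@dataclass(frozen=True)
class AbundanceSeries:
    """Daily and cumulative abundance derived from one state.

    ``n_daily[t]`` individuals inside A on occasion t; ``n_cumulative``
    (non-decreasing) counts individuals that have used A by occasion t;
    ``n_total`` is total independent individuals in the state space and
    ``n_cubs`` their dependent offspring.
    """

    n_daily: np.ndarray
    n_cumulative: np.ndarray
    n_total: int
    n_cubs: int

    def __post_init__(self):
        if np.any(np.diff(self.n_cumulative) < 0):
            raise ValueError("cumulative abundance must be non-decreasing")
        if np.any(self.n_daily > self.n_cumulative):
            raise ValueError("daily abundance cannot exceed cumulative abundance")


def in_region(s: np.ndarray, region: SurveyRegion) -> np.ndarray:
    """Indicator of membership in region A (union of the surveyed trap
    cells), half-open cell convention.  Broadcasts over leading axes."""
    return region.contains(s).astype(np.int8)


def daily_abundance(z: np.ndarray, w: np.ndarray, t: int) -> int:
    """``sum_i z_i w_it`` for occasion ``t`` (0-based)."""
    z = np.asarray(z)
    w = np.asarray(w)
    return int(np.sum(z * w[:, t]))


def cumulative_abundance(z: np.ndarray, w: np.ndarray, t: int) -> int:
    """Individuals that used A at least once by occasion ``t`` (0-based)."""
    z = np.asarray(z)
    w = np.asarray(w)
    used = w[:, : t + 1].max(axis=1)
    return int(np.sum(z * used))


def cub_total(z: np.ndarray, r: np.ndarray, n: np.ndarray) -> int:
    """Total dependent offspring ``sum_i z_i 1{r_i=3} n_i``.

    Raises if any included state-3 female lacks a litter size.
    """
    z = np.asarray(z)
    r = np.asarray(r)
    n = np.asarray(n)
    mothers = (r == 3) & (z == 1)
    if np.any(n[mothers] < 1):
        raise ValueError("litter size missing for an included female with offspring")
    return int(np.sum(np.where(mothers, n, 0)))


def expected_litter_size(omega: np.ndarray, require_normalized: bool = True) -> float:
    """Expected offspring per female with dependent young:
    ``1*omega_1 + 2*omega_2 + 3*omega_3``.

    With ``require_normalized`` (default) the probabilities must sum to one.
    Passing ``require_normalized=False`` evaluates the raw dot product, e.g.
    for posterior medians, which need not be normalized.
    """
    omega = np.asarray(omega, dtype=float)
    if omega.shape != (3,) or np.any(omega < 0):
        raise ValueError("omega must be 3 non-negative probabilities")
    if require_normalized and not np.isclose(omega.sum(), 1.0, atol=1e-8):
        raise ValueError("omega must sum to 1 (pass require_normalized=False "
                         "to evaluate unnormalized weights)")
    return float(np.dot(np.arange(1, 4), omega))


def abundance_series(
    z: np.ndarray, w: np.ndarray, r: np.ndarray, n: np.ndarray
) -> AbundanceSeries:
    """All derived abundance quantities from one augmented-population state."""
    z = np.asarray(z)
    w = np.asarray(w)
    daily = (z[:, None] * w).sum(axis=0)
    cum = (z[:, None] * np.maximum.accumulate(w, axis=1)).sum(axis=0)
    return AbundanceSeries(
        n_daily=daily.astype(np.int64),
        n_cumulative=cum.astype(np.int64),
        n_total=int(z.sum()),
        n_cubs=cub_total(z, r, n),
    )


def density_surface(
    s_draws: np.ndarray,
    z_draws: np.ndarray,
    region: SurveyRegion,
    r: np.ndarray = None,
    n_draws: np.ndarray = None,
    include_cubs: bool = True,
    per_draw: bool = False,
):
    """Mean daily abundance per surveyed trap cell.

    Parameters
    ----------
    s_draws : (n_draws, M, T, 2)
        Posterior trajectory draws.
    z_draws : (n_draws, M)
        Matching inclusion-indicator draws.
    r : (M,) reproductive states, required when ``include_cubs``.
    n_draws : (n_draws, M) litter-size draws, required when ``include_cubs``.
    include_cubs : bool
        Count each included state-3 female as ``1 + n_i`` bears (the total
        bears convention) instead of 1.
    per_draw : bool
        If True return the raw (n_draws, T, J) per-cell counts; otherwise a
        DataFrame with mean and central 95% interval of the per-day cell
        count, plus a per-km^2 convenience column.
    """
    s_draws = np.asarray(s_draws, dtype=float)
    z_draws = np.asarray(z_draws)
    nd, M, T, _ = s_draws.shape
    J = region.n_traps
    trap = region.trap_of(s_draws)  # (nd, M, T), -1 outside A
    weight = z_draws.astype(float)  # (nd, M)
    if include_cubs:
        if r is None or n_draws is None:
            raise ValueError("include_cubs requires r and n_draws")
        cubs = (np.asarray(r) == 3) * np.asarray(n_draws)
        weight = weight * (1.0 + cubs)
    counts = np.zeros((nd, T, J))
    inside = trap >= 0
    d_idx, i_idx, t_idx = np.nonzero(inside)
    np.add.at(counts, (d_idx, t_idx, trap[inside]), weight[d_idx, i_idx])
    if per_draw:
        return counts
    per_cell = counts.mean(axis=1)  # (nd, J) day-averaged
    lo, hi = np.quantile(per_cell, [0.025, 0.975], axis=0)
    cent = region.centroids
    return pd.DataFrame(
        {
            "trap_cell": np.arange(J),
            "x_km": cent[:, 0],
            "y_km": cent[:, 1],
            "bears_per_cell_day": per_cell.mean(axis=0),
            "q2.5": lo,
            "q97.5": hi,
            "bears_per_km2_day": per_cell.mean(axis=0) / region.resolution_km**2,
        }
    )
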