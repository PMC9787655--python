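"""Model and Results objects for the integrated SCR-movement model.

:class:`SCRMovementModel` bundles encounter histories, survey effort,
optional telemetry and the habitat state space; :meth:`fit` runs the
Metropolis-within-Gibbs sampler and returns a :class:`SCRMovementResults`
carrying parameter draws, derived abundance series, convergence diagnostics
and (optionally) thinned trajectory draws for density surfaces.

    >>> model = SCRMovementModel(enc, ss, region, telemetry=tel)
    >>> res = model.fit(iterations=4000, burn=2000, chains=3, seed=1)
    >>> res.summary()
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import population
from .diagnostics import effective_sample_size, gelman_rubin
from .inference import MCMCState, ModelConfig, Sampler, _ModelData
from .landscape import (
    PotentialSurface,
    StateSpace,
    SurveyRegion,
    build_potential,
)
from .observation import EncounterData, TelemetryData

__all__ = ["SCRMovementModel", "SCRMovementResults", "ModelConfig"]


class SCRMovementModel:
    """Integrated spatial capture-recapture + movement model.

    Parameters
    ----------
    encounters : EncounterData
        Spatial encounter histories and survey effort for the observed
        individuals.
    state_space : StateSpace
        Discretized habitat domain.
    survey_region : SurveyRegion
        The J trap cells (region A) over which detection operates and
        abundance is reported.
    potential : PotentialSurface, optional
        Habitat potential; defaults to the distance-to-ice surface of the
        state space.
    telemetry : TelemetryData, optional
    config : ModelConfig, optional
        Priors, augmentation sizes, movement-model choice, sampler settings.
    """

    def __init__(
        self,
        encounters: EncounterData,
        state_space: StateSpace,
        survey_region: SurveyRegion,
        potential: Optional[PotentialSurface] = None,
        telemetry: Optional[TelemetryData] = None,
        config: Optional[ModelConfig] = None,
    ):
        self.config = config if config is not None else ModelConfig()
        if potential is None:
            potential = build_potential(state_space)
        xmin, xmax, ymin, ymax = state_space.extent
        org = survey_region.origins
        hi = org + survey_region.resolution_km
        if (
            org[:, 0].min() < xmin
            or org[:, 1].min() < ymin
            or hi[:, 0].max() > xmax
            or hi[:, 1].max() > ymax
        ):
            raise ValueError("survey region extends outside the state space")
        self.encounters = encounters
        self.telemetry = telemetry
        self.state_space = state_space
        self.survey_region = survey_region
        self.potential = potential
        self.data = _ModelData(
            encounters, telemetry, state_space, survey_region, potential, self.config
        )

    # convenience -----------------------------------------------------------

    @classmethod
    def from_simulation(cls, dataset, config: Optional[ModelConfig] = None):
        """Build a model directly from a :class:`~scrmove.simstudy.SimulatedDataset`."""
        return cls(
            encounters=dataset.encounters,
            state_space=dataset.state_space,
            survey_region=dataset.region,
            potential=dataset.potential,
            telemetry=dataset.telemetry,
            config=config,
        )

    def sampler(self, rng: np.random.Generator, state: Optional[MCMCState] = None):
        """A fresh :class:`~scrmove.inference.Sampler` over this model's data."""
        return Sampler(self.data, rng, state=state)

    def joint_logdensity(self, state: MCMCState) -> float:
        """Joint log-density of a complete latent state (audit entry point)."""
        smp = Sampler(self.data, np.random.default_rng(0), state=state)
        return smp.joint_logdensity()

    # fitting ---------------------------------------------------------------

    def fit(
        self,
        iterations: int = 4000,
        burn: int = 2000,
        thin: int = 2,
        chains: int = 3,
        seed: int = 0,
    ) -> "SCRMovementResults":
        """Run ``chains`` independent MCMC chains and collect retained draws.

        Proposal scales adapt (Robbins-Monro) during burn-in only and are
        frozen afterwards, so retained draws come from fixed kernels.  Fully
        reproducible given ``seed``.
        """
        if iterations <= burn:
            raise ValueError("iterations must exceed burn")
        d = self.data
        cfg = self.config
        seeds = np.random.SeedSequence(seed).spawn(chains)
        scalar_names = self._scalar_names()
        params = {k: [] for k in scalar_names}
        series = {k: [] for k in ("N_At", "N_star_At", "N_At_total", "N_star_At_total")}
        s_draws, z_draws, n_draws = [], [], []
        n_ret = len(range(burn, iterations, thin))
        for c in range(chains):
            rng = np.random.default_rng(seeds[c])
            smp = Sampler(d, rng)
            smp.adapting = cfg.adapt
            ch_params = {k: np.empty(n_ret) for k in scalar_names}
            ch_series = {k: np.empty((n_ret, d.T)) for k in series}
            ridx = 0
            for it in range(iterations):
                if it == burn:
                    smp.adapting = False
                smp.sweep()
                if it >= burn and (it - burn) % thin == 0:
                    self._record(smp.state, ch_params, ch_series, ridx)
                    if cfg.store_trajectories and ridx % cfg.trajectory_thin == 0:
                        s_draws.append(smp.state.s.copy())
                        z_draws.append(smp.state.z.copy())
                        n_draws.append(smp.state.n.copy())
                    ridx += 1
            for k in scalar_names:
                params[k].append(ch_params[k])
            for k in series:
                series[k].append(ch_series[k])
        params = {k: np.stack(v) for k, v in params.items()}
        series = {k: np.stack(v) for k, v in series.items()}
        traj = None
        if cfg.store_trajectories and s_draws:
            traj = (np.stack(s_draws), np.stack(z_draws), np.stack(n_draws))
        return SCRMovementResults(
            model=self,
            params=params,
            series=series,
            trajectory_draws=traj,
            seed=seed,
            n_iterations=iterations,
            n_burn=burn,
            thin=thin,
        )

    def _scalar_names(self):
        d, cfg = self.data, self.config
        names = [f"sigma_{lab}" for lab in d.class_labels]
        if cfg.movement_model == "crw":
            names += [f"gamma_{lab}" for lab in d.class_labels]
        if cfg.delta is None:
            names.append("delta")
        names += ["alpha0", "alpha1", "alpha2", "sigma_det"]
        names += [f"psi_{r}" for r in d.strata]
        names += ["omega_1", "omega_2", "omega_3", "N_M", "N_cubs"]
        return names

    def _record(self, st: MCMCState, ch_params, ch_series, ridx: int):
        d, cfg = self.data, self.config
        th = st.theta
        for c, lab in enumerate(d.class_labels):
            ch_params[f"sigma_{lab}"][ridx] = th.sigma[c]
            if cfg.movement_model == "crw":
                ch_params[f"gamma_{lab}"][ridx] = th.gamma[c]
        if cfg.delta is None:
            ch_params["delta"][ridx] = th.delta
        ch_params["alpha0"][ridx] = th.alpha0
        ch_params["alpha1"][ridx] = th.alpha1
        ch_params["alpha2"][ridx] = th.alpha2
        ch_params["sigma_det"][ridx] = th.sigma_det
        for k, r in enumerate(d.strata):
            ch_params[f"psi_{r}"][ridx] = th.psi[k]
        for k in range(3):
            ch_params[f"omega_{k + 1}"][ridx] = th.omega[k]
        ch_params["N_M"][ridx] = st.z.sum()
        cubs = np.where((d.state == 3) & (st.z == 1), st.n, 0)
        ch_params["N_cubs"][ridx] = cubs.sum()
        w = population.in_region(st.s, self.survey_region)  # (M, T)
        zw = st.z[:, None] * w
        used = st.z[:, None] * np.maximum.accumulate(w, axis=1)
        ch_series["N_At"][ridx] = zw.sum(axis=0)
        ch_series["N_star_At"][ridx] = used.sum(axis=0)
        weight = 1.0 + np.where(d.state == 3, st.n, 0)
        ch_series["N_At_total"][ridx] = (zw * weight[:, None]).sum(axis=0)
        ch_series["N_star_At_total"][ridx] = (used * weight[:, None]).sum(axis=0)


@dataclass
class SCRMovementResults:
    """Posterior draws and derived quantities from :meth:`SCRMovementModel.fit`.

    ``params`` maps scalar names to (chains, n_retained) arrays; ``series``
    maps abundance-series names to (chains, n_retained, T) arrays.
    """

    model: SCRMovementModel
    params: dict
    series: dict
    trajectory_draws: Optional[tuple]
    seed: int
    n_iterations: int
    n_burn: int
    thin: int

    # -- summaries ----------------------------------------------------------

    def summary(self, quantiles=(0.025, 0.975)) -> pd.DataFrame:
        """Posterior medians, central credible intervals, split-chain
        diagnostics (R-hat) and effective sample sizes for every scalar
        parameter and derived scalar."""
        rows = []
        lo, hi = quantiles
        items = dict(self.params)
        items["mean_N_At"] = self.series["N_At"].mean(axis=2)
        items["N_superpop"] = self.series["N_star_At"][:, :, -1]
        items["N_superpop_total"] = self.series["N_star_At_total"][:, :, -1]
        for name, x in items.items():
            flat = x.ravel()
            rows.append(
                {
                    "parameter": name,
                    "median": np.median(flat),
                    f"q{100 * lo:g}": np.quantile(flat, lo),
                    f"q{100 * hi:g}": np.quantile(flat, hi),
                    "rhat": gelman_rubin(x) if x.shape[0] >= 2 else np.nan,
                    "ess": effective_sample_size(x),
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def abundance_summary(self, total: bool = True) -> pd.DataFrame:
        """Per-occasion daily and cumulative abundance in the survey region
        (posterior median and 95% interval).  ``total`` includes dependent
        offspring (the reporting default); otherwise independent bears only.
        """
        daily = self.series["N_At_total" if total else "N_At"]
        cum = self.series["N_star_At_total" if total else "N_star_At"]
        T = daily.shape[2]
        out = {"occasion": np.arange(T)}
        for name, x in (("daily", daily), ("cumulative", cum)):
            flat = x.reshape(-1, T)
            out[f"{name}_median"] = np.median(flat, axis=0)
            out[f"{name}_q2.5"] = np.quantile(flat, 0.025, axis=0)
            out[f"{name}_q97.5"] = np.quantile(flat, 0.975, axis=0)
        return pd.DataFrame(out).set_index("occasion")

    def density_surface(self, include_cubs: bool = True, per_draw: bool = False):
        """Mean daily abundance per surveyed trap cell from the stored
        trajectory draws (requires ``store_trajectories``)."""
        if self.trajectory_draws is None:
            raise ValueError("fit was run without stored trajectory draws")
        s_d, z_d, n_d = self.trajectory_draws
        return population.density_surface(
            s_d,
            z_d,
            self.model.survey_region,
            r=self.model.data.state,
            n_draws=n_d,
            include_cubs=include_cubs,
            per_draw=per_draw,
        )

    @property
    def rhat(self) -> pd.Series:
        return pd.Series(
            {k: gelman_rubin(v) for k, v in self.params.items() if v.shape[0] >= 2}
        )

    @property
    def converged(self) -> bool:
        """All scalar parameters below the conventional 1.1 threshold."""
        r = self.rhat
        return bool((r.dropna() <= 1.1).all())

    def param_draws(self, name: str) -> np.ndarray:
        """Pooled draws of one scalar parameter."""
        return self.params[name].ravel()
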