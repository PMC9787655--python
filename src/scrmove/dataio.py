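"""Interchange formats: datasets, posterior draws and run manifests.

A dataset directory holds

* ``habitat.asc``  - ESRI ASCII grid of the binary ice raster (0/1), or
  ``habitat.csv`` - a bare CSV matrix (fixture-friendly);
* ``meta.yaml``    - resolution_km, trap_resolution_km, attraction_sign,
  n_occasions;
* ``region.csv``   - trap_cell, x_origin_km, y_origin_km;
* ``encounters.csv`` - individual_id, occasion, trap_cell (empty = not
  detected), state, B_flag, litter_size (long format, one row per
  individual x occasion);
* ``effort.csv``   - occasion, trap_cell, km_searched (positive rows only);
* ``telemetry.csv`` (optional) - individual_id, occasion, x_km, y_km,
  semi_major_km, semi_minor_km, orientation_rad, tag_type.

All coordinates are km in one projected CRS; rasters are stored north-up and
flipped to the internal bottom-up row order on read.  Credible intervals
everywhere use linear-interpolation (type 7) empirical quantiles.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .landscape import StateSpace, SurveyRegion, build_state_space
from .observation import EncounterData, TelemetryData

__all__ = [
    "read_ascii_grid",
    "write_ascii_grid",
    "read_dataset",
    "write_dataset",
    "write_posterior",
    "read_posterior",
    "make_manifest",
]


# ---------------------------------------------------------------------------
# rasters


def write_ascii_grid(path, grid: np.ndarray, cellsize: float, nodata: int = -9999):
    """Write a 2-D array (internal bottom-up row order) as an ESRI ASCII
    grid (stored north-up)."""
    grid = np.asarray(grid)
    nrows, ncols = grid.shape
    lines = [
        f"ncols {ncols}",
        f"nrows {nrows}",
        "xllcorner 0.0",
        "yllcorner 0.0",
        f"cellsize {cellsize}",
        f"NODATA_value {nodata}",
    ]
    for row in grid[::-1]:
        lines.append(" ".join(str(int(v)) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_ascii_grid(path) -> tuple[np.ndarray, float]:
    """Read an ESRI ASCII grid; returns (bottom-up array, cellsize)."""
    text = Path(path).read_text().strip().splitlines()
    header = {}
    i = 0
    while i < len(text) and text[i].split()[0].lower() in (
        "ncols",
        "nrows",
        "xllcorner",
        "yllcorner",
        "cellsize",
        "nodata_value",
    ):
        k, v = text[i].split()[:2]
        header[k.lower()] = float(v)
        i += 1
    rows = [list(map(float, ln.split())) for ln in text[i:]]
    grid = np.asarray(rows)[::-1]
    if grid.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("ASCII grid data does not match declared shape")
    return grid, float(header["cellsize"])


# ---------------------------------------------------------------------------
# datasets


def write_dataset(
    out_dir,
    state_space: StateSpace,
    region: SurveyRegion,
    encounters: EncounterData,
    telemetry: Optional[TelemetryData] = None,
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_ascii_grid(out / "habitat.asc", state_space.ice, state_space.resolution_km)
    meta = {
        "resolution_km": float(state_space.resolution_km),
        "trap_resolution_km": float(region.resolution_km),
        "n_occasions": int(encounters.n_occasions),
    }
    (out / "meta.yaml").write_text(yaml.safe_dump(meta))
    pd.DataFrame(
        {
            "trap_cell": np.arange(region.n_traps),
            "x_origin_km": region.origins[:, 0],
            "y_origin_km": region.origins[:, 1],
        }
    ).to_csv(out / "region.csv", index=False)
    n, T = encounters.y.shape
    J = encounters.n_traps
    ii, tt = np.meshgrid(np.arange(n), np.arange(T), indexing="ij")
    enc = pd.DataFrame(
        {
            "individual_id": ii.ravel(),
            "occasion": tt.ravel(),
            "trap_cell": [v if v < J else "" for v in encounters.y.ravel()],
            "state": np.repeat(encounters.state, T),
            "B_flag": encounters.B.ravel(),
            "litter_size": np.repeat(encounters.litter, T),
        }
    )
    enc.to_csv(out / "encounters.csv", index=False)
    t_idx, j_idx = np.nonzero(encounters.effort > 0)
    pd.DataFrame(
        {
            "occasion": t_idx,
            "trap_cell": j_idx,
            "km_searched": encounters.effort[t_idx, j_idx],
        }
    ).to_csv(out / "effort.csv", index=False)
    if telemetry is not None and telemetry.n_fixes:
        ell = (
            telemetry.ellipse
            if telemetry.ellipse is not None
            else np.full((telemetry.n_fixes, 3), np.nan)
        )
        pd.DataFrame(
            {
                "individual_id": telemetry.individual,
                "occasion": telemetry.occasion,
                "x_km": telemetry.u[:, 0],
                "y_km": telemetry.u[:, 1],
                "semi_major_km": ell[:, 0],
                "semi_minor_km": ell[:, 1],
                "orientation_rad": ell[:, 2],
                "tag_type": np.where(np.isnan(ell[:, 0]), "gps", "argos"),
            }
        ).to_csv(out / "telemetry.csv", index=False)


def read_dataset(in_dir):
    """Read and cross-validate a dataset directory.

    Returns ``(state_space, region, encounters, telemetry)``; ``telemetry``
    is ``None`` when no telemetry file is present.  Schema violations raise
    ``ValueError`` naming the offending rows.
    """
    src = Path(in_dir)
    meta = yaml.safe_load((src / "meta.yaml").read_text())
    if (src / "habitat.asc").exists():
        grid, cellsize = read_ascii_grid(src / "habitat.asc")
        if not np.isclose(cellsize, meta["resolution_km"]):
            raise ValueError("habitat cellsize disagrees with meta.yaml")
    else:
        grid = pd.read_csv(src / "habitat.csv", header=None).to_numpy()[::-1]
    ss = build_state_space(grid.astype(int), meta["resolution_km"])
    reg_df = pd.read_csv(src / "region.csv")
    region = SurveyRegion(
        origins=reg_df[["x_origin_km", "y_origin_km"]].to_numpy(),
        resolution_km=float(meta["trap_resolution_km"]),
    )
    J = region.n_traps
    T = int(meta["n_occasions"])

    eff_df = pd.read_csv(src / "effort.csv")
    bad = eff_df[eff_df["km_searched"] < 0]
    if len(bad):
        raise ValueError(f"negative survey effort in effort.csv rows {list(bad.index)}")
    bad = eff_df[(eff_df["trap_cell"] < 0) | (eff_df["trap_cell"] >= J)]
    if len(bad):
        raise ValueError(f"unknown trap cell in effort.csv rows {list(bad.index)}")
    effort = np.zeros((T, J))
    effort[eff_df["occasion"], eff_df["trap_cell"]] = eff_df["km_searched"]

    enc_df = pd.read_csv(src / "encounters.csv")
    ids = np.sort(enc_df["individual_id"].unique())
    n = len(ids)
    y = np.full((n, T), J, dtype=np.int64)
    B = np.zeros((n, T), dtype=np.int8)
    state = np.zeros(n, dtype=np.int64)
    litter = np.zeros(n, dtype=np.int64)
    id_row = {v: k for k, v in enumerate(ids)}
    det = enc_df[enc_df["trap_cell"].notna() & (enc_df["trap_cell"].astype(str) != "")]
    bad = det[
        (pd.to_numeric(det["trap_cell"]) < 0) | (pd.to_numeric(det["trap_cell"]) >= J)
    ]
    if len(bad):
        raise ValueError(
            f"encounter references unknown trap cell in rows {list(bad.index)}"
        )
    for _, row in enc_df.iterrows():
        i = id_row[row["individual_id"]]
        t = int(row["occasion"])
        cell = row["trap_cell"]
        if pd.notna(cell) and str(cell) != "":
            y[i, t] = int(cell)
        B[i, t] = int(row["B_flag"])
        state[i] = int(row["state"])
        litter[i] = int(row["litter_size"])
    encounters = EncounterData(y=y, effort=effort, B=B, state=state, litter=litter)

    telemetry = None
    if (src / "telemetry.csv").exists():
        tel_df = pd.read_csv(src / "telemetry.csv")
        bad = tel_df[~tel_df["individual_id"].isin(ids)]
        if len(bad):
            raise ValueError(
                f"telemetry references unknown individuals in rows {list(bad.index)}"
            )
        ell = tel_df[["semi_major_km", "semi_minor_km", "orientation_rad"]].to_numpy()
        telemetry = TelemetryData(
            individual=np.array([id_row[v] for v in tel_df["individual_id"]]),
            occasion=tel_df["occasion"].to_numpy(),
            u=tel_df[["x_km", "y_km"]].to_numpy(),
            ellipse=ell if np.isfinite(ell).any() else None,
        )
    return ss, region, encounters, telemetry


# ---------------------------------------------------------------------------
# posteriors


def write_posterior(results, out_dir) -> None:
    """Lossless dump of retained draws plus a summary table and manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = []
    for name, x in results.params.items():
        m, nret = x.shape
        cc, dd = np.meshgrid(np.arange(m), np.arange(nret), indexing="ij")
        frames.append(
            pd.DataFrame(
                {"chain": cc.ravel(), "draw": dd.ravel(), "name": name, "value": x.ravel()}
            )
        )
    if not frames:
        raise ValueError("empty draw set; refusing to write an empty posterior")
    pd.concat(frames).to_csv(out / "draws.csv", index=False)
    sframes = []
    for name, x in results.series.items():
        m, nret, T = x.shape
        cc, dd, tt = np.meshgrid(
            np.arange(m), np.arange(nret), np.arange(T), indexing="ij"
        )
        sframes.append(
            pd.DataFrame(
                {
                    "chain": cc.ravel(),
                    "draw": dd.ravel(),
                    "name": name,
                    "occasion": tt.ravel(),
                    "value": x.ravel(),
                }
            )
        )
    pd.concat(sframes).to_csv(out / "draws_series.csv", index=False)
    results.summary().to_csv(out / "summary.csv")
    results.abundance_summary().to_csv(out / "abundance.csv")
    if results.trajectory_draws is not None:
        results.density_surface().to_csv(out / "density.csv", index=False)
    manifest = make_manifest(
        seed=results.seed,
        config={
            "iterations": results.n_iterations,
            "burn": results.n_burn,
            "thin": results.thin,
            "movement_model": results.model.config.movement_model,
            "trap_resolution_km": float(results.model.survey_region.resolution_km),
        },
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_posterior(in_dir) -> tuple[dict, dict, pd.DataFrame]:
    """Read back draws written by :func:`write_posterior`.

    Returns ``(params, series, summary)`` with the same array shapes that
    were written.  Missing or partial files raise.
    """
    src = Path(in_dir)
    for fname in ("draws.csv", "draws_series.csv", "summary.csv", "manifest.json"):
        if not (src / fname).exists():
            raise ValueError(f"partial posterior directory: missing {fname}")
    draws = pd.read_csv(src / "draws.csv", float_precision="round_trip")
    params = {}
    for name, grp in draws.groupby("name", sort=False):
        m = grp["chain"].max() + 1
        n = grp["draw"].max() + 1
        x = np.empty((m, n))
        x[grp["chain"], grp["draw"]] = grp["value"]
        params[name] = x
    sdraws = pd.read_csv(src / "draws_series.csv", float_precision="round_trip")
    series = {}
    for name, grp in sdraws.groupby("name", sort=False):
        m = grp["chain"].max() + 1
        n = grp["draw"].max() + 1
        T = grp["occasion"].max() + 1
        x = np.empty((m, n, T))
        x[grp["chain"], grp["draw"], grp["occasion"]] = grp["value"]
        series[name] = x
    summary = pd.read_csv(src / "summary.csv", index_col=0)
    return params, series, summary


def make_manifest(seed: int, config: dict, inputs: Optional[dict] = None) -> dict:
    """Run manifest: seed, config snapshot + hash, versions, timestamps."""
    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "seed": int(seed),
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "scrmove_version": __version__,
        "numpy_version": np.__version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    if inputs:
        manifest["input_sha256"] = {
            k: hashlib.sha256(Path(v).read_bytes()).hexdigest()
            for k, v in inputs.items()
        }
    return manifest
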