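"""CSV readers/writers, run configuration and the staged pipeline driver.

Canonical interchange formats (all plain CSV):

* stations: station_id, x, y [, survey_area, covariate columns...]
* daily detections: station_id, day_index, detected, active
* capture-recapture files in the three-file layout used by the SPACECAP
  tradition: animal captures (ANIMAL_ID, LOC_ID, SO), trap deployment
  (LOC_ID, X, Y, occasion flags...), habitat grid (X, Y, HABITAT).

Coordinates are planar projected metres throughout; no geodesic math.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import SchemaError


def _require(df: pd.DataFrame, cols: list, what: str):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} missing columns: {missing}")


def read_stations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["station_id", "x", "y"], "stations file")
    if df["station_id"].duplicated().any():
        row = int(df.index[df["station_id"].duplicated()][0])
        raise SchemaError(f"duplicate station_id at row {row}")
    return df


def read_daily(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["station_id", "day_index", "detected", "active"], "daily file")
    for col in ("detected", "active"):
        bad = ~df[col].isin((0, 1))
        if bad.any():
            raise SchemaError(
                f"non-binary {col} value at row {int(df.index[bad][0])}"
            )
    return df


def read_scr_files(animals_path, traps_path, habitat_path):
    """Read the three-file capture layout into (CaptureHistory, habitat frame).

    Occasion flag columns in the trap file are every column beyond LOC_ID,
    X, Y, in order.
    """
    from .scr import CaptureHistory

    animals = pd.read_csv(animals_path)
    traps = pd.read_csv(traps_path)
    habitat = pd.read_csv(habitat_path)
    _require(animals, ["ANIMAL_ID", "LOC_ID", "SO"], "animal capture file")
    _require(traps, ["LOC_ID", "X", "Y"], "trap file")
    _require(habitat, ["X", "Y", "HABITAT"], "habitat file")
    if traps["LOC_ID"].duplicated().any():
        raise SchemaError("duplicate LOC_ID in trap file")
    loc_index = {t: j for j, t in enumerate(traps["LOC_ID"])}
    unknown = ~animals["LOC_ID"].isin(loc_index)
    if unknown.any():
        raise SchemaError(
            f"animal capture references unknown LOC_ID at row "
            f"{int(animals.index[unknown][0])}"
        )
    occ_cols = [c for c in traps.columns if c not in ("LOC_ID", "X", "Y")]
    usage = traps[occ_cols].to_numpy(dtype=float) if occ_cols else None
    if usage is None:
        raise SchemaError("trap file has no occasion activity columns")
    K = usage.shape[1]
    if (animals["SO"] < 1).any() or (animals["SO"] > K).any():
        raise SchemaError("capture occasion (SO) outside 1..n_occasions")
    ids = list(pd.unique(animals["ANIMAL_ID"]))
    counts = np.zeros((len(ids), len(traps)), dtype=int)
    aidx = {a: i for i, a in enumerate(ids)}
    for _, r in animals.iterrows():
        counts[aidx[r["ANIMAL_ID"]], loc_index[r["LOC_ID"]]] += 1
    history = CaptureHistory(
        individuals=ids,
        counts=counts,
        trap_xy=traps[["X", "Y"]].to_numpy(dtype=float),
        usage=usage,
    )
    habitat = habitat.rename(columns={"X": "x", "Y": "y", "HABITAT": "habitat"})
    return history, habitat


def write_occasion_matrix(occ, path):
    """One row per station: y_1..y_K then eff_1..eff_K (y blank if missing)."""
    K = occ.n_occasions
    df = pd.DataFrame({"station_id": occ.stations})
    for k in range(K):
        df[f"y_{k + 1}"] = occ.y[:, k]
    for k in range(K):
        df[f"eff_{k + 1}"] = occ.effort[:, k]
    df.to_csv(path, index=False)


def read_occasion_matrix(path, occasion_length: int = 15):
    from .detections import OccasionMatrix

    df = pd.read_csv(path)
    ycols = sorted((c for c in df.columns if c.startswith("y_")),
                   key=lambda c: int(c.split("_")[1]))
    ecols = sorted((c for c in df.columns if c.startswith("eff_")),
                   key=lambda c: int(c.split("_")[1]))
    return OccasionMatrix(
        stations=list(df["station_id"]),
        y=df[ycols].to_numpy(dtype=float),
        effort=df[ecols].to_numpy(dtype=float),
        occasion_length=occasion_length,
    )


def write_scr_files(captures, habitat: pd.DataFrame, out_dir):
    """Write a CaptureHistory back to the three-file layout."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, aid in enumerate(captures.individuals):
        for j in np.flatnonzero(captures.counts[i] > 0):
            active = np.flatnonzero(captures.usage[j] > 0) + 1
            for c in range(captures.counts[i, j]):
                so = active[c % len(active)]
                rows.append({"ANIMAL_ID": aid, "LOC_ID": f"T{j:03d}", "SO": so})
    pd.DataFrame(rows).to_csv(out / "animals.csv", index=False)
    traps = pd.DataFrame({
        "LOC_ID": [f"T{j:03d}" for j in range(captures.n_traps)],
        "X": captures.trap_xy[:, 0], "Y": captures.trap_xy[:, 1],
    })
    for k in range(captures.n_occasions):
        traps[f"OCC_{k + 1}"] = captures.usage[:, k].astype(int)
    traps.to_csv(out / "traps.csv", index=False)
    habitat.rename(columns={"x": "X", "y": "Y", "habitat": "HABITAT"}).to_csv(
        out / "habitat.csv", index=False
    )


class RunConfig:
    """Validated YAML run configuration for the staged pipeline."""

    def __init__(self, stages: list, params: dict, seed: int, out_dir):
        self.stages = list(stages)
        self.params = dict(params)
        self.seed = int(seed)
        self.out_dir = Path(out_dir)

    @classmethod
    def from_yaml(cls, path):
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            stages=raw.get("stages", []),
            params=raw.get("params", {}),
            seed=raw.get("seed", 0),
            out_dir=raw.get("out_dir", "results"),
        )


def run_pipeline(config: RunConfig, force: bool = False) -> dict:
    """Execute requested stages in order, writing outputs and a manifest.

    Supported stages: simulate, prep, occupancy-ml. Refuses to overwrite an
    output directory holding a previous manifest unless ``force``.
    """
    out = config.out_dir
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not force:
        raise FileExistsError(
            f"{manifest_path} exists; pass force=True to overwrite"
        )
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__, "seed": config.seed,
        "stages": [], "status": "running",
    }
    t0 = time.time()
    try:
        for stage in config.stages:
            ts = time.time()
            _run_stage(stage, config)
            manifest["stages"].append(
                {"name": stage, "seconds": round(time.time() - ts, 3)}
            )
        manifest["status"] = "complete"
    except Exception:
        manifest["status"] = "failed"
        raise
    finally:
        manifest["total_seconds"] = round(time.time() - t0, 3)
        manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


def _run_stage(stage: str, config: RunConfig):
    from . import detections, occupancy_ml, synthetic

    out = config.out_dir
    p = config.params.get(stage.replace("-", "_"), {})
    if stage == "simulate":
        spec = synthetic.LandscapeSpec(
            n_stations=p.get("n_stations", 200),
            extent=tuple(p.get("extent", (0, 0, 60000, 60000))),
            min_spacing=p.get("min_spacing", 2000.0),
            seed=config.seed,
        )
        stations, pixels = synthetic.simulate_landscape(spec)
        std_cols = [c for c in stations.columns if c not in ("station_id", "x", "y")]
        stations_std, _ = detections.zscore(stations, std_cols)
        daily, truth = synthetic.simulate_occupancy_detections(
            stations_std,
            beta_psi=p.get("beta_psi", list(synthetic.STUDY_BETA_PSI)),
            beta_p=p.get("beta_p", [-1.8]),
            tau=p.get("tau", 1.0),
            seed=config.seed,
        )
        stations.to_csv(out / "stations.csv", index=False)
        rows = []
        for i, sid in enumerate(daily.stations):
            days = np.arange(daily.n_days)
            rows.append(pd.DataFrame({
                "station_id": sid, "day_index": days,
                "detected": daily.detected[i], "active": daily.active[i],
            }))
        pd.concat(rows, ignore_index=True).to_csv(out / "daily.csv", index=False)
        (out / "truth.json").write_text(json.dumps({
            "beta_psi": list(map(float, truth.beta_psi)),
            "tau": truth.tau,
            "mean_psi_true": float(truth.psi_true.mean()),
        }, indent=2))
    elif stage == "prep":
        stations = read_stations(out / "stations.csv")
        records = read_daily(out / "daily.csv")
        daily = detections.build_daily_matrix(records, stations)
        occ = detections.collapse_occasions(daily, p.get("occasion_length", 15))
        write_occasion_matrix(occ, out / "occasions.csv")
    elif stage == "occupancy-ml":
        stations = read_stations(out / "stations.csv")
        occ = read_occasion_matrix(out / "occasions.csv",
                                   p.get("occasion_length", 15))
        cov_cols = [c for c in stations.columns
                    if c not in ("station_id", "x", "y", "survey_area")]
        covs, _ = detections.zscore(stations, cov_cols)
        spec = occupancy_ml.OccupancyModelSpec(
            psi_terms=p.get("psi_terms", cov_cols),
            p_terms=p.get("p_terms", ["effort"]),
        )
        fit = occupancy_ml.fit_occupancy(spec, occ, covs, seed=config.seed)
        (out / "occupancy_ml.json").write_text(json.dumps({
            "model": fit.spec.label(),
            "loglik": fit.loglik, "K": fit.K, "AICc": fit.aicc,
            "beta_psi": fit.beta_psi.to_dict(),
            "beta_p": fit.beta_p.to_dict(),
            "converged": fit.converged,
        }, indent=2))
    else:
        raise ValueError(f"unknown stage {stage!r}")
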