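"""Output bundle serialization: CSVs, raster snapshots, logs.

All CSVs are RFC-4180 UTF-8 with "." decimals, a header row and units in
the column names, written atomically (temp file + rename).  Raster
snapshots of per-cell quantities are single-band float32 TIFFs with an
accompanying ESRI world file (.tfw) encoding the synthetic 100-m grid
transform (north-up, origin at 0/0).
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SPECIES, RunConfig
from .errors import InvalidInputError
from .experiment import ExperimentResult
from .indicators import IndicatorVector
from .landscape import LandscapeState

log = logging.getLogger("beetlescape")


def _atomic_write(path: Path, write_fn) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    try:
        write_fn(Path(tmp))
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_csv(df: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    path = Path(path)
    _atomic_write(path, lambda p: df.to_csv(p, index=index,
                                            lineterminator="\n"))
    return path


def landscape_to_frame(state: LandscapeState) -> pd.DataFrame:
    """Long-format cohort table (one row per occupied cohort slot)."""
    rr, cc, kk = np.nonzero(state.occupied)
    return pd.DataFrame({
        "row": rr, "col": cc,
        "species": [SPECIES[s] for s in state.species[rr, cc, kk]],
        "stems_per_ha": state.stems[rr, cc, kk],
        "mean_dbh_cm": state.dbh[rr, cc, kk],
        "mean_height_m": state.height[rr, cc, kk],
        "age_yr": state.age[rr, cc, kk],
    })


def write_landscape_csv(state: LandscapeState, path: str | Path) -> Path:
    return write_csv(landscape_to_frame(state), path)


def write_raster(field2d: np.ndarray, path: str | Path,
                 cell_size_m: float = 100.0) -> Path:
    """Single-band float32 TIFF + .tfw world file (100-m pixels, north-up)."""
    import tifffile

    path = Path(path)
    arr = np.asarray(field2d, dtype=np.float32)
    if arr.ndim != 2:
        raise InvalidInputError("raster snapshots must be 2-D")
    _atomic_write(path, lambda p: tifffile.imwrite(p, arr))
    # ESRI world file: x-size, rotations, negative y-size, center of top-left
    tfw = path.with_suffix(".tfw")
    lines = [cell_size_m, 0.0, 0.0, -cell_size_m,
             cell_size_m / 2.0, -cell_size_m / 2.0]
    _atomic_write(tfw, lambda p: p.write_text(
        "\n".join(f"{v:.6f}" for v in lines) + "\n"))
    return path


def read_raster(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a raster snapshot; returns (array, cell size from the .tfw)."""
    import tifffile

    path = Path(path)
    arr = tifffile.imread(path)
    cell = float(Path(path).with_suffix(".tfw").read_text().splitlines()[0])
    return arr, cell


def kill_series_frame(experiment: ExperimentResult) -> pd.DataFrame:
    rows = []
    for (climate, dist, rep), run in sorted(experiment.runs.items()):
        for year in range(run.annual_kill.size):
            rows.append({
                "climate": climate, "disturbed": dist, "replicate": rep,
                "year": year + 1,
                "beetle_kill_m3_ha": run.annual_kill[year],
                "wind_kill_m3_ha": run.annual_wind[year],
            })
    return pd.DataFrame(rows)


def indicator_frame(experiment: ExperimentResult) -> pd.DataFrame:
    rows = []
    for (climate, dist, rep), run in sorted(experiment.runs.items()):
        for iv in run.indicators:
            row = {"climate": climate, "disturbed": dist, "replicate": rep,
                   "year": iv.year}
            row.update({f: getattr(iv, f) for f in IndicatorVector.FIELDS})
            rows.append(row)
    return pd.DataFrame(rows)


def events_frame(experiment: ExperimentResult) -> pd.DataFrame:
    rows = []
    for (climate, dist, rep), run in sorted(experiment.runs.items()):
        for rec in run.kill_events:
            rows.append({"climate": climate, "replicate": rep,
                         "year": rec.year, "row": rec.cell_index[0],
                         "col": rec.cell_index[1], "agent": "beetle",
                         "volume_m3_ha": rec.volume_m3_ha})
        for ev in run.wind_events:
            rows.append({"climate": climate, "replicate": rep,
                         "year": ev.year, "row": ev.cell_index[0],
                         "col": ev.cell_index[1], "agent": "wind",
                         "volume_m3_ha": ev.downed_spruce_volume_m3_ha})
    return pd.DataFrame(rows, columns=["climate", "replicate", "year", "row",
                                       "col", "agent", "volume_m3_ha"])


def write_outputs(out_dir: str | Path, experiment: ExperimentResult,
                  cfg: RunConfig | None = None) -> dict:
    """Write the standard output bundle for an experiment.

    Files: config echo (JSON, with hash and seeds), kill series CSV,
    indicator CSV and event-log CSV.  Analysis outputs (attribution,
    feedback, PCA) are written by their own subcommands so re-running them
    on a bundle never re-simulates.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = cfg or experiment.config
    paths = {}
    if cfg is not None:
        echo = {"config": cfg.to_dict(), "config_hash": cfg.config_hash(),
                "seeds": sorted({r.seed for r in experiment.runs.values()})}
        _atomic_write(out / "config.json",
                      lambda p: p.write_text(json.dumps(echo, indent=2,
                                                        default=str)))
        paths["config"] = out / "config.json"
    paths["kill_series"] = write_csv(kill_series_frame(experiment),
                                     out / "kill_series.csv")
    paths["indicators"] = write_csv(indicator_frame(experiment),
                                    out / "indicators.csv")
    paths["events"] = write_csv(events_frame(experiment), out / "events.csv")
    log.info("wrote output bundle to %s", out)
    return paths
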