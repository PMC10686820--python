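"""File dialects: colony tables, result records, configs, images + sidecars.

Colony tables are CSV/TSV with a header (``tip_id, x_mm`` and optional
``y_mm, z_mm, radius_px`` columns the estimator ignores).  Results are one
record per tip, as CSV or JSON-lines.  Geometry/run configuration is YAML or
JSON.  Synthetic images are 16-bit PNG/TIFF with a JSON sidecar carrying the
ground truth and calibration.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .estimator import CfuEstimate, ColonySet
from .geometry import GEOMETRY_PROFILES, ConeGeometry
from .imaging import OpticsProfile, SyntheticTipImage

__all__ = [
    "read_colony_table",
    "write_colony_table",
    "write_results",
    "read_results",
    "load_config",
    "geometry_from_config",
    "resolve_geometry",
    "save_tip_image",
    "load_tip_image",
]

RESULT_FIELDS = ["tip_id", "n_colonies", "x1_mm", "x2_mm", "cfu_per_ml_sample", "below_lod"]


def _read_table(path) -> pd.DataFrame:
    # sniff the delimiter so .csv/.tsv/.txt all parse identically
    return pd.read_csv(path, sep=None, engine="python")


def read_colony_table(
    path,
    geom: ConeGeometry | None = None,
    dilution_factor: float = 100.0,
) -> list[ColonySet]:
    """Read a colony-position table into one :class:`ColonySet` per tip.

    Rows with positions outside ``[0, h]`` are rejected (reported with their
    line numbers); unsorted positions are sorted with a warning.
    """
    geom = geom or ConeGeometry()
    df = _read_table(path)
    missing = {"tip_id", "x_mm"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    h = geom.axial_length_mm
    bad = df.index[(df["x_mm"] < 0) | (df["x_mm"] > h)]
    if len(bad):
        # +2: header line and 1-based numbering
        lines = [int(i) + 2 for i in bad[:20]]
        warnings.warn(
            f"{path}: rejected {len(bad)} row(s) with x_mm outside [0, {h:g}] "
            f"(file lines {lines}{'...' if len(bad) > 20 else ''})",
            stacklevel=2,
        )
        df = df.drop(index=bad)
    out = []
    for tip_id, grp in df.groupby("tip_id", sort=False):
        x = grp["x_mm"].to_numpy(dtype=float)
        if x.size > 1 and np.any(np.diff(x) < 0):
            warnings.warn(f"{path}: tip {tip_id!r} positions unsorted; sorting", stacklevel=2)
            x = np.sort(x, kind="stable")
        out.append(
            ColonySet(
                tip_id=str(tip_id),
                positions_mm=x,
                geom=geom,
                dilution_factor=dilution_factor,
                y_mm=grp["y_mm"].to_numpy(dtype=float) if "y_mm" in grp else None,
                z_mm=grp["z_mm"].to_numpy(dtype=float) if "z_mm" in grp else None,
            )
        )
    return out


def write_colony_table(colony_sets: list[ColonySet], path) -> None:
    frames = []
    for cs in colony_sets:
        d = {"tip_id": cs.tip_id, "x_mm": cs.positions_mm}
        if cs.y_mm is not None:
            d["y_mm"] = cs.y_mm
        if cs.z_mm is not None:
            d["z_mm"] = cs.z_mm
        frames.append(pd.DataFrame(d))
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=["tip_id", "x_mm"])
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df.to_csv(path, sep=sep, index=False)


def _record(est: CfuEstimate) -> dict:
    x1, x2 = est.interval_mm if est.interval_mm else (None, None)
    return {
        "tip_id": est.tip_id,
        "n_colonies": est.n_counted,
        "x1_mm": x1,
        "x2_mm": x2,
        "cfu_per_ml_sample": est.cfu_per_ml_sample,
        "below_lod": bool(est.below_lod),
    }


def write_results(estimates: list[CfuEstimate], path, header: dict | None = None) -> None:
    """Write per-tip result records as CSV or JSON-lines (by extension).

    ``header`` (seed, config, ...) is embedded as a leading ``#`` comment in
    CSV, or as a first ``{"_header": ...}`` line in JSON-lines, so every
    stochastic run records its provenance.
    """
    path = Path(path)
    records = [_record(e) for e in estimates]
    if path.suffix in (".jsonl", ".ndjson", ".json"):
        with open(path, "w", encoding="utf-8") as fh:
            if header:
                fh.write(json.dumps({"_header": header}) + "\n")
            for r in records:
                fh.write(json.dumps(r) + "\n")
    else:
        with open(path, "w", encoding="utf-8") as fh:
            if header:
                fh.write("# " + json.dumps(header) + "\n")
            pd.DataFrame(records, columns=RESULT_FIELDS).to_csv(fh, index=False)


def read_results(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix in (".jsonl", ".ndjson", ".json"):
        rows = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                obj = json.loads(line)
                if "_header" not in obj:
                    rows.append(obj)
        return pd.DataFrame(rows, columns=RESULT_FIELDS)
    return pd.read_csv(path, comment="#")


def load_config(path) -> dict:
    """Load a YAML or JSON configuration mapping."""
    text = Path(path).read_text(encoding="utf-8")
    cfg = yaml.safe_load(text)  # YAML is a JSON superset
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return cfg


def geometry_from_config(cfg: dict) -> ConeGeometry:
    """Build a geometry from config keys ``shape, axial_length_mm, volume_uL``."""
    if "profile" in cfg:
        return resolve_geometry(cfg["profile"])
    return ConeGeometry(
        shape=cfg.get("shape", "circular_cone"),
        axial_length_mm=float(cfg["axial_length_mm"]),
        volume_uL=float(cfg["volume_uL"]),
    )


def resolve_geometry(name_or_path: str) -> ConeGeometry:
    """A profile name ("p200"), or a YAML/JSON geometry file path."""
    if name_or_path in GEOMETRY_PROFILES:
        return GEOMETRY_PROFILES[name_or_path]
    p = Path(name_or_path)
    if p.exists():
        return geometry_from_config(load_config(p))
    raise ValueError(
        f"unknown geometry {name_or_path!r}: not a profile "
        f"({sorted(GEOMETRY_PROFILES)}) and not an existing config file"
    )


def save_tip_image(image: SyntheticTipImage, path) -> None:
    """Write pixels (16-bit PNG or TIFF by extension) plus a JSON sidecar."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, image.pixels)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, image.pixels)
    sidecar = {
        "pixel_size_um": image.optics.pixel_size_um,
        "noise_sd": image.optics.noise_sd,
        "geometry": dataclasses.asdict(image.geom),
        "truth_positions_mm": image.truth_positions_mm.tolist(),
        "truth_radii_px": image.truth_radii_px.tolist(),
        "apex_px": list(image.apex_px),
        "axis_angle_deg": image.axis_angle_deg,
        "resolution_warning": image.resolution_warning,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1), encoding="utf-8"
    )


def load_tip_image(path) -> SyntheticTipImage:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        pixels = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        pixels = iio.imread(path)
    sc = json.loads(path.with_suffix(path.suffix + ".json").read_text(encoding="utf-8"))
    return SyntheticTipImage(
        pixels=np.asarray(pixels),
        optics=OpticsProfile(pixel_size_um=sc["pixel_size_um"], noise_sd=sc.get("noise_sd", 0.0)),
        geom=ConeGeometry(**sc["geometry"]),
        truth_positions_mm=np.asarray(sc["truth_positions_mm"], dtype=float),
        truth_radii_px=np.asarray(sc["truth_radii_px"], dtype=float),
        apex_px=tuple(sc["apex_px"]),
        axis_angle_deg=sc["axis_angle_deg"],
        resolution_warning=sc.get("resolution_warning", False),
    )
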