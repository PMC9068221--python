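"""End-to-end planning driver, configuration, JSON reports and exports.

``run_plan`` wires the whole pipeline: load and validate the label volume,
resample to an isotropic grid, anchor at the target centroid, search the pose
grid (optionally shrinking the drill until a path exists), rank the feasible
corridors by clearance, and write a deterministic JSON report plus an optional
feasible-corridor overlay volume.

Config files are flat ``key = value`` text; every key has a CLI flag of the
same name.  Reports contain no timestamps, so identical inputs produce
byte-identical payloads.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import Anchor, Pose, SearchGrid, ToolSpec, pose_to_corridor, target_anchor, rasterize_corridor
from .phantom import standard_phantom_specs
from .search import (
    ClearanceMap,
    FeasibilityResult,
    adapt_tool_size,
    build_clearance_map,
    rank_paths,
    search_paths,
)
from .volume_io import LabelScheme, LabelVolume, read_labelmap, resample_isotropic, write_labelmap

__all__ = [
    "PlanConfig",
    "load_config",
    "run_plan",
    "write_report",
    "read_report",
    "export_path_mask",
    "sweep_diameters",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PlanConfig:
    """Everything one planning run needs; mirrors the flat config keys."""

    input_path: str
    output_dir: str = "."
    scheme: LabelScheme = field(default_factory=LabelScheme)
    tool: ToolSpec = field(default_factory=ToolSpec)
    grid: SearchGrid = field(default_factory=SearchGrid)
    adapt: bool = True
    resample_spacing: float | None = None  # None: min input spacing
    export_overlay: bool = False
    overlay_top_k: int | None = None
    report_max_poses: int = 50
    report_name: str = "plan_report.json"
    overlay_name: str = "feasible_corridors.nii.gz"


_SCHEME_KEYS = {"air", "surgical_space", "non_surgical", "target"}
_TOOL_KEYS = {"head_diameter", "shaft_diameter", "min_diameter", "decrement"}
_GRID_KEYS = {"rot_step", "rot_range", "spin_step", "spin_range", "travel_step", "travel_range"}


def _parse_value(text: str):
    text = text.strip()
    low = text.lower()
    if low in ("true", "yes", "on"):
        return True
    if low in ("false", "no", "off"):
        return False
    if low in ("none", "null"):
        return None
    try:
        return int(text)
    except ValueError:
        pass
    try:
        return float(text)
    except ValueError:
        return text


def load_config(path: str | os.PathLike) -> dict:
    """Parse a flat ``key = value`` config file (# starts a comment)."""
    out: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, val = line.split("=", 1)
        out[key.strip()] = _parse_value(val)
    return out


def config_from_mapping(mapping: dict) -> PlanConfig:
    """Build a PlanConfig from flat keys (config file and/or CLI overrides)."""
    m = dict(mapping)
    scheme = LabelScheme(**{k: m.pop(k) for k in list(m) if k in _SCHEME_KEYS})
    tool = ToolSpec(**{k: m.pop(k) for k in list(m) if k in _TOOL_KEYS})
    grid = SearchGrid(**{k: m.pop(k) for k in list(m) if k in _GRID_KEYS})
    known = {f.name for f in dataclasses.fields(PlanConfig)}
    unknown = set(m) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return PlanConfig(scheme=scheme, tool=tool, grid=grid, **m)


# -- report serialization --------------------------------------------------


def _grid_dict(grid: SearchGrid) -> dict:
    return {k: getattr(grid, k) for k in sorted(_GRID_KEYS)}


def _tool_dict(tool: ToolSpec) -> dict:
    return {k: getattr(tool, k) for k in sorted(_TOOL_KEYS)}


def result_to_dict(result: FeasibilityResult,
                   ranked: list[tuple[Pose, float]] | None = None,
                   max_poses: int | None = None) -> dict:
    """JSON-ready dict: config echo, counts, fraction, trace, ranked poses."""
    if ranked is None:
        poses = [{"rx": p.rx, "ry": p.ry, "rz": p.rz, "spin": p.spin,
                  "depth": p.depth} for p in result.feasible_poses]
    else:
        poses = [{"rx": p.rx, "ry": p.ry, "rz": p.rz, "spin": p.spin,
                  "depth": p.depth,
                  "clearance_mm": (None if np.isinf(c) else c)}
                 for p, c in ranked]
    n_listed = len(poses)
    if max_poses is not None:
        poses = poses[:max_poses]
    return {
        "grid": _grid_dict(result.grid),
        "tool": _tool_dict(result.tool),
        "anchor": {"point": list(result.anchor.point),
                   "outward": list(result.anchor.outward)},
        "tool_diameter_used": result.tool_diameter_used,
        "n_poses_total": result.n_poses_total,
        "n_feasible": result.n_feasible,
        "feasible_fraction": result.feasible_fraction,
        "adaptation_trace": list(result.adaptation_trace),
        "infeasible_at_floor": result.infeasible_at_floor,
        "n_poses_listed": min(n_listed, max_poses) if max_poses is not None else n_listed,
        "poses": poses,
    }


def result_from_dict(d: dict) -> FeasibilityResult:
    """Inverse of :func:`result_to_dict` for reports listing all feasible poses."""
    grid = SearchGrid(**d["grid"])
    tool = ToolSpec(**d["tool"])
    anchor = Anchor(point=tuple(d["anchor"]["point"]),
                    outward=tuple(d["anchor"]["outward"]))
    poses = tuple(Pose(p["rx"], p["ry"], p["rz"], p["spin"], p["depth"])
                  for p in d["poses"])
    return FeasibilityResult(
        grid=grid, tool=tool, anchor=anchor,
        tool_diameter_used=d["tool_diameter_used"],
        n_poses_total=d["n_poses_total"], n_feasible=d["n_feasible"],
        feasible_poses=poses,
        adaptation_trace=tuple(d["adaptation_trace"]),
        infeasible_at_floor=d["infeasible_at_floor"],
    )


def write_report(result: FeasibilityResult, path: str | os.PathLike,
                 ranked: list[tuple[Pose, float]] | None = None,
                 max_poses: int | None = None,
                 config_echo: dict | None = None) -> None:
    """Write the JSON report with stable key order and no timestamps."""
    payload = result_to_dict(result, ranked=ranked, max_poses=max_poses)
    if config_echo is not None:
        payload["config"] = config_echo
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=2)
        fh.write("\n")


def read_report(path: str | os.PathLike) -> dict:
    with open(path) as fh:
        return json.load(fh)


def export_path_mask(result: FeasibilityResult, vol: LabelVolume,
                     path: str | os.PathLike,
                     ranked: list[tuple[Pose, float]] | None = None,
                     top_k: int | None = None) -> LabelVolume:
    """Write the union of rasterized feasible corridors as a binary overlay.

    With ``top_k`` the union covers only the k best-ranked poses (ranked list
    required); otherwise every feasible pose contributes.  The overlay shares
    the volume's grid and spacing.
    """
    tool = replace(result.tool, head_diameter=result.tool_diameter_used,
                   shaft_diameter=None)
    if top_k is not None:
        if ranked is None:
            raise ValueError("top_k export requires the ranked pose list")
        poses = [p for p, _ in ranked[:top_k]]
    else:
        poses = list(result.feasible_poses)
    mask = np.zeros(vol.shape, dtype=np.int16)
    seen: set[tuple[float, float, float, float]] = set()
    for pose in poses:
        key = (pose.rx, pose.ry, pose.rz, pose.depth)  # spin leaves the capsule unchanged
        if key in seen:
            continue
        seen.add(key)
        idx = rasterize_corridor(pose_to_corridor(pose, result.anchor, tool, vol), vol)
        if idx.size:
            mask[idx[:, 0], idx[:, 1], idx[:, 2]] = 1
    overlay = LabelVolume(mask, vol.spacing, vol.origin)
    write_labelmap(overlay, path)
    return overlay


# -- end-to-end driver -----------------------------------------------------


def run_plan(cfg: PlanConfig) -> tuple[FeasibilityResult, list[tuple[Pose, float]]]:
    """Load -> validate -> resample -> anchor -> search/adapt -> rank -> write.

    Returns the feasibility result and the clearance-ranked pose list; the
    JSON report (and optional overlay) land in ``cfg.output_dir``.
    """
    vol = read_labelmap(cfg.input_path, cfg.scheme)
    vol = resample_isotropic(vol, cfg.resample_spacing)
    anchor = target_anchor(vol, cfg.scheme)
    cmap = build_clearance_map(vol, cfg.scheme)
    logger.info("volume %s at %.3g mm; %d poses on the grid",
                vol.shape, vol.spacing[0], cfg.grid.n_poses)
    if cfg.adapt:
        result = adapt_tool_size(vol, cfg.scheme, anchor, cfg.tool, cfg.grid, cmap=cmap)
    else:
        result = search_paths(vol, cfg.scheme, anchor, cfg.tool, cfg.grid, cmap=cmap)
    ranked = rank_paths(result, cmap, vol)
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_report(result, outdir / cfg.report_name, ranked=ranked,
                 max_poses=cfg.report_max_poses, config_echo=_config_echo(cfg))
    if cfg.export_overlay:
        export_path_mask(result, vol, outdir / cfg.overlay_name,
                         ranked=ranked, top_k=cfg.overlay_top_k)
    logger.info("%d / %d poses feasible at %.2f mm",
                result.n_feasible, result.n_poses_total, result.tool_diameter_used)
    return result, ranked


def _config_echo(cfg: PlanConfig) -> dict:
    return {
        "input_path": str(cfg.input_path),
        "adapt": cfg.adapt,
        "resample_spacing": cfg.resample_spacing,
        "scheme": {"air": cfg.scheme.air, "surgical_space": cfg.scheme.surgical_space,
                   "non_surgical": cfg.scheme.non_surgical, "target": cfg.scheme.target},
        "tool": _tool_dict(cfg.tool),
        "grid": _grid_dict(cfg.grid),
    }


def sweep_diameters(vol: LabelVolume, scheme: LabelScheme, anchor: Anchor,
                    grid: SearchGrid, diameters: list[float],
                    cmap: ClearanceMap | None = None) -> pd.DataFrame:
    """Feasible-path fraction as a function of drill diameter.

    Reproduces the drill-size screening curve: one exhaustive search per
    diameter on a shared clearance map.
    """
    if cmap is None:
        cmap = build_clearance_map(vol, scheme)
    rows = []
    for d in diameters:
        tool = ToolSpec(head_diameter=float(d))
        res = search_paths(vol, scheme, anchor, tool, grid, cmap=cmap)
        rows.append({"diameter_mm": float(d),
                     "n_feasible": res.n_feasible,
                     "n_poses_total": res.n_poses_total,
                     "feasible_fraction": res.feasible_fraction})
    return pd.DataFrame(rows)
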