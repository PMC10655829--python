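"""File formats, run configuration and manifests.

All interchange formats are plain text: frames are zero-padded PNG (or TIFF)
files in a directory, time series are comma-separated CSV with a mandatory
header row (times in ms, forces in μN, angles in degrees), structured results
are JSON, and configuration is YAML.  Every pipeline run can write a manifest
(config, seed, input checksums) sufficient to reproduce its outputs
byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .forces import BodyGeometry, ForceTrace
from .kinematics import AngleSeries
from .synthetic import SceneParams, StrokeModel
from .tracking import Calibration, Trajectory

__all__ = [
    "RunConfig",
    "write_frames",
    "read_frames",
    "write_trace",
    "read_trace",
    "write_angles",
    "read_angles",
    "write_trajectory",
    "read_trajectory",
    "write_json",
    "read_json",
    "write_manifest",
]

_FRAME_RE = re.compile(r"frame_(\d+)\.(png|tif|tiff)$", re.IGNORECASE)


# ---------------------------------------------------------------- frames

def write_frames(stack: np.ndarray, outdir: str | Path, fmt: str = "png") -> list[Path]:
    """Write a frame stack as zero-padded ``frame_000001.png`` files."""
    if fmt not in ("png", "tif"):
        raise ConfigError(f"unsupported frame format {fmt!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(np.asarray(stack, dtype=np.uint8)):
        path = outdir / f"frame_{i + 1:06d}.{fmt}"
        iio.imwrite(path, frame)
        paths.append(path)
    return paths


def read_frames(indir: str | Path) -> np.ndarray:
    """Read a directory of PNG/TIFF frames in natural (numeric) sort order."""
    indir = Path(indir)
    entries = []
    for path in indir.iterdir():
        m = _FRAME_RE.search(path.name)
        if m:
            entries.append((int(m.group(1)), path))
    if not entries:
        raise ConfigError(f"no frame_NNNNNN.png/.tif files in {indir}")
    entries.sort()
    return np.stack([iio.imread(p) for _, p in entries])


# ----------------------------------------------------------- time series

def write_trace(trace: ForceTrace, path: str | Path) -> None:
    pd.DataFrame({"t_ms": trace.t_ms, "force_uN": trace.force_uN}).to_csv(
        path, index=False
    )


def read_trace(path: str | Path) -> ForceTrace:
    df = pd.read_csv(path)
    for col in ("t_ms", "force_uN"):
        if col not in df.columns:
            raise ConfigError(f"trace CSV missing column {col!r}")
    t = df["t_ms"].to_numpy(float)
    if len(t) < 2:
        raise ConfigError("trace needs >= 2 samples")
    fs_hz = 1000.0 / float(t[1] - t[0])
    return ForceTrace(t_ms=t, force_uN=df["force_uN"].to_numpy(float), fs_hz=fs_hz)


def write_angles(angles: AngleSeries, path: str | Path) -> None:
    pd.DataFrame({"t_ms": angles.t_ms, "theta_deg": angles.theta_deg}).to_csv(
        path, index=False
    )


def read_angles(path: str | Path) -> AngleSeries:
    df = pd.read_csv(path)
    for col in ("t_ms", "theta_deg"):
        if col not in df.columns:
            raise ConfigError(f"angle CSV missing column {col!r}")
    return AngleSeries(t_ms=df["t_ms"].to_numpy(float),
                       theta_deg=df["theta_deg"].to_numpy(float))


def write_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    """Trajectory CSV plus a JSON metadata sidecar (calibration, gap count)."""
    path = Path(path)
    pd.DataFrame({
        "t_ms": trajectory.t_ms,
        "x_mm": trajectory.x_mm,
        "y_mm": trajectory.y_mm,
    }).to_csv(path, index=False)
    meta = {
        "mm_per_px": trajectory.calibration.mm_per_px,
        "calibration_source": trajectory.calibration.source,
        "n_interpolated": trajectory.n_interpolated,
    }
    write_json(meta, path.with_suffix(".meta.json"))


def read_trajectory(path: str | Path) -> Trajectory:
    path = Path(path)
    df = pd.read_csv(path)
    meta_path = path.with_suffix(".meta.json")
    if meta_path.exists():
        meta = read_json(meta_path)
        cal = Calibration(mm_per_px=meta["mm_per_px"],
                          source=meta.get("calibration_source", "file"))
        n_interp = int(meta.get("n_interpolated", 0))
    else:
        cal = Calibration(mm_per_px=1.0, source="unknown (no sidecar)")
        n_interp = 0
    return Trajectory(t_ms=df["t_ms"].to_numpy(float),
                      x_mm=df["x_mm"].to_numpy(float),
                      y_mm=df["y_mm"].to_numpy(float),
                      calibration=cal, n_interpolated=n_interp)


# ------------------------------------------------------------------ JSON

def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(data, path: str | Path) -> None:
    Path(path).write_text(json.dumps(data, indent=2, default=_jsonable) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


# ----------------------------------------------------------- run config

@dataclass
class RunConfig:
    """Validated parameters for a full simulate/track/analyse run."""

    stroke: StrokeModel = field(default_factory=StrokeModel)
    scene: SceneParams = field(default_factory=SceneParams)
    geometry: BodyGeometry = field(default_factory=BodyGeometry)
    duration_ms: float = 80.0
    seed: int = 0
    # tracking
    threshold_frac: float = 0.5
    min_area_px: int = 4
    gap_limit: int = 3
    # kinematics
    window_pts: int = 7
    baseline_ms: float = 15.0
    k_sigma: float = 3.0
    sustain_pts: int = 3
    # force constants
    apportionment: float = 0.7
    n_legs: int = 2
    vertical_factor: float = 1.2
    # direct-trace generator settings
    trace_peak_uN: float = 2172.0
    trace_onset_ms: float = 50.0
    trace_rise_ms: float = 160.0
    trace_decay_ms: float = 150.0
    trace_noise_uN: float = 5.0
    trace_duration_ms: float = 600.0
    trace_baseline_ms: float = 40.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Check every stage's preconditions before any stage runs."""
        if self.duration_ms < self.stroke.start_ms + self.stroke.thrust_duration_ms:
            raise ConfigError("duration_ms too short for the stroke window")
        if self.window_pts < 3 or self.window_pts % 2 == 0:
            raise ConfigError("window_pts must be odd and >= 3")
        if not 0 < self.apportionment <= 1:
            raise ConfigError("apportionment must be in (0, 1]")
        if self.n_legs < 1:
            raise ConfigError("n_legs must be >= 1")
        if self.vertical_factor < 1:
            raise ConfigError("vertical_factor must be >= 1")
        if self.baseline_ms >= self.stroke.start_ms + 1:
            # the baseline window must precede stroke onset
            raise ConfigError("baseline_ms must end before the stroke starts")
        if self.trace_baseline_ms >= self.trace_onset_ms:
            raise ConfigError("trace_baseline_ms must end before trace onset")
        n_base = int(self.baseline_ms * self.scene.fps / 1000.0)
        if n_base < 5:
            raise ConfigError("baseline window holds fewer than 5 samples")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        for key, typ in (("stroke", StrokeModel), ("scene", SceneParams),
                         ("geometry", BodyGeometry)):
            if key in data and isinstance(data[key], dict):
                sub = dict(data[key])
                if key == "scene" and "frame_shape" in sub:
                    sub["frame_shape"] = tuple(sub["frame_shape"])
                data[key] = typ(**sub)
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        data = self.to_dict()
        data["scene"]["frame_shape"] = list(data["scene"]["frame_shape"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


# -------------------------------------------------------------- manifest

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir: str | Path, config: RunConfig,
                   inputs: dict[str, str | Path] | None = None) -> Path:
    """Record config, seed and input checksums so a run can be replayed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": _listify(config.to_dict()),
        "seed": config.seed,
        "inputs": {},
    }
    for name, path in (inputs or {}).items():
        path = Path(path)
        if path.is_dir():
            digests = {p.name: _sha256(p) for p in sorted(path.iterdir()) if p.is_file()}
            manifest["inputs"][name] = {"dir": str(path), "sha256": digests}
        else:
            manifest["inputs"][name] = {"file": str(path), "sha256": _sha256(path)}
    path = outdir / "manifest.json"
    write_json(manifest, path)
    return path


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return list(obj)
    return obj
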