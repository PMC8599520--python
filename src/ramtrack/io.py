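"""Frame sources, run configuration and result writers.

Replaces an interactive capture/display UI with a file-based batch pipeline:
frames come from a directory of numbered PNG/BMP images (or a video file if
an imageio video backend is available), and a completed session is written
out as a trajectory CSV, a summary table (CSV and XLSX), a trajectory bitmap
with the maze outline, and a zone-occupancy heatmap.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterator, Mapping

import imageio.v3 as iio
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from .geometry import MazeGeometry, build_geometry
from .metrics import SessionReport, Trajectory, zone_histogram

__all__ = [
    "read_frames",
    "read_trajectory",
    "write_outputs",
    "load_config",
    "save_frames",
]

_FRAME_EXTS = {".png", ".bmp", ".tif", ".tiff", ".jpg", ".jpeg"}


def _numeric_key(p: Path):
    nums = re.findall(r"\d+", p.stem)
    return (int(nums[-1]) if nums else 0, p.name)


def read_frames(source: str | Path, fps: float = 20.0) -> Iterator[tuple[float, np.ndarray]]:
    """Yield ``(t_seconds, frame)`` from a frame directory or a video file.

    Directory frames are ordered by the trailing number in their filename and
    timestamped at ``index / fps``.  Video files are decoded through imageio
    (requires a video plugin).
    """
    source = Path(source)
    if not source.exists():
        raise FileNotFoundError(f"frame source does not exist: {source}")
    if source.is_dir():
        files = sorted(
            (p for p in source.iterdir() if p.suffix.lower() in _FRAME_EXTS),
            key=_numeric_key,
        )
        if not files:
            raise ValueError(f"no image frames found in directory: {source}")

        def gen() -> Iterator[tuple[float, np.ndarray]]:
            for i, p in enumerate(files):
                try:
                    yield i / fps, np.asarray(iio.imread(p))
                except Exception as exc:  # pragma: no cover - corrupt input
                    raise ValueError(f"unreadable frame: {p}") from exc

        return gen()

    def gen_video() -> Iterator[tuple[float, np.ndarray]]:
        try:
            frames = iio.imiter(source)
        except Exception as exc:
            raise ValueError(
                f"cannot open video {source}: no imageio backend available "
                "(use a directory of PNG/BMP frames instead)"
            ) from exc
        n = 0
        for i, frame in enumerate(frames):
            n += 1
            yield i / fps, np.asarray(frame)
        if n == 0:
            raise ValueError(f"video contains no frames: {source}")

    return gen_video()


def save_frames(frames, outdir: str | Path, prefix: str = "frame") -> list[Path]:
    """Write a frame sequence as numbered PNGs (round-trips with read_frames)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, item in enumerate(frames):
        frame = item[1] if isinstance(item, tuple) else item
        p = outdir / f"{prefix}_{i:06d}.png"
        iio.imwrite(p, np.asarray(frame))
        paths.append(p)
    return paths


def read_trajectory(path: str | Path, sample_period: float | None = None) -> Trajectory:
    """Read a trajectory CSV written by :func:`write_outputs`."""
    df = pd.read_csv(path, float_precision="round_trip")
    cm_per_px = 1.0
    if "x_cm" in df and "x_px" in df:
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.asarray(df["x_cm"] / df["x_px"], float)
        ratio = ratio[np.isfinite(ratio) & (np.asarray(df["x_px"]) != 0)]
        if ratio.size:
            cm_per_px = float(np.median(ratio))
    t = np.asarray(df["t_s"], float)
    if sample_period is None:
        sample_period = float(np.median(np.diff(t))) if t.size > 1 else 0.05
    return Trajectory(
        t=t,
        x=np.asarray(df["x_px"], float),
        y=np.asarray(df["y_px"], float),
        found=np.asarray(df["found"], int).astype(bool),
        source=[str(s) for s in df["source"]],
        cm_per_px=cm_per_px,
        sample_period=sample_period,
    )


def _maze_outline(ax, geometry: MazeGeometry) -> None:
    mask = geometry.mask
    ax.contour(mask.astype(float), levels=[0.5], colors="0.6", linewidths=0.8)


def render_trajectory_bitmap(
    traj: Trajectory, geometry: MazeGeometry, path: str | Path
) -> None:
    """Food-search trajectory over the maze outline, saved as a bitmap."""
    fig, ax = plt.subplots(figsize=(5, 5), dpi=110)
    _maze_outline(ax, geometry)
    ok = np.isfinite(traj.x) & np.isfinite(traj.y)
    ax.plot(traj.x[ok], traj.y[ok], lw=0.7, color="tab:red")
    w, h = geometry.image_size
    ax.set_xlim(0, w)
    ax.set_ylim(h, 0)
    ax.set_aspect("equal")
    ax.set_title("food search trajectory")
    fig.savefig(path)
    plt.close(fig)


def render_zone_heatmap(traj: Trajectory, geometry: MazeGeometry, path: str | Path) -> None:
    """Per-zone dot-count heatmap (rainfall-statistics style)."""
    counts = zone_histogram(traj, geometry)
    zmap = geometry.zone_map
    img = np.full(zmap.shape, np.nan)
    inside = zmap >= 0
    img[inside] = counts[zmap[inside]]
    fig, ax = plt.subplots(figsize=(5, 5), dpi=110)
    m = ax.imshow(img, cmap="viridis", interpolation="nearest")
    fig.colorbar(m, ax=ax, label="samples per zone")
    ax.set_title("zone occupancy")
    fig.savefig(path)
    plt.close(fig)


def write_outputs(
    traj: Trajectory,
    report: SessionReport,
    geometry: MazeGeometry,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write the four session artifacts; returns name → path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "trajectory_csv": outdir / "trajectory.csv",
        "summary_csv": outdir / "summary.csv",
        "trajectory_png": outdir / "trajectory.png",
        "heatmap_png": outdir / "zone_heatmap.png",
    }
    traj.to_dataframe(geometry).to_csv(paths["trajectory_csv"], index=False)
    summary = report.to_series().to_frame("value")
    summary.index.name = "quantity"
    summary.to_csv(paths["summary_csv"])
    try:
        summary.to_excel(outdir / "summary.xlsx")
        paths["summary_xlsx"] = outdir / "summary.xlsx"
    except (ImportError, ModuleNotFoundError):  # spreadsheet output is optional
        pass
    render_trajectory_bitmap(traj, geometry, paths["trajectory_png"])
    render_zone_heatmap(traj, geometry, paths["heatmap_png"])
    return paths


def load_config(path: str | Path) -> dict:
    """Load a YAML run config.

    Recognised top-level keys: ``geometry`` (see
    :func:`ramtrack.geometry.build_geometry`), ``baited_arms`` (list of
    1-based arm numbers), ``tracker`` / ``behavior`` parameter overrides.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, Mapping):
        raise ValueError(f"config root must be a mapping: {path}")
    cfg = dict(cfg)
    baited = cfg.get("baited_arms", [])
    if len(set(baited)) != len(baited):
        raise ValueError("baited_arms must not contain duplicates")
    return cfg


def geometry_from_config(cfg: Mapping) -> MazeGeometry:
    return build_geometry(cfg.get("geometry", {}))
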