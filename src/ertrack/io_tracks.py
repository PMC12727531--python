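"""Trajectory, puncta and image I/O plus compartment assignment.

Trajectories come from a single-particle tracker (e.g. TrackMate) either as
the simplified ``<Tracks>`` XML export or as a flat CSV table with columns
``track_id, frame, t_s, x_um, y_um, intensity``.  All coordinates are stored
in micrometres with the origin at image (0, 0) and pixel centres at
``(i + 0.5) * pixel_size``; times are in seconds with ``t = frame *
frame_interval`` unless the file carries explicit times.

Compartment assignment labels each trajectory *cytoplasmic* or *nuclear*
from binary cell and nucleus masks so that nuclear localizations can be
removed before motion analysis.
"""

from __future__ import annotations

import logging
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

CSV_COLUMNS = ["track_id", "frame", "t_s", "x_um", "y_um", "intensity"]


class TrackParseError(ValueError):
    """Raised when a trajectory file cannot be parsed in the declared dialect."""


@dataclass(frozen=True)
class Localization:
    """A single localization: time (s), position (µm), optional intensity (a.u.)."""

    t: float
    x: float
    y: float
    frame: int = 0
    intensity: float | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.t) and math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite localization (t={self.t}, x={self.x}, y={self.y})")


@dataclass
class Trajectory:
    """One particle's time-ordered 2D localizations with compartment label."""

    track_id: str
    points: list[Localization]
    cell_id: str = "cell0"
    compartment: str = "unassigned"  # cytoplasmic | nuclear | unassigned

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError(f"track {self.track_id}: needs >=2 points, got {len(self.points)}")
        ts = [p.t for p in self.points]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError(f"track {self.track_id}: times not strictly increasing")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of positions in µm."""
        return np.array([(p.x, p.y) for p in self.points], dtype=float)

    @property
    def times(self) -> np.ndarray:
        return np.array([p.t for p in self.points], dtype=float)

    @property
    def frames(self) -> np.ndarray:
        return np.array([p.frame for p in self.points], dtype=int)


@dataclass
class TrajectorySet:
    trajectories: list[Trajectory]
    frame_interval: float  # s
    pixel_size: float  # µm / pixel
    condition: str = ""

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    def filter(self, compartment: str) -> "TrajectorySet":
        kept = [t for t in self.trajectories if t.compartment == compartment]
        return replace(self, trajectories=kept)


@dataclass
class ImageStack:
    """2D image or (t, y, x) stack with physical pixel size and frame interval."""

    pixels: np.ndarray
    pixel_size: float  # µm / pixel
    frame_interval: float = 1.0  # s

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.size == 0:
            raise ValueError("empty image")
        if self.pixels.ndim not in (2, 3):
            raise ValueError(f"expected 2D or 3D pixels, got ndim={self.pixels.ndim}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def n_frames(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[0]

    def frame(self, i: int) -> np.ndarray:
        return self.pixels if self.pixels.ndim == 2 else self.pixels[i]


# ---------------------------------------------------------------------------
# coordinate conversion


def um_to_pixel(coords_um: np.ndarray, pixel_size: float) -> np.ndarray:
    """Map µm coordinates to integer pixel indices (pixel centres at (i+0.5)·px)."""
    return np.floor(np.asarray(coords_um, dtype=float) / pixel_size).astype(int)


def pixel_to_um(indices: np.ndarray, pixel_size: float) -> np.ndarray:
    return (np.asarray(indices, dtype=float) + 0.5) * pixel_size


# ---------------------------------------------------------------------------
# readers / writers


def read_tracks(
    path: str | Path,
    format: str | None = None,
    pixel_size: float | None = None,
    frame_interval: float | None = None,
    condition: str = "",
) -> TrajectorySet:
    """Read trajectories from TrackMate-dialect XML or the package CSV schema.

    Tracks with fewer than two spots are dropped (and counted in the log);
    spots are sorted by frame and tracks by ascending track id.  For CSV the
    physical units are in the columns themselves, but ``pixel_size`` must be
    given (or defaults to 1 µm with a warning) since CSV carries no pixel
    metadata; XML carries ``frameInterval`` but not pixel size.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "xml_trackmate" if path.suffix.lower() == ".xml" else "csv"
    if format == "csv":
        return _read_tracks_csv(path, pixel_size, frame_interval, condition)
    if format == "xml_trackmate":
        return _read_tracks_xml(path, pixel_size, frame_interval, condition)
    raise ValueError(f"unknown track format {format!r}")


def _build_trajectories(groups: Iterable[tuple[str, list[Localization]]]) -> list[Trajectory]:
    trajectories: list[Trajectory] = []
    dropped = 0
    for tid, pts in groups:
        pts = sorted(pts, key=lambda p: (p.frame, p.t))
        if len(pts) < 2:
            dropped += 1
            continue
        trajectories.append(Trajectory(track_id=str(tid), points=pts))
    if dropped:
        logger.info("dropped %d track(s) with <2 spots", dropped)
    trajectories.sort(key=lambda tr: _natural_key(tr.track_id))
    return trajectories


def _natural_key(s: str):
    try:
        return (0, float(s), s)
    except ValueError:
        return (1, 0.0, s)


def _read_tracks_csv(
    path: Path, pixel_size: float | None, frame_interval: float | None, condition: str
) -> TrajectorySet:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise TrackParseError(f"{path}: not parseable as CSV ({exc})") from exc
    missing = [c for c in ("track_id", "frame", "x_um", "y_um") if c not in df.columns]
    if missing:
        raise TrackParseError(f"{path}: missing required column(s) {missing}")
    if "t_s" not in df.columns:
        if frame_interval is None:
            raise TrackParseError(
                f"{path}: no t_s column and no frame_interval override; "
                "pass frame_interval explicitly"
            )
        df = df.assign(t_s=df["frame"] * frame_interval)
    has_int = "intensity" in df.columns
    groups = []
    for tid, sub in df.groupby("track_id", sort=False):
        pts = []
        for row in sub.itertuples(index=True):
            try:
                pts.append(
                    Localization(
                        t=float(row.t_s),
                        x=float(row.x_um),
                        y=float(row.y_um),
                        frame=int(row.frame),
                        intensity=float(row.intensity) if has_int and pd.notna(row.intensity) else None,
                    )
                )
            except (TypeError, ValueError) as exc:
                raise TrackParseError(
                    f"{path}: bad record at row {row.Index} (track_id={tid}): {exc}"
                ) from exc
        groups.append((str(tid), pts))
    if frame_interval is None:
        frame_interval = _infer_frame_interval(df)
        if frame_interval is None:
            raise TrackParseError(
                f"{path}: cannot infer frame interval; pass frame_interval explicitly"
            )
    if pixel_size is None:
        logger.warning("%s: pixel_size unknown for CSV tracks; defaulting to 1 µm", path)
        pixel_size = 1.0
    return TrajectorySet(_build_trajectories(groups), frame_interval, pixel_size, condition)


def _infer_frame_interval(df: pd.DataFrame) -> float | None:
    d = df.sort_values(["track_id", "frame"])
    dt = d.groupby("track_id")["t_s"].diff()
    dframe = d.groupby("track_id")["frame"].diff()
    ok = dframe > 0
    if not ok.any():
        return None
    per = (dt[ok] / dframe[ok]).dropna()
    return float(per.median()) if len(per) else None


def _read_tracks_xml(
    path: Path, pixel_size: float | None, frame_interval: float | None, condition: str
) -> TrajectorySet:
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise TrackParseError(f"{path}: malformed XML ({exc})") from exc
    if root.tag != "Tracks":
        raise TrackParseError(f"{path}: expected <Tracks> root, got <{root.tag}>")
    if frame_interval is None:
        fi_attr = root.get("frameInterval")
        if fi_attr is None:
            raise TrackParseError(
                f"{path}: no frameInterval attribute; pass frame_interval explicitly"
            )
        frame_interval = float(fi_attr)
    if pixel_size is None:
        ps_attr = root.get("pixelSize")
        if ps_attr is None:
            raise TrackParseError(
                f"{path}: no pixelSize attribute; pass pixel_size explicitly"
            )
        pixel_size = float(ps_attr)
    groups = []
    for i, particle in enumerate(root.findall("particle")):
        tid = particle.get("id", str(i))
        pts = []
        for det in particle.findall("detection"):
            try:
                frame = int(float(det.get("t")))
                x = float(det.get("x"))
                y = float(det.get("y"))
            except (TypeError, ValueError) as exc:
                raise TrackParseError(
                    f"{path}: bad <detection> in particle {tid}: {dict(det.attrib)}"
                ) from exc
            inten = det.get("intensity")
            pts.append(
                Localization(
                    t=frame * frame_interval,
                    x=x,
                    y=y,
                    frame=frame,
                    intensity=float(inten) if inten is not None else None,
                )
            )
        groups.append((tid, pts))
    return TrajectorySet(_build_trajectories(groups), frame_interval, pixel_size, condition)


def write_tracks(tracks: TrajectorySet, path: str | Path, format: str | None = None) -> Path:
    """Write a TrajectorySet as CSV (package schema) or TrackMate-dialect XML."""
    path = Path(path)
    if format is None:
        format = "xml_trackmate" if path.suffix.lower() == ".xml" else "csv"
    if format == "csv":
        rows = []
        for tr in tracks:
            for p in tr.points:
                rows.append(
                    dict(
                        track_id=tr.track_id,
                        frame=p.frame,
                        t_s=p.t,
                        x_um=p.x,
                        y_um=p.y,
                        intensity="" if p.intensity is None else p.intensity,
                    )
                )
        pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)
        return path
    if format == "xml_trackmate":
        root = ET.Element(
            "Tracks",
            nTracks=str(len(tracks)),
            frameInterval=repr(tracks.frame_interval),
            pixelSize=repr(tracks.pixel_size),
            spaceUnits="micron",
            timeUnits="s",
        )
        for tr in tracks:
            pel = ET.SubElement(root, "particle", id=tr.track_id, nSpots=str(len(tr)))
            for p in tr.points:
                attrs = dict(t=str(p.frame), x=repr(p.x), y=repr(p.y), z="0.0")
                if p.intensity is not None:
                    attrs["intensity"] = repr(p.intensity)
                ET.SubElement(pel, "detection", **attrs)
        ET.indent(root)
        ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")
        return path
    raise ValueError(f"unknown track format {format!r}")


def read_puncta(path: str | Path) -> list[Localization]:
    """Read a puncta table (t_s, x_um, y_um, intensity[, frame]) as Localizations."""
    df = pd.read_csv(path)
    missing = [c for c in ("x_um", "y_um") if c not in df.columns]
    if missing:
        raise TrackParseError(f"{path}: missing column(s) {missing}")
    out = []
    for i, row in df.iterrows():
        out.append(
            Localization(
                t=float(row.get("t_s", 0.0)),
                x=float(row["x_um"]),
                y=float(row["y_um"]),
                frame=int(row.get("frame", 0)),
                intensity=float(row["intensity"]) if "intensity" in df.columns else None,
            )
        )
    return out


def read_image(path: str | Path, pixel_size: float, frame_interval: float = 1.0) -> ImageStack:
    """Read a single- or multi-page TIFF as an ImageStack."""
    data = tifffile.imread(str(path))
    return ImageStack(np.asarray(data), pixel_size=pixel_size, frame_interval=frame_interval)


def write_image(stack: ImageStack, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(str(path), np.asarray(stack.pixels))
    return path


# ---------------------------------------------------------------------------
# compartment assignment


def _points_in_mask(xy_um: np.ndarray, mask: np.ndarray, pixel_size: float) -> np.ndarray:
    """Boolean per-point membership in a binary 2D mask, out-of-range -> False."""
    idx = um_to_pixel(xy_um, pixel_size)
    cols, rows = idx[:, 0], idx[:, 1]
    inside = (rows >= 0) & (rows < mask.shape[0]) & (cols >= 0) & (cols < mask.shape[1])
    out = np.zeros(len(xy_um), dtype=bool)
    out[inside] = mask[rows[inside], cols[inside]] > 0
    return out


def apply_compartment_mask(
    tracks: TrajectorySet,
    cell_mask: ImageStack,
    nuclear_mask: ImageStack | None = None,
    min_cell_fraction: float = 1.0,
) -> TrajectorySet:
    """Label trajectories cytoplasmic / nuclear from binary masks.

    A trajectory is *nuclear* (excluded downstream) if any localization falls
    in the nuclear mask, and *cytoplasmic* if at least ``min_cell_fraction``
    of its localizations fall inside the cell mask (and none in the nucleus).
    Coordinates are never modified.
    """
    if not 0 < min_cell_fraction <= 1:
        raise ValueError("min_cell_fraction must be in (0, 1]")
    cmask = cell_mask.frame(0) > 0
    nmask = None if nuclear_mask is None else nuclear_mask.frame(0) > 0
    if nmask is not None and nmask.shape != cmask.shape:
        raise ValueError("cell and nuclear masks have different shapes")
    px = cell_mask.pixel_size
    extent = np.array(cmask.shape[::-1]) * px  # (x, y) µm
    labelled = []
    for tr in tracks:
        xy = tr.xy
        if xy[:, 0].max() > extent[0] or xy[:, 1].max() > extent[1] or xy.min() < 0:
            raise ValueError(
                f"track {tr.track_id}: coordinates outside mask extent "
                f"{extent[0]:.2f} x {extent[1]:.2f} µm"
            )
        if nmask is not None and _points_in_mask(xy, nmask, px).any():
            comp = "nuclear"
        elif _points_in_mask(xy, cmask, px).mean() >= min_cell_fraction:
            comp = "cytoplasmic"
        else:
            comp = "unassigned"
        labelled.append(replace(tr, compartment=comp))
    n_cyt = sum(t.compartment == "cytoplasmic" for t in labelled)
    n_nuc = sum(t.compartment == "nuclear" for t in labelled)
    logger.info(
        "compartment assignment: %d tracks -> %d cytoplasmic, %d nuclear, %d unassigned",
        len(labelled), n_cyt, n_nuc, len(labelled) - n_cyt - n_nuc,
    )
    return replace(tracks, trajectories=labelled)
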