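"""File formats for still frames, merged data sets and run configuration.

Frame format
------------
One plain-text file per frame: a ``key: value`` header followed by a blank
line and a whitespace-delimited observation table with columns
``h k l I sigI x_mm y_mm``.  Angles in the header are degrees, lengths in
Angstrom, detector quantities in mm.  The format is language-neutral and
diff-able; adapters for integration output of external packages are an
extension point, not a dependency.

Merged data sets are written both as a tab-separated table and as an mmCIF
``_refln`` loop.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
import yaml

from .geometry import CrystalOrientation, UnitCell

__all__ = [
    "ObservationTable",
    "StillFrame",
    "read_still_frames",
    "read_still_frame",
    "write_still_frame",
    "write_merged",
    "read_merged_tsv",
]

log = logging.getLogger("stillpost")

_TABLE_COLUMNS = ["h", "k", "l", "I", "sigI", "x_mm", "y_mm"]


@dataclass
class ObservationTable:
    """Column-oriented observations of one frame.

    ``weight`` is derived as 1/sigma^2; the ``pol_corrected`` flag guards
    against applying the polarization correction twice.
    """

    miller: np.ndarray  # (n, 3) int
    intensity: np.ndarray  # (n,)
    sigma: np.ndarray  # (n,)
    xy_obs: np.ndarray  # (n, 2) mm
    pol_corrected: bool = False

    def __post_init__(self) -> None:
        self.miller = np.atleast_2d(np.asarray(self.miller, dtype=int))
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.xy_obs = np.atleast_2d(np.asarray(self.xy_obs, dtype=float))
        if np.any(self.sigma <= 0):
            raise ValueError("all sigmas must be positive")

    def __len__(self) -> int:
        return len(self.intensity)

    @property
    def weight(self) -> np.ndarray:
        return 1.0 / np.square(self.sigma)


@dataclass
class StillFrame:
    """One still image: metadata plus its observation table."""

    frame_id: str
    wavelength: float
    cell: UnitCell
    space_group: str
    orientation: CrystalOrientation
    distance: float
    beam_center: tuple[float, float]
    pixel_size: float
    obs: ObservationTable
    # cached reduced (asymmetric-unit) indices, filled lazily by merging
    reduced: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if len(self.obs) < 1:
            raise ValueError("a frame needs at least one observation")


def write_still_frame(frame: StillFrame, path) -> None:
    buf = _io.StringIO()
    tx, ty, tz = frame.orientation.as_degrees()
    buf.write("# stillpost still frame\n")
    buf.write(f"frame_id: {frame.frame_id}\n")
    buf.write(f"wavelength: {float(frame.wavelength)!r}\n")
    buf.write(f"space_group: {frame.space_group}\n")
    buf.write("unit_cell: " + " ".join(repr(float(p)) for p in frame.cell.parameters) + "\n")
    buf.write(f"orientation_deg: {float(tx)!r} {float(ty)!r} {float(tz)!r}\n")
    buf.write(f"distance_mm: {float(frame.distance)!r}\n")
    buf.write(f"beam_center_mm: {float(frame.beam_center[0])!r} {float(frame.beam_center[1])!r}\n")
    buf.write(f"pixel_size_mm: {float(frame.pixel_size)!r}\n")
    buf.write(f"polarization_corrected: {int(frame.obs.pol_corrected)}\n")
    buf.write("\n")
    buf.write("\t".join(_TABLE_COLUMNS) + "\n")
    for (h, k, l), i, s, (x, y) in zip(
        frame.obs.miller, frame.obs.intensity, frame.obs.sigma, frame.obs.xy_obs
    ):
        buf.write(f"{h}\t{k}\t{l}\t{float(i)!r}\t{float(s)!r}\t{float(x)!r}\t{float(y)!r}\n")
    Path(path).write_text(buf.getvalue())


def read_still_frame(path) -> StillFrame:
    """Parse one frame file; observations with sigma <= 0 are dropped."""
    text = Path(path).read_text()
    header: dict[str, str] = {}
    lines = text.splitlines()
    i = 0
    for i, line in enumerate(lines):
        line = line.strip()
        if not line:
            break
        if line.startswith("#"):
            continue
        key, _, value = line.partition(":")
        header[key.strip()] = value.strip()
    table = pd.read_csv(
        _io.StringIO("\n".join(lines[i + 1 :])), sep=r"\s+",
        float_precision="round_trip",
    )
    missing = [c for c in _TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    good = table["sigI"] > 0
    n_bad = int((~good).sum())
    if n_bad:
        log.warning("%s: dropped %d observations with sigma <= 0", path, n_bad)
        table = table[good]
    cell = UnitCell.from_parameters(float(v) for v in header["unit_cell"].split())
    tx, ty, tz = (float(v) for v in header["orientation_deg"].split())
    bx, by = (float(v) for v in header["beam_center_mm"].split())
    obs = ObservationTable(
        miller=table[["h", "k", "l"]].to_numpy(dtype=int),
        intensity=table["I"].to_numpy(dtype=float),
        sigma=table["sigI"].to_numpy(dtype=float),
        xy_obs=table[["x_mm", "y_mm"]].to_numpy(dtype=float),
        pol_corrected=bool(int(header.get("polarization_corrected", "0"))),
    )
    return StillFrame(
        frame_id=header.get("frame_id", Path(path).stem),
        wavelength=float(header["wavelength"]),
        cell=cell,
        space_group=header["space_group"],
        orientation=CrystalOrientation.from_degrees(tx, ty, tz),
        distance=float(header["distance_mm"]),
        beam_center=(bx, by),
        pixel_size=float(header.get("pixel_size_mm", "0.1")),
        obs=obs,
    )


def read_still_frames(path) -> list[StillFrame]:
    """Read a frame file or a directory of ``*.still`` / ``*.txt`` files.

    Malformed frames are skipped with a logged diagnostic; mixed space
    groups abort, and an empty collection aborts.
    """
    p = Path(path)
    files = sorted(p.glob("*.still")) + sorted(p.glob("*.txt")) if p.is_dir() else [p]
    frames: list[StillFrame] = []
    for f in files:
        try:
            frames.append(read_still_frame(f))
        except Exception as exc:  # malformed frame: skip, keep going
            log.warning("skipping %s: %s", f, exc)
    if not frames:
        raise ValueError(f"no readable frames under {path}")
    groups = {f.space_group for f in frames}
    if len(groups) > 1:
        raise ValueError(f"mixed space groups in one run: {sorted(groups)}")
    return frames


def write_merged(dataset, path, fmt: str = "tsv") -> None:
    """Write a merged data set as TSV or as an mmCIF reflection loop.

    In anomalous mode the table already carries I+ and I- as separate rows
    (Friedel mates reduced to opposite signs).
    """
    table = dataset.table
    if table is None or len(table) == 0:
        raise ValueError("refusing to write an empty merged data set")
    path = Path(path)
    if fmt == "tsv":
        table.to_csv(path, sep="\t", index=False)
    elif fmt == "mmcif":
        doc = gemmi.cif.Document()
        block = doc.add_new_block("merged")
        block.set_pair("_cell.length_a", f"{dataset.cell.a:.4f}")
        block.set_pair("_cell.length_b", f"{dataset.cell.b:.4f}")
        block.set_pair("_cell.length_c", f"{dataset.cell.c:.4f}")
        block.set_pair("_cell.angle_alpha", f"{dataset.cell.alpha:.4f}")
        block.set_pair("_cell.angle_beta", f"{dataset.cell.beta:.4f}")
        block.set_pair("_cell.angle_gamma", f"{dataset.cell.gamma:.4f}")
        block.set_pair("_symmetry.space_group_name_H-M", gemmi.cif.quote(dataset.space_group))
        loop = block.init_loop(
            "_refln.",
            ["index_h", "index_k", "index_l", "intensity_meas", "intensity_sigma"],
        )
        for row in table.itertuples(index=False):
            loop.add_row(
                [str(int(row.h)), str(int(row.k)), str(int(row.l)), f"{row.I:.6g}", f"{row.sigma:.6g}"]
            )
        doc.write_file(str(path))
    else:
        raise ValueError(f"unknown merged format {fmt!r}")


def read_merged_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_config(path) -> dict:
    """Load a YAML run configuration as a plain dict (lossless round trip)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
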