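"""Domain types and tabular IO for AFM force-distance data.

A force-distance (FD) curve records the force on an AFM cantilever tip as a
function of tip-sample separation.  All quantities are kept in the units the
nanomechanical analysis is reported in: separation in nanometres, force in
piconewtons.  Attractive (adhesive) force is stored as negative; reported
adhesion magnitudes are positive.

Curves travel in groups: an :class:`FDGrid` is a force-volume map, by default
a 20 x 20 raster over a 2 x 2 um^2 patch of a functionalized capture surface.

The on-disk format is a long-form, tab-separated table (one file per grid)
with columns ``curve_id``, ``segment``, ``separation_nm``, ``force_pN``, plus
a JSON sidecar holding grid metadata.  Numeric formatting is fixed so that a
write -> read -> write round trip is byte-identical.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ForceDistanceCurve",
    "FDGrid",
    "FormatError",
    "ValidationError",
    "read_fd_curves",
    "write_fd_curves",
    "curve_id_for",
]

#: minimum number of samples for a usable trace
MIN_SAMPLES = 8

#: fixed decimal formats ensuring bit-stable round trips
_SEP_FMT = "%.9f"
_FORCE_FMT = "%.6f"


class FormatError(ValueError):
    """Raised when a file does not conform to the FD table dialect."""


class ValidationError(ValueError):
    """Raised when data violate FD-curve invariants."""


@dataclass
class ForceDistanceCurve:
    """One approach/retract trace with its grid position.

    Parameters
    ----------
    separation : ndarray
        Tip-sample separation in nm, non-negative, zero at the surface.
    force : ndarray
        Baseline-referenced force in pN; adhesion is negative.
    segment : ndarray of str
        Per-sample label, ``"approach"`` or ``"retract"``.
    grid_index : tuple of int
        (row, col) position in the force-volume raster.
    surface_label : str
        Name of the capture surface the curve was acquired on.
    sample_spacing : float
        Nominal separation step in nm (informational; traces may carry
        extra samples at breakpoints of the underlying geometry).
    """

    separation: np.ndarray
    force: np.ndarray
    segment: np.ndarray
    grid_index: tuple[int, int] = (0, 0)
    surface_label: str = ""
    sample_spacing: float = 0.5

    def __post_init__(self) -> None:
        self.separation = np.asarray(self.separation, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.segment = np.asarray(self.segment, dtype=object)
        self.validate()
        self._canonicalize()

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        n = self.separation.size
        if self.force.size != n or self.segment.size != n:
            raise ValidationError("separation/force/segment lengths differ")
        if n < MIN_SAMPLES:
            raise ValidationError(
                f"curve has {n} samples; at least {MIN_SAMPLES} required"
            )
        if not np.all(np.isfinite(self.separation)) or not np.all(
            np.isfinite(self.force)
        ):
            raise ValidationError("non-finite separation or force value")
        if np.any(self.separation < 0):
            raise ValidationError("negative separation")
        row, col = self.grid_index
        if row < 0 or col < 0:
            raise ValidationError("grid_index components must be non-negative")
        bad = set(np.unique(self.segment)) - {"approach", "retract"}
        if bad:
            raise ValidationError(f"unknown segment labels: {sorted(bad)}")

    def _canonicalize(self) -> None:
        # store each segment with strictly increasing separation
        for seg in ("approach", "retract"):
            mask = self.segment == seg
            if not mask.any():
                continue
            z = self.separation[mask]
            order = np.argsort(z, kind="stable")
            self.separation[mask] = z[order]
            self.force[mask] = self.force[mask][order]
            if np.any(np.diff(self.separation[mask]) <= 0) and z.size > 1:
                raise ValidationError(
                    f"{seg} separations not strictly monotone after sorting"
                )

    # -- accessors ----------------------------------------------------------

    def retract(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (separation, force) of the retract segment."""
        mask = self.segment == "retract"
        return self.separation[mask], self.force[mask]

    def has_retract(self) -> bool:
        return bool((self.segment == "retract").any())

    def with_force(self, force: np.ndarray) -> "ForceDistanceCurve":
        """Copy of this curve with a replaced force array."""
        return replace(self, force=np.asarray(force, dtype=float).copy(),
                       separation=self.separation.copy(),
                       segment=self.segment.copy())

    def with_retract_force(self, retract_force: np.ndarray) -> "ForceDistanceCurve":
        """Copy with the retract-segment force replaced in place."""
        force = self.force.copy()
        force[self.segment == "retract"] = retract_force
        return self.with_force(force)


@dataclass
class FDGrid:
    """A force-volume map: a raster of FD curves over one surface."""

    curves: list[ForceDistanceCurve] = field(default_factory=list)
    n_rows: int = 20
    n_cols: int = 20
    scan_extent_um: float = 2.0
    surface_label: str = ""

    def __post_init__(self) -> None:
        if len(self.curves) > self.n_rows * self.n_cols:
            raise ValidationError("more curves than grid positions")
        seen: set[tuple[int, int]] = set()
        for c in self.curves:
            if c.grid_index in seen:
                raise ValidationError(f"duplicate grid_index {c.grid_index}")
            seen.add(c.grid_index)

    def __len__(self) -> int:
        return len(self.curves)

    def __iter__(self) -> Iterable[ForceDistanceCurve]:
        return iter(self.curves)


_CURVE_ID_RE = re.compile(r"^r(\d+)c(\d+)$")


def curve_id_for(curve: ForceDistanceCurve) -> str:
    """Stable identifier encoding the grid position, e.g. ``r03c17``."""
    row, col = curve.grid_index
    return f"r{row:02d}c{col:02d}"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_fd_curves(grid: FDGrid, path: str | Path) -> None:
    """Write a grid to the long-form TSV dialect plus a JSON sidecar.

    Column order and decimal formatting are fixed, so writing the result of
    :func:`read_fd_curves` reproduces the file byte for byte.
    """
    path = Path(path)
    frames = []
    for curve in grid.curves:
        frames.append(
            pd.DataFrame(
                {
                    "curve_id": curve_id_for(curve),
                    "segment": curve.segment,
                    "separation_nm": curve.separation,
                    "force_pN": curve.force,
                }
            )
        )
    if frames:
        table = pd.concat(frames, ignore_index=True)
    else:
        table = pd.DataFrame(
            columns=["curve_id", "segment", "separation_nm", "force_pN"]
        )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("curve_id\tsegment\tseparation_nm\tforce_pN\n")
        for cid, seg, z, f in table.itertuples(index=False):
            fh.write(f"{cid}\t{seg}\t{_SEP_FMT % z}\t{_FORCE_FMT % f}\n")
    meta = {
        "n_rows": grid.n_rows,
        "n_cols": grid.n_cols,
        "scan_extent_um": grid.scan_extent_um,
        "surface_label": grid.surface_label,
    }
    with open(_sidecar_path(path), "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_fd_curves(path: str | Path, dialect: str = "long-tsv") -> FDGrid:
    """Read an FD grid from the long-form TSV dialect.

    Parameters
    ----------
    path : path
        TSV file written by :func:`write_fd_curves` (a ``<path>.json``
        sidecar with grid metadata is used when present).
    dialect : str
        Only ``"long-tsv"`` is supported.
    """
    if dialect != "long-tsv":
        raise FormatError(f"unknown dialect {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = pd.read_csv(path, sep="\t", dtype={"curve_id": str, "segment": str})
    required = ["curve_id", "segment", "separation_nm", "force_pN"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise FormatError(f"missing columns: {missing}")

    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar, encoding="utf-8") as fh:
            meta = json.load(fh)

    curves = []
    for cid, sub in table.groupby("curve_id", sort=True):
        z = sub["separation_nm"].to_numpy(dtype=float)
        f = sub["force_pN"].to_numpy(dtype=float)
        if not (np.all(np.isfinite(z)) and np.all(np.isfinite(f))):
            raise ValidationError(f"curve {cid!r}: non-finite value in table")
        if z.size < MIN_SAMPLES:
            raise ValidationError(
                f"curve {cid!r}: {z.size} samples, at least {MIN_SAMPLES} required"
            )
        m = _CURVE_ID_RE.match(str(cid))
        grid_index = (int(m.group(1)), int(m.group(2))) if m else (0, 0)
        try:
            curve = ForceDistanceCurve(
                separation=z,
                force=f,
                segment=sub["segment"].to_numpy(dtype=object),
                grid_index=grid_index,
                surface_label=meta.get("surface_label", ""),
            )
        except ValidationError as err:
            raise ValidationError(f"curve {cid!r}: {err}") from err
        curves.append(curve)

    return FDGrid(
        curves=curves,
        n_rows=int(meta.get("n_rows", 20)),
        n_cols=int(meta.get("n_cols", 20)),
        scan_extent_um=float(meta.get("scan_extent_um", 2.0)),
        surface_label=str(meta.get("surface_label", "")),
    )
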