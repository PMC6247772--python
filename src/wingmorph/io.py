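"""Reading, writing and assembling wing morphometric datasets.

Landmark data travel as TPS files (the de-facto interchange format of
landmark morphometrics); outlines travel as long-format CSV.  All
coordinates are stored in pixel units together with a millimetre-per-pixel
scale factor, so size variables can be reported in mm while shape analyses
remain unit-free.

Coordinate convention: coordinates are taken verbatim from the file with y
increasing upward (no image-row flip).  Digitizing programs differ on this;
a dataset digitized with y-down simply appears mirrored, which is harmless
as long as every specimen in a dataset shares the convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("wingmorph")

__all__ = [
    "LandmarkConfiguration",
    "OutlineContour",
    "MorphoDataset",
    "MorphoIOError",
    "read_tps",
    "write_tps",
    "read_contours_csv",
    "write_contours_csv",
    "average_replicates",
    "write_report_tables",
    "signed_area",
]

#: numeric formatting used for every CSV the package writes
SIGNIFICANT_DIGITS = 6


class MorphoIOError(ValueError):
    """Raised for malformed input files or inconsistent datasets."""


def _fmt(x: float) -> str:
    """Format a number at 6 significant digits (stable across runs)."""
    return f"{x:.{SIGNIFICANT_DIGITS}g}"


def signed_area(points: np.ndarray) -> float:
    """Signed area of the closed polygon through *points* (shoelace).

    Positive for counter-clockwise orientation.
    """
    p = np.asarray(points, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class LandmarkConfiguration:
    """One specimen's named landmarks.

    Attributes
    ----------
    specimen_id : str
        Unique (case-sensitive) specimen identifier.
    species : str
        Species label.
    coords : (K, 2) ndarray
        Landmark coordinates in pixel units.  Landmark order is semantic:
        row i is the same anatomical locus on every specimen.
    scale : float
        Millimetres per pixel (> 0).
    scale_defaulted : bool
        True when the source file carried no SCALE and 1.0 was assumed;
        size analyses refuse datasets containing such records.
    """

    specimen_id: str
    species: str
    coords: np.ndarray
    scale: float = 1.0
    scale_defaulted: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise MorphoIOError(
                f"{self.specimen_id}: coords must be K x 2, got {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise MorphoIOError(f"{self.specimen_id}: non-finite coordinate")
        if not self.scale > 0:
            raise MorphoIOError(f"{self.specimen_id}: scale must be > 0")

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]


@dataclass
class OutlineContour:
    """One specimen's ordered outline contour.

    For closed contours the first point is *not* repeated at the end;
    closure is implicit.  Orientation is normalized to counter-clockwise
    (positive signed area) on load.
    """

    specimen_id: str
    species: str
    points: np.ndarray
    closed: bool = True
    scale: float = 1.0
    scale_defaulted: bool = False

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise MorphoIOError(
                f"{self.specimen_id}: points must be M x 2, got {self.points.shape}"
            )
        if self.points.shape[0] < 3:
            raise MorphoIOError(
                f"{self.specimen_id}: a contour needs at least 3 points"
            )
        if not np.all(np.isfinite(self.points)):
            raise MorphoIOError(f"{self.specimen_id}: non-finite coordinate")
        if not self.scale > 0:
            raise MorphoIOError(f"{self.specimen_id}: scale must be > 0")
        diffs = np.diff(self.points, axis=0)
        if np.any(np.all(diffs == 0, axis=1)):
            raise MorphoIOError(
                f"{self.specimen_id}: consecutive contour points must be distinct"
            )
        if self.closed and np.all(self.points[0] == self.points[-1]):
            raise MorphoIOError(
                f"{self.specimen_id}: closed contour must not repeat the first point"
            )

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass
class MorphoDataset:
    """A labeled collection of landmark configurations or contours."""

    records: list = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.specimen_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise MorphoIOError(f"duplicate specimen ids: {dupes}")

    @property
    def species_table(self) -> dict[str, int]:
        table: dict[str, int] = {}
        for r in self.records:
            table[r.species] = table.get(r.species, 0) + 1
        return table

    @property
    def species(self) -> list[str]:
        return sorted(self.species_table)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, species: list[str]) -> "MorphoDataset":
        keep = set(species)
        return MorphoDataset([r for r in self.records if r.species in keep])


# ---------------------------------------------------------------------------
# TPS landmark files
# ---------------------------------------------------------------------------

def read_tps(path) -> list[LandmarkConfiguration]:
    """Read a TPS landmark file.

    Recognized keys: ``LM=`` (starts a record), ``ID=``, ``SCALE=``; the
    ``IMAGE=`` and ``COMMENT=`` keys are accepted and ignored.  A record
    missing ``SCALE=`` gets scale 1.0 with a logged warning.  Species are
    encoded in the ID as ``species:specimen`` when present, otherwise the
    species label is empty and must be attached downstream.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    configs: list[LandmarkConfiguration] = []
    i = 0
    record_no = 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        if not line.upper().startswith("LM="):
            raise MorphoIOError(
                f"{path}: expected LM= at line {i}, found {line!r}"
            )
        record_no += 1
        try:
            k = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise MorphoIOError(
                f"{path}: bad LM count in record {record_no} (line {i})"
            ) from exc
        coords = np.empty((k, 2))
        for j in range(k):
            if i >= len(lines):
                raise MorphoIOError(
                    f"{path}: record {record_no} declares LM={k} but the "
                    f"file ends after {j} coordinate lines"
                )
            raw = lines[i].strip()
            if "=" in raw:
                raise MorphoIOError(
                    f"{path}: record {record_no} declares LM={k} but only "
                    f"{j} coordinate lines precede {raw.split('=')[0]}= (line {i + 1})"
                )
            parts = raw.split()
            if len(parts) != 2:
                raise MorphoIOError(
                    f"{path}: line {i + 1}: expected two coordinates, got {raw!r}"
                )
            try:
                coords[j] = [float(parts[0]), float(parts[1])]
            except ValueError as exc:
                raise MorphoIOError(
                    f"{path}: non-numeric coordinate at line {i + 1}: {raw!r}"
                ) from exc
            i += 1
        spec_id = f"record_{record_no}"
        scale = None
        while i < len(lines):
            keyline = lines[i].strip()
            if not keyline:
                i += 1
                continue
            if keyline.upper().startswith("LM="):
                break
            if "=" not in keyline:
                raise MorphoIOError(
                    f"{path}: unexpected line {i + 1} in record {record_no}: {keyline!r}"
                )
            key, value = keyline.split("=", 1)
            key = key.strip().upper()
            if key == "ID":
                spec_id = value.strip()
            elif key == "SCALE":
                try:
                    scale = float(value)
                except ValueError as exc:
                    raise MorphoIOError(
                        f"{path}: non-numeric SCALE at line {i + 1}"
                    ) from exc
            elif key in ("IMAGE", "COMMENT"):
                pass
            else:
                logger.warning("%s: ignoring unknown TPS key %s=", path, key)
            i += 1
        defaulted = scale is None
        if defaulted:
            logger.warning(
                "%s: record %s has no SCALE=, assuming 1.0 (size analyses "
                "will refuse this dataset)", path, spec_id,
            )
            scale = 1.0
        species, _, _ = spec_id.partition(":")
        species = species if ":" in spec_id else ""
        configs.append(
            LandmarkConfiguration(
                specimen_id=spec_id,
                species=species,
                coords=coords,
                scale=scale,
                scale_defaulted=defaulted,
            )
        )
    return configs


def write_tps(configs, path) -> None:
    """Write landmark configurations as a TPS file (plumbing helper)."""
    path = Path(path)
    out = []
    for c in configs:
        out.append(f"LM={c.n_landmarks}")
        for x, y in c.coords:
            out.append(f"{float(x)!r} {float(y)!r}")
        spec_id = c.specimen_id
        if c.species and not spec_id.startswith(f"{c.species}:"):
            spec_id = f"{c.species}:{spec_id}"
        out.append(f"ID={spec_id}")
        if not c.scale_defaulted:
            out.append(f"SCALE={float(c.scale)!r}")
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Contour CSV files
# ---------------------------------------------------------------------------

def read_contours_csv(path) -> list[OutlineContour]:
    """Read outline contours from long-format CSV.

    Required columns: ``specimen_id``, ``species``, ``point_index``, ``x``,
    ``y``; optional ``scale``.  Points are sorted by ``point_index`` within
    each specimen and clockwise contours are reversed to counter-clockwise
    (signed polygon area made positive).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"specimen_id", "species", "point_index", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise MorphoIOError(f"{path}: missing columns {sorted(missing)}")
    has_scale = "scale" in df.columns
    contours: list[OutlineContour] = []
    for spec_id, grp in df.groupby("specimen_id", sort=False):
        if grp["point_index"].duplicated().any():
            raise MorphoIOError(
                f"{path}: duplicate point_index for specimen {spec_id!r}"
            )
        grp = grp.sort_values("point_index")
        if len(grp) < 3:
            raise MorphoIOError(
                f"{path}: specimen {spec_id!r} has fewer than 3 points"
            )
        species = grp["species"].iloc[0]
        if grp["species"].nunique() > 1:
            raise MorphoIOError(
                f"{path}: specimen {spec_id!r} carries conflicting species labels"
            )
        pts = grp[["x", "y"]].to_numpy(dtype=float)
        defaulted = True
        scale = 1.0
        if has_scale and not grp["scale"].isna().all():
            scale = float(grp["scale"].iloc[0])
            defaulted = False
        else:
            logger.warning(
                "%s: specimen %s has no scale, assuming 1.0", path, spec_id
            )
        if signed_area(pts) < 0:
            pts = pts[::-1].copy()
        contours.append(
            OutlineContour(
                specimen_id=str(spec_id),
                species=str(species),
                points=pts,
                closed=True,
                scale=scale,
                scale_defaulted=defaulted,
            )
        )
    return contours


def write_contours_csv(contours, path) -> None:
    """Write contours in the long CSV format read_contours_csv expects."""
    rows = []
    for c in contours:
        for j, (x, y) in enumerate(c.points):
            rows.append(
                {
                    "specimen_id": c.specimen_id,
                    "species": c.species,
                    "point_index": j,
                    "x": repr(float(x)),
                    "y": repr(float(y)),
                    "scale": repr(float(c.scale)),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Replicate digitizations
# ---------------------------------------------------------------------------

def average_replicates(first: MorphoDataset, second: MorphoDataset) -> MorphoDataset:
    """Average two replicate digitizations coordinate-wise.

    Digitization error is reduced by averaging the two digitizations of
    each specimen before analysis.  Both datasets must contain the same
    specimen ids with matching species labels and point counts.
    """
    a = {r.specimen_id: r for r in first.records}
    b = {r.specimen_id: r for r in second.records}
    only_a = sorted(set(a) - set(b))
    only_b = sorted(set(b) - set(a))
    if only_a or only_b:
        raise MorphoIOError(
            "specimen sets differ between replicates: "
            f"only in first={only_a}, only in second={only_b}"
        )
    merged = []
    for spec_id in a:
        ra, rb = a[spec_id], b[spec_id]
        if ra.species != rb.species:
            raise MorphoIOError(
                f"species label conflict for {spec_id!r}: "
                f"{ra.species!r} vs {rb.species!r}"
            )
        pa = ra.coords if isinstance(ra, LandmarkConfiguration) else ra.points
        pb = rb.coords if isinstance(rb, LandmarkConfiguration) else rb.points
        if pa.shape != pb.shape:
            raise MorphoIOError(
                f"point-count mismatch for {spec_id!r}: {pa.shape} vs {pb.shape}"
            )
        if ra.scale != rb.scale:
            raise MorphoIOError(f"scale mismatch for {spec_id!r}")
        mean_pts = 0.5 * (pa + pb)
        if isinstance(ra, LandmarkConfiguration):
            merged.append(
                LandmarkConfiguration(
                    spec_id, ra.species, mean_pts, ra.scale,
                    ra.scale_defaulted or rb.scale_defaulted,
                )
            )
        else:
            merged.append(
                OutlineContour(
                    spec_id, ra.species, mean_pts, ra.closed, ra.scale,
                    ra.scale_defaulted or rb.scale_defaulted,
                )
            )
    return MorphoDataset(merged)


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

def write_report_tables(results: dict, out_dir) -> list:
    """Write the pipeline's summary tables as CSV files.

    Expects a mapping with (any subset of) keys ``size_summary`` (DataFrame
    with per-species statistics and significance letters), ``mahalanobis``
    (square DataFrame) with optional ``mahalanobis_flags`` (same shape,
    significance markers), and ``reclassification`` (per-species DataFrame).
    Returns the list of written paths.
    """
    if not results:
        raise MorphoIOError("empty results: nothing to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    def _write(df: pd.DataFrame, name: str, index: bool) -> None:
        p = out_dir / name
        df.to_csv(p, index=index, float_format=f"%.{SIGNIFICANT_DIGITS}g")
        written.append(p)

    if "size_summary" in results:
        _write(results["size_summary"], "size_summary.csv", index=True)
    if "mahalanobis" in results:
        d = results["mahalanobis"]
        if d.shape[0] != d.shape[1]:
            raise MorphoIOError("mahalanobis table must be square")
        out = d.copy().astype(object)
        flags = results.get("mahalanobis_flags")
        for i in range(d.shape[0]):
            for j in range(d.shape[1]):
                s = _fmt(float(d.iloc[i, j]))
                if flags is not None and bool(flags.iloc[i, j]):
                    s += "*"
                out.iloc[i, j] = s
        _write(out, "mahalanobis.csv", index=True)
    if "reclassification" in results:
        _write(results["reclassification"], "reclassification.csv", index=True)
    if not written:
        raise MorphoIOError(
            f"no recognized result tables among keys {sorted(results)}"
        )
    return written
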