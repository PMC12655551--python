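"""Tabular and coordinate-file input/output.

Screening tables are comma-separated UTF-8 with a mandatory header; score
orientation is never inferred from the data — callers state it explicitly
because docking engines disagree (Glide energies are lower-is-better, GOLD
ChemPLP fitness higher-is-better).

Pose files are multi-record XYZ (comment line carries the compound id) or
SDF (V2000, title line carries the id). Atom order is preserved exactly as
written; it defines the correspondence used for pose-agreement RMSD.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import DataError, FormatError

LOWER = "lower_is_better"
HIGHER = "higher_is_better"

VALID_LABELS = {"active", "decoy", "unknown"}

# Element symbols accepted without a warning (H–Rn, common organics first).
_KNOWN_ELEMENTS = {
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne", "Na", "Mg", "Al",
    "Si", "P", "S", "Cl", "Ar", "K", "Ca", "Sc", "Ti", "V", "Cr", "Mn", "Fe",
    "Co", "Ni", "Cu", "Zn", "Ga", "Ge", "As", "Se", "Br", "Kr", "Rb", "Sr",
    "Y", "Zr", "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn",
    "Sb", "Te", "I", "Xe",
}


@dataclass(frozen=True)
class ScreeningRecord:
    """One row of a ranked screening table."""

    compound_id: str
    score: float
    label: str = "unknown"

    def __post_init__(self):
        if not self.compound_id:
            raise DataError("compound_id must be non-empty")
        if not np.isfinite(self.score):
            raise DataError(f"non-finite score for {self.compound_id!r}")
        if self.label not in VALID_LABELS:
            raise DataError(
                f"label {self.label!r} for {self.compound_id!r} not one of "
                f"{sorted(VALID_LABELS)}"
            )


@dataclass(frozen=True)
class PoseRecord:
    """One docked pose: element symbols plus Cartesian coordinates in Å."""

    compound_id: str
    elements: tuple[str, ...]
    coords: np.ndarray  # (n_atoms, 3) float

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "elements", tuple(self.elements))
        if len(self.elements) == 0:
            raise FormatError(f"pose {self.compound_id!r} has no atoms")
        if coords.shape != (len(self.elements), 3):
            raise FormatError(
                f"pose {self.compound_id!r}: {len(self.elements)} elements "
                f"but coordinate array of shape {coords.shape}"
            )
        if not np.all(np.isfinite(coords)):
            raise FormatError(f"pose {self.compound_id!r} has non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def heavy(self) -> "PoseRecord":
        """Return a copy with hydrogen atoms removed."""
        keep = [i for i, e in enumerate(self.elements) if e != "H"]
        if not keep:
            raise FormatError(f"pose {self.compound_id!r} has no heavy atoms")
        return PoseRecord(
            self.compound_id,
            tuple(self.elements[i] for i in keep),
            self.coords[keep],
        )

    def translated(self, vector) -> "PoseRecord":
        return PoseRecord(self.compound_id, self.elements,
                          self.coords + np.asarray(vector, float))


@dataclass
class RunConfig:
    """Validated campaign configuration."""

    score_direction: str = LOWER
    fractions: Sequence[float] = (0.01, 0.02, 0.05, 0.10)
    rmsd_threshold: float = 3.0
    hit_ic50_threshold: float = 100.0
    seed: int = 0
    stages: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.score_direction not in (LOWER, HIGHER):
            raise DataError(f"unknown score_direction {self.score_direction!r}")
        fr = list(self.fractions)
        if any(not (0 < f <= 1) for f in fr):
            raise DataError("fractions must lie in (0, 1]")
        if fr != sorted(fr):
            raise DataError("fractions must be sorted ascending")
        if self.rmsd_threshold <= 0 or self.hit_ic50_threshold <= 0:
            raise DataError("thresholds must be positive")


def read_score_table(path, direction: str = LOWER) -> list[ScreeningRecord]:
    """Read a ranked-screening CSV with columns id, score, label.

    Labels are normalised case-insensitively; duplicate ids are rejected.
    ``direction`` is carried by the caller (see :mod:`screenval.enrichment`);
    it is accepted here so CLI plumbing can validate it early.
    """
    if direction not in (LOWER, HIGHER):
        raise DataError(f"unknown score direction {direction!r}")
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = [h.strip().lower() for h in (reader.fieldnames or [])]
        for col in ("id", "score", "label"):
            if col not in header:
                raise FormatError(f"{path.name}: missing required column {col!r}")
        lookup = {h.strip().lower(): h for h in reader.fieldnames}
        records: list[ScreeningRecord] = []
        seen: set[str] = set()
        for lineno, row in enumerate(reader, start=2):
            cid = (row[lookup["id"]] or "").strip()
            raw_score = (row[lookup["score"]] or "").strip()
            try:
                score = float(raw_score)
            except ValueError:
                raise FormatError(
                    f"{path.name} line {lineno}: non-numeric score {raw_score!r}"
                ) from None
            label = (row[lookup["label"]] or "unknown").strip().lower() or "unknown"
            if label not in VALID_LABELS:
                raise FormatError(
                    f"{path.name} line {lineno}: unknown label {label!r}"
                )
            if cid in seen:
                raise DataError(f"{path.name}: duplicate compound id {cid!r}")
            seen.add(cid)
            records.append(ScreeningRecord(cid, score, label))
    return records


def _read_xyz(path: Path) -> list[PoseRecord]:
    poses = []
    lines = path.read_text(encoding="utf-8").splitlines()
    i = 0
    block = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        block += 1
        try:
            count = int(lines[i].strip())
        except ValueError:
            raise FormatError(
                f"{path.name} block {block}: expected atom count, got "
                f"{lines[i].strip()!r}"
            ) from None
        if count < 1:
            raise FormatError(f"{path.name} block {block}: zero-atom block")
        if i + 1 >= len(lines):
            raise FormatError(f"{path.name} block {block}: truncated header")
        comment = lines[i + 1].strip()
        cid = comment.split()[0] if comment else f"block{block}"
        atom_lines = lines[i + 2 : i + 2 + count]
        if len(atom_lines) < count:
            raise FormatError(
                f"{path.name} block {block} ({cid}): declared {count} atoms, "
                f"file ends after {len(atom_lines)}"
            )
        elements, coords = [], []
        for ln in atom_lines:
            parts = ln.split()
            if len(parts) < 4:
                raise FormatError(
                    f"{path.name} block {block} ({cid}): malformed atom line {ln!r}"
                )
            sym = parts[0]
            if sym not in _KNOWN_ELEMENTS:
                warnings.warn(
                    f"{path.name} ({cid}): unknown element symbol {sym!r}; atom kept",
                    stacklevel=3,
                )
            elements.append(sym)
            try:
                coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
            except ValueError:
                raise FormatError(
                    f"{path.name} block {block} ({cid}): non-numeric coordinate "
                    f"in {ln!r}"
                ) from None
        poses.append(PoseRecord(cid, tuple(elements), np.array(coords)))
        i += 2 + count
    return poses


def _read_sdf(path: Path) -> list[PoseRecord]:
    # Minimal V2000 reader: title line + counts line + atom block. Bond and
    # property blocks are skipped — only coordinates matter downstream.
    poses = []
    text = path.read_text(encoding="utf-8")
    for block_no, block in enumerate(text.split("$$$$"), start=1):
        lines = block.strip("\n").splitlines()
        if not any(ln.strip() for ln in lines):
            continue
        while lines and not lines[0].strip():
            lines.pop(0)
        if len(lines) < 4:
            raise FormatError(f"{path.name} record {block_no}: truncated molblock")
        cid = lines[0].strip() or f"mol{block_no}"
        counts = lines[3]
        try:
            n_atoms = int(counts[0:3])
        except ValueError:
            raise FormatError(
                f"{path.name} record {block_no} ({cid}): bad counts line "
                f"{counts!r}"
            ) from None
        if n_atoms < 1:
            raise FormatError(f"{path.name} record {block_no} ({cid}): zero atoms")
        atom_lines = lines[4 : 4 + n_atoms]
        if len(atom_lines) < n_atoms:
            raise FormatError(
                f"{path.name} record {block_no} ({cid}): declared {n_atoms} "
                f"atoms, block holds {len(atom_lines)}"
            )
        elements, coords = [], []
        for ln in atom_lines:
            parts = ln.split()
            if len(parts) < 4:
                raise FormatError(
                    f"{path.name} record {block_no} ({cid}): malformed atom "
                    f"line {ln!r}"
                )
            x, y, z, sym = parts[0], parts[1], parts[2], parts[3]
            if sym not in _KNOWN_ELEMENTS:
                warnings.warn(
                    f"{path.name} ({cid}): unknown element symbol {sym!r}; "
                    "atom kept",
                    stacklevel=3,
                )
            elements.append(sym)
            coords.append([float(x), float(y), float(z)])
        poses.append(PoseRecord(cid, tuple(elements), np.array(coords)))
    return poses


def read_poses(path) -> list[PoseRecord]:
    """Read a multi-record XYZ or SDF pose file (dialect by extension)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".xyz":
        return _read_xyz(path)
    if suffix in (".sdf", ".sd", ".mol"):
        return _read_sdf(path)
    raise FormatError(f"unrecognised pose-file extension {suffix!r}")


def write_poses_xyz(poses: Iterable[PoseRecord], path) -> None:
    """Write poses as a multi-record XYZ file (comment line = compound id)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for pose in poses:
            fh.write(f"{pose.n_atoms}\n{pose.compound_id}\n")
            for sym, (x, y, z) in zip(pose.elements, pose.coords):
                fh.write(f"{sym} {x:.6f} {y:.6f} {z:.6f}\n")


def to_frame(results) -> pd.DataFrame:
    """Coerce a stage result (DataFrame, list of dataclasses/dicts) to a frame."""
    if isinstance(results, pd.DataFrame):
        return results
    rows = []
    for item in results:
        if isinstance(item, dict):
            rows.append(item)
        elif hasattr(item, "__dataclass_fields__"):
            rows.append({k: getattr(item, k) for k in item.__dataclass_fields__})
        else:
            raise DataError(f"cannot serialise result item of type {type(item)}")
    return pd.DataFrame(rows)


def write_report(results, path) -> None:
    """Write any stage output as CSV with deterministic column order and
    floats at 6 significant digits."""
    frame = to_frame(results)
    frame.to_csv(path, index=False, float_format="%.6g")


def write_screening_csv(records: Iterable[ScreeningRecord], path) -> None:
    frame = pd.DataFrame(
        [{"id": r.compound_id, "score": r.score, "label": r.label}
         for r in records]
    )
    frame.to_csv(path, index=False, float_format="%.6g")
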