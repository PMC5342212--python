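"""Reading and writing TPS landmark files and specimen metadata tables.

The TPS dialect accepted here is the one produced by the classic tps-series
digitizing tools: records introduced by ``LM=k`` followed by k whitespace-
separated ``x y`` coordinate lines, with optional ``IMAGE=``, ``ID=`` and
``SCALE=`` lines (keys case-insensitive).  Wing side is encoded as an
``_R``/``_L`` suffix on the record ID.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "LandmarkConfiguration",
    "SpecimenRecord",
    "TPSParseError",
    "read_tps",
    "write_tps",
    "select_wing_per_specimen",
    "read_specimen_table",
    "match_specimens",
]

_SIDE_SUFFIX = re.compile(r"^(?P<stem>.*)_(?P<side>[RL])$", re.IGNORECASE)


class TPSParseError(ValueError):
    """Raised when a TPS file cannot be parsed."""


@dataclass(frozen=True)
class LandmarkConfiguration:
    """One wing's labeled 2-D landmark set.

    ``coords`` are in image units with any ``SCALE=`` factor already applied.
    """

    specimen_id: str
    side: str  # "right" | "left"
    coords: np.ndarray  # (k, 2)
    scale: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "coords", np.asarray(self.coords, dtype=float).reshape(-1, 2)
        )
        if self.side not in ("right", "left"):
            raise ValueError(f"side must be 'right' or 'left', got {self.side!r}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(
                f"non-finite coordinates for specimen {self.specimen_id!r}"
            )

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    def reflected(self) -> "LandmarkConfiguration":
        """Mirror about the vertical axis (x -> -x), preserving side label."""
        c = self.coords.copy()
        c[:, 0] = -c[:, 0]
        return replace(self, coords=c)


@dataclass(frozen=True)
class SpecimenRecord:
    specimen_id: str
    species: str
    population_id: str
    longitude: float
    latitude: float
    elevation: float
    temperature: float
    precipitation: float

    def __post_init__(self) -> None:
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(
                f"longitude {self.longitude} out of range for {self.specimen_id!r}"
            )
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(
                f"latitude {self.latitude} out of range for {self.specimen_id!r}"
            )
        if not self.population_id:
            raise ValueError(f"empty population_id for {self.specimen_id!r}")


def _parse_side(record_id: str) -> tuple[str, str]:
    """Split a TPS ID into (specimen_id, side) using the _R/_L convention."""
    m = _SIDE_SUFFIX.match(record_id)
    if m:
        side = "right" if m.group("side").upper() == "R" else "left"
        return m.group("stem"), side
    return record_id, "right"


def read_tps(path) -> list[LandmarkConfiguration]:
    """Parse a TPS file into landmark configurations, in file order.

    Raises
    ------
    TPSParseError
        On short records, non-numeric coordinates, or mixed landmark counts.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    configs: list[LandmarkConfiguration] = []
    i = 0
    record_index = 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        m = re.match(r"LM\s*=\s*(\d+)\s*$", line, re.IGNORECASE)
        if not m:
            raise TPSParseError(f"{path}: expected LM= line, got {line!r}")
        k = int(m.group(1))
        record_index += 1
        coords = []
        while len(coords) < k and i < len(lines):
            row = lines[i].strip()
            i += 1
            if not row:
                continue
            parts = row.split()
            if len(parts) != 2:
                raise TPSParseError(
                    f"{path}: record {record_index}: expected 'x y', got {row!r}"
                )
            try:
                coords.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise TPSParseError(
                    f"{path}: record {record_index}: non-numeric coordinate {row!r}"
                ) from exc
        if len(coords) < k:
            raise TPSParseError(
                f"{path}: record {record_index}: expected {k} coordinate lines, "
                f"got {len(coords)}"
            )
        record_id = f"record{record_index}"
        scale: float | None = None
        while i < len(lines):
            row = lines[i].strip()
            if not row:
                i += 1
                continue
            kv = re.match(r"(LM|IMAGE|ID|SCALE)\s*=\s*(.*)$", row, re.IGNORECASE)
            if kv is None:
                raise TPSParseError(
                    f"{path}: record {record_index}: unexpected line {row!r}"
                )
            key = kv.group(1).upper()
            if key == "LM":
                break  # next record
            i += 1
            if key == "ID":
                record_id = kv.group(2).strip()
            elif key == "SCALE":
                try:
                    scale = float(kv.group(2))
                except ValueError as exc:
                    raise TPSParseError(
                        f"{path}: record {record_index}: bad SCALE {kv.group(2)!r}"
                    ) from exc
        arr = np.asarray(coords, dtype=float)
        if scale is not None:
            arr = arr * scale
        specimen_id, side = _parse_side(record_id)
        configs.append(
            LandmarkConfiguration(
                specimen_id=specimen_id, side=side, coords=arr, scale=scale
            )
        )
    _check_homogeneous_k(configs, str(path))
    seen = set()
    for c in configs:
        key = (c.specimen_id, c.side)
        if key in seen:
            raise TPSParseError(
                f"{path}: duplicate specimen/side {c.specimen_id!r}/{c.side}"
            )
        seen.add(key)
    return configs


def _check_homogeneous_k(configs: Sequence[LandmarkConfiguration], where: str) -> None:
    ks = {c.k for c in configs}
    if len(ks) > 1:
        raise TPSParseError(
            f"{where}: mixed landmark counts across records: {sorted(ks)}"
        )


def write_tps(configs: Sequence[LandmarkConfiguration], path) -> None:
    """Write configurations as a TPS file (ID carries the _R/_L side suffix).

    Coordinates are written at full float precision (repr), so a read/write
    round trip is lossless.
    """
    configs = list(configs)
    if not configs:
        raise ValueError("cannot write an empty TPS file")
    _check_homogeneous_k(configs, str(path))
    out = []
    for c in configs:
        out.append(f"LM={c.k}")
        for x, y in c.coords:
            out.append(f"{float(x)!r} {float(y)!r}")
        suffix = "R" if c.side == "right" else "L"
        out.append(f"ID={c.specimen_id}_{suffix}")
    Path(path).write_text("\n".join(out) + "\n")


def select_wing_per_specimen(
    configs: Sequence[LandmarkConfiguration],
) -> list[LandmarkConfiguration]:
    """Keep one wing per specimen: right if present, else left mirrored.

    Left wings are reflected about the vertical axis so that all retained
    configurations share chirality and are homologous under proper rotation;
    after reflection their side flag becomes "right" (the flag encodes
    chirality, making normalization idempotent).  Specimens contributing no
    wing at all never appear in the input, so the output has exactly one
    entry per distinct specimen_id, in first-seen order.
    """
    by_specimen: dict[str, dict[str, LandmarkConfiguration]] = {}
    order: list[str] = []
    for c in configs:
        sides = by_specimen.setdefault(c.specimen_id, {})
        if c.side in sides:
            raise ValueError(
                f"specimen {c.specimen_id!r} has two {c.side} wing configurations"
            )
        if c.specimen_id not in order:
            order.append(c.specimen_id)
        sides[c.side] = c
    selected = []
    for sid in order:
        sides = by_specimen[sid]
        if "right" in sides:
            selected.append(sides["right"])
        else:
            logger.info("specimen %s: using reflected left wing", sid)
            selected.append(replace(sides["left"].reflected(), side="right"))
    return selected


_REQUIRED_COLUMNS = [
    "specimen_id",
    "species",
    "population_id",
    "longitude",
    "latitude",
    "elevation",
    "temperature",
    "precipitation",
]


def read_specimen_table(path) -> list[SpecimenRecord]:
    """Read the specimen metadata CSV (UTF-8, header required)."""
    records: list[SpecimenRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file")
        missing = [c for c in _REQUIRED_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        seen: set[str] = set()
        for row in reader:
            sid = row["specimen_id"].strip()
            if sid in seen:
                raise ValueError(f"{path}: duplicate specimen_id {sid!r}")
            seen.add(sid)
            records.append(
                SpecimenRecord(
                    specimen_id=sid,
                    species=row["species"].strip(),
                    population_id=row["population_id"].strip(),
                    longitude=float(row["longitude"]),
                    latitude=float(row["latitude"]),
                    elevation=float(row["elevation"]),
                    temperature=float(row["temperature"]),
                    precipitation=float(row["precipitation"]),
                )
            )
    return records


def match_specimens(
    records: Sequence[SpecimenRecord], configs: Sequence[LandmarkConfiguration]
) -> tuple[list[str], list[str], list[str]]:
    """Join-key check between the metadata table and landmark data.

    Returns (matched, table_only, landmarks_only) specimen-id lists.
    """
    table_ids = {r.specimen_id for r in records}
    lm_ids = {c.specimen_id for c in configs}
    matched = sorted(table_ids & lm_ids)
    table_only = sorted(table_ids - lm_ids)
    lm_only = sorted(lm_ids - table_ids)
    if table_only:
        logger.warning("%d specimens in table without landmarks", len(table_only))
    if lm_only:
        logger.warning("%d landmark specimens missing from table", len(lm_only))
    return matched, table_only, lm_only
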