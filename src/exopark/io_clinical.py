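"""Clinical cohort ingestion, UPDRS subscores, and the responder (MCD) filter.

The clinical side of the pipeline works from a flat CSV table, one row per
subject, whose column encodings are fixed by a versioned JSON schema shipped
with the package (``exopark/data/clinical_schema.json``).  The packaged
cohort fixture (``exopark/data/clinical_cohort.csv``) holds the 26-subject
parkinsonian cohort used throughout the examples: per-subject age, sex,
disease duration, levodopa dose, UPDRS Part III motor scores OFF and ON
dopamine replacement therapy (DRT), and MoCA.

UPDRS Part III item-level scores, when available, are stored per body side
for the bilateral items so that bradykinesia (items 23-26), rigidity
(item 22) and postural-stability (item 30) subscores and their right-minus-
left asymmetries can be computed.  Missing items raise: subscores are never
silently zero-filled.

The minimal-clinical-difference (MCD) responder criterion is a *strictly*
greater-than-6-point reduction in total UPDRS Part III after DRT.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "SubjectRecord",
    "UpdrsSubscores",
    "ClinicalSchemaError",
    "ClinicalParseError",
    "MissingItemError",
    "load_schema",
    "packaged_cohort_path",
    "read_cohort_table",
    "updrs_subscores",
    "mcd_filter",
    "MCD_THRESHOLD",
]

#: Strict responder threshold: OFF - ON must exceed this many UPDRS-III points.
MCD_THRESHOLD = 6

# Item-level key conventions.  Bilateral items carry a side suffix; item 22
# (rigidity) additionally scores the neck.  Every entry is a 0-4 integer.
RIGIDITY_KEYS = ("22_neck", "22_rue", "22_rle", "22_lue", "22_lle")
BRADY_RIGHT_KEYS = ("23_r", "24_r", "25_r", "26_r")
BRADY_LEFT_KEYS = ("23_l", "24_l", "25_l", "26_l")
BRADY_UE_RIGHT_KEYS = ("23_r", "24_r", "25_r")
BRADY_UE_LEFT_KEYS = ("23_l", "24_l", "25_l")
POSTURE_KEY = "30"


class ClinicalSchemaError(ValueError):
    """The table header or a value violates the clinical schema."""


class ClinicalParseError(ValueError):
    """A cell could not be parsed; carries row index and column name."""

    def __init__(self, row: int, column: str, message: str):
        self.row = row
        self.column = column
        super().__init__(f"row {row}, column '{column}': {message}")


class MissingItemError(KeyError):
    """A required UPDRS item is absent from an item map."""


@dataclass(frozen=True)
class SubjectRecord:
    """One participant: clinical metadata plus UPDRS/MoCA scores."""

    subject_id: str
    group: str  # "PD" | "control"
    age: float
    sex: str  # "M" | "F"
    handedness: str  # "right" | "left"
    disease_duration: float | None = None
    levodopa_dose: float | None = None
    updrs3_off: int | None = None
    updrs3_on: int | None = None
    moca: int | None = None
    updrs_items_off: Mapping[str, int] | None = None
    updrs_items_on: Mapping[str, int] | None = None
    other_medications: str | None = None
    other_dose_mg: str | None = None

    def __post_init__(self):
        if self.group not in ("PD", "control"):
            raise ClinicalSchemaError(
                f"{self.subject_id}: group must be 'PD' or 'control', got {self.group!r}"
            )
        if not self.age > 0:
            raise ClinicalSchemaError(f"{self.subject_id}: age must be > 0")
        if self.sex not in ("M", "F"):
            raise ClinicalSchemaError(f"{self.subject_id}: sex must be 'M' or 'F'")
        if self.handedness not in ("right", "left"):
            raise ClinicalSchemaError(f"{self.subject_id}: bad handedness {self.handedness!r}")
        if self.disease_duration is not None and self.disease_duration < 0:
            raise ClinicalSchemaError(f"{self.subject_id}: disease_duration < 0")
        for name in ("updrs3_off", "updrs3_on"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ClinicalSchemaError(f"{self.subject_id}: {name} must be >= 0")
        if self.moca is not None and not (0 <= self.moca <= 30):
            raise ClinicalSchemaError(f"{self.subject_id}: moca must be in [0, 30]")
        for items, total in (
            (self.updrs_items_off, self.updrs3_off),
            (self.updrs_items_on, self.updrs3_on),
        ):
            if items is not None and total is not None and sum(items.values()) > total:
                raise ClinicalSchemaError(
                    f"{self.subject_id}: item map sums above the Part III total"
                )

    @property
    def updrs_delta(self) -> int | None:
        """OFF minus ON total; positive means improvement on DRT."""
        if self.updrs3_off is None or self.updrs3_on is None:
            return None
        return self.updrs3_off - self.updrs3_on


@dataclass(frozen=True)
class UpdrsSubscores:
    """Derived UPDRS-III subscores and right-minus-left asymmetries."""

    bradykinesia: int  # items 23-26, both sides; max 32
    bradykinesia_ue_right: int  # items 23-25 right; max 12
    bradykinesia_ue_left: int
    rigidity: int  # item 22, all five entries; max 20
    rigidity_ue_right: int  # item 22 right arm; max 4
    rigidity_ue_left: int
    posture: int  # item 30; max 4
    asymmetry_bradykinesia: int  # right minus left, items 23-26
    asymmetry_rigidity: int  # right minus left, item 22 (arm + leg)

    _MAXIMA = {
        "bradykinesia": 32,
        "bradykinesia_ue_right": 12,
        "bradykinesia_ue_left": 12,
        "rigidity": 20,
        "rigidity_ue_right": 4,
        "rigidity_ue_left": 4,
        "posture": 4,
    }

    def __post_init__(self):
        for name, mx in self._MAXIMA.items():
            v = getattr(self, name)
            if not 0 <= v <= mx:
                raise ValueError(f"{name}={v} outside [0, {mx}]")
        if abs(self.asymmetry_bradykinesia) > 16:
            raise ValueError("bradykinesia asymmetry exceeds per-side maximum")
        if abs(self.asymmetry_rigidity) > 8:
            raise ValueError("rigidity asymmetry exceeds per-side maximum")


def load_schema(path: str | Path | None = None) -> dict:
    """Load the clinical table schema (packaged version by default)."""
    if path is None:
        ref = resources.files("exopark.data").joinpath("clinical_schema.json")
        return json.loads(ref.read_text(encoding="utf-8"))
    return json.loads(Path(path).read_text(encoding="utf-8"))


def packaged_cohort_path() -> Path:
    """Path to the packaged 26-subject clinical cohort fixture."""
    return Path(str(resources.files("exopark.data").joinpath("clinical_cohort.csv")))


def _parse_cell(raw: str, spec: dict, row: int, column: str):
    raw = raw.strip()
    if raw == "" or raw.lower() in ("na", "nan", "none") and spec["type"] != "string":
        if raw.lower() == "none" and spec["type"] == "string":
            return raw
        if spec.get("required"):
            raise ClinicalParseError(row, column, "required value missing")
        return None
    t = spec["type"]
    if t == "string":
        return raw
    if t == "enum":
        if raw not in spec["values"]:
            raise ClinicalParseError(row, column, f"{raw!r} not in {spec['values']}")
        return raw
    try:
        value = float(raw)
    except ValueError as exc:
        raise ClinicalParseError(row, column, f"non-numeric value {raw!r}") from exc
    if t == "int":
        if value != int(value):
            raise ClinicalParseError(row, column, f"expected integer, got {raw!r}")
        value = int(value)
    if "min" in spec and value < spec["min"]:
        raise ClinicalParseError(row, column, f"{value} below minimum {spec['min']}")
    if "min_exclusive" in spec and value <= spec["min_exclusive"]:
        raise ClinicalParseError(row, column, f"{value} not above {spec['min_exclusive']}")
    if "max" in spec and value > spec["max"]:
        raise ClinicalParseError(row, column, f"{value} above maximum {spec['max']}")
    return value


def read_cohort_table(path: str | Path, schema: dict | None = None) -> list[SubjectRecord]:
    """Read and validate a clinical cohort CSV into ``SubjectRecord`` objects.

    Raises ``ClinicalSchemaError`` if a required column is missing and
    ``ClinicalParseError`` (naming row and column) for malformed cells.
    """
    schema = schema or load_schema()
    cols = schema["columns"]
    path = Path(path)
    records: list[SubjectRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c, s in cols.items() if s.get("required") and c not in header]
        if missing:
            raise ClinicalSchemaError(f"missing required column(s): {missing}")
        for i, row in enumerate(reader, start=1):
            values = {
                col: _parse_cell(row.get(col, ""), spec, i, col)
                for col, spec in cols.items()
                if col in header
            }
            try:
                records.append(SubjectRecord(**values))
            except ClinicalSchemaError as exc:
                raise ClinicalSchemaError(f"row {i}: {exc}") from exc
    return records


def _require(items: Mapping[str, int], keys: Iterable[str]) -> list[int]:
    missing = [k for k in keys if k not in items]
    if missing:
        raise MissingItemError(f"UPDRS item(s) missing: {missing}")
    return [int(items[k]) for k in keys]


def updrs_subscores(items: Mapping[str, int]) -> UpdrsSubscores:
    """Compute bradykinesia/rigidity/posture subscores from an item map.

    Bradykinesia sums items 23-26 over both sides (maximum 32); the
    upper-extremity variants sum items 23-25 per side (maximum 12 each).
    Rigidity sums the five item-22 entries (maximum 20) with per-arm
    variants (maximum 4 each).  Asymmetries are right minus left over the
    lateralized entries of each item group.
    """
    rig = _require(items, RIGIDITY_KEYS)
    br = _require(items, BRADY_RIGHT_KEYS)
    bl = _require(items, BRADY_LEFT_KEYS)
    posture = _require(items, (POSTURE_KEY,))[0]
    rig_map = dict(zip(RIGIDITY_KEYS, rig))
    return UpdrsSubscores(
        bradykinesia=sum(br) + sum(bl),
        bradykinesia_ue_right=sum(_require(items, BRADY_UE_RIGHT_KEYS)),
        bradykinesia_ue_left=sum(_require(items, BRADY_UE_LEFT_KEYS)),
        rigidity=sum(rig),
        rigidity_ue_right=rig_map["22_rue"],
        rigidity_ue_left=rig_map["22_lue"],
        posture=posture,
        asymmetry_bradykinesia=sum(br) - sum(bl),
        asymmetry_rigidity=(rig_map["22_rue"] + rig_map["22_rle"])
        - (rig_map["22_lue"] + rig_map["22_lle"]),
    )


def mcd_filter(records: Iterable[SubjectRecord]) -> tuple[set[str], set[str]]:
    """Partition the PD cohort into DRT responders and non-responders.

    A responder shows a reduction in total UPDRS Part III strictly greater
    than :data:`MCD_THRESHOLD` points (OFF - ON > 6).  A 6-point reduction
    exactly is a non-responder.  Control records are ignored.
    """
    pd_records = [r for r in records if r.group == "PD"]
    incomplete = [r.subject_id for r in pd_records if r.updrs_delta is None]
    if incomplete:
        raise ValueError(f"missing OFF/ON UPDRS totals for: {sorted(incomplete)}")
    responders = {r.subject_id for r in pd_records if r.updrs_delta > MCD_THRESHOLD}
    nonresponders = {r.subject_id for r in pd_records} - responders
    return responders, nonresponders
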