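"""Health-facility capability classification.

Facilities audited in a Service Provision Assessment (SPA)-style survey are
assigned to capability tiers by fixed infrastructure / personnel / supply
criteria derived from the WHO Integrated Management for Emergency and
Essential Surgical Care toolkit:

* **Level A** — 24-hour emergency services: overnight beds, a 24-hour duty
  schedule, at least 2 qualified providers (specialist physicians, medical
  officers, or nurses), water, electricity, a functioning telephone, and
  on-site latrines.
* **Level B** — resuscitative capability: all Level A criteria plus IV
  fluids, blood products, basic surgical instruments (forceps, a needle
  driver, and sterile scissors — all three), local anesthesia, sterile
  dressings, and supplemental oxygen.
* **Level C** — tertiary care: a tertiary hospital designation, OR all
  Level B criteria together with more than 50 inpatient beds and a surgeon
  on staff.
* **Level X** — none of the above.

Capability flags are *overlapping* booleans: a facility meeting the Level B
criteria also carries the Level A flag, and per-level summaries therefore may
sum to more than 100%.  A designation-route Level C facility does *not*
inherit the A or B flags — a government-designated tertiary hospital lacking,
say, running water or blood products is counted for tertiary catchments only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "FacilityRecord",
    "CapabilityProfile",
    "ClassificationError",
    "classify_facility",
    "classify_roster",
    "read_roster_csv",
    "profiles_to_frame",
    "LEVELS",
]

LEVELS = ("A", "B", "C")

#: boolean audit attributes, in roster-CSV column order
BOOL_ATTRS = (
    "overnight_beds",
    "duty_24h",
    "water",
    "electricity",
    "telephone_functioning",
    "latrines_onsite",
    "iv_fluids",
    "blood_products",
    "has_forceps",
    "has_needle_driver",
    "has_sterile_scissors",
    "local_anesthesia",
    "sterile_dressings",
    "supplemental_oxygen",
    "tertiary_designation",
    "surgeon_on_staff",
)

COUNT_ATTRS = ("n_qualified_providers", "n_inpatient_beds")

_LEVEL_A_BOOLS = (
    "overnight_beds",
    "duty_24h",
    "water",
    "electricity",
    "telephone_functioning",
    "latrines_onsite",
)
_LEVEL_B_BOOLS = (
    "iv_fluids",
    "blood_products",
    "has_forceps",
    "has_needle_driver",
    "has_sterile_scissors",
    "local_anesthesia",
    "sterile_dressings",
    "supplemental_oxygen",
)


class ClassificationError(ValueError):
    """Raised for unusable audit attributes (missing under strict policy,
    or non-finite counts)."""


@dataclass
class FacilityRecord:
    """One audited facility: planar location plus readiness attributes.

    ``None`` in any audit attribute means *not recorded* — distinct from an
    observed absence (``False`` / ``0``).  Coordinates are projected meters;
    see :mod:`emaccess.pipeline` for the CRS contract.
    """

    facility_id: str
    name: str = ""
    x: float = float("nan")
    y: float = float("nan")
    overnight_beds: bool | None = None
    duty_24h: bool | None = None
    n_qualified_providers: int | None = None
    water: bool | None = None
    electricity: bool | None = None
    telephone_functioning: bool | None = None
    latrines_onsite: bool | None = None
    iv_fluids: bool | None = None
    blood_products: bool | None = None
    has_forceps: bool | None = None
    has_needle_driver: bool | None = None
    has_sterile_scissors: bool | None = None
    local_anesthesia: bool | None = None
    sterile_dressings: bool | None = None
    supplemental_oxygen: bool | None = None
    tertiary_designation: bool | None = None
    n_inpatient_beds: int | None = None
    surgeon_on_staff: bool | None = None


@dataclass(frozen=True)
class CapabilityProfile:
    """Overlapping capability flags for one facility.

    Invariants: ``level_b`` implies ``level_a`` (the B criteria contain the
    A criteria); ``level_x`` is true exactly when no other flag is.
    """

    facility_id: str
    level_a: bool
    level_b: bool
    level_c: bool

    @property
    def level_x(self) -> bool:
        return not (self.level_a or self.level_b or self.level_c)

    def has_level(self, level: str) -> bool:
        return {"A": self.level_a, "B": self.level_b, "C": self.level_c,
                "X": self.level_x}[level.upper()]


def _get(record: FacilityRecord, attr: str, missing_policy: str):
    value = getattr(record, attr)
    if value is None:
        if missing_policy == "error":
            raise ClassificationError(
                f"facility {record.facility_id!r}: attribute {attr!r} is missing"
            )
        return 0 if attr in COUNT_ATTRS else False
    if attr in COUNT_ATTRS:
        value = float(value)
        if not math.isfinite(value) or value < 0:
            raise ClassificationError(
                f"facility {record.facility_id!r}: {attr}={value!r} is not a "
                "finite nonnegative count"
            )
    return value


def classify_facility(
    record: FacilityRecord, missing_policy: str = "as_false"
) -> CapabilityProfile:
    """Apply the capability criteria to one facility.

    Parameters
    ----------
    record
        The audit record.
    missing_policy
        ``"as_false"`` (default) treats unrecorded attributes as absent —
        the conservative reading; ``"error"`` raises
        :class:`ClassificationError` naming the first missing field.
    """
    if missing_policy not in ("as_false", "error"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")

    # evaluate every attribute eagerly so bad values surface regardless of
    # which criteria short-circuit
    a = {attr: _get(record, attr, missing_policy)
         for attr in BOOL_ATTRS + COUNT_ATTRS}

    level_a = all(a[k] for k in _LEVEL_A_BOOLS) and a["n_qualified_providers"] >= 2
    level_b = level_a and all(a[k] for k in _LEVEL_B_BOOLS)
    level_c = bool(a["tertiary_designation"]) or (
        level_b and a["n_inpatient_beds"] > 50 and bool(a["surgeon_on_staff"])
    )
    return CapabilityProfile(record.facility_id, bool(level_a), bool(level_b), level_c)


def classify_roster(
    records: Sequence[FacilityRecord], missing_policy: str = "as_false"
) -> tuple[list[CapabilityProfile], pd.DataFrame]:
    """Classify every facility and summarise per-level counts.

    Returns the profiles (roster order) and a summary frame with one row per
    level A, B, C, X holding ``count`` and ``percent`` of the roster.  A, B
    and C counts are *overlapping* (each counts every facility carrying that
    flag); X counts facilities with no capability.
    """
    if not records:
        raise ValueError("empty facility roster")
    ids = [r.facility_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate facility_id(s): {dupes}")

    profiles = [classify_facility(r, missing_policy) for r in records]
    n = len(profiles)
    counts = {
        "A": sum(p.level_a for p in profiles),
        "B": sum(p.level_b for p in profiles),
        "C": sum(p.level_c for p in profiles),
        "X": sum(p.level_x for p in profiles),
    }
    summary = pd.DataFrame(
        {
            "level": list(counts),
            "count": list(counts.values()),
            "percent": [100.0 * c / n for c in counts.values()],
        }
    )
    summary.attrs["overlapping"] = True
    summary.attrs["n_facilities"] = n
    return profiles, summary


# ---------------------------------------------------------------------------
# roster CSV I/O
# ---------------------------------------------------------------------------

_FIELD_NAMES = tuple(f.name for f in dc_fields(FacilityRecord))


def _parse_bool(raw) -> bool | None:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "":
        return None
    s = str(raw).strip()
    if s == "":
        return None
    if s in ("1", "1.0", "true", "True"):
        return True
    if s in ("0", "0.0", "false", "False"):
        return False
    raise ValueError(f"cannot parse boolean audit value {raw!r} (use 1/0/empty)")


def read_roster_csv(path) -> list[FacilityRecord]:
    """Read a facility roster CSV.

    One header row; columns named as :class:`FacilityRecord` fields; boolean
    attributes encoded ``1`` / ``0`` / empty (empty = not recorded);
    coordinates in projected-meter columns ``x``, ``y``.  ``lon``/``lat``
    columns are rejected: project upstream and supply planar meters.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "lon" in df.columns or "lat" in df.columns:
        raise ValueError(
            "roster carries lon/lat columns; reproject to a projected CRS "
            "and provide planar-meter x,y columns"
        )
    for required in ("facility_id", "x", "y"):
        if required not in df.columns:
            raise ValueError(f"roster CSV missing required column {required!r}")

    records = []
    for row in df.to_dict("records"):
        kwargs = {"facility_id": str(row["facility_id"]),
                  "name": str(row.get("name", ""))}
        for coord in ("x", "y"):
            kwargs[coord] = float(row[coord])
            if not math.isfinite(kwargs[coord]):
                raise ValueError(
                    f"facility {kwargs['facility_id']!r}: non-finite coordinate"
                )
        for attr in BOOL_ATTRS:
            if attr in row:
                kwargs[attr] = _parse_bool(row[attr])
        for attr in COUNT_ATTRS:
            if attr in row:
                raw = str(row[attr]).strip()
                kwargs[attr] = None if raw == "" else int(float(raw))
        records.append(FacilityRecord(**kwargs))
    return records


def roster_to_frame(records: Iterable[FacilityRecord]) -> pd.DataFrame:
    """Serialise records to the roster-CSV column layout (1/0/empty booleans)."""
    rows = []
    for r in records:
        row = {}
        for name in _FIELD_NAMES:
            v = getattr(r, name)
            if name in BOOL_ATTRS:
                row[name] = "" if v is None else str(int(v))
            elif name in COUNT_ATTRS:
                row[name] = "" if v is None else str(int(v))
            else:
                row[name] = v
        rows.append(row)
    return pd.DataFrame(rows, columns=_FIELD_NAMES)


def profiles_to_frame(profiles: Iterable[CapabilityProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "facility_id": p.facility_id,
                "level_a": int(p.level_a),
                "level_b": int(p.level_b),
                "level_c": int(p.level_c),
                "level_x": int(p.level_x),
            }
            for p in profiles
        ],
        columns=["facility_id", "level_a", "level_b", "level_c", "level_x"],
    )
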