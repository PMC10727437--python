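"""Harmonization of literature-derived temperature–growth records.

Source studies report growth in three interchangeable currencies: a relative
growth rate (RGR, g g⁻¹ d⁻¹) directly, an initial/final biomass pair over a
known duration, or a doubling time.  This module converts all three to a
uniform per-day RGR, validates each record, and assembles them into a
:class:`RecordTable` ready for curve fitting.

Conventions
-----------
* RGR from masses: ``ln(mass_final / mass_initial) / duration`` — the
  standard exponential-growth definition.
* RGR from doubling time: ``ln 2 / doubling_time``.
* Precedence when several currencies are present: a reported RGR wins over
  masses, which win over doubling time.
* Negative RGR is accepted: die-off at thermal extremes is biologically real.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Controlled vocabulary of species labels.
SPECIES = (
    "A_pinnata",
    "A_filiculoides",
    "A_caroliniana",
    "A_mexicana",
    "A_microphylla",
    "A_nilotica",
)

#: Provenance labels for the harmonized growth rate.
RGR_SOURCES = ("reported", "from_masses", "from_doubling_time")

#: Fixed column order of the canonical harmonized CSV.
CANONICAL_COLUMNS = (
    "study_id",
    "species",
    "strain",
    "temperature_C",
    "rgr_per_day",
    "rgr_source",
    "sd",
    "conditions",
)

#: Default mapping canonical-field -> source-file column header.
DEFAULT_COLUMN_MAP = {
    "study_id": "study_id",
    "species": "species",
    "strain": "strain",
    "temperature": "temperature_C",
    "rgr": "rgr_per_day",
    "sd": "sd",
    "conditions": "conditions",
    "mass_initial": "mass_initial_g",
    "mass_final": "mass_final_g",
    "time_initial": "time_initial_d",
    "time_final": "time_final_d",
    "doubling_time": "doubling_time_d",
}


class ValidationError(ValueError):
    """A record or file failed validation; the message names the offence."""


def rgr_from_masses(mass_initial: float, mass_final: float, duration: float) -> float:
    """Relative growth rate (d⁻¹) from an initial/final biomass pair.

    RGR = ln(mass_final / mass_initial) / duration, with masses in grams and
    duration in days.  Negative output (mass loss) is permitted.
    """
    if not (mass_initial > 0):
        raise ValidationError(f"mass_initial must be > 0, got {mass_initial!r}")
    if not (mass_final > 0):
        raise ValidationError(f"mass_final must be > 0, got {mass_final!r}")
    if not (duration > 0):
        raise ValidationError(f"duration must be > 0, got {duration!r}")
    return math.log(mass_final / mass_initial) / duration


def rgr_from_doubling_time(doubling_time: float) -> float:
    """Relative growth rate (d⁻¹) from a doubling time in days (ln 2 / DT)."""
    if not (doubling_time > 0):
        raise ValidationError(f"doubling_time must be > 0, got {doubling_time!r}")
    return math.log(2.0) / doubling_time


@dataclass(frozen=True)
class GrowthRecord:
    """One harmonized (temperature, RGR) observation with study provenance."""

    study_id: str
    species: str
    temperature: float
    rgr: float
    rgr_source: str
    strain: str | None = None
    sd: float | None = None
    conditions: str | None = None

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValidationError(
                f"species {self.species!r} not in controlled vocabulary {SPECIES}"
            )
        if not math.isfinite(self.temperature):
            raise ValidationError(f"temperature must be finite, got {self.temperature!r}")
        if not math.isfinite(self.rgr):
            raise ValidationError(f"rgr must be finite, got {self.rgr!r}")
        if self.rgr_source not in RGR_SOURCES:
            raise ValidationError(
                f"rgr_source {self.rgr_source!r} not one of {RGR_SOURCES}"
            )


@dataclass(frozen=True)
class RawRecord:
    """A record as read from a source file, before harmonization.

    At least one growth currency must be recoverable: a reported ``rgr``, a
    complete (mass_initial, mass_final, duration) triple, or a
    ``doubling_time``.
    """

    study_id: str
    species: str
    temperature: float
    rgr: float | None = None
    mass_initial: float | None = None
    mass_final: float | None = None
    time_initial: float | None = None
    time_final: float | None = None
    doubling_time: float | None = None
    strain: str | None = None
    sd: float | None = None
    conditions: str | None = None

    @property
    def duration(self) -> float | None:
        if self.time_initial is None or self.time_final is None:
            return None
        return self.time_final - self.time_initial


def harmonize(raw: RawRecord) -> GrowthRecord:
    """Convert a raw record to a harmonized one, recording which path fired.

    Precedence: reported RGR > masses > doubling time.  A reported RGR is
    never altered.
    """
    if raw.rgr is not None and math.isfinite(raw.rgr):
        rgr, source = raw.rgr, "reported"
    elif (
        raw.mass_initial is not None
        and raw.mass_final is not None
        and raw.duration is not None
    ):
        rgr = rgr_from_masses(raw.mass_initial, raw.mass_final, raw.duration)
        source = "from_masses"
    elif raw.doubling_time is not None:
        rgr = rgr_from_doubling_time(raw.doubling_time)
        source = "from_doubling_time"
    else:
        raise ValidationError(
            f"record (study={raw.study_id!r}, T={raw.temperature}) has no usable "
            "growth information: need rgr, a mass pair with times, or doubling_time"
        )
    return GrowthRecord(
        study_id=str(raw.study_id),
        species=raw.species,
        temperature=float(raw.temperature),
        rgr=float(rgr),
        rgr_source=source,
        strain=raw.strain,
        sd=raw.sd,
        conditions=raw.conditions,
    )


@dataclass
class RecordTable:
    """An ordered collection of harmonized growth records with provenance."""

    records: list[GrowthRecord]
    source: str | None = None
    filter_log: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def species(self) -> set[str]:
        return {r.species for r in self.records}

    @property
    def study_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.study_id, None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        """Canonical DataFrame with the fixed harmonized column order."""
        rows = [
            {
                "study_id": r.study_id,
                "species": r.species,
                "strain": r.strain,
                "temperature_C": r.temperature,
                "rgr_per_day": r.rgr,
                "rgr_source": r.rgr_source,
                "sd": r.sd,
                "conditions": r.conditions,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def flag_duplicates(self) -> list[int]:
        """Indices of records repeating a (study, species, T, rgr) quadruple.

        Replicates are kept — true within-treatment replicates exist in the
        literature — but flagged so a caller can audit them.
        """
        seen: set[tuple] = set()
        dups = []
        for i, r in enumerate(self.records):
            key = (r.study_id, r.species, r.temperature, r.rgr)
            if key in seen:
                dups.append(i)
            seen.add(key)
        return dups


def filter_species(table: RecordTable, species: str | Sequence[str]) -> RecordTable:
    """Subset a table to one or more species labels, preserving order."""
    wanted = {species} if isinstance(species, str) else set(species)
    unknown = wanted - set(SPECIES)
    if unknown:
        raise ValidationError(f"unknown species label(s): {sorted(unknown)}")
    kept = [r for r in table.records if r.species in wanted]
    msg = (
        f"filter_species({sorted(wanted)}): {len(table.records)} -> {len(kept)} records"
    )
    logger.info(msg)
    return RecordTable(
        records=kept, source=table.source, filter_log=table.filter_log + [msg]
    )


def filter_plain_conditions(table: RecordTable) -> RecordTable:
    """Drop records carrying extra environmental manipulations.

    Records whose ``conditions`` field is non-empty (added phosphorus, CO₂,
    pH, light manipulations) are excluded.  Off by default in the pipeline;
    retained records keep their condition labels either way.
    """
    kept = [r for r in table.records if not r.conditions]
    msg = f"filter_plain_conditions: {len(table.records)} -> {len(kept)} records"
    logger.info(msg)
    return RecordTable(
        records=kept, source=table.source, filter_log=table.filter_log + [msg]
    )


def load_column_map(path: str | Path) -> dict[str, str]:
    """Read a canonical-field -> source-header mapping from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        loaded = yaml.safe_load(fh) or {}
    cmap = dict(DEFAULT_COLUMN_MAP)
    cmap.update({str(k): str(v) for k, v in loaded.items()})
    return cmap


def _coerce_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str):
        value = value.strip()
        if not value:
            return None
    try:
        return float(value)
    except (TypeError, ValueError):
        return None


def _coerce_str(value) -> str | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    return s or None


def _parse_temperature(value) -> float | None:
    """Reduce a temperature cell to a single °C value.

    Ranges ("20-30") and day/night pairs ("30/20") are reduced to their
    arithmetic mean; the caller preserves the original text in conditions.
    """
    f = _coerce_float(value)
    if f is not None:
        return f
    if isinstance(value, str):
        for sep in ("/", "-", "–"):
            # leading '-' of a negative number is not a separator
            parts = value.strip().split(sep)
            if len(parts) == 2:
                lo, hi = _coerce_float(parts[0]), _coerce_float(parts[1])
                if lo is not None and hi is not None:
                    return 0.5 * (lo + hi)
    return None


def load_records(
    path: str | Path,
    column_map: Mapping[str, str] | str | Path | None = None,
) -> RecordTable:
    """Read a CSV or XLSX file of growth records and harmonize every row.

    ``column_map`` maps canonical field names (see ``DEFAULT_COLUMN_MAP``) to
    the headers actually present in the file; it may be a dict or a path to a
    YAML file.  Rows that cannot be harmonized are logged and skipped, never
    silently dropped without trace.  Missing mandatory columns (species,
    temperature) raise immediately.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if isinstance(column_map, (str, Path)):
        cmap = load_column_map(column_map)
    else:
        cmap = dict(DEFAULT_COLUMN_MAP)
        if column_map:
            cmap.update(column_map)

    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)

    missing = [
        cmap[f] for f in ("species", "temperature") if cmap[f] not in df.columns
    ]
    if missing:
        raise ValidationError(
            f"{path.name}: missing mandatory column(s): {missing}; "
            f"present: {list(df.columns)}"
        )

    def cell(row, field):
        col = cmap.get(field)
        return row[col] if col in df.columns else None

    records: list[GrowthRecord] = []
    log: list[str] = []
    for i, row in df.iterrows():
        raw_temp = cell(row, "temperature")
        temp = _parse_temperature(raw_temp)
        if temp is None:
            log.append(f"row {i}: unparseable temperature {raw_temp!r}; skipped")
            continue
        conditions = _coerce_str(cell(row, "conditions"))
        if _coerce_float(raw_temp) is None and _coerce_str(raw_temp):
            note = f"temperature_as_given={_coerce_str(raw_temp)}"
            conditions = f"{conditions}; {note}" if conditions else note
        raw = RawRecord(
            study_id=_coerce_str(cell(row, "study_id")) or f"study_{i}",
            species=_coerce_str(cell(row, "species")) or "",
            temperature=temp,
            rgr=_coerce_float(cell(row, "rgr")),
            mass_initial=_coerce_float(cell(row, "mass_initial")),
            mass_final=_coerce_float(cell(row, "mass_final")),
            time_initial=_coerce_float(cell(row, "time_initial")),
            time_final=_coerce_float(cell(row, "time_final")),
            doubling_time=_coerce_float(cell(row, "doubling_time")),
            strain=_coerce_str(cell(row, "strain")),
            sd=_coerce_float(cell(row, "sd")),
            conditions=conditions,
        )
        try:
            records.append(harmonize(raw))
        except ValidationError as exc:
            log.append(f"row {i}: {exc}; skipped")
    for msg in log:
        logger.warning("%s: %s", path.name, msg)
    return RecordTable(records=records, source=str(path), filter_log=log)


def from_frame(df: pd.DataFrame, source: str | None = None) -> RecordTable:
    """Build a RecordTable from a DataFrame already in canonical layout."""
    records = [
        GrowthRecord(
            study_id=str(row.study_id),
            species=str(row.species),
            temperature=float(row.temperature_C),
            rgr=float(row.rgr_per_day),
            rgr_source=str(row.rgr_source),
            strain=_coerce_str(getattr(row, "strain", None)),
            sd=_coerce_float(getattr(row, "sd", None)),
            conditions=_coerce_str(getattr(row, "conditions", None)),
        )
        for row in df.itertuples(index=False)
    ]
    return RecordTable(records=records, source=source)
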