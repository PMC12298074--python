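"""Formulation dataset model and delimited-table I/O.

A formulation dataset joins per-batch process settings (one categorical
nozzle configuration plus five continuous variables) with the five measured
batch responses.  Failed batches are kept as rows whose response cells all
carry the ``*`` marker; every modelling stage downstream decides its own
inclusion rule.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .errors import DomainError, FormatError, TableParseError

#: canonical column order for the settings block
SETTING_COLUMNS = ("nc", "kgm_conc", "alg_conc", "p_outer", "p_inner", "airflow")
#: canonical column order for the response block
RESPONSE_COLUMNS = ("prilling_score", "feret_mm", "circularity", "core_score", "coating_mm")

NOZZLE_LEVELS = ("A", "B", "C")

#: nozzle outer/inner orifice diameters in mm — informational lookup only;
#: models treat the configuration as an unordered 3-level factor.
NOZZLE_GEOMETRY_MM = {"A": (0.5, 0.15), "B": (0.8, 0.15), "C": (0.8, 0.35)}

#: design-space bounds of the continuous process variables
DESIGN_BOUNDS = {
    "kgm_conc": (0.6, 0.7),
    "alg_conc": (0.75, 1.25),
    "p_outer": (0.4, 1.2),
    "p_inner": (0.2, 1.0),
    "airflow": (1.75, 2.65),
}

MISSING = "*"


@dataclass(frozen=True)
class ProcessSettings:
    """One point in the six-variable prilling design space."""

    nc: str
    kgm_conc: float
    alg_conc: float
    p_outer: float
    p_inner: float
    airflow: float

    def __post_init__(self):
        if self.nc not in NOZZLE_LEVELS:
            raise DomainError(f"nozzle configuration must be one of {NOZZLE_LEVELS}, got {self.nc!r}")

    def validate_bounds(self) -> None:
        """Raise DomainError if any continuous variable leaves the design space."""
        for name, (lo, hi) in DESIGN_BOUNDS.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise DomainError(f"{name}={v} outside design bounds [{lo}, {hi}]")

    def as_dict(self) -> dict:
        return {c: getattr(self, c) for c in SETTING_COLUMNS}


@dataclass(frozen=True)
class BatchOutcome:
    """Five measured responses of one batch; all-None means the batch failed."""

    prilling_score: float | None = None
    feret_mm: float | None = None
    circularity: float | None = None
    core_score: float | None = None
    coating_mm: float | None = None

    def __post_init__(self):
        if self.feret_mm is not None and self.feret_mm <= 0:
            raise DomainError(f"feret_mm must be > 0, got {self.feret_mm}")
        if self.circularity is not None and not (0.0 <= self.circularity <= 1.0):
            raise DomainError(f"circularity must lie in [0, 1], got {self.circularity}")
        if self.coating_mm is not None and self.coating_mm < 0:
            raise DomainError(f"coating_mm must be >= 0, got {self.coating_mm}")
        if self.prilling_score is not None and not 0 <= self.prilling_score <= 2:
            raise DomainError(f"prilling_score must lie in [0, 2], got {self.prilling_score}")
        if self.core_score is not None and not 0 <= self.core_score <= 5:
            raise DomainError(f"core_score must lie in [0, 5], got {self.core_score}")

    @property
    def failed(self) -> bool:
        return all(getattr(self, c) is None for c in RESPONSE_COLUMNS)

    def as_dict(self) -> dict:
        return {c: getattr(self, c) for c in RESPONSE_COLUMNS}


@dataclass(frozen=True)
class FormulationRecord:
    sample_id: int
    settings: ProcessSettings
    outcome: BatchOutcome

    def __post_init__(self):
        if self.sample_id <= 0:
            raise DomainError(f"sample_id must be positive, got {self.sample_id}")


@dataclass
class FormulationDataset:
    """Ordered collection of formulation records; iteration preserves input order."""

    records: list[FormulationRecord] = field(default_factory=list)

    def __post_init__(self):
        ids = [r.sample_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise DomainError("sample_id values must be unique within a dataset")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[FormulationRecord]:
        return iter(self.records)

    @property
    def n_failed(self) -> int:
        return sum(1 for r in self.records if r.outcome.failed)

    @property
    def failed_sample_ids(self) -> list[int]:
        return [r.sample_id for r in self.records if r.outcome.failed]

    def n_usable(self, response: str) -> int:
        return len(usable_records(self, response))

    def to_frame(self) -> pd.DataFrame:
        """Flat table: sample, six settings, five responses (NaN where missing)."""
        rows = []
        for r in self.records:
            row = {"sample": r.sample_id}
            row.update(r.settings.as_dict())
            row.update(r.outcome.as_dict())
            rows.append(row)
        cols = ["sample", *SETTING_COLUMNS, *RESPONSE_COLUMNS]
        return pd.DataFrame(rows, columns=cols).astype({"sample": int})

    def to_json(self) -> str:
        recs = []
        for r in self.records:
            recs.append(
                {
                    "sample": r.sample_id,
                    "settings": r.settings.as_dict(),
                    "outcome": r.outcome.as_dict(),
                    "failed": r.outcome.failed,
                }
            )
        return json.dumps({"records": recs}, indent=2)


def _parse_float(cell: str, column: str, row: int) -> float | None:
    cell = cell.strip()
    if cell == MISSING or cell == "":
        return None
    try:
        return float(cell)
    except ValueError:
        raise TableParseError(
            f"cannot parse cell {cell!r} in column {column!r} at data row {row}", row=row
        ) from None


def load_design(source) -> FormulationDataset:
    """Load a formulation table from a CSV path, file object or string buffer.

    Requires the sample + settings columns; the five response columns are
    optional.  ``*`` or empty response cells become missing values.
    """
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        raw = pd.read_csv(source, dtype=str, keep_default_na=False)
    else:
        if isinstance(source, str):
            source = io.StringIO(source)
        raw = pd.read_csv(source, dtype=str, keep_default_na=False)

    required = ["sample", *SETTING_COLUMNS]
    for col in required:
        if col not in raw.columns:
            raise FormatError(f"required column {col!r} is missing")
    present_responses = [c for c in RESPONSE_COLUMNS if c in raw.columns]

    records = []
    for i, row in enumerate(raw.itertuples(index=False)):
        row = dict(zip(raw.columns, row))
        sample_cell = row["sample"].strip()
        try:
            sample_id = int(sample_cell)
        except ValueError:
            raise TableParseError(
                f"cannot parse sample id {sample_cell!r} at data row {i}", row=i
            ) from None
        nc = row["nc"].strip()
        if nc not in NOZZLE_LEVELS:
            raise DomainError(f"nozzle configuration {nc!r} at data row {i} not in {NOZZLE_LEVELS}")
        setting_vals = {}
        for col in SETTING_COLUMNS[1:]:
            v = _parse_float(row[col], col, i)
            if v is None:
                raise TableParseError(f"missing value in settings column {col!r} at data row {i}", row=i)
            setting_vals[col] = v
        settings = ProcessSettings(nc=nc, **setting_vals)
        outcome_vals = {c: _parse_float(row[c], c, i) for c in present_responses}
        records.append(
            FormulationRecord(sample_id=sample_id, settings=settings, outcome=BatchOutcome(**outcome_vals))
        )
    return FormulationDataset(records)


def _fmt(v, ordinal: bool) -> str:
    if v is None:
        return MISSING
    if ordinal and float(v) == int(v):
        return str(int(v))
    return repr(float(v))


def write_design(dataset: FormulationDataset, target) -> None:
    """Write a dataset back to CSV in the canonical schema (``*`` for missing)."""
    ordinals = {"prilling_score", "core_score"}
    lines = [",".join(["sample", *SETTING_COLUMNS, *RESPONSE_COLUMNS])]
    for r in dataset:
        cells = [str(r.sample_id), r.settings.nc]
        cells += [repr(float(getattr(r.settings, c))) for c in SETTING_COLUMNS[1:]]
        cells += [_fmt(getattr(r.outcome, c), c in ordinals) for c in RESPONSE_COLUMNS]
        lines.append(",".join(cells))
    text = "\n".join(lines) + "\n"
    if isinstance(target, (str, Path)):
        Path(target).write_text(text)
    else:
        target.write(text)


def usable_records(dataset: FormulationDataset, response: str) -> FormulationDataset:
    """Subset of records with a present value for one response; order preserved."""
    if response not in RESPONSE_COLUMNS:
        raise DomainError(f"unknown response {response!r}; expected one of {RESPONSE_COLUMNS}")
    return FormulationDataset([r for r in dataset if getattr(r.outcome, response) is not None])


def design_balance_report(dataset: FormulationDataset, min_count: int = 4) -> dict:
    """Per-variable level counts with a flag for levels occurring < ``min_count`` times."""
    report = {}
    for var in SETTING_COLUMNS:
        counts: dict = {}
        for r in dataset:
            level = getattr(r.settings, var)
            counts[level] = counts.get(level, 0) + 1
        report[var] = {
            "levels": dict(sorted(counts.items(), key=lambda kv: str(kv[0]))),
            "n_levels": len(counts),
            "underrepresented": sorted(
                (lvl for lvl, n in counts.items() if n < min_count), key=str
            ),
        }
    return report


def score_failed_blockage(dataset: FormulationDataset,
                          filament_samples: Iterable[int] = (15,)) -> FormulationDataset:
    """Assign prilling_score = 0 to failed batches (blockage defines score 0).

    Batches listed in ``filament_samples`` failed by continuous-filament
    formation rather than blockage and stay fully missing.  This inclusion
    rule is off by default throughout the pipeline; modelling stages opt in.
    """
    filament = set(filament_samples)
    records = []
    for r in dataset:
        if r.outcome.failed and r.sample_id not in filament:
            records.append(
                FormulationRecord(r.sample_id, r.settings, BatchOutcome(prilling_score=0.0))
            )
        else:
            records.append(r)
    return FormulationDataset(records)


def load_reference_dataset() -> FormulationDataset:
    """Load the packaged 24-formulation design/outcome table."""
    with resources.files("prillopt.data").joinpath("formulations.csv").open("r") as fh:
        return load_design(fh)


def reference_fixture_text() -> str:
    """Raw text of the packaged formulation table (for round-trip checks)."""
    return resources.files("prillopt.data").joinpath("formulations.csv").read_text()
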