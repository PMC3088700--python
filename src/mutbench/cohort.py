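"""Cohort table data model and I/O.

The benchmark cohort is a small table of non-small-cell lung cancer
specimens, one row per reported mutation event (or per wild-type
specimen): patient identifiers, histology, tissue type, the
pathologist's tumor-cell content estimate, the mutant-allele fraction
measured by deep amplicon sequencing, the TKI response annotation, and
the MUT/WT call of each of the three detection methods (dideoxy
"Sanger" sequencing, pyrosequencing, massively parallel sequencing).

A specimen carrying two distinct mutations occupies two rows, so the
number of rows can exceed the number of physical specimens; `Cohort`
exposes all three counts (rows, specimens, patients).  The bundled
fixture is loaded with :func:`load_table1`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterator

import pandas as pd

__all__ = [
    "SpecimenRecord",
    "Cohort",
    "CohortSchemaError",
    "COHORT_COLUMNS",
    "read_cohort",
    "write_cohort",
    "load_table1",
    "mutated_specimens",
    "responders",
]

COHORT_COLUMNS = (
    "case_id",
    "specimen_label",
    "histotype",
    "sex",
    "age",
    "tissue_type",
    "specimen_type",
    "tumor_content_pct",
    "allele_pct",
    "tki_response",
    "call_dideoxy",
    "call_pyro",
    "call_parallel",
    "gene",
    "mutation_label",
    "sensitizing",
)

_METHOD_TO_FIELD = {
    "dideoxy": "call_dideoxy",
    "pyro": "call_pyro",
    "parallel": "call_parallel",
}

_VALID_CALLS = {"MUT", "WT"}
_VALID_RESPONSES = {"PR", "SD", "PD", "RL", "PR+RL"}
_VALID_HISTOTYPES = {"AD", "SQ"}
_VALID_GENES = {"EGFR", "KRAS", "none"}
_MISSING = {"", "N/A", "NA", "n/a"}


class CohortSchemaError(ValueError):
    """Raised when a cohort table violates the declared schema."""


@dataclass
class SpecimenRecord:
    """One cohort-table row: a specimen/mutation pair with per-method calls."""

    case_id: str
    specimen_label: str | None  # 'a'/'b' for multi-specimen patients, else None
    histotype: str
    sex: str
    age: int
    tissue_type: str
    specimen_type: str
    tumor_content_pct: float | None
    allele_pct: float | None
    tki_response: str | None
    call_dideoxy: str
    call_pyro: str
    call_parallel: str
    gene: str
    mutation_label: str
    sensitizing: bool

    @property
    def row_key(self) -> tuple[str, str]:
        return (self.case_id, self.specimen_label or "none")

    @property
    def specimen_key(self) -> tuple:
        # Rows of one case with an identical specimen description are the
        # same physical specimen reported once per mutation.
        return (
            self.case_id,
            self.tissue_type,
            self.specimen_type,
            self.tumor_content_pct,
        )

    def call(self, method: str) -> str:
        """MUT/WT call of one method ('dideoxy', 'pyro' or 'parallel')."""
        try:
            return getattr(self, _METHOD_TO_FIELD[method])
        except KeyError:
            raise ValueError(
                f"unknown method {method!r}; expected one of "
                f"{sorted(_METHOD_TO_FIELD)}"
            ) from None


@dataclass
class Cohort:
    """Ordered collection of :class:`SpecimenRecord` with a provenance note."""

    records: list[SpecimenRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for rec in self.records:
            if rec.row_key in seen:
                raise CohortSchemaError(
                    f"duplicate (case_id, specimen_label) {rec.row_key}"
                )
            seen.add(rec.row_key)

    def __iter__(self) -> Iterator[SpecimenRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_rows(self) -> int:
        return len(self.records)

    @property
    def n_specimens(self) -> int:
        """Physical specimens: rows sharing a specimen description collapse."""
        return len({rec.specimen_key for rec in self.records})

    @property
    def n_patients(self) -> int:
        return len({rec.case_id for rec in self.records})

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(r) for r in self.records], columns=COHORT_COLUMNS)
        return df.astype(
            {"tumor_content_pct": "float64", "allele_pct": "float64"}
        )


def _parse_optional_float(cell: str, *, row: int, column: str) -> float | None:
    if cell.strip() in _MISSING:
        return None
    try:
        return float(cell)
    except ValueError:
        raise CohortSchemaError(
            f"row {row}: cannot parse {column}={cell!r} as a number"
        ) from None


def _parse_record(row: dict[str, str], idx: int) -> SpecimenRecord:
    def req(column: str, valid: set[str]) -> str:
        value = row[column].strip()
        if value not in valid:
            raise CohortSchemaError(
                f"row {idx}: invalid {column}={value!r}; expected one of "
                f"{sorted(valid)}"
            )
        return value

    label = row["specimen_label"].strip()
    response = row["tki_response"].strip()
    if response in _MISSING:
        tki_response = None
    elif response in _VALID_RESPONSES:
        tki_response = response
    else:
        raise CohortSchemaError(
            f"row {idx}: unknown response code {response!r}"
        )
    sens = row["sensitizing"].strip().lower()
    if sens not in {"true", "false"}:
        raise CohortSchemaError(f"row {idx}: sensitizing must be true/false")
    return SpecimenRecord(
        case_id=row["case_id"].strip(),
        specimen_label=None if label in _MISSING | {"none"} else label,
        histotype=req("histotype", _VALID_HISTOTYPES),
        sex=req("sex", {"M", "F"}),
        age=int(row["age"]),
        tissue_type=row["tissue_type"].strip(),
        specimen_type=row["specimen_type"],
        tumor_content_pct=_parse_optional_float(
            row["tumor_content_pct"], row=idx, column="tumor_content_pct"
        ),
        allele_pct=_parse_optional_float(
            row["allele_pct"], row=idx, column="allele_pct"
        ),
        tki_response=tki_response,
        call_dideoxy=req("call_dideoxy", _VALID_CALLS),
        call_pyro=req("call_pyro", _VALID_CALLS),
        call_parallel=req("call_parallel", _VALID_CALLS),
        gene=req("gene", _VALID_GENES),
        mutation_label=row["mutation_label"],
        sensitizing=sens == "true",
    )


def read_cohort(path: str | Path, provenance: str | None = None) -> Cohort:
    """Read a cohort TSV (UTF-8, tab-separated, declared header).

    "N/A" and empty cells parse as missing.  Raises
    :class:`CohortSchemaError` on a header mismatch, a duplicate
    (case_id, specimen_label) pair, or an unknown call/response code,
    naming the offending row.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if tuple(reader.fieldnames or ()) != COHORT_COLUMNS:
            raise CohortSchemaError(
                f"{path}: header does not match cohort schema "
                f"{list(COHORT_COLUMNS)}"
            )
        records = [_parse_record(row, idx) for idx, row in enumerate(reader, 2)]
    return Cohort(records, provenance or str(path))


def _format_cell(value) -> str:
    if value is None:
        return "N/A"
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return f"{value:g}"
    return str(value)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort back to TSV; inverse of :func:`read_cohort`."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(COHORT_COLUMNS)
        for rec in cohort:
            row = []
            for column in COHORT_COLUMNS:
                value = getattr(rec, column)
                if column == "specimen_label" and value is None:
                    row.append("none")
                else:
                    row.append(_format_cell(value))
            writer.writerow(row)


def load_table1() -> Cohort:
    """Load the bundled 24-specimen (25-row, 22-patient) cohort fixture."""
    ref = resources.files("mutbench.data") / "table1.tsv"
    with resources.as_file(ref) as path:
        return read_cohort(path, provenance="bundled cohort fixture (table1.tsv)")


def mutated_specimens(cohort: Cohort, method: str) -> list[SpecimenRecord]:
    """Rows called MUT by one method, in table order."""
    if method not in _METHOD_TO_FIELD:
        raise ValueError(
            f"unknown method {method!r}; expected one of {sorted(_METHOD_TO_FIELD)}"
        )
    return [rec for rec in cohort if rec.call(method) == "MUT"]


def responders(cohort: Cohort) -> dict[str, SpecimenRecord]:
    """Patients with a confirmed partial response, mapped to the PR specimen.

    A patient qualifies when any of their rows carries a response
    annotation containing "PR"; for patients with both PR and relapse
    specimens the PR-annotated row is returned (first in table order).
    """
    out: dict[str, SpecimenRecord] = {}
    for rec in cohort:
        if rec.tki_response and "PR" in rec.tki_response:
            out.setdefault(rec.case_id, rec)
    return out
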