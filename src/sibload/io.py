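"""Tabular readers and writers for cross records, schedules and reports.

The primary dialect is TSV (UTF-8, "." decimal); CSV is accepted on read.
Booleans are encoded as 0/1 and missing values as empty fields.  When a
cross table carries no F column, parental inbreeding coefficients are
attached from the generation number via the full-sib recursion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .fitness import ReproSchedule
from .load_model import LoadFit, CrossRecord
from .pedigree import parental_F_for_cross, sib_mating_F

__all__ = [
    "StrainReport",
    "read_cross_table",
    "records_from_frame",
    "write_cross_table",
    "read_schedules",
    "write_schedules",
    "write_report",
]

CROSS_COLUMNS = ["line_id", "generation", "copulated", "fertile", "developed", "success"]
SCHEDULE_COLUMNS = [
    "female_id", "strain_id", "role", "start_h", "end_h", "adult_progeny", "censored",
]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _parse_bool(value, *, row: int, column: str) -> Optional[bool]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    try:
        iv = int(value)
    except (TypeError, ValueError):
        raise ValueError(f"row {row}: column {column!r} must be 0, 1 or empty, got {value!r}")
    if iv not in (0, 1):
        raise ValueError(f"row {row}: column {column!r} must be 0, 1 or empty, got {value!r}")
    return bool(iv)


def read_cross_table(path: str | Path) -> list[CrossRecord]:
    """Read single-pair cross records from TSV/CSV.

    Required columns: line_id, generation, success.  Stage flags
    (copulated, fertile, developed) are optional, as is F_parents; when
    the F column is absent it is derived from the generation number.
    Stage-consistency invariants are enforced with row numbers in errors.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    return records_from_frame(df, source=str(path))


def records_from_frame(df: pd.DataFrame, source: str = "<frame>") -> list[CrossRecord]:
    """Validate and convert a cross-record DataFrame to CrossRecord objects."""
    missing = {"line_id", "generation", "success"} - set(df.columns)
    if missing:
        raise ValueError(f"{source}: missing required columns {sorted(missing)}")
    has_stages = all(c in df.columns for c in ("copulated", "fertile", "developed"))
    if "F_parents" not in df.columns:
        gmax = int(df["generation"].max())
        schedule = sib_mating_F(max(gmax - 2, 0))
        df = df.assign(
            F_parents=[parental_F_for_cross(int(g), schedule) for g in df["generation"]]
        )
    records = []
    errors = []
    for idx, row in df.iterrows():
        rownum = idx + 2  # 1-based with header
        try:
            records.append(
                CrossRecord(
                    line_id=str(row["line_id"]),
                    generation=int(row["generation"]),
                    F_parents=float(row["F_parents"]),
                    success=bool(_parse_bool(row["success"], row=rownum, column="success")),
                    copulated=_parse_bool(row["copulated"], row=rownum, column="copulated")
                    if has_stages else None,
                    fertile=_parse_bool(row["fertile"], row=rownum, column="fertile")
                    if has_stages else None,
                    developed=_parse_bool(row["developed"], row=rownum, column="developed")
                    if has_stages else None,
                )
            )
        except ValueError as err:
            errors.append(f"row {rownum}: {err}")
    if errors:
        raise ValueError(f"{source}: {len(errors)} invalid record(s):\n" + "\n".join(errors))
    return records


def _bool_field(value: Optional[bool]) -> str:
    return "" if value is None else str(int(value))


def write_cross_table(records: Iterable[CrossRecord], path: str | Path) -> None:
    """Write cross records as TSV in the layout read_cross_table accepts."""
    path = Path(path)
    recs = list(records)
    df = pd.DataFrame(
        {
            "line_id": [r.line_id for r in recs],
            "generation": [r.generation for r in recs],
            "copulated": [_bool_field(r.copulated) for r in recs],
            "fertile": [_bool_field(r.fertile) for r in recs],
            "developed": [_bool_field(r.developed) for r in recs],
            "success": [int(r.success) for r in recs],
            "F_parents": [f"{r.F_parents:.10g}" for r in recs],
        }
    )
    df.to_csv(path, sep=_sep_for(path), index=False)


def read_schedules(path: str | Path) -> list[ReproSchedule]:
    """Read reproductive schedules (one row per female x laying interval)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = set(SCHEDULE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    out = []
    for fid, grp in df.groupby("female_id", sort=False):
        grp = grp.sort_values("start_h")
        strains = grp["strain_id"].unique()
        roles = grp["role"].unique()
        if len(strains) != 1 or len(roles) != 1:
            raise ValueError(f"{path}: female {fid} has inconsistent strain or role")
        out.append(
            ReproSchedule(
                female_id=str(fid),
                strain_id=str(strains[0]),
                role=str(roles[0]),
                intervals=tuple(
                    (float(s), float(e), int(m))
                    for s, e, m in zip(grp["start_h"], grp["end_h"], grp["adult_progeny"])
                ),
                censored=bool(grp["censored"].astype(int).any()),
            )
        )
    return out


def write_schedules(schedules: Iterable[ReproSchedule], path: str | Path) -> None:
    path = Path(path)
    rows = []
    for s in schedules:
        for start, end, m in s.intervals:
            rows.append(
                {
                    "female_id": s.female_id,
                    "strain_id": s.strain_id,
                    "role": s.role,
                    "start_h": start,
                    "end_h": end,
                    "adult_progeny": m,
                    "censored": int(s.censored),
                }
            )
    pd.DataFrame(rows, columns=SCHEDULE_COLUMNS).to_csv(path, sep=_sep_for(path), index=False)


@dataclass(frozen=True)
class StrainReport:
    """Per-strain report row: fitted coefficients and load estimates."""

    strain_id: str
    fit: LoadFit
    locality: str = ""


REPORT_COLUMNS = [
    "strain", "locality", "stage", "n",
    "beta0", "se0", "beta1", "se1", "A_R", "B_R", "p",
]


def write_report(reports: Sequence[StrainReport], path: str | Path) -> None:
    """Write a per-strain load report, coefficients and loads at 3 decimals."""
    rows = []
    for rep in reports:
        f = rep.fit
        rows.append(
            {
                "strain": rep.strain_id,
                "locality": rep.locality,
                "stage": f.stage,
                "n": f.n_crosses,
                "beta0": f"{f.beta0:.3f}",
                "se0": f"{f.se_beta0:.3f}",
                "beta1": f"{f.beta1:.3f}",
                "se1": f"{f.se_beta1:.3f}",
                "A_R": f"{f.A_R:.3f}",
                "B_R": f"{f.B_R:.3f}",
                "p": f"{f.p_beta1:.3g}",
            }
        )
    path = Path(path)
    pd.DataFrame(rows, columns=REPORT_COLUMNS).to_csv(path, sep=_sep_for(path), index=False)
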