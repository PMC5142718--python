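"""Per-cycle aggregate tables for prospective conception studies.

A study table has one row per menstrual cycle with the number of women
starting the cycle, the hCG-detected and clinically recognised pregnancies
in that cycle, and the women leaving the study non-pregnant at cycle end
(finishers and dropouts).  Cohort bookkeeping follows the conservation
identity

    n_start(k+1) = n_start(k) - preg_clin(k) - finished(k) - dropped(k),

i.e. only a clinical pregnancy, study completion or withdrawal removes a
woman from the risk set; an hCG-only pregnancy does not.

Files are plain CSV with a header row.  Dataset-level metadata (study name
and the optional long-horizon never-pregnant count) is carried in leading
``# key: value`` comment lines so a table remains a single self-contained
text file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "CANONICAL_COLUMNS",
    "CycleRecord",
    "StudyDataset",
    "Violation",
    "SchemaError",
    "DataFormatError",
    "read_study_csv",
    "write_study_csv",
    "validate_dataset",
]

#: canonical column names, in file order
CANONICAL_COLUMNS = ("cycle", "n_start", "preg_hcg", "preg_clin", "finished", "dropped")

_CONSERVATION_TOL = 1e-9


class SchemaError(ValueError):
    """A required column cannot be resolved in the input file."""


class DataFormatError(ValueError):
    """The file or dataset content violates the table format."""


@dataclass(frozen=True)
class CycleRecord:
    """Aggregate counts for one menstrual cycle.

    ``preg_hcg is None`` means the hCG count was *not observed* in that
    cycle (e.g. assays were only run early in the study); it is distinct
    from an observed count of zero.
    """

    cycle_index: int
    n_start: float
    preg_hcg: float | None
    preg_clin: float
    finished: float
    dropped: float


@dataclass(frozen=True)
class Violation:
    """One validation finding; ``severity`` is ``"error"`` or ``"warning"``."""

    severity: str
    cycle_index: int | None
    message: str


@dataclass(frozen=True)
class StudyDataset:
    """An ordered per-cycle table plus dataset-level metadata.

    ``nonpreg_horizon`` is an optional ``(horizon_cycles, nonpreg_count)``
    pair recording how many women had still not conceived after a long
    follow-up horizon (kept as metadata, not a pseudo-cycle, because it is
    a different observation type from the per-cycle rows).

    ``allow_fractional`` marks datasets holding real-valued expected counts
    (produced by the deterministic generator for testing); integrality is
    then not enforced.
    """

    study_name: str
    n_initial: float
    cycles: tuple[CycleRecord, ...]
    nonpreg_horizon: tuple[int, float] | None = None
    allow_fractional: bool = False

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    @property
    def hcg_observed_cycles(self) -> frozenset[int]:
        return frozenset(r.cycle_index for r in self.cycles if r.preg_hcg is not None)

    def record(self, cycle_index: int) -> CycleRecord:
        return self.cycles[cycle_index - 1]


def _is_count(x: float, *, fractional_ok: bool) -> bool:
    if not math.isfinite(x) or x < 0:
        return False
    if fractional_ok:
        return True
    return abs(x - round(x)) <= 1e-9


def validate_dataset(dataset: StudyDataset) -> list[Violation]:
    """Check every record and dataset invariant; return findings, raise nothing.

    An empty list means the dataset is fully consistent.  Each violation
    pinpoints the first cycle at which it occurs.  ``preg_hcg < preg_clin``
    is only a warning: whether reported hCG counts include the clinical
    pregnancies is a study-reporting convention, and the model reads them
    as the superset.
    """
    out: list[Violation] = []
    frac = dataset.allow_fractional

    if not dataset.cycles:
        return [Violation("error", None, "dataset has no cycle records")]

    for pos, rec in enumerate(dataset.cycles):
        if rec.cycle_index != pos + 1:
            out.append(
                Violation(
                    "error",
                    rec.cycle_index,
                    f"cycle indices must be contiguous from 1; found {rec.cycle_index} at row {pos + 1}",
                )
            )
            break

    first = dataset.cycles[0]
    if abs(first.n_start - dataset.n_initial) > _CONSERVATION_TOL:
        out.append(
            Violation(
                "error",
                1,
                f"n_start of cycle 1 ({first.n_start}) != n_initial ({dataset.n_initial})",
            )
        )

    for rec in dataset.cycles:
        counts = {
            "n_start": rec.n_start,
            "preg_clin": rec.preg_clin,
            "finished": rec.finished,
            "dropped": rec.dropped,
        }
        if rec.preg_hcg is not None:
            counts["preg_hcg"] = rec.preg_hcg
        bad = [name for name, v in counts.items() if not _is_count(v, fractional_ok=frac)]
        if bad:
            out.append(
                Violation(
                    "error",
                    rec.cycle_index,
                    f"cycle {rec.cycle_index}: non-negative integral count required for {', '.join(bad)}",
                )
            )
            continue
        if rec.preg_clin > rec.n_start + _CONSERVATION_TOL:
            out.append(
                Violation(
                    "error",
                    rec.cycle_index,
                    f"cycle {rec.cycle_index}: preg_clin ({rec.preg_clin}) exceeds n_start ({rec.n_start})",
                )
            )
        if rec.preg_hcg is not None:
            if rec.preg_hcg > rec.n_start + _CONSERVATION_TOL:
                out.append(
                    Violation(
                        "error",
                        rec.cycle_index,
                        f"cycle {rec.cycle_index}: preg_hcg ({rec.preg_hcg}) exceeds n_start ({rec.n_start})",
                    )
                )
            elif rec.preg_hcg < rec.preg_clin - _CONSERVATION_TOL:
                out.append(
                    Violation(
                        "warning",
                        rec.cycle_index,
                        f"cycle {rec.cycle_index}: preg_hcg ({rec.preg_hcg}) < preg_clin "
                        f"({rec.preg_clin}); hCG counts are normally the superset",
                    )
                )

    for prev, nxt in zip(dataset.cycles, dataset.cycles[1:]):
        implied = prev.n_start - prev.preg_clin - prev.finished - prev.dropped
        if abs(nxt.n_start - implied) > _CONSERVATION_TOL:
            out.append(
                Violation(
                    "error",
                    nxt.cycle_index,
                    f"cycle {nxt.cycle_index}: n_start ({nxt.n_start}) breaks conservation; "
                    f"cycle {prev.cycle_index} implies {implied}",
                )
            )
            break

    if dataset.nonpreg_horizon is not None:
        horizon, count = dataset.nonpreg_horizon
        if horizon < dataset.n_cycles:
            out.append(
                Violation(
                    "error",
                    None,
                    f"nonpreg horizon ({horizon} cycles) shorter than the reported table "
                    f"({dataset.n_cycles} cycles)",
                )
            )
        if not _is_count(count, fractional_ok=frac):
            out.append(Violation("error", None, f"nonpreg count ({count}) is not a valid count"))

    return out


def _read_metadata(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped.startswith("#"):
                break
            body = stripped.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    return meta


def read_study_csv(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> StudyDataset:
    """Read a per-cycle study table.

    ``column_map`` maps canonical names (:data:`CANONICAL_COLUMNS`) to the
    column names actually used in the file, for foreign layouts; columns
    not mentioned are looked up under their canonical names.  Empty cells
    in the hCG column are recorded as unobserved (``None``), never as zero.

    Raises :class:`SchemaError` for unresolvable columns,
    :class:`DataFormatError` for empty files, malformed counts (with the
    offending row number) or any hard invariant violation.
    """
    path = Path(path)
    meta = _read_metadata(path)
    try:
        frame = pd.read_csv(path, comment="#", skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise DataFormatError(f"{path}: file contains no table") from None
    if frame.empty:
        raise DataFormatError(f"{path}: table has a header but no data rows")

    resolved: dict[str, str] = {}
    for canon in CANONICAL_COLUMNS:
        name = (column_map or {}).get(canon, canon)
        if name not in frame.columns:
            raise SchemaError(f"{path}: required column {name!r} (for {canon!r}) not found")
        resolved[canon] = name

    fractional = meta.get("allow_fractional", "false").lower() in ("true", "1", "yes")
    records: list[CycleRecord] = []
    for row_number, (_, row) in enumerate(frame.iterrows(), start=2):
        values: dict[str, float | None] = {}
        for canon in CANONICAL_COLUMNS:
            raw = row[resolved[canon]]
            if canon == "preg_hcg" and (pd.isna(raw) or str(raw).strip() == ""):
                values[canon] = None
                continue
            try:
                value = float(raw)
            except (TypeError, ValueError):
                raise DataFormatError(
                    f"{path}: row {row_number}: non-numeric value {raw!r} in column {resolved[canon]!r}"
                ) from None
            if not _is_count(value, fractional_ok=fractional):
                raise DataFormatError(
                    f"{path}: row {row_number}: column {resolved[canon]!r} must be a "
                    f"non-negative{'' if fractional else ' integral'} count, got {raw!r}"
                )
            values[canon] = value
        records.append(
            CycleRecord(
                cycle_index=int(values["cycle"]),
                n_start=values["n_start"],
                preg_hcg=values["preg_hcg"],
                preg_clin=values["preg_clin"],
                finished=values["finished"],
                dropped=values["dropped"],
            )
        )

    horizon = None
    if "nonpreg_horizon_cycles" in meta or "nonpreg_count" in meta:
        try:
            horizon = (int(meta["nonpreg_horizon_cycles"]), float(meta["nonpreg_count"]))
        except (KeyError, ValueError):
            raise DataFormatError(
                f"{path}: horizon metadata requires integer '# nonpreg_horizon_cycles:' and "
                "numeric '# nonpreg_count:' comment lines"
            ) from None

    dataset = StudyDataset(
        study_name=meta.get("study_name", path.stem),
        n_initial=records[0].n_start,
        cycles=tuple(records),
        nonpreg_horizon=horizon,
        allow_fractional=fractional,
    )
    errors = [v for v in validate_dataset(dataset) if v.severity == "error"]
    if errors:
        raise DataFormatError(f"{path}: {errors[0].message}")
    return dataset


def _fmt(value: float | None) -> str:
    if value is None:
        return ""
    if abs(value - round(value)) <= 1e-9:
        return str(int(round(value)))
    return repr(value)


def write_study_csv(dataset: StudyDataset, path: str | Path) -> None:
    """Write a dataset so that :func:`read_study_csv` maps it back identically.

    Metadata goes into leading ``#`` comment lines; unobserved hCG cells
    are written empty.  Refuses to write a dataset with hard violations or
    an empty cycle list.
    """
    if not dataset.cycles:
        raise DataFormatError("refusing to write a dataset with no cycle records")
    errors = [v for v in validate_dataset(dataset) if v.severity == "error"]
    if errors:
        raise DataFormatError(f"refusing to write invalid dataset: {errors[0].message}")

    path = Path(path)
    lines = [f"# study_name: {dataset.study_name}"]
    if dataset.allow_fractional:
        lines.append("# allow_fractional: true")
    if dataset.nonpreg_horizon is not None:
        horizon, count = dataset.nonpreg_horizon
        lines.append(f"# nonpreg_horizon_cycles: {horizon}")
        lines.append(f"# nonpreg_count: {_fmt(count)}")
    lines.append(",".join(CANONICAL_COLUMNS))
    for rec in dataset.cycles:
        lines.append(
            ",".join(
                [
                    str(rec.cycle_index),
                    _fmt(rec.n_start),
                    _fmt(rec.preg_hcg),
                    _fmt(rec.preg_clin),
                    _fmt(rec.finished),
                    _fmt(rec.dropped),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
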