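"""CSV readers/writers for motility and fertilisation tables, plus reports.

Dialect: plain UTF-8 comma-separated files with a header row.  Treatment
and cross labels are case-insensitive on read and canonical on write.
Proportions are never stored — every proportion downstream is computed
from the integer counts kept here, so binomial denominators are exact.

Validation never silently drops rows: structural problems raise typed
errors naming the offending column/row/identifier, and soft problems
(kinematic ordering violations) are logged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import is_dataclass
from pathlib import Path
from typing import Iterable, List, Sequence, Union

import numpy as np
import pandas as pd

from .records import (
    CROSSES,
    TREATMENTS,
    FertilisationTrial,
    MotilitySample,
    ValidationError,
    record_to_dict,
)

log = logging.getLogger("spermcomp.io")

MOTILITY_COLUMNS = [
    "male_id", "treatment", "motile_count", "total_count",
    "vap", "vsl", "vcl", "str", "lin", "alh", "bcf",
]
FERTILISATION_COLUMNS = [
    "pair_id", "cross", "eggs_scored", "fertilised_count", "labelled_count",
]

# short spellings accepted on read for the cross column
_CROSS_ALIASES = {
    "a": "A_focal_dyed", "b": "B_rival_dyed", "c": "C_undyed",
    "a_focal_dyed": "A_focal_dyed", "b_rival_dyed": "B_rival_dyed",
    "c_undyed": "C_undyed",
}


class TableFormatError(ValueError):
    """The file does not match the expected CSV dialect."""


class ParseError(ValueError):
    """A cell could not be parsed; the message carries the row number."""


class PairingError(ValueError):
    """A male is missing one of its two treatments (or appears twice in one)."""


class CompletenessError(ValueError):
    """A pair is missing one of crosses A, B, C."""


class DuplicationError(ValueError):
    """Duplicate (pair_id, cross) or (male_id, treatment) rows."""


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {', '.join(missing)}")


def _to_int(value, row: int, column: str):
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise ParseError(f"row {row}: non-numeric {column} value {value!r}") from None
    if not float(f).is_integer():
        raise ParseError(f"row {row}: {column} value {value!r} is not an integer")
    return int(f)


def _to_float(value, row: int, column: str) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ParseError(f"row {row}: non-numeric {column} value {value!r}") from None


def read_motility_table(path) -> List[MotilitySample]:
    """Read per-male, per-treatment CASA summaries.

    Raises :class:`PairingError` unless every male appears exactly once per
    treatment; logs a warning for rows violating the kinematic ordering
    VSL ≤ VCL, VAP ≤ VCL.
    """
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, MOTILITY_COLUMNS, path)
    samples: List[MotilitySample] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is row 1
        treatment = str(row.treatment).strip().lower()
        if treatment not in TREATMENTS:
            raise ParseError(f"row {i}: unknown treatment {row.treatment!r}")
        try:
            sample = MotilitySample(
                male_id=str(row.male_id).strip(),
                treatment=treatment,
                motile_count=_to_int(row.motile_count, i, "motile_count"),
                total_count=_to_int(row.total_count, i, "total_count"),
                vap=_to_float(row.vap, i, "vap"),
                vsl=_to_float(row.vsl, i, "vsl"),
                vcl=_to_float(row.vcl, i, "vcl"),
                str_ratio=_to_float(getattr(row, "str"), i, "str"),
                lin_ratio=_to_float(row.lin, i, "lin"),
                alh=_to_float(row.alh, i, "alh"),
                bcf=_to_float(row.bcf, i, "bcf"),
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from None
        if not sample.kinematic_ordering_ok():
            log.warning(
                "row %d: kinematic ordering violated (vap=%.3g vsl=%.3g vcl=%.3g) "
                "for male %s", i, sample.vap, sample.vsl, sample.vcl, sample.male_id,
            )
        samples.append(sample)

    seen = {}
    for s in samples:
        key = (s.male_id, s.treatment)
        if key in seen:
            raise DuplicationError(f"male {s.male_id!r} has duplicate {s.treatment} rows")
        seen[key] = s
    incomplete = sorted(
        {m for m, _ in seen}
        - {m for m in {m for m, _ in seen}
           if all((m, t) in seen for t in TREATMENTS)}
    )
    if incomplete:
        raise PairingError(
            "male(s) missing one treatment: " + ", ".join(incomplete)
        )
    return samples


def read_fertilisation_table(path) -> List[FertilisationTrial]:
    """Read per-pair fertilisation-trial egg counts (crosses A, B, C).

    ``labelled_count`` must be blank for cross C (no dyed sperm in that
    cross) and present otherwise.  Every pair must have exactly the three
    crosses.
    """
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, FERTILISATION_COLUMNS, path)
    trials: List[FertilisationTrial] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        raw_cross = str(row.cross).strip().lower()
        if raw_cross not in _CROSS_ALIASES:
            raise ParseError(f"row {i}: unknown cross {row.cross!r}")
        cross = _CROSS_ALIASES[raw_cross]
        labelled = row.labelled_count
        blank = labelled is None or (isinstance(labelled, float) and np.isnan(labelled)) \
            or str(labelled).strip() == "" or str(labelled).lower() == "nan"
        if cross == "C_undyed":
            if not blank:
                raise TableFormatError(
                    f"row {i}: labelled_count given for cross C (pair {row.pair_id!r})"
                )
            labelled_count = None
        else:
            if blank:
                raise TableFormatError(
                    f"row {i}: labelled_count missing for cross {cross} "
                    f"(pair {row.pair_id!r})"
                )
            labelled_count = _to_int(labelled, i, "labelled_count")
        try:
            trials.append(
                FertilisationTrial(
                    pair_id=str(row.pair_id).strip(),
                    cross=cross,
                    eggs_scored=_to_int(row.eggs_scored, i, "eggs_scored"),
                    fertilised_count=_to_int(row.fertilised_count, i, "fertilised_count"),
                    labelled_count=labelled_count,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from None

    seen = set()
    for t in trials:
        key = (t.pair_id, t.cross)
        if key in seen:
            raise DuplicationError(f"duplicate cross {t.cross} for pair {t.pair_id!r}")
        seen.add(key)
    pairs = {p for p, _ in seen}
    offenders = sorted(
        p for p in pairs if not all((p, c) in seen for c in CROSSES)
    )
    if offenders:
        raise CompletenessError(
            "pair(s) missing a cross: " + ", ".join(offenders)
        )
    return trials


def write_motility_table(samples: Iterable[MotilitySample], path) -> None:
    rows = [
        {
            "male_id": s.male_id, "treatment": s.treatment,
            "motile_count": s.motile_count, "total_count": s.total_count,
            "vap": repr(s.vap), "vsl": repr(s.vsl), "vcl": repr(s.vcl),
            "str": repr(s.str_ratio), "lin": repr(s.lin_ratio),
            "alh": repr(s.alh), "bcf": repr(s.bcf),
        }
        for s in samples
    ]
    pd.DataFrame(rows, columns=MOTILITY_COLUMNS).to_csv(path, index=False)


def write_fertilisation_table(trials: Iterable[FertilisationTrial], path) -> None:
    rows = [
        {
            "pair_id": t.pair_id, "cross": t.cross,
            "eggs_scored": t.eggs_scored, "fertilised_count": t.fertilised_count,
            "labelled_count": "" if t.labelled_count is None else t.labelled_count,
        }
        for t in trials
    ]
    pd.DataFrame(rows, columns=FERTILISATION_COLUMNS).to_csv(path, index=False)


def write_report(result, path: Union[str, Path]) -> Path:
    """Serialize a stage result.

    Tabular results (a PowerCurve, a list of records, a DataFrame) become
    CSV; everything else (fits, test results, nested summaries) becomes
    JSON with full float precision.  Returns the path written.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    from .records import PowerCurve  # local to avoid cycles in type checks

    if isinstance(result, PowerCurve):
        pd.DataFrame(
            result.to_records(),
            columns=["delta", "power", "mc_se", "n_converged"],
        ).to_csv(path.with_suffix(".csv"), index=False)
        return path.with_suffix(".csv")
    if isinstance(result, pd.DataFrame):
        result.to_csv(path.with_suffix(".csv"), index=False)
        return path.with_suffix(".csv")
    if isinstance(result, (list, tuple)):
        rows = [record_to_dict(r) if is_dataclass(r) else dict(r) for r in result]
        cols = list(rows[0]) if rows else []
        pd.DataFrame(rows, columns=cols or None).to_csv(path.with_suffix(".csv"), index=False)
        return path.with_suffix(".csv")

    payload = record_to_dict(result) if is_dataclass(result) else result
    out = path.with_suffix(".json")
    with open(out, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, default=str)
        fh.write("\n")
    return out
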