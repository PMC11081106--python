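"""Experimental-restraint template tables and the JSON results format.

Templates are comma-delimited tables with a header row, one schema per
datatype:

====== ==========================================================================
pre    ``res1,atom1,res2,atom2``
noe    ``res1,atom1,atom1_multiple_assignments,res2,atom2,atom2_multiple_assignments``
jc     ``resnum``
smfret ``res1,res2,scale``
====== ==========================================================================

NOE alternative-assignment cells hold zero or more extra atom names separated
by spaces or semicolons; a blank cell means no alternatives. Extra columns
(e.g. experimental values) are tolerated and preserved in the results echo
but never interpreted.

Results are written as human-readable JSON: a ``"format"`` key echoing the
template column-wise, then one key per conformer label mapping to the ordered
list of back-calculated values (4-decimal floats; ``null`` where the
missing-atom policy permitted a gap).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import InputError, SchemaError

DATATYPES = ("pre", "noe", "jc", "smfret")


@dataclass(frozen=True)
class PrePair:
    res1: int
    atom1: str
    res2: int
    atom2: str

    def __post_init__(self):
        if self.res1 == self.res2 and self.atom1 == self.atom2:
            raise SchemaError(f"pre pair is degenerate: {self}")


@dataclass(frozen=True)
class NoePair:
    res1: int
    atom1: str
    atom1_alts: tuple[str, ...]
    res2: int
    atom2: str
    atom2_alts: tuple[str, ...]

    @property
    def n_combinations(self) -> int:
        return (1 + len(self.atom1_alts)) * (1 + len(self.atom2_alts))


@dataclass(frozen=True)
class JcRecord:
    resnum: int

    def __post_init__(self):
        if self.resnum < 2:
            raise SchemaError(f"jc residue must be >= 2 (phi undefined at residue 1), got {self.resnum}")


@dataclass(frozen=True)
class SmfretPair:
    res1: int
    res2: int
    scale: float

    def __post_init__(self):
        if self.res1 == self.res2:
            raise SchemaError("smfret residues must differ")
        if not self.scale > 0:
            raise SchemaError(f"smfret scale factor must be positive, got {self.scale}")


@dataclass
class RestraintTemplate:
    datatype: str
    rows: list
    source: str = ""
    extra_columns: dict[str, list] = field(default_factory=dict)

    def __len__(self):
        return len(self.rows)

    def format_echo(self) -> dict[str, list]:
        """Column-oriented echo of the template, as written to results JSON."""
        echo: dict[str, list] = {}
        for col in _SCHEMAS[self.datatype]:
            echo[col] = [getattr(row, _FIELD_OF[col]) for row in self.rows]
            if col.endswith("_multiple_assignments"):
                echo[col] = [" ".join(v) for v in echo[col]]
        echo.update(self.extra_columns)
        return echo


@dataclass
class BackcalcResult:
    datatype: str
    format_echo: dict[str, list]
    per_conformer: dict[str, list]

    def __post_init__(self):
        lengths = {len(v) for v in self.format_echo.values()}
        n_rows = lengths.pop() if lengths else 0
        for label, values in self.per_conformer.items():
            if len(values) != n_rows:
                raise SchemaError(
                    f"{label}: {len(values)} values for {n_rows} template rows"
                )

    @property
    def n_rows(self) -> int:
        return len(next(iter(self.format_echo.values())))


_SCHEMAS = {
    "pre": ("res1", "atom1", "res2", "atom2"),
    "noe": ("res1", "atom1", "atom1_multiple_assignments",
            "res2", "atom2", "atom2_multiple_assignments"),
    "jc": ("resnum",),
    "smfret": ("res1", "res2", "scale"),
}
_FIELD_OF = {
    "res1": "res1", "atom1": "atom1", "res2": "res2", "atom2": "atom2",
    "atom1_multiple_assignments": "atom1_alts",
    "atom2_multiple_assignments": "atom2_alts",
    "resnum": "resnum", "scale": "scale",
}
_INT_COLUMNS = {"res1", "res2", "resnum"}


def _split_alts(cell) -> tuple[str, ...]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return ()
    text = str(cell).replace(";", " ").strip()
    return tuple(text.split()) if text else ()


def _parse_int(value, column: str, line: int) -> int:
    try:
        as_float = float(value)
        as_int = int(as_float)
        if as_int != as_float:
            raise ValueError
        return as_int
    except (TypeError, ValueError):
        raise SchemaError(
            f"line {line}: column {column!r} must be an integer residue number, got {value!r}"
        ) from None


def parse_template(path, datatype: str) -> RestraintTemplate:
    """Parse a comma-delimited template table for one datatype."""
    if datatype not in DATATYPES:
        raise SchemaError(f"unknown datatype {datatype!r}; expected one of {DATATYPES}")
    path = Path(path)
    if not path.is_file():
        raise InputError(f"cannot read template: {path}")
    try:
        df = pd.read_csv(path, skipinitialspace=True, dtype=str)
    except pd.errors.EmptyDataError:
        raise InputError(f"{path}: empty template") from None
    df.columns = [c.strip() for c in df.columns]

    required = _SCHEMAS[datatype]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r} for datatype {datatype}")
    if df.empty:
        raise InputError(f"{path}: template has a header but no rows")

    rows = []
    for i, rec in enumerate(df.to_dict("records")):
        line = i + 2  # header is line 1
        kwargs = {}
        for col in required:
            raw = rec[col]
            fieldname = _FIELD_OF[col]
            if col in _INT_COLUMNS:
                kwargs[fieldname] = _parse_int(raw, col, line)
            elif col.endswith("_multiple_assignments"):
                kwargs[fieldname] = _split_alts(raw)
            elif col == "scale":
                try:
                    kwargs[fieldname] = float(raw)
                except (TypeError, ValueError):
                    raise SchemaError(f"line {line}: scale must be numeric, got {raw!r}") from None
            else:
                kwargs[fieldname] = str(raw).strip()
        rows.append(_ROW_TYPES[datatype](**kwargs))

    extra = {
        col: df[col].tolist() for col in df.columns if col not in required
    }
    return RestraintTemplate(datatype=datatype, rows=rows, source=str(path), extra_columns=extra)


_ROW_TYPES = {"pre": PrePair, "noe": NoePair, "jc": JcRecord, "smfret": SmfretPair}


def write_template(template: RestraintTemplate, path) -> Path:
    """Serialize a template back to its CSV schema (inverse of parse)."""
    echo = template.format_echo()
    pd.DataFrame(echo).to_csv(path, index=False)
    return Path(path)


def _round4(value):
    return None if value is None else round(float(value), 4)


def write_results_json(result: BackcalcResult, path) -> Path:
    """Write a results JSON: {"format": <echo>, "<label>": [values...], ...}.

    Conformer keys keep ensemble order; floats carry 4 decimal places.
    """
    payload: dict = {"format": result.format_echo}
    for label, values in result.per_conformer.items():
        payload[label] = [_round4(v) for v in values]
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path


def read_results_json(path, datatype: str = "") -> BackcalcResult:
    """Read a results JSON written by :func:`write_results_json`."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise InputError(f"{path}: unreadable results JSON ({exc})") from exc
    if "format" not in payload:
        raise SchemaError(f"{path}: results JSON lacks the 'format' key")
    echo = payload.pop("format")
    return BackcalcResult(datatype=datatype, format_echo=echo, per_conformer=payload)
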