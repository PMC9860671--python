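"""Delimited-table readers/writers and run configuration.

All tables are comma-separated, dot-decimal, UTF-8, with a header row
and ISO 8601 dates. Readers validate the header against a registered
schema and report parse failures with the offending row and column.
Report writers always emit full-precision values alongside the
presentation-rounded ones so downstream consumers never depend on
display rounding.
"""

from __future__ import annotations

import csv
import dataclasses
import datetime as dt
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Sequence

import pandas as pd

from .exceptions import InvalidInputError, SchemaError
from .qc import QCVerdict
from .stability import AnovaResult

__all__ = [
    "RunConfig",
    "SCHEMAS",
    "read_table",
    "detect_masses_schema",
    "round_half_up",
    "render_report",
    "fit_to_json",
    "fit_from_json",
]


@dataclass(frozen=True)
class RunConfig:
    """Run-wide knobs: compliance tolerance (%), ANOVA level, the
    procedural dilution factor, presentation rounding digits and an
    optional seed for simulation subcommands."""

    tolerance_pct: float = 10.0
    alpha: float = 0.05
    dilution_factor: float = 10.0
    rounding: int = 4
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.tolerance_pct <= 0:
            raise InvalidInputError("tolerance must be > 0")
        if not 0 < self.alpha < 1:
            raise InvalidInputError("alpha must be in (0, 1)")
        if self.dilution_factor <= 0:
            raise InvalidInputError("dilution factor must be > 0")


# column -> parser; None means keep as string
_FLOAT = "float"
_INT = "int"
_DATE = "date"
_STR = "str"

SCHEMAS: dict[str, dict[str, str]] = {
    "calibration_points": {
        "level_id": _STR,
        "concentration_mmol_L": _FLOAT,
        "absorbance": _FLOAT,
    },
    "absorbances": {
        "sample_id": _STR,
        "absorbance": _FLOAT,
        "replicates": _INT,
    },
    "tubes_meta": {
        "label": _STR,
        "nominal_conc_mmol_L": _FLOAT,
        "nominal_ac_volume_mL": _FLOAT,
        "nominal_draw_volume_mL": _FLOAT,
        "expiration_date": _DATE,
        "buffered": _INT,
    },
    "determinations": {
        "label": _STR,
        "kind": _STR,
        "concentration_mmol_L": _FLOAT,
        "flask_volume_mL": _FLOAT,
        "tube_count": _INT,
        "added_volume_mL": _FLOAT,
    },
    "masses_raw": {
        "tube_type": _STR,
        "date": _DATE,
        "replicate": _INT,
        "mass_g": _FLOAT,
    },
    "masses_summary": {
        "tube_type": _STR,
        "date": _STR,
        "count": _INT,
        "sum": _FLOAT,
        "mean": _FLOAT,
        "variance": _FLOAT,
    },
    "draw_volumes": {
        "tube_type": _STR,
        "date": _DATE,
        "volume_mL": _FLOAT,
    },
}


def _parse_cell(raw: str, kind: str, path: Path, row: int, col: str) -> Any:
    raw = raw.strip()
    if raw == "":
        return None
    try:
        if kind == _FLOAT:
            # dot-decimal dialect: a comma decimal mark must fail loudly
            return float(raw)
        if kind == _INT:
            return int(raw)
        if kind == _DATE:
            return dt.date.fromisoformat(raw)
        return raw
    except ValueError as exc:
        raise SchemaError(
            f"{path}: row {row}, column {col!r}: cannot parse {raw!r} as {kind} "
            f"(dialect is comma-separated, dot-decimal, ISO 8601 dates)"
        ) from exc


def read_table(path: str | Path, schema_name: str) -> list[dict[str, Any]]:
    """Read and validate one CSV table against a registered schema.

    Returns one dict per row with typed values (floats, ints, dates);
    empty cells become None. Row numbers in error messages count the
    header as row 1.
    """
    path = Path(path)
    if schema_name not in SCHEMAS:
        raise SchemaError(
            f"unknown schema {schema_name!r}; registered: {sorted(SCHEMAS)}"
        )
    schema = SCHEMAS[schema_name]
    if not path.exists():
        raise InvalidInputError(f"no such file: {path}")
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in schema if c not in header]
        if missing:
            raise SchemaError(
                f"{path}: header {header} does not match schema "
                f"{schema_name!r}; missing columns {missing} "
                f"(expected {list(schema)})"
            )
        records = []
        for i, row in enumerate(reader, start=2):
            records.append(
                {
                    col: _parse_cell(row[col] or "", kind, path, i, col)
                    for col, kind in schema.items()
                }
            )
    return records


def detect_masses_schema(path: str | Path) -> str:
    """Auto-detect whether a masses table is raw weighings or per-date
    summaries, by header."""
    with Path(path).open(newline="", encoding="utf-8") as fh:
        header = next(csv.reader(fh), [])
    if "mass_g" in header:
        return "masses_raw"
    if "variance" in header:
        return "masses_summary"
    raise SchemaError(
        f"{path}: header {header} matches neither the raw masses schema "
        f"({list(SCHEMAS['masses_raw'])}) nor the summary schema "
        f"({list(SCHEMAS['masses_summary'])})"
    )


def round_half_up(value: float, digits: int) -> float:
    """Decimal round-half-up, the convention of printed report tables
    (plain ``round`` rounds half to even and is binary-float hostile)."""
    if not math.isfinite(value):
        return value
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


_ROUNDING = {
    # presentation digits per verdict column
    "amount_per_tube": 1,
    "expected_amount": 1,
    "amount_bias_pct": 1,
    "ac_volume": 3,
    "ac_volume_bias_pct": 1,
    "conc_at_nominal_total": 1,
    "expected_conc": 1,
    "determined_conc": 1,
    "conc_bias_pct": 1,
}


def verdicts_frame(verdicts: Sequence[QCVerdict]) -> pd.DataFrame:
    """Verdicts as a DataFrame with full-precision columns plus
    ``*_rounded`` presentation columns."""
    cols = [f.name for f in dataclasses.fields(QCVerdict) if f.name != "warnings"]
    data = {c: [getattr(v, c) for v in verdicts] for c in cols}
    data["warnings"] = ["; ".join(v.warnings) for v in verdicts]
    df = pd.DataFrame(data)
    for col, digits in _ROUNDING.items():
        df[f"{col}_rounded"] = [round_half_up(x, digits) for x in df[col]]
    return df


def _anova_to_dict(name: str, res: AnovaResult) -> dict[str, Any]:
    return {
        "tube_type": name,
        "f_statistic": res.f_statistic,
        "df_between": res.df_between,
        "df_within": res.df_within,
        "ms_between": res.ms_between,
        "ms_within": res.ms_within,
        "p_value": res.p_value,
        "f_critical": res.f_critical,
        "alpha": res.alpha,
        "significant": res.significant,
        "lsd": res.lsd,
        "letters": dict(res.letters),
        "group_means": dict(res.group_means),
        "significant_pairs": sorted(list(p) for p in res.significant_pairs),
        "degenerate": res.degenerate,
    }


def render_report(
    verdicts: Sequence[QCVerdict],
    anova_results: dict[str, AnovaResult] | None = None,
    config: RunConfig | None = None,
    csv_path: str | Path | None = None,
    json_path: str | Path | None = None,
) -> dict[str, Any]:
    """Assemble (and optionally write) the QC report.

    The CSV mirrors the verdict table; the JSON additionally carries
    the ANOVA results, the run configuration and the warning list. The
    returned dict is the JSON document.
    """
    config = config or RunConfig()
    df = verdicts_frame(verdicts)
    if csv_path is not None:
        df.to_csv(csv_path, index=False)
    doc: dict[str, Any] = {
        "config": dataclasses.asdict(config),
        "verdicts": df.to_dict(orient="records"),
        "warnings": [w for v in verdicts for w in v.warnings],
    }
    if anova_results:
        doc["anova"] = [
            _anova_to_dict(name, res) for name, res in anova_results.items()
        ]
    if json_path is not None:
        Path(json_path).write_text(json.dumps(doc, indent=2), encoding="utf-8")
    return doc


def fit_to_json(fit: Any, path: str | Path) -> None:
    """Serialize a CalibrationFit to JSON."""
    Path(path).write_text(
        json.dumps(dataclasses.asdict(fit), indent=2), encoding="utf-8"
    )


def fit_from_json(path: str | Path):
    """Load a CalibrationFit written by :func:`fit_to_json`."""
    from .calibration import CalibrationFit

    data = json.loads(Path(path).read_text(encoding="utf-8"))
    return CalibrationFit(**data)
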