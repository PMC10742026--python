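"""Reading and writing screen tables in the raw and prefitted dialects.

The raw dialect has per-row concentration columns ``C0..C10`` (micromolar)
and matched response columns ``dat0..dat10`` (% of DMSO control).  The
prefitted dialect carries deposited 4PL parameters: ``LAC50`` (log10
molar AC50), ``R2``, ``TAUC``, ``INF`` and ``ZERO``.  Headers are matched
case-insensitively and can be remapped via ``column_map``.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .types import (
    MAX_POINTS,
    CompoundSummary,
    DoseResponseSeries,
    PairwiseDelta,
    PrefittedRecord,
    ScreenTable,
)

# canonical key -> accepted header spellings (lower-cased)
_DEFAULT_ALIASES: dict[str, tuple[str, ...]] = {
    "compound": ("drug name", "drug_name", "drug", "compound", "compound_id", "name"),
    "cell_line": ("cell line name", "cell_line_name", "cell line", "cell_line", "cellline", "cell_line_id"),
    "target": ("drug target", "drug_target", "target", "target_annotation"),
    "lac50": ("lac50", "log_ac50", "logac50"),
    "r2": ("r2", "r^2", "rsq"),
    "tauc": ("tauc", "auc"),
    "asym_inf": ("inf", "asym_inf", "asymptote_min"),
    "asym_zero": ("zero", "asym_zero", "asymptote_max"),
}


def lac50_to_ac50_um(lac50: float) -> float:
    """Convert a log10-molar AC50 to AC50 in micromolar: ``10**(lac50 + 6)``."""
    if lac50 is None or not math.isfinite(lac50):
        raise ValueError("lac50 must be finite; absent fits carry a no-fit flag, not a sentinel")
    return 10.0 ** (lac50 + 6.0)


def ac50_um_to_lac50(ac50_um: float) -> float:
    """Inverse of :func:`lac50_to_ac50_um`."""
    if ac50_um is None or not (math.isfinite(ac50_um) and ac50_um > 0):
        raise ValueError("ac50_um must be finite and positive")
    return math.log10(ac50_um) - 6.0


def _normalize_columns(
    columns: Sequence[str], column_map: Optional[Mapping[str, str]]
) -> dict[str, str]:
    """Map canonical keys to the actual header names of *columns*."""
    lower = {c.strip().lower(): c for c in columns}
    out: dict[str, str] = {}
    cmap = {k.lower(): v for k, v in (column_map or {}).items()}
    for key, aliases in _DEFAULT_ALIASES.items():
        if key in cmap:
            if cmap[key].strip().lower() in lower:
                out[key] = lower[cmap[key].strip().lower()]
            continue
        for alias in aliases:
            if alias in lower:
                out[key] = lower[alias]
                break
    # point columns C0..C10 / dat0..dat10
    for i in range(MAX_POINTS):
        for key, alias in ((f"c{i}", f"c{i}"), (f"dat{i}", f"dat{i}")):
            if key in cmap:
                if cmap[key].strip().lower() in lower:
                    out[key] = lower[cmap[key].strip().lower()]
            elif alias in lower:
                out[key] = lower[alias]
    return out


def _detect_dialect(colmap: Mapping[str, str]) -> str:
    if "lac50" in colmap:
        return "prefitted"
    if "c0" in colmap and "dat0" in colmap:
        return "raw"
    raise ValueError(
        "cannot detect dialect: header has neither a LAC50 column (prefitted) "
        "nor C0/dat0 columns (raw)"
    )


def _opt_float(value) -> Optional[float]:
    if value is None:
        return None
    try:
        v = float(value)
    except (TypeError, ValueError):
        return None
    return v if math.isfinite(v) else None


def read_screen_table(
    path: Union[str, Path],
    dialect: str = "auto",
    column_map: Optional[Mapping[str, str]] = None,
    delimiter: Optional[str] = None,
    reference: Optional[str] = None,
    test_lines: Optional[Iterable[str]] = None,
) -> ScreenTable:
    """Parse a delimited screen table into a validated :class:`ScreenTable`.

    Dialect is auto-detected from the header unless forced.  Every parse
    anomaly is recorded in ``table.warnings`` with the offending row;
    rows with no usable data are excluded and counted in
    ``table.n_rejected``.  Duplicate (compound, cell line) keys raise.
    """
    path = Path(path)
    sep = delimiter if delimiter is not None else None
    df = pd.read_csv(path, sep=sep, engine="python")
    colmap = _normalize_columns(df.columns, column_map)
    if dialect == "auto":
        dialect = _detect_dialect(colmap)
    elif dialect == "prefitted" and "lac50" not in colmap:
        raise ValueError("prefitted dialect requires a LAC50 column")
    elif dialect == "raw" and ("c0" not in colmap or "dat0" not in colmap):
        raise ValueError("raw dialect requires C0 and dat0 columns")
    elif dialect not in ("raw", "prefitted"):
        raise ValueError(f"unknown dialect {dialect!r}")

    for required in ("compound", "cell_line"):
        if required not in colmap:
            raise ValueError(f"missing required column: {required}")

    table = ScreenTable(dialect=dialect, source=str(path))
    duplicates: list[tuple[str, str]] = []
    for idx, row in df.iterrows():
        compound = str(row[colmap["compound"]]).strip()
        cell_line = str(row[colmap["cell_line"]]).strip()
        if not compound or compound == "nan" or not cell_line or cell_line == "nan":
            table.warnings.append(f"row {idx}: missing compound or cell line id")
            table.n_rejected += 1
            continue
        target = None
        if "target" in colmap:
            t = row[colmap["target"]]
            target = None if pd.isna(t) else str(t).strip()
        key = (compound, cell_line)
        if key in table.records:
            duplicates.append(key)
            continue
        if dialect == "prefitted":
            record = PrefittedRecord(
                compound_id=compound,
                cell_line_id=cell_line,
                target_annotation=target,
                lac50=_opt_float(row.get(colmap.get("lac50"))),
                r2=_opt_float(row.get(colmap.get("r2"))),
                tauc=_opt_float(row.get(colmap.get("tauc"))),
                asym_inf=_opt_float(row.get(colmap.get("asym_inf"))),
                asym_zero=_opt_float(row.get(colmap.get("asym_zero"))),
            )
            if not any(
                getattr(record, f) is not None
                for f in ("lac50", "r2", "tauc", "asym_inf", "asym_zero")
            ):
                table.warnings.append(f"row {idx} ({compound}/{cell_line}): no usable data")
                table.n_rejected += 1
                continue
            table.records[key] = record
        else:
            conc, resp = [], []
            for i in range(MAX_POINTS):
                ckey, dkey = colmap.get(f"c{i}"), colmap.get(f"dat{i}")
                if ckey is None or dkey is None:
                    continue
                c, r = _opt_float(row[ckey]), _opt_float(row[dkey])
                if c is None or r is None:
                    continue  # pairwise drop of incomplete points
                conc.append(c)
                resp.append(r)
            try:
                series = DoseResponseSeries(
                    compound_id=compound,
                    cell_line_id=cell_line,
                    concentrations=tuple(conc),
                    responses=tuple(resp),
                    target_annotation=target,
                )
            except ValueError as exc:
                table.warnings.append(f"row {idx}: {exc}")
                table.n_rejected += 1
                continue
            table.records[key] = series

    if duplicates:
        raise ValueError(
            "duplicate (compound, cell line) keys: "
            + ", ".join(f"{c}/{l}" for c, l in sorted(set(duplicates)))
        )

    if reference is not None:
        table.roles[reference] = "reference"
    if test_lines is not None:
        for line in test_lines:
            table.roles.setdefault(line, "test")
    for line in table.cell_lines:
        table.roles.setdefault(line, "test" if reference is not None else "other")
    return table


# ---------------------------------------------------------------------------
# writing

_LAYOUTS = {
    "per_cell_line": [
        "compound", "target", "reference_cell_line", "test_cell_line",
        "delta_s", "delta_pac50", "delta_pauc", "call", "reason",
    ],
    "per_compound_summary": [
        "compound", "target", "ds_mean", "ds_variance", "ds_variance_of_mean",
        "n_lines", "verdict",
    ],
    "rank_comparison": [
        "compound", "ds_mean", "dpac50_mean", "dpauc_mean",
        "rank_ds_mean", "rank_dpac50_mean", "rank_dpauc_mean",
    ],
    "prefitted": [
        "cell line name", "drug name", "drug target", "LAC50", "R2", "TAUC",
        "INF", "ZERO",
    ],
}


def _rows_to_frame(records, layout: str) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    rows = []
    for rec in records:
        if isinstance(rec, PairwiseDelta):
            rows.append({
                "compound": rec.compound_id,
                "target": rec.target_annotation,
                "reference_cell_line": rec.reference_cell_line,
                "test_cell_line": rec.test_cell_line,
                "delta_s": rec.delta_s,
                "delta_pac50": rec.delta_pac50,
                "delta_pauc": rec.delta_pauc,
                "call": rec.call,
                "reason": rec.reason,
            })
        elif isinstance(rec, CompoundSummary):
            rows.append({
                "compound": rec.compound_id,
                "target": rec.target_annotation,
                "ds_mean": rec.ds_mean,
                "ds_variance": rec.ds_variance,
                "ds_variance_of_mean": rec.ds_variance_of_mean,
                "n_lines": rec.n_lines,
                "verdict": rec.verdict,
            })
        elif isinstance(rec, dict):
            rows.append(rec)
        else:
            raise TypeError(f"cannot serialize {type(rec).__name__} records")
    columns = _LAYOUTS[layout]
    return pd.DataFrame(rows, columns=columns) if rows else pd.DataFrame(columns=columns)


def write_results(
    records,
    path: Union[str, Path],
    layout: str = "per_compound_summary",
    precision: int = 2,
    allow_empty: bool = False,
) -> Path:
    """Write scored or summary records as CSV with a deterministic column order.

    Floats are rendered at a fixed *precision* (default 2 decimals).
    An empty record set is an error unless ``allow_empty`` is set, in
    which case a header-only file is written.
    """
    if layout not in _LAYOUTS:
        raise ValueError(f"unknown layout {layout!r}; expected one of {sorted(_LAYOUTS)}")
    df = _rows_to_frame(records, layout)
    if df.empty and not allow_empty:
        raise ValueError("refusing to write an empty table without allow_empty=True")
    ordered = [c for c in _LAYOUTS[layout] if c in df.columns]
    ordered += [c for c in df.columns if c not in ordered]
    df = df[ordered]
    path = Path(path)
    df.to_csv(path, index=False, float_format=f"%.{precision}f")
    return path


def prefitted_frame(fits: Iterable, screen: Optional[ScreenTable] = None) -> pd.DataFrame:
    """Assemble a prefitted-dialect DataFrame from (series, CurveFit4PL) pairs."""
    rows = []
    for series, fit in fits:
        rows.append({
            "cell line name": series.cell_line_id,
            "drug name": series.compound_id,
            "drug target": series.target_annotation,
            "LAC50": fit.lac50 if fit.converged else np.nan,
            "R2": fit.r2 if fit.r2 is not None else np.nan,
            "TAUC": fit.auc if fit.auc is not None else np.nan,
            "INF": fit.asym_inf if fit.converged else np.nan,
            "ZERO": fit.asym_zero if fit.converged else np.nan,
        })
    return pd.DataFrame(rows, columns=_LAYOUTS["prefitted"])
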