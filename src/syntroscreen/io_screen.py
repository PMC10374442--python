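"""Readers and writers for plate-reader exports, layouts and result tables.

Two generic reader dialects are supported and auto-detected:

* **wide** — a matrix with row letters down the first column and column
  numbers across the header (8x12 or 16x24);
* **long** — a two-column table with ``well`` and ``value`` headers.

Everything downstream works on a *tidy* table with one row per
(well, time) observation. All files are plain CSV/TSV; no vendor binary
formats.
"""

from __future__ import annotations

import csv
import io
import logging
import os
from typing import Iterable, Sequence, TextIO

import pandas as pd

from .plate_model import (
    Condition,
    Config,
    PLATE_SHAPES,
    StrainRecord,
    WellObservation,
    well_index,
    well_label,
)

logger = logging.getLogger(__name__)

TIDY_COLUMNS = [
    "plate_id",
    "batch",
    "well",
    "row",
    "col",
    "condition_id",
    "kind",
    "strain_1",
    "strain_2",
    "time",
    "od600",
]


class ParseError(ValueError):
    """Malformed plate export; the message names the offending cell."""


class ConsistencyError(ValueError):
    """Layout, condition and strain tables disagree."""


def _as_text_rows(source: str | os.PathLike | TextIO) -> list[list[str]]:
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    sample = text[:4096]
    delim = "\t" if sample.count("\t") > sample.count(",") else ","
    rows = [row for row in csv.reader(io.StringIO(text), delimiter=delim)]
    return [r for r in rows if any(cell.strip() for cell in r)]


def _parse_number(cell: str, where: str) -> float | None:
    cell = cell.strip()
    if cell == "" or cell.upper() in {"NA", "NAN"}:
        return None
    try:
        return float(cell)
    except ValueError:
        raise ParseError(f"non-numeric value {cell!r} at {where}")


def read_plate_matrix(
    source: str | os.PathLike | TextIO,
    plate_id: str,
    time: float,
    batch: str = "",
) -> list[WellObservation]:
    """Parse one plate export (wide matrix or long table) at one timepoint.

    Returns one :class:`WellObservation` per non-empty well; empty cells
    are treated as missing, never as zero. Raises :class:`ParseError` with
    the offending cell named for ragged matrices, non-numeric cells or
    duplicate wells in long form.
    """
    rows = _as_text_rows(source)
    if not rows:
        raise ParseError(f"{plate_id}: empty plate file")

    header = [c.strip().lower() for c in rows[0]]
    if "well" in header and "value" in header:
        return _read_long(rows, header, plate_id, time, batch)
    return _read_wide(rows, plate_id, time, batch)


def _read_wide(
    rows: list[list[str]], plate_id: str, time: float, batch: str
) -> list[WellObservation]:
    header = rows[0]
    body = rows[1:]
    n_rows = len(body)
    shapes = {shape: fmt for fmt, shape in PLATE_SHAPES.items()}
    widths = {len(r) - 1 for r in body}
    if len(widths) != 1:
        raise ParseError(f"{plate_id}: ragged matrix (row widths {sorted(widths)})")
    n_cols = widths.pop()
    if (n_rows, n_cols) not in shapes:
        raise ParseError(
            f"{plate_id}: matrix shape {n_rows}x{n_cols} is neither 8x12 nor 16x24"
        )
    plate_format = shapes[(n_rows, n_cols)]
    # header column numbers, when present, must be 1..n_cols
    head_nums = [c.strip() for c in header[1:] if c.strip()]
    if head_nums and head_nums != [str(i + 1) for i in range(n_cols)]:
        raise ParseError(f"{plate_id}: unexpected column header {head_nums[:5]}...")

    observations: list[WellObservation] = []
    for r_i, row in enumerate(body):
        letter = row[0].strip()
        label0 = well_label(r_i, 0, plate_format)
        if letter and letter.upper() != label0[0]:
            raise ParseError(
                f"{plate_id}: row label {letter!r} where {label0[0]!r} expected"
            )
        for c_i, cell in enumerate(row[1:]):
            label = well_label(r_i, c_i, plate_format)
            value = _parse_number(cell, f"{plate_id} well {label}")
            if value is None:
                continue
            observations.append(
                WellObservation(
                    plate_id=plate_id,
                    batch=batch,
                    row=r_i,
                    col=c_i,
                    od600={float(time): value},
                )
            )
    return observations


def _read_long(
    rows: list[list[str]], header: list[str], plate_id: str, time: float, batch: str
) -> list[WellObservation]:
    iw, iv = header.index("well"), header.index("value")
    n_rows = max(
        (well_index(r[iw], 384)[0] for r in rows[1:] if r[iw].strip()), default=0
    )
    n_cols = max(
        (well_index(r[iw], 384)[1] for r in rows[1:] if r[iw].strip()), default=0
    )
    plate_format = 96 if n_rows < 8 and n_cols < 12 else 384
    seen: set[str] = set()
    observations: list[WellObservation] = []
    for r in rows[1:]:
        label = r[iw].strip().upper()
        if not label:
            continue
        if label in seen:
            raise ParseError(f"{plate_id}: duplicate well {label} in long-form table")
        seen.add(label)
        value = _parse_number(r[iv], f"{plate_id} well {label}")
        if value is None:
            continue
        row_i, col_i = well_index(label, plate_format)
        observations.append(
            WellObservation(
                plate_id=plate_id,
                batch=batch,
                row=row_i,
                col=col_i,
                od600={float(time): value},
            )
        )
    return observations


def join_layout(
    observations: Iterable[WellObservation],
    conditions: Sequence[Condition],
    layout: pd.DataFrame,
) -> pd.DataFrame:
    """Annotate observations with their conditions; return the tidy table.

    ``layout`` needs columns ``plate_id``, ``well``, ``condition_id``.
    Blank wells are retained and labelled. Observed wells absent from the
    layout are dropped with a logged warning listing them; a layout
    condition_id missing from the condition table raises
    :class:`ConsistencyError`.
    """
    cond_by_id = {c.condition_id: c for c in conditions}
    missing = set(layout["condition_id"]) - set(cond_by_id)
    if missing:
        raise ConsistencyError(
            f"layout references unknown condition_id(s): {sorted(missing)}"
        )
    key_to_cond = {
        (str(r.plate_id), str(r.well).upper()): str(r.condition_id)
        for r in layout.itertuples()
    }

    records, unmapped = [], []
    for obs in observations:
        # plate format is recoverable from coordinates; prefer 384 labels
        fmt = 96 if obs.row < 8 and obs.col < 12 else 384
        label = well_label(obs.row, obs.col, fmt)
        cid = key_to_cond.get((obs.plate_id, label))
        if cid is None:
            unmapped.append(f"{obs.plate_id}:{label}")
            continue
        cond = cond_by_id[cid]
        s1 = cond.strains[0] if len(cond.strains) > 0 else ""
        s2 = cond.strains[1] if len(cond.strains) > 1 else ""
        for t, v in sorted(obs.od600.items()):
            records.append(
                (obs.plate_id, obs.batch, label, obs.row, obs.col, cid,
                 cond.kind, s1, s2, t, v)
            )
    if unmapped:
        logger.warning(
            "%d observed well(s) not in layout, dropped: %s",
            len(unmapped),
            ", ".join(unmapped[:20]),
        )
    return pd.DataFrame(records, columns=TIDY_COLUMNS)


def write_results(
    table: pd.DataFrame,
    path: str | os.PathLike,
    config: Config | None = None,
    version: str = "0.1.0",
) -> None:
    """Write a result table as CSV with a provenance comment header."""
    if len(table) == 0:
        logger.warning("writing empty result table to %s", path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# syntroscreen v{version}\n")
        if config is not None:
            fh.write(f"# config_hash={config.config_hash()}\n")
        table.to_csv(fh, index=False)


def read_results(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---- strain / condition table round trips (mandated CSV headers) ----

def write_strains(strains: Sequence[StrainRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "strain_id": s.strain_id,
                "deleted_gene": s.deleted_gene,
                "is_reference": s.is_reference,
                "fluorophore": s.fluorophore,
            }
            for s in strains
        ]
    ).to_csv(path, index=False)


def read_strains(path) -> list[StrainRecord]:
    df = pd.read_csv(path, keep_default_na=False)
    return [
        StrainRecord(
            strain_id=str(r.strain_id),
            deleted_gene=str(r.deleted_gene),
            is_reference=bool(r.is_reference) if str(r.is_reference) not in ("", "False", "false", "0") else False,
            fluorophore=str(r.fluorophore) or "none",
        )
        for r in df.itertuples()
    ]


def write_conditions(conditions: Sequence[Condition], path) -> None:
    rows = []
    for c in conditions:
        r1, r2 = c.inoculation_ratio if c.inoculation_ratio else ("", "")
        rows.append(
            {
                "condition_id": c.condition_id,
                "kind": c.kind,
                "strain_1": c.strains[0] if len(c.strains) > 0 else "",
                "strain_2": c.strains[1] if len(c.strains) > 1 else "",
                "ratio_1": r1,
                "ratio_2": r2,
                "media": c.media,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_conditions(path) -> list[Condition]:
    df = pd.read_csv(path, keep_default_na=False)
    out = []
    for r in df.itertuples():
        strains = tuple(s for s in (str(r.strain_1), str(r.strain_2)) if s)
        ratio = None
        if str(r.ratio_1) != "" and str(r.ratio_2) != "":
            ratio = (float(r.ratio_1), float(r.ratio_2))
        out.append(
            Condition(
                condition_id=str(r.condition_id),
                kind=str(r.kind),
                strains=strains,
                inoculation_ratio=ratio,
                media=str(r.media) or "SM",
            )
        )
    return out
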