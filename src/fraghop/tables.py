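"""Score-table I/O.

The score table is the interchange format between the sampler, the
reduction and the analysis tools (and the import path for externally
scored decoys, e.g. Rosetta score tables reshaped to this layout):
tab-separated, ``#`` comments allowed, header

    id  hop  accepted  E_<term>...  total  mu_prev  lrmsd_native

with ``total`` equal to the sum of the E_ columns (validated on read to
1e-6) and ``NA`` for missing optional values.  Numbers are written with 6
decimal places so repeated writes are byte-identical.
"""

from __future__ import annotations

import math
from typing import List

import numpy as np
import pandas as pd

from .pareto import DecoyEnsemble
from .sampling import Trajectory

TOTAL_TOLERANCE = 1e-6

_LEAD_COLUMNS = ["id", "hop", "accepted"]
_TAIL_COLUMNS = ["total", "mu_prev", "lrmsd_native"]


class ScoreTableError(ValueError):
    """Malformed score table (carries file/line context in the message)."""


def trajectory_to_ensemble(trajectory: Trajectory) -> DecoyEnsemble:
    """Flatten a trajectory into the score-table schema."""
    rows = []
    for rec in trajectory.records:
        row = {
            "id": f"m{rec.hop:06d}",
            "hop": rec.hop,
            "accepted": int(rec.accepted),
        }
        for name, value in rec.terms.as_dict().items():
            row[f"E_{name}"] = value
        row["total"] = rec.terms.total
        row["mu_prev"] = rec.mu_prev
        row["lrmsd_native"] = rec.lrmsd_native
        rows.append(row)
    return DecoyEnsemble(pd.DataFrame(rows))


def _ordered_columns(frame: pd.DataFrame) -> List[str]:
    term_cols = [c for c in frame.columns if c.startswith("E_")]
    lead = [c for c in _LEAD_COLUMNS if c in frame.columns]
    tail = [c for c in _TAIL_COLUMNS if c in frame.columns]
    return lead + term_cols + tail


def _format_cell(value) -> str:
    if isinstance(value, (float, np.floating)):
        if math.isnan(value):
            return "NA"
        return f"{value:.6f}"
    return str(value)


def write_score_table(data, path) -> None:
    """Write an ensemble or trajectory as a score-table TSV.

    Column order is fixed (id, hop, accepted, E_* in schema order, total,
    mu_prev, lrmsd_native); floats use 6 decimals; output ends with a
    newline.  Two writes of the same data are byte-identical.
    """
    if isinstance(data, Trajectory):
        data = trajectory_to_ensemble(data)
    frame = data.frame.copy()
    term_cols = [c for c in frame.columns if c.startswith("E_")]
    # write the total of the *rounded* terms so the file validates exactly
    frame["total"] = frame[term_cols].round(6).sum(axis=1)
    cols = _ordered_columns(frame)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in frame[cols].itertuples(index=False):
            fh.write("\t".join(_format_cell(v) for v in row) + "\n")


def read_score_table(path, allow_empty: bool = False) -> DecoyEnsemble:
    """Read and validate a score-table TSV.

    The term schema is inferred from the ``E_``-prefixed columns; ``total``
    must equal their sum to 1e-6 on every row.  ``lrmsd_native`` and the
    sampler bookkeeping columns are optional.  Errors name the offending
    line.
    """
    header: List[str] = []
    records: List[List[str]] = []
    line_numbers: List[int] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if not header:
                header = fields
                continue
            if len(fields) != len(header):
                raise ScoreTableError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            records.append(fields)
            line_numbers.append(lineno)
    if not header:
        raise ScoreTableError(f"{path}: missing header line")
    term_cols = [c for c in header if c.startswith("E_")]
    if not term_cols:
        raise ScoreTableError(f"{path}: no E_ term columns in header")
    if "id" not in header or "total" not in header:
        raise ScoreTableError(f"{path}: header must contain 'id' and 'total'")
    if not records:
        if allow_empty:
            return DecoyEnsemble(pd.DataFrame(columns=header))
        raise ScoreTableError(f"{path}: table has no data rows")

    frame = pd.DataFrame(records, columns=header)
    numeric = [c for c in header if c not in ("id",)]
    for col in numeric:
        series = frame[col].replace("NA", "nan")
        try:
            frame[col] = series.astype(float)
        except ValueError:
            bad = series.apply(lambda s: not _is_float(s)).to_numpy().nonzero()[0][0]
            raise ScoreTableError(
                f"{path}:{line_numbers[bad]}: non-numeric value in column {col!r}"
            ) from None
    if "hop" in frame:
        frame["hop"] = frame["hop"].astype(int)
    if "accepted" in frame:
        frame["accepted"] = frame["accepted"].astype(int)
    totals = frame[term_cols].sum(axis=1).to_numpy()
    declared = frame["total"].to_numpy(dtype=float)
    bad = np.flatnonzero(np.abs(totals - declared) > TOTAL_TOLERANCE)
    if bad.size:
        i = int(bad[0])
        raise ScoreTableError(
            f"{path}:{line_numbers[i]}: total {declared[i]:.6f} does not match "
            f"sum of terms {totals[i]:.6f} (row id {frame['id'].iloc[i]!r})"
        )
    return DecoyEnsemble(frame)


def _is_float(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return s == "NA"
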