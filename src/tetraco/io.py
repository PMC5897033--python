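"""Readers and writers for tetrad tables and result frames.

Two delimited-text dialects are supported, both also readable from XLSX
(the format of typical raw fluorescent-tetrad supplements):

* spore-level: ``tetrad_id, spore_index(1-4), m1, m2, m3`` with marker
  states in {0, 1}; optional ``genotype`` and ``interval_pair`` columns
  split the file into multiple tables.
* class-counts: ``genotype, interval_pair, class_A .. class_L,
  n_irregular``.

Marker phase: states are interpreted relative to the all-cis parental
configuration.  For real data where a marker's fluorophore sits on the
other homolog, pass ``phase`` with a ``False`` at that marker and the
reader flips it.

All CSV output is UTF-8 with a header row and "." decimal separator.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .stats import GeneticDistance, InterferenceResult
from .tetrads import CLASS_LABELS, Tetrad, TetradCountTable, tabulate

_COUNT_COLUMNS = (
    ["genotype", "interval_pair"]
    + [f"class_{label}" for label in CLASS_LABELS]
    + ["n_irregular"]
)
_SPORE_COLUMNS = ["tetrad_id", "spore_index", "m1", "m2", "m3"]


def _read_frame(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path)
    return pd.read_csv(path, sep=None, engine="python")


def _fail(problems: List[str], skip_bad_rows: bool) -> None:
    if problems and not skip_bad_rows:
        raise ValueError(
            "malformed tetrad data:\n  " + "\n  ".join(problems[:50])
        )


def read_tetrad_data(
    path,
    dialect: str = "spore",
    phase: Sequence[bool] = (True, True, True),
    skip_bad_rows: bool = False,
) -> List[TetradCountTable]:
    """Read tetrad observations and normalise them to count tables.

    Parameters
    ----------
    path : path-like
        CSV/TSV (delimiter sniffed) or XLSX file.
    dialect : {"spore", "counts"}
        Input schema (see module docstring).
    phase : 3-sequence of bool
        Which marker states sit on the reference homolog; ``False`` flips
        the corresponding marker on input.  Spore dialect only.
    skip_bad_rows : bool
        Malformed rows are reported with their line numbers and abort the
        read unless this is set, in which case they are dropped.  (Well
        formed but non-2:2 tetrads are *not* errors; they are tallied in
        ``n_irregular``.)
    """
    if dialect not in ("spore", "counts"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = _read_frame(path)
    if dialect == "counts":
        return _counts_from_frame(df, skip_bad_rows)
    return _tables_from_spore_frame(df, phase, skip_bad_rows)


def _counts_from_frame(df: pd.DataFrame, skip_bad_rows: bool) -> List[TetradCountTable]:
    missing = set(_COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"count table lacks columns {sorted(missing)}")
    tables, problems = [], []
    for idx, row in df.iterrows():
        line = idx + 2  # 1-based, after the header
        try:
            counts = {
                label: int(row[f"class_{label}"]) for label in CLASS_LABELS
            }
            tables.append(
                TetradCountTable(
                    counts=counts,
                    genotype=str(row["genotype"]),
                    interval_pair=str(row["interval_pair"]),
                    n_irregular=int(row["n_irregular"]),
                )
            )
        except (ValueError, TypeError) as exc:
            problems.append(f"line {line}: {exc}")
    _fail(problems, skip_bad_rows)
    return tables


def _tables_from_spore_frame(
    df: pd.DataFrame, phase: Sequence[bool], skip_bad_rows: bool
) -> List[TetradCountTable]:
    missing = set(_SPORE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"spore table lacks columns {sorted(missing)}")
    phase = tuple(bool(p) for p in phase)
    if len(phase) != 3:
        raise ValueError("phase must have three entries")
    for col in ("genotype", "interval_pair"):
        if col not in df.columns:
            df = df.assign(**{col: ""})
        else:
            df[col] = df[col].fillna("")  # empty labels read back as NaN
    problems = []
    markers = ["m1", "m2", "m3"]
    bad = ~df[markers].isin([0, 1]).all(axis=1)
    for idx in df.index[bad]:
        problems.append(f"line {idx + 2}: marker states must be 0 or 1")
    df = df[~bad]

    tables = []
    for (genotype, pair), group in df.groupby(["genotype", "interval_pair"], sort=True):
        tetrads = []
        for tid, spores in group.groupby("tetrad_id", sort=True):
            if len(spores) != 4 or set(spores["spore_index"]) != {1, 2, 3, 4}:
                first_line = spores.index.min() + 2
                problems.append(
                    f"line {first_line}: tetrad {tid!r} does not have spores 1-4"
                )
                continue
            spores = spores.sort_values("spore_index")
            tetrads.append(
                Tetrad(
                    tuple(
                        tuple(
                            bool(row[m]) == phase[k]
                            for k, m in enumerate(markers)
                        )
                        for _, row in spores.iterrows()
                    ),
                    id=str(tid),
                )
            )
        tables.append(tabulate(tetrads, genotype=str(genotype), interval_pair=str(pair)))
    _fail(problems, skip_bad_rows)
    return tables


def write_spore_table(
    tetrads: Iterable[Tetrad],
    path,
    genotype: str = "",
    interval_pair: str = "",
) -> None:
    """Write tetrads in the spore-level CSV dialect."""
    rows = []
    for k, t in enumerate(tetrads, start=1):
        tid = t.id if t.id is not None else f"tetrad-{k}"
        for s_idx, spore in enumerate(t.spores, start=1):
            rows.append(
                {
                    "tetrad_id": tid,
                    "spore_index": s_idx,
                    "m1": int(spore.m1),
                    "m2": int(spore.m2),
                    "m3": int(spore.m3),
                    "genotype": genotype,
                    "interval_pair": interval_pair,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def count_tables_to_frame(tables: Iterable[TetradCountTable]) -> pd.DataFrame:
    rows = []
    for t in tables:
        row = {"genotype": t.genotype, "interval_pair": t.interval_pair}
        row.update({f"class_{label}": t.counts[label] for label in CLASS_LABELS})
        row["n_irregular"] = t.n_irregular
        rows.append(row)
    return pd.DataFrame(rows, columns=_COUNT_COLUMNS)


def write_count_tables(tables: Iterable[TetradCountTable], path) -> None:
    """Write count tables in the class-counts CSV dialect."""
    count_tables_to_frame(tables).to_csv(path, index=False)


def distances_to_frame(
    results: Iterable[Tuple[TetradCountTable, int, GeneticDistance]]
) -> pd.DataFrame:
    """Tidy frame: one row per (genotype, interval_pair, interval)."""
    return pd.DataFrame(
        [
            {
                "genotype": table.genotype,
                "interval_pair": table.interval_pair,
                "interval": interval,
                "d_cM": d.d_cM,
                "se_cM": d.se_cM,
                "n": d.n,
                "t_freq": d.t_freq,
                "npd_freq": d.npd_freq,
            }
            for table, interval, d in results
        ]
    )


def interference_to_frame(
    results: Iterable[Tuple[TetradCountTable, InterferenceResult]]
) -> pd.DataFrame:
    """Tidy frame: one row per (genotype, interval_pair, target interval)."""
    return pd.DataFrame(
        [
            {
                "genotype": table.genotype,
                "interval_pair": table.interval_pair,
                "target": r.target,
                "d1_cM": r.d1.d_cM,
                "d2_cM": r.d2.d_cM,
                "n_with_co": r.d1.n,
                "n_without_co": r.d2.n,
                "ir": r.ir,
                "chi2": r.chi2,
                "df": r.df,
                "p": r.p,
                "ir_avg": r.ir_avg,
            }
            for table, r in results
        ]
    )
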