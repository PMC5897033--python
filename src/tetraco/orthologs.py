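"""Reciprocal-best-hit ortholog assignment with a score-margin criterion.

Distinguishing the meiotic recombinase DMC1 from its paralog RAD51 (and
FIGL1 from its AAA-ATPase relatives) by sequence similarity requires more
than a best hit: a query is assigned to a family only when its best hit's
alignment score exceeds the best hit from any *other* family by at least a
10% margin, and reciprocal best-hit searches confirm the pairing.  The
margin is computed on raw or bit scores and is therefore invariant under
positive rescaling; the 10% threshold is inclusive (margin >= 0.10
assigns).  An exact cross-family tie gives margin 0 and leaves the query
unassigned.

This module only implements the decision rules on pre-computed score
tables (tabular BLAST output or plain score matrices); it performs no
alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

#: Inclusive relative score margin required over the best other-family hit.
SCORE_MARGIN = 0.10

_BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass
class ScoreTable:
    """Pairwise alignment scores of queries against annotated references.

    Parameters
    ----------
    scores : DataFrame
        Long-format columns ``query``, ``reference``, ``score``; scores
        finite and non-negative.
    families : mapping
        reference id -> family label (e.g. ``"DMC1"`` / ``"RAD51"``);
        every scored reference must be annotated.
    """

    scores: pd.DataFrame
    families: Mapping[str, str]

    def __post_init__(self):
        required = {"query", "reference", "score"}
        missing = required - set(self.scores.columns)
        if missing:
            raise ValueError(f"score table lacks columns {sorted(missing)}")
        s = self.scores["score"].to_numpy(dtype=float)
        if not np.isfinite(s).all() or (s < 0).any():
            raise ValueError("scores must be finite and non-negative")
        unknown = set(self.scores["reference"]) - set(self.families)
        if unknown:
            raise ValueError(f"references without family annotation: {sorted(unknown)}")

    @classmethod
    def from_matrix(cls, matrix: pd.DataFrame, families: Mapping[str, str]) -> "ScoreTable":
        """Build from a wide query x reference score matrix."""
        long = matrix.rename_axis("query").reset_index().melt(
            id_vars="query", var_name="reference", value_name="score"
        )
        return cls(long, families)

    @classmethod
    def from_blast(cls, path, families: Mapping[str, str]) -> "ScoreTable":
        """Read 12-column tabular BLAST output; the bitscore is the score."""
        df = pd.read_csv(path, sep="\t", names=_BLAST_COLUMNS, comment="#")
        long = df.rename(columns={"qseqid": "query", "sseqid": "reference",
                                  "bitscore": "score"})
        # keep the best HSP per query/reference pair
        long = (
            long[["query", "reference", "score"]]
            .sort_values("score", ascending=False)
            .drop_duplicates(["query", "reference"])
        )
        return cls(long.reset_index(drop=True), families)

    def hits(self, query: str) -> pd.DataFrame:
        """Hits of one query, best first; ties broken by reference id."""
        h = self.scores[self.scores["query"] == query].copy()
        if h.empty:
            raise ValueError(f"query {query!r} has no scored references")
        h["family"] = h["reference"].map(self.families)
        return h.sort_values(
            ["score", "reference"], ascending=[False, True]
        ).reset_index(drop=True)

    def family_labels(self) -> set:
        return set(self.families[r] for r in self.scores["reference"].unique())


@dataclass(frozen=True)
class OrthologCall:
    """Family assignment of one query under the score-margin rule."""

    query: str
    assigned_family: str  # family label or "unassigned"
    best_hit: Optional[str]
    best_score: float
    second_best_hit: Optional[str]
    second_best_score: float
    margin: float


def assign_family(query: str, table: ScoreTable) -> OrthologCall:
    """Assign a query to a family by the best-hit score-margin rule.

    The best hit overall is found; the runner-up is the best hit from any
    *different* family; the query is assigned to the best hit's family iff
    ``(best - second) / second >= 0.10``.  All-zero scores leave the query
    unassigned.

    Raises
    ------
    ValueError
        If the query has no scored references, or all its references
        belong to one family (no cross-family margin exists).
    """
    hits = table.hits(query)
    if hits["family"].nunique() < 2:
        raise ValueError(
            f"cannot compute cross-family margin for {query!r}: "
            "only one family among its scored references"
        )
    best = hits.iloc[0]
    if best["score"] <= 0:
        return OrthologCall(query, "unassigned", None, 0.0, None, 0.0, 0.0)
    others = hits[hits["family"] != best["family"]]
    second = others.iloc[0]
    if second["score"] > 0:
        margin = (best["score"] - second["score"]) / second["score"]
    else:
        margin = float("inf")
    assigned = best["family"] if margin >= SCORE_MARGIN else "unassigned"
    return OrthologCall(
        query=query,
        assigned_family=str(assigned),
        best_hit=str(best["reference"]),
        best_score=float(best["score"]),
        second_best_hit=str(second["reference"]),
        second_best_score=float(second["score"]),
        margin=float(margin),
    )


@dataclass(frozen=True)
class RBHResult:
    """Outcome of a reciprocal-best-hit check for one query."""

    query: str
    forward_best: str
    reverse_best: str
    confirmed: bool


def reciprocal_best_hit(
    query: str, forward: ScoreTable, reverse: ScoreTable
) -> RBHResult:
    """Confirm a hit by the reciprocal-best-hit criterion.

    The query's best forward hit is itself queried in the reverse table;
    the pair is confirmed iff the reverse best hit is the original query.

    Raises
    ------
    ValueError
        If the forward best hit has no reverse scores.
    """
    fwd_best = forward.hits(query).iloc[0]["reference"]
    try:
        rev_best = reverse.hits(fwd_best).iloc[0]["reference"]
    except ValueError as exc:
        raise ValueError(
            f"missing reverse scores for forward best hit {fwd_best!r}"
        ) from exc
    return RBHResult(query, str(fwd_best), str(rev_best), rev_best == query)


def cooccurrence_table(
    calls: Mapping[str, Iterable[OrthologCall]]
) -> pd.DataFrame:
    """Species x family presence/absence matrix from per-species calls.

    A family is present in a species iff any of that species' queries was
    assigned to it.  Unassigned calls contribute nothing.
    """
    families: set = set()
    presence = {}
    for species, species_calls in calls.items():
        assigned = {
            c.assigned_family for c in species_calls if c.assigned_family != "unassigned"
        }
        presence[species] = assigned
        families |= assigned
    columns = sorted(families)
    data = {
        species: [int(f in assigned) for f in columns]
        for species, assigned in presence.items()
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=columns).sort_index()


def count_present_without(matrix: pd.DataFrame, present: str, absent: str) -> int:
    """Number of species carrying ``present`` but lacking ``absent``.

    Either family may be missing from the matrix entirely (treated as
    absent everywhere).
    """
    has = matrix[present].astype(bool) if present in matrix else pd.Series(False, index=matrix.index)
    lacks = ~matrix[absent].astype(bool) if absent in matrix else pd.Series(True, index=matrix.index)
    return int((has & lacks).sum())
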