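"""Tetrad data structures and fluorescence-class assignment.

A tetrad is the set of four spores produced by one meiosis.  In the
*Arabidopsis qrt* background the four pollen grains stay attached, and three
linked fluorescent markers delimit two adjacent genetic intervals
(marker1-marker2 = interval 1, marker2-marker3 = interval 2).  Every
*regular* tetrad — 2:2 segregation at each marker — shows one of three
segregation patterns per interval (parental ditype PD, tetratype T,
non-parental ditype NPD) and falls into one of twelve classes overall: the
eight non-double-tetratype combinations plus the four chromatid
configurations (2-strand, two 3-strand, 4-strand) of the (T,T) double
crossover.

Markers are scored relative to the all-*cis* parental phase: one parental
homolog carries all three fluorophores.  Readers for real data can flip
phase before constructing :class:`Tetrad` objects.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, NamedTuple, Optional


class IntervalType(str, Enum):
    """Segregation pattern of a tetrad for one marker pair."""

    PD = "PD"
    T = "T"
    NPD = "NPD"


class StrandConfig(str, Enum):
    """Chromatid configuration of a double-tetratype (T,T) tetrad.

    The two 3-strand patterns are distinguished by which parental genotype
    survives: ``THREE_STRAND_A`` retains the triple-fluorescent spore,
    ``THREE_STRAND_B`` the triple-dark spore.
    """

    TWO_STRAND = "2-strand"
    THREE_STRAND_A = "3-strand-a"
    THREE_STRAND_B = "3-strand-b"
    FOUR_STRAND = "4-strand"


class SporeGenotype(NamedTuple):
    """Fluorescence state (present/absent) at the three ordered markers."""

    m1: bool
    m2: bool
    m3: bool

    @classmethod
    def of(cls, m1, m2, m3) -> "SporeGenotype":
        return cls(bool(m1), bool(m2), bool(m3))


class IrregularTetradError(ValueError):
    """Raised when a non-2:2 tetrad reaches an operation that requires regularity."""


@dataclass(frozen=True)
class Tetrad:
    """The four spores of one meiosis, as an (unordered) multiset.

    Parameters
    ----------
    spores : iterable of spore genotypes
        Exactly four entries; each entry is a ``SporeGenotype`` or a
        3-sequence of truthy/falsy marker states.
    id : str, optional
        Free-form label carried through to tabulated output.
    """

    spores: tuple
    id: Optional[str] = None

    def __post_init__(self):
        spores = tuple(
            s if isinstance(s, SporeGenotype) else SporeGenotype.of(*s)
            for s in self.spores
        )
        if len(spores) != 4:
            raise ValueError(f"a tetrad has exactly 4 spores, got {len(spores)}")
        object.__setattr__(self, "spores", spores)

    def irregular_markers(self) -> list:
        """1-based indices of markers that do not segregate 2:2."""
        return [
            m + 1
            for m in range(3)
            if sum(s[m] for s in self.spores) != 2
        ]

    @property
    def is_regular(self) -> bool:
        """True iff every marker is present in exactly two of the four spores."""
        return not self.irregular_markers()


@dataclass(frozen=True)
class TetradClass:
    """One of the twelve tetrad classes (labels A..L)."""

    label: str
    i1_type: IntervalType
    i2_type: IntervalType
    strand_config: Optional[StrandConfig] = None


# Canonical label scheme: A=(PD,PD), B=(T,PD), C=(PD,T), D-G the four (T,T)
# strand patterns, H=(NPD,PD), I=(PD,NPD), J=(NPD,T), K=(T,NPD), L=(NPD,NPD).
# The statistics downstream depend only on the per-interval types, so the
# letters are a convention, centralised here.
LABEL_BY_TYPES: Mapping[tuple, str] = {
    (IntervalType.PD, IntervalType.PD): "A",
    (IntervalType.T, IntervalType.PD): "B",
    (IntervalType.PD, IntervalType.T): "C",
    (IntervalType.NPD, IntervalType.PD): "H",
    (IntervalType.PD, IntervalType.NPD): "I",
    (IntervalType.NPD, IntervalType.T): "J",
    (IntervalType.T, IntervalType.NPD): "K",
    (IntervalType.NPD, IntervalType.NPD): "L",
}
LABEL_BY_STRAND: Mapping[StrandConfig, str] = {
    StrandConfig.TWO_STRAND: "D",
    StrandConfig.THREE_STRAND_A: "E",
    StrandConfig.THREE_STRAND_B: "F",
    StrandConfig.FOUR_STRAND: "G",
}

CLASS_LABELS = tuple("ABCDEFGHIJKL")


def _build_class_defs() -> Mapping[str, TetradClass]:
    defs = {}
    for (i1, i2), label in LABEL_BY_TYPES.items():
        defs[label] = TetradClass(label, i1, i2, None)
    for sc, label in LABEL_BY_STRAND.items():
        defs[label] = TetradClass(label, IntervalType.T, IntervalType.T, sc)
    return {label: defs[label] for label in CLASS_LABELS}


CLASS_DEFS: Mapping[str, TetradClass] = _build_class_defs()


def _require_regular(t: Tetrad) -> None:
    bad = t.irregular_markers()
    if bad:
        raise IrregularTetradError(
            f"tetrad {t.id or ''} is irregular: marker(s) {bad} do not segregate 2:2"
        )


def interval_type(t: Tetrad, interval: int) -> IntervalType:
    """Segregation type of a regular tetrad in one interval.

    The interval's two flanking markers give four (left, right) state pairs;
    with all-cis phase, a pair is recombinant iff the two states differ.
    Zero, two or four recombinant spores correspond to PD, T and NPD (2:2
    marker segregation forbids odd counts and forces the tetratype to carry
    one of each recombinant pair).

    Parameters
    ----------
    t : Tetrad
        Must be regular, else :class:`IrregularTetradError` is raised.
    interval : {1, 2}
        1 = markers 1-2, 2 = markers 2-3.
    """
    if interval not in (1, 2):
        raise ValueError("interval must be 1 or 2")
    _require_regular(t)
    left, right = (0, 1) if interval == 1 else (1, 2)
    n_rec = sum(1 for s in t.spores if s[left] != s[right])
    return {0: IntervalType.PD, 2: IntervalType.T, 4: IntervalType.NPD}[n_rec]


def classify_tetrad(t: Tetrad) -> TetradClass:
    """Assign a regular tetrad to one of the twelve classes A..L.

    Non-(T,T) classes are determined by the per-interval type pair alone.
    (T,T) tetrads are split by the chromatid configuration of the underlying
    double crossover, identified from which parental genotypes survive:
    both parentals present = 2-strand, exactly one = 3-strand (a/b by which
    one), neither = 4-strand.
    """
    i1 = interval_type(t, 1)
    i2 = interval_type(t, 2)
    if not (i1 is IntervalType.T and i2 is IntervalType.T):
        return CLASS_DEFS[LABEL_BY_TYPES[(i1, i2)]]
    genotypes = set(t.spores)
    has_ppp = SporeGenotype(True, True, True) in genotypes
    has_mmm = SporeGenotype(False, False, False) in genotypes
    if has_ppp and has_mmm:
        sc = StrandConfig.TWO_STRAND
    elif has_ppp:
        sc = StrandConfig.THREE_STRAND_A
    elif has_mmm:
        sc = StrandConfig.THREE_STRAND_B
    else:
        sc = StrandConfig.FOUR_STRAND
    return CLASS_DEFS[LABEL_BY_STRAND[sc]]


@dataclass
class TetradCountTable:
    """Per-genotype counts over the twelve tetrad classes.

    Attributes
    ----------
    counts : dict
        Class label (A..L) -> non-negative count; missing labels mean 0.
    genotype, interval_pair : str
        Identifiers carried from the input data (e.g. ``"figl1-1"``,
        ``"I2ab"``).
    n_irregular : int
        Tetrads with non-2:2 segregation; excluded from all class counts
        and from every downstream statistic.
    """

    counts: dict
    genotype: str = ""
    interval_pair: str = ""
    n_irregular: int = 0

    def __post_init__(self):
        full = {label: 0 for label in CLASS_LABELS}
        for label, c in self.counts.items():
            if label not in full:
                raise ValueError(f"unknown tetrad class label {label!r}")
            c = int(c)
            if c < 0:
                raise ValueError(f"negative count for class {label}: {c}")
            full[label] = c
        self.counts = full
        if self.n_irregular < 0:
            raise ValueError("n_irregular must be non-negative")

    @property
    def n_total(self) -> int:
        """Number of regular (classified) tetrads."""
        return sum(self.counts.values())

    def type_counts(self, interval: int) -> "dict[IntervalType, int]":
        """Counts of PD/T/NPD tetrads in one interval, summed over classes."""
        if interval not in (1, 2):
            raise ValueError("interval must be 1 or 2")
        out = {it: 0 for it in IntervalType}
        for label, c in self.counts.items():
            cls = CLASS_DEFS[label]
            it = cls.i1_type if interval == 1 else cls.i2_type
            out[it] += c
        return out

    def joint_type_counts(self) -> "dict[tuple, int]":
        """Counts over the nine (interval-1 type, interval-2 type) pairs."""
        out: Counter = Counter()
        for label, c in self.counts.items():
            cls = CLASS_DEFS[label]
            out[(cls.i1_type, cls.i2_type)] += c
        return dict(out)


def tabulate(
    tetrads: Iterable[Tetrad],
    genotype: str = "",
    interval_pair: str = "",
) -> TetradCountTable:
    """Classify tetrads and tally them into a :class:`TetradCountTable`.

    Irregular tetrads are never classified; they are counted in
    ``n_irregular`` only.
    """
    counts: Counter = Counter()
    n_irregular = 0
    for t in tetrads:
        if not t.is_regular:
            n_irregular += 1
            continue
        counts[classify_tetrad(t).label] += 1
    return TetradCountTable(
        counts=dict(counts),
        genotype=genotype,
        interval_pair=interval_pair,
        n_irregular=n_irregular,
    )
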