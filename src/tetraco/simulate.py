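"""Four-strand meiosis simulator with tunable crossover interference.

Crossovers are placed on the bivalent along a genetic axis spanning the two
marker intervals.  Positions are drawn from a stationary gamma renewal
process measured in genetic distance: inter-event distances are
Gamma(shape=nu, mean=1/rate) with rate fixed at 2 events per Morgan per
bivalent, so an interval of genetic size d cM receives on average
``2 * d/100`` crossovers and each chromatid is recombinant with probability
about d/100 for small d.  ``nu = 1`` reduces to a Poisson process
(independent placement, no interference); larger ``nu`` regularises the
spacing and suppresses nearby double crossovers.

Each crossover involves one of the two chromatids of each homolog, chosen
uniformly and independently (no chromatid interference).  Spore genotypes
are read off the four chromatids at the marker positions 0, d1 and d1+d2,
with the all-cis parental phase (one homolog carries all three markers).

The module also provides :func:`enumerate_tetrad_patterns`, the exhaustive
brute-force enumeration of all 2:2 spore-genotype matrices, used as an
independent oracle for the rule-based classifier in
:mod:`tetraco.tetrads`.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations, product
from typing import List, Tuple

import numpy as np

from .tetrads import (
    CLASS_DEFS,
    LABEL_BY_STRAND,
    LABEL_BY_TYPES,
    IntervalType,
    StrandConfig,
    Tetrad,
    TetradClass,
    TetradCountTable,
)

# Crossover intensity per bivalent, events per Morgan of genetic distance.
_RATE = 2.0
# Burn-in, in mean inter-event distances, so the renewal process is
# effectively stationary when it reaches the marked region.
_BURNIN_GAPS = 10.0


@dataclass(frozen=True)
class SimParams:
    """Parameters of a simulated tetrad experiment.

    Parameters
    ----------
    d1_cM, d2_cM : float
        Genetic sizes of the two adjacent intervals, in centimorgans
        (non-negative, finite).
    nu : float
        Gamma shape parameter of the crossover renewal process; ``nu >= 1``.
        ``nu = 1`` means independent crossover placement (no interference).
    n_tetrads : int
        Number of meioses to simulate (> 0).
    seed : int
        Root seed; identical parameters (including the seed) yield
        bit-identical output.
    """

    d1_cM: float
    d2_cM: float
    nu: float = 1.0
    n_tetrads: int = 1000
    seed: int = 0

    def __post_init__(self):
        for name in ("d1_cM", "d2_cM", "nu"):
            v = float(getattr(self, name))
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if self.d1_cM < 0 or self.d2_cM < 0:
            raise ValueError("interval sizes must be non-negative")
        if self.nu < 1:
            raise ValueError(f"nu must be >= 1, got {self.nu}")
        if int(self.n_tetrads) <= 0:
            raise ValueError("n_tetrads must be positive")


def _crossover_positions(params: SimParams, rng: np.random.Generator):
    """Event positions (Morgans) of the renewal process, per meiosis.

    Returns an (n, m) position array; entries outside (0, L1+L2) are
    burn-in or overshoot and must be masked by the caller.
    """
    n = int(params.n_tetrads)
    l_total = (params.d1_cM + params.d2_cM) / 100.0
    burnin = _BURNIN_GAPS / _RATE
    span = burnin + l_total
    mean_events = span * _RATE
    m = int(np.ceil(mean_events + 10.0 * np.sqrt(mean_events) + 20.0))
    scale = 1.0 / (_RATE * params.nu)
    pos = rng.gamma(params.nu, scale, size=(n, m)).cumsum(axis=1) - burnin
    while pos[:, -1].min() < l_total:  # overwhelmingly rare safety extension
        extra = rng.gamma(params.nu, scale, size=(n, 16)).cumsum(axis=1)
        pos = np.concatenate([pos, pos[:, -1:] + extra], axis=1)
    return pos


def _occupancy_alleles(track_path: np.ndarray) -> np.ndarray:
    """Marker states of the four spore paths given track occupancy.

    ``track_path[r, t]`` is the index of the path currently occupying
    physical chromatid (track) ``t`` in meiosis ``r``; tracks 0-1 belong to
    the fluorescent homolog, 2-3 to the dark one.
    """
    n = track_path.shape[0]
    alleles = np.empty((n, 4), dtype=bool)
    rows = np.arange(n)[:, None]
    alleles[rows, track_path[:, :2]] = True
    alleles[rows, track_path[:, 2:]] = False
    return alleles


def _apply_exchanges(track_path, mask, top, bot) -> None:
    """Apply crossovers (in position order) as track-occupancy swaps.

    A crossover between chromatid ``i`` of homolog 1 and ``j`` of homolog 2
    reconnects the two paths currently travelling along those tracks, so
    the paths swap tracks for all more distal positions.
    """
    for e in range(mask.shape[1]):
        rows = np.flatnonzero(mask[:, e])
        if rows.size == 0:
            continue
        i = top[rows, e]
        j = bot[rows, e]
        pi = track_path[rows, i]
        pj = track_path[rows, j]
        track_path[rows, i] = pj
        track_path[rows, j] = pi


def simulate_genotypes(params: SimParams) -> Tuple[np.ndarray, np.ndarray]:
    """Simulate meioses; return raw genotype and crossover-count arrays.

    Returns
    -------
    genotypes : (n, 4, 3) bool array
        Marker states of the four spores of each tetrad at the three
        markers.
    co_counts : (n, 2) int array
        Number of crossovers that fell in interval 1 and interval 2 of each
        bivalent (before any chromatid choice — the counts are per
        bivalent, not per spore).
    """
    rng = np.random.default_rng(params.seed)
    n = int(params.n_tetrads)
    l1 = params.d1_cM / 100.0
    l_total = (params.d1_cM + params.d2_cM) / 100.0

    pos = _crossover_positions(params, rng)
    top = rng.integers(0, 2, size=pos.shape, dtype=np.int8)
    bot = rng.integers(2, 4, size=pos.shape, dtype=np.int8)

    in_i1 = (pos > 0.0) & (pos < l1)
    in_i2 = (pos >= l1) & (pos < l_total)

    track_path = np.broadcast_to(np.arange(4), (n, 4)).copy()
    m1 = _occupancy_alleles(track_path)  # marker 1 sits at the origin
    _apply_exchanges(track_path, in_i1, top, bot)
    m2 = _occupancy_alleles(track_path)
    _apply_exchanges(track_path, in_i2, top, bot)
    m3 = _occupancy_alleles(track_path)

    genotypes = np.stack([m1, m2, m3], axis=2)
    co_counts = np.stack(
        [in_i1.sum(axis=1), in_i2.sum(axis=1)], axis=1
    ).astype(np.int64)
    return genotypes, co_counts


def interval_types_from_genotypes(genotypes: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorised per-interval segregation types.

    Returns two int arrays coded 0=PD, 1=T, 2=NPD (half the number of
    recombinant spores in the interval).
    """
    rec1 = (genotypes[:, :, 0] != genotypes[:, :, 1]).sum(axis=1)
    rec2 = (genotypes[:, :, 1] != genotypes[:, :, 2]).sum(axis=1)
    return rec1 // 2, rec2 // 2


_TYPE_ORDER = (IntervalType.PD, IntervalType.T, IntervalType.NPD)


def classify_genotypes(genotypes: np.ndarray) -> np.ndarray:
    """Vectorised class labels (A..L) for an (n, 4, 3) genotype array."""
    t1, t2 = interval_types_from_genotypes(genotypes)
    labels = np.empty(genotypes.shape[0], dtype="U1")
    for (i1, i2), label in LABEL_BY_TYPES.items():
        sel = (t1 == _TYPE_ORDER.index(i1)) & (t2 == _TYPE_ORDER.index(i2))
        labels[sel] = label
    tt = (t1 == 1) & (t2 == 1)
    has_ppp = genotypes.all(axis=2).any(axis=1)
    has_mmm = (~genotypes).all(axis=2).any(axis=1)
    labels[tt & has_ppp & has_mmm] = LABEL_BY_STRAND[StrandConfig.TWO_STRAND]
    labels[tt & has_ppp & ~has_mmm] = LABEL_BY_STRAND[StrandConfig.THREE_STRAND_A]
    labels[tt & ~has_ppp & has_mmm] = LABEL_BY_STRAND[StrandConfig.THREE_STRAND_B]
    labels[tt & ~has_ppp & ~has_mmm] = LABEL_BY_STRAND[StrandConfig.FOUR_STRAND]
    return labels


def simulate_tetrads(params: SimParams) -> List[Tetrad]:
    """Simulate tetrads as :class:`~tetraco.tetrads.Tetrad` objects."""
    genotypes, _ = simulate_genotypes(params)
    width = len(str(params.n_tetrads))
    return [
        Tetrad(tuple(map(tuple, g)), id=f"sim-{k:0{width}d}")
        for k, g in enumerate(genotypes, start=1)
    ]


def simulate_count_table(
    params: SimParams, genotype: str = "sim", interval_pair: str = "sim"
) -> TetradCountTable:
    """Simulate tetrads and tally them directly into a count table.

    Equivalent to ``tabulate(simulate_tetrads(params))`` but vectorised;
    simulated tetrads are always regular, so ``n_irregular`` is 0.
    """
    labels = classify_genotypes(simulate_genotypes(params)[0])
    uniq, counts = np.unique(labels, return_counts=True)
    return TetradCountTable(
        counts=dict(zip(uniq.tolist(), counts.tolist())),
        genotype=genotype,
        interval_pair=interval_pair,
    )


def _multiset_pair_type(pairs: Counter) -> IntervalType:
    """Interval type from the multiset of (left, right) marker-state pairs.

    Written against the ditype/tetratype definitions directly (multiset
    equality), independently of the recombinant-spore counting used by the
    classifier, so the enumeration can serve as its oracle.
    """
    parental = Counter({(True, True): 2, (False, False): 2})
    recombinant = Counter({(True, False): 2, (False, True): 2})
    tetratype = Counter(
        {(True, True): 1, (False, False): 1, (True, False): 1, (False, True): 1}
    )
    if pairs == parental:
        return IntervalType.PD
    if pairs == recombinant:
        return IntervalType.NPD
    if pairs == tetratype:
        return IntervalType.T
    raise ValueError(f"pattern is not a regular tetrad pairing: {dict(pairs)}")


def enumerate_tetrad_patterns() -> "dict[tuple, TetradClass]":
    """Exhaustively enumerate all regular tetrad patterns and their classes.

    Every 4-spore x 3-marker genotype matrix with 2:2 segregation per
    marker (6^3 = 216 matrices) is generated and grouped into orbits under
    reordering of the four spores.  The orbit's canonical representative —
    the sorted tuple of spore genotype tuples — is mapped to its
    :class:`TetradClass`.

    Returns
    -------
    dict
        canonical spore multiset -> TetradClass; exactly twelve distinct
        classes appear.
    """
    patterns = {}
    for c1, c2, c3 in product(combinations(range(4), 2), repeat=3):
        matrix = tuple(
            (spore in c1, spore in c2, spore in c3) for spore in range(4)
        )
        canonical = tuple(sorted(matrix))
        if canonical in patterns:
            continue
        i1 = _multiset_pair_type(Counter((s[0], s[1]) for s in canonical))
        i2 = _multiset_pair_type(Counter((s[1], s[2]) for s in canonical))
        if i1 is IntervalType.T and i2 is IntervalType.T:
            has_ppp = (True, True, True) in canonical
            has_mmm = (False, False, False) in canonical
            sc = {
                (True, True): StrandConfig.TWO_STRAND,
                (True, False): StrandConfig.THREE_STRAND_A,
                (False, True): StrandConfig.THREE_STRAND_B,
                (False, False): StrandConfig.FOUR_STRAND,
            }[(has_ppp, has_mmm)]
            patterns[canonical] = CLASS_DEFS[LABEL_BY_STRAND[sc]]
        else:
            patterns[canonical] = CLASS_DEFS[LABEL_BY_TYPES[(i1, i2)]]
    return patterns
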