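"""Genetic distances, between-genotype tests and the interference ratio.

The map distance of an interval is estimated from tetrad type frequencies
with the Perkins equation,

    D = 100 * (T + 6 * NPD) / 2   [cM],

where T and NPD are the tetratype and non-parental-ditype frequencies; the
6x weight on NPD corrects for the double crossovers the NPD class implies.

The crossover interference ratio (IR) of a target interval, conditioned on
its adjacent interval, is D1/D2 where D1 is the Perkins distance computed
among tetrads *with* at least one crossover in the adjacent interval (type
T or NPD there) and D2 among tetrads *without* (type PD).  IR < 1 indicates
interference; IR close to 1 or above indicates its absence.  The null
hypothesis D1 = D2 is tested with a contingency chi-square on the
(PD, T, NPD) counts of the target interval in the two subpopulations, and
the ratio is also averaged over the two reciprocal conditioning directions.

Standard errors of D use the delta method under multinomial sampling of
(PD, T, NPD):

    Var(D) = 50^2 * [t(1-t) + 36 * f(1-f) - 12 * t * f] / n

with t, f the tetratype and NPD frequencies.  Between-genotype comparisons
use the normal two-sample Z statistic on these SEs.

No multiple-testing correction is applied anywhere; p-values are reported
per interval/genotype pair as-is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .tetrads import IntervalType, TetradCountTable


@dataclass(frozen=True)
class GeneticDistance:
    """Perkins map-distance estimate for one interval.

    Attributes
    ----------
    d_cM : float
        Map distance in centimorgans.
    se_cM : float
        Delta-method standard error, in cM.
    n : int
        Number of regular tetrads the estimate is based on.
    t_freq, npd_freq : float
        Tetratype and non-parental-ditype frequencies.
    """

    d_cM: float
    se_cM: float
    n: int
    t_freq: float
    npd_freq: float


def distance_from_type_counts(n_pd: int, n_t: int, n_npd: int) -> GeneticDistance:
    """Perkins distance from raw (PD, T, NPD) tetrad counts."""
    if min(n_pd, n_t, n_npd) < 0:
        raise ValueError("type counts must be non-negative")
    n = n_pd + n_t + n_npd
    if n == 0:
        raise ValueError("cannot estimate a distance from zero tetrads")
    t = n_t / n
    f = n_npd / n
    d = 100.0 * (t + 6.0 * f) / 2.0
    var = 2500.0 * (t * (1.0 - t) + 36.0 * f * (1.0 - f) - 12.0 * t * f) / n
    return GeneticDistance(d, math.sqrt(max(var, 0.0)), n, t, f)


def perkins_distance(counts: TetradCountTable, interval: int) -> GeneticDistance:
    """Perkins map distance of one interval of a tetrad count table.

    Parameters
    ----------
    counts : TetradCountTable
        Must contain at least one regular tetrad.
    interval : {1, 2}
        Which interval of the pair to estimate.
    """
    if counts.n_total == 0:
        raise ValueError("count table has no regular tetrads")
    tc = counts.type_counts(interval)
    return distance_from_type_counts(
        tc[IntervalType.PD], tc[IntervalType.T], tc[IntervalType.NPD]
    )


def compare_distances_z(a: GeneticDistance, b: GeneticDistance) -> Tuple[float, float]:
    """Two-sided Z-test for equality of two genetic distances.

    Returns ``(z, p)`` with ``z = (a.d - b.d) / sqrt(a.se^2 + b.se^2)``.
    """
    if a.n <= 0 or b.n <= 0:
        raise ValueError("both estimates must be based on at least one tetrad")
    if not (np.isfinite(a.se_cM) and np.isfinite(b.se_cM)):
        raise ValueError("standard errors must be finite")
    denom = math.hypot(a.se_cM, b.se_cM)
    if denom == 0.0:
        if a.d_cM == b.d_cM:
            return 0.0, 1.0
        raise ValueError("zero combined standard error with unequal distances")
    z = (a.d_cM - b.d_cM) / denom
    return z, 2.0 * sps.norm.sf(abs(z))


@dataclass(frozen=True)
class InterferenceResult:
    """Interference ratio of a target interval and its chi-square test.

    ``d1`` / ``d2`` are the target-interval distances among tetrads with /
    without a crossover in the conditioning (adjacent) interval; ``ir`` is
    their ratio, NaN when D2 = 0.  ``chi2``, ``df`` and ``p`` come from the
    2x3 contingency test of distribution equality between the two
    subpopulations; they are ``None`` when any expected cell count falls
    below 1.  ``ir_avg`` averages the IR over the two reciprocal
    conditioning directions.
    """

    target: int
    d1: GeneticDistance
    d2: GeneticDistance
    ir: float
    chi2: Optional[float]
    df: Optional[int]
    p: Optional[float]
    ir_avg: float


def _split_by_conditioning(counts: TetradCountTable, target: int):
    """(PD,T,NPD) counts of the target interval in the with-CO / no-CO
    subpopulations defined by the adjacent interval."""
    conditioning = 2 if target == 1 else 1
    with_co = {it: 0 for it in IntervalType}
    without_co = {it: 0 for it in IntervalType}
    for (i1, i2), c in counts.joint_type_counts().items():
        t_type = i1 if target == 1 else i2
        c_type = i2 if target == 1 else i1
        bucket = without_co if c_type is IntervalType.PD else with_co
        bucket[t_type] += c
    return with_co, without_co


def _one_direction(counts: TetradCountTable, target: int):
    with_co, without_co = _split_by_conditioning(counts, target)
    n_with = sum(with_co.values())
    n_without = sum(without_co.values())
    if n_with == 0 or n_without == 0:
        raise ValueError(
            "insufficient tetrads for conditioning: the "
            f"{'with' if n_with == 0 else 'without'}-crossover subpopulation "
            "is empty"
        )
    d1 = distance_from_type_counts(*(with_co[it] for it in IntervalType))
    d2 = distance_from_type_counts(*(without_co[it] for it in IntervalType))
    ir = d1.d_cM / d2.d_cM if d2.d_cM > 0 else float("nan")

    table = np.array(
        [
            [with_co[it] for it in IntervalType],
            [without_co[it] for it in IntervalType],
        ]
    )
    table = table[:, table.sum(axis=0) > 0]  # drop type classes absent overall
    chi2 = df = p = None
    if table.shape[1] >= 2:
        res = sps.chi2_contingency(table, correction=False)
        if res.expected_freq.min() >= 1.0:
            chi2, df, p = float(res.statistic), int(res.dof), float(res.pvalue)
    return d1, d2, ir, chi2, df, p


def interference_ratio(counts: TetradCountTable, target: int) -> InterferenceResult:
    """Crossover interference ratio for one target interval.

    Tetrads are split by whether the *adjacent* interval shows a crossover
    (type T or NPD; NPD implies at least two) or none (PD); the Perkins
    distance of the target interval is computed in each subpopulation.

    Parameters
    ----------
    counts : TetradCountTable
    target : {1, 2}
        Interval whose conditional distances D1 and D2 are reported; the
        other interval of the pair conditions the split.

    Raises
    ------
    ValueError
        If either conditioning subpopulation is empty, in either direction.
    """
    if target not in (1, 2):
        raise ValueError("target must be 1 or 2")
    d1, d2, ir, chi2, df, p = _one_direction(counts, target)
    other_ir = _one_direction(counts, 2 if target == 1 else 1)[2]
    ir_avg = (ir + other_ir) / 2.0
    return InterferenceResult(target, d1, d2, ir, chi2, df, p, ir_avg)


def pooled_proportion(events: Sequence[int], totals: Sequence[int]) -> float:
    """Pooled frequency of an event across samples: sum(events)/sum(totals).

    Used e.g. to pool per-allele univalent cell counts into a single
    frequency.
    """
    events = np.asarray(events, dtype=float)
    totals = np.asarray(totals, dtype=float)
    if events.shape != totals.shape or events.size == 0:
        raise ValueError("events and totals must be equal-length, non-empty")
    if (events < 0).any() or (totals <= 0).any() or (events > totals).any():
        raise ValueError("require 0 <= events <= totals and totals > 0")
    return float(events.sum() / totals.sum())
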