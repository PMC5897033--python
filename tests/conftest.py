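import pytest

from tetraco.tetrads import IntervalType, TetradCountTable
from tetraco.simulate import enumerate_tetrad_patterns

# (i1, i2) -> a representative class label; statistics never depend on which
# of the four (T,T) strand classes carries the count.
_TYPE_LABEL = {
    (IntervalType.PD, IntervalType.PD): "A",
    (IntervalType.T, IntervalType.PD): "B",
    (IntervalType.PD, IntervalType.T): "C",
    (IntervalType.T, IntervalType.T): "D",
    (IntervalType.NPD, IntervalType.PD): "H",
    (IntervalType.PD, IntervalType.NPD): "I",
    (IntervalType.NPD, IntervalType.T): "J",
    (IntervalType.T, IntervalType.NPD): "K",
    (IntervalType.NPD, IntervalType.NPD): "L",
}


def make_table(joint_counts, **kwargs) -> TetradCountTable:
    """Count table from {(i1_type, i2_type): count} pairs."""
    counts = {}
    for pair, c in joint_counts.items():
        label = _TYPE_LABEL[pair]
        counts[label] = counts.get(label, 0) + c
    return TetradCountTable(counts=counts, **kwargs)


@pytest.fixture(scope="session")
def pattern_classes():
    """Exhaustive orbit -> class mapping (216 matrices, 12 orbits)."""
    return enumerate_tetrad_patterns()
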