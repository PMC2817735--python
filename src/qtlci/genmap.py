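"""Genetic-map data model, mapping-function math, and the benchmark map.

Positions are centimorgans (cM) on a per-chromosome coordinate axis starting
at 0.  The mapping function converting map distance to a recombination
fraction is Haldane's (no crossover interference); for selfed recombinant
inbred lines (RI1) the single-meiosis fraction ``r`` is expanded to the
terminal-generation fraction ``R = 2r / (1 + 2r)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "MarkerLocus",
    "ChromosomeMap",
    "GeneticMap",
    "QTLPlacement",
    "haldane_recomb",
    "inverse_haldane",
    "kosambi_recomb",
    "ril_expand",
    "benchmark_map",
    "place_qtls",
    "BENCHMARK_POSITIONS",
    "BENCHMARK_QTL_INTERVALS",
]

#: Marker positions (cM) used on every chromosome of the benchmark map: 23
#: whole-number positions grading from dense near the short-arm telomere to
#: sparse near the long arm, with telomeric markers at 0 and 165 and the four
#: QTL-flanking intervals (11,12), (23,26), (69,84), (114,134) left free of
#: interior markers.
BENCHMARK_POSITIONS: tuple[float, ...] = (
    0, 2, 4, 6, 8, 10, 11, 12, 14, 17, 20, 23, 26, 33, 43, 55, 69, 84, 99,
    114, 134, 154, 165,
)

#: (left marker, right marker) flanking interval hosting the QTL of each
#: benchmark chromosome, ordered Q1..Q4 (dense to sparse marker region).
BENCHMARK_QTL_INTERVALS: tuple[tuple[float, float], ...] = (
    (11.0, 12.0),
    (23.0, 26.0),
    (69.0, 84.0),
    (114.0, 134.0),
)

BENCHMARK_CHROM_LENGTH = 165.0
BENCHMARK_N_MARKERS = 23


@dataclass(frozen=True)
class MarkerLocus:
    """A named marker at a cM position on one chromosome."""

    chromosome_id: int
    name: str
    position: float

    def __post_init__(self) -> None:
        if self.chromosome_id < 1:
            raise ValueError(f"chromosome_id must be >= 1, got {self.chromosome_id}")
        if self.position < 0:
            raise ValueError(f"marker position must be >= 0 cM, got {self.position}")


@dataclass(frozen=True)
class ChromosomeMap:
    """An ordered set of markers on a chromosome of known cM length."""

    chromosome_id: int
    length: float
    markers: tuple[MarkerLocus, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "markers", tuple(self.markers))
        pos = [m.position for m in self.markers]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError(
                f"chromosome {self.chromosome_id}: marker positions must be strictly increasing"
            )
        if pos and pos[-1] > self.length:
            raise ValueError(
                f"chromosome {self.chromosome_id}: last marker at {pos[-1]} cM exceeds "
                f"chromosome length {self.length} cM"
            )
        for m in self.markers:
            if m.chromosome_id != self.chromosome_id:
                raise ValueError(
                    f"marker {m.name} labelled chromosome {m.chromosome_id} placed on "
                    f"chromosome {self.chromosome_id}"
                )

    @property
    def positions(self) -> tuple[float, ...]:
        return tuple(m.position for m in self.markers)

    def flanking(self, position: float) -> tuple[MarkerLocus | None, MarkerLocus | None]:
        """Nearest markers left (<=) and right (>=) of ``position``.

        At an exact marker position both elements are that marker.
        """
        left = None
        right = None
        for m in self.markers:
            if m.position <= position:
                left = m
            if m.position >= position and right is None:
                right = m
        return left, right


@dataclass(frozen=True)
class GeneticMap:
    """Ordered chromosomes; the coordinate frame for scans and intervals."""

    chromosomes: tuple[ChromosomeMap, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))
        ids = [c.chromosome_id for c in self.chromosomes]
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError(f"chromosome ids must be contiguous starting at 1, got {ids}")

    def chromosome(self, chromosome_id: int) -> ChromosomeMap:
        return self.chromosomes[chromosome_id - 1]

    @property
    def n_markers(self) -> int:
        return sum(len(c.markers) for c in self.chromosomes)

    @property
    def marker_names(self) -> list[str]:
        return [m.name for c in self.chromosomes for m in c.markers]

    def marker_table(self) -> list[MarkerLocus]:
        return [m for c in self.chromosomes for m in c.markers]


@dataclass(frozen=True)
class QTLPlacement:
    """A simulated QTL: chromosome, cM position, and additive effect ``a``.

    The genotype at the locus is coded +1/-1 for the two inbred homozygote
    classes, so the expected genetic variance contributed is ``a**2`` when
    class frequencies are 1/2.
    """

    chromosome_id: int
    position: float
    additive_effect: float

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"QTL position must be >= 0 cM, got {self.position}")


def haldane_recomb(distance: float) -> float:
    """Haldane map-distance (cM) to single-meiosis recombination fraction.

    ``r = (1 - exp(-2 d)) / 2`` with ``d`` in Morgans; monotone in distance,
    approaching 1/2 as distance grows.
    """
    if distance < 0:
        raise ValueError(f"map distance must be >= 0 cM, got {distance}")
    return 0.5 * (1.0 - math.exp(-2.0 * distance / 100.0))


def inverse_haldane(r: float) -> float:
    """Recombination fraction back to Haldane cM distance (r in [0, 0.5))."""
    if not 0.0 <= r < 0.5:
        raise ValueError(f"recombination fraction must be in [0, 0.5), got {r}")
    return -50.0 * math.log(1.0 - 2.0 * r)


def kosambi_recomb(distance: float) -> float:
    """Kosambi mapping function, ``r = tanh(2d)/2``; optional alternative."""
    if distance < 0:
        raise ValueError(f"map distance must be >= 0 cM, got {distance}")
    return 0.5 * math.tanh(2.0 * distance / 100.0)


def ril_expand(r: float) -> float:
    """Expand an F2 recombination fraction to the selfed-RIL (RI1) fraction.

    Repeated selfing to fixation accumulates recombination:
    ``R = 2r / (1 + 2r)`` (Haldane & Waddington).  ``R >= r`` with equality
    only at 0 and 1/2.
    """
    if not 0.0 <= r <= 0.5:
        raise ValueError(f"recombination fraction must be in [0, 0.5], got {r}")
    return 2.0 * r / (1.0 + 2.0 * r)


def _build_chromosome(chromosome_id: int, positions: Sequence[float], length: float) -> ChromosomeMap:
    markers = tuple(
        MarkerLocus(chromosome_id, f"c{chromosome_id}m{i + 1}", float(p))
        for i, p in enumerate(positions)
    )
    return ChromosomeMap(chromosome_id, float(length), markers)


def benchmark_map() -> GeneticMap:
    """The four-chromosome benchmark map of the interval-coverage study.

    Four identical 165-cM chromosomes, 23 markers each at whole-cM positions,
    density grading dense to sparse with distance from the position-0
    telomere.  Each chromosome carries one marker interval reserved for a
    simulated QTL: (11,12), (23,26), (69,84) and (114,134) cM, i.e. 1, 3, 15
    and 20 cM wide, are consecutive-marker intervals on every chromosome.
    """
    return GeneticMap(
        tuple(
            _build_chromosome(cid, BENCHMARK_POSITIONS, BENCHMARK_CHROM_LENGTH)
            for cid in range(1, 5)
        )
    )


def validate_benchmark_map(gmap: GeneticMap) -> None:
    """Assert the structural constraints of the benchmark map.

    Checks chromosome count/length, marker count, telomeric markers, the
    four reserved flanking intervals (1, 3, 15, 20 cM wide with no interior
    marker), and presence of the 134/154/165 markers needed by the
    chromosome-end control experiment.
    """
    if len(gmap.chromosomes) != 4:
        raise AssertionError("benchmark map must have 4 chromosomes")
    for chrom in gmap.chromosomes:
        pos = set(chrom.positions)
        if chrom.length != BENCHMARK_CHROM_LENGTH:
            raise AssertionError(f"chromosome {chrom.chromosome_id} length != 165 cM")
        if len(chrom.markers) != BENCHMARK_N_MARKERS:
            raise AssertionError(f"chromosome {chrom.chromosome_id} must carry 23 markers")
        if not {0.0, 134.0, 154.0, 165.0} <= pos:
            raise AssertionError("markers required at 0, 134, 154 and 165 cM")
        for lo, hi in BENCHMARK_QTL_INTERVALS:
            if lo not in pos or hi not in pos:
                raise AssertionError(f"flanking markers {lo}, {hi} missing")
            if any(lo < p < hi for p in pos):
                raise AssertionError(f"interval ({lo}, {hi}) must contain no interior marker")
        if any(p != int(p) for p in chrom.positions):
            raise AssertionError("benchmark positions must be whole cM numbers")


def place_qtls(
    gmap: GeneticMap,
    D: float,
    a: float,
    intervals: Iterable[tuple[int, float, float]] | None = None,
) -> list[QTLPlacement]:
    """Place one QTL per chromosome at fraction ``D`` of its flanking interval.

    ``D`` is the fractional distance from the left flanking marker (0 = on
    the marker, 0.5 = interval midpoint).  With the default intervals this
    yields the benchmark placements Q1..Q4 on chromosomes 1..4; e.g. D=0.30
    puts Q3 at 69 + 0.30*15 = 73.5 cM.  All four QTL get the same additive
    effect ``a``.

    Parameters
    ----------
    intervals
        Optional override: (chromosome_id, left, right) triples.  Defaults to
        the benchmark flanking intervals on chromosomes 1..4.
    """
    if not 0.0 <= D < 1.0:
        raise ValueError(f"fractional distance D must be in [0, 1), got {D}")
    if intervals is None:
        intervals = [
            (cid, lo, hi) for cid, (lo, hi) in enumerate(BENCHMARK_QTL_INTERVALS, start=1)
        ]
    placements = []
    for cid, lo, hi in intervals:
        chrom = gmap.chromosome(cid)
        pos = lo + D * (hi - lo)
        if not 0.0 <= pos <= chrom.length:
            raise ValueError(f"QTL position {pos} outside chromosome {cid} [0, {chrom.length}]")
        placements.append(QTLPlacement(cid, pos, a))
    return placements
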