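"""Simulation of selfed recombinant-inbred-line (RI1) genotypes and traits.

Genotypes at fully inbred loci take one of two homozygote classes, coded +1
and -1.  Along a chromosome the genotype process is simulated as a
first-order Markov chain: adjacent loci at map distance ``d`` differ with
probability ``ril_expand(haldane_recomb(d))``, the terminal-generation RIL
recombination fraction.  Chromosomes are independent, individuals i.i.d.

Traits are additive: ``y = a * sum_k q_k + e`` with Gaussian residual noise
scaled so the *expected* broad-sense heritability equals ``h2`` (each +-1
QTL with class frequency 1/2 contributes expected variance ``a**2``).
Realized per-dataset heritability therefore fluctuates around ``h2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from qtlci.genmap import (
    ChromosomeMap,
    GeneticMap,
    MarkerLocus,
    QTLPlacement,
    haldane_recomb,
    ril_expand,
)

__all__ = [
    "GenotypeMatrix",
    "TraitVector",
    "SimulatedDataset",
    "simulate_genotypes",
    "simulate_trait",
    "make_dataset",
    "insert_pseudoloci",
    "dataset_rng",
]

#: name given to QTL pseudo-loci temporarily spliced into a map
_PSEUDO_PREFIX = "QTL_"


@dataclass(frozen=True)
class GenotypeMatrix:
    """n x L matrix of +-1 homozygote codes with per-locus metadata."""

    values: np.ndarray
    loci: tuple[MarkerLocus, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[1] != len(self.loci):
            raise ValueError(
                f"genotype matrix shape {v.shape} does not match {len(self.loci)} loci"
            )
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "loci", tuple(self.loci))

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class TraitVector:
    """Quantitative trait measurements, one per individual."""

    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class SimulatedDataset:
    """A mapping population: map, marker genotypes, trait, hidden truth.

    ``truth`` is empty for datasets read from files (real data carries no
    known QTL placements).
    """

    map: GeneticMap
    genotypes: GenotypeMatrix
    trait: TraitVector
    truth: tuple[QTLPlacement, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "truth", tuple(self.truth))
        if self.genotypes.values.shape[1] != self.map.n_markers:
            raise ValueError("genotype columns must correspond 1:1 to map markers")
        if self.trait.n != self.genotypes.n:
            raise ValueError("trait length must equal number of individuals")

    @property
    def n(self) -> int:
        return self.trait.n


def dataset_rng(master_seed: int, index: int) -> np.random.Generator:
    """Independent per-dataset stream ``index`` under one master seed.

    Uses :class:`numpy.random.SeedSequence` spawning by counter so any
    dataset of a study is reproducible in isolation.
    """
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(index,)))


def _switch_probabilities(chrom: ChromosomeMap) -> np.ndarray:
    d = np.diff(np.asarray(chrom.positions, dtype=float))
    return np.array([ril_expand(haldane_recomb(di)) for di in d])


def simulate_genotypes(gmap: GeneticMap, n: int, rng: np.random.Generator) -> GenotypeMatrix:
    """Draw n i.i.d. RI1 individuals at every locus of ``gmap``.

    The first locus of each chromosome is +-1 with probability 1/2; each
    subsequent locus flips relative to its left neighbour with the
    RIL-expanded Haldane recombination probability for their distance.
    """
    if n < 1:
        raise ValueError(f"population size must be >= 1, got {n}")
    blocks = []
    for chrom in gmap.chromosomes:
        L = len(chrom.markers)
        if L == 0:
            continue
        R = _switch_probabilities(chrom)  # (L-1,)
        start = rng.choice([-1.0, 1.0], size=(n, 1))
        if L == 1:
            blocks.append(start)
            continue
        flips = np.where(rng.random(size=(n, L - 1)) < R, -1.0, 1.0)
        # cumulative product of flip signs propagates the chain along the chromosome
        blocks.append(start * np.cumprod(np.concatenate([np.ones((n, 1)), flips], axis=1), axis=1))
    values = np.concatenate(blocks, axis=1)
    return GenotypeMatrix(values, tuple(gmap.marker_table()))


def simulate_trait(
    qtl_genotypes: np.ndarray,
    a: float,
    h2: float,
    rng: np.random.Generator,
) -> TraitVector:
    """Additive trait from QTL genotype codes at expected heritability ``h2``.

    ``y_i = a * sum_k q_ik + e_i`` with ``e_i ~ N(0, s2)`` and
    ``s2 = K * a**2 * (1 - h2) / h2`` for K QTL, the residual variance that
    makes the *expected* genetic variance fraction equal ``h2``.  The
    expected trait mean is zero.
    """
    if not 0.0 < h2 < 1.0:
        raise ValueError(f"heritability must be in (0, 1), got {h2}")
    q = np.asarray(qtl_genotypes, dtype=float)
    if q.ndim == 1:
        q = q[:, None]
    n, k = q.shape
    sigma2_e = k * a * a * (1.0 - h2) / h2
    if sigma2_e == 0.0:
        # a == 0 with h2 fixed: degenerate; emit unit-variance noise
        sigma2_e = 1.0
    y = a * q.sum(axis=1) + rng.normal(0.0, np.sqrt(sigma2_e), size=n)
    return TraitVector(y)


def insert_pseudoloci(gmap: GeneticMap, qtls: list[QTLPlacement]) -> tuple[GeneticMap, list[int]]:
    """Splice QTL pseudo-loci into a map; return the map and their column indices.

    A QTL coincident with a marker still gets its own pseudo-locus column
    offset by nothing (zero distance, hence an identical genotype column).
    Returns the augmented map and the flat locus indices of the QTL columns,
    ordered as ``qtls``.
    """
    by_chrom: dict[int, list[tuple[int, QTLPlacement]]] = {}
    for k, q in enumerate(qtls):
        by_chrom.setdefault(q.chromosome_id, []).append((k, q))

    new_chroms = []
    qtl_index: dict[int, int] = {}
    offset = 0
    for chrom in gmap.chromosomes:
        entries: list[tuple[float, int, MarkerLocus]] = [
            (m.position, 1, m) for m in chrom.markers
        ]
        for k, q in by_chrom.get(chrom.chromosome_id, []):
            if not 0.0 <= q.position <= chrom.length:
                raise ValueError(
                    f"QTL at {q.position} cM outside chromosome {chrom.chromosome_id}"
                )
            entries.append(
                (q.position, 0, MarkerLocus(chrom.chromosome_id, f"{_PSEUDO_PREFIX}{k + 1}", q.position))
            )
        # sort by position; pseudo-loci (flag 0) precede a coincident marker so
        # strictly-increasing map validation is bypassed via tiny separation
        entries.sort(key=lambda t: (t[0], t[1]))
        loci = [e[2] for e in entries]
        for i, e in enumerate(entries):
            if e[1] == 0:
                k = int(e[2].name[len(_PSEUDO_PREFIX):]) - 1
                qtl_index[k] = offset + i
        offset += len(loci)
        # positions may tie when a QTL sits exactly on a marker; ChromosomeMap
        # forbids ties, so separate coincident loci by an exact-zero-distance
        # bookkeeping: build the chromosome without validation via object list
        new_chroms.append(_ChromWithTies(chrom.chromosome_id, chrom.length, tuple(loci)))
    aug = GeneticMap(tuple(new_chroms))
    return aug, [qtl_index[k] for k in range(len(qtls))]


class _ChromWithTies(ChromosomeMap):
    """Chromosome map allowing coincident loci (QTL placed exactly at a marker)."""

    def __post_init__(self) -> None:  # relax strict ordering to non-decreasing
        object.__setattr__(self, "markers", tuple(self.markers))
        pos = [m.position for m in self.markers]
        if any(b < a for a, b in zip(pos, pos[1:])):
            raise ValueError("locus positions must be non-decreasing")


def make_dataset(
    gmap: GeneticMap,
    qtls: list[QTLPlacement],
    n: int,
    h2: float,
    rng: np.random.Generator,
) -> SimulatedDataset:
    """Simulate one RI1 dataset: genotypes at markers + QTL, trait, truth.

    QTL pseudo-loci are spliced into the map for genotype simulation and for
    the trait, then dropped from the released genotype matrix; the true
    placements are recorded in ``truth``.
    """
    aug_map, qtl_cols = insert_pseudoloci(gmap, qtls)
    full = simulate_genotypes(aug_map, n, rng)
    a_effects = {q.additive_effect for q in qtls}
    if len(a_effects) > 1:
        # heterogeneous effects: build trait manually with per-QTL scaling
        q_mat = full.values[:, qtl_cols]
        a_vec = np.array([q.additive_effect for q in qtls])
        sigma2_e = float(np.sum(a_vec**2)) * (1.0 - h2) / h2
        y = q_mat @ a_vec + rng.normal(0.0, np.sqrt(sigma2_e), size=n)
        trait = TraitVector(y)
    else:
        a = qtls[0].additive_effect if qtls else 0.0
        trait = simulate_trait(full.values[:, qtl_cols], a, h2, rng)
    keep = [i for i in range(len(full.loci)) if not full.loci[i].name.startswith(_PSEUDO_PREFIX)]
    released = GenotypeMatrix(full.values[:, keep], tuple(gmap.marker_table()))
    return SimulatedDataset(gmap, released, trait, tuple(qtls))
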