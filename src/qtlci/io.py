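"""File formats and fixture generation.

Native formats are minimal text files:

- map TSV: columns ``chromosome_id``, ``marker_name``, ``position_cM`` with
  a header line; markers must appear sorted by position within chromosome.
- dataset CSV: one row per individual, one column per marker (``+1``/``-1``
  codes, or ``AA``/``BB`` with ``letters=True``) followed by a ``trait``
  column; marker columns must match the companion map.
"""

from __future__ import annotations

import json
import platform
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from qtlci.genmap import ChromosomeMap, GeneticMap, MarkerLocus, QTLPlacement, benchmark_map, place_qtls
from qtlci.popsim import GenotypeMatrix, SimulatedDataset, TraitVector, dataset_rng, make_dataset

__all__ = [
    "read_map",
    "write_map",
    "read_dataset",
    "write_dataset",
    "make_fixture",
    "RunManifest",
    "MapFormatError",
    "DatasetFormatError",
]

FIXTURE_KINDS = ("tiny-null", "tiny-one-qtl", "benchmark-mini")


class MapFormatError(ValueError):
    """A genetic-map file violates the TSV contract."""


class DatasetFormatError(ValueError):
    """A genotype/phenotype file violates the CSV contract."""


@dataclass
class RunManifest:
    """Everything needed to reproduce a CLI run bit-for-bit."""

    command: str
    seed: int
    config: dict = field(default_factory=dict)
    package_version: str = ""
    replicate_counts: dict = field(default_factory=dict)
    timestamp: str = ""
    python: str = ""

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def create(cls, command: str, seed: int, config: dict, counts: dict | None = None) -> "RunManifest":
        from qtlci import __version__

        return cls(
            command=command,
            seed=seed,
            config=config,
            package_version=__version__,
            replicate_counts=counts or {},
            timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
            python=platform.python_version(),
        )


def write_map(gmap: GeneticMap, path: str | Path) -> None:
    """Write a genetic map as the native TSV format."""
    rows = [
        {"chromosome_id": m.chromosome_id, "marker_name": m.name, "position_cM": m.position}
        for m in gmap.marker_table()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_map(path: str | Path, lengths: dict[int, float] | None = None) -> GeneticMap:
    """Read a genetic map TSV; chromosome length defaults to the last marker.

    Raises :class:`MapFormatError` (naming the offending line) on unsorted
    or duplicate positions, missing columns, or an empty file.
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise MapFormatError(f"{path}: empty map file") from None
    required = {"chromosome_id", "marker_name", "position_cM"}
    if not required <= set(df.columns):
        raise MapFormatError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    if df.empty:
        raise MapFormatError(f"{path}: map contains no markers")
    chroms = []
    for cid in sorted(df["chromosome_id"].unique()):
        sub = df[df["chromosome_id"] == cid]
        markers = []
        prev = -np.inf
        for row in sub.itertuples():
            line_no = row.Index + 2  # header is line 1
            pos = float(row.position_cM)
            if pos <= prev:
                raise MapFormatError(
                    f"{path}:{line_no}: position {pos} not strictly increasing "
                    f"on chromosome {cid}"
                )
            prev = pos
            markers.append(MarkerLocus(int(cid), str(row.marker_name), pos))
        length = (lengths or {}).get(int(cid), markers[-1].position)
        chroms.append(ChromosomeMap(int(cid), length, tuple(markers)))
    return GeneticMap(tuple(chroms))


def write_dataset(dataset: SimulatedDataset, path: str | Path, letters: bool = False) -> None:
    """Write genotypes + trait as the native CSV (``+1``/``-1`` or AA/BB codes)."""
    names = dataset.map.marker_names
    values = dataset.genotypes.values
    if letters:
        cols = {nm: np.where(values[:, j] > 0, "AA", "BB") for j, nm in enumerate(names)}
    else:
        cols = {nm: values[:, j].astype(int) for j, nm in enumerate(names)}
    df = pd.DataFrame(cols)
    df["trait"] = dataset.trait.values
    df.to_csv(path, index=False)


def read_dataset(map_path: str | Path, data_path: str | Path) -> SimulatedDataset:
    """Read a dataset CSV against its companion map TSV.

    Accepts ``+1``/``-1`` (any integer spelling) or ``AA``/``BB`` genotype
    codes; raises :class:`DatasetFormatError` listing offending cells for
    any other value, and on missing marker or trait columns.  The returned
    dataset has no truth (real data carries no known QTL placements).
    """
    gmap = read_map(map_path)
    df = pd.read_csv(data_path)
    if "trait" not in df.columns:
        raise DatasetFormatError(f"{data_path}: missing required 'trait' column")
    names = gmap.marker_names
    missing = [nm for nm in names if nm not in df.columns]
    if missing:
        raise DatasetFormatError(f"{data_path}: missing marker columns {missing[:5]}")
    geno = np.empty((len(df), len(names)))
    bad: list[str] = []
    for j, nm in enumerate(names):
        col = df[nm]
        if col.dtype == object:
            vals = col.astype(str).str.strip()
            ok = vals.isin(["AA", "BB"])
            geno[:, j] = np.where(vals == "AA", 1.0, -1.0)
        else:
            vals = col.astype(float)
            ok = vals.isin([1.0, -1.0])
            geno[:, j] = vals
        for i in np.nonzero(~ok.to_numpy())[0]:
            bad.append(f"row {i + 1}, marker {nm}: {col.iloc[i]!r}")
    if bad:
        raise DatasetFormatError(
            f"{data_path}: {len(bad)} cells outside the two-class alphabet; first: "
            + "; ".join(bad[:5])
        )
    return SimulatedDataset(
        gmap,
        GenotypeMatrix(geno, tuple(gmap.marker_table())),
        TraitVector(df["trait"].to_numpy(dtype=float)),
        (),
    )


def _tiny_map() -> GeneticMap:
    chroms = []
    for cid in (1, 2):
        markers = tuple(
            MarkerLocus(cid, f"c{cid}m{i + 1}", p) for i, p in enumerate((0.0, 10.0, 20.0, 35.0, 50.0))
        )
        chroms.append(ChromosomeMap(cid, 50.0, markers))
    return GeneticMap(tuple(chroms))


def make_fixture(kind: str, seed: int = 11) -> SimulatedDataset:
    """Small deterministic datasets for tests and examples.

    - ``tiny-one-qtl``: 2 chromosomes x 5 markers (50 cM), n = 60, one
      strong QTL at the 10-cM marker of chromosome 1.
    - ``tiny-null``: the same map with no genetic effect (a = 0).
    - ``benchmark-mini``: the full benchmark map, n = 200, QTL at markers
      (D = 0) with the study's effect size and heritability.
    """
    rng = dataset_rng(seed, 0)
    if kind == "tiny-one-qtl":
        gmap = _tiny_map()
        return make_dataset(gmap, [QTLPlacement(1, 10.0, 2.0)], 60, 0.8, rng)
    if kind == "tiny-null":
        gmap = _tiny_map()
        return make_dataset(gmap, [QTLPlacement(1, 10.0, 0.0)], 60, 0.8, rng)
    if kind == "benchmark-mini":
        gmap = benchmark_map()
        return make_dataset(gmap, place_qtls(gmap, 0.0, 1.0), 200, 0.6, rng)
    raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
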