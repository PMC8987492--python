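"""Phased haplotype panels and marker maps.

The central containers of the package: a :class:`MarkerMap` describing SNP
positions on a physical and genetic map, and a :class:`HaplotypePanel`
holding phased binary haplotypes for a set of individuals together with
their pedigree and breed labels.

Alleles are coded 0 (reference) / 1 (alternative).  Haplotype axis order is
``(individual, parent-of-origin, marker)`` with index 0 = paternal,
1 = maternal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MarkerMap", "HaplotypePanel", "PATERNAL", "MATERNAL"]

PATERNAL = 0
MATERNAL = 1


@dataclass(frozen=True)
class MarkerMap:
    """Ordered SNP map with physical (bp) and genetic (Morgan) positions.

    Markers must be strictly sorted by (chromosome, position_bp), with no
    duplicate physical positions within a chromosome, and genetic positions
    non-decreasing within each chromosome.
    """

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("marker_id", "chromosome", "position_bp", "genetic_pos_morgan")

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise ValueError(f"marker map is missing columns {missing}")
        if (t["position_bp"] < 1).any() or (t["chromosome"] < 1).any():
            raise ValueError("positions and chromosomes must be >= 1")
        key = list(zip(t["chromosome"], t["position_bp"]))
        if key != sorted(key) or len(set(key)) != len(key):
            raise ValueError(
                "markers must be strictly sorted by (chromosome, position_bp) "
                "with unique positions per chromosome"
            )
        for _, g in t.groupby("chromosome", sort=False):
            gp = g["genetic_pos_morgan"].to_numpy()
            if (np.diff(gp) < 0).any() or (gp < 0).any():
                raise ValueError("genetic positions must be non-decreasing and >= 0")

    # -- construction ----------------------------------------------------
    @classmethod
    def uniform_random(
        cls,
        n_markers: int,
        n_chromosomes: int,
        chromosome_length_bp: int,
        cm_per_mb: float = 1.0,
        rng: np.random.Generator | None = None,
    ) -> "MarkerMap":
        """Random marker positions, near-equal marker counts per chromosome.

        The genetic map is linear: ``cm_per_mb`` centiMorgan per megabase
        (default 1 cM/Mb, the usual cattle average).
        """
        if n_markers < n_chromosomes:
            raise ValueError("need at least one marker per chromosome")
        rng = np.random.default_rng(rng)
        per = np.full(n_chromosomes, n_markers // n_chromosomes)
        per[: n_markers % n_chromosomes] += 1
        rows = []
        morgan_per_bp = cm_per_mb * 1e-8
        for c in range(n_chromosomes):
            pos = np.sort(
                rng.choice(np.arange(1, chromosome_length_bp + 1), size=per[c], replace=False)
            )
            for p in pos:
                rows.append((f"snp{c + 1}_{p}", c + 1, int(p), p * morgan_per_bp))
        return cls(pd.DataFrame(rows, columns=list(cls.REQUIRED)))

    # -- views -----------------------------------------------------------
    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def marker_ids(self) -> np.ndarray:
        return self.table["marker_id"].to_numpy()

    @property
    def chromosomes(self) -> np.ndarray:
        return np.unique(self.table["chromosome"].to_numpy())

    def chromosome_slices(self) -> dict[int, slice]:
        """Map chromosome -> contiguous slice of marker indices."""
        chrom = self.table["chromosome"].to_numpy()
        out: dict[int, slice] = {}
        for c in np.unique(chrom):
            idx = np.flatnonzero(chrom == c)
            out[int(c)] = slice(int(idx[0]), int(idx[-1]) + 1)
        return out

    def subset(self, indices: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.table.iloc[np.asarray(indices)].reset_index(drop=True))

    def same_map(self, other: "MarkerMap") -> bool:
        return self.table[list(self.REQUIRED)].equals(other.table[list(self.REQUIRED)])


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes with pedigree and breed labels.

    Parameters
    ----------
    individuals
        DataFrame with columns ``id``, ``sire_id``, ``dam_id``,
        ``breed_label``; parent ids may be None for founders.
    haplotypes
        ``(N, 2, M)`` array of 0/1 alleles; axis 1 is (paternal, maternal).
    marker_map
        The shared :class:`MarkerMap` (``M`` markers).
    """

    individuals: pd.DataFrame
    haplotypes: np.ndarray
    marker_map: MarkerMap

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 3 or self.haplotypes.shape[1] != 2:
            raise ValueError("haplotypes must have shape (N, 2, M)")
        if self.haplotypes.shape[0] != len(self.individuals):
            raise ValueError("individual table and haplotype array disagree on N")
        if self.haplotypes.shape[2] != self.marker_map.n_markers:
            raise ValueError("haplotype array and marker map disagree on M")
        if self.haplotypes.size and self.haplotypes.max() > 1:
            raise ValueError("alleles must be 0/1")
        for col in ("id", "sire_id", "dam_id", "breed_label"):
            if col not in self.individuals.columns:
                raise ValueError(f"individual table is missing column {col!r}")
        if self.individuals["id"].duplicated().any():
            raise ValueError("duplicate individual ids")
        self.individuals = self.individuals.reset_index(drop=True)

    # -- views -----------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[2]

    @property
    def ids(self) -> np.ndarray:
        return self.individuals["id"].to_numpy()

    def dosages(self) -> np.ndarray:
        """(N, M) count of the alternative allele, in {0, 1, 2}."""
        return self.haplotypes.sum(axis=1, dtype=np.int16)

    def allele_frequencies(self) -> np.ndarray:
        """(M,) alternative-allele frequency across the panel."""
        return self.haplotypes.mean(axis=(0, 1))

    def heterozygosity(self) -> np.ndarray:
        """(M,) observed heterozygosity per marker."""
        return (self.haplotypes[:, 0, :] != self.haplotypes[:, 1, :]).mean(axis=0)

    # -- manipulation ----------------------------------------------------
    def subset(self, index: np.ndarray) -> "HaplotypePanel":
        """Row-subset by positional index (order preserved)."""
        index = np.asarray(index)
        return HaplotypePanel(
            self.individuals.iloc[index].reset_index(drop=True),
            self.haplotypes[index],
            self.marker_map,
        )

    def subset_ids(self, ids) -> "HaplotypePanel":
        pos = pd.Index(self.individuals["id"]).get_indexer(list(ids))
        if (pos < 0).any():
            raise KeyError("unknown individual id(s)")
        return self.subset(pos)

    def subset_markers(self, marker_index: np.ndarray) -> "HaplotypePanel":
        marker_index = np.asarray(marker_index)
        if marker_index.dtype == bool:
            marker_index = np.flatnonzero(marker_index)
        return HaplotypePanel(
            self.individuals.copy(),
            self.haplotypes[:, :, marker_index],
            self.marker_map.subset(marker_index),
        )

    @staticmethod
    def concat(panels: list["HaplotypePanel"]) -> "HaplotypePanel":
        first = panels[0]
        for p in panels[1:]:
            if not first.marker_map.same_map(p.marker_map):
                raise ValueError("panels are on different marker maps")
        return HaplotypePanel(
            pd.concat([p.individuals for p in panels], ignore_index=True),
            np.concatenate([p.haplotypes for p in panels], axis=0),
            first.marker_map,
        )
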