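"""File formats: phased VCF, haplotype tables, maps, pedigrees, origin tracks.

Conventions
-----------
* VCF genotypes must be phased ("a|b"); the first allele is the paternal
  haplotype.  Multiallelic records are rejected.
* Physical positions are 1-based (VCF convention).  The origin track is a
  BED-like TSV with 1-based *closed* intervals — dialect tagged ``bed1`` in
  the header to avoid confusion with standard 0-based half-open BED.
* Every non-VCF output starts with ``#`` header lines carrying the tool
  version, the seed and a config hash, so reruns are auditable.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .origins import OriginMap, origins_to_segments, segments_to_origins
from .panel import HaplotypePanel, MarkerMap

__all__ = ["read_phased_genotypes", "write_vcf", "write_haplotype_tsv",
           "read_haplotype_tsv", "write_marker_map", "read_marker_map",
           "write_pedigree", "write_phenotypes", "read_phenotypes",
           "write_origin_track", "read_origin_track", "header_lines",
           "config_hash"]


def config_hash(config: object) -> str:
    return hashlib.sha1(repr(config).encode()).hexdigest()[:12]


def header_lines(seed=None, config=None, dialect: str | None = None) -> list[str]:
    lines = [f"# boablup v{__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config is not None:
        lines.append(f"# config_hash: {config_hash(config)}")
    if dialect:
        lines.append(f"# dialect: {dialect}")
    return lines


def _write_table(df: pd.DataFrame, path, seed=None, config=None, dialect=None):
    path = Path(path)
    with path.open("w") as fh:
        for line in header_lines(seed, config, dialect):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(panel: HaplotypePanel, path, seed=None, config=None) -> None:
    """Write a panel as a phased VCF (REF=A, ALT=G placeholders, GT only)."""
    t = panel.marker_map.table
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=boablup_v{__version__}\n")
        if seed is not None:
            fh.write(f"##boablup_seed={seed}\n")
        if config is not None:
            fh.write(f"##boablup_config_hash={config_hash(config)}\n")
        fh.write("##boablup_haplotype_order=paternal|maternal\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in panel.marker_map.chromosomes:
            end = int(t.loc[t["chromosome"] == c, "position_bp"].max())
            fh.write(f"##contig=<ID={c},length={end + 1}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.ids) + "\n")
        pat = panel.haplotypes[:, 0, :]
        mat = panel.haplotypes[:, 1, :]
        for m in range(panel.n_markers):
            row = t.iloc[m]
            gts = "\t".join(f"{a}|{b}" for a, b in zip(pat[:, m], mat[:, m]))
            fh.write(f"{row.chromosome}\t{row.position_bp}\t{row.marker_id}"
                     f"\tA\tG\t.\t.\t.\tGT\t{gts}\n")


def read_phased_genotypes(
    path,
    fmt: str = "vcf",
    breed_label: str = "NA",
    marker_map: MarkerMap | None = None,
    cm_per_mb: float = 1.0,
) -> HaplotypePanel:
    """Read a phased panel from VCF or a haplotype TSV.

    VCF input must be strictly phased and biallelic; the first GT allele is
    taken as the paternal haplotype.  For ``haplotype_tsv`` a ``marker_map``
    must be supplied (the TSV stores alleles only).
    """
    if fmt == "vcf":
        return _read_vcf(path, breed_label, cm_per_mb)
    if fmt == "haplotype_tsv":
        if marker_map is None:
            raise ValueError("haplotype_tsv input needs a marker_map")
        return read_haplotype_tsv(path, marker_map, breed_label)
    raise ValueError(f"unknown format {fmt!r}")


def _read_vcf(path, breed_label, cm_per_mb):
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, haps = [], []
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(
                f"multiallelic record at {v.CHROM}:{v.POS} ({v.ID}); only "
                "biallelic SNPs are supported"
            )
        g = np.array(v.genotypes, dtype=object)
        phased = np.array([row[2] for row in v.genotypes], dtype=bool)
        if not phased.all():
            bad = samples[int(np.flatnonzero(~phased)[0])]
            raise ValueError(
                f"unphased genotype for sample {bad} at {v.CHROM}:{v.POS} "
                f"({v.ID}); phased input ('|') is required"
            )
        alleles = np.array([[row[0], row[1]] for row in v.genotypes], dtype=np.int16)
        if alleles.min() < 0 or alleles.max() > 1:
            raise ValueError(f"missing or non-binary allele at {v.CHROM}:{v.POS}")
        rows.append((v.ID or f"snp{v.CHROM}_{v.POS}", int(v.CHROM), int(v.POS),
                     int(v.POS) * cm_per_mb * 1e-8))
        haps.append(alleles)
    table = pd.DataFrame(rows, columns=list(MarkerMap.REQUIRED))
    arr = np.stack(haps, axis=-1) if haps else np.zeros((len(samples), 2, 0), np.uint8)
    inds = pd.DataFrame({"id": samples, "sire_id": None, "dam_id": None,
                         "breed_label": breed_label})
    return HaplotypePanel(inds, arr.astype(np.uint8), MarkerMap(table))


# ---------------------------------------------------------------------------
# Haplotype / map / pedigree / phenotype tables
# ---------------------------------------------------------------------------

def write_haplotype_tsv(panel: HaplotypePanel, path, seed=None, config=None):
    """One row per haplotype: individual_id, parent_of_origin, allele string."""
    rows = []
    for i, ind in enumerate(panel.ids):
        for h, name in enumerate(("pat", "mat")):
            rows.append((ind, name, "".join(map(str, panel.haplotypes[i, h]))))
    _write_table(pd.DataFrame(rows, columns=["individual_id", "parent_of_origin",
                                             "alleles"]),
                 path, seed, config)


def read_haplotype_tsv(path, marker_map: MarkerMap, breed_label="NA") -> HaplotypePanel:
    df = _read_table(path)
    ids = df["individual_id"].unique()
    n, m = len(ids), marker_map.n_markers
    haps = np.zeros((n, 2, m), dtype=np.uint8)
    pos = {ind: i for i, ind in enumerate(ids)}
    for row in df.itertuples(index=False):
        alleles = np.frombuffer(row.alleles.encode(), dtype=np.uint8) - ord("0")
        if alleles.size != m:
            raise ValueError("haplotype length does not match the marker map")
        h = 0 if row.parent_of_origin == "pat" else 1
        haps[pos[row.individual_id], h] = alleles
    inds = pd.DataFrame({"id": ids, "sire_id": None, "dam_id": None,
                         "breed_label": breed_label})
    return HaplotypePanel(inds, haps, marker_map)


def write_marker_map(marker_map: MarkerMap, path, seed=None, config=None):
    """PLINK .bim-compatible TSV: chrom, id, genetic position (Morgan), bp."""
    t = marker_map.table
    bim = pd.DataFrame({
        "chromosome": t["chromosome"], "marker_id": t["marker_id"],
        "genetic_pos_morgan": t["genetic_pos_morgan"],
        "position_bp": t["position_bp"], "allele1": "G", "allele2": "A",
    })
    _write_table(bim, path, seed, config)


def read_marker_map(path) -> MarkerMap:
    df = _read_table(path)
    return MarkerMap(df[list(MarkerMap.REQUIRED)].copy())


def write_pedigree(panel: HaplotypePanel, path, seed=None, config=None):
    ped = panel.individuals[["id", "sire_id", "dam_id"]].fillna("0")
    _write_table(ped, path, seed, config)


def write_phenotypes(pheno: pd.DataFrame, path, seed=None, config=None):
    _write_table(pheno[["individual_id", "y", "tbv"]], path, seed, config)


def read_phenotypes(path) -> pd.DataFrame:
    return _read_table(path)


# ---------------------------------------------------------------------------
# Origin track (BED-like, dialect bed1)
# ---------------------------------------------------------------------------

def write_origin_track(origins: OriginMap, panel: HaplotypePanel, path,
                       seed=None, config=None):
    """Per-haplotype origin segments, 1-based closed intervals (bed1)."""
    seg = origins_to_segments(origins, panel)
    _write_table(seg, path, seed, config, dialect="bed1")


def read_origin_track(path, panel: HaplotypePanel, group_labels) -> OriginMap:
    seg = _read_table(path)
    return segments_to_origins(seg, panel, group_labels)
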