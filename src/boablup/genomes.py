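"""Two-breed genome simulator with historic one-way admixture.

Stands in for real SNP-chip founder data: two breeds diverge from a common
ancestral population under a Balding–Nichols model (ancestral allele
frequencies uniform, breed frequencies Beta-distributed around them with a
configurable F_ST), the small target breed (AN) receives a single pulse of
migrant haplotypes from the large breed (HF) a configurable number of
generations ago, and the admixed population then mates at random so that
introgressed material fragments into mosaic segments by recombination.  The
true breed origin of every allele is tracked through every meiosis.

Meiosis uses a Haldane model: crossover counts are Poisson with mean equal
to the chromosome's genetic length in Morgans, crossover positions uniform
in genetic distance, no interference, no mutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .origins import OriginMap
from .panel import HaplotypePanel, MarkerMap

__all__ = ["FounderSimConfig", "FounderSimResult", "simulate_founder_breeds",
           "simulate_generation", "gamete_sources"]

TARGET_BREED = "AN"
DONOR_BREED = "HF"


@dataclass(frozen=True)
class FounderSimConfig:
    """Configuration of the two-breed founder simulation.

    ``admixture_fraction`` is the proportion of HF migrant haplotypes in the
    pulse generation; it is also the expected genome-wide HF-origin fraction
    in the admixed breed (default 0.157).  With ``n_pool_haplotypes`` set,
    each breed is founded from a finite haplotype pool expanded through
    ``n_ld_generations`` rounds of random mating, which creates within-breed
    linkage disequilibrium and haplotype sharing; with ``None`` (default)
    haplotypes are drawn site-independently from the breed frequencies.
    """

    n_markers: int = 1000
    n_chromosomes: int = 3
    chromosome_length_bp: int = 100_000_000
    fst: float = 0.10
    ancestral_maf_range: tuple[float, float] = (0.05, 0.95)
    admixture_fraction: float = 0.157
    admixture_generations_ago: int = 10
    breed_sizes: dict = field(default_factory=lambda: {"AN": 500, "HF": 1000})
    n_native_reference: int = 100
    n_pool_haplotypes: int | None = None
    n_ld_generations: int = 4
    cm_per_mb: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.admixture_fraction <= 1.0:
            raise ValueError("admixture_fraction must be in [0, 1]")
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must be in the open interval (0, 1)")
        if self.n_markers < self.n_chromosomes:
            raise ValueError("n_markers must be >= n_chromosomes")
        if self.admixture_generations_ago < 1:
            raise ValueError("admixture_generations_ago must be >= 1")
        if min(self.breed_sizes.values()) < 1:
            raise ValueError("breed sizes must be >= 1")


@dataclass
class FounderSimResult:
    """Founder panels, the true origin map of the admixed breed, and extras.

    ``an_native_reference`` is a held-aside purebred AN cohort (never part
    of the admixture pulse) usable as the target-breed reference panel for
    segment-based origin assignment.  ``breed_frequencies`` are the
    Balding–Nichols breed allele frequencies the panels were drawn from.
    """

    hf: HaplotypePanel
    an: HaplotypePanel
    true_origins: OriginMap
    an_native_reference: HaplotypePanel
    breed_frequencies: pd.DataFrame


# ---------------------------------------------------------------------------
# Meiosis
# ---------------------------------------------------------------------------

def gamete_sources(rng: np.random.Generator, marker_map: MarkerMap) -> np.ndarray:
    """Sample one meiosis: which parental haplotype each marker is copied from.

    Returns an (M,) array of 0/1.  Per chromosome the crossover count is
    Poisson(genetic length in Morgan), positions are uniform on the genetic
    map (Haldane, no interference), and the starting haplotype is random.
    """
    gpos = marker_map.table["genetic_pos_morgan"].to_numpy()
    src = np.empty(marker_map.n_markers, dtype=np.int8)
    for sl in marker_map.chromosome_slices().values():
        g = gpos[sl]
        lo, hi = g[0], g[-1]
        length = hi - lo
        n_cx = rng.poisson(length) if length > 0 else 0
        start = rng.integers(2)
        if n_cx == 0:
            src[sl] = start
            continue
        cx = np.sort(rng.uniform(lo, hi, size=n_cx))
        # crossovers strictly before a marker flip the source haplotype
        flips = np.searchsorted(cx, g, side="left")
        src[sl] = (start + flips) % 2
    return src


def _make_gamete(rng, marker_map, hap_pair, companions=()):
    """Recombine a (2, M) haplotype pair; companions recombine identically."""
    src = gamete_sources(rng, marker_map)
    cols = np.arange(hap_pair.shape[1])
    out = [hap_pair[src, cols]]
    for comp in companions:
        out.append(comp[src, cols])
    return out if companions else out[0]


# ---------------------------------------------------------------------------
# Founder breeds
# ---------------------------------------------------------------------------

def _balding_nichols_frequencies(rng, cfg: FounderSimConfig, n_breeds: int = 2):
    lo, hi = cfg.ancestral_maf_range
    p_anc = rng.uniform(lo, hi, size=cfg.n_markers)
    scale = (1.0 - cfg.fst) / cfg.fst
    freqs = [rng.beta(p_anc * scale, (1.0 - p_anc) * scale) for _ in range(n_breeds)]
    return p_anc, freqs


def _random_mating(rng, marker_map, haps, origins, n_offspring, n_generations):
    """Gene-drop ``n_generations`` of random mating at size ``n_offspring``.

    ``haps``: (N, 2, M); ``origins``: matching array or None.  Two distinct
    parents per offspring, one gamete each.  Returns the final generation.
    """
    for _ in range(n_generations):
        n_par = haps.shape[0]
        new_h = np.empty((n_offspring, 2, haps.shape[2]), dtype=haps.dtype)
        new_o = None if origins is None else np.empty_like(new_h)
        for j in range(n_offspring):
            sire, dam = rng.choice(n_par, size=2, replace=False)
            for slot, par in ((0, sire), (1, dam)):
                if origins is None:
                    new_h[j, slot] = _make_gamete(rng, marker_map, haps[par])
                else:
                    g, og = _make_gamete(rng, marker_map, haps[par], (origins[par],))
                    new_h[j, slot], new_o[j, slot] = g, og
        haps, origins = new_h, new_o
    return haps, origins


def _breed_haplotypes(rng, cfg, freqs, n_ind, marker_map):
    """Draw a purebred cohort, optionally through a finite founder-hap pool."""
    if cfg.n_pool_haplotypes is None:
        return (rng.random((n_ind, 2, cfg.n_markers)) < freqs).astype(np.uint8)
    pool = (rng.random((cfg.n_pool_haplotypes, cfg.n_markers)) < freqs).astype(np.uint8)
    picks = rng.integers(cfg.n_pool_haplotypes, size=(n_ind, 2))
    haps = pool[picks]
    haps, _ = _random_mating(rng, marker_map, haps, None, n_ind, cfg.n_ld_generations)
    return haps


def _individual_table(prefix, n, breed):
    return pd.DataFrame(
        {"id": [f"{prefix}{j:05d}" for j in range(n)],
         "sire_id": [None] * n, "dam_id": [None] * n, "breed_label": breed}
    )


def simulate_founder_breeds(config: FounderSimConfig) -> FounderSimResult:
    """Simulate the HF and admixed AN founder panels on a shared marker map.

    The AN panel is produced by gene-dropping ``admixture_generations_ago``
    generations of random mating after a single pulse in which a fraction
    ``admixture_fraction`` of the haplotypes (rounded to a whole count) are
    copies of HF panel haplotypes; segment lengths therefore emerge from
    recombination.  The generating origin of every AN allele is recorded.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    marker_map = MarkerMap.uniform_random(
        cfg.n_markers, cfg.n_chromosomes, cfg.chromosome_length_bp, cfg.cm_per_mb, rng
    )
    _, (p_an, p_hf) = _balding_nichols_frequencies(rng, cfg)

    n_an = cfg.breed_sizes["AN"]
    n_hf = cfg.breed_sizes["HF"]

    hf_haps = _breed_haplotypes(rng, cfg, p_hf, n_hf, marker_map)
    an_pure = _breed_haplotypes(rng, cfg, p_an, n_an + cfg.n_native_reference, marker_map)
    an_ref_haps = an_pure[:cfg.n_native_reference]
    an_base = an_pure[cfg.n_native_reference:]

    # admixture pulse: replace a fixed number of AN haplotypes by HF copies
    flat = an_base.reshape(n_an * 2, cfg.n_markers).copy()
    o_flat = np.zeros_like(flat)
    n_migrant = int(round(cfg.admixture_fraction * n_an * 2))
    if n_migrant > 0:
        slots = rng.choice(n_an * 2, size=n_migrant, replace=False)
        hf_flat = hf_haps.reshape(n_hf * 2, cfg.n_markers)
        sources = rng.integers(n_hf * 2, size=n_migrant)
        flat[slots] = hf_flat[sources]
        o_flat[slots] = 1
    an_haps = flat.reshape(n_an, 2, cfg.n_markers)
    an_orig = o_flat.reshape(n_an, 2, cfg.n_markers)

    an_haps, an_orig = _random_mating(
        rng, marker_map, an_haps, an_orig, n_an, cfg.admixture_generations_ago
    )

    freq_df = pd.DataFrame(
        {"marker_id": marker_map.marker_ids, TARGET_BREED: p_an, DONOR_BREED: p_hf}
    )
    return FounderSimResult(
        hf=HaplotypePanel(_individual_table("HF", n_hf, DONOR_BREED), hf_haps, marker_map),
        an=HaplotypePanel(_individual_table("AN", n_an, TARGET_BREED), an_haps, marker_map),
        true_origins=OriginMap(an_orig, (TARGET_BREED, DONOR_BREED)),
        an_native_reference=HaplotypePanel(
            _individual_table("ANREF", cfg.n_native_reference, TARGET_BREED),
            an_ref_haps, marker_map,
        ),
        breed_frequencies=freq_df,
    )


# ---------------------------------------------------------------------------
# One further generation of breeding
# ---------------------------------------------------------------------------

def simulate_generation(
    panel: HaplotypePanel,
    n_offspring: int,
    n_sires: int,
    n_dams: int | None = None,
    equal_family_sizes: bool = True,
    seed: int | np.random.Generator = 0,
    origins: OriginMap | None = None,
    id_prefix: str | None = None,
) -> tuple[HaplotypePanel, OriginMap | None]:
    """Breed one generation from ``panel`` with recorded pedigree.

    Sires and dams are drawn (disjointly, without replacement) from the
    panel; under ``equal_family_sizes`` every sire has exactly
    ``n_offspring / n_sires`` offspring, and each offspring's dam is drawn
    at random from the dam set.  If ``origins`` is given, the true origin of
    every transmitted allele is propagated through the same crossovers.
    """
    rng = np.random.default_rng(seed)
    n = panel.n_individuals
    if n_dams is None:
        n_dams = n - n_sires
    if n_sires < 1 or n_dams < 1 or n_sires + n_dams > n:
        raise ValueError("need n_sires + n_dams distinct parents in the panel")
    if equal_family_sizes and n_offspring % n_sires != 0:
        raise ValueError("n_offspring must be divisible by n_sires for equal family sizes")

    parents = rng.choice(n, size=n_sires + n_dams, replace=False)
    sires, dams = parents[:n_sires], parents[n_sires:]
    if equal_family_sizes:
        sire_of = np.repeat(sires, n_offspring // n_sires)
    else:
        sire_of = rng.choice(sires, size=n_offspring)
    dam_of = rng.choice(dams, size=n_offspring)

    m = panel.n_markers
    haps = np.empty((n_offspring, 2, m), dtype=np.uint8)
    ocodes = None if origins is None else np.empty((n_offspring, 2, m), dtype=np.uint8)
    for j in range(n_offspring):
        for slot, par in ((0, sire_of[j]), (1, dam_of[j])):
            if origins is None:
                haps[j, slot] = _make_gamete(rng, panel.marker_map, panel.haplotypes[par])
            else:
                g, og = _make_gamete(
                    rng, panel.marker_map, panel.haplotypes[par], (origins.codes[par],)
                )
                haps[j, slot], ocodes[j, slot] = g, og

    breed = panel.individuals["breed_label"].iloc[0]
    if id_prefix is None:
        id_prefix = f"{breed}G1_"
    ids = panel.ids
    table = pd.DataFrame(
        {"id": [f"{id_prefix}{j:05d}" for j in range(n_offspring)],
         "sire_id": ids[sire_of], "dam_id": ids[dam_of], "breed_label": breed}
    )
    out_origins = None if origins is None else OriginMap(ocodes, origins.group_labels)
    return HaplotypePanel(table, haps, panel.marker_map), out_origins
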