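"""Quantitative trait simulation with origin-specific QTL effects.

QTLs are drawn from the markers segregating in both breeds; each QTL q
carries one additive effect per origin group, (a_q,AN, a_q,HF), sampled from
a bivariate normal with correlation rho (default 0.95).  Effects are scaled
per breed so that the additive variance V_A = sum_q 2 p_q (1 - p_q) a_q^2
(linkage-equilibrium formula) hits the target exactly in each pure breed.
The true breeding value of an individual sums, over QTLs and origins, the
origin-specific effect times the number of alternative-allele copies of
that origin; phenotypes add normal noise calibrated to the target
phenotypic variance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .origins import OriginMap
from .panel import HaplotypePanel, MarkerMap

__all__ = ["TraitArchitecture", "select_qtls", "sample_qtl_effects",
           "scale_effects_to_va", "additive_variance", "compute_tbv",
           "simulate_phenotypes"]


@dataclass(frozen=True)
class TraitArchitecture:
    """QTL marker indices with per-origin additive effects.

    ``effects`` has shape (n_qtl, K); column order follows ``group_labels``.
    ``effects`` is None for a freshly selected skeleton.
    """

    qtl_indices: np.ndarray
    group_labels: tuple[str, ...]
    effects: np.ndarray | None = None
    effect_correlation: float | None = None
    base_effect_variance: float | None = None

    def __post_init__(self) -> None:
        idx = np.asarray(self.qtl_indices)
        if len(np.unique(idx)) != idx.size:
            raise ValueError("QTL indices must be unique")
        object.__setattr__(self, "qtl_indices", idx)
        if self.effects is not None:
            eff = np.asarray(self.effects, dtype=float)
            if eff.shape != (idx.size, len(self.group_labels)):
                raise ValueError("effects must be (n_qtl, n_groups)")
            object.__setattr__(self, "effects", eff)

    @property
    def n_qtl(self) -> int:
        return self.qtl_indices.size


def select_qtls(
    marker_map: MarkerMap,
    eligible: np.ndarray,
    n_qtl: int,
    seed: int | np.random.Generator = 0,
    group_labels: tuple[str, ...] = ("AN", "HF"),
) -> TraitArchitecture:
    """Sample ``n_qtl`` distinct QTL markers uniformly from ``eligible``.

    ``eligible`` is a boolean mask over the map, typically the markers
    segregating in both breeds.  Selected markers are meant to be excluded
    from the prediction marker set by the caller.
    """
    eligible = np.asarray(eligible, dtype=bool)
    if eligible.size != marker_map.n_markers:
        raise ValueError("eligible mask length must equal the marker map")
    pool = np.flatnonzero(eligible)
    if n_qtl > pool.size:
        raise ValueError(f"requested {n_qtl} QTLs but only {pool.size} eligible markers")
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(pool, size=n_qtl, replace=False))
    return TraitArchitecture(chosen, tuple(group_labels))


def sample_qtl_effects(
    arch: TraitArchitecture,
    sigma_a2: float = 1.0,
    rho: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> TraitArchitecture:
    """Draw per-QTL effect pairs from N(0, sigma_a2 * [[1, rho], [rho, 1]]).

    Generalises to K groups with a compound-symmetric correlation rho.
    """
    if abs(rho) > 1:
        raise ValueError("|rho| must be <= 1")
    if sigma_a2 <= 0:
        raise ValueError("sigma_a2 must be > 0")
    k = len(arch.group_labels)
    corr = np.full((k, k), rho)
    np.fill_diagonal(corr, 1.0)
    rng = np.random.default_rng(seed)
    # Cholesky with a tolerance for the rho=1 degenerate case
    lam, vec = np.linalg.eigh(sigma_a2 * corr)
    root = vec * np.sqrt(np.clip(lam, 0.0, None))
    eff = rng.standard_normal((arch.n_qtl, k)) @ root.T
    return replace(arch, effects=eff, effect_correlation=rho, base_effect_variance=sigma_a2)


def additive_variance(effects_col: np.ndarray, freqs: np.ndarray) -> float:
    """Falconer linkage-equilibrium additive variance: sum 2 p (1-p) a^2."""
    return float(np.sum(2.0 * freqs * (1.0 - freqs) * effects_col**2))


def scale_effects_to_va(
    arch: TraitArchitecture,
    qtl_frequencies: dict[str, np.ndarray],
    target_va: float = 0.3,
) -> TraitArchitecture:
    """Rescale each group's effect column so V_A equals ``target_va`` exactly.

    ``qtl_frequencies`` maps group label -> (n_qtl,) allele frequencies at
    the QTLs in that pure breed.  A single positive scalar per breed leaves
    the effect correlation unchanged.
    """
    if arch.effects is None:
        raise ValueError("architecture has no effects to scale")
    eff = arch.effects.copy()
    for k, lab in enumerate(arch.group_labels):
        p = np.asarray(qtl_frequencies[lab], dtype=float)
        va = additive_variance(eff[:, k], p)
        if va <= 0:
            raise ValueError(
                f"additive variance in {lab} is zero (all effects zero or all "
                "QTLs monomorphic); scale factor undefined"
            )
        eff[:, k] *= np.sqrt(target_va / va)
    return replace(arch, effects=eff)


def compute_tbv(
    panel: HaplotypePanel, origin_map: OriginMap, arch: TraitArchitecture
) -> np.ndarray:
    """True breeding values: TBV_i = sum_q sum_k Z_Aiqk * a_qk.

    Z_Aiqk counts the alternative-allele copies at QTL q in individual i
    whose haplotype origin is group k.
    """
    if arch.effects is None:
        raise ValueError("architecture has no effects")
    if origin_map.codes.shape[:2] != panel.haplotypes.shape[:2] or \
            origin_map.codes.shape[2] != panel.n_markers:
        raise ValueError("origin map does not cover the panel")
    q = arch.qtl_indices
    haps = panel.haplotypes[:, :, q].astype(np.float64)
    tbv = np.zeros(panel.n_individuals)
    for k in range(len(arch.group_labels)):
        z_k = (haps * (origin_map.codes[:, :, q] == k)).sum(axis=1)
        tbv += z_k @ arch.effects[:, k]
    return tbv


def simulate_phenotypes(
    tbv: np.ndarray,
    individual_ids,
    target_va: float = 0.3,
    target_vp: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Phenotypes y_i = TBV_i + e_i with e ~ N(0, target_vp - target_va).

    ``target_va`` must be the additive variance the effects were scaled to,
    so that the phenotypic variance comes out at ``target_vp``.
    """
    if target_vp <= target_va:
        raise ValueError("target_vp must exceed target_va (error variance > 0)")
    rng = np.random.default_rng(seed)
    tbv = np.asarray(tbv, dtype=float)
    e = rng.normal(0.0, np.sqrt(target_vp - target_va), size=tbv.size)
    return pd.DataFrame({"individual_id": list(individual_ids), "y": tbv + e, "tbv": tbv})
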