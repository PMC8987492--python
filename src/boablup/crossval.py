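"""Sire-family cross-validation and the breed-size scenario experiment.

The accuracy of each prediction model is measured by 5-fold cross-validation
in which whole sire families are held out together: sires are shuffled and
dealt round-robin into folds, every individual inherits its sire's fold, so
folds never share sires.  Within-breed models are fitted on the target-breed
reference folds only; multi-breed and origin-split models add the entire
donor-breed panel to the reference.  Accuracy is the Pearson correlation
between predicted GEBVs and true breeding values in the held-out fold.

The scenario runner reproduces the breed-size experiment: a fixed donor
panel, target-breed panels of increasing size with equal sire families,
several independent simulation replicates, and (optionally) a grid search
over the across-origin effect correlation r.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .blup import (BreedOriginBLUP, DesignSet, SNPBlup, VarianceSpec,
                   filter_markers)
from .genomes import (DONOR_BREED, TARGET_BREED, FounderSimConfig,
                      simulate_founder_breeds, simulate_generation)
from .origins import OriginMap, SegmentRule, assign_origins
from .panel import HaplotypePanel
from .trait import (compute_tbv, sample_qtl_effects, scale_effects_to_va,
                    select_qtls, simulate_phenotypes)

__all__ = ["CVPlan", "make_cv_plan", "run_cv", "grid_search_correlation",
           "summarize", "ScenarioConfig", "ReplicateData", "simulate_dataset",
           "run_scenario", "run_replicate", "scenario_design",
           "SCENARIO_SIZES", "DEFAULT_GRID"]

SCENARIO_SIZES = {"simAN1": 750, "simAN2": 1500, "simAN3": 3000}
#: default grid for the effect-correlation search (upper end just below 1
#: to keep Sigma positive definite)
DEFAULT_GRID = tuple(np.round(np.arange(0.05, 0.96, 0.10), 2)) + (1 - 1e-6,)

ALL_MODELS = ("boa", "snp_blup_multi", "snp_blup_within")


@dataclass(frozen=True)
class CVPlan:
    """Partition of target-breed individuals into sire-disjoint folds."""

    n_folds: int
    fold_of: pd.Series          # individual id -> fold
    sire_folds: dict            # sire id -> fold

    def fold_ids(self, fold: int) -> np.ndarray:
        return self.fold_of.index[self.fold_of == fold].to_numpy()


def make_cv_plan(
    panel: HaplotypePanel, n_folds: int = 5, seed: int | np.random.Generator = 0
) -> CVPlan:
    """Deal sires round-robin into folds; offspring inherit the sire's fold."""
    if n_folds < 2:
        raise ValueError("need at least 2 folds (1 fold leaves no held-out set)")
    sires = panel.individuals["sire_id"]
    if sires.isna().any():
        raise ValueError("every individual needs a known sire for sire-family CV")
    unique_sires = pd.unique(sires)
    if len(unique_sires) < n_folds:
        raise ValueError("fewer sires than folds")
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(unique_sires)
    sire_folds = {s: i % n_folds for i, s in enumerate(shuffled)}
    fold_of = pd.Series(
        [sire_folds[s] for s in sires], index=panel.individuals["id"].to_numpy()
    )
    return CVPlan(n_folds, fold_of, sire_folds)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn("zero-variance vector in accuracy computation; accuracy undefined")
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def _variance_spec_from_freqs(freqs: list[np.ndarray], r, target_va, target_vp, labels):
    var_k = []
    for p in freqs:
        het = float(np.sum(2.0 * p * (1.0 - p)))
        if het <= 0:
            raise ValueError("zero heterozygosity sum in a reference group")
        var_k.append(target_va / het)
    sd = np.sqrt(var_k)
    sigma = r * np.outer(sd, sd)
    np.fill_diagonal(sigma, var_k)
    return VarianceSpec(sigma, target_vp - target_va, labels)


def run_cv(
    an_panel: HaplotypePanel,
    an_phenotypes: pd.DataFrame,
    hf_panel: HaplotypePanel,
    hf_phenotypes: pd.DataFrame,
    an_origins: OriginMap,
    marker_mask: np.ndarray,
    cv_plan: CVPlan,
    models: tuple[str, ...] = ALL_MODELS,
    r: float = 0.75,
    target_va: float = 0.3,
    target_vp: float = 1.0,
    solver: str = "auto",
) -> pd.DataFrame:
    """Sire-family CV of the requested models; one row per (fold, model).

    Phenotype frames need columns ``individual_id``, ``y``, ``tbv`` and must
    cover the panels.  Only reference individuals' phenotypes enter any fit;
    validation folds contribute genotypes and TBVs alone.
    """
    unknown = set(models) - set(ALL_MODELS)
    if unknown:
        raise ValueError(f"unknown models {sorted(unknown)}")
    labels = an_origins.group_labels
    cols = np.flatnonzero(np.asarray(marker_mask))

    an_y, an_tbv = _aligned_pheno(an_phenotypes, an_panel)
    hf_y, _ = _aligned_pheno(hf_phenotypes, hf_panel)

    an_dos = an_panel.dosages()[:, cols].astype(np.float64)
    hf_dos = hf_panel.dosages()[:, cols].astype(np.float64)

    need_boa = "boa" in models
    if need_boa:
        an_haps = an_panel.haplotypes[:, :, cols].astype(np.float64)
        oc = an_origins.codes[:, :, cols]
        an_zk = []
        an_x = np.empty((an_panel.n_individuals, len(labels)))
        for k in range(len(labels)):
            delta = oc == k
            an_zk.append((an_haps * delta).sum(axis=1))
            an_x[:, k] = delta.mean(axis=(1, 2))
        hf_group = labels.index(DONOR_BREED) if DONOR_BREED in labels else 1
        hf_zk = [hf_dos if k == hf_group else np.zeros_like(hf_dos)
                 for k in range(len(labels))]
        hf_x = np.zeros((hf_panel.n_individuals, len(labels)))
        hf_x[:, hf_group] = 1.0

    folds = np.array([cv_plan.fold_of[i] for i in an_panel.ids])
    sigma_e2 = target_vp - target_va
    rows = []
    for fold in range(cv_plan.n_folds):
        val = folds == fold
        ref = ~val
        n_val, n_ref_within = int(val.sum()), int(ref.sum())
        n_ref_multi = n_ref_within + hf_panel.n_individuals
        for model in models:
            if model == "snp_blup_within":
                z_ref, y_ref = an_dos[ref], an_y[ref]
                s_a2 = _sigma_a2_from_dosage(z_ref, target_va)
                fit = SNPBlup(y_ref, z_ref, s_a2, sigma_e2).fit(method=solver)
                gebv = fit.predict_gebv(an_dos[val])
                n_ref = n_ref_within
            elif model == "snp_blup_multi":
                z_ref = np.vstack([an_dos[ref], hf_dos])
                y_ref = np.concatenate([an_y[ref], hf_y])
                s_a2 = _sigma_a2_from_dosage(z_ref, target_va)
                fit = SNPBlup(y_ref, z_ref, s_a2, sigma_e2).fit(method=solver)
                gebv = fit.predict_gebv(an_dos[val])
                n_ref = n_ref_multi
            else:  # boa
                zk_ref = [np.vstack([zk[ref], hk]) for zk, hk in zip(an_zk, hf_zk)]
                x_ref = np.vstack([an_x[ref], hf_x])
                y_ref = np.concatenate([an_y[ref], hf_y])
                p_an = an_dos[ref].mean(axis=0) / 2.0
                p_hf = hf_dos.mean(axis=0) / 2.0
                freqs = [p_an if lab == TARGET_BREED else p_hf for lab in labels]
                vs = _variance_spec_from_freqs(freqs, r, target_va, target_vp, labels)
                design = DesignSet(y_ref, x_ref, zk_ref,
                                   marker_ids=an_panel.marker_map.marker_ids[cols],
                                   group_labels=labels)
                fit = BreedOriginBLUP(design, vs).fit(method=solver)
                gebv = fit.predict_gebv([zk[val] for zk in an_zk])
                n_ref = n_ref_multi
            rows.append({
                "fold": fold, "model": model,
                "r": r if model == "boa" else np.nan,
                "accuracy": _pearson(gebv, an_tbv[val]),
                "n_validation": n_val, "n_reference": n_ref,
            })
    return pd.DataFrame(rows)


def _aligned_pheno(pheno: pd.DataFrame, panel: HaplotypePanel):
    p = pheno.set_index("individual_id")
    try:
        p = p.loc[panel.ids]
    except KeyError as exc:
        raise ValueError("phenotypes do not cover the panel") from exc
    return p["y"].to_numpy(float), p["tbv"].to_numpy(float)


def _sigma_a2_from_dosage(z: np.ndarray, target_va: float) -> float:
    p = z.mean(axis=0) / 2.0
    het = float(np.sum(2.0 * p * (1.0 - p)))
    if het <= 0:
        raise ValueError("zero heterozygosity sum in the reference")
    return target_va / het


def grid_search_correlation(
    an_panel, an_phenotypes, hf_panel, hf_phenotypes, an_origins,
    marker_mask, cv_plan, grid=DEFAULT_GRID,
    target_va: float = 0.3, target_vp: float = 1.0, solver: str = "auto",
) -> tuple[float, pd.DataFrame]:
    """Choose the across-origin effect correlation by CV accuracy.

    Runs the sire-family CV with the origin model for every candidate r and
    returns the candidate maximising the mean accuracy across folds, with
    the full accuracy profile.  Ties are broken toward the larger r.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty correlation grid")
    if any(not -1.0 < g <= 1.0 for g in grid):
        raise ValueError("grid values must be in (-1, 1]")
    prof = []
    for r in grid:
        res = run_cv(an_panel, an_phenotypes, hf_panel, hf_phenotypes,
                     an_origins, marker_mask, cv_plan, models=("boa",), r=r,
                     target_va=target_va, target_vp=target_vp, solver=solver)
        prof.append({"r": r, "mean_accuracy": res["accuracy"].mean()})
    profile = pd.DataFrame(prof)
    best = profile.sort_values(["mean_accuracy", "r"]).iloc[-1]
    return float(best["r"]), profile


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Mean, sd and se of the accuracies per model (and scenario if present).

    Accuracies are first averaged over folds within a replicate; the sd is
    taken across replicate means and se = sd / sqrt(n_replicates).  The sd
    across all individual fold values is reported as ``sd_fold``.
    """
    if results.empty:
        raise ValueError("no accuracy values to summarize")
    df = results.copy()
    if "replicate" not in df.columns:
        df["replicate"] = 0
    keys = [c for c in ("scenario", "model") if c in df.columns]
    rep_means = df.groupby(keys + ["replicate"])["accuracy"].mean().reset_index()
    out = rep_means.groupby(keys)["accuracy"].agg(
        mean="mean", sd="std", n_replicates="count"
    ).reset_index()
    out["sd"] = out["sd"].fillna(0.0)
    out["se"] = out["sd"] / np.sqrt(out["n_replicates"])
    fold_sd = df.groupby(keys)["accuracy"].std().rename("sd_fold").reset_index()
    return out.merge(fold_sd, on=keys)


# ---------------------------------------------------------------------------
# Scenario runner
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioConfig:
    """One breed-size scenario of the simulation experiment.

    ``n_an`` target-breed individuals (750/1,500/3,000 in the named
    scenarios) with ``n_sires`` equal-size sire families, a constant donor
    panel of ``n_hf``, 5-fold sire-family CV, ``n_replicates`` independent
    simulation replicates.  ``r`` may be a number or ``"grid"`` to select
    the correlation per replicate by grid search.  ``origin_source`` picks
    the origin map the model sees: ``"assigned"`` (segment-based estimate,
    as a real analysis would) or ``"true"`` (simulator truth).
    """

    scenario_name: str = "custom"
    n_an: int = 750
    n_hf: int = 6000
    n_sires: int = 50
    n_sires_hf: int = 100
    n_folds: int = 5
    n_replicates: int = 10
    n_qtl: int = 100
    models: tuple[str, ...] = ALL_MODELS
    r: float | str = 0.75
    grid: tuple = DEFAULT_GRID
    target_va: float = 0.3
    target_vp: float = 1.0
    effect_correlation: float = 0.95
    maf_min: float = 0.03
    founder: FounderSimConfig = field(
        default_factory=lambda: FounderSimConfig(n_pool_haplotypes=80)
    )
    segment_rule: SegmentRule = field(default_factory=SegmentRule)
    origin_source: str = "assigned"
    n_assignment_reference: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario_name in SCENARIO_SIZES:
            object.__setattr__(self, "n_an", SCENARIO_SIZES[self.scenario_name])
        if self.n_an % (self.n_folds * (self.n_sires // self.n_folds)) and \
                self.n_an % self.n_sires:
            raise ValueError("n_an must be divisible by n_sires for equal families")
        if self.origin_source not in ("assigned", "true"):
            raise ValueError("origin_source must be 'assigned' or 'true'")


@dataclass
class ReplicateData:
    """Everything one simulated replicate produces before model fitting."""

    an_panel: HaplotypePanel
    hf_panel: HaplotypePanel
    an_true_origins: OriginMap
    hf_origins: OriginMap
    model_origins: OriginMap
    arch: object
    an_phenotypes: pd.DataFrame
    hf_phenotypes: pd.DataFrame
    marker_mask: np.ndarray
    cv_plan: CVPlan
    seed: int


def simulate_dataset(cfg: ScenarioConfig, replicate: int = 0) -> ReplicateData:
    """Simulate one replicate: genomes, trait, origins, marker set, CV plan."""
    base_seed = cfg.seed + replicate
    fcfg = replace(
        cfg.founder, seed=base_seed,
        breed_sizes={"AN": cfg.n_an, "HF": cfg.n_hf},
    )
    sim = simulate_founder_breeds(fcfg)
    rng = np.random.default_rng(base_seed + 2_000_000)

    an_panel, an_true = simulate_generation(
        sim.an, cfg.n_an, cfg.n_sires, seed=rng, origins=sim.true_origins
    )
    n_sires_hf = min(cfg.n_sires_hf, cfg.n_hf // 2)
    hf_panel, _ = simulate_generation(sim.hf, cfg.n_hf, n_sires_hf,
                                      equal_family_sizes=False, seed=rng)
    labels = an_true.group_labels
    hf_group = labels.index(DONOR_BREED)
    hf_origins = OriginMap.constant(hf_panel.n_individuals, hf_panel.n_markers,
                                    hf_group, labels)

    # trait: QTLs segregating in both breeds, correlated effects, scaling
    p_an_all = an_panel.allele_frequencies()
    p_hf_all = hf_panel.allele_frequencies()
    eligible = (p_an_all > 0) & (p_an_all < 1) & (p_hf_all > 0) & (p_hf_all < 1)
    arch = select_qtls(an_panel.marker_map, eligible, cfg.n_qtl, seed=rng,
                       group_labels=labels)
    arch = sample_qtl_effects(arch, rho=cfg.effect_correlation, seed=rng)
    arch = scale_effects_to_va(
        arch,
        {TARGET_BREED: p_an_all[arch.qtl_indices], DONOR_BREED: p_hf_all[arch.qtl_indices]},
        cfg.target_va,
    )

    an_tbv = compute_tbv(an_panel, an_true, arch)
    hf_tbv = compute_tbv(hf_panel, hf_origins, arch)
    an_pheno = simulate_phenotypes(an_tbv, an_panel.ids, cfg.target_va,
                                   cfg.target_vp, seed=rng)
    hf_pheno = simulate_phenotypes(hf_tbv, hf_panel.ids, cfg.target_va,
                                   cfg.target_vp, seed=rng)

    mask = filter_markers({TARGET_BREED: an_panel, DONOR_BREED: hf_panel},
                          arch.qtl_indices, cfg.maf_min)

    if cfg.origin_source == "true":
        model_origins = an_true
    else:
        n_ref = min(cfg.n_assignment_reference, hf_panel.n_individuals)
        hf_ref = hf_panel.subset(rng.choice(hf_panel.n_individuals, n_ref, replace=False))
        model_origins = assign_origins(
            an_panel,
            {TARGET_BREED: sim.an_native_reference, DONOR_BREED: hf_ref},
            cfg.segment_rule,
            target=TARGET_BREED,
        )

    plan = make_cv_plan(an_panel, cfg.n_folds, seed=rng)
    return ReplicateData(
        an_panel=an_panel, hf_panel=hf_panel, an_true_origins=an_true,
        hf_origins=hf_origins, model_origins=model_origins, arch=arch,
        an_phenotypes=an_pheno, hf_phenotypes=hf_pheno, marker_mask=mask,
        cv_plan=plan, seed=base_seed,
    )


def run_replicate(cfg: ScenarioConfig, replicate: int = 0) -> pd.DataFrame:
    """Simulate one replicate end to end and cross-validate all models."""
    d = simulate_dataset(cfg, replicate)
    if cfg.r == "grid":
        r_used, _ = grid_search_correlation(
            d.an_panel, d.an_phenotypes, d.hf_panel, d.hf_phenotypes,
            d.model_origins, d.marker_mask, d.cv_plan,
            cfg.grid, cfg.target_va, cfg.target_vp,
        )
    else:
        r_used = float(cfg.r)
    res = run_cv(d.an_panel, d.an_phenotypes, d.hf_panel, d.hf_phenotypes,
                 d.model_origins, d.marker_mask, d.cv_plan, cfg.models, r_used,
                 cfg.target_va, cfg.target_vp)
    res.insert(0, "replicate", replicate)
    res.insert(0, "scenario", cfg.scenario_name)
    return res


def run_scenario(cfg: ScenarioConfig) -> pd.DataFrame:
    """All replicates of a scenario; rows (scenario, replicate, fold, model)."""
    return pd.concat(
        [run_replicate(cfg, rep) for rep in range(cfg.n_replicates)],
        ignore_index=True,
    )


def scenario_design(
    n_an: int, n_hf: int = 6000, n_folds: int = 5, n_sires: int = 50,
    seed: int = 0,
) -> dict:
    """Reference/validation sizes of the sire-family CV design.

    Computes the numbers by actually building a CV plan for an equal-family
    pedigree: validation-set size, within-breed reference size, multi-breed
    reference size, the percentage of target-breed individuals in the
    multi-breed reference, and sires per fold.
    """
    if n_an % n_sires:
        raise ValueError("n_an must be divisible by n_sires")
    fam = n_an // n_sires
    table = pd.DataFrame({
        "id": [f"I{j}" for j in range(n_an)],
        "sire_id": [f"S{j // fam}" for j in range(n_an)],
        "dam_id": [f"D{j}" for j in range(n_an)],
        "breed_label": TARGET_BREED,
    })
    panel = HaplotypePanel(table, np.zeros((n_an, 2, 1), np.uint8),
                           _dummy_map())
    plan = make_cv_plan(panel, n_folds, seed)
    sizes = plan.fold_of.value_counts().sort_index()
    sires_per_fold = pd.Series(plan.sire_folds).value_counts().sort_index()
    val = int(sizes.iloc[0])
    ref_within = n_an - val
    ref_multi = ref_within + n_hf
    return {
        "n": n_an,
        "validation": val,
        "reference_within": ref_within,
        "reference_multi": ref_multi,
        "pct_an_multi": round(100.0 * ref_within / ref_multi, 2),
        "sires_per_fold": int(sires_per_fold.iloc[0]),
        "fold_sizes": sizes.tolist(),
        "sires_per_fold_all": sires_per_fold.tolist(),
    }


def _dummy_map():
    from .panel import MarkerMap
    return MarkerMap(pd.DataFrame({
        "marker_id": ["m1"], "chromosome": [1], "position_bp": [1],
        "genetic_pos_morgan": [0.0],
    }))
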