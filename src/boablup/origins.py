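"""Breed origin of alleles: origin maps and segment-based assignment.

An :class:`OriginMap` records, for every haplotype allele of every
individual, the breed (genetic group) it descends from.  The simulator
produces true origin maps; :func:`assign_origins` estimates them for admixed
individuals by matching haplotype windows against purebred reference panels
and accepting matched stretches as introgressed segments only when they are
long enough, both in markers and in physical length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import HaplotypePanel, MarkerMap

__all__ = ["OriginMap", "SegmentRule", "assign_origins", "origin_accuracy",
           "origins_to_segments", "segments_to_origins"]

_HAP_NAMES = ("pat", "mat")


@dataclass
class OriginMap:
    """Per-allele breed-origin codes aligned with a haplotype panel.

    ``codes`` has shape (N, 2, M); entry ``codes[i, h, m]`` indexes into
    ``group_labels``.  Group 0 is the target breed by convention.
    """

    codes: np.ndarray
    group_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        self.group_labels = tuple(self.group_labels)
        if self.codes.ndim != 3 or self.codes.shape[1] != 2:
            raise ValueError("origin codes must have shape (N, 2, M)")
        if self.codes.size and self.codes.max() >= len(self.group_labels):
            raise ValueError("origin code exceeds number of groups")

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)

    def indicator(self, k: int) -> np.ndarray:
        """Boolean (N, 2, M) indicator of group ``k`` (the delta of the model)."""
        return self.codes == k

    def group_fractions(self) -> pd.Series:
        """Genome-wide fraction of alleles per origin group."""
        total = self.codes.size
        return pd.Series(
            {lab: float((self.codes == k).sum()) / total
             for k, lab in enumerate(self.group_labels)}
        )

    def subset(self, index: np.ndarray) -> "OriginMap":
        return OriginMap(self.codes[np.asarray(index)], self.group_labels)

    def subset_markers(self, marker_index: np.ndarray) -> "OriginMap":
        marker_index = np.asarray(marker_index)
        if marker_index.dtype == bool:
            marker_index = np.flatnonzero(marker_index)
        return OriginMap(self.codes[:, :, marker_index], self.group_labels)

    @classmethod
    def constant(cls, n: int, m: int, group: int, group_labels) -> "OriginMap":
        return cls(np.full((n, 2, m), group, dtype=np.uint8), tuple(group_labels))


@dataclass(frozen=True)
class SegmentRule:
    """Acceptance rule for introgressed haplotype segments.

    A candidate foreign segment is kept only if it spans at least
    ``min_markers`` consecutive markers and at least ``min_length_bp`` on the
    physical map.  Window classification: a window of exactly ``min_markers``
    markers is foreign-supported for group k when it matches at least
    ``min_foreign_matches`` reference haplotypes of group k exactly.

    ``max_native_matches`` optionally vetoes windows that also occur in the
    target-breed references more than that many times.  It is off (``None``)
    by default: the veto window shortens together with ``min_markers``, which
    breaks the guarantee that tightening the rule only removes
    foreign-assigned positions, so the default classifier relies on foreign
    matches alone and is exactly monotone under rule tightening.
    """

    min_markers: int = 20
    min_length_bp: int = 1_500_000
    min_foreign_matches: int = 1
    max_native_matches: int | None = None

    def __post_init__(self) -> None:
        if self.min_markers < 1 or self.min_length_bp < 1:
            raise ValueError("min_markers and min_length_bp must be >= 1")
        if self.min_foreign_matches < 1 or \
                (self.max_native_matches is not None and self.max_native_matches < 0):
            raise ValueError("invalid match thresholds")


def _zero_mismatch_windows(hap: np.ndarray, refs: np.ndarray, w: int) -> np.ndarray:
    """Count, per window start, reference haplotypes matching ``hap`` exactly.

    hap: (W,) alleles; refs: (H, W); returns (W - w + 1,) int counts.
    """
    if refs.shape[0] == 0 or hap.size < w:
        return np.zeros(max(hap.size - w + 1, 0), dtype=np.int32)
    diff = (refs != hap[None, :]).astype(np.int32)
    cs = np.concatenate([np.zeros((refs.shape[0], 1), np.int32), np.cumsum(diff, axis=1)], axis=1)
    mism = cs[:, w:] - cs[:, :-w]
    return (mism == 0).sum(axis=0).astype(np.int32)


def assign_origins(
    admixed: HaplotypePanel,
    references: dict[str, HaplotypePanel],
    rule: SegmentRule = SegmentRule(),
    target: str | None = None,
) -> OriginMap:
    """Assign a breed origin to every marker allele of ``admixed``.

    Parameters
    ----------
    admixed
        Panel of admixed (target-breed) individuals to classify.
    references
        Breed label -> purebred reference panel.  Must contain the target
        breed; every other key is a potential foreign origin.
    rule
        Segment acceptance rule.
    target
        Target breed label; defaults to the breed label of the admixed
        individuals.  The target breed becomes group 0.

    Any position not inside an accepted foreign segment is assigned the
    target-breed origin.  Segments never span chromosome boundaries.
    """
    if target is None:
        labels = admixed.individuals["breed_label"].unique()
        if len(labels) != 1:
            raise ValueError("admixed panel has mixed breed labels; pass target=")
        target = str(labels[0])
    if target not in references:
        raise ValueError(f"no reference panel for target breed {target!r}")
    foreign_labels = [b for b in references if b != target]
    if not foreign_labels:
        raise ValueError("need at least one non-target reference panel")
    for b, p in references.items():
        if p.n_individuals == 0:
            raise ValueError(f"reference panel for {b!r} is empty")
        if not admixed.marker_map.same_map(p.marker_map):
            raise ValueError(f"reference panel for {b!r} is on a different marker map")

    group_labels = (target, *foreign_labels)
    w = rule.min_markers
    pos = admixed.marker_map.table["position_bp"].to_numpy()
    chrom_slices = admixed.marker_map.chromosome_slices()
    native_refs = references[target].haplotypes.reshape(-1, admixed.n_markers)
    foreign_refs = {
        b: references[b].haplotypes.reshape(-1, admixed.n_markers) for b in foreign_labels
    }

    codes = np.zeros((admixed.n_individuals, 2, admixed.n_markers), dtype=np.uint8)
    for i in range(admixed.n_individuals):
        for h in (0, 1):
            hap = admixed.haplotypes[i, h]
            for sl in chrom_slices.values():
                seg = _classify_chromosome(
                    hap[sl], native_refs[:, sl], {b: r[:, sl] for b, r in foreign_refs.items()},
                    pos[sl], w, rule,
                )
                for k, (a, b) in seg:  # k indexes foreign_labels
                    codes[i, h, sl][a:b] = k + 1
    return OriginMap(codes, group_labels)


def _classify_chromosome(hap, native, foreign, pos, w, rule):
    """Return [(foreign_group_index, (start, stop)), ...] accepted segments.

    Positions are marker indices local to the chromosome, stop exclusive.
    """
    n_win = hap.size - w + 1
    if n_win <= 0:
        return []
    if rule.max_native_matches is not None:
        native_ok = _zero_mismatch_windows(hap, native, w) <= rule.max_native_matches
    else:
        native_ok = True
    candidates = []  # (support, length_bp, group_index, start, stop)
    for gi, (lab, refs) in enumerate(foreign.items()):
        counts = _zero_mismatch_windows(hap, refs, w)
        supported = (counts >= rule.min_foreign_matches) & native_ok
        if not supported.any():
            continue
        # positions covered by any supported window
        cover = np.zeros(hap.size + 1, dtype=np.int32)
        starts = np.flatnonzero(supported)
        np.add.at(cover, starts, 1)
        np.add.at(cover, starts + w, -1)
        covered = np.cumsum(cover[:-1]) > 0
        # maximal runs of covered positions
        edges = np.diff(np.concatenate([[0], covered.view(np.int8), [0]]))
        run_starts = np.flatnonzero(edges == 1)
        run_stops = np.flatnonzero(edges == -1)
        for a, b in zip(run_starts, run_stops):
            length_bp = int(pos[b - 1] - pos[a])
            if (b - a) >= rule.min_markers and length_bp >= rule.min_length_bp:
                support = int(supported[a : max(a + 1, b - w + 1)].sum())
                candidates.append((support, length_bp, gi, int(a), int(b)))
    if not candidates:
        return []
    # paint lowest-priority first so higher priority wins overlapping spans;
    # priority: more window support, then longer segment, then lower group index
    candidates.sort(key=lambda c: (c[0], c[1], -c[2]))
    return [(gi, (a, b)) for _, _, gi, a, b in candidates]


def origin_accuracy(estimated: OriginMap, truth: OriginMap) -> dict:
    """Per-allele agreement between an estimated and a true origin map.

    Returns overall agreement plus recall per true group (fraction of
    positions truly of group k that were recovered as group k).
    """
    if estimated.codes.shape != truth.codes.shape:
        raise ValueError("origin maps have different dimensions")
    if estimated.group_labels != truth.group_labels:
        raise ValueError("origin maps have different group labels")
    agree = estimated.codes == truth.codes
    out = {"overall": float(agree.mean())}
    for k, lab in enumerate(truth.group_labels):
        mask = truth.codes == k
        out[lab] = float(agree[mask].mean()) if mask.any() else float("nan")
    return out


# ---------------------------------------------------------------------------
# Segment (BED-like, 1-based closed intervals, dialect "bed1") round trip
# ---------------------------------------------------------------------------

def origins_to_segments(origins: OriginMap, panel: HaplotypePanel) -> pd.DataFrame:
    """Collapse an origin map to per-haplotype segments.

    Columns: individual, haplotype ("pat"/"mat"), chrom, start_bp, end_bp,
    origin_label.  Intervals are 1-based closed marker spans and never cross
    chromosome boundaries.
    """
    pos = panel.marker_map.table["position_bp"].to_numpy()
    rows = []
    for i, ind in enumerate(panel.ids):
        for h in (0, 1):
            for c, sl in panel.marker_map.chromosome_slices().items():
                o = origins.codes[i, h, sl]
                p = pos[sl]
                cut = np.flatnonzero(np.diff(o)) + 1
                bounds = np.concatenate([[0], cut, [o.size]])
                for a, b in zip(bounds[:-1], bounds[1:]):
                    rows.append(
                        (ind, _HAP_NAMES[h], c, int(p[a]), int(p[b - 1]),
                         origins.group_labels[o[a]])
                    )
    return pd.DataFrame(
        rows, columns=["individual", "haplotype", "chrom", "start_bp", "end_bp", "origin_label"]
    )


def segments_to_origins(
    segments: pd.DataFrame, panel: HaplotypePanel, group_labels
) -> OriginMap:
    """Inverse of :func:`origins_to_segments` on the same marker map."""
    group_labels = tuple(group_labels)
    code_of = {lab: k for k, lab in enumerate(group_labels)}
    idx_of = {ind: i for i, ind in enumerate(panel.ids)}
    pos = panel.marker_map.table["position_bp"].to_numpy()
    chrom = panel.marker_map.table["chromosome"].to_numpy()
    codes = np.zeros((panel.n_individuals, 2, panel.n_markers), dtype=np.uint8)
    filled = np.zeros_like(codes, dtype=bool)
    for row in segments.itertuples(index=False):
        i = idx_of[row.individual]
        h = _HAP_NAMES.index(row.haplotype)
        sel = (chrom == row.chrom) & (pos >= row.start_bp) & (pos <= row.end_bp)
        codes[i, h, sel] = code_of[row.origin_label]
        filled[i, h, sel] = True
    if not filled.all():
        warnings.warn("origin segments do not cover every marker; gaps set to group 0")
    return OriginMap(codes, group_labels)
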