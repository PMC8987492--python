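"""SNP-BLUP mixed models with breed-origin-specific marker effects.

Two model classes in the statsmodels idiom:

* :class:`SNPBlup` — the conventional model ``y = beta*1 + Z_A a + e`` with
  ``a ~ N(0, sigma_a2 I)``, used for both within-breed and multi-breed
  baselines (no breed fixed effect, matching the simulated data).
* :class:`BreedOriginBLUP` — the origin-split model
  ``y = X beta + sum_k Z_Ak a_k + e`` where ``Z_Ak`` counts alternative
  alleles of origin group k, ``X`` holds the genetic contributions c_ik,
  and the stacked marker effects have covariance ``Sigma (x) I`` (Kronecker),
  so effects of the same marker are correlated across origins.

``fit()`` solves Henderson's mixed-model equations

    [ X'X        X'Z        ] [beta]   [X'y]
    [ Z'X   Z'Z + s_e^2 Dinv] [ a  ] = [Z'y]

densely (Cholesky, least-squares fallback for rank-deficient X) or by
conjugate gradients through a matrix-free operator for large systems, and
returns an :class:`MMEResults` with estimates, diagnostics and prediction.
Genomic breeding values contain only the marker part, never fixed effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse.linalg

from .origins import OriginMap
from .panel import HaplotypePanel

__all__ = ["VarianceSpec", "DesignSet", "filter_markers", "build_design",
           "make_variance_spec", "snp_blup_sigma_a2", "SNPBlup",
           "BreedOriginBLUP", "MMEResults"]


@dataclass(frozen=True)
class VarianceSpec:
    """K x K marker-effect covariance Sigma and residual variance.

    ``sigma[k, l]`` is the covariance between the effects of one marker in
    origin groups k and l; the full prior covariance of the stacked effect
    vector is Sigma Kronecker I.
    """

    sigma: np.ndarray
    sigma_e2: float
    group_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        s = np.asarray(self.sigma, dtype=float)
        if s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise ValueError("sigma must be square")
        if not np.allclose(s, s.T):
            raise ValueError("sigma must be symmetric")
        if np.linalg.eigvalsh(s).min() < -1e-12 * max(1.0, np.abs(s).max()):
            raise ValueError("sigma must be positive semidefinite")
        if self.sigma_e2 <= 0:
            raise ValueError("sigma_e2 must be > 0")
        object.__setattr__(self, "sigma", s)
        object.__setattr__(self, "group_labels", tuple(self.group_labels))

    @property
    def n_groups(self) -> int:
        return self.sigma.shape[0]


@dataclass
class DesignSet:
    """Phenotypes and design matrices of the origin-split model."""

    y: np.ndarray
    X: np.ndarray                  # (N, K) genetic contributions c_ik
    Z: list                        # K matrices (N, M) of origin-split counts
    marker_ids: np.ndarray
    group_labels: tuple[str, ...]
    individual_ids: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        n = self.y.size
        if self.X.shape[0] != n or any(z.shape[0] != n for z in self.Z):
            raise ValueError("row mismatch between y, X and Z")


# ---------------------------------------------------------------------------
# Marker filtering and design construction
# ---------------------------------------------------------------------------

def filter_markers(
    panels: dict[str, HaplotypePanel],
    qtl_indices=(),
    maf_min: float = 0.03,
) -> np.ndarray:
    """Prediction-marker mask: non-QTL, segregating with MAF >= maf_min in
    every breed panel.

    Returns a boolean mask over the shared marker map.
    """
    if not 0.0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    panels = dict(panels)
    first = next(iter(panels.values()))
    mask = np.ones(first.n_markers, dtype=bool)
    for p in panels.values():
        freq = p.allele_frequencies()
        maf = np.minimum(freq, 1.0 - freq)
        mask &= (freq > 0.0) & (freq < 1.0) & (maf >= maf_min)
    mask[np.asarray(list(qtl_indices), dtype=int)] = False
    if not mask.any():
        raise ValueError("no markers left after filtering")
    return mask


def build_design(
    panel: HaplotypePanel,
    origin_map: OriginMap,
    y: np.ndarray,
    marker_mask: np.ndarray | None = None,
) -> DesignSet:
    """Origin-split design: Z_Ak from the delta indicators, X from c_ik.

    ``c_ik`` is the fraction of the individual's 2M retained-marker alleles
    assigned to group k, so rows of X sum to one.
    """
    y = np.asarray(y, dtype=float)
    if y.size != panel.n_individuals:
        raise ValueError("phenotype vector does not match the panel")
    if marker_mask is None:
        marker_mask = np.ones(panel.n_markers, dtype=bool)
    cols = np.flatnonzero(np.asarray(marker_mask))
    haps = panel.haplotypes[:, :, cols].astype(np.float64)
    oc = origin_map.codes[:, :, cols]
    k_groups = origin_map.n_groups
    z_list = []
    contrib = np.empty((panel.n_individuals, k_groups))
    for k in range(k_groups):
        delta = oc == k
        z_list.append((haps * delta).sum(axis=1))
        contrib[:, k] = delta.mean(axis=(1, 2))
    return DesignSet(
        y=y, X=contrib, Z=z_list,
        marker_ids=panel.marker_map.marker_ids[cols],
        group_labels=origin_map.group_labels,
        individual_ids=panel.ids,
    )


def make_variance_spec(
    panels: dict[str, HaplotypePanel],
    marker_mask: np.ndarray,
    r: float,
    target_va: float = 0.3,
    target_vp: float = 1.0,
) -> VarianceSpec:
    """Deterministic marker-effect variances from the heterozygosity sums.

    Per group k, ``sigma_Ak^2 = target_va / sum_m 2 p_mk (1 - p_mk)`` over
    the retained markers, off-diagonals ``r * sqrt(sigma_Ak^2 sigma_Al^2)``,
    and residual variance ``target_vp - target_va``.
    """
    if not -1.0 < r <= 1.0:
        raise ValueError("r must be in (-1, 1]")
    if target_va <= 0 or target_vp <= target_va:
        raise ValueError("need 0 < target_va < target_vp")
    labels = tuple(panels)
    cols = np.flatnonzero(np.asarray(marker_mask))
    var_k = []
    for lab in labels:
        p = panels[lab].allele_frequencies()[cols]
        het = float(np.sum(2.0 * p * (1.0 - p)))
        if het <= 0:
            raise ValueError(f"zero heterozygosity sum in breed {lab!r}")
        var_k.append(target_va / het)
    sd = np.sqrt(var_k)
    sigma = r * np.outer(sd, sd)
    np.fill_diagonal(sigma, var_k)
    return VarianceSpec(sigma, target_vp - target_va, labels)


def snp_blup_sigma_a2(
    panels, marker_mask: np.ndarray, target_va: float = 0.3
) -> float:
    """Baseline marker-effect variance V_A / sum 2p(1-p) on the pooled panel."""
    if isinstance(panels, HaplotypePanel):
        panels = [panels]
    elif isinstance(panels, dict):
        panels = list(panels.values())
    pooled = HaplotypePanel.concat(list(panels)) if len(panels) > 1 else panels[0]
    cols = np.flatnonzero(np.asarray(marker_mask))
    p = pooled.allele_frequencies()[cols]
    het = float(np.sum(2.0 * p * (1.0 - p)))
    if het <= 0:
        raise ValueError("zero heterozygosity sum")
    return target_va / het


# ---------------------------------------------------------------------------
# Mixed-model equation solvers
# ---------------------------------------------------------------------------

def _solve_mme_dense(X, Zc, dinv_times, sigma_e2, y):
    """Assemble and solve the MME densely; minimum-norm fallback."""
    n_fix = X.shape[1]
    dim = n_fix + Zc.shape[1]
    lhs = np.empty((dim, dim))
    lhs[:n_fix, :n_fix] = X.T @ X
    xz = X.T @ Zc
    lhs[:n_fix, n_fix:] = xz
    lhs[n_fix:, :n_fix] = xz.T
    lhs[n_fix:, n_fix:] = Zc.T @ Zc
    lhs[n_fix:, n_fix:] += sigma_e2 * dinv_times(np.eye(dim - n_fix))
    rhs = np.concatenate([X.T @ y, Zc.T @ y])
    try:
        c, low = scipy.linalg.cho_factor(lhs)
        sol = scipy.linalg.cho_solve((c, low), rhs)
        method = "dense-cholesky"
    except np.linalg.LinAlgError:
        sol, *_ = scipy.linalg.lstsq(lhs, rhs, lapack_driver="gelsd")
        method = "dense-lstsq"
    resid = float(np.linalg.norm(lhs @ sol - rhs))
    diag = {"solver": method, "mme_residual_norm": resid, "dim": dim}
    if dim <= 500:
        diag["condition_estimate"] = float(np.linalg.cond(lhs))
    return sol, diag


def _solve_mme_cg(X, Zc, dinv_times, sigma_e2, y, rtol=1e-10, maxiter=5000):
    """Matrix-free conjugate-gradient solve of the (SPD) MME."""
    n_fix = X.shape[1]
    dim = n_fix + Zc.shape[1]

    def matvec(v):
        b, a = v[:n_fix], v[n_fix:]
        w = X @ b + Zc @ a
        top = X.T @ w
        bot = Zc.T @ w + sigma_e2 * dinv_times(a)
        return np.concatenate([top, bot])

    op = scipy.sparse.linalg.LinearOperator((dim, dim), matvec=matvec, dtype=float)
    rhs = np.concatenate([X.T @ y, Zc.T @ y])
    sol, info = scipy.sparse.linalg.cg(op, rhs, rtol=rtol, maxiter=maxiter)
    if info != 0:
        raise RuntimeError(f"CG did not converge (info={info})")
    resid = float(np.linalg.norm(matvec(sol) - rhs))
    return sol, {"solver": "cg", "mme_residual_norm": resid, "dim": dim}


class _BlupModelBase:
    """Shared fit machinery for the SNP-BLUP model family."""

    dense_limit = 6000  # switch to CG above this MME dimension

    def _fit(self, X, Zc, dinv_times, sigma_e2, y, method):
        dim = X.shape[1] + Zc.shape[1]
        if method == "auto":
            method = "dense" if dim <= self.dense_limit else "cg"
        if method == "dense":
            sol, diag = _solve_mme_dense(X, Zc, dinv_times, sigma_e2, y)
        elif method == "cg":
            sol, diag = _solve_mme_cg(X, Zc, dinv_times, sigma_e2, y)
        else:
            raise ValueError(f"unknown method {method!r}")
        if not np.all(np.isfinite(sol)):
            raise RuntimeError("non-finite MME solution")
        return sol, diag


class SNPBlup(_BlupModelBase):
    """Conventional SNP-BLUP: ``y = beta*1 + Z_A a + e``, a ~ N(0, s_a^2 I).

    Parameters
    ----------
    y : (N,) phenotypes
    Z : (N, M) allele dosages in {0, 1, 2}
    sigma_a2, sigma_e2 : marker-effect and residual variances
    include_intercept : fit a single overall mean (default True)
    """

    model_kind = "snp_blup"

    def __init__(self, y, Z, sigma_a2, sigma_e2, include_intercept=True,
                 marker_ids=None):
        if sigma_a2 <= 0 or sigma_e2 <= 0:
            raise ValueError("variances must be > 0")
        self.y = np.asarray(y, dtype=float)
        self.Z = np.asarray(Z, dtype=float)
        if self.Z.shape[0] != self.y.size:
            raise ValueError("y and Z disagree on N")
        self.sigma_a2 = float(sigma_a2)
        self.sigma_e2 = float(sigma_e2)
        self.include_intercept = include_intercept
        self.marker_ids = marker_ids

    def fit(self, method: str = "auto") -> "MMEResults":
        n = self.y.size
        X = np.ones((n, 1)) if self.include_intercept else np.empty((n, 0))
        sol, diag = self._fit(
            X, self.Z, lambda a: a / self.sigma_a2, self.sigma_e2, self.y, method
        )
        n_fix = X.shape[1]
        vs = VarianceSpec(np.array([[self.sigma_a2]]), self.sigma_e2, ("all",))
        return MMEResults(
            model=self, beta=sol[:n_fix], marker_effects=sol[n_fix:][None, :],
            group_labels=("all",), variance_spec=vs, diagnostics=diag,
            model_kind=self.model_kind, marker_ids=self.marker_ids,
        )


class BreedOriginBLUP(_BlupModelBase):
    """Origin-split SNP-BLUP with correlated effects across breed origins.

    Built from a :class:`DesignSet` (origin-split allele counts Z_Ak and
    genetic contributions X) and a :class:`VarianceSpec` (Sigma, sigma_e2).
    The prior on the stacked effects is N(0, Sigma Kronecker I).
    """

    model_kind = "boa"

    def __init__(self, design: DesignSet, variance: VarianceSpec):
        if tuple(design.group_labels) != tuple(variance.group_labels):
            raise ValueError("design and variance spec disagree on group labels")
        if np.linalg.eigvalsh(variance.sigma).min() <= 0:
            raise ValueError("the MME solver requires a strictly positive definite Sigma")
        if design.y.size < variance.n_groups:
            raise ValueError("need at least K observations")
        self.design = design
        self.variance = variance

    @classmethod
    def from_panel(cls, panel, origin_map, y, variance, marker_mask=None):
        return cls(build_design(panel, origin_map, y, marker_mask), variance)

    def fit(self, method: str = "auto") -> "MMEResults":
        d, vs = self.design, self.variance
        k = vs.n_groups
        m = d.Z[0].shape[1]
        n_fix = d.X.shape[1]
        zc = np.concatenate(d.Z, axis=1)
        sigma_inv = np.linalg.inv(vs.sigma)

        def dinv_times(a):
            # (Sigma^-1 kron I) a, for a of shape (K*M,) or (K*M, cols)
            blocks = a.reshape(k, m, -1) if a.ndim > 1 else a.reshape(k, m)
            out = np.tensordot(sigma_inv, blocks, axes=(1, 0))
            return out.reshape(a.shape)

        sol, diag = self._fit(d.X, zc, dinv_times, vs.sigma_e2, d.y, method)
        return MMEResults(
            model=self, beta=sol[:n_fix], marker_effects=sol[n_fix:].reshape(k, m),
            group_labels=d.group_labels, variance_spec=vs, diagnostics=diag,
            model_kind=self.model_kind, marker_ids=d.marker_ids,
        )


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

@dataclass
class MMEResults:
    """Solution of the mixed-model equations.

    ``marker_effects`` has shape (K, M): one row of estimated SNP effects
    per origin group (K=1 for the conventional model).  GEBVs contain only
    the marker part.
    """

    model: object
    beta: np.ndarray
    marker_effects: np.ndarray
    group_labels: tuple[str, ...]
    variance_spec: VarianceSpec
    diagnostics: dict
    model_kind: str
    marker_ids: np.ndarray | None = None

    def predict_gebv(self, Z) -> np.ndarray:
        """Genomic breeding values for new individuals.

        ``Z`` is either a list of K origin-split count matrices (origin
        model) or a single (N, M) dosage matrix (conventional model, or an
        origin model whose effect rows coincide).
        """
        if isinstance(Z, (list, tuple)):
            if len(Z) != self.marker_effects.shape[0]:
                raise ValueError("wrong number of origin-split blocks")
            return sum(
                np.asarray(zk, dtype=float) @ self.marker_effects[k]
                for k, zk in enumerate(Z)
            )
        Z = np.asarray(Z, dtype=float)
        if self.marker_effects.shape[0] != 1:
            raise ValueError("origin-split model needs per-group count matrices")
        return Z @ self.marker_effects[0]

    def predict_gebv_design(self, design: DesignSet) -> np.ndarray:
        return self.predict_gebv(design.Z if self.model_kind == "boa" else
                                 sum(np.asarray(z) for z in design.Z))

    @property
    def fittedvalues(self) -> np.ndarray:
        if self.model_kind == "boa":
            d = self.model.design
            return d.X @ self.beta + self.predict_gebv(d.Z)
        x_part = self.beta[0] if self.model.include_intercept else 0.0
        return x_part + self.predict_gebv(self.model.Z)

    @property
    def resid(self) -> np.ndarray:
        y = self.model.design.y if self.model_kind == "boa" else self.model.y
        return y - self.fittedvalues

    def effects_frame(self) -> pd.DataFrame:
        k, m = self.marker_effects.shape
        ids = self.marker_ids if self.marker_ids is not None else np.arange(m)
        return pd.DataFrame({
            "marker_id": np.tile(ids, k),
            "group_label": np.repeat(list(self.group_labels), m),
            "a_hat": self.marker_effects.ravel(),
        })

    def summary(self) -> str:
        k, m = self.marker_effects.shape
        lines = [
            f"{'Breed-origin SNP-BLUP' if self.model_kind == 'boa' else 'SNP-BLUP'} "
            "mixed-model solution",
            "=" * 58,
            f"observations: {self.resid.size}    markers: {m}    origin groups: {k}",
            f"residual variance: {self.variance_spec.sigma_e2:.6g}",
            "marker-effect covariance Sigma:",
        ]
        for row, lab in zip(self.variance_spec.sigma, self.group_labels):
            lines.append("  " + lab.rjust(6) + "  " + "  ".join(f"{v: .4e}" for v in row))
        lines.append("fixed effects:")
        names = self.group_labels if self.model_kind == "boa" else ("intercept",)
        for name, b in zip(names, self.beta):
            lines.append(f"  beta[{name}] = {b: .6f}")
        sd = self.marker_effects.std(axis=1)
        for lab, s in zip(self.group_labels, sd):
            lines.append(f"  sd(a_hat[{lab}]) = {s: .4e}")
        lines.append(f"solver: {self.diagnostics.get('solver')}  "
                     f"MME residual norm: {self.diagnostics.get('mme_residual_norm'):.3e}")
        return "\n".join(lines)
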