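"""Preprocessing of omics matrices and construction of relationship kernels.

This module takes individual x feature matrices of SNP dosages or gene
transcript levels through the standard genomic-prediction pipeline:

* genotype quality control (minor-allele frequency, call rate, pruning of
  near-duplicate adjacent markers),
* rank-based inverse-normal (rank-Z) transformation of transcript levels,
* column centering/standardization,
* construction of the n x n relationship kernels G = ZZ'/m (genomic),
  T = WW'/k (transcriptomic), their Hadamard interaction G#T, and the
  genotype-conditioned transcript kernel Tc = WcWc'/k, where Wc removes
  from the transcripts whatever a ridge regression on the SNPs predicts
  (the "smoother matrix" Z(Z'Z + lambda*I)^-1 Z').
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "OmicsMatrix",
    "StandardizedMatrix",
    "ConditionedMatrix",
    "RelationshipKernel",
    "QCReport",
    "qc_filter_genotypes",
    "rank_z_transform",
    "center_standardize",
    "build_genomic_kernel",
    "build_transcript_kernel",
    "build_interaction_kernel",
    "compute_lambda",
    "condition_transcripts",
    "build_conditioned_kernel",
]

_KINDS = ("genotype", "transcript")
_COMPONENTS = ("g", "t", "tc", "gt")


def _check_unique(ids, what: str) -> list:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        seen, dup = set(), None
        for i in ids:
            if i in seen:
                dup = i
                break
            seen.add(i)
        raise ValueError(f"duplicate {what} identifier: {dup!r}")
    return ids


@dataclass
class OmicsMatrix:
    """An individuals x features matrix of genotype dosages or transcript levels.

    Genotype dosages follow the 0/1/2 convention (continuous dosages in
    [0, 2] are accepted); missing values are NaN.
    """

    values: np.ndarray
    row_ids: list
    col_ids: list
    kind: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        self.row_ids = _check_unique(self.row_ids, "individual")
        self.col_ids = _check_unique(self.col_ids, "feature")
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.row_ids)} row ids x {len(self.col_ids)} col ids"
            )
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.kind == "genotype":
            finite = self.values[np.isfinite(self.values)]
            if finite.size and (finite.min() < 0 or finite.max() > 2):
                raise ValueError("genotype dosages must lie in [0, 2] (or be missing)")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class StandardizedMatrix:
    """A column-centered, unit-sample-SD feature matrix (Z or W)."""

    values: np.ndarray
    row_ids: list
    col_ids: list
    feature_means: np.ndarray
    feature_sds: np.ndarray
    dropped_features: list = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class ConditionedMatrix:
    """Transcripts with the genotype-predictable part removed (Wc).

    Columns are intentionally *not* re-standardized: the conditioned kernel
    divides by the gene count only, so the variance removed by conditioning
    stays removed.
    """

    values: np.ndarray
    row_ids: list
    col_ids: list
    lam: float

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class RelationshipKernel:
    """An n x n symmetric PSD similarity matrix among individuals."""

    values: np.ndarray
    component: str
    row_ids: list
    n_features_used: int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.component not in _COMPONENTS:
            raise ValueError(f"component must be one of {_COMPONENTS}")
        n = len(self.row_ids)
        if self.values.shape != (n, n):
            raise ValueError("kernel must be square and match row_ids")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def mean_diag(self) -> float:
        return float(np.mean(np.diag(self.values)))


@dataclass
class QCReport:
    """Counts of markers removed by each genotype-QC rule, in application order."""

    n_input: int
    n_removed_maf: int
    n_removed_callrate: int
    n_removed_corr: int
    n_retained: int
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self):
        expect = (
            self.n_input
            - self.n_removed_maf
            - self.n_removed_callrate
            - self.n_removed_corr
        )
        if self.n_retained != expect:
            raise ValueError("inconsistent QC counts")


def _pairwise_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation on pairwise-complete observations; 0 if undefined."""
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 2:
        return 0.0
    aa, bb = a[ok], b[ok]
    if np.ptp(aa) == 0 or np.ptp(bb) == 0:
        return 0.0
    return float(np.corrcoef(aa, bb)[0, 1])


def qc_filter_genotypes(
    X: OmicsMatrix,
    maf_min: float = 0.05,
    call_rate_min: float = 0.90,
    corr_max: float = 0.80,
) -> tuple[OmicsMatrix, QCReport]:
    """Filter markers by MAF, call rate and adjacent-marker correlation.

    Rules are applied in that order: markers with minor-allele frequency
    below ``maf_min`` are removed first, then markers with call rate below
    ``call_rate_min``, then a left-to-right scan removes any marker whose
    absolute correlation with the most recently *retained* marker exceeds
    ``corr_max`` (the earlier marker of a violating pair is kept).
    """
    if X.kind != "genotype":
        raise ValueError("QC filter applies to genotype matrices")
    for name, v in (("maf_min", maf_min), ("call_rate_min", call_rate_min),
                    ("corr_max", corr_max)):
        if not 0 < v < 1:
            raise ValueError(f"{name} must lie in (0, 1), got {v}")

    V = X.values
    n, m = V.shape
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        p = np.nanmean(V, axis=0) / 2.0
    call_rate = np.isfinite(V).mean(axis=0)
    maf = np.minimum(p, 1.0 - p)

    fail_maf = ~(maf >= maf_min)  # NaN-frequency markers fail here too
    fail_cr = (call_rate < call_rate_min) & ~fail_maf

    keep_after = ~fail_maf & ~fail_cr
    retained: list[int] = []
    n_corr = 0
    for j in np.flatnonzero(keep_after):
        if retained and abs(_pairwise_corr(V[:, retained[-1]], V[:, j])) > corr_max:
            n_corr += 1
            continue
        retained.append(j)

    if not retained:
        raise ValueError("empty matrix after QC: all markers removed")

    report = QCReport(
        n_input=m,
        n_removed_maf=int(fail_maf.sum()),
        n_removed_callrate=int(fail_cr.sum()),
        n_removed_corr=n_corr,
        n_retained=len(retained),
        thresholds={
            "maf_min": maf_min,
            "call_rate_min": call_rate_min,
            "corr_max": corr_max,
        },
    )
    out = OmicsMatrix(
        values=V[:, retained].copy(),
        row_ids=list(X.row_ids),
        col_ids=[X.col_ids[j] for j in retained],
        kind="genotype",
    )
    return out, report


def rank_z_transform(X: OmicsMatrix) -> OmicsMatrix:
    """Rank-based inverse-normal transform of each feature across individuals.

    Value ``x`` with (average, for ties) rank ``r`` among ``n`` individuals is
    mapped to the normal quantile ``Phi^-1(r / (n + 1))``, so every feature
    shares the same fixed set of marginal quantiles.
    """
    if X.kind != "transcript":
        raise ValueError("rank-Z transform applies to transcript matrices")
    V = X.values
    if not np.all(np.isfinite(V)):
        raise ValueError("rank-Z transform requires complete data (no missing values)")
    n = V.shape[0]
    tied = np.ptp(V, axis=0) == 0
    if tied.any():
        j = int(np.flatnonzero(tied)[0])
        raise ValueError(f"feature {X.col_ids[j]!r} has all-tied values; "
                         "rank-Z transform is undefined")
    ranks = stats.rankdata(V, axis=0)
    out = stats.norm.ppf(ranks / (n + 1.0))
    return OmicsMatrix(out, list(X.row_ids), list(X.col_ids), "transcript")


def center_standardize(X: OmicsMatrix) -> StandardizedMatrix:
    """Center each feature and scale to unit sample standard deviation (ddof=1).

    Missing values are mean-imputed per feature beforehand (imputed entries
    become exact zeros after centering). Zero-variance features are dropped
    and reported in ``dropped_features``.
    """
    V = X.values.copy()
    n = V.shape[0]
    if n < 2:
        raise ValueError("standardization requires at least 2 individuals")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_means = np.nanmean(V, axis=0)
    miss = ~np.isfinite(V)
    if miss.any():
        V[miss] = np.broadcast_to(col_means, V.shape)[miss]
    means = V.mean(axis=0)
    sds = V.std(axis=0, ddof=1)
    keep = sds > 1e-12
    dropped = [c for c, k in zip(X.col_ids, keep) if not k]
    if not keep.any():
        raise ValueError("all features have zero variance")
    Z = (V[:, keep] - means[keep]) / sds[keep]
    return StandardizedMatrix(
        values=Z,
        row_ids=list(X.row_ids),
        col_ids=[c for c, k in zip(X.col_ids, keep) if k],
        feature_means=means[keep],
        feature_sds=sds[keep],
        dropped_features=dropped,
    )


def _crossprod_kernel(V: np.ndarray, divisor: int, component: str,
                      row_ids: list) -> RelationshipKernel:
    if divisor < 1:
        raise ValueError("kernel divisor (number of features) must be >= 1")
    K = V @ V.T / divisor
    K = (K + K.T) / 2.0  # exact symmetry against round-off
    return RelationshipKernel(K, component, list(row_ids), n_features_used=divisor)


def build_genomic_kernel(Z: StandardizedMatrix) -> RelationshipKernel:
    """Genomic relationship matrix G = ZZ'/m (VanRaden's second method)."""
    return _crossprod_kernel(Z.values, Z.n_features, "g", Z.row_ids)


def build_transcript_kernel(W: StandardizedMatrix) -> RelationshipKernel:
    """Transcriptomic relationship matrix T = WW'/k."""
    return _crossprod_kernel(W.values, W.n_features, "t", W.row_ids)


def build_interaction_kernel(
    G: RelationshipKernel, T: RelationshipKernel
) -> RelationshipKernel:
    """Hadamard (elementwise) product kernel G#T for genome x transcriptome
    interaction effects; PSD by the Schur product theorem."""
    if G.component != "g" or T.component not in ("t", "tc"):
        raise ValueError("interaction kernel requires a g kernel and a t/tc kernel")
    if G.n != T.n or list(G.row_ids) != list(T.row_ids):
        raise ValueError("kernels must share dimension and individual ordering")
    return RelationshipKernel(G.values * T.values, "gt", list(G.row_ids))


def compute_lambda(sigma_e2: float, sigma_g2: float, m: int) -> float:
    """Ridge parameter lambda = m * sigma_e^2 / sigma_g^2 for the smoother.

    The variances are the residual and additive-genomic variance components
    estimated with a GBLUP fit of the same trait; m is the marker count.
    """
    if sigma_g2 <= 0:
        raise ValueError(
            "sigma_g2 must be positive; with a (near-)zero genomic variance the "
            "ridge parameter diverges and conditioning should be skipped "
            "(the trait has nothing genotype-predictable to remove)"
        )
    if sigma_e2 < 0:
        raise ValueError("sigma_e2 must be non-negative")
    if m < 1:
        raise ValueError("marker count m must be >= 1")
    return m * sigma_e2 / sigma_g2


def _smoother_apply(M: np.ndarray, lam: float, W: np.ndarray) -> np.ndarray:
    """Return S @ W with S = M (M + lam I)^-1 for symmetric PSD M."""
    A = M + lam * np.eye(M.shape[0])
    if lam > 0:
        coef = np.linalg.solve(A, W)
    else:
        coef = np.linalg.lstsq(A, W, rcond=None)[0]  # min-norm: projection limit
    return M @ coef


def condition_transcripts(
    W: StandardizedMatrix,
    Z: StandardizedMatrix,
    lam: float,
    method: str = "n",
) -> ConditionedMatrix:
    """Remove the genotype-predictable part of each transcript.

    Computes ``Wc = (I - Z (Z'Z + lam I_m)^-1 Z') W``. The default method
    uses the algebraically identical n-dimensional form
    ``Wc = (I - ZZ'(ZZ' + lam I_n)^-1) W``, preferable when the marker count
    m far exceeds the number of individuals n. ``method="m"`` evaluates the
    m-dimensional textbook form directly (useful for cross-checking).
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    Zv, Wv = Z.values, W.values
    if Zv.shape[0] != Wv.shape[0] or list(Z.row_ids) != list(W.row_ids):
        raise ValueError("W and Z must share individuals and their ordering")
    if method == "n":
        M = Zv @ Zv.T
        Wc = Wv - _smoother_apply(M, lam, Wv)
    elif method == "m":
        m = Zv.shape[1]
        A = Zv.T @ Zv + lam * np.eye(m)
        if lam > 0:
            coef = np.linalg.solve(A, Zv.T @ Wv)
        else:
            coef = np.linalg.lstsq(A, Zv.T @ Wv, rcond=None)[0]
        Wc = Wv - Zv @ coef
    else:
        raise ValueError("method must be 'n' or 'm'")
    return ConditionedMatrix(Wc, list(W.row_ids), list(W.col_ids), lam=lam)


def build_conditioned_kernel(
    Wc: ConditionedMatrix, k: int | None = None
) -> RelationshipKernel:
    """Conditioned transcriptomic kernel Tc = Wc Wc'/k.

    k defaults to the number of genes in Wc (the divisor of the unconditioned
    kernel T, so that Tc -> T as lambda -> infinity).
    """
    if k is None:
        k = Wc.n_features
    if k == 0:
        raise ValueError("gene count k must be >= 1")
    return _crossprod_kernel(Wc.values, k, "tc", Wc.row_ids)
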