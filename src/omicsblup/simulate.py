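"""Synthetic genotype-transcript-phenotype studies for the multi-omics models.

The generator emulates the statistical structure of an outbred mouse
population phenotyped across non-overlapping generations, with liver
transcript levels that are partly under genetic control:

* genotypes: biallelic dosages on an evenly spaced marker grid, with
  adjacent-marker linkage disequilibrium from a haplotype copying rule;
* transcripts: each gene is a linear function of a small cis block of
  markers plus Gaussian noise, with ``prop_cis`` of its variance genetic
  (the genome/transcriptome redundancy knob), then rank-Z transformed;
* phenotype: y = g_direct + coupling * t_effect + gt_effect + e, with
  components rescaled so the realized variance fractions match the
  configuration. ``coupling`` in [0, 1] attenuates the transcript pathway,
  emulating a growing time gap between transcript sampling and phenotyping.

All randomness flows from a single seed; identical configurations give
bit-identical studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kernels import OmicsMatrix, StandardizedMatrix, center_standardize, rank_z_transform

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "simulate_genotypes",
    "simulate_transcripts",
    "simulate_phenotype",
    "simulate_study",
]

#: Generation sizes of the emulated population (478 individuals in four
#: non-overlapping generations).
DEFAULT_GENERATION_SIZES = {4: 47, 5: 47, 7: 192, 11: 192}


@dataclass
class SimulationConfig:
    """Parameters of one synthetic study.

    ``h2_direct`` is the variance share carried by marker effects that do
    not pass through transcripts; ``t2_mediated`` the share carried by the
    transcript pathway (at coupling 1); ``prop_cis`` the genetic share of
    each gene's variance; ``gt2`` the genome-by-transcriptome interaction
    share; ``ld_autocorr`` the haplotype copying probability between
    adjacent markers.
    """

    n_individuals: int = 478
    n_markers: int = 1000
    n_genes: int = 2000
    maf_range: tuple = (0.05, 0.5)
    ld_autocorr: float = 0.9
    n_founders: int = 24
    recomb_rate: float = 0.01
    n_cis: int = 5
    h2_direct: float = 0.15
    t2_mediated: float = 0.45
    prop_cis: float = 0.7
    gt2: float = 0.0
    coupling: float = 1.0
    generation_sizes: dict = field(
        default_factory=lambda: dict(DEFAULT_GENERATION_SIZES)
    )
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 2 or self.n_markers < 1 or self.n_genes < 1:
            raise ValueError("empty configuration")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for name in ("ld_autocorr", "recomb_rate", "h2_direct", "t2_mediated",
                     "prop_cis", "gt2", "coupling"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_founders < 2:
            raise ValueError("need at least 2 founders")
        if self.h2_direct + self.coupling * self.t2_mediated + self.gt2 > 1 + 1e-12:
            raise ValueError("variance fractions sum above 1")
        if self.generation_sizes and sum(self.generation_sizes.values()) != self.n_individuals:
            raise ValueError("generation_sizes must sum to n_individuals")


@dataclass
class SimulatedStudy:
    """A complete synthetic dataset with its generating truth."""

    genotypes: OmicsMatrix
    transcripts: OmicsMatrix
    phenotype: np.ndarray
    generations: np.ndarray
    truth: dict
    config: SimulationConfig


def _scale_to_var(x: np.ndarray, target_var: float) -> np.ndarray:
    """Rescale a vector so its realized sample variance (ddof=1) equals target."""
    if target_var == 0:
        return np.zeros_like(x)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot scale a constant vector to positive variance")
    return x * (np.sqrt(target_var) / sd)


def _markov_haplotypes(n_hap: int, cfg: SimulationConfig, rng) -> np.ndarray:
    """Founder haplotypes with first-order LD from an allele copying rule.

    Allele frequencies are uniform on ``maf_range``; along the grid each
    haplotype copies its previous allele with probability ``ld_autocorr``
    and otherwise draws fresh.
    """
    m = cfg.n_markers
    p = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    H = np.empty((n_hap, m), dtype=np.int8)
    H[:, 0] = rng.random(n_hap) < p[0]
    for j in range(1, m):
        fresh = rng.random(n_hap) < p[j]
        copy = rng.random(n_hap) < cfg.ld_autocorr
        H[:, j] = np.where(copy, H[:, j - 1], fresh)
    return H


def _gametes(h1: np.ndarray, h2: np.ndarray, rate: float, rng) -> np.ndarray:
    """Recombined gametes, one per row pair: crossovers occur between
    adjacent markers with probability ``rate``."""
    n, m = h1.shape
    switch = rng.random((n, m)) < rate
    switch[:, 0] = rng.random(n) < 0.5  # random starting phase
    phase = np.cumsum(switch, axis=1) % 2
    return np.where(phase == 0, h1, h2)


def simulate_genotypes(cfg: SimulationConfig, rng=None) -> OmicsMatrix:
    """Dosage matrix for non-overlapping generations bred from a founder pool.

    A pool of ``n_founders`` unrelated individuals (haplotypes from the
    Markov LD rule) parents the first observed generation; each later
    generation is bred from the previous one by random mating of two
    distinct parents with recombination. The finite pool and sib/half-sib
    families give the cousin-level relatedness the emulated population is
    maintained at, so the genomic relationship matrix carries real family
    structure.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n = cfg.n_individuals
    sizes = ([cnt for _, cnt in sorted(cfg.generation_sizes.items())]
             if cfg.generation_sizes else [n])
    founders = _markov_haplotypes(2 * cfg.n_founders, cfg, rng)
    prev = (founders[0::2], founders[1::2])  # parent generation haplotypes
    hap1_parts, hap2_parts = [], []
    for size in sizes:
        n_par = prev[0].shape[0]
        dams = rng.integers(0, n_par, size)
        sires = (dams + 1 + rng.integers(0, n_par - 1, size)) % n_par  # distinct
        child1 = _gametes(prev[0][dams], prev[1][dams], cfg.recomb_rate, rng)
        child2 = _gametes(prev[0][sires], prev[1][sires], cfg.recomb_rate, rng)
        hap1_parts.append(child1)
        hap2_parts.append(child2)
        prev = (child1, child2)
    H1 = np.vstack(hap1_parts)
    H2 = np.vstack(hap2_parts)
    X = (H1 + H2).astype(float)
    row_ids = [f"ind_{i + 1:04d}" for i in range(n)]
    col_ids = [f"snp_{j + 1:05d}" for j in range(cfg.n_markers)]
    return OmicsMatrix(X, row_ids, col_ids, "genotype")


def simulate_transcripts(
    Z: StandardizedMatrix, cfg: SimulationConfig, rng=None
) -> OmicsMatrix:
    """Gene expression as cis-genetic signal plus noise, rank-Z transformed.

    Each gene draws a contiguous block of ``n_cis`` markers and effects
    ``b``; the genetic part ``Z b`` is rescaled to realized variance
    ``prop_cis`` and the Gaussian noise to ``1 - prop_cis``.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n, m = Z.values.shape
    k = cfg.n_genes
    ncis = min(cfg.n_cis, m)
    raw = np.empty((n, k))
    for j in range(k):
        start = rng.integers(0, m - ncis + 1)
        b = rng.standard_normal(ncis)
        gsig = Z.values[:, start:start + ncis] @ b
        noise = rng.standard_normal(n)
        raw[:, j] = (_scale_to_var(gsig, cfg.prop_cis)
                     + _scale_to_var(noise, 1.0 - cfg.prop_cis))
    mat = OmicsMatrix(raw, list(Z.row_ids),
                      [f"gene_{j + 1:05d}" for j in range(k)], "transcript")
    return rank_z_transform(mat)


def simulate_phenotype(
    Z: StandardizedMatrix,
    W: StandardizedMatrix,
    cfg: SimulationConfig,
    rng=None,
) -> tuple[np.ndarray, dict]:
    """Phenotype y = g_direct + coupling * t_effect + gt_effect + e.

    ``g_direct`` (variance ``h2_direct``) loads on all markers;
    ``t_effect`` (variance ``t2_mediated``) loads on all transcripts; the
    interaction is the elementwise product of standardized latent genomic
    and transcriptomic scores scaled to ``gt2``. The residual variance is
    ``1 - h2_direct - coupling^2 * t2_mediated - gt2`` (the coupling factor
    multiplies the transcript pathway, so its contribution scales with the
    square). Realized component variances match the targets exactly; cross
    terms are sampling noise. The truth record keeps every latent component
    and the realized variance fractions.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n = Z.values.shape[0]
    if W.values.shape[0] != n:
        raise ValueError("Z and W must cover the same individuals")

    g_direct = (_scale_to_var(Z.values @ rng.standard_normal(Z.n_features),
                              cfg.h2_direct)
                if cfg.h2_direct > 0 else np.zeros(n))
    t_effect = (_scale_to_var(W.values @ rng.standard_normal(W.n_features),
                              cfg.t2_mediated)
                if cfg.t2_mediated > 0 else np.zeros(n))
    if cfg.gt2 > 0:
        gl = _scale_to_var(Z.values @ rng.standard_normal(Z.n_features), 1.0)
        tl = _scale_to_var(W.values @ rng.standard_normal(W.n_features), 1.0)
        prod = gl * tl
        gt_effect = _scale_to_var(prod - prod.mean(), cfg.gt2)
    else:
        gt_effect = np.zeros(n)

    e_var = 1.0 - cfg.h2_direct - cfg.coupling**2 * cfg.t2_mediated - cfg.gt2
    e_var = max(e_var, 0.0)
    e = (_scale_to_var(rng.standard_normal(n), e_var) if e_var > 0
         else np.zeros(n))

    y = g_direct + cfg.coupling * t_effect + gt_effect + e
    var_y = y.var(ddof=1)
    truth = {
        "g_direct": g_direct,
        "t_effect": t_effect,
        "gt_effect": gt_effect,
        "e": e,
        "realized_fractions": {
            "h2_direct": float(g_direct.var(ddof=1) / var_y),
            "t2": float((cfg.coupling * t_effect).var(ddof=1) / var_y),
            "gt2": float(gt_effect.var(ddof=1) / var_y),
            "e2": float(e.var(ddof=1) / var_y) if var_y > 0 else 0.0,
        },
        "config_fractions": {
            "h2_direct": cfg.h2_direct,
            "t2_mediated": cfg.t2_mediated,
            "gt2": cfg.gt2,
            "coupling": cfg.coupling,
            "prop_cis": cfg.prop_cis,
        },
    }
    return y, truth


def simulate_study(cfg: SimulationConfig) -> SimulatedStudy:
    """Compose genotypes, transcripts, phenotype and generation labels.

    The three stages draw from independent child streams of ``cfg.seed``,
    so studies differing only in ``coupling`` share genotypes, transcripts
    and latent effect draws (matched-seed comparisons across couplings).
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_g, rng_t, rng_p = (np.random.default_rng(c) for c in ss.spawn(3))

    genotypes = simulate_genotypes(cfg, rng_g)
    Z = center_standardize(genotypes)
    transcripts = simulate_transcripts(Z, cfg, rng_t)
    W = center_standardize(transcripts)
    y, truth = simulate_phenotype(Z, W, cfg, rng_p)

    if cfg.generation_sizes:
        labels = np.concatenate([
            np.full(cnt, gen)
            for gen, cnt in sorted(cfg.generation_sizes.items())
        ])
    else:
        labels = np.zeros(cfg.n_individuals, dtype=int)
    return SimulatedStudy(
        genotypes=genotypes,
        transcripts=transcripts,
        phenotype=y,
        generations=labels,
        truth=truth,
        config=cfg,
    )
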