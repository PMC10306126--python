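"""Synthetic Fos count tables and expression matrices with known ground truth.

The generator emulates the structure the pipeline is built to detect: regions
organized into correlated blocks (the modules of the coactivation network),
with log-scale counts per subject, and a global-synchrony knob that mimics the
brain-wide increase in coactivation seen under drug withdrawal.  Expression
matrices carry a planted fraction of genes whose regional profile correlates
(at a chosen rho) with a supplied log-fold-change vector, among independent
null genes.

Counts are produced by inverting the analysis transform: latent values z are
multivariate normal on the log10 scale and counts are max(round(10**z - 1), 0),
so that log10(count + 1) recovers z up to rounding and planted correlations
are interpretable on the scale the pipeline analyzes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CONTROL, TREATMENT, FosCountTable, ValidationError

logger = logging.getLogger("fosnet")

_PSD_TOL = 1e-10


@dataclass(frozen=True)
class SyntheticCountSpec:
    """Parameters of the block-correlated count generator.

    Defaults mirror a small-animal Fos study: three modules of 20 regions,
    strong within-module and weak between-module coactivation, five subjects
    per group, counts of order 10**2 cells per region with ~2-fold
    subject-to-subject spread on the log10 scale.
    """

    n_regions: int = 60
    block_sizes: tuple[int, ...] = (20, 20, 20)
    within_r: float = 0.6
    between_r: float = 0.1
    global_r_boost: float = 0.2
    n_subjects_per_group: int = 5
    base_log_mean: float = 2.0
    log_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "block_sizes", tuple(self.block_sizes))
        if sum(self.block_sizes) != self.n_regions:
            raise ValidationError(
                f"block_sizes sum to {sum(self.block_sizes)}, expected n_regions={self.n_regions}"
            )
        if not 0.0 <= self.within_r < 1.0:
            raise ValidationError(f"within_r must be in [0, 1), got {self.within_r}")
        if self.within_r <= self.between_r and self.within_r != 0.0:
            raise ValidationError(
                f"within_r ({self.within_r}) must exceed between_r ({self.between_r})"
            )
        if self.n_subjects_per_group < 2:
            raise ValidationError("need >=2 subjects per group")
        if self.log_sd <= 0:
            raise ValidationError("log_sd must be positive")


@dataclass(frozen=True)
class SyntheticExpressionSpec:
    """Parameters of the planted-correlation expression generator."""

    n_null_genes: int = 2000
    n_signal_genes: int = 200
    signal_rho: float = 0.4
    noise_sd: float = 0.1
    n_experiments_per_gene: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not abs(self.signal_rho) < 1.0:
            raise ValidationError(f"|signal_rho| must be < 1, got {self.signal_rho}")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.n_experiments_per_gene < 1:
            raise ValidationError("need >=1 experiment per gene")


@dataclass
class GroundTruth:
    """What the generator planted: region -> module and/or signal-gene ids."""

    module_of_region: dict[str, int] = field(default_factory=dict)
    signal_gene_ids: set[str] = field(default_factory=set)
    realized_rho: dict[str, float] = field(default_factory=dict)


def block_correlation_matrix(spec: SyntheticCountSpec, boosted: bool) -> np.ndarray:
    """Target correlation matrix: ``within_r`` inside blocks, ``between_r``
    outside, plus ``global_r_boost`` on every off-diagonal entry for the
    treatment condition.  The base matrix must be positive semi-definite
    (hard error otherwise); the boosted matrix is eigenvalue-clipped with a
    warning if the additive boost breaks PSD."""
    n = spec.n_regions
    corr = np.full((n, n), spec.between_r, dtype=float)
    start = 0
    for size in spec.block_sizes:
        corr[start : start + size, start : start + size] = spec.within_r
        start += size
    np.fill_diagonal(corr, 1.0)
    min_eig = np.linalg.eigvalsh(corr).min()
    if min_eig < -_PSD_TOL:
        raise ValidationError(
            f"requested correlation matrix is not PSD (min eigenvalue {min_eig:.3g}); "
            f"within_r={spec.within_r}, between_r={spec.between_r} infeasible for "
            f"blocks {spec.block_sizes}"
        )
    if boosted and spec.global_r_boost != 0.0:
        off = ~np.eye(n, dtype=bool)
        corr = corr.copy()
        corr[off] = np.clip(corr[off] + spec.global_r_boost, -0.999, 0.999)
        vals, vecs = np.linalg.eigh(corr)
        if vals.min() < -_PSD_TOL:
            logger.warning(
                "global_r_boost=%.3g broke positive semi-definiteness "
                "(min eigenvalue %.3g); clipping eigenvalues",
                spec.global_r_boost, vals.min(),
            )
            vals = np.clip(vals, 0.0, None)
            corr = vecs @ np.diag(vals) @ vecs.T
            d = np.sqrt(np.diag(corr))
            corr = corr / np.outer(d, d)
            np.fill_diagonal(corr, 1.0)
    return corr


def _sample_counts(rng: np.random.Generator, corr: np.ndarray, spec: SyntheticCountSpec) -> np.ndarray:
    n = spec.n_regions
    cov = corr * spec.log_sd**2
    z = rng.multivariate_normal(
        np.full(n, spec.base_log_mean), cov, size=spec.n_subjects_per_group, method="eigh"
    )
    counts = np.rint(10.0**z - 1.0)
    return np.clip(counts, 0, None).astype(int).T  # regions x subjects


def generate_counts(spec: SyntheticCountSpec) -> tuple[FosCountTable, GroundTruth]:
    """Draw a two-group Fos count table with planted block structure.

    Both groups share the block assignment; the treatment group's latent
    correlation receives ``global_r_boost`` on every off-diagonal entry,
    emulating brain-wide synchronization.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    regions = [f"R{i:03d}" for i in range(spec.n_regions)]
    module_of_region: dict[str, int] = {}
    start = 0
    for b, size in enumerate(spec.block_sizes, start=1):
        for i in range(start, start + size):
            module_of_region[regions[i]] = b
        start += size

    ctrl = _sample_counts(rng, block_correlation_matrix(spec, boosted=False), spec)
    trt = _sample_counts(rng, block_correlation_matrix(spec, boosted=True), spec)

    n = spec.n_subjects_per_group
    subjects = [f"ctrl{i + 1}" for i in range(n)] + [f"trt{i + 1}" for i in range(n)]
    groups = {s: CONTROL for s in subjects[:n]} | {s: TREATMENT for s in subjects[n:]}
    counts = pd.DataFrame(np.hstack([ctrl, trt]), index=regions, columns=subjects)
    return FosCountTable(counts=counts, group_of_subject=groups), GroundTruth(
        module_of_region=module_of_region
    )


def generate_expression(
    spec: SyntheticExpressionSpec, lfc: pd.Series
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a long-format expression table against a regional LFC vector.

    Signal genes are ``signal_rho``-correlated (in population) linear
    transforms of the standardized LFC plus Gaussian noise; null genes are
    independent noise.  Each gene contributes ``n_experiments_per_gene``
    replicate experiments (shared latent profile plus experiment noise).
    Values are mapped affinely onto a non-negative "percentage of pixels"
    scale in [0, 100].

    Returns a DataFrame with columns (gene_id, experiment_id, region_id,
    density) and the ground truth of planted signal genes with their realized
    sample correlations.
    """
    lfc = pd.Series(lfc)
    if lfc.std(ddof=0) == 0:
        raise ValidationError("LFC vector has zero variance; planted correlation undefined")
    rng = np.random.default_rng(spec.seed)
    regions = list(lfc.index)
    n_reg = len(regions)
    z_lfc = (lfc.to_numpy(float) - lfc.mean()) / lfc.std(ddof=0)

    n_sig, n_null = spec.n_signal_genes, spec.n_null_genes
    gene_ids = [f"sig{i:04d}" for i in range(n_sig)] + [f"null{i:04d}" for i in range(n_null)]
    rho = spec.signal_rho
    latent = np.empty((n_sig + n_null, n_reg))
    latent[:n_sig] = rho * z_lfc + np.sqrt(1 - rho**2) * rng.standard_normal((n_sig, n_reg))
    latent[n_sig:] = rng.standard_normal((n_null, n_reg))

    truth = GroundTruth(signal_gene_ids=set(gene_ids[:n_sig]))
    records = []
    for g, gene in enumerate(gene_ids):
        profile = latent[g]
        observed = np.empty((spec.n_experiments_per_gene, n_reg))
        for e in range(spec.n_experiments_per_gene):
            vec = profile + spec.noise_sd * rng.standard_normal(n_reg)
            observed[e] = vec
            # map onto the reporting scale; ~8-sigma headroom keeps clipping rare
            density = np.clip(50.0 + 6.0 * vec, 0.0, 100.0)
            records.append(
                pd.DataFrame(
                    {
                        "gene_id": gene,
                        "experiment_id": f"{gene}_e{e}",
                        "region_id": regions,
                        "density": density,
                    }
                )
            )
        truth.realized_rho[gene] = float(np.corrcoef(observed.mean(axis=0), z_lfc)[0, 1])
    return pd.concat(records, ignore_index=True), truth
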