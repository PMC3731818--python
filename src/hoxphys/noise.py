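"""Developmental-noise Monte Carlo on Factors of Phenotypic Realization.

Each intergenic stretch d(i,i+1) sets the functioning time of gene i, which
in the unperturbed embryo produces a body segment of constant ideal length
l via the Factor of Phenotypic Realization (FPR)

    f(i,i+1) = l / d(i,i+1).

Gaussian white noise perturbs the FPRs; the realized segment lengths

    l'(i,i+1) = f'(i,i+1) * d(i,i+1)

then scatter around l, and the pooled variance of l' measures how well a
given cluster geometry buffers developmental noise.  Compact, regular
clusters (vertebrate-type) yield a markedly smaller variance than loose,
irregular ones (amphioxus-type): this is the quantitative content of the
evolutionary argument the package reproduces.

Four noise families are provided; all have mean-zero Gaussian innovations
eta drawn independently per realization and per segment:

========================  =======================  =========================
model                     perturbation             pooled variance (closed)
========================  =======================  =========================
additive-mean-relative    f' = f + eta,            (eps*mean_f)^2 * mean(d^2)
                          sd(eta) = eps*mean(f)
additive-absolute         f' = f + eta,            eps^2 * mean(d^2)
                          sd(eta) = eps
multiplicative            f' = f*(1+eta),          eps^2 * l^2
                          sd(eta) = eps
brownian                  l' = l + eta,            eps^2 * mean(d)
                          sd(eta) = eps*sqrt(d)
========================  =======================  =========================

The brownian family models noise accumulating over the functioning time
(proportional to d).  Under every family except multiplicative the pooled
variance grows with the cluster's distance dispersion, which is the ordering
property the cross-organism comparison relies on.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np

from .cluster import HoxCluster, HoxValidationError, cluster_stats

__all__ = [
    "NOISE_MODELS",
    "FPRProfile",
    "NoiseSpec",
    "PerturbedSegments",
    "SegmentStats",
    "OrganismComparison",
    "compute_fpr",
    "perturb_and_realize",
    "segment_stats",
    "segment_theoretical_variances",
    "theoretical_variance",
    "monte_carlo_standard_errors",
    "compare_organisms",
]

logger = logging.getLogger(__name__)

NOISE_MODELS = (
    "additive-mean-relative",
    "additive-absolute",
    "multiplicative",
    "brownian",
)


@dataclass(frozen=True)
class FPRProfile:
    """Per-segment factors of phenotypic realization, f(i,i+1) = l/d(i,i+1)."""

    ideal_length_l: float
    factors: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "factors", np.asarray(self.factors, dtype=float)
        )


@dataclass(frozen=True)
class NoiseSpec:
    """Noise family, level eps (sd scale), realization count and seed."""

    model: str = "additive-mean-relative"
    level: float = 0.05
    realizations_R: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in NOISE_MODELS:
            raise HoxValidationError(
                f"unknown noise model {self.model!r}; choose from {NOISE_MODELS}"
            )
        if self.level < 0:
            raise HoxValidationError("noise level must be >= 0")
        if self.realizations_R < 1:
            raise HoxValidationError("need at least one realization")


@dataclass(frozen=True)
class PerturbedSegments:
    """Matrix of realized segment lengths l', shape (R, n_segments)."""

    lengths: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "lengths", np.asarray(self.lengths, dtype=float)
        )


@dataclass(frozen=True)
class SegmentStats:
    """Pooled mean and population variance over all R*n realized lengths."""

    pooled_mean: float
    pooled_variance: float


@dataclass(frozen=True)
class OrganismComparison:
    """Per-cluster noise-experiment summary plus the variance ranking."""

    rows: tuple[dict, ...]
    ranking: tuple[str, ...] = field(default=())


def compute_fpr(cluster: HoxCluster, l: float) -> FPRProfile:
    """FPRs for ``cluster`` at ideal segment length ``l``: f = l/d."""
    if l <= 0:
        raise HoxValidationError(f"ideal segment length must be > 0, got {l}")
    d = np.asarray(cluster.distances_kbp, dtype=float)
    if d.size == 0:
        raise HoxValidationError("cluster has no intergenic distances")
    if np.any(d <= 0):
        raise HoxValidationError("all distances must be > 0 to define FPRs")
    return FPRProfile(ideal_length_l=float(l), factors=l / d)


def perturb_and_realize(
    fpr: FPRProfile,
    cluster: HoxCluster,
    noise: NoiseSpec,
    rng: np.random.Generator | None = None,
    mean_fpr: float | None = None,
) -> PerturbedSegments:
    """Draw R noisy realizations of the segment lengths l' = f'·d.

    ``rng`` overrides the spec's seed (used for substream control);
    ``mean_fpr`` overrides the reference mean FPR of the
    additive-mean-relative family, so that several clusters can be driven by
    one common noise amplitude ("the same white noise").
    """
    d = np.asarray(cluster.distances_kbp, dtype=float)
    f = fpr.factors
    if f.shape != d.shape:
        raise HoxValidationError("FPR profile is not aligned with the cluster")
    l = fpr.ideal_length_l
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    R, n = noise.realizations_R, d.size
    eps = noise.level

    if noise.model == "additive-mean-relative":
        ref = float(f.mean()) if mean_fpr is None else float(mean_fpr)
        eta = rng.normal(0.0, eps * ref, size=(R, n)) if eps * ref > 0 else np.zeros((R, n))
        lengths = (f + eta) * d
    elif noise.model == "additive-absolute":
        eta = rng.normal(0.0, eps, size=(R, n)) if eps > 0 else np.zeros((R, n))
        lengths = (f + eta) * d
    elif noise.model == "multiplicative":
        eta = rng.normal(0.0, eps, size=(R, n)) if eps > 0 else np.zeros((R, n))
        lengths = l * (1.0 + eta)
    elif noise.model == "brownian":
        sd = eps * np.sqrt(d)
        eta = rng.normal(0.0, 1.0, size=(R, n)) * sd if eps > 0 else np.zeros((R, n))
        lengths = l + eta
    else:  # pragma: no cover - guarded by NoiseSpec
        raise HoxValidationError(f"unknown noise model {noise.model!r}")

    negatives = int((lengths < 0).sum())
    if negatives:
        # retained, not clipped: clipping would bias the variance
        logger.warning(
            "%d of %d perturbed segment lengths are negative (level=%g)",
            negatives, lengths.size, eps,
        )
    return PerturbedSegments(lengths=lengths)


def segment_stats(perturbed: PerturbedSegments) -> SegmentStats:
    """Pooled mean and population variance over all R*n realized lengths."""
    x = perturbed.lengths
    if x.size == 0:
        raise HoxValidationError("empty realization matrix")
    return SegmentStats(
        pooled_mean=float(x.mean()), pooled_variance=float(x.var(ddof=0))
    )


def segment_theoretical_variances(
    cluster: HoxCluster,
    l: float,
    noise: NoiseSpec,
    mean_fpr: float | None = None,
) -> np.ndarray:
    """Closed-form Var(l') per segment for the selected noise family."""
    d = np.asarray(cluster.distances_kbp, dtype=float)
    eps = noise.level
    if noise.model == "additive-mean-relative":
        ref = float((l / d).mean()) if mean_fpr is None else float(mean_fpr)
        return (eps * ref) ** 2 * d**2
    if noise.model == "additive-absolute":
        return eps**2 * d**2
    if noise.model == "multiplicative":
        return np.full_like(d, eps**2 * l**2)
    if noise.model == "brownian":
        return eps**2 * d
    raise HoxValidationError(f"unknown noise model {noise.model!r}")


def theoretical_variance(
    cluster: HoxCluster,
    l: float,
    noise: NoiseSpec,
    mean_fpr: float | None = None,
) -> float:
    """Closed-form pooled variance (the Monte-Carlo oracle).

    All families have per-segment mean exactly l, so the pooled variance is
    the plain average of the per-segment variances.
    """
    return float(segment_theoretical_variances(cluster, l, noise, mean_fpr).mean())


def monte_carlo_standard_errors(
    cluster: HoxCluster,
    l: float,
    noise: NoiseSpec,
    mean_fpr: float | None = None,
) -> tuple[float, float]:
    """(SE of pooled mean, SE of pooled variance) for R realizations.

    For independent Gaussian segments with known means, the pooled-variance
    estimator averages per-segment sample variances, giving
    Var = 2 Σ σ_i^4 / (n² R).
    """
    sig2 = segment_theoretical_variances(cluster, l, noise, mean_fpr)
    n, R = sig2.size, noise.realizations_R
    se_mean = float(np.sqrt(sig2.mean() / (n * R)))
    se_var = float(np.sqrt(2.0 * (sig2**2).sum() / (n**2 * R)))
    return se_mean, se_var


def _substream(seed: int, organism: str) -> np.random.Generator:
    # order-independent, deterministic child stream keyed by organism name
    key = zlib.crc32(organism.encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence([seed, key]))


def compare_organisms(
    clusters: list[HoxCluster] | tuple[HoxCluster, ...],
    l: float,
    noise: NoiseSpec,
) -> OrganismComparison:
    """Run the noise experiment on several clusters under the same white noise.

    For the additive-mean-relative family a single common noise amplitude —
    eps times the pooled mean FPR over all compared clusters — is applied to
    every organism, so that the comparison perturbs all geometries with the
    same noise rather than rescaling it per cluster.  Each cluster gets an
    independent substream keyed by its organism name, so the result does not
    depend on the order of the input list.
    """
    if len(clusters) < 2:
        raise HoxValidationError("need at least two clusters to compare")
    profiles = [compute_fpr(c, l) for c in clusters]
    all_factors = np.concatenate([p.factors for p in profiles])
    common_mean_fpr = float(all_factors.mean())

    rows = []
    for cluster, profile in zip(clusters, profiles):
        rng = _substream(noise.seed, cluster.organism)
        realized = perturb_and_realize(
            profile, cluster, noise, rng=rng, mean_fpr=common_mean_fpr
        )
        stats = segment_stats(realized)
        rows.append(
            {
                "organism": cluster.organism,
                "n_segments": len(cluster.distances_kbp),
                "total_kbp": cluster_stats(cluster).total_kbp,
                "pooled_mean": stats.pooled_mean,
                "pooled_variance": stats.pooled_variance,
                "theoretical_variance": theoretical_variance(
                    cluster, l, noise, mean_fpr=common_mean_fpr
                ),
            }
        )
    ranking = tuple(
        r["organism"] for r in sorted(rows, key=lambda r: r["pooled_variance"])
    )
    return OrganismComparison(rows=tuple(rows), ranking=ranking)
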