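"""Variance stabilization, mean density profiles, and profile statistics.

A mean density profile (MDP) is a genotype's per-passage mean culture size
(with standard deviation) over its replicate cultures.  Raw image-derived
sizes are heteroscedastic, so they are first variance-stabilized with a
Box-Cox power transform (power 0.6).  Profiles are then compared with
three statistics: Pearson's r between mean curves (shape similarity,
invariant to the absolute fitness level), the root-mean-square difference
(absolute disagreement), and the profile area (total fitness, the sum of
mean size over all passages).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .plate_model import ScreenDataset

__all__ = [
    "TransformConfig",
    "MDP",
    "ProfileComparison",
    "TransformStateError",
    "transform_sizes",
    "compute_mdp",
    "compute_all_mdps",
    "mdp_area",
    "rms_difference",
    "pearson_correlation",
    "compare_profiles",
    "write_mdp_table",
]


class TransformStateError(ValueError):
    """Raised when a transform is applied to already-transformed data."""


@dataclass(frozen=True)
class TransformConfig:
    """Box-Cox power transform settings.

    ``plain_power`` maps x -> x**lambda (keeps 0 at 0 and leaves raw sizes
    of order 1e6 near the familiar few-thousand-unit fitness scale);
    ``scaled_power`` is the textbook Box-Cox form (x**lambda - 1)/lambda.
    Both are strictly increasing, so within-passage rankings are preserved
    and shape-based statistics downstream are unaffected by the choice.
    """

    lambda_power: float = 0.6
    variant: str = "plain_power"

    def __post_init__(self) -> None:
        if self.lambda_power <= 0:
            raise ValueError("lambda_power must be positive")
        if self.variant not in ("plain_power", "scaled_power"):
            raise ValueError(f"unknown transform variant {self.variant!r}")

    def apply(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        lam = self.lambda_power
        if self.variant == "plain_power":
            return np.power(x, lam)
        out = np.where(x > 0, (np.power(x, lam) - 1.0) / lam, -1.0 / lam)
        return out


@dataclass
class MDP:
    """Mean density profile: per-passage mean and sd over replicates."""

    genotype: str
    n_repeats: int
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.mean.shape != self.sd.shape or self.mean.ndim != 1:
            raise ValueError("mean and sd must be 1-D arrays of equal length")
        if np.any(self.sd < 0):
            raise ValueError("standard deviations must be non-negative")

    @property
    def passage_count(self) -> int:
        return int(self.mean.shape[0])


@dataclass(frozen=True)
class ProfileComparison:
    """All three pairwise profile statistics for a pair of genotypes.

    ``r`` is None when either profile is constant (zero variance); this is
    flagged rather than coerced to 0, which would fabricate dissimilarity.
    """

    genotype_a: str
    genotype_b: str
    r: float | None
    rms: float
    area_a: float
    area_b: float


def transform_sizes(dataset: ScreenDataset, cfg: TransformConfig | None = None) -> ScreenDataset:
    """Variance-stabilize every culture size in a raw-scale dataset.

    Raises :class:`TransformStateError` if the dataset is already on the
    transformed scale.
    """
    cfg = cfg or TransformConfig()
    if dataset.scale != "raw":
        raise TransformStateError(
            f"dataset is already on scale {dataset.scale!r}; transform applies to raw data"
        )
    return dataset.with_sizes(
        (cfg.apply(c.sizes) for c in dataset.cultures), scale="transformed"
    )


def compute_mdp(dataset: ScreenDataset, genotype: str) -> MDP:
    """Mean density profile of one genotype.

    The per-passage mean is the arithmetic mean over replicate cultures;
    sd is the sample standard deviation (n-1 denominator), defined as 0
    for a single replicate.
    """
    mat = dataset.size_matrix(genotype)  # raises KeyError for unknown genotype
    n = mat.shape[0]
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1) if n > 1 else np.zeros(mat.shape[1])
    return MDP(genotype=genotype, n_repeats=n, mean=mean, sd=sd)


def compute_all_mdps(dataset: ScreenDataset) -> dict[str, MDP]:
    """MDPs for every genotype in the dataset, keyed by label."""
    return {g: compute_mdp(dataset, g) for g in dataset.genotypes()}


def mdp_area(mdp: MDP) -> float:
    """Total fitness across the experiment: the plain sum of per-passage
    mean culture sizes (no normalization by passage count)."""
    return float(np.sum(mdp.mean))


def rms_difference(a: MDP, b: MDP) -> float:
    """Root-mean-square difference between two mean curves."""
    if a.passage_count != b.passage_count:
        raise ValueError(
            f"profiles have different passage counts: {a.passage_count} vs {b.passage_count}"
        )
    return float(np.sqrt(np.mean((a.mean - b.mean) ** 2)))


def pearson_correlation(a: MDP, b: MDP) -> float | None:
    """Pearson's r between two mean curves; None if either is constant.

    Shape similarity only: invariant under positive-affine rescaling of
    either profile, so a sick strain and a healthy strain with similarly
    shaped trajectories correlate strongly.
    """
    if a.passage_count != b.passage_count:
        raise ValueError(
            f"profiles have different passage counts: {a.passage_count} vs {b.passage_count}"
        )
    if a.passage_count < 3:
        raise ValueError("Pearson correlation needs at least 3 passages")
    xa = a.mean - a.mean.mean()
    xb = b.mean - b.mean.mean()
    na, nb = np.linalg.norm(xa), np.linalg.norm(xb)
    if na == 0.0 or nb == 0.0:
        return None
    r = float(np.dot(xa, xb) / (na * nb))
    return float(np.clip(r, -1.0, 1.0))


def compare_profiles(a: MDP, b: MDP) -> ProfileComparison:
    return ProfileComparison(
        genotype_a=a.genotype,
        genotype_b=b.genotype,
        r=pearson_correlation(a, b),
        rms=rms_difference(a, b),
        area_a=mdp_area(a),
        area_b=mdp_area(b),
    )


def write_mdp_table(mdps: Iterable[MDP], path) -> None:
    """Export MDPs as a long tab-separated table
    (genotype, n_repeats, passage, mean, sd)."""
    with open(path, "w") as fh:
        fh.write("genotype\tn_repeats\tpassage\tmean\tsd\n")
        for mdp in mdps:
            for p in range(mdp.passage_count):
                fh.write(
                    f"{mdp.genotype}\t{mdp.n_repeats}\t{p + 1}\t"
                    f"{float(mdp.mean[p])!r}\t{float(mdp.sd[p])!r}\n"
                )
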