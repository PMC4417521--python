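"""Sample sizes for trials comparing mean CRCI between two arms.

Uses the standard normal-approximation formula for comparing two means,

    n_valid = (z_{1-alpha/2} + z_{power})^2 * (sd_c^2 + sd_i^2) / delta^2,

inflated by 1/v for households without a defined score (they are recruited
but contribute no outcome), and by the design effect 1 + (m - 1) * rho for
cluster randomization with clusters of m households and intra-cluster
correlation rho.  Reported sizes are rounded to the nearest 10.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, floor

from scipy.stats import norm

__all__ = [
    "SampleSizeInputs",
    "ClusterSpec",
    "SampleSizeResult",
    "n_per_arm",
    "design_effect",
    "clustered_sample_size",
    "round_to_ten",
]


@dataclass(frozen=True)
class SampleSizeInputs:
    """Two-arm summary statistics and test operating characteristics."""

    mean_control: float
    mean_intervention: float
    sd_control: float
    sd_intervention: float
    alpha: float = 0.05
    power: float = 0.90
    valid_fraction: float = 1.0

    def __post_init__(self) -> None:
        for name in ("mean_control", "mean_intervention"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.sd_control < 0 or self.sd_intervention < 0:
            raise ValueError("SDs must be >= 0")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if not (0.0 < self.power < 1.0):
            raise ValueError("power must be in (0, 1)")
        if not (0.0 < self.valid_fraction <= 1.0):
            raise ValueError("valid_fraction must be in (0, 1]")

    @property
    def delta(self) -> float:
        return abs(self.mean_intervention - self.mean_control)


@dataclass(frozen=True)
class ClusterSpec:
    """Cluster randomization: households per cluster and intra-cluster
    correlation (one cluster = one community health worker's patch)."""

    m: int = 100
    icc: float = 0.0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("cluster size m must be >= 1")
        if not (0.0 <= self.icc < 1.0):
            raise ValueError("icc must be in [0, 1)")


@dataclass(frozen=True)
class SampleSizeResult:
    """Households per arm before and after the design-effect inflation."""

    n_unclustered: float
    design_effect: float
    n_clustered: float
    n_reported: int
    clusters_per_arm: int


def round_to_ten(x: float) -> int:
    """Round half up to the nearest multiple of 10 (reporting convention)."""
    return int(floor(x / 10.0 + 0.5)) * 10


def n_per_arm(inputs: SampleSizeInputs) -> float:
    """Households per arm (real-valued) for an individually randomized
    comparison of mean scores, inflated for households without a defined
    score."""
    if inputs.delta == 0:
        raise ValueError("mean difference is zero: required n is infinite")
    z = norm.ppf(1.0 - inputs.alpha / 2.0) + norm.ppf(inputs.power)
    var_sum = inputs.sd_control**2 + inputs.sd_intervention**2
    n_valid = z**2 * var_sum / inputs.delta**2
    return n_valid / inputs.valid_fraction


def design_effect(cluster: ClusterSpec) -> float:
    """Variance inflation 1 + (m - 1) * rho for cluster randomization."""
    return 1.0 + (cluster.m - 1) * cluster.icc


def clustered_sample_size(
    inputs: SampleSizeInputs, cluster: ClusterSpec
) -> SampleSizeResult:
    """Per-arm sample size under cluster randomization."""
    base = n_per_arm(inputs)
    de = design_effect(cluster)
    n_clustered = base * de
    return SampleSizeResult(
        n_unclustered=base,
        design_effect=de,
        n_clustered=n_clustered,
        n_reported=round_to_ten(n_clustered),
        clusters_per_arm=ceil(n_clustered / cluster.m),
    )
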