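"""Sex-partitioning decision for reference intervals (Harris-Boyd criterion).

Subgroup-specific reference intervals are warranted when the standardized
between-group mean difference

    z = |mean1 - mean2| / sqrt(s1^2/n1 + s2^2/n2)

exceeds the sample-size-scaled critical value z* = 3 sqrt(nbar/120) with
nbar = (n1 + n2)/2, or when the ratio of the larger to the smaller group
standard deviation reaches 1.5. This is the Harris-Boyd rule as
operationalized in CLSI EP28-A3c. Because the criterion assumes roughly
Gaussian groups, it is normally applied on the symmetrized scale produced
by transform selection; a raw-scale mode is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimate import RIConfig, DEFAULT_CONFIG, select_transform

__all__ = ["PartitionDecision", "harris_boyd", "mann_whitney",
           "harris_boyd_transformed"]


@dataclass
class PartitionDecision:
    """Outcome of the Harris-Boyd partitioning test for two subgroups."""

    z: float
    z_star: float
    sd_ratio: float           # larger / smaller
    n1: int
    n2: int
    means: tuple
    sds: tuple
    partition_required: bool
    rationale: str
    scale: str = "raw"

    def to_dict(self) -> dict:
        return {
            "z": self.z, "z_star": self.z_star, "sd_ratio": self.sd_ratio,
            "n1": self.n1, "n2": self.n2,
            "means": list(self.means), "sds": list(self.sds),
            "partition_required": self.partition_required,
            "rationale": self.rationale, "scale": self.scale,
        }


def harris_boyd(group1, group2, sd_ratio_threshold: float = 1.5,
                scale: str = "raw") -> PartitionDecision:
    """Harris-Boyd partitioning decision for two subgroups.

    Partitioning is required when z > z* = 3 sqrt(nbar/120) or when the
    SD ratio (larger/smaller) reaches ``sd_ratio_threshold``.

    Raises
    ------
    ValueError
        If either group has fewer than 2 values or zero variance.
    """
    x1 = np.asarray(group1, dtype=float)
    x2 = np.asarray(group2, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise ValueError("both groups need at least 2 values")
    s1, s2 = float(x1.std(ddof=1)), float(x2.std(ddof=1))
    if s1 == 0.0 or s2 == 0.0:
        raise ValueError("both groups must have positive variance")
    m1, m2 = float(x1.mean()), float(x2.mean())
    n1, n2 = x1.size, x2.size
    z = abs(m1 - m2) / math.sqrt(s1 * s1 / n1 + s2 * s2 / n2)
    nbar = (n1 + n2) / 2.0
    z_star = 3.0 * math.sqrt(nbar / 120.0)
    sd_ratio = max(s1, s2) / min(s1, s2)
    by_z = z > z_star
    by_sd = sd_ratio >= sd_ratio_threshold
    required = by_z or by_sd
    if required:
        parts = []
        if by_z:
            parts.append(f"z = {z:.3f} exceeds z* = {z_star:.3f}")
        if by_sd:
            parts.append(f"SD ratio {sd_ratio:.3f} >= {sd_ratio_threshold}")
        rationale = "partition required: " + " and ".join(parts)
    else:
        rationale = (f"no partition: z = {z:.3f} <= z* = {z_star:.3f} and "
                     f"SD ratio {sd_ratio:.3f} < {sd_ratio_threshold}")
    return PartitionDecision(
        z=z, z_star=z_star, sd_ratio=sd_ratio, n1=n1, n2=n2,
        means=(m1, m2), sds=(s1, s2),
        partition_required=required, rationale=rationale, scale=scale,
    )


def harris_boyd_transformed(group1, group2, sd_ratio_threshold: float = 1.5,
                            config: RIConfig = DEFAULT_CONFIG) -> PartitionDecision:
    """Harris-Boyd on the symmetrized scale chosen for the pooled sample."""
    pooled = np.concatenate([np.asarray(group1, float), np.asarray(group2, float)])
    transform = select_transform(pooled, config)
    return harris_boyd(transform.apply(group1), transform.apply(group2),
                       sd_ratio_threshold, scale=transform.family)


def mann_whitney(group1, group2):
    """Two-sided Mann-Whitney rank-sum test (normal approximation, tie
    corrected). Returns ``(U, p)`` with U the statistic of ``group1``."""
    x1 = np.asarray(group1, dtype=float)
    x2 = np.asarray(group2, dtype=float)
    if x1.size == 0 or x2.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(x1, x2, alternative="two-sided",
                             method="asymptotic")
    return float(res.statistic), float(min(res.pvalue, 1.0))
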