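"""Null data-generating process for balanced two-arm cluster randomized trials.

A cluster randomized trial (CRT) randomizes groups (clusters) of subjects
rather than individuals.  Under the null hypothesis of no treatment effect,
outcomes follow a one-way random-effects structure

    y_ij = b_i + e_ij,   b_i ~ N(0, sigma_b2),   e_ij ~ N(0, sigma2),

for clusters i = 1..K and subjects j = 1..N within each cluster, with the
cluster intercepts ``b_i`` independent of the residuals ``e_ij``.  The first
K/2 clusters are assigned to the control arm and the remaining K/2 to the
treatment arm; the arm indicator plays no role in generation (the treatment
effect is exactly zero) but is carried so that downstream analysis models can
estimate and test it.

The generator is deterministic given a :class:`DesignConfig` (including its
seed), draws the K cluster intercepts before the K*N residuals, and scales
standard-normal variates by the requested standard deviations.  This fixed
draw order makes generation *scale equivariant*: multiplying both variance
components by c > 0 multiplies every outcome by exactly sqrt(c), which is the
mechanism behind the invariance of all test statistics to the absolute size
of the variance components.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DesignConfig",
    "NullDataset",
    "generate_null_dataset",
    "icc",
    "replicate_rng",
    "read_dataset_csv",
    "write_dataset_csv",
]


@dataclass(frozen=True)
class DesignConfig:
    """One simulation condition for a balanced two-arm null CRT.

    Parameters
    ----------
    K : int
        Total number of clusters, split evenly between two arms.  Must be
        even and at least 4 (two clusters per arm is the minimum for a
        between-cluster variance estimate).
    N : int
        Subjects per cluster; at least 2 so the within-cluster variance is
        estimable.
    sigma_b2 : float
        Between-cluster (random intercept) variance, in squared outcome
        units.  May be zero (no clustering).
    sigma2 : float
        Within-cluster residual variance, in squared outcome units; strictly
        positive.
    seed : int
        Random-stream identifier used when the dataset is generated directly
        from the config.
    """

    K: int
    N: int
    sigma_b2: float
    sigma2: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 4:
            raise ValueError(f"K must be >= 4, got {self.K}")
        if self.K % 2 != 0:
            raise ValueError(f"K must be even (two equal arms), got {self.K}")
        if self.N < 2:
            raise ValueError(f"N must be >= 2, got {self.N}")
        if self.sigma_b2 < 0:
            raise ValueError(f"sigma_b2 must be >= 0, got {self.sigma_b2}")
        if self.sigma2 <= 0:
            raise ValueError(f"sigma2 must be > 0, got {self.sigma2}")

    @property
    def icc(self) -> float:
        """Intraclass correlation coefficient implied by the variances."""
        return icc(self.sigma_b2, self.sigma2)

    @property
    def n_obs(self) -> int:
        return self.K * self.N

    def replace(self, **changes) -> "DesignConfig":
        return dataclasses.replace(self, **changes)


@dataclass
class NullDataset:
    """A balanced two-arm CRT dataset in long, cluster-major layout.

    Rows are ordered by (cluster, subject); cluster labels run 1..K with
    exactly N rows each; clusters 1..K/2 carry ``arm == 0`` (control) and
    clusters K/2+1..K carry ``arm == 1`` (treatment).
    """

    y: np.ndarray
    cluster: np.ndarray
    arm: np.ndarray

    @property
    def K(self) -> int:
        return int(self.cluster[-1])

    @property
    def N(self) -> int:
        return self.y.shape[0] // self.K

    def validate(self) -> None:
        """Check the balanced-layout invariants; raise ValueError on breach."""
        y, cluster, arm = np.asarray(self.y), np.asarray(self.cluster), np.asarray(self.arm)
        if not (y.shape == cluster.shape == arm.shape) or y.ndim != 1:
            raise ValueError("y, cluster, arm must be 1-D arrays of equal length")
        labels, counts = np.unique(cluster, return_counts=True)
        K = labels.size
        if K < 4 or K % 2 != 0:
            raise ValueError(f"need an even number >= 4 of clusters, found {K}")
        if not np.array_equal(labels, np.arange(1, K + 1)):
            raise ValueError("cluster labels must be exactly 1..K")
        if counts.min() != counts.max():
            raise ValueError("unbalanced design: clusters differ in size")
        N = int(counts[0])
        if N < 2:
            raise ValueError(f"cluster size must be >= 2, found {N}")
        expected_cluster = np.repeat(np.arange(1, K + 1), N)
        if not np.array_equal(cluster, expected_cluster):
            raise ValueError("rows must be in cluster-major order (cluster 1..K)")
        expected_arm = np.repeat((np.arange(1, K + 1) > K // 2).astype(arm.dtype), N)
        if not np.array_equal(arm, expected_arm):
            raise ValueError(
                "arm must be 0 for clusters 1..K/2 and 1 for clusters K/2+1..K, "
                "constant within cluster"
            )
        if not np.all(np.isfinite(y)):
            raise ValueError("y contains non-finite values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cluster": self.cluster, "arm": self.arm, "y": self.y})

    def cluster_means(self) -> np.ndarray:
        """Per-cluster outcome means, ordered by cluster label."""
        return self.y.reshape(self.K, self.N).mean(axis=1)


def icc(sigma_b2: float, sigma2: float) -> float:
    """Intraclass correlation rho = sigma_b2 / (sigma_b2 + sigma2).

    The share of total outcome variance attributable to between-cluster
    variation; lies in [0, 1) since ``sigma2 > 0``.
    """
    if sigma2 <= 0:
        raise ValueError(f"sigma2 must be > 0, got {sigma2}")
    if sigma_b2 < 0:
        raise ValueError(f"sigma_b2 must be >= 0, got {sigma_b2}")
    return sigma_b2 / (sigma_b2 + sigma2)


def replicate_rng(master_seed: int, condition_index: int, replicate_index: int) -> np.random.Generator:
    """Independent per-replicate generator from a (seed, condition, replicate) tree.

    Streams are pre-assigned from ``SeedSequence(master_seed,
    spawn_key=(condition_index, replicate_index))`` so conditions and
    replicates are reproducible independently, in any execution order and
    with any degree of parallelism.
    """
    ss = np.random.SeedSequence(master_seed, spawn_key=(condition_index, replicate_index))
    return np.random.default_rng(ss)


def _generate(config: DesignConfig, rng: np.random.Generator) -> NullDataset:
    # Intercepts first, then residuals: fixed order makes y exactly
    # sqrt(c)-equivariant under (sigma_b2, sigma2) -> (c*sigma_b2, c*sigma2).
    K, N = config.K, config.N
    b = np.sqrt(config.sigma_b2) * rng.standard_normal(K)
    e = np.sqrt(config.sigma2) * rng.standard_normal(K * N)
    y = np.repeat(b, N) + e
    cluster = np.repeat(np.arange(1, K + 1), N)
    arm = np.repeat((np.arange(1, K + 1) > K // 2).astype(np.int64), N)
    return NullDataset(y=y, cluster=cluster, arm=arm)


def generate_null_dataset(config: DesignConfig, rng: np.random.Generator | None = None) -> NullDataset:
    """Simulate one balanced two-arm CRT dataset under the null model.

    Outcomes are ``y_ij = b_i + e_ij`` with ``b_i ~ N(0, sigma_b2)`` i.i.d.
    across clusters and ``e_ij ~ N(0, sigma2)`` i.i.d., independent of the
    intercepts.  Two calls with an identical config (including seed) return
    bit-identical datasets.

    Parameters
    ----------
    config
        The design; validated at construction.
    rng
        Optional generator overriding ``config.seed`` — used by the
        simulation engine, which pre-assigns one stream per replicate.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return _generate(config, rng)


def write_dataset_csv(data: NullDataset, path) -> None:
    """Write the long-format interchange CSV with header ``cluster,arm,y``."""
    data.to_frame().to_csv(path, index=False)


def read_dataset_csv(path) -> NullDataset:
    """Read an interchange CSV and validate the balanced-design invariants."""
    df = pd.read_csv(path)
    missing = {"cluster", "arm", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"dataset CSV missing columns: {sorted(missing)}")
    if len(df) == 0:
        raise ValueError("dataset CSV is empty")
    data = NullDataset(
        y=df["y"].to_numpy(dtype=float),
        cluster=df["cluster"].to_numpy(dtype=np.int64),
        arm=df["arm"].to_numpy(dtype=np.int64),
    )
    data.validate()
    return data
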