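"""Brain-state observation construction.

One correlation network per full run: Spearman rank correlation between
all aligned channels (the fully connected network), labelled sub-network
extraction (motor, occipital, cross block), sample-wise region pooling
and the mesoscale network over the pooled series.  The four blocks
together form the observation matrix consumed by the dynamics stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sp_stats

from .types import (
    CANONICAL_CHANNELS,
    LOC_CHANNELS,
    MC_CHANNELS,
    AlignedRun,
    InvalidInputError,
    ObservationMatrix,
)


@dataclass(frozen=True)
class RegionScheme:
    """Channel groupings for sub-network extraction and region pooling.

    The occipital pooling set for the mesoscale network (``loc_pool``)
    deliberately differs from the occipital sub-network channel set
    (``loc_channels``); both are configurable.
    """

    lmc: tuple[str, ...] = ("C3", "Cz")
    rmc: tuple[str, ...] = ("C4", "Cz")
    loc_pool: tuple[str, ...] = ("P7", "Pz", "Oz")
    mc_channels: tuple[str, ...] = MC_CHANNELS
    loc_channels: tuple[str, ...] = LOC_CHANNELS

    def __post_init__(self) -> None:
        named = set(self.lmc) | set(self.rmc) | set(self.loc_pool)
        named |= set(self.mc_channels) | set(self.loc_channels)
        unknown = named - set(CANONICAL_CHANNELS)
        if unknown:
            raise InvalidInputError(f"unknown channels in scheme: {sorted(unknown)}")
        if set(self.mc_channels) & set(self.loc_channels):
            raise InvalidInputError("mc_channels and loc_channels must be disjoint")


DEFAULT_SCHEME = RegionScheme()

#: Pooled-region order used by the mesoscale network.
REGION_ORDER = ("LMC", "RMC", "LOC")


@dataclass
class FCNet:
    """Fully connected network: Spearman correlations between all channels."""

    matrix: np.ndarray
    channel_names: tuple[str, ...] = CANONICAL_CHANNELS

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        n = len(self.channel_names)
        if self.matrix.shape != (n, n):
            raise InvalidInputError(
                f"FCNet matrix must be {n}x{n}, got {self.matrix.shape}"
            )

    def index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)  # type: ignore[union-attr]
        except (ValueError, AttributeError):
            return tuple(self.channel_names).index(name)

    def submatrix(self, rows, cols) -> np.ndarray:
        ri = [self.index(r) for r in rows]
        ci = [self.index(c) for c in cols]
        return self.matrix[np.ix_(ri, ci)]


def _check_nonconstant(data: np.ndarray, names) -> None:
    ptp = data.max(axis=1) - data.min(axis=1)
    for i, span in enumerate(ptp):
        if span == 0:
            raise InvalidInputError(f"channel '{names[i]}' is constant")


def spearman_matrix(data: np.ndarray, names) -> np.ndarray:
    """Spearman correlation matrix over rows (average ranks for ties)."""
    data = np.asarray(data, dtype=np.float64)
    if data.shape[1] < 3:
        raise InvalidInputError("need at least 3 samples for rank correlation")
    _check_nonconstant(data, names)
    rho = sp_stats.spearmanr(data, axis=1).statistic
    if data.shape[0] == 2:  # spearmanr returns a scalar for two rows
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    return np.asarray(rho, dtype=np.float64)


def spearman_network(run: AlignedRun) -> FCNet:
    """Spearman rank-correlation network between all channels of a run."""
    mat = spearman_matrix(run.data, run.channel_names)
    return FCNet(matrix=mat, channel_names=tuple(run.channel_names))


def extract_subnets(
    net: FCNet, scheme: RegionScheme = DEFAULT_SCHEME
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Slice the motor (3x3), occipital (4x4) and cross (3x4) blocks."""
    mc = net.submatrix(scheme.mc_channels, scheme.mc_channels)
    loc = net.submatrix(scheme.loc_channels, scheme.loc_channels)
    mc_loc = net.submatrix(scheme.mc_channels, scheme.loc_channels)
    return mc, loc, mc_loc


def pool_regions(run: AlignedRun, scheme: RegionScheme = DEFAULT_SCHEME) -> np.ndarray:
    """Sample-wise mean over each region's channels -> 3 x samples array.

    Rows follow :data:`REGION_ORDER` (left motor, right motor, occipital).
    """
    names = list(run.channel_names)

    def region_mean(channels):
        idx = [names.index(c) for c in channels]
        return run.data[idx].mean(axis=0)

    return np.vstack(
        [region_mean(scheme.lmc), region_mean(scheme.rmc), region_mean(scheme.loc_pool)]
    )


def mesoscale_network(pooled: np.ndarray) -> np.ndarray:
    """3x3 Spearman matrix over the pooled region series."""
    pooled = np.asarray(pooled, dtype=np.float64)
    if pooled.shape[0] != len(REGION_ORDER):
        raise InvalidInputError(f"pooled signal must have {len(REGION_ORDER)} rows")
    return spearman_matrix(pooled, REGION_ORDER)


def assemble_observation(
    run: AlignedRun, scheme: RegionScheme = DEFAULT_SCHEME
) -> ObservationMatrix:
    """Compose the four-block observation matrix for one run."""
    net = spearman_network(run)
    mc, loc, mc_loc = extract_subnets(net, scheme)
    mnet = mesoscale_network(pool_regions(run, scheme))
    return ObservationMatrix(mc=mc, loc=loc, mc_loc=mc_loc, mnet=mnet)
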