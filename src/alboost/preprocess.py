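"""Information-gain screening of descriptors against the binary label.

The gain of a feature is the reduction in Shannon entropy (bits) of the
class label after partitioning the compounds by that feature, with
continuous descriptors discretized into equal-frequency bins. Gains are
reported for inspection only; no feature is ever dropped on their basis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import FeatureTable

__all__ = ["InfoGainReport", "information_gain"]


@dataclass
class InfoGainReport:
    feature_names: list[str]
    gains: np.ndarray            # bits, >= 0, one per feature
    bin_assignments: list[np.ndarray]  # per-feature integer bin ids per compound
    n_bins: int

    def as_pairs(self) -> list[tuple[str, float]]:
        return list(zip(self.feature_names, self.gains.tolist()))


def _entropy_bits(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _equal_frequency_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Rank-based equal-frequency bin ids.

    Each distinct value is assigned to the bin containing the midpoint of
    its cumulative-frequency span, so the binning depends only on the rank
    structure of the data: any strictly monotone transform of the feature
    yields the same partition (reversed bin labels for decreasing maps).
    """
    values, inverse, counts = np.unique(x, return_inverse=True, return_counts=True)
    cum = np.concatenate(([0], np.cumsum(counts)))
    mid_frac = (cum[:-1] + counts / 2) / x.size
    bin_of_value = np.minimum((mid_frac * n_bins).astype(int), n_bins - 1)
    return bin_of_value[inverse]


def information_gain(table: FeatureTable, n_bins: int = 10) -> InfoGainReport:
    """Per-feature information gain of the class label, in bits.

    IG(f) = H(labels) - sum_b (n_b/n) H(labels | bin b), with the feature
    discretized into at most `n_bins` equal-frequency bins. A constant
    feature occupies a single bin and scores exactly 0.
    """
    if table.n < 2:
        raise ValueError("need at least two compounds")
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    counts = table.class_counts()
    if min(counts.values()) == 0:
        raise ValueError(f"both classes must be present; got {counts}")

    parent = _entropy_bits(table.labels)
    gains = np.empty(table.d)
    assignments: list[np.ndarray] = []
    for j in range(table.d):
        bins = _equal_frequency_bins(table.matrix[:, j], n_bins)
        assignments.append(bins)
        child = 0.0
        for b in np.unique(bins):
            mask = bins == b
            child += mask.mean() * _entropy_bits(table.labels[mask])
        gains[j] = max(parent - child, 0.0)  # clip float dust
    return InfoGainReport(
        feature_names=list(table.feature_names),
        gains=gains,
        bin_assignments=assignments,
        n_bins=n_bins,
    )
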