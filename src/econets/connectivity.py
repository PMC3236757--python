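"""Mutual-information connectivity between band-limited channel series.

MI captures linear and nonlinear zero-lag statistical dependence between a
pair of electrode signals and is used to assemble the symmetric association
matrix from which cost-thresholded graphs are built.  The estimator is the
plug-in (maximum-likelihood) histogram estimator on equiprobable rank-based
marginal bins, reported in bits.  Rank binning makes the estimate invariant
to any monotone rescaling of either series; ties are broken by first
occurrence so results are deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .signals import Band, BandSeries

__all__ = ["MIMatrix", "mutual_information", "association_matrix"]

DEFAULT_N_BINS = 16


@dataclass
class MIMatrix:
    """Symmetric nonnegative association matrix of pairwise MI (bits)."""

    values: np.ndarray
    band: Band | None = None
    subject_id: str = ""
    condition: str = ""
    labels: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"association matrix must be square, got shape {v.shape}")
        if not np.allclose(v, v.T):
            raise ValueError("association matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("association matrix diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("association matrix entries must be nonnegative")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path: str | Path, header_comment: str | None = None) -> None:
        labels = self.labels or tuple(f"ch{i}" for i in range(self.n_channels))
        df = pd.DataFrame(self.values, index=list(labels), columns=list(labels))
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            df.to_csv(fh)

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "MIMatrix":
        df = pd.read_csv(path, index_col=0, comment="#")
        return cls(values=df.to_numpy(), labels=tuple(df.columns), **kwargs)


def _rank_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign each sample to one of ``n_bins`` equiprobable bins by rank.

    Ordinal ranks from a stable sort: tied values keep first-occurrence
    order, so the binning is deterministic.
    """
    n = x.shape[-1]
    order = np.argsort(x, axis=-1, kind="stable")
    ranks = np.empty_like(order)
    idx = np.broadcast_to(np.arange(n), order.shape)
    np.put_along_axis(ranks, order, idx, axis=-1)
    return (ranks * n_bins) // n


def _mi_from_codes(bx: np.ndarray, by: np.ndarray, n_bins: int) -> float:
    n = bx.size
    joint = np.bincount(bx * n_bins + by, minlength=n_bins * n_bins).astype(float)
    joint = joint.reshape(n_bins, n_bins) / n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    mi = float(np.sum(joint[nz] * np.log2(joint[nz] / np.outer(px, py)[nz])))
    return max(mi, 0.0)


def mutual_information(x: np.ndarray, y: np.ndarray, n_bins: int = DEFAULT_N_BINS) -> float:
    """Plug-in MI of two series over equiprobable rank bins, in bits.

    Symmetric in its arguments and clipped at zero.  Requires at least
    ``10 * n_bins`` samples so every marginal bin is well populated.
    A constant series has a degenerate marginal; MI is then 0 by convention
    (with a warning).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"series length mismatch: {x.size} vs {y.size}")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if x.size < 10 * n_bins:
        raise ValueError(f"need at least {10 * n_bins} samples for {n_bins} bins, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant series: MI is 0 by convention (degenerate marginal)")
        return 0.0
    return _mi_from_codes(_rank_bins(x, n_bins), _rank_bins(y, n_bins), n_bins)


def association_matrix(
    series: BandSeries,
    n_bins: int = DEFAULT_N_BINS,
    per_epoch: bool = True,
    subject_id: str = "",
    condition: str = "",
) -> MIMatrix:
    """MI between every unordered channel pair of a band series.

    By default MI is estimated per epoch and averaged across epochs (limits
    nonstationarity leakage); ``per_epoch=False`` concatenates epochs into a
    single series per channel before estimation.  The diagonal is zero by
    convention.
    """
    data = np.asarray(series.data, dtype=float)
    if data.shape[0] == 0:
        raise ValueError("association matrix requires at least one epoch")
    n_ch = data.shape[1]
    if n_ch < 2:
        raise ValueError("association matrix requires at least 2 channels")

    if not per_epoch:
        data = data.transpose(1, 0, 2).reshape(1, n_ch, -1)

    acc = np.zeros((n_ch, n_ch))
    for epoch in data:
        codes = _rank_bins(epoch, n_bins)
        for i in range(n_ch - 1):
            base = codes[i] * n_bins
            for j in range(i + 1, n_ch):
                mi = _mi_from_codes_precoded(base, codes[j], n_bins)
                acc[i, j] += mi
    acc /= data.shape[0]
    values = acc + acc.T
    return MIMatrix(
        values=values,
        band=series.band,
        subject_id=subject_id,
        condition=condition,
        labels=series.labels,
    )


def _mi_from_codes_precoded(base: np.ndarray, by: np.ndarray, n_bins: int) -> float:
    n = by.size
    joint = np.bincount(base + by, minlength=n_bins * n_bins).astype(float)
    joint = joint.reshape(n_bins, n_bins) / n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    mi = float(np.sum(joint[nz] * np.log2(joint[nz] / np.outer(px, py)[nz])))
    return max(mi, 0.0)
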