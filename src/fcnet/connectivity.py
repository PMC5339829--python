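"""Subject-level functional connectivity.

One subject's regional BOLD signals (T time points x N regions of interest)
are turned into an N x N connectivity matrix: Pearson correlation between
every pair of regional time series, Fisher r-to-z transformed, and finally
restricted to positive values (negative correlations have no agreed
biological interpretation in binary-graph analyses and are discarded before
thresholding).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np

#: |r| is clamped below 1 by this margin before atanh so that duplicated
#: signals still yield finite, sortable z-values.
R_CLAMP = 1e-7


def aal90_labels() -> list[str]:
    """The 90 region names of the AAL atlas (45 per hemisphere), in the
    conventional index order."""
    text = (
        importlib.resources.files("fcnet.data").joinpath("aal90_labels.txt").read_text()
    )
    return text.split()


@dataclass
class RoiTimeSeries:
    """A T x N matrix of regional mean time series for one subject.

    Parameters
    ----------
    values : ndarray of shape (T, N)
        One column per region of interest.
    tr_seconds : float
        Sampling interval (repetition time) in seconds.
    roi_labels : list of str, optional
        Region names; defaults to the AAL-90 list when N == 90, else
        generated placeholders.
    """

    values: np.ndarray
    tr_seconds: float = 2.0
    roi_labels: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D (T x N) array")
        t, n = self.values.shape
        if n < 3:
            raise ValueError(f"need at least 3 ROIs, got {n}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains NaN or Inf")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.roi_labels is None:
            self.roi_labels = (
                aal90_labels() if n == 90 else [f"ROI{i + 1:03d}" for i in range(n)]
            )
        if len(self.roi_labels) != n:
            raise ValueError("roi_labels length does not match column count")
        sd = self.values.std(axis=0)
        if np.any(sd == 0):
            bad = [self.roi_labels[i] for i in np.flatnonzero(sd == 0)]
            raise ValueError(f"constant time series for ROI(s): {', '.join(bad)}")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityMatrix:
    """A symmetric N x N matrix of Fisher-z connectivity values, zero diagonal."""

    z_values: np.ndarray
    roi_labels: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.z_values = np.asarray(self.z_values, dtype=float)
        n = self.z_values.shape[0]
        if self.z_values.shape != (n, n):
            raise ValueError("connectivity matrix must be square")
        if not np.all(np.isfinite(self.z_values)):
            raise ValueError("connectivity matrix contains NaN or Inf")
        if not np.allclose(self.z_values, self.z_values.T):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(np.diag(self.z_values) != 0):
            raise ValueError("connectivity diagonal must be zero")
        if self.roi_labels is None:
            self.roi_labels = (
                aal90_labels() if n == 90 else [f"ROI{i + 1:03d}" for i in range(n)]
            )

    @property
    def n_rois(self) -> int:
        return self.z_values.shape[0]


def pearson_matrix(ts: RoiTimeSeries) -> np.ndarray:
    """Pearson correlation between all pairs of regional time series.

    Returns a symmetric N x N matrix with unit diagonal and entries in
    [-1, 1]. Constant columns are rejected by :class:`RoiTimeSeries` at
    construction, so the correlation is always defined.
    """
    r = np.corrcoef(ts.values, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return (r + r.T) / 2.0


def fisher_z(corr: np.ndarray, roi_labels: list[str] | None = None) -> ConnectivityMatrix:
    """Fisher r-to-z transform, z = atanh(r), applied off-diagonal.

    |r| is clamped to ``1 - R_CLAMP`` so perfectly correlated pairs map to a
    large finite z rather than infinity; the diagonal is fixed at zero.
    """
    corr = np.asarray(corr, dtype=float)
    if np.any(np.abs(corr) > 1 + 1e-12):
        raise ValueError("correlations must lie in [-1, 1]")
    clamped = np.clip(corr, -(1 - R_CLAMP), 1 - R_CLAMP)
    z = np.arctanh(clamped)
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(z_values=(z + z.T) / 2.0, roi_labels=roi_labels)


def positive_part(cm: ConnectivityMatrix) -> ConnectivityMatrix:
    """Zero out negative connectivity values (idempotent)."""
    return ConnectivityMatrix(
        z_values=np.maximum(cm.z_values, 0.0), roi_labels=cm.roi_labels
    )


def subject_connectivity(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Pearson -> Fisher z -> positive part, the full per-subject edge definition."""
    return positive_part(fisher_z(pearson_matrix(ts), roi_labels=ts.roi_labels))


def write_connectivity_tsv(cm: ConnectivityMatrix, path) -> None:
    """Square-matrix TSV with an ROI-label header row and column."""
    import pandas as pd

    pd.DataFrame(cm.z_values, index=cm.roi_labels, columns=cm.roi_labels).to_csv(
        path, sep="\t"
    )


def read_connectivity_tsv(path) -> ConnectivityMatrix:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    return ConnectivityMatrix(z_values=df.to_numpy(), roi_labels=list(df.columns))
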