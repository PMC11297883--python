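"""Per-channel CWT scalograms and the channel-wise correlation matrix.

An epoch of C channels is transformed channel-by-channel with a continuous
wavelet transform (Gaussian-derivative mother wavelet, default order 6,
integer scales 1..30), the per-channel scalograms are stacked channel-major
into a (C * n_scales) x L matrix, and the Pearson correlation between every
pair of scale rows gives a symmetric (C * n_scales)^2 image.  For the
default 12-channel montage and 30 scales the image is 360 x 360; this is
the input representation the CNN classifies.

Notes on conventions: the CWT uses PyWavelets' ``cwt`` (1/sqrt(a)
normalisation, same-length output with zero-padded edges); edge
coefficients therefore enter the correlation.  Correlations are computed on
signed coefficients, not magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pywt

from .io import Epoch


@dataclass(frozen=True)
class CWTConfig:
    """Continuous wavelet transform settings.

    Parameters
    ----------
    wavelet_order : int
        Derivative order p of the Gaussian mother wavelet ('gaus{p}').
    scales : tuple of float
        Strictly increasing positive scale values a_1..a_n; default the
        integer grid 1..30.
    """

    wavelet_order: int = 6
    scales: tuple[float, ...] = tuple(range(1, 31))

    def __post_init__(self) -> None:
        if self.wavelet_order < 1:
            raise ValueError("wavelet_order must be >= 1")
        s = np.asarray(self.scales, dtype=float)
        if s.size == 0 or np.any(s <= 0) or np.any(np.diff(s) <= 0):
            raise ValueError("scales must be strictly positive and increasing")

    @property
    def wavelet(self) -> str:
        return f"gaus{self.wavelet_order}"

    @property
    def n_scales(self) -> int:
        return len(self.scales)

    def center_frequency(self) -> float:
        """Normalised center frequency of the mother wavelet (cycles/sample at scale 1)."""
        return pywt.central_frequency(self.wavelet)


@dataclass
class Scalogram:
    """CWT coefficients of one channel: rows = scales, columns = time."""

    coefficients: np.ndarray
    scales: tuple[float, ...]
    channel_label: str = ""

    @property
    def n_scales(self) -> int:
        return self.coefficients.shape[0]


@dataclass
class StackedScalogram:
    """Channel-major vertical stack of per-channel scalograms.

    Row ``r`` holds channel ``r // n_scales`` at scale index ``r % n_scales``.
    """

    matrix: np.ndarray
    channel_labels: tuple[str, ...]
    n_scales: int

    def row_index(self, row: int) -> tuple[str, float]:
        """Map a stacked row to its (channel label, scale index)."""
        return self.channel_labels[row // self.n_scales], row % self.n_scales


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson correlation between all stacked scale rows."""

    R: np.ndarray
    channel_labels: tuple[str, ...]
    n_scales: int

    @property
    def side(self) -> int:
        return self.R.shape[0]


def cwt_scalogram(signal: np.ndarray, cfg: CWTConfig = CWTConfig(),
                  channel_label: str = "") -> Scalogram:
    """Continuous wavelet transform of one channel.

    Correlates the signal with scaled/translated copies of the Gaussian-
    derivative mother wavelet (1/sqrt(a) normalisation); output has one row
    per scale and the same number of columns as the input.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValueError("signal must be 1-D")
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal contains non-finite values")
    coefs, _ = pywt.cwt(signal, np.asarray(cfg.scales), cfg.wavelet, method="fft")
    return Scalogram(coefs, cfg.scales, channel_label)


def stack_scalograms(scalograms: Sequence[Scalogram]) -> StackedScalogram:
    """Vertically concatenate per-channel scalograms, channel-major."""
    if len(scalograms) == 0:
        raise ValueError("cannot stack an empty sequence of scalograms")
    shape = scalograms[0].coefficients.shape
    scales = scalograms[0].scales
    for s in scalograms[1:]:
        if s.coefficients.shape != shape or s.scales != scales:
            raise ValueError("all scalograms must share shape and scale grid")
    matrix = np.vstack([s.coefficients for s in scalograms])
    labels = tuple(s.channel_label for s in scalograms)
    return StackedScalogram(matrix, labels, shape[0])


def _rowwise_pearson(matrix: np.ndarray) -> np.ndarray:
    """Pearson correlation between all rows; zero-variance rows give 0
    off-diagonal and 1 on the diagonal."""
    centred = matrix - matrix.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->i", centred, centred))
    ok = norms > 0
    safe = np.where(ok, norms, 1.0)
    unit = centred / safe[:, None]
    R = unit @ unit.T
    R[~ok, :] = 0.0
    R[:, ~ok] = 0.0
    np.fill_diagonal(R, 1.0)
    return np.clip(R, -1.0, 1.0)


def pearson_matrix(stacked: StackedScalogram) -> CorrelationMatrix:
    """Pearson correlation of every pair of stacked scale rows."""
    if stacked.matrix.shape[1] < 2:
        raise ValueError("need at least 2 time points for a correlation")
    R = _rowwise_pearson(np.asarray(stacked.matrix, dtype=float))
    return CorrelationMatrix(R, stacked.channel_labels, stacked.n_scales)


def transform_epoch(epoch: Epoch, cfg: CWTConfig = CWTConfig()) -> CorrelationMatrix:
    """Full preprocessing of one epoch: CWT per channel, stack, correlate."""
    scalograms = [
        cwt_scalogram(epoch.data[i], cfg, epoch.channel_names[i])
        for i in range(epoch.n_channels)
    ]
    return pearson_matrix(stack_scalograms(scalograms))


class CWTCorrelation:
    """Transformer turning epochs (N, C, L) into correlation images (N, D, D).

    A stateless scikit-learn style transformer (``fit`` records the input
    channel count only); composes with sklearn pipelines ahead of
    :class:`~eegcorrcam.model.CorrelationCNNClassifier`.

    Parameters
    ----------
    wavelet_order : int
        Gaussian-derivative order of the mother wavelet.
    scales : sequence of float
        CWT scale grid; output side length is ``C * len(scales)``.
    """

    def __init__(self, wavelet_order: int = 6,
                 scales: Sequence[float] = tuple(range(1, 31))):
        self.wavelet_order = wavelet_order
        self.scales = tuple(scales)

    # -- sklearn plumbing -------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {"wavelet_order": self.wavelet_order, "scales": self.scales}

    def set_params(self, **params) -> "CWTCorrelation":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    @property
    def config_(self) -> CWTConfig:
        return CWTConfig(self.wavelet_order, tuple(self.scales))

    def fit(self, X: np.ndarray, y=None) -> "CWTCorrelation":
        X = np.asarray(X)
        if X.ndim != 3:
            raise ValueError("X must have shape (n_epochs, n_channels, n_samples)")
        self.n_channels_ = X.shape[1]
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Correlation images, shape (N, C * n_scales, C * n_scales), float32."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("X must have shape (n_epochs, n_channels, n_samples)")
        cfg = self.config_
        n, c, _ = X.shape
        side = c * cfg.n_scales
        out = np.empty((n, side, side), dtype=np.float32)
        scales = np.asarray(cfg.scales)
        for i in range(n):
            stacked = np.vstack([
                pywt.cwt(X[i, ch], scales, cfg.wavelet, method="fft")[0]
                for ch in range(c)
            ])
            out[i] = _rowwise_pearson(stacked)
        return out

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X, y).transform(X)
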