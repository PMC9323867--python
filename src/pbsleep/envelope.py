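"""Motion-envelope extraction from multichannel pressure recordings.

The motion signal is the per-sample standard deviation of each pressure
channel inside a sliding raised-cosine (Hann) window, averaged over channels
(or computed on the first principal component of the channel matrix), then
max-normalized per recording.  The per-second mean square of this envelope is
the power that the state thresholds act on.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_array, check_is_fitted

from .containers import ChannelMatrix, MotionSignal
from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "MotionEnvelope",
    "sliding_std_envelope",
    "pca_motion",
    "normalize_max",
]


def _window_weights(n: int, kind: str) -> np.ndarray:
    if n < 2:
        raise InvalidParameterError("window must span at least 2 samples")
    if kind == "hann":
        w = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / (n - 1)))
    elif kind == "boxcar":
        w = np.ones(n)
    else:
        raise InvalidParameterError(f"unknown window kind {kind!r}")
    if w.sum() <= 0:
        raise InvalidParameterError(f"window of {n} samples has zero total weight")
    return w


def _sliding_weighted_std(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted standard deviation of ``x`` around every sample.

    Windows are truncated at the edges and the weights renormalized there, so
    the output has the same length as the input.  Variances are computed as
    E_w[x^2] - E_w[x]^2 with a relative floor that removes the cancellation
    dust this formula leaves on (near-)constant windows.
    """
    norm = fftconvolve(np.ones_like(x), w, mode="same")
    m1 = fftconvolve(x, w, mode="same") / norm
    m2 = fftconvolve(x * x, w, mode="same") / norm
    var = m2 - m1 * m1
    var[var < 1e-12 * np.abs(m2)] = 0.0
    return np.sqrt(np.maximum(var, 0.0))


class MotionEnvelope(BaseEstimator, TransformerMixin):
    """Transform a (samples, channels) pressure matrix into the motion envelope.

    Parameters
    ----------
    fs : float
        Sampling rate of the input in Hz.
    window_s : float
        Length of the sliding raised-cosine window in seconds (default 4 s).
    method : {"channel_std", "pca"}
        ``channel_std`` averages the channel-wise windowed standard deviations;
        ``pca`` takes the windowed standard deviation of the scores on the
        first principal component of the whole recording.
    window : {"hann", "boxcar"}
        Window weighting.  ``hann`` is the raised cosine used throughout;
        ``boxcar`` gives the plain (unweighted) windowed standard deviation.
    normalize : bool
        Divide the envelope by its maximum over the fitted recording.

    Attributes
    ----------
    norm_max_ : float
        Maximum of the raw envelope on the fitted recording.
    pca_ : sklearn.decomposition.PCA
        Fitted whole-recording PCA (only when ``method="pca"``).
    """

    def __init__(
        self,
        fs: float = 50.0,
        window_s: float = 4.0,
        method: str = "channel_std",
        window: str = "hann",
        normalize: bool = True,
    ) -> None:
        self.fs = fs
        self.window_s = window_s
        self.method = method
        self.window = window
        self.normalize = normalize

    # -- internals ---------------------------------------------------------

    def _validate(self, X) -> np.ndarray:
        if self.fs <= 0:
            raise InvalidParameterError(f"fs must be positive, got {self.fs}")
        if self.method not in ("channel_std", "pca"):
            raise InvalidParameterError(f"unknown method {self.method!r}")
        X = check_array(X, ensure_2d=True, dtype=float)
        n_win = int(round(self.window_s * self.fs))
        if n_win < 2:
            raise InvalidParameterError(
                f"window of {self.window_s} s at {self.fs} Hz spans <2 samples"
            )
        if X.shape[0] <= n_win:
            raise InvalidInputError(
                f"recording of {X.shape[0]} samples is not longer than one "
                f"window ({n_win} samples)"
            )
        if self.method == "pca" and X.shape[1] < 2:
            raise InvalidInputError("PCA envelope needs at least 2 channels")
        return X

    def _raw_envelope(self, X: np.ndarray) -> np.ndarray:
        w = _window_weights(int(round(self.window_s * self.fs)), self.window)
        if self.method == "pca":
            check_is_fitted(self, "pca_")
            scores = self.pca_.transform(X)[:, 0]
            return _sliding_weighted_std(scores, w)
        stds = [_sliding_weighted_std(X[:, c], w) for c in range(X.shape[1])]
        return np.mean(stds, axis=0)

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y=None) -> "MotionEnvelope":
        X = self._validate(X)
        self.n_features_in_ = X.shape[1]
        if self.method == "pca":
            if not np.any(X.var(axis=0) > 0):
                raise InvalidInputError("all channels are constant; PCA is rank-0")
            self.pca_ = PCA(n_components=1).fit(X)
        env = self._raw_envelope(X)
        maxv = float(env.max())
        if self.normalize and maxv <= 0:
            raise InvalidInputError("cannot max-normalize an all-zero envelope")
        self.norm_max_ = maxv
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "norm_max_")
        X = self._validate(X)
        env = self._raw_envelope(X)
        if self.normalize:
            env = env / self.norm_max_
        return env

    def to_motion_signal(self, X) -> MotionSignal:
        """Transform and wrap the result in a :class:`MotionSignal`."""
        env = self.transform(X)
        return MotionSignal(
            env,
            fs=self.fs,
            normalized=self.normalize,
            norm_max=self.norm_max_ if self.normalize else None,
        )


# -- functional wrappers ----------------------------------------------------


def sliding_std_envelope(
    channels: ChannelMatrix, window_s: float = 4.0, window: str = "hann"
) -> MotionSignal:
    """Mean over channels of the sliding raised-cosine windowed standard deviation."""
    est = MotionEnvelope(
        fs=channels.fs, window_s=window_s, method="channel_std", window=window, normalize=False
    )
    return est.fit(channels.values.T).to_motion_signal(channels.values.T)


def pca_motion(channels: ChannelMatrix, window_s: float = 4.0, window: str = "hann") -> MotionSignal:
    """Envelope of the scores on the first whole-recording principal component.

    The sign of the component is irrelevant: the windowed standard deviation is
    invariant to flipping every channel.
    """
    est = MotionEnvelope(
        fs=channels.fs, window_s=window_s, method="pca", window=window, normalize=False
    )
    return est.fit(channels.values.T).to_motion_signal(channels.values.T)


def normalize_max(signal: MotionSignal) -> MotionSignal:
    """Divide the envelope by its maximum, recording the maximum in ``norm_max``."""
    maxv = float(signal.values.max())
    if maxv <= 0:
        raise InvalidInputError("cannot max-normalize an all-zero envelope")
    norm_max = signal.norm_max if signal.normalized else maxv
    return MotionSignal(signal.values / maxv, fs=signal.fs, normalized=True, norm_max=norm_max)
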