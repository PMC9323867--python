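import numpy as np
import pytest

from pbsleep.containers import MotionSignal


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def normalized_signal():
    """A small normalized envelope: 8 s at 4 Hz, quiet then active."""
    values = np.array([0.0] * 16 + [1.0] * 16)
    return MotionSignal(values, fs=4.0, normalized=True, norm_max=3.0)


def windowed_weighted_std_oracle(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Direct-definition sliding weighted std with truncated, renormalized edges.

    Alignment matches 'same'-mode convolution with a kernel of length L:
    output i covers x[i+o-L+1 : i+o+1] with o = (L-1)//2.
    """
    L, n = len(w), len(x)
    o = (L - 1) // 2
    out = np.empty(n)
    for i in range(n):
        js = np.arange(max(0, i + o - L + 1), min(n, i + o + 1))
        ww = w[i + o - js]
        m = np.sum(ww * x[js]) / ww.sum()
        out[i] = np.sqrt(max(np.sum(ww * (x[js] - m) ** 2) / ww.sum(), 0.0))
    return out


def dfa_oracle(x, scales, order=1):
    """Naive three-loop DFA reference: integrate, detrend epochs, pool residuals."""
    x = np.asarray(x, dtype=float)
    y = np.cumsum(x - x.mean())
    rms = []
    for s in scales:
        total, count = 0.0, 0
        for e in range(len(y) // s):
            seg = y[e * s : (e + 1) * s]
            t = np.arange(s)
            coef = np.polyfit(t, seg, order)
            res = seg - np.polyval(coef, t)
            total += float(np.sum(res * res))
            count += s
        rms.append(np.sqrt(total / count))
    return np.array(rms)
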