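"""Per-burst feature extraction: time domain, frequency domain, and ODBA.

Nine descriptors are computed per channel — the x axis (surge) and the
rotation-invariant yz-plane magnitude — giving 18 features, plus one
tri-axial ODBA, 19 in total:

==============  =============================================================
mean, variance, population moments of the centered series (variance with the
sd              N divisor; sd = sqrt(variance))
max, min, range extrema and their difference
freqmain        frequency (Hz) of the largest magnitude in the DFT spectrum
                of the mean-removed series, DC excluded; ties break to the
                lowest frequency
freqamp         that maximum magnitude scaled by 2/N, so a pure sinusoid of
                amplitude A reports ~A counts
entropy         Shannon entropy of the magnitude-normalized spectrum divided
                by log(#bins), in [0, 1]; 0 for a degenerate (all-zero)
                spectrum
odba            overall dynamic body acceleration: per axis the running-mean
                static component (centered window, truncated at the edges)
                is removed and the absolute dynamic residuals are summed
                over the three axes and averaged over the burst
==============  =============================================================

The ODBA running-window default is 22 samples — one fifth of a 110-sample
burst (0.67 s at 33.3 Hz).  All features are computed on centered counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .preprocess import CenteredBurst

#: Default ODBA running-mean window (samples); 110/5 for the standard burst.
DEFAULT_ODBA_WINDOW = 22

#: Stable column order of the feature matrix (header contract).
FEATURE_COLUMNS: tuple[str, ...] = tuple(
    f"{ch}_{name}"
    for ch in ("x", "yz")
    for name in (
        "mean",
        "variance",
        "sd",
        "max",
        "min",
        "range",
        "freqmain",
        "freqamp",
        "entropy",
    )
) + ("odba",)


def time_features(series) -> tuple[float, float, float, float, float, float]:
    """(mean, variance, sd, max, min, range) with the population N divisor."""
    arr = np.asarray(series, dtype=float)
    if arr.size < 2:
        raise ValueError("time features need at least 2 samples")
    var = float(arr.var())  # ddof=0
    return (
        float(arr.mean()),
        var,
        float(np.sqrt(var)),
        float(arr.max()),
        float(arr.min()),
        float(arr.max() - arr.min()),
    )


def _spectrum(arr: np.ndarray, axis: int = -1) -> np.ndarray:
    """Magnitude spectrum of the mean-removed series over bins 1..N//2."""
    centered = arr - arr.mean(axis=axis, keepdims=True)
    mags = np.abs(np.fft.rfft(centered, axis=axis))
    return np.take(mags, np.arange(1, arr.shape[axis] // 2 + 1), axis=axis)


def freq_features(series, fs: float) -> tuple[float, float, float]:
    """(freqmain Hz, freqamp counts, entropy in [0,1]); see module docstring.

    A constant (or otherwise spectrally empty) series degenerates to
    ``(0, 0, 0)``.
    """
    arr = np.asarray(series, dtype=float)
    if arr.size < 4:
        raise ValueError("frequency features need at least 4 samples")
    mags = _spectrum(arr)
    total = mags.sum()
    if total <= 0.0:
        return 0.0, 0.0, 0.0
    k = int(np.argmax(mags))  # argmax takes the first (lowest-frequency) tie
    freqmain = (k + 1) * fs / arr.size
    freqamp = 2.0 * mags[k] / arr.size
    p = mags / total
    nz = p[p > 0]
    entropy = float(-(nz * np.log(nz)).sum() / np.log(mags.size)) if mags.size > 1 else 0.0
    return float(freqmain), float(freqamp), entropy


def _running_mean_truncated(arr: np.ndarray, window: int) -> np.ndarray:
    """Centered running mean with shrinking (truncated) edge windows.

    For even windows the centre sample sits left of the midpoint: sample i
    averages indices [i - (w-1)//2, i + w//2], clipped to the series.
    Vectorized over leading dimensions; operates on the last axis.
    """
    n = arr.shape[-1]
    if window < 1 or window > n:
        raise ValueError(f"window must be in [1, {n}], got {window}")
    left, right = (window - 1) // 2, window // 2
    csum = np.cumsum(arr, axis=-1, dtype=float)
    csum = np.concatenate([np.zeros(arr.shape[:-1] + (1,)), csum], axis=-1)
    idx = np.arange(n)
    lo = np.maximum(idx - left, 0)
    hi = np.minimum(idx + right + 1, n)
    return (np.take(csum, hi, axis=-1) - np.take(csum, lo, axis=-1)) / (hi - lo)


def odba(burst: CenteredBurst, window: int = DEFAULT_ODBA_WINDOW) -> float:
    """Overall dynamic body acceleration of one burst, in counts.

    Per axis, the static component is the running mean over ``window``
    samples (centered, truncated at the edges); ODBA is the burst mean of
    the summed absolute dynamic residuals of all three axes.
    """
    total = np.zeros(burst.n)
    for arr in (burst.x, burst.y, burst.z):
        a = np.asarray(arr, dtype=float)
        total += np.abs(a - _running_mean_truncated(a, window))
    return float(total.mean())


def feature_vector(
    burst: CenteredBurst, window: int = DEFAULT_ODBA_WINDOW
) -> dict[str, float]:
    """The 19 named features of one burst, keyed as in FEATURE_COLUMNS."""
    out: dict[str, float] = {}
    for ch, series in (("x", burst.x), ("yz", burst.ayz)):
        m, v, s, mx, mn, rg = time_features(series)
        fm, fa, en = freq_features(series, burst.fs)
        out.update(
            {
                f"{ch}_mean": m,
                f"{ch}_variance": v,
                f"{ch}_sd": s,
                f"{ch}_max": mx,
                f"{ch}_min": mn,
                f"{ch}_range": rg,
                f"{ch}_freqmain": fm,
                f"{ch}_freqamp": fa,
                f"{ch}_entropy": en,
            }
        )
    out["odba"] = odba(burst, window)
    return out


def _channel_features_vectorized(mat: np.ndarray, fs: float) -> dict[str, np.ndarray]:
    var = mat.var(axis=1)
    mx, mn = mat.max(axis=1), mat.min(axis=1)
    n = mat.shape[1]
    mags = _spectrum(mat, axis=1)
    total = mags.sum(axis=1)
    ok = total > 0
    k = np.argmax(mags, axis=1)
    freqmain = np.where(ok, (k + 1) * fs / n, 0.0)
    freqamp = np.where(ok, 2.0 * mags[np.arange(len(mags)), k] / n, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = mags / total[:, None]
        plogp = np.where(p > 0, p * np.log(p), 0.0)
        entropy = np.where(ok, -plogp.sum(axis=1) / np.log(mags.shape[1]), 0.0)
    return {
        "mean": mat.mean(axis=1),
        "variance": var,
        "sd": np.sqrt(var),
        "max": mx,
        "min": mn,
        "range": mx - mn,
        "freqmain": freqmain,
        "freqamp": freqamp,
        "entropy": entropy,
    }


def feature_matrix(
    bursts, window: int = DEFAULT_ODBA_WINDOW
) -> pd.DataFrame:
    """Feature matrix for a burst sequence, one row per burst.

    Column order follows ``FEATURE_COLUMNS``; an ``individual_id`` and
    ``timestamp`` column are prepended for joining.  Equal-length bursts
    are processed in a single vectorized pass.
    """
    bursts = list(bursts)
    if not bursts:
        return pd.DataFrame(columns=["individual_id", "timestamp", *FEATURE_COLUMNS])
    ns = {b.n for b in bursts}
    fss = {b.fs for b in bursts}
    if len(ns) == 1 and len(fss) == 1:
        fs = bursts[0].fs
        x = np.stack([b.x for b in bursts]).astype(float)
        y = np.stack([b.y for b in bursts]).astype(float)
        z = np.stack([b.z for b in bursts]).astype(float)
        ayz = np.sqrt(y**2 + z**2)
        cols: dict[str, np.ndarray] = {}
        for ch, mat in (("x", x), ("yz", ayz)):
            for name, vals in _channel_features_vectorized(mat, fs).items():
                cols[f"{ch}_{name}"] = vals
        dyn = sum(
            np.abs(mat - _running_mean_truncated(mat, window)) for mat in (x, y, z)
        )
        cols["odba"] = dyn.mean(axis=1)
        frame = pd.DataFrame(cols)
    else:
        frame = pd.DataFrame([feature_vector(b, window) for b in bursts])
    frame = frame[list(FEATURE_COLUMNS)]
    frame.insert(0, "timestamp", [b.timestamp for b in bursts])
    frame.insert(0, "individual_id", [b.individual_id for b in bursts])
    return frame
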