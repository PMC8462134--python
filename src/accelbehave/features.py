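"""Time- and frequency-domain features of accelerometer segments.

The time-domain set comprises, per axis, the sample mean, variance (n-1
denominator), standard deviation, maximum, minimum and range, plus a single
Overall Dynamic Body Acceleration (ODBA) column computed across all axes.
ODBA separates each axis into a slowly varying *static* (gravity) component,
estimated by a moving average of ``winlen_dba`` samples, and a residual
*dynamic* component; it is the per-sample sum across axes of the absolute
dynamic acceleration, averaged over the segment, and is widely used as an
energy-expenditure proxy.

The frequency-domain set comprises, per axis, the main (dominant) frequency,
the amplitude at that frequency, and the Shannon entropy of the normalized
spectral power distribution — low for periodic signals such as wingbeats,
high for noise-like signals.  Spectra are computed by FFT of the mean-removed
signal; the DC bin is excluded throughout.

Feature tables are plain :class:`pandas.DataFrame` objects, one row per
segment (aligned with the source dataset) and one named column per feature.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, NameCollisionError, ParameterError
from .segments import AXIS_NAMES, SegmentDataset

__all__ = [
    "Spectrum",
    "time_domain_features",
    "freq_domain_features",
    "odba",
    "amplitude_spectrum",
    "combine_features",
    "write_features",
    "read_features",
]

#: Spectral power below this total is treated as zero (degenerate spectrum).
ZERO_POWER = 1e-12

TIME_FEATURES = ("mean", "variance", "sd", "max", "min", "range")
FREQ_FEATURES = ("main_freq", "main_amp", "entropy")


@dataclass(frozen=True)
class Spectrum:
    """One-sided amplitude spectrum at positive frequencies (DC excluded)."""

    freqs: np.ndarray  # Hz, strictly increasing, up to and including Nyquist
    amplitudes: np.ndarray  # nonnegative, same length


def _running_mean(x: np.ndarray, winlen: int) -> np.ndarray:
    """Centered moving average along the last axis.

    The window keeps its full length at the segment edges by sliding inward
    (clamped to the bounds) rather than shrinking, so with ``winlen`` equal
    to the segment length the static estimate is the segment mean everywhere.
    """
    n = x.shape[-1]
    w = min(winlen, n)
    cs = np.cumsum(x, axis=-1)
    cs = np.concatenate([np.zeros(x.shape[:-1] + (1,)), cs], axis=-1)
    starts = np.clip(np.arange(n) - (w - 1) // 2, 0, n - w)
    return (cs[..., starts + w] - cs[..., starts]) / w


def odba(axes: Sequence[Sequence[float]] | np.ndarray, winlen_dba: int) -> float:
    """Overall Dynamic Body Acceleration of one segment.

    Parameters
    ----------
    axes
        Per-axis sample sequences, shape ``(n_axes, seg_len)``.
    winlen_dba
        Length, in samples, of the moving average estimating the static
        (gravity) component; a window spanning about one second of data is a
        reasonable choice.
    """
    arr = np.atleast_2d(np.asarray(axes, dtype=float))
    seg_len = arr.shape[-1]
    if not 1 <= winlen_dba <= seg_len:
        raise ParameterError(
            f"winlen_dba must be in [1, seg_len={seg_len}], got {winlen_dba}"
        )
    dynamic = arr - _running_mean(arr, winlen_dba)
    return float(np.mean(np.sum(np.abs(dynamic), axis=0)))


def time_domain_features(ds: SegmentDataset, winlen_dba: int) -> pd.DataFrame:
    """Per-axis summary statistics plus ODBA, one row per segment.

    Returns ``6 * n_axes + 1`` columns ordered as all x features, all y, all
    z, then ``ODBA``.  Variance uses the n-1 (sample) denominator.
    """
    if not 1 <= winlen_dba <= ds.seg_len:
        raise ParameterError(
            f"winlen_dba must be in [1, seg_len={ds.seg_len}], got {winlen_dba}"
        )
    axes = ds.axis_view()  # (n, seg_len, n_axes)
    cols: dict[str, np.ndarray] = {}
    for a in range(ds.n_axes):
        sig = axes[:, :, a]
        prefix = AXIS_NAMES[a]
        mx = sig.max(axis=1)
        mn = sig.min(axis=1)
        var = sig.var(axis=1, ddof=1)
        cols[f"{prefix}_mean"] = sig.mean(axis=1)
        cols[f"{prefix}_variance"] = var
        cols[f"{prefix}_sd"] = np.sqrt(var)
        cols[f"{prefix}_max"] = mx
        cols[f"{prefix}_min"] = mn
        cols[f"{prefix}_range"] = mx - mn
    per_axis = np.transpose(axes, (0, 2, 1))  # (n, n_axes, seg_len)
    dynamic = per_axis - _running_mean(per_axis, winlen_dba)
    cols["ODBA"] = np.mean(np.sum(np.abs(dynamic), axis=1), axis=1)
    return pd.DataFrame(cols)


def amplitude_spectrum(signal: Sequence[float] | np.ndarray, samp_freq: float) -> Spectrum:
    """One-sided amplitude spectrum of a mean-removed signal.

    Amplitudes are scaled ``2|X_k|/N`` at the positive-frequency bins
    ``k * samp_freq / N`` for ``k = 1 .. floor(N/2)`` (``|X_k|/N`` at the
    Nyquist bin when ``N`` is even), so a pure sinusoid of amplitude ``A``
    lying exactly on a bin shows amplitude ``A`` at that bin.  The DC bin is
    excluded.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise ParameterError(f"signal must be 1-D with >= 4 samples, got {x.shape}")
    if not samp_freq > 0:
        raise ParameterError(f"samp_freq must be positive, got {samp_freq}")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    n = x.size
    coeffs = np.fft.rfft(x - x.mean())
    amps = 2.0 * np.abs(coeffs[1:]) / n
    if n % 2 == 0:
        amps[-1] /= 2.0  # Nyquist bin is not duplicated in the one-sided sum
    freqs = np.arange(1, n // 2 + 1) * samp_freq / n
    return Spectrum(freqs=freqs, amplitudes=amps)


def _spectral_features(sig: np.ndarray, samp_freq: float) -> tuple[np.ndarray, ...]:
    """Vectorized main frequency / amplitude / entropy for (n, seg_len) signals."""
    n, seg_len = sig.shape
    coeffs = np.fft.rfft(sig - sig.mean(axis=1, keepdims=True), axis=1)
    amps = 2.0 * np.abs(coeffs[:, 1:]) / seg_len
    if seg_len % 2 == 0:
        amps[:, -1] /= 2.0
    freqs = np.arange(1, seg_len // 2 + 1) * samp_freq / seg_len
    power = amps**2
    total = power.sum(axis=1)
    degenerate = total < ZERO_POWER
    # argmax takes the first maximum, i.e. ties resolve to the lowest frequency
    peak = np.argmax(amps, axis=1)
    peak[degenerate] = 0
    main_freq = freqs[peak]
    main_amp = amps[np.arange(n), peak]
    with np.errstate(divide="ignore", invalid="ignore"):
        p = power / total[:, None]
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    entropy = -plogp.sum(axis=1)
    entropy[degenerate] = 0.0
    main_amp[degenerate] = 0.0
    return main_freq, main_amp, entropy


def freq_domain_features(
    ds: SegmentDataset, samp_freq: float | None = None
) -> pd.DataFrame:
    """Main frequency, main amplitude and frequency entropy per axis.

    The main frequency is the positive-frequency bin of maximum amplitude
    (ties break to the lowest frequency); entropy is the Shannon entropy, in
    nats, of the normalized spectral power ``p_k = a_k^2 / sum_j a_j^2``.  A
    segment with (numerically) zero spectral power gets entropy 0, amplitude
    0 and the first bin as main frequency.
    """
    fs = samp_freq if samp_freq is not None else ds.samp_freq
    if fs is None or not fs > 0:
        raise ParameterError(
            "samp_freq must be supplied (positive) either on the dataset or "
            "as an argument"
        )
    if ds.seg_len < 4:
        raise ParameterError(f"seg_len must be >= 4, got {ds.seg_len}")
    axes = ds.axis_view()
    cols: dict[str, np.ndarray] = {}
    for a in range(ds.n_axes):
        prefix = AXIS_NAMES[a]
        mf, ma, ent = _spectral_features(axes[:, :, a], fs)
        cols[f"{prefix}_main_freq"] = mf
        cols[f"{prefix}_main_amp"] = ma
        cols[f"{prefix}_entropy"] = ent
    return pd.DataFrame(cols)


def combine_features(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Column-wise concatenation of two row-aligned feature tables.

    Order is preserved a-then-b.  Row-count mismatch raises
    :class:`AlignmentError`; a shared column name raises
    :class:`NameCollisionError`.  Custom user features can be merged into the
    standard tables this way.
    """
    if len(a) != len(b):
        raise AlignmentError(
            f"feature tables have {len(a)} and {len(b)} rows; must match"
        )
    shared = [c for c in a.columns if c in set(b.columns)]
    if shared:
        raise NameCollisionError(f"duplicate feature names: {shared}")
    return pd.concat(
        [a.reset_index(drop=True), b.reset_index(drop=True)], axis=1
    )


def write_features(
    ft: pd.DataFrame, path: str | Path, labels: Sequence[str] | None = None
) -> None:
    """Write a feature table as CSV, appending a trailing ``label`` column
    when labels are attached."""
    out = ft.copy()
    if labels is not None:
        if len(labels) != len(ft):
            raise AlignmentError(
                f"{len(ft)} feature rows but {len(labels)} labels"
            )
        out["label"] = list(labels)
    out.to_csv(path, index=False)


def read_features(path: str | Path) -> tuple[pd.DataFrame, np.ndarray | None]:
    """Read a feature CSV; returns ``(table, labels)`` with labels taken from
    a trailing ``label`` column when present (None otherwise)."""
    df = pd.read_csv(path)
    labels = None
    if len(df.columns) and df.columns[-1] == "label":
        labels = df["label"].to_numpy(dtype=object)
        df = df.drop(columns=["label"])
    return df, labels
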