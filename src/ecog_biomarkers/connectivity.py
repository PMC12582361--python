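"""Burst binarization of z-scored spectral amplitude and transfer-entropy connectivity.

The z-scored band amplitude is reduced to a binary burst train: time is cut
into bins of ``bin_cycles`` wave-cycles (cycle frequency = the band's lower
edge, the conservative reading of "at least six wave-cycles"), and a bin is 1
iff it contains a sustained excursion above z = 2 lasting at least
``min_cycles`` cycles.  Excursions spanning a bin boundary credit every bin
they touch; bins overlapping masked samples are missing (NaN), not 0.

Directed influence between burst trains is rated by plug-in transfer entropy
with history length k = 1 and a one-bin lag:

    TE(x -> y) = sum p(y_t+1, y_t, x_t) log2[ p(y_t+1 | y_t, x_t) / p(y_t+1 | y_t) ]

estimated from joint counts over jointly non-missing triplets (0 log 0 = 0).
The plug-in estimator is non-negative and carries a small positive O(1/N)
bias, which is quantified in the tests rather than corrected.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import shares_contact
from .spectral import BANDS

#: Wave-cycle reference frequency per band: the lower band edge.
CYCLE_FREQ = {band: edges[0] for band, edges in BANDS.items()}


@dataclass
class BinaryBurstSeries:
    """Binary burst train of one channel on a fixed bin grid (NaN = missing bin)."""

    bits: np.ndarray
    bin_duration_s: float
    cycle_freq_hz: float
    band: str
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=float)
        if self.bin_duration_s < 6.0 / self.cycle_freq_hz - 1e-9:
            raise ValueError("bins must be at least six wave-cycles long")

    @property
    def n_bins(self) -> int:
        return self.bits.size


@dataclass
class EcMatrix:
    """Pairwise transfer entropy (bits); diagonal and excluded pairs are NaN."""

    te: np.ndarray
    labels: list[str]
    band: str
    stage: str = ""
    epoch_index: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.te, index=self.labels, columns=self.labels)


def binarize_bursts(
    z: np.ndarray,
    fs: float,
    band: str,
    threshold: float = 2.0,
    min_cycles: int = 3,
    bin_cycles: int = 6,
    cycle_freq: float | None = None,
    channel_label: str = "",
) -> BinaryBurstSeries:
    """Binarize one channel's z-scored amplitude into a burst train.

    ``z`` is a 1-D z-scored amplitude series with NaN at masked samples.
    """
    z = np.asarray(z, dtype=float)
    if band not in CYCLE_FREQ and cycle_freq is None:
        raise ValueError(f"unknown band {band!r} and no explicit cycle_freq")
    f_cyc = CYCLE_FREQ[band] if cycle_freq is None else cycle_freq
    bin_len = int(round(bin_cycles / f_cyc * fs))
    n_bins = z.size // bin_len
    if n_bins < 1:
        raise ValueError(
            f"epoch of {z.size / fs:.2f}s is shorter than one {bin_len / fs:.2f}s bin"
        )
    min_run = min_cycles / f_cyc * fs  # samples, float

    n_used = n_bins * bin_len
    bits = np.zeros(n_bins)

    above = z[:n_used] > threshold  # NaN compares False, breaking runs
    if above.any():
        d = np.diff(above.astype(np.int8))
        starts = list(np.flatnonzero(d == 1) + 1)
        ends = list(np.flatnonzero(d == -1) + 1)
        if above[0]:
            starts.insert(0, 0)
        if above[-1]:
            ends.append(n_used)
        for s, e in zip(starts, ends):
            if e - s >= min_run:
                bits[s // bin_len : (e - 1) // bin_len + 1] = 1.0

    # Bins overlapping masked samples are missing, not 0.
    nan_bins = np.isnan(z[:n_used]).reshape(n_bins, bin_len).any(axis=1)
    bits[nan_bins] = np.nan
    return BinaryBurstSeries(bits, bin_len / fs, f_cyc, band, channel_label)


def _as_bits(x: BinaryBurstSeries | np.ndarray) -> np.ndarray:
    return x.bits if isinstance(x, BinaryBurstSeries) else np.asarray(x, dtype=float)


def transfer_entropy(
    src: BinaryBurstSeries | np.ndarray,
    dst: BinaryBurstSeries | np.ndarray,
    k: int = 1,
    min_triplets: int = 50,
) -> float:
    """Plug-in transfer entropy (bits) from ``src`` to ``dst`` at one-bin lag.

    Probabilities are joint counts over time points where the future value,
    the k-bin destination history, and the source bin are all non-missing.
    A constant destination gives TE = 0 (degenerate; a warning is raised).
    """
    x, y = _as_bits(src), _as_bits(dst)
    if x.size != y.size:
        raise ValueError("source and destination trains are on different bin grids")
    if k < 1:
        raise ValueError("history length k must be >= 1")

    n = y.size
    if n <= k:
        raise ValueError("train shorter than the history length")
    future = y[k:]
    hist = np.stack([y[k - 1 - j : n - 1 - j] for j in range(k)])  # (k, n-k)
    source = x[k - 1 : n - 1]
    valid = np.isfinite(future) & np.isfinite(source) & np.all(np.isfinite(hist), axis=0)
    n_valid = int(valid.sum())
    if n_valid < min_triplets:
        raise ValueError(f"only {n_valid} jointly valid triplets; need >= {min_triplets}")

    future_v = future[valid].astype(np.int64)
    source_v = source[valid].astype(np.int64)
    hist_code = np.zeros(n_valid, dtype=np.int64)
    for j in range(k):
        hist_code = hist_code * 2 + hist[j][valid].astype(np.int64)

    if np.all(future_v == future_v[0]):
        warnings.warn("destination train is constant; TE degenerates to 0")
        return 0.0

    n_hist = 2**k
    code = (source_v * n_hist + hist_code) * 2 + future_v
    counts = np.bincount(code, minlength=n_hist * 4).astype(float)
    joint = counts.reshape(2, n_hist, 2)  # (x, y_hist, y_future)
    p = joint / n_valid

    p_xh = p.sum(axis=2, keepdims=True)  # p(x, hist)
    p_h = p.sum(axis=(0, 2), keepdims=True)  # p(hist)
    p_hf = p.sum(axis=0, keepdims=True)  # p(hist, future)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (p * p_h) / (p_xh * p_hf)
        term = p * np.log2(ratio)
    te = float(np.nansum(term[p > 0]))
    return max(te, 0.0)


def ec_matrix(
    all_series: list[BinaryBurstSeries],
    k: int = 1,
    min_triplets: int = 50,
    exclude_shared_contacts: bool = True,
    stage: str = "",
    epoch_index: int = 0,
) -> EcMatrix:
    """Pairwise TE over all ordered channel pairs on a common bin grid.

    Pairs of bipolar channels sharing a physical electrode contact are
    excluded (NaN) to guard against montage-induced spurious coupling.
    """
    if len(all_series) < 2:
        raise ValueError("need at least 2 channels")
    n_bins = all_series[0].n_bins
    bin_s = all_series[0].bin_duration_s
    band = all_series[0].band
    for s in all_series[1:]:
        if s.n_bins != n_bins or abs(s.bin_duration_s - bin_s) > 1e-12 or s.band != band:
            raise ValueError("burst trains are not on a common bin grid")
    labels = [s.channel_label for s in all_series]
    n = len(all_series)
    te = np.full((n, n), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=UserWarning)  # constant-destination trains
        for i, j in itertools.permutations(range(n), 2):
            if exclude_shared_contacts and shares_contact(labels[i], labels[j]):
                continue
            try:
                te[i, j] = transfer_entropy(
                    all_series[i], all_series[j], k=k, min_triplets=min_triplets
                )
            except ValueError:
                te[i, j] = np.nan
    return EcMatrix(te, labels, band, stage, epoch_index)


def channel_ec(m: EcMatrix, mode: str = "combined") -> pd.Series:
    """Per-channel EC summary: mean of efferent, afferent, or all connections."""
    n = m.te.shape[0]
    if n < 2:
        raise ValueError("need at least 2 channels")
    if mode not in ("combined", "efferent", "afferent"):
        raise ValueError(f"unknown mode {mode!r}")
    out = np.full(n, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)  # all-NaN slices
        for i in range(n):
            eff = np.delete(m.te[i, :], i)
            aff = np.delete(m.te[:, i], i)
            if mode == "efferent":
                vals = eff
            elif mode == "afferent":
                vals = aff
            else:
                vals = np.concatenate([eff, aff])
            out[i] = np.nanmean(vals)
    return pd.Series(out, index=m.labels, name=f"{m.band}_ec_{mode}")
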