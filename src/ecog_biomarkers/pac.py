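"""Delta-HFO phase-amplitude coupling via the normalized mean-vector modulation index.

The raw (preprocessed, bipolar) trace is band-passed twice with zero-phase FIR
filters: once in the delta band (3-4 Hz), whose analytic-signal angle gives the
instantaneous phase phi(t), and once in the HFO band (80-300 Hz), whose
analytic-signal magnitude gives the amplitude envelope A(t).  The modulation
index is the length of the amplitude-weighted mean phase vector, normalized by
the mean amplitude:

    MI = | mean_t A(t) exp(i phi(t)) | / mean_t A(t)

so MI is scale-free, lies in [0, 1], and for an envelope of the form
A = 1 + kappa*cos(phi - phi0) converges to kappa/2 with preferred phase phi0.
An optional surrogate z-score compares the observed MI against circular
time-shifts of the envelope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

DELTA_BAND = (3.0, 4.0)
HFO_BAND = (80.0, 300.0)


@dataclass
class PacResult:
    mi: float
    preferred_phase: float  # radians in (-pi, pi]
    n_samples_used: int
    degenerate: bool = False  # amplitude identically zero
    surrogate_z: float | None = None


def _fir_bandpass(x: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    # Kernel length scales with the period of the low edge (~3 cycles) so the
    # delta band gets the long kernel it needs for a usable transition width.
    numtaps = int(round(3.0 * fs / band[0]))
    numtaps += 1 - numtaps % 2  # odd
    numtaps = max(numtaps, 101)
    taps = signal.firwin(numtaps, band, pass_zero=False, fs=fs)
    return signal.filtfilt(taps, [1.0], x)


def phase_and_amplitude(
    x: np.ndarray,
    fs: float,
    delta_band: tuple[float, float] = DELTA_BAND,
    hfo_band: tuple[float, float] = HFO_BAND,
) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous delta phase and HFO amplitude envelope of a raw trace."""
    x = np.asarray(x, dtype=float)
    phi = np.angle(signal.hilbert(_fir_bandpass(x, fs, delta_band)))
    amp = np.abs(signal.hilbert(_fir_bandpass(x, fs, hfo_band)))
    return phi, amp


def _mean_vector(amp: np.ndarray, phi: np.ndarray) -> complex:
    return complex(np.mean(amp * np.exp(1j * phi)))


def modulation_index(
    x: np.ndarray,
    fs: float,
    delta_band: tuple[float, float] = DELTA_BAND,
    hfo_band: tuple[float, float] = HFO_BAND,
    mask: np.ndarray | None = None,
    min_duration_s: float = 30.0,
) -> PacResult:
    """Modulation index of one channel; masked samples are excluded.

    Raises on fewer than ``min_duration_s`` seconds of unmasked data.  An
    identically-zero HFO envelope yields MI = 0 with the ``degenerate`` flag.
    """
    phi, amp = phase_and_amplitude(x, fs, delta_band, hfo_band)
    keep = np.ones(phi.size, dtype=bool) if mask is None else ~np.asarray(mask, dtype=bool)
    phi, amp = phi[keep], amp[keep]
    if phi.size < int(min_duration_s * fs):
        raise ValueError(
            f"only {phi.size / fs:.1f}s of unmasked data; need >= {min_duration_s:.0f}s"
        )
    mean_amp = float(np.mean(amp))
    if mean_amp == 0.0:
        return PacResult(mi=0.0, preferred_phase=0.0, n_samples_used=int(phi.size), degenerate=True)
    mv = _mean_vector(amp, phi)
    return PacResult(
        mi=float(abs(mv) / mean_amp),
        preferred_phase=float(np.angle(mv)),
        n_samples_used=int(phi.size),
    )


def surrogate_mi_z(
    x: np.ndarray,
    fs: float,
    delta_band: tuple[float, float] = DELTA_BAND,
    hfo_band: tuple[float, float] = HFO_BAND,
    n_surrogates: int = 200,
    seed: int = 0,
    min_shift_s: float = 1.0,
) -> float:
    """Surrogate-normalized MI: z against circular time-shifts of the envelope.

    Each surrogate circularly shifts A(t) relative to phi(t) by a uniform
    offset of at least ``min_shift_s`` seconds, destroying phase-locked
    coupling while preserving both marginals.
    """
    if n_surrogates < 20:
        raise ValueError("need at least 20 surrogates for a stable z-score")
    phi, amp = phase_and_amplitude(x, fs, delta_band, hfo_band)
    mean_amp = float(np.mean(amp))
    if mean_amp == 0.0:
        return 0.0
    observed = abs(_mean_vector(amp, phi)) / mean_amp
    rng = np.random.default_rng(seed)
    min_shift = int(round(min_shift_s * fs))
    if 2 * min_shift >= phi.size:
        raise ValueError("signal too short for the minimum surrogate shift")
    shifts = rng.integers(min_shift, phi.size - min_shift, size=n_surrogates)
    null = np.empty(n_surrogates)
    for k, s in enumerate(shifts):
        null[k] = abs(_mean_vector(np.roll(amp, int(s)), phi)) / mean_amp
    sd = null.std()
    if sd == 0:
        return 0.0
    return float((observed - null.mean()) / sd)
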