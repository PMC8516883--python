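"""Shared filter designs for the preprocessing chain and the signal generator.

The analysis bandpass is a Hamming-window FIR applied forward-backward
(zero phase).  The synthetic generator reuses the same designs so that the
band conventions of simulated oscillators and of the analysis chain are
identical by construction.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

#: transition width of the FIR designs, Hz. ~1 Hz keeps the 1 Hz lower band
#: edge usable at typical EEG sampling rates (≈1651 taps at 500 Hz).
DEFAULT_TRANSITION_HZ = 1.0


def fir_bandpass(lo_hz: float, hi_hz: float, fs_hz: float,
                 transition_hz: float = DEFAULT_TRANSITION_HZ) -> np.ndarray:
    """Design a Hamming-window bandpass FIR with ~`transition_hz` transition width.

    Returns the (odd-length, linear-phase) tap vector.
    """
    nyq = fs_hz / 2.0
    if not (0.0 < lo_hz < hi_hz < nyq):
        raise ValueError(
            f"invalid band edges ({lo_hz}, {hi_hz}) for fs={fs_hz} Hz")
    numtaps = int(np.ceil(3.3 * fs_hz / transition_hz))
    if numtaps % 2 == 0:
        numtaps += 1
    return signal.firwin(numtaps, [lo_hz, hi_hz], window="hamming",
                         pass_zero=False, fs=fs_hz)


def zero_phase_fir(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply a linear-phase FIR forward-backward (net zero phase).

    For a symmetric FIR the backward pass equals a second forward pass, so
    the two passes collapse into one convolution with ``taps ∗ taps`` whose
    magnitude response is |H|²; this is done with FFT convolution, which is
    what makes the long (multi-thousand-tap) designs affordable.  Edges are
    odd-reflection padded, as in ``scipy.signal.filtfilt``.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    h2 = np.convolve(taps, taps)  # symmetric, length 2L-1, delay L-1
    padlen = min(len(h2), n - 1)
    left = 2.0 * x[..., :1] - x[..., padlen:0:-1]
    right = 2.0 * x[..., -1:] - x[..., -2:-padlen - 2:-1]
    xp = np.concatenate([left, x, right], axis=-1)
    shape = (1,) * (x.ndim - 1) + (len(h2),)
    y = signal.fftconvolve(xp, h2.reshape(shape), mode="same", axes=-1)
    return y[..., padlen:padlen + n]


def bandlimit_noise(white: np.ndarray, lo_hz: float, hi_hz: float,
                    fs_hz: float) -> np.ndarray:
    """Band-limit white noise with the analysis FIR (single pass, FFT conv).

    Phase is irrelevant for stationary noise, so a single pass of the same
    Hamming design used by the analysis chain suffices; stopband rejection
    of one pass (>50 dB) already confines the component to its band.
    """
    taps = fir_bandpass(lo_hz, hi_hz, fs_hz)
    shape = (1,) * (white.ndim - 1) + (len(taps),)
    return signal.fftconvolve(white, taps.reshape(shape), mode="same",
                              axes=-1)


def iir_notch(f0_hz: float, fs_hz: float, quality: float = 30.0):
    """Second-order IIR notch (b, a) at `f0_hz`; −3 dB width = f0/quality."""
    if f0_hz >= fs_hz / 2.0:
        raise ValueError(f"notch frequency {f0_hz} Hz ≥ Nyquist ({fs_hz / 2} Hz)")
    return signal.iirnotch(f0_hz, quality, fs=fs_hz)
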