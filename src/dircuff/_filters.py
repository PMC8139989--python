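"""Shared IIR filter designs for the ENG processing chain.

The spike band-pass (250 Hz–10 kHz, Butterworth, 8th order overall) is used
both by the spike pipeline and inside the respiratory nerve-profile (RnP)
computation so the two stages see identical pass-band behaviour. All filters
are applied zero-phase (forward-backward) so detected peak times are not
shifted; this doubles the effective order, which is the documented convention
throughout the package.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

#: Spike pass-band edges in Hz.
SPIKE_BAND = (250.0, 10_000.0)


def design_bandpass(fs: float, low: float = SPIKE_BAND[0], high: float = SPIKE_BAND[1]):
    """Second-order sections for the 8th-order Butterworth band-pass.

    ``scipy.signal.butter`` with ``N=4`` and ``btype='bandpass'`` yields an
    8th-order transfer function, matching the stated filter order.
    """
    if not fs > 2 * high:
        raise ValueError(f"sampling rate {fs} Hz must exceed twice the upper band edge {high} Hz")
    if not 0 < low < high:
        raise ValueError(f"invalid band edges ({low}, {high})")
    return signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")


def design_lowpass(fs: float, cutoff: float, order: int = 4):
    """Second-order sections for a Butterworth low-pass (RnP envelope)."""
    if not 0 < cutoff < fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz outside (0, fs/2)")
    return signal.butter(order, cutoff, btype="lowpass", fs=fs, output="sos")


def sos_padlen(sos: np.ndarray) -> int:
    """Default forward-backward padding length for a SOS filter."""
    return 3 * (2 * sos.shape[0] + 1)


def apply_zero_phase(sos: np.ndarray, x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Zero-phase application with an explicit length check."""
    n = x.shape[axis]
    if n <= sos_padlen(sos):
        raise ValueError(f"trace of length {n} shorter than filter warm-up ({sos_padlen(sos)} samples)")
    return signal.sosfiltfilt(sos, x, axis=axis)
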