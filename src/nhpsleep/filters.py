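"""Zero-phase bandpass preprocessing.

The standard preprocessing bands are 0.3-35 Hz for EEG/EOG and 10-100 Hz
for EMG.  Filtering is a 4th-order Butterworth applied forward-backward
(zero phase), so epoch boundaries are not shifted by group delay.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

#: Preprocessing band edges in Hz, by channel role.
DEFAULT_BANDS = {"EEG": (0.3, 35.0), "EOG": (0.3, 35.0), "EMG": (10.0, 100.0)}


def bandpass(x: np.ndarray, fs: float, low: float, high: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth bandpass; output length equals input length.

    Raises ``ValueError`` unless ``0 < low < high < fs/2``.
    """
    if not (0.0 < low < high):
        raise ValueError(f"need 0 < low < high, got low={low}, high={high}")
    if high >= fs / 2.0:
        raise ValueError(f"high edge {high} Hz must be below Nyquist {fs / 2.0} Hz")
    x = np.asarray(x, dtype=float)
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def bandpass_recording(rec, bands=None):
    """Apply the per-channel preprocessing bands to a whole recording."""
    from .psg import PsgRecording

    bands = dict(DEFAULT_BANDS if bands is None else bands)
    channels = {}
    for name, x in rec.channels.items():
        if name in bands:
            lo, hi = bands[name]
            hi = min(hi, rec.sampling_rate / 2.0 * 0.99)
            channels[name] = bandpass(x, rec.sampling_rate, lo, hi)
        else:
            channels[name] = x
    return PsgRecording(channels=channels, sampling_rate=rec.sampling_rate, start_time=rec.start_time)
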