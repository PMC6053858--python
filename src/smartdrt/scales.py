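"""ERB_N-number (Cam) scale conversions.

The Cam scale is the ERB_N-number scale: frequency warped so that one unit
corresponds to one equivalent rectangular bandwidth (ERB_N) of the normal
auditory filter.  The standard conversion is

    Cam(F) = 21.4 * log10(4.37 * F + 1),        F in kHz
    ERB_N(F) = 24.7 * (4.37 * F + 1)            Hz

Both functions accept scalars or numpy arrays and return the same kind.
"""

from __future__ import annotations

import numpy as np

__all__ = ["cam_from_hz", "hz_from_cam", "erb_n_hz", "cams_per_octave"]

_CAM_SCALE = 21.4
_CAM_COEF_PER_HZ = 4.37e-3  # 4.37 per kHz


def _as_array(x, name: str):
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"{name} must be non-negative")
    return arr


def cam_from_hz(f_hz):
    """Convert frequency in Hz to ERB_N-number in Cams.

    Monotonically increasing; ``cam_from_hz(0) == 0``.  Raises
    ``ValueError`` for negative frequencies.
    """
    f = _as_array(f_hz, "frequency")
    cam = _CAM_SCALE * np.log10(_CAM_COEF_PER_HZ * f + 1.0)
    return cam if isinstance(f_hz, np.ndarray) else float(cam)


def hz_from_cam(cam):
    """Convert ERB_N-number in Cams back to frequency in Hz (inverse of
    :func:`cam_from_hz`)."""
    c = _as_array(cam, "Cam value")
    f = (10.0 ** (c / _CAM_SCALE) - 1.0) / _CAM_COEF_PER_HZ
    return f if isinstance(cam, np.ndarray) else float(f)


def erb_n_hz(f_hz):
    """Equivalent rectangular bandwidth (Hz) of the normal auditory filter
    centred at ``f_hz``."""
    f = _as_array(f_hz, "frequency")
    b = 24.7 * (_CAM_COEF_PER_HZ * f + 1.0)
    return b if isinstance(f_hz, np.ndarray) else float(b)


def cams_per_octave(f_hz):
    """Local density of the Cam scale in Cams per octave at ``f_hz``.

    Used to translate audiogram slopes between dB/octave and dB/Cam.
    """
    f = _as_array(f_hz, "frequency")
    # d(Cam)/d(ln f) * ln 2
    dcam_dlnf = _CAM_SCALE / np.log(10.0) * (_CAM_COEF_PER_HZ * f) / (
        _CAM_COEF_PER_HZ * f + 1.0
    )
    out = dcam_dlnf * np.log(2.0)
    return out if isinstance(f_hz, np.ndarray) else float(out)
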