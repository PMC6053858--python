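"""Audiogram representation and queries.

An audiogram tabulates the total hearing loss HL_total (dB HL) at a set of
frequencies for one ear.  It is the fixed, known part of the hearing model:
the engine interpolates it, and the TEN screening cascade inverts it to find
the frequencies where the loss first reaches 65, 70 and 75 dB HL.

Interpolation is piecewise linear on the (Cam, dB HL) plane, i.e. on the
same warped frequency axis the rest of the machinery uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scales import cam_from_hz, hz_from_cam

__all__ = ["Audiogram", "interpolate_hl", "find_freq_at_hl"]

HL_MIN_DB = -10.0
HL_MAX_DB = 120.0


@dataclass(frozen=True)
class Audiogram:
    """Tabulated HL_total(f) for one ear.

    Parameters
    ----------
    freqs_hz : array-like
        Strictly increasing positive frequencies in Hz (>= 2 points).
    hl_db : array-like
        HL_total in dB HL at each frequency, within [-10, 120].
    ear_label : str
        Free-text ear identifier.
    """

    freqs_hz: np.ndarray
    hl_db: np.ndarray
    ear_label: str = ""
    _cams: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        f = np.atleast_1d(np.asarray(self.freqs_hz, dtype=float))
        h = np.atleast_1d(np.asarray(self.hl_db, dtype=float))
        if f.size < 2:
            raise ValueError("audiogram needs at least 2 points")
        if f.size != h.size:
            raise ValueError("frequency and HL arrays must have equal length")
        if np.any(f <= 0):
            raise ValueError("audiogram frequencies must be positive")
        if np.any(np.diff(f) <= 0):
            raise ValueError("audiogram frequencies must be strictly increasing")
        if np.any(h < HL_MIN_DB) or np.any(h > HL_MAX_DB):
            raise ValueError(
                f"HL_total values must lie within [{HL_MIN_DB}, {HL_MAX_DB}] dB HL"
            )
        object.__setattr__(self, "freqs_hz", f)
        object.__setattr__(self, "hl_db", h)
        object.__setattr__(self, "_cams", cam_from_hz(f))

    # -- queries -----------------------------------------------------------

    @property
    def fmin_hz(self) -> float:
        return float(self.freqs_hz[0])

    @property
    def fmax_hz(self) -> float:
        return float(self.freqs_hz[-1])

    def hl_at(self, f_hz):
        """HL_total at ``f_hz`` (scalar or array), linear in (Cam, dB).

        Raises ``ValueError`` for frequencies outside the tabulated range
        (no silent clamping).
        """
        f = np.asarray(f_hz, dtype=float)
        if np.any(f < self.freqs_hz[0]) or np.any(f > self.freqs_hz[-1]):
            raise ValueError(
                f"frequency outside audiogram range "
                f"[{self.fmin_hz:g}, {self.fmax_hz:g}] Hz; refusing to extrapolate"
            )
        out = np.interp(cam_from_hz(f), self._cams, self.hl_db)
        return out if isinstance(f_hz, np.ndarray) else float(out)

    def freq_at_hl(self, criterion_db: float):
        """Lowest frequency (Hz) at which interpolated HL_total equals
        ``criterion_db``; ``None`` if the criterion is never reached.

        Scans segments from low to high frequency, so on non-monotonic
        audiograms the lower-frequency crossing wins.
        """
        if not (0.0 <= criterion_db <= HL_MAX_DB):
            raise ValueError("criterion must be within [0, 120] dB HL")
        h = self.hl_db
        for i in range(h.size - 1):
            if h[i] == criterion_db:
                return float(self.freqs_hz[i])
            lo, hi = h[i], h[i + 1]
            if (lo - criterion_db) * (hi - criterion_db) < 0:
                frac = (criterion_db - lo) / (hi - lo)
                cam_x = self._cams[i] + frac * (self._cams[i + 1] - self._cams[i])
                return hz_from_cam(float(cam_x))
        if h[-1] == criterion_db:
            return float(self.freqs_hz[-1])
        return None

    # -- file round trip ---------------------------------------------------

    @classmethod
    def from_csv(cls, path, ear_label: str = "") -> "Audiogram":
        """Read a two-column CSV (``frequency_hz, hl_total_db``, header
        required)."""
        df = pd.read_csv(path)
        required = {"frequency_hz", "hl_total_db"}
        if not required.issubset(df.columns):
            raise ValueError(
                f"audiogram CSV must have columns {sorted(required)}, "
                f"got {list(df.columns)}"
            )
        return cls(
            df["frequency_hz"].to_numpy(float),
            df["hl_total_db"].to_numpy(float),
            ear_label=ear_label,
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"frequency_hz": self.freqs_hz, "hl_total_db": self.hl_db}
        ).to_csv(path, index=False)


def interpolate_hl(a: Audiogram, f_hz):
    """Functional alias for :meth:`Audiogram.hl_at`."""
    return a.hl_at(f_hz)


def find_freq_at_hl(a: Audiogram, criterion_db: float):
    """Functional alias for :meth:`Audiogram.freq_at_hl`."""
    return a.freq_at_hl(criterion_db)
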