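"""Excitation-pattern hearing model.

The detectability of a tone presented together with a narrowband masker is
modelled at a single cochlear place: the auditory filter centred at the
dead-region edge frequency f_e.  The filter is a rounded-exponential
("roex") weighting

    W(g) = (1 + p|g|) * exp(-p|g|),        g = (f - cf) / cf,

with independent slope parameters for the lower and upper skirts.  The
upper skirt keeps the normal sharpness p51 = 4*cf/ERB_N(cf).  The lower
skirt broadens with outer-hair-cell loss (OHCL) and with stimulus level
above 51 dB, mimicking the loss of the active mechanism:

    p_lower = max(0.2*p51,
                  p51 * max(0.2, 1 - ohcl/65)
                  - 0.35 * (p51/p51_1k) * max(0, L - 51))

Excitation levels of the signal tone (E_sig) and the masking noise
(E_noise) are evaluated at cf = f_e, the effective masker excitation is
max(E_noise, HL_total(f_e)) because the absolute threshold can limit
audibility, and the hit probability is a Gaussian CDF of the excitation
difference scaled into [lapse, 1 - lapse].  At E_sig = E_noise_eff the hit
probability is exactly 0.5.

All levels are in dB HL; excitation levels share that reference so E_noise
is directly comparable with HL_total(f_e).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .audiogram import Audiogram
from .scales import erb_n_hz

__all__ = [
    "EarModelParams",
    "Stimulus",
    "SignalSpec",
    "RoexShape",
    "filter_slopes",
    "excitation_tone",
    "excitation_noise",
    "excitation_broadband",
    "hit_probability",
    "hit_probability_grid",
    "signal_excitation_at_edge",
    "predict_ptc",
    "OHCL_CAP_DB",
    "TEN_BACKGROUND_DB",
    "MIN_NOISE_EDGE_HZ",
]

OHCL_CAP_DB = 65.0          # filter broadening saturates beyond this loss
LEVEL_REF_DB = 51.0         # slopes are level-independent below this level
LEVEL_SLOPE = 0.35          # p-units lost per dB above 51 dB (at 1 kHz)
P_LOWER_FLOOR_FRAC = 0.2    # lower-skirt floor as a fraction of p51
TEN_BACKGROUND_DB = 35.0    # broadband TEN floor, dB HL/ERB_N
MIN_NOISE_EDGE_HZ = 20.0    # noise bands are truncated at this floor

_P51_AT_1K = 4000.0 / erb_n_hz(1000.0)


@dataclass(frozen=True)
class EarModelParams:
    """Latent parameters θ: dead-region edge frequency and OHCL at it."""

    f_e_hz: float
    ohcl_db: float


@dataclass(frozen=True)
class Stimulus:
    """Masker presentation parameters x = (f_mask, L_mask)."""

    f_mask_hz: float
    l_mask_db: float


@dataclass(frozen=True)
class SignalSpec:
    """The fixed probe tone (frequency and level, dB HL)."""

    f_sig_hz: float
    l_sig_db: float


@dataclass(frozen=True)
class RoexShape:
    """A roex(p) filter: centre frequency and skirt slopes."""

    cf_hz: float
    p_lower: float
    p_upper: float

    def __post_init__(self):
        if self.p_lower <= 0 or self.p_upper <= 0:
            raise ValueError("roex slopes must be positive")
        if self.p_lower > self.p_upper + 1e-9:
            raise ValueError(
                "p_lower must not exceed p_upper (impairment/level only "
                "broadens the lower skirt)"
            )


def _p51(cf_hz):
    return 4.0 * np.asarray(cf_hz, float) / erb_n_hz(np.asarray(cf_hz, float))


def _p_lower(cf_hz, input_level_db, ohcl_db):
    """Vectorised lower-skirt slope (see module docstring)."""
    p51 = _p51(cf_hz)
    broad = np.maximum(P_LOWER_FLOOR_FRAC, 1.0 - np.asarray(ohcl_db, float) / OHCL_CAP_DB)
    level_term = LEVEL_SLOPE * (p51 / _P51_AT_1K) * np.maximum(
        0.0, np.asarray(input_level_db, float) - LEVEL_REF_DB
    )
    return np.maximum(P_LOWER_FLOOR_FRAC * p51, p51 * broad - level_term)


def filter_slopes(cf_hz: float, input_level_db: float, ohcl_db: float) -> RoexShape:
    """Auditory-filter slopes at ``cf_hz`` for a given context level and OHCL.

    The upper skirt is fixed at the normal sharpness p51; the lower skirt
    broadens with level above 51 dB and with OHCL, floored at 0.2*p51.
    OHCL above the 65-dB cap is clipped with a warning.
    """
    if ohcl_db < 0:
        raise ValueError("ohcl must be non-negative")
    if not (0.0 <= input_level_db <= 110.0):
        raise ValueError("input level must be within [0, 110] dB HL")
    if ohcl_db > OHCL_CAP_DB:
        warnings.warn(
            f"OHCL {ohcl_db:g} dB exceeds the {OHCL_CAP_DB:g}-dB cap; clipping",
            stacklevel=2,
        )
        ohcl_db = OHCL_CAP_DB
    p51 = float(_p51(cf_hz))
    return RoexShape(
        cf_hz=float(cf_hz),
        p_lower=float(_p_lower(cf_hz, input_level_db, ohcl_db)),
        p_upper=p51,
    )


# ---------------------------------------------------------------------------
# roex evaluation and band integrals
# ---------------------------------------------------------------------------

def _roex_w(g, p):
    """W(|g|) for a single skirt slope p (vectorised)."""
    a = p * np.abs(g)
    return (1.0 + a) * np.exp(-a)


def _roex_cum(u, p):
    """∫_0^u (1 + p t) e^{-p t} dt for u >= 0 (vectorised, exact)."""
    return 2.0 / p - np.exp(-p * u) * (u + 2.0 / p)


def _band_integral(p_lower, p_upper, g_lo, g_hi):
    """∫_{g_lo}^{g_hi} W(g) dg with p_lower below cf (g<0) and p_upper above.

    All arguments broadcast; requires g_lo <= g_hi.
    """
    neg_hi = np.clip(-g_lo, 0.0, None)   # extent into the lower skirt
    neg_lo = np.clip(-g_hi, 0.0, None)
    pos_hi = np.clip(g_hi, 0.0, None)    # extent into the upper skirt
    pos_lo = np.clip(g_lo, 0.0, None)
    return (_roex_cum(neg_hi, p_lower) - _roex_cum(neg_lo, p_lower)) + (
        _roex_cum(pos_hi, p_upper) - _roex_cum(pos_lo, p_upper)
    )


def excitation_tone(shape: RoexShape, f_tone_hz: float, l_tone_db: float) -> float:
    """Excitation level (dB) of a pure tone at the place ``shape.cf_hz``.

    E = L + 10 log10 W(g); an on-frequency tone excites at exactly its own
    level (0-dB tip gain convention).
    """
    g = (f_tone_hz - shape.cf_hz) / shape.cf_hz
    p = shape.p_lower if f_tone_hz < shape.cf_hz else shape.p_upper
    return float(l_tone_db + 10.0 * np.log10(_roex_w(g, p)))


def noise_bandwidth_hz(f_mask_hz):
    """Masker bandwidth rule: 1 ERB_N or 200 Hz, whichever is greater."""
    return np.maximum(erb_n_hz(f_mask_hz), 200.0)


def excitation_noise(
    shape: RoexShape,
    x: Stimulus,
    bandwidth_hz: float | None = None,
    background_ten_db: float | None = None,
) -> float:
    """Excitation level (dB) of a flat-spectrum noise band at the place cf.

    The band is centred at ``x.f_mask_hz`` with bandwidth
    max(ERB_N(f_mask), 200 Hz) unless overridden, carries total level
    ``x.l_mask_db``, and is truncated (with renormalisation of the spectrum
    density) at a 20-Hz floor.  If ``background_ten_db`` is given, the
    excitation of a broadband threshold-equalising noise at that
    dB HL/ERB_N level is added in intensity.
    """
    b = float(noise_bandwidth_hz(x.f_mask_hz)) if bandwidth_hz is None else float(bandwidth_hz)
    lo = x.f_mask_hz - b / 2.0
    hi = x.f_mask_hz + b / 2.0
    lo = max(lo, MIN_NOISE_EDGE_HZ)
    if hi <= lo:
        raise ValueError("noise band fully below the 20-Hz floor")
    b_eff = hi - lo
    g_lo = (lo - shape.cf_hz) / shape.cf_hz
    g_hi = (hi - shape.cf_hz) / shape.cf_hz
    integral = shape.cf_hz * _band_integral(shape.p_lower, shape.p_upper, g_lo, g_hi)
    e_band = x.l_mask_db + 10.0 * np.log10(integral / b_eff)
    if background_ten_db is None:
        return float(e_band)
    e_bg = excitation_broadband(shape, background_ten_db)
    return float(10.0 * np.log10(10.0 ** (e_band / 10.0) + 10.0 ** (e_bg / 10.0)))


def excitation_broadband(shape: RoexShape, level_per_erb_db: float) -> float:
    """Excitation of a broadband noise with constant level per ERB_N.

    For a normal filter this equals the per-ERB level by construction; a
    broadened filter collects more noise power.
    """
    # ∫W df = cf * (2/p_l + 2/p_u): the filter's own equivalent bandwidth
    erb_model = shape.cf_hz * (2.0 / shape.p_lower + 2.0 / shape.p_upper)
    return float(level_per_erb_db + 10.0 * np.log10(erb_model / erb_n_hz(shape.cf_hz)))


# ---------------------------------------------------------------------------
# detection likelihood
# ---------------------------------------------------------------------------

def signal_excitation_at_edge(f_e_hz, sig: SignalSpec):
    """E_sig at the place f_e (vectorised over f_e).

    Requires f_e < f_sig, so only the level-independent upper skirt is
    involved: the result does not depend on the masker context level.
    """
    f_e = np.asarray(f_e_hz, float)
    g = (sig.f_sig_hz - f_e) / f_e
    return sig.l_sig_db + 10.0 * np.log10(_roex_w(g, _p51(f_e)))


def hit_probability_grid(
    f_e_hz,
    ohcl_db,
    hl_fe_db,
    f_mask_hz,
    l_mask_db,
    sig: SignalSpec,
    sd_db: float = 3.0,
    lapse: float = 0.01,
    background_ten_db: float | None = TEN_BACKGROUND_DB,
    p_lower_scale: float = 1.0,
):
    """Vectorised hit probabilities over parameter cells x stimuli.

    ``f_e_hz``, ``ohcl_db``, ``hl_fe_db`` are (m,) cell arrays;
    ``f_mask_hz``, ``l_mask_db`` are (k,) stimulus arrays.  Returns the
    (m, k) matrix of p(yes | x, θ).  ``p_lower_scale`` perturbs the
    lower-skirt slope (model-mismatch experiments); 1.0 is the nominal
    model.
    """
    f_e = np.asarray(f_e_hz, float)[:, None]
    ohcl = np.asarray(ohcl_db, float)[:, None]
    hl_fe = np.asarray(hl_fe_db, float)[:, None]
    f_m = np.asarray(f_mask_hz, float)[None, :]
    l_m = np.asarray(l_mask_db, float)[None, :]

    d = excitation_difference_grid(
        f_e, ohcl, hl_fe, f_m, l_m, sig,
        background_ten_db=background_ten_db, p_lower_scale=p_lower_scale,
    )
    return lapse + (1.0 - 2.0 * lapse) * ndtr(d / sd_db)


def excitation_difference_grid(
    f_e, ohcl, hl_fe, f_m, l_m, sig: SignalSpec,
    background_ten_db: float | None = TEN_BACKGROUND_DB,
    p_lower_scale: float = 1.0,
):
    """E_sig - max(E_noise, HL_total(f_e)) with full broadcasting (dB)."""
    p_u = _p51(f_e)
    p_l = _p_lower(f_e, l_m, ohcl) * p_lower_scale
    p_l = np.minimum(p_l, p_u)  # keep the roex invariant under perturbation

    b = noise_bandwidth_hz(f_m)
    lo = np.maximum(f_m - b / 2.0, MIN_NOISE_EDGE_HZ)
    hi = f_m + b / 2.0
    g_lo = (lo - f_e) / f_e
    g_hi = (hi - f_e) / f_e
    integral = f_e * _band_integral(p_l, p_u, g_lo, g_hi)
    e_band = l_m + 10.0 * np.log10(np.maximum(integral, 1e-300) / (hi - lo))
    if background_ten_db is not None:
        erb_model = f_e * (2.0 / p_l + 2.0 / p_u)
        e_bg = background_ten_db + 10.0 * np.log10(erb_model / erb_n_hz(f_e))
        e_noise = 10.0 * np.log10(
            10.0 ** (e_band / 10.0) + 10.0 ** (e_bg / 10.0)
        )
    else:
        e_noise = e_band
    e_eff = np.maximum(e_noise, hl_fe)
    e_sig = sig.l_sig_db + 10.0 * np.log10(_roex_w((sig.f_sig_hz - f_e) / f_e, p_u))
    return e_sig - e_eff


def hit_probability(
    x: Stimulus,
    theta: EarModelParams,
    sig: SignalSpec,
    a: Audiogram,
    sd_db: float = 3.0,
    lapse: float = 0.01,
    background_ten_db: float | None = TEN_BACKGROUND_DB,
) -> float:
    """p(yes | x, θ): Gaussian-CDF detection likelihood, scaled into
    [lapse, 1 - lapse].

    Excitation levels are evaluated at cf = f_e (where the signal-to-masker
    excitation ratio peaks when f_sig lies in the dead region); the masker
    level sets the filter's level-dependent lower skirt; E_noise is replaced
    by max(E_noise, HL_total(f_e)) because the threshold in quiet can limit
    audibility.
    """
    if sd_db <= 0:
        raise ValueError("sd must be positive")
    if not (0.0 <= lapse < 0.5):
        raise ValueError("lapse must lie in [0, 0.5)")
    if theta.f_e_hz >= sig.f_sig_hz:
        raise ValueError("f_e must lie below f_sig")
    hl_fe = a.hl_at(theta.f_e_hz)
    if not (0.0 <= theta.ohcl_db <= hl_fe + 1e-9):
        raise ValueError("ohcl must lie within [0, HL_total(f_e)]")
    p = hit_probability_grid(
        np.array([theta.f_e_hz]),
        np.array([theta.ohcl_db]),
        np.array([hl_fe]),
        np.array([x.f_mask_hz]),
        np.array([x.l_mask_db]),
        sig,
        sd_db=sd_db,
        lapse=lapse,
        background_ten_db=background_ten_db,
    )
    return float(p[0, 0])


# ---------------------------------------------------------------------------
# predicted psychophysical tuning curve
# ---------------------------------------------------------------------------

def predict_ptc(
    theta: EarModelParams,
    sig: SignalSpec,
    a: Audiogram,
    f_mask_grid_hz,
    level_bounds_db: tuple[float, float] = (20.0, 90.0),
    background_ten_db: float | None = TEN_BACKGROUND_DB,
):
    """Predicted PTC: the masker level giving a 50% hit rate at each
    masker frequency (i.e. E_noise_eff = E_sig), found by monotone
    root-finding; NaN where no level within ``level_bounds_db`` reaches
    the criterion.

    If the signal is inaudible in quiet under θ (E_sig at f_e below
    HL_total(f_e)) every point is undefined and the result is flagged.
    """
    from scipy.optimize import brentq

    f_grid = np.atleast_1d(np.asarray(f_mask_grid_hz, float))
    if np.any(f_grid <= 0):
        raise ValueError("masker grid frequencies must be positive")
    hl_fe = a.hl_at(theta.f_e_hz)
    e_sig = float(signal_excitation_at_edge(theta.f_e_hz, sig))
    levels = np.full(f_grid.shape, np.nan)
    if e_sig < hl_fe:  # signal inaudible in quiet: PTC undefined everywhere
        return levels, True

    fe_arr = np.array([theta.f_e_hz])
    ohcl_arr = np.array([theta.ohcl_db])
    hl_arr = np.array([hl_fe])

    def noise_minus_sig(l_mask, f_mask):
        d = excitation_difference_grid(
            fe_arr[:, None], ohcl_arr[:, None], hl_arr[:, None],
            np.array([[f_mask]]), np.array([[l_mask]]), sig,
            background_ten_db=background_ten_db,
        )
        return -float(d[0, 0])  # E_noise_eff - E_sig

    lo, hi = level_bounds_db
    for i, f_mask in enumerate(f_grid):
        f_lo, f_hi = noise_minus_sig(lo, f_mask), noise_minus_sig(hi, f_mask)
        if f_lo > 0 or f_hi < 0:
            continue  # criterion not reachable within bounds
        levels[i] = brentq(noise_minus_sig, lo, hi, args=(f_mask,), xtol=1e-9)
    return levels, False
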