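"""Simulated listeners and a synthetic test-ear cohort.

A :class:`ListenerProfile` is the generative counterpart of the model
parameters: a true edge frequency, a true OHCL(f_e), an audiogram, the
slope (sd) of the psychometric function, a false-alarm rate for catch
trials and a lapse rate.  The responder draws yes/no answers from exactly
the detection likelihood the engine uses (optionally with a perturbed
filter-broadening coefficient, to probe robustness to excitation-model
misspecification).

The cohort generator emulates ears with sloping high-frequency losses:
sigmoidal HL_total on the Cam axis with the slope at the 65-dB-HL point
between 14 and 145 dB/octave, true edge frequencies between 0.5 and
3.3 kHz, psychometric sd mostly 3 dB with designated ~10-dB outliers, and
false-alarm rates mostly 1% with two tinnitus-like profiles at 10% and
17%.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .audiogram import Audiogram
from .excitation import (
    SignalSpec,
    Stimulus,
    TEN_BACKGROUND_DB,
    excitation_broadband,
    filter_slopes,
    hit_probability_grid,
    signal_excitation_at_edge,
)
from .scales import cam_from_hz, cams_per_octave, hz_from_cam

__all__ = ["ListenerProfile", "SimulatedListener", "respond", "generate_cohort"]


@dataclass(frozen=True)
class ListenerProfile:
    true_fe_hz: float
    true_ohcl_db: float
    audiogram: Audiogram
    psych_sd_db: float = 3.0
    false_alarm_rate: float = 0.01
    lapse: float = 0.01
    label: str = ""
    broadening_scale: float = 1.0  # 1.0 = responder shares the engine's model

    def __post_init__(self):
        hl_fe = self.audiogram.hl_at(self.true_fe_hz)
        if not (0.0 <= self.true_ohcl_db <= hl_fe + 1e-9):
            raise ValueError(
                f"true_ohcl ({self.true_ohcl_db:g} dB) must lie within "
                f"[0, HL_total(f_e) = {hl_fe:g}] dB"
            )
        if not (0.0 <= self.false_alarm_rate <= 0.5):
            raise ValueError("false_alarm_rate must lie in [0, 0.5]")
        if self.psych_sd_db <= 0:
            raise ValueError("psych_sd must be positive")

    # -- JSON round trip ---------------------------------------------------

    def to_json(self, path) -> None:
        d = asdict(self)
        d["audiogram"] = {
            "frequency_hz": self.audiogram.freqs_hz.tolist(),
            "hl_total_db": self.audiogram.hl_db.tolist(),
            "ear_label": self.audiogram.ear_label,
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ListenerProfile":
        with open(path) as fh:
            d = json.load(fh)
        ag = d.pop("audiogram")
        if isinstance(ag, str):  # CSV reference
            audiogram = Audiogram.from_csv(ag)
        else:
            audiogram = Audiogram(
                np.asarray(ag["frequency_hz"], float),
                np.asarray(ag["hl_total_db"], float),
                ear_label=ag.get("ear_label", ""),
            )
        return cls(audiogram=audiogram, **d)


class SimulatedListener:
    """Yes/no responder driven by a :class:`ListenerProfile`.

    Draws are deterministic given the supplied ``numpy`` Generator.
    """

    def __init__(self, profile: ListenerProfile):
        self.profile = profile

    def hit_probability(self, x: Stimulus, sig: SignalSpec) -> float:
        pr = self.profile
        hl_fe = pr.audiogram.hl_at(pr.true_fe_hz)
        p = hit_probability_grid(
            np.array([pr.true_fe_hz]),
            np.array([pr.true_ohcl_db]),
            np.array([hl_fe]),
            np.array([x.f_mask_hz]),
            np.array([x.l_mask_db]),
            sig,
            sd_db=pr.psych_sd_db,
            lapse=pr.lapse,
            background_ten_db=TEN_BACKGROUND_DB,
            p_lower_scale=pr.broadening_scale,
        )
        return float(p[0, 0])

    def respond(self, x: Stimulus, sig: SignalSpec, is_catch: bool, rng) -> bool:
        if is_catch:
            return bool(rng.random() < self.profile.false_alarm_rate)
        return bool(rng.random() < self.hit_probability(x, sig))

    def ten_hit_probability(
        self, f_sig_hz: float, l_sig_db: float, ten_level_db: float
    ) -> float:
        """Detectability of the probe in broadband threshold-equalising
        noise at ``ten_level_db`` dB HL/ERB_N.

        Detection happens at the better of two places: the listener's own
        edge frequency (off-place listening, if f_sig falls in the dead
        region) or the signal place itself.
        """
        pr = self.profile
        probs = []
        if f_sig_hz > pr.true_fe_hz:  # off-place detection at f_e
            shape = filter_slopes(pr.true_fe_hz, min(ten_level_db, 110.0),
                                  pr.true_ohcl_db)
            if pr.broadening_scale != 1.0:
                from .excitation import RoexShape
                shape = RoexShape(
                    shape.cf_hz,
                    min(shape.p_lower * pr.broadening_scale, shape.p_upper),
                    shape.p_upper,
                )
            e_sig = float(signal_excitation_at_edge(pr.true_fe_hz,
                                                    SignalSpec(f_sig_hz, l_sig_db)))
            e_ten = excitation_broadband(shape, ten_level_db)
            e_eff = max(e_ten, pr.audiogram.hl_at(pr.true_fe_hz))
            probs.append(_scaled_cdf((e_sig - e_eff) / pr.psych_sd_db, pr.lapse))
        # on-place detection at f_sig (normal-sharpness filter): inside a dead
        # region this route is unavailable
        if f_sig_hz <= pr.true_fe_hz:
            try:
                hl_sig = pr.audiogram.hl_at(f_sig_hz)
            except ValueError:
                hl_sig = 0.0
            e_eff = max(ten_level_db, hl_sig)
            probs.append(_scaled_cdf((l_sig_db - e_eff) / pr.psych_sd_db, pr.lapse))
        return max(probs)

    def respond_ten(
        self, f_sig_hz: float, l_sig_db: float, ten_level_db: float,
        signal_present: bool, rng,
    ) -> bool:
        if not signal_present:
            return bool(rng.random() < self.profile.false_alarm_rate)
        return bool(
            rng.random() < self.ten_hit_probability(f_sig_hz, l_sig_db, ten_level_db)
        )


def _scaled_cdf(z: float, lapse: float) -> float:
    from scipy.special import ndtr

    return float(lapse + (1.0 - 2.0 * lapse) * ndtr(z))


def respond(p: ListenerProfile, x: Stimulus, sig: SignalSpec, is_catch: bool, rng) -> bool:
    """Functional form of :meth:`SimulatedListener.respond`."""
    return SimulatedListener(p).respond(x, sig, is_catch, rng)


# ---------------------------------------------------------------------------
# synthetic cohort
# ---------------------------------------------------------------------------

def _probe_audible_at_edge(audiogram: Audiogram, fe_hz: float, ohcl_db: float,
                           margin_db: float = 2.0) -> bool:
    """Study-condition check used by the cohort generator.

    The screening cascade confirms the 10-dB-SL probe is clearly audible in
    quiet before testing, so a valid test ear must hear the probe at its
    edge place at whichever tier the cascade selects.  This predicts the
    selected tier deterministically (first tier whose in-noise
    detectability drops below chance-at-threshold) and requires the
    probe's excitation at f_e to clear HL_total(f_e) by ``margin_db``.
    """
    from .ten import TIERS

    trial = ListenerProfile.__new__(ListenerProfile)  # skip validation: probe only
    object.__setattr__(trial, "true_fe_hz", fe_hz)
    object.__setattr__(trial, "true_ohcl_db", ohcl_db)
    object.__setattr__(trial, "audiogram", audiogram)
    object.__setattr__(trial, "psych_sd_db", 3.0)
    object.__setattr__(trial, "false_alarm_rate", 0.01)
    object.__setattr__(trial, "lapse", 0.01)
    object.__setattr__(trial, "label", "")
    object.__setattr__(trial, "broadening_scale", 1.0)
    listener = SimulatedListener(trial)
    some_tier_fails = False
    for tier in TIERS:
        f_t = audiogram.freq_at_hl(tier)
        if f_t is None:
            return False  # cascade would run out of tiers: no DR detected
        l_t = float(audiogram.hl_at(f_t)) + 10.0
        p_hit = listener.ten_hit_probability(f_t, l_t, tier)
        if p_hit < 0.98:
            # the 10-trial block can plausibly score below criterion here,
            # so the cascade may pick this tier: its probe must be audible
            # in quiet at the edge place
            e_sig = float(signal_excitation_at_edge(fe_hz, SignalSpec(f_t, l_t)))
            if e_sig < audiogram.hl_at(fe_hz) + margin_db:
                return False
        if p_hit < 0.2:
            some_tier_fails = True
            break  # cascade all but surely stops at this tier
    return some_tier_fails

def _sigmoid_audiogram(rng, slope_db_per_oct: float, fe_cam: float,
                       label: str) -> tuple[Audiogram, float]:
    """Sloping-loss audiogram: logistic HL_total on the Cam axis.

    The 65-dB-HL point sits ``delta`` Cams above the true edge frequency
    (shallower slopes get smaller offsets so the 10-dB-SL probe stays
    audible at the edge place).  Returns the audiogram and the offset.
    """
    lo = rng.uniform(10.0, 40.0)
    hi = rng.uniform(80.0, 110.0)
    delta = 0.5 + (slope_db_per_oct - 14.0) / 131.0  # in [0.5, 1.5] Cams
    cam65 = fe_cam + delta
    f65 = hz_from_cam(cam65)
    q = (65.0 - lo) / (hi - lo)
    slope_db_per_cam = slope_db_per_oct / cams_per_octave(f65)
    w = (hi - lo) * q * (1.0 - q) / slope_db_per_cam
    c0 = cam65 - w * np.log(q / (1.0 - q))
    cams = np.arange(cam_from_hz(125.0), cam_from_hz(16000.0) + 1.0, 1.0)
    hl = lo + (hi - lo) / (1.0 + np.exp(-(cams - c0) / w))
    return Audiogram(hz_from_cam(cams), np.clip(hl, -10.0, 120.0), ear_label=label), delta


def generate_cohort(seed: int, n_profiles: int = 12,
                    model_mismatch: bool = False) -> list[ListenerProfile]:
    """Reproducible synthetic cohort of test ears with basal dead regions.

    Profiles 0 to ``n-4`` are the standard cohort (sd 3 dB, 1% false
    alarms).  The last three profiles are designated outliers: one with a
    10% false-alarm rate, one tinnitus-like ear with 17% false alarms and
    a ~10-dB psychometric sd, and one with a ~10-dB sd but normal false
    alarms.  With ``model_mismatch`` the responder's filter-broadening
    coefficient is perturbed by ±25%.
    """
    if n_profiles < 4:
        raise ValueError("cohort needs at least 4 profiles")
    rng = np.random.default_rng(seed)
    cam_lo, cam_hi = cam_from_hz(500.0), cam_from_hz(3300.0)
    profiles = []
    for i in range(n_profiles):
        for _attempt in range(1000):
            slope = float(np.exp(rng.uniform(np.log(14.0), np.log(145.0))))
            fe_cam = float(rng.uniform(cam_lo, cam_hi))
            fe_hz = hz_from_cam(fe_cam)
            audiogram, _ = _sigmoid_audiogram(rng, slope, fe_cam, label=f"sim{i:02d}")
            hl_fe = audiogram.hl_at(fe_hz)
            if hl_fe < 10.0 or audiogram.freq_at_hl(65.0) is None:
                continue
            ohcl = float(rng.uniform(10.0, min(hl_fe, 65.0)))
            if _probe_audible_at_edge(audiogram, fe_hz, ohcl):
                break
        else:  # pragma: no cover - generator parameters make this unreachable
            raise RuntimeError("failed to draw an admissible profile")
        sd, fa = 3.0, 0.01
        if i == n_profiles - 3:
            fa = 0.10
        elif i == n_profiles - 2:
            fa, sd = 0.17, 10.0
        elif i == n_profiles - 1:
            sd = 10.0
        scale = 1.0
        if model_mismatch:
            scale = 0.75 if i % 2 == 0 else 1.25
        profiles.append(
            ListenerProfile(
                true_fe_hz=fe_hz,
                true_ohcl_db=ohcl,
                audiogram=audiogram,
                psych_sd_db=sd,
                false_alarm_rate=fa,
                lapse=0.01,
                label=f"sim{i:02d}",
                broadening_scale=scale,
            )
        )
    return profiles
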