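"""Quick threshold-equalising-noise (TEN) screening cascade.

The cascade decides whether a dead region is present and, if so, fixes the
probe tone for the adaptive test.  At each tier the probe is placed at the
frequency where the audiogram first reaches 65, 70 or 75 dB HL, presented
at 10 dB SL in TEN at the matching dB HL/ERB_N level; 10 signal trials and
10 noise-only trials are scored.  With hit proportion X and
correct-rejection proportion Y, the signal counts as detectable when
X + Y >= 1.5 — equivalently, at least 15 of the 20 trials correct.  A
score below 15 indicates a dead region at that tier and stops the
cascade; passing every tier yields a "no dead region detected" outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .audiogram import Audiogram

__all__ = ["ten_score", "quick_ten_protocol", "TenResult", "TIERS"]

TIERS = (65.0, 70.0, 75.0)
_N_EACH = 10
PASS_TOTAL = 15  # X + Y >= 1.5 with 10 trials of each type


def ten_score(hits: int, correct_rejections: int) -> bool:
    """Pass/fail of one 20-trial block: pass (signal detectable, hence no
    dead region at this frequency) iff hits + correct rejections >= 15."""
    if not (0 <= hits <= _N_EACH and 0 <= correct_rejections <= _N_EACH):
        raise ValueError("counts must lie in [0, 10]")
    return hits + correct_rejections >= PASS_TOTAL


@dataclass(frozen=True)
class TenResult:
    outcome: str                      # "dr_detected" | "no_dr" | "not_testable"
    f_sig_hz: Optional[float] = None
    l_sig_db: Optional[float] = None
    tier: Optional[float] = None      # 65 / 70 / 75
    scores: dict = field(default_factory=dict)  # tier -> (hits, correct_rej)

    @property
    def signal(self):
        from .excitation import SignalSpec

        if self.outcome != "dr_detected":
            raise ValueError(f"no signal defined for outcome {self.outcome!r}")
        return SignalSpec(self.f_sig_hz, self.l_sig_db)


def quick_ten_protocol(a: Audiogram, responder, rng) -> TenResult:
    """Run the f_65 → f_70 → f_75 cascade against a responder.

    ``responder`` must expose ``respond_ten(f_sig_hz, l_sig_db,
    ten_level_db, signal_present, rng) -> bool``.  The signal level is
    always the interpolated threshold plus 10 dB (10 dB SL); the TEN level
    equals the tier criterion.  Trial order within a block is randomised
    (10 signal + 10 noise-only).
    """
    scores: dict = {}
    if a.freq_at_hl(TIERS[0]) is None:
        return TenResult(outcome="not_testable", scores=scores)
    for tier in TIERS:
        f_sig = a.freq_at_hl(tier)
        if f_sig is None:
            break  # loss never reaches this tier: nothing more to screen
        l_sig = float(a.hl_at(f_sig)) + 10.0
        order = rng.permutation([True] * _N_EACH + [False] * _N_EACH)
        hits = 0
        correct_rej = 0
        for present in order:
            said_yes = responder.respond_ten(f_sig, l_sig, tier, bool(present), rng)
            if present and said_yes:
                hits += 1
            elif not present and not said_yes:
                correct_rej += 1
        scores[tier] = (hits, correct_rej)
        if not ten_score(hits, correct_rej):
            return TenResult(
                outcome="dr_detected", f_sig_hz=f_sig, l_sig_db=l_sig,
                tier=tier, scores=scores,
            )
    return TenResult(outcome="no_dr", scores=scores)
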