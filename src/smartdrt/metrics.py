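"""Post-hoc consistency and convergence diagnostics.

Three ways of judging whether a run can be trusted:

* the false-alarm rate on signal-absent catch trials;
* the slope (sd) of the psychometric function, estimated from responses
  against masker level expressed relative to the tuning curve predicted by
  the most likely (f_e, OHCL) pair, with iterative 3-sd outlier rejection
  — values far above the 3 dB assumed by the engine mean the responses
  carry little level information;
* three convergence curves as a function of the number of trials N: the
  mean negative log posterior-predictive probability of all responses
  given only the first N, the ratio of the f_e estimate after N trials to
  the final estimate (folded to be >= 1), and the information queried on
  trial N.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .audiogram import Audiogram
from .engine import build_prior, likelihood_column
from .estimator import PsychometricSlopeEstimator
from .excitation import EarModelParams, SignalSpec, TEN_BACKGROUND_DB, predict_ptc
from .scales import hz_from_cam

__all__ = [
    "false_alarm_rate",
    "normalize_levels",
    "estimate_slope",
    "SlopeEstimate",
    "diagnostics",
    "DiagnosticsResult",
]


def false_alarm_rate(trials) -> float:
    """Proportion of yes responses on catch trials."""
    catch = [t for t in trials if t.is_catch]
    if not catch:
        raise ValueError("no catch trials in the record")
    return sum(t.y for t in catch) / len(catch)


def normalize_levels(
    trials,
    theta_map: EarModelParams,
    sig: SignalSpec,
    a: Audiogram,
    background_ten_db: float | None = TEN_BACKGROUND_DB,
) -> list[tuple[float, bool]]:
    """Express each inference trial's masker level relative to the
    predicted 50%-point level at its frequency.

    Catch and practice trials are excluded; trials whose frequency has no
    defined tuning-curve point are dropped with a warning.
    """
    usable = [t for t in trials if not (t.is_catch or t.is_practice)]
    freqs = sorted({t.x.f_mask_hz for t in usable})
    levels, inaudible = predict_ptc(theta_map, sig, a, np.array(freqs),
                                    background_ten_db=background_ten_db)
    if inaudible:
        raise ValueError("signal inaudible in quiet under theta_map; "
                         "tuning curve undefined")
    ptc = dict(zip(freqs, levels))
    out = []
    n_dropped = 0
    for t in usable:
        ref = ptc[t.x.f_mask_hz]
        if np.isnan(ref):
            n_dropped += 1
            continue
        out.append((t.x.l_mask_db - ref, t.y))
    if n_dropped:
        warnings.warn(f"{n_dropped} trial(s) dropped: predicted tuning curve "
                      "undefined at their masker frequency", stacklevel=2)
    return out


@dataclass(frozen=True)
class SlopeEstimate:
    sd_db: float
    separable: bool
    n_outliers: int
    n_used: int
    flagged_low_n: bool


def estimate_slope(normalized, **kwargs) -> SlopeEstimate:
    """Psychometric sd (dB) from (relative level, response) pairs.

    Thin wrapper over :class:`PsychometricSlopeEstimator`.
    """
    levels = np.array([v for v, _ in normalized], float)
    y = np.array([r for _, r in normalized], bool)
    est = PsychometricSlopeEstimator(**kwargs).fit(levels[:, None], y)
    return SlopeEstimate(
        sd_db=est.sd_db_,
        separable=est.separable_,
        n_outliers=est.n_outliers_,
        n_used=int(levels.size - est.n_outliers_),
        flagged_low_n=est.flagged_low_n_,
    )


@dataclass(frozen=True)
class DiagnosticsResult:
    n: np.ndarray            # 1..N_inference
    nlp: np.ndarray          # mean negative log predictive probability
    ratio: np.ndarray        # folded f_e(N)/f_e(final) on the Hz scale
    mi_bits: np.ndarray      # queried information (NaN for grid trials)


def diagnostics(
    trials,
    a: Audiogram,
    sig: SignalSpec,
    sd_db: float = 3.0,
    lapse: float = 0.01,
    background_ten_db: float | None = TEN_BACKGROUND_DB,
) -> DiagnosticsResult:
    """Convergence curves, recomputed by exact replay of the trial list.

    nlp(N) is the mean (over all inference trials) negative natural-log
    posterior-predictive probability of the observed response given the
    posterior after the first N trials; ratio(N) folds the f_e estimate
    after N trials against the final one; mi(N) echoes the information
    queried on trial N (defined for actively selected trials only).
    """
    inference = [t for t in trials if not (t.is_catch or t.is_practice)]
    if not inference:
        raise ValueError("no inference trials")
    prior = build_prior(a, sig)
    g = prior.grid
    n_tr = len(inference)

    lik_yes = np.stack(
        [likelihood_column(g, t.x, sig, sd_db=sd_db, lapse=lapse,
                           background_ten_db=background_ten_db)
         for t in inference], axis=1)                       # (m, n_tr)
    lik_obs = np.where([t.y for t in inference], lik_yes, 1.0 - lik_yes)

    cum_log = np.concatenate(
        [np.zeros((g.n_cells, 1)), np.cumsum(np.log(lik_obs), axis=1)], axis=1
    ) + prior.log_prob[:, None]                              # (m, n_tr+1)
    log_z = logsumexp(cum_log, axis=0)
    probs = np.exp(cum_log - log_z)                          # posterior after N

    # posterior predictive of each observed response under each prefix
    pred = probs[:, 1:].T @ lik_obs                          # (n_tr, n_tr)
    nlp = -np.log(pred).mean(axis=1)

    fe_hz = np.empty(n_tr)
    for k in range(n_tr):
        marg = np.zeros(g.fe_cam.size)
        np.add.at(marg, g.cell_fe_idx, probs[:, k + 1])
        fe_hz[k] = hz_from_cam(float(g.fe_cam[int(np.argmax(marg))]))
    r = fe_hz / fe_hz[-1]
    ratio = np.maximum(r, 1.0 / r)

    mi = np.array([np.nan if t.mi_bits is None else t.mi_bits for t in inference])
    return DiagnosticsResult(n=np.arange(1, n_tr + 1), nlp=nlp, ratio=ratio,
                             mi_bits=mi)
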