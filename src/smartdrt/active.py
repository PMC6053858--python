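"""Active-learning session: stimulus selection, scheduling and stopping.

Each trial's masker is chosen from a candidate lattice (0.25-Cam steps
over the eight Cams below the signal, 2-dB level steps over 20-90 dB HL)
with probability proportional to

    I(y*; θ | x*)  *  N(cam(f_mask); f̂_e, 1.5 Cams),

where I is the mutual information between the next response and the model
parameters (the BALD decomposition: predictive binary entropy minus the
expected conditional entropy, at most 1 bit), and the Gaussian factor
keeps maskers near the current edge-frequency estimate.  Candidates
within 2 Cams of the previous trial's masker frequency are excluded to
avoid querying near-duplicate information.

A full session presents 4 practice trials (ignored by inference), a fixed
16-trial familiarisation grid (levels -20, -9, -6, -3, 0, 3, 6, 9 dB re
L_sig at 2 then 4 Cams below f_sig, included in inference), then
information-selected trials, with signal-absent catch trials mixed in at
positions drawn once at session start.

Hit probabilities for every (cell, candidate) pair are precomputed once
per session, so per-trial selection reduces to two matrix-vector products.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.special import ndtr, xlogy

from .audiogram import Audiogram
from .engine import (
    Posterior,
    TrialRecord,
    build_prior,
    likelihood_column,
    map_fe,
    map_theta,
    marginal_fe,
    posterior_entropy_bits,
    update_posterior,
)
from .excitation import (
    SignalSpec,
    Stimulus,
    TEN_BACKGROUND_DB,
    excitation_difference_grid,
)
from .scales import cam_from_hz, hz_from_cam

__all__ = [
    "CandidateGrid",
    "SessionConfig",
    "SessionResult",
    "initial_grid",
    "practice_stimuli",
    "mutual_information",
    "select_next_stimulus",
    "run_session",
    "stopping_check",
]

LEVEL_BOUNDS_DB = (20.0, 90.0)
N_INITIAL_GRID = 16
_INITIAL_REL_LEVELS = (-20.0, -9.0, -6.0, -3.0, 0.0, 3.0, 6.0, 9.0)


@dataclass(frozen=True)
class CandidateGrid:
    """Masker lattice the active learner selects from."""

    f_mask_hz: np.ndarray   # (k,) paired with l_mask_db
    l_mask_db: np.ndarray
    f_mask_cam: np.ndarray

    @classmethod
    def for_signal(
        cls,
        sig: SignalSpec,
        cam_step: float = 0.25,
        span_cam: float = 8.0,
        level_step_db: float = 2.0,
        level_bounds_db: tuple[float, float] = LEVEL_BOUNDS_DB,
    ) -> "CandidateGrid":
        cam_sig = cam_from_hz(sig.f_sig_hz)
        cams = cam_sig - np.arange(0.0, span_cam + cam_step / 2, cam_step)
        cams = np.sort(cams[cams > 0])
        lo, hi = level_bounds_db
        levels = np.arange(lo, hi + level_step_db / 2, level_step_db)
        fc, lc = np.meshgrid(cams, levels, indexing="ij")
        return cls(
            f_mask_hz=hz_from_cam(fc.ravel()),
            l_mask_db=lc.ravel(),
            f_mask_cam=fc.ravel(),
        )

    @property
    def n(self) -> int:
        return int(self.f_mask_hz.size)


@dataclass(frozen=True)
class SessionConfig:
    """Session parameters; defaults follow the standard protocol."""

    n_active_trials: int = 100   # inference trials, incl. the 16-trial grid
    n_catch: int = 20
    n_practice: int = 4
    sd_db: float = 3.0
    lapse: float = 0.01
    weight_sigma_cam: float = 1.5
    exclusion_radius_cam: float = 2.0
    rng_seed: int = 0
    adaptive_sd: bool = False
    sd_floor_db: float = 2.0
    sd_restart_db: float = 20.0
    enable_early_stop: bool = False
    stop_mi_threshold_bits: float = 0.1
    background_ten_db: float = TEN_BACKGROUND_DB

    def __post_init__(self):
        if self.n_catch > self.n_active_trials / 2:
            raise ValueError("n_catch must not exceed n_active_trials / 2")
        if self.sd_db <= 0 or not (0 <= self.lapse < 0.5):
            raise ValueError("invalid sd or lapse")


@dataclass
class SessionResult:
    """Everything a session produced, in presentation order."""

    config: SessionConfig
    trials: list[TrialRecord]
    posterior: Posterior
    fe_map_trace: list[float]            # Cam, one entry per inference trial
    mi_trace: list[float]                # bits, one entry per active trial
    posterior_trace: list[dict]          # per-inference-trial marginal summaries
    final_fe_cam: float = 0.0
    final_fe_hz: float = 0.0
    flags: list[str] = field(default_factory=list)
    sd_trace: list[float] = field(default_factory=list)


def practice_stimuli(sig: SignalSpec) -> list[Stimulus]:
    """Four easy introductory trials: one clearly audible and one clearly
    masked example (masker 3 Cams below the signal), each twice."""
    f = hz_from_cam(cam_from_hz(sig.f_sig_hz) - 3.0)
    lo, hi = LEVEL_BOUNDS_DB
    levels = [sig.l_sig_db - 30.0, sig.l_sig_db + 10.0] * 2
    return [Stimulus(f, float(np.clip(l, lo, hi))) for l in levels]


def initial_grid(sig: SignalSpec) -> list[Stimulus]:
    """The fixed 16-trial familiarisation grid.

    Eight ascending levels (-20 to +9 dB re L_sig) at 2 Cams below f_sig,
    then the same eight at 4 Cams below.  Levels outside [20, 90] dB HL
    are clipped with a warning.
    """
    import warnings

    cam_sig = cam_from_hz(sig.f_sig_hz)
    out = []
    lo, hi = LEVEL_BOUNDS_DB
    for d_cam in (2.0, 4.0):
        f = hz_from_cam(cam_sig - d_cam)
        for rel in _INITIAL_REL_LEVELS:
            level = sig.l_sig_db + rel
            if not (lo <= level <= hi):
                warnings.warn(
                    f"initial-grid level {level:g} dB HL clipped into "
                    f"[{lo:g}, {hi:g}]", stacklevel=2,
                )
                level = float(np.clip(level, lo, hi))
            out.append(Stimulus(f, float(level)))
    return out


def _binary_entropy_bits(p):
    return -(xlogy(p, p) + xlogy(1.0 - p, 1.0 - p)) / math.log(2.0)


def mutual_information_vector(prob: np.ndarray, p_hit: np.ndarray) -> np.ndarray:
    """BALD scores in bits for candidate columns of ``p_hit`` (m, k) under
    cell probabilities ``prob`` (m,)."""
    p_bar = prob @ p_hit
    mi = _binary_entropy_bits(p_bar) - prob @ _binary_entropy_bits(p_hit)
    # roundoff can produce -1e-17 for near-deterministic predictions
    return np.clip(mi, 0.0, None)


def mutual_information(
    p: Posterior,
    x_star: Stimulus,
    sig: SignalSpec,
    a: Audiogram,
    sd_db: float = 3.0,
    lapse: float = 0.01,
    background_ten_db: float | None = TEN_BACKGROUND_DB,
) -> float:
    """Mutual information (bits) between the next response at ``x_star``
    and the model parameters; bounded by 1 bit."""
    lik = likelihood_column(p.grid, x_star, sig, sd_db=sd_db, lapse=lapse,
                            background_ten_db=background_ten_db)
    return float(mutual_information_vector(p.prob, lik[:, None])[0])


class _SessionCache:
    """Per-session precomputation: excitation differences and hit
    probabilities for every (admissible cell, candidate) pair."""

    def __init__(self, posterior: Posterior, cand: CandidateGrid,
                 sig: SignalSpec, sd_db: float, lapse: float,
                 background_ten_db: float):
        g = posterior.grid
        self.cand = cand
        self.lapse = lapse
        self.diff_db = excitation_difference_grid(
            g.cell_fe_hz[:, None], g.cell_ohcl_db[:, None],
            g.cell_hl_fe_db[:, None],
            cand.f_mask_hz[None, :], cand.l_mask_db[None, :], sig,
            background_ten_db=background_ten_db,
        )
        self.set_sd(sd_db)

    def set_sd(self, sd_db: float) -> None:
        self.sd_db = sd_db
        self.p_hit = self.lapse + (1.0 - 2.0 * self.lapse) * ndtr(self.diff_db / sd_db)
        self.hb = _binary_entropy_bits(self.p_hit)

    def mi_all(self, prob: np.ndarray) -> np.ndarray:
        p_bar = prob @ self.p_hit
        return np.clip(_binary_entropy_bits(p_bar) - prob @ self.hb, 0.0, None)


def _selection_weights(mi: np.ndarray, cand: CandidateGrid, fe_hat_cam: float,
                       prev_f_mask_hz: Optional[float], weight_sigma: float,
                       exclusion_radius: float) -> tuple[np.ndarray, bool]:
    w = mi * np.exp(-0.5 * ((cand.f_mask_cam - fe_hat_cam) / weight_sigma) ** 2)
    if prev_f_mask_hz is not None:
        excl = np.abs(cand.f_mask_cam - cam_from_hz(prev_f_mask_hz)) < exclusion_radius
        w = np.where(excl, 0.0, w)
    else:
        excl = np.zeros(cand.n, dtype=bool)
    total = w.sum()
    if total > 0:
        return w / total, False
    # degenerate: fall back to uniform over the non-excluded candidates
    w = (~excl).astype(float)
    if w.sum() == 0:
        raise ValueError("every candidate is excluded; cannot select a stimulus")
    return w / w.sum(), True


def select_next_stimulus(
    p: Posterior,
    cand: CandidateGrid,
    fe_hat_cam: float,
    prev_f_mask_hz: Optional[float],
    rng,
    sig: SignalSpec,
    a: Audiogram,
    sd_db: float = 3.0,
    lapse: float = 0.01,
    background_ten_db: float | None = TEN_BACKGROUND_DB,
    weight_sigma_cam: float = 1.5,
    exclusion_radius_cam: float = 2.0,
    _cache: Optional[_SessionCache] = None,
) -> tuple[Stimulus, float, bool]:
    """Draw the next stimulus ∝ MI x Gaussian f_e weight, excluding
    candidates within the exclusion radius of the previous masker.

    Returns (stimulus, its MI in bits, fallback flag).
    """
    if _cache is not None:
        mi = _cache.mi_all(p.prob)
    else:
        lik = np.stack([
            likelihood_column(p.grid, Stimulus(f, l), sig, sd_db=sd_db,
                              lapse=lapse, background_ten_db=background_ten_db)
            for f, l in zip(cand.f_mask_hz, cand.l_mask_db)
        ], axis=1)
        mi = mutual_information_vector(p.prob, lik)
    weights, fell_back = _selection_weights(
        mi, cand, fe_hat_cam, prev_f_mask_hz, weight_sigma_cam, exclusion_radius_cam
    )
    idx = int(rng.choice(cand.n, p=weights))
    return (
        Stimulus(float(cand.f_mask_hz[idx]), float(cand.l_mask_db[idx])),
        float(mi[idx]),
        fell_back,
    )


def stopping_check(mi_trace, threshold_bits: float) -> bool:
    """Stop once the information queried on the last three trials all fell
    below the threshold (one quiet trial is not enough)."""
    if len(mi_trace) < 3:
        return False
    return all(m < threshold_bits for m in mi_trace[-3:])


class _CountingRNG:
    """numpy Generator wrapper that counts draw calls (for trial logs)."""

    def __init__(self, seed: int):
        self._rng = np.random.default_rng(seed)
        self.calls = 0

    def random(self, *a, **k):
        self.calls += 1
        return self._rng.random(*a, **k)

    def choice(self, *a, **k):
        self.calls += 1
        return self._rng.choice(*a, **k)

    def permutation(self, *a, **k):
        self.calls += 1
        return self._rng.permutation(*a, **k)


def run_session(
    cfg: SessionConfig,
    responder,
    a: Audiogram,
    sig: SignalSpec,
    cand: Optional[CandidateGrid] = None,
) -> SessionResult:
    """Run one complete adaptive session against a responder.

    ``responder`` must expose ``respond(stimulus, sig, is_catch, rng) ->
    bool``.  The session presents ``n_practice`` practice trials (ignored),
    then ``n_active_trials + n_catch`` trials in which the catch positions
    were drawn once up front; the posterior is updated after every
    non-catch trial; the final f_e estimate is the MAP of the last
    posterior.
    """
    rng = _CountingRNG(cfg.rng_seed)
    posterior = build_prior(a, sig)
    if cand is None:
        cand = CandidateGrid.for_signal(sig)
    cache = _SessionCache(posterior, cand, sig, cfg.sd_db, cfg.lapse,
                          cfg.background_ten_db)

    trials: list[TrialRecord] = []
    flags: list[str] = []
    fe_map_trace: list[float] = []
    mi_trace: list[float] = []
    posterior_trace: list[dict] = []
    sd_trace: list[float] = []
    sd_now = cfg.sd_db

    grid_stims = initial_grid(sig)
    index = 0

    for stim in practice_stimuli(sig)[: cfg.n_practice]:
        y = responder.respond(stim, sig, False, rng)
        trials.append(TrialRecord(index=index, x=stim, y=y, is_practice=True,
                                  phase="practice", rng_call_count=rng.calls))
        index += 1

    n_total = cfg.n_active_trials + cfg.n_catch
    catch_positions = set(
        int(i) for i in rng.choice(n_total, size=cfg.n_catch, replace=False)
    )

    prev_stim: Optional[Stimulus] = None
    n_inference = 0
    n_active = 0
    stopped = False

    for pos in range(n_total):
        if pos in catch_positions:
            stim = prev_stim if prev_stim is not None else grid_stims[0]
            y = responder.respond(stim, sig, True, rng)
            trials.append(TrialRecord(index=index, x=stim, y=y, is_catch=True,
                                      phase="active", rng_call_count=rng.calls))
            index += 1
            prev_stim = stim
            continue
        if stopped:
            break
        if n_inference < min(N_INITIAL_GRID, cfg.n_active_trials):
            stim, phase, mi = grid_stims[n_inference], "initial_grid", None
        else:
            fe_hat = map_fe(posterior)
            prev_f = prev_stim.f_mask_hz if prev_stim is not None else None
            mi_all = cache.mi_all(posterior.prob)
            weights, fell_back = _selection_weights(
                mi_all, cand, fe_hat, prev_f,
                cfg.weight_sigma_cam, cfg.exclusion_radius_cam,
            )
            if fell_back:
                flags.append(f"trial {index}: zero selection weights, "
                             "uniform fallback")
            k = int(rng.choice(cand.n, p=weights))
            stim = Stimulus(float(cand.f_mask_hz[k]), float(cand.l_mask_db[k]))
            phase, mi = "active", float(mi_all[k])

        y = responder.respond(stim, sig, False, rng)
        rec = TrialRecord(index=index, x=stim, y=y, phase=phase, mi_bits=mi,
                          rng_call_count=rng.calls)
        posterior = update_posterior(posterior, rec, sig, a, sd_db=sd_now,
                                     lapse=cfg.lapse,
                                     background_ten_db=cfg.background_ten_db)
        fe_now = map_fe(posterior)
        rec = replace(rec, fe_map_cam=fe_now,
                      posterior_entropy_bits=posterior_entropy_bits(posterior))
        trials.append(rec)
        index += 1
        prev_stim = stim
        n_inference += 1
        fe_map_trace.append(fe_now)
        sd_trace.append(sd_now)
        m = marginal_fe(posterior)
        posterior_trace.append({
            "entropy_bits": posterior_entropy_bits(posterior),
            "fe_map_cam": fe_now,
            "fe_ci90_width_cam": _ci_width(posterior.grid.fe_cam, m, 0.90),
        })
        if phase == "active":
            n_active += 1
            mi_trace.append(mi)
            if cfg.adaptive_sd and n_active >= 10 and n_active % 5 == 0:
                est = _adaptive_sd_estimate(trials, posterior, sig, a, cfg)
                if est is not None:
                    if est > cfg.sd_restart_db:
                        if "restart_recommended" not in flags:
                            flags.append("restart_recommended")
                    sd_new = max(cfg.sd_floor_db, min(est, cfg.sd_restart_db))
                    if sd_new != sd_now:
                        sd_now = sd_new
                        cache.set_sd(sd_now)
            if cfg.enable_early_stop and stopping_check(
                mi_trace, cfg.stop_mi_threshold_bits
            ):
                flags.append(f"early_stop_after_{n_inference}_trials")
                stopped = True

    result = SessionResult(
        config=cfg, trials=trials, posterior=posterior,
        fe_map_trace=fe_map_trace, mi_trace=mi_trace,
        posterior_trace=posterior_trace, flags=flags, sd_trace=sd_trace,
    )
    result.final_fe_cam = map_fe(posterior)
    result.final_fe_hz = hz_from_cam(result.final_fe_cam)
    return result


def _ci_width(fe_cam: np.ndarray, marginal: np.ndarray, mass: float) -> float:
    """Width (Cams) of the shortest central credible interval."""
    c = np.cumsum(marginal)
    lo = float(np.interp((1 - mass) / 2, c, fe_cam))
    hi = float(np.interp(1 - (1 - mass) / 2, c, fe_cam))
    return hi - lo


def _adaptive_sd_estimate(trials, posterior, sig, a, cfg):
    """Current psychometric-sd estimate from the normalised trial levels."""
    from .metrics import estimate_slope, normalize_levels
    from .excitation import EarModelParams

    fe_hz, ohcl = map_theta(posterior)
    theta = EarModelParams(fe_hz, ohcl)
    try:
        normalized = normalize_levels(trials, theta, sig, a,
                                      background_ten_db=cfg.background_ten_db)
    except ValueError:
        return None
    if len(normalized) < 10:
        return None
    est = estimate_slope(normalized)
    if est.flagged_low_n:
        return None
    return est.sd_db
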