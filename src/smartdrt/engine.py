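"""Discrete-grid Bayesian inference over θ = (f_e, OHCL(f_e)).

The posterior lives on a rectangular grid with an admissibility mask:
edge-frequency bins at 0.1-Cam spacing spanning the eight Cams below the
signal frequency (clipped to the audiogram's coverage), OHCL bins at
2.5-dB spacing in [0, 65].  The prior is uniform over the admissible cells:

* OHCL(f_e) cannot exceed HL_total(f_e);
* f_e must lie below f_sig (known a priori);
* the 10-dB-SL signal must be audible in quiet under θ, i.e. its
  excitation at f_e must reach HL_total(f_e).

Updates multiply each cell by the detection likelihood of the observed
response and renormalise; accumulation is done in log space so that a long
run of small likelihoods cannot underflow.  Catch trials carry no
masker-model likelihood and leave the posterior unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import logsumexp

from .audiogram import Audiogram
from .excitation import (
    SignalSpec,
    Stimulus,
    TEN_BACKGROUND_DB,
    hit_probability_grid,
    signal_excitation_at_edge,
)
from .scales import cam_from_hz, hz_from_cam

__all__ = [
    "ParameterGrid",
    "Posterior",
    "TrialRecord",
    "build_prior",
    "update_posterior",
    "marginal_fe",
    "map_fe",
    "posterior_entropy_bits",
    "FE_STEP_CAM",
    "OHCL_STEP_DB",
    "OHCL_MAX_DB",
    "FE_SPAN_CAM",
]

FE_STEP_CAM = 0.1
OHCL_STEP_DB = 2.5
OHCL_MAX_DB = 65.0
FE_SPAN_CAM = 8.0


@dataclass(frozen=True)
class ParameterGrid:
    """Discretised θ-space with its admissibility mask.

    ``fe_cam``/``fe_hz`` index the rows, ``ohcl_db`` the columns.  The
    flat arrays (``cell_*``) enumerate admissible cells in row-major order
    and are what the vectorised likelihood operates on.
    """

    fe_cam: np.ndarray          # (nf,)
    fe_hz: np.ndarray           # (nf,)
    ohcl_db: np.ndarray         # (no,)
    support_mask: np.ndarray    # (nf, no) bool
    hl_fe_db: np.ndarray        # (nf,) interpolated HL_total at each fe bin
    cell_fe_idx: np.ndarray = field(repr=False, default=None)
    cell_ohcl_idx: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        rows, cols = np.nonzero(self.support_mask)
        object.__setattr__(self, "cell_fe_idx", rows)
        object.__setattr__(self, "cell_ohcl_idx", cols)

    @property
    def n_cells(self) -> int:
        return int(self.cell_fe_idx.size)

    @property
    def cell_fe_hz(self) -> np.ndarray:
        return self.fe_hz[self.cell_fe_idx]

    @property
    def cell_fe_cam(self) -> np.ndarray:
        return self.fe_cam[self.cell_fe_idx]

    @property
    def cell_ohcl_db(self) -> np.ndarray:
        return self.ohcl_db[self.cell_ohcl_idx]

    @property
    def cell_hl_fe_db(self) -> np.ndarray:
        return self.hl_fe_db[self.cell_fe_idx]


@dataclass(frozen=True)
class Posterior:
    """Probability distribution over admissible grid cells.

    ``log_prob`` is stored unnormalised-safe: it is always renormalised on
    construction, so ``prob`` sums to one within 1e-9.
    """

    grid: ParameterGrid
    log_prob: np.ndarray  # (n_cells,)

    def __post_init__(self):
        lp = np.asarray(self.log_prob, dtype=float)
        if lp.shape != (self.grid.n_cells,):
            raise ValueError("log_prob must have one entry per admissible cell")
        z = logsumexp(lp)
        if not np.isfinite(z):
            raise FloatingPointError(
                "posterior mass vanished (all-zero likelihood product)"
            )
        object.__setattr__(self, "log_prob", lp - z)

    @property
    def prob(self) -> np.ndarray:
        return np.exp(self.log_prob)

    def joint(self) -> np.ndarray:
        """Dense (nf, no) probability array, zero off-support."""
        out = np.zeros(self.grid.support_mask.shape)
        out[self.grid.cell_fe_idx, self.grid.cell_ohcl_idx] = self.prob
        return out


@dataclass(frozen=True)
class TrialRecord:
    """One presented trial: stimulus, response and selection metadata."""

    index: int
    x: Stimulus
    y: bool
    is_catch: bool = False
    is_practice: bool = False
    phase: str = "active"  # practice | initial_grid | active
    mi_bits: Optional[float] = None
    fe_map_cam: Optional[float] = None
    posterior_entropy_bits: Optional[float] = None
    rng_call_count: int = 0


def build_prior(
    a: Audiogram,
    sig: SignalSpec,
    fe_step_cam: float = FE_STEP_CAM,
    ohcl_step_db: float = OHCL_STEP_DB,
    ohcl_max_db: float = OHCL_MAX_DB,
    span_cam: float = FE_SPAN_CAM,
) -> Posterior:
    """Uniform prior over the admissible (f_e, OHCL) cells.

    Raises a ``ValueError`` naming the offending constraint if the support
    comes out empty.
    """
    cam_sig = cam_from_hz(sig.f_sig_hz)
    n_bins = int(round(span_cam / fe_step_cam))
    # bins strictly below f_sig: top bin one step under cam(f_sig)
    fe_cam = cam_sig - fe_step_cam * np.arange(n_bins, 0, -1)
    fe_cam = fe_cam[fe_cam > 0]
    fe_hz = hz_from_cam(fe_cam)
    in_range = (fe_hz >= a.fmin_hz) & (fe_hz <= a.fmax_hz)
    fe_cam, fe_hz = fe_cam[in_range], fe_hz[in_range]
    if fe_cam.size == 0:
        raise ValueError(
            "empty f_e support: audiogram does not cover any frequency "
            f"within {span_cam:g} Cams below f_sig = {sig.f_sig_hz:g} Hz"
        )
    ohcl = np.arange(0.0, ohcl_max_db + ohcl_step_db / 2, ohcl_step_db)
    hl_fe = np.asarray(a.hl_at(fe_hz))

    ohcl_ok = ohcl[None, :] <= hl_fe[:, None] + 1e-9
    audible = np.asarray(signal_excitation_at_edge(fe_hz, sig)) >= hl_fe
    mask = ohcl_ok & audible[:, None]
    if not mask.any():
        parts = []
        if not ohcl_ok.any():
            parts.append("OHCL <= HL_total(f_e)")
        if not audible.any():
            parts.append("signal audible in quiet (E_sig at f_e >= HL_total(f_e))")
        raise ValueError(
            "empty prior support; constraint(s) excluding every cell: "
            + (", ".join(parts) or "joint combination of constraints")
        )
    grid = ParameterGrid(
        fe_cam=fe_cam, fe_hz=fe_hz, ohcl_db=ohcl, support_mask=mask, hl_fe_db=hl_fe
    )
    return Posterior(grid=grid, log_prob=np.zeros(grid.n_cells))


def likelihood_column(
    grid: ParameterGrid,
    x: Stimulus,
    sig: SignalSpec,
    sd_db: float = 3.0,
    lapse: float = 0.01,
    background_ten_db: float | None = TEN_BACKGROUND_DB,
) -> np.ndarray:
    """p(yes | x, θ) for every admissible cell (vectorised)."""
    p = hit_probability_grid(
        grid.cell_fe_hz,
        grid.cell_ohcl_db,
        grid.cell_hl_fe_db,
        np.array([x.f_mask_hz]),
        np.array([x.l_mask_db]),
        sig,
        sd_db=sd_db,
        lapse=lapse,
        background_ten_db=background_ten_db,
    )
    return p[:, 0]


def update_posterior(
    p: Posterior,
    t: TrialRecord,
    sig: SignalSpec,
    a: Audiogram,
    sd_db: float = 3.0,
    lapse: float = 0.01,
    background_ten_db: float | None = TEN_BACKGROUND_DB,
) -> Posterior:
    """One Bayes step: multiply by the trial likelihood and renormalise.

    Catch trials leave the posterior unchanged; practice trials are
    rejected (they are excluded from all inference).  Sequential updates
    over a trial list equal the batch likelihood product followed by a
    single normalisation.
    """
    if t.is_practice:
        raise ValueError("practice trials are excluded from inference")
    if t.is_catch:
        return p
    lik_yes = likelihood_column(p.grid, t.x, sig, sd_db=sd_db, lapse=lapse,
                                background_ten_db=background_ten_db)
    lik = lik_yes if t.y else 1.0 - lik_yes
    return Posterior(grid=p.grid, log_prob=p.log_prob + np.log(lik))


def marginal_fe(p: Posterior) -> np.ndarray:
    """Marginal distribution over the f_e bins (sums to 1)."""
    out = np.zeros(p.grid.fe_cam.size)
    np.add.at(out, p.grid.cell_fe_idx, p.prob)
    return out


def map_fe(p: Posterior) -> float:
    """MAP estimate of f_e in Cams (argmax of the marginal; ties break
    toward the lowest bin)."""
    m = marginal_fe(p)
    return float(p.grid.fe_cam[int(np.argmax(m))])


def map_theta(p: Posterior):
    """Joint MAP (f_e in Hz, OHCL in dB) over the admissible cells."""
    i = int(np.argmax(p.prob))
    return float(p.grid.cell_fe_hz[i]), float(p.grid.cell_ohcl_db[i])


def posterior_entropy_bits(p: Posterior) -> float:
    """Shannon entropy of the joint posterior in bits."""
    pr = p.prob
    nz = pr > 0
    return float(-np.sum(pr[nz] * np.log2(pr[nz])))
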