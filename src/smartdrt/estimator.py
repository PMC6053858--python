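"""scikit-learn-style estimators over the inference core.

:class:`EdgeFrequencyEstimator` fits the grid posterior over
(f_e, OHCL(f_e)) from arrays of trials: ``X`` holds one masker per row
(``f_mask_hz``, ``l_mask_db``) and ``y`` the yes/no responses.  It
composes with sklearn tooling (``get_params``/``set_params``, clone,
``partial_fit`` for trial-by-trial updating) and its posterior predictive
is exposed through ``predict_proba``.

:class:`PsychometricSlopeEstimator` fits a Gaussian-CDF (probit)
psychometric function to responses against masker level relative to the
predicted tuning curve, with iterative 3-sd outlier rejection, and reports
the standard deviation of the fitted CDF — the slope of the listener's
psychometric function in dB.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.special import log_ndtr, ndtr
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .audiogram import Audiogram
from .engine import Posterior, build_prior, map_fe, map_theta, marginal_fe
from .scales import hz_from_cam
from .excitation import SignalSpec, TEN_BACKGROUND_DB, hit_probability_grid

__all__ = ["EdgeFrequencyEstimator", "PsychometricSlopeEstimator"]


class EdgeFrequencyEstimator(BaseEstimator):
    """Grid-Bayes estimator of a dead region's edge frequency.

    Parameters
    ----------
    audiogram : Audiogram
        HL_total(f) for the test ear.
    signal : SignalSpec
        The fixed probe tone (10 dB SL in the standard protocol).
    sd_db : float, default 3.0
        Assumed psychometric-function standard deviation.
    lapse : float, default 0.01
        Floor/ceiling of the detection likelihood.
    background_ten_db : float, default 35.0
        Level (dB HL/ERB_N) of the broadband background noise present in
        every trial.

    Attributes
    ----------
    posterior_ : Posterior
        Joint posterior over the admissible (f_e, OHCL) cells.
    fe_map_cam_, fe_map_hz_ : float
        MAP estimate of the edge frequency.
    ohcl_map_db_ : float
        OHCL at the joint MAP cell.
    n_trials_ : int
        Number of inference trials absorbed so far.
    """

    def __init__(self, audiogram=None, signal=None, sd_db=3.0, lapse=0.01,
                 background_ten_db=TEN_BACKGROUND_DB):
        self.audiogram = audiogram
        self.signal = signal
        self.sd_db = sd_db
        self.lapse = lapse
        self.background_ten_db = background_ten_db

    # -- internals ---------------------------------------------------------

    def _validate(self, X, y=None):
        if not isinstance(self.audiogram, Audiogram):
            raise ValueError("audiogram must be an Audiogram instance")
        if not isinstance(self.signal, SignalSpec):
            raise ValueError("signal must be a SignalSpec instance")
        X = check_array(X, ensure_2d=True)
        if X.shape[1] != 2:
            raise ValueError("X must have two columns: f_mask_hz, l_mask_db")
        if y is None:
            return X, None
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y length mismatch")
        return X, y.astype(bool)

    def _log_lik(self, X, y):
        g = self.posterior_.grid
        p_yes = hit_probability_grid(
            g.cell_fe_hz, g.cell_ohcl_db, g.cell_hl_fe_db,
            X[:, 0], X[:, 1], self.signal,
            sd_db=self.sd_db, lapse=self.lapse,
            background_ten_db=self.background_ten_db,
        )
        lik = np.where(y[None, :], p_yes, 1.0 - p_yes)
        return np.log(lik).sum(axis=1)

    def _set_map(self):
        self.fe_map_cam_ = map_fe(self.posterior_)
        self.fe_map_hz_ = hz_from_cam(self.fe_map_cam_)
        fe_hz, ohcl = map_theta(self.posterior_)
        self.ohcl_map_db_ = ohcl
        self.fe_marginal_ = marginal_fe(self.posterior_)

    # -- sklearn surface ---------------------------------------------------

    def fit(self, X, y):
        """Rebuild the prior and absorb all trials in one batch update."""
        X, y = self._validate(X, y)
        self.posterior_ = build_prior(self.audiogram, self.signal)
        self.posterior_ = Posterior(
            grid=self.posterior_.grid,
            log_prob=self.posterior_.log_prob + self._log_lik(X, y),
        )
        self.n_trials_ = int(X.shape[0])
        self._set_map()
        return self

    def partial_fit(self, X, y):
        """Sequential update: equivalent to refitting on the concatenated
        trials (the likelihood is exchangeable)."""
        X, y = self._validate(X, y)
        if not hasattr(self, "posterior_"):
            self.posterior_ = build_prior(self.audiogram, self.signal)
            self.n_trials_ = 0
        self.posterior_ = Posterior(
            grid=self.posterior_.grid,
            log_prob=self.posterior_.log_prob + self._log_lik(X, y),
        )
        self.n_trials_ += int(X.shape[0])
        self._set_map()
        return self

    def predict_proba(self, X):
        """Posterior-predictive response probabilities, columns
        [P(no), P(yes)]."""
        check_is_fitted(self, "posterior_")
        X, _ = self._validate(X)
        g = self.posterior_.grid
        p_yes = hit_probability_grid(
            g.cell_fe_hz, g.cell_ohcl_db, g.cell_hl_fe_db,
            X[:, 0], X[:, 1], self.signal,
            sd_db=self.sd_db, lapse=self.lapse,
            background_ten_db=self.background_ten_db,
        )
        p = self.posterior_.prob @ p_yes
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        """Most probable response (yes = True) for each stimulus."""
        return self.predict_proba(X)[:, 1] >= 0.5


class PsychometricSlopeEstimator(BaseEstimator):
    """Probit psychometric-function fit with iterative outlier rejection.

    ``X`` is the masker level relative to the predicted tuning curve (dB);
    ``y`` the yes/no response.  The latent model is linear in level with a
    Gaussian-CDF link, fitted by MAP with a weak Gaussian prior on the
    coefficients so that perfectly separated data remain well posed.  Yes
    responses more than ``n_sd_outlier`` current standard deviations above
    the curve and no responses equally far below are discarded and the fit
    repeated until the discarded set stabilises.

    Attributes
    ----------
    sd_db_ : float
        Standard deviation of the fitted Gaussian CDF (dB).  Values above
        ~20 dB indicate responses unrelated to level.
    separable_ : bool
        True when yes and no responses are perfectly separated by level.
    n_outliers_ : int
    n_iterations_ : int
    flagged_low_n_ : bool
        True when fewer than ``min_points`` usable points remained.
    """

    def __init__(self, max_iter=10, init_sd_db=3.0, n_sd_outlier=3.0,
                 prior_scale=100.0, min_points=10):
        self.max_iter = max_iter
        self.init_sd_db = init_sd_db
        self.n_sd_outlier = n_sd_outlier
        self.prior_scale = prior_scale
        self.min_points = min_points

    def _map_probit(self, levels, y):
        """MAP probit fit of P(yes) = Φ(b0 + b1*level); returns (b0, b1)."""
        s = np.where(y, 1.0, -1.0)

        def neg_log_post(beta):
            z = s * (beta[0] + beta[1] * levels)
            nll = -log_ndtr(z).sum()
            return nll + 0.5 * (beta @ beta) / self.prior_scale**2

        def grad(beta):
            z = s * (beta[0] + beta[1] * levels)
            # d/dz log Φ(z) = φ(z)/Φ(z), computed stably in log space
            log_phi = -0.5 * z**2 - 0.5 * np.log(2 * np.pi)
            w = s * np.exp(log_phi - log_ndtr(z))
            g0 = -w.sum()
            g1 = -(w * levels).sum()
            return np.array([g0, g1]) + beta / self.prior_scale**2

        x0 = np.array([0.0, -1.0 / self.init_sd_db])
        res = minimize(neg_log_post, x0, jac=grad, method="BFGS",
                       options={"maxiter": 500, "gtol": 1e-8})
        return res.x

    def fit(self, X, y):
        X = np.asarray(X, float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("X must be a single column of relative levels")
            X = X[:, 0]
        y = np.asarray(y).astype(bool)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        if X.shape[0] < self.min_points:
            raise ValueError(f"need at least {self.min_points} points")

        yes, no = X[y], X[~y]
        self.separable_ = bool(
            yes.size and no.size and yes.max() < no.min()
        ) or not (yes.size and no.size)

        keep = np.ones(X.shape[0], dtype=bool)
        sd = self.init_sd_db
        beta = None
        for it in range(1, self.max_iter + 1):
            out = (y & (X > self.n_sd_outlier * sd)) | (
                (~y) & (X < -self.n_sd_outlier * sd)
            )
            new_keep = ~out
            if beta is not None and np.array_equal(new_keep, keep):
                break
            keep = new_keep
            if keep.sum() < self.min_points:
                break
            beta = self._map_probit(X[keep], y[keep])
            sd = np.inf if beta[1] == 0 else 1.0 / abs(beta[1])
        self.n_iterations_ = it
        self.n_outliers_ = int((~keep).sum())
        self.flagged_low_n_ = bool(keep.sum() < self.min_points)
        if beta is None:  # every iteration fell below min_points
            beta = self._map_probit(X, y)
            sd = np.inf if beta[1] == 0 else 1.0 / abs(beta[1])
        self.coef_ = beta
        self.sd_db_ = float(sd)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, float).ravel()
        p = ndtr(self.coef_[0] + self.coef_[1] * X)
        return np.column_stack([1.0 - p, p])
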