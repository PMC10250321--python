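"""Standard linear solid (SLS) creep model for micropipette aspiration.

A cell aspirated into a pipette of radius Rp under constant pressure ΔP
creeps according to the three-element standard linear solid (treating the
cell as a semi-infinite medium):

    L(t) = (2 Rp ΔP / (π k1)) · [1 + (k1/(k1+k2) − 1) · exp(−t/τ)],
    τ    = μ (k1 + k2) / (k1 k2)

so L jumps instantaneously to L(0) = 2 Rp ΔP / (π (k1+k2)) and relaxes
exponentially to the plateau L_max = 2 Rp ΔP / (π k1). ``k1`` therefore
follows from the plateau alone, and ``k2`` and ``μ`` from the transient.

Two fitting routes are provided: a deterministic plateau/log-linear
procedure (``method="two_point"``) that generalises reading (t, L) point
pairs off the curve into regressions over all points, and a nonlinear
least-squares refinement (``method="nls"``) over log-parameters.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import (
    DegenerateTransientError,
    DomainError,
    InvalidParameterError,
)
from .types import CreepRecord, SLSFit, SLSParams

__all__ = [
    "sls_forward",
    "sls_lmax",
    "sls_time_constant",
    "fit_k1_from_lmax",
    "fit_two_point",
    "fit_nls",
    "SLSCreepModel",
]


def sls_forward(params: SLSParams, delta_p: float, rp: float, times) -> np.ndarray:
    """Aspirated length L(t) of the SLS model, elementwise over ``times``.

    Parameters
    ----------
    params : SLSParams
        Model triplet (k1, k2, mu); all positive.
    delta_p : float
        Aspiration pressure ΔP, Pa; may be 0 (then L ≡ 0).
    rp : float
        Pipette radius, m; > 0.
    times : array-like
        Times, s; all >= 0.

    Returns
    -------
    ndarray
        L(t) in meters, monotonically nondecreasing in t.
    """
    if not isinstance(params, SLSParams):
        params = SLSParams(*params)
    if delta_p < 0:
        raise DomainError(f"delta_p must be >= 0, got {delta_p}")
    if rp <= 0:
        raise InvalidParameterError(f"rp must be > 0, got {rp}")
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise DomainError("times must be >= 0")
    lmax = 2.0 * rp * delta_p / (np.pi * params.k1)
    frac = params.k1 / (params.k1 + params.k2)
    return lmax * (1.0 + (frac - 1.0) * np.exp(-t / params.time_constant))


def sls_lmax(params: SLSParams, delta_p: float, rp: float) -> float:
    """Plateau length L_max = 2 Rp ΔP / (π k1), the t→∞ limit of L(t)."""
    if not isinstance(params, SLSParams):
        params = SLSParams(*params)
    if params.k1 <= 0:
        raise InvalidParameterError(f"k1 must be > 0, got {params.k1}")
    if delta_p < 0:
        raise DomainError(f"delta_p must be >= 0, got {delta_p}")
    if rp <= 0:
        raise InvalidParameterError(f"rp must be > 0, got {rp}")
    return 2.0 * rp * delta_p / (np.pi * params.k1)


def sls_time_constant(params: SLSParams) -> float:
    """Creep time constant τ = μ (k1+k2) / (k1 k2), seconds."""
    if not isinstance(params, SLSParams):
        params = SLSParams(*params)
    return params.time_constant


def fit_k1_from_lmax(l_max: float, delta_p: float, rp: float) -> float:
    """Invert the plateau relation: k1 = 2 Rp ΔP / (π L_max)."""
    if l_max <= 0:
        raise DomainError(f"l_max must be > 0, got {l_max}")
    if delta_p <= 0 or rp <= 0:
        raise DomainError("delta_p and rp must be > 0")
    return 2.0 * rp * delta_p / (np.pi * l_max)


# --------------------------------------------------------------------------
# internal array-level fitters shared by the estimator and the functional API


def _two_point_arrays(
    t: np.ndarray,
    L: np.ndarray,
    delta_p: float,
    rp: float,
    plateau_fraction: float,
    slope_tol: float,
    max_iter: int = 60,
) -> dict:
    """Plateau + log-linear estimate of (k1, k2, mu).

    L_max starts as the mean of the final ``plateau_fraction`` of samples
    and is refined by a fixed point: with the current (C, τ) from a
    log-linear regression of log(L_max − L) on t over the transient,
    L_max ← window mean + C·mean(exp(−t_w/τ)), which removes the bias of
    reading the plateau off a still-relaxing tail. On a noiseless
    exponential the truth is the fixed point, so recovery is exact.
    """
    n = t.size
    w = max(3, int(round(plateau_fraction * n)))
    w = min(w, n - 3)
    window_mean = float(L[-w:].mean())
    # noise floor from the plateau window (residuals about a local line)
    win_res = stats.linregress(t[-w:], L[-w:])
    sigma_hat = float(np.std(L[-w:] - (win_res.intercept + win_res.slope * t[-w:]), ddof=2))
    lmax = window_mean
    tau = np.nan
    C = np.nan
    ok = False
    for _ in range(max_iter):
        gap = lmax - L
        g0 = lmax - L[0]
        flat_tol = max(1e-9 * abs(lmax), 4.0 * sigma_hat)
        if g0 <= flat_tol:
            if g0 >= -flat_tol:
                return {"ok": False, "reason": "no resolvable transient (series flat)",
                        "lmax": lmax, "tau": tau, "C": C}
            raise DegenerateTransientError(
                "first sample lies above the plateau; creep transient is degenerate"
            )
        mask = np.zeros(n, dtype=bool)
        mask[: n - w] = True
        mask &= gap > max(0.02 * g0, 4.0 * sigma_hat)
        if mask.sum() < 3:
            return {"ok": False, "reason": "no resolvable transient (series flat)",
                    "lmax": lmax, "tau": tau, "C": C}
        # log-linear regression; weights ~ gap because sd(log gap) ~ sigma/gap
        slope, intercept = np.polyfit(t[mask], np.log(gap[mask]), 1, w=gap[mask])
        if slope >= 0:
            return {"ok": False, "reason": "transient gap does not decay",
                    "lmax": lmax, "tau": tau, "C": C}
        tau_new = -1.0 / slope
        C_new = float(np.exp(intercept))
        lmax_new = window_mean + C_new * float(np.exp(-t[-w:] / tau_new).mean())
        done = abs(lmax_new - lmax) <= 1e-14 * abs(lmax_new)
        lmax, tau, C = lmax_new, tau_new, C_new
        ok = True
        if done:
            break
    if not ok:
        return {"ok": False, "reason": "fixed point did not start", "lmax": lmax,
                "tau": tau, "C": C}

    l0 = lmax - C
    if l0 <= 0:
        raise DegenerateTransientError(
            f"extrapolated L(0) = {l0:.3e} m is non-positive; transient amplitude "
            "exceeds the plateau"
        )
    k1 = fit_k1_from_lmax(lmax, delta_p, rp)
    ksum = 2.0 * rp * delta_p / (np.pi * l0)
    k2 = ksum - k1
    if k2 <= 0:
        return {"ok": False, "reason": "plateau and L(0) coincide (k2 <= 0)",
                "lmax": lmax, "tau": tau, "C": C}
    mu = tau * k1 * k2 / ksum

    # plateau acceptance: the tail must be flat relative to the transient rate
    res = stats.linregress(t[-w:], L[-w:])
    thresh = max(slope_tol * C / tau, 2.0 * res.stderr if np.isfinite(res.stderr) else 0.0)
    plateaued = abs(res.slope) < thresh or thresh == 0.0
    return {
        "ok": plateaued,
        "reason": "" if plateaued else "no plateau detected (tail still rising)",
        "k1": k1, "k2": k2, "mu": mu, "lmax": lmax, "l0": l0, "tau": tau, "C": C,
    }


def _nls_arrays(
    t: np.ndarray,
    L: np.ndarray,
    delta_p: float,
    rp: float,
    x0: np.ndarray,
    weights: Optional[np.ndarray] = None,
) -> dict:
    """Least squares over log(k1, k2, mu); positivity is built in."""
    scale = max(float(np.max(np.abs(L))), np.finfo(float).tiny)
    w = np.ones_like(L) if weights is None else np.asarray(weights, dtype=float)

    def resid(logp: np.ndarray) -> np.ndarray:
        k1, k2, mu = np.exp(logp)
        model = sls_forward(SLSParams(k1, k2, mu), delta_p, rp, t)
        return w * (model - L) / scale

    res = optimize.least_squares(
        resid, x0, method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=2000
    )
    k1, k2, mu = np.exp(res.x)
    dof = max(t.size - 3, 1)
    s2 = 2.0 * res.cost / dof
    try:
        cov_log = s2 * np.linalg.pinv(res.jac.T @ res.jac)
        cov_diag = np.diag(cov_log) * np.array([k1, k2, mu]) ** 2
    except np.linalg.LinAlgError:  # pragma: no cover - pinv rarely fails
        cov_diag = np.full(3, np.nan)
    return {
        "k1": k1, "k2": k2, "mu": mu,
        "converged": bool(res.success),
        "cov_diag": cov_diag,
        "message": res.message,
    }


def _residual_rms(params: SLSParams, record: CreepRecord) -> float:
    model = sls_forward(params, record.delta_p, record.rp, record.times)
    return float(np.sqrt(np.mean((model - record.lengths) ** 2)))


class SLSCreepModel(BaseEstimator, RegressorMixin):
    """Scikit-learn style estimator for SLS creep curves.

    Fits aspirated length against time for one aspiration experiment.
    The experiment constants ΔP and Rp are data, not hyperparameters, and
    are passed to :meth:`fit`.

    Parameters
    ----------
    method : {"nls", "two_point"}
        "two_point": deterministic plateau + log-linear transient
        regression. "nls": nonlinear least squares over log-parameters,
        initialised from the two-point estimate.
    plateau_fraction : float
        Final fraction of samples averaged for the plateau (default 0.2).
    slope_tol : float
        Plateau acceptance: |tail slope| must be below ``slope_tol`` ×
        (L_max − L(0))/τ (or within 2 SE of zero).
    init : SLSParams or None
        Optional explicit start for "nls"; default is the two-point fit.

    Attributes
    ----------
    k1_, k2_, mu_ : float
        Fitted parameters (Pa, Pa, Pa·s); NaN when not converged.
    params_ : SLSParams or None
    tau_, lmax_ : float
        Derived time constant and plateau length.
    residual_rms_ : float
        RMS misfit in meters.
    converged_ : bool
    covariance_diag_ : ndarray or None
        Per-parameter variance estimates (nls only).

    Examples
    --------
    >>> from cellmech import SLSParams, simulate_creep, SLSCreepModel
    >>> rec = simulate_creep(SLSParams(200, 100, 300))
    >>> m = SLSCreepModel().fit(rec.times, rec.lengths,
    ...                         delta_p=rec.delta_p, rp=rec.rp)
    >>> round(m.k1_)
    200
    """

    def __init__(self, method: str = "nls", plateau_fraction: float = 0.2,
                 slope_tol: float = 0.01, init: Optional[SLSParams] = None):
        self.method = method
        self.plateau_fraction = plateau_fraction
        self.slope_tol = slope_tol
        self.init = init

    def _record_from(self, X, y, delta_p, rp) -> CreepRecord:
        t = np.asarray(X, dtype=float)
        if t.ndim == 2:
            if t.shape[1] != 1:
                raise DomainError("X must be a single time column")
            t = t[:, 0]
        if delta_p is None or rp is None:
            raise DomainError("fit requires delta_p (Pa) and rp (m)")
        return CreepRecord(delta_p=delta_p, rp=rp, times=t,
                           lengths=np.asarray(y, dtype=float))

    def fit(self, X, y, delta_p: Optional[float] = None, rp: Optional[float] = None):
        """Fit to times ``X`` (s) and aspirated lengths ``y`` (m)."""
        if self.method not in ("nls", "two_point"):
            raise InvalidParameterError(f"unknown method {self.method!r}")
        if not 0 < self.plateau_fraction <= 1:
            raise InvalidParameterError("plateau_fraction must lie in (0, 1]")
        record = self._record_from(X, y, delta_p, rp)
        self.delta_p_ = record.delta_p
        self.rp_ = record.rp
        self.covariance_diag_ = None

        tp = _two_point_arrays(record.times, record.lengths, record.delta_p,
                               record.rp, self.plateau_fraction, self.slope_tol)
        tp_params = None
        if "k1" in tp:
            try:
                tp_params = SLSParams(tp["k1"], tp["k2"], tp["mu"])
            except InvalidParameterError:
                tp_params = None

        if self.method == "two_point":
            self.converged_ = bool(tp["ok"]) and tp_params is not None
            self.message_ = tp.get("reason", "")
            self._finish(tp_params, record)
            return self

        # --- nls ---
        if self.init is not None:
            start = self.init
        elif tp_params is not None:
            start = tp_params
        else:  # fallback heuristic when the transient is unresolvable
            lmax0 = max(float(np.max(record.lengths)), np.finfo(float).tiny)
            k1 = fit_k1_from_lmax(lmax0, record.delta_p, record.rp)
            tau0 = max((record.times[-1] - record.times[0]) / 3.0, 1e-6)
            start = SLSParams(k1, k1, tau0 * k1 / 2.0)
        out = _nls_arrays(record.times, record.lengths, record.delta_p, record.rp,
                          np.log(start.as_array()))
        try:
            params = SLSParams(out["k1"], out["k2"], out["mu"])
        except InvalidParameterError:
            params = None
        converged = out["converged"] and params is not None
        # never report a refinement worse than its initialisation
        if params is not None and _residual_rms(params, record) > _residual_rms(start, record):
            params, converged = start, tp is not None and bool(tp.get("ok"))
        self.converged_ = bool(converged)
        self.message_ = out["message"]
        self.covariance_diag_ = out["cov_diag"]
        self._finish(params, record)
        return self

    def _finish(self, params: Optional[SLSParams], record: CreepRecord) -> None:
        self.params_ = params
        if params is None:
            self.k1_ = self.k2_ = self.mu_ = self.tau_ = self.lmax_ = np.nan
            self.residual_rms_ = np.nan
            self.converged_ = False
        else:
            self.k1_, self.k2_, self.mu_ = params.k1, params.k2, params.mu
            self.tau_ = params.time_constant
            self.lmax_ = sls_lmax(params, record.delta_p, record.rp)
            self.residual_rms_ = _residual_rms(params, record)

    def predict(self, X) -> np.ndarray:
        """Model L(t) at times ``X`` using the fitted parameters."""
        t = np.asarray(X, dtype=float)
        if t.ndim == 2:
            t = t[:, 0]
        if self.params_ is None:
            raise InvalidParameterError("model did not converge; no parameters to predict with")
        return sls_forward(self.params_, self.delta_p_, self.rp_, t)

    def to_fit(self) -> SLSFit:
        """Package the fitted state as an :class:`SLSFit` record."""
        return SLSFit(
            params=self.params_,
            residual_rms=self.residual_rms_,
            converged=self.converged_,
            method=self.method,
            covariance_diag=self.covariance_diag_,
            message=getattr(self, "message_", ""),
        )


def fit_two_point(record: CreepRecord, plateau_fraction: float = 0.2) -> SLSFit:
    """Deterministic plateau/log-linear SLS fit of one creep record.

    k1 comes from the plateau (L_max), k1+k2 from the back-extrapolated
    L(0), and μ from the decay rate of log(L_max − L). A record without a
    resolvable plateau returns ``converged=False`` rather than garbage.
    """
    m = SLSCreepModel(method="two_point", plateau_fraction=plateau_fraction)
    m.fit(record.times, record.lengths, delta_p=record.delta_p, rp=record.rp)
    return m.to_fit()


def fit_nls(record: CreepRecord, init: Optional[SLSParams] = None) -> SLSFit:
    """Nonlinear least-squares SLS fit (log-parameterised, positivity built in).

    Initialised from :func:`fit_two_point` unless ``init`` is given; the
    result is never worse (in residual RMS) than its initialisation.
    """
    m = SLSCreepModel(method="nls", init=init)
    m.fit(record.times, record.lengths, delta_p=record.delta_p, rp=record.rp)
    return m.to_fit()
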