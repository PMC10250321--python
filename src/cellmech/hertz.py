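"""Hertz spherical-contact analysis of ferrule-top nanoindentation curves.

A rigid sphere of radius R pressed a depth δ into an elastic half-space
carries the load

    F(δ) = (4/3) · E_r · √R · δ^{3/2}

with E_r the reduced Young's modulus. The pipeline is: reduce raw
(piezo z, cantilever deflection d) recordings to (depth, load) via
F = k·d and δ = z − d; locate the contact point against the pre-contact
force baseline; fit E_r to the loading segment. Because F is linear in
δ^{3/2}, the fit is a closed-form regression through the origin — no
iteration, no starting value.

Young's modulus follows as E = E_r·(1−ν²) for a rigid indenter; the cell
is conventionally taken as incompressible (ν = 0.5).
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import (
    ConfigError,
    DomainError,
    InsufficientDataError,
    InvalidParameterError,
    NoContactError,
)
from .types import HertzFit, IndentationCurve, InstrumentConfig

__all__ = [
    "hertz_force",
    "reduce_raw",
    "detect_contact_point",
    "fit_hertz",
    "aggregate_moduli",
    "young_from_reduced",
    "HertzContactModel",
]


def hertz_force(e_reduced: float, tip_radius: float, depth) -> np.ndarray:
    """Hertz load F = (4/3)·E_r·√R·δ^{3/2} (N); vectorised over ``depth``."""
    if e_reduced < 0:
        raise InvalidParameterError(f"e_reduced must be >= 0, got {e_reduced}")
    if tip_radius < 0:
        raise InvalidParameterError(f"tip_radius must be >= 0, got {tip_radius}")
    d = np.asarray(depth, dtype=float)
    if np.any(d < 0):
        raise DomainError("indentation depth must be >= 0")
    return (4.0 / 3.0) * e_reduced * np.sqrt(tip_radius) * d ** 1.5


def young_from_reduced(e_reduced: float, poisson: float = 0.5) -> float:
    """Young's modulus E = E_r·(1−ν²) for a rigid indenter (default ν=0.5)."""
    return e_reduced * (1.0 - poisson ** 2)


def reduce_raw(curve: IndentationCurve) -> IndentationCurve:
    """Convert a raw (z, d) recording to a reduced (depth-coordinate, load) curve.

    Load is spring_constant × deflection; the tip-advance coordinate is
    z − d. A reduced curve passes through unchanged (with a warning), so
    the reduction is idempotent.
    """
    if curve.mode == "reduced":
        warnings.warn("curve is already reduced; returning it unchanged", stacklevel=2)
        return curve
    k = curve.instrument.spring_constant
    if k is None or k <= 0:  # InstrumentConfig validates, but be explicit
        raise ConfigError("raw-curve reduction requires a positive spring constant")
    return IndentationCurve(
        mode="reduced",
        x=curve.x - curve.y,
        y=k * curve.y,
        instrument=curve.instrument,
        meta=dict(curve.meta),
    )


def detect_contact_point(
    curve: IndentationCurve, min_post: int = 5, min_pre: int = 1
) -> tuple:
    """Locate the contact sample of a reduced curve.

    Every candidate index c splits the curve into a constant baseline
    (samples before c) and a Hertzian branch F = b + a·(x − x_c)^{3/2}
    (samples from c on, a >= 0); the index minimising the total squared
    error wins. The split model is only accepted if it beats the
    all-baseline (no contact) model under BIC, which charges it for its
    two extra parameters — a pure-noise baseline is then rejected rather
    than over-fitted.

    Returns
    -------
    (contact_index, baseline_force) : (int, float)

    Raises
    ------
    NoContactError
        If no candidate split improves on the no-contact model.
    """
    if curve.mode != "reduced":
        raise ConfigError("contact detection requires a reduced curve; call reduce_raw first")
    x, F = curve.x, curve.y
    n = x.size
    sse_flat = float(np.sum((F - F.mean()) ** 2))

    best = (np.inf, -1, 0.0)  # (sse, index, baseline)
    for c in range(min_pre, n - min_post + 1):
        pre = F[:c]
        b = float(pre.mean())
        sse_pre = float(np.sum((pre - b) ** 2))
        s = np.maximum(x[c:] - x[c], 0.0) ** 1.5
        ss = float(s @ s)
        if ss == 0.0:
            continue
        a = float((F[c:] - b) @ s) / ss
        if a <= 0.0:
            continue
        r = F[c:] - b - a * s
        sse = sse_pre + float(r @ r)
        if sse < best[0]:
            best = (sse, c, b)

    sse_best, c_best, b_best = best
    if c_best < 0:
        raise NoContactError("no candidate contact index admits a rising Hertz branch")
    # BIC with unknown noise variance: n·log(SSE/n) + (#params)·log(n)
    tiny = np.finfo(float).tiny
    bic_flat = n * np.log(max(sse_flat, tiny) / n) + 1.0 * np.log(n)
    bic_split = n * np.log(max(sse_best, tiny) / n) + 3.0 * np.log(n)
    if bic_split >= bic_flat:
        raise NoContactError(
            "piecewise baseline+Hertz model does not improve on the no-contact model"
        )
    return c_best, b_best


def _loading_segment_end(x: np.ndarray) -> int:
    """Index one past the deepest point — unloading (retract) is ignored."""
    return int(np.argmax(x)) + 1


class HertzContactModel(BaseEstimator, RegressorMixin):
    """Scikit-learn style estimator for Hertz spherical indentation.

    Fits load (N) against the tip-advance coordinate (m), handling
    contact detection and baseline subtraction internally.

    Parameters
    ----------
    tip_radius : float
        Sphere radius, m (default 9e-6).
    depth_fraction : float
        Fraction of the maximum post-contact depth to fit, in (0, 1];
        default 1.0 fits the whole controlled depth.
    detect_contact : bool
        If False, contact is taken at index 0 with zero baseline.

    Attributes
    ----------
    e_reduced_ : float
        Reduced Young's modulus, Pa.
    contact_index_ : int
    baseline_force_ : float
    residual_rms_ : float
        RMS load misfit over the fitted range, N.
    fit_depth_range_ : tuple of float
        (0, deepest fitted depth), m.
    converged_ : bool
    """

    def __init__(self, tip_radius: float = 9e-6, depth_fraction: float = 1.0,
                 detect_contact: bool = True):
        self.tip_radius = tip_radius
        self.depth_fraction = depth_fraction
        self.detect_contact = detect_contact

    def fit(self, X, y):
        if not 0 < self.depth_fraction <= 1:
            raise InvalidParameterError("depth_fraction must lie in (0, 1]")
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            x = x[:, 0]
        F = np.asarray(y, dtype=float)
        if self.detect_contact:
            curve = IndentationCurve(mode="reduced", x=x, y=F,
                                     instrument=InstrumentConfig(tip_radius=self.tip_radius))
            c, b = detect_contact_point(curve)
        else:
            c, b = 0, 0.0
        self.contact_index_ = int(c)
        self.baseline_force_ = float(b)
        self.x_contact_ = float(x[c])

        end = _loading_segment_end(x)
        depth = x[c:end] - x[c]
        load = F[c:end] - b
        dmax = float(depth.max()) if depth.size else 0.0
        keep = depth <= self.depth_fraction * dmax
        depth, load = depth[keep], load[keep]
        if np.count_nonzero(depth > 0) < 5 or depth.size < 5:
            raise InsufficientDataError(
                f"only {int(np.count_nonzero(depth > 0))} post-contact loading points; need >= 5"
            )
        s = depth ** 1.5
        slope = float(load @ s) / float(s @ s)
        self.e_reduced_ = 0.75 * slope / np.sqrt(self.tip_radius)
        resid = load - slope * s
        self.residual_rms_ = float(np.sqrt(np.mean(resid ** 2)))
        self.fit_depth_range_ = (0.0, float(depth.max()))
        self.converged_ = bool(np.isfinite(self.e_reduced_) and self.e_reduced_ > 0)
        return self

    def predict(self, X) -> np.ndarray:
        """Piecewise model load: baseline before contact, Hertz after."""
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            x = x[:, 0]
        depth = np.maximum(x - self.x_contact_, 0.0)
        return self.baseline_force_ + hertz_force(self.e_reduced_, self.tip_radius, depth)

    def to_fit(self) -> HertzFit:
        return HertzFit(
            e_reduced=self.e_reduced_,
            contact_index=self.contact_index_,
            baseline_force=self.baseline_force_,
            residual_rms=self.residual_rms_,
            converged=self.converged_,
            fit_depth_range=self.fit_depth_range_,
        )


def fit_hertz(
    curve: IndentationCurve,
    depth_fraction: float = 1.0,
    contact: Optional[tuple] = None,
) -> HertzFit:
    """Fit the reduced Young's modulus of one indentation curve.

    Raw curves are reduced first. Contact is detected with
    :func:`detect_contact_point` unless a ``(contact_index,
    baseline_force)`` pair is supplied. The modulus comes from a
    regression of baseline-subtracted load on δ^{3/2} through the origin
    over the loading segment, optionally restricted to depths below
    ``depth_fraction`` of the deepest point.
    """
    if curve.mode == "raw":
        curve = reduce_raw(curve)
    model = HertzContactModel(
        tip_radius=curve.instrument.tip_radius,
        depth_fraction=depth_fraction,
        detect_contact=contact is None,
    )
    if contact is not None:
        # bypass detection but keep the same fitting path
        c, b = contact
        model.detect_contact = False
        x = curve.x[c:]
        y = curve.y[c:] - b
        model.fit(x, y)
        model.contact_index_ += int(c)
        model.baseline_force_ += float(b)
        return model.to_fit()
    model.fit(curve.x, curve.y)
    return model.to_fit()


def aggregate_moduli(
    fits: Sequence[HertzFit], group_labels: Sequence[str]
) -> pd.DataFrame:
    """Per-group summary of fitted moduli: n, mean (Pa), SEM (Pa).

    Non-converged fits are excluded and counted per group; a group with
    no converged fit keeps its row (NaN mean) rather than crashing. Row
    order follows first appearance of each label. Mirrors the usual
    practice of averaging 20–30 single indents per condition.
    """
    if len(fits) != len(group_labels):
        raise DomainError("fits and group_labels must have equal length")
    order = list(dict.fromkeys(group_labels))
    rows = []
    for g in order:
        vals = [f.e_reduced for f, lbl in zip(fits, group_labels)
                if lbl == g and f.converged]
        n_excl = sum(1 for f, lbl in zip(fits, group_labels)
                     if lbl == g and not f.converged)
        n = len(vals)
        mean = float(np.mean(vals)) if n else np.nan
        sem = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        rows.append({"group": g, "n": n, "n_excluded": n_excl,
                     "mean_pa": mean, "sem_pa": sem})
    return pd.DataFrame(rows, columns=["group", "n", "n_excluded", "mean_pa", "sem_pa"])
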