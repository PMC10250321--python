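"""Seeded synthetic-data generators.

Every generator draws from ``numpy.random.default_rng`` seeded through
the spec it receives, so identical specs give bit-identical output, and
writes its ground truth into the returned object's ``meta`` sidecar so
recovery tests can assert against it automatically.

What is emulated — and what is not: creep records are the exact SLS
forward model plus measurement noise (no pressure-application transient,
no pipette-wall friction); indentation curves are a flat zero-load
baseline followed by an exact Hertz loading branch (no adhesion, no
viscoelastic rate dependence); trajectories are biased persistent random
walks (no cell–cell interaction, no channel walls). Parameter-recovery
results on these inputs therefore validate the estimators, not the
instruments.
"""

from __future__ import annotations

import warnings
from typing import Dict, Optional, Sequence

import numpy as np

from .errors import ConfigError, DomainError, InsufficientDataError
from .hertz import hertz_force
from .sls import sls_forward, sls_lmax
from .types import (
    CreepRecord,
    IndentationCurve,
    InstrumentConfig,
    NoiseSpec,
    SLSParams,
    Trajectory,
    WalkSpec,
)

__all__ = [
    "simulate_creep",
    "simulate_indentation",
    "simulate_trajectories",
    "simulate_cohort_mechanics",
]


def _rng_for(noise: Optional[NoiseSpec], rng: Optional[np.random.Generator]):
    if rng is not None:
        return rng
    return np.random.default_rng(noise.seed if noise is not None else 0)


def simulate_creep(
    params: SLSParams,
    delta_p: float = 500.0,
    rp: float = 3.5e-6,
    n_points: int = 200,
    t_max: Optional[float] = None,
    noise: Optional[NoiseSpec] = None,
    rng: Optional[np.random.Generator] = None,
) -> CreepRecord:
    """Aspiration creep record: SLS forward model plus measurement noise.

    Defaults: ΔP = 500 Pa, Rp = 3.5 μm (a ~7 μm pipette), 200 samples
    over 10 time constants. Noise scales on L_max (the signal ceiling).
    Ground truth lands in ``record.meta["true_params"]``.
    """
    if not isinstance(params, SLSParams):
        params = SLSParams(*params)
    if n_points < 4:
        raise InsufficientDataError(f"n_points must be >= 4, got {n_points}")
    tau = params.time_constant
    if t_max is None:
        t_max = 10.0 * tau
    if t_max < 5.0 * tau:
        warnings.warn(
            f"t_max = {t_max:.3g} s covers only {t_max / tau:.1f} time constants; "
            "the plateau may be unresolved (>= 5 recommended)",
            stacklevel=2,
        )
    times = np.linspace(0.0, t_max, n_points)
    clean = sls_forward(params, delta_p, rp, times)
    rng = _rng_for(noise, rng)
    lmax = sls_lmax(params, delta_p, rp)
    lengths = noise.apply(clean, lmax, rng) if noise is not None else clean.copy()
    return CreepRecord(
        delta_p=delta_p,
        rp=rp,
        times=times,
        lengths=lengths,
        meta={
            "true_params": params,
            "noise": noise,
            "t_max": t_max,
        },
    )


def simulate_indentation(
    e_reduced: float,
    instrument: Optional[InstrumentConfig] = None,
    n_points: int = 200,
    baseline_points: int = 50,
    contact_offset: float = 0.5e-6,
    noise: Optional[NoiseSpec] = None,
    rng: Optional[np.random.Generator] = None,
    as_raw: bool = False,
) -> IndentationCurve:
    """Indentation curve: flat zero-load baseline, then a Hertz loading branch.

    The tip-advance coordinate runs from 0 to ``contact_offset +
    max_depth``; contact sits exactly at a sample (index
    ``baseline_points``), with ``baseline_points`` pre-contact samples
    before it. Noise scales on the peak load. With ``as_raw`` the curve
    is emitted as (piezo z, deflection d) so the reduction path is
    exercised: d = F/k, z = position + d.
    """
    if e_reduced <= 0:
        raise DomainError(f"e_reduced must be > 0, got {e_reduced}")
    if contact_offset < 0:
        raise DomainError("contact_offset must be >= 0")
    instrument = instrument or InstrumentConfig()
    n_load = n_points - baseline_points
    if n_load < 6:
        raise ConfigError(
            f"degenerate curve: only {n_load} loading samples after {baseline_points} "
            f"baseline points (contact offset {contact_offset:.2g} m consumes the scan)"
        )
    if baseline_points > 0 and contact_offset <= 0:
        raise ConfigError("baseline_points > 0 requires a positive contact_offset")

    if baseline_points > 0:
        pre = np.linspace(0.0, contact_offset, baseline_points, endpoint=False)
    else:
        pre = np.empty(0)
    post = np.linspace(contact_offset, contact_offset + instrument.max_depth, n_load)
    position = np.concatenate([pre, post])
    depth = np.maximum(position - contact_offset, 0.0)
    clean = hertz_force(e_reduced, instrument.tip_radius, depth)
    rng = _rng_for(noise, rng)
    ceiling = float(clean.max())
    load = noise.apply(clean, ceiling, rng) if noise is not None else clean.copy()
    meta = {
        "e_reduced": e_reduced,
        "contact_offset": contact_offset,
        "contact_index": int(baseline_points),
        "noise": noise,
    }
    if as_raw:
        d = load / instrument.spring_constant
        z = position + d
        return IndentationCurve(mode="raw", x=z, y=d, instrument=instrument, meta=meta)
    return IndentationCurve(mode="reduced", x=position, y=load,
                            instrument=instrument, meta=meta)


def simulate_trajectories(
    n_cells: int,
    spec: WalkSpec,
    rng: Optional[np.random.Generator] = None,
) -> list:
    """Biased persistent random-walk tracks for a cohort of cells.

    Per frame of length ``step_time`` the cell's velocity is

        v_t = f·s·û + (1 − f)·w_t,

    with f = ``drift_fraction``, s = ``speed_scale`` (μm/min, converted
    to μm/s), û the gradient axis, and w_t a stationary AR(1) Gaussian
    velocity with coefficient ``persistence`` whose magnitude (2-D
    Rayleigh) averages s — so f = 1 gives deterministic straight runs
    (directionality exactly 1) and f = 0 an unbiased persistent walk.
    """
    if n_cells < 1:
        raise DomainError("n_cells must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    n_steps = max(1, int(round(spec.duration / spec.step_time)))
    dt = spec.step_time
    speed = spec.speed_scale / 60.0  # μm/s
    # stationary per-component sd so that E|w| = speed for a 2-D Gaussian
    sigma = speed / np.sqrt(np.pi / 2.0)
    rho = spec.persistence
    innov_sd = sigma * np.sqrt(1.0 - rho ** 2)

    w = rng.normal(0.0, sigma, size=(n_cells, 2))  # stationary start
    steps = np.empty((n_steps, n_cells, 2))
    drift = spec.drift_fraction * speed * np.array([1.0, 0.0])
    for i in range(n_steps):
        v = drift + (1.0 - spec.drift_fraction) * w
        steps[i] = v * dt
        w = rho * w + rng.normal(0.0, innov_sd, size=(n_cells, 2))

    times = dt * np.arange(n_steps + 1)
    pos = np.concatenate([np.zeros((1, n_cells, 2)), np.cumsum(steps, axis=0)])
    out = []
    for c in range(n_cells):
        out.append(
            Trajectory(
                cell_id=f"cell{c:04d}",
                times=times,
                xs=pos[:, c, 0],
                ys=pos[:, c, 1],
                gradient_axis=(1.0, 0.0),
            )
        )
    return out


def _lognormal_around(mean: float, cv: float, size, rng) -> np.ndarray:
    """Mean-preserving log-normal draws with coefficient of variation cv."""
    if cv == 0:
        return np.full(size, mean)
    s2 = np.log1p(cv ** 2)
    return rng.lognormal(np.log(mean) - s2 / 2.0, np.sqrt(s2), size=size)


def simulate_cohort_mechanics(
    group_specs: Dict[str, dict],
    seed: int = 0,
    noise: Optional[NoiseSpec] = None,
    **sim_kwargs,
) -> Dict[str, list]:
    """Labeled synthetic measurement sets with per-cell biological variability.

    ``group_specs`` maps a label to either ``{"e_mean": Pa, "cv": float,
    "n": int}`` (indentation cohort) or ``{"params": SLSParams, "cv":
    float, "n": int}`` (aspiration cohort). Per-cell ground truths are
    drawn log-normally around the group mean — moduli are positive with
    heavy right tails, matching the large spreads typical of single-cell
    mechanics — and one curve is generated per cell. Extra keyword
    arguments pass through to the per-curve simulator.

    Randomness is fanned out from ``seed`` via ``SeedSequence.spawn``, so
    group order and sizes fully determine every draw.
    """
    noise = noise if noise is not None else NoiseSpec()
    root = np.random.SeedSequence(seed)
    out: Dict[str, list] = {}
    for label, gspec in group_specs.items():
        n = int(gspec["n"])
        cv = float(gspec.get("cv", 0.0))
        if n < 1:
            raise DomainError(f"group {label!r}: n must be >= 1")
        if cv < 0:
            raise DomainError(f"group {label!r}: cv must be >= 0")
        child = np.random.default_rng(root.spawn(1)[0])
        items = []
        if "e_mean" in gspec:
            truths = _lognormal_around(float(gspec["e_mean"]), cv, n, child)
            for e in truths:
                curve = simulate_indentation(float(e), noise=noise, rng=child, **sim_kwargs)
                curve.meta["group"] = label
                items.append(curve)
        elif "params" in gspec:
            base = gspec["params"]
            if not isinstance(base, SLSParams):
                base = SLSParams(*base)
            trip = np.column_stack([
                _lognormal_around(base.k1, cv, n, child),
                _lognormal_around(base.k2, cv, n, child),
                _lognormal_around(base.mu, cv, n, child),
            ])
            for k1, k2, mu in trip:
                rec = simulate_creep(SLSParams(k1, k2, mu), noise=noise, rng=child,
                                     **sim_kwargs)
                rec.meta["group"] = label
                items.append(rec)
        else:
            raise ConfigError(
                f"group {label!r} must declare 'e_mean' (indentation) or 'params' (creep)"
            )
        out[label] = items
    return out
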