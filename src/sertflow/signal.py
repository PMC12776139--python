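"""Raw fluorescence -> within-session z-score.

The pipeline is detrend (double-exponential photobleaching fit, optional)
followed by within-session z-scoring with the population SD.  Both the
detrended and the literal raw-trace z-score paths are supported because
recordings bleach: leaving the bleach in inflates the session SD and
shrinks every event response.

An optional static control-channel regression (least squares) is provided
for rigs that co-record a serotonin-insensitive fluorophore.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


from .types import PhotometrySession, ValidationError, ZScoredTrace

__all__ = ["detrend", "detrend_array", "zscore", "zscore_session", "downsample", "DetrendResult"]

#: minimum record length (s) for a meaningful bleach fit
MIN_DETREND_SPAN = 60.0


@dataclass
class DetrendResult:
    residual: np.ndarray
    fitted: np.ndarray
    params: dict
    fallback: bool
    residual_norm: float


def detrend_array(t: np.ndarray, F: np.ndarray) -> DetrendResult:
    """Least-squares fit of ``c + a1*exp(-t/tau1) + a2*exp(-t/tau2)``; returns F - fit.

    The fit uses variable projection: only the two time constants are
    optimized (on a log scale, so positivity is automatic) while the offset
    and amplitudes are solved by linear least squares at every step.  If
    the fit fails or returns non-finite values the function falls back to
    a linear detrend and sets ``fallback=True``.
    """
    from scipy.optimize import least_squares

    t = np.asarray(t, dtype=float)
    F = np.asarray(F, dtype=float)
    if t[-1] - t[0] < MIN_DETREND_SPAN:
        raise ValidationError(f"detrend needs >= {MIN_DETREND_SPAN:.0f} s of data")
    span = t[-1] - t[0]
    t0 = t - t[0]

    def design(log_taus: np.ndarray) -> np.ndarray:
        taus = np.exp(log_taus)
        return np.column_stack([np.ones_like(t0), np.exp(-t0 / taus[0]), np.exp(-t0 / taus[1])])

    def solve(log_taus: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        A = design(log_taus)
        coef, *_ = np.linalg.lstsq(A, F, rcond=None)
        return coef, F - A @ coef

    def residual_fn(log_taus: np.ndarray) -> np.ndarray:
        return solve(log_taus)[1]

    try:
        x0 = np.log([span / 5.0, span])
        sol = least_squares(residual_fn, x0, method="trf", max_nfev=200,
                            bounds=(np.log(1e-2), np.log(1e4 * span)))
        coef, residual = solve(sol.x)
        fitted = F - residual
        if not (np.isfinite(fitted).all() and np.isfinite(coef).all()):
            raise RuntimeError("non-finite fit")
        taus = np.exp(sol.x)
        params = {"c": float(coef[0]), "a1": float(coef[1]), "tau1": float(taus[0]),
                  "a2": float(coef[2]), "tau2": float(taus[1])}
        fallback = False
    except (RuntimeError, ValueError, np.linalg.LinAlgError):
        coefs = np.polyfit(t0, F, 1)
        fitted = np.polyval(coefs, t0)
        residual = F - fitted
        params = {"slope": float(coefs[0]), "intercept": float(coefs[1])}
        fallback = True
    return DetrendResult(
        residual=residual,
        fitted=fitted,
        params=params,
        fallback=fallback,
        residual_norm=float(np.linalg.norm(residual)),
    )


def detrend(session: PhotometrySession) -> DetrendResult:
    """Remove the photobleaching trend from a session (see :func:`detrend_array`)."""
    return detrend_array(session.t, session.F)


def zscore(x: np.ndarray) -> np.ndarray:
    """``(x - mean(x)) / SD(x)`` with the population (n-denominator) SD."""
    x = np.asarray(x, dtype=float)
    sd = float(np.std(x))
    if sd == 0:
        raise ValidationError("zero-variance input cannot be z-scored (degenerate session)")
    return (x - float(np.mean(x))) / sd


def _regress_out_control(F: np.ndarray, control: np.ndarray) -> np.ndarray:
    A = np.column_stack([np.ones_like(control), control])
    coef, *_ = np.linalg.lstsq(A, F, rcond=None)
    return F - A @ coef


def zscore_session(
    session: PhotometrySession,
    detrend_first: bool = True,
    control: np.ndarray | None = None,
) -> ZScoredTrace:
    """Full conversion: (optional control regression) -> (optional detrend) -> z-score.

    With ``detrend_first=False`` the raw trace is z-scored directly, i.e.
    the literal "z-scored within session" convention.
    """
    F = session.F
    params: dict = {}
    fallback = False
    if control is not None:
        control = np.asarray(control, dtype=float)
        if len(control) != len(F):
            raise ValidationError("control channel length must match the session")
        F = _regress_out_control(F, control)
        params["control_regressed"] = True
    if detrend_first:
        res = detrend_array(session.t, F)
        F = res.residual
        params.update(res.params)
        fallback = res.fallback
    z = zscore(F)
    return ZScoredTrace(
        t=session.t,
        z=z,
        fs=session.fs,
        source=f"{session.subject_id}/{session.region}/{session.assay_label}/wk{session.week}",
        detrend_params=params if detrend_first or control is not None else None,
        detrend_fallback=fallback,
    )


def downsample(trace: ZScoredTrace, target_fs: float) -> ZScoredTrace:
    """Block-mean decimation to ``target_fs``; timestamps at block centres.

    ``target_fs`` must be positive and not exceed the trace rate.  When
    ``target_fs == fs`` the trace is returned unchanged (a copy).
    """
    if target_fs <= 0:
        raise ValidationError("target_fs must be positive")
    if target_fs > trace.fs * (1 + 1e-9):
        raise ValidationError("target_fs must not exceed the trace sampling rate")
    k = int(round(trace.fs / target_fs))
    if k <= 1:
        return ZScoredTrace(t=trace.t.copy(), z=trace.z.copy(), fs=trace.fs, source=trace.source,
                            detrend_params=trace.detrend_params, detrend_fallback=trace.detrend_fallback)
    n = (len(trace.z) // k) * k
    z2 = trace.z[:n].reshape(-1, k).mean(axis=1)
    t2 = trace.t[:n].reshape(-1, k).mean(axis=1)
    return ZScoredTrace(t=t2, z=z2, fs=trace.fs / k, source=trace.source,
                        detrend_params=trace.detrend_params, detrend_fallback=trace.detrend_fallback)
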