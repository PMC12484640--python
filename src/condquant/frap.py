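"""FRAP recovery normalization and single-exponential fitting.

Normalization follows the standard percent-recovery convention: after
background subtraction, recovery(t) = (I - Imin) / (I0 - Imin) x 100%, where
I0 is the mean pre-bleach intensity and Imin the intensity at the bleach
frame (0 s after bleaching).  The normalized curve is then fit with
R(t) = 100 * M * (1 - exp(-k (t - t_bleach))), giving the mobile fraction M,
the recovery rate k (1/s) and the half-time t1/2 = ln2 / k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .synthetic import FrapTrace

__all__ = ["FrapFit", "normalize_frap", "fit_recovery", "analyze_trace"]

# fitted M below this is treated as an immobile trace: k is unidentifiable
_M_IDENTIFIABILITY_FLOOR = 0.02


@dataclass
class FrapFit:
    """Fit of a normalized FRAP recovery curve."""

    recovery_pct: np.ndarray
    mobile_fraction: float
    rate_k: float  # 1/s
    t_half: float  # ln2 / k, s
    residual_rms: float
    converged: bool
    flags: tuple[str, ...] = ()


def normalize_frap(trace: FrapTrace) -> np.ndarray:
    """Percent-recovery curve (I - Imin)/(I0 - Imin) x 100 after background subtraction.

    The bleach frame maps to exactly 0% and any frame at the pre-bleach mean
    to exactly 100%.  Raises ``ValueError`` when there is no bleach depth
    (I0 == Imin).
    """
    if trace.bleach_index < 1:
        raise ValueError("need at least one pre-bleach frame")
    sub = np.asarray(trace.intensity, dtype=float) - np.asarray(
        trace.background, dtype=float
    )
    i0 = sub[: trace.bleach_index].mean()
    imin = sub[trace.bleach_index]
    if i0 == imin:
        raise ValueError("no bleach depth: I0 equals Imin")
    return 100.0 * (sub - imin) / (i0 - imin)


def _recovery_model(t: np.ndarray, m: float, k: float) -> np.ndarray:
    return 100.0 * m * (1.0 - np.exp(-k * t))


def fit_recovery(recovery_pct: np.ndarray, time_s: np.ndarray,
                 bleach_index: int) -> FrapFit:
    """Least-squares single-exponential fit of the post-bleach recovery.

    Fits R(t) = 100 M (1 - exp(-k (t - t_bleach))) to the samples from the
    bleach frame on; M is bounded to [0, 1.05] to absorb fit/noise overshoot.
    Non-convergence or an unidentifiable rate (immobile trace) is flagged on
    the result rather than raised.
    """
    recovery_pct = np.asarray(recovery_pct, dtype=float)
    time_s = np.asarray(time_s, dtype=float)
    post = recovery_pct[bleach_index:]
    t = time_s[bleach_index:] - time_s[bleach_index]
    if len(post) < 5:
        raise ValueError("need at least 5 post-bleach samples to fit")

    plateau = float(np.mean(post[-max(3, len(post) // 5):]))
    m0 = min(max(plateau / 100.0, 1e-3), 1.05)
    # first time the curve passes half its plateau -> crude k
    above = np.flatnonzero(post >= plateau / 2.0)
    t_half0 = t[above[0]] if len(above) and t[above[0]] > 0 else max(t[-1] / 4, 1e-6)
    k0 = np.log(2.0) / t_half0

    flags: list[str] = []
    try:
        popt, _ = curve_fit(
            _recovery_model, t, post, p0=[m0, k0],
            bounds=([0.0, 1e-9], [1.05, np.inf]), maxfev=10000,
        )
        m_hat, k_hat = float(popt[0]), float(popt[1])
        converged = True
    except RuntimeError:
        m_hat, k_hat = m0, k0
        converged = False
        flags.append("fit_not_converged")

    if m_hat < _M_IDENTIFIABILITY_FLOOR:
        flags.append("rate_unidentifiable")
    residual = post - _recovery_model(t, m_hat, k_hat)
    return FrapFit(
        recovery_pct=recovery_pct,
        mobile_fraction=m_hat,
        rate_k=k_hat,
        t_half=float(np.log(2.0) / k_hat),
        residual_rms=float(np.sqrt(np.mean(residual**2))),
        converged=converged,
        flags=tuple(flags),
    )


def analyze_trace(trace: FrapTrace) -> FrapFit:
    """Normalize then fit a trace in one call."""
    recovery = normalize_frap(trace)
    return fit_recovery(recovery, trace.time_s, trace.bleach_index)
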