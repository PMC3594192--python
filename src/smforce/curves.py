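"""Force-curve analysis: baseline correction, contact-point and rupture detection,
worm-like-chain fitting, and specificity classification.

Conventions
-----------
* Piezo z-displacement increases away from the surface on retract.
* Force is signed as cantilever tension: a stretched tether pulls the tip toward
  the surface and registers as *positive* force; hard-contact repulsion on the
  approach is *negative*.
* Tip–sample separation (tether extension) is ``x = z - z0 - F / k`` where ``z0``
  is the contact point and ``k`` the cantilever spring constant: under tension
  the cantilever bends toward the surface, so the molecule is stretched less
  than the piezo has travelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.optimize import brentq, least_squares

from .constants import ROOM_TEMPERATURE_K, thermal_energy

__all__ = [
    "ForceCurve",
    "RuptureEvent",
    "wlc_force",
    "wlc_extension",
    "correct_baseline",
    "find_contact_point",
    "detect_ruptures",
    "fit_wlc",
    "classify_specificity",
    "analyze_curve",
    "analyze_curves",
]


@dataclass
class ForceCurve:
    """One approach/retract cycle: force (pN) versus piezo z-displacement (nm)."""

    curve_id: str
    z: np.ndarray
    force_approach: np.ndarray
    force_retract: np.ndarray
    retract_velocity: float = 400.0  # nm/s
    dwell_time: float = 0.5  # s
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.force_approach = np.asarray(self.force_approach, dtype=float)
        self.force_retract = np.asarray(self.force_retract, dtype=float)
        if not (len(self.z) == len(self.force_approach) == len(self.force_retract)):
            raise ValueError("z, force_approach and force_retract must have equal length")
        dz = np.diff(self.z)
        if len(dz) and not (np.all(dz > 0) or np.all(dz < 0)):
            raise ValueError("z must be strictly monotone")


@dataclass
class RuptureEvent:
    """One detected unbinding event on a retract curve."""

    curve_id: str
    rupture_force: float  # pN
    rupture_distance: float  # nm, z at rupture minus contact point
    contour_length: float = np.nan  # nm
    persistence_length: float = np.nan  # nm
    fit_residual: float = np.nan  # pN RMS
    specific: bool = False
    multiplicity: int = 1
    index: int = -1  # sample index of the rupture on the retract segment


# ---------------------------------------------------------------------------
# Worm-like chain model
# ---------------------------------------------------------------------------

def wlc_force(x, persistence_length: float, contour_length: float,
              temperature: float = ROOM_TEMPERATURE_K):
    """Marko–Siggia interpolation for the entropic force of a worm-like chain.

    F(x) = (kB*T / Lp) * [ 1 / (4 (1 - x/Lc)^2) - 1/4 + x/Lc ]

    Parameters
    ----------
    x : float or array
        Extension (tip–sample separation), nm. Must satisfy 0 <= x < Lc.
    persistence_length, contour_length : float
        Lp and Lc in nm.

    Returns
    -------
    Force in pN. Strictly increasing in x, diverging as x -> Lc.
    """
    if persistence_length <= 0:
        raise ValueError("persistence length must be positive")
    if contour_length <= 0:
        raise ValueError("contour length must be positive")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x >= contour_length):
        raise ValueError("extension must satisfy 0 <= x < Lc")
    t = x / contour_length
    f = (thermal_energy(temperature) / persistence_length) * (
        0.25 / (1.0 - t) ** 2 - 0.25 + t
    )
    return f if f.shape else float(f)


def wlc_extension(force: float, persistence_length: float, contour_length: float,
                  temperature: float = ROOM_TEMPERATURE_K) -> float:
    """Invert the Marko–Siggia relation: extension at which the chain exerts `force`."""
    if force < 0:
        raise ValueError("force must be non-negative")
    if force == 0:
        return 0.0
    hi = contour_length * (1.0 - 1e-9)

    def g(x):
        return wlc_force(x, persistence_length, contour_length, temperature) - force

    return brentq(g, 0.0, hi, xtol=1e-10 * contour_length)


# ---------------------------------------------------------------------------
# Baseline and contact point
# ---------------------------------------------------------------------------

def _tail_slice(n: int, fraction: float = 0.25) -> slice:
    """Indices of the far-from-surface tail (largest z; arrays are ordered by z)."""
    start = int(np.ceil(n * (1.0 - fraction)))
    return slice(start, n)


def correct_baseline(curve: ForceCurve, tail_fraction: float = 0.25) -> ForceCurve:
    """Remove a linear baseline (tilt + offset) fitted to the far-from-surface tail.

    The fit uses the last `tail_fraction` of samples (largest z), assumed to be
    free of tether stretch; the fitted line is subtracted from the whole segment.
    Both approach and retract are corrected with their own tails.
    """
    n = len(curve.z)
    if n < 20 or int(n * tail_fraction) < 5:
        raise ValueError("retract tail too short for baseline estimation")
    sl = _tail_slice(n, tail_fraction)
    out = {}
    for name in ("force_approach", "force_retract"):
        f = getattr(curve, name)
        coef = np.polyfit(curve.z[sl], f[sl], 1)
        out[name] = f - np.polyval(coef, curve.z)
    return ForceCurve(
        curve_id=curve.curve_id,
        z=curve.z.copy(),
        force_approach=out["force_approach"],
        force_retract=out["force_retract"],
        retract_velocity=curve.retract_velocity,
        dwell_time=curve.dwell_time,
        metadata=dict(curve.metadata),
    )


def estimate_noise_sd(curve: ForceCurve, tail_fraction: float = 0.25) -> float:
    """Robust (MAD-based) noise SD of the retract baseline tail, in pN."""
    sl = _tail_slice(len(curve.z), tail_fraction)
    tail = curve.force_retract[sl]
    resid = tail - np.polyval(np.polyfit(curve.z[sl], tail, 1), curve.z[sl])
    return float(1.4826 * np.median(np.abs(resid - np.median(resid))))


def find_contact_point(curve: ForceCurve, noise_sd: float | None = None,
                       threshold_factor: float = 3.0) -> float:
    """Locate the surface contact point z0 on the approach segment.

    Walking from the free (large-z) end, find where the approach force first
    exceeds `threshold_factor` × noise SD in the repulsive direction, then
    refine z0 as the zero crossing of a line fitted to the contact region.
    """
    f = curve.force_approach
    z = curve.z
    if noise_sd is None:
        noise_sd = estimate_noise_sd(
            ForceCurve(curve.curve_id, z, f, f, metadata=curve.metadata)
        )
    s = uniform_filter1d(f, size=5, mode="nearest")
    thr = max(threshold_factor * noise_sd / np.sqrt(5), 1e-9)
    i_min = int(np.argmin(s))
    depth = -float(s[i_min])
    if depth <= thr:
        raise ValueError("no contact region found on the approach segment")
    # walk outward from the deepest contact until the repulsion has released
    # to a few percent of its depth; starting at the contact side is immune
    # to baseline noise outliers and residual baseline drift
    release = -max(0.05 * depth, thr)
    idx = i_min
    while idx + 1 < len(z) and s[idx + 1] < release:
        idx += 1
    # refine: intersect the contact line with the local free-level baseline
    lo = max(0, idx - 30)
    zc, fc = z[lo:idx + 1], f[lo:idx + 1]
    if len(zc) >= 3:
        coef = np.polyfit(zc, fc, 1)
        free = f[min(idx + 10, len(f) - 1):min(idx + 110, len(f))]
        level = float(np.median(free)) if len(free) else 0.0
        if abs(coef[0]) > 1e-12:
            z0 = (level - coef[1]) / coef[0]
            if z[lo] - 2.0 <= z0 <= z[min(idx + 5, len(z) - 1)] + 2.0:
                return float(z0)
    return float(z[idx])


# ---------------------------------------------------------------------------
# Rupture detection
# ---------------------------------------------------------------------------

def detect_ruptures(curve: ForceCurve, noise_sd: float,
                    drop_factor: float = 5.0,
                    rise_samples: int = 10,
                    max_drop_span: int = 3) -> list[RuptureEvent]:
    """Detect rupture (unbinding) candidates on a baseline-corrected retract.

    An event is a force drop of at least ``drop_factor × noise_sd`` completed
    within ``max_drop_span`` samples, preceded by ``rise_samples`` samples of
    (noise-tolerant) monotonically increasing tension. Candidates within
    ``max_drop_span`` samples of each other are merged (multiplicity counts
    the merged drops). Returned ordered by z with the drop magnitude as the
    provisional rupture force.
    """
    f = curve.force_retract
    z = curve.z
    n = len(f)
    thr = max(drop_factor * noise_sd, 1e-9)
    win = 5
    s = uniform_filter1d(f, size=win, mode="nearest")
    s_sd = noise_sd / np.sqrt(win)

    # the centered smoothing window reaches (win-1)/2 samples past its index,
    # so the rise test ends this far before the candidate to stay uncontaminated
    # by the post-rupture drop
    guard = (win - 1) // 2 + 1
    cands: list[tuple[int, float]] = []
    for i in range(rise_samples + guard, n - max_drop_span):
        drop = f[i] - np.min(f[i + 1:i + 1 + max_drop_span])
        if drop < thr:
            continue
        m = i - guard
        rise = s[m] - s[m - rise_samples]
        if rise < max(2.0 * noise_sd, 1e-9):
            continue
        diffs = np.diff(s[m - rise_samples:m + 1])
        slack = 0.0 if noise_sd == 0 else 1.5 * s_sd
        if np.sum(diffs < -slack) > 2:
            continue
        cands.append((i, drop))
    if not cands:
        return []

    # merge candidates closer than max_drop_span samples; the last candidate
    # of a cluster is the final pre-rupture sample, so it represents the event
    merged: list[tuple[int, float, int]] = []
    cur_i, cur_d, mult = cands[0][0], cands[0][1], 1
    for i, d in cands[1:]:
        if i - cur_i <= max_drop_span:
            cur_i, cur_d = i, d
        else:
            merged.append((cur_i, cur_d, mult))
            cur_i, cur_d, mult = i, d, 1
    merged.append((cur_i, cur_d, mult))

    # advance to the true final rising sample when the rise test rejected it
    # (the drop must still complete within the span after the new index)
    refined: list[tuple[int, float, int]] = []
    for i, d, m in merged:
        while (i + 1 < n - max_drop_span
               and f[i + 1] >= f[i] - max(noise_sd, 1e-12)):
            d_next = f[i + 1] - np.min(f[i + 2:i + 2 + max_drop_span])
            if d_next < thr:
                break
            i, d = i + 1, d_next
        refined.append((i, d, m))

    events = []
    for i, d, m in refined:
        events.append(RuptureEvent(
            curve_id=curve.curve_id,
            rupture_force=float(d),
            rupture_distance=float(z[i]),  # referenced to z0 by analyze_curve
            multiplicity=m,
            index=i,
        ))
    return events


# ---------------------------------------------------------------------------
# WLC fitting
# ---------------------------------------------------------------------------

def fit_wlc(extension: np.ndarray, force: np.ndarray,
            temperature: float = ROOM_TEMPERATURE_K,
            lp_init: float = 0.38,
            max_restarts: int = 3) -> tuple[float, float, float]:
    """Least-squares fit of the Marko–Siggia WLC to a stretch segment.

    Both the persistence length Lp and the contour length Lc are free. The fit
    is restarted from a few contour-length guesses (Lc slightly above, well
    above, and far above the maximal extension); the lowest-residual solution
    wins.

    Returns
    -------
    (Lp, Lc, residual) with residual the RMS misfit in pN.

    Raises
    ------
    RuntimeError if no restart converges.
    """
    extension = np.asarray(extension, dtype=float)
    force = np.asarray(force, dtype=float)
    if len(extension) < 15:
        raise ValueError("need at least 15 points for a WLC fit")
    xmax = float(np.max(extension))
    if xmax <= 0:
        raise ValueError("extensions must be positive")
    kt = thermal_energy(temperature)

    def model(params, x):
        lp, lc = params
        t = np.clip(x / lc, 0.0, 1.0 - 1e-9)
        return (kt / lp) * (0.25 / (1.0 - t) ** 2 - 0.25 + t)

    def resid(params):
        return model(params, extension) - force

    best = None
    for fac in (1.05, 1.3, 2.0)[: max(1, max_restarts)]:
        p0 = np.array([lp_init, xmax * fac])
        try:
            sol = least_squares(
                resid, p0,
                bounds=([1e-3, xmax * 1.0001], [50.0, max(10.0 * xmax, 500.0)]),
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:
            continue
        if not sol.success:
            continue
        rms = float(np.sqrt(np.mean(sol.fun ** 2)))
        if best is None or rms < best[2]:
            best = (float(sol.x[0]), float(sol.x[1]), rms)
    if best is None:
        raise RuntimeError("WLC fit failed to converge")
    return best


# ---------------------------------------------------------------------------
# Specificity
# ---------------------------------------------------------------------------

def classify_specificity(event: RuptureEvent,
                         tether_window: tuple[float, float] = (10.0, 60.0),
                         residual_max: float = 10.0,
                         spring_constant: float | None = None) -> bool:
    """Specific iff the rupture distance lies in the tether-length window
    (default 10–60 nm, the PEG-3400 + peptide scale), the WLC fit residual is
    below `residual_max` (ignored when no fit is available), and the rupture
    extension stays below the fitted contour length.

    The piezo rupture distance includes the cantilever deflection F/k, so the
    contour-length bound is checked on the extension (distance − F/k) when the
    spring constant is known; a chain cannot be stretched past its contour.
    """
    lo, hi = tether_window
    if event.rupture_distance <= 0 or not (lo <= event.rupture_distance <= hi):
        return False
    if np.isfinite(event.fit_residual) and event.fit_residual > residual_max:
        return False
    if np.isfinite(event.contour_length):
        x_rupt = event.rupture_distance
        if spring_constant is not None and spring_constant > 0:
            x_rupt -= event.rupture_force / spring_constant
        if not (0.0 < x_rupt < event.contour_length):
            return False
    return True


# ---------------------------------------------------------------------------
# Per-curve pipeline
# ---------------------------------------------------------------------------

def _wlc_vs_piezo(z_rel: np.ndarray, lp: float, lc: float, k: float,
                  temperature: float, f_cap: float) -> np.ndarray:
    """WLC tension as a function of piezo position (z − z0).

    Solves the load line F = wlc(z_rel − F/k) parametrically: the chain
    extension and the cantilever deflection share the piezo travel. The branch
    is evaluated up to tension ``f_cap`` and extended linearly beyond so the
    model stays smooth for the optimizer.
    """
    x_hi = wlc_extension(f_cap, lp, lc, temperature)
    x_par = np.linspace(0.0, x_hi, 300)
    f_par = wlc_force(x_par, lp, lc, temperature)
    z_par = x_par + f_par / k
    out = np.interp(z_rel, z_par, f_par)
    beyond = z_rel > z_par[-1]
    if np.any(beyond):
        slope = (f_par[-1] - f_par[-2]) / max(z_par[-1] - z_par[-2], 1e-12)
        out[beyond] = f_par[-1] + slope * (z_rel[beyond] - z_par[-1])
    return out


def _fit_wlc_piezo(z_rel: np.ndarray, force: np.ndarray, k: float,
                   temperature: float,
                   lp_init: float = 0.38) -> tuple[float, float, float]:
    """Least-squares WLC fit against piezo position (z − z0).

    Fitting in piezo coordinates keeps measurement noise out of the abscissa
    (the tip–sample-separation correction would otherwise inject the force
    noise into the extension axis and attenuate the fitted stiffness).
    """
    z_rel = np.asarray(z_rel, dtype=float)
    force = np.asarray(force, dtype=float)
    f_cap = float(np.max(force)) * 1.5 + 30.0
    z_max = float(np.max(z_rel))

    def resid(params):
        lp, lc = params
        return _wlc_vs_piezo(z_rel, lp, lc, k, temperature, f_cap) - force

    best = None
    for fac in (1.05, 1.3, 2.0):
        p0 = np.array([lp_init, z_max * fac])
        try:
            sol = least_squares(resid, p0,
                                bounds=([1e-3, 2.0], [50.0, 20.0 * z_max]),
                                xtol=1e-10, ftol=1e-10, gtol=1e-10)
        except Exception:
            continue
        if not sol.success:
            continue
        rms = float(np.sqrt(np.mean(sol.fun ** 2)))
        if best is None or rms < best[2]:
            best = (float(sol.x[0]), float(sol.x[1]), rms)
    if best is None:
        raise RuntimeError("WLC fit failed to converge")
    return best


def _loadline_force(z_rel: float, lp: float, lc: float, k: float,
                    temperature: float) -> float | None:
    """Force where the WLC curve crosses the cantilever load line at piezo
    position ``z_rel`` (= z − z0): solves F = wlc(z_rel − F/k).

    This is the model's prediction of the tension at that piezo position and
    serves as a denoised rupture-force estimate.
    """
    if z_rel <= 0:
        return None

    def g(force):
        x = z_rel - force / k
        if x >= lc:
            return -1e12  # chain would be beyond its contour: tension higher
        if x <= 0:
            return force  # slack chain exerts no tension
        return force - wlc_force(x, lp, lc, temperature)

    hi = max(k * z_rel, 1.0)
    if g(0.0) >= 0 or g(hi) <= 0:
        return None
    try:
        return float(brentq(g, 0.0, hi, xtol=1e-6))
    except ValueError:
        return None

def analyze_curve(curve: ForceCurve,
                  noise_sd: float | None = None,
                  spring_constant: float | None = None,
                  temperature: float = ROOM_TEMPERATURE_K,
                  tether_window: tuple[float, float] = (10.0, 60.0),
                  residual_max: float = 10.0) -> list[RuptureEvent]:
    """Full per-curve analysis: baseline, contact point, rupture detection,
    per-event WLC fit and specificity classification.

    The provisional rupture force (drop magnitude) is refined with the fitted
    WLC model evaluated at the rupture extension whenever the fit converges and
    agrees with the drop estimate; on superposed multi-tether stretches, where
    a single-chain fit is poor, the raw drop magnitude is kept (the drop at one
    tether's rupture equals that tether's force since the others are continuous
    through it).
    """
    if spring_constant is None:
        spring_constant = curve.metadata.get("spring_constant_pN_nm")
    if spring_constant is None:
        raise ValueError("spring constant required (argument or curve metadata)")
    curve = correct_baseline(curve)
    if noise_sd is None:
        noise_sd = estimate_noise_sd(curve)
    z0 = find_contact_point(curve, noise_sd=max(noise_sd, 1e-6))
    events = detect_ruptures(curve, noise_sd)
    z = curve.z
    f = curve.force_retract
    prev_idx = int(np.searchsorted(z, z0))
    for ev in events:
        i = ev.index
        ev.rupture_distance = float(z[i] - z0)
        lo = max(prev_idx + 2, 0)
        z_seg = z[lo:i + 1] - z0
        f_seg = f[lo:i + 1]
        keep = z_seg > 0.2
        z_seg, f_seg = z_seg[keep], f_seg[keep]
        if len(z_seg) >= 15:
            try:
                lp, lc, rms = _fit_wlc_piezo(z_seg, f_seg, spring_constant,
                                             temperature)
                ev.persistence_length = lp
                ev.contour_length = lc
                ev.fit_residual = rms
                f_fit = _loadline_force(z[i] - z0, lp, lc, spring_constant,
                                        temperature)
                tol = 5.0 * max(noise_sd, 1.0)
                if f_fit is not None and abs(f_fit - ev.rupture_force) <= tol:
                    ev.rupture_force = float(f_fit)
            except (RuntimeError, ValueError):
                pass
        ev.specific = classify_specificity(ev, tether_window, residual_max,
                                           spring_constant=spring_constant)
        prev_idx = i
    return events


def analyze_curves(curves: Sequence[ForceCurve], **kwargs) -> list[RuptureEvent]:
    """analyze_curve over a batch; curves that fail (no contact, too short)
    contribute no events."""
    out: list[RuptureEvent] = []
    for c in curves:
        try:
            out.extend(analyze_curve(c, **kwargs))
        except ValueError:
            continue
    return out
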