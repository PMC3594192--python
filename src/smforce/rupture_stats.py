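"""Rupture-force statistics.

The statistical core of the analysis: experimental yield, the Poisson
multiple-tether correction (discarding the p×n highest forces), the binned
two-Gaussian Levenberg–Marquardt histogram fit, effective-counts standard
errors, condition summaries and the control-vs-treated comparison.

Standard errors of the fitted peak positions follow the effective-counts
estimator: SE_i = sigma_i / sqrt(N_eff,i) with N_eff,i = N × (area fraction of
component i), where N is the total number of retained events.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

__all__ = [
    "MixtureFit",
    "TetherCorrection",
    "ConditionSummary",
    "compute_yield",
    "multi_tether_probability",
    "discard_highest",
    "fit_double_gaussian",
    "fit_double_gaussian_histogram",
    "effective_counts_se",
    "summarize_condition",
    "compare_conditions",
    "plot_histogram_fit",
]


@dataclass
class MixtureFit:
    """Two-Gaussian fit to a binned rupture-force histogram.

    Amplitudes A1/A2 are in counts; means and SDs in pN. Components are
    ordered by mean. Area fractions are A_i*sigma_i normalized to one.
    """

    A1: float
    mu1: float
    sigma1: float
    A2: float
    mu2: float
    sigma2: float
    area_fraction1: float
    area_fraction2: float
    N: int
    bin_width: float
    residual: float  # RMS misfit, counts
    Neff1: float = np.nan
    Neff2: float = np.nan
    SE1: float = np.nan
    SE2: float = np.nan
    degenerate: bool = False
    bin_centers: np.ndarray = field(default=None, repr=False)
    counts: np.ndarray = field(default=None, repr=False)


@dataclass
class TetherCorrection:
    """Yield and Poisson multiple-tether correction bookkeeping."""

    n_curves: int
    n_specific: int
    yield_percent: float
    lam: float
    p_multi: float
    n_discarded: int


@dataclass
class ConditionSummary:
    """One Table-shaped row: fitted peaks ± SE, mean retained force, yield."""

    label: str
    mu1: float
    se1: float
    mu2: float
    se2: float
    mean_force: float
    yield_percent: float
    area_fraction1: float
    n_events: int
    fit: MixtureFit = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# Yield and multiple-tether correction
# ---------------------------------------------------------------------------

def compute_yield(n_curves: int, n_specific: int) -> float:
    """Experimental yield in percent: 100 × n_specific / n_curves."""
    if n_curves == 0:
        raise ValueError("n_curves must be positive")
    if n_specific > n_curves:
        raise ValueError("n_specific cannot exceed n_curves")
    return 100.0 * n_specific / n_curves


def multi_tether_probability(yield_fraction: float) -> tuple[float, float]:
    """Probability that >=2 tethers rupture in a curve that shows any event.

    Under Poisson attachment with rate lambda per approach, the observed yield
    is 1 - e^{-lambda}, so lambda = -ln(1 - yield). Conditional on at least
    one attachment,

        p_multi = [1 - e^{-lambda} (1 + lambda)] / (1 - e^{-lambda}).

    Returns (lambda, p_multi). p_multi -> 0 (as lambda/2) for small yields and
    is strictly increasing in the yield.
    """
    if not 0.0 <= yield_fraction < 1.0:
        raise ValueError("yield fraction must lie in [0, 1)")
    if yield_fraction == 0.0:
        return 0.0, 0.0
    lam = -math.log1p(-yield_fraction)
    p_multi = (1.0 - math.exp(-lam) * (1.0 + lam)) / (1.0 - math.exp(-lam))
    return lam, p_multi


def discard_highest(forces: np.ndarray, p_multi: float) -> np.ndarray:
    """Drop the floor(p_multi × n) largest forces (possible simultaneous
    double ruptures); the retained values keep their original order."""
    forces = np.asarray(forces, dtype=float)
    n = len(forces)
    if n == 0:
        raise ValueError("forces must be non-empty")
    m = int(math.floor(p_multi * n))
    if m <= 0:
        return forces.copy()
    # stable: among ties the later occurrences are dropped first is avoided by
    # kind='stable' argsort on the negated values
    order = np.argsort(-forces, kind="stable")
    drop = np.zeros(n, dtype=bool)
    drop[order[:m]] = True
    return forces[~drop]


def tether_correction(n_curves: int, n_specific: int) -> TetherCorrection:
    """Bundle yield, Poisson rate, p_multi and the discard count."""
    y = compute_yield(n_curves, n_specific)
    lam, p = multi_tether_probability(y / 100.0)
    return TetherCorrection(
        n_curves=n_curves,
        n_specific=n_specific,
        yield_percent=y,
        lam=lam,
        p_multi=p,
        n_discarded=int(math.floor(p * n_specific)),
    )


# ---------------------------------------------------------------------------
# Double-Gaussian histogram fit
# ---------------------------------------------------------------------------

def _double_gauss(c, a1, m1, s1, a2, m2, s2):
    return (a1 * np.exp(-0.5 * ((c - m1) / s1) ** 2)
            + a2 * np.exp(-0.5 * ((c - m2) / s2) ** 2))


def _quantile_inits(centers: np.ndarray, counts: np.ndarray) -> list:
    cdf = np.cumsum(counts) / max(np.sum(counts), 1)
    m1 = centers[np.searchsorted(cdf, 0.25)]
    m2 = centers[min(np.searchsorted(cdf, 0.75), len(centers) - 1)]
    amp = max(np.max(counts), 1.0)
    return [(amp, m1), (amp, m2)]


def _initial_guesses(centers: np.ndarray, counts: np.ndarray) -> tuple[list, bool]:
    """Initial (A, mu) pairs from the two most separated histogram modes.

    Mode finding runs on lightly smoothed counts (3-bin moving average) so a
    single noisy bin does not masquerade as a peak; quartile positions serve
    as the fallback when fewer than two modes survive.
    """
    s = np.convolve(counts, np.ones(3) / 3.0, mode="same")
    modes = []
    for i in range(1, len(s) - 1):
        if s[i] >= s[i - 1] and s[i] >= s[i + 1] and counts[i] > 0:
            modes.append((s[i], centers[i]))
    if len(s) >= 2 and s[0] > s[1] and counts[0] > 0:
        modes.append((s[0], centers[0]))
    if len(s) >= 2 and s[-1] > s[-2] and counts[-1] > 0:
        modes.append((s[-1], centers[-1]))
    # keep the four strongest, require meaningful support
    modes.sort(reverse=True)
    modes = [m for m in modes[:4] if m[0] >= 0.1 * modes[0][0]]
    if len(modes) < 2:
        return _quantile_inits(centers, counts), True
    best = max(
        ((a, b) for i, a in enumerate(modes) for b in modes[i + 1:]),
        key=lambda pair: abs(pair[0][1] - pair[1][1]),
    )
    (a1, m1), (a2, m2) = sorted(best, key=lambda t: t[1])
    return [(a1, m1), (a2, m2)], False


def fit_double_gaussian(forces: np.ndarray, bin_width: float = 10.0,
                        n_restarts: int = 5, restart_seed: int = 12345,
                        weighted: bool = True) -> MixtureFit:
    """Fit a sum of two Gaussians to the binned rupture-force histogram.

    The histogram (default 10 pN bins) is fitted by Levenberg–Marquardt
    least squares on the bin counts, restarted from perturbed mode-pair
    guesses (fixed sub-seed); the best sane solution wins and components are
    reported ordered by mean. Poisson (sqrt-count) weights are applied by
    default — the natural error model for bin counts, and in practice the
    safeguard that keeps a sparse high-force tail from being absorbed into
    one overly wide component; ``weighted=False`` gives plain least squares.

    Raises RuntimeError when no restart converges. A histogram without two
    resolvable modes is fitted anyway but flagged ``degenerate``.
    """
    forces = np.asarray(forces, dtype=float)
    n = len(forces)
    if n < 40:
        raise ValueError("need at least 40 forces for a two-component fit")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    lo = math.floor(np.min(forces) / bin_width) * bin_width
    hi = math.ceil(np.max(forces) / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    if len(edges) < 5:
        edges = np.linspace(lo, hi, 5)
    counts, edges = np.histogram(forces, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return fit_double_gaussian_histogram(
        centers, counts, bin_width=bin_width, n_restarts=n_restarts,
        restart_seed=restart_seed, weighted=weighted, n_total=n)


def fit_double_gaussian_histogram(bin_centers: np.ndarray, counts: np.ndarray,
                                  bin_width: float | None = None,
                                  n_restarts: int = 5,
                                  restart_seed: int = 12345,
                                  weighted: bool = True,
                                  n_total: int | None = None) -> MixtureFit:
    """Two-Gaussian Levenberg–Marquardt fit to pre-binned histogram counts.

    Effective counts use ``n_total`` (the number of underlying events) when
    given, otherwise the summed counts.
    """
    centers = np.asarray(bin_centers, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if len(centers) != len(counts) or len(centers) < 5:
        raise ValueError("need matching center/count arrays with >= 5 bins")
    if bin_width is None:
        bin_width = float(np.median(np.diff(centers)))
    n = int(n_total) if n_total is not None else int(np.sum(counts))
    lo = float(centers[0] - bin_width / 2)
    hi = float(centers[-1] + bin_width / 2)

    (g1, g2), degenerate = _initial_guesses(centers, counts)
    span = max(hi - lo, bin_width)
    s0 = span / 8.0
    rng = np.random.default_rng(restart_seed)
    sigma_w = None
    if weighted:
        sigma_w = np.sqrt(np.clip(counts, 1, None))

    def is_valid(popt):
        """Sanity screen: positive amplitudes, widths between a third of a
        bin and half the data span, means inside the data range, and
        resolvably separated components."""
        a1, m1, s1, a2, m2, s2 = popt
        s1, s2 = abs(s1), abs(s2)
        if a1 <= 0 or a2 <= 0:
            return False
        if not (bin_width / 3 <= s1 <= span / 2 and bin_width / 3 <= s2 <= span / 2):
            return False
        if not (lo - bin_width <= m1 <= hi + bin_width
                and lo - bin_width <= m2 <= hi + bin_width):
            return False
        if abs(m2 - m1) < 1.5 * bin_width:
            return False
        frac1 = a1 * s1 / (a1 * s1 + a2 * s2)
        return 0.05 <= frac1 <= 0.95  # a ~zero-area component is single-mode

    starts = [
        [g1[0], g1[1], s0, g2[0], g2[1], s0],
    ]
    q1, q2 = _quantile_inits(centers, counts)
    starts.append([q1[0], q1[1], s0, q2[0], q2[1], s0])
    for _ in range(max(0, n_restarts - len(starts))):
        starts.append([
            g1[0] * rng.uniform(0.5, 1.5),
            g1[1] + rng.normal(0, bin_width),
            s0 * rng.uniform(0.6, 1.6),
            g2[0] * rng.uniform(0.5, 1.5),
            g2[1] + rng.normal(0, bin_width),
            s0 * rng.uniform(0.6, 1.6),
        ])

    best = None  # best valid solution
    best_any = None  # best solution ignoring the sanity screen
    for p0 in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", OptimizeWarning)
                popt, _ = curve_fit(_double_gauss, centers, counts, p0=p0,
                                    sigma=sigma_w, method="lm", maxfev=20000)
        except RuntimeError:
            continue
        if not np.isfinite(popt).all():
            continue
        resid = _double_gauss(centers, *popt) - counts
        if sigma_w is not None:
            score = float(np.sum((resid / sigma_w) ** 2))
        else:
            score = float(np.sum(resid ** 2))
        entry = (popt, score, float(np.sqrt(np.mean(resid ** 2))))
        if best_any is None or score < best_any[1]:
            best_any = entry
        if is_valid(popt) and (best is None or score < best[1]):
            best = entry
    if best is None:
        # rescue: bounded trust-region fit confined to the sane region
        from scipy.optimize import least_squares

        amp_hi = 3.0 * max(float(np.max(counts)), 1.0)
        lb = [1e-6, lo, bin_width / 3, 1e-6, lo, bin_width / 3]
        ub = [amp_hi, hi, span / 2, amp_hi, hi, span / 2]

        def resid_fn(p):
            r = _double_gauss(centers, *p) - counts
            return r / sigma_w if sigma_w is not None else r

        for p0 in starts:
            p0c = np.clip(p0, lb, ub)
            try:
                sol = least_squares(resid_fn, p0c, bounds=(lb, ub),
                                    xtol=1e-10, ftol=1e-10)
            except Exception:
                continue
            if not sol.success or not np.isfinite(sol.x).all():
                continue
            resid = _double_gauss(centers, *sol.x) - counts
            score = float(np.sum(resid ** 2)) if sigma_w is None else \
                float(np.sum((resid / sigma_w) ** 2))
            entry = (sol.x, score, float(np.sqrt(np.mean(resid ** 2))))
            if is_valid(sol.x) and (best is None or score < best[1]):
                best = entry
            if best_any is None or score < best_any[1]:
                best_any = entry

    if best is None:
        # nothing separable anywhere: fall back, flagged degenerate
        best = best_any
        degenerate = True
    if best is None:
        raise RuntimeError("double-Gaussian fit failed to converge")

    a1, m1, s1, a2, m2, s2 = best[0]
    s1, s2 = abs(s1), abs(s2)
    comp = sorted([(m1, a1, s1), (m2, a2, s2)])  # order by mean
    (m1, a1, s1), (m2, a2, s2) = comp
    area1, area2 = a1 * s1, a2 * s2
    tot = area1 + area2
    if tot <= 0:
        raise RuntimeError("degenerate fit: non-positive total area")
    fit = MixtureFit(
        A1=float(a1), mu1=float(m1), sigma1=float(s1),
        A2=float(a2), mu2=float(m2), sigma2=float(s2),
        area_fraction1=float(area1 / tot), area_fraction2=float(area2 / tot),
        N=n, bin_width=float(bin_width), residual=best[2],
        degenerate=degenerate,
        bin_centers=centers, counts=counts,
    )
    fit.Neff1, fit.SE1, fit.Neff2, fit.SE2 = _effective_counts(fit, n)
    return fit


def _effective_counts(fit: MixtureFit, n_total: int):
    ne1 = n_total * fit.area_fraction1
    ne2 = n_total * fit.area_fraction2
    se1 = fit.sigma1 / math.sqrt(ne1) if ne1 > 0 else np.nan
    se2 = fit.sigma2 / math.sqrt(ne2) if ne2 > 0 else np.nan
    return ne1, se1, ne2, se2


def effective_counts_se(fit: MixtureFit, n_total: int
                        ) -> tuple[float, float, float, float]:
    """Effective counts and standard errors: Neff_i = N × area_fraction_i,
    SE_i = sigma_i / sqrt(Neff_i)."""
    if n_total <= 0:
        raise ValueError("N must be positive")
    if fit.area_fraction1 <= 0 or fit.area_fraction2 <= 0:
        raise ValueError("zero area fraction: SE undefined for that component")
    ne1, se1, ne2, se2 = _effective_counts(fit, n_total)
    return ne1, se1, ne2, se2


# ---------------------------------------------------------------------------
# Summaries and comparison
# ---------------------------------------------------------------------------

def summarize_condition(forces: np.ndarray, fit: MixtureFit,
                        yield_percent: float = np.nan,
                        label: str = "") -> ConditionSummary:
    """Table-shaped row: fitted peaks ± SE, arithmetic mean of the retained
    forces (computed after the multiple-tether discard), and yield."""
    forces = np.asarray(forces, dtype=float)
    return ConditionSummary(
        label=label,
        mu1=fit.mu1, se1=fit.SE1,
        mu2=fit.mu2, se2=fit.SE2,
        mean_force=float(np.mean(forces)),
        yield_percent=float(yield_percent),
        area_fraction1=fit.area_fraction1,
        n_events=len(forces),
        fit=fit,
    )


def compare_conditions(control: ConditionSummary,
                       treated: ConditionSummary) -> dict:
    """Peak shifts and area-fraction shift, treated − control, with standard
    errors propagated in quadrature."""
    se_frac = lambda s: (math.sqrt(s.area_fraction1 * (1 - s.area_fraction1)
                                   / s.n_events) if s.n_events else np.nan)
    return {
        "delta_mu1_pN": treated.mu1 - control.mu1,
        "delta_mu1_se_pN": math.hypot(control.se1, treated.se1),
        "delta_mu2_pN": treated.mu2 - control.mu2,
        "delta_mu2_se_pN": math.hypot(control.se2, treated.se2),
        "delta_area_fraction1": treated.area_fraction1 - control.area_fraction1,
        "delta_area_fraction1_se": math.hypot(se_frac(control), se_frac(treated)),
        "delta_mean_force_pN": treated.mean_force - control.mean_force,
    }


def plot_histogram_fit(fit: MixtureFit, path, title: str = "") -> None:
    """Save the binned histogram with the fitted two-Gaussian overlay."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.bar(fit.bin_centers, fit.counts, width=fit.bin_width * 0.9,
           color="0.7", label="events")
    grid = np.linspace(fit.bin_centers[0], fit.bin_centers[-1], 400)
    ax.plot(grid, _double_gauss(grid, fit.A1, fit.mu1, fit.sigma1,
                                fit.A2, fit.mu2, fit.sigma2),
            "k-", label="two-Gaussian fit")
    ax.axvline(fit.mu1, color="C0", ls="--", lw=1)
    ax.axvline(fit.mu2, color="C3", ls="--", lw=1)
    ax.set_xlabel("rupture force (pN)")
    ax.set_ylabel("count")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
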