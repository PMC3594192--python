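"""Synthetic-data generators with known ground truth.

Emulates the three kinds of raw data the analysis pipeline consumes, so that
every downstream stage can be validated by recovery:

* force–distance cycles with PEG-tether worm-like-chain stretch signatures and
  Poisson-distributed multiple-tether attachment;
* thermal deflection series for cantilever spring-constant calibration
  (equipartition: Var = kB·T / k);
* AFM topographs containing spherical-cap oligomers, half-cylinder fibril
  ridges and irregular amorphous blobs on a tilted, noisy background.

Rupture forces are drawn from a two-component Gaussian mixture. The bundled
``CONTROL_MIXTURE`` and ``COPPER_MIXTURE`` place the component means at
66/132 pN and 83/164 pN respectively; the weights and widths are fixture
constants chosen to produce overlapping two-peak histograms, not measured
truths (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import ROOM_TEMPERATURE_K, thermal_energy
from .curves import ForceCurve, wlc_extension, wlc_force

__all__ = [
    "MixtureParams",
    "SimulationConfig",
    "GroundTruth",
    "CurveTruth",
    "CONTROL_MIXTURE",
    "COPPER_MIXTURE",
    "UnattainableRuptureError",
    "simulate_rupture_forces",
    "simulate_force_curve",
    "simulate_experiment",
    "simulate_thermal_spectrum",
    "FeatureSpec",
    "simulate_topograph",
    "fig_timecourse_features",
]


@dataclass(frozen=True)
class MixtureParams:
    """Two-component Gaussian rupture-force mixture (pN); components ordered
    by mean, weights sum to one."""

    w1: float
    mu1: float
    sigma1: float
    mu2: float
    sigma2: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.w1 <= 1.0:
            raise ValueError("mixture weight must lie in [0, 1]")
        if self.sigma1 < 0 or self.sigma2 < 0:
            raise ValueError("mixture SDs must be non-negative")
        if self.mu2 <= self.mu1:
            raise ValueError("components must be ordered: mu2 > mu1")

    @property
    def w2(self) -> float:
        return 1.0 - self.w1

    @property
    def mean(self) -> float:
        return self.w1 * self.mu1 + self.w2 * self.mu2

    @property
    def variance(self) -> float:
        m = self.mean
        return (self.w1 * (self.sigma1 ** 2 + (self.mu1 - m) ** 2)
                + self.w2 * (self.sigma2 ** 2 + (self.mu2 - m) ** 2))


#: Control condition: peaks at 66 and 132 pN, equal weights (fixture choice).
CONTROL_MIXTURE = MixtureParams(w1=0.5, mu1=66.0, sigma1=20.0, mu2=132.0, sigma2=30.0)
#: Cu2+ condition: peaks at 83 and 164 pN; the first peak carries less weight,
#: reflecting the shift of events toward the stronger complex.
COPPER_MIXTURE = MixtureParams(w1=0.35, mu1=83.0, sigma1=20.0, mu2=164.0, sigma2=30.0)


@dataclass
class SimulationConfig:
    """Ground-truth parameters for a simulated force-spectroscopy experiment.

    ``specific_event_probability`` is the Poisson rate λ of tether attachment
    per approach; the fraction of curves with at least one event is 1 − e^{−λ}
    (λ = 0.155 gives the ~14.3 % experimental yield).
    """

    seed: int = 0
    n_curves: int = 1000
    specific_event_probability: float = 0.155  # Poisson rate λ per approach
    mixture: MixtureParams = field(default_factory=lambda: CONTROL_MIXTURE)
    tether_contour_mean: float = 35.0  # nm, PEG(3400) + peptide
    tether_contour_sd: float = 5.0  # nm, linker-length inhomogeneity
    persistence_length: float = 0.38  # nm
    retract_velocity: float = 400.0  # nm/s
    sample_rate: float = 2000.0  # Hz
    force_noise_sd: float = 3.0  # pN
    baseline_tilt: float = 0.02  # pN/nm
    spring_constant: float = 30.0  # pN/nm
    temperature: float = ROOM_TEMPERATURE_K  # K
    contact_z: float = 5.0  # nm, surface contact point on the z axis
    z_range: float = 95.0  # nm, retract travel

    def __post_init__(self) -> None:
        if self.specific_event_probability < 0:
            raise ValueError("Poisson rate must be non-negative")
        if self.tether_contour_mean <= 0:
            raise ValueError("contour mean must be positive")
        for name in ("tether_contour_sd", "force_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class CurveTruth:
    curve_id: str
    n_events: int
    forces: list[float]  # pN
    contour_lengths: list[float]  # nm


@dataclass
class GroundTruth:
    curves: list[CurveTruth]

    @property
    def all_forces(self) -> np.ndarray:
        return np.array([f for c in self.curves for f in c.forces])

    @property
    def fraction_with_events(self) -> float:
        if not self.curves:
            return 0.0
        return sum(c.n_events > 0 for c in self.curves) / len(self.curves)


class UnattainableRuptureError(ValueError):
    """The requested rupture force cannot be reached within the retract range
    for the given contour length."""


# ---------------------------------------------------------------------------
# Rupture forces
# ---------------------------------------------------------------------------

def simulate_rupture_forces(config: SimulationConfig, n: int,
                            rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw n i.i.d. rupture forces (pN) from the configured two-Gaussian mixture."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    m = config.mixture
    pick2 = rng.random(n) >= m.w1
    forces = np.where(
        pick2,
        rng.normal(m.mu2, m.sigma2, n),
        rng.normal(m.mu1, m.sigma1, n),
    )
    return forces


# ---------------------------------------------------------------------------
# Force curves
# ---------------------------------------------------------------------------

def _rupture_z(z_max: float, z0: float, force: float, lc: float,
               lp: float, k: float, temperature: float) -> float:
    """Piezo position of the rupture; raises when outside the retract range."""
    x_r = wlc_extension(force, lp, lc, temperature)
    z_r = z0 + x_r + force / k
    if z_r > z_max - 2.0:
        raise UnattainableRuptureError(
            f"rupture at z={z_r:.1f} nm beyond retract range for Lc={lc:.1f} nm"
        )
    return z_r


def _tether_force_on_grid(z: np.ndarray, z0: float, force: float, lc: float,
                          lp: float, k: float, temperature: float,
                          z_r: float) -> np.ndarray:
    """Force (pN) of one tether on the piezo grid, truncated at its rupture.

    The cantilever deflects toward the surface under tension, so at piezo
    position z the extension x solves x = (z - z0) - F(x)/k. The branch is
    built parametrically in x and interpolated onto the grid; rupture is
    instantaneous (the force returns to baseline within one sample).
    """
    x_r = wlc_extension(force, lp, lc, temperature)
    x_par = np.linspace(0.0, x_r, 400)
    f_par = wlc_force(x_par, lp, lc, temperature)
    z_par = z0 + x_par + f_par / k
    f = np.interp(z, z_par, f_par, left=0.0, right=0.0)
    f[z > z_r + 1e-9] = 0.0
    at_rupture = np.isclose(z, z_r, rtol=0.0, atol=1e-9)
    f[at_rupture] = force  # the sample at the rupture instant reads F exactly
    return f


def simulate_force_curve(config: SimulationConfig,
                         events: list[tuple[float, float]],
                         rng: np.random.Generator | None = None,
                         curve_id: str = "sim-0") -> ForceCurve:
    """Simulate one approach/retract cycle.

    Parameters
    ----------
    events : list of (rupture_force_pN, contour_length_nm)
        Tethers attached during the dwell; each contributes a WLC stretch
        branch truncated at its rupture force (instantaneous, one-sample
        return to baseline). Multiple tethers superpose.

    Raises
    ------
    UnattainableRuptureError
        If a rupture force cannot be reached within the retract range for the
        given contour length (callers typically resample the contour length).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    dz = config.retract_velocity / config.sample_rate
    n = int(round(config.z_range / dz))
    z0 = config.contact_z
    k = config.spring_constant

    # sample exactly at each rupture instant: augment the uniform piezo grid
    # with the rupture positions (z stays strictly monotone)
    z = np.arange(n) * dz
    z_max = z[-1]
    ruptures = [
        _rupture_z(z_max, z0, force, lc, config.persistence_length, k,
                   config.temperature)
        for force, lc in events
    ]
    if ruptures:
        z = np.unique(np.concatenate([z, np.asarray(ruptures)]))
    n = len(z)

    contact = -k * np.clip(z0 - z, 0.0, None)  # repulsive, negative
    tilt = config.baseline_tilt * (z - z0)

    retract = contact + tilt
    for (force, lc), z_r in zip(events, ruptures):
        retract = retract + _tether_force_on_grid(
            z, z0, force, lc, config.persistence_length, k,
            config.temperature, z_r
        )
    approach = contact + tilt

    if config.force_noise_sd > 0:
        retract = retract + rng.normal(0.0, config.force_noise_sd, n)
        approach = approach + rng.normal(0.0, config.force_noise_sd, n)

    return ForceCurve(
        curve_id=curve_id,
        z=z,
        force_approach=approach,
        force_retract=retract,
        retract_velocity=config.retract_velocity,
        dwell_time=0.5,
        metadata={
            "spring_constant_pN_nm": k,
            "contact_z_nm": z0,
            "noise_sd_pN": config.force_noise_sd,
        },
    )


def simulate_experiment(config: SimulationConfig,
                        rng: np.random.Generator | None = None
                        ) -> tuple[list[ForceCurve], GroundTruth]:
    """Simulate a full experiment of ``config.n_curves`` approach cycles.

    Event counts per curve are Poisson(λ); rupture forces are i.i.d. mixture
    draws; contour lengths are Gaussian (resampled when non-positive or when
    the rupture would fall outside the retract range).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lam = config.specific_event_probability
    curves: list[ForceCurve] = []
    truths: list[CurveTruth] = []
    for i in range(config.n_curves):
        cid = f"sim-{i:05d}"
        m = int(rng.poisson(lam))
        ok_events: list[tuple[float, float]] = []
        for _ in range(m):
            force = float(np.clip(simulate_rupture_forces(config, 1, rng)[0], 5.0, None))
            for _attempt in range(100):
                lc = float(rng.normal(config.tether_contour_mean,
                                      config.tether_contour_sd))
                if lc < 5.0:
                    continue
                try:
                    _rupture_z(config.z_range, config.contact_z, force, lc,
                               config.persistence_length,
                               config.spring_constant, config.temperature)
                except UnattainableRuptureError:
                    continue
                ok_events.append((force, lc))
                break
            else:
                raise RuntimeError("could not place tether within retry budget")
        # distinct contour lengths -> distinct, resolvable rupture positions
        ok_events.sort(key=lambda e: e[1])
        curves.append(simulate_force_curve(config, ok_events, rng, curve_id=cid))
        truths.append(CurveTruth(
            curve_id=cid,
            n_events=len(ok_events),
            forces=[e[0] for e in ok_events],
            contour_lengths=[e[1] for e in ok_events],
        ))
    return curves, GroundTruth(truths)


# ---------------------------------------------------------------------------
# Thermal deflection series
# ---------------------------------------------------------------------------

def simulate_thermal_spectrum(spring_constant: float,
                              temperature: float = ROOM_TEMPERATURE_K,
                              n_samples: int = 100_000,
                              seed: int | np.random.Generator = 0) -> np.ndarray:
    """Thermal deflection time series (nm) of a cantilever of stiffness k.

    Stationary Gaussian with variance kB·T / k (equipartition). A white series
    is sufficient for variance-based calibration; no resonance line shape is
    modeled.
    """
    if spring_constant <= 0:
        raise ValueError("spring constant must be positive")
    var = thermal_energy(temperature) / spring_constant
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.normal(0.0, math.sqrt(var), n_samples)


# ---------------------------------------------------------------------------
# Topographs
# ---------------------------------------------------------------------------

@dataclass
class FeatureSpec:
    """One planted surface feature.

    kind : 'cap' (spherical-cap oligomer), 'ridge' (half-cylinder fibril) or
    'blob' (irregular amorphous aggregate). Heights in nm; lateral sizes in nm.
    ``position`` (x, y in nm) and ridge ``orientation`` (radians) are drawn at
    random when omitted.
    """

    kind: str
    height: float
    radius: float = 50.0  # cap / blob nominal radius
    length: float = 500.0  # ridge length
    width: float = 30.0  # ridge width
    orientation: float | None = None
    irregularity: float = 0.3  # blob boundary modulation amplitude
    position: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("cap", "ridge", "blob"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.height <= 0:
            raise ValueError("feature height must be positive")


def _raster_feature(spec: FeatureSpec, X: np.ndarray, Y: np.ndarray,
                    cx: float, cy: float, theta: float,
                    phases: np.ndarray) -> np.ndarray:
    dx, dy = X - cx, Y - cy
    if spec.kind == "cap":
        d2 = dx * dx + dy * dy
        return spec.height * np.clip(1.0 - d2 / spec.radius ** 2, 0.0, None)
    if spec.kind == "ridge":
        ux, uy = math.cos(theta), math.sin(theta)
        t = np.clip(dx * ux + dy * uy, -spec.length / 2, spec.length / 2)
        px, py = dx - t * ux, dy - t * uy
        d = np.hypot(px, py)
        half = spec.width / 2.0
        return spec.height * np.sqrt(np.clip(1.0 - (d / half) ** 2, 0.0, None))
    # irregular blob: radius modulated with low-order harmonics, rounded dome
    phi = np.arctan2(dy, dx)
    r_eff = spec.radius * (1.0 + spec.irregularity * (
        0.5 * np.cos(2 * phi + phases[0])
        + 0.3 * np.cos(3 * phi + phases[1])
        + 0.2 * np.cos(4 * phi + phases[2])))
    r_eff = np.clip(r_eff, 0.3 * spec.radius, None)
    d = np.hypot(dx, dy)
    return spec.height * np.clip(1.0 - (d / r_eff) ** 2, 0.0, None) ** 0.8


def _bounding_radius(spec: FeatureSpec) -> float:
    if spec.kind == "cap":
        return spec.radius
    if spec.kind == "ridge":
        return math.hypot(spec.length / 2, spec.width / 2)
    return spec.radius * (1.0 + spec.irregularity)


def simulate_topograph(features: list[FeatureSpec],
                       image_size: tuple[int, int] = (500, 500),
                       pixel_size: float = 10.0,
                       noise_sd: float = 0.3,
                       tilt: tuple[float, float] = (5e-4, 0.0),
                       seed: int | np.random.Generator = 0,
                       max_tries: int = 500,
                       metadata: dict | None = None):
    """Render a synthetic AFM topograph: tilted plane + features + pixel noise.

    Features are placed at random non-overlapping positions (occupancy-mask
    rejection, ``max_tries`` attempts each; RuntimeError on exhaustion) unless
    a position is given. Feature centers snap to the pixel grid so that a
    noiseless cap's maximum equals its nominal height exactly. ``tilt`` is the
    background plane gradient in nm per nm (5e-4 = 0.5 nm/µm).
    """
    from .afm import Topograph  # local import to avoid a cycle

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ny, nx = image_size
    y = np.arange(ny) * pixel_size
    x = np.arange(nx) * pixel_size
    X, Y = np.meshgrid(x, y)
    heights = tilt[0] * X + tilt[1] * Y
    occupied = np.zeros(image_size, dtype=bool)
    margin = 2 * pixel_size

    for spec in features:
        rb = _bounding_radius(spec)
        placed = False
        for _ in range(max_tries):
            theta = spec.orientation if spec.orientation is not None \
                else float(rng.uniform(0, math.pi))
            if spec.kind == "ridge":
                hx = abs(math.cos(theta)) * spec.length / 2 + spec.width / 2
                hy = abs(math.sin(theta)) * spec.length / 2 + spec.width / 2
            else:
                hx = hy = rb
            lo_x, hi_x = hx + margin, x[-1] - hx - margin
            lo_y, hi_y = hy + margin, y[-1] - hy - margin
            if hi_x <= lo_x or hi_y <= lo_y:
                raise ValueError(f"feature {spec.kind} does not fit in the image")
            if spec.position is not None:
                cx, cy = spec.position
            else:
                cx = float(rng.uniform(lo_x, hi_x))
                cy = float(rng.uniform(lo_y, hi_y))
            # snap to the pixel grid so the apex lands on a sample
            cx = round(cx / pixel_size) * pixel_size
            cy = round(cy / pixel_size) * pixel_size
            phases = rng.uniform(0, 2 * math.pi, 3)
            patch = _raster_feature(spec, X, Y, cx, cy, theta, phases)
            mask = patch > 0.05 * spec.height
            # 1-px dilation for clearance
            grown = np.zeros_like(mask)
            grown |= mask
            grown[1:, :] |= mask[:-1, :]
            grown[:-1, :] |= mask[1:, :]
            grown[:, 1:] |= mask[:, :-1]
            grown[:, :-1] |= mask[:, 1:]
            if np.any(grown & occupied):
                if spec.position is not None:
                    raise RuntimeError("explicitly placed features overlap")
                continue
            heights = np.maximum(heights, patch + tilt[0] * X + tilt[1] * Y)
            occupied |= grown
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place {spec.kind} feature within {max_tries} tries")

    if noise_sd > 0:
        heights = heights + rng.normal(0.0, noise_sd, image_size)
    return Topograph(heights=heights, pixel_size=pixel_size,
                     metadata=dict(metadata or {}))


# Heights observed along the aggregation time course: oligomers ~3.13 nm at
# 1 h; short ~4.5 nm fibrils at 6 h and long ~7.2 nm fibrils (up to 3 µm) at
# 24 h without copper; ~9.3 nm amorphous aggregates with copper.
OLIGOMER_HEIGHT_NM = 3.13
SHORT_FIBRIL_HEIGHT_NM = 4.5
FIBRIL_HEIGHT_NM = 7.2
AMORPHOUS_HEIGHT_NM = 9.3


def fig_timecourse_features(condition: str, time_h: float,
                            rng: np.random.Generator | None = None
                            ) -> list[FeatureSpec]:
    """Feature mix emulating the aggregation time course for one image.

    Control: oligomeric caps at 1 h; caps + short fibril ridges at 6 h;
    dominantly long fibrils at 24 h. Copper: caps at 1 h; large amorphous
    blobs from 6 h on, with no fibrils at 24 h.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    caps = lambda n, h: [FeatureSpec("cap", h, radius=float(rng.uniform(40, 80)))
                         for _ in range(n)]
    ridges = lambda n, h, lo, hi: [
        FeatureSpec("ridge", h, length=float(rng.uniform(lo, hi)), width=30.0)
        for _ in range(n)]
    blobs = lambda n, h: [FeatureSpec("blob", h, radius=float(rng.uniform(60, 200)))
                          for _ in range(n)]
    cond = condition.lower()
    if cond not in ("control", "copper"):
        raise ValueError("condition must be 'control' or 'copper'")
    if cond == "control":
        if time_h <= 1:
            return caps(20, OLIGOMER_HEIGHT_NM)
        if time_h <= 6:
            return caps(12, OLIGOMER_HEIGHT_NM) + ridges(6, SHORT_FIBRIL_HEIGHT_NM, 200, 600)
        return ridges(5, FIBRIL_HEIGHT_NM, 1000, 3000) + caps(5, OLIGOMER_HEIGHT_NM)
    if time_h <= 1:
        return caps(20, OLIGOMER_HEIGHT_NM)
    return blobs(8, AMORPHOUS_HEIGHT_NM) + caps(6, OLIGOMER_HEIGHT_NM)


def copper_config(seed: int = 0, **overrides) -> SimulationConfig:
    """SimulationConfig preset for the Cu2+ condition."""
    return replace(SimulationConfig(seed=seed, mixture=COPPER_MIXTURE), **overrides)
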