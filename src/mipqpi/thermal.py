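"""Heat conduction after pulsed mid-infrared absorption, and the design
metrics derived from it.

The photothermal signal observed in MIP-QPI is the optical phase delay

    Δθ(x, y, t) ≈ (2π/λ) (dn/dT) ∫ ΔT(x, y, z, t) dz,

so the simulation task is: solve the heat equation

    ∂ΔT/∂t = ν ∇²ΔT + q(x, t)

for a uniformly heated sphere in water (spherically symmetric), project the
temperature field along the line of sight (Abel projection), and extract
image metrics — the e⁻² radius of the projected spot and the center phase —
as functions of the MIR pulse duration and the probe delay.

The solver is an explicit forward-Euler scheme on a conservative
finite-volume discretization of spherical shells: with adiabatic boundaries
and no source the total thermal energy is conserved to round-off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import PhaseProfile, TemperatureField
from .materials import WATER, Medium

__all__ = [
    "HeatingProfile",
    "RadialGrid",
    "solve_radial",
    "project_phase",
    "e2_radius",
    "resolution_degradation",
    "cw_resolution_plateau",
    "saturation_curve",
    "saturation_time",
    "probe_delay_metrics",
    "decay_time",
    "estimate_temperature_rise",
]

#: Default safety factor on the explicit stability limit dt ≤ dx²/(2 d ν).
STABILITY_SAFETY = 0.4


@dataclass(frozen=True)
class HeatingProfile:
    """Heat source description.

    ``mode`` is one of

    - ``"constant_power"``: fixed peak deposition rate for ``pulse_duration``
      (a long-pulse / CW-like source such as a QCL),
    - ``"constant_energy"``: total deposited energy fixed at the value a
      ``reference_duration`` pulse would deposit at ``deposition_rate``
      (an OPO whose pulse energy does not depend on duration),
    - ``"impulse"``: no source; the initial temperature field is given
      directly to the solver.

    ``deposition_rate`` lumps I·α/(ρ c_p) into a peak heating rate in K µs⁻¹.
    Exactly one of ``sphere_radius`` (uniformly heated sphere, µm) or
    ``lateral_fwhm`` (Gaussian lateral spot, µm) must be set.
    ``axial_attenuation`` is a Lambert–Beer 1/e depth in µm (layered solver).
    """

    mode: str = "constant_power"
    pulse_duration: float = 0.01  # µs
    sphere_radius: float | None = None
    lateral_fwhm: float | None = None
    axial_attenuation: float | None = None
    deposition_rate: float = 1.0  # K µs⁻¹ peak
    reference_duration: float = 0.01  # µs, for constant_energy

    def __post_init__(self) -> None:
        if self.mode not in ("constant_power", "constant_energy", "impulse"):
            raise ValueError(f"unknown heating mode {self.mode!r}")
        if (self.sphere_radius is None) == (self.lateral_fwhm is None):
            raise ValueError("set exactly one of sphere_radius / lateral_fwhm")
        if self.mode != "impulse" and self.pulse_duration <= 0:
            raise ValueError("pulse_duration must be > 0 unless mode='impulse'")

    def rate(self) -> float:
        """Effective deposition rate in K µs⁻¹ during the pulse."""
        if self.mode == "constant_energy":
            return self.deposition_rate * self.reference_duration / self.pulse_duration
        return self.deposition_rate


@dataclass(frozen=True)
class RadialGrid:
    """Uniform radial grid: nodes at r_i = i·dr, i = 0 … n_r − 1.

    ``dt`` defaults to ``STABILITY_SAFETY × dr²/(6 ν)`` (three-dimensional
    explicit stability limit) when the solver is invoked.
    """

    dr: float
    n_r: int
    dt: float | None = None

    def __post_init__(self) -> None:
        if self.dr <= 0 or self.n_r < 4:
            raise ValueError("need dr > 0 and at least 4 radial nodes")

    @property
    def r_max(self) -> float:
        return self.dr * (self.n_r - 1)

    @property
    def r(self) -> np.ndarray:
        return self.dr * np.arange(self.n_r)

    def stable_dt(self, nu: float) -> float:
        return STABILITY_SAFETY * self.dr**2 / (6.0 * nu)

    def resolve_dt(self, nu: float) -> float:
        limit = self.dr**2 / (6.0 * nu)
        if self.dt is None:
            return STABILITY_SAFETY * limit
        if self.dt > limit:
            raise ValueError(
                f"dt = {self.dt:g} µs violates the explicit stability bound "
                f"dr²/(6ν) = {limit:g} µs"
            )
        return self.dt


def default_grid(sphere_radius: float, t_max: float, nu: float = WATER.thermal_diffusivity,
                 points_per_radius: int = 25) -> RadialGrid:
    """Grid sized for a sphere problem: dr = R/points_per_radius and a domain
    covering both 20 source radii and the diffusion length at ``t_max``."""
    dr = sphere_radius / points_per_radius
    r_max = max(20.0 * sphere_radius, sphere_radius + 8.0 * math.sqrt(2.0 * nu * t_max))
    n_r = int(math.ceil(r_max / dr)) + 1
    return RadialGrid(dr=dr, n_r=n_r)


def _sphere_overlap_fraction(r_lo: np.ndarray, r_hi: np.ndarray, radius: float) -> np.ndarray:
    """Fraction of each spherical shell [r_lo, r_hi] lying inside r < radius."""
    lo = np.minimum(r_lo, radius)
    hi = np.minimum(r_hi, radius)
    shell = r_hi**3 - r_lo**3
    return (hi**3 - lo**3) / shell


def solve_radial(
    source: HeatingProfile,
    medium: Medium,
    grid: RadialGrid,
    t_end: float,
    snapshot_times: list[float] | None = None,
    initial_field: np.ndarray | None = None,
) -> list[TemperatureField]:
    """Solve the spherically symmetric heat equation.

    Returns ΔT(r) snapshots at the requested times (always including the end
    of the pulse, when a pulse is active, and ``t_end``).  Negative times are
    rejected.  The time step is subdivided so that every snapshot and the
    pulse end are hit exactly.
    """
    if t_end < 0:
        raise ValueError("t_end must be non-negative")
    snapshot_times = sorted(set(snapshot_times or []))
    if snapshot_times and snapshot_times[0] < 0:
        raise ValueError("negative snapshot times are not allowed")

    nu = medium.thermal_diffusivity
    dt0 = grid.resolve_dt(nu)
    r = grid.r
    dr = grid.dr

    # control volumes and face areas (factor 4π/3 resp. 4π divided out of both)
    r_face_lo = np.maximum(r - dr / 2.0, 0.0)
    r_face_hi = r + dr / 2.0
    vol = (r_face_hi**3 - r_face_lo**3) / 3.0
    area_face = r_face_hi[:-1] ** 2  # interior faces between node i and i+1

    T = np.zeros(grid.n_r) if initial_field is None else np.array(initial_field, dtype=float)
    if T.shape != r.shape:
        raise ValueError("initial_field must match the radial grid")
    if not np.all(np.isfinite(T)):
        raise ValueError("initial_field contains non-finite values")

    if source.mode == "impulse":
        pulse_end = 0.0
        src = None
    else:
        if source.sphere_radius is None:
            raise ValueError("radial solver requires a sphere source")
        pulse_end = min(source.pulse_duration, t_end)
        src = source.rate() * _sphere_overlap_fraction(r_face_lo, r_face_hi, source.sphere_radius)

    events = sorted({t for t in snapshot_times + [t_end] if t <= t_end} | {t_end}
                    | ({pulse_end} if src is not None else set()))
    wanted = set(snapshot_times) | {t_end}

    out: list[TemperatureField] = []
    if 0.0 in wanted:
        out.append(TemperatureField(r.copy(), T.copy(), 0.0))

    flux = np.empty(grid.n_r - 1)
    t_now = 0.0
    for t_ev in events:
        if t_ev <= t_now:
            continue
        span = t_ev - t_now
        n_steps = max(1, int(math.ceil(span / dt0)))
        dt = span / n_steps
        heating = src is not None and t_now < pulse_end
        for _ in range(n_steps):
            np.multiply(area_face, T[1:] - T[:-1], out=flux)
            flux *= nu / dr
            dT = np.empty_like(T)
            dT[0] = flux[0] / vol[0]
            dT[1:-1] = (flux[1:] - flux[:-1]) / vol[1:-1]
            dT[-1] = -flux[-1] / vol[-1]
            if heating:
                T += dt * (dT + src)
            else:
                T += dt * dT
        t_now = t_ev
        if t_now in wanted or (src is not None and t_now == pulse_end):
            out.append(TemperatureField(r.copy(), T.copy(), t_now))
    return out


def thermal_energy(field: TemperatureField, medium: Medium) -> float:
    """∫ ρ c_p ΔT dV in J, for a spherically symmetric field on a uniform grid."""
    r = field.coordinates
    dr = r[1] - r[0]
    r_lo = np.maximum(r - dr / 2.0, 0.0)
    r_hi = r + dr / 2.0
    vol_um3 = 4.0 * math.pi / 3.0 * (r_hi**3 - r_lo**3)
    cv = medium.volumetric_heat_capacity * 1e-18  # J µm⁻³ K⁻¹
    return float(np.sum(field.values * vol_um3) * cv)


def deposited_energy(source: HeatingProfile, medium: Medium, duration: float | None = None) -> float:
    """Energy (J) a sphere source deposits over ``duration`` (default: the pulse)."""
    if source.sphere_radius is None:
        raise ValueError("sphere source required")
    duration = source.pulse_duration if duration is None else duration
    duration = min(duration, source.pulse_duration)
    v_sphere = 4.0 * math.pi / 3.0 * source.sphere_radius**3
    cv = medium.volumetric_heat_capacity * 1e-18
    return source.rate() * duration * v_sphere * cv


def project_phase(
    field: TemperatureField,
    wavelength: float = 0.532,
    dn_dT: float | None = None,
    x: np.ndarray | None = None,
    oversample: int = 2,
) -> PhaseProfile:
    """Abel-project a spherically symmetric ΔT(r) to the phase image profile.

    Δθ(x) = (2π/λ)|dn/dT| · 2 ∫₀^∞ ΔT(√(x² + z²)) dz, returned in mrad.
    The line integral is evaluated on a z grid finer than the radial grid by
    ``oversample``; the singularity of the classical Abel kernel never
    appears because the integration runs along z, not r.
    """
    if dn_dT is None:
        dn_dT = abs(WATER.dn_dT)
    r = field.coordinates
    T = field.values
    if not np.all(np.isfinite(T)):
        raise ValueError("non-finite temperature field")
    if x is None:
        x = r
    dz = (r[1] - r[0]) / oversample
    r_max = r[-1]
    out = np.zeros_like(x, dtype=float)
    for j, xj in enumerate(x):
        if xj >= r_max:
            continue
        z_max = math.sqrt(r_max**2 - xj**2)
        z = np.arange(0.0, z_max + dz, dz)
        rr = np.hypot(xj, z)
        vals = np.interp(rr, r, T, right=0.0)
        out[j] = 2.0 * np.trapezoid(vals, z)
    phase_mrad = 2.0 * math.pi / wavelength * abs(dn_dT) * out * 1e3
    return PhaseProfile(x=np.asarray(x, dtype=float), values=phase_mrad, wavelength=wavelength)


def e2_radius(profile: PhaseProfile) -> float:
    """Radius where a center-peaked profile first falls to max·e⁻², by linear
    interpolation.  Rejects profiles that do not peak at x = 0 or never drop
    below the threshold inside the domain."""
    y = profile.values
    if y[0] < y.max() * (1.0 - 1e-9) or y.max() <= 0:
        raise ValueError("profile must have its maximum at x = 0")
    target = y[0] * math.exp(-2.0)
    below = np.nonzero(y < target)[0]
    if below.size == 0:
        raise ValueError("profile never drops below e^-2 of its peak; enlarge the domain")
    i = below[0]
    x0, x1 = profile.x[i - 1], profile.x[i]
    y0, y1 = y[i - 1], y[i]
    return float(x0 + (target - y0) * (x1 - x0) / (y1 - y0))


def _end_of_pulse_profile(
    sphere_radius: float,
    pulse_duration: float,
    mode: str,
    medium: Medium,
    grid: RadialGrid | None,
    extra_time: float = 0.0,
) -> tuple[PhaseProfile, list[TemperatureField]]:
    t_end = pulse_duration + extra_time
    if grid is None:
        grid = default_grid(sphere_radius, t_end, medium.thermal_diffusivity)
    src = HeatingProfile(mode=mode, pulse_duration=pulse_duration, sphere_radius=sphere_radius)
    fields = solve_radial(src, medium, grid, t_end=t_end, snapshot_times=[pulse_duration, t_end])
    fld = next(f for f in fields if f.t == t_end)
    return project_phase(fld), fields


def resolution_degradation(
    sphere_radius: float,
    pulse_duration: float,
    mode: str = "constant_power",
    medium: Medium = WATER,
    grid: RadialGrid | None = None,
) -> float:
    """e⁻² radius of the end-of-pulse phase image divided by the true sphere
    radius (probe delay 0).  ≈ 0.99 in the short-pulse limit (projection
    geometry alone), growing with pulse duration as heat diffuses."""
    prof, _ = _end_of_pulse_profile(sphere_radius, pulse_duration, mode, medium, grid)
    return e2_radius(prof) / sphere_radius


def steady_state_sphere(
    sphere_radius: float,
    medium: Medium = WATER,
    grid: RadialGrid | None = None,
    deposition_rate: float = 1.0,
) -> TemperatureField:
    """Steady temperature field of a continuously heated sphere.

    Solves ν ∇²T + q = 0 on the radial finite-volume grid with a heat-sink
    (T = 0) outer boundary — the long-time limit of CW heating when the
    surroundings act as a thermal bath.  The analytic solution outside the
    sphere is T ∝ 1/r − 1/r_max.
    """
    from scipy.linalg import solve_banded

    if grid is None:
        dr = sphere_radius / 25.0
        grid = RadialGrid(dr=dr, n_r=int(math.ceil(200.0 * sphere_radius / dr)) + 1)
    nu = medium.thermal_diffusivity
    r = grid.r
    dr = grid.dr
    r_face_lo = np.maximum(r - dr / 2.0, 0.0)
    r_face_hi = r + dr / 2.0
    vol = (r_face_hi**3 - r_face_lo**3) / 3.0
    area = r_face_hi[:-1] ** 2
    src = deposition_rate * _sphere_overlap_fraction(r_face_lo, r_face_hi, sphere_radius)

    n = grid.n_r
    # conduction operator, Dirichlet T = 0 at the outer node
    ab = np.zeros((3, n))
    w = nu / (dr)
    for_face = np.zeros(n)  # coupling through face i (between node i and i+1)
    for_face[:-1] = w * area
    ab[0, 1:] = for_face[:-1] / vol[:-1]          # super-diagonal
    ab[2, :-1] = for_face[:-1] / vol[1:]          # sub-diagonal
    diag = np.zeros(n)
    diag[:-1] -= for_face[:-1] / vol[:-1]
    diag[1:] -= for_face[:-1] / vol[1:]
    ab[1] = diag
    rhs = -src * 1.0
    # Dirichlet at the last node
    ab[1, -1] = 1.0
    ab[0, -1] = 0.0
    ab[2, -2] = 0.0
    rhs[-1] = 0.0
    T = solve_banded((1, 1), ab, rhs)
    return TemperatureField(r.copy(), T, math.inf)


def cw_resolution_plateau(
    sphere_radius: float,
    medium: Medium = WATER,
    grid: RadialGrid | None = None,
) -> float:
    """Long-pulse (CW) limit of the thermal-spread ratio.

    Under continuous constant-power heating the line-of-sight projection of
    the 1/r steady far field has no finite e⁻² radius (it grows with the
    diffusion front), but the 3-D temperature field converges to a steady
    state whose e⁻² radius is (2/3)e² ≈ 4.93 sphere radii in an unbounded
    bath.  This function solves the steady conduction problem numerically
    (heat-sink boundary at 200 radii by default) and returns the e⁻² radius
    of the steady temperature field divided by the sphere radius.
    """
    field = steady_state_sphere(sphere_radius, medium, grid)
    prof = PhaseProfile(x=field.coordinates, values=field.values)
    return e2_radius(prof) / sphere_radius


def saturation_curve(
    sphere_radius: float,
    durations: list[float],
    medium: Medium = WATER,
    grid: RadialGrid | None = None,
    reference_duration: float = 0.01,
) -> np.ndarray:
    """Center phase at the end of a constant-power pulse vs pulse duration,
    normalized to the ``reference_duration`` (10 ns) value."""
    if not durations:
        raise ValueError("durations list is empty")
    durations = sorted(durations)
    all_t = sorted(set(durations) | {reference_duration})
    if grid is None:
        grid = default_grid(sphere_radius, all_t[-1], medium.thermal_diffusivity)
    src = HeatingProfile(mode="constant_power", pulse_duration=all_t[-1],
                         sphere_radius=sphere_radius)
    fields = solve_radial(src, medium, grid, t_end=all_t[-1], snapshot_times=all_t)
    by_t = {f.t: f for f in fields}
    center = {t: project_phase(by_t[t], x=np.array([0.0])).values[0] for t in all_t}
    ref = center[reference_duration]
    return np.array([center[t] / ref for t in durations])


def saturation_time(
    sphere_radius: float,
    medium: Medium = WATER,
    level: float = 1.0 - math.exp(-1.0),
    points_per_radius: int = 25,
) -> float:
    """Heat-confinement saturation time of a continuously heated sphere.

    Time (µs) at which the center temperature reaches ``level`` of its
    steady-state value q R²/(2ν).  The problem is self-similar in ν t / R²,
    so this time is proportional to the sphere radius squared — the design
    rule that sets the usable MIR pulse duration per object size.  (The
    center of the *projected phase* image keeps creeping up logarithmically
    with the 1/r far field and has no comparably crisp saturation point.)
    """
    nu = medium.thermal_diffusivity
    t_scale = sphere_radius**2 / nu
    t_end = 3.0 * t_scale
    grid = default_grid(sphere_radius, t_end, nu, points_per_radius)
    src = HeatingProfile(mode="constant_power", pulse_duration=t_end,
                         sphere_radius=sphere_radius)
    snaps = list(np.linspace(0.02 * t_scale, t_end, 150))
    fields = solve_radial(src, medium, grid, t_end=t_end, snapshot_times=snaps)
    t = np.array([f.t for f in fields if f.t > 0])
    center = np.array([f.values[0] for f in fields if f.t > 0])
    target = level * sphere_radius**2 / (2.0 * nu)  # deposition_rate = 1
    above = np.nonzero(center >= target)[0]
    if above.size == 0 or above[0] == 0:
        raise ValueError("center temperature does not cross the level in the window")
    i = above[0]
    return float(np.interp(target, center[i - 1 : i + 1], t[i - 1 : i + 1]))


def probe_delay_metrics(
    sphere_radius: float,
    delays: list[float],
    mir_duration: float = 0.01,
    medium: Medium = WATER,
    grid: RadialGrid | None = None,
) -> list[tuple[float, float]]:
    """(e⁻² radius ratio, normalized center phase) for each probe delay after
    a short constant-power pulse.  The center phase is normalized by its
    delay-0 value; the radius ratio is relative to the true sphere radius."""
    if any(d < 0 for d in delays):
        raise ValueError("negative probe delays are not allowed")
    delays = list(delays)
    t_end = mir_duration + max(delays + [0.0])
    if grid is None:
        grid = default_grid(sphere_radius, t_end, medium.thermal_diffusivity)
    src = HeatingProfile(mode="constant_power", pulse_duration=mir_duration,
                         sphere_radius=sphere_radius)
    snaps = sorted({mir_duration + d for d in delays} | {mir_duration})
    fields = solve_radial(src, medium, grid, t_end=t_end, snapshot_times=snaps)
    by_t = {f.t: f for f in fields}
    ref_center = project_phase(by_t[mir_duration], x=np.array([0.0])).values[0]
    out = []
    for d in delays:
        prof = project_phase(by_t[mir_duration + d])
        out.append((e2_radius(prof) / sphere_radius, prof.values[0] / ref_center))
    return out


def decay_time(t: np.ndarray, values: np.ndarray, level: float = math.exp(-1.0)) -> float:
    """First time (linear interpolation) at which a decaying curve crosses
    ``level`` × its maximum, measured from the time axis origin."""
    t = np.asarray(t, dtype=float)
    values = np.asarray(values, dtype=float)
    i_max = int(np.argmax(values))
    target = values[i_max] * level
    tail = values[i_max:]
    below = np.nonzero(tail < target)[0]
    if below.size == 0:
        raise ValueError("curve never crosses the requested level in the window")
    j = below[0] + i_max
    t0, t1 = t[j - 1], t[j]
    y0, y1 = values[j - 1], values[j]
    return float(t0 + (target - y0) * (t1 - t0) / (y1 - y0))


def estimate_temperature_rise(
    phase_mrad: float,
    diameter: float,
    wavelength: float = 0.532,
    dn_dT: float | None = None,
) -> float:
    """Peak temperature rise (K) implied by a phase change over a uniform
    sphere, assuming the optical path equals the diameter:
    ΔT = Δθ λ / (2π |dn/dT| d)."""
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    if dn_dT is None:
        dn_dT = abs(WATER.dn_dT)
    return phase_mrad * 1e-3 * wavelength / (2.0 * math.pi * abs(dn_dT) * diameter)
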