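"""Wave-speed models, refraction and Fermat travel times in a layered leg.

The scanned region is modelled as a stack of three horizontal layers below a
linear/phased array at ``z = 0``: cutaneous tissue, cortical bone, and marrow.
The compressional wave speed in cortical bone is more than double the soft
tissue speed, so rays bend strongly at the periosteal (skin/bone) and
endosteal (bone/marrow) interfaces and a homogeneous-speed beamformer
misplaces everything inside the bone.  This module computes refracted plane
wavefront arrival times and Fermat-minimal point-to-point travel times
through the stack, producing the delay tables the delay-and-sum beamformer
consumes.

Coordinate convention (shared by every module): ``x`` is the long-bone axis
in mm, positive toward the heart (proximal); ``z`` is depth in mm, 0 at the
probe face, increasing toward the marrow.  Times are in microseconds,
frequencies in MHz, speeds accepted in m/s.

Cortical bone is weakly anisotropic: the wave speed depends on the angle
``gamma`` between the propagation direction and the bone long axis through a
three-parameter even, pi-periodic model ``c(gamma) = c0 * (1 + a2*cos(2*gamma)
+ a4*cos(4*gamma))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.optimize import brentq, minimize_scalar

MM_PER_US_PER_MS = 1e-3  # m/s -> mm/us


class TotalInternalReflectionError(ValueError):
    """Raised when Snell's law has no real transmitted angle."""


class EvanescentTransmissionError(ValueError):
    """Raised when a steered plane wave cannot propagate into a layer."""


class FermatBracketError(RuntimeError):
    """Raised when the interface-crossing search does not bracket a minimum."""


class NonPositiveSpeedError(ValueError):
    """Raised when anisotropy parameters produce c(gamma) <= 0 somewhere."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProbeModel:
    """Linear/phased array at z = 0, elements along x.

    Parameters
    ----------
    element_count : int
    pitch : float
        Element spacing in mm.
    center_frequency, sampling_frequency : float
        MHz.  ``center_frequency`` must stay below Nyquist.
    pulse_bandwidth : float
        Fractional -6 dB bandwidth of the emitted pulse (dimensionless).
    """

    element_count: int
    pitch: float
    center_frequency: float
    sampling_frequency: float
    pulse_bandwidth: float = 0.6

    def __post_init__(self) -> None:
        if self.element_count < 2:
            raise ValueError("element_count must be >= 2")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")
        if not self.center_frequency < self.sampling_frequency / 2:
            raise ValueError("center_frequency must be < sampling_frequency/2")
        if not 0 < self.pulse_bandwidth < 2:
            raise ValueError("pulse_bandwidth must be in (0, 2)")

    @property
    def element_positions(self) -> np.ndarray:
        """Lateral element coordinates (mm), strictly increasing, centred on 0."""
        n = self.element_count
        return (np.arange(n) - (n - 1) / 2.0) * self.pitch

    @property
    def aperture(self) -> float:
        return (self.element_count - 1) * self.pitch


@dataclass(frozen=True)
class LayeredMediumModel:
    """Tissue / cortical bone / marrow stack with horizontal interfaces.

    Speeds in m/s; ``bone_speed_params = (c0, a2, a4)`` parameterizes the
    weak-anisotropy model of the cortex (``c0`` along the bone axis).
    """

    interface_skin_bone_depth: float = 8.0
    interface_bone_marrow_depth: float = 13.0
    c_tissue: float = 1570.0
    c_marrow: float = 1480.0
    bone_speed_params: tuple[float, float, float] = (3300.0, 0.06, 0.01)

    def __post_init__(self) -> None:
        if not 0 < self.interface_skin_bone_depth < self.interface_bone_marrow_depth:
            raise ValueError("need 0 < skin/bone depth < bone/marrow depth")
        if self.c_tissue <= 0 or self.c_marrow <= 0:
            raise ValueError("all speeds must be positive")
        _validate_bone_params(self.bone_speed_params)

    def bone_speed(self, gamma: float | np.ndarray) -> float | np.ndarray:
        """Cortical wave speed (m/s) at angle gamma (rad) from the bone axis."""
        return bone_speed(gamma, self.bone_speed_params)

    def layer_of(self, z: float) -> str:
        if z < self.interface_skin_bone_depth:
            return "tissue"
        if z < self.interface_bone_marrow_depth:
            return "cortex"
        return "marrow"

    def perturbed(self, fraction: float) -> "LayeredMediumModel":
        """Copy with all speeds scaled by (1 + fraction); geometry unchanged."""
        c0, a2, a4 = self.bone_speed_params
        return LayeredMediumModel(
            self.interface_skin_bone_depth,
            self.interface_bone_marrow_depth,
            self.c_tissue * (1 + fraction),
            self.c_marrow * (1 + fraction),
            (c0 * (1 + fraction), a2, a4),
        )


@dataclass(frozen=True)
class ImagingGrid:
    """Regular pixel grid: x along the bone axis, z depth from the probe face."""

    x_coords: np.ndarray
    z_coords: np.ndarray

    def __post_init__(self) -> None:
        for name, c in (("x_coords", self.x_coords), ("z_coords", self.z_coords)):
            c = np.asarray(c, dtype=float)
            if c.ndim != 1 or c.size < 2:
                raise ValueError(f"{name} must be 1D with >= 2 entries")
            steps = np.diff(c)
            if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
                raise ValueError(f"{name} must be regularly spaced")
        object.__setattr__(self, "x_coords", np.asarray(self.x_coords, float))
        object.__setattr__(self, "z_coords", np.asarray(self.z_coords, float))

    @classmethod
    def regular(cls, x_min: float, x_max: float, z_min: float, z_max: float,
                pitch: float, pitch_z: float | None = None) -> "ImagingGrid":
        """Regular grid; ``pitch_z`` (default = ``pitch``) may be finer so the
        axial analytic carrier is not spatially aliased."""
        if pitch > 0.75:
            raise ValueError(
                "pixel pitch must be <= 0.75 mm (half the ~1.5 mm resolution cell)")
        pitch_z = pitch if pitch_z is None else pitch_z
        nx = int(round((x_max - x_min) / pitch)) + 1
        nz = int(round((z_max - z_min) / pitch_z)) + 1
        return cls(x_min + pitch * np.arange(nx), z_min + pitch_z * np.arange(nz))

    @property
    def pixel_pitch(self) -> float:
        return float(self.x_coords[1] - self.x_coords[0])

    @property
    def shape(self) -> tuple[int, int]:
        return self.x_coords.size, self.z_coords.size

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.x_coords, self.z_coords, indexing="ij")


@dataclass
class DelayTables:
    """Transmit/receive round-trip delay tables on one imaging grid.

    ``tx_delays``: (n_angles, nx, nz) arrival time (us) of each steered,
    refracted plane wavefront at each pixel, referenced so every entry is
    non-negative.  ``rx_delays``: (n_elements, nx, nz) Fermat one-way times.
    ``valid``: (n_angles, nx, nz) False where transmission is evanescent.
    """

    tx_delays: np.ndarray
    rx_delays: np.ndarray
    valid: np.ndarray
    angles: np.ndarray
    grid: ImagingGrid
    probe: ProbeModel
    medium: LayeredMediumModel


# ---------------------------------------------------------------------------
# wave-speed model and Snell refraction
# ---------------------------------------------------------------------------


def bone_speed(gamma, params) -> float | np.ndarray:
    """c(gamma) = c0*(1 + a2*cos(2*gamma) + a4*cos(4*gamma)) in m/s.

    Even in gamma and pi-periodic; reduces to the isotropic limit for
    a2 = a4 = 0.
    """
    if len(params) != 3:
        raise ValueError("bone_speed_params must be (c0, a2, a4)")
    c0, a2, a4 = params
    g = np.asarray(gamma, dtype=float)
    c = c0 * (1.0 + a2 * np.cos(2 * g) + a4 * np.cos(4 * g))
    return float(c) if np.isscalar(gamma) else c


def _validate_bone_params(params) -> None:
    g = np.linspace(0, np.pi, 721)
    c = bone_speed(g, params)
    if np.any(np.asarray(c) <= 0):
        raise NonPositiveSpeedError(f"bone speed non-positive for params {params}")


def refract_angle(theta_incident: float, c1: float, c2: float) -> float:
    """Snell transmitted angle (rad); preserves the sign of the incidence.

    Raises :class:`TotalInternalReflectionError` when |(c2/c1) sin(theta)| > 1.
    """
    if c1 <= 0 or c2 <= 0:
        raise ValueError("speeds must be positive")
    if abs(theta_incident) > math.pi / 2:
        raise ValueError("|theta_incident| must be <= pi/2")
    s = (c2 / c1) * math.sin(theta_incident)
    if abs(s) > 1.0:
        raise TotalInternalReflectionError(
            f"total internal reflection: (c2/c1)*sin(theta) = {s:.4f}")
    return math.asin(s)


# ---------------------------------------------------------------------------
# Fermat travel times
# ---------------------------------------------------------------------------


def _speed_mmus(c, dx: float, dz: float) -> float:
    """Segment speed in mm/us; c is m/s or a callable of gamma (from x-axis)."""
    if callable(c):
        gamma = math.atan2(dz, dx)
        return c(gamma) * MM_PER_US_PER_MS
    return c * MM_PER_US_PER_MS


def _segment_time(p, q, c) -> float:
    dx, dz = q[0] - p[0], q[1] - p[1]
    return math.hypot(dx, dz) / _speed_mmus(c, dx, dz)


def two_layer_travel_time(src, dst, interface_depth: float, c_upper: float,
                          c_lower) -> tuple[float, tuple[float, float]]:
    """Fermat-minimal travel time (us) between two points across one interface.

    Parameters
    ----------
    src, dst : (x, z) in mm.  When both lie on the same side of the interface
        the straight-ray time is returned.
    c_upper : float
        Speed above the interface (m/s).
    c_lower : float or callable
        Speed below; a callable receives the propagation angle gamma (rad,
        from the x axis) and returns m/s (angle-dependent cortical speed).

    Returns
    -------
    (time_us, crossing_point) where crossing_point is the (x, z) at which the
    minimizing ray crosses the interface (dst itself for same-side inputs).
    """
    xs, zs = float(src[0]), float(src[1])
    xd, zd = float(dst[0]), float(dst[1])
    zi = float(interface_depth)
    side_s, side_d = zs - zi, zd - zi
    # order so that "upper" really is the src side; the time is symmetric
    if side_s > 0 and side_d < 0:
        return two_layer_travel_time(dst, src, interface_depth, c_upper, c_lower)
    if side_s * side_d >= 0:  # same side (or touching the interface)
        if max(zs, zd) <= zi:
            c = c_upper
        elif min(zs, zd) >= zi:
            c = c_lower
        else:  # pragma: no cover - excluded by the sign test above
            raise AssertionError
        # a point exactly on the interface pairs with the other point's layer
        if zs == zi and zd != zi:
            c = c_upper if zd < zi else c_lower
        if zd == zi and zs != zi:
            c = c_upper if zs < zi else c_lower
        return _segment_time((xs, zs), (xd, zd), c), (xd, zd)

    span = abs(xd - xs)
    margin = 0.75 * span + 1.0
    lo, hi = min(xs, xd) - margin, max(xs, xd) + margin

    def t_of(xc: float) -> float:
        return (_segment_time((xs, zs), (xc, zi), c_upper)
                + _segment_time((xc, zi), (xd, zd), c_lower))

    xs_scan = np.linspace(lo, hi, 512)
    ts = np.array([t_of(x) for x in xs_scan])
    i = int(np.argmin(ts))
    if i == 0 or i == xs_scan.size - 1:
        raise FermatBracketError("coarse scan minimum at search boundary")
    res = minimize_scalar(t_of, bracket=None, bounds=(xs_scan[i - 1], xs_scan[i + 1]),
                          method="bounded", options={"xatol": 1e-11})
    return float(res.fun), (float(res.x), zi)


def three_layer_travel_time(src, dst, medium: LayeredMediumModel
                            ) -> tuple[float, tuple[float, float], tuple[float, float]]:
    """Fermat time from a tissue point to a marrow point (two refractions).

    Returns (time_us, crossing1, crossing2).  Used for marrow pixels; the
    outer crossing is refined by golden search with an inner two-layer solve.
    """
    z1 = medium.interface_skin_bone_depth
    z2 = medium.interface_bone_marrow_depth
    xs, zs = float(src[0]), float(src[1])
    xd, zd = float(dst[0]), float(dst[1])
    if zs > z1:
        raise ValueError("src must lie in the tissue layer")
    if zd < z2:
        raise ValueError("dst must lie in the marrow layer")
    c1 = medium.c_tissue
    cb = medium.bone_speed
    c3 = medium.c_marrow

    def t_of(x1: float) -> float:
        t_upper = _segment_time((xs, zs), (x1, z1), c1)
        t_lower, _ = two_layer_travel_time((x1, z1), (xd, zd), z2, cb, c3)
        return t_upper + t_lower

    span = abs(xd - xs)
    lo, hi = min(xs, xd) - 0.75 * span - 1.0, max(xs, xd) + 0.75 * span + 1.0
    xs_scan = np.linspace(lo, hi, 192)
    ts = np.array([t_of(x) for x in xs_scan])
    i = int(np.argmin(ts))
    if i == 0 or i == xs_scan.size - 1:
        raise FermatBracketError("coarse scan minimum at search boundary")
    res = minimize_scalar(t_of, bounds=(xs_scan[i - 1], xs_scan[i + 1]),
                          method="bounded", options={"xatol": 1e-9})
    x1 = float(res.x)
    _, xc2 = two_layer_travel_time((x1, z1), (xd, zd), z2, cb, c3)
    return float(res.fun), (x1, z1), xc2


def point_travel_time(src, dst, medium: LayeredMediumModel) -> float:
    """One-way Fermat time (us) between any two points of the layered stack.

    Dispatches on the layers of the endpoints (0, 1 or 2 interface
    crossings); the src is expected at or above the skin while dst may sit in
    any layer (the typical element->pixel call).
    """
    z1, z2 = medium.interface_skin_bone_depth, medium.interface_bone_marrow_depth
    zd = float(dst[1])
    if zd <= z1:
        return _segment_time(src, dst, medium.c_tissue)
    if zd <= z2:
        t, _ = two_layer_travel_time(src, dst, z1, medium.c_tissue,
                                     medium.bone_speed)
        return t
    t, _, _ = three_layer_travel_time(src, dst, medium)
    return t


# ---------------------------------------------------------------------------
# plane-wave arrival times (slowness matching across the stack)
# ---------------------------------------------------------------------------


def _refracted_vertical_slowness(p: float, layer: str,
                                 medium: LayeredMediumModel) -> float:
    """Vertical slowness (us/mm) in a layer given horizontal slowness p.

    For the anisotropic cortex the transmitted angle theta_b solves
    sin(theta_b) = p * c(pi/2 - theta_b); raises EvanescentTransmissionError
    when no propagating solution exists.
    """
    ap = abs(p)
    if layer == "tissue":
        c = medium.c_tissue * MM_PER_US_PER_MS
        s = ap * c
        if s > 1.0:
            raise EvanescentTransmissionError("evanescent in tissue")
        return math.cos(math.asin(s)) / c
    if layer == "marrow":
        c = medium.c_marrow * MM_PER_US_PER_MS
        s = ap * c
        if s > 1.0:
            raise EvanescentTransmissionError("evanescent in marrow")
        return math.cos(math.asin(s)) / c
    # cortex: angle-dependent speed, gamma = pi/2 - theta_b
    def f(theta_b: float) -> float:
        c = bone_speed(math.pi / 2 - theta_b,
                       medium.bone_speed_params) * MM_PER_US_PER_MS
        return math.sin(theta_b) - ap * c

    if f(math.pi / 2 * 0.999999) < 0:
        raise EvanescentTransmissionError("steering beyond critical angle in bone")
    theta_b = brentq(f, 0.0, math.pi / 2 * 0.999999, xtol=1e-14)
    c = bone_speed(math.pi / 2 - theta_b, medium.bone_speed_params) * MM_PER_US_PER_MS
    return math.cos(theta_b) / c


def plane_wave_arrival_time(steer_angle: float, pixel, medium: LayeredMediumModel,
                            x_ref: float = 0.0) -> float:
    """Arrival time (us) of a refracted plane wavefront at a pixel.

    The wavefront is tilted ``steer_angle`` (rad) in the cutaneous tissue and
    refracts at each interface conserving horizontal slowness.  t = 0 when the
    wavefront passes (x_ref, 0); with the default x_ref = 0 this is the array
    center, so entries can be negative on one side of the array.
    """
    x, z = float(pixel[0]), float(pixel[1])
    ct = medium.c_tissue * MM_PER_US_PER_MS
    p = math.sin(steer_angle) / ct
    q1 = math.cos(steer_angle) / ct
    z1, z2 = medium.interface_skin_bone_depth, medium.interface_bone_marrow_depth
    tau = p * (x - x_ref)
    if z <= z1:
        return tau + q1 * z
    tau += q1 * z1
    qb = _refracted_vertical_slowness(p, "cortex", medium)
    if z <= z2:
        return tau + qb * (z - z1)
    tau += qb * (z2 - z1)
    qm = _refracted_vertical_slowness(p, "marrow", medium)
    return tau + qm * (z - z2)


# ---------------------------------------------------------------------------
# fast table building (numba kernels)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _c_bone_mmus(dx, dz, c0, a2, a4):
    gamma = math.atan2(dz, dx)
    return c0 * (1.0 + a2 * math.cos(2 * gamma) + a4 * math.cos(4 * gamma)) * 1e-3


@njit(cache=True)
def _t_two_layer(xs, zs, xd, zd, zi, c1_mmus, c0, a2, a4):
    """Scalar Fermat two-layer time: coarse scan + golden section."""
    span = abs(xd - xs)
    lo = min(xs, xd) - 0.75 * span - 1.0
    hi = max(xs, xd) + 0.75 * span + 1.0
    n = 192
    best = 1e30
    xb = lo
    for k in range(n):
        xc = lo + (hi - lo) * k / (n - 1)
        d1 = math.hypot(xc - xs, zi - zs)
        dx2 = xd - xc
        dz2 = zd - zi
        d2 = math.hypot(dx2, dz2)
        t = d1 / c1_mmus + d2 / _c_bone_mmus(dx2, dz2, c0, a2, a4)
        if t < best:
            best = t
            xb = xc
    step = (hi - lo) / (n - 1)
    a = xb - step
    b = xb + step
    gr = 0.6180339887498949
    x1 = b - gr * (b - a)
    x2 = a + gr * (b - a)
    for _ in range(64):
        d1 = math.hypot(x1 - xs, zi - zs)
        dxa = xd - x1
        dza = zd - zi
        f1 = d1 / c1_mmus + math.hypot(dxa, dza) / _c_bone_mmus(dxa, dza, c0, a2, a4)
        d1 = math.hypot(x2 - xs, zi - zs)
        dxb = xd - x2
        f2 = d1 / c1_mmus + math.hypot(dxb, dza) / _c_bone_mmus(dxb, dza, c0, a2, a4)
        if f1 < f2:
            b = x2
            x2 = x1
            x1 = b - gr * (b - a)
        else:
            a = x1
            x1 = x2
            x2 = a + gr * (b - a)
    xc = 0.5 * (a + b)
    d1 = math.hypot(xc - xs, zi - zs)
    dx2 = xd - xc
    dz2 = zd - zi
    return d1 / c1_mmus + math.hypot(dx2, dz2) / _c_bone_mmus(dx2, dz2, c0, a2, a4)


@njit(cache=True)
def _t_lower_pair(x1, z1, xd, zd, z2, c0, a2, a4, c3_mmus):
    """Bone->marrow two-layer time from (x1,z1) to (xd,zd) crossing z2."""
    span = abs(xd - x1)
    lo = min(x1, xd) - 0.75 * span - 1.0
    hi = max(x1, xd) + 0.75 * span + 1.0
    n = 96
    best = 1e30
    xb = lo
    for k in range(n):
        xc = lo + (hi - lo) * k / (n - 1)
        dxa = xc - x1
        dza = z2 - z1
        t = (math.hypot(dxa, dza) / _c_bone_mmus(dxa, dza, c0, a2, a4)
             + math.hypot(xd - xc, zd - z2) / c3_mmus)
        if t < best:
            best = t
            xb = xc
    step = (hi - lo) / (n - 1)
    a = xb - step
    b = xb + step
    gr = 0.6180339887498949
    for _ in range(48):
        x1g = b - gr * (b - a)
        x2g = a + gr * (b - a)
        dza = z2 - z1
        f1 = (math.hypot(x1g - x1, dza) / _c_bone_mmus(x1g - x1, dza, c0, a2, a4)
              + math.hypot(xd - x1g, zd - z2) / c3_mmus)
        f2 = (math.hypot(x2g - x1, dza) / _c_bone_mmus(x2g - x1, dza, c0, a2, a4)
              + math.hypot(xd - x2g, zd - z2) / c3_mmus)
        if f1 < f2:
            b = x2g
        else:
            a = x1g
    xc = 0.5 * (a + b)
    dza = z2 - z1
    return (math.hypot(xc - x1, dza) / _c_bone_mmus(xc - x1, dza, c0, a2, a4)
            + math.hypot(xd - xc, zd - z2) / c3_mmus)


@njit(cache=True)
def _t_three_layer(xs, zs, xd, zd, z1, z2, c1_mmus, c0, a2, a4, c3_mmus):
    span = abs(xd - xs)
    lo = min(xs, xd) - 0.75 * span - 1.0
    hi = max(xs, xd) + 0.75 * span + 1.0
    n = 64
    best = 1e30
    xb = lo
    for k in range(n):
        x1 = lo + (hi - lo) * k / (n - 1)
        t = (math.hypot(x1 - xs, z1 - zs) / c1_mmus
             + _t_lower_pair(x1, z1, xd, zd, z2, c0, a2, a4, c3_mmus))
        if t < best:
            best = t
            xb = x1
    step = (hi - lo) / (n - 1)
    a = xb - step
    b = xb + step
    gr = 0.6180339887498949
    for _ in range(40):
        x1g = b - gr * (b - a)
        x2g = a + gr * (b - a)
        f1 = (math.hypot(x1g - xs, z1 - zs) / c1_mmus
              + _t_lower_pair(x1g, z1, xd, zd, z2, c0, a2, a4, c3_mmus))
        f2 = (math.hypot(x2g - xs, z1 - zs) / c1_mmus
              + _t_lower_pair(x2g, z1, xd, zd, z2, c0, a2, a4, c3_mmus))
        if f1 < f2:
            b = x2g
        else:
            a = x1g
    x1 = 0.5 * (a + b)
    return (math.hypot(x1 - xs, z1 - zs) / c1_mmus
            + _t_lower_pair(x1, z1, xd, zd, z2, c0, a2, a4, c3_mmus))


@njit(cache=True)
def _golden_two_layer(u, zp, z1, c1_mmus, c0, a2, a4, xc0, half_bracket):
    """Two-layer time to offset u, crossing search near warm start xc0."""
    a = xc0 - half_bracket
    b = xc0 + half_bracket
    gr = 0.6180339887498949
    for _ in range(56):
        x1 = b - gr * (b - a)
        x2 = a + gr * (b - a)
        dza = zp - z1
        f1 = (math.hypot(x1, z1) / c1_mmus
              + math.hypot(u - x1, dza) / _c_bone_mmus(u - x1, dza, c0, a2, a4))
        f2 = (math.hypot(x2, z1) / c1_mmus
              + math.hypot(u - x2, dza) / _c_bone_mmus(u - x2, dza, c0, a2, a4))
        if f1 < f2:
            b = x2
        else:
            a = x1
    xc = 0.5 * (a + b)
    dz2 = zp - z1
    t = (math.hypot(xc, z1) / c1_mmus
         + math.hypot(u - xc, dz2) / _c_bone_mmus(u - xc, dz2, c0, a2, a4))
    return t, xc


@njit(cache=True)
def _t3_eval(x1, x2, u, zp, z1, z2, c1_mmus, c0, a2, a4, c3_mmus):
    dxb = x2 - x1
    dzb = z2 - z1
    return (math.hypot(x1, z1) / c1_mmus
            + math.hypot(dxb, dzb) / _c_bone_mmus(dxb, dzb, c0, a2, a4)
            + math.hypot(u - x2, zp - z2) / c3_mmus)


@njit(cache=True)
def _golden_three_layer(u, zp, z1, z2, c1_mmus, c0, a2, a4, c3_mmus,
                        x1c0, x2c0, half_bracket):
    """Warm-started coordinate descent over the two interface crossings."""
    gr = 0.6180339887498949
    x1 = x1c0
    x2 = x2c0
    half = half_bracket
    for _ in range(8):
        # refine x1 with x2 fixed
        a = x1 - half
        b = x1 + half
        for _ in range(18):
            g1 = b - gr * (b - a)
            g2 = a + gr * (b - a)
            if _t3_eval(g1, x2, u, zp, z1, z2, c1_mmus, c0, a2, a4, c3_mmus) < \
               _t3_eval(g2, x2, u, zp, z1, z2, c1_mmus, c0, a2, a4, c3_mmus):
                b = g2
            else:
                a = g1
        x1 = 0.5 * (a + b)
        # refine x2 with x1 fixed
        a = x2 - half
        b = x2 + half
        for _ in range(18):
            g1 = b - gr * (b - a)
            g2 = a + gr * (b - a)
            if _t3_eval(x1, g1, u, zp, z1, z2, c1_mmus, c0, a2, a4, c3_mmus) < \
               _t3_eval(x1, g2, u, zp, z1, z2, c1_mmus, c0, a2, a4, c3_mmus):
                b = g2
            else:
                a = g1
        x2 = 0.5 * (a + b)
        half = max(half * 0.35, 1e-4)
    t = _t3_eval(x1, x2, u, zp, z1, z2, c1_mmus, c0, a2, a4, c3_mmus)
    return t, x1, x2


@njit(cache=True)
def _row_profiles(u_grid, z_rows, z1, z2, c1_mmus, c0, a2, a4, c3_mmus, out):
    """Travel time vs horizontal offset per depth row (lateral invariance).

    Marches the offset grid warm-starting the interface-crossing search from
    the previous offset (the crossing moves slower than the offset itself).
    """
    nu = u_grid.size
    du = u_grid[1] - u_grid[0]
    half = 3.0 * du + 0.05
    for j in range(z_rows.size):
        zp = z_rows[j]
        if zp <= z1:
            for k in range(nu):
                out[j, k] = math.hypot(u_grid[k], zp) / c1_mmus
        elif zp <= z2:
            xc = 0.0
            for k in range(nu):
                t, xc = _golden_two_layer(u_grid[k], zp, z1, c1_mmus,
                                          c0, a2, a4, xc, half)
                out[j, k] = t
        else:
            x1 = 0.0
            x2 = 0.0
            for k in range(nu):
                t, x1, x2 = _golden_three_layer(u_grid[k], zp, z1, z2, c1_mmus,
                                                c0, a2, a4, c3_mmus, x1, x2,
                                                half)
                out[j, k] = t


def rx_time_profiles(z_rows: np.ndarray, u_max: float,
                     medium: LayeredMediumModel, du: float = 0.1
                     ) -> tuple[np.ndarray, np.ndarray]:
    """One-way Fermat time vs |lateral offset| for each depth row.

    Returns (u_grid, times[len(z_rows), len(u_grid)]).  Exploits the lateral
    invariance of the horizontal-layer stack: an element->pixel time depends
    only on the offset |x_pixel - x_element| and the pixel depth.
    """
    z_rows = np.asarray(z_rows, dtype=float)
    nu = int(math.ceil(u_max / du)) + 2
    u_grid = du * np.arange(nu)
    out = np.empty((z_rows.size, nu))
    c0, a2, a4 = medium.bone_speed_params
    _row_profiles(u_grid, z_rows, medium.interface_skin_bone_depth,
                  medium.interface_bone_marrow_depth,
                  medium.c_tissue * MM_PER_US_PER_MS, c0, a2, a4,
                  medium.c_marrow * MM_PER_US_PER_MS, out)
    return u_grid, out


class LayeredRxInterpolator:
    """Cubic-in-offset, exact-in-depth-row evaluator of one-way rx times.

    Built once per scene geometry; evaluated for any (element x, pixel x,
    pixel z on the row grid).  Since t(u) is even with t'(0) = 0, the spline
    is clamped at u = 0.
    """

    def __init__(self, z_rows, u_max, medium: LayeredMediumModel,
                 du: float = 0.1):
        from scipy.interpolate import CubicSpline

        self.z_rows = np.asarray(z_rows, dtype=float)
        self.u_grid, self.profiles = rx_time_profiles(self.z_rows, u_max,
                                                      medium, du)
        self._splines = [
            CubicSpline(self.u_grid, self.profiles[j],
                        bc_type=((1, 0.0), "not-a-knot"))
            for j in range(self.z_rows.size)
        ]

    def row_times(self, j: int, offsets: np.ndarray) -> np.ndarray:
        return self._splines[j](np.abs(offsets))


def _rx_table(el_x, grid: ImagingGrid, medium: LayeredMediumModel,
              du: float = 0.1) -> np.ndarray:
    u_max = (np.abs(grid.x_coords[:, None] - el_x[None, :]).max()) + 0.5
    interp = LayeredRxInterpolator(grid.z_coords, u_max, medium, du)
    ne, nx, nz = el_x.size, *grid.shape
    out = np.empty((ne, nx, nz))
    offs = np.abs(grid.x_coords[:, None] - el_x[None, :])  # (nx, ne)
    for j in range(nz):
        out[:, :, j] = interp.row_times(j, offs).T
    return out


def build_delay_tables(probe: ProbeModel, grid: ImagingGrid,
                       medium: LayeredMediumModel, angles,
                       rx_offset_step: float = 0.1) -> DelayTables:
    """Precompute transmit and receive delay tables for one scene geometry.

    ``tx_delays[a, i, j]`` is the refracted plane-wavefront arrival time of
    steering angle ``angles[a]`` at pixel (i, j), referenced to the wavefront
    passing the trailing edge of the aperture so all entries are >= 0.
    ``rx_delays[e, i, j]`` is the one-way Fermat time from element ``e``.
    Pixels a steering angle cannot reach (evanescent transmission) are masked
    in ``valid`` instead of aborting the build.
    """
    angles = np.atleast_1d(np.asarray(angles, dtype=float))
    nx, nz = grid.shape
    half = probe.aperture / 2.0
    tx = np.zeros((angles.size, nx, nz))
    valid = np.ones((angles.size, nx, nz), dtype=bool)
    z1, z2 = medium.interface_skin_bone_depth, medium.interface_bone_marrow_depth
    ct = medium.c_tissue * MM_PER_US_PER_MS
    for a, th in enumerate(angles):
        x_ref = -half if th >= 0 else half
        p = math.sin(th) / ct
        q1 = math.cos(th) / ct
        try:
            qb = _refracted_vertical_slowness(p, "cortex", medium)
        except EvanescentTransmissionError:
            qb = np.nan
        try:
            qm = _refracted_vertical_slowness(p, "marrow", medium)
        except EvanescentTransmissionError:
            qm = np.nan
        X, Z = grid.meshgrid()
        tau = p * (X - x_ref)
        in_tissue = Z <= z1
        in_bone = (Z > z1) & (Z <= z2)
        in_marrow = Z > z2
        tau = tau + np.where(in_tissue, q1 * Z, q1 * z1)
        tau = tau + np.where(in_bone, qb * (Z - z1), 0.0)
        tau = tau + np.where(in_marrow, qb * (z2 - z1) + qm * (Z - z2), 0.0)
        bad = np.isnan(tau)
        tx[a] = np.where(bad, 0.0, tau)
        valid[a] = ~bad

    rx = _rx_table(probe.element_positions, grid, medium, du=rx_offset_step)
    return DelayTables(tx_delays=tx, rx_delays=rx, valid=valid, angles=angles,
                       grid=grid, probe=probe, medium=medium)
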