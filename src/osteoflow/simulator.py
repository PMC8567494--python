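"""Synthetic channel-data generator for intraosseous and arterial flow scenes.

The generator produces per-transmit, per-element RF traces with the
statistical structure the downstream analysis assumes:

* fully developed static speckle in the cutaneous tissue, the cortical bone
  matrix and the marrow (point scatterers, Born single-scattering model);
* slow, non-pulsatile hand-held probe drift (< 0.5 mm over a recording, peak
  velocity ~0.1 mm/s) displacing every scatterer rigidly;
* blood scatterers moving pulsatilely at 1-10 mm/s along the two canal
  networks of cortical bone -- axial movers (Haversian canals, along the bone
  axis x) filling the cortex and radial movers (perforating Volkmann canals,
  along depth z) in discrete transcortical strips;
* a soft-tissue tube scene with parabolic (Poiseuille) flow emulating the
  superficial femoral artery for the conventional-Doppler reference branch.

Travel times of the forward model come from the :mod:`osteoflow.acoustics`
layered-medium solver, optionally with a finer interface search and slightly
perturbed wave speeds than the beamformer's tables so that simulation and
reconstruction never share the exact same numerics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from osteoflow.acoustics import (
    EvanescentTransmissionError,
    LayeredMediumModel,
    ProbeModel,
    _refracted_vertical_slowness,
    rx_time_profiles,
    MM_PER_US_PER_MS,
)


class EmptyRegionError(RuntimeError):
    """A region of nonzero density and area > 1 mm^2 drew zero scatterers."""


class ReinjectionError(ValueError):
    """Blood displacement per cardiac period exceeds the wrap span."""


# ---------------------------------------------------------------------------
# waveforms and protocols
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PulsatileWaveform:
    """Baseline + raised-cosine systolic pulse, exactly periodic.

    v(t) = v_baseline + v_peak * p(u),  u = frac(t * heart_rate / 60),
    p(u) = 0.5 * (1 - cos(2*pi*u/w)) for u < w = systolic_fraction, else 0.

    ``v_peak`` is signed: the crest of the pulse reaches
    v_baseline + v_peak.
    """

    heart_rate: float = 60.0
    v_peak: float = -9.5
    v_baseline: float = -0.5
    systolic_fraction: float = 0.3
    pulse_shape: str = "raised-cosine"

    def __post_init__(self) -> None:
        if not 0 < self.systolic_fraction < 1:
            raise ValueError("systolic_fraction must be in (0, 1)")
        if self.pulse_shape != "raised-cosine":
            raise ValueError("only the raised-cosine pulse shape is supported")
        if self.heart_rate <= 0:
            raise ValueError("heart_rate must be positive")

    @property
    def period(self) -> float:
        return 60.0 / self.heart_rate

    def velocity(self, t) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        u = np.mod(t / self.period, 1.0)
        w = self.systolic_fraction
        p = np.where(u < w, 0.5 * (1 - np.cos(2 * np.pi * np.minimum(u, w) / w)),
                     0.0)
        v = self.v_baseline + self.v_peak * p
        return float(v) if v.ndim == 0 else v

    def displacement(self, t) -> np.ndarray | float:
        """Closed-form integral of the velocity from 0 to t (mm)."""
        t = np.asarray(t, dtype=float)
        T, w = self.period, self.systolic_fraction
        n = np.floor(t / T)
        u = t / T - n
        uw = np.minimum(u, w)
        partial = 0.5 * (uw - (w / (2 * np.pi)) * np.sin(2 * np.pi * uw / w))
        d = self.v_baseline * t + self.v_peak * T * (n * w / 2.0 + partial)
        return float(d) if d.ndim == 0 else d

    def displacement_per_period(self) -> float:
        return self.v_baseline * self.period + \
            self.v_peak * self.period * self.systolic_fraction / 2.0


def waveform_velocity(t, w: PulsatileWaveform):
    """Blood speed (mm/s) of waveform ``w`` at time(s) ``t`` (s)."""
    return w.velocity(t)


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Transmit schedule of one recording.

    ``bone_compound``: each frame is ``len(angles)`` steered plane waves
    compounded into one image, frames at ``frame_rate``.  ``artery_ensemble``:
    each frame is an ensemble of ``ensemble_size`` identical transmits at
    ``angles[0]`` fired at ``prf``; scatterers move between the transmits of
    an ensemble (the intra-ensemble motion is the Doppler signal).
    """

    mode: str = "bone_compound"
    angles_deg: tuple = tuple(np.linspace(-8.0, 8.0, 15))
    frames: int = 400
    frame_rate: float = 100.0
    ensemble_size: int = 30
    prf: float = 5000.0
    intra_frame_motion: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("bone_compound", "artery_ensemble"):
            raise ValueError(f"unknown protocol mode {self.mode!r}")
        if self.mode == "artery_ensemble" and len(self.angles_deg) != 1:
            raise ValueError("artery_ensemble uses a single steering angle")

    @classmethod
    def bone_default(cls, frames: int = 400) -> "AcquisitionProtocol":
        return cls(frames=frames)

    @classmethod
    def artery_default(cls, frames: int = 400) -> "AcquisitionProtocol":
        return cls(mode="artery_ensemble", angles_deg=(20.0,), frames=frames,
                   ensemble_size=30, prf=5000.0, intra_frame_motion=True)

    @property
    def transmits_per_frame(self) -> int:
        return self.ensemble_size if self.mode == "artery_ensemble" \
            else len(self.angles_deg)

    @property
    def recording_duration(self) -> float:
        return self.frames / self.frame_rate

    def emission_time(self, frame: int, transmit: int) -> float:
        t = frame / self.frame_rate
        if self.intra_frame_motion:
            t += transmit / self.prf
        return t

    def transmit_angle_rad(self, transmit: int) -> float:
        if self.mode == "artery_ensemble":
            return math.radians(self.angles_deg[0])
        return math.radians(self.angles_deg[transmit])


# ---------------------------------------------------------------------------
# phantoms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DriftModel:
    """Rigid probe-bone drift: raised-cosine ramp from 0 to ``amplitude``.

    The ramp s(t) = 0.5*(1 - cos(pi * t / duration)) is smooth, monotone and
    capped at 1, so the displacement never exceeds ``amplitude`` and carries
    no pulsatility by construction.  Peak velocity = amplitude*pi/(2*duration).
    """

    amplitude: float = 0.4
    duration: float = 4.0
    direction: tuple[float, float] = (0.8, 0.6)

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("drift amplitude must be >= 0")
        n = math.hypot(*self.direction)
        if self.amplitude > 0 and not math.isclose(n, 1.0, rel_tol=1e-9):
            object.__setattr__(self, "direction",
                               (self.direction[0] / n, self.direction[1] / n))

    @property
    def peak_velocity(self) -> float:
        return self.amplitude * math.pi / (2.0 * self.duration)

    def displacement(self, t) -> np.ndarray:
        """(..., 2) displacement in mm at time(s) t (s)."""
        t = np.asarray(t, dtype=float)
        s = 0.5 * (1 - np.cos(np.pi * np.clip(t / self.duration, 0.0, 1.0)))
        return self.amplitude * s[..., None] * np.asarray(self.direction)


@dataclass
class FlowPhantom:
    """Scatterer positions, reflectivities and kinematics of one scene.

    Blood scatterers advance along their unit ``canal_axis`` by the closed
    form integral of their waveform (scaled by ``velocity_scale``, e.g. the
    parabolic tube profile) and wrap periodically inside
    [``wrap_lo``, ``wrap_hi``] measured along the canal axis, so the
    scatterer count and spatial statistics are stationary for the SVD filter.
    """

    static_pos: np.ndarray          # (Ns, 2)
    static_amp: np.ndarray          # (Ns,)
    blood_pos0: np.ndarray          # (Nb, 2)
    blood_amp: np.ndarray           # (Nb,)
    canal_axis: np.ndarray          # (Nb, 2) unit vectors
    waveform_id: np.ndarray         # (Nb,) int index into waveforms
    velocity_scale: np.ndarray      # (Nb,)
    wrap_lo: np.ndarray             # (Nb,) along-axis wrap bounds
    wrap_hi: np.ndarray
    waveforms: tuple[PulsatileWaveform, ...]
    drift: DriftModel = field(default_factory=lambda: DriftModel(amplitude=0.0))
    region_geometry: dict = field(default_factory=dict)
    # flow-through scenes (speed constant along the wrap axis) may wrap more
    # than once per period; canal scenes must not
    strict_reinjection: bool = True

    def __post_init__(self) -> None:
        if self.blood_pos0.shape[0]:
            norms = np.linalg.norm(self.canal_axis, axis=1)
            if not np.allclose(norms, 1.0):
                raise ValueError("canal_axis vectors must be unit length")
        if not self.strict_reinjection:
            return
        for wid, w in enumerate(self.waveforms):
            sel = self.waveform_id == wid
            if not np.any(sel):
                continue
            span = (self.wrap_hi[sel] - self.wrap_lo[sel]).min()
            dpp = abs(w.displacement_per_period()) * \
                np.abs(self.velocity_scale[sel]).max()
            if dpp > span:
                raise ReinjectionError(
                    f"waveform {wid}: displacement/period {dpp:.2f} mm exceeds "
                    f"wrap span {span:.2f} mm")

    @property
    def n_static(self) -> int:
        return self.static_pos.shape[0]

    @property
    def n_blood(self) -> int:
        return self.blood_pos0.shape[0]

    def region_of(self, x: float, z: float) -> str:
        g = self.region_geometry
        if "tube_center_depth" in g:
            if abs(z - g["tube_center_depth"]) <= g["tube_radius"]:
                return "vessel"
            return "tissue"
        if z < g["z_skin_bone"]:
            return "tissue"
        if z < g["z_bone_marrow"]:
            for x0, wdt in g.get("radial_strips", []):
                if abs(x - x0) <= wdt / 2:
                    return "vessel"
            return "cortex"
        return "marrow"

    def blood_displacement(self, t: float) -> np.ndarray:
        """Along-axis blood displacement (Nb,) at time t, before wrapping."""
        d = np.empty(self.n_blood)
        for wid, w in enumerate(self.waveforms):
            sel = self.waveform_id == wid
            if np.any(sel):
                d[sel] = w.displacement(t) * self.velocity_scale[sel]
        return d

    def positions_at(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        """(static, blood) scatterer positions (mm) at time t (s)."""
        dr = self.drift.displacement(t) if self.drift.amplitude > 0 \
            else np.zeros(2)
        static = self.static_pos + dr
        if self.n_blood == 0:
            return static, np.zeros((0, 2))
        s0 = np.einsum("ij,ij->i", self.blood_pos0, self.canal_axis)
        s = s0 + self.blood_displacement(t)
        span = self.wrap_hi - self.wrap_lo
        s = self.wrap_lo + np.mod(s - self.wrap_lo, span)
        blood = self.blood_pos0 + (s - s0)[:, None] * self.canal_axis + dr
        return static, blood


def advance_scatterers(phantom: FlowPhantom, t: float) -> np.ndarray:
    """All scatterer positions (static then blood) at time t (s)."""
    if t < 0:
        raise ValueError("t must be >= 0")
    static, blood = phantom.positions_at(t)
    return np.vstack([static, blood])


@dataclass(frozen=True)
class RegionDensities:
    """Scatterers per mm^2 per region of the cortical scene."""

    tissue: float = 1.2
    cortex: float = 2.0
    marrow: float = 0.8
    blood: float = 3.0


@dataclass(frozen=True)
class RegionReflectivities:
    """RMS reflectivity per region (blood is echo-weak relative to matrix)."""

    tissue: float = 1.0
    cortex: float = 1.0
    marrow: float = 0.6
    blood: float = 0.25


def _poisson_uniform(rng, density, x0, x1, z0, z1):
    area = (x1 - x0) * (z1 - z0)
    if density <= 0 or area <= 0:
        return np.zeros((0, 2))
    n = rng.poisson(density * area)
    if n == 0:
        if area > 1.0:
            raise EmptyRegionError(
                f"density {density}/mm^2 drew 0 scatterers in {area:.1f} mm^2")
        return np.zeros((0, 2))
    return np.column_stack([rng.uniform(x0, x1, n), rng.uniform(z0, z1, n)])


def make_cortical_phantom(
    medium: LayeredMediumModel,
    extent: tuple[float, float] = (20.0, 18.0),
    densities: RegionDensities | None = None,
    blood_fraction_axial: float = 0.7,
    seed: int = 0,
    reflectivities: RegionReflectivities | None = None,
    axial_waveform: PulsatileWaveform | None = None,
    radial_waveform: PulsatileWaveform | None = None,
    drift: DriftModel | None = None,
    n_radial_strips: int = 1,
    z_top: float = 0.8,
) -> FlowPhantom:
    """Layered tibia scene: static speckle plus two orthogonal canal networks.

    ``extent = (lateral width, depth)`` centred on x = 0.  Blood movers along
    the bone axis fill the cortex outside ``n_radial_strips`` vertical
    perforating strips whose total width is ``(1 - blood_fraction_axial)``
    of the lateral width, so the axial:radial scatterer-count ratio equals
    ``blood_fraction_axial`` in expectation.  Scatterer counts are Poisson in
    each region, placement uniform, everything reproducible from ``seed``.
    """
    densities = densities or RegionDensities()
    refl = reflectivities or RegionReflectivities()
    axial_waveform = axial_waveform or PulsatileWaveform(
        heart_rate=60.0, v_peak=-9.5, v_baseline=-0.5)
    radial_waveform = radial_waveform or PulsatileWaveform(
        heart_rate=axial_waveform.heart_rate, v_peak=-1.9, v_baseline=-0.1,
        systolic_fraction=axial_waveform.systolic_fraction)
    drift = drift if drift is not None else DriftModel()
    if not 0.0 <= blood_fraction_axial <= 1.0:
        raise ValueError("blood_fraction_axial must be in [0, 1]")

    rng = np.random.default_rng(seed)
    width, depth = extent
    xlo, xhi = -width / 2, width / 2
    z1 = medium.interface_skin_bone_depth
    z2 = medium.interface_bone_marrow_depth

    # static speckle in the three layers (bone matrix also inside the strips)
    pos_t = _poisson_uniform(rng, densities.tissue, xlo, xhi, z_top, z1)
    pos_c = _poisson_uniform(rng, densities.cortex, xlo, xhi, z1, z2)
    pos_m = _poisson_uniform(rng, densities.marrow, xlo, xhi, z2, depth)
    static_pos = np.vstack([pos_t, pos_c, pos_m])
    static_amp = np.concatenate([
        refl.tissue * rng.standard_normal(len(pos_t)),
        refl.cortex * rng.standard_normal(len(pos_c)),
        refl.marrow * rng.standard_normal(len(pos_m)),
    ])

    # perforating (radial) strips and the axial segments between them
    strip_total = (1.0 - blood_fraction_axial) * width
    strips: list[tuple[float, float]] = []
    if n_radial_strips > 0 and strip_total > 0:
        w_strip = strip_total / n_radial_strips
        # strip centers spread evenly across the width
        centers = xlo + (np.arange(n_radial_strips) + 0.5) * width / n_radial_strips
        strips = [(float(c), w_strip) for c in centers]
    edges = [xlo]
    for c, wd in strips:
        edges += [c - wd / 2, c + wd / 2]
    edges.append(xhi)
    axial_segments = [(edges[i], edges[i + 1]) for i in range(0, len(edges), 2)]

    blood_pos, axis, wf_id, wrap_lo, wrap_hi = [], [], [], [], []
    if densities.blood > 0 and blood_fraction_axial > 0:
        for (a, b) in axial_segments:
            p = _poisson_uniform(rng, densities.blood, a, b, z1, z2)
            blood_pos.append(p)
            axis.append(np.tile([1.0, 0.0], (len(p), 1)))
            wf_id.append(np.zeros(len(p), dtype=np.int64))
            wrap_lo.append(np.full(len(p), a))
            wrap_hi.append(np.full(len(p), b))
    if densities.blood > 0 and blood_fraction_axial < 1:
        for (c, wd) in strips:
            p = _poisson_uniform(rng, densities.blood, c - wd / 2, c + wd / 2,
                                 z1, z2)
            blood_pos.append(p)
            axis.append(np.tile([0.0, 1.0], (len(p), 1)))
            wf_id.append(np.ones(len(p), dtype=np.int64))
            wrap_lo.append(np.full(len(p), z1))
            wrap_hi.append(np.full(len(p), z2))
    if blood_pos:
        blood_pos = np.vstack(blood_pos)
        axis = np.vstack(axis)
        wf_id = np.concatenate(wf_id)
        wrap_lo = np.concatenate(wrap_lo)
        wrap_hi = np.concatenate(wrap_hi)
    else:
        blood_pos = np.zeros((0, 2))
        axis = np.zeros((0, 2))
        wf_id = np.zeros(0, dtype=np.int64)
        wrap_lo = np.zeros(0)
        wrap_hi = np.zeros(0)
    blood_amp = refl.blood * rng.standard_normal(len(blood_pos))

    return FlowPhantom(
        static_pos=static_pos, static_amp=static_amp,
        blood_pos0=blood_pos, blood_amp=blood_amp, canal_axis=axis,
        waveform_id=wf_id, velocity_scale=np.ones(len(blood_pos)),
        wrap_lo=wrap_lo, wrap_hi=wrap_hi,
        waveforms=(axial_waveform, radial_waveform),
        drift=drift,
        region_geometry={
            "z_skin_bone": z1, "z_bone_marrow": z2,
            "radial_strips": strips, "extent": extent,
        },
    )


def make_artery_phantom(
    tube_center_depth: float = 20.0,
    radius: float = 2.5,
    v_center: float = 470.0,
    seed: int = 0,
    extent: tuple[float, float] = (14.0, 27.0),
    waveform: PulsatileWaveform | None = None,
    densities: RegionDensities | None = None,
    reflectivities: RegionReflectivities | None = None,
    blood_density_3d: float = 2.0,
) -> FlowPhantom:
    """Soft-tissue tube with parabolic flow along x (femoral-artery scene).

    Blood scatterers are drawn uniformly in the 3D tube cross-section
    (p(r) ~ r) and move along x with v(r, t) = waveform(t) * (1 - r^2/R^2);
    only their in-plane depth offset enters the image.  The mean speed over
    the scatterers is therefore half the centerline speed.  ``v_center``
    scales the waveform's crest speed (waveform built from it when omitted).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    densities = densities or RegionDensities(tissue=1.0)
    refl = reflectivities or RegionReflectivities(blood=0.35)
    waveform = waveform or PulsatileWaveform(
        heart_rate=60.0, v_peak=v_center - 30.0, v_baseline=30.0,
        systolic_fraction=0.35)
    rng = np.random.default_rng(seed)
    width, depth = extent
    xlo, xhi = -width / 2, width / 2
    zc = tube_center_depth

    tissue = _poisson_uniform(rng, densities.tissue, xlo, xhi, 0.8, depth)
    keep = np.abs(tissue[:, 1] - zc) > radius
    static_pos = tissue[keep]
    static_amp = refl.tissue * rng.standard_normal(len(static_pos))

    n_blood = rng.poisson(blood_density_3d * (xhi - xlo) * math.pi * radius**2)
    if n_blood == 0:
        raise EmptyRegionError("no blood scatterers drawn in the tube")
    x = rng.uniform(xlo, xhi, n_blood)
    r = radius * np.sqrt(rng.uniform(0, 1, n_blood))
    phi = rng.uniform(0, 2 * np.pi, n_blood)
    z = zc + r * np.cos(phi)
    blood_pos = np.column_stack([x, z])
    scale = 1.0 - (r / radius) ** 2

    return FlowPhantom(
        static_pos=static_pos, static_amp=static_amp,
        blood_pos0=blood_pos,
        blood_amp=refl.blood * rng.standard_normal(n_blood),
        canal_axis=np.tile([1.0, 0.0], (n_blood, 1)),
        waveform_id=np.zeros(n_blood, dtype=np.int64),
        velocity_scale=scale,
        wrap_lo=np.full(n_blood, xlo), wrap_hi=np.full(n_blood, xhi),
        waveforms=(waveform,),
        drift=DriftModel(amplitude=0.0),
        region_geometry={"tube_center_depth": zc, "tube_radius": radius,
                         "extent": extent},
        strict_reinjection=False,
    )


# ---------------------------------------------------------------------------
# RF forward model
# ---------------------------------------------------------------------------


@dataclass
class ChannelDataCube:
    """Raw RF data: (frames, transmits, elements, samples) float32."""

    rf: np.ndarray
    sample_rate: float  # MHz
    t0: float           # us, time of sample 0 relative to each emission
    protocol: AcquisitionProtocol
    probe: ProbeModel
    medium: LayeredMediumModel

    def __post_init__(self) -> None:
        if self.rf.ndim != 4:
            raise ValueError("rf must be (frames, transmits, elements, samples)")


def gaussian_pulse_sigma_us(f0: float, fractional_bandwidth: float) -> float:
    """Time sigma (us) of a Gaussian pulse with the given -6 dB fractional BW."""
    sigma_f = fractional_bandwidth * f0 / (2.0 * math.sqrt(2 * math.log(2)))
    return 1.0 / (2 * math.pi * sigma_f)


def _pulse_lut(f0: float, sigma: float, fs: float, oversample: int = 32):
    dt = 1.0 / (fs * oversample)
    half = 4.0 * sigma
    n = int(math.ceil(half / dt))
    t = dt * np.arange(-n, n + 1)
    g = np.exp(-0.5 * (t / sigma) ** 2) * np.cos(2 * np.pi * f0 * t)
    return g.astype(np.float64), -n * dt, dt, half


@njit(cache=True)
def _accumulate_transmit(rf, tx_tau, rx_tau, amp, t0, fs,
                         lut, lut_t0, lut_dt, half_support):
    """Add every scatterer's pulse to one transmit's element traces."""
    ns, ne = rx_tau.shape
    n_samp = rf.shape[1]
    for s in range(ns):
        a = amp[s]
        if a == 0.0:
            continue
        ts = tx_tau[s]
        for e in range(ne):
            tarr = ts + rx_tau[s, e]
            i0 = int(math.ceil((tarr - half_support - t0) * fs))
            i1 = int(math.floor((tarr + half_support - t0) * fs))
            if i0 < 0:
                i0 = 0
            if i1 >= n_samp:
                i1 = n_samp - 1
            for i in range(i0, i1 + 1):
                tt = t0 + i / fs - tarr
                u = (tt - lut_t0) / lut_dt
                k = int(u)
                if k < 0 or k + 1 >= lut.size:
                    continue
                w = u - k
                rf[e, i] += a * ((1.0 - w) * lut[k] + w * lut[k + 1])


@njit(cache=True)
def _rx_tau_layered(sx, sz, el_x, z_rows0, dz_row, u0, du, profiles, out):
    """Bilinear lookup of one-way times on the (depth row, offset) profile."""
    ns = sx.size
    ne = el_x.size
    nz, nu = profiles.shape
    for s in range(ns):
        zq = (sz[s] - z_rows0) / dz_row
        j = int(zq)
        if j < 0:
            j = 0
        if j > nz - 2:
            j = nz - 2
        wz = zq - j
        for e in range(ne):
            uq = (abs(sx[s] - el_x[e]) - u0) / du
            k = int(uq)
            if k < 0:
                k = 0
            if k > nu - 2:
                k = nu - 2
            wu = uq - k
            t00 = profiles[j, k]
            t01 = profiles[j, k + 1]
            t10 = profiles[j + 1, k]
            t11 = profiles[j + 1, k + 1]
            out[s, e] = (1 - wz) * ((1 - wu) * t00 + wu * t01) \
                + wz * ((1 - wu) * t10 + wu * t11)


class ForwardDelayModel:
    """One-way travel times for the forward model of one scene geometry.

    Built on a fine (depth-row x lateral-offset) grid -- a finer interface
    search than the beamformer's tables -- and optionally with all layer
    speeds perturbed by ``speed_perturbation`` (inverse-crime mitigation: the
    simulation never uses the exact numerics the reconstruction assumes).
    """

    def __init__(self, probe: ProbeModel, medium: LayeredMediumModel,
                 x_extent: tuple[float, float], z_extent: tuple[float, float],
                 speed_perturbation: float = 0.0, row_step: float = 0.05,
                 offset_step: float = 0.05):
        self.medium_true = medium.perturbed(speed_perturbation) \
            if speed_perturbation else medium
        self.probe = probe
        z_lo = max(min(z_extent[0] - 0.6, z_extent[0]), 1e-3)
        z_hi = z_extent[1] + 0.6
        n_rows = int(math.ceil((z_hi - z_lo) / row_step)) + 1
        self.z_rows = z_lo + row_step * np.arange(n_rows)
        half_ap = probe.aperture / 2
        u_max = max(abs(x_extent[0]), abs(x_extent[1])) + half_ap + 1.0
        self.u_grid, self.profiles = rx_time_profiles(
            self.z_rows, u_max, self.medium_true, du=offset_step)
        self._slowness_cache: dict[float, tuple] = {}

    def rx_times(self, pos: np.ndarray) -> np.ndarray:
        """(n_scatterers, n_elements) one-way times (us)."""
        out = np.empty((pos.shape[0], self.probe.element_count))
        if pos.shape[0] == 0:
            return out
        _rx_tau_layered(np.ascontiguousarray(pos[:, 0]),
                        np.ascontiguousarray(pos[:, 1]),
                        self.probe.element_positions,
                        self.z_rows[0], self.z_rows[1] - self.z_rows[0],
                        self.u_grid[0], self.u_grid[1] - self.u_grid[0],
                        self.profiles, out)
        return out

    def _slownesses(self, angle: float):
        if angle not in self._slowness_cache:
            m = self.medium_true
            ct = m.c_tissue * MM_PER_US_PER_MS
            p = math.sin(angle) / ct
            q1 = math.cos(angle) / ct
            qb = _refracted_vertical_slowness(p, "cortex", m)
            qm = _refracted_vertical_slowness(p, "marrow", m)
            self._slowness_cache[angle] = (p, q1, qb, qm)
        return self._slowness_cache[angle]

    def tx_times(self, angle: float, pos: np.ndarray) -> np.ndarray:
        """Plane-wavefront arrival times, trailing-edge reference (us)."""
        p, q1, qb, qm = self._slownesses(angle)
        m = self.medium_true
        z1, z2 = m.interface_skin_bone_depth, m.interface_bone_marrow_depth
        half = self.probe.aperture / 2
        x_ref = -half if angle >= 0 else half
        x, z = pos[:, 0], pos[:, 1]
        tau = p * (x - x_ref) + np.minimum(z, z1) * q1
        tau += np.clip(z - z1, 0.0, z2 - z1) * qb
        tau += np.clip(z - z2, 0.0, None) * qm
        return tau

    def max_round_trip(self) -> float:
        return float(self.profiles.max() * 2 +
                     abs(math.sin(math.radians(25))) * self.probe.aperture
                     / (self.medium_true.c_tissue * MM_PER_US_PER_MS))


def simulate_channel_data(
    phantom: FlowPhantom,
    protocol: AcquisitionProtocol,
    probe: ProbeModel,
    medium: LayeredMediumModel,
    noise_snr_db: float | None = 30.0,
    seed: int = 0,
    speed_perturbation: float = 0.0,
    forward_model: "ForwardDelayModel | None" = None,
    duration_us: float | None = None,
) -> ChannelDataCube:
    """Simulate the full RF cube of one recording (materialized in memory).

    Thin wrapper over :func:`iter_channel_frames`; see there for the model.
    """
    frames = [f for f in iter_channel_frames(
        phantom, protocol, probe, medium, noise_snr_db, seed,
        speed_perturbation, forward_model, duration_us)]
    rf = np.stack([f[0] for f in frames])
    t0 = frames[0][1]
    return ChannelDataCube(rf=rf, sample_rate=probe.sampling_frequency, t0=t0,
                           protocol=protocol, probe=probe, medium=medium)


def iter_channel_frames(
    phantom: FlowPhantom,
    protocol: AcquisitionProtocol,
    probe: ProbeModel,
    medium: LayeredMediumModel,
    noise_snr_db: float | None = 30.0,
    seed: int = 0,
    speed_perturbation: float = 0.0,
    forward_model: "ForwardDelayModel | None" = None,
    duration_us: float | None = None,
):
    """Yield (rf_frame, t0) per frame; rf_frame is (transmits, elements, samples).

    Each element trace is the superposition of Gaussian-windowed sinusoids at
    the probe center frequency, delayed by the transmit wavefront arrival at
    the scatterer plus the scatterer-to-element Fermat return time, both
    evaluated at the scatterer position at that transmit's emission time
    (scatterers are frozen during a compound frame unless the protocol's
    ``intra_frame_motion`` is set).  White Gaussian noise is added at
    ``noise_snr_db`` relative to the first frame's RMS signal.
    """
    if forward_model is not None:
        fwd = forward_model
    else:
        all_pos = advance_scatterers(phantom, 0.0)
        if all_pos.shape[0] == 0:
            all_pos = np.array([[0.0, 5.0]])  # empty scene: nominal extent
        margin = phantom.drift.amplitude + 0.1
        x_lo = all_pos[:, 0].min() - margin - 0.1
        x_hi = all_pos[:, 0].max() + margin + 0.1
        z_lo = max(all_pos[:, 1].min() - margin, 0.2)
        z_hi = all_pos[:, 1].max() + margin
        fwd = ForwardDelayModel(probe, medium, (x_lo, x_hi), (z_lo, z_hi),
                                speed_perturbation)

    fs = probe.sampling_frequency
    sigma = gaussian_pulse_sigma_us(probe.center_frequency,
                                    probe.pulse_bandwidth)
    lut, lut_t0, lut_dt, half_sup = _pulse_lut(probe.center_frequency, sigma, fs)
    t0 = -half_sup
    t_end = fwd.max_round_trip()
    if duration_us is not None:
        t_end = max(t_end, duration_us)
    n_samp = int(math.ceil((t_end + half_sup - t0) * fs)) + 4

    amps = np.concatenate([phantom.static_amp, phantom.blood_amp])
    rng = np.random.default_rng(seed)
    noise_sigma = None
    n_tx = protocol.transmits_per_frame

    for f in range(protocol.frames):
        rf = np.zeros((n_tx, probe.element_count, n_samp))
        if not protocol.intra_frame_motion:
            pos = advance_scatterers(phantom, protocol.emission_time(f, 0))
            rx_tau = fwd.rx_times(pos)
        for a in range(n_tx):
            if protocol.intra_frame_motion:
                pos = advance_scatterers(phantom, protocol.emission_time(f, a))
                rx_tau = fwd.rx_times(pos)
            angle = protocol.transmit_angle_rad(a)
            tx_tau = fwd.tx_times(angle, pos)
            _accumulate_transmit(rf[a], tx_tau, rx_tau, amps, t0, fs,
                                 lut, lut_t0, lut_dt, half_sup)
        if noise_sigma is None:
            rms = float(np.sqrt(np.mean(rf ** 2)))
            if noise_snr_db is None or rms == 0.0:
                noise_sigma = 0.0
            else:
                noise_sigma = rms * 10 ** (-noise_snr_db / 20.0)
        if noise_sigma > 0:
            rf = rf + rng.normal(0.0, noise_sigma, rf.shape)
        yield rf.astype(np.float32), t0
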