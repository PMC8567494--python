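"""Refraction-corrected delay-and-sum, compounding, and transverse oscillations.

The beamformer sums, per pixel, the analytic (complex) element traces at the
round-trip delay ``tau_tx(angle, pixel) + tau_rx(element, pixel)`` taken from
precomputed :class:`~osteoflow.acoustics.DelayTables`, with a Hanning receive
apodization over a configurable acceptance angle.  Low-resolution images from
the steered transmits of one frame are summed coherently (plane-wave
compounding), yielding a complex IQ image sequence at the compound frame
rate.

The transverse-oscillation (TO) pair is built after beamforming by filtering
each frame's lateral spatial spectrum with two Gaussian passbands centred at
+-1/lambda_0x: the ``s_plus``/``s_minus`` images carry conjugate lateral
carriers, so lateral motion produces opposite phase shifts in the two images
while axial motion shifts both equally -- which is what lets a phase-based
estimator separate the two velocity components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.signal import hilbert

from osteoflow.acoustics import DelayTables, ImagingGrid, LayeredMediumModel

DEFAULT_ACCEPTANCE_DEG = 30.0


class SampleRangeError(ValueError):
    """A requested delay falls outside the recorded trace duration."""


class GridMismatchError(ValueError):
    """Images to combine do not share one grid."""


@dataclass
class IQImageSequence:
    """Beamformed complex images on a fixed grid: iq is (nx, nz, n_frames)."""

    iq: np.ndarray
    grid: ImagingGrid
    frame_rate: float
    carrier_frequency: float        # MHz (axial analytic carrier)
    medium: LayeredMediumModel | None = None
    lambda0x: float | None = None   # mm, set on TO-filtered sequences

    @property
    def n_frames(self) -> int:
        return self.iq.shape[2]


@dataclass
class TOImagePair:
    """Laterally oscillating image pair sharing one grid and carrier.

    ``lambda_z`` is the axial carrier wavelength (mm) enforced by the axial
    passband when 2D spectral filtering was used (None = broadband axial).
    """

    s_plus: IQImageSequence
    s_minus: IQImageSequence
    lambda0x: float
    lambda_z: float | None = None

    @property
    def grid(self) -> ImagingGrid:
        return self.s_plus.grid


def receive_apodization(tables: DelayTables,
                        acceptance_deg: float = DEFAULT_ACCEPTANCE_DEG
                        ) -> np.ndarray:
    """Hanning receive weights (n_elements, nx, nz) over an acceptance cone.

    The angle between the element->pixel direction and the vertical is
    computed on the straight ray; elements seeing the pixel beyond the
    acceptance half-angle get zero weight.
    """
    el = tables.probe.element_positions
    X, Z = tables.grid.meshgrid()
    theta = np.arctan2(X[None] - el[:, None, None], Z[None])
    u = theta / math.radians(acceptance_deg)
    w = np.where(np.abs(u) < 1.0, 0.5 * (1 + np.cos(np.pi * u)), 0.0)
    return w


@njit(cache=True)
def _das_kernel(traces_re, traces_im, tx, rx, apod, valid, t0, fs,
                out_re, out_im):
    ne, n_samp = traces_re.shape
    nx, nz = tx.shape
    for i in range(nx):
        for j in range(nz):
            if not valid[i, j]:
                continue
            acc_re = 0.0
            acc_im = 0.0
            t_tx = tx[i, j]
            for e in range(ne):
                w = apod[e, i, j]
                if w == 0.0:
                    continue
                u = (t_tx + rx[e, i, j] - t0) * fs
                k = int(u)
                if k < 0 or k + 1 >= n_samp:
                    continue
                frac = u - k
                acc_re += w * ((1 - frac) * traces_re[e, k]
                               + frac * traces_re[e, k + 1])
                acc_im += w * ((1 - frac) * traces_im[e, k]
                               + frac * traces_im[e, k + 1])
            out_re[i, j] = acc_re
            out_im[i, j] = acc_im


def das_beamform(frame_rf: np.ndarray, tables: DelayTables, transmit_index: int,
                 apodization: np.ndarray, t0: float, sample_rate: float,
                 check_range: bool = True) -> np.ndarray:
    """Delay-and-sum one transmit's element traces onto the grid.

    ``frame_rf`` is (n_elements, n_samples), real RF (the analytic signal is
    taken along the trace) or already-complex analytic traces.  Pixels whose
    transmit is evanescent (masked in the tables) are set to 0.  Raises
    :class:`SampleRangeError` when a valid pixel's delay exceeds the trace.
    """
    if np.iscomplexobj(frame_rf):
        analytic = frame_rf
    else:
        analytic = hilbert(frame_rf, axis=-1)
    tx = tables.tx_delays[transmit_index]
    valid = tables.valid[transmit_index]
    if check_range:
        tau_max = (tx + tables.rx_delays.max(axis=0))[valid].max()
        if (tau_max - t0) * sample_rate > frame_rf.shape[-1] - 1:
            raise SampleRangeError(
                f"delay {tau_max:.2f} us beyond trace duration")
    nx, nz = tables.grid.shape
    out_re = np.zeros((nx, nz))
    out_im = np.zeros((nx, nz))
    _das_kernel(np.ascontiguousarray(analytic.real),
                np.ascontiguousarray(analytic.imag),
                tx, tables.rx_delays, apodization, valid,
                t0, sample_rate, out_re, out_im)
    return out_re + 1j * out_im


def compound(low_res_images: list[np.ndarray]) -> np.ndarray:
    """Coherent (pixel-wise complex) sum of the steered-transmit images."""
    shapes = {im.shape for im in low_res_images}
    if len(shapes) != 1:
        raise GridMismatchError(f"images on different grids: {shapes}")
    return np.sum(low_res_images, axis=0)


def beamform_frames(frames, tables: DelayTables, sample_rate: float,
                    frame_rate: float,
                    acceptance_deg: float = DEFAULT_ACCEPTANCE_DEG,
                    ) -> IQImageSequence:
    """Beamform and compound an iterable of (rf_frame, t0) into IQ images.

    ``rf_frame`` is (transmits, elements, samples); each transmit is
    beamformed with its own steering-angle delay table and the transmits of
    one frame are compounded coherently.
    """
    apod = None
    out = []
    for rf_frame, t0 in frames:
        if apod is None:
            apod = receive_apodization(tables, acceptance_deg)
        analytic = hilbert(rf_frame, axis=-1)
        lows = [das_beamform(analytic[a], tables, a, apod, t0, sample_rate)
                for a in range(rf_frame.shape[0])]
        out.append(compound(lows))
    iq = np.stack(out, axis=-1)
    return IQImageSequence(iq=iq, grid=tables.grid, frame_rate=frame_rate,
                           carrier_frequency=tables.probe.center_frequency,
                           medium=tables.medium)


def beamform_cube(cube, tables: DelayTables,
                  acceptance_deg: float = DEFAULT_ACCEPTANCE_DEG
                  ) -> IQImageSequence:
    """Beamform a :class:`~osteoflow.simulator.ChannelDataCube`."""
    frames = ((cube.rf[f], cube.t0) for f in range(cube.rf.shape[0]))
    seq = beamform_frames(frames, tables, cube.sample_rate,
                          cube.protocol.frame_rate, acceptance_deg)
    return seq


def transverse_oscillation_pair(seq: IQImageSequence, lambda0x: float = 3.5,
                                axial_band: tuple[float, float] | None = None
                                ) -> TOImagePair:
    """Build the TO image pair by spectral filtering of each frame.

    Multiplies the lateral spatial spectrum with Gaussian passbands centred
    at +-1/lambda0x (sigma_f = 1/(4*lambda0x)); ``s_plus`` keeps the positive
    lateral-frequency band, ``s_minus`` the negative one.

    ``axial_band = (center, sigma)`` in cycles/mm applies, in addition, a
    Gaussian passband to the axial spatial spectrum around the (positive)
    analytic carrier.  The broadband beamformed pulse has a spatially varying
    axial phase slope; narrowbanding enforces one clean axial carrier
    lambda_z = 2/center (two-way), which the phase estimator requires for an
    unbiased depth-velocity.  Requires the z-pitch to resolve the carrier.
    """
    grid = seq.grid
    dx = grid.pixel_pitch
    nx = grid.x_coords.size
    extent = grid.x_coords[-1] - grid.x_coords[0]
    if extent < 2 * lambda0x:
        raise ValueError("grid lateral extent must be >= 2*lambda0x")
    if lambda0x <= 2 * dx:
        raise ValueError("lambda0x must exceed 2 pixels")
    f0x = 1.0 / lambda0x
    sigma_f = 1.0 / (4.0 * lambda0x)
    fx = np.fft.fftfreq(nx, d=dx)
    nyq = 0.5 / dx
    if f0x + 2 * sigma_f > nyq:
        raise ValueError("TO passband exceeds the lateral Nyquist frequency")
    h_plus = np.exp(-0.5 * ((fx - f0x) / sigma_f) ** 2)
    h_minus = np.exp(-0.5 * ((fx + f0x) / sigma_f) ** 2)
    work = seq.iq
    lambda_z = None
    if axial_band is not None:
        fc, fsig = axial_band
        dz = grid.z_coords[1] - grid.z_coords[0]
        if fc + 2 * fsig > 0.5 / dz:
            raise ValueError("axial passband exceeds the axial Nyquist "
                             "frequency; use a finer z-pitch")
        fz = np.fft.fftfreq(grid.z_coords.size, d=dz)
        hz = np.exp(-0.5 * ((fz - fc) / fsig) ** 2)
        work = np.fft.ifft(np.fft.fft(work, axis=1) * hz[None, :, None],
                           axis=1)
        lambda_z = 2.0 / fc
    spec = np.fft.fft(work, axis=0)
    s_plus = np.fft.ifft(spec * h_plus[:, None, None], axis=0)
    s_minus = np.fft.ifft(spec * h_minus[:, None, None], axis=0)

    def wrap(arr):
        return IQImageSequence(iq=arr, grid=grid, frame_rate=seq.frame_rate,
                               carrier_frequency=seq.carrier_frequency,
                               medium=seq.medium, lambda0x=lambda0x)

    return TOImagePair(s_plus=wrap(s_plus), s_minus=wrap(s_minus),
                       lambda0x=lambda0x, lambda_z=lambda_z)


def cortex_axial_carrier(tables: DelayTables, apodization: np.ndarray,
                         sigma: float = 0.25) -> tuple[float, float]:
    """Axial passband (center, sigma) in cycles/mm for the cortical layer.

    The center is the mean axial phase sensitivity (delay-table z-gradient)
    over the cortex pixels times the pulse center frequency -- i.e. the
    actual analytic carrier of the beamformed images inside the bone, which
    the refraction model sets via the (anisotropic) cortical wave speed.
    """
    kappa = axial_phase_sensitivity(tables, apodization)
    m = tables.medium
    z = tables.grid.z_coords
    sel = (z > m.interface_skin_bone_depth + 0.5) & \
          (z < m.interface_bone_marrow_depth - 0.5)
    center = float(kappa[:, sel].mean() * tables.probe.center_frequency)
    return center, sigma


def axial_phase_sensitivity(tables: DelayTables, apodization: np.ndarray
                            ) -> np.ndarray:
    """Round-trip delay change per mm of axial scatterer motion (us/mm).

    kappa(pixel) is the apodization-weighted mean, over transmits and
    elements, of the z-gradient of tau_tx + tau_rx.  In a homogeneous medium
    at normal incidence it equals 2/c; inside the cortex it reflects the
    (anisotropic) bone speed and the aperture geometry, and converts the
    Doppler phase into a velocity without assuming the tissue speed there:
    v_z = -phi / (2*pi*f0*kappa*dt).
    """
    dz = tables.grid.z_coords[1] - tables.grid.z_coords[0]
    gtx = np.gradient(tables.tx_delays, dz, axis=2)      # (na, nx, nz)
    grx = np.gradient(tables.rx_delays, dz, axis=2)      # (ne, nx, nz)
    w = apodization
    wsum = w.sum(axis=0)
    grx_mean = (w * grx).sum(axis=0) / np.where(wsum > 0, wsum, 1.0)
    gtx_mean = gtx.mean(axis=0)
    return gtx_mean + grx_mean


def axial_wavelength_map(tables: DelayTables, apodization: np.ndarray
                         ) -> np.ndarray:
    """Effective axial carrier wavelength lambda_z (mm) per pixel.

    Defined so that an axial displacement dz changes the pixel phase by
    4*pi*dz/lambda_z; equals c/f0 in a homogeneous medium at normal
    incidence.
    """
    kappa = axial_phase_sensitivity(tables, apodization)
    f0 = tables.probe.center_frequency
    return 2.0 / (f0 * np.where(kappa > 0, kappa, np.nan))


def envelope_db(image: np.ndarray) -> np.ndarray:
    """Envelope in dB re the image maximum."""
    env = np.abs(image)
    return 20 * np.log10(env / env.max() + 1e-30)


def psf_width(image: np.ndarray, grid: ImagingGrid, level_db: float = -6.0,
              axis: str = "x", oversample: int = 16) -> float:
    """Width (mm) of the envelope mainlobe at ``level_db`` through the peak.

    The profile through the envelope peak is Fourier-interpolated by
    ``oversample`` before measuring the crossing width.
    """
    env = np.abs(image)
    i, j = np.unravel_index(np.argmax(env), env.shape)
    if axis == "x":
        prof = env[:, j]
        pitch = grid.x_coords[1] - grid.x_coords[0]
    else:
        prof = env[i, :]
        pitch = grid.z_coords[1] - grid.z_coords[0]
    n = prof.size
    spec = np.fft.rfft(prof)
    fine = np.fft.irfft(spec, n * oversample) * oversample
    fine = fine[: n * oversample]
    ipk = int(np.argmax(fine))
    thr = fine[ipk] * 10 ** (level_db / 20.0)
    lo = ipk
    while lo > 0 and fine[lo] > thr:
        lo -= 1
    hi = ipk
    while hi < fine.size - 1 and fine[hi] > thr:
        hi += 1
    return (hi - lo) * pitch / oversample
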