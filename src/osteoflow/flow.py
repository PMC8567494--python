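"""Clutter rejection and velocity estimation.

The slow, spatially coherent signal of the quasi-static scene (bone matrix,
skin, marrow, hand-held probe drift) dominates the raw IQ sequence; moving
erythrocytes contribute a weak, rapidly decorrelating component.  A singular
value decomposition of the Casorati matrix (pixels x frames) separates the
two: the ``k`` strongest singular components are the clutter, the remainder
the blood signal.

Velocities are estimated from lag-1 temporal autocorrelation phases:

* :func:`to_vector_velocity` -- the transverse-oscillation 2D estimator.
  With the conjugate-carrier pair s+/s-, the half-sum of the two
  autocorrelation phases responds to axial (depth) motion only and the
  half-difference to lateral motion only, giving both in-plane components of
  the blood velocity at every pixel.
* :func:`kasai_axial_velocity` -- the conventional (Kasai) Doppler estimator
  applied per transmit ensemble, for the femoral-artery reference branch.

:func:`probe_drift_track` measures the slow probe-bone motion from the
clutter component by subpixel phase correlation against the first frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.registration import phase_cross_correlation

from osteoflow.reconstruction import IQImageSequence, TOImagePair


class RankError(ValueError):
    """Too few frames for the requested decomposition."""


@dataclass(frozen=True)
class ClutterFilterConfig:
    """Number of leading singular components removed as clutter."""

    threshold_k: int = 40

    def validate(self, n_frames: int) -> None:
        if not 0 <= self.threshold_k < n_frames:
            raise ValueError(
                f"threshold_k={self.threshold_k} must be in [0, frames={n_frames})")


@dataclass
class VelocityFieldSequence:
    """Estimated blood velocity components on the imaging grid.

    ``v_axial`` is along the bone axis (x, positive toward the heart);
    ``v_radial`` across the cortex (z, positive toward the marrow).  Both are
    (nx, nz, nt) in mm/s.  ``w_axial``/``w_radial`` are the per-pixel
    coherent Doppler energies of each component (used as spatial-averaging
    weights); ``alias`` flags pixels whose phase approached +-pi.
    """

    v_axial: np.ndarray
    v_radial: np.ndarray
    frame_rate: float
    w_axial: np.ndarray
    w_radial: np.ndarray
    alias: np.ndarray
    r_plus: np.ndarray | None = None     # sliding lag-1 autocorrelations
    r_minus: np.ndarray | None = None    # (kept for coherent ROI reduction)


def svd_clutter_filter(seq: np.ndarray, k: int
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Split an image sequence into (blood, clutter) by Casorati-matrix SVD.

    ``seq`` is (..., n_frames); the clutter is the sum of the ``k`` largest
    singular components, the blood the remainder, so blood + clutter
    reconstructs the input to machine precision for any k.
    """
    shape = seq.shape
    n_frames = shape[-1]
    if n_frames < 2:
        raise RankError("need at least 2 frames")
    if not 0 <= k < n_frames:
        raise ValueError(f"k={k} must be in [0, n_frames={n_frames})")
    if k == 0:
        return seq, np.zeros_like(seq)
    cas = seq.reshape(-1, n_frames)
    u, s, vh = np.linalg.svd(cas, full_matrices=False)
    clutter = (u[:, :k] * s[:k]) @ vh[:k]
    blood = cas - clutter
    return blood.reshape(shape), clutter.reshape(shape)


def suggest_clutter_threshold(seq: np.ndarray, floor_ratio: float = 1e-4
                              ) -> int:
    """Optional utility: clutter rank estimate from the singular spectrum.

    Returns the smallest k whose residual energy fraction (sum of squared
    singular values beyond k) drops below ``floor_ratio`` of the total --
    an energy-elbow heuristic.  The pipeline never selects its threshold
    automatically; this exists for exploratory use only.
    """
    cas = seq.reshape(-1, seq.shape[-1])
    s = np.linalg.svd(cas, compute_uv=False)
    e = s ** 2
    resid = 1.0 - np.cumsum(e) / e.sum()
    k = int(np.searchsorted(-resid, -floor_ratio)) + 1
    return min(k, s.size - 1)


def power_doppler(blood_seq: np.ndarray, smoothing_window: int = 9
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Power-Doppler map and smoothed per-pixel power series (linear units).

    ``pd_map`` is the temporal mean of |blood|^2 per pixel (proportional to
    the volume of blood in motion); ``pd_series`` is |blood|^2 smoothed by a
    centred moving average of ``smoothing_window`` frames.
    """
    p = np.abs(blood_seq) ** 2
    pd_map = p.mean(axis=-1)
    if smoothing_window > 1:
        kernel = np.ones(smoothing_window) / smoothing_window
        pad = smoothing_window // 2
        padded = np.concatenate(
            [p[..., :1].repeat(pad, axis=-1), p,
             p[..., -1:].repeat(smoothing_window - 1 - pad, axis=-1)], axis=-1)
        pd_series = np.apply_along_axis(
            lambda a: np.convolve(a, kernel, mode="valid"), -1, padded)
    else:
        pd_series = p
    return pd_map, pd_series


def _sliding_lag1(seq: np.ndarray, window: int) -> np.ndarray:
    """Sliding-window lag-1 autocorrelation R(t) = sum s(t+1) conj(s(t)).

    Returns (..., n_frames - 1) complex; window frames are averaged with
    stride 1 (centred, edges use the available part of the window).
    """
    prod = seq[..., 1:] * np.conj(seq[..., :-1])
    if window <= 1:
        return prod
    n = prod.shape[-1]
    win = min(window, n)
    c = np.cumsum(prod, axis=-1)
    out = np.empty_like(prod)
    half = win // 2
    for t in range(n):
        lo = max(0, t - half)
        hi = min(n, lo + win)
        lo = max(0, hi - win)
        s = c[..., hi - 1] - (c[..., lo - 1] if lo > 0 else 0)
        out[..., t] = s / (hi - lo)
    return out


def to_vector_velocity(pair: TOImagePair, dt: float | None = None,
                       ensemble: int = 10,
                       lambda_z_map: np.ndarray | float | None = None,
                       alias_margin: float = 0.05) -> VelocityFieldSequence:
    """Transverse-oscillation 2D vector velocity from a clutter-filtered pair.

    Per pixel and sliding ensemble, the lag-1 autocorrelations R+ and R- of
    s_plus/s_minus give phases phi+ and phi-:

    * phi_sum  = (phi+ + phi-)/2 responds only to axial (z) motion through
      the two-way carrier: v_radial = -phi_sum * lambda_z / (4*pi*dt);
    * phi_diff = (phi+ - phi-)/2 responds only to lateral (x) motion through
      the one-way TO carrier: v_axial = -phi_diff * lambda0x / (2*pi*dt).

    Signs map positive v_axial to motion toward the heart (+x) and positive
    v_radial toward the marrow (+z).  ``lambda_z_map`` defaults to c/f0 of
    the sequence medium's tissue speed; pass the per-pixel map from
    :func:`osteoflow.reconstruction.axial_wavelength_map` for layered scenes.
    Pixels with |phi| within ``alias_margin`` of pi are flagged, not
    corrected.
    """
    sp, sm = pair.s_plus, pair.s_minus
    if dt is None:
        dt = 1.0 / sp.frame_rate
    if lambda_z_map is None:
        if sp.medium is None:
            raise ValueError("need lambda_z_map or a sequence medium")
        lambda_z_map = (sp.medium.c_tissue / 1000.0) / sp.carrier_frequency
    lam_z = np.asarray(lambda_z_map)
    rp = _sliding_lag1(sp.iq, ensemble)
    rm = _sliding_lag1(sm.iq, ensemble)
    phi_p = np.angle(rp)
    phi_m = np.angle(rm)
    phi_sum = 0.5 * (phi_p + phi_m)
    phi_diff = 0.5 * (phi_p - phi_m)
    v_radial = -phi_sum * lam_z[..., None] / (4 * np.pi * dt)
    v_axial = -phi_diff * pair.lambda0x / (2 * np.pi * dt)
    alias = (np.abs(phi_p) > (1 - alias_margin) * np.pi) | \
            (np.abs(phi_m) > (1 - alias_margin) * np.pi)
    w_axial = np.abs(rp - rm).sum(axis=-1) / 2.0
    w_radial = np.abs(np.imag(rp + rm)).sum(axis=-1) / 2.0
    return VelocityFieldSequence(v_axial=v_axial, v_radial=v_radial,
                                 frame_rate=1.0 / dt, w_axial=w_axial,
                                 w_radial=w_radial, alias=alias,
                                 r_plus=rp, r_minus=rm)


def effective_lateral_carrier(blood_plus: np.ndarray, grid_pitch_x: float,
                              z_slice: slice | np.ndarray = slice(None)
                              ) -> float:
    """Centroid (cycles/mm) of the lateral spatial spectrum of s_plus blood.

    The Gaussian TO passband is pulled toward lower frequencies by the
    band-limited image spectrum, so the carrier actually present in the
    filtered images sits below 1/lambda0x; the phase-to-velocity conversion
    uses this measured centroid instead of the nominal passband centre.
    """
    nx = blood_plus.shape[0]
    fx = np.fft.fftfreq(nx, d=grid_pitch_x)
    power = (np.abs(np.fft.fft(blood_plus[:, z_slice, :], axis=0)) ** 2
             ).mean(axis=tuple(range(1, blood_plus.ndim)))
    return float((power * fx).sum() / power.sum())


def kasai_axial_velocity(ensemble: np.ndarray, f0: float, c: float, prf: float,
                         steer_angle: float, vessel_axis_angle: float = 0.0,
                         rx_angle: float = 0.0
                         ) -> tuple[np.ndarray, float]:
    """Kasai (lag-1 autocorrelation) velocity per pixel from one ensemble.

    ``ensemble`` is (nx, nz, n) clutter-filtered complex images from ``n``
    identical transmits at ``prf``.  The Doppler phase of a displacement d is
    2*pi*f0/c * d . (k_tx + k_rx), i.e. the tx/rx bisector direction with a
    cos(separation/2) gain; the velocity is then projected on the vessel
    axis.  With rx_angle == steer_angle this reduces to the conventional
    two-way formula v_b*prf*c/(4*pi*f0) with a cos(beam-vessel) correction.

    Parameters
    ----------
    f0 : MHz; c : m/s; prf : Hz; angles in rad (from the z axis, in-plane).
    vessel_axis_angle : angle of the vessel axis from the *x* axis.

    Returns
    -------
    (velocity_map mm/s along the vessel axis, mean Doppler power).
    """
    if ensemble.shape[-1] < 2:
        raise RankError("ensemble needs at least 2 images")
    bis = 0.5 * (steer_angle + rx_angle)
    sep = 0.5 * abs(steer_angle - rx_angle)
    # angle between the bisector direction (from z axis) and the vessel axis
    # (from x axis): their unit vectors are (sin bis, cos bis) and
    # (cos va, sin va)
    cos_beam_vessel = (math.sin(bis) * math.cos(vessel_axis_angle)
                       + math.cos(bis) * math.sin(vessel_axis_angle))
    if abs(cos_beam_vessel) < math.cos(math.radians(85.0)):
        raise ValueError("beam and vessel axis within 5 deg of perpendicular")
    r1 = (ensemble[..., 1:] * np.conj(ensemble[..., :-1])).sum(axis=-1)
    phi = np.angle(r1)
    c_mm_s = c * 1000.0
    # displacement per pulse along the bisector (mm)
    d_bis = -phi * c_mm_s / (4 * np.pi * f0 * 1e6 * math.cos(sep))
    v = d_bis * prf / cos_beam_vessel
    power = float(np.mean(np.abs(ensemble) ** 2))
    return v, power


def probe_drift_track(clutter_seq: np.ndarray,
                      grid_pitch: float | tuple[float, float],
                      frame_rate: float, upsample: int = 400,
                      min_correlation: float = 0.5,
                      velocity_smoothing_s: float = 0.25
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Track rigid probe-bone motion from the clutter (or raw) sequence.

    Subpixel phase correlation of each frame's envelope against the first
    frame gives the cumulative 2D displacement (mm, (nt, 2) as (dx, dz)).
    The velocity (mm/s) is the time derivative of the displacement after a
    short moving average (drift is slow; the raw staircase is dominated by
    the tracker's 1/upsample quantization).  Raises when an image pair
    decorrelates (normalized cross-correlation peak below
    ``min_correlation``).
    """
    pitch = np.broadcast_to(np.asarray(grid_pitch, dtype=float), (2,))
    env = np.abs(clutter_seq)
    ref = env[..., 0]
    nt = env.shape[-1]
    disp = np.zeros((nt, 2))
    for t in range(1, nt):
        img = env[..., t]
        shift, error, _ = phase_cross_correlation(
            ref, img, upsample_factor=upsample, normalization=None)
        a = ref - ref.mean()
        b = img - img.mean()
        ncc = float((a * b).sum() / math.sqrt((a ** 2).sum() * (b ** 2).sum()))
        if ncc < min_correlation:
            raise RuntimeError(f"frame {t}: decorrelation (ncc={ncc:.2f})")
        # phase_cross_correlation returns the shift to register the moving
        # image onto the reference; the scene moved by the negative of it
        disp[t] = -shift * pitch
    n_smooth = max(1, int(round(velocity_smoothing_s * frame_rate)))
    if n_smooth > 1 and nt > n_smooth:
        kernel = np.ones(n_smooth) / n_smooth
        pad = n_smooth // 2
        sm = np.stack([np.convolve(
            np.concatenate([np.repeat(d[0], pad), d,
                            np.repeat(d[-1], n_smooth - 1 - pad)]),
            kernel, mode="valid") for d in disp.T], axis=1)
    else:
        sm = disp
    vel = np.gradient(sm, 1.0 / frame_rate, axis=0)
    return disp, vel


def cardiac_band_fraction(series: np.ndarray, sample_rate: float,
                          band: tuple[float, float] = (0.7, 3.0)) -> float:
    """Fraction of non-DC spectral energy inside the cardiac band (Hz).

    Used to verify that tracked probe drift shows no pulsatility.
    """
    x = np.asarray(series, dtype=float)
    x = x - x.mean()
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, d=1.0 / sample_rate)
    total = spec[1:].sum()
    if total == 0:
        return 0.0
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return float(spec[sel].sum() / total)
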