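"""Run configuration: strict YAML schema with resolvable defaults.

One config file describes a full recording-and-analysis run: probe, layered
medium, acquisition protocol, phantom, clutter filter, transverse
oscillations, hemodynamics and seeds.  Unknown keys are rejected with the
offending key path so typos fail fast rather than silently falling back to
defaults.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from osteoflow.acoustics import LayeredMediumModel, ProbeModel


class ConfigError(ValueError):
    """Schema violation; the message names the offending key path."""


@dataclass
class ProbeConfig:
    element_count: int = 64
    pitch_mm: float = 0.3
    center_frequency_mhz: float = 2.5
    sampling_frequency_mhz: float = 10.0
    pulse_bandwidth: float = 0.6

    def build(self) -> ProbeModel:
        return ProbeModel(self.element_count, self.pitch_mm,
                          self.center_frequency_mhz,
                          self.sampling_frequency_mhz, self.pulse_bandwidth)


@dataclass
class MediumConfig:
    # defaults are design values for a healthy tibia, not measured constants
    interface_skin_bone_depth_mm: float = 8.0
    interface_bone_marrow_depth_mm: float = 13.0
    c_tissue_m_s: float = 1570.0
    c_marrow_m_s: float = 1480.0
    bone_c0_m_s: float = 3300.0
    bone_a2: float = 0.06
    bone_a4: float = 0.01

    def build(self) -> LayeredMediumModel:
        return LayeredMediumModel(
            self.interface_skin_bone_depth_mm,
            self.interface_bone_marrow_depth_mm,
            self.c_tissue_m_s, self.c_marrow_m_s,
            (self.bone_c0_m_s, self.bone_a2, self.bone_a4))


@dataclass
class ProtocolConfig:
    mode: str = "bone_compound"
    angle_min_deg: float = -8.0
    angle_max_deg: float = 8.0
    n_angles: int = 15
    frames: int = 400
    frame_rate_hz: float = 100.0
    ensemble_size: int = 30
    prf_hz: float = 5000.0
    steer_angle_deg: float = 20.0


@dataclass
class PhantomConfig:
    kind: str = "cortical"
    lateral_extent_mm: float = 20.0
    depth_mm: float = 16.0
    blood_fraction_axial: float = 0.7
    n_radial_strips: int = 1
    heart_rate_bpm: float = 60.0
    axial_peak_mm_s: float = -10.0
    axial_baseline_mm_s: float = -0.5
    radial_peak_mm_s: float = -2.0
    radial_baseline_mm_s: float = -0.1
    systolic_fraction: float = 0.3
    drift_amplitude_mm: float = 0.4
    noise_snr_db: float = 30.0
    density_tissue: float = 1.2
    density_cortex: float = 2.0
    density_marrow: float = 0.8
    density_blood: float = 3.0
    # artery scene
    tube_center_depth_mm: float = 20.0
    tube_radius_mm: float = 2.5
    v_center_mm_s: float = 470.0


@dataclass
class GridConfig:
    x_min_mm: float = -10.0
    x_max_mm: float = 10.0
    z_min_mm: float = 1.0
    z_max_mm: float = 16.0
    pitch_mm: float = 0.5
    pitch_z_mm: float = 0.125


@dataclass
class FilterConfig:
    k: int = 12            # clutter components removed for axial/PD routes
    k_radial: int = 18     # heavier threshold for the slow transcortex route
    k_artery: int = 3      # per-ensemble threshold in the artery branch


@dataclass
class TOConfig:
    lambda0x_mm: float = 3.5
    axial_band_sigma_per_mm: float = 0.25
    radial_pair_center_per_mm: float = 0.35
    radial_pair_sigma_per_mm: float = 0.2
    ensemble_frames: int = 6
    method: str = "spectral"


@dataclass
class HemodynamicsConfig:
    roi_lateral_extent_mm: float = 15.0
    n_keep: int = 5
    band_low_hz: float = 0.3
    band_high_hz: float = 10.0
    pd_smoothing_frames: int = 9
    axial_mask_fraction: float = 0.5
    radial_mask_fraction: float = 1.0


@dataclass
class RunConfig:
    probe: ProbeConfig = field(default_factory=ProbeConfig)
    medium: MediumConfig = field(default_factory=MediumConfig)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    grid: GridConfig = field(default_factory=GridConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    to: TOConfig = field(default_factory=TOConfig)
    hemodynamics: HemodynamicsConfig = field(default_factory=HemodynamicsConfig)
    seed: int = 0
    forward_speed_perturbation: float = 0.005
    output_dir: str = "."

    def validate(self) -> None:
        if self.filter.k >= self.protocol.frames or \
                self.filter.k_radial >= self.protocol.frames:
            raise ConfigError(
                "filter.k: SVD threshold must be below protocol.frames")
        if self.filter.k < 0 or self.filter.k_radial < 0:
            raise ConfigError("filter.k: must be non-negative")
        if self.filter.k_artery >= self.protocol.ensemble_size:
            raise ConfigError(
                "filter.k_artery: must be below protocol.ensemble_size")
        if self.to.lambda0x_mm <= 2 * self.grid.pitch_mm:
            raise ConfigError("to.lambda0x_mm: must exceed two pixels")
        self.probe.build()
        self.medium.build()

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _from_mapping(cls, data, path=""):
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path or 'config'}: expected a mapping")
    known = {f.name: f for f in fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in known:
            raise ConfigError(f"unknown key {path + key!r}")
        f = known[key]
        if hasattr(f.type, "__dataclass_fields__") or f.name in (
                "probe", "medium", "protocol", "phantom", "grid", "filter",
                "to", "hemodynamics"):
            sub = {"probe": ProbeConfig, "medium": MediumConfig,
                   "protocol": ProtocolConfig, "phantom": PhantomConfig,
                   "grid": GridConfig, "filter": FilterConfig,
                   "to": TOConfig, "hemodynamics": HemodynamicsConfig}[f.name]
            kwargs[key] = _from_mapping(sub, value, path=f"{path}{key}.")
        else:
            kwargs[key] = value
    return cls(**kwargs)


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Load a RunConfig from YAML (all keys optional); validate strictly."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if overrides:
        data = {**data, **overrides}
    cfg = _from_mapping(RunConfig, data)
    cfg.validate()
    return cfg


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)
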