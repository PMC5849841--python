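"""Synthetic B-mode phantom and in-air images with analytic ground truth.

The simulator renders log-compressed speckle images of a CIRS 040GSE-like
tissue-mimicking phantom — attenuating Rayleigh speckle background, ±dB
contrast cylinders, a column of Gaussian pin targets — together with paired
in-air noise images, so every measurement in the package can be validated
against a known answer.

Model
-----
Each pixel carries a complex echo amplitude.  Homogeneous gel contributes
circular complex Gaussian speckle whose Rayleigh envelope scale at depth
``z`` (cm) is ``A0 · 10^(−2·α·f·z/20)`` (round-trip amplitude attenuation
with the one-way attenuation coefficient α in dB/cm/MHz), multiplied by
``10^(contrast/20)`` inside contrast cylinders.  Pins add deterministic
Gaussian amplitude blobs coherently (to the in-phase component).  Electronic
noise adds an independent complex Gaussian of per-component RMS ``N0``
(hence a Rayleigh envelope of scale ``N0`` in air).  The envelope is then
amplified (overall gain, optional TGC), log-compressed at ``s`` gray levels
per dB with the reference amplitude mapped to the top code, quantized, and
passed through the display gray map:

    pixel = graymap( clip( round( s·20·log10(gain·env/ref) + 255 ), 0, 255 ) )

Both ``A0`` and ``N0`` are Rayleigh scale parameters, so mean-envelope
factors cancel in gel/air gray-level ratios and the analytic SNR=1 crossing
is ``z* = 20·log10(A0_eff/N0) / (2·α·f)`` cm.  By default the gel member of
a pair is rendered speckle-only (see ``noise_in_gel`` in the docs): a gel
image carrying the full noise floor can never fall below the air image in
mean gray level, which would make the ratio-based penetration estimator
censored by construction.

Speckle is modeled per pixel with no lateral correlation; this exercises the
analyzers but is not a physical beam simulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .image_io import (
    AcquisitionSettings,
    BModeImage,
    ContrastTarget,
    PhantomModel,
    Rect,
    save_image,
)

__all__ = [
    "CylinderSpec",
    "GroundTruth",
    "PinSpec",
    "SimulationConfig",
    "WIDTH_FACTOR_6DB",
    "default_contrast_config",
    "default_dop_config",
    "default_resolution_config",
    "gamma_map",
    "hourglass_sigma",
    "make_protocol_fixtures",
    "phantom_model_for",
    "simulate_air_image",
    "simulate_gel_image",
    "simulate_tilted_pin_image",
]

#: Full −6 dB width of a Gaussian amplitude profile, in units of its σ:
#: solving exp(−x²/2σ²) = 10^(−6/20) gives half-width 1.17741·σ… times 2.
WIDTH_FACTOR_6DB = 2.0 * np.sqrt(2.0 * 6.0 * np.log(10.0) / 20.0)


class PinSpec(NamedTuple):
    """A pin target: position, per-axis Gaussian beam σ (mm), and linear peak
    amplitude (unattenuated)."""

    depth_mm: float
    lateral_mm: float
    sigma_axial_mm: float
    sigma_lateral_mm: float
    sigma_elevational_mm: float
    amplitude: float


class CylinderSpec(NamedTuple):
    """A contrast cylinder: center, diameter, and contrast in dB relative to
    the background."""

    depth_mm: float
    lateral_mm: float
    diameter_mm: float
    contrast_db: float


@dataclass
class SimulationConfig:
    """Scene description for the phantom simulator.

    ``background_echogenicity`` (A0) and ``noise_rms`` (N0) are Rayleigh
    envelope scale parameters on the same linear amplitude scale as
    ``compression_reference`` (the amplitude mapped to the top gray code).
    ``compression_slope`` s (gray/dB) relates to displayed dynamic range as
    s = 256/DR.  ``power_pct`` scales the transmit amplitude by
    ``sqrt(power/100)``; ``gain_db`` is a pre-compression receive gain that
    amplifies signal and noise alike.
    """

    rows: int = 256
    cols: int = 256
    axial_spacing: float = 0.1  # mm/row
    lateral_spacing: float = 0.1  # mm/col
    depth_offset: float = 0.0  # mm
    background_echogenicity: float = 1.0  # A0, Rayleigh scale
    attenuation: float = 0.7  # dB/cm/MHz, one-way
    frequency: float = 5.0  # MHz
    tgc_db: np.ndarray | None = None  # optional per-row receive gain, dB
    pins: list[PinSpec] = field(default_factory=list)
    contrast_cylinders: list[CylinderSpec] = field(default_factory=list)
    noise_rms: float = 0.0  # N0, Rayleigh scale of the electronic noise
    compression_slope: float = 5.0  # s, gray levels per dB
    compression_reference: float = 1.0  # amplitude mapped to gray 255
    gray_map: np.ndarray | None = None  # forward display LUT (256 codes)
    gray_map_id: str = "identity"
    gain_db: float = 0.0
    power_pct: float = 100.0
    noise_in_gel: bool = False
    ramp_roi: Rect | None = None
    transducer_id: str = "SIM"
    focal_depth_mm: float | None = None
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if self.axial_spacing <= 0 or self.lateral_spacing <= 0:
            raise ValueError("pixel spacings must be > 0")
        if self.compression_slope <= 0:
            raise ValueError("compression_slope must be > 0")
        if self.compression_reference <= 0:
            raise ValueError("compression_reference must be > 0")
        if self.background_echogenicity < 0 or self.noise_rms < 0:
            raise ValueError("amplitudes must be non-negative")
        if not (0 < self.power_pct <= 100):
            raise ValueError("power_pct must be in (0, 100]")
        self.pins = [PinSpec(*p) for p in self.pins]
        self.contrast_cylinders = [CylinderSpec(*c) for c in self.contrast_cylinders]
        for p in self.pins:
            if min(p.sigma_axial_mm, p.sigma_lateral_mm, p.sigma_elevational_mm) <= 0:
                raise ValueError("pin beam sigmas must be > 0")
            if p.amplitude <= 0:
                raise ValueError("pin amplitudes must be > 0")
        if self.ramp_roi is not None:
            self.ramp_roi = Rect(*self.ramp_roi)

    @property
    def dynamic_range(self) -> float:
        """Displayed dynamic range implied by the compression slope (dB)."""
        return 256.0 / self.compression_slope

    def settings(self) -> AcquisitionSettings:
        return AcquisitionSettings(
            transducer_id=self.transducer_id,
            transmit_frequency=self.frequency,
            gain=self.gain_db,
            power=self.power_pct,
            dynamic_range=self.dynamic_range,
            gray_map_id=self.gray_map_id,
            focal_depth=self.focal_depth_mm,
        )


@dataclass
class GroundTruth:
    """Analytic expected values for a simulated scene."""

    expected_contrast_slope: float  # gray/dB (= compression slope)
    expected_widths: list[dict[str, float]]  # per pin, axis -> −6 dB width, mm
    expected_dop_cm: float | None
    target_centers: list[tuple[float, float]]  # (depth, lateral) mm
    pin_centers: list[tuple[float, float]]


def gamma_map(gamma: float, bit_depth: int = 8) -> np.ndarray:
    """Forward display gray map ``g(v) = max·(v/max)^gamma`` as a LUT table."""
    max_code = 2**bit_depth - 1
    v = np.arange(max_code + 1, dtype=float)
    return np.clip(np.round(max_code * (v / max_code) ** gamma), 0, max_code).astype(np.int64)


def hourglass_sigma(depth_mm, focus_mm: float, sigma_at_focus_mm: float,
                    depth_of_field_mm: float):
    """Beam-width profile σ(z) = σ0·sqrt(1 + ((z−z_f)/DOF)²).

    A diffraction-style hourglass: narrowest (σ0) at the focal depth,
    broadening symmetrically away from it with characteristic scale
    ``depth_of_field_mm``.
    """
    z = np.asarray(depth_mm, dtype=float)
    out = sigma_at_focus_mm * np.sqrt(1.0 + ((z - focus_mm) / depth_of_field_mm) ** 2)
    return float(out) if np.isscalar(depth_mm) else out


def _amplitude_factor(config: SimulationConfig) -> float:
    return np.sqrt(config.power_pct / 100.0)


def _attenuation_amp(config: SimulationConfig, z_mm: np.ndarray) -> np.ndarray:
    db = 2.0 * config.attenuation * config.frequency * (z_mm / 10.0)
    return 10.0 ** (-db / 20.0)


def _scale_map(config: SimulationConfig) -> np.ndarray:
    """Rayleigh scale of the speckle field per pixel (background + cylinders)."""
    z = config.depth_offset + np.arange(config.rows) * config.axial_spacing
    x = np.arange(config.cols) * config.lateral_spacing
    scale = (
        config.background_echogenicity
        * _amplitude_factor(config)
        * _attenuation_amp(config, z)[:, None]
        * np.ones((1, config.cols))
    )
    zz = z[:, None]
    xx = x[None, :]
    for cyl in config.contrast_cylinders:
        inside = (zz - cyl.depth_mm) ** 2 + (xx - cyl.lateral_mm) ** 2 <= (cyl.diameter_mm / 2) ** 2
        scale[inside] *= 10.0 ** (cyl.contrast_db / 20.0)
    return scale


def _pin_field(config: SimulationConfig, tilted: bool) -> np.ndarray:
    """Deterministic coherent pin amplitude map (local 5σ windows per pin)."""
    field_map = np.zeros((config.rows, config.cols))
    z = config.depth_offset + np.arange(config.rows) * config.axial_spacing
    x = np.arange(config.cols) * config.lateral_spacing
    amp_f = _amplitude_factor(config)
    for pin in config.pins:
        sig_lat = (
            float(np.hypot(pin.sigma_elevational_mm, pin.sigma_lateral_mm))
            if tilted
            else pin.sigma_lateral_mm
        )
        r0 = np.searchsorted(z, pin.depth_mm - 5 * pin.sigma_axial_mm)
        r1 = np.searchsorted(z, pin.depth_mm + 5 * pin.sigma_axial_mm)
        c0 = np.searchsorted(x, pin.lateral_mm - 5 * sig_lat)
        c1 = np.searchsorted(x, pin.lateral_mm + 5 * sig_lat)
        if r1 <= r0 or c1 <= c0:
            continue
        gz = np.exp(-((z[r0:r1] - pin.depth_mm) ** 2) / (2 * pin.sigma_axial_mm**2))
        gx = np.exp(-((x[c0:c1] - pin.lateral_mm) ** 2) / (2 * sig_lat**2))
        atten = _attenuation_amp(config, z[r0:r1])
        field_map[r0:r1, c0:c1] += (
            pin.amplitude * amp_f * (gz * atten)[:, None] * gx[None, :]
        )
    return field_map


def _compress(config: SimulationConfig, envelope: np.ndarray) -> np.ndarray:
    max_code = 2**config.bit_depth - 1
    env = envelope * 10.0 ** (config.gain_db / 20.0)
    if config.tgc_db is not None:
        tgc = np.asarray(config.tgc_db, dtype=float)
        if tgc.size != config.rows:
            raise ValueError("tgc_db must have one entry per image row")
        env = env * (10.0 ** (tgc / 20.0))[:, None]
    with np.errstate(divide="ignore"):
        gray = config.compression_slope * 20.0 * np.log10(env / config.compression_reference)
    gray = np.clip(np.round(gray + max_code), 0, max_code).astype(np.int64)
    if config.gray_map is not None:
        table = np.asarray(config.gray_map, dtype=np.int64)
        if table.size != max_code + 1:
            raise ValueError("gray_map table must cover every code")
        gray = table[gray]
    if config.ramp_roi is not None:
        gray = _paint_ramp(config, gray)
    return gray


def _paint_ramp(config: SimulationConfig, gray: np.ndarray) -> np.ndarray:
    """Overwrite the ramp ROI with the display's rendering of a linear input
    sweep (dark to bright along the strip's long axis)."""
    max_code = 2**config.bit_depth - 1
    r = config.ramp_roi
    h, w = r.row_stop - r.row_start, r.col_stop - r.col_start
    n = max(h, w)
    sweep = np.round(np.linspace(0.0, float(max_code), n)).astype(np.int64)
    if config.gray_map is not None:
        sweep = np.asarray(config.gray_map, dtype=np.int64)[sweep]
    block = np.repeat(sweep[:, None], w, axis=1) if h >= w else np.repeat(sweep[None, :], h, axis=0)
    out = gray.copy()
    out[r.slices()] = block
    return out


def _ground_truth(config: SimulationConfig, tilted: bool) -> GroundTruth:
    widths = []
    for pin in config.pins:
        if tilted:
            apparent = float(np.hypot(pin.sigma_elevational_mm, pin.sigma_lateral_mm))
            widths.append(
                {
                    "elevational": WIDTH_FACTOR_6DB * pin.sigma_elevational_mm,
                    "elevational_apparent": WIDTH_FACTOR_6DB * apparent,
                    "axial": WIDTH_FACTOR_6DB * pin.sigma_axial_mm,
                }
            )
        else:
            widths.append(
                {
                    "lateral": WIDTH_FACTOR_6DB * pin.sigma_lateral_mm,
                    "axial": WIDTH_FACTOR_6DB * pin.sigma_axial_mm,
                }
            )
    dop = None
    if (
        config.noise_rms > 0
        and config.background_echogenicity > 0
        and config.attenuation > 0
        and config.frequency > 0
    ):
        a_eff = config.background_echogenicity * _amplitude_factor(config)
        snr0_db = 20.0 * np.log10(a_eff / config.noise_rms)
        dop = float(snr0_db / (2.0 * config.attenuation * config.frequency))
    return GroundTruth(
        expected_contrast_slope=config.compression_slope,
        expected_widths=widths,
        expected_dop_cm=dop,
        target_centers=[(c.depth_mm, c.lateral_mm) for c in config.contrast_cylinders],
        pin_centers=[(p.depth_mm, p.lateral_mm) for p in config.pins],
    )


def speckle_field(rng: np.random.Generator, scale: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """In-phase/quadrature components of a circular complex Gaussian speckle
    field with the given per-pixel Rayleigh envelope scale."""
    shape = np.shape(scale)
    return rng.normal(0.0, 1.0, shape) * scale, rng.normal(0.0, 1.0, shape) * scale


def _simulate(config: SimulationConfig, seed, tilted: bool) -> tuple[BModeImage, GroundTruth]:
    rng = np.random.default_rng(seed)
    i_part, q_part = speckle_field(rng, _scale_map(config))
    if config.pins:
        i_part = i_part + _pin_field(config, tilted)
    if config.noise_in_gel and config.noise_rms > 0:
        i_part = i_part + rng.normal(0.0, config.noise_rms, i_part.shape)
        q_part = q_part + rng.normal(0.0, config.noise_rms, q_part.shape)
    envelope = np.hypot(i_part, q_part)
    image = BModeImage(
        pixels=_compress(config, envelope),
        bit_depth=config.bit_depth,
        axial_spacing=config.axial_spacing,
        lateral_spacing=config.lateral_spacing,
        depth_offset=config.depth_offset,
        settings=config.settings(),
    )
    return image, _ground_truth(config, tilted)


def simulate_gel_image(config: SimulationConfig, seed=None) -> tuple[BModeImage, GroundTruth]:
    """Render the gel (phantom) member of an acquisition, with ground truth.

    Reproducible: identical (config, seed) yields a bit-identical image.
    """
    return _simulate(config, seed, tilted=False)


def simulate_air_image(config: SimulationConfig, seed=None) -> BModeImage:
    """Render the paired in-air image: electronic noise only, identical
    compression, gray map and settings."""
    rng = np.random.default_rng(seed)
    shape = (config.rows, config.cols)
    if config.noise_rms > 0:
        envelope = np.hypot(
            rng.normal(0.0, config.noise_rms, shape), rng.normal(0.0, config.noise_rms, shape)
        )
    else:
        envelope = np.zeros(shape)
    return BModeImage(
        pixels=_compress(config, envelope),
        bit_depth=config.bit_depth,
        axial_spacing=config.axial_spacing,
        lateral_spacing=config.lateral_spacing,
        depth_offset=config.depth_offset,
        settings=config.settings(),
    )


def simulate_tilted_pin_image(
    config: SimulationConfig, tilt_degrees: float = 45.0, seed=None
) -> tuple[BModeImage, GroundTruth]:
    """Render the 45°-protocol image for elevational resolution.

    At 45° the in-plane streak of each filament equals the slice thickness,
    so pins are rendered with apparent lateral σ equal to the quadrature
    combination of the elevational and in-plane lateral beam widths; the
    ground truth records both the pure elevational and the broadened apparent
    −6 dB widths.  Only 45° is supported.
    """
    if tilt_degrees != 45.0:
        raise ValueError("only the 45-degree protocol is supported")
    return _simulate(config, seed, tilted=True)


def phantom_model_for(config: SimulationConfig) -> PhantomModel:
    """The PhantomModel describing a simulated scene, for the analyzers."""
    return PhantomModel(
        background_attenuation=config.attenuation,
        contrast_targets=[
            ContrastTarget(c.depth_mm, c.lateral_mm, c.diameter_mm, c.contrast_db)
            for c in config.contrast_cylinders
        ],
        pin_column=[p.depth_mm for p in config.pins],
        pin_lateral_mm=config.pins[0].lateral_mm if config.pins else 0.0,
        ramp_roi=config.ramp_roi,
    )


# ---------------------------------------------------------------------------
# Study-condition presets


def default_contrast_config() -> SimulationConfig:
    """Contrast-response scene: four 8 mm cylinders of −6/−3/+3/+6 dB at a
    common 30 mm depth in a 0.7 dB/cm/MHz background, with an on-screen
    grayscale ramp strip along the right edge."""
    cols = 640
    return SimulationConfig(
        rows=480,
        cols=cols,
        axial_spacing=0.1,
        lateral_spacing=0.15,
        contrast_cylinders=[
            CylinderSpec(30.0, 15.0, 8.0, -6.0),
            CylinderSpec(30.0, 35.0, 8.0, -3.0),
            CylinderSpec(30.0, 55.0, 8.0, +3.0),
            CylinderSpec(30.0, 75.0, 8.0, +6.0),
        ],
        attenuation=0.7,
        frequency=5.0,
        compression_slope=5.0,
        compression_reference=10.0 ** (8.0 / 20.0),  # background ≈ gray 110 at 30 mm
        noise_rms=0.0,
        ramp_roi=Rect(0, 480, cols - 12, cols),
        transducer_id="SIM-L",
    )


def default_dop_config() -> SimulationConfig:
    """Penetration scene: plain 0.7 dB/cm/MHz gel at 5 MHz with a 70 dB
    initial amplitude SNR, giving an analytic SNR=1 crossing at 10.0 cm
    within a 12 cm analysis window; 90 dB displayed dynamic range."""
    return SimulationConfig(
        rows=480,  # 12 cm at 0.25 mm/row
        cols=192,
        axial_spacing=0.25,
        lateral_spacing=0.3,
        attenuation=0.7,
        frequency=5.0,
        background_echogenicity=1.0,
        noise_rms=10.0 ** (-70.0 / 20.0),
        compression_slope=256.0 / 90.0,
        # 12 dB headroom over the background scale keeps the Rayleigh tail of
        # the shallowest rows off the top code (saturation screen stays clean)
        compression_reference=10.0 ** (12.0 / 20.0),
        transducer_id="SIM-L",
    )


def default_resolution_config() -> SimulationConfig:
    """Resolution scene: seven pins every 10 mm, depth-constant axial beam
    (σ 0.25 mm), hourglass lateral beam (σ 0.6 mm at the 40 mm focus) and
    hourglass elevational beam (σ 1.2 mm at the same focus); pins 30 dB above
    the speckle background."""
    pin_depths = [10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0]
    focus = 40.0
    amp = 10.0 ** (30.0 / 20.0)
    pins = [
        PinSpec(
            depth_mm=d,
            lateral_mm=25.0,
            sigma_axial_mm=0.25,
            sigma_lateral_mm=hourglass_sigma(d, focus, 0.6, 30.0),
            sigma_elevational_mm=hourglass_sigma(d, focus, 1.2, 25.0),
            amplitude=amp,
        )
        for d in pin_depths
    ]
    return SimulationConfig(
        rows=1280,  # 76.8 mm at 0.06 mm/row
        cols=840,
        axial_spacing=0.06,
        lateral_spacing=0.06,
        attenuation=0.7,
        frequency=5.0,
        pins=pins,
        compression_slope=256.0 / 90.0,
        compression_reference=amp * 0.9,  # pin peaks just below the top code
        noise_rms=0.0,
        transducer_id="SIM-L",
        focal_depth_mm=focus,
    )


# ---------------------------------------------------------------------------
# Protocol fixture sets

_PROTOCOL_BASES = {
    "contrast": default_contrast_config,
    "dop": default_dop_config,
    "resolution": default_resolution_config,
}

_GRAY_MAPS = {
    "identity": (None, "identity"),
    "gamma_0.5": (gamma_map(0.5), "gamma_0.5"),
    "gamma_2": (gamma_map(2.0), "gamma_2"),
}


def _apply_variant(base: SimulationConfig, changes: dict) -> SimulationConfig:
    """Translate a table of scan-parameter changes into simulator terms."""
    cfg = replace(base)
    for param, value in changes.items():
        if param == "gain":
            cfg = replace(cfg, gain_db=float(value))
        elif param == "dynamic_range":
            cfg = replace(cfg, compression_slope=256.0 / float(value))
        elif param == "gray_map":
            if value not in _GRAY_MAPS:
                raise ValueError(f"unknown gray map {value!r}; choose from {sorted(_GRAY_MAPS)}")
            table, name = _GRAY_MAPS[value]
            cfg = replace(cfg, gray_map=table, gray_map_id=name)
        elif param == "frequency":
            f_new = float(value)
            # beam width scales inversely with frequency; attenuation scales with it
            ratio = cfg.frequency / f_new
            pins = [
                p._replace(
                    sigma_axial_mm=p.sigma_axial_mm * ratio,
                    sigma_lateral_mm=p.sigma_lateral_mm * ratio,
                    sigma_elevational_mm=p.sigma_elevational_mm * ratio,
                )
                for p in cfg.pins
            ]
            cfg = replace(cfg, frequency=f_new, pins=pins)
        elif param == "power":
            cfg = replace(cfg, power_pct=float(value))
        elif param == "attenuation":
            cfg = replace(cfg, attenuation=float(value))
        else:
            raise ValueError(
                f"unknown stability/sensitivity parameter {param!r}; supported: "
                "gain, dynamic_range, gray_map, frequency, power, attenuation"
            )
    return cfg


_PROTOCOL_ROLES = {"contrast": ("gel",), "dop": ("gel", "air"), "resolution": ("pins", "pins45")}


def make_protocol_fixtures(
    protocol: str,
    variant_table: dict[str, dict],
    out_dir,
    base_config: SimulationConfig | None = None,
    n_seeds: int = 6,
    base_seed: int = 0,
):
    """Write a simulated stability/sensitivity image set plus a manifest.

    ``variant_table`` maps condition names to scan-parameter changes, e.g.
    ``{"power_50": {"power": 50}}``; a ``baseline`` condition with no changes
    is always included.  Supported parameters: ``gain`` (dB, pre-compression
    multiplier), ``dynamic_range`` (dB, sets the compression slope 256/DR),
    ``gray_map`` (identity / gamma_0.5 / gamma_2), ``frequency`` (MHz; scales
    beam σ and attenuation), ``power`` (percent; scales transmit amplitude),
    ``attenuation`` (dB/cm/MHz background).  Six seeds per condition by
    default, mirroring the six-acquisition averaging protocol.

    Returns the manifest as a pandas DataFrame; also written to
    ``out_dir/manifest.csv`` with one row per image (condition, seed, role,
    path, and the scene's analytic ground truth).
    """
    import pandas as pd

    if protocol not in _PROTOCOL_BASES:
        raise ValueError(f"unknown protocol {protocol!r}; choose from {sorted(_PROTOCOL_BASES)}")
    base = base_config if base_config is not None else _PROTOCOL_BASES[protocol]()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    conditions = {"baseline": {}}
    conditions.update(variant_table)
    rows = []
    for ci, (name, changes) in enumerate(conditions.items()):
        cfg = _apply_variant(base, changes)
        for i in range(n_seeds):
            for ri, role in enumerate(_PROTOCOL_ROLES[protocol]):
                seed = (base_seed * 1000003 + ci * 1009 + i * 13 + ri) % (2**31 - 1)
                if role == "gel" or role == "pins":
                    image, gt = simulate_gel_image(cfg, seed=seed)
                elif role == "pins45":
                    image, gt = simulate_tilted_pin_image(cfg, seed=seed)
                else:
                    image = simulate_air_image(cfg, seed=seed)
                    gt = _ground_truth(cfg, tilted=False)
                path = out_dir / f"{name}_{role}_{i}.png"
                save_image(image, path)
                rows.append(
                    dict(
                        condition=name,
                        changes=json.dumps(changes, sort_keys=True),
                        seed=seed,
                        role=role,
                        path=str(path),
                        expected_slope=gt.expected_contrast_slope,
                        expected_dop_cm=gt.expected_dop_cm,
                        expected_widths=json.dumps(gt.expected_widths),
                    )
                )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
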