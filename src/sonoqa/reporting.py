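"""Protocol execution, measurement records, and report aggregation.

A protocol file (YAML/JSON) describes a list of measurements to run, each
either on simulated scenes (a ``simulate`` block naming a preset and
scan-parameter overrides) or on image files on disk.  Every value lands in a
:class:`MeasurementRecord` carrying enough provenance (config hash, seed,
package version, input paths) to re-run it; re-running a protocol from its
own provenance reproduces every value bit-exactly.

Records are never averaged across different acquisition settings: the
aggregation key is the measurement id, which binds one settings tuple.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .calibration import (
    GrayMapLUT,
    extract_graymap_lut,
    locate_contrast_targets,
    measure_contrast_response,
)
from .image_io import BModeImage, load_image, load_phantom_model
from .penetration import compute_snr_profile, depth_of_penetration
from .qa import success_rate
from .resolution import detect_pins, measure_pin_width, select_reference_pin
from .simulate import (
    SimulationConfig,
    _apply_variant,
    _PROTOCOL_BASES,
    phantom_model_for,
    simulate_air_image,
    simulate_gel_image,
)

__all__ = ["MeasurementRecord", "ProtocolReport", "run_protocol"]


@dataclass
class MeasurementRecord:
    """One measured value with full provenance."""

    measurement_id: str
    timestamp: str
    transducer_id: str
    measurement_type: str  # contrast_slope | dop | lateral_width | axial_width
    value: float
    units: str
    method: str  # auto | manual
    flags: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["flags"] = ";".join(self.flags)
        d["provenance"] = json.dumps(self.provenance, sort_keys=True)
        return d


@dataclass
class ProtocolReport:
    """Aggregated outcome of a protocol run."""

    records: list[MeasurementRecord]
    summary: dict
    config_hash: str
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_dict() for r in self.records])

    def text_summary(self) -> str:
        lines = [f"sonoqa protocol report (config {self.config_hash[:12]}, seed {self.seed})"]
        for mid, stats in self.summary["measurements"].items():
            lines.append(
                f"  {mid} [{stats['type']}]: {stats['mean']:.4g} ± {stats['sd']:.2g} "
                f"{stats['units']} (n={stats['n']})"
                + (" FLAGGED" if stats["flagged"] else "")
            )
        sr = self.summary.get("success_rate")
        if sr is not None:
            lines.append(f"  semi-automated success rate: {sr['n_auto']}/{sr['n_total']} "
                         f"= {sr['rate']:.1%}")
        return "\n".join(lines)

    def write(self, out_dir) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out_dir / "records.csv", index=False)
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(self.summary, fh, indent=2, sort_keys=True)
        (out_dir / "summary.txt").write_text(self.text_summary() + "\n")
        return out_dir


def _canonical_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def _load_protocol(config) -> dict:
    if isinstance(config, dict):
        return config
    with open(config) as fh:
        return yaml.safe_load(fh)


def _sim_config(block: dict) -> SimulationConfig:
    preset = block.get("preset")
    if preset is not None:
        if preset not in _PROTOCOL_BASES:
            raise ValueError(f"unknown simulate preset {preset!r}")
        base = _PROTOCOL_BASES[preset]()
    else:
        base = SimulationConfig(**{k: v for k, v in block.items() if k != "overrides"})
    return _apply_variant(base, block.get("overrides", {}))


def run_protocol(config, out_dir=None, seed: int | None = None) -> ProtocolReport:
    """Execute a protocol and aggregate its records.

    ``config`` is a dict or a YAML/JSON path with keys ``seed`` (default 0,
    overridable by the ``seed`` argument) and ``measurements``: a list of
    blocks with ``id``, ``type`` (contrast | dop | resolution),
    ``n_acquisitions`` (default 6) and either a ``simulate`` block
    ({preset, overrides}) or file inputs (``gel``/``air`` path pairs for dop;
    ``image`` + ``phantom`` for contrast and resolution).

    Returns a :class:`ProtocolReport`; when ``out_dir`` is given, also writes
    ``records.csv``, ``summary.json`` and ``summary.txt`` there.  Exit-level
    errors (unreadable config, nothing to do, missing inputs) raise.
    """
    cfg = _load_protocol(config)
    measurements = cfg.get("measurements") or []
    if not measurements:
        raise ValueError("nothing to do: protocol lists no measurements")
    run_seed = int(cfg.get("seed", 0) if seed is None else seed)
    cfg_hash = _canonical_hash({k: v for k, v in cfg.items() if k != "seed"})
    timestamp = datetime.now(timezone.utc).isoformat(timespec="seconds")

    records: list[MeasurementRecord] = []
    for mi, block in enumerate(measurements):
        mtype = block.get("type")
        mid = block.get("id", f"{mtype}_{mi}")
        n_acq = int(block.get("n_acquisitions", 6))
        base_prov = {"config_hash": cfg_hash, "seed": run_seed, "version": __version__,
                     "measurement_index": mi}
        if mtype == "dop":
            records += _run_dop(block, mid, n_acq, run_seed, mi, timestamp, base_prov)
        elif mtype == "contrast":
            records += _run_contrast(block, mid, n_acq, run_seed, mi, timestamp, base_prov)
        elif mtype == "resolution":
            records += _run_resolution(block, mid, n_acq, run_seed, mi, timestamp, base_prov)
        else:
            raise ValueError(f"unknown measurement type {mtype!r}")

    summary: dict = {"config_hash": cfg_hash, "seed": run_seed, "version": __version__,
                     "measurements": {}}
    frame = pd.DataFrame([r.to_dict() for r in records])
    for (mid, mtype, units), grp in frame.groupby(
        ["measurement_id", "measurement_type", "units"], sort=False
    ):
        vals = grp["value"].to_numpy(dtype=float)
        summary["measurements"][f"{mid}:{mtype}"] = {
            "type": mtype,
            "units": units,
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            "n": int(vals.size),
            "flagged": bool((grp["flags"] != "").any()),
        }
    sr = success_rate([r.method for r in records])
    summary["success_rate"] = {"n_total": sr.n_total, "n_auto": sr.n_auto, "rate": sr.rate}

    report = ProtocolReport(records=records, summary=summary, config_hash=cfg_hash,
                            seed=run_seed)
    if out_dir is not None:
        report.write(out_dir)
    return report


def _acq_seed(run_seed: int, measurement_index: int, acq: int, role: int) -> int:
    return (run_seed * 1000003 + measurement_index * 7919 + acq * 13 + role) % (2**31 - 1)


def _pairs_for(block: dict, n_acq: int, run_seed: int, mi: int):
    """Yield (gel, air, provenance) tuples for a DOP block."""
    if "simulate" in block:
        sim = _sim_config(block["simulate"])
        for i in range(n_acq):
            s_gel = _acq_seed(run_seed, mi, i, 0)
            s_air = _acq_seed(run_seed, mi, i, 1)
            gel, _ = simulate_gel_image(sim, seed=s_gel)
            air = simulate_air_image(sim, seed=s_air)
            yield gel, air, {"gel_seed": s_gel, "air_seed": s_air}
    elif "pairs" in block:
        for pair in block["pairs"]:
            gel = load_image(pair["gel"])
            air = load_image(pair["air"])
            yield gel, air, {"gel": pair["gel"], "air": pair["air"]}
    else:
        raise ValueError("dop measurement needs a 'simulate' block or 'pairs' list")


def _run_dop(block, mid, n_acq, run_seed, mi, timestamp, base_prov):
    records = []
    lut = GrayMapLUT.identity()
    for gel, air, prov in _pairs_for(block, n_acq, run_seed, mi):
        profile = compute_snr_profile(gel, air, lut=lut)
        res = depth_of_penetration(profile)
        flags = [f for f, on in (("saturation", res.saturation_flag),
                                 ("censored", res.censored),
                                 ("shallow", res.shallow_flag)) if on]
        records.append(
            MeasurementRecord(
                measurement_id=mid, timestamp=timestamp,
                transducer_id=gel.settings.transducer_id if gel.settings else "unknown",
                measurement_type="dop", value=res.dop, units="cm", method="auto",
                flags=flags, provenance={**base_prov, **prov},
            )
        )
    return records


def _scenes_for(block: dict, n_acq: int, run_seed: int, mi: int, tilted: bool = False):
    if "simulate" in block:
        sim = _sim_config(block["simulate"])
        phantom = phantom_model_for(sim)
        for i in range(n_acq):
            s = _acq_seed(run_seed, mi, i, 2)
            image, _ = simulate_gel_image(sim, seed=s)
            yield image, phantom, {"seed": s}
    elif "image" in block:
        image = load_image(block["image"])
        phantom = load_phantom_model(block["phantom"])
        yield image, phantom, {"image": block["image"], "phantom": block["phantom"]}
    else:
        raise ValueError(f"{block.get('type')} measurement needs 'simulate' or 'image'+'phantom'")


def _lut_for(image: BModeImage, phantom) -> GrayMapLUT:
    if phantom.ramp_roi is not None:
        return extract_graymap_lut(image, phantom.ramp_roi)
    return GrayMapLUT.identity(image.bit_depth)


def _run_contrast(block, mid, n_acq, run_seed, mi, timestamp, base_prov):
    records = []
    for image, phantom, prov in _scenes_for(block, n_acq, run_seed, mi):
        lut = _lut_for(image, phantom)
        rois = locate_contrast_targets(image, phantom, lut=lut)
        ok = [r for r in rois if r.detection_status == "ok"]
        result = measure_contrast_response(image, ok, lut=lut)
        flags = list(result.flags) + (["saturation"] if result.saturation_flag else [])
        records.append(
            MeasurementRecord(
                measurement_id=mid, timestamp=timestamp,
                transducer_id=image.settings.transducer_id if image.settings else "unknown",
                measurement_type="contrast_slope", value=result.slope, units="gray/dB",
                method=result.detection_method, flags=flags,
                provenance={**base_prov, **prov},
            )
        )
    return records


def _run_resolution(block, mid, n_acq, run_seed, mi, timestamp, base_prov):
    from .calibration import ContrastResponseResult

    records = []
    slope = float(block.get("calibration_slope", 0.0))
    for image, phantom, prov in _scenes_for(block, n_acq, run_seed, mi):
        lut = _lut_for(image, phantom)
        if slope <= 0:
            if image.settings is None:
                raise ValueError("resolution needs calibration_slope or image settings with DR")
            cal_slope = 256.0 / image.settings.dynamic_range
        else:
            cal_slope = slope
        cal = ContrastResponseResult(slope=cal_slope, intercept=0.0, r_squared=1.0,
                                     per_target=[])
        detection = detect_pins(image, phantom, lut=lut)
        if detection.failed:
            raise ValueError(f"{mid}: no pins detected; supply manual centers")
        focal = image.settings.focal_depth if image.settings else None
        pin = select_reference_pin(detection, focal_depth_mm=focal,
                                   dop_cm=block.get("dop_cm"))
        for axis in ("lateral", "axial"):
            m = measure_pin_width(image, pin, axis, cal, lut=lut)
            records.append(
                MeasurementRecord(
                    measurement_id=mid, timestamp=timestamp,
                    transducer_id=image.settings.transducer_id if image.settings else "unknown",
                    measurement_type=f"{axis}_width", value=m.width_mm, units="mm",
                    method=detection.method, flags=m.flags,
                    provenance={**base_prov, **prov, "pin_depth_mm": pin.depth_mm},
                )
            )
    return records
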