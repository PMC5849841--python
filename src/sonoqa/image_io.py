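"""Reading, writing and screening of scan-converted B-mode raster images.

All measurements in this package consume :class:`BModeImage`: an 8-bit (by
default) grayscale raster whose rows index depth below the transducer face and
whose columns index lateral position, together with the physical pixel spacing
and the acquisition settings the image was made with.  Only scan-converted
images are supported; curved/sector acquisitions are analyzed in raster space
with depth taken along image rows.

Conventions
-----------
* Row 0 is the shallowest depth.  The physical depth of row ``r`` is
  ``depth_offset + r * axial_spacing`` (mm from the transducer face).
* All rectangular ROIs are half-open pixel rectangles ``(row_start, row_stop,
  col_start, col_stop)``.
* Pixel saturation means a pixel at the top code value ``2**bit_depth - 1``.
  Every quantitative measurement is invalid on saturated data, so the
  measurement modules screen their ROIs through :func:`assert_unsaturated`
  and propagate the flag into their results.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import yaml

__all__ = [
    "AcquisitionSettings",
    "BModeImage",
    "ContrastTarget",
    "PhantomModel",
    "Rect",
    "SaturationCheck",
    "assert_unsaturated",
    "load_image",
    "load_phantom_model",
    "save_image",
    "saturation_fraction",
]


class Rect(NamedTuple):
    """Half-open pixel rectangle: rows ``[row_start, row_stop)``, cols
    ``[col_start, col_stop)``."""

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int

    def slices(self) -> tuple[slice, slice]:
        return slice(self.row_start, self.row_stop), slice(self.col_start, self.col_stop)

    @property
    def n_pixels(self) -> int:
        return max(0, self.row_stop - self.row_start) * max(0, self.col_stop - self.col_start)


@dataclass(frozen=True)
class AcquisitionSettings:
    """Scanner settings an image was acquired with.

    ``dynamic_range`` (DR, dB) is the span of echo amplitudes mapped onto the
    displayed gray scale; for an 8-bit display the predicted contrast response
    is ``256 / DR`` gray levels per dB.
    """

    transducer_id: str = "unknown"
    transmit_frequency: float = 5.0  # MHz
    gain: float = 0.0  # dB
    power: float = 100.0  # percent acoustic output
    dynamic_range: float = 60.0  # dB
    gray_map_id: str = "identity"
    focal_depth: float | None = None  # mm, or None when no focal zone is set

    def __post_init__(self) -> None:
        if self.dynamic_range <= 0:
            raise ValueError("dynamic_range must be > 0")
        if self.transmit_frequency <= 0:
            raise ValueError("transmit_frequency must be > 0")
        if not (0 < self.power <= 100):
            raise ValueError("power must be in (0, 100]")


@dataclass
class BModeImage:
    """Scan-converted grayscale B-mode image with physical calibration.

    Parameters
    ----------
    pixels
        2-D integer array, rows = depth (axial), columns = lateral position.
    bit_depth
        Bits per pixel; values must lie in ``[0, 2**bit_depth - 1]``.
    axial_spacing, lateral_spacing
        mm per row / mm per column.
    depth_offset
        Depth (mm) of row 0 below the transducer face.
    settings
        Acquisition settings, or None when unknown.
    """

    pixels: np.ndarray
    bit_depth: int = 8
    axial_spacing: float = 0.1
    lateral_spacing: float = 0.1
    depth_offset: float = 0.0
    settings: AcquisitionSettings | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if self.pixels.shape[0] < 16 or self.pixels.shape[1] < 16:
            raise ValueError("image must be at least 16x16 pixels")
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise ValueError("pixels must be an integer array")
        if self.axial_spacing <= 0 or self.lateral_spacing <= 0:
            raise ValueError("pixel spacings must be > 0")
        if self.pixels.min() < 0 or self.pixels.max() > self.max_code:
            raise ValueError(
                f"pixel values must lie in [0, {self.max_code}] for bit_depth={self.bit_depth}"
            )

    @property
    def max_code(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def n_rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.pixels.shape[1]

    def full_rect(self) -> Rect:
        return Rect(0, self.n_rows, 0, self.n_cols)

    def depth_mm(self, row: float) -> float:
        """Physical depth (mm) of a (possibly fractional) row index."""
        return self.depth_offset + row * self.axial_spacing

    def lateral_mm(self, col: float) -> float:
        return col * self.lateral_spacing

    def row_at_depth(self, depth_mm: float) -> float:
        return (depth_mm - self.depth_offset) / self.axial_spacing

    def col_at_lateral(self, lateral_mm: float) -> float:
        return lateral_mm / self.lateral_spacing


class ContrastTarget(NamedTuple):
    """A cylindrical contrast target: position, size, and nominal contrast
    (dB relative to the phantom background)."""

    depth_mm: float
    lateral_mm: float
    diameter_mm: float
    contrast_db: float


@dataclass
class PhantomModel:
    """Declarative layout of the phantom's targets.

    Mirrors a CIRS 040GSE-like phantom: a speckle background of known
    attenuation, cylindrical gray-scale contrast targets, a vertical column of
    nylon pin targets, and (optionally) the location of the on-screen
    grayscale ramp.
    """

    background_attenuation: float = 0.7  # dB/cm/MHz, one-way
    contrast_targets: list[ContrastTarget] = field(default_factory=list)
    pin_column: list[float] = field(default_factory=list)  # pin depths, mm
    pin_lateral_mm: float = 0.0  # lateral position of the pin column
    ramp_roi: Rect | None = None

    def __post_init__(self) -> None:
        self.contrast_targets = [ContrastTarget(*t) for t in self.contrast_targets]
        if any(t.diameter_mm <= 0 for t in self.contrast_targets):
            raise ValueError("contrast target diameters must be > 0")
        depths = list(self.pin_column)
        if depths != sorted(depths) or len(set(depths)) != len(depths):
            raise ValueError("pin depths must be strictly increasing")
        if self.ramp_roi is not None:
            self.ramp_roi = Rect(*self.ramp_roi)


@dataclass(frozen=True)
class SaturationCheck:
    """Outcome of a saturation screen: ``ok`` is False when the fraction of
    top-code pixels exceeded the allowed maximum."""

    ok: bool
    fraction: float

    @property
    def flagged(self) -> bool:
        return not self.ok


def _roi_pixels(image: BModeImage, roi: Rect | None) -> np.ndarray:
    if roi is None:
        return image.pixels
    r = Rect(*roi)
    if r.n_pixels == 0:
        raise ValueError("empty ROI")
    if not (0 <= r.row_start < r.row_stop <= image.n_rows):
        raise ValueError("ROI rows out of image bounds")
    if not (0 <= r.col_start < r.col_stop <= image.n_cols):
        raise ValueError("ROI columns out of image bounds")
    return image.pixels[r.slices()]


def saturation_fraction(image: BModeImage, roi: Rect | None = None) -> float:
    """Fraction of ROI pixels at the top code value (255 for 8-bit)."""
    px = _roi_pixels(image, roi)
    return float(np.count_nonzero(px == image.max_code) / px.size)


def assert_unsaturated(
    image: BModeImage, roi: Rect | None = None, max_fraction: float = 0.001
) -> SaturationCheck:
    """Screen an ROI for pixel saturation.

    Returns ``ok`` when the saturated fraction is at most ``max_fraction``
    (strict inequality flags; the boundary passes).  A strict-zero rule would
    be brittle on real captures, so a small default tolerance of 0.1% of ROI
    pixels is used; callers may set ``max_fraction=0``.
    """
    frac = saturation_fraction(image, roi)
    return SaturationCheck(ok=frac <= max_fraction, fraction=frac)


# ---------------------------------------------------------------------------
# File IO


_SETTINGS_KEYS = {f.name for f in dataclasses.fields(AcquisitionSettings)}


def _settings_from_dict(d: dict) -> AcquisitionSettings:
    return AcquisitionSettings(**{k: v for k, v in d.items() if k in _SETTINGS_KEYS})


def _settings_to_dict(s: AcquisitionSettings) -> dict:
    return dataclasses.asdict(s)


def _load_sidecar(sidecar_meta) -> dict:
    if sidecar_meta is None:
        return {}
    if isinstance(sidecar_meta, dict):
        return dict(sidecar_meta)
    with open(sidecar_meta) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def _collapse_rgb(arr: np.ndarray) -> np.ndarray:
    """Accept RGB-encoded grayscale (all channels equal); reject true color."""
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop fully-opaque alpha
            if not np.all(arr[..., 3] == arr[..., 3].flat[0]):
                raise ValueError("not grayscale: image has a varying alpha channel")
            arr = arr[..., :3]
        if arr.shape[2] == 3:
            if not (np.array_equal(arr[..., 0], arr[..., 1]) and np.array_equal(arr[..., 0], arr[..., 2])):
                raise ValueError("not grayscale: RGB channels differ")
            arr = arr[..., 0]
        else:
            raise ValueError(f"unsupported channel count {arr.shape[2]}")
    if arr.ndim != 2:
        raise ValueError("expected a single-frame 2-D image; extract one frame first")
    return arr


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = path.suffix.lower()
    if suffix in (".dcm", ".dicom"):
        return "dicom"
    if suffix in (".png",):
        return "png"
    if suffix in (".tif", ".tiff"):
        return "tiff"
    raise ValueError(f"cannot infer image format from suffix {suffix!r}; pass format=")


def load_image(path, fmt: str | None = None, sidecar_meta=None) -> BModeImage:
    """Load a single-frame grayscale raster (DICOM secondary capture, PNG or
    TIFF) into a :class:`BModeImage`.

    Physical spacing is taken from the file when the format carries it (DICOM
    PixelSpacing) and otherwise from the sidecar metadata; spacing present in
    the file takes precedence over the sidecar.  A missing spacing is a hard
    error naming the missing field.

    ``sidecar_meta`` may be a dict or a path to a YAML file with keys
    ``axial_spacing_mm``, ``lateral_spacing_mm``, ``depth_offset_mm``,
    ``bit_depth`` and ``settings`` (AcquisitionSettings fields).  When omitted
    and ``<path stem>.yaml`` exists next to the image, that file is used.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, fmt)

    default_sidecar = path.with_suffix(".yaml")
    if sidecar_meta is None and default_sidecar.exists():
        sidecar_meta = default_sidecar
    meta = _load_sidecar(sidecar_meta)

    axial = meta.get("axial_spacing_mm")
    lateral = meta.get("lateral_spacing_mm")

    if fmt == "dicom":
        import pydicom

        ds = pydicom.dcmread(str(path))
        n_frames = int(getattr(ds, "NumberOfFrames", 1) or 1)
        if n_frames > 1:
            raise ValueError(
                f"multi-frame DICOM ({n_frames} frames); extract a single frame before loading"
            )
        arr = _collapse_rgb(np.asarray(ds.pixel_array))
        spacing = getattr(ds, "PixelSpacing", None)
        if spacing is not None:
            # DICOM PixelSpacing is (row spacing, column spacing): file wins
            axial, lateral = float(spacing[0]), float(spacing[1])
        bit_depth = meta.get("bit_depth", int(getattr(ds, "BitsStored", 8)))
    else:
        import imageio.v3 as iio

        arr = _collapse_rgb(np.asarray(iio.imread(path)))
        bit_depth = meta.get("bit_depth", 16 if arr.dtype.itemsize > 1 else 8)

    if axial is None:
        raise ValueError("missing axial_spacing_mm: not in file or sidecar metadata")
    if lateral is None:
        raise ValueError("missing lateral_spacing_mm: not in file or sidecar metadata")

    settings = _settings_from_dict(meta.get("settings", {})) if meta.get("settings") else None
    return BModeImage(
        pixels=arr.astype(np.int64),
        bit_depth=int(bit_depth),
        axial_spacing=float(axial),
        lateral_spacing=float(lateral),
        depth_offset=float(meta.get("depth_offset_mm", 0.0)),
        settings=settings,
    )


def save_image(image: BModeImage, path, fmt: str | None = None, write_sidecar: bool = True) -> Path:
    """Write an image as PNG/TIFF (plus a YAML sidecar with calibration and
    settings) or as a DICOM secondary capture carrying PixelSpacing.

    Round-trips pixels bit-exactly through :func:`load_image`.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    sidecar = {
        "axial_spacing_mm": float(image.axial_spacing),
        "lateral_spacing_mm": float(image.lateral_spacing),
        "depth_offset_mm": float(image.depth_offset),
        "bit_depth": int(image.bit_depth),
    }
    if image.settings is not None:
        sidecar["settings"] = _settings_to_dict(image.settings)

    if fmt == "dicom":
        import pydicom
        from pydicom.dataset import FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

        if image.bit_depth > 16:
            raise ValueError("DICOM writer supports up to 16-bit images")
        file_meta = FileMetaDataset()
        file_meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
        file_meta.MediaStorageSOPInstanceUID = generate_uid()
        file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = pydicom.Dataset()
        ds.file_meta = file_meta
        ds.SOPClassUID = SecondaryCaptureImageStorage
        ds.SOPInstanceUID = file_meta.MediaStorageSOPInstanceUID
        ds.Modality = "OT"
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.Rows, ds.Columns = image.pixels.shape
        nbytes = 1 if image.bit_depth <= 8 else 2
        ds.BitsAllocated = 8 * nbytes
        ds.BitsStored = image.bit_depth
        ds.HighBit = image.bit_depth - 1
        ds.PixelRepresentation = 0
        ds.PixelSpacing = [f"{image.axial_spacing:.10g}", f"{image.lateral_spacing:.10g}"]
        dtype = np.uint8 if nbytes == 1 else np.uint16
        ds.PixelData = np.ascontiguousarray(image.pixels.astype(dtype)).tobytes()
        ds.save_as(str(path), enforce_file_format=True)
    else:
        import imageio.v3 as iio

        dtype = np.uint8 if image.bit_depth <= 8 else np.uint16
        iio.imwrite(path, image.pixels.astype(dtype))

    if write_sidecar:
        with open(path.with_suffix(".yaml"), "w") as fh:
            yaml.safe_dump(sidecar, fh, sort_keys=False)
    return path


def load_phantom_model(source) -> PhantomModel:
    """Build a :class:`PhantomModel` from a dict or a YAML/JSON file.

    Recognized keys: ``background_attenuation_db_cm_mhz``, ``contrast_targets``
    (each ``[depth_mm, lateral_mm, diameter_mm, contrast_db]``), ``pin_column``
    (depths, mm), ``pin_lateral_mm``, ``ramp_roi``
    (``[row_start, row_stop, col_start, col_stop]``).
    """
    if isinstance(source, PhantomModel):
        return source
    if isinstance(source, dict):
        data = source
    else:
        with open(source) as fh:
            data = yaml.safe_load(fh)
    return PhantomModel(
        background_attenuation=float(data.get("background_attenuation_db_cm_mhz", 0.7)),
        contrast_targets=[ContrastTarget(*t) for t in data.get("contrast_targets", [])],
        pin_column=[float(d) for d in data.get("pin_column", [])],
        pin_lateral_mm=float(data.get("pin_lateral_mm", 0.0)),
        ramp_roi=Rect(*data["ramp_roi"]) if data.get("ramp_roi") else None,
    )
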