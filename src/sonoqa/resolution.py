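"""Spatial resolution from nylon-pin targets: −6 dB beam widths.

A thin filament ("pin") imaged in cross-section approximates the system
point-spread function.  The lateral (axial) resolution at a pin is the
lateral (axial) extent over which the pixel value stays within 6 dB of the
pin's peak.  The 6 dB drop is evaluated on the compressed pixel scale through
the contrast-response calibration: the threshold is ``peak − 6·slope`` gray
levels, where ``slope`` is the calibrated gray-levels-per-dB response, so
the measurement tracks the scanner's compression and gray map.

Elevational resolution (slice thickness) uses the 45°-filament protocol: the
scan plane intersects the pin column at 45°, making the in-plane streak
length of each pin equal to the slice thickness, so the elevational width is
read with the same lateral-width computation on the tilted acquisition (no
geometric rescaling is applied).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .calibration import ContrastResponseResult, GrayMapLUT, _lut_or_identity
from .image_io import BModeImage, PhantomModel

__all__ = [
    "Pin",
    "PinDetection",
    "ResolutionMeasurement",
    "detect_pins",
    "measure_elevational",
    "measure_pin_width",
    "resolution_vs_depth",
    "select_reference_pin",
]


@dataclass(frozen=True)
class Pin:
    """A detected pin target (sub-pixel position and peak level)."""

    depth_mm: float
    lateral_mm: float
    peak_level: float  # linearized gray at the peak


@dataclass
class PinDetection:
    """Outcome of pin-column detection."""

    pins: list[Pin]
    method: str  # auto | manual
    n_expected: int
    n_found: int

    @property
    def failed(self) -> bool:
        return self.n_found == 0


@dataclass
class ResolutionMeasurement:
    """A −6 dB width at one pin along one axis."""

    pin_depth_mm: float
    axis: str  # lateral | axial | elevational
    width_mm: float
    peak_level: float
    threshold_level: float
    calibration_slope: float  # gray/dB
    saturation_flag: bool = False
    method: str = "auto"
    flags: list[str] = field(default_factory=list)


def _parabolic_refine(y: np.ndarray, i: int) -> tuple[float, float]:
    """3-point parabolic sub-sample refinement of a local maximum.

    Returns (offset in samples relative to i, refined peak value)."""
    if i <= 0 or i >= y.size - 1:
        return 0.0, float(y[i])
    y0, y1, y2 = float(y[i - 1]), float(y[i]), float(y[i + 1])
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:  # not a strict local max in the parabola sense
        return 0.0, y1
    off = 0.5 * (y0 - y2) / denom
    off = float(np.clip(off, -0.5, 0.5))
    peak = y1 - 0.25 * (y0 - y2) * off
    return off, peak


def detect_pins(
    image: BModeImage,
    phantom: PhantomModel,
    lut: GrayMapLUT | None = None,
    search_mm: float = 3.0,
    k_sigma: float = 4.0,
    manual_centers: list[tuple[float, float]] | None = None,
) -> PinDetection:
    """Locate the pin column.

    Background is removed as a median-filter residual: the per-row median of
    the linearized image (the pin column occupies a small fraction of each
    row, so the row median tracks the depth-dependent background level while
    ignoring the pins).  Each expected pin is then sought as the local
    maximum of the residual within ±``search_mm`` of its nominal position,
    refined to sub-pixel by a 3-point parabolic fit in each axis.  Pins whose
    residual peak is below ``k_sigma`` robust (MAD-based) standard deviations
    of the local residual are reported missing.  Zero pins found is a failure
    status (not an exception) prompting manual input; ``manual_centers``
    entries ``(depth_mm, lateral_mm)`` are accepted verbatim.
    """
    lut = _lut_or_identity(lut, image)
    lin = lut.linearize(image).astype(float)

    if manual_centers is not None:
        pins = [
            Pin(d, l, float(lin[int(round(image.row_at_depth(d))),
                                int(round(image.col_at_lateral(l)))]))
            for d, l in manual_centers
        ]
        return PinDetection(pins=pins, method="manual",
                            n_expected=len(phantom.pin_column), n_found=len(pins))

    if not phantom.pin_column:
        raise ValueError("phantom model lists no pin column")

    residual = lin - np.median(lin, axis=1)[:, None]

    pins: list[Pin] = []
    for depth in phantom.pin_column:
        row = image.row_at_depth(depth)
        col = image.col_at_lateral(phantom.pin_lateral_mm)
        dr = search_mm / image.axial_spacing
        dc = search_mm / image.lateral_spacing
        r0, r1 = int(max(1, row - dr)), int(min(image.n_rows - 1, row + dr + 1))
        c0, c1 = int(max(1, col - dc)), int(min(image.n_cols - 1, col + dc + 1))
        if r1 <= r0 or c1 <= c0:
            continue
        window = residual[r0:r1, c0:c1]
        # robust local noise scale: MAD of the residual in the search window
        sigma = 1.4826 * float(np.median(np.abs(window - np.median(window))))
        br, bc = np.unravel_index(int(np.argmax(window)), window.shape)
        peak_res = float(window[br, bc])
        if peak_res < k_sigma * max(sigma, 1e-12):
            continue  # pin missing
        pr, pc = br + r0, bc + c0
        off_r, _ = _parabolic_refine(residual[:, pc], pr)
        off_c, _ = _parabolic_refine(residual[pr, :], pc)
        pins.append(
            Pin(
                depth_mm=image.depth_mm(pr + off_r),
                lateral_mm=image.lateral_mm(pc + off_c),
                peak_level=float(lin[pr, pc]),
            )
        )
    pins.sort(key=lambda p: p.depth_mm)
    return PinDetection(pins=pins, method="auto",
                        n_expected=len(phantom.pin_column), n_found=len(pins))


def measure_pin_width(
    image: BModeImage,
    pin: Pin | tuple[float, float],
    axis: str,
    calibration: ContrastResponseResult,
    lut: GrayMapLUT | None = None,
    orthogonal_avg_px: int = 3,
    drop_db: float = 6.0,
    lobe_gap_mm: float = 1.0,
    max_saturated_fraction: float = 0.001,
) -> ResolutionMeasurement:
    """−6 dB width of a pin along ``axis`` ('lateral' or 'axial').

    The profile through the pin is averaged over ``orthogonal_avg_px`` pixels
    in the orthogonal direction to suppress speckle spikes, the peak is
    refined with a 3-point parabolic fit, and the width is the distance
    between the two outermost threshold crossings adjacent to the peak, each
    located by linear interpolation between bracketing pixels.  The threshold
    is ``peak − drop_db·slope`` gray levels.

    The outermost-crossing rule guards against speckle dips inside the main
    lobe: after the profile falls below the threshold, the scan continues for
    another ``lobe_gap_mm`` outward, and any above-threshold re-rise within
    that gap (a speckle dip or a sidelobe) extends the measured lobe and sets
    the ``multi_lobe`` flag.  Structure farther away than the gap — e.g. the
    neighboring pin of the column on an axial profile — is not part of this
    pin.

    Raises ``ValueError`` ("pin truncated") when the profile does not fall
    below the threshold on both sides before the image edge.
    """
    if axis not in ("lateral", "axial"):
        raise ValueError("axis must be 'lateral' or 'axial'")
    if calibration.slope <= 0:
        raise ValueError("calibration slope must be > 0")
    lut = _lut_or_identity(lut, image)
    lin = lut.linearize(image).astype(float)

    if isinstance(pin, Pin):
        depth_mm, lateral_mm = pin.depth_mm, pin.lateral_mm
    else:
        depth_mm, lateral_mm = pin
    row = int(round(image.row_at_depth(depth_mm)))
    col = int(round(image.col_at_lateral(lateral_mm)))
    if not (0 <= row < image.n_rows and 0 <= col < image.n_cols):
        raise ValueError("pin position outside the image")

    half = orthogonal_avg_px // 2
    if axis == "lateral":
        r0, r1 = max(0, row - half), min(image.n_rows, row + half + 1)
        profile = lin[r0:r1, :].mean(axis=0)
        spacing = image.lateral_spacing
        idx = col
    else:
        c0, c1 = max(0, col - half), min(image.n_cols, col + half + 1)
        profile = lin[:, c0:c1].mean(axis=1)
        spacing = image.axial_spacing
        idx = row
    if idx < 10 or idx > profile.size - 11:
        raise ValueError("pin too close to the image edge along the measured axis")

    # re-find the local maximum near the nominal index (the supplied center
    # may come from a different detection pass)
    lo, hi = max(1, idx - 3), min(profile.size - 1, idx + 4)
    idx = int(lo + np.argmax(profile[lo:hi]))
    _, peak = _parabolic_refine(profile, idx)

    threshold = peak - drop_db * calibration.slope
    if threshold >= peak:
        raise ValueError("degenerate threshold: non-positive dB drop")

    above = profile >= threshold
    if not above[idx]:
        raise ValueError("pin truncated: no above-threshold main lobe at the peak")

    gap_px = max(1, int(round(lobe_gap_mm / spacing)))
    flags: list[str] = []

    def outward_crossing(direction: int) -> float:
        """Sub-pixel position of the outermost crossing on one side."""
        j = idx
        multi = False
        while True:
            # walk to the next below-threshold sample
            while 0 <= j < profile.size and above[j]:
                j += direction
            if j < 0 or j >= profile.size:
                raise ValueError(
                    "pin truncated: profile does not fall below threshold before the edge"
                )
            # re-rise within the gap extends the lobe (speckle dip / sidelobe)
            stretch = range(j, j + direction * gap_px, direction)
            rerise = [k for k in stretch if 0 <= k < profile.size and above[k]]
            if rerise:
                multi = True
                j = rerise[0]
                continue
            break
        if multi:
            flags.append("multi_lobe")
        inner = j - direction  # last above-threshold sample
        frac = (threshold - profile[j]) / (profile[inner] - profile[j])
        return j - direction * frac

    xl = outward_crossing(-1)
    xr = outward_crossing(+1)

    width_mm = (xr - xl) * spacing
    peak_saturated = image.pixels[row, col] == image.max_code
    if peak_saturated:
        flags.append("peak_saturated")
    flags = list(dict.fromkeys(flags))
    return ResolutionMeasurement(
        pin_depth_mm=depth_mm,
        axis=axis,
        width_mm=float(width_mm),
        peak_level=float(peak),
        threshold_level=float(threshold),
        calibration_slope=float(calibration.slope),
        saturation_flag=bool(peak_saturated),
        flags=flags,
    )


def measure_elevational(
    image_45: BModeImage,
    pin: Pin | tuple[float, float],
    calibration: ContrastResponseResult,
    lut: GrayMapLUT | None = None,
    lateral_width_mm: float | None = None,
    **kwargs,
) -> ResolutionMeasurement:
    """Elevational width (slice thickness) from a 45°-tilted acquisition.

    Identical to the lateral width computation on the tilted image (at 45°
    the in-plane streak length equals the slice thickness, so no geometric
    rescaling is applied); the axis is recorded as ``elevational``.  Because
    the streak also convolves the in-plane beam, the estimate is biased high
    when the lateral beam is not narrow; pass ``lateral_width_mm`` (the
    lateral −6 dB width at the same depth) to get a warning when the lateral
    beam contributes at least as much as the elevational beam to the streak
    (lateral width ≥ measured width / √2, the two beams combining in
    quadrature).  The caller asserts the 45° protocol; the package cannot
    verify it from the image.
    """
    m = measure_pin_width(image_45, pin, "lateral", calibration, lut=lut, **kwargs)
    m.axis = "elevational"
    if lateral_width_mm is not None and lateral_width_mm >= m.width_mm / np.sqrt(2.0):
        m.flags.append("lateral_beam_dominates")
        warnings.warn(
            "the 45-degree measurement is dominated by the in-plane beam: "
            "the lateral width at this depth is not narrow relative to the "
            "elevational estimate",
            stacklevel=2,
        )
    return m


def select_reference_pin(
    detection: PinDetection,
    focal_depth_mm: float | None = None,
    dop_cm: float | None = None,
) -> Pin:
    """Pick the single pin used for stability/sensitivity/repeatability.

    The pin closest to the observed focal depth; when no clear focal depth is
    available, the pin closest to half the depth of penetration.  Ties break
    toward the shallower pin.
    """
    if not detection.pins:
        raise ValueError("no pins detected")
    if focal_depth_mm is not None:
        target = float(focal_depth_mm)
    elif dop_cm is not None:
        target = float(dop_cm) * 10.0 / 2.0
    else:
        raise ValueError("no selection criterion: supply focal_depth_mm or dop_cm")
    best = min(detection.pins, key=lambda p: (abs(p.depth_mm - target), p.depth_mm))
    return best


def resolution_vs_depth(
    image: BModeImage,
    detection: PinDetection,
    calibration: ContrastResponseResult,
    lut: GrayMapLUT | None = None,
    axes: tuple[str, ...] = ("lateral", "axial"),
    **kwargs,
):
    """Widths for every detected pin along each in-plane axis.

    Returns a pandas DataFrame with columns ``pin_depth_mm``, ``axis``,
    ``width_mm``, ``method``, ``status``, ``flags``; truncated pins are kept
    as rows with status ``truncated`` and NaN width.
    """
    import pandas as pd

    rows = []
    for pin in detection.pins:
        for axis in axes:
            try:
                m = measure_pin_width(image, pin, axis, calibration, lut=lut, **kwargs)
                rows.append(
                    dict(pin_depth_mm=pin.depth_mm, axis=axis, width_mm=m.width_mm,
                         method=detection.method, status="ok", flags=";".join(m.flags))
                )
            except ValueError as exc:
                rows.append(
                    dict(pin_depth_mm=pin.depth_mm, axis=axis, width_mm=np.nan,
                         method=detection.method, status="truncated", flags=str(exc))
                )
    columns = ["pin_depth_mm", "axis", "width_mm", "method", "status", "flags"]
    return pd.DataFrame(rows, columns=columns)
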