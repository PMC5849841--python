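"""Gray-map linearization and contrast-response measurement.

Scanners render compressed echo level through a display gray map (a LUT) that
is often deliberately nonlinear.  Pixel-value-based measurements are only
quantitative after that map is undone, so this module extracts the inverse
LUT from the on-screen grayscale ramp, locates the phantom's cylindrical
contrast targets, and fits the contrast response: the slope, in gray levels
per dB, relating displayed (linearized) gray level to nominal target contrast.
That slope is also the pixel→dB calibration every other measurement uses.

The dB convention throughout the package is amplitude dB (20·log10).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .image_io import BModeImage, PhantomModel, Rect

__all__ = [
    "ContrastResponseResult",
    "GrayMapLUT",
    "TargetROI",
    "extract_graymap_lut",
    "locate_contrast_targets",
    "measure_contrast_response",
    "pixel_to_db",
]


@dataclass(frozen=True)
class GrayMapLUT:
    """Mapping from displayed gray level to linearized level.

    ``table[v]`` is the linearized value of displayed code ``v``; it is
    non-decreasing and normalized so its endpoints span the full code range.
    """

    table: np.ndarray
    source: str = "identity"  # ramp_extracted | identity | user_supplied

    def __post_init__(self) -> None:
        t = np.asarray(self.table, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("LUT table must be a 1-D array of per-code values")
        if np.any(np.diff(t) < 0):
            raise ValueError("LUT must be monotonically non-decreasing")
        object.__setattr__(self, "table", t)

    @classmethod
    def identity(cls, bit_depth: int = 8) -> "GrayMapLUT":
        return cls(np.arange(2**bit_depth, dtype=float), source="identity")

    def __call__(self, pixels: np.ndarray) -> np.ndarray:
        """Linearize an integer pixel array."""
        return self.table[np.asarray(pixels, dtype=np.intp)]

    def linearize(self, image: BModeImage) -> np.ndarray:
        if self.table.size != 2**image.bit_depth:
            raise ValueError("LUT size does not match image bit depth")
        return self(image.pixels)


def _lut_or_identity(lut: GrayMapLUT | None, image: BModeImage) -> GrayMapLUT:
    if lut is None:
        warnings.warn(
            "no gray-map LUT supplied; assuming the display gray map is linear",
            stacklevel=3,
        )
        return GrayMapLUT.identity(image.bit_depth)
    return lut


def extract_graymap_lut(
    image: BModeImage, ramp_roi: Rect, monotone_tol: float = 4.0
) -> GrayMapLUT:
    """Extract the linearizing LUT from the on-screen grayscale ramp.

    The ramp ROI must contain a strip whose displayed values sweep
    (near-)monotonically from dark to bright along one axis; the underlying
    input is assumed linear in position.  The observed transfer curve is
    monotone-regularized (pool-adjacent-violators) and inverted, then
    normalized so the LUT endpoints span the full code range.

    Raises
    ------
    ValueError
        "degenerate ramp" when the strip spans less than half the code range;
        "ramp not monotone" when the RMS residual from the monotone
        regularization exceeds ``monotone_tol`` gray levels.
    """
    strip = image.pixels[Rect(*ramp_roi).slices()].astype(float)
    if strip.size == 0:
        raise ValueError("empty ramp ROI")
    # sweep axis = the axis along which the mean profile varies most
    prof_rows = strip.mean(axis=1)
    prof_cols = strip.mean(axis=0)
    profile = prof_rows if np.ptp(prof_rows) >= np.ptp(prof_cols) else prof_cols
    max_code = image.max_code
    if np.ptp(profile) < max_code / 2:
        raise ValueError("degenerate ramp: strip spans less than half the code range")
    if profile[-1] < profile[0]:
        profile = profile[::-1]

    iso = _pava_nondecreasing(profile)
    rms = float(np.sqrt(np.mean((profile - iso) ** 2)))
    if rms > monotone_tol:
        raise ValueError(f"ramp not monotone: RMS deviation {rms:.1f} gray levels")

    # invert: displayed level -> ramp position, with position linear in input
    positions = np.linspace(0.0, float(max_code), profile.size)
    d_unique, inverse = np.unique(iso, return_inverse=True)
    v_mean = np.zeros_like(d_unique)
    np.add.at(v_mean, inverse, positions)
    v_mean /= np.bincount(inverse).astype(float)

    codes = np.arange(max_code + 1, dtype=float)
    table = np.interp(codes, d_unique, v_mean)
    # normalize endpoints to the code-range endpoints
    table = (table - table[0]) * (max_code / (table[-1] - table[0]))
    return GrayMapLUT(np.maximum.accumulate(table), source="ramp_extracted")


def _pava_nondecreasing(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators: least-squares non-decreasing fit to y."""
    n = y.size
    blocks: list[tuple[float, float]] = []  # (sum, count)
    for v in y.astype(float):
        blocks.append((v, 1.0))
        while len(blocks) > 1 and blocks[-2][0] / blocks[-2][1] > blocks[-1][0] / blocks[-1][1]:
            s2, c2 = blocks.pop()
            s1, c1 = blocks.pop()
            blocks.append((s1 + s2, c1 + c2))
    out = np.empty(n)
    i = 0
    for s, c in blocks:
        k = int(round(c))
        out[i : i + k] = s / c
        i += k
    return out


@dataclass
class TargetROI:
    """A located contrast target: a disc ROI and a paired background annulus
    at the same depth."""

    center_row: float
    center_col: float
    radius_px: float
    annulus_inner_px: float
    annulus_outer_px: float
    nominal_contrast_db: float
    detection_status: str = "ok"  # ok | failed
    detection_method: str = "auto"  # auto | manual
    score: float = 0.0

    def disc_mask(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        return (rr - self.center_row) ** 2 + (cc - self.center_col) ** 2 <= self.radius_px**2

    def annulus_mask(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        d2 = (rr - self.center_row) ** 2 + (cc - self.center_col) ** 2
        return (d2 >= self.annulus_inner_px**2) & (d2 <= self.annulus_outer_px**2)

    def bounding_rect(self, shape: tuple[int, int]) -> Rect:
        r = int(np.ceil(self.radius_px))
        return Rect(
            max(0, int(self.center_row) - r),
            min(shape[0], int(self.center_row) + r + 1),
            max(0, int(self.center_col) - r),
            min(shape[1], int(self.center_col) + r + 1),
        )


def _disc_kernel(radius: float) -> np.ndarray:
    r = int(np.ceil(radius))
    rr, cc = np.ogrid[-r : r + 1, -r : r + 1]
    return (rr**2 + cc**2 <= radius**2).astype(float)


def locate_contrast_targets(
    image: BModeImage,
    phantom: PhantomModel,
    lut: GrayMapLUT | None = None,
    roi_diameter_fraction: float = 0.7,
    score_threshold_se: float = 4.0,
    manual_centers: dict[int, tuple[float, float]] | None = None,
) -> list[TargetROI]:
    """Locate the phantom's contrast cylinders and build measurement ROIs.

    For each nominal target the center is refined by maximizing the absolute
    difference between the disc mean and the surrounding-annulus mean over a
    search window of ± half a diameter around the nominal position.  The disc
    ROI radius is ``roi_diameter_fraction`` (default 70%) of the nominal
    diameter, which keeps boundary partial-volume pixels out.

    A target whose refined score is below ``score_threshold_se`` local
    standard errors is reported with ``detection_status='failed'`` and no
    usable center; the caller then supplies ``manual_centers`` entries
    ``{target_index: (depth_mm, lateral_mm)}``, which are used verbatim with
    ``detection_method='manual'``.

    Raises
    ------
    ValueError
        when every target failed and no manual centers were given.
    """
    if not phantom.contrast_targets:
        raise ValueError("phantom model lists no contrast targets")
    lut = _lut_or_identity(lut, image)
    lin = lut.linearize(image).astype(float)
    manual_centers = manual_centers or {}

    rois: list[TargetROI] = []
    for idx, tgt in enumerate(phantom.contrast_targets):
        radius_px_lat = 0.5 * roi_diameter_fraction * tgt.diameter_mm / image.lateral_spacing
        radius_px_ax = 0.5 * roi_diameter_fraction * tgt.diameter_mm / image.axial_spacing
        # analysis runs in pixel space with an isotropy assumption for the
        # disc; use the mean radius and record it
        radius_px = 0.5 * (radius_px_lat + radius_px_ax)
        ann_in = radius_px / roi_diameter_fraction * 1.2
        ann_out = radius_px / roi_diameter_fraction * 1.8

        if idx in manual_centers:
            d_mm, l_mm = manual_centers[idx]
            rois.append(
                TargetROI(
                    center_row=image.row_at_depth(d_mm),
                    center_col=image.col_at_lateral(l_mm),
                    radius_px=radius_px,
                    annulus_inner_px=ann_in,
                    annulus_outer_px=ann_out,
                    nominal_contrast_db=tgt.contrast_db,
                    detection_method="manual",
                )
            )
            continue

        nom_row = image.row_at_depth(tgt.depth_mm)
        nom_col = image.col_at_lateral(tgt.lateral_mm)
        half_d_rows = 0.5 * tgt.diameter_mm / image.axial_spacing
        half_d_cols = 0.5 * tgt.diameter_mm / image.lateral_spacing

        r0 = int(max(np.ceil(ann_out), nom_row - half_d_rows))
        r1 = int(min(image.n_rows - np.ceil(ann_out) - 1, nom_row + half_d_rows))
        c0 = int(max(np.ceil(ann_out), nom_col - half_d_cols))
        c1 = int(min(image.n_cols - np.ceil(ann_out) - 1, nom_col + half_d_cols))
        if r1 < r0 or c1 < c0:
            rois.append(
                TargetROI(nom_row, nom_col, radius_px, ann_in, ann_out, tgt.contrast_db,
                          detection_status="failed")
            )
            continue

        disc_k = _disc_kernel(radius_px)
        ann_k = _disc_kernel(ann_out) - np.pad(
            _disc_kernel(ann_in),
            int(np.ceil(ann_out)) - int(np.ceil(ann_in)),
        )
        disc_mean = signal.fftconvolve(lin, disc_k / disc_k.sum(), mode="same")
        ann_mean = signal.fftconvolve(lin, ann_k / ann_k.sum(), mode="same")
        score_map = np.abs(disc_mean - ann_mean)

        window = score_map[r0 : r1 + 1, c0 : c1 + 1]
        flat = int(np.argmax(window))
        br, bc = np.unravel_index(flat, window.shape)
        # tie-break toward the smallest displacement from the nominal position
        best = window[br, bc]
        ties = np.argwhere(window >= best - 1e-12)
        if len(ties) > 1:
            disp = (ties[:, 0] + r0 - nom_row) ** 2 + (ties[:, 1] + c0 - nom_col) ** 2
            br, bc = ties[int(np.argmin(disp))]
        row, col = float(br + r0), float(bc + c0)
        score = float(score_map[int(row), int(col)])

        roi = TargetROI(row, col, radius_px, ann_in, ann_out, tgt.contrast_db, score=score)
        ann_px = lin[roi.annulus_mask(lin.shape)]
        n_disc = max(1, int(np.pi * radius_px**2))
        se = float(ann_px.std(ddof=1)) * np.sqrt(1.0 / n_disc + 1.0 / max(1, ann_px.size))
        if score < score_threshold_se * max(se, 1e-12):
            roi.detection_status = "failed"
        rois.append(roi)

    if all(r.detection_status == "failed" for r in rois):
        failed = ", ".join(
            f"target {i} ({t.contrast_db:+g} dB at {t.depth_mm:g} mm)"
            for i, t in enumerate(phantom.contrast_targets)
        )
        raise ValueError(f"all contrast targets failed auto-detection: {failed}; "
                         "supply manual centers")
    return rois


@dataclass
class ContrastResponseResult:
    """Contrast response: the fitted gray-levels-per-dB slope plus fit
    diagnostics and per-target means."""

    slope: float  # gray levels per dB
    intercept: float  # gray levels
    r_squared: float
    per_target: list[tuple[float, float, int]]  # (nominal dB, mean linearized gray, n pixels)
    predicted_slope: float | None = None  # 256/DR when DR is known
    saturation_flag: bool = False
    detection_method: str = "auto"
    flags: list[str] = field(default_factory=list)


def measure_contrast_response(
    image: BModeImage,
    rois: list[TargetROI],
    nominal_contrasts: list[float] | None = None,
    lut: GrayMapLUT | None = None,
    max_saturated_fraction: float = 0.001,
) -> ContrastResponseResult:
    """Fit the contrast response from ≥3 cylindrical targets of known
    echogenicity contrast.

    Ordinary least squares of mean linearized gray level versus nominal
    contrast (dB); the slope is the contrast response in gray levels/dB and
    the intercept absorbs the background level.  Each disc ROI is screened
    for saturation and the flag is carried on the result.  When the image
    settings carry a dynamic range DR, the predicted slope 256/DR is
    reported alongside.
    """
    lut = _lut_or_identity(lut, image)
    usable = [r for r in rois if r.detection_status == "ok"]
    if nominal_contrasts is not None:
        if len(nominal_contrasts) != len(rois):
            raise ValueError("nominal_contrasts length must match rois")
        for r, c in zip(rois, nominal_contrasts):
            r.nominal_contrast_db = float(c)
    if len(usable) < 3:
        raise ValueError(f"need at least 3 usable targets, got {len(usable)}")
    contrasts = np.array([r.nominal_contrast_db for r in usable], dtype=float)
    if np.ptp(contrasts) == 0:
        raise ValueError("all nominal contrasts are equal; cannot fit a response")

    lin = lut.linearize(image).astype(float)
    saturated = False
    per_target: list[tuple[float, float, int]] = []
    for r in usable:
        mask = r.disc_mask(lin.shape)
        # saturation screen on the disc pixels themselves
        disc_sat = float(np.count_nonzero(image.pixels[mask] == image.max_code)) / max(
            1, int(mask.sum())
        )
        saturated = saturated or (disc_sat > max_saturated_fraction)
        per_target.append((float(r.nominal_contrast_db), float(lin[mask].mean()), int(mask.sum())))

    y = np.array([p[1] for p in per_target])
    x = contrasts
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    sxy = float(((x - xm) * (y - ym)).sum())
    syy = float(((y - ym) ** 2).sum())
    slope = sxy / sxx
    intercept = ym - slope * xm
    flags: list[str] = []
    if syy == 0.0:
        r_squared = 0.0
        flags.append("no contrast discrimination")
    else:
        r_squared = (sxy * sxy) / (sxx * syy)

    predicted = None
    if image.settings is not None:
        predicted = 256.0 / image.settings.dynamic_range
    method = "manual" if any(r.detection_method == "manual" for r in usable) else "auto"
    return ContrastResponseResult(
        slope=slope,
        intercept=intercept,
        r_squared=float(r_squared),
        per_target=per_target,
        predicted_slope=predicted,
        saturation_flag=saturated,
        detection_method=method,
        flags=flags,
    )


def pixel_to_db(pixel_difference: float, calibration: ContrastResponseResult) -> float:
    """Convert a gray-level difference to dB using the contrast-response
    slope."""
    if calibration.slope == 0:
        raise ValueError("uncalibrated: contrast-response slope is zero")
    return float(pixel_difference) / calibration.slope
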