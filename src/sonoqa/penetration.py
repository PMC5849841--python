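"""Depth of penetration from gel/air image pairs.

The depth of penetration (DOP) is the depth at which the tissue signal
becomes indistinguishable from electronic noise.  It is measured from a pair
of images acquired with identical settings: one of a plain gel region of the
phantom and one in air (transducer coupled to nothing), so the air image
records the noise floor alone.  A depth-wise SNR profile is formed as the
ratio of band-mean linearized gray levels (gel over air), and the DOP is the
depth of the first downward crossing of SNR = 1, interpolated log-linearly
between bands.

This is this package's dialect of the IEC 61391-2-style estimator: 4-row
depth bands, the central 50% lateral window, mean/mean band statistics, and
log-linear crossing interpolation; each choice is configurable.  Profiles are
computed on LUT-linearized pixels so the result is gray-map independent by
construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .calibration import GrayMapLUT, _lut_or_identity
from .image_io import BModeImage, Rect, assert_unsaturated

__all__ = [
    "DOPResult",
    "SNRProfile",
    "average_dop",
    "compute_snr_profile",
    "depth_of_penetration",
]

_SNR_FLOOR = 1e-6  # keeps log-interpolation finite when a band mean hits 0


@dataclass
class SNRProfile:
    """Depth-wise signal-to-noise profile.

    ``depth`` (cm, band centers, strictly increasing) and ``snr``
    (dimensionless, non-negative) have one entry per analyzed row band.
    """

    depth: np.ndarray  # cm
    snr: np.ndarray
    band_rows: int
    lateral_window: tuple[int, int]  # column range used (half-open)
    saturation_flag: bool = False

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        self.snr = np.asarray(self.snr, dtype=float)
        if self.depth.shape != self.snr.shape:
            raise ValueError("depth and snr must have the same length")
        if np.any(np.diff(self.depth) <= 0):
            raise ValueError("depths must be strictly increasing")
        if not np.all(np.isfinite(self.snr)) or np.any(self.snr < 0):
            raise ValueError("snr must be finite and non-negative")


@dataclass
class DOPResult:
    """Depth of penetration: depth (cm) where SNR first falls to the
    threshold.  ``censored`` means the profile never crossed, in which case
    ``dop`` is the deepest analyzed depth."""

    dop: float  # cm
    threshold: float = 1.0
    censored: bool = False
    saturation_flag: bool = False
    n_pairs_averaged: int = 1
    dispersion: float | None = None  # cm, sample SD over pairs
    shallow_flag: bool = False  # SNR already below threshold at the first band


def _check_pair(gel: BModeImage, air: BModeImage) -> None:
    if gel.pixels.shape != air.pixels.shape:
        raise ValueError("pair mismatch: gel and air images differ in dimensions")
    if (gel.axial_spacing, gel.lateral_spacing, gel.depth_offset) != (
        air.axial_spacing,
        air.lateral_spacing,
        air.depth_offset,
    ):
        raise ValueError("pair mismatch: gel and air images differ in pixel spacing")
    if gel.settings is not None and air.settings is not None and gel.settings != air.settings:
        raise ValueError("pair mismatch: gel and air images differ in acquisition settings")


def compute_snr_profile(
    gel: BModeImage,
    air: BModeImage,
    lut: GrayMapLUT | None = None,
    lateral_window: float = 0.5,
    band_rows: int = 4,
    max_saturated_fraction: float = 0.001,
) -> SNRProfile:
    """Depth-wise SNR from a gel/air pair with identical settings.

    Per depth band the signal S is the mean linearized gel level over the
    central ``lateral_window`` fraction of columns, the noise N is the mean
    linearized air level over the same window (floored at 1 linearized level
    to avoid division by zero on ideal noise-free captures), and
    ``snr = S/N``.  Saturation of the gel window is flagged (not fatal);
    saturation of the air image is ignored since air captures only noise.
    """
    _check_pair(gel, air)
    if band_rows < 1:
        raise ValueError("band_rows must be >= 1")
    if not (0 < lateral_window <= 1):
        raise ValueError("lateral_window must be a fraction in (0, 1]")
    lut = _lut_or_identity(lut, gel)

    n_cols = gel.n_cols
    half = max(1, int(round(lateral_window * n_cols / 2)))
    mid = n_cols // 2
    c0, c1 = max(0, mid - half), min(n_cols, mid + half)

    sat = assert_unsaturated(gel, Rect(0, gel.n_rows, c0, c1), max_saturated_fraction)

    gl = lut.linearize(gel)[:, c0:c1].astype(float)
    al = lut.linearize(air)[:, c0:c1].astype(float)
    n_bands = gel.n_rows // band_rows
    if n_bands < 1:
        raise ValueError("image too short for the requested band size")
    gl = gl[: n_bands * band_rows].reshape(n_bands, band_rows, -1)
    al = al[: n_bands * band_rows].reshape(n_bands, band_rows, -1)
    s_band = gl.mean(axis=(1, 2))
    n_band = np.maximum(al.mean(axis=(1, 2)), 1.0)

    if np.all(s_band < n_band):
        raise ValueError("air image brighter than gel at all depths: images swapped?")

    centers_rows = np.arange(n_bands) * band_rows + (band_rows - 1) / 2.0
    depth_cm = (gel.depth_offset + centers_rows * gel.axial_spacing) / 10.0
    return SNRProfile(
        depth=depth_cm,
        snr=s_band / n_band,
        band_rows=band_rows,
        lateral_window=(c0, c1),
        saturation_flag=sat.flagged,
    )


def depth_of_penetration(profile: SNRProfile, threshold: float = 1.0) -> DOPResult:
    """Depth (cm) of the first downward crossing of the SNR threshold.

    The crossing is located by linear interpolation in log(SNR) versus depth
    between the bracketing bands; bands beyond the first crossing are
    ignored.  If the profile never falls below the threshold the result is
    censored at the deepest analyzed depth.  If the SNR is already below the
    threshold at the first band, the first depth is returned with a warning
    (penetration is shallower than the analysis window).
    """
    if profile.snr.size == 0:
        raise ValueError("empty SNR profile")
    snr = np.maximum(profile.snr, _SNR_FLOOR)
    depth = profile.depth
    if snr[0] < threshold:
        warnings.warn("penetration shallower than analysis window", stacklevel=2)
        return DOPResult(dop=float(depth[0]), threshold=threshold, shallow_flag=True,
                         saturation_flag=profile.saturation_flag)
    below = np.nonzero(snr < threshold)[0]
    # a band exactly at threshold is a crossing at that node
    at = np.nonzero(snr == threshold)[0]
    first_below = below[0] if below.size else None
    first_at = at[0] if at.size else None
    if first_below is None and first_at is None:
        return DOPResult(dop=float(depth[-1]), threshold=threshold, censored=True,
                         saturation_flag=profile.saturation_flag)
    if first_at is not None and (first_below is None or first_at < first_below):
        return DOPResult(dop=float(depth[first_at]), threshold=threshold,
                         saturation_flag=profile.saturation_flag)
    i = int(first_below)
    ln_prev, ln_next = np.log(snr[i - 1]), np.log(snr[i])
    t = (np.log(threshold) - ln_prev) / (ln_next - ln_prev)
    dop = depth[i - 1] + t * (depth[i] - depth[i - 1])
    return DOPResult(dop=float(dop), threshold=threshold,
                     saturation_flag=profile.saturation_flag)


def average_dop(
    pairs: list[tuple[BModeImage, BModeImage]],
    lut: GrayMapLUT | None = None,
    threshold: float = 1.0,
    lateral_window: float = 0.5,
    band_rows: int = 4,
) -> DOPResult:
    """DOP averaged over repeated gel/air acquisitions.

    Each pair yields its own DOP; the result reports the mean and the sample
    standard deviation over pairs (the usual six-acquisition protocol).  The
    result is censored if any pair was censored.
    """
    if not pairs:
        raise ValueError("no image pairs supplied")
    results = []
    for gel, air in pairs:
        prof = compute_snr_profile(gel, air, lut=lut, lateral_window=lateral_window,
                                   band_rows=band_rows)
        results.append(depth_of_penetration(prof, threshold=threshold))
    dops = np.array([r.dop for r in results])
    return DOPResult(
        dop=float(dops.mean()),
        threshold=threshold,
        censored=any(r.censored for r in results),
        saturation_flag=any(r.saturation_flag for r in results),
        n_pairs_averaged=len(results),
        dispersion=float(dops.std(ddof=1)) if len(results) > 1 else 0.0,
        shallow_flag=any(r.shallow_flag for r in results),
    )
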