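"""Assay readout quantification.

Net normalized fluorescence intensity (NNFI) from flow-cytometry geometric
means, percent inhibition of adhesion, and the elliptical form factor of a
cell mask (moments-based ellipse fit, major/minor axis ratio).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from skimage import measure

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# flow cytometry


def geometric_mean(values: Sequence[float]) -> float:
    """exp(mean(log v)); requires strictly positive values."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty value list")
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ValueError("geometric mean requires finite positive values")
    return float(np.exp(np.mean(np.log(arr))))


@dataclass(frozen=True)
class FlowSummary:
    """Geometric-mean fluorescence triplet for one sample.

    ``expression_ratio`` is the relative surface receptor expression as a
    dimensionless fraction (0.8 for 80%).
    """

    gmfi_sample: float
    gmfi_background: float
    expression_ratio: float

    def __post_init__(self) -> None:
        if self.gmfi_sample <= 0 or self.gmfi_background <= 0:
            raise ValueError("GMFI values must be > 0")
        if self.expression_ratio <= 0:
            raise ValueError("expression_ratio must be > 0")


@dataclass(frozen=True)
class NNFIResult:
    nnfi: float
    gmfi_sample: float
    gmfi_background: float
    expression_ratio: float
    below_background: bool


def nnfi(summary: FlowSummary) -> NNFIResult:
    """Background-subtracted GMFI divided by relative receptor expression.

    Negative results (sample below background) are permitted and flagged.
    """
    net = summary.gmfi_sample - summary.gmfi_background
    value = net / summary.expression_ratio
    return NNFIResult(
        nnfi=value,
        gmfi_sample=summary.gmfi_sample,
        gmfi_background=summary.gmfi_background,
        expression_ratio=summary.expression_ratio,
        below_background=net < 0,
    )


def percent_inhibition(signal_control: float, signal_treated: float) -> float:
    """(1 - treated/control) x 100."""
    if signal_control <= 0:
        raise ValueError("control signal must be > 0")
    return (1.0 - signal_treated / signal_control) * 100.0


# ---------------------------------------------------------------------------
# cell-shape morphometry


@dataclass(frozen=True)
class EllipseFit:
    centroid: Tuple[float, float]   # (row, col) px
    major_axis_length: float        # px, full axis (b)
    minor_axis_length: float        # px, full axis (a)
    orientation: float              # radians, in (-pi/2, pi/2]
    area_px: int

    @property
    def form_factor(self) -> float:
        return self.major_axis_length / self.minor_axis_length


def fit_ellipse(mask: np.ndarray, min_pixels: int = 16) -> EllipseFit:
    """Moments-based ellipse fit of the foreground of a binary mask.

    Axis lengths follow the regionprops convention (4 x sqrt of the
    covariance eigenvalues), so the form factor equals
    sqrt(lambda_max / lambda_min).  If several connected components are
    present the largest is used (logged).
    """
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {arr.shape}")
    fg = arr != 0
    if not fg.any():
        raise ValueError("empty mask: no foreground pixels")

    labels = measure.label(fg, connectivity=2)
    props = measure.regionprops(labels)
    if len(props) > 1:
        logger.warning("mask has %d connected components; using the largest",
                       len(props))
        props.sort(key=lambda p: p.area, reverse=True)
    region = props[0]
    if region.area < min_pixels:
        raise ValueError(
            f"largest component has {region.area} px; need >= {min_pixels}")
    minor = float(region.axis_minor_length)
    major = float(region.axis_major_length)
    if minor <= 0:
        raise ValueError("degenerate mask: collinear foreground pixels")
    orientation = float(region.orientation)
    if orientation <= -math.pi / 2:
        orientation += math.pi
    return EllipseFit(
        centroid=tuple(float(c) for c in region.centroid),
        major_axis_length=major,
        minor_axis_length=minor,
        orientation=orientation,
        area_px=int(region.area),
    )


def elliptical_form_factor(fit: EllipseFit) -> float:
    """Major/minor axis ratio of a fitted ellipse (>= 1)."""
    return fit.form_factor
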