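"""Geometric shape descriptors of a binary region mask.

Ten morphological features distinguish compact nodule blobs from elongated
vessel-like distractors: area A, perimeter P, equivalent-circle diameter D,
solidity S, eccentricity E, aspect ratio M/L, compactness P^2/(4*pi*A),
roundness 4A/(pi*L^2), circularity 4*pi*A/P^2 and ellipticity
pi*L^2/(2A), where L and M are the major and minor axis lengths of the
ellipse with the same normalized second central moments as the region.

Conventions: the largest connected component is used (with a warning if
there are several), interior holes are filled, and the perimeter is the
length of the 8-connected boundary chain with diagonal steps weighted
sqrt(2) — a low-bias estimator for smooth blobs.  Given a pixel spacing,
lengths are in mm and areas in mm^2; the ratio descriptors are
dimensionless and unit-free.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
from scipy import ndimage
from skimage import measure

from .patterns import EmptyMaskError

GEO_NAMES = [
    "geo_area", "geo_perimeter", "geo_diameter", "geo_solidity",
    "geo_eccentricity", "geo_aspect_ratio", "geo_compactness",
    "geo_roundness", "geo_circularity", "geo_ellipticity",
]


@dataclasses.dataclass
class GeometricFeatures:
    """The ten descriptors plus the moment-ellipse axes L and M."""

    area: float
    perimeter: float
    diameter: float
    solidity: float
    eccentricity: float
    aspect_ratio: float
    compactness: float
    roundness: float
    circularity: float
    ellipticity: float
    major_axis_length: float
    minor_axis_length: float

    def as_dict(self) -> dict[str, float]:
        return {
            "geo_area": self.area,
            "geo_perimeter": self.perimeter,
            "geo_diameter": self.diameter,
            "geo_solidity": self.solidity,
            "geo_eccentricity": self.eccentricity,
            "geo_aspect_ratio": self.aspect_ratio,
            "geo_compactness": self.compactness,
            "geo_roundness": self.roundness,
            "geo_circularity": self.circularity,
            "geo_ellipticity": self.ellipticity,
        }

    def as_vector(self) -> np.ndarray:
        return np.array([self.as_dict()[name] for name in GEO_NAMES])


# Moore neighbourhood in clockwise order starting east.  Step weights are
# Kulpa's bias-corrected chain-code lengths: the raw 1 / sqrt(2) weights
# overestimate smooth boundaries by ~5% from staircase zigzag, so axis and
# diagonal steps are scaled by pi/8*(1 + sqrt(2)) ~= 0.948, which makes
# the estimated circle perimeter converge to the true one under refinement.
_KULPA = math.pi / 8.0 * (1.0 + math.sqrt(2.0))
_NEIGHBORS = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]
_STEP_LEN = [math.hypot(dr, dc) * _KULPA for dr, dc in _NEIGHBORS]


def chain_perimeter(mask: np.ndarray) -> float:
    """Length of the 8-connected boundary chain (Moore-neighbour tracing).

    Diagonal steps weigh sqrt(2) relative to axis steps; both carry Kulpa's
    0.948 staircase correction.  Single-pixel regions fall back to the
    unit-square boundary length 4.
    """
    mask = np.asarray(mask) != 0
    if mask.sum() == 0:
        raise EmptyMaskError("empty mask")
    if mask.sum() == 1:
        return 4.0
    padded = np.pad(mask, 1)
    rows, cols = np.nonzero(padded)
    start = (rows[0], cols[0])  # raster order: topmost, then leftmost
    # Backtrack begins at the pixel west of the start (exterior by rasterization)
    prev_dir = 4  # direction from current pixel toward the backtrack (west)
    current = start
    length = 0.0
    first_move: tuple[tuple[int, int], int] | None = None
    max_steps = 4 * int(mask.sum()) + 8
    for _ in range(max_steps):
        found = False
        # scan clockwise starting just after the backtrack direction
        for k in range(1, 9):
            d = (prev_dir + k) % 8
            nr, nc = current[0] + _NEIGHBORS[d][0], current[1] + _NEIGHBORS[d][1]
            if padded[nr, nc]:
                if first_move is None:
                    first_move = (current, d)
                elif (current, d) == first_move:
                    return length
                length += _STEP_LEN[d]
                current = (nr, nc)
                prev_dir = (d + 4) % 8  # backtrack = opposite of arrival
                found = True
                break
        if not found:  # isolated pixel among the component (cannot happen post-check)
            return 4.0
    return length


def compute_geometric_features(
    mask: np.ndarray, pixel_spacing_mm: float = 1.0
) -> GeometricFeatures:
    """Descriptors of the (largest) foreground component of ``mask``."""
    mask = np.asarray(mask) != 0
    if not mask.any():
        raise EmptyMaskError("empty mask")
    labeled, n_comp = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n_comp > 1:
        warnings.warn(
            f"mask has {n_comp} components; using the largest", stacklevel=2
        )
        sizes = ndimage.sum_labels(mask, labeled, index=range(1, n_comp + 1))
        mask = labeled == (int(np.argmax(sizes)) + 1)
    mask = ndimage.binary_fill_holes(mask)

    s = pixel_spacing_mm
    props = measure.regionprops(mask.astype(np.uint8))[0]
    area = float(props.area) * s * s
    perimeter = chain_perimeter(mask) * s
    diameter = math.sqrt(4.0 * area / math.pi)
    solidity = float(props.area) / float(props.area_convex)

    major = float(props.axis_major_length) * s
    minor = float(props.axis_minor_length) * s
    if major <= 0:  # degenerate (single pixel / line): treat as circle-equivalent
        major = minor = diameter
    if minor <= 0:
        minor = s  # one-pixel-thin line: one pixel wide
    ecc = math.sqrt(max(0.0, 1.0 - (minor / major) ** 2))

    return GeometricFeatures(
        area=area,
        perimeter=perimeter,
        diameter=diameter,
        solidity=solidity,
        eccentricity=ecc,
        aspect_ratio=minor / major,
        compactness=perimeter ** 2 / (4.0 * math.pi * area),
        roundness=4.0 * area / (math.pi * major ** 2),
        circularity=4.0 * math.pi * area / perimeter ** 2,
        ellipticity=math.pi * major ** 2 / (2.0 * area),
        major_axis_length=major,
        minor_axis_length=minor,
    )
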