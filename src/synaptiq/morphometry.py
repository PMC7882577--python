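"""Field-level morphometry: cell densities, thresholded signal area,
axonal line-crossing counts, and the lesion/perilesion partition.

The perilesion compartment is the band extending 150 um from the lesion
border (Euclidean distance in physical micrometres on the 2D section).
Axonal density is measured as the number of distinct foreground runs of a
fiber mask intersecting a rasterised 100 um line, the automatable analogue
of a manual double-blinded crossing count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line
from skimage.measure import label as sk_label

from .segmentation import SegmentationParams, local_threshold_section


def cell_density(
    positions_um: np.ndarray,
    field_area_mm2: Optional[float] = None,
    compartment_mask: Optional[np.ndarray] = None,
    pixel_size_um: Optional[float] = None,
) -> float:
    """Cells per mm^2, optionally restricted to a compartment mask.

    With a mask, only cells whose centre falls on a True pixel are counted
    and the area is the mask area; otherwise ``field_area_mm2`` is used.
    """
    positions_um = np.asarray(positions_um, dtype=float).reshape(-1, 2)
    if compartment_mask is not None:
        if pixel_size_um is None:
            raise ValueError("pixel_size_um required with a compartment mask")
        area_mm2 = compartment_mask.sum() * pixel_size_um**2 * 1e-6
        if area_mm2 <= 0:
            raise ValueError("compartment area is zero")
        count = 0
        for x, y in positions_um:
            r, c = int(y / pixel_size_um), int(x / pixel_size_um)
            if 0 <= r < compartment_mask.shape[0] and 0 <= c < compartment_mask.shape[1]:
                count += compartment_mask[r, c]
        return count / area_mm2
    if field_area_mm2 is None or field_area_mm2 <= 0:
        raise ValueError("field_area_mm2 must be > 0")
    return len(positions_um) / field_area_mm2


def signal_area(
    image: np.ndarray,
    params: SegmentationParams,
    pixel_size_um: float,
    exclude_somata: bool = False,
    soma_equiv_diameter_um: float = 20.0,
) -> float:
    """Thresholded signal area in um^2.

    With ``exclude_somata``, connected components whose equivalent
    diameter reaches ``soma_equiv_diameter_um`` are removed before
    measuring (puncta-only area, e.g. interneuron boutons without the
    labelled cell bodies).
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    mask = local_threshold_section(np.asarray(image, dtype=float), params)
    if exclude_somata and mask.any():
        lab = sk_label(mask, connectivity=2)
        areas_px = np.bincount(lab.ravel())
        equiv_diam_um = 2.0 * np.sqrt(areas_px * pixel_size_um**2 / np.pi)
        soma_labels = np.flatnonzero(equiv_diam_um >= soma_equiv_diameter_um)
        mask &= ~np.isin(lab, soma_labels[soma_labels > 0])
    return float(mask.sum()) * pixel_size_um**2


def line_crossings(
    fiber_mask: np.ndarray,
    line_segment_um: Tuple[Tuple[float, float], Tuple[float, float]],
    pixel_size_um: float,
    length_um: float = 100.0,
    length_tolerance: float = 0.05,
) -> int:
    """Number of distinct foreground runs of the mask along the query line.

    A run is a maximal set of consecutive rasterised line pixels that are
    foreground; each run counts as one fiber crossing regardless of fiber
    thickness.
    """
    (x0, y0), (x1, y1) = line_segment_um
    length = float(np.hypot(x1 - x0, y1 - y0))
    if abs(length - length_um) > length_tolerance * length_um:
        raise ValueError(f"line length {length:.2f} um differs from required {length_um} um")

    def to_px(x: float, y: float) -> Tuple[int, int]:
        return int(round(y / pixel_size_um - 0.5)), int(round(x / pixel_size_um - 0.5))

    r0, c0 = to_px(x0, y0)
    r1, c1 = to_px(x1, y1)
    h, w = fiber_mask.shape
    for r, c in ((r0, c0), (r1, c1)):
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError("query line falls outside the image")
    rr, cc = draw_line(r0, c0, r1, c1)
    profile = np.asarray(fiber_mask[rr, cc], dtype=bool)
    # count runs of consecutive foreground samples
    padded = np.concatenate(([False], profile))
    return int(np.count_nonzero(~padded[:-1] & profile))


@dataclass
class LesionPartition:
    """Mutually exclusive, jointly exhaustive field compartments."""

    lesion: np.ndarray
    perilesion: np.ndarray
    outside: np.ndarray
    band_um: float

    def labels(self) -> np.ndarray:
        """0 = lesion, 1 = perilesion, 2 = outside."""
        return np.where(self.lesion, 0, np.where(self.perilesion, 1, 2))


def perilesion_partition(
    lesion_mask: np.ndarray,
    pixel_size_um: float,
    band_um: float = 150.0,
) -> LesionPartition:
    """Split the field into lesion, perilesion band, and outside.

    Perilesion = pixels outside the lesion whose Euclidean distance to the
    nearest lesion pixel is at most ``band_um``.
    """
    lesion_mask = np.asarray(lesion_mask, dtype=bool)
    if not lesion_mask.any():
        raise ValueError("lesion mask is empty")
    if pixel_size_um <= 0 or band_um <= 0:
        raise ValueError("pixel_size_um and band_um must be > 0")
    dist_um = ndimage.distance_transform_edt(~lesion_mask, sampling=pixel_size_um)
    perilesion = (~lesion_mask) & (dist_um <= band_um)
    outside = (~lesion_mask) & (~perilesion)
    return LesionPartition(lesion=lesion_mask, perilesion=perilesion, outside=outside, band_um=band_um)
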