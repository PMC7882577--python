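"""Neuropil ROIs, pre/post puncta pairing, and volumetric synapse densities.

A structural synapse is declared where a presynaptic and a postsynaptic
punctum have centres within a set physical distance (1.0 um for the human
material, 0.5 um for mouse).  Pairing is one-to-one by default: candidate
cross-channel pairs within the radius are sorted by ascending distance and
accepted greedily so no punctum is double-counted; an any-within-radius
mode is retained for sensitivity analysis.

Densities are reported per mm^3 over the analysed neuropil volume: a
regular grid of 10 x 10 um ROIs, dropping ROIs that touch the exclusion
mask (cell bodies, blood vessels).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.spatial import cKDTree

from .segmentation import PunctumObject

UM3_PER_MM3 = 1e9


@dataclass
class NeuropilROIGrid:
    """Axis-aligned, non-overlapping analysis boxes inside the field."""

    roi_size_um: float
    boxes: List[Tuple[float, float, float, float]]  # (x0, y0, x1, y1), kept ROIs only
    depth_um: float
    analyzed_volume_um3: float
    n_dropped: int = 0

    @property
    def n_rois(self) -> int:
        return len(self.boxes)

    def roi_of(self, x: float, y: float) -> Optional[int]:
        """Index of the kept ROI containing (x, y), or None."""
        for i, (x0, y0, x1, y1) in enumerate(self.boxes):
            if x0 <= x < x1 and y0 <= y < y1:
                return i
        return None


def make_neuropil_rois(
    field_extent_um: Union[float, Tuple[float, float]],
    depth_um: float,
    exclusion_mask: Optional[np.ndarray] = None,
    pixel_size_um: Optional[float] = None,
    roi_size_um: float = 10.0,
    max_excluded_fraction: float = 0.0,
) -> NeuropilROIGrid:
    """Regular grid of ``roi_size_um`` boxes avoiding the exclusion mask.

    An ROI whose excluded-area fraction exceeds ``max_excluded_fraction``
    (default: any overlap) is dropped.  The analysed volume sums the kept
    ROI areas minus their residual excluded pixels, times the stack depth.
    """
    if isinstance(field_extent_um, (int, float)):
        field_extent_um = (float(field_extent_um), float(field_extent_um))
    ex, ey = field_extent_um
    if roi_size_um <= 0 or roi_size_um > min(ex, ey):
        raise ValueError("roi_size_um must be positive and fit inside the field")
    if depth_um <= 0:
        raise ValueError("depth_um must be > 0")
    if exclusion_mask is not None:
        if pixel_size_um is None:
            raise ValueError("pixel_size_um required with an exclusion mask")
        mh, mw = exclusion_mask.shape
        if abs(mw * pixel_size_um - ex) > pixel_size_um or abs(mh * pixel_size_um - ey) > pixel_size_um:
            raise ValueError(
                f"exclusion mask of shape {exclusion_mask.shape} at {pixel_size_um} um/px "
                f"does not cover the {ex:.2f} x {ey:.2f} um field"
            )

    nx = int(np.floor(ex / roi_size_um))
    ny = int(np.floor(ey / roi_size_um))
    boxes: List[Tuple[float, float, float, float]] = []
    volume = 0.0
    dropped = 0
    for iy in range(ny):
        for ix in range(nx):
            x0, y0 = ix * roi_size_um, iy * roi_size_um
            x1, y1 = x0 + roi_size_um, y0 + roi_size_um
            excluded_um2 = 0.0
            if exclusion_mask is not None:
                c0 = int(np.floor(x0 / pixel_size_um))
                c1 = int(np.ceil(x1 / pixel_size_um))
                r0 = int(np.floor(y0 / pixel_size_um))
                r1 = int(np.ceil(y1 / pixel_size_um))
                sub = exclusion_mask[r0:r1, c0:c1]
                excluded_um2 = float(sub.sum()) * pixel_size_um**2
            frac = excluded_um2 / roi_size_um**2
            if frac > max_excluded_fraction:
                dropped += 1
                continue
            boxes.append((x0, y0, x1, y1))
            volume += (roi_size_um**2 - excluded_um2) * depth_um
    return NeuropilROIGrid(
        roi_size_um=roi_size_um, boxes=boxes, depth_um=depth_um,
        analyzed_volume_um3=volume, n_dropped=dropped,
    )


@dataclass
class SynapsePairing:
    max_dist_um: float
    pairs: List[Tuple[int, int, float]]  # (pre_id, post_id, distance_um)
    unmatched_pre: List[int]
    unmatched_post: List[int]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def pair_ids(self) -> set:
        return {(a, b) for a, b, _ in self.pairs}


def _coords_ids(objs) -> Tuple[np.ndarray, np.ndarray]:
    if len(objs) == 0:
        return np.empty((0, 3)), np.empty(0, dtype=int)
    if isinstance(objs[0], PunctumObject):
        return (np.array([o.centroid_um for o in objs], dtype=float),
                np.array([o.id for o in objs], dtype=int))
    arr = np.asarray(objs, dtype=float)
    return arr, np.arange(len(arr))


def pair_puncta(
    pre, post, max_dist_um: float, mode: str = "one_to_one"
) -> SynapsePairing:
    """Match pre- and post-synaptic centres within ``max_dist_um``.

    ``one_to_one`` (default): all candidate pairs within the radius are
    sorted by ascending distance (ties broken by (pre_id, post_id)) and
    accepted iff both puncta are still unused.  ``any_within``: every
    within-radius pair is returned (sensitivity analysis only).

    ``pre``/``post`` are sequences of :class:`PunctumObject` or (n, 3)
    arrays of centres in physical micrometres.
    """
    if max_dist_um <= 0:
        raise ValueError("max_dist_um must be > 0")
    if mode not in ("one_to_one", "any_within"):
        raise ValueError("mode must be 'one_to_one' or 'any_within'")
    pre_xyz, pre_ids = _coords_ids(pre)
    post_xyz, post_ids = _coords_ids(post)
    if len(pre_xyz) == 0 or len(post_xyz) == 0:
        return SynapsePairing(max_dist_um, [], list(pre_ids), list(post_ids))

    tree = cKDTree(post_xyz)
    candidates: List[Tuple[float, int, int]] = []  # (distance, pre_idx, post_idx)
    for i, neighbours in enumerate(tree.query_ball_point(pre_xyz, r=max_dist_um)):
        for j in neighbours:
            d = float(np.linalg.norm(pre_xyz[i] - post_xyz[j]))
            candidates.append((d, i, j))
    candidates.sort(key=lambda t: (t[0], pre_ids[t[1]], post_ids[t[2]]))

    pairs: List[Tuple[int, int, float]] = []
    if mode == "any_within":
        pairs = [(int(pre_ids[i]), int(post_ids[j]), d) for d, i, j in candidates]
        matched_pre = {i for _, i, _ in candidates}
        matched_post = {j for _, _, j in candidates}
    else:
        used_pre: set = set()
        used_post: set = set()
        for d, i, j in candidates:
            if i in used_pre or j in used_post:
                continue
            used_pre.add(i)
            used_post.add(j)
            pairs.append((int(pre_ids[i]), int(post_ids[j]), d))
        matched_pre, matched_post = used_pre, used_post
    return SynapsePairing(
        max_dist_um=max_dist_um,
        pairs=pairs,
        unmatched_pre=[int(pre_ids[i]) for i in range(len(pre_ids)) if i not in matched_pre],
        unmatched_post=[int(post_ids[j]) for j in range(len(post_ids)) if j not in matched_post],
    )


@dataclass
class DensityResult:
    synapse_density_per_mm3: float
    pre_puncta_per_mm3: float
    post_puncta_per_mm3: float
    n_pairs_counted: int
    n_pre_counted: int
    n_post_counted: int
    analyzed_volume_um3: float
    per_roi_pair_density: np.ndarray = field(default=None, repr=False)


def compute_densities(
    pairing: SynapsePairing,
    pre,
    post,
    grid: NeuropilROIGrid,
) -> DensityResult:
    """Volumetric densities over the analysed neuropil volume.

    A pair is counted in the ROI that contains its presynaptic centroid
    (deterministic ownership); single-channel puncta are counted by their
    own centroids.  Density = count / analysed volume x 1e9 (um^3 -> mm^3).
    """
    if grid.analyzed_volume_um3 <= 0:
        raise ValueError("analysed volume is zero")
    pre_xyz, pre_ids = _coords_ids(pre)
    post_xyz, post_ids = _coords_ids(post)
    pre_by_id = {int(pid): pre_xyz[k] for k, pid in enumerate(pre_ids)}

    roi_counts = np.zeros(grid.n_rois, dtype=int)
    n_pairs = 0
    for pre_id, _post_id, _d in pairing.pairs:
        x, y, _z = pre_by_id[pre_id]
        roi = grid.roi_of(x, y)
        if roi is not None:
            roi_counts[roi] += 1
            n_pairs += 1
    n_pre = sum(1 for x, y, _z in pre_xyz if grid.roi_of(x, y) is not None)
    n_post = sum(1 for x, y, _z in post_xyz if grid.roi_of(x, y) is not None)

    roi_vol = grid.roi_size_um**2 * grid.depth_um
    per_roi = roi_counts / roi_vol * UM3_PER_MM3
    scale = UM3_PER_MM3 / grid.analyzed_volume_um3
    return DensityResult(
        synapse_density_per_mm3=n_pairs * scale,
        pre_puncta_per_mm3=n_pre * scale,
        post_puncta_per_mm3=n_post * scale,
        n_pairs_counted=n_pairs,
        n_pre_counted=n_pre,
        n_post_counted=n_post,
        analyzed_volume_um3=grid.analyzed_volume_um3,
        per_roi_pair_density=per_roi,
    )
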