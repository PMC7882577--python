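"""Puncta segmentation on serial fluorescence sections.

Each channel of a :class:`SectionSeries` is thresholded section by section
with a local (adaptive) rule, in-plane connected components are linked
across consecutive sections into 3D objects, and objects that do not
persist across at least two consecutive sections are discarded as
single-section artifacts.

Coordinate convention used throughout the package: physical coordinates are
in micrometres with the origin at the field corner; the centre of voxel
(row=i, col=j, section=k) is at
``x=(j+0.5)*pixel_size, y=(i+0.5)*pixel_size, z=(k+0.5)*section_spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage.measure import label as sk_label


@dataclass
class SectionSeries:
    """Ordered stack of 2D sections per channel with physical spacing.

    ``channels`` maps channel name to a float array of shape
    ``(n_sections, ny, nx)``.  ``section_spacing_um`` is the optical z-step
    for confocal stacks (0.15 um) or the physical section thickness for
    array-tomography ribbons (0.07 um).
    """

    channels: Dict[str, np.ndarray]
    pixel_size_um: float
    section_spacing_um: float

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.section_spacing_um <= 0:
            raise ValueError("pixel size and section spacing must be > 0")
        shapes = {arr.shape for arr in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channel stacks disagree in shape: {shapes}")
        for name, arr in self.channels.items():
            if arr.ndim != 3:
                raise ValueError(f"channel {name!r} is not a (z, y, x) stack")

    @property
    def n_sections(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def shape(self) -> Tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def field_extent_um(self) -> Tuple[float, float]:
        _, ny, nx = self.shape
        return (nx * self.pixel_size_um, ny * self.pixel_size_um)

    @property
    def depth_um(self) -> float:
        return self.n_sections * self.section_spacing_um

    def voxel_volume_um3(self) -> float:
        return self.pixel_size_um**2 * self.section_spacing_um


# Alias: a confocal stack and an AT ribbon share the same in-memory layout.
VolumeImage = SectionSeries


@dataclass
class SegmentationParams:
    """Per-channel local-threshold settings, constant across sections.

    method:
        ``"niblack"`` — foreground iff intensity > local mean + offset_k * local SD;
        ``"mean"``    — intensity > local mean + offset;
        ``"median"``  — intensity > local median + offset.
    window_radius_px:
        half-width of the square window (window side = 2r + 1).
    min_footprint_px:
        in-plane components smaller than this are dropped before linking.
    """

    method: str = "niblack"
    window_radius_px: int = 8
    offset_k: float = 2.0
    offset: float = 0.0
    min_footprint_px: int = 2

    def __post_init__(self) -> None:
        if self.method not in ("niblack", "mean", "median"):
            raise ValueError(f"unknown threshold method {self.method!r}")
        if self.window_radius_px < 1:
            raise ValueError("window_radius_px must be >= 1")
        if self.min_footprint_px < 0:
            raise ValueError("min_footprint_px must be >= 0")


@dataclass(eq=False)
class PunctumObject:
    """A segmented 3D object linked across sections.

    ``footprints`` maps section index -> (n, 2) array of (row, col) voxel
    indices.  ``centroid_um`` is the unweighted mean of member voxel centres
    in physical micrometres, ordered (x, y, z).
    """

    id: int
    channel: str
    footprints: Dict[int, np.ndarray]
    centroid_um: Tuple[float, float, float]
    volume_um3: float
    section_span: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.section_span:
            self.section_span = frozenset(self.footprints)

    @property
    def n_voxels(self) -> int:
        return sum(len(fp) for fp in self.footprints.values())

    @property
    def n_sections(self) -> int:
        return len(self.section_span)

    def max_consecutive_sections(self) -> int:
        """Length of the longest run of consecutive section indices."""
        idx = sorted(self.section_span)
        best = run = 1
        for a, b in zip(idx, idx[1:]):
            run = run + 1 if b == a + 1 else 1
            best = max(best, run)
        return best


def local_threshold_section(section: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Binarise one section with the configured local-threshold rule.

    A pixel is foreground iff its intensity strictly exceeds the local
    statistic plus the offset term.  On a perfectly uniform image with a
    positive offset the mask is therefore empty (documented behaviour,
    not an error).
    """
    section = np.asarray(section, dtype=np.float64)
    if section.ndim != 2:
        raise ValueError("section must be 2D")
    window = 2 * params.window_radius_px + 1
    if window > min(section.shape):
        raise ValueError(
            f"window side {window} px does not fit in section of shape {section.shape}"
        )
    # guard against float cancellation in the moving-sum filters: on flat
    # regions the computed local mean can drift a hair below the pixel value
    eps = 1e-8 * max(1.0, float(np.abs(section).max()))
    if params.method == "median":
        stat = ndimage.median_filter(section, size=window, mode="nearest")
        return section > stat + params.offset + eps
    mean = ndimage.uniform_filter(section, size=window, mode="nearest")
    if params.method == "mean":
        return section > mean + params.offset + eps
    # Niblack-style: mean + k * SD over the same window
    sq = ndimage.uniform_filter(section * section, size=window, mode="nearest")
    sd = np.sqrt(np.clip(sq - mean * mean, 0.0, None))
    return section > mean + params.offset_k * sd + eps


def _section_labels(
    series: SectionSeries, channel: str, params: SegmentationParams
) -> List[np.ndarray]:
    """Label in-plane 8-connected components per section, minus small footprints."""
    stack = series.channels[channel]
    labels = []
    for k in range(stack.shape[0]):
        mask = local_threshold_section(stack[k], params)
        lab = sk_label(mask, connectivity=2)
        if params.min_footprint_px > 1 and lab.max() > 0:
            counts = np.bincount(lab.ravel())
            small = np.flatnonzero(counts < params.min_footprint_px)
            lab[np.isin(lab, small[small > 0])] = 0
        labels.append(lab)
    return labels


class _UnionFind:
    def __init__(self) -> None:
        self.parent: Dict[Tuple[int, int], Tuple[int, int]] = {}

    def add(self, x: Tuple[int, int]) -> None:
        self.parent.setdefault(x, x)

    def find(self, x: Tuple[int, int]) -> Tuple[int, int]:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: Tuple[int, int], b: Tuple[int, int]) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def extract_objects(
    series: SectionSeries, channel: str, params: SegmentationParams
) -> List[PunctumObject]:
    """Segment ``channel`` and link footprints across sections into 3D objects.

    In-plane components (8-connectivity) on consecutive sections are merged
    into one object when their footprints overlap in at least one pixel,
    transitively across the whole series.  Footprints smaller than
    ``params.min_footprint_px`` are removed before linking.
    """
    if series.n_sections < 2:
        raise ValueError("object extraction requires at least 2 sections")
    if channel not in series.channels:
        raise KeyError(f"channel {channel!r} not in series")
    labels = _section_labels(series, channel, params)

    uf = _UnionFind()
    for k, lab in enumerate(labels):
        for lid in np.unique(lab):
            if lid > 0:
                uf.add((k, int(lid)))
    for k in range(len(labels) - 1):
        a, b = labels[k], labels[k + 1]
        both = (a > 0) & (b > 0)
        if not both.any():
            continue
        pairs = np.unique(np.stack([a[both], b[both]], axis=1), axis=0)
        for la, lb in pairs:
            uf.union((k, int(la)), (k + 1, int(lb)))

    groups: Dict[Tuple[int, int], Dict[int, np.ndarray]] = {}
    for k, lab in enumerate(labels):
        if lab.max() == 0:
            continue
        objs = ndimage.find_objects(lab)
        for lid, sl in enumerate(objs, start=1):
            if sl is None:
                continue
            rows, cols = np.nonzero(lab[sl] == lid)
            rows = rows + sl[0].start
            cols = cols + sl[1].start
            root = uf.find((k, lid))
            fp = np.stack([rows, cols], axis=1)
            sec = groups.setdefault(root, {})
            # an object may own several in-plane components on one section
            sec[k] = np.concatenate([sec[k], fp]) if k in sec else fp

    px = series.pixel_size_um
    dz = series.section_spacing_um
    out: List[PunctumObject] = []
    # deterministic ordering: by first section then first voxel
    for oid, root in enumerate(sorted(groups, key=lambda r: (min(groups[r]),) + tuple(groups[r][min(groups[r])][0]))):
        fps = groups[root]
        n_vox = sum(len(v) for v in fps.values())
        sx = sy = sz = 0.0
        for k, rc in fps.items():
            sy += float((rc[:, 0] + 0.5).sum()) * px
            sx += float((rc[:, 1] + 0.5).sum()) * px
            sz += len(rc) * (k + 0.5) * dz
        out.append(
            PunctumObject(
                id=oid,
                channel=channel,
                footprints=fps,
                centroid_um=(sx / n_vox, sy / n_vox, sz / n_vox),
                volume_um3=n_vox * px * px * dz,
            )
        )
    return out


def persistence_filter(
    objects: Sequence[PunctumObject], min_consecutive: int = 2
) -> List[PunctumObject]:
    """Remove objects not present in at least ``min_consecutive`` consecutive sections.

    Keeps exactly the objects whose section span contains a run of
    ``min_consecutive`` consecutive indices; order is preserved and the
    operation is idempotent.
    """
    if min_consecutive < 1:
        raise ValueError("min_consecutive must be >= 1")
    return [o for o in objects if o.max_consecutive_sections() >= min_consecutive]
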