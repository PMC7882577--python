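"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the statistical structure the analysis assumes:

* two-channel 3D puncta stacks at confocal geometry (58.7 nm pixels,
  150 nm z-step) in which a controlled fraction of presynaptic puncta has a
  postsynaptic partner at a controlled isotropic centre offset;
* array-tomography-style section series (70 nm sections) where each 3D
  punctum is rendered only on the sections its z-extent intersects, plus
  single-section "flicker" artifacts that the persistence filter is meant
  to remove;
* 2D fields of cell bodies (disks) or straight axonal fibers with a stored
  100 um query line;
* miniature-PSC current traces: Poisson event onsets, unit-peak
  triexponential kernels scaled by truncated-normal amplitudes, Gaussian
  baseline noise and optional linear drift.

Puncta are rendered as Gaussian-blurred ellipsoids (a solid ball of radius
r approximated by a Gaussian of sigma r/2, combined in quadrature with the
PSF sigma) rather than by full-field convolution; at the puncta scale the
statistics are identical and the rendering cost is per-object.

Channel density defaults follow measured human motor-cortex control
values: presynaptic ~4.2e8 and postsynaptic ~3.7e8 puncta/mm^3 with
~2.6e8 colocalized pairs/mm^3 (excitatory-like), and 1.6e8/2.2e8 with
9.2e7 pairs/mm^3 (inhibitory-like).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from shapely.geometry import LineString, box

from .ephys import Recording, make_template
from .segmentation import SectionSeries

# Confocal geometry of the source acquisitions: 184.58 um fields at
# 3144 x 3144 px, 150 nm optical z-step over ~2 um.
ACQ_FIELD_UM = 184.58
ACQ_PIXEL_UM = ACQ_FIELD_UM / 3144.0  # 0.0587 um
ACQ_Z_STEP_UM = 0.15
AT_SECTION_UM = 0.07

# Control-group single-channel and paired densities (per mm^3), human motor cortex.
EXCITATORY_DENSITIES = {"pre": 4.167e8, "post": 3.731e8, "pairs": 2.589e8}
INHIBITORY_DENSITIES = {"pre": 1.630e8, "post": 2.151e8, "pairs": 9.217e7}
# Mouse cortex control (PBS) inhibitory paired density is ~1.8e7/mm^3; the
# single-channel densities are not reported, so they are scaled from the
# human single-channel:paired ratios (pre ~1.77x, post ~2.33x the pairs).
MOUSE_INHIBITORY_DENSITIES = {"pre": 3.26e7, "post": 4.30e7, "pairs": 1.844e7}


@dataclass
class ChannelSim:
    """Per-channel puncta population and optics."""

    puncta_density_per_mm3: float
    punctum_radius_um: float = 0.2
    peak_intensity: float = 50.0
    psf_sigma_um: Tuple[float, float, float] = (0.1, 0.1, 0.2)  # (x, y, z)

    def render_sigma_um(self) -> Tuple[float, float, float]:
        """Effective Gaussian sigma of a rendered punctum (ball (+) PSF in quadrature)."""
        r2 = (self.punctum_radius_um / 2.0) ** 2
        return tuple(math.sqrt(s * s + r2) for s in self.psf_sigma_um)


@dataclass
class SimImageConfig:
    """Geometry, populations and noise of a simulated two-channel volume.

    The default field is a 30 um (512 px) crop at the source pixel size;
    full acquisition fields (184.58 um) are supported but large.
    """

    field_size_um: float = 512 * ACQ_PIXEL_UM  # ~30.06 um
    pixel_size_um: float = ACQ_PIXEL_UM
    z_step_um: float = ACQ_Z_STEP_UM
    section_thickness_um: float = AT_SECTION_UM
    n_sections: int = 14
    channels: Dict[str, ChannelSim] = field(default_factory=lambda: {
        "pre": ChannelSim(EXCITATORY_DENSITIES["pre"]),
        "post": ChannelSim(EXCITATORY_DENSITIES["post"]),
    })
    pre_channel: str = "pre"
    post_channel: str = "post"
    colocalization_fraction: float = EXCITATORY_DENSITIES["pairs"] / EXCITATORY_DENSITIES["pre"]
    pair_offset_sd_um: float = 0.15
    flicker_density_per_mm3: Optional[float] = None  # None: 0 for stacks, 10% of channel density for ribbons
    background_level: float = 10.0
    gaussian_noise_sd: float = 2.0
    poisson_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.field_size_um, self.pixel_size_um, self.z_step_um,
               self.section_thickness_um) <= 0:
            raise ValueError("physical sizes must be > 0")
        if self.n_sections < 1:
            raise ValueError("need at least one section")
        if not 0.0 <= self.colocalization_fraction <= 1.0:
            raise ValueError("colocalization_fraction must lie in [0, 1]")
        if self.pair_offset_sd_um < 0:
            raise ValueError("pair_offset_sd_um must be >= 0")
        if int(round(self.field_size_um / self.pixel_size_um)) < 1:
            raise ValueError("field smaller than one pixel")
        if self.pre_channel not in self.channels or self.post_channel not in self.channels:
            raise ValueError("pre/post channel names must exist in channels")


@dataclass
class SimFieldConfig:
    """A 150x150 um 2D field of cell bodies or axonal fibers."""

    field_size_um: float = 150.0
    pixel_size_um: float = 0.5
    n_objects: int = 20
    cell_radius_um: float = 5.0
    fiber_thickness_um: float = 1.0
    fiber_angles_deg: Optional[Sequence[float]] = None
    fiber_points_um: Optional[Sequence[Tuple[float, float]]] = None
    line_um: Tuple[Tuple[float, float], Tuple[float, float]] = ((25.0, 75.0), (125.0, 75.0))
    peak_intensity: float = 100.0
    background_level: float = 10.0
    gaussian_noise_sd: float = 2.0
    max_overlap_fraction: float = 0.0
    seed: int = 0


@dataclass
class SimEphysConfig:
    """A 5-minute, 20 kHz miniature-PSC recording."""

    duration_s: float = 300.0
    sampling_hz: float = 20_000.0
    event_rate_hz: float = 2.0
    amplitude_mean_pA: float = 20.0
    amplitude_sd_pA: float = 5.0
    tau_rise_ms: float = 0.5
    tau_decay1_ms: float = 3.0
    tau_decay2_ms: float = 12.0
    decay_mix: float = 0.7
    kernel_length_ms: float = 50.0
    polarity: str = "outward"
    baseline_noise_sd_pA: float = 2.0
    drift_pA_per_s: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.tau_rise_ms, self.tau_decay1_ms, self.tau_decay2_ms) <= 0:
            raise ValueError("time constants must be > 0")
        if self.amplitude_mean_pA <= 0:
            raise ValueError("amplitude_mean_pA must be > 0")
        if not 0.0 <= self.decay_mix <= 1.0:
            raise ValueError("decay_mix must lie in [0, 1]")
        n = self.duration_s * self.sampling_hz
        if abs(n - round(n)) > 1e-6:
            raise ValueError("duration_s * sampling_hz must be an integer sample count")
        if self.polarity not in ("inward", "outward"):
            raise ValueError("polarity must be 'inward' or 'outward'")


@dataclass
class GroundTruth:
    """True objects, pairs and events underlying a simulated dataset."""

    field_extent_um: Optional[Tuple[float, ...]] = None
    volume_um3: Optional[float] = None
    centers_um: Dict[str, np.ndarray] = field(default_factory=dict)
    pairs: Optional[np.ndarray] = None  # (m, 2) indices into pre/post center arrays
    flicker_centers_um: Dict[str, np.ndarray] = field(default_factory=dict)
    flicker_sections: Dict[str, np.ndarray] = field(default_factory=dict)
    densities_per_mm3: Dict[str, float] = field(default_factory=dict)
    pair_density_per_mm3: Optional[float] = None
    amplitude_truncated_at_zero: bool = False
    # 2D field modes
    n_objects: Optional[int] = None
    fiber_segments_um: Optional[List[Tuple[Tuple[float, float], Tuple[float, float]]]] = None
    line_um: Optional[Tuple[Tuple[float, float], Tuple[float, float]]] = None
    n_crossings: Optional[int] = None
    # ephys
    event_onsets_s: Optional[np.ndarray] = None
    event_amplitudes_pA: Optional[np.ndarray] = None
    event_rate_hz: Optional[float] = None

    @property
    def n_pairs(self) -> int:
        return 0 if self.pairs is None else len(self.pairs)


def _add_blob(
    img: np.ndarray,
    center_um: Tuple[float, float, float],
    amp: float,
    sigma_um: Tuple[float, float, float],
    pixel_um: float,
    spacing_um: float,
    z_mode: str,
    z_extent_um: float = 0.0,
    only_section: Optional[int] = None,
) -> None:
    """Add one separable-Gaussian punctum into a (z, y, x) stack in place."""
    nz, ny, nx = img.shape
    cx, cy, cz = center_um
    sx, sy, sz = sigma_um
    reach = 4.0

    def axis_range(c: float, s: float, step: float, n: int) -> Tuple[int, int]:
        lo = max(0, int(math.floor((c - reach * s) / step - 0.5)))
        hi = min(n - 1, int(math.ceil((c + reach * s) / step - 0.5)))
        return lo, hi

    j0, j1 = axis_range(cx, sx, pixel_um, nx)
    i0, i1 = axis_range(cy, sy, pixel_um, ny)
    if j1 < j0 or i1 < i0:
        return
    xs = (np.arange(j0, j1 + 1) + 0.5) * pixel_um
    ys = (np.arange(i0, i1 + 1) + 0.5) * pixel_um
    gx = np.exp(-0.5 * ((xs - cx) / sx) ** 2)
    gy = np.exp(-0.5 * ((ys - cy) / sy) ** 2)

    if only_section is not None:
        gz = np.ones(1)
        k0 = k1 = only_section
    elif z_mode == "gaussian":
        k0, k1 = axis_range(cz, sz, spacing_um, nz)
        if k1 < k0:
            return
        zs = (np.arange(k0, k1 + 1) + 0.5) * spacing_um
        gz = np.exp(-0.5 * ((zs - cz) / sz) ** 2)
    elif z_mode == "extent":
        # render on exactly the sections the z-extent [cz-r, cz+r] intersects
        k0 = max(0, int(math.floor((cz - z_extent_um) / spacing_um)))
        k1 = min(nz - 1, int(math.ceil((cz + z_extent_um) / spacing_um - 1.0)))
        if k1 < k0:
            return
        gz = np.ones(k1 - k0 + 1)
    else:  # pragma: no cover
        raise ValueError(z_mode)
    img[k0 : k1 + 1, i0 : i1 + 1, j0 : j1 + 1] += (
        amp * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
    )


def _simulate_volume(cfg: SimImageConfig, spacing_um: float, z_mode: str) -> Tuple[SectionSeries, GroundTruth]:
    rng = np.random.default_rng(cfg.seed)
    px = cfg.pixel_size_um
    n_xy = int(round(cfg.field_size_um / px))
    nz = cfg.n_sections
    extent_xy = n_xy * px
    depth = nz * spacing_um
    vol_um3 = extent_xy * extent_xy * depth
    vol_mm3 = vol_um3 * 1e-9
    n_voxels = n_xy * n_xy * nz
    hi = np.array([extent_xy, extent_xy, depth])

    pre_name, post_name = cfg.pre_channel, cfg.post_channel
    for name, ch in cfg.channels.items():
        expected = ch.puncta_density_per_mm3 * vol_mm3
        if expected > n_voxels / 27.0:
            raise ValueError(
                f"field too small to place the requested puncta count for channel {name!r} "
                f"(expected {expected:.0f} puncta in {n_voxels} voxels)"
            )

    # --- place centres (draw order fixed for reproducibility) ---
    d_pre = cfg.channels[pre_name].puncta_density_per_mm3
    d_post = cfg.channels[post_name].puncta_density_per_mm3
    n_pre = int(rng.poisson(d_pre * vol_mm3))
    pre_centers = rng.uniform(0.0, 1.0, size=(n_pre, 3)) * hi
    n_paired = int(round(cfg.colocalization_fraction * n_pre))
    offsets = rng.normal(0.0, cfg.pair_offset_sd_um, size=(n_paired, 3))
    partners = np.clip(pre_centers[:n_paired] + offsets, 0.0, hi - 1e-9)
    extra_mean = max(0.0, (d_post - cfg.colocalization_fraction * d_pre) * vol_mm3)
    n_extra = int(rng.poisson(extra_mean))
    extras = rng.uniform(0.0, 1.0, size=(n_extra, 3)) * hi
    post_centers = np.concatenate([partners, extras], axis=0)
    pairs = np.stack([np.arange(n_paired), np.arange(n_paired)], axis=1) if n_paired else np.empty((0, 2), dtype=int)

    centers = {pre_name: pre_centers, post_name: post_centers}

    # --- single-section flicker artifacts ---
    flicker_centers: Dict[str, np.ndarray] = {}
    flicker_sections: Dict[str, np.ndarray] = {}
    for name, ch in cfg.channels.items():
        if cfg.flicker_density_per_mm3 is None:
            d_fl = 0.1 * ch.puncta_density_per_mm3 if z_mode == "extent" else 0.0
        else:
            d_fl = cfg.flicker_density_per_mm3
        n_fl = int(rng.poisson(d_fl * vol_mm3)) if d_fl > 0 else 0
        flicker_centers[name] = rng.uniform(0.0, 1.0, size=(n_fl, 2)) * extent_xy
        flicker_sections[name] = rng.integers(0, nz, size=n_fl)

    # --- render + noise ---
    stacks: Dict[str, np.ndarray] = {}
    for name, ch in cfg.channels.items():
        img = np.zeros((nz, n_xy, n_xy), dtype=np.float64)
        sig = ch.render_sigma_um()
        for c in centers[name]:
            _add_blob(img, tuple(c), ch.peak_intensity, sig, px, spacing_um,
                      z_mode, z_extent_um=ch.punctum_radius_um)
        for (fx, fy), fk in zip(flicker_centers[name], flicker_sections[name]):
            fz = (fk + 0.5) * spacing_um
            _add_blob(img, (fx, fy, fz), ch.peak_intensity, sig, px, spacing_um,
                      z_mode, only_section=int(fk))
        img += cfg.background_level
        if cfg.poisson_noise:
            img = rng.poisson(np.clip(img, 0.0, None)).astype(np.float64)
        if cfg.gaussian_noise_sd > 0:
            img += rng.normal(0.0, cfg.gaussian_noise_sd, size=img.shape)
        stacks[name] = img

    series = SectionSeries(channels=stacks, pixel_size_um=px, section_spacing_um=spacing_um)
    truth = GroundTruth(
        field_extent_um=(extent_xy, extent_xy, depth),
        volume_um3=vol_um3,
        centers_um=centers,
        pairs=pairs,
        flicker_centers_um=flicker_centers,
        flicker_sections=flicker_sections,
        densities_per_mm3={name: len(centers[name]) / vol_mm3 for name in centers},
        pair_density_per_mm3=n_paired / vol_mm3,
    )
    return series, truth


def simulate_puncta_stack(cfg: SimImageConfig) -> Tuple[SectionSeries, GroundTruth]:
    """Two-channel confocal-style stack with partially colocalized puncta.

    A fraction ``colocalization_fraction`` of presynaptic puncta gets a
    postsynaptic partner displaced by an isotropic Gaussian offset
    (SD ``pair_offset_sd_um``); remaining puncta of both channels are
    uniform in the field.  Identical seed gives bit-identical output.
    """
    return _simulate_volume(cfg, spacing_um=cfg.z_step_um, z_mode="gaussian")


def simulate_section_series(cfg: SimImageConfig) -> Tuple[SectionSeries, GroundTruth]:
    """Array-tomography-style ribbon of thin physical sections.

    Each 3D punctum appears only on the sections its z-extent
    (centre +/- radius) intersects; flicker artifacts appear on exactly one
    section and are recorded separately in the truth.
    """
    if cfg.n_sections < 2:
        raise ValueError("a section series needs >= 2 sections (persistence undefined otherwise)")
    return _simulate_volume(cfg, spacing_um=cfg.section_thickness_um, z_mode="extent")


def _clip_line_to_field(point: np.ndarray, angle_rad: float, extent: float) -> Optional[LineString]:
    d = np.array([math.cos(angle_rad), math.sin(angle_rad)])
    diag = 2.0 * extent * math.sqrt(2.0)
    raw = LineString([tuple(point - diag * d), tuple(point + diag * d)])
    seg = raw.intersection(box(0.0, 0.0, extent, extent))
    if seg.is_empty or seg.geom_type != "LineString" or seg.length == 0:
        return None
    return seg


def simulate_field(cfg: SimFieldConfig, mode: str) -> Tuple[np.ndarray, GroundTruth]:
    """2D field of cell bodies (``mode='cells'``) or straight fibers (``'fibers'``).

    Cells are disks placed with rejection sampling; if the requested count
    cannot be placed without exceeding ``max_overlap_fraction`` the call
    errors.  Fibers are straight segments clipped to the field; the truth
    stores how many cross the configured 100 um query line (parallel or
    collinear fibers never count as crossings).
    """
    from skimage.draw import disk as draw_disk
    from skimage.draw import polygon as draw_polygon

    rng = np.random.default_rng(cfg.seed)
    px = cfg.pixel_size_um
    n_px = int(round(cfg.field_size_um / px))
    extent = n_px * px
    img = np.zeros((n_px, n_px), dtype=np.float64)

    truth = GroundTruth(field_extent_um=(extent, extent), n_objects=cfg.n_objects)

    if mode == "cells":
        r = cfg.cell_radius_um
        min_dist = 2.0 * r * (1.0 - cfg.max_overlap_fraction)
        placed: List[np.ndarray] = []
        for _ in range(cfg.n_objects):
            for _attempt in range(1000):
                c = rng.uniform(r, extent - r, size=2)
                if all(np.linalg.norm(c - q) >= min_dist for q in placed):
                    placed.append(c)
                    break
            else:
                raise ValueError(
                    f"could not place {cfg.n_objects} cells of radius {r} um without "
                    f"exceeding the overlap limit {cfg.max_overlap_fraction}"
                )
        centers = np.array(placed) if placed else np.empty((0, 2))
        for cx, cy in centers:
            rr, cc = draw_disk((cy / px - 0.5, cx / px - 0.5), r / px, shape=img.shape)
            img[rr, cc] += cfg.peak_intensity
        truth.centers_um = {"cells": centers}
    elif mode == "fibers":
        line = LineString(cfg.line_um)
        ld = np.array(line.coords[1]) - np.array(line.coords[0])
        segments = []
        n_cross = 0
        for i in range(cfg.n_objects):
            for _attempt in range(1000):
                if cfg.fiber_angles_deg is not None:
                    ang = math.radians(cfg.fiber_angles_deg[i % len(cfg.fiber_angles_deg)])
                else:
                    ang = rng.uniform(0.0, math.pi)
                if cfg.fiber_points_um is not None:
                    p = np.array(cfg.fiber_points_um[i % len(cfg.fiber_points_um)], dtype=float)
                else:
                    p = rng.uniform(0.0, extent, size=2)
                seg = _clip_line_to_field(p, ang, extent)
                if seg is not None:
                    break
            else:  # pragma: no cover
                raise ValueError("could not place fiber inside the field")
            segments.append(seg)
            fd = np.array(seg.coords[-1]) - np.array(seg.coords[0])
            parallel = abs(fd[0] * ld[1] - fd[1] * ld[0]) < 1e-9 * np.linalg.norm(fd) * np.linalg.norm(ld)
            if seg.intersects(line) and not parallel:
                n_cross += 1
            poly = seg.buffer(cfg.fiber_thickness_um / 2.0, cap_style="flat")
            ex = np.asarray(poly.exterior.coords)
            rr, cc = draw_polygon(ex[:, 1] / px - 0.5, ex[:, 0] / px - 0.5, shape=img.shape)
            img[rr, cc] = np.maximum(img[rr, cc], cfg.peak_intensity)
        truth.fiber_segments_um = [tuple(map(tuple, np.asarray(s.coords))) for s in segments]
        truth.line_um = cfg.line_um
        truth.n_crossings = n_cross
    else:
        raise ValueError("mode must be 'cells' or 'fibers'")

    img += cfg.background_level
    if cfg.gaussian_noise_sd > 0:
        img += rng.normal(0.0, cfg.gaussian_noise_sd, size=img.shape)
    return img, truth


def simulate_mpsc_trace(cfg: SimEphysConfig) -> Tuple[Recording, GroundTruth]:
    """Simulated miniature-PSC recording with known onsets and amplitudes.

    Onsets are Poisson (uniform over the window that keeps every kernel
    fully inside the trace); amplitudes are normal truncated at zero so the
    polarity never flips; the polarity sign makes inward events negative
    deflections.  Truth amplitudes are stored as positive magnitudes.
    """
    rng = np.random.default_rng(cfg.seed)
    n_samples = int(round(cfg.duration_s * cfg.sampling_hz))
    template = make_template(
        cfg.tau_rise_ms, cfg.tau_decay1_ms, cfg.tau_decay2_ms,
        decay_mix=cfg.decay_mix, length_ms=cfg.kernel_length_ms, sampling_hz=cfg.sampling_hz,
    )
    if template.n_samples >= n_samples:
        raise ValueError("event kernel is longer than the trace")

    n_events = int(rng.poisson(cfg.event_rate_hz * cfg.duration_s))
    onset_max = cfg.duration_s - cfg.kernel_length_ms * 1e-3
    onsets = np.sort(rng.uniform(0.0, onset_max, size=n_events))
    if cfg.amplitude_sd_pA > 0:
        a = (0.0 - cfg.amplitude_mean_pA) / cfg.amplitude_sd_pA
        amps = stats.truncnorm.rvs(
            a, np.inf, loc=cfg.amplitude_mean_pA, scale=cfg.amplitude_sd_pA,
            size=n_events, random_state=rng,
        )
    else:
        amps = np.full(n_events, cfg.amplitude_mean_pA)

    trace = np.zeros(n_samples, dtype=np.float64)
    w = template.waveform
    for t0, a_pA in zip(onsets, amps):
        i0 = int(round(t0 * cfg.sampling_hz))
        trace[i0 : i0 + len(w)] += a_pA * w
    if cfg.polarity == "inward":
        trace = -trace
    if cfg.baseline_noise_sd_pA > 0:
        trace += rng.normal(0.0, cfg.baseline_noise_sd_pA, size=n_samples)
    if cfg.drift_pA_per_s != 0.0:
        trace += cfg.drift_pA_per_s * (np.arange(n_samples) / cfg.sampling_hz)

    rec = Recording(samples=trace, sampling_hz=cfg.sampling_hz, polarity=cfg.polarity)
    truth = GroundTruth(
        event_onsets_s=onsets,
        event_amplitudes_pA=np.asarray(amps, dtype=np.float64),
        event_rate_hz=cfg.event_rate_hz,
        amplitude_truncated_at_zero=cfg.amplitude_sd_pA > 0,
    )
    return rec, truth
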