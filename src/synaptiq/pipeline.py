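"""Study orchestration: presets, the segment->persist->pair->density chain
per stack, per-subject aggregation, and group summary statistics.

Aggregation order is fixed: ROIs -> stack -> subject -> group.  Per-subject
values are the mean over that subject's stacks (3-5 stacks/sections per
subject in the source material), and group statistics are computed over
subject-level means only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import __version__
from .colocalization import compute_densities, make_neuropil_rois, pair_puncta
from .segmentation import SectionSeries, SegmentationParams, extract_objects, persistence_filter
from .synthetic import SimImageConfig, simulate_puncta_stack, simulate_section_series

#: Species/modality presets; the pairing radius follows the preset.
SPECIES_PRESETS: Dict[str, Dict[str, float]] = {
    "human_confocal": {"max_dist_um": 1.0, "field_size_um": 184.58,
                       "section_spacing_um": 0.15},
    "human_at": {"max_dist_um": 1.0, "section_spacing_um": 0.07},
    "mouse_confocal": {"max_dist_um": 0.5, "field_size_um": 184.58,
                       "section_spacing_um": 0.15},
}


@dataclass
class StudyConfig:
    """Declarative description of one densities study.

    ``stacks`` maps group -> subject -> list of stack sources.  A source is
    either ``{"file": "path.tif"}`` (multi-channel TIFF) or
    ``{"simulate": {...SimImageConfig overrides...}}``.
    """

    preset: str = "mouse_confocal"
    pre_channel: str = "pre"
    post_channel: str = "post"
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    roi_size_um: float = 10.0
    max_dist_um: Optional[float] = None  # None: taken from the preset
    pairing_mode: str = "one_to_one"
    stacks: Dict[str, Dict[str, List[dict]]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.preset not in SPECIES_PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; choose from {sorted(SPECIES_PRESETS)}")
        if self.max_dist_um is None:
            self.max_dist_um = SPECIES_PRESETS[self.preset]["max_dist_um"]

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        seg = SegmentationParams(**raw.pop("segmentation", {}))
        return cls(segmentation=seg, **raw)


def _load_stack(source: dict, cfg: StudyConfig, subject_seed: int) -> SectionSeries:
    from .io import read_series_tiff

    if "file" in source:
        path = Path(source["file"])
        if not path.exists():
            raise FileNotFoundError(f"stack file not found: {path}")
        return read_series_tiff(path)
    if "simulate" in source:
        overrides = dict(source["simulate"])
        overrides.setdefault("seed", subject_seed)
        if "channels" in overrides:
            from .synthetic import ChannelSim

            overrides["channels"] = {
                name: ch if isinstance(ch, ChannelSim) else ChannelSim(**ch)
                for name, ch in overrides["channels"].items()
            }
        sim_cfg = SimImageConfig(**overrides)
        if cfg.preset == "human_at":
            series, _ = simulate_section_series(sim_cfg)
        else:
            series, _ = simulate_puncta_stack(sim_cfg)
        return series
    raise ValueError(f"stack source must contain 'file' or 'simulate': {source}")


def analyze_stack(
    series: SectionSeries,
    pre_channel: str,
    post_channel: str,
    seg_params: SegmentationParams,
    max_dist_um: float,
    roi_size_um: float = 10.0,
    exclusion_mask: Optional[np.ndarray] = None,
    pairing_mode: str = "one_to_one",
) -> dict:
    """Run segment -> persistence -> pair -> densities on one stack."""
    pre = persistence_filter(extract_objects(series, pre_channel, seg_params))
    post = persistence_filter(extract_objects(series, post_channel, seg_params))
    pairing = pair_puncta(pre, post, max_dist_um, mode=pairing_mode)
    grid = make_neuropil_rois(
        series.field_extent_um, depth_um=series.depth_um,
        exclusion_mask=exclusion_mask, pixel_size_um=series.pixel_size_um,
        roi_size_um=roi_size_um,
    )
    dens = compute_densities(pairing, pre, post, grid)
    return {
        "synapse_density_per_mm3": dens.synapse_density_per_mm3,
        "pre_puncta_per_mm3": dens.pre_puncta_per_mm3,
        "post_puncta_per_mm3": dens.post_puncta_per_mm3,
        "n_pairs": dens.n_pairs_counted,
        "n_pre_objects": len(pre),
        "n_post_objects": len(post),
        "analyzed_volume_um3": dens.analyzed_volume_um3,
    }


def _plain(x):
    """Recursively convert dataclasses/tuples for a YAML-safe config echo."""
    import dataclasses

    if dataclasses.is_dataclass(x) and not isinstance(x, type):
        return _plain(dataclasses.asdict(x))
    if isinstance(x, dict):
        return {k: _plain(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_plain(v) for v in x]
    return x


def run_pipeline(cfg: StudyConfig, outdir: Optional[Path] = None) -> Dict[str, pd.DataFrame]:
    """Execute the full densities chain for every stack in the config.

    Returns tidy tables: one row per stack and one row per subject
    (subject value = mean over its stacks).  Deterministic: permuting the
    config's file order leaves the outputs identical, and reruns with the
    same seed are bit-identical.
    """
    rows = []
    root = np.random.SeedSequence(cfg.seed)
    groups = sorted(cfg.stacks)
    for gi, group in enumerate(groups):
        for si, subject in enumerate(sorted(cfg.stacks[group])):
            sources = cfg.stacks[group][subject]
            for ki, source in enumerate(sources):
                sub_seed = int(np.random.SeedSequence([cfg.seed, gi, si, ki]).generate_state(1)[0] % (2**31))
                try:
                    series = _load_stack(source, cfg, sub_seed)
                    res = analyze_stack(
                        series, cfg.pre_channel, cfg.post_channel, cfg.segmentation,
                        cfg.max_dist_um, cfg.roi_size_um, pairing_mode=cfg.pairing_mode,
                    )
                except Exception as err:
                    name = source.get("file", f"simulated stack #{ki} of {subject}")
                    raise RuntimeError(f"pipeline failed on {name}: {err}") from err
                rows.append({"group": group, "subject": subject, "stack": ki, **res})
    stacks_df = pd.DataFrame(rows)
    metric_cols = [c for c in stacks_df.columns if c not in ("group", "subject", "stack")]
    subjects_df = (
        stacks_df.groupby(["group", "subject"], as_index=False)[metric_cols].mean()
        .sort_values(["group", "subject"]).reset_index(drop=True)
    )
    result = {"stacks": stacks_df, "subjects": subjects_df}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        stacks_df.to_csv(outdir / "stacks.csv", index=False)
        subjects_df.to_csv(outdir / "subjects.csv", index=False)
        log = {"synaptiq_version": __version__, "config": {
            "preset": cfg.preset, "max_dist_um": cfg.max_dist_um,
            "roi_size_um": cfg.roi_size_um, "pairing_mode": cfg.pairing_mode,
            "seed": cfg.seed,
            "segmentation": vars(cfg.segmentation),
            "stacks": _plain(cfg.stacks),
        }}
        (outdir / "run_log.yaml").write_text(yaml.safe_dump(log, sort_keys=False))
    return result


def percent_change(reference_mean: float, group_mean: float) -> float:
    """Percent reduction of ``group_mean`` relative to ``reference_mean``.

    Positive when the group lies below the reference:
    (ref - group) / ref x 100.
    """
    if reference_mean == 0:
        raise ValueError("reference mean is zero")
    return (reference_mean - group_mean) / reference_mean * 100.0


@dataclass
class GroupSummary:
    groups: pd.DataFrame  # one row per group: n, mean, sem, percent_change, percent_of_reference
    reference_group: str
    test: str
    statistic: float
    p_value: float


_TESTS = {"welch_t", "mann_whitney", "anova", "kruskal_wallis"}


def group_stats(
    values_by_group: Dict[str, Sequence[float]],
    reference_group: str,
    test: str = "welch_t",
) -> GroupSummary:
    """Per-group mean/SEM, percent change vs the reference, and an omnibus test.

    Two conventions of the change are reported because legends and text of
    such studies mix them: ``percent_change`` = (ref - group)/ref x 100
    (the reduction) and ``percent_of_reference`` = group/ref x 100 (what
    remains).  Tests are delegated to scipy.stats on subject-level values.
    """
    if test not in _TESTS:
        raise ValueError(f"test must be one of {sorted(_TESTS)}")
    if reference_group not in values_by_group:
        raise ValueError(f"reference group {reference_group!r} missing")
    if len(values_by_group) < 2:
        raise ValueError("need at least two groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    for g, arr in arrays.items():
        if len(arr) < 2:
            raise ValueError(f"group {g!r} has n < 2")

    ref_mean = float(arrays[reference_group].mean())
    rows = []
    for g in values_by_group:  # preserve caller order
        arr = arrays[g]
        rows.append({
            "group": g,
            "n": len(arr),
            "mean": float(arr.mean()),
            "sem": float(arr.std(ddof=1) / np.sqrt(len(arr))),
            "percent_change": percent_change(ref_mean, float(arr.mean())),
            "percent_of_reference": float(arr.mean()) / ref_mean * 100.0,
        })

    samples = list(arrays.values())
    if test == "welch_t":
        if len(samples) != 2:
            raise ValueError("welch_t requires exactly two groups")
        stat, p = sps.ttest_ind(*samples, equal_var=False)
    elif test == "mann_whitney":
        if len(samples) != 2:
            raise ValueError("mann_whitney requires exactly two groups")
        stat, p = sps.mannwhitneyu(*samples, alternative="two-sided")
    elif test == "anova":
        stat, p = sps.f_oneway(*samples)
    else:
        stat, p = sps.kruskal(*samples)
    return GroupSummary(
        groups=pd.DataFrame(rows),
        reference_group=reference_group,
        test=test,
        statistic=float(stat),
        p_value=float(p),
    )
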