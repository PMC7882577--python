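#!/usr/bin/env python
"""Generate one example of each synthetic dataset and write it to disk.

Products (under results/simulated/): a two-channel confocal-style stack as
TIFF + ground-truth JSON, an array-tomography ribbon, a cell field, a fiber
field, and a 60 s miniature-PSC trace as CSV.  Everything downstream is
recomputed from code; these files exist to show the on-disk formats.
"""

from pathlib import Path

import numpy as np

from synaptiq import SimEphysConfig, SimFieldConfig, SimImageConfig, simulate_field, \
    simulate_mpsc_trace, simulate_puncta_stack, simulate_section_series
from synaptiq.io import write_series_tiff, write_trace_csv, write_truth_json

OUT = Path(__file__).resolve().parents[1] / "results" / "simulated"
OUT.mkdir(parents=True, exist_ok=True)


def main() -> None:
    stack_cfg = SimImageConfig(field_size_um=15.0, seed=1)
    stack, stack_truth = simulate_puncta_stack(stack_cfg)
    write_series_tiff(stack, OUT / "confocal_stack.tif")
    write_truth_json(stack_truth, OUT / "confocal_stack_truth.json")
    print(f"confocal stack: {stack.shape} voxels, "
          f"{len(stack_truth.centers_um['pre'])} pre / {len(stack_truth.centers_um['post'])} post puncta, "
          f"{stack_truth.n_pairs} true pairs")

    ribbon_cfg = SimImageConfig(field_size_um=15.0, n_sections=30, seed=2)
    ribbon, ribbon_truth = simulate_section_series(ribbon_cfg)
    write_series_tiff(ribbon, OUT / "at_ribbon.tif")
    write_truth_json(ribbon_truth, OUT / "at_ribbon_truth.json")
    n_flick = sum(len(v) for v in ribbon_truth.flicker_centers_um.values())
    print(f"AT ribbon: {ribbon.n_sections} x 70 nm sections, {n_flick} flicker artifacts")

    cells_cfg = SimFieldConfig(n_objects=20, seed=3)
    _, cells_truth = simulate_field(cells_cfg, "cells")
    write_truth_json(cells_truth, OUT / "cell_field_truth.json")
    fibers_cfg = SimFieldConfig(n_objects=8, seed=4)
    _, fibers_truth = simulate_field(fibers_cfg, "fibers")
    write_truth_json(fibers_truth, OUT / "fiber_field_truth.json")
    print(f"fields: {cells_truth.n_objects} cells; {fibers_truth.n_objects} fibers, "
          f"{fibers_truth.n_crossings} crossing the 100 um line")

    trace_cfg = SimEphysConfig(duration_s=10.0, seed=5)
    rec, trace_truth = simulate_mpsc_trace(trace_cfg)
    write_trace_csv(rec, OUT / "mpsc_trace.csv")
    write_truth_json(trace_truth, OUT / "mpsc_trace_truth.json")
    print(f"mPSC trace: {rec.duration_s:.0f} s at {rec.sampling_hz:.0f} Hz, "
          f"{len(trace_truth.event_onsets_s)} true events")


if __name__ == "__main__":
    main()
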