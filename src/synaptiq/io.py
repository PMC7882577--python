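"""Readers/writers for the package's on-disk formats.

Image volumes travel as multi-page TIFF with a small JSON sidecar carrying
channel names and physical spacing; detected objects and events as CSV;
ground truth as JSON; current traces as two-column CSV (time_s,
current_pA).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .colocalization import SynapsePairing
from .ephys import MiniEvent, Recording, RecordingQC
from .segmentation import PunctumObject, SectionSeries
from .synthetic import GroundTruth


def write_series_tiff(series: SectionSeries, path) -> None:
    """Write channels as a (C, Z, Y, X) TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    names = sorted(series.channels)
    data = np.stack([series.channels[n] for n in names], axis=0).astype(np.float32)
    tifffile.imwrite(path, data, metadata={"axes": "CZYX"})
    meta = {
        "channels": names,
        "pixel_size_um": series.pixel_size_um,
        "section_spacing_um": series.section_spacing_um,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_series_tiff(path) -> SectionSeries:
    path = Path(path)
    data = tifffile.imread(path)
    meta_path = path.with_suffix(path.suffix + ".json")
    if not meta_path.exists():
        raise FileNotFoundError(f"metadata sidecar missing: {meta_path}")
    meta = json.loads(meta_path.read_text())
    if data.ndim == 3:  # single channel
        data = data[None]
    channels = {name: np.asarray(data[i], dtype=np.float64) for i, name in enumerate(meta["channels"])}
    return SectionSeries(
        channels=channels,
        pixel_size_um=float(meta["pixel_size_um"]),
        section_spacing_um=float(meta["section_spacing_um"]),
    )


def objects_to_frame(objects) -> pd.DataFrame:
    rows = [
        {
            "id": o.id,
            "channel": o.channel,
            "centroid_x_um": o.centroid_um[0],
            "centroid_y_um": o.centroid_um[1],
            "centroid_z_um": o.centroid_um[2],
            "volume_um3": o.volume_um3,
            "n_sections": o.n_sections,
        }
        for o in objects
    ]
    return pd.DataFrame(rows)


def pairs_to_frame(pairing: SynapsePairing) -> pd.DataFrame:
    return pd.DataFrame(
        [{"pre_id": a, "post_id": b, "distance_um": d} for a, b, d in pairing.pairs]
    )


def events_to_frame(events) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "onset_s": e.onset_s,
                "peak_amplitude_pA": e.peak_amplitude_pA,
                "criterion_value": e.criterion_value,
                "charge_pC": e.charge_pC,
            }
            for e in events
        ]
    )


def write_trace_csv(rec: Recording, path, qc: Optional[RecordingQC] = None) -> None:
    """Two-column trace CSV with an optional QC JSON sidecar."""
    path = Path(path)
    pd.DataFrame({"time_s": rec.time_s, "current_pA": rec.samples}).to_csv(path, index=False)
    qc = qc or rec.qc
    if qc is not None:
        path.with_suffix(".json").write_text(json.dumps(vars(qc), indent=1))


def read_trace_csv(path, sampling_hz: Optional[float] = None, polarity: str = "outward") -> Recording:
    path = Path(path)
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    if sampling_hz is None:
        sampling_hz = 1.0 / float(np.median(np.diff(t)))
    qc = None
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        qc = RecordingQC(**json.loads(sidecar.read_text()))
    return Recording(
        samples=df["current_pA"].to_numpy(),
        sampling_hz=float(round(sampling_hz)),
        polarity=polarity,
        qc=qc,
    )


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.integer, np.floating)):
        return x.item()
    return x


def write_truth_json(truth: GroundTruth, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(vars(truth)), indent=1))
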