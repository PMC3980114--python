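"""File formats shared by all pipeline stages.

Interchange is deliberately plain: two-column CSVs with JSON sidecars for
histograms and IRFs, long-format CSVs for frame series and FRAP traces,
multi-page TIFF (one page per time channel) for pixel-wise stacks.  Every
writer has a reader that round-trips exactly (integers) or to full float
precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .frap import FRAPTrace
from .model import IRFCurve, PhotonHistogram

__all__ = [
    "write_histogram_csv", "read_histogram_csv",
    "write_irf_csv", "read_irf_csv",
    "write_frames_csv", "read_frames_csv",
    "write_frap_csv", "read_frap_csv",
    "write_stack_tiff", "read_stack_tiff",
    "write_json", "read_json",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def write_histogram_csv(hist: PhotonHistogram, path) -> None:
    path = Path(path)
    pd.DataFrame({"channel_index": np.arange(hist.n_channels),
                  "count": hist.counts}).to_csv(path, index=False)
    write_json({"channel_width": hist.channel_width,
                "n_channels": hist.n_channels,
                "period": hist.period}, _sidecar(path))


def read_histogram_csv(path) -> PhotonHistogram:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    meta = read_json(_sidecar(path))
    return PhotonHistogram(df["count"].to_numpy(),
                           channel_width=meta["channel_width"],
                           period=meta["period"], allowed_n_channels=())


def write_irf_csv(irf: IRFCurve, path) -> None:
    path = Path(path)
    pd.DataFrame({"channel_index": np.arange(irf.n_channels),
                  "value": irf.values}).to_csv(
        path, index=False, float_format="%.17g")
    write_json({"channel_width": irf.channel_width,
                "n_channels": irf.n_channels,
                "period": irf.period}, _sidecar(path))


def read_irf_csv(path) -> IRFCurve:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    meta = read_json(_sidecar(path))
    return IRFCurve(df["value"].to_numpy(), channel_width=meta["channel_width"])


def write_frames_csv(frames: dict, path) -> None:
    """Frame series as long CSV: compartment, frame, time_s, channel, count.

    ``frames`` maps compartment name -> (times, list of PhotonHistogram).
    """
    path = Path(path)
    rows = []
    meta = None
    for comp, (times, hists) in sorted(frames.items()):
        for i, (t, h) in enumerate(zip(times, hists)):
            rows.append(pd.DataFrame({
                "compartment": comp, "frame": i, "time_s": float(t),
                "channel_index": np.arange(h.n_channels),
                "count": h.counts}))
            meta = {"channel_width": h.channel_width, "period": h.period}
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
    write_json(meta, _sidecar(path))


def read_frames_csv(path) -> dict:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    meta = read_json(_sidecar(path))
    out: dict = {}
    for comp, sub in df.groupby("compartment"):
        times, hists = [], []
        for _, fr in sub.groupby("frame"):
            fr = fr.sort_values("channel_index")
            times.append(float(fr["time_s"].iloc[0]))
            hists.append(PhotonHistogram(
                fr["count"].to_numpy(), channel_width=meta["channel_width"],
                period=meta["period"], allowed_n_channels=()))
        out[comp] = (np.asarray(times), hists)
    return out


def write_frap_csv(traces, path) -> None:
    """FRAP traces as CSV (time_ms, fluorescence, acquisition_id, roi_class)
    with bleach time in the JSON sidecar."""
    path = Path(path)
    traces = list(traces)
    parts = [pd.DataFrame({"time_ms": tr.time,
                           "fluorescence": tr.fluorescence,
                           "acquisition_id": tr.acquisition_id,
                           "roi_class": tr.roi_class}) for tr in traces]
    pd.concat(parts, ignore_index=True).to_csv(
        path, index=False, float_format="%.17g")
    write_json({"bleach_time_ms": traces[0].bleach_time}, _sidecar(path))


def read_frap_csv(path) -> list:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    bleach = read_json(_sidecar(path))["bleach_time_ms"]
    out = []
    for (acq, roi), sub in df.groupby(["acquisition_id", "roi_class"],
                                      sort=True):
        out.append(FRAPTrace(time=sub["time_ms"].to_numpy(),
                             fluorescence=sub["fluorescence"].to_numpy(),
                             bleach_time=bleach, acquisition_id=int(acq),
                             roi_class=str(roi)))
    return out


def write_stack_tiff(stack: np.ndarray, channel_width: float, path) -> None:
    """Pixel-wise histogram stack as multi-page TIFF (one page per channel)."""
    import tifffile

    path = Path(path)
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be (ny, nx, n_channels)")
    tifffile.imwrite(path, np.moveaxis(stack, 2, 0).astype(np.uint32))
    write_json({"channel_width": channel_width,
                "n_channels": int(stack.shape[2]),
                "axes": "channel,y,x"}, _sidecar(path))


def read_stack_tiff(path) -> tuple[np.ndarray, float]:
    import tifffile

    path = Path(path)
    meta = read_json(_sidecar(path))
    pages = tifffile.imread(path)
    return np.moveaxis(pages, 0, 2).astype(np.int64), meta["channel_width"]
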