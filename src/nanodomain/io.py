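"""Delimited-text readers/writers for the package's tabular formats.

Peak lists follow a ThunderSTORM-compatible column ordering
(id, frame, x_nm, y_nm, photons, sigma_nm); correlation curves are stored as
(lag, value, sem, n) tables.  Header comment lines starting with '#' carry
metadata (ROI, bin time, seed) and are ignored by the readers of other
tools.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .correlate import CorrelationCurve, IntensityTrace
from .pcpalm import PeakList

__all__ = [
    "read_peaks_csv",
    "write_peaks_csv",
    "read_curve_csv",
    "write_curve_csv",
    "read_trace_csv",
    "write_trace_csv",
    "read_intensity_tiff",
    "write_fit_report",
    "read_fit_report",
    "sim_config_to_yaml",
    "sim_config_from_yaml",
]

PEAK_COLUMNS = ["id", "frame", "x_nm", "y_nm", "photons", "sigma_nm"]


def _read_meta(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                key, _, val = line[1:].partition("=")
                meta[key.strip()] = val.strip()
    return meta


def write_peaks_csv(path: str | Path, peaks: PeakList) -> None:
    path = Path(path)
    frame = pd.DataFrame(
        {
            "id": np.arange(len(peaks)),
            "frame": peaks.frame,
            "x_nm": peaks.x,
            "y_nm": peaks.y,
            "photons": peaks.photons,
            "sigma_nm": peaks.sigma,
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# roi_um = {peaks.roi[0]} {peaks.roi[1]}\n")
        fh.write(f"# frame_time_s = {peaks.frame_time}\n")
        if peaks.label:
            fh.write(f"# label = {peaks.label}\n")
        frame.to_csv(fh, index=False)


def read_peaks_csv(
    path: str | Path,
    roi: tuple[float, float] | None = None,
    frame_time: float | None = None,
) -> PeakList:
    """Read a peak list; ROI/frame-time fall back to header metadata."""
    path = Path(path)
    meta = _read_meta(path)
    if roi is None:
        if "roi_um" not in meta:
            raise ValueError("ROI not given and not present in the file header")
        w, h = (float(v) for v in meta["roi_um"].split())
        roi = (w, h)
    if frame_time is None:
        frame_time = float(meta.get("frame_time_s", 0.1))
    table = pd.read_csv(path, comment="#")
    return PeakList(
        x=table["x_nm"].to_numpy(),
        y=table["y_nm"].to_numpy(),
        frame=table["frame"].to_numpy(),
        photons=table["photons"].to_numpy(),
        sigma=table["sigma_nm"].to_numpy(),
        roi=roi,
        frame_time=frame_time,
        label=meta.get("label", ""),
    )


def write_curve_csv(path: str | Path, curve: CorrelationCurve) -> None:
    table = pd.DataFrame(
        {
            "lag": curve.lags,
            "value": curve.values,
            "sem": curve.sem if curve.sem is not None else np.nan,
            "n": curve.n_averaged,
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# kind = {curve.kind}\n")
        fh.write(f"# baseline = {curve.baseline}\n")
        if curve.label:
            fh.write(f"# label = {curve.label}\n")
        table.to_csv(fh, index=False)


def read_curve_csv(path: str | Path) -> CorrelationCurve:
    meta = _read_meta(Path(path))
    table = pd.read_csv(path, comment="#")
    sem = table["sem"].to_numpy()
    return CorrelationCurve(
        lags=table["lag"].to_numpy(),
        values=table["value"].to_numpy(),
        sem=None if np.all(np.isnan(sem)) else sem,
        n_averaged=int(table["n"].iloc[0]),
        kind=meta.get("kind", "temporal-auto"),
        baseline=float(meta.get("baseline", 1.0)),
        label=meta.get("label", ""),
    )


def write_trace_csv(path: str | Path, trace: IntensityTrace) -> None:
    with open(path, "w") as fh:
        fh.write(f"# bin_time_s = {trace.bin_time}\n")
        if trace.channel_label:
            fh.write(f"# label = {trace.channel_label}\n")
        fh.write("counts\n")
        np.savetxt(fh, trace.counts, fmt="%d")


def read_trace_csv(path: str | Path, bin_time: float | None = None) -> IntensityTrace:
    meta = _read_meta(Path(path))
    if bin_time is None:
        if "bin_time_s" not in meta:
            raise ValueError("bin_time not given and not present in the header")
        bin_time = float(meta["bin_time_s"])
    counts = pd.read_csv(path, comment="#")["counts"].to_numpy()
    return IntensityTrace(counts=counts, bin_time=bin_time, channel_label=meta.get("label", ""))


def write_fit_report(
    path: str | Path,
    estimates: dict[str, float],
    stderr: dict[str, float | None] | None = None,
    meta: dict[str, object] | None = None,
) -> None:
    """Write fitted parameters as a (parameter, estimate, stderr) table."""
    stderr = stderr or {}
    table = pd.DataFrame(
        {
            "parameter": list(estimates),
            "estimate": [estimates[k] for k in estimates],
            "stderr": [stderr.get(k, np.nan) for k in estimates],
        }
    )
    with open(path, "w") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key} = {val}\n")
        table.to_csv(fh, index=False)


def read_fit_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def sim_config_to_yaml(path: str | Path, cfg) -> None:
    """Persist a simulation config (PALM or FCS) as a YAML mapping.

    The dataclass type name is stored under ``kind`` so the file fully
    specifies the simulation.
    """
    import yaml
    from dataclasses import asdict

    payload = {"kind": type(cfg).__name__, **asdict(cfg)}
    if isinstance(payload.get("roi"), tuple):
        payload["roi"] = list(payload["roi"])
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def sim_config_from_yaml(path: str | Path):
    """Load a simulation config written by :func:`sim_config_to_yaml`."""
    import yaml

    from .simulate import FcsSimConfig, PalmSimConfig

    with open(path) as fh:
        payload = yaml.safe_load(fh)
    kind = payload.pop("kind")
    if kind == "PalmSimConfig":
        payload["roi"] = tuple(payload["roi"])
        return PalmSimConfig(**payload)
    if kind == "FcsSimConfig":
        return FcsSimConfig(**payload)
    raise ValueError(f"unknown simulation config kind {kind!r}")


def read_intensity_tiff(path: str | Path) -> np.ndarray:
    """Single-channel intensity image (e.g., for pixel colocalization)."""
    import tifffile

    img = tifffile.imread(str(path))
    return np.asarray(img, dtype=float)
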