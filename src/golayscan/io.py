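"""File I/O: traces, feature/label grids, renders, reports, manifests.

Formats are deliberately plain: delimited text for traces and grids
(with a comment header carrying geometry and units), float WAV for
waveforms, JSON for reports and run manifests, PNG for renders.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.io import wavfile

from .scan import CScanImage, OverlapReport, ScanPlan
from .waveforms import Waveform

__all__ = [
    "save_waveform_csv", "load_waveform_csv",
    "save_waveform_wav", "load_waveform_wav",
    "load_trace",
    "save_grid_csv", "load_grid_csv",
    "save_label_csv", "load_label_csv",
    "save_png", "save_report", "write_manifest",
]


def save_waveform_csv(wave: Waveform, path) -> None:
    """Two-column delimited text: time_s, value."""
    data = np.column_stack([wave.times, wave.samples])
    np.savetxt(path, data, delimiter=",", fmt="%.9g",
               header="time_s,value", comments="# ")


def load_waveform_csv(path) -> Waveform:
    data = np.loadtxt(path, delimiter=",", comments="#", ndmin=2)
    if data.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns (time_s, value)")
    t = data[:, 0]
    dt = np.diff(t)
    if len(dt) == 0 or not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError(f"{path}: time base is not uniform")
    fs = (len(t) - 1) / (t[-1] - t[0])
    # printed time stamps are rounded; snap near-integer rates
    if abs(fs - round(fs)) < 1e-3:
        fs = float(round(fs))
    return Waveform(samples=data[:, 1], fs=fs, t0=float(t[0]))


def load_trace(path, fs: float) -> Waveform:
    """One sample per row with a caller-stated sampling rate."""
    samples = np.loadtxt(path, comments="#", ndmin=1)
    if samples.ndim != 1:
        raise ValueError(f"{path}: expected a single column of samples")
    return Waveform(samples=samples, fs=fs)


def save_waveform_wav(wave: Waveform, path, metadata: dict | None = None):
    """Single-channel float32 WAV plus a JSON metadata sidecar."""
    wavfile.write(path, int(round(wave.fs)),
                  wave.samples.astype(np.float32))
    sidecar = {"fs": wave.fs, "t0": wave.t0}
    if metadata:
        sidecar.update(metadata)
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def load_waveform_wav(path) -> Waveform:
    fs, samples = wavfile.read(path)
    t0 = 0.0
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        fs = meta.get("fs", fs)
        t0 = meta.get("t0", 0.0)
    return Waveform(samples=np.asarray(samples, dtype=float), fs=fs, t0=t0)


def _plan_header(plan: ScanPlan, units: str) -> str:
    return (
        f"x0_m={plan.x0:g} y0_m={plan.y0:g} interval_m={plan.interval:g} "
        f"width_m={plan.width:g} height_m={plan.height:g} units={units} "
        "layout=row-major origin=top-left indices=0-based"
    )


def _parse_plan_header(line: str) -> ScanPlan:
    fields = dict(tok.split("=") for tok in line.strip("# \n").split())
    return ScanPlan(
        x0=float(fields["x0_m"]), y0=float(fields["y0_m"]),
        width=float(fields["width_m"]), height=float(fields["height_m"]),
        interval=float(fields["interval_m"]),
    )


def save_grid_csv(image: CScanImage, path, units: str = "V") -> None:
    """Feature grid as CSV with a geometry comment header."""
    np.savetxt(path, image.features, delimiter=",", fmt="%.9g",
               header=_plan_header(image.plan, units), comments="# ")


def load_grid_csv(path) -> CScanImage:
    with open(path) as fh:
        header = fh.readline()
    if not header.startswith("#"):
        raise ValueError(f"{path}: missing geometry header line")
    plan = _parse_plan_header(header)
    features = np.loadtxt(path, delimiter=",", comments="#", ndmin=2)
    return CScanImage(features=features, plan=plan)


def save_label_csv(labels: np.ndarray, plan: ScanPlan, path) -> None:
    with open(path, "w") as fh:
        fh.write("# " + _plan_header(plan, "label") + "\n")
        for row in labels:
            fh.write(",".join(str(v) for v in row) + "\n")


def load_label_csv(path) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rows.append(line.split(","))
    if not rows:
        raise ValueError(f"{path}: no label rows found")
    return np.asarray(rows, dtype=object)


def save_png(raster: np.ndarray, path) -> None:
    Image.fromarray(raster).save(path, format="PNG")


def save_report(report: OverlapReport | dict, path) -> None:
    if isinstance(report, OverlapReport):
        report = {
            "coincidence": report.coincidence,
            "dice": report.dice,
            "per_class": report.per_class,
        }
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True))


def write_manifest(out_dir, config: dict, seed: int,
                   extra: dict | None = None) -> Path:
    """Write the run manifest enabling bit-reproduction of any output.

    Records the full configuration, its SHA-256 hash, every seed, and
    the library versions that produced the run.
    """
    import scipy

    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    canonical = json.dumps(config, sort_keys=True)
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": seed,
        "versions": {
            "golayscan": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
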