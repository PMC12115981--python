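"""A-scan / C-scan orchestration, defect classification and scoring.

An A-scan measures one point: transmit the coded excitation(s) through
the board at (x, y), decode, and read the peak voltage.  A C-scan
rasters a grid of A-scans (boustrophedon traversal, like the physical
two-axis stage) and images the per-point peak voltages.  Knots darken
the image (higher impedance + scattering → lower peak), pits brighten
it (thinner board → higher peak), and sound wood sits in a narrow band
in between — so a three-way amplitude threshold classifies every pixel.

Thresholds are calibrated from sound-region peak voltages as
``mean ± k·sd·scale``; the default scales reproduce, on the reference
peak-voltage tables, a knot bound near 0.4 V and a pit bound near
0.75 V.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from . import channel as ch
from . import compression as comp
from .codes import CodePair, barker7, burst, generate_golay_pair
from .waveforms import (
    ModulationSpec,
    Waveform,
    modulate_square_carrier,
    modulate_wide_pulse,
    pulse_cancelation_excitation,
)

__all__ = [
    "ScanPlan",
    "CScanImage",
    "ClassifierThresholds",
    "OverlapReport",
    "Pipeline",
    "METHODS",
    "ascan_point",
    "calibrate_thresholds",
    "classify_point",
    "classify_grid",
    "run_cscan",
    "render_rgb",
    "coincidence",
    "score_scan",
    "compare_excitations",
    "noise_sigma_for_snr",
]

METHODS = ("golay8", "barker7", "burst8", "cancelation")

LABELS = ("sound", "knot", "pit")


@dataclass(frozen=True)
class ScanPlan:
    """Raster geometry: origin, extent and scanning interval (meters).

    Grid points include both endpoints: a 5 cm span at 1 mm interval
    yields 51 points per axis.
    """

    x0: float = 0.0
    y0: float = 0.0
    width: float = 0.05
    height: float = 0.05
    interval: float = 1e-3
    serpentine: bool = True

    def __post_init__(self):
        if self.interval <= 0:
            raise ValueError("interval must be positive")
        if self.width < self.interval or self.height < self.interval:
            raise ValueError("scan extent must be at least one interval")

    @property
    def nx(self) -> int:
        return int(np.floor(self.width / self.interval + 1e-9)) + 1

    @property
    def ny(self) -> int:
        return int(np.floor(self.height / self.interval + 1e-9)) + 1

    @property
    def xs(self) -> np.ndarray:
        return self.x0 + np.arange(self.nx) * self.interval

    @property
    def ys(self) -> np.ndarray:
        return self.y0 + np.arange(self.ny) * self.interval

    def point(self, i: int, j: int) -> tuple[float, float]:
        """Coordinates of grid point (row i, col j), row-major 0-based."""
        return (self.x0 + j * self.interval, self.y0 + i * self.interval)

    def traversal(self):
        """(i, j, flat_index) in scan order; serpentine flips odd rows."""
        for i in range(self.ny):
            cols = range(self.nx)
            if self.serpentine and i % 2 == 1:
                cols = reversed(cols)
            for j in cols:
                yield i, j, i * self.nx + j


@dataclass
class CScanImage:
    """Per-point peak-voltage grid plus optional classification map."""

    features: np.ndarray  # (ny, nx) volts
    plan: ScanPlan
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        if self.features.shape != (self.plan.ny, self.plan.nx):
            raise ValueError(
                f"feature grid {self.features.shape} does not match plan "
                f"({self.plan.ny}, {self.plan.nx})"
            )
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features must be finite")


@dataclass(frozen=True)
class ClassifierThresholds:
    """Amplitude bands: peak ≤ knot_max → knot, ≥ pit_min → pit."""

    knot_max: float
    pit_min: float

    def __post_init__(self):
        if not self.knot_max < self.pit_min:
            raise ValueError("need knot_max < pit_min")


@dataclass(frozen=True)
class OverlapReport:
    """Detection overlap against the ground-truth defect mask.

    ``coincidence`` is truth-normalized: |detected ∩ truth| / |truth|,
    pooled over both defect classes; ``per_class`` holds the same ratio
    per label.  ``dice`` is 2|∩| / (|detected| + |truth|).
    """

    coincidence: float
    dice: float
    per_class: dict = field(default_factory=dict)

    def __post_init__(self):
        for v in (self.coincidence, self.dice):
            if not 0 <= v <= 1:
                raise ValueError("overlap fractions must lie in [0, 1]")


@dataclass(frozen=True)
class Pipeline:
    """Everything needed to measure one point: code, drive and channel.

    ``method`` selects the excitation scheme:

    * ``golay8`` — two shots (sequences A and B of the order-``order``
      pair), matched-filtered and summed;
    * ``barker7`` — one Barker-coded shot, matched-filtered;
    * ``burst8`` — one uncoded 8-chip burst, matched-filtered;
    * ``cancelation`` — a short burst (``cancel_cycles`` carrier
      cycles) plus an anti-phase canceling cycle, read out directly
      from the received envelope (no compression).  The burst is short
      by design: the technique trades transmitted energy for axial
      resolution, which is also why it loses penetration on thick,
      strongly attenuating boards.

    ``feature`` picks the peak read-out: ``"envelope"`` (analytic
    magnitude, robust to carrier phase), ``"raw"`` (plain maximum), or
    ``"auto"`` (envelope when a carrier is present).
    """

    order: int = 3
    spec: ModulationSpec = field(default_factory=ModulationSpec)
    tx: ch.TransducerModel = field(default_factory=ch.TransducerModel)
    rx: ch.TransducerModel = field(default_factory=ch.TransducerModel)
    chain: ch.ReceiverChain = field(default_factory=ch.ReceiverChain)
    channel: ch.ChannelConfig = field(default_factory=ch.ChannelConfig)
    method: str = "golay8"
    feature: str = "auto"
    cancel_cycles: int = 2

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(
                f"unknown method {self.method!r}; choose from {METHODS}"
            )
        if self.feature not in ("auto", "envelope", "raw"):
            raise ValueError("feature must be auto, envelope or raw")

    @property
    def pair(self) -> CodePair:
        return generate_golay_pair(self.order)

    @property
    def use_envelope(self) -> bool:
        if self.feature == "auto":
            return self.spec.carrier_freq > 0
        return self.feature == "envelope"

    def excitations(self) -> list[Waveform]:
        """The transmitted shot(s) for this method, in order."""
        if self.method == "cancelation":
            return [pulse_cancelation_excitation(self.cancel_cycles,
                                                 self.spec)]
        if self.method == "golay8":
            codes = [self.pair.a, self.pair.b]
        elif self.method == "barker7":
            codes = [barker7().values]
        else:  # burst8
            codes = [burst(2**self.order).values]
        if self.spec.carrier_freq > 0:
            return [modulate_square_carrier(c, self.spec) for c in codes]
        return [modulate_wide_pulse(c, self.spec) for c in codes]

    def _simulate(self, specimen, x, y, seed: int) -> list[Waveform]:
        received = []
        for k, exc in enumerate(self.excitations()):
            cfg = replace(self.channel, rng_seed=2 * seed + k)
            received.append(
                ch.simulate_received(
                    exc, specimen, x, y, self.tx, self.rx, self.chain, cfg
                )
            )
        return received

    def decode(self, received: list[Waveform]) -> comp.CompressionResult:
        if self.method == "cancelation":
            raise ValueError("the cancelation method is not decoded")
        if self.method == "golay8":
            return comp.golay_decode(
                received[0], received[1], self.pair, self.spec
            )
        code = (
            barker7().values
            if self.method == "barker7"
            else burst(2**self.order).values
        )
        return comp.single_code_decode(received[0], code, self.spec)

    def measure(self, specimen, x: float, y: float, seed: int) -> float:
        """Peak-voltage feature at one point (the imaging parameter)."""
        received = self._simulate(specimen, x, y, seed)
        if self.method == "cancelation":
            trace = received[0]
        else:
            res = self.decode(received)
            trace = Waveform(samples=res.trace, fs=res.fs)
        if self.use_envelope:
            return float(np.max(comp.envelope(trace).samples))
        return float(np.max(trace.samples))


def ascan_point(
    specimen: ch.Specimen, x: float, y: float, pipeline: Pipeline, seed: int
) -> comp.CompressionResult:
    """Single-point measurement: simulate both Golay shots and decode."""
    received = pipeline._simulate(specimen, x, y, seed)
    return pipeline.decode(received)


def calibrate_thresholds(
    sound_peaks,
    k: float = 1.0,
    scale_low: float = 34.0,
    scale_high: float = 15.0,
) -> ClassifierThresholds:
    """Derive amplitude bands from sound-region calibration peaks.

    ``knot_max = mean − k·sd·scale_low`` and ``pit_min = mean +
    k·sd·scale_high`` (sample sd).  The default scales place the bands
    at ≈ 0.62× and ≈ 1.17× the mean for the spread typical of sound
    pine, i.e. ≈ 0.40 V and ≈ 0.75 V for peaks near 0.645 V.  With
    identical calibration values (sd = 0) the bands fall back to ±20%
    of the mean.
    """
    peaks = np.asarray(list(sound_peaks), dtype=float)
    if peaks.size < 3:
        raise ValueError("need at least 3 calibration values")
    if k <= 0:
        raise ValueError("k must be positive")
    mean = float(np.mean(peaks))
    sd = float(np.std(peaks, ddof=1))
    if sd == 0:
        return ClassifierThresholds(knot_max=0.8 * mean, pit_min=1.2 * mean)
    return ClassifierThresholds(
        knot_max=mean - k * sd * scale_low, pit_min=mean + k * sd * scale_high
    )


def classify_point(peak: float, thr: ClassifierThresholds) -> str:
    """Label one peak voltage: knot (low), pit (high), else sound."""
    if not np.isfinite(peak):
        raise ValueError("peak must be finite")
    if peak <= thr.knot_max:
        return "knot"
    if peak >= thr.pit_min:
        return "pit"
    return "sound"


def classify_grid(
    image: CScanImage, thr: ClassifierThresholds
) -> np.ndarray:
    """Label every pixel of a feature grid; stored on the image too."""
    labels = np.full(image.features.shape, "sound", dtype=object)
    labels[image.features <= thr.knot_max] = "knot"
    labels[image.features >= thr.pit_min] = "pit"
    image.labels = labels
    return labels


def run_cscan(
    specimen: ch.Specimen,
    plan: ScanPlan,
    pipeline: Pipeline,
    base_seed: int = 0,
) -> CScanImage:
    """Raster the plan and collect per-point peak voltages.

    Each grid point uses its own RNG stream seeded from ``base_seed``
    plus the row-major flat index, so the resulting grid is identical
    whichever way the stage traverses it.
    """
    features = np.zeros((plan.ny, plan.nx))
    for i, j, idx in plan.traversal():
        x, y = plan.point(i, j)
        features[i, j] = pipeline.measure(specimen, x, y, base_seed + idx)
    return CScanImage(features=features, plan=plan)


_COLD = np.array([30, 30, 120], dtype=float)  # low peak (knot-like)
_HOT = np.array([230, 60, 40], dtype=float)  # high peak (pit-like)


def render_rgb(
    image: CScanImage, upsample: int = 4, cmap: str = "gray"
) -> np.ndarray:
    """Render the feature grid as an 8-bit raster, dark = low peak.

    The grid is min–max normalized (a constant grid renders mid-gray),
    bilinearly interpolated so each axis grows from ``n`` to
    ``(n − 1) * upsample + 1`` pixels, and mapped through a grayscale
    (default) or blue–red color map.  Returns an (H, W, 3) uint8 array.
    """
    if upsample < 1:
        raise ValueError("upsample must be a positive integer")
    if cmap not in ("gray", "rgb"):
        raise ValueError("cmap must be 'gray' or 'rgb'")
    f = image.features
    lo, hi = float(f.min()), float(f.max())
    norm = np.full(f.shape, 0.5) if hi == lo else (f - lo) / (hi - lo)
    ny, nx = norm.shape
    out_y = (ny - 1) * upsample + 1
    out_x = (nx - 1) * upsample + 1
    ii, jj = np.meshgrid(
        np.arange(out_y) / upsample, np.arange(out_x) / upsample,
        indexing="ij",
    )
    up = ndimage.map_coordinates(norm, [ii, jj], order=1, mode="nearest")
    if cmap == "gray":
        gray = np.round(255 * up).astype(np.uint8)
        return np.stack([gray] * 3, axis=-1)
    rgb = _COLD[None, None, :] + up[..., None] * (_HOT - _COLD)[None, None, :]
    return np.round(rgb).clip(0, 255).astype(np.uint8)


def _defect_mask(labels: np.ndarray) -> np.ndarray:
    return (labels == "knot") | (labels == "pit")


def coincidence(detected: np.ndarray, truth: np.ndarray) -> OverlapReport:
    """Truth-normalized overlap and Dice of the detected defect maps."""
    detected = np.asarray(detected, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if detected.shape != truth.shape:
        raise ValueError(
            f"label grids differ in shape: {detected.shape} vs {truth.shape}"
        )
    det = _defect_mask(detected)
    tru = _defect_mask(truth)
    inter = int(np.sum(det & tru))
    n_tru = int(np.sum(tru))
    n_det = int(np.sum(det))
    pooled = inter / n_tru if n_tru else 1.0
    dice = 2 * inter / (n_det + n_tru) if (n_det + n_tru) else 1.0
    per_class = {}
    for lab in ("knot", "pit"):
        t = truth == lab
        nt = int(np.sum(t))
        per_class[lab] = (
            int(np.sum((detected == lab) & t)) / nt if nt else 1.0
        )
    return OverlapReport(coincidence=pooled, dice=dice, per_class=per_class)


def _calibration_values(
    image: CScanImage, truth: np.ndarray, max_points: int = 64
) -> np.ndarray:
    vals = image.features[truth == "sound"]
    if vals.size < 3:
        raise ValueError("need at least 3 sound-region points to calibrate")
    step = max(1, vals.size // max_points)
    return vals[::step]


def score_scan(
    image: CScanImage,
    specimen: ch.Specimen,
    k: float = 1.0,
) -> tuple[np.ndarray, OverlapReport, ClassifierThresholds]:
    """Calibrate on sound pixels, classify the scan, score vs truth."""
    truth = specimen.label_grid(image.plan.xs, image.plan.ys)
    thr = calibrate_thresholds(_calibration_values(image, truth), k=k)
    labels = classify_grid(image, thr)
    return labels, coincidence(labels, truth), thr


def noise_sigma_for_snr(
    specimen: ch.Specimen,
    pipeline: Pipeline,
    snr_db: float,
    at: tuple[float, float],
) -> float:
    """Noise sigma giving the requested pre-filter SNR at a sound point.

    SNR here is peak sensor amplitude over noise sigma, measured where
    the noise is injected (before the receiver filter).
    """
    x, y = at
    exc = pipeline.excitations()[0]
    peak = ch.noiseless_prefilter_peak(
        exc, specimen, x, y, pipeline.tx, pipeline.rx, pipeline.chain,
        replace(pipeline.channel, noise_sigma=0.0),
    )
    return peak / 10.0 ** (snr_db / 20.0)


def compare_excitations(
    specimen: ch.Specimen,
    plan: ScanPlan,
    methods=METHODS,
    pipeline: Pipeline | None = None,
    base_seed: int = 0,
) -> dict:
    """Run the full chain per excitation method with shared seeds.

    Returns ``{method: (CScanImage, OverlapReport)}``; every method
    sees the same board, plan, channel noise level and per-point seeds,
    so differences reflect only the excitation/compression scheme.
    """
    methods = tuple(methods)
    if not methods:
        raise ValueError("methods must be non-empty")
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}; choose from {METHODS}")
    if pipeline is None:
        pipeline = Pipeline()
    results = {}
    for m in methods:
        pipe = replace(pipeline, method=m)
        image = run_cscan(specimen, plan, pipe, base_seed=base_seed)
        _, report, _ = score_scan(image, specimen)
        results[m] = (image, report)
    return results
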