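"""Single-channel ERP preprocessing and N1/P2 quantification.

The pipeline mirrors a standard auditory ERP workflow on one virtual vertex
(Cz-like) channel:

1. zero-phase 1-30 Hz band-pass filtering,
2. amplitude/gradient artifact rejection on the continuous signal,
3. epoching (-500..+1500 ms around first-tone onsets) with exclusion of
   epochs touching rejected samples,
4. baseline correction by the -500..-150 ms pre-stimulus mean,
5. component areas as the trapezoidal integral of the block-average
   waveform over fixed post-onset windows (N1: 70-130 ms, P2: 150-250 ms),
   in uV*ms.

Artifact rejection applies three rules to the non-segmented data and takes
their union:

* any sample exceeding +/-100 uV rejects +/-300 ms around it;
* a max-min range above 100 uV within any 50 ms window rejects +/-200 ms
  around that window;
* a jump above 50 uV between adjacent samples rejects +/-300 ms around it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import binary_dilation, maximum_filter1d, minimum_filter1d
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "Recording", "RejectionMask", "Epoch", "ComponentArea",
    "COMPONENT_WINDOWS", "bandpass_filter", "detect_artifacts",
    "epoch_and_baseline", "average_and_area",
    "write_recording", "read_recording",
]

#: Post-onset integration windows in seconds, closed intervals.
COMPONENT_WINDOWS: dict[str, tuple[float, float]] = {
    "n1": (0.070, 0.130),
    "p2": (0.150, 0.250),
}

EPOCH_PRE = 0.5          # s before first-tone onset
EPOCH_DURATION = 2.0     # s total epoch length
BASELINE_WINDOW = (-0.5, -0.15)  # s relative to onset


@dataclass
class Recording:
    """Uniformly sampled single-channel EEG in microvolts.

    ``events`` is a list of ``(onset_s, kind)`` with kind ``"tone1"`` (first
    tone of a trial / the only tone of a passive event) or ``"tone2"``.
    """

    samples: np.ndarray
    sampling_rate: float
    events: list[tuple[float, str]] = field(default_factory=list)
    block_id: str | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("amplitudes must be finite")
        dur = len(self.samples) / self.sampling_rate
        for onset, _kind in self.events:
            if not 0 <= onset <= dur:
                raise ValueError(f"event at {onset} s outside recording span")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sampling_rate


@dataclass
class RejectionMask:
    """Per-sample rejection flags with per-rule provenance."""

    flags: np.ndarray                      # union of the three rules
    by_rule: dict[str, np.ndarray]

    @property
    def n_rejected(self) -> int:
        return int(self.flags.sum())


@dataclass
class Epoch:
    """One baseline-corrected epoch, time-locked to a first-tone onset."""

    samples: np.ndarray
    sampling_rate: float
    t0: float = -EPOCH_PRE
    baseline_corrected: bool = True

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.samples)) / self.sampling_rate


@dataclass(frozen=True)
class ComponentArea:
    """Windowed area of a component on the block-average waveform."""

    component: str
    window_ms: tuple[float, float]
    area_uv_ms: float
    n_epochs: int


def bandpass_filter(rec: Recording, low: float = 1.0, high: float = 30.0,
                    order: int = 2) -> Recording:
    """Zero-phase Butterworth band-pass (default 1-30 Hz).

    ``order`` is the one-way section order; forward-backward filtering
    doubles the effective roll-off and removes phase distortion, so
    component latencies are preserved.
    """
    fs = rec.sampling_rate
    if fs < 100:
        raise ValueError("sampling rate below 100 Hz not supported")
    if high >= fs / 2:
        raise ValueError("upper passband edge must be below Nyquist")
    sos = butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    filtered = sosfiltfilt(sos, rec.samples)
    return Recording(filtered, fs, list(rec.events), rec.block_id)


def detect_artifacts(
    rec: Recording,
    abs_threshold: float = 100.0,
    range_threshold: float = 100.0,
    range_window: float = 0.050,
    step_threshold: float = 50.0,
    abs_pad: float = 0.300,
    range_pad: float = 0.200,
    step_pad: float = 0.300,
) -> RejectionMask:
    """Flag artifactual samples on the continuous (non-segmented) signal.

    Returns the union of the three rejection rules; each rule's own span is
    kept for provenance.  The 50 ms range rule uses a sliding window whose
    sample span does not exceed 50 ms.
    """
    x = rec.samples
    fs = rec.sampling_rate
    n = len(x)

    def dilate(mask: np.ndarray, pad_s: float) -> np.ndarray:
        pad = int(round(pad_s * fs))
        if not mask.any() or pad == 0:
            return mask
        structure = np.ones(2 * pad + 1, dtype=bool)
        return binary_dilation(mask, structure=structure)

    # rule 1: absolute amplitude
    r1 = dilate(np.abs(x) > abs_threshold, abs_pad)

    # rule 2: max-min range within 50 ms.  A window of w samples spans
    # (w-1)/fs seconds; choose the largest w whose span is <= 50 ms.
    w = int(np.floor(range_window * fs)) + 1
    if w >= 2:
        rng = maximum_filter1d(x, size=w) - minimum_filter1d(x, size=w)
        r2 = dilate(rng > range_threshold, range_pad)
    else:
        r2 = np.zeros(n, dtype=bool)

    # rule 3: adjacent-sample step
    step = np.zeros(n, dtype=bool)
    jumps = np.abs(np.diff(x)) > step_threshold
    step[:-1] |= jumps
    step[1:] |= jumps
    r3 = dilate(step, step_pad)

    by_rule = {"abs": r1, "range": r2, "step": r3}
    return RejectionMask(flags=r1 | r2 | r3, by_rule=by_rule)


def epoch_and_baseline(
    rec: Recording,
    mask: RejectionMask | None = None,
    event_kinds: tuple[str, ...] = ("tone1",),
) -> list[Epoch]:
    """Cut epochs around first-tone onsets, drop rejected ones, baseline.

    An epoch spans -500..+1500 ms around its event.  Epochs that extend
    beyond the recording or that overlap any rejected sample are dropped.
    The baseline is the mean over -500..-150 ms and is subtracted from the
    whole epoch.
    """
    fs = rec.sampling_rate
    n_epoch = int(round(EPOCH_DURATION * fs))
    pre = int(round(EPOCH_PRE * fs))
    b0 = int(round((BASELINE_WINDOW[0] + EPOCH_PRE) * fs))
    b1 = int(round((BASELINE_WINDOW[1] + EPOCH_PRE) * fs))
    flags = mask.flags if mask is not None else None

    epochs: list[Epoch] = []
    for onset, kind in rec.events:
        if kind not in event_kinds:
            continue
        i_on = int(round(onset * fs))
        i0, i1 = i_on - pre, i_on - pre + n_epoch
        if i0 < 0 or i1 > len(rec.samples):
            continue
        if flags is not None and flags[i0:i1].any():
            continue
        seg = rec.samples[i0:i1].astype(float)
        seg = seg - seg[b0:b1 + 1].mean()
        epochs.append(Epoch(seg, fs))
    return epochs


def average_and_area(epochs: list[Epoch], component: str) -> ComponentArea:
    """Area (uV*ms) of a component window on the grand-average waveform."""
    comp = component.lower()
    if comp not in COMPONENT_WINDOWS:
        raise ValueError(f"unknown component {component!r}")
    if not epochs:
        raise ValueError("no surviving epochs: block must be excluded")
    fs = epochs[0].sampling_rate
    avg = np.mean([e.samples for e in epochs], axis=0)
    lo_s, hi_s = COMPONENT_WINDOWS[comp]
    # integrate the piecewise-linear waveform over the exact closed window,
    # interpolating the fractional-sample endpoints
    times = -EPOCH_PRE + np.arange(len(avg)) / fs
    inner = times[(times > lo_s) & (times < hi_s)]
    grid = np.concatenate([[lo_s], inner, [hi_s]])
    area = np.trapezoid(np.interp(grid, times, avg), grid) * 1000.0
    return ComponentArea(component=comp, window_ms=(lo_s * 1e3, hi_s * 1e3),
                         area_uv_ms=float(area), n_epochs=len(epochs))


# ---------------------------------------------------------------------------
# interchange format: raw float32 or CSV samples + JSON sidecar
# ---------------------------------------------------------------------------

def write_recording(rec: Recording, path: str | Path, fmt: str = "csv") -> None:
    """Write samples (CSV one value per line, or little-endian float32 raw)
    plus a ``.json`` sidecar with sampling rate, unit and event markers."""
    path = Path(path)
    if fmt == "csv":
        np.savetxt(path, rec.samples, fmt="%.6f")
    elif fmt == "raw":
        rec.samples.astype("<f4").tofile(path)
    else:
        raise ValueError("fmt must be 'csv' or 'raw'")
    sidecar = {
        "sampling_rate_hz": rec.sampling_rate,
        "unit": "uV",
        "format": fmt,
        "block_id": rec.block_id,
        "events": [{"onset_s": float(t), "kind": k} for t, k in rec.events],
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_recording(path: str | Path) -> Recording:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    if meta.get("format") == "raw":
        samples = np.fromfile(path, dtype="<f4").astype(float)
    else:
        samples = np.loadtxt(path)
    events = [(e["onset_s"], e["kind"]) for e in meta["events"]]
    return Recording(samples, meta["sampling_rate_hz"], events,
                     meta.get("block_id"))
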