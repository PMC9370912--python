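"""Waveform serialization (CSV, WFDB), beat-rate estimation, run manifests.

CSV files carry one time column plus one column per channel at full decimal
precision (shortest round-trip ``repr``), so write -> read -> write is
byte-identical.  WFDB records use the standard text header plus a 16-bit
little-endian signal file; the per-channel gain is chosen so the millivolt
dynamic range fills the integer range without clipping, bounding the
read-back error by one quantization step.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import find_peaks

from .integrator import ECGTrace

__all__ = ["write_csv", "read_csv", "write_wfdb", "read_wfdb",
           "estimate_beat_rate", "BeatRateEstimate", "RunManifest"]

_INT16_FULL_SCALE = 32000  # headroom below the int16 limit of 32767


def _check_traces(traces: Sequence[ECGTrace]) -> None:
    if len(traces) == 0:
        raise ValueError("at least one channel is required")
    n = traces[0].values.size
    fs = traces[0].fs
    if n == 0:
        raise ValueError("channels must be non-empty")
    for tr in traces:
        if tr.values.size != n:
            raise ValueError("channels must have equal lengths")
        if tr.fs != fs:
            raise ValueError("channels must share a sampling rate")


def write_csv(traces: Sequence[ECGTrace], path) -> Path:
    """Write channels to CSV: ``time_s`` column plus one column per channel."""
    _check_traces(traces)
    path = Path(path)
    t = traces[0].times
    header = ",".join(["time_s"] + [tr.label for tr in traces])
    lines = [header]
    columns = [tr.values for tr in traces]
    for i in range(t.size):
        row = [repr(float(t[i]))] + [repr(float(col[i])) for col in columns]
        lines.append(",".join(row))
    try:
        path.write_text("\n".join(lines) + "\n", encoding="utf-8",
                        newline="\n")
    except OSError as err:
        raise OSError(f"cannot write CSV to {path}: {err}") from err
    return path


def read_csv(path) -> list[ECGTrace]:
    """Read a CSV written by :func:`write_csv` back into traces."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip().split(",")
        if header[0] != "time_s":
            raise ValueError(f"{path} is not an ECG CSV (no time_s column)")
        data = np.loadtxt(fh, delimiter=",", ndmin=2)
    t = data[:, 0]
    if t.size < 2:
        raise ValueError("need at least two samples to infer sampling rate")
    dt = t[1] - t[0]
    fs = 1.0 / dt
    # snap to an integer rate when the float time column allows it
    if abs(fs - round(fs)) < 1e-6 * fs:
        fs = float(round(fs))
    return [ECGTrace(values=data[:, 1 + i], fs=fs, label=label, t0=float(t[0]))
            for i, label in enumerate(header[1:])]


def _wfdb_checksum(digital: np.ndarray) -> int:
    total = int(np.sum(digital.astype(np.int64)) % 65536)
    return total - 65536 if total >= 32768 else total


def write_wfdb(traces: Sequence[ECGTrace], record: str, directory) -> Path:
    """Write a WFDB record (``<record>.hea`` + 16-bit ``<record>.dat``).

    Per-channel gain (ADC units per mV) is chosen from the channel's
    dynamic range; a channel that would exceed the representable integer
    range raises instead of clipping silently.
    """
    _check_traces(traces)
    if any(sep in record for sep in ("/", "\\", os.sep)):
        raise ValueError(f"record name must not contain path separators: "
                         f"{record!r}")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n = traces[0].values.size
    fs = traces[0].fs

    digital = np.empty((n, len(traces)), dtype=np.int16)
    signal_lines = []
    for ch, tr in enumerate(traces):
        vmax = float(np.max(np.abs(tr.values)))
        gain = _INT16_FULL_SCALE / vmax if vmax > 0 else 200.0
        scaled = np.rint(tr.values * gain)
        if np.any(np.abs(scaled) > 32767):
            raise ValueError(
                f"channel {tr.label!r} exceeds the representable range at "
                f"gain {gain:g}; refusing to clip")
        digital[:, ch] = scaled.astype(np.int16)
        checksum = _wfdb_checksum(digital[:, ch])
        signal_lines.append(
            f"{record}.dat 16 {gain:.12g}(0)/mV 16 0 "
            f"{int(digital[0, ch])} {checksum} 0 {tr.label}")

    fs_text = f"{fs:.12g}"
    header = [f"{record} {len(traces)} {fs_text} {n}"] + signal_lines
    (directory / f"{record}.hea").write_text("\n".join(header) + "\n",
                                             encoding="utf-8", newline="\n")
    digital.astype("<i2").tofile(directory / f"{record}.dat")
    return directory / f"{record}.hea"


def read_wfdb(record: str, directory) -> list[ECGTrace]:
    """Read back a format-16 WFDB record written by :func:`write_wfdb`."""
    directory = Path(directory)
    lines = (directory / f"{record}.hea").read_text().splitlines()
    name, nsig_s, fs_s, n_s = lines[0].split()[:4]
    nsig, fs, n = int(nsig_s), float(fs_s), int(n_s)
    raw = np.fromfile(directory / f"{record}.dat", dtype="<i2")
    digital = raw.reshape(n, nsig)
    traces = []
    for ch in range(nsig):
        fields = lines[1 + ch].split()
        gain = float(fields[2].split("(")[0])
        checksum = int(fields[6])
        if _wfdb_checksum(digital[:, ch]) != checksum:
            raise ValueError(f"checksum mismatch on signal {ch} of {record}")
        label = fields[8] if len(fields) > 8 else f"ch{ch}"
        traces.append(ECGTrace(values=digital[:, ch] / gain, fs=fs,
                               label=label))
    return traces


@dataclass(frozen=True)
class BeatRateEstimate:
    """R-peak based rate estimate.

    ``bpm`` is 60 over the median inter-peak interval (NaN when undefined);
    ``irregular`` marks a coefficient of variation of the intervals above
    the irregularity threshold; ``flagged`` is the combined
    irregular-or-undefined indicator used for fibrillation-like rhythms.
    """

    bpm: float
    n_peaks: int
    defined: bool
    irregular: bool
    intervals: np.ndarray = field(repr=False, default_factory=lambda: np.array([]))

    @property
    def flagged(self) -> bool:
        return (not self.defined) or self.irregular


def estimate_beat_rate(trace: ECGTrace, *, threshold: float = 0.6,
                       refractory: float = 0.2,
                       cv_irregular: float = 0.1) -> BeatRateEstimate:
    """Estimate beats per minute from R peaks.

    Slow baseline wander is removed with a 0.6 s rolling-median filter and
    the dominant deflection flipped upward; candidate peaks are local maxima
    separated by at least the ``refractory`` window in seconds, and the
    adaptive threshold is ``threshold`` times the 98th percentile of the
    candidate-peak amplitudes -- a robust stand-in for the R amplitude that
    ignores the smaller P and T crests.  With fewer than two peaks the rate
    is undefined and the estimate is flagged.
    """
    if trace.duration < 5.0:
        raise ValueError(
            f"need at least 5 s of signal, got {trace.duration:.2f} s")
    win = max(3, int(round(0.6 * trace.fs)) | 1)
    baseline = median_filter(trace.values, size=min(win, trace.values.size),
                             mode="nearest")
    y = trace.values - baseline
    if -np.min(y) > np.max(y):
        y = -y
    distance = max(1, int(round(refractory * trace.fs)))
    candidates, props = find_peaks(y, height=0.0, distance=distance)
    if candidates.size == 0:
        return BeatRateEstimate(bpm=math.nan, n_peaks=0, defined=False,
                                irregular=False)
    level = np.percentile(props["peak_heights"], 98)
    if level <= 0:
        return BeatRateEstimate(bpm=math.nan, n_peaks=0, defined=False,
                                irregular=False)
    peaks, _ = find_peaks(y, height=threshold * level, distance=distance)
    if peaks.size < 2:
        return BeatRateEstimate(bpm=math.nan, n_peaks=int(peaks.size),
                                defined=False, irregular=False)
    intervals = np.diff(peaks) / trace.fs
    bpm = 60.0 / float(np.median(intervals))
    cv = float(np.std(intervals) / np.mean(intervals))
    return BeatRateEstimate(bpm=bpm, n_peaks=int(peaks.size), defined=True,
                            irregular=cv > cv_irregular, intervals=intervals)


def _sha256(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


@dataclass(frozen=True)
class RunManifest:
    """Everything needed to reproduce one generation run bit-for-bit."""

    model: str
    rhythm: str
    config: dict
    version: str
    outputs: tuple[dict, ...] = ()

    @classmethod
    def create(cls, model: str, rhythm: str, config: dict, version: str,
               paths: Sequence) -> "RunManifest":
        outputs = tuple({"path": str(Path(p).name), "sha256": _sha256(p)}
                        for p in paths)
        return cls(model=model, rhythm=rhythm, config=dict(config),
                   version=version, outputs=outputs)

    def to_json(self) -> str:
        return json.dumps(
            {"model": self.model, "rhythm": self.rhythm,
             "config": self.config, "version": self.version,
             "outputs": list(self.outputs)}, indent=2, sort_keys=True)

    def write(self, path) -> Path:
        path = Path(path)
        path.write_text(self.to_json() + "\n", encoding="utf-8")
        return path

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        obj = json.loads(text)
        return cls(model=obj["model"], rhythm=obj["rhythm"],
                   config=obj["config"], version=obj["version"],
                   outputs=tuple(obj["outputs"]))
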