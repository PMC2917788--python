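"""Plain-text sweep and manifest I/O.

One evoked sweep per file: a ``#``-prefixed ``key: value`` header block
carrying all metadata, a column-header line, then two tab-separated columns
(time in ms from sweep start, voltage in mV).  Voltages are written with
shortest round-trip ``repr`` so read(write(trace)) is bit-exact.  A dataset
manifest (YAML) lists the slices of a cohort and, per slice, the sweep files
with their drug condition and within-session time.

Times are stored relative to sweep start; the stimulus time is metadata,
never a time-axis shift, because latency-to-peak is measured from the
stimulus.  Voltages are mV throughout — no unit autodetection.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .protocol import CONDITIONS, ProtocolSpec

HEMISPHERES = ("left", "right")
EYE_INPUTS = ("operated", "unoperated", "control")
GROUPS = ("AMC", "OHT")
TIMEPOINTS = (3, 16, 32)


class FormatError(ValueError):
    """A sweep file violates the documented format."""


class ManifestError(ValueError):
    """A dataset manifest violates its schema or references missing files."""


@dataclass(frozen=True)
class TraceMeta:
    """Slice/condition metadata attached to one sweep."""

    slice_id: str
    hemisphere: str = "left"
    eye_input: str = "control"
    group: str = "AMC"
    timepoint_weeks: int = 32
    condition: str = "baseline"
    sweep_time_s: float = 0.0

    def __post_init__(self) -> None:
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"hemisphere must be one of {HEMISPHERES}")
        if self.eye_input not in EYE_INPUTS:
            raise ValueError(f"eye_input must be one of {EYE_INPUTS}")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if int(self.timepoint_weeks) not in TIMEPOINTS:
            raise ValueError(f"timepoint_weeks must be one of {TIMEPOINTS}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.sweep_time_s < 0:
            raise ValueError("sweep_time_s must be non-negative")


@dataclass
class Trace:
    """One evoked sweep: uniformly sampled voltage with stimulus timing.

    Parameters
    ----------
    voltage_mV : array of float
        Sampled voltage, mV.
    sampling_interval_ms : float
        Sample spacing, ms (default 0.1, i.e. 10 kHz).
    stimulus_time_ms : float
        Stimulus onset relative to sweep start, ms.
    meta : TraceMeta
        Slice / condition metadata.
    """

    voltage_mV: np.ndarray
    sampling_interval_ms: float = 0.1
    stimulus_time_ms: float = 10.0
    meta: TraceMeta = field(default_factory=lambda: TraceMeta("unknown"))

    def __post_init__(self) -> None:
        self.voltage_mV = np.asarray(self.voltage_mV, dtype=float)
        self.validate()

    def validate(self, strict: bool = False) -> None:
        """Check basic invariants; ``strict`` additionally requires the
        record to extend 100 ms past the stimulus so the AUC window fits."""
        if self.sampling_interval_ms <= 0:
            raise ValueError("sampling_interval_ms must be positive")
        if self.voltage_mV.ndim != 1 or self.voltage_mV.size == 0:
            raise ValueError("voltage_mV must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.voltage_mV)):
            raise ValueError("voltage_mV contains non-finite values")
        if not 0 <= self.stimulus_time_ms < self.record_length_ms:
            raise ValueError("stimulus_time_ms must lie within the record")
        if strict and self.record_length_ms < self.stimulus_time_ms + 100.0:
            raise ValueError(
                "record must extend >= 100 ms past the stimulus "
                f"(length {self.record_length_ms:.1f} ms, "
                f"stimulus at {self.stimulus_time_ms:.1f} ms)")

    @property
    def n_samples(self) -> int:
        return int(self.voltage_mV.size)

    @property
    def record_length_ms(self) -> float:
        return self.n_samples * self.sampling_interval_ms

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.sampling_interval_ms

    def index_at(self, time_ms: float) -> int:
        """Grid index of the sample nearest ``time_ms`` (clipped to range)."""
        i = int(round(time_ms / self.sampling_interval_ms))
        return min(max(i, 0), self.n_samples - 1)


_META_KEYS = ("slice_id", "hemisphere", "eye_input", "group",
              "timepoint_weeks", "condition", "sweep_time_s")
_HEADER_KEYS = _META_KEYS + ("stimulus_time_ms",)
_TIME_TOL_MS = 1e-9


def read_sweep_table(path: str | Path) -> Trace:
    """Read one sweep file (documented tab-separated format) into a Trace."""
    path = Path(path)
    header: dict[str, str] = {}
    times: list[float] = []
    volts: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" not in body:
                    raise FormatError(f"{path}:{lineno}: malformed header line")
                key, _, value = body.partition(":")
                header[key.strip()] = value.strip()
                continue
            cols = line.split("\t")
            if cols[0] == "time_ms":  # column-header line
                continue
            if len(cols) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            try:
                t, v = float(cols[0]), float(cols[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            times.append(t)
            volts.append(v)

    for key in _HEADER_KEYS:
        if key not in header:
            raise FormatError(f"{path}: missing header key {key!r}")
    if len(times) == 0:
        raise FormatError(f"{path}: no data rows")
    t = np.asarray(times)
    v = np.asarray(volts)
    if not np.all(np.isfinite(v)):
        raise FormatError(f"{path}: non-finite voltage value")
    if abs(t[0]) > _TIME_TOL_MS:
        raise FormatError(f"{path}: time axis must start at 0 ms")
    if len(t) < 2:
        raise FormatError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if np.ptp(dt) > _TIME_TOL_MS:
        raise FormatError(f"{path}: time base is not uniform (max deviation "
                          f"{np.ptp(dt):.3g} ms)")
    meta = TraceMeta(
        slice_id=header["slice_id"],
        hemisphere=header["hemisphere"],
        eye_input=header["eye_input"],
        group=header["group"],
        timepoint_weeks=int(header["timepoint_weeks"]),
        condition=header["condition"],
        sweep_time_s=float(header["sweep_time_s"]),
    )
    return Trace(voltage_mV=v,
                 sampling_interval_ms=float(dt[0]),
                 stimulus_time_ms=float(header["stimulus_time_ms"]),
                 meta=meta)


def write_sweep_table(trace: Trace, path: str | Path) -> Path:
    """Write ``trace`` so that :func:`read_sweep_table` reproduces it exactly."""
    trace.validate()
    path = Path(path)
    lines = [f"# stimulus_time_ms: {trace.stimulus_time_ms!r}"]
    for key in _META_KEYS:
        lines.append(f"# {key}: {getattr(trace.meta, key)}")
    lines.append("time_ms\tvoltage_mV")
    dt = trace.sampling_interval_ms
    for i, v in enumerate(trace.voltage_mV):
        lines.append(f"{i * dt!r}\t{float(v)!r}")
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# dataset manifests

@dataclass(frozen=True)
class SweepRef:
    file: str
    condition: str
    sweep_time_s: float


@dataclass
class SliceEntry:
    slice_id: str
    hemisphere: str
    eye_input: str
    group: str
    timepoint_weeks: int
    sweeps: list[SweepRef]


@dataclass
class DatasetManifest:
    """A cohort: protocol plus per-slice sweep-file listings."""

    protocol: ProtocolSpec
    slices: list[SliceEntry]
    root: Path = field(default_factory=Path)

    def slice_ids(self) -> list[str]:
        return [s.slice_id for s in self.slices]

    def validate(self, check_files: bool = True) -> None:
        if not self.slices:
            raise ManifestError("manifest lists no slices")
        order = {c: i for i, c in enumerate(CONDITIONS)}
        for entry in self.slices:
            loc = f"slice {entry.slice_id!r}"
            counts = {c: 0 for c in CONDITIONS}
            last = (-1, -1.0)
            for ref in entry.sweeps:
                if ref.condition not in order:
                    raise ManifestError(f"{loc}: unknown condition {ref.condition!r}")
                key = (order[ref.condition], ref.sweep_time_s)
                if key < last:
                    raise ManifestError(
                        f"{loc}: sweeps out of protocol order at {ref.file}")
                last = key
                counts[ref.condition] += 1
                if check_files and not (self.root / ref.file).exists():
                    raise ManifestError(f"{loc}: dangling file reference {ref.file}")
            for cond in CONDITIONS:
                if counts[cond] < self.protocol.avg_window_sweeps:
                    raise ManifestError(
                        f"{loc}: only {counts[cond]} {cond} sweeps "
                        f"(need >= {self.protocol.avg_window_sweeps})")

    def load_slice(self, slice_id: str) -> dict[str, list[Trace]]:
        """Read all sweep files of one slice, grouped by condition."""
        entry = next((s for s in self.slices if s.slice_id == slice_id), None)
        if entry is None:
            raise ManifestError(f"unknown slice_id {slice_id!r}")
        out: dict[str, list[Trace]] = {c: [] for c in CONDITIONS}
        for ref in entry.sweeps:
            out[ref.condition].append(read_sweep_table(self.root / ref.file))
        return out


def read_manifest(path: str | Path, check_files: bool = True) -> DatasetManifest:
    """Read and validate a YAML dataset manifest."""
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ManifestError(f"{path}: not valid YAML ({exc})") from None
    if not isinstance(doc, Mapping):
        raise ManifestError(f"{path}: top level must be a mapping")
    try:
        proto_kwargs = dict(doc.get("protocol") or {})
        if "peak_window_ms" in proto_kwargs:
            proto_kwargs["peak_window_ms"] = tuple(proto_kwargs["peak_window_ms"])
        protocol = ProtocolSpec(**proto_kwargs)
    except (TypeError, ValueError) as exc:
        raise ManifestError(f"{path}: protocol: {exc}") from None
    raw_slices = doc.get("slices")
    if not isinstance(raw_slices, Sequence) or not raw_slices:
        raise ManifestError(f"{path}: slices: must be a non-empty list")
    slices = []
    for i, raw in enumerate(raw_slices):
        loc = f"{path}: slices[{i}]"
        try:
            sweeps = [SweepRef(file=str(s["file"]), condition=str(s["condition"]),
                               sweep_time_s=float(s["sweep_time_s"]))
                      for s in raw["sweeps"]]
            entry = SliceEntry(
                slice_id=str(raw["slice_id"]),
                hemisphere=str(raw["hemisphere"]),
                eye_input=str(raw["eye_input"]),
                group=str(raw["group"]),
                timepoint_weeks=int(raw["timepoint_weeks"]),
                sweeps=sweeps,
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ManifestError(f"{loc}: {exc!r}") from None
        slices.append(entry)
    manifest = DatasetManifest(protocol=protocol, slices=slices, root=path.parent)
    manifest.validate(check_files=check_files)
    return manifest


def write_manifest(manifest: DatasetManifest, path: str | Path) -> Path:
    path = Path(path)
    proto = dataclasses.asdict(manifest.protocol)
    proto["peak_window_ms"] = list(proto["peak_window_ms"])
    doc = {
        "protocol": proto,
        "slices": [
            {
                "slice_id": s.slice_id,
                "hemisphere": s.hemisphere,
                "eye_input": s.eye_input,
                "group": s.group,
                "timepoint_weeks": s.timepoint_weeks,
                "sweeps": [dataclasses.asdict(r) for r in s.sweeps],
            }
            for s in manifest.slices
        ],
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path
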