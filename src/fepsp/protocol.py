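"""Recording-protocol description.

The experiment this package analyses follows a fixed three-epoch drug
timeline: a stable baseline in normal Krebs, addition of GABA-receptor
antagonists (picrotoxin + CGP55845, blocking GABA_A/B/C), then addition of
the NMDA antagonist D-AP5 on top of the GABA blockers.  Stimuli are 0.1 ms
pulses delivered every 20 s; responses are waveform-averaged in groups of
three sweeps (60 s of recording) and the analysis uses the last three
minutes of each epoch.
"""
from __future__ import annotations

from dataclasses import dataclass, field

#: drug conditions in the order they occur within a recording session
CONDITIONS = ("baseline", "gaba_block", "gaba_nmda_block")


@dataclass(frozen=True)
class ProtocolSpec:
    """Drug-epoch timeline and stimulation/analysis schedule.

    Defaults mirror the experimental protocol: 20 min baseline, >=20 min
    GABA blockade, 10 min combined GABA+NMDA blockade, one 0.1 ms stimulus
    every 20 s, 3-sweep waveform averages, last-3-min analysis windows, and
    a late-phase AUC window ending 100 ms after stimulation.
    """

    baseline_min: float = 20.0
    gaba_block_min: float = 20.0
    full_block_min: float = 10.0
    stim_interval_s: float = 20.0
    pulse_ms: float = 0.1
    avg_window_sweeps: int = 3
    analysis_window_min: float = 3.0
    auc_end_ms: float = 100.0
    peak_window_ms: tuple[float, float] = (0.5, 10.0)

    def __post_init__(self) -> None:
        for name in ("baseline_min", "gaba_block_min", "full_block_min",
                     "stim_interval_s", "pulse_ms", "analysis_window_min",
                     "auc_end_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"ProtocolSpec.{name} must be positive")
        if self.avg_window_sweeps < 1:
            raise ValueError("avg_window_sweeps must be >= 1")
        lo, hi = self.peak_window_ms
        if not 0 <= lo < hi:
            raise ValueError("peak_window_ms must be an increasing interval")
        if self.analysis_sweeps < self.avg_window_sweeps:
            raise ValueError(
                "analysis window shorter than one waveform average "
                f"({self.analysis_sweeps} < {self.avg_window_sweeps} sweeps)")

    @property
    def analysis_sweeps(self) -> int:
        """Number of sweeps in the per-epoch analysis window (default 9)."""
        return int(round(self.analysis_window_min * 60.0 / self.stim_interval_s))

    def epoch_minutes(self, condition: str) -> float:
        try:
            return {
                "baseline": self.baseline_min,
                "gaba_block": self.gaba_block_min,
                "gaba_nmda_block": self.full_block_min,
            }[condition]
        except KeyError:
            raise ValueError(f"unknown condition {condition!r}") from None

    def sweeps_per_epoch(self, condition: str) -> int:
        return int(round(self.epoch_minutes(condition) * 60.0 / self.stim_interval_s))
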