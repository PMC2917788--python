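"""Receptor-contribution statistics from the three drug epochs.

The GABA-receptor contribution is the fraction of the disinhibited
(GABA-blocked) response AUC that intact inhibition suppresses:

    GABA% = 100 * (AUC_gaba_block - AUC_baseline) / AUC_gaba_block

and the NMDA-receptor contribution is the fraction of the disinhibited AUC
removed by D-AP5:

    NMDA% = 100 * (AUC_gaba_block - AUC_full_block) / AUC_gaba_block.

Analysis responses come from the last 3 min of each drug epoch (nine sweeps
at the 20 s stimulus interval), taken as three consecutive 3-sweep waveform
averages whose measurements are themselves averaged.  Out-of-range
percentages are never clamped; they are QC-flagged so pathology stays
visible.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .features import FeatureSet, average_sweeps, extract_features, mean_features
from .io import Trace
from .protocol import CONDITIONS, ProtocolSpec

QC_GABA_OUT_OF_RANGE = "gaba-contribution-out-of-range"
QC_NMDA_OUT_OF_RANGE = "nmda-contribution-out-of-range"


class ContributionError(ValueError):
    """A contribution is undefined (zero disinhibited AUC)."""


@dataclass(frozen=True)
class AnalysisResponse:
    """Analysis-window summary of one drug epoch."""

    mean_trace: Trace                      # 9-sweep mean
    window_features: tuple[FeatureSet, ...]  # one per 3-sweep average
    features: FeatureSet                   # field-wise mean of the above


@dataclass(frozen=True)
class ContributionResult:
    """Per-slice receptor contributions with the three condition AUCs."""

    slice_id: str
    auc_baseline: float
    auc_gaba_block: float
    auc_full_block: float
    gaba_pct: float
    nmda_pct: float
    amp_ratio_gaba: float
    amp_ratio_dap5: float
    features: Mapping[str, FeatureSet]
    qc: tuple[str, ...] = ()


def select_analysis_response(sweeps: Sequence[Trace],
                             protocol: ProtocolSpec | None = None,
                             ) -> AnalysisResponse:
    """Summarise the last 3 min of one epoch.

    Requires at least ``protocol.analysis_sweeps`` (default 9) sweeps of a
    single condition; uses exactly the last nine, split into three
    consecutive 3-sweep averages.
    """
    protocol = protocol or ProtocolSpec()
    n_win = protocol.analysis_sweeps
    if len(sweeps) < n_win:
        raise ValueError(
            f"epoch too short: {len(sweeps)} sweeps, need >= {n_win} "
            f"(last {protocol.analysis_window_min:g} min)")
    tail = list(sweeps)[-n_win:]
    w = protocol.avg_window_sweeps
    averages = [average_sweeps(tail[i:i + w], window=w)
                for i in range(0, n_win - n_win % w, w)]
    feats = tuple(extract_features(tr, protocol, n_sweeps_averaged=w)
                  for tr in averages)
    mean_trace = average_sweeps(tail, window=n_win)
    return AnalysisResponse(mean_trace=mean_trace, window_features=feats,
                            features=mean_features(feats))


def gaba_contribution(auc_baseline: float, auc_gaba_block: float) -> float:
    """GABA-receptor contribution (%) from baseline and disinhibited AUCs."""
    if auc_gaba_block <= 0:
        raise ContributionError(
            "GABA contribution undefined: disinhibited AUC is zero")
    return 100.0 * (auc_gaba_block - auc_baseline) / auc_gaba_block


def nmda_contribution(auc_gaba_block: float, auc_full_block: float) -> float:
    """NMDA-receptor contribution (%) from disinhibited and D-AP5 AUCs."""
    if auc_gaba_block <= 0:
        raise ContributionError(
            "NMDA contribution undefined: disinhibited AUC is zero")
    return 100.0 * (auc_gaba_block - auc_full_block) / auc_gaba_block


def normalize_to_baseline(feature_drug: float, feature_baseline: float) -> float:
    """Drug-condition measurement as a ratio of its baseline value."""
    if feature_baseline == 0:
        raise ValueError("cannot normalise to a zero baseline measurement")
    return feature_drug / feature_baseline


def slice_contributions(sweeps, protocol: ProtocolSpec | None = None,
                        ) -> ContributionResult:
    """Full per-slice analysis: epoch selection, features, contributions.

    ``sweeps`` is either a mapping ``condition -> sweeps`` or a flat
    sequence of traces which is grouped by ``meta.condition``.  All three
    drug conditions must be present.
    """
    protocol = protocol or ProtocolSpec()
    if isinstance(sweeps, Mapping):
        by_cond = {c: list(sweeps.get(c, ())) for c in CONDITIONS}
    else:
        by_cond = {c: [] for c in CONDITIONS}
        for tr in sweeps:
            by_cond[tr.meta.condition].append(tr)
    for cond in CONDITIONS:
        if not by_cond[cond]:
            raise ValueError(f"missing condition epoch {cond!r}")
    responses = {c: select_analysis_response(by_cond[c], protocol)
                 for c in CONDITIONS}
    feats = {c: r.features for c, r in responses.items()}
    auc_b = feats["baseline"].auc_mV_ms
    auc_g = feats["gaba_block"].auc_mV_ms
    auc_f = feats["gaba_nmda_block"].auc_mV_ms
    gaba = gaba_contribution(auc_b, auc_g)
    nmda = nmda_contribution(auc_g, auc_f)
    qc: set[str] = set()
    for fs in feats.values():
        qc.update(fs.qc)
    if not 0.0 <= gaba <= 100.0:
        qc.add(QC_GABA_OUT_OF_RANGE)
    if not 0.0 <= nmda <= 100.0:
        qc.add(QC_NMDA_OUT_OF_RANGE)
    slice_id = by_cond["baseline"][0].meta.slice_id
    return ContributionResult(
        slice_id=slice_id,
        auc_baseline=auc_b, auc_gaba_block=auc_g, auc_full_block=auc_f,
        gaba_pct=gaba, nmda_pct=nmda,
        amp_ratio_gaba=normalize_to_baseline(
            feats["gaba_block"].peak_amplitude_mV,
            feats["baseline"].peak_amplitude_mV),
        amp_ratio_dap5=normalize_to_baseline(
            feats["gaba_nmda_block"].peak_amplitude_mV,
            feats["gaba_block"].peak_amplitude_mV),
        features=feats, qc=tuple(sorted(qc)))
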