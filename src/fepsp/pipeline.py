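"""End-to-end orchestration: simulate/load -> features -> contributions -> stats.

The top-level surface follows the model/results idiom: build a
:class:`ReceptorContributionModel` from data (a dataset manifest, in-memory
sweeps, or cohort specs to simulate), call :meth:`~ReceptorContributionModel.fit`,
and read estimates, uncertainties and tests off the returned
:class:`ReceptorContributionResults` (``summary()`` prints the group tables).
:func:`run_experiment` wraps the same flow for config-driven batch runs and
writes the CSV report bundle plus a reproducibility log.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .contributions import ContributionResult, slice_contributions
from .io import DatasetManifest, Trace, read_manifest
from .protocol import CONDITIONS, ProtocolSpec
from .stats import (GroupSummary, StatResult, anova_from_summary,
                    one_way_anova, paired_t_test, summarize_group, tukey_hsd)
from .synth import CohortSpec, cohort_spec, simulate_cohort

log = logging.getLogger("fepsp")

_GROUP_COLS = ["group", "timepoint_weeks", "eye_input", "hemisphere"]


@dataclass
class RunConfig:
    """Configuration of one batch run."""

    cohorts: list  # CohortSpec | preset name | manifest path
    seed: int = 0
    output_dir: Path | None = None
    protocol: ProtocolSpec = field(default_factory=ProtocolSpec)

    def __post_init__(self) -> None:
        if not self.cohorts:
            raise ValueError("config lists no cohorts")


class ReceptorContributionModel:
    """Receptor-contribution analysis of a set of slice recordings.

    Parameters
    ----------
    sweeps_by_slice : mapping of slice_id -> list of Trace
        All sweeps of each slice (three drug epochs each).
    design : DataFrame
        One row per slice with columns ``slice_id, group, timepoint_weeks,
        eye_input, hemisphere``.
    protocol : ProtocolSpec, optional
    """

    def __init__(self, sweeps_by_slice: Mapping[str, Sequence[Trace]],
                 design: pd.DataFrame,
                 protocol: ProtocolSpec | None = None) -> None:
        if not sweeps_by_slice:
            raise ValueError("no slices supplied")
        missing = set(design["slice_id"]) ^ set(sweeps_by_slice)
        if missing:
            raise ValueError(f"design/sweeps slice mismatch: {sorted(missing)}")
        self.sweeps_by_slice = dict(sweeps_by_slice)
        self.design = design.reset_index(drop=True)
        self.protocol = protocol or ProtocolSpec()

    # -- constructors -------------------------------------------------
    @classmethod
    def from_manifest(cls, path, protocol: ProtocolSpec | None = None
                      ) -> "ReceptorContributionModel":
        manifest = read_manifest(path)
        return cls.from_loaded_manifest(manifest, protocol)

    @classmethod
    def from_loaded_manifest(cls, manifest: DatasetManifest,
                             protocol: ProtocolSpec | None = None
                             ) -> "ReceptorContributionModel":
        sweeps, rows = {}, []
        for entry in manifest.slices:
            by_cond = manifest.load_slice(entry.slice_id)
            sweeps[entry.slice_id] = [t for c in CONDITIONS for t in by_cond[c]]
            rows.append({"slice_id": entry.slice_id, "group": entry.group,
                         "timepoint_weeks": entry.timepoint_weeks,
                         "eye_input": entry.eye_input,
                         "hemisphere": entry.hemisphere})
        return cls(sweeps, pd.DataFrame(rows),
                   protocol or manifest.protocol)

    @classmethod
    def from_simulation(cls, specs: Sequence[CohortSpec],
                        protocol: ProtocolSpec | None = None
                        ) -> "ReceptorContributionModel":
        protocol = protocol or ProtocolSpec()
        sweeps, rows = {}, []
        for spec in specs:
            _, by_slice = simulate_cohort(spec, protocol)
            for slice_id, trs in by_slice.items():
                sweeps[slice_id] = trs
                rows.append({"slice_id": slice_id, "group": spec.group,
                             "timepoint_weeks": spec.timepoint_weeks,
                             "eye_input": spec.eye_input,
                             "hemisphere": spec.hemisphere})
        return cls(sweeps, pd.DataFrame(rows), protocol)

    # -- estimation ---------------------------------------------------
    def fit(self) -> "ReceptorContributionResults":
        """Run feature extraction and contribution analysis on every slice."""
        results: list[ContributionResult] = []
        for slice_id, sweeps in self.sweeps_by_slice.items():
            log.debug("analysing slice %s (%d sweeps)", slice_id, len(sweeps))
            results.append(slice_contributions(sweeps, self.protocol))
        log.info("analysed %d slices", len(results))
        return ReceptorContributionResults(self, results)


def _group_label(row) -> str:
    return (f"{row['group']}-{row['timepoint_weeks']}wk-"
            f"{row['eye_input']}-{row['hemisphere']}")


class ReceptorContributionResults:
    """Fitted per-slice contributions plus group-level inference."""

    def __init__(self, model: ReceptorContributionModel,
                 slice_results: Sequence[ContributionResult]) -> None:
        self.model = model
        self.slice_results = list(slice_results)
        self.contributions = self._contributions_frame()
        self.features = self._features_frame()

    # -- tidy tables --------------------------------------------------
    def _contributions_frame(self) -> pd.DataFrame:
        rows = []
        design = self.model.design.set_index("slice_id")
        for r in self.slice_results:
            d = design.loc[r.slice_id]
            rows.append({
                "slice_id": r.slice_id,
                **{c: d[c] for c in _GROUP_COLS},
                "auc_baseline": r.auc_baseline,
                "auc_gaba_block": r.auc_gaba_block,
                "auc_full_block": r.auc_full_block,
                "gaba_pct": r.gaba_pct, "nmda_pct": r.nmda_pct,
                "amp_ratio_gaba": r.amp_ratio_gaba,
                "amp_ratio_dap5": r.amp_ratio_dap5,
                "qc": ";".join(r.qc),
            })
        return pd.DataFrame(rows)

    def _features_frame(self) -> pd.DataFrame:
        rows = []
        design = self.model.design.set_index("slice_id")
        for r in self.slice_results:
            d = design.loc[r.slice_id]
            for cond in CONDITIONS:
                fs = r.features[cond]
                rows.append({
                    "slice_id": r.slice_id,
                    **{c: d[c] for c in _GROUP_COLS},
                    "condition": cond,
                    "peak_amplitude_mV": fs.peak_amplitude_mV,
                    "latency_to_peak_ms": fs.latency_to_peak_ms,
                    "duration_ms": fs.duration_ms,
                    "auc_mV_ms": fs.auc_mV_ms,
                    "baseline_mV": fs.baseline_mV,
                    "noise_sd_mV": fs.noise_sd_mV,
                    "n_sweeps_averaged": fs.n_sweeps_averaged,
                    "qc": ";".join(fs.qc),
                })
        return pd.DataFrame(rows)

    # -- group-level inference ----------------------------------------
    def group_summaries(self, value: str = "nmda_pct") -> pd.DataFrame:
        """Mean +/- SEM of ``value`` per experimental group."""
        df = self.contributions
        rows = []
        for _, sub in df.groupby(_GROUP_COLS, sort=True):
            label = _group_label(sub.iloc[0])
            s = summarize_group(sub[value].to_numpy(), label)
            rows.append({"label": label, "n": s.n, "mean": s.mean,
                         "sem": s.sem, "measure": value})
        return pd.DataFrame(rows)

    def drug_effect_tests(self, feature: str = "peak_amplitude_mV"
                          ) -> pd.DataFrame:
        """Paired t-tests of each drug step against its preceding epoch.

        Mirrors the published drug-effect tables: GABA blockade is compared
        with the drug-free baseline, and the added NMDA blockade with the
        GABA-blocked condition, within slices.
        """
        feats = self.features
        rows = []
        for _, sub in feats.groupby(_GROUP_COLS, sort=True):
            label = _group_label(sub.iloc[0])
            wide = sub.pivot(index="slice_id", columns="condition",
                             values=feature)
            if len(wide) < 2:
                continue
            for pre, post in (("baseline", "gaba_block"),
                              ("gaba_block", "gaba_nmda_block")):
                res = paired_t_test(wide[pre], wide[post], (pre, post))
                rows.append({
                    "label": label, "feature": feature, "n": len(wide),
                    "pre": pre, "post": post,
                    "mean_pre": wide[pre].mean(), "sem_pre":
                        summarize_group(wide[pre], "x").sem,
                    "mean_post": wide[post].mean(), "sem_post":
                        summarize_group(wide[post], "x").sem,
                    "t": res.statistic, "df": res.df, "p": res.p_value,
                    "stars": res.stars,
                })
        return pd.DataFrame(rows)

    def compare_groups(self, value: str = "nmda_pct",
                       subset: pd.DataFrame | None = None) -> pd.DataFrame:
        """One-way ANOVA + pairwise Tukey HSD across experimental groups."""
        df = subset if subset is not None else self.contributions
        return compare_groups(df, value=value)

    def _stats_or_empty(self, value: str) -> pd.DataFrame:
        """Group comparison, or an empty frame when only one group exists."""
        if self.contributions.groupby(_GROUP_COLS).ngroups < 2:
            return pd.DataFrame(columns=["method", "comparison", "statistic",
                                         "df", "p", "stars"])
        return self.compare_groups(value)

    # -- presentation --------------------------------------------------
    def summary(self) -> str:
        """Readable report: group means +/- SEM and the Tukey contrasts."""
        lines = ["Receptor contribution analysis",
                 "=" * 31,
                 f"slices: {len(self.slice_results)}    "
                 f"groups: {self.contributions.groupby(_GROUP_COLS).ngroups}",
                 ""]
        for value in ("gaba_pct", "nmda_pct"):
            name = {"gaba_pct": "GABA receptor contribution (%)",
                    "nmda_pct": "NMDA receptor contribution (%)"}[value]
            lines.append(name)
            for _, row in self.group_summaries(value).iterrows():
                lines.append(f"  {row['label']:<32s} (n={row['n']:>2d})  "
                             f"{row['mean']:6.1f} +/- {row['sem']:.2f}")
            stats_df = self._stats_or_empty(value)
            for _, row in stats_df[stats_df.method == "tukey"].iterrows():
                lines.append(f"    {row['comparison']:<52s} "
                             f"p = {row['p']:.4f} {row['stars']}")
            lines.append("")
        return "\n".join(lines)

    def save_tables(self, out_dir) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        tables = {
            "features.csv": self.features,
            "contributions.csv": self.contributions,
            "contribution_groups.csv": pd.concat(
                [self.group_summaries("gaba_pct"),
                 self.group_summaries("nmda_pct")], ignore_index=True),
            "contribution_stats.csv": pd.concat(
                [self._stats_or_empty("gaba_pct").assign(measure="gaba_pct"),
                 self._stats_or_empty("nmda_pct").assign(measure="nmda_pct")],
                ignore_index=True),
            "amplitude_effects.csv": self.drug_effect_tests("peak_amplitude_mV"),
            "latency_effects.csv": self.drug_effect_tests("latency_to_peak_ms"),
            "duration_effects.csv": self.drug_effect_tests("duration_ms"),
        }
        for name, df in tables.items():
            path = out_dir / name
            df.to_csv(path, index=False, float_format="%.10g")
            paths[name] = path
        return paths


def compare_groups(contributions: pd.DataFrame, value: str = "nmda_pct",
                   group_cols: Sequence[str] = tuple(_GROUP_COLS)) -> pd.DataFrame:
    """Omnibus ANOVA + Tukey HSD over the groups present in a table.

    Returns one ``anova`` row and one ``tukey`` row per group pair, with the
    conventional significance stars.
    """
    groups, labels = [], []
    for key, sub in contributions.groupby(list(group_cols), sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        labels.append("-".join(str(k) for k in key))
        groups.append(sub[value].to_numpy())
    if len(groups) < 2:
        raise ValueError("need >= 2 groups to compare")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group in comparison")
    omnibus = one_way_anova(groups, labels)
    pairs = tukey_hsd(groups, labels)
    rows = [{"method": "anova", "comparison": "omnibus",
             "statistic": omnibus.statistic, "df": str(omnibus.df),
             "p": omnibus.p_value, "stars": omnibus.stars}]
    for r in pairs:
        rows.append({"method": "tukey", "comparison": " vs ".join(r.comparison),
                     "statistic": r.statistic, "df": str(r.df),
                     "p": r.p_value, "stars": r.stars})
    return pd.DataFrame(rows)


def _resolve_cohorts(config: RunConfig) -> tuple[list[CohortSpec], list[Path]]:
    specs, manifests = [], []
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(config.cohorts))
    for item, child in zip(config.cohorts, children):
        if isinstance(item, CohortSpec):
            specs.append(dataclasses.replace(item, seed=child))
        elif isinstance(item, str) and item in _preset_names():
            specs.append(cohort_spec(item, seed=child))
        else:
            manifests.append(Path(item))
    return specs, manifests


def _preset_names():
    from .synth import PRESETS
    return PRESETS


def run_experiment(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run the full pipeline for a config and emit the CSV report bundle."""
    specs, manifest_paths = _resolve_cohorts(config)
    models = []
    if specs:
        models.append(ReceptorContributionModel.from_simulation(
            specs, config.protocol))
    for path in manifest_paths:
        models.append(ReceptorContributionModel.from_manifest(path))
    sweeps, frames = {}, []
    for m in models:
        sweeps.update(m.sweeps_by_slice)
        frames.append(m.design)
    model = ReceptorContributionModel(sweeps, pd.concat(frames,
                                                        ignore_index=True),
                                      config.protocol)
    log.info("fitting %d slices from %d cohorts", len(sweeps),
             len(config.cohorts))
    results = model.fit()
    tables = {
        "features": results.features,
        "contributions": results.contributions,
        "contribution_groups": pd.concat(
            [results.group_summaries("gaba_pct"),
             results.group_summaries("nmda_pct")], ignore_index=True),
    }
    if config.output_dir is not None:
        out = Path(config.output_dir)
        results.save_tables(out)
        run_log = {
            "package": "fepsp", "version": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__, "pandas": pd.__version__,
            "seed": config.seed,
            "protocol": dataclasses.asdict(config.protocol),
            "cohorts": [getattr(c, "name", str(c)) for c in config.cohorts],
            "n_slices": len(sweeps),
        }
        (out / "run_log.json").write_text(json.dumps(run_log, indent=2,
                                                     default=str))
        log.info("report bundle written to %s", out)
    return tables
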