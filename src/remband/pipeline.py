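"""End-to-end orchestration: cohort -> epochs -> features -> stats -> CV.

The pipeline reads a cohort manifest (or generates and writes a synthetic
cohort first, then reads it back through the same file readers), extracts
30-s REM epochs per channel, computes the 28-feature table, the two-group
significance table, and the stratified k-fold fine-tree metrics per channel,
and writes every report surface as CSV plus a JSON run log with config hash,
seed, per-subject epoch accounting and exclusion reasons.

Everything is deterministic under a fixed config and seed: rerunning into a
fresh directory produces byte-identical CSVs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .errors import DataFormatError, ValidationError
from .features import FEATURE_NAMES, FeatureConfig, SampEnParams, feature_table
from .io import (
    Hypnogram,
    RemEpoch,
    accounting_from_counts,
    extract_rem_epochs,
    read_hypnogram,
    read_manifest,
    read_recording,
)
from .stats import compare_groups, rpsd_group_summary
from .synth import DEFAULT_CHANNELS, CohortSpec, generate_cohort, write_fixture
from .tree import CVMetrics, TreeParams, cv_evaluate

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Declarative run configuration; defaults reproduce the study settings."""

    manifest: Optional[str] = None  # None -> synthetic cohort
    synthetic: Optional[CohortSpec] = None
    channels: Tuple[str, ...] = DEFAULT_CHANNELS
    control_group: str = "healthy"
    positive_group: str = "bruxism"
    stats_policy: str = "force-mw"
    features: FeatureConfig = field(default_factory=FeatureConfig)
    tree: TreeParams = field(default_factory=TreeParams)
    k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.manifest is None and self.synthetic is None:
            object.__setattr__(self, "synthetic", CohortSpec(seed=self.seed))
        if self.manifest is not None and self.synthetic is not None:
            raise ValidationError("config must give either a manifest or a synthetic spec")
        if self.k < 2:
            raise ValidationError("k must be >= 2")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"]["group_profiles"] = {
                g: {
                    "band_sd": dict(p.band_sd),
                    "drift_amp": p.drift_amp,
                    "hf_amp": p.hf_amp,
                }
                for g, p in self.synthetic.group_profiles.items()
            }
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        from .synth import BandProfile, profile_from_rpsd

        kwargs = dict(raw)
        if "synthetic" in kwargs and kwargs["synthetic"] is not None:
            syn = dict(kwargs["synthetic"])
            if "group_profiles" in syn and syn["group_profiles"] is not None:
                profiles = {}
                for g, p in syn["group_profiles"].items():
                    if "rpsd" in p:
                        profiles[g] = profile_from_rpsd(
                            p["rpsd"],
                            total_sd=p.get("total_sd", 10.0),
                            drift_amp=p.get("drift_amp", 0.0),
                            hf_amp=p.get("hf_amp", 0.0),
                        )
                    else:
                        profiles[g] = BandProfile(
                            band_sd=p["band_sd"],
                            drift_amp=p.get("drift_amp", 0.0),
                            hf_amp=p.get("hf_amp", 0.0),
                        )
                syn["group_profiles"] = profiles
            if "channels" in syn:
                syn["channels"] = tuple(syn["channels"])
            kwargs["synthetic"] = CohortSpec(**syn)
        if "channels" in kwargs:
            kwargs["channels"] = tuple(kwargs["channels"])
        if "features" in kwargs:
            f = dict(kwargs["features"])
            if "sampen" in f:
                f["sampen"] = SampEnParams(**f["sampen"])
            kwargs["features"] = FeatureConfig(**f)
        if "tree" in kwargs:
            kwargs["tree"] = TreeParams(**kwargs["tree"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    """All report surfaces of one run, in memory and on disk."""

    accounting: pd.DataFrame
    features: Dict[str, pd.DataFrame]
    significance: Dict[str, pd.DataFrame]
    rpsd_summary: pd.DataFrame
    metrics: pd.DataFrame
    ranking: pd.DataFrame
    cv: Dict[str, CVMetrics]
    run_log: dict
    outdir: Optional[Path] = None


def _load_cohort_files(
    manifest_path: Path,
) -> List[Tuple[str, str, Path, Path]]:
    base = manifest_path.parent
    out = []
    for rec in read_manifest(manifest_path):
        out.append(
            (
                rec["subject_id"],
                rec["group"],
                base / rec["edf_path"],
                base / rec["hypnogram_path"],
            )
        )
    return out


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> ReportBundle:
    """Execute the full analysis; write reports under ``outdir`` if given."""
    outdir = Path(outdir) if outdir is not None else None
    if config.manifest is not None:
        manifest_path = Path(config.manifest)
    else:
        if outdir is None:
            raise ValidationError("synthetic runs need an output directory for fixtures")
        stage = "synthesis"
        try:
            cohort = generate_cohort(config.synthetic)
            paths = write_fixture(cohort, outdir / "fixtures")
        except Exception as exc:
            raise DataFormatError(f"stage {stage} failed: {exc}") from exc
        manifest_path = paths["manifest"]

    subjects = _load_cohort_files(manifest_path)

    epochs_by_channel: Dict[str, List[RemEpoch]] = {ch: [] for ch in config.channels}
    per_subject_counts: Dict[str, Tuple[str, int]] = {}
    for subject_id, group, edf_path, hyp_path in subjects:
        try:
            rec = read_recording(edf_path, subject_id=subject_id)
            hyp = read_hypnogram(hyp_path)
        except Exception as exc:
            raise DataFormatError(
                f"stage reading failed for subject {subject_id!r}: {exc}"
            ) from exc
        for ch in config.channels:
            eps = extract_rem_epochs(rec, hyp, ch, group)
            epochs_by_channel[ch].extend(eps)
            if ch == config.channels[0]:
                per_subject_counts[subject_id] = (group, len(eps))
    accounting = accounting_from_counts(per_subject_counts)

    features: Dict[str, pd.DataFrame] = {}
    significance: Dict[str, pd.DataFrame] = {}
    cv: Dict[str, CVMetrics] = {}
    exclusions: List[dict] = []
    metric_rows = []
    for ch in config.channels:
        table, excluded = feature_table(epochs_by_channel[ch], config.features)
        exclusions.extend(excluded)
        features[ch] = table
        by_group = {
            g: table[table["group"] == g]
            for g in (config.control_group, config.positive_group)
        }
        for g, df in by_group.items():
            if len(df) < 2:
                raise ValidationError(
                    f"stage statistics: group {g!r} has {len(df)} epochs on {ch}"
                )
        significance[ch] = compare_groups(
            by_group, policy=config.stats_policy, channel=ch
        )
        X = table[list(FEATURE_NAMES)].to_numpy(dtype=float)
        y = (table["group"] == config.positive_group).to_numpy(dtype=np.int64)
        m = cv_evaluate(X, y, config.tree, k=config.k, seed=config.seed)
        cv[ch] = m
        metric_rows.append(
            {
                "channel": ch,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "accuracy": m.accuracy,
                "ppv": m.ppv,
                "tp": m.confusion[0],
                "fp": m.confusion[1],
                "tn": m.confusion[2],
                "fn": m.confusion[3],
            }
        )
    metrics = pd.DataFrame(metric_rows)
    ranking = channel_ranking(metrics)
    summary = rpsd_group_summary(pd.concat(features.values(), ignore_index=True))

    run_log = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "epoch_counts": {
            s: {"group": g, "epochs": c} for s, (g, c) in per_subject_counts.items()
        },
        "total_epochs_per_channel": int(
            accounting.loc[accounting["subject"] == "total", "epoch_count"].iloc[0]
        ),
        "exclusions": exclusions,
    }

    bundle = ReportBundle(
        accounting=accounting,
        features=features,
        significance=significance,
        rpsd_summary=summary,
        metrics=metrics,
        ranking=ranking,
        cv=cv,
        run_log=run_log,
        outdir=outdir,
    )
    if outdir is not None:
        _write_reports(bundle, outdir)
    return bundle


def _write_reports(bundle: ReportBundle, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.accounting.to_csv(outdir / "accounting.csv", index=False)
    for ch, df in bundle.features.items():
        df.to_csv(outdir / f"features_{ch}.csv", index=False)
    for ch, df in bundle.significance.items():
        df.to_csv(outdir / f"significance_{ch}.csv", index=False)
    bundle.rpsd_summary.to_csv(outdir / "rpsd_summary.csv", index=False)
    bundle.metrics.to_csv(outdir / "metrics.csv", index=False)
    bundle.ranking.to_csv(outdir / "ranking.csv", index=False)
    (outdir / "run_log.json").write_text(
        json.dumps(bundle.run_log, indent=2, default=str) + "\n", encoding="utf-8"
    )


def channel_ranking(metrics: pd.DataFrame) -> pd.DataFrame:
    """Channels by accuracy descending; ties break on PPV descending."""
    if len(metrics) == 0:
        raise ValidationError("no channel metrics to rank")
    ranked = metrics.sort_values(
        ["accuracy", "ppv"], ascending=[False, False], kind="mergesort"
    ).reset_index(drop=True)
    ranked.insert(0, "rank", np.arange(1, len(ranked) + 1))
    ranked["top"] = ranked["rank"] == 1
    return ranked
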