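"""Self-contained rehearsal experiments on synthetic cohorts.

Two canned studies used for validation and reporting:

* :func:`recovery_experiment` — two groups whose relative-band-power
  profiles are set to the reported group means (delta/theta/alpha/beta
  healthy 65.26/20.619/8.424/5.696%, bruxism 65.302/17.480/9.931/7.287%,
  with the bruxism group at higher total power). The full pipeline runs on
  the generated cohort and the experiment reports how closely the group-mean
  RPSD estimates recover the targets, whether the theta/alpha/beta contrasts
  are flagged significant in the expected directions, and the fine-tree CV
  metrics.

* :func:`null_experiment` — both groups share one profile, so every feature
  difference is noise: the starred-feature fraction should sit near the
  test's alpha level and CV accuracy near the majority-class rate.

Sizes default to 100 epochs/group (recovery) and 30 epochs/group over three
seeds (null) on the C4P4 channel: large enough for stable group means,
small enough to run on a laptop in minutes.
"""

from __future__ import annotations

import tempfile
from pathlib import Path
from typing import Dict, Optional

import numpy as np

from .pipeline import PipelineConfig, run_pipeline
from .synth import CohortSpec, profile_from_rpsd

#: Reported group-mean relative band powers (percent) used as recovery targets.
RPSD_TARGETS: Dict[str, Dict[str, float]] = {
    "healthy": {"delta": 65.26, "theta": 20.619, "alpha": 8.424, "beta": 5.696},
    "bruxism": {"delta": 65.302, "theta": 17.480, "alpha": 9.931, "beta": 7.287},
}

#: Group total signal SDs (mV): the bruxism group carries more total power so
#: its theta/alpha/beta band SDs exceed the healthy group's.
TOTAL_SD = {"healthy": 10.0, "bruxism": 11.5}

#: Directions of the significant relative-power contrasts: -1 means lower in
#: the bruxism group, +1 higher.
EXPECTED_DIRECTIONS = {"rpsd_theta": -1, "rpsd_alpha": +1, "rpsd_beta": +1}


def _profiles(identical: bool = False):
    healthy = profile_from_rpsd(
        RPSD_TARGETS["healthy"], TOTAL_SD["healthy"], drift_amp=2.0, hf_amp=0.5
    )
    if identical:
        return {"healthy": healthy, "bruxism": healthy}
    bruxism = profile_from_rpsd(
        RPSD_TARGETS["bruxism"], TOTAL_SD["bruxism"], drift_amp=2.0, hf_amp=0.5
    )
    return {"healthy": healthy, "bruxism": bruxism}


def _run(
    seed: int,
    epochs_per_subject: int,
    n_subjects: int,
    identical_profiles: bool,
    channel: str,
    k: int,
    outdir: Optional[Path],
) -> "remband.pipeline.ReportBundle":  # noqa: F821
    config = PipelineConfig(
        synthetic=CohortSpec(
            n_subjects_per_group=n_subjects,
            epochs_per_subject=epochs_per_subject,
            group_profiles=_profiles(identical=identical_profiles),
            seed=seed,
            channels=(channel,),
        ),
        channels=(channel,),
        k=k,
        seed=seed,
    )
    if outdir is None:
        with tempfile.TemporaryDirectory() as tmp:
            return run_pipeline(config, Path(tmp))
    return run_pipeline(config, outdir)


def recovery_experiment(
    seed: int = 0,
    epochs_per_group: int = 100,
    n_subjects: int = 2,
    channel: str = "C4P4",
    outdir: Optional[Path] = None,
) -> dict:
    """Run the pipeline on the two-profile cohort and score the recovery."""
    bundle = _run(
        seed,
        epochs_per_subject=epochs_per_group // n_subjects,
        n_subjects=n_subjects,
        identical_profiles=False,
        channel=channel,
        k=5,
        outdir=outdir,
    )
    feats = bundle.features[channel]
    errors = {}
    estimates = {}
    for group, targets in RPSD_TARGETS.items():
        sub = feats[feats["group"] == group]
        norm = 100.0 / sum(targets.values())
        estimates[group] = {
            b: float(sub[f"rpsd_{b}"].mean()) for b in ("delta", "theta", "alpha", "beta")
        }
        errors[group] = {
            b: estimates[group][b] - targets[b] * norm for b in estimates[group]
        }
    sig = bundle.significance[channel].set_index("feature")
    contrasts = {}
    for feat, direction in EXPECTED_DIRECTIONS.items():
        row = sig.loc[feat]
        observed = np.sign(row["bruxism_mean"] - row["healthy_mean"])
        contrasts[feat] = {
            "p_value": float(row["p_value"]),
            "starred": row["stars"] in ("*", "**"),
            "direction_ok": observed == direction,
        }
    cv = bundle.cv[channel]
    n_pos = int((feats["group"] == "bruxism").sum())
    majority = 100.0 * max(n_pos, len(feats) - n_pos) / len(feats)
    return {
        "estimates": estimates,
        "errors": errors,
        "max_abs_error": max(abs(e) for g in errors.values() for e in g.values()),
        "contrasts": contrasts,
        "cv_accuracy": cv.accuracy,
        "cv_sensitivity": cv.sensitivity,
        "cv_specificity": cv.specificity,
        "cv_ppv": cv.ppv,
        "majority_rate": majority,
        "n_epochs": int(len(feats)),
    }


def null_experiment(
    seed: int = 0,
    n_seeds: int = 3,
    epochs_per_group: int = 30,
    channel: str = "C4P4",
) -> dict:
    """Identical-profile cohorts across several seeds: false-positive audit."""
    starred = 0
    total = 0
    accuracies = []
    for i in range(n_seeds):
        bundle = _run(
            seed + 1000 * (i + 1),
            epochs_per_subject=epochs_per_group,
            n_subjects=1,
            identical_profiles=True,
            channel=channel,
            k=5,
            outdir=None,
        )
        sig = bundle.significance[channel]
        starred += int(sig["stars"].isin(["*", "**"]).sum())
        total += len(sig)
        accuracies.append(float(bundle.cv[channel].accuracy))
    return {
        "n_features_tested": total,
        "n_starred": starred,
        "starred_fraction": starred / total,
        "cv_accuracies": accuracies,
        "n_epochs_per_run": 2 * epochs_per_group,
    }
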