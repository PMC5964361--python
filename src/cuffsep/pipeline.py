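"""End-to-end experiment orchestration.

Three designs are supported, mirroring the in-vivo protocols the pipeline
is meant to analyse:

* ``exp1A`` — ten stimulus classes; 3-channel cuff distal, 16-channel cuff
  proximal; nociception epochs shortened to 1 s ON / 1 s OFF.
* ``exp1B`` — ten classes; cuff positions swapped (16-channel distal).
* ``exp2``  — six proprioceptive classes; 16-channel cuffs at both sites;
  2.5 s analysis windows.

One simulated session drives BOTH cuffs: they observe the same protocol and
the same fascicular source processes (shared source seed) with independent
per-contact noise, and are scored with a shared fold assignment so the
per-fold cuff difference is a paired comparison.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .classify import (
    ConfusionMatrix,
    confusion_difference,
    cross_validate,
    fold_difference,
    pair_search,
    stratified_folds,
)
from .features import build_feature_table, normalize_features
from .preprocess import (
    FilterSpec,
    apply_filter,
    design_bandpass_fir,
    detect_onsets_from_markers,
    extract_trial_windows,
    reject_noisy_trials,
)
from .synth import (
    build_cuff_layout,
    generate_protocol,
    make_site_model,
    proprioception_classes,
    synthesize_recording,
    ten_class_set,
)

__all__ = ["ExperimentConfig", "RunReport", "run_experiment", "make_figures"]

_DESIGNS = ("exp1A", "exp1B", "exp2")

#: cuff model assigned to each site, per design
_CUFF_ASSIGNMENT = {
    "exp1A": {"distal": "cuff3", "proximal": "cuff16"},
    "exp1B": {"distal": "cuff16", "proximal": "cuff3"},
    "exp2": {"distal": "cuff16", "proximal": "cuff16"},
}


@dataclass
class ExperimentConfig:
    """Full configuration of one simulated session + analysis run.

    Defaults reproduce the in-paper protocol scales (50 trials per class
    for exp1, 300 trials for exp2, 30 kHz sampling).  Tests and the
    acceptance suite pass scaled-down overrides (shorter epochs, lower fs,
    fewer repetitions) to stay within desk-scale budgets.
    """

    design: str = "exp2"
    fs: float = 30000.0
    on_s: float = 3.0
    off_s: float = 3.0
    noci_on_s: Optional[float] = None   # defaults: 1 s for exp1A, else on_s
    noci_off_s: Optional[float] = None
    reps_per_class_per_block: int = 10
    n_blocks: int = 5
    window_len_s: Optional[float] = None  # defaults: 0.5 (exp1), 2.5 (exp2)
    window_offset_s: float = 0.25
    filter_low: float = 800.0
    filter_high: float = 2200.0
    n_taps: int = 401
    n_folds: int = 5
    shrinkage: float = 0.05
    noise_sd: float = 0.01
    trial_jitter_sd: float = 0.15
    source_band: tuple = (300.0, 3000.0)
    k_mad: float = 8.0
    lead_in_s: float = 1.0
    sim_seed: int = 0
    fold_seed: int = 0
    run_pair_search: bool = True

    def __post_init__(self):
        if self.design not in _DESIGNS:
            raise ValueError(
                f"unknown design {self.design!r}; valid: {', '.join(_DESIGNS)}"
            )
        if self.window_len_s is None:
            self.window_len_s = 2.5 if self.design == "exp2" else 0.5
        if self.noci_on_s is None:
            self.noci_on_s = 1.0 if self.design == "exp1A" else self.on_s
        if self.noci_off_s is None:
            self.noci_off_s = 1.0 if self.design == "exp1A" else self.off_s
        self.validate()

    def validate(self) -> None:
        FilterSpec(self.filter_low, self.filter_high, self.fs, self.n_taps)
        min_on = min(c.on_duration for c in self.classes())
        if self.window_offset_s + self.window_len_s > min_on + 1e-9:
            raise ValueError(
                f"analysis window [{self.window_offset_s}, "
                f"{self.window_offset_s + self.window_len_s}] s does not fit "
                f"inside the shortest {min_on} s stimulus ON epoch"
            )

    def classes(self):
        if self.design == "exp2":
            return proprioception_classes(self.on_s, self.off_s)
        return ten_class_set(
            self.on_s, self.off_s, self.noci_on_s, self.noci_off_s
        )


@dataclass
class RunReport:
    """Everything needed to inspect or exactly rerun one session."""

    design: str
    config: dict
    cuffs: dict            # role ("distal"/"proximal") -> result payload
    fold_diff: list        # primary comparison, per fold
    fold_diff_median: float
    fold_diff_label: str
    confusion_diff: list   # row-normalised, primary comparison
    rejected_trials: list
    n_trials: int
    version: str = field(default=__version__)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(asdict(self), indent=indent, sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "RunReport":
        return cls(**json.loads(Path(path).read_text()))


def _analyse_cuff(rec, cfg: ExperimentConfig, on_durations):
    """Filter + segment one cuff recording; returns candidate trial windows."""
    taps = design_bandpass_fir(
        FilterSpec(cfg.filter_low, cfg.filter_high, cfg.fs, cfg.n_taps)
    )
    filtered = apply_filter(rec, taps)
    onsets = detect_onsets_from_markers(filtered)
    return extract_trial_windows(
        filtered, onsets, cfg.window_offset_s, cfg.window_len_s,
        on_durations=on_durations,
    )


def run_experiment(config: ExperimentConfig) -> RunReport:
    """Simulate one session and run the full analysis for both cuffs."""
    classes = config.classes()
    protocol = generate_protocol(
        classes,
        reps_per_class_per_block=config.reps_per_class_per_block,
        n_blocks=config.n_blocks,
        seed=config.sim_seed,
    )
    on_durations = {c.class_id: c.on_duration for c in classes}
    roles = ("distal", "proximal")

    windows = {}
    for k, role in enumerate(roles):
        layout = build_cuff_layout(_CUFF_ASSIGNMENT[config.design][role])
        site = make_site_model(role, classes)
        rec = synthesize_recording(
            protocol, layout, site,
            noise_sd=config.noise_sd,
            fs=config.fs,
            seed=config.sim_seed,                       # shared sources
            noise_seed=config.sim_seed * 2 + 10_007 + k,  # independent noise
            lead_in=config.lead_in_s,
            source_band=tuple(config.source_band),
            trial_jitter_sd=config.trial_jitter_sd,
        )
        windows[role] = _analyse_cuff(rec, config, on_durations)

    # Trials are aligned across cuffs (same protocol, marker-based
    # segmentation); reject the union of per-cuff noisy trials so both
    # feature tables keep identical trial sets for the paired comparison.
    rejected: set[int] = set()
    for role in roles:
        _, bad = reject_noisy_trials(
            windows[role], k_mad=config.k_mad, by_class=True
        )
        rejected.update(bad)
    # rejection must not starve any class below the fold count; if it
    # would, keep that class's trials instead
    by_class: dict[int, set[int]] = {}
    for w in windows[roles[0]]:
        by_class.setdefault(w.class_id, set()).add(w.trial_id)
    for cid, ids in by_class.items():
        if len(ids - rejected) < config.n_folds:
            rejected -= ids
    kept = {
        role: [w for w in ws if w.trial_id not in rejected]
        for role, ws in windows.items()
    }

    tables = {role: build_feature_table(kept[role]) for role in roles}
    labels = tables["distal"].labels
    folds = stratified_folds(labels, k=config.n_folds, seed=config.fold_seed)

    cuffs = {}
    results = {}
    for role in roles:
        table = tables[role]
        res = cross_validate(table, folds, shrinkage=config.shrinkage)
        results[role] = res
        payload = {
            "layout": _CUFF_ASSIGNMENT[config.design][role],
            "site": role,
            "n_channels": table.n_channels,
            "fold_scores": res.fold_scores.tolist(),
            "median_score": res.median_score,
            "confusion_counts": res.confusion.counts.tolist(),
            "class_ids": res.confusion.class_ids.tolist(),
        }
        if config.run_pair_search:
            ranking = pair_search(table, folds, shrinkage=config.shrinkage)
            best_pair, best_score = ranking[0]
            norm = normalize_features(table)
            idx = [
                int(np.flatnonzero(table.channel_ids == ch)[0])
                for ch in best_pair
            ]
            payload.update(
                best_pair=list(best_pair),
                best_pair_score=best_score,
                n_pairs_evaluated=len(ranking),
                pair_ranking_top5=[
                    {"pair": list(p), "mean_score": s}
                    for p, s in ranking[:5]
                ],
                scatter={
                    "x": norm.values[:, idx[0]].tolist(),
                    "y": norm.values[:, idx[1]].tolist(),
                    "labels": norm.labels.tolist(),
                },
            )
        cuffs[role] = payload

    # primary comparison: 16 vs 3 channels for exp1, distal vs proximal
    # for exp2 (identical cuffs at the two sites)
    if config.design == "exp2":
        a_role, b_role = "distal", "proximal"
        diff_label = "distal_minus_proximal"
    else:
        by_layout = {cuffs[r]["layout"]: r for r in roles}
        a_role, b_role = by_layout["cuff16"], by_layout["cuff3"]
        diff_label = "cuff16_minus_cuff3"
    diff, diff_median = fold_difference(results[a_role], results[b_role])
    cdiff = confusion_difference(
        results[a_role].confusion, results[b_role].confusion,
        row_normalise=True,
    )

    return RunReport(
        design=config.design,
        config=asdict(config),
        cuffs=cuffs,
        fold_diff=diff.tolist(),
        fold_diff_median=diff_median,
        fold_diff_label=diff_label,
        confusion_diff=cdiff.tolist(),
        rejected_trials=sorted(rejected),
        n_trials=int(tables["distal"].n_trials),
    )


def make_figures(report: RunReport, out_dir: str | Path) -> list[Path]:
    """Write the four summary figures for a run report.

    Box plots of fold scores, best-pair normalised-MAV scatters, pooled
    confusion heatmaps and the row-normalised confusion difference.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    roles = list(report.cuffs)
    paths = []

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.boxplot(
        [report.cuffs[r]["fold_scores"] for r in roles],
        tick_labels=[f"{r}\n({report.cuffs[r]['layout']})" for r in roles],
    )
    ax.set_ylabel("balanced accuracy (%)")
    ax.set_title(f"{report.design}: fold scores")
    paths.append(out_dir / "fold_scores.png")
    fig.savefig(paths[-1], dpi=120, bbox_inches="tight")
    plt.close(fig)

    if all("scatter" in report.cuffs[r] for r in roles):
        fig, axes = plt.subplots(1, len(roles), figsize=(5 * len(roles), 4))
        axes = np.atleast_1d(axes)
        for ax, r in zip(axes, roles):
            sc = report.cuffs[r]["scatter"]
            labels = np.asarray(sc["labels"])
            for cid in np.unique(labels):
                m = labels == cid
                ax.scatter(
                    np.asarray(sc["x"])[m], np.asarray(sc["y"])[m],
                    s=12, label=str(cid),
                )
            pair = report.cuffs[r]["best_pair"]
            ax.set_xlabel(f"normalised MAV ch{pair[0]}")
            ax.set_ylabel(f"normalised MAV ch{pair[1]}")
            ax.set_title(f"{r} ({report.cuffs[r]['layout']})")
            ax.set_xlim(-0.05, 1.05)
            ax.set_ylim(-0.05, 1.05)
        axes[-1].legend(fontsize=7, title="class")
        paths.append(out_dir / "best_pair_scatter.png")
        fig.savefig(paths[-1], dpi=120, bbox_inches="tight")
        plt.close(fig)

    fig, axes = plt.subplots(1, len(roles), figsize=(5 * len(roles), 4))
    axes = np.atleast_1d(axes)
    for ax, r in zip(axes, roles):
        cm = np.asarray(report.cuffs[r]["confusion_counts"], dtype=float)
        cm = cm / cm.sum(axis=1, keepdims=True)
        im = ax.imshow(cm, vmin=0, vmax=1, cmap="viridis")
        ax.set_title(f"{r} ({report.cuffs[r]['layout']})")
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        fig.colorbar(im, ax=ax, shrink=0.8)
    paths.append(out_dir / "confusion.png")
    fig.savefig(paths[-1], dpi=120, bbox_inches="tight")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    cd = np.asarray(report.confusion_diff)
    lim = max(abs(cd).max(), 1e-9)
    im = ax.imshow(cd, vmin=-lim, vmax=lim, cmap="coolwarm")
    ax.set_title(f"confusion difference ({report.fold_diff_label})")
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    fig.colorbar(im, ax=ax, shrink=0.8)
    paths.append(out_dir / "confusion_difference.png")
    fig.savefig(paths[-1], dpi=120, bbox_inches="tight")
    plt.close(fig)

    return paths
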