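"""End-to-end experiment orchestration.

``run_experiment`` drives the whole synthetic pipeline from one config:
per subject simulate -> preprocess -> decode (three schemes) -> smooth, then
for each analysis family {across groups, musicians, non-musicians} x
{all_all, full_to_f0, full_to_timbre} a TFCE sign-flip permutation test and
cluster summary — the 3 x 3 analysis grid.  All artifacts are written as TSV
plus a JSON manifest carrying the config hash and every seed, so a rerun
with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as edio
from .decoding import SCHEMES, AccuracyTimecourse, smooth_timecourse, \
    time_resolved_decode
from .design import Subject, build_cohort, build_stimulus_design, \
    build_trial_table
from .preprocessing import PreprocessConfig, preprocess, segment_epochs
from .simulate import EpochedEEG, SimulationConfig, simulate_subject_eeg
from .stats import ClusterStatResult, StatConfig, permutation_test_timecourses

log = logging.getLogger("emodecode")

POPULATIONS = ("across", "musician", "non_musician")


@dataclass(frozen=True)
class ExperimentConfig:
    simulation: SimulationConfig = SimulationConfig()
    preprocess: PreprocessConfig = PreprocessConfig()
    stats: StatConfig = StatConfig()
    schemes: tuple[str, ...] = ("all_all", "full_to_f0", "full_to_timbre")
    n_musicians: int = 38
    n_non_musicians: int = 39
    n_speakers: int = 8
    n_words: int = 3
    n_reps: int = 2
    n_blocks: int = 8
    prompt_rate: float = 0.10
    smoothing_window: int = 5
    include_baseline: bool = False

    def validate(self) -> None:
        self.simulation.validate()
        self.preprocess.validate()
        self.stats.validate()
        for name in self.schemes:
            if name not in SCHEMES:
                raise ValueError(f"unknown scheme {name!r}")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be odd and >= 1")


def config_from_dict(raw: dict) -> ExperimentConfig:
    """Build an ExperimentConfig from a (YAML-loaded) nested mapping,
    filling every omitted field with its default."""
    from .simulate import EffectSpec

    def sub(cls, key):
        args = dict(raw.get(key) or {})
        if cls is SimulationConfig and "effects" in args:
            args["effects"] = tuple(
                EffectSpec(**{**e, "window_ms": tuple(e.get("window_ms",
                                                            (500.0, 900.0)))})
                for e in args["effects"]
            )
        for tup in ("epoch_window", "baseline_window"):
            if tup in args:
                args[tup] = tuple(args[tup])
        if "emotions" in args:
            args["emotions"] = tuple(args["emotions"])
        if "drop_labels" in args:
            args["drop_labels"] = tuple(args["drop_labels"])
        return cls(**args)

    top = {k: v for k, v in raw.items()
           if k not in ("simulation", "preprocess", "stats")}
    if "schemes" in top:
        top["schemes"] = tuple(top["schemes"])
    cfg = ExperimentConfig(
        simulation=sub(SimulationConfig, "simulation"),
        preprocess=sub(PreprocessConfig, "preprocess"),
        stats=sub(StatConfig, "stats"),
        **top,
    )
    cfg.validate()
    return cfg


def simulate_cohort(config: ExperimentConfig):
    """Yield (subject, preprocessed EpochedEEG) for the whole cohort."""
    design = build_stimulus_design(config.n_speakers, config.n_words,
                                   config.simulation.emotions)
    cohort = build_cohort(config.n_musicians, config.n_non_musicians,
                          config.simulation.master_seed)
    for subject in cohort:
        trials = build_trial_table(
            design, config.n_reps, config.n_blocks, config.prompt_rate,
            seed=np.random.SeedSequence(
                [int(config.simulation.master_seed), int(subject.seed), 1]),
        )
        raw = simulate_subject_eeg(trials, design, subject, config.simulation)
        yield subject, preprocess(raw, config.preprocess)


def decode_subject(eeg: EpochedEEG, config: ExperimentConfig
                   ) -> dict[str, AccuracyTimecourse]:
    """Smoothed accuracy timecourses for every configured scheme."""
    out = {}
    for name in config.schemes:
        tc = time_resolved_decode(eeg, name,
                                  include_baseline=config.include_baseline)
        out[name] = smooth_timecourse(tc, config.smoothing_window)
    return out


def _population_mask(groups: np.ndarray, population: str) -> np.ndarray:
    if population == "across":
        return np.ones(len(groups), dtype=bool)
    return groups == population


def run_group_stats(timecourses: list[AccuracyTimecourse],
                    config: ExperimentConfig
                    ) -> dict[tuple[str, str], ClusterStatResult]:
    """The 3 x 3 grid: each population x scheme analysis is corrected
    separately (its own permutation null)."""
    results = {}
    for scheme in config.schemes:
        tcs = [tc for tc in timecourses if tc.scheme == scheme]
        groups = np.array([tc.group for tc in tcs])
        times = tcs[0].times
        curves = np.vstack([tc.accuracy for tc in tcs])
        for population in POPULATIONS:
            mask = _population_mask(groups, population)
            if mask.sum() < 2:
                log.warning("population %s has <2 subjects; skipped",
                            population)
                continue
            res = permutation_test_timecourses(curves[mask], times,
                                               config.stats)
            results[(population, scheme)] = res
    return results


def write_stat_result(res: ClusterStatResult, outdir: Path,
                      population: str, scheme: str) -> None:
    stem = f"{population}__{scheme}"
    per_tp = pd.DataFrame(
        {
            "time_ms": res.times,
            "mean_accuracy": res.group_mean_accuracy,
            "t": res.t_map,
            "tfce": res.tfce_map,
            "p_corrected": res.p_corrected,
            "significant": res.sig_mask,
        }
    )
    edio.write_table(per_tp, outdir / f"map__{stem}.tsv")
    edio.write_table(res.clusters, outdir / f"clusters__{stem}.tsv")
    with open(outdir / f"statcfg__{stem}.json", "w") as f:
        json.dump(
            {**dataclasses.asdict(res.config), "n_subjects": res.n_subjects},
            f, indent=2, sort_keys=True,
        )


def run_experiment(config: ExperimentConfig, outdir: str | Path
                   ) -> dict:
    """Simulate, preprocess, decode, smooth, and test the full cohort.

    Writes per-subject accuracy TSVs, nine per-analysis map/cluster TSVs,
    and a manifest with the config hash and all seeds.  Returns the result
    bundle (timecourses + stat results) for further use in-process.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = edio.config_hash(config)
    log.info("experiment start: config hash %s", chash)

    timecourses: list[AccuracyTimecourse] = []
    seeds: dict[str, int] = {}
    subject = None
    try:
        for subject, eeg in simulate_cohort(config):
            seeds[subject.subject_id] = subject.seed
            log.info("subject %s (%s): %d trials", subject.subject_id,
                     subject.group, eeg.n_trials)
            for tc in decode_subject(eeg, config).values():
                timecourses.append(tc)
    except Exception as err:
        marker = {"failed_at": "decode",
                  "subject": getattr(subject, "subject_id", None),
                  "error": str(err)}
        with open(outdir / "FAILED.json", "w") as f:
            json.dump(marker, f, indent=2)
        raise RuntimeError(
            f"stage 'decode' failed for subject "
            f"{getattr(subject, 'subject_id', '?')}: {err}") from err

    acc = pd.concat([tc.to_frame() for tc in timecourses], ignore_index=True)
    edio.write_table(acc, outdir / "accuracy_timecourses.tsv")

    results = run_group_stats(timecourses, config)
    for (population, scheme), res in results.items():
        write_stat_result(res, outdir, population, scheme)

    manifest = {
        "config_hash": chash,
        "master_seed": config.simulation.master_seed,
        "subject_seeds": seeds,
        "schemes": list(config.schemes),
        "n_analyses": len(results),
    }
    with open(outdir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)
    edio.save_config(config, outdir / "config.yaml")
    log.info("experiment done: %d analyses", len(results))
    return {"timecourses": timecourses, "stats": results,
            "manifest": manifest, "outdir": outdir}


# ------------------------------------------------------------------ plotting

def plot_results(bundle: dict, outdir: str | Path | None = None,
                 formats: tuple[str, ...] = ("pdf", "png")) -> list[Path]:
    """Accuracy-vs-time panels per scheme: across-group curve on the left,
    the two groups on the right; chance line at 0.25, a 95% CI band across
    subjects, and dots above the curve at significant timepoints."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir) if outdir is not None else Path(bundle["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    timecourses = bundle["timecourses"]
    results = bundle["stats"]
    schemes = sorted({tc.scheme for tc in timecourses},
                     key=lambda s: list(SCHEMES).index(s))

    fig, axes = plt.subplots(len(schemes), 2,
                             figsize=(10, 2.8 * len(schemes)),
                             squeeze=False, sharex=True, sharey=True)
    colors = {"across": "k", "musician": "tab:blue",
              "non_musician": "tab:orange"}
    for r, scheme in enumerate(schemes):
        tcs = [tc for tc in timecourses if tc.scheme == scheme]
        groups = np.array([tc.group for tc in tcs])
        times = tcs[0].times
        curves = np.vstack([tc.accuracy for tc in tcs])
        for c, pops in enumerate([("across",), ("musician", "non_musician")]):
            ax = axes[r, c]
            ax.axhline(0.25, color="gray", ls=":", lw=1, label="chance")
            for j, pop in enumerate(pops):
                mask = _population_mask(groups, pop)
                if not mask.any():
                    continue
                mean = curves[mask].mean(axis=0)
                sem = curves[mask].std(axis=0, ddof=1) / np.sqrt(mask.sum())
                ax.plot(times, mean, color=colors[pop], lw=1.2, label=pop)
                ax.fill_between(times, mean - 1.96 * sem, mean + 1.96 * sem,
                                color=colors[pop], alpha=0.2, lw=0)
                res = results.get((pop, scheme))
                if res is None:
                    log.warning("analysis (%s, %s) missing; skipped",
                                pop, scheme)
                    continue
                sig = res.sig_mask
                if sig.any():
                    y = mean.max() + 0.01 * (1 + j)
                    ax.plot(res.times[sig], np.full(sig.sum(), y), ".",
                            color=colors[pop], ms=4)
            ax.set_title(f"{scheme} — {'across groups' if c == 0 else 'by group'}",
                         fontsize=9)
            ax.set_ylabel("accuracy")
            ax.legend(fontsize=7, frameon=False)
    for ax in axes[-1]:
        ax.set_xlabel("time (ms)")
    fig.tight_layout()

    paths = []
    for fmt in formats:
        p = outdir / f"decoding_results.{fmt}"
        fig.savefig(p, dpi=150)
        paths.append(p)
    plt.close(fig)
    return paths


# ---------------------------------------------------------------- real data

def load_real_dataset(manifest_path: str | Path):
    """Yield (Subject, EpochedEEG) from a TSV manifest of recorded files.

    Manifest columns: ``subject``, ``group``, ``file`` (EDF/BDF path,
    relative to the manifest), ``events`` (TSV sidecar with an ``onset_ms``
    column).  Epochs are cut on the default -200..1000 ms window and routed
    into the same pipeline as synthetic subjects.
    """
    manifest_path = Path(manifest_path)
    manifest = edio.read_table(manifest_path)
    required = {"subject", "group", "file", "events"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    base = manifest_path.parent
    for i, row in manifest.iterrows():
        if row.isna().any():
            raise ValueError(f"manifest row {i}: missing values")
        fpath = base / str(row["file"])
        if not fpath.exists():
            raise FileNotFoundError(f"manifest row {i}: no such file {fpath}")
        data, rate, labels = edio.read_raw_edf(fpath)
        events = edio.read_table(base / str(row["events"]))
        if "onset_ms" not in events.columns:
            raise ValueError(f"manifest row {i}: events file lacks onset_ms")
        eeg = segment_epochs(data, rate, labels,
                             events["onset_ms"].to_numpy(),
                             trial_meta=events)
        eeg.subject_id = str(row["subject"])
        eeg.group = str(row["group"])
        yield Subject(str(row["subject"]), str(row["group"]), 0), eeg
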