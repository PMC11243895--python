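"""End-to-end study-replica pipeline.

Orchestrates the full analysis: simulate (or ingest) the cohort, cut each
recording into overlapping 2-minute windows, assign consensus labels, drop
discordant windows, extract the 20 HRV features, compare alert vs fatigued
per group, and run the exhaustive CART subset searches.  Every stage reads
and writes plain delimited text so stages can also be run independently
through the CLI.  Identical configuration and seed reproduce byte-identical
artifacts.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, ingest, stats, synthetic, windows
from .features import FEATURE_NAMES, SpectralConfig, extract_features
from .synthetic import CohortConfig

__all__ = ["PipelineConfig", "RunReport", "validate_config", "run_pipeline",
           "features_from_recordings", "load_recordings"]

logger = logging.getLogger("hrvfatigue")

_FLOAT_FMT = "%.10g"

_KNOWN_KEYS = {
    "mode", "seed", "out_dir", "input_dir", "window_s", "step_s", "alpha",
    "test_fraction", "min_samples", "subset_sizes", "groups", "cohort",
    "spectral", "write_ecg", "ecg_fs", "subject_wise_split", "sex_specific",
}
_COHORT_KEYS = {"n_male", "n_female", "duration_s", "fatigue_onset_s",
                "rater_error_rate"}
_SPECTRAL_KEYS = {"resample_hz", "detrend", "vlf_band", "lf_band", "hf_band",
                  "window_s", "overlap_fraction"}


@dataclass
class PipelineConfig:
    mode: str = "synthetic"            # synthetic | rr | ecg
    seed: int = 0
    out_dir: str = "hrvfatigue_out"
    input_dir: str | None = None       # rr/ecg modes
    window_s: float = 120.0
    step_s: float = 60.0
    alpha: float = 0.01
    test_fraction: float = 0.2
    min_samples: int = 5
    subset_sizes: tuple[int, ...] = (2, 3, 4)
    groups: tuple[str, ...] = ("all", "male", "female")
    cohort: CohortConfig = field(default_factory=CohortConfig)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    sex_specific: bool = True
    subject_wise_split: bool = False
    write_ecg: bool = False
    ecg_fs: float = 1000.0

    def __post_init__(self):
        if self.mode not in ("synthetic", "rr", "ecg"):
            raise ValueError(f"mode must be synthetic/rr/ecg, got {self.mode!r}")
        if self.mode != "synthetic" and not self.input_dir:
            raise ValueError(f"mode={self.mode!r} requires input_dir")
        if not 0 < self.step_s <= self.window_s:
            raise ValueError("constraint violated: 0 < step_s <= window_s")
        if not 0 < self.alpha < 1:
            raise ValueError("constraint violated: 0 < alpha < 1")
        if not 0 < self.test_fraction < 1:
            raise ValueError("constraint violated: 0 < test_fraction < 1")
        if self.min_samples < 2:
            raise ValueError("constraint violated: min_samples >= 2")
        for k in self.subset_sizes:
            if not 1 <= int(k) <= len(FEATURE_NAMES):
                raise ValueError(f"constraint violated: subset size {k} not in 1..20")
        for g in self.groups:
            if g not in ("all", "male", "female"):
                raise ValueError(f"unknown group {g!r}")


@dataclass
class RunReport:
    """Artifacts and headline numbers of one pipeline run."""

    out_dir: Path
    segment_counts: dict
    n_segments_per_subject: int
    features_path: Path
    comparison_paths: dict
    direction_summary_path: Path | None
    subset_search_paths: dict
    n_significant: dict
    best_subsets: dict        # (group, k) -> dict(subset, SEN, SPE, PPV, ACC)
    config_echo_path: Path


def validate_config(path) -> PipelineConfig:
    """Load a YAML config, fill defaults, and check cross-field constraints."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = dict(raw)
    if "cohort" in kwargs:
        c = kwargs.pop("cohort") or {}
        unknown = set(c) - _COHORT_KEYS
        if unknown:
            raise ValueError(f"unknown cohort keys: {sorted(unknown)}")
        if "fatigue_onset_s" in c and isinstance(c["fatigue_onset_s"], list):
            c["fatigue_onset_s"] = tuple(c["fatigue_onset_s"])
        kwargs["cohort"] = CohortConfig(seed=int(raw.get("seed", 0)), **c)
    if "spectral" in kwargs:
        s = kwargs.pop("spectral") or {}
        unknown = set(s) - _SPECTRAL_KEYS
        if unknown:
            raise ValueError(f"unknown spectral keys: {sorted(unknown)}")
        for b in ("vlf_band", "lf_band", "hf_band"):
            if b in s:
                s[b] = tuple(s[b])
        kwargs["spectral"] = SpectralConfig(**s)
    if "subset_sizes" in kwargs:
        kwargs["subset_sizes"] = tuple(int(k) for k in kwargs["subset_sizes"])
    if "groups" in kwargs:
        kwargs["groups"] = tuple(kwargs["groups"])
    cfg = PipelineConfig(**kwargs)
    if "cohort" not in raw:
        cfg.cohort = CohortConfig(seed=cfg.seed)
    return cfg


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def load_recordings(config: PipelineConfig) -> list[synthetic.SubjectRecording]:
    """Simulate the cohort or ingest RR/ECG files plus vote tables.

    In ``rr``/``ecg`` modes, ``input_dir`` holds per-subject files named
    ``<id>_<sex>.rr.tsv`` / ``<id>_<sex>.ecg.txt`` (with sidecar header)
    and matching ``<id>_<sex>.votes.tsv`` tables.
    """
    if config.mode == "synthetic":
        cohort = CohortConfig(
            n_male=config.cohort.n_male,
            n_female=config.cohort.n_female,
            duration_s=config.cohort.duration_s,
            fatigue_onset_s=config.cohort.fatigue_onset_s,
            rater_error_rate=config.cohort.rater_error_rate,
            seed=config.seed,
        )
        return synthetic.generate_cohort(cohort, sex_specific=config.sex_specific)
    in_dir = Path(config.input_dir)
    suffix = ".rr.tsv" if config.mode == "rr" else ".ecg.txt"
    paths = sorted(in_dir.glob(f"*{suffix}"))
    if not paths:
        raise FileNotFoundError(f"no {suffix} files in {in_dir}")
    recordings = []
    for p in paths:
        stem = p.name[: -len(suffix)]
        subject_id, _, sex = stem.rpartition("_")
        if config.mode == "rr":
            rr = ingest.read_rr(p)
        else:
            record = ingest.read_ecg(p, fs=config.ecg_fs)
            peaks = ingest.detect_r_peaks(record)
            rr = ingest.rr_from_peaks(peaks)
        votes = synthetic.read_votes(in_dir / f"{stem}.votes.tsv")
        recordings.append(
            synthetic.SubjectRecording(
                subject_id=subject_id, sex=sex, rr=rr, fatigue_onset_s=float("nan"),
                truth_minutes=(), votes=votes,
            )
        )
    return recordings


def features_from_recordings(
    recordings,
    window_s: float = 120.0,
    step_s: float = 60.0,
    spectral: SpectralConfig | None = None,
    duration_s: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Window, label, filter, and extract features for every subject.

    Returns ``(features, segment_table)``: one feature row per retained
    (alert/fatigued) segment, and the full per-segment label table.
    """
    feat_rows, seg_rows = [], []
    for rec in recordings:
        dur = duration_s if duration_s is not None else rec.rr.duration_s
        segs = windows.segment_recording(
            rec.rr, dur, window_s, step_s, subject_id=rec.subject_id, sex=rec.sex
        )
        segs = windows.label_segments(segs, rec.votes)
        for seg in segs:
            seg_rows.append({
                "subject_id": seg.subject_id, "sex": seg.sex,
                "window_index": seg.window_index, "start_s": seg.start_s,
                "label": seg.label, "n_beats": seg.n_beats,
            })
        for seg in windows.filter_discordant(segs):
            fv = extract_features(seg, spectral)
            row = {
                "subject_id": seg.subject_id, "sex": seg.sex,
                "window_index": seg.window_index, "start_s": seg.start_s,
                "label": seg.label,
            }
            row.update(fv.to_dict())
            feat_rows.append(row)
    features = pd.DataFrame(feat_rows)
    segments = pd.DataFrame(seg_rows)
    return features, segments


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages and write report artifacts under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    echo_path = out / "config_echo.yaml"
    echo_path.write_text(yaml.safe_dump(asdict(config), sort_keys=True))

    logger.info("stage simulate/ingest: mode=%s", config.mode)
    recordings = load_recordings(config)
    logger.info("loaded %d recordings in %.1f s", len(recordings), time.time() - t0)
    if config.mode == "synthetic":
        for rec in recordings:
            ingest.write_rr(rec.rr, out / f"{rec.subject_id}_{rec.sex}.rr.tsv")
            synthetic.write_votes(rec.votes, out / f"{rec.subject_id}_{rec.sex}.votes.tsv")
            if config.write_ecg:
                ecg = synthetic.generate_ecg(
                    rec.rr, fs=config.ecg_fs, subject_id=rec.subject_id, sex=rec.sex
                )
                ingest.write_ecg(ecg, out / f"{rec.subject_id}_{rec.sex}.ecg.txt")

    t1 = time.time()
    duration = config.cohort.duration_s if config.mode == "synthetic" else None
    features, segments = features_from_recordings(
        recordings, config.window_s, config.step_s, config.spectral, duration
    )
    n_per_subject = (
        int(segments.groupby("subject_id").size().iloc[0]) if len(segments) else 0
    )
    seg_counts = {
        str(k): int(v) for k, v in segments.groupby("label").size().items()
    }
    logger.info(
        "stage features: %d segments (%s), %d feature rows, %.1f s",
        len(segments), seg_counts, len(features), time.time() - t1,
    )
    seg_path = out / "segments.tsv"
    segments.to_csv(seg_path, sep="\t", index=False, float_format=_FLOAT_FMT)
    feat_path = out / "features.tsv"
    features.to_csv(feat_path, sep="\t", index=False, float_format=_FLOAT_FMT)

    comparison_paths, n_sig, tables = {}, {}, {}
    for group in config.groups:
        try:
            table = stats.compare_states(features, group=group, alpha=config.alpha)
        except ValueError as exc:
            logger.warning("skipping comparison for group %s: %s", group, exc)
            continue
        path = out / f"compare_{group}.tsv"
        table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
        comparison_paths[group] = path
        tables[group] = table
        n_sig[group] = int(table["significant"].sum())
        logger.info("group %s: %d/%d features significant at alpha=%g",
                    group, n_sig[group], len(table), config.alpha)
    direction_path = None
    if tables:
        direction = stats.direction_summary(tables)
        direction_path = out / "direction_summary.tsv"
        direction.to_csv(direction_path, sep="\t", index=False)

    subset_paths, best = {}, {}
    for group in config.groups:
        if group not in tables:
            continue
        df = features if group == "all" else features[features["sex"] == group]
        rows = []
        for k in config.subset_sizes:
            t2 = time.time()
            results = classify.exhaustive_subset_search(
                df, k=k, min_samples=config.min_samples, seed=config.seed,
                test_fraction=config.test_fraction,
                subject_wise=config.subject_wise_split,
            )
            topk = results[0]
            best[(group, int(k))] = {
                "subset": topk.feature_subset,
                "SEN": topk.metrics.sen, "SPE": topk.metrics.spe,
                "PPV": topk.metrics.ppv, "ACC": topk.metrics.acc,
                "n_subsets": len(results),
            }
            (out / f"tree_{group}_k{k}.txt").write_text(
                classify.format_tree(topk.tree)
            )
            for res in results[:20]:
                rows.append({
                    "group": group, "k": int(k), "rank": res.rank,
                    "subset": "+".join(res.feature_subset),
                    "SEN": res.metrics.sen, "SPE": res.metrics.spe,
                    "PPV": res.metrics.ppv, "ACC": res.metrics.acc,
                })
            logger.info(
                "group %s k=%d: %d subsets searched in %.1f s; best ACC %.1f%% (%s)",
                group, k, len(results), time.time() - t2, topk.metrics.acc,
                "+".join(topk.feature_subset),
            )
        path = out / f"subsets_{group}.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
        subset_paths[group] = path

    logger.info("pipeline finished in %.1f s", time.time() - t0)
    return RunReport(
        out_dir=out,
        segment_counts=seg_counts,
        n_segments_per_subject=n_per_subject,
        features_path=feat_path,
        comparison_paths=comparison_paths,
        direction_summary_path=direction_path,
        subset_search_paths=subset_paths,
        n_significant=n_sig,
        best_subsets=best,
        config_echo_path=echo_path,
    )
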