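"""Experiment orchestration: the study designs behind one config object.

Supported kinds:

* ``within`` — source and target from the same session, per-run disjoint
  trial splits;
* ``cross_session`` — every ordered (source session, target session) pair;
  cross-session summaries exclude the within-session diagonal;
* ``cross_task`` — sessions recorded in different modes (task vs rest);
* ``sweep`` — identification accuracy as a function of the number of
  trials used for featurization;
* ``preproc_compare`` — clean vs degraded ("raw") cohort comparison with
  an unpaired t test per feature;
* ``rf_baseline`` — the topomap random-forest baseline;
* ``subfeatures`` — component-wise accuracy grids.

Every report is a pure function of (config, seed); outputs are CSV/JSON.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError
from .identify import run_identification
from .metrics import (chance_levels, confusion_matrix,
                      differential_identifiability_result,
                      identification_accuracy, permutation_pvalue,
                      unpaired_t_test)
from .simulate import (Cohort, CohortSpec, degrade_cohort, draw_signatures,
                       make_cohort)
from .subfeatures import SensorGroupLayout, subfeature_accuracy_map
from .rf_baseline import rf_cv_accuracy, topomap_dataset

__all__ = [
    "ExperimentConfig",
    "run_experiment",
    "sweep_sample_size",
    "compare_preprocessing",
    "session_pairs",
]

EXPERIMENT_KINDS = ("within", "cross_session", "cross_task",
                    "cross_modality", "sweep", "preproc_compare",
                    "rf_baseline", "subfeatures")


@dataclass
class ExperimentConfig:
    """Declarative description of one experiment."""

    kind: str
    cohort: dict[str, Any] = field(default_factory=dict)  # CohortSpec kwargs
    features: Sequence[str] = ("sp", "tp", "fq")
    n: int = 100
    R: int = 100
    seed: int = 0
    out_dir: str | None = None
    # kind-specific knobs
    modes: Sequence[str] | None = None           # cross_task
    second_modality_channels: int = 32           # cross_modality
    n_grid: Sequence[int] | None = None          # sweep
    degrade_noise_sd: float = 2.0                # preproc_compare
    permutation_B: int = 999
    topomap_count: int = 1000                    # rf_baseline
    one_per_trial: bool = False
    n_estimators: int = 256
    folds: int = 10
    n_segments: int = 10                         # subfeatures (tp)
    layout_path: str | None = None               # subfeatures (sp)
    split_fraction: float = 0.5

    def __post_init__(self) -> None:
        problems = []
        if self.kind not in EXPERIMENT_KINDS:
            problems.append(f"kind must be one of {EXPERIMENT_KINDS}, "
                            f"got {self.kind!r}")
        bad = [f for f in self.features if f not in ("sp", "tp", "fq")]
        if bad:
            problems.append(f"unknown features {bad}")
        if self.n < 1 or self.R < 1:
            problems.append("n and R must be >= 1")
        if self.kind == "sweep" and not self.n_grid:
            problems.append("sweep requires n_grid")
        if self.layout_path and not Path(self.layout_path).exists():
            problems.append(f"layout file not found: {self.layout_path}")
        if problems:
            raise ConfigError("; ".join(problems))

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "ExperimentConfig":
        path = Path(path)
        with open(path) as f:
            raw = json.load(f) if path.suffix == ".json" else yaml.safe_load(f)
        raw.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)

    def spec(self) -> CohortSpec:
        kwargs = dict(self.cohort)
        kwargs.setdefault("seed", self.seed)
        return CohortSpec(**kwargs)


def session_pairs(sessions: Sequence[str], kind: str) -> list[tuple[str, str]]:
    """Session pairs evaluated by an experiment kind.

    ``cross_session`` evaluates all ordered off-diagonal pairs (S(S-1) of
    them: 12 for 4 sessions, 6 for 3); ``within`` the diagonal.
    """
    if kind == "within":
        return [(s, s) for s in sessions]
    return [(a, b) for a in sessions for b in sessions if a != b]


def _identification_tables(
    cohort: Cohort, pairs: list[tuple[str, str]], features: Sequence[str],
    n: int, R: int, rng: np.random.Generator, split_fraction: float,
    permutation_B: int,
):
    acc_rows, indiv_rows, confusions, signif = [], [], {}, []
    k = cohort.spec.K
    chance = chance_levels(k)
    for feature in features:
        for src_ses, tgt_ses in pairs:
            source, target = cohort.pair(src_ses, tgt_ses)
            res = run_identification(source, target, feature, n=n, R=R,
                                     rng=rng, split_fraction=split_fraction)
            pooled = identification_accuracy(res, "pooled")
            pooled["chance_identification"] = chance.identification
            pooled["chance_rank"] = chance.rank
            acc_rows.append(pooled)
            indiv = identification_accuracy(res, "individual")
            indiv_rows.append(indiv)
            confusions[(feature, src_ses, tgt_ses)] = confusion_matrix(res)
            di, di_se = differential_identifiability_result(res)
            perm = permutation_pvalue(res, B=permutation_B, rng=rng)
            signif.append({
                "feature": feature, "source_session": src_ses,
                "target_session": tgt_ses,
                "observed_accuracy": perm.observed, "B": perm.B,
                "p_value": perm.p_value,
                "differential_identifiability": di,
                "differential_identifiability_se": di_se,
                "tie_runs": int(res.tie_flags.any(axis=1).sum()),
            })
    return (pd.concat(acc_rows, ignore_index=True),
            pd.concat(indiv_rows, ignore_index=True),
            confusions, signif)


def sweep_sample_size(config: ExperimentConfig,
                      n_grid: Sequence[int] | None = None,
                      cohort: Cohort | None = None) -> pd.DataFrame:
    """Pooled cross-session accuracy per (feature, n) over ``n_grid``.

    Only off-diagonal (cross-session) pairs enter the averages.
    """
    n_grid = list(n_grid if n_grid is not None else config.n_grid)
    cohort = cohort if cohort is not None else make_cohort(config.spec())
    pairs = session_pairs(cohort.spec.session_ids, "cross_session")
    rows = []
    for n in n_grid:
        for fi, feature in enumerate(config.features):
            # stream keyed by (seed, n, feature): equal grid points repeat
            rng = np.random.default_rng([config.seed, int(n), fi])
            correct = []
            for src_ses, tgt_ses in pairs:
                source, target = cohort.pair(src_ses, tgt_ses)
                res = run_identification(
                    source, target, feature, n=n, R=config.R, rng=rng,
                    split_fraction=config.split_fraction)
                correct.append(res.correct.astype(float).ravel())
            correct = np.concatenate(correct)
            rows.append({"feature": feature, "n": n,
                         "accuracy": correct.mean(),
                         "se": correct.std(ddof=1) / np.sqrt(correct.size),
                         "n_runs": config.R, "n_pairs": len(pairs)})
    return pd.DataFrame(rows)


def compare_preprocessing(
    config: ExperimentConfig, cohort_raw: Cohort, cohort_clean: Cohort,
) -> pd.DataFrame:
    """Clean vs raw comparison: per-(session pair x individual) accuracy
    vectors (each entry averaged over runs) per feature and condition, with
    a two-sided unpaired t test per feature.

    Vector length = (#ordered cross-session pairs) x K per condition.
    """
    if set(cohort_raw.blocks) != set(cohort_clean.blocks):
        raise ConfigError("raw and clean cohorts must share individuals "
                          "and sessions")
    pairs = session_pairs(cohort_clean.spec.session_ids, "cross_session")
    rows = []
    for fi, feature in enumerate(config.features):
        vectors = {}
        for name, cohort in (("clean", cohort_clean), ("raw", cohort_raw)):
            # same stream per condition: identical cohorts give identical runs
            rng = np.random.default_rng([config.seed, fi])
            per_cell = []
            for src_ses, tgt_ses in pairs:
                source, target = cohort.pair(src_ses, tgt_ses)
                res = run_identification(
                    source, target, feature, n=config.n, R=config.R, rng=rng,
                    split_fraction=config.split_fraction)
                per_cell.append(res.correct.mean(axis=0))  # [K]
            vectors[name] = np.concatenate(per_cell)
        t, p = unpaired_t_test(vectors["clean"], vectors["raw"]) \
            if (np.std(vectors["clean"]) + np.std(vectors["raw"])) > 0 \
            else (0.0, 1.0)
        rows.append({
            "feature": feature,
            "clean_mean": vectors["clean"].mean(),
            "clean_se": vectors["clean"].std(ddof=1)
            / np.sqrt(vectors["clean"].size),
            "raw_mean": vectors["raw"].mean(),
            "raw_se": vectors["raw"].std(ddof=1) / np.sqrt(vectors["raw"].size),
            "t": t, "p_value": p, "n_per_group": vectors["clean"].size,
        })
    return pd.DataFrame(rows)


def run_experiment(config: ExperimentConfig) -> dict[str, Any]:
    """Execute one experiment and (optionally) write its report bundle.

    Returns the in-memory artifacts; when ``config.out_dir`` is set, writes
    CSV tables, confusion matrices, a significance JSON and a run manifest.
    """
    spec = config.spec()
    rng = np.random.default_rng(config.seed)
    out: dict[str, Any] = {"config": config}
    kind = config.kind

    if kind in ("within", "cross_session", "cross_task"):
        modes = config.modes
        if kind == "cross_task" and modes is None:
            modes = ["task"] + ["rest"] * (spec.S - 1)
        cohort = make_cohort(spec, modes=modes)
        pairs = session_pairs(
            spec.session_ids, "within" if kind == "within" else "cross_session")
        acc, indiv, confusions, signif = _identification_tables(
            cohort, pairs, config.features, config.n, config.R, rng,
            config.split_fraction, config.permutation_B)
        out.update(accuracy=acc, accuracy_by_individual=indiv,
                   confusions=confusions, significance=signif)
    elif kind == "cross_modality":
        # same individuals measured through a second sensor array: spatial
        # mixing is re-drawn per modality while the temporal and spectral
        # signatures are shared, so only tp and fq can transfer
        spec_a = spec
        sigs_a = draw_signatures(spec_a)
        spec_b = dataclasses.replace(
            spec_a, C=config.second_modality_channels,
            seed=spec_a.seed + 1_000_003)
        sigs_b = [dataclasses.replace(sa, mixing=sb.mixing)
                  for sa, sb in zip(sigs_a, draw_signatures(spec_b))]
        cohort_a = make_cohort(spec_a, signatures=sigs_a)
        cohort_b = make_cohort(spec_b, signatures=sigs_b)
        features = [f for f in config.features if f != "sp"]
        source = cohort_a.session_set(spec_a.session_ids[0], "source")
        target = cohort_b.session_set(spec_b.session_ids[0], "target")
        acc_rows = []
        chance = chance_levels(spec_a.K)
        for feature in features:
            res = run_identification(source, target, feature, n=config.n,
                                     R=config.R, rng=rng,
                                     split_fraction=config.split_fraction)
            pooled = identification_accuracy(res, "pooled")
            pooled["chance_identification"] = chance.identification
            pooled["chance_rank"] = chance.rank
            acc_rows.append(pooled)
        out["accuracy"] = pd.concat(acc_rows, ignore_index=True)
    elif kind == "sweep":
        out["sweep"] = sweep_sample_size(config)
    elif kind == "preproc_compare":
        clean = make_cohort(spec)
        raw = degrade_cohort(clean, config.degrade_noise_sd)
        out["comparison"] = compare_preprocessing(config, raw, clean)
    elif kind == "rf_baseline":
        cohort = make_cohort(spec)
        ses = spec.session_ids[0]
        blocks = [cohort.blocks[(ind, ses)] for ind in spec.individual_ids]
        X, y = topomap_dataset(blocks, config.topomap_count,
                               config.one_per_trial, rng)
        res = rf_cv_accuracy(X, y, n_estimators=config.n_estimators,
                             folds=config.folds, rng=rng)
        out["rf_baseline"] = res
    elif kind == "subfeatures":
        cohort = make_cohort(spec)
        src_ses, tgt_ses = session_pairs(spec.session_ids, "cross_session")[0] \
            if spec.S > 1 else (spec.session_ids[0], spec.session_ids[0])
        source, target = cohort.pair(src_ses, tgt_ses)
        layout = SensorGroupLayout.from_csv(config.layout_path) \
            if config.layout_path else None
        grids = {}
        for feature in config.features:
            grids[feature] = subfeature_accuracy_map(
                source, target, feature, n=config.n, R=config.R, rng=rng,
                layout=layout, n_segments=config.n_segments,
                split_fraction=config.split_fraction)
        out["grids"] = grids

    if config.out_dir:
        _write_bundle(out, config)
    return out


def _write_bundle(out: dict[str, Any], config: ExperimentConfig) -> None:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": {k: (list(v) if isinstance(v, (tuple, list)) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "seed": config.seed,
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
    }
    with open(out_dir / "run_manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)
    for key in ("accuracy", "accuracy_by_individual", "sweep", "comparison"):
        if key in out:
            out[key].to_csv(out_dir / f"{key}.csv", index=False)
    if "confusions" in out:
        for (feature, src, tgt), cm in out["confusions"].items():
            cm.to_csv(out_dir / f"confusion_{feature}_{src}_to_{tgt}.csv")
    if "significance" in out:
        with open(out_dir / "significance.json", "w") as f:
            json.dump(out["significance"], f, indent=2, sort_keys=True)
    if "rf_baseline" in out:
        out["rf_baseline"].to_frame().to_csv(
            out_dir / "rf_fold_accuracies.csv", index=False)
    if "grids" in out:
        for feature, grid in out["grids"].items():
            grid.to_csv(out_dir / f"subfeature_grid_{feature}.csv", index=False)
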