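"""Orchestration of the six test strategies over a source/target cohort
pair, strategy comparison tables with paired permutation statistics, and
the scaled-down synthetic reference benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .adapt_dann import DannConfig, extract_features, train_dann
from .adapt_du import DuConfig, train_du
from .adapt_tl import finetune
from .metrics import domain_accuracy_probe, evaluate_subject, max_t_correction
from .model import (
    PlanarUNetConfig,
    TriplanarEnsemble,
    binarize,
    build_triplanar_ensemble,
    predict_volume,
)
from .preproc import PLANES, PreprocConfig
from .synthgen import DomainShift, DomainSpec, Subject, generate_cohort, make_domain_pair
from .training import AugmentConfig, TrainConfig, train_model

__all__ = [
    "STRATEGIES",
    "StrategySpec",
    "CohortSplit",
    "ExperimentConfig",
    "StrategyResult",
    "run_strategy",
    "compare_strategies",
    "swap_domains",
    "reference_benchmark_config",
    "run_benchmark",
]

STRATEGIES = ("source_only", "tl", "dann", "semi_dann", "du", "target_trained")
METRICS = ("si", "voxel_tpr", "voxel_fpr", "cluster_tpr",
           "cluster_precision", "cluster_f1", "lavd")


@dataclass(frozen=True)
class StrategySpec:
    name: str
    seed: int = 0
    tl_layers: int = 3
    tl_subjects: int | None = None
    semi_fraction: float = 0.25
    grl_lambda: float = 1.0
    beta: float = 50.0
    dann_dropout: float = 0.2
    domain_lr: float = 1e-3

    def __post_init__(self):
        if self.name not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.name!r}")


@dataclass
class CohortSplit:
    """Disjoint subject-level train/test split (validation comes out of train)."""

    train: list[Subject]
    test: list[Subject]

    def __post_init__(self):
        train_ids = {s.subject_id for s in self.train}
        test_ids = {s.subject_id for s in self.test}
        if train_ids & test_ids:
            raise ValueError(f"overlapping train/test subjects: {train_ids & test_ids}")

    @classmethod
    def from_cohort(cls, subjects: list[Subject], n_test: int, seed: int = 0):
        order = np.random.default_rng(seed).permutation(len(subjects))
        test_idx = set(order[:n_test].tolist())
        return cls(train=[s for i, s in enumerate(subjects) if i not in test_idx],
                   test=[s for i, s in enumerate(subjects) if i in test_idx])


@dataclass
class ExperimentConfig:
    source_spec: DomainSpec
    target_spec: DomainSpec
    n_subjects: int = 12
    n_test: int = 3
    model: PlanarUNetConfig = field(default_factory=PlanarUNetConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    augment: AugmentConfig | None = None
    planes: tuple[str, ...] = PLANES
    threshold: float = 0.5
    #: per-strategy StrategySpec keyword overrides (e.g. a stronger GRL scale)
    strategy_overrides: dict[str, dict] = field(default_factory=dict)


@dataclass
class StrategyResult:
    name: str
    seed: int
    ensemble: TriplanarEnsemble
    target_reports: pd.DataFrame
    source_reports: pd.DataFrame | None = None
    log: pd.DataFrame | None = None


def _evaluate(ensemble: TriplanarEnsemble, subjects: list[Subject],
              config: ExperimentConfig) -> pd.DataFrame:
    rows = []
    for subject in subjects:
        prob = predict_volume(ensemble, subject, config.preproc, planes=config.planes)
        pred = binarize(prob, config.threshold)
        report = evaluate_subject(pred, subject.lesion_mask, subject.voxel_dims,
                                  region=subject.brain_mask)
        rows.append({"subject_id": subject.subject_id, **report.as_dict()})
    return pd.DataFrame(rows)


def _train_source_baseline(config: ExperimentConfig, source: CohortSplit,
                           seed: int) -> TriplanarEnsemble:
    ensemble = build_triplanar_ensemble(config.model, seed=seed)
    train_model(ensemble, source.train, replace(config.train, seed=seed),
                augment=config.augment, preproc=config.preproc, planes=config.planes)
    return ensemble


def run_strategy(spec: StrategySpec, source: CohortSplit, target: CohortSplit,
                 config: ExperimentConfig,
                 source_ensemble: TriplanarEnsemble | None = None) -> StrategyResult:
    """Train one strategy and evaluate it on the held-out target test set.

    `source_ensemble` lets callers reuse a source-trained baseline for the
    strategies that start from it (source_only, tl).
    """
    seed = spec.seed
    train_cfg = replace(config.train, seed=seed)
    log = None
    source_reports = None

    if spec.name == "target_trained":
        ensemble = build_triplanar_ensemble(config.model, seed=seed)
        _, log = train_model(ensemble, target.train, train_cfg,
                             augment=config.augment, preproc=config.preproc,
                             planes=config.planes)
    elif spec.name == "source_only":
        ensemble = source_ensemble or _train_source_baseline(config, source, seed)
        source_reports = _evaluate(ensemble, source.test, config)
    elif spec.name == "tl":
        base = source_ensemble or _train_source_baseline(config, source, seed)
        ensemble = _clone(base, config.model)
        finetune(ensemble, target.train, i=spec.tl_layers,
                 n_subjects=spec.tl_subjects, config=train_cfg,
                 augment=config.augment, preproc=config.preproc,
                 planes=config.planes, seed=seed)
    elif spec.name in ("dann", "semi_dann"):
        ensemble = (_clone(source_ensemble, config.model) if source_ensemble
                    else build_triplanar_ensemble(config.model, seed=seed))
        dann_cfg = DannConfig(
            grl_lambda=spec.grl_lambda,
            semi_fraction=spec.semi_fraction if spec.name == "semi_dann" else 0.0,
            dropout=spec.dann_dropout, domain_lr=spec.domain_lr)
        _, _, log = train_dann(ensemble, source.train, target.train, dann_cfg,
                               train_cfg, preproc=config.preproc,
                               planes=config.planes)
        source_reports = _evaluate(ensemble, source.test, config)
    elif spec.name == "du":
        ensemble = (_clone(source_ensemble, config.model) if source_ensemble
                    else build_triplanar_ensemble(config.model, seed=seed))
        _, _, log = train_du(ensemble, source.train, target.train,
                             DuConfig(beta=spec.beta), train_cfg,
                             preproc=config.preproc, planes=config.planes)
        source_reports = _evaluate(ensemble, source.test, config)
    else:  # pragma: no cover - guarded by StrategySpec
        raise ValueError(spec.name)

    target_reports = _evaluate(ensemble, target.test, config)
    return StrategyResult(spec.name, seed, ensemble, target_reports,
                          source_reports, log)


def _clone(ensemble: TriplanarEnsemble, model_cfg: PlanarUNetConfig) -> TriplanarEnsemble:
    clone = build_triplanar_ensemble(model_cfg, seed=0)
    clone.load_state_dict(ensemble.state_dict())
    return clone


def compare_strategies(results: dict[str, pd.DataFrame],
                       n_permutations: int = 10000, seed: int = 0):
    """Per-metric medians/IQRs plus pairwise max-T-corrected p-values.

    `results` maps strategy name -> per-subject metrics DataFrame; all
    frames must cover the same test subjects. Returns (summary table,
    pairwise p-value table, long-format boxplot data).
    """
    names = list(results)
    subject_sets = [tuple(sorted(df["subject_id"])) for df in results.values()]
    if len(set(subject_sets)) != 1:
        raise ValueError("strategies were evaluated on different subject sets")

    summary_rows, long_rows = [], []
    for name, df in results.items():
        df = df.sort_values("subject_id")
        for metric in METRICS:
            vals = df[metric].to_numpy(dtype=float)
            summary_rows.append({
                "strategy": name, "metric": metric,
                "median": float(np.median(vals)),
                "iqr_low": float(np.percentile(vals, 25)),
                "iqr_high": float(np.percentile(vals, 75)),
            })
            long_rows.extend({"strategy": name, "metric": metric,
                              "subject_id": sid, "value": float(v)}
                             for sid, v in zip(df["subject_id"], vals))

    pair_rows = []
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i:]]
    for metric in METRICS:
        diffs, labels = [], []
        for a, b in pairs:
            va = results[a].sort_values("subject_id")[metric].to_numpy(dtype=float)
            vb = results[b].sort_values("subject_id")[metric].to_numpy(dtype=float)
            diffs.append(va - vb)
            labels.append((a, b))
        corrected = max_t_correction(np.column_stack(diffs), n_permutations, seed)
        for (a, b), p in zip(labels, corrected):
            pair_rows.append({"metric": metric, "strategy_a": a, "strategy_b": b,
                              "p_corrected": float(p)})
    return (pd.DataFrame(summary_rows), pd.DataFrame(pair_rows),
            pd.DataFrame(long_rows))


def swap_domains(config: ExperimentConfig) -> ExperimentConfig:
    """Exchange the source/target roles; pure relabelling, no data mutation."""
    return replace(config, source_spec=config.target_spec,
                   target_spec=config.source_spec)


# -- reference synthetic benchmark -------------------------------------------

def reference_benchmark_config() -> ExperimentConfig:
    """The shipped desk-scale two-domain benchmark.

    Sized for a single CPU: small volumes, a narrow ensemble and short fixed
    training budgets, with a domain shift strong enough that the strategy
    ordering of the full-scale experiments remains detectable.
    """
    base = DomainSpec(
        name="bench",
        volume_shape=(28, 32, 28),
        tissue_means={"background": 0.0, "brain": 100.0, "lesion": 185.0},
        bias_amplitude=0.05,
        noise_sigma=6.0,
        lesion_count_range=(3, 7),
        lesion_radius_range=(1.5, 3.5),
        periventricular_fraction=0.5,
    )
    # target differs in overall intensity, bias, noise, slice smoothing and,
    # crucially, carries unlabelled bright rim artifacts the source lacks;
    # target lesions are slightly brighter to offset the artifact-driven
    # inflation of the normalisation std
    shift = DomainShift(intensity_scale=1.2, lesion_contrast_scale=1.15,
                        noise_delta=3.0, bias_delta=0.1,
                        anisotropy_delta=(0.0, 0.0, 0.8),
                        artifact_delta=1.2)
    source_spec, target_spec = make_domain_pair(base, shift)
    size = (24, 24)
    return ExperimentConfig(
        source_spec=source_spec,
        target_spec=target_spec,
        n_subjects=13,
        n_test=4,
        model=PlanarUNetConfig(base_channels=8, bottleneck_channels=32),
        train=TrainConfig(batch_size=8, pretrain_epochs=0, patience=100,
                          max_epochs=14, val_fraction=0.15, lr_step_epochs=8),
        preproc=PreprocConfig(resize={p: size for p in PLANES}, crop_margin=1),
        augment=None,
        planes=("axial",),
        strategy_overrides={"dann": {"grl_lambda": 3.0},
                            "semi_dann": {"grl_lambda": 3.0}},
    )


def run_benchmark(config: ExperimentConfig | None = None,
                  seeds: tuple[int, ...] = (0, 1, 2),
                  strategies: tuple[str, ...] = STRATEGIES,
                  out_dir: str | Path | None = None,
                  probe: bool = True) -> dict:
    """Run every strategy for every seed; returns metric frames and probes.

    Output dict: ``results`` (strategy -> concatenated per-seed metric
    frames), ``probe`` (bottleneck domain-probe accuracy before/after DANN
    per seed), and optional CSV files under `out_dir`.
    """
    config = config or reference_benchmark_config()
    frames: dict[str, list[pd.DataFrame]] = {s: [] for s in strategies}
    probe_rows = []
    for seed in seeds:
        source_cohort = generate_cohort(config.source_spec, config.n_subjects, seed=seed)
        target_cohort = generate_cohort(config.target_spec, config.n_subjects,
                                        seed=seed + 1000)
        source = CohortSplit.from_cohort(source_cohort, config.n_test, seed=seed)
        target = CohortSplit.from_cohort(target_cohort, config.n_test, seed=seed)

        source_baseline = None
        results_this_seed: dict[str, StrategyResult] = {}
        for name in strategies:
            spec = StrategySpec(name=name, seed=seed,
                                **config.strategy_overrides.get(name, {}))
            if name in ("source_only", "tl", "dann") and source_baseline is None:
                source_baseline = _train_source_baseline(config, source, seed)
            # adversarial strategies train cold (from scratch, as the paper
            # does); only source_only/tl start from the source baseline
            warm = source_baseline if name in ("source_only", "tl") else None
            res = run_strategy(spec, source, target, config,
                               source_ensemble=warm)
            results_this_seed[name] = res
            df = res.target_reports.copy()
            df.insert(0, "seed", seed)
            frames[name].append(df)

        if probe and "dann" in results_this_seed and source_baseline is not None:
            probe_subjects = source.test + target.test
            pre_feats, pre_labels = extract_features(
                source_baseline, probe_subjects, tap="bottleneck",
                preproc=config.preproc, plane=config.planes[0])
            post_feats, post_labels = extract_features(
                results_this_seed["dann"].ensemble, probe_subjects,
                tap="bottleneck", preproc=config.preproc, plane=config.planes[0])
            probe_rows.append({
                "seed": seed,
                "probe_before": domain_accuracy_probe(pre_feats, pre_labels, seed=seed),
                "probe_after": domain_accuracy_probe(post_feats, post_labels, seed=seed),
            })

    results = {name: pd.concat(fs, ignore_index=True) for name, fs in frames.items()}
    probe_df = pd.DataFrame(probe_rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, df in results.items():
            df.to_csv(out_dir / f"{name}_metrics.csv", index=False)
        if not probe_df.empty:
            probe_df.to_csv(out_dir / "domain_probe.csv", index=False)
    return {"results": results, "probe": probe_df}
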