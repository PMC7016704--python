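"""End-to-end experiment drivers.

Four experiments probe the temporal accuracy of the saliency + LIF/WTA
model against (synthetic) human first-fixation latency data:

1. default parameters, one saccade per image, 44-image dataset;
2. GA and Nelder-Mead optimization of the 12 parameters on the same
   ground truth;
3. ten independent "first" saccades per image, optimized against the
   44-image and then the 91-image dataset;
4. per-image fitness (sum of per-image KS statistics) against
   all-fixation ground truth, which forces the model to produce
   within-image variance from its own noise parameters rather than
   from between-image saliency differences.

By default the drivers run on synthetic saliency maps (one per
synthetic "image"); supply ``maps`` to run on maps computed from real
images through :mod:`salif.saliency`.  Every statistic in a report is
recomputable from the CSVs archived in the output directory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from salif.config import default_params, save_params
from salif.lif import batch_simulate, count_distinct_latencies, saccades_to_frame
from salif.optimize import (
    FitnessSpec,
    GAConfig,
    OptimizationResult,
    ParamVector,
    SimContext,
    ga_optimize,
    nm_optimize,
)
from salif.stats import (
    ComparisonResult,
    LatencySample,
    compare_distributions,
    extract_first_fixations,
    filter_outliers,
    variance_decomposition,
)
from salif.synthetic import (
    dataset1_config,
    dataset2_config,
    generate_all_fixation_dataset,
    generate_first_fixation_dataset,
    random_map_set,
)

log = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig",
    "ExperimentReport",
    "run_experiment_1",
    "run_experiment_2",
    "run_experiment_3",
    "run_experiment_4",
    "run_experiment",
    "make_report_plots",
]


@dataclass(frozen=True)
class ExperimentConfig:
    experiment_id: int = 1
    dataset: str = "dataset1"          # dataset1 | dataset2
    runs_per_image: int = 1            # 1 for Exp 1-2, 10 for Exp 3-4
    method: str = "both"               # ga | nm | both
    fitness_variant: str = "sum_ks_z"
    seed: int = 0
    outdir: str | None = None
    map_shape: tuple[int, int] = (24, 32)
    max_generations: int = 50
    timeout_ms: float = 2000.0

    def __post_init__(self) -> None:
        if self.experiment_id not in (1, 2, 3, 4):
            raise ValueError("experiment_id must be 1-4")
        if self.dataset not in ("dataset1", "dataset2"):
            raise ValueError("dataset must be dataset1 or dataset2")


@dataclass
class ExperimentReport:
    experiment_id: int
    comparison: ComparisonResult
    within_image_sd: float
    between_image_sd: float
    distinct_counts: dict[int, int]
    default_comparison: ComparisonResult | None = None
    best_params: ParamVector | None = None
    optimizer: str = "none"
    fitness_trace: list[float] = field(default_factory=list)
    files: dict[str, str] = field(default_factory=dict)

    @property
    def max_distinct(self) -> int:
        return max(self.distinct_counts.values())


def _dataset_cfg(label: str, seed: int):
    return dataset1_config(seed) if label == "dataset1" else dataset2_config(seed)


def _ground_truth(label: str, seed: int) -> LatencySample:
    ds = generate_first_fixation_dataset(_dataset_cfg(label, seed))
    return filter_outliers(extract_first_fixations(ds))


def _maps(cfg: ExperimentConfig, maps=None):
    if maps is not None:
        return maps
    n = _dataset_cfg(cfg.dataset, cfg.seed).n_images
    return random_map_set(n, cfg.map_shape, seed=cfg.seed + 1000)


def _probe(ctx: SimContext, vec: ParamVector, seed: int, runs: int = 10):
    """Distinct-latency counts and variance decomposition at ``runs``
    independent runs per image."""
    lif, wta, noise = vec.to_bundles(ctx.base_lif, ctx.base_wta)
    saccades = batch_simulate(ctx.maps, lif, wta, noise, runs_per_image=runs,
                              seed=seed, timeout_ms=ctx.timeout_ms,
                              engine=ctx.engine)
    per_image: dict[int, list] = {}
    for s in saccades:
        per_image.setdefault(s.image_id, []).append(s)
    counts = {img: count_distinct_latencies(group)
              for img, group in per_image.items()
              if any(not s.censored for s in group)}
    frame = saccades_to_frame(saccades)
    frame.loc[frame["censored"], "latency_ms"] = np.nan
    try:
        within, between = variance_decomposition(frame)
    except ValueError:
        within, between = float("nan"), float("nan")
    return counts, within, between, frame


def _model_sample(ctx: SimContext, vec: ParamVector, seed: int) -> LatencySample:
    lif, wta, noise = vec.to_bundles(ctx.base_lif, ctx.base_wta)
    saccades = batch_simulate(ctx.maps, lif, wta, noise,
                              runs_per_image=ctx.runs_per_image, seed=seed,
                              timeout_ms=ctx.timeout_ms, engine=ctx.engine)
    lat = [s.latency_ms for s in saccades if not s.censored]
    n_cens = sum(s.censored for s in saccades)
    if n_cens:
        log.info("%d of %d runs censored", n_cens, len(saccades))
    return LatencySample(np.asarray(lat), label="model")


def _archive(report: ExperimentReport, cfg: ExperimentConfig,
             model: LatencySample, truth: LatencySample,
             ctx: SimContext) -> None:
    if cfg.outdir is None:
        return
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    tag = f"exp{cfg.experiment_id}_{cfg.dataset}"
    pd.DataFrame({"latency_ms": model.values}).to_csv(
        out / f"{tag}_model_latencies.csv", index=False)
    pd.DataFrame({"latency_ms": truth.values}).to_csv(
        out / f"{tag}_truth_latencies.csv", index=False)
    pd.DataFrame([asdict(report.comparison)]).to_csv(
        out / f"{tag}_comparison.csv", index=False)
    if report.best_params is not None:
        lif, wta, noise = report.best_params.to_bundles(ctx.base_lif,
                                                        ctx.base_wta)
        save_params((lif, wta, noise), out / f"{tag}_best_params.yaml")
    if report.fitness_trace:
        pd.DataFrame({"best_fitness": report.fitness_trace}).to_csv(
            out / f"{tag}_trace.csv", index=False)
    report.files = {p.name: str(p) for p in out.glob(f"{tag}_*")}


def _context(cfg: ExperimentConfig, maps) -> tuple[SimContext, ParamVector]:
    lif, wta, noise = default_params()
    ctx = SimContext(maps=_maps(cfg, maps), base_lif=lif, base_wta=wta,
                     runs_per_image=cfg.runs_per_image,
                     timeout_ms=cfg.timeout_ms)
    return ctx, ParamVector.from_bundles(lif, wta, noise)


def run_experiment_1(cfg: ExperimentConfig, maps=None) -> ExperimentReport:
    """Default parameters, one saccade per image, vs first-fixation truth."""
    ctx, defaults = _context(cfg, maps)
    truth = _ground_truth(cfg.dataset, cfg.seed)
    model = _model_sample(ctx, defaults, cfg.seed + 1)
    comparison = compare_distributions(model, truth)
    counts, within, between, _ = _probe(ctx, defaults, cfg.seed + 2)
    report = ExperimentReport(1, comparison, within, between, counts)
    _archive(report, cfg, model, truth, ctx)
    log.info("Exp 1: D=%.4f z=%.3f model mean=%.1f SD=%.1f",
             comparison.D, comparison.z, comparison.mean_model,
             comparison.sd_model)
    return report


def _optimize(cfg: ExperimentConfig, ctx: SimContext, defaults: ParamVector,
              truth) -> tuple[OptimizationResult, str]:
    spec = FitnessSpec(variant=cfg.fitness_variant,
                       runs_per_image=cfg.runs_per_image)
    results: list[tuple[OptimizationResult, str]] = []
    if cfg.method in ("ga", "both"):
        ga_cfg = GAConfig(max_generations=cfg.max_generations, seed=cfg.seed)
        results.append((ga_optimize(defaults, truth, ctx, ga_cfg, spec), "ga"))
    if cfg.method in ("nm", "both"):
        results.append((nm_optimize(defaults, truth, ctx, spec,
                                    seed=cfg.seed), "nm"))
    return min(results, key=lambda rm: rm[0].best_fitness)


def run_experiment_2(cfg: ExperimentConfig, maps=None) -> ExperimentReport:
    """Optimize the defaults (GA and NM) on first-fixation truth."""
    cfg = ExperimentConfig(**{**asdict(cfg), "experiment_id": 2})
    ctx, defaults = _context(cfg, maps)
    truth = _ground_truth(cfg.dataset, cfg.seed)
    d_model = _model_sample(ctx, defaults, cfg.seed + 1)
    default_cmp = compare_distributions(d_model, truth)
    best, method = _optimize(cfg, ctx, defaults, truth)
    model = _model_sample(ctx, best.best_params, cfg.seed + 3)
    comparison = compare_distributions(model, truth)
    counts, within, between, _ = _probe(ctx, best.best_params, cfg.seed + 4)
    report = ExperimentReport(2, comparison, within, between, counts,
                              default_comparison=default_cmp,
                              best_params=best.best_params, optimizer=method,
                              fitness_trace=best.fitness_trace)
    _archive(report, cfg, model, truth, ctx)
    log.info("Exp 2 (%s): D=%.4f z=%.4f (defaults: D=%.4f z=%.3f)", method,
             comparison.D, comparison.z, default_cmp.D, default_cmp.z)
    return report


def run_experiment_3(cfg: ExperimentConfig, maps=None
                     ) -> dict[str, ExperimentReport]:
    """Ten saccades per image; sub-run (a) on the 44-image truth,
    sub-run (b) on the 91-image truth, each restarted from defaults."""
    reports = {}
    for key, dataset in (("a", "dataset1"), ("b", "dataset2")):
        sub = ExperimentConfig(**{**asdict(cfg), "experiment_id": 3,
                                  "dataset": dataset, "runs_per_image": 10})
        ctx, defaults = _context(sub, maps if dataset == cfg.dataset else None)
        truth = _ground_truth(dataset, sub.seed)
        best, method = _optimize(sub, ctx, defaults, truth)
        model = _model_sample(ctx, best.best_params, sub.seed + 3)
        comparison = compare_distributions(model, truth)
        counts, within, between, _ = _probe(ctx, best.best_params, sub.seed + 4)
        report = ExperimentReport(3, comparison, within, between, counts,
                                  best_params=best.best_params,
                                  optimizer=method,
                                  fitness_trace=best.fitness_trace)
        _archive(report, sub, model, truth, ctx)
        log.info("Exp 3%s (%s): n_model=%d D=%.4f z=%.4f", key, method,
                 comparison.n_model, comparison.D, comparison.z)
        reports[key] = report
    return reports


def per_image_truth_from_dataset(dataset_label: str, seed: int
                                 ) -> dict[int, LatencySample]:
    """All-fixation ground truth split by image (1500 ms rule applied)."""
    ds = generate_all_fixation_dataset(_dataset_cfg(dataset_label, seed))
    out: dict[int, LatencySample] = {}
    for img, group in ds.records.groupby("image_id"):
        dur = group["duration_ms"].to_numpy()
        dur = dur[dur <= 1500.0]
        if dur.size:
            out[int(img)] = LatencySample(dur, label="human")
        else:
            log.warning("image %s: no retained fixations; skipped", img)
    return out


def run_experiment_4(cfg: ExperimentConfig, maps=None) -> ExperimentReport:
    """Per-image KS fitness against all-fixation ground truth."""
    cfg = ExperimentConfig(**{**asdict(cfg), "experiment_id": 4,
                              "dataset": "dataset2", "runs_per_image": 10,
                              "fitness_variant": "per_image_ks",
                              "method": "ga"})
    ctx, defaults = _context(cfg, maps)
    per_image = per_image_truth_from_dataset(cfg.dataset, cfg.seed)
    best, method = _optimize(cfg, ctx, defaults, per_image)
    pooled_truth = LatencySample(
        np.concatenate([s.values for s in per_image.values()]), "human")
    model = _model_sample(ctx, best.best_params, cfg.seed + 3)
    comparison = compare_distributions(model, pooled_truth)
    counts, within, between, _ = _probe(ctx, best.best_params, cfg.seed + 4)
    report = ExperimentReport(4, comparison, within, between, counts,
                              best_params=best.best_params, optimizer=method,
                              fitness_trace=best.fitness_trace)
    _archive(report, cfg, model, pooled_truth, ctx)
    log.info("Exp 4 (%s): D=%.4f max distinct latencies per image=%d",
             method, comparison.D, report.max_distinct)
    return report


def run_experiment(cfg: ExperimentConfig, maps=None):
    return {1: run_experiment_1, 2: run_experiment_2,
            3: run_experiment_3, 4: run_experiment_4}[cfg.experiment_id](cfg, maps)


def make_report_plots(report: ExperimentReport, outdir, model: LatencySample,
                      truth: LatencySample, maps=None) -> list[str]:
    """Overlaid histogram + density, per-image strip plot, and an
    optional saliency-noise illustration.  Refuses an empty model
    sample."""
    if model.n == 0:
        raise ValueError("cannot plot an empty model sample")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.stats import gaussian_kde

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    files = []

    fig, ax = plt.subplots(figsize=(7, 4))
    bins = np.linspace(0, max(model.values.max(), truth.values.max()), 40)
    ax.hist(truth.values, bins=bins, density=True, alpha=0.45,
            label=f"human-like (n={truth.n})")
    ax.hist(model.values, bins=bins, density=True, alpha=0.45,
            label=f"model (n={model.n})")
    for sample in (truth, model):
        if sample.n > 2 and sample.sd() > 0:
            xs = np.linspace(bins[0], bins[-1], 200)
            ax.plot(xs, gaussian_kde(sample.values)(xs))
    ax.set_xlabel("first-fixation latency (ms)")
    ax.set_ylabel("density")
    ax.legend()
    p = out / f"exp{report.experiment_id}_distributions.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    files.append(str(p))

    fig, ax = plt.subplots(figsize=(7, 4))
    imgs = sorted(report.distinct_counts)
    ax.bar(imgs, [report.distinct_counts[i] for i in imgs])
    ax.set_xlabel("image")
    ax.set_ylabel("distinct model latencies (10 runs)")
    p = out / f"exp{report.experiment_id}_distinct_counts.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    files.append(str(p))

    if maps:
        fig, axes = plt.subplots(1, min(3, len(maps)), figsize=(9, 3))
        for ax_, m in zip(np.atleast_1d(axes), maps):
            ax_.imshow(m.values, cmap="viridis")
            ax_.set_axis_off()
        p = out / f"exp{report.experiment_id}_maps.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        files.append(str(p))
    return files
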