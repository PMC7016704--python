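"""Fitting the 12-dimensional LIF/WTA/noise vector to latency data.

Two optimizers, as in the study design being reproduced: a
mutation-only genetic algorithm (40 contenders, relative mutations up
to 10% with random sign, worst 10 reset to the initial vector, 50
generations, stop early once the best contender is statistically
indistinguishable from the ground truth by both KS and z at alpha =
0.05) and the Nelder-Mead simplex with the classic fminsearch stopping
defaults.  Fitness functions compare simulated first-fixation latency
samples to a ground-truth sample: D + |z| summed without weights, a
z-gate ranking, or a per-image sum of KS statistics.

The search space is unbounded; parameters span ~10 orders of
magnitude, which is why GA mutations are multiplicative.  Every
stochastic fitness evaluation gets a fresh seed derived from the
master seed (logged for replay); Nelder-Mead uses common random
numbers (one fixed evaluation seed) so the simplex logic sees a
deterministic surface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from salif.lif import LIFParams, NoiseParams, WTAParams, batch_simulate
from salif.stats import ComparisonResult, LatencySample, compare_distributions, ks_two_sample
from salif.synthetic import SaliencyMap

log = logging.getLogger(__name__)

__all__ = [
    "PARAM_NAMES",
    "ParamVector",
    "GAConfig",
    "FitnessSpec",
    "SimContext",
    "OptimizationResult",
    "simulate_latencies",
    "fitness_sum_ks_z",
    "fitness_z_gate_then_ks",
    "fitness_per_image_ks",
    "ga_optimize",
    "nm_optimize",
]

#: order of the optimization vector
PARAM_NAMES = (
    "lif_Eexc", "lif_Einh", "lif_Gleak", "lif_Ginput", "lif_Vthresh",
    "lif_C", "wta_C", "wta_Gleak", "wta_Ginh",
    "noise_ampl", "noise_const", "map_range",
)

NON_FIRING_PENALTY = 1e6


@dataclass(frozen=True)
class ParamVector:
    """Ordered 12-vector <-> (LIFParams, WTAParams, NoiseParams)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected {len(PARAM_NAMES)} parameters")
        object.__setattr__(self, "values", v)

    @classmethod
    def from_bundles(cls, lif: LIFParams, wta: WTAParams,
                     noise: NoiseParams) -> "ParamVector":
        return cls(np.array([
            lif.Eexc, lif.Einh, lif.Gleak, lif.Ginput, lif.Vthresh, lif.C,
            wta.C, wta.Gleak, wta.Ginh,
            noise.noise_ampl, noise.noise_const, noise.map_range,
        ]))

    def to_bundles(self, base_lif: LIFParams, base_wta: WTAParams
                   ) -> tuple[LIFParams, WTAParams, NoiseParams]:
        v = self.values
        lif = replace(base_lif, Eexc=v[0], Einh=v[1], Gleak=max(v[2], 0.0),
                      Ginput=max(v[3], 0.0), Vthresh=v[4], C=abs(v[5]) or 1e-30)
        wta = replace(base_wta, C=abs(v[6]) or 1e-30, Gleak=max(v[7], 0.0),
                      Ginh=max(v[8], 0.0))
        noise = NoiseParams(noise_ampl=max(v[9], 0.0),
                            noise_const=max(v[10], 0.0),
                            map_range=abs(v[11]) or 1e-30)
        return lif, wta, noise


@dataclass(frozen=True)
class GAConfig:
    population: int = 40
    mutation_max: float = 0.10
    reset_count: int = 10
    max_generations: int = 50
    alpha: float = 0.05  # indistinguishability threshold for early stop
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.mutation_max < 1:
            raise ValueError("mutation_max must be in [0, 1)")
        if self.reset_count >= self.population:
            raise ValueError("reset_count must be < population")


@dataclass(frozen=True)
class FitnessSpec:
    variant: str = "sum_ks_z"  # sum_ks_z | z_gate_then_ks | per_image_ks
    runs_per_image: int = 1

    def __post_init__(self) -> None:
        if self.variant not in ("sum_ks_z", "z_gate_then_ks", "per_image_ks"):
            raise ValueError(f"unknown fitness variant {self.variant!r}")


@dataclass
class SimContext:
    """Everything a fitness evaluation needs besides the vector."""

    maps: list[SaliencyMap]
    base_lif: LIFParams = field(default_factory=LIFParams)
    base_wta: WTAParams = field(default_factory=WTAParams)
    runs_per_image: int = 1
    timeout_ms: float = 2000.0
    engine: str = "reduced"
    free_mask: np.ndarray | None = None   # restrict which params mutate/vary


@dataclass
class OptimizationResult:
    best_params: ParamVector
    best_fitness: float
    fitness_trace: list[float]
    stopping_reason: str
    comparison: ComparisonResult | None
    n_evaluations: int


def simulate_latencies(vec: ParamVector, ctx: SimContext, seed: int
                       ) -> tuple[np.ndarray, np.ndarray, int]:
    """Simulated latency sample for a parameter vector.

    Returns (latencies_ms, image_ids, n_censored) with censored runs
    dropped.
    """
    lif, wta, noise = vec.to_bundles(ctx.base_lif, ctx.base_wta)
    try:
        saccades = batch_simulate(ctx.maps, lif, wta, noise,
                                  runs_per_image=ctx.runs_per_image,
                                  seed=seed, timeout_ms=ctx.timeout_ms,
                                  engine=ctx.engine)
    except (FloatingPointError, ValueError):
        return np.empty(0), np.empty(0, dtype=int), len(ctx.maps) * ctx.runs_per_image
    lat = np.array([s.latency_ms for s in saccades if not s.censored])
    ids = np.array([s.image_id for s in saccades if not s.censored], dtype=int)
    return lat, ids, sum(s.censored for s in saccades)


def fitness_sum_ks_z(vec: ParamVector, truth: LatencySample, ctx: SimContext,
                     seed: int) -> tuple[float, ComparisonResult | None]:
    """D + |z| against the ground truth; non-firing sets get a large
    penalty (the optimizer treats them as hopeless, not as errors)."""
    lat, _, n_cens = simulate_latencies(vec, ctx, seed)
    if lat.size == 0:
        log.debug("non-firing parameter set (censored=%d)", n_cens)
        return NON_FIRING_PENALTY, None
    cmp_ = compare_distributions(LatencySample(lat, "model"), truth)
    return cmp_.D + abs(cmp_.z), cmp_


def fitness_z_gate_then_ks(evals: list[tuple[float, float, float]]) -> list[int]:
    """Ranking for (D, z, p_z) triples: contenders passing the z gate
    (p_z >= 0.05) first, by ascending D; the rest after, by ascending
    |z|.  Returns indices, best first."""
    passers = [i for i, (_, _, p) in enumerate(evals) if p >= 0.05]
    failers = [i for i in range(len(evals)) if i not in set(passers)]
    passers.sort(key=lambda i: evals[i][0])
    failers.sort(key=lambda i: abs(evals[i][1]))
    return passers + failers


def fitness_per_image_ks(vec: ParamVector,
                         per_image_truth: dict[int, LatencySample],
                         ctx: SimContext, seed: int) -> float:
    """Sum over images of D(model runs on that image, truth for it).

    Images whose model runs are all censored contribute a penalty of
    10 (far above the attainable D of 1); empty truth images are
    skipped with a warning.
    """
    lat, ids, _ = simulate_latencies(vec, ctx, seed)
    total = 0.0
    for img, truth in per_image_truth.items():
        if truth.n == 0:
            log.warning("image %s has empty ground truth; skipped", img)
            continue
        model = lat[ids == img]
        if model.size == 0:
            total += 10.0
            continue
        D, _ = ks_two_sample(LatencySample(model, "model"), truth)
        total += D
    return total


def _mutate(vec: np.ndarray, rng: np.random.Generator, mutation_max: float,
            mask: np.ndarray) -> np.ndarray:
    """Each free parameter scaled by (1 +/- m), m ~ U(0, mutation_max)."""
    m = rng.uniform(0.0, mutation_max, size=vec.size)
    sign = rng.choice((-1.0, 1.0), size=vec.size)
    out = vec * (1.0 + np.where(mask, sign * m, 0.0))
    return out


def ga_optimize(
    initial: ParamVector,
    truth: LatencySample | dict[int, LatencySample],
    ctx: SimContext,
    config: GAConfig = GAConfig(),
    fitness: FitnessSpec = FitnessSpec(),
    objective=None,
) -> OptimizationResult:
    """Mutation-only GA with elitism over the parameter vector.

    Per generation: evaluate all contenders, keep the single best
    unchanged, reset the worst ``reset_count`` to the initial vector,
    mutate the rest multiplicatively.  Stops at ``max_generations``, on
    a perfect fitness, or when the best contender passes both the KS
    and z indistinguishability gates (sum_ks_z variant only).
    """
    rng = np.random.default_rng(config.seed)
    ss = np.random.SeedSequence(config.seed)
    mask = (ctx.free_mask if ctx.free_mask is not None
            else np.ones(len(PARAM_NAMES), dtype=bool))
    per_image = isinstance(truth, dict)
    if per_image and fitness.variant != "per_image_ks":
        raise ValueError("per-image truth requires the per_image_ks variant")

    def evaluate(vec: ParamVector, seed: int):
        if objective is not None:
            return objective(vec), None
        if fitness.variant == "per_image_ks":
            return fitness_per_image_ks(vec, truth, ctx, seed), None
        return fitness_sum_ks_z(vec, truth, ctx, seed)

    population = [ParamVector(initial.values.copy())
                  for _ in range(config.population)]
    trace: list[float] = []
    n_eval = 0
    best_vec, best_fit, best_cmp = population[0], np.inf, None
    reason = "max_generations"
    for gen in range(config.max_generations):
        seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(config.population)]
        fits, cmps = [], []
        for vec, sd in zip(population, seeds):
            if vec is best_vec and np.isfinite(best_fit):
                # elite carried unchanged with its recorded fitness
                fits.append(best_fit)
                cmps.append(best_cmp)
                continue
            f, c = evaluate(vec, sd)
            n_eval += 1
            fits.append(f)
            cmps.append(c)
        if fitness.variant == "z_gate_then_ks":
            # selection by the gate ranking: z-test passers first by D,
            # the rest by |z|; the scalar trace still records D + |z|
            triples = [(c.D, c.z, c.p_z) if c is not None
                       else (2.0, np.inf, 0.0) for c in cmps]
            order = np.asarray(fitness_z_gate_then_ks(triples))
        else:
            order = np.argsort(fits, kind="stable")
        if fits[order[0]] < best_fit:
            best_vec, best_fit = population[order[0]], fits[order[0]]
            best_cmp = cmps[order[0]]
        trace.append(best_fit)
        log.info("GA gen %d: best fitness %.5g", gen, best_fit)
        if best_fit <= 0.0:
            reason = "tolerance"
            break
        if (config.alpha > 0
                and fitness.variant in ("sum_ks_z", "z_gate_then_ks")
                and best_cmp is not None
                and best_cmp.p_ks > config.alpha and best_cmp.p_z > config.alpha):
            reason = "statistical_indistinguishability"
            break
        population = next_generation(population, list(order), best_vec,
                                     initial, config, rng, mask)
    return OptimizationResult(best_vec, float(best_fit), trace, reason,
                              best_cmp, n_eval)


def next_generation(
    population: list[ParamVector],
    order: list[int],
    elite: ParamVector,
    initial: ParamVector,
    config: GAConfig,
    rng: np.random.Generator,
    mask: np.ndarray,
) -> list[ParamVector]:
    """One GA selection step: elite unchanged, worst ``reset_count``
    contenders replaced by the initial vector, the rest mutated."""
    survivors = [population[i]
                 for i in order[: config.population - config.reset_count]]
    next_pop = [elite]
    for vec in survivors:
        if vec is elite:
            continue
        next_pop.append(ParamVector(_mutate(vec.values, rng,
                                            config.mutation_max, mask)))
    next_pop = next_pop[: config.population - config.reset_count]
    while len(next_pop) < config.population:
        next_pop.append(ParamVector(initial.values.copy()))
    return next_pop


def nm_optimize(
    initial: ParamVector,
    truth: LatencySample | dict[int, LatencySample],
    ctx: SimContext,
    fitness: FitnessSpec = FitnessSpec(),
    seed: int = 0,
    maxiter: int | None = None,
    objective=None,
) -> OptimizationResult:
    """Nelder-Mead simplex (reflection 1, expansion 2, contraction 0.5,
    shrink 0.5) with the classic default stop criteria: parameter and
    fitness tolerances 1e-4, iteration/evaluation cap 200 x dimension.

    The fitness is evaluated with one fixed seed (common random
    numbers) so the surface is deterministic.
    """
    per_image = isinstance(truth, dict)
    mask = (ctx.free_mask if ctx.free_mask is not None
            else np.ones(len(PARAM_NAMES), dtype=bool))
    free_idx = np.flatnonzero(mask)
    eval_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31))
    n_eval = 0
    trace: list[float] = []

    def fun(x_free: np.ndarray) -> float:
        nonlocal n_eval
        v = initial.values.copy()
        v[free_idx] = x_free
        vec = ParamVector(v)
        if objective is not None:
            f = objective(vec)
        elif per_image or fitness.variant == "per_image_ks":
            f = fitness_per_image_ks(vec, truth, ctx, eval_seed)
        else:
            f, _ = fitness_sum_ks_z(vec, truth, ctx, eval_seed)
        n_eval += 1
        trace.append(min(f, trace[-1]) if trace else f)
        return f

    x0 = initial.values[free_idx]
    n = x0.size
    cap = maxiter if maxiter is not None else 200 * n
    res = minimize(fun, x0, method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-4,
                            "maxiter": cap, "maxfev": cap})
    v = initial.values.copy()
    v[free_idx] = res.x
    best = ParamVector(v)
    cmp_ = None
    if not per_image and fitness.variant == "sum_ks_z":
        _, cmp_ = fitness_sum_ks_z(best, truth, ctx, eval_seed)
    reason = "tolerance" if res.success else "max_iter"
    return OptimizationResult(best, float(res.fun), trace or [float(res.fun)],
                              reason, cmp_, n_eval)
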