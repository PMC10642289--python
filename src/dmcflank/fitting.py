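"""Simulation-based G2 fitting of the DMC with differential evolution.

Observed data per condition are summarized by the correct-RT cumulative
distribution at five percentiles (inducing six bins) and the conditional
accuracy function in five equal-count bins, separately for congruent and
incongruent trials.  A candidate parameter set is scored by simulating trials
under the identical deadline/floor handling and computing the likelihood-ratio
statistic

    G2 = 2 * sum_congruency [ sum_6 O_i ln(p_obs,i / p_pred,i)
                              + sum_5 n_b (pc ln(pc/phat) + (1-pc) ln((1-pc)/(1-phat))) ]

which is zero when predicted and observed summaries agree and positive
otherwise.  Parameters are estimated by differential evolution over the two
object conditions jointly: boundary ``b`` and the residual-time parameters are
always shared; each conflict parameter (``mu_t``, ``A``, ``tau``) is either
shared or free per condition, giving the eight-model ladder.  Model comparison
uses BIC = G2 + k ln(N) with k the model's estimated-parameter count and N the
included trials entering the condition's summary; the lower the BIC, the
better the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution

from .activation import drift_grid
from .params import DMCParams, SimOptions
from .simulate import (
    CONGRUENCY_SIGN,
    STATUS_OK,
    _walk_batch,
    _walk_batch_pool,
    simulate_condition,
)

__all__ = [
    "CONFLICT_PARAMS",
    "SHARED_PARAMS",
    "ModelSpec",
    "all_model_specs",
    "Bounds",
    "DEFAULT_BOUNDS",
    "DEOptions",
    "CongruencySummary",
    "ObservedSummary",
    "FitResult",
    "summarize_observed",
    "g2",
    "bic",
    "fit_de",
    "model_ladder",
    "recovery_study",
    "split_conditions",
    "CDF_PERCENTILES",
]

CONFLICT_PARAMS = ("mu_t", "A", "tau")
SHARED_PARAMS = ("b", "mu_r", "sigma_r")
CDF_PERCENTILES = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
_CLIP = 1e-10
_MIN_TRIALS = 25
_MAX_SEED = 2**31 - 1
_CONGRUENCIES = ("congruent", "incongruent")


@dataclass(frozen=True)
class ModelSpec:
    """Which conflict parameters may differ between the two object conditions."""

    free_across_conditions: tuple[str, ...] = ()

    def __post_init__(self):
        bad = set(self.free_across_conditions) - set(CONFLICT_PARAMS)
        if bad:
            raise ValueError(f"unknown conflict parameters: {sorted(bad)}")
        ordered = tuple(p for p in CONFLICT_PARAMS if p in self.free_across_conditions)
        object.__setattr__(self, "free_across_conditions", ordered)

    @property
    def k(self) -> int:
        """Number of estimated parameters: 3 shared + 3 conflict + 1 per freed one."""
        return 6 + len(self.free_across_conditions)

    @property
    def name(self) -> str:
        if not self.free_across_conditions:
            return "M_null"
        return "M_" + "+".join(self.free_across_conditions)


def all_model_specs() -> list[ModelSpec]:
    """The eight-model ladder: every subset of {mu_t, A, tau} free."""
    specs = []
    for r in range(len(CONFLICT_PARAMS) + 1):
        for combo in combinations(CONFLICT_PARAMS, r):
            specs.append(ModelSpec(combo))
    return specs


@dataclass(frozen=True)
class Bounds:
    """Box bounds of the estimated parameters (search space of the optimizer)."""

    mu_t: tuple[float, float] = (0.1, 1.5)
    A: tuple[float, float] = (0.0, 40.0)
    tau: tuple[float, float] = (1.0, 500.0)
    b: tuple[float, float] = (20.0, 100.0)
    mu_r: tuple[float, float] = (200.0, 500.0)
    sigma_r: tuple[float, float] = (5.0, 50.0)

    def __post_init__(self):
        for name in ("mu_t", "A", "tau", "b", "mu_r", "sigma_r"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"bounds for {name} must satisfy low < high, got {(lo, hi)}")

    def get(self, name: str) -> tuple[float, float]:
        return getattr(self, name)

    def contains(self, params: DMCParams) -> bool:
        return all(
            self.get(p)[0] <= getattr(params, p) <= self.get(p)[1]
            for p in CONFLICT_PARAMS + SHARED_PARAMS
        )


DEFAULT_BOUNDS = Bounds()


@dataclass(frozen=True)
class DEOptions:
    """Differential-evolution hyperparameters and stopping rule.

    ``popsize`` follows scipy's convention (population = popsize * n_free).
    The search stops when the best G2 has not improved by at least
    ``improvement_tol`` (relative) over the last ``improvement_window``
    generations, or after ``maxiter`` generations.
    """

    popsize: int = 10
    maxiter: int = 500
    improvement_window: int = 50
    improvement_tol: float = 0.01
    mutation: tuple[float, float] = (0.5, 1.0)
    recombination: float = 0.9
    init: str = "latinhypercube"
    common_random_numbers: bool = False
    refine_iters: int = 0  # trailing generations re-scored at n_sim_final trials
    refine_stages: int = 1  # noise-pool refreshes across the refine phase; the
    # reported optimum averages the per-stage bests, shrinking the bias that a
    # single finite noise realization imprints on weakly identified parameters


@dataclass(frozen=True)
class CongruencySummary:
    """Observed fitting target for one congruency."""

    cdf_cuts: np.ndarray  # 5 correct-RT percentile cuts (ms)
    cdf_counts: np.ndarray  # 6 observed correct counts in the induced bins
    n_correct: int
    caf_edges: np.ndarray  # 4 inner RT-quintile edges over included trials
    caf_n: np.ndarray  # 5 trial counts
    caf_correct: np.ndarray  # 5 correct counts
    n_total: int


@dataclass(frozen=True)
class ObservedSummary:
    congruent: CongruencySummary
    incongruent: CongruencySummary

    @property
    def n_included(self) -> int:
        return self.congruent.n_total + self.incongruent.n_total

    def for_congruency(self, congruency: str) -> CongruencySummary:
        return getattr(self, congruency)


def _summarize_congruency(rt: np.ndarray, acc: np.ndarray, label: str) -> CongruencySummary:
    if rt.size < _MIN_TRIALS:
        raise ValueError(
            f"cell {label!r} has {rt.size} included trials; at least {_MIN_TRIALS} required"
        )
    correct_rt = rt[acc == 1]
    if correct_rt.size < _MIN_TRIALS:
        raise ValueError(
            f"cell {label!r} has {correct_rt.size} correct trials; at least {_MIN_TRIALS} required"
        )
    cuts = np.quantile(correct_rt, CDF_PERCENTILES)
    cdf_counts = np.bincount(np.searchsorted(cuts, correct_rt, side="right"), minlength=6)
    edges = np.quantile(rt, np.arange(1, 5) / 5.0)
    idx = np.searchsorted(edges, rt, side="left")
    caf_n = np.bincount(idx, minlength=5).astype(np.int64)
    caf_correct = np.bincount(idx, weights=acc, minlength=5)
    return CongruencySummary(
        cdf_cuts=cuts,
        cdf_counts=cdf_counts.astype(np.int64),
        n_correct=int(correct_rt.size),
        caf_edges=edges,
        caf_n=caf_n,
        caf_correct=caf_correct,
        n_total=int(rt.size),
    )


def summarize_observed(trials: pd.DataFrame) -> ObservedSummary:
    """Build the fitting target from a trial table (status-ok trials only)."""
    ok = trials[trials["status"] == STATUS_OK]
    parts = {}
    for cong in _CONGRUENCIES:
        cell = ok[ok["congruency"] == cong]
        parts[cong] = _summarize_congruency(
            cell["rt_ms"].to_numpy(dtype=float),
            cell["accuracy"].to_numpy(dtype=float),
            cong,
        )
    return ObservedSummary(**parts)


def _xlogy(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    out = np.zeros_like(np.asarray(x, dtype=float))
    pos = np.asarray(x) > 0
    out[pos] = np.asarray(x)[pos] * np.log(np.asarray(y)[pos])
    return out


def _g2_half_terms(obs: CongruencySummary, rt: np.ndarray, acc: np.ndarray) -> float:
    """One congruency's contribution to G2/2 given predicted ok-trial arrays."""
    if rt.size == 0:
        raise ValueError("empty predicted trial set")
    pred_correct = rt[acc == 1]
    if pred_correct.size == 0:
        p_pred = np.full(6, _CLIP)
    else:
        counts = np.bincount(
            np.searchsorted(obs.cdf_cuts, pred_correct, side="right"), minlength=6
        )
        p_pred = counts / pred_correct.size
    p_obs = obs.cdf_counts / obs.n_correct
    p_pred_c = np.clip(p_pred, _CLIP, 1.0)
    cdf_terms = _xlogy(obs.cdf_counts, p_obs / p_pred_c)
    cdf_term = float(np.sum(np.where(p_obs == p_pred, 0.0, cdf_terms)))

    idx = np.searchsorted(obs.caf_edges, rt, side="left")
    n_pred = np.bincount(idx, minlength=5).astype(float)
    c_pred = np.bincount(idx, weights=acc, minlength=5)
    phat_raw = np.where(n_pred > 0, c_pred / np.maximum(n_pred, 1.0), 0.5)
    phat = np.clip(phat_raw, _CLIP, 1.0 - _CLIP)
    pc = obs.caf_correct / obs.caf_n
    caf_terms = _xlogy(obs.caf_n * pc, pc / phat) + _xlogy(
        obs.caf_n * (1.0 - pc), (1.0 - pc) / (1.0 - phat)
    )
    caf_term = float(np.sum(np.where(pc == phat_raw, 0.0, caf_terms)))
    return cdf_term + caf_term


def g2(observed: ObservedSummary, predicted_trials: pd.DataFrame) -> float:
    """Likelihood-ratio statistic between observed summary and predicted trials.

    ``predicted_trials`` must have been simulated under the same deadline and
    floor handling; only status-ok trials enter.  Zero iff the predicted
    summaries coincide with the observed ones.
    """
    ok = predicted_trials[predicted_trials["status"] == STATUS_OK]
    if len(ok) == 0:
        raise ValueError("empty predicted trial table")
    total = 0.0
    for cong in _CONGRUENCIES:
        cell = ok[ok["congruency"] == cong]
        total += _g2_half_terms(
            observed.for_congruency(cong),
            cell["rt_ms"].to_numpy(dtype=float),
            cell["accuracy"].to_numpy(dtype=float),
        )
    return 2.0 * total


def bic(g2_value: float, k: int, n: int) -> float:
    """Bayesian information criterion: G2 + k ln(n); lower is better."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(g2_value) + k * math.log(n)


# ---------------------------------------------------------------------------
# Differential-evolution fitting
# ---------------------------------------------------------------------------


def split_conditions(trials: pd.DataFrame, factor: str = "object") -> dict[str, pd.DataFrame]:
    """Split a trial table into the condition subtables used for joint fitting."""
    return {str(level): sub for level, sub in trials.groupby(factor, sort=True)}


@dataclass
class FitResult:
    """Outcome of one joint DE fit over the two object conditions."""

    spec: ModelSpec
    conditions: tuple[str, ...]
    params_by_condition: dict[str, DMCParams]
    g2_by_condition: dict[str, float]
    bic_by_condition: dict[str, float]
    mean_bic: float
    g2_search: float
    n_iterations: int
    converged: bool
    seed: int
    trace: np.ndarray = field(repr=False, default=None)

    @property
    def mean_g2(self) -> float:
        return float(np.mean(list(self.g2_by_condition.values())))


def _vector_layout(spec: ModelSpec, conditions: tuple[str, ...]):
    """(name, condition-or-None) per free-vector entry; shared params first."""
    layout = [(p, None) for p in SHARED_PARAMS]
    for p in CONFLICT_PARAMS:
        if p in spec.free_across_conditions:
            layout.extend((p, c) for c in conditions)
        else:
            layout.append((p, None))
    return layout


def _decode(x: np.ndarray, layout, conditions, fixed: DMCParams | None = None) -> dict[str, DMCParams]:
    base = dict(sigma=4.0, alpha_s=3.0, a_shape=2.0) if fixed is None else dict(
        sigma=fixed.sigma, alpha_s=fixed.alpha_s, a_shape=fixed.a_shape
    )
    per_cond = {c: dict(base) for c in conditions}
    for value, (name, cond) in zip(x, layout):
        if cond is None:
            for c in conditions:
                per_cond[c][name] = float(value)
        else:
            per_cond[cond][name] = float(value)
    return {c: DMCParams(**kw) for c, kw in per_cond.items()}


_POOL_HORIZON = 2048  # per-trial noise horizon (steps) of a CRN pool


@dataclass(frozen=True)
class NoisePool:
    """Pre-generated per-trial noise for common-random-numbers evaluation."""

    noise: np.ndarray  # (n, horizon) float32 standard normals
    z0: np.ndarray  # (n,) starting points as fractions of b in (-1, 1)
    resid_std: np.ndarray  # (n,) standard normals for the residual stage
    fallback_seed: int


def make_noise_pool(n: int, alpha_s: float, rng: np.random.Generator,
                    horizon: int = _POOL_HORIZON) -> NoisePool:
    return NoisePool(
        noise=rng.standard_normal((int(n), int(horizon))).astype(np.float32),
        z0=2.0 * rng.beta(alpha_s, alpha_s, int(n)) - 1.0,
        resid_std=rng.standard_normal(int(n)),
        fallback_seed=int(rng.integers(_MAX_SEED)),
    )


def _predict_cell(
    params: DMCParams, sign: int, n_sim: int, options: SimOptions, seed: int,
    pool: NoisePool | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one cell and return status-ok (rt, accuracy) arrays.

    With a ``pool``, the walk consumes pre-generated noise indexed by
    (trial, step) so that repeated evaluations differ only through the
    parameters (common random numbers); otherwise fresh noise is drawn.
    """
    auto = drift_grid(params, sign, options.dt, options.max_steps)
    if pool is not None:
        dec_t, correct, absorbed = _walk_batch_pool(
            pool.z0.size,
            float(params.mu_t),
            auto,
            float(params.b),
            float(params.sigma),
            float(options.dt),
            int(options.max_steps),
            pool.noise,
            pool.z0,
            pool.fallback_seed,
        )
        resid = np.maximum(params.mu_r + params.sigma_r * pool.resid_std, 0.0)
    else:
        dec_t, correct, absorbed = _walk_batch(
            int(n_sim),
            float(params.mu_t),
            auto,
            float(params.b),
            float(params.sigma),
            float(params.alpha_s),
            float(options.dt),
            int(options.max_steps),
            int(seed) % _MAX_SEED,
        )
        rng = np.random.default_rng(int(seed))
        resid = rng.normal(params.mu_r, params.sigma_r, size=int(n_sim))
        bad = resid < 0
        while bad.any():
            resid[bad] = rng.normal(params.mu_r, params.sigma_r, size=int(bad.sum()))
            bad = resid < 0
    rt = dec_t + resid
    ok = absorbed & (rt >= options.rt_floor) & (rt <= options.deadline)
    return rt[ok], correct[ok].astype(float)


def _total_g2(
    params_by_cond: dict[str, DMCParams],
    observed: dict[str, ObservedSummary],
    n_sim: int,
    options: SimOptions,
    seeds: np.ndarray,
    pools: list[NoisePool] | None = None,
) -> float:
    total = 0.0
    i = 0
    for cond, obs in observed.items():
        for cong in _CONGRUENCIES:
            rt, acc = _predict_cell(
                params_by_cond[cond],
                CONGRUENCY_SIGN[cong],
                n_sim,
                options,
                int(seeds[i]),
                pool=pools[i] if pools is not None else None,
            )
            i += 1
            if rt.size == 0:
                return 1e12  # pathological candidate: nothing survives the window
            total += _g2_half_terms(obs.for_congruency(cong), rt, acc)
    return 2.0 * total


def fit_de(
    trials_by_condition: dict[str, pd.DataFrame],
    spec: ModelSpec,
    bounds: Bounds = DEFAULT_BOUNDS,
    n_sim: int = 10_000,
    de_options: DEOptions = DEOptions(),
    seed: int | None = None,
    n_sim_final: int | None = None,
    sim_options: SimOptions = SimOptions(),
) -> FitResult:
    """Jointly fit the DMC to two conditions by G2 minimization.

    ``trials_by_condition`` maps the two object-condition labels to trial
    tables containing both congruencies.  Shared parameters (``b``, ``mu_r``,
    ``sigma_r`` and any conflict parameter not freed by ``spec``) take a
    single value across conditions.  Each candidate is scored with ``n_sim``
    fresh simulated trials per condition-congruency cell; the returned
    per-condition G2 and BIC are re-evaluated at ``n_sim_final`` trials
    (default: max(n_sim, 10000)).  Fully reproducible for a fixed ``seed``.
    """
    conditions = tuple(trials_by_condition)
    if len(conditions) != 2:
        raise ValueError(f"joint fitting expects exactly 2 conditions, got {conditions}")
    observed = {c: summarize_observed(t) for c, t in trials_by_condition.items()}
    layout = _vector_layout(spec, conditions)
    box = [bounds.get(name) for name, _ in layout]

    master = np.random.SeedSequence(seed if seed is not None else np.random.randint(_MAX_SEED))
    ss_de, ss_eval, ss_final = master.spawn(3)
    eval_rng = np.random.default_rng(ss_eval)
    n_cells = len(conditions) * 2
    alpha_s = 3.0
    n_final = n_sim_final if n_sim_final is not None else max(n_sim, 10_000)

    def _pools(n: int) -> list[NoisePool]:
        return [make_noise_pool(n, alpha_s, eval_rng) for _ in range(n_cells)]

    crn = de_options.common_random_numbers
    search_pools = _pools(n_sim) if crn else None

    best_so_far = [np.inf]
    trace: list[float] = []
    phase_pools = [search_pools]
    phase_n = [n_sim]

    def objective(x: np.ndarray) -> float:
        seeds = (
            np.zeros(n_cells, dtype=np.int64)
            if phase_pools[0] is not None
            else eval_rng.integers(_MAX_SEED, size=n_cells)
        )
        val = _total_g2(
            _decode(x, layout, conditions), observed, phase_n[0], sim_options, seeds,
            pools=phase_pools[0],
        )
        if val < best_so_far[0]:
            best_so_far[0] = val
        return val

    win, tol = de_options.improvement_window, de_options.improvement_tol

    def callback(xk, convergence=0.0) -> bool:
        trace.append(best_so_far[0])
        if len(trace) > win:
            ref = trace[-win - 1]
            if ref > 0 and (ref - trace[-1]) < tol * ref:
                return True
        return False

    de_rng = np.random.default_rng(ss_de)
    refine = min(de_options.refine_iters, de_options.maxiter - 1)
    common = dict(
        strategy="best1bin",
        popsize=de_options.popsize,
        tol=0.0,
        mutation=de_options.mutation,
        recombination=de_options.recombination,
        polish=False,
        updating="deferred",
        callback=callback,
    )
    result = differential_evolution(
        objective,
        box,
        maxiter=de_options.maxiter - refine,
        init=de_options.init,
        seed=int(de_rng.integers(_MAX_SEED)),
        **common,
    )
    if refine > 0:
        # final-evaluation phase: re-score the surviving population with the
        # larger simulation budget and let the search settle there; with
        # several stages the noise pools are refreshed between stages and the
        # per-stage optima averaged
        stages = max(1, de_options.refine_stages)
        per_stage = [refine // stages + (1 if s < refine % stages else 0) for s in range(stages)]
        stage_bests = []
        phase_n[0] = n_final
        for iters in per_stage:
            if iters == 0:
                continue
            phase_pools[0] = _pools(n_final) if crn else None
            best_so_far[0] = np.inf
            result = differential_evolution(
                objective,
                box,
                maxiter=iters,
                init=result.population,
                seed=int(de_rng.integers(_MAX_SEED)),
                **common,
            )
            stage_bests.append(np.asarray(result.x, dtype=float))
        x_best = np.mean(stage_bests, axis=0)
    else:
        x_best = np.asarray(result.x, dtype=float)

    params_by_cond = _decode(x_best, layout, conditions)
    final_rng = np.random.default_rng(ss_final)
    g2_by_cond: dict[str, float] = {}
    bic_by_cond: dict[str, float] = {}
    for cond in conditions:
        total = 0.0
        for cong in _CONGRUENCIES:
            rt, acc = _predict_cell(
                params_by_cond[cond],
                CONGRUENCY_SIGN[cong],
                n_final,
                sim_options,
                int(final_rng.integers(_MAX_SEED)),
            )
            total += _g2_half_terms(observed[cond].for_congruency(cong), rt, acc)
        g2_c = 2.0 * total
        g2_by_cond[cond] = g2_c
        bic_by_cond[cond] = bic(g2_c, spec.k, observed[cond].n_included)

    n_iter = len(trace)
    return FitResult(
        spec=spec,
        conditions=conditions,
        params_by_condition=params_by_cond,
        g2_by_condition=g2_by_cond,
        bic_by_condition=bic_by_cond,
        mean_bic=float(np.mean(list(bic_by_cond.values()))),
        g2_search=float(result.fun),
        n_iterations=n_iter,
        converged=bool(n_iter < de_options.maxiter),
        seed=int(master.entropy) if isinstance(master.entropy, int) else -1,
        trace=np.asarray(trace),
    )


def model_ladder(
    trials_by_condition: dict[str, pd.DataFrame],
    n_sim: int = 10_000,
    seed: int | None = None,
    bounds: Bounds = DEFAULT_BOUNDS,
    de_options: DEOptions = DEOptions(),
    specs: list[ModelSpec] | None = None,
    sim_options: SimOptions = SimOptions(),
    n_sim_final: int | None = None,
) -> tuple[pd.DataFrame, dict[str, FitResult]]:
    """Fit the eight-model hierarchy to one participant's data.

    Returns a table (one row per model, ascending mean BIC) and the underlying
    ``FitResult`` objects.  Failures of individual fits are recorded as rows
    with NaN scores; the remaining models are still reported.
    """
    specs = all_model_specs() if specs is None else specs
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % _MAX_SEED) for s in ss.spawn(len(specs))]
    rows = []
    results: dict[str, FitResult] = {}
    for ms, s in zip(specs, child_seeds):
        row: dict = {"model": ms.name, "free": ",".join(ms.free_across_conditions), "k": ms.k}
        try:
            fr = fit_de(
                trials_by_condition,
                ms,
                bounds=bounds,
                n_sim=n_sim,
                de_options=de_options,
                seed=s,
                sim_options=sim_options,
                n_sim_final=n_sim_final,
            )
            results[ms.name] = fr
            row["mean_bic"] = fr.mean_bic
            row["mean_g2"] = fr.mean_g2
            row["converged"] = fr.converged
            for cond, p in fr.params_by_condition.items():
                for name in CONFLICT_PARAMS + SHARED_PARAMS:
                    row[f"{name}[{cond}]"] = getattr(p, name)
        except Exception as exc:  # keep partial ladder results
            row["mean_bic"] = np.nan
            row["mean_g2"] = np.nan
            row["converged"] = False
            row["error"] = str(exc)
        rows.append(row)
    table = pd.DataFrame(rows).sort_values("mean_bic", na_position="last").reset_index(drop=True)
    return table, results


def recovery_study(
    true_params_by_condition: dict[str, DMCParams],
    spec: ModelSpec,
    n_trials: int,
    n_reps: int,
    seed: int | None = None,
    bounds: Bounds = DEFAULT_BOUNDS,
    n_sim: int = 2_000,
    de_options: DEOptions = DEOptions(),
    sim_options: SimOptions = SimOptions(),
    n_sim_final: int | None = None,
) -> pd.DataFrame:
    """Simulate-and-refit: quantify parameter recovery for a generating model.

    For each replicate, ``n_trials`` trials per condition-congruency cell are
    simulated from the true parameters and the generating ``spec`` is refitted.
    Returns a tidy frame with one row per replicate x condition x parameter
    (columns: rep, condition, param, true, estimated, error).
    """
    for cond, p in true_params_by_condition.items():
        if not bounds.contains(p):
            raise ValueError(f"true parameters for condition {cond!r} violate the fitting bounds")
    ss = np.random.SeedSequence(seed)
    rows = []
    for rep, rep_ss in enumerate(ss.spawn(n_reps)):
        gen_rng = np.random.default_rng(rep_ss)
        fit_seed = int(gen_rng.integers(_MAX_SEED))
        trials_by_cond = {}
        for cond, p in true_params_by_condition.items():
            tabs = [
                simulate_condition(
                    p, cong, n_trials, sim_options, gen_rng, object_membership=cond
                )
                for cong in _CONGRUENCIES
            ]
            trials_by_cond[cond] = pd.concat(tabs, ignore_index=True)
        fr = fit_de(
            trials_by_cond,
            spec,
            bounds=bounds,
            n_sim=n_sim,
            de_options=de_options,
            seed=fit_seed,
            sim_options=sim_options,
            n_sim_final=n_sim_final,
        )
        for cond, truth in true_params_by_condition.items():
            est = fr.params_by_condition[cond]
            for name in CONFLICT_PARAMS + SHARED_PARAMS:
                rows.append(
                    {
                        "rep": rep,
                        "condition": cond,
                        "param": name,
                        "true": getattr(truth, name),
                        "estimated": getattr(est, name),
                        "error": getattr(est, name) - getattr(truth, name),
                    }
                )
    return pd.DataFrame(rows)


def recovery_summary(report: pd.DataFrame) -> pd.DataFrame:
    """Per-parameter bias and RMSE across replicates of a recovery study."""
    g = report.groupby(["param", "condition"])
    out = g.agg(
        true=("true", "first"),
        bias=("error", "mean"),
        rmse=("error", lambda e: float(np.sqrt(np.mean(np.square(e))))),
    ).reset_index()
    return out
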