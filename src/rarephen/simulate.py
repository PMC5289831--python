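"""Synthetic-data generation and the three simulation studies.

The generator emulates a high-throughput phenotyping screen: weekly control
cohorts of seven males and seven females accumulated over two years (104
weeks, 728 animals per sex), each binary trait drawn independently per
animal from a per-trait abnormality rate.  Knockout cohorts of seven per
sex are either relabeled from the control pool (null resampling) or drawn
fresh with abnormality probability baseline + effect, clamped at 1 —
effects are additive on the probability scale.

Three studies are provided:

* ``resample_null_t1e`` — global-null type-I error: relabel 7+7 control
  animals as knockouts and tally rejections per method and threshold.
* ``stage2_t1e_with_genotype_effect`` — stage-2 type-I error when a genuine
  genotype effect (equal in both sexes, so no true interaction) is present,
  with and without stage-1 filtering.
* ``power_sim`` — stage-1 and stage-2 power over grids of baseline rates,
  main effects and one-sex interaction effects.

All randomness flows from a single integer seed; per-cell substreams are
spawned deterministically, so identical seeds give identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .pipeline import STAGE1_METHODS, STAGE2_METHODS
from .tables import SexStratifiedCounts, TwoByTwo, ValidationError

__all__ = [
    "ControlPool",
    "SimulationGrid",
    "default_rate_panel",
    "gen_control",
    "resample_null_t1e",
    "stage2_t1e_with_genotype_effect",
    "power_sim",
]

_ALL_METHODS = {**STAGE1_METHODS, **STAGE2_METHODS}


@lru_cache(maxsize=2_000_000)
def _p_cached(method: str, kwf: int, nwf: int, kwm: int, nwm: int,
              kkf: int, nkf: int, kkm: int, nkm: int) -> float:
    d = SexStratifiedCounts(
        male=TwoByTwo(kkm, nkm, kwm, nwm),
        female=TwoByTwo(kkf, nkf, kwf, nwf),
    )
    return _ALL_METHODS[method](d).p_value


def _mc_se(frac: float, iters: int) -> float:
    return float(np.sqrt(frac * (1 - frac) / iters)) if iters else float("nan")


@dataclass(frozen=True)
class ControlPool:
    """Simulated control outcomes: one row per trait, one column per animal."""

    rates: np.ndarray          # (n_traits,)
    male: np.ndarray           # (n_traits, n_per_sex) of 0/1
    female: np.ndarray
    seed: int
    weeks: int
    per_sex_per_week: int

    @property
    def n_traits(self) -> int:
        return self.male.shape[0]

    @property
    def n_per_sex(self) -> int:
        return self.male.shape[1]


@dataclass(frozen=True)
class SimulationGrid:
    """Parameter grids for the simulation studies (study-design defaults)."""

    baseline_rates: tuple = (0.0, 0.01, 0.025, 0.05, 0.075)
    main_effects: tuple = (0.0, 0.1, 0.2, 0.3)
    interaction_effects: tuple = (0.0, 0.2, 0.35)
    thresholds: tuple = (0.05, 0.025, 0.01, 0.001)
    stage1_filters: tuple = (0.001, 0.01, 0.025, 0.05)
    iterations: int = 1000
    n_ko_per_sex: int = 7
    weeks: int = 104
    per_sex_per_week: int = 7
    interaction_sex: str = "M"
    stage1_methods: tuple = ("FE", "FE_mid", "MH_mid", "LR_G")
    stage2_methods: tuple = ("Zelen", "LR_I", "LR_KO", "FE_KO")

    def __post_init__(self) -> None:
        for r in self.baseline_rates:
            if not 0 <= r <= 1:
                raise ValidationError("baseline rates must lie in [0, 1]")
        for e in self.main_effects + self.interaction_effects:
            if not 0 <= e <= 1:
                raise ValidationError("effects must lie in [0, 1]")
        if self.interaction_sex not in ("M", "F"):
            raise ValidationError("interaction_sex must be 'M' or 'F'")
        if self.iterations < 1:
            raise ValidationError("iterations must be >= 1")


def default_rate_panel(n_traits: int = 100, low: float = 1e-5,
                       high: float = 0.05) -> np.ndarray:
    """Log-spaced per-trait abnormality rates spanning the rare-event range."""
    return np.geomspace(low, high, n_traits)


def gen_control(rates: Sequence[float], weeks: int = 104,
                per_sex_per_week: int = 7, seed: int = 0) -> ControlPool:
    """Draw a control pool: independent Bernoulli outcomes per animal/trait/sex."""
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0) or np.any(rates > 1) or np.any(~np.isfinite(rates)):
        raise ValidationError("rates must lie in [0, 1]")
    n = weeks * per_sex_per_week
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    male = (rng.random((rates.size, n)) < rates[:, None]).astype(np.int8)
    female = (rng.random((rates.size, n)) < rates[:, None]).astype(np.int8)
    return ControlPool(rates=rates, male=male, female=female, seed=seed,
                       weeks=weeks, per_sex_per_week=per_sex_per_week)


def resample_null_t1e(pool: ControlPool, n_ko_per_sex: int = 7,
                      iterations: int = 1000,
                      methods: Sequence[str] = ("FE", "FE_mid", "MH_mid"),
                      thresholds: Sequence[float] = (0.05,),
                      seed: int = 0, shared_draw: bool = True) -> pd.DataFrame:
    """Global-null resampling: relabel control animals as knockouts.

    Each iteration samples ``n_ko_per_sex`` animals per sex without
    replacement from the pool and relabels them knockout; every requested
    method is run on every trait and rejections at each threshold tallied.
    With ``shared_draw`` (default) the same animals are relabeled for all
    traits, mirroring a real cohort re-assayed across traits; otherwise each
    trait draws its own animals.
    """
    for m in methods:
        if m not in _ALL_METHODS:
            raise ValidationError(f"unknown method {m!r}")
    n = pool.n_per_sex
    if n_ko_per_sex > n:
        raise ValidationError("knockout draw exceeds pool size")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    totals_m = pool.male.sum(axis=1)
    totals_f = pool.female.sum(axis=1)
    n_wt = n - n_ko_per_sex
    T = pool.n_traits
    rej = {(m, th): np.zeros(T, dtype=np.int64)
           for m in methods for th in thresholds}
    for _ in range(iterations):
        if shared_draw:
            idx_m = rng.choice(n, n_ko_per_sex, replace=False)
            idx_f = rng.choice(n, n_ko_per_sex, replace=False)
            kkm = pool.male[:, idx_m].sum(axis=1)
            kkf = pool.female[:, idx_f].sum(axis=1)
        else:
            kkm = np.empty(T, dtype=np.int64)
            kkf = np.empty(T, dtype=np.int64)
            for t in range(T):
                kkm[t] = pool.male[t, rng.choice(n, n_ko_per_sex,
                                                 replace=False)].sum()
                kkf[t] = pool.female[t, rng.choice(n, n_ko_per_sex,
                                                   replace=False)].sum()
        kwm = totals_m - kkm
        kwf = totals_f - kkf
        for t in range(T):
            for m in methods:
                p = _p_cached(m, int(kwf[t]), n_wt, int(kwm[t]), n_wt,
                              int(kkf[t]), n_ko_per_sex, int(kkm[t]),
                              n_ko_per_sex)
                for th in thresholds:
                    if p <= th:
                        rej[(m, th)][t] += 1
    rows = []
    for m in methods:
        for th in thresholds:
            counts = rej[(m, th)]
            for t in range(T):
                f = counts[t] / iterations
                rows.append({"method": m, "threshold": th,
                             "trait": f"trait_{t:03d}",
                             "rate": pool.rates[t],
                             "rejection_fraction": f,
                             "mc_se": _mc_se(f, iterations),
                             "iterations": iterations})
            overall = counts.sum() / (iterations * T)
            rows.append({"method": m, "threshold": th, "trait": "overall",
                         "rate": np.nan, "rejection_fraction": overall,
                         "mc_se": _mc_se(overall, iterations * T),
                         "iterations": iterations * T})
    return pd.DataFrame(rows)


def _draw_counts(rng, iters: int, n_wt: int, baseline: float,
                 n_ko: int, p_ko_m: float, p_ko_f: float):
    """Margin counts for one grid cell: WT and KO events per sex, per iteration."""
    kwm = rng.binomial(n_wt, baseline, size=iters)
    kwf = rng.binomial(n_wt, baseline, size=iters)
    kkm = rng.binomial(n_ko, p_ko_m, size=iters)
    kkf = rng.binomial(n_ko, p_ko_f, size=iters)
    return kwm, kwf, kkm, kkf


def _pvals_for(method: str, kwm, kwf, kkm, kkf, n_wt: int, n_ko: int):
    stacked = np.stack([kwf, kwm, kkf, kkm], axis=1)
    uniq, inv = np.unique(stacked, axis=0, return_inverse=True)
    ps = np.array([
        _p_cached(method, int(a), n_wt, int(b), n_wt, int(c), n_ko, int(d), n_ko)
        for a, b, c, d in uniq
    ])
    return ps[inv]


def stage2_t1e_with_genotype_effect(grid: SimulationGrid,
                                    seed: int = 0,
                                    baseline: float = 0.05,
                                    effects: Optional[Sequence[float]] = None,
                                    stage1_method: str = "MH_mid",
                                    stage2_method: str = "LR_KO") -> pd.DataFrame:
    """Stage-2 type-I error when a genotype effect hits both sexes equally.

    Knockouts of both sexes get abnormality probability min(1, baseline +
    effect) — a pure main effect, so any stage-2 rejection is a false call.
    Rejection fractions are tabulated per (effect, stage-2 threshold) cell,
    without filtering and after requiring stage-1 significance at each
    filter level in ``grid.stage1_filters``.
    """
    effects = tuple(grid.main_effects if effects is None
                    else effects) or (0.0,)
    n_ko = grid.n_ko_per_sex
    n_wt = grid.weeks * grid.per_sex_per_week - n_ko
    rows = []
    for ci, eff in enumerate(effects):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(1, ci)))
        p_ko = min(1.0, baseline + eff)
        kwm, kwf, kkm, kkf = _draw_counts(rng, grid.iterations, n_wt,
                                          baseline, n_ko, p_ko, p_ko)
        p1 = _pvals_for(stage1_method, kwm, kwf, kkm, kkf, n_wt, n_ko)
        p2 = _pvals_for(stage2_method, kwm, kwf, kkm, kkf, n_wt, n_ko)
        for th in grid.thresholds:
            reject2 = p2 <= th
            for filt in (None,) + tuple(grid.stage1_filters):
                mask = reject2 if filt is None else (reject2 & (p1 <= filt))
                f = float(mask.mean())
                rows.append({"effect": eff, "threshold": th,
                             "stage1_filter": np.nan if filt is None else filt,
                             "rejection_fraction": f,
                             "mc_se": _mc_se(f, grid.iterations),
                             "iterations": grid.iterations})
    return pd.DataFrame(rows)


def power_sim(grid: SimulationGrid, seed: int = 0,
              alpha: float = 0.05,
              stage1_filter_method: str = "MH_mid") -> pd.DataFrame:
    """Power of every stage-1 and stage-2 method over the effect grids.

    One sex (``grid.interaction_sex``) receives baseline + main +
    interaction, the other baseline + main; wild-types stay at baseline.
    Stage-2 power is reported both unconditionally and after the stage-1
    significance filter (``stage1_filter_method`` at level ``alpha``) on the
    same draws, so comparisons between methods are paired.
    """
    n_ko = grid.n_ko_per_sex
    n_wt = grid.weeks * grid.per_sex_per_week - n_ko
    rows = []
    cells = [(b, me, ie)
             for b in grid.baseline_rates
             for me in grid.main_effects
             for ie in grid.interaction_effects]
    for ci, (b, me, ie) in enumerate(cells):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(2, ci)))
        p_int = min(1.0, b + me + ie)
        p_main = min(1.0, b + me)
        p_m, p_f = (p_int, p_main) if grid.interaction_sex == "M" else \
                   (p_main, p_int)
        kwm, kwf, kkm, kkf = _draw_counts(rng, grid.iterations, n_wt, b,
                                          n_ko, p_m, p_f)
        pvals = {m: _pvals_for(m, kwm, kwf, kkm, kkf, n_wt, n_ko)
                 for m in set(grid.stage1_methods) | set(grid.stage2_methods)
                 | {stage1_filter_method}}
        stage1_pass = pvals[stage1_filter_method] <= alpha
        base = {"baseline": b, "main_effect": me, "interaction_effect": ie,
                "iterations": grid.iterations}
        for m in grid.stage1_methods:
            f = float((pvals[m] <= alpha).mean())
            rows.append({**base, "stage": 1, "method": m,
                         "stage1_filtered": False, "power": f,
                         "mc_se": _mc_se(f, grid.iterations)})
        for m in grid.stage2_methods:
            rej = pvals[m] <= alpha
            for filtered, mask in ((False, rej), (True, rej & stage1_pass)):
                f = float(mask.mean())
                rows.append({**base, "stage": 2, "method": m,
                             "stage1_filtered": filtered, "power": f,
                             "mc_se": _mc_se(f, grid.iterations)})
    return pd.DataFrame(rows)
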