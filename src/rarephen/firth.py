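"""Firth bias-reduced logistic regression and penalized likelihood-ratio tests.

Rare-event binary phenotypes routinely produce separated data (e.g. every
knockout abnormal, no wild-type abnormal), under which ordinary maximum
likelihood diverges.  Firth's correction maximizes the penalized
log-likelihood

    l*(beta) = l(beta) + 1/2 log det I(beta),

where I(beta) = X' W X is the Fisher information (W = diag of n_i pi_i
(1 - pi_i)); the penalty is Jeffreys' invariant prior and keeps every
coefficient finite.

Nested models are compared with a penalized likelihood-ratio test: the
constrained fit fixes the tested coefficients at zero but retains the FULL
design's penalty (the tested columns still enter I(beta)), and twice the
penalized log-likelihood difference is referred to a chi-square law.  A
separate-null mode (each model carries its own penalty) is available but is
not the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .tables import SexStratifiedCounts, TestResult, ValidationError

__all__ = [
    "FirthFit",
    "SingularDesignError",
    "fit_firth",
    "penalized_lrt",
    "lr_g",
    "lr_i",
    "lr_ko",
    "batch_screen",
]


class SingularDesignError(ValidationError):
    """The free columns of the design matrix are rank deficient."""


@dataclass
class FirthFit:
    coefficients: np.ndarray
    penalized_loglik: float
    loglik: float
    converged: bool
    iterations: int
    fisher_information: np.ndarray


def _validate_design(X: np.ndarray, y: np.ndarray, weights: np.ndarray) -> None:
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValidationError("design matrix must be 2-D with >= 1 column")
    if not np.all(np.isfinite(X)):
        raise ValidationError("design matrix entries must be finite")
    if X.shape[0] != y.shape[0]:
        raise ValidationError("rows of X must match length of y")
    if not np.all((y == 0) | (y == 1)):
        raise ValidationError("response must be binary (0/1)")
    if np.any(weights < 0) or not np.all(np.isfinite(weights)):
        raise ValidationError("weights must be finite and non-negative")


def _penalized_loglik(X, y, w, beta):
    eta = X @ beta
    pi = 1.0 / (1.0 + np.exp(-eta))
    # clip only to guard log of exactly 0/1 at extreme eta; fits stay interior
    pi = np.clip(pi, 1e-300, 1 - 1e-16)
    ll = float(np.sum(w * (y * np.log(pi) + (1 - y) * np.log1p(-pi))))
    W = w * pi * (1 - pi)
    info = X.T @ (X * W[:, None])
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return ll, -np.inf, info
    return ll, ll + 0.5 * logdet, info


def fit_firth(
    X: np.ndarray,
    y: np.ndarray,
    fixed_zero: Iterable[int] = (),
    *,
    weights: Optional[np.ndarray] = None,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> FirthFit:
    """Maximize the Firth-penalized log-likelihood.

    Parameters
    ----------
    X, y
        Design matrix and binary response.  Rows may be aggregated: pass
        ``weights`` with per-row replication counts (fractional weights are
        accepted but untypical).
    fixed_zero
        Column indices whose coefficients are constrained to zero.  The
        penalty remains that of the full design: constrained columns still
        contribute to the Fisher information, which is the convention the
        penalized LRT relies on.

    Newton iterations with step-halving start from beta = 0; convergence
    requires the penalized score on the free coordinates and the coefficient
    update both below ``tol``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    w = np.ones(X.shape[0]) if weights is None else np.asarray(weights, float).ravel()
    _validate_design(X, y, w)

    p = X.shape[1]
    fixed = set(int(j) for j in fixed_zero)
    if not all(0 <= j < p for j in fixed):
        raise ValidationError("fixed_zero indices out of range")
    free = np.array([j for j in range(p) if j not in fixed], dtype=int)
    if free.size == 0:
        raise ValidationError("no free coefficients to fit")

    # rank check on the weighted free columns
    Xw = X[w > 0][:, free]
    if np.linalg.matrix_rank(Xw) < free.size:
        raise SingularDesignError("free columns of the design are rank deficient")

    beta = np.zeros(p)
    ll, pll, info = _penalized_loglik(X, y, w, beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        pi = 1.0 / (1.0 + np.exp(-eta))
        W = w * pi * (1 - pi)
        info = X.T @ (X * W[:, None])
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            raise SingularDesignError("Fisher information is singular")
        # hat diagonals of the full design; the 1/2 - pi term is Firth's
        # bias-reducing score modification
        h = W * np.einsum("ij,jk,ik->i", X, info_inv, X)
        score = X.T @ (w * (y - pi) + h * (0.5 - pi))
        score_free = score[free]
        info_free = info[np.ix_(free, free)]
        try:
            step = np.linalg.solve(info_free, score_free)
        except np.linalg.LinAlgError:
            raise SingularDesignError("free-block Fisher information is singular")

        candidate = beta.copy()
        candidate[free] += step
        ll_new, pll_new, _ = _penalized_loglik(X, y, w, candidate)
        halvings = 0
        while pll_new < pll and halvings < 25:
            step *= 0.5
            candidate = beta.copy()
            candidate[free] += step
            ll_new, pll_new, _ = _penalized_loglik(X, y, w, candidate)
            halvings += 1
        beta = candidate
        ll, pll = ll_new, pll_new
        if np.max(np.abs(score_free)) <= tol and np.max(np.abs(step)) <= tol:
            converged = True
            break

    _, _, info = _penalized_loglik(X, y, w, beta)
    return FirthFit(
        coefficients=beta,
        penalized_loglik=pll,
        loglik=ll,
        converged=converged,
        iterations=it,
        fisher_information=info,
    )


def penalized_lrt(
    X: np.ndarray,
    y: np.ndarray,
    tested_columns: Iterable[int],
    *,
    weights: Optional[np.ndarray] = None,
    method: str = "penalized_lrt",
    mode: str = "full-penalty",
    tol: float = 1e-8,
    max_iter: int = 50,
) -> TestResult:
    """Penalized likelihood-ratio test for the listed coefficients being zero.

    ``mode='full-penalty'`` (default) evaluates the constrained model with
    the full design's Jeffreys penalty; ``mode='separate-null'`` refits the
    reduced design with its own penalty.
    """
    tested = sorted(set(int(j) for j in tested_columns))
    if not tested:
        raise ValidationError("tested_columns must be nonempty")
    full = fit_firth(X, y, weights=weights, tol=tol, max_iter=max_iter)
    if mode == "full-penalty":
        null = fit_firth(X, y, fixed_zero=tested, weights=weights, tol=tol,
                         max_iter=max_iter)
    elif mode == "separate-null":
        keep = [j for j in range(np.asarray(X).shape[1]) if j not in tested]
        null = fit_firth(np.asarray(X, float)[:, keep], y, weights=weights,
                         tol=tol, max_iter=max_iter)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    warnings: tuple[str, ...] = ()
    if not (full.converged and null.converged):
        return TestResult(method=method, p_value=1.0, statistic=0.0,
                          df=len(tested), converged=False,
                          warnings=("non-converged Firth fit; p set to 1",))
    stat = 2.0 * (full.penalized_loglik - null.penalized_loglik)
    if stat < 0:
        stat = 0.0  # tiny negatives can arise from the shared-penalty convention
    df = len(tested)
    p = float(chi2.sf(stat, df))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return TestResult(method=method, p_value=p, statistic=float(stat), df=df,
                      warnings=warnings)


# ---------------------------------------------------------------------------
# Count-level designs.  Every stage test is a function of the eight cell
# counts only, so results are memoized on those counts.

def _cell_design(cells: Sequence[tuple[Sequence[float], int, int]]):
    """Expand (covariate row, events, trials) cells into weighted 0/1 rows."""
    rows, ys, ws = [], [], []
    for x, events, trials in cells:
        if trials < 0 or events < 0 or events > trials:
            raise ValidationError("inconsistent cell counts")
        rows.extend([list(x), list(x)])
        ys.extend([1.0, 0.0])
        ws.extend([events, trials - events])
    return np.array(rows, float), np.array(ys), np.array(ws, float)


@lru_cache(maxsize=100_000)
def _lr_ko_counts(n_m: int, n_f: int, k_m: int, k_f: int, mode: str) -> tuple:
    # knockout-only: Y ~ sex  vs  Y ~ 1; sex coded male=1 (female reference)
    X, y, w = _cell_design([
        ((1, 0), k_f, n_f),
        ((1, 1), k_m, n_m),
    ])
    r = penalized_lrt(X, y, [1], weights=w, method="LR_KO", mode=mode)
    return (r.p_value, r.statistic, r.df, r.converged, r.warnings)


@lru_cache(maxsize=100_000)
def _lr_full_counts(counts: tuple, tested: tuple, method: str, mode: str) -> tuple:
    """counts = (wt_f, wt_m, ko_f, ko_m) as (events, trials) pairs flattened."""
    (kwf, nwf, kwm, nwm, kkf, nkf, kkm, nkm) = counts
    # columns: intercept, sex(M=1), genotype(KO=1), sex*genotype
    X, y, w = _cell_design([
        ((1, 0, 0, 0), kwf, nwf),
        ((1, 1, 0, 0), kwm, nwm),
        ((1, 0, 1, 0), kkf, nkf),
        ((1, 1, 1, 1), kkm, nkm),
    ])
    r = penalized_lrt(X, y, list(tested), weights=w, method=method, mode=mode)
    return (r.p_value, r.statistic, r.df, r.converged, r.warnings)


def _result_from_tuple(t: tuple) -> TestResult:
    p, stat, df, converged, warnings = t
    return TestResult(method="", p_value=p, statistic=stat, df=df,
                      converged=converged, warnings=warnings)


def lr_g(d: SexStratifiedCounts, *, mode: str = "full-penalty") -> TestResult:
    """Stage-1 genotype test: Y ~ sex  vs  Y ~ genotype + sex + genotype*sex.

    The tested block is {genotype, genotype x sex}, df = 2, so a main effect
    in either or both sexes can trigger it.  With a single-sex data set the
    model degrades to Y ~ genotype vs constant (df = 1) with a warning.
    """
    single_sex = d.male.total == 0 or d.female.total == 0
    if single_sex:
        s = d.male if d.male.total else d.female
        X, y, w = _cell_design([
            ((1, 0), s.events_b, s.total_b),
            ((1, 1), s.events_a, s.total_a),
        ])
        r = penalized_lrt(X, y, [1], weights=w, method="LR_G", mode=mode)
        r.warnings = r.warnings + ("single-sex input: degraded to Y ~ genotype, df = 1",)
        return r
    counts = (d.female.events_b, d.female.total_b, d.male.events_b, d.male.total_b,
              d.female.events_a, d.female.total_a, d.male.events_a, d.male.total_a)
    r = _result_from_tuple(_lr_full_counts(counts, (2, 3), "LR_G", mode))
    r.method = "LR_G"
    return r


def lr_i(d: SexStratifiedCounts, *, mode: str = "full-penalty") -> TestResult:
    """Stage-2 interaction test: Y ~ sex + genotype  vs  + genotype*sex (df = 1)."""
    if d.male.total == 0 or d.female.total == 0:
        raise ValidationError("LR_I requires both sexes")
    counts = (d.female.events_b, d.female.total_b, d.male.events_b, d.male.total_b,
              d.female.events_a, d.female.total_a, d.male.events_a, d.male.total_a)
    r = _result_from_tuple(_lr_full_counts(counts, (3,), "LR_I", mode))
    r.method = "LR_I"
    return r


def lr_ko(d: SexStratifiedCounts, *, mode: str = "full-penalty") -> TestResult:
    """Stage-2 sex test on knockouts only: Y ~ sex  vs  Y constant (df = 1)."""
    if d.male.total_a == 0 or d.female.total_a == 0:
        raise ValidationError("LR_KO requires knockout animals of both sexes")
    r = _result_from_tuple(_lr_ko_counts(d.male.total_a, d.female.total_a,
                                         d.male.events_a, d.female.events_a, mode))
    r.method = "LR_KO"
    return r


def lr_ko_from_counts(n_male: int, n_female: int, k_male: int, k_female: int,
                      *, mode: str = "full-penalty") -> TestResult:
    """LR_KO directly from knockout counts (used by attainability scans)."""
    if n_male == 0 or n_female == 0:
        raise ValidationError("LR_KO requires knockout animals of both sexes")
    r = _result_from_tuple(_lr_ko_counts(n_male, n_female, k_male, k_female, mode))
    r.method = "LR_KO"
    return r


def batch_screen(
    control_records: pd.DataFrame,
    *,
    fdr_level: float = 0.05,
    mode: str = "full-penalty",
) -> pd.DataFrame:
    """Screen control data for batch-to-batch variation, one trait at a time.

    For each trait a penalized LRT compares Y ~ sex + batch against
    Y ~ sex (df = number of batches - 1).  Expects columns ``trait_id``,
    ``sex`` ('M'/'F'), ``batch``, ``outcome`` (0/1).  Returns one row per
    trait with the raw p-value and its BH-adjusted q-value at ``fdr_level``.
    """
    from .multiplicity import bh

    required = {"trait_id", "sex", "batch", "outcome"}
    missing = required - set(control_records.columns)
    if missing:
        raise ValidationError(f"missing columns: {sorted(missing)}")
    batches = sorted(control_records["batch"].unique())
    if len(batches) < 2:
        raise ValidationError("batch screen requires >= 2 batches")

    rows = []
    for trait, grp in control_records.groupby("trait_id", sort=True):
        if grp["outcome"].sum() == 0:
            rows.append({"trait_id": trait, "p_value": 1.0, "statistic": 0.0,
                         "df": len(batches) - 1, "converged": True,
                         "uninformative": True})
            continue
        cells = []
        for (sex, batch), g in grp.groupby(["sex", "batch"]):
            x = [1, 1 if sex == "M" else 0] + [
                1 if batch == b else 0 for b in batches[1:]
            ]
            cells.append((x, int(g["outcome"].sum()), len(g)))
        X, y, w = _cell_design(cells)
        tested = list(range(2, 2 + len(batches) - 1))
        r = penalized_lrt(X, y, tested, weights=w, method="batch", mode=mode)
        rows.append({"trait_id": trait, "p_value": r.p_value,
                     "statistic": r.statistic, "df": r.df,
                     "converged": r.converged, "uninformative": False})
    out = pd.DataFrame(rows)
    rej, padj = bh(out["p_value"].tolist(), fdr_level)
    out["q_value"] = padj
    out["batch_effect"] = rej
    return out
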