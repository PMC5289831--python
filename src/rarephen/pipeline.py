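"""Two-stage analysis workflow for wild-type-vs-knockout categorical traits.

Stage 1 tests the genotype effect (default: exact stratified Mantel-Haenszel
with mid-P).  Stage 2 tests sexual dimorphism (default: Firth penalized LRT
on knockouts only, LR_KO), normally restricted to data sets significant at
stage 1.  Attainability (alpha-star) filters may remove hypotheses that can
never reach significance before either stage, and FDR control is applied
per stage, either globally (BH) or within gene x zygosity families (BB).

The ten numbered analysis approaches differ only in which filters are
applied, the FDR scope, and the stage-2 FDR level; ``PipelineConfig.from_approach``
encodes that matrix.  A legacy mode replaces FDR control by a fixed
significance threshold (historically 1e-4).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from . import exact, firth
from .attainability import lrko_alpha_star, mh_alpha_star
from .effects import ko_sex_difference, sex_averaged_effect
from .multiplicity import FamilyLayout, bb, bh
from .tables import SexStratifiedCounts, ValidationError

__all__ = ["PipelineConfig", "Report", "run_stage1", "run_stage2",
           "run_pipeline", "STAGE1_METHODS", "STAGE2_METHODS"]


STAGE1_METHODS: dict[str, Callable] = {
    "FE": lambda d: exact.fe_stage1(d, mid=False),
    "FE_mid": lambda d: exact.fe_stage1(d, mid=True),
    "MH_mid": lambda d: exact.mh_exact_mid(d, mid=True),
    "LR_G": firth.lr_g,
}

STAGE2_METHODS: dict[str, Callable] = {
    "Zelen": exact.zelen_mid,
    "LR_I": firth.lr_i,
    "LR_KO": firth.lr_ko,
    "FE_KO": exact.fe_ko,
}


@dataclass(frozen=True)
class PipelineConfig:
    stage1_method: str = "MH_mid"
    stage2_method: str = "LR_KO"
    use_mh_alpha_star_filter: bool = True
    use_lrko_alpha_star_filter: bool = True
    restrict_stage2_to_stage1_significant: bool = True
    fdr_scope_stage1: str = "global"   # "global" (BH) or "family" (BB)
    fdr_scope_stage2: str = "global"
    stage1_fdr_level: float = 0.05
    stage2_fdr_level: float = 0.20
    alpha_star_threshold_stage1: float = 0.05
    alpha_star_threshold_stage2: float = 0.05
    legacy_fixed_threshold: Optional[float] = None

    def __post_init__(self) -> None:
        if self.stage1_method not in STAGE1_METHODS:
            raise ValidationError(f"unknown stage-1 method {self.stage1_method!r}")
        if self.stage2_method not in STAGE2_METHODS:
            raise ValidationError(f"unknown stage-2 method {self.stage2_method!r}")
        for lvl in (self.stage1_fdr_level, self.stage2_fdr_level):
            if not (0 < lvl < 1):
                raise ValidationError("FDR levels must lie in (0, 1)")
        if self.fdr_scope_stage1 not in ("global", "family") or \
           self.fdr_scope_stage2 not in ("global", "family"):
            raise ValidationError("fdr scope must be 'global' or 'family'")

    @classmethod
    def from_approach(cls, n: int) -> "PipelineConfig":
        """The numbered approach matrix (filters / FDR scope / stage-2 level).

        Approaches: alpha-star filter at stage 1 in {2, 5, 6, 9, 10};
        within-family FDR in {7, 8, 9, 10}; restriction of stage 2 to
        stage-1 significant in {3..10}; LR_KO alpha-star filter in
        {2, 9, 10}; stage-2 FDR at 20% in {4, 6, 8, 10}, else 5%.
        """
        if not 1 <= n <= 10:
            raise ValidationError("approach number must be 1..10")
        scope = "family" if n in (7, 8, 9, 10) else "global"
        return cls(
            use_mh_alpha_star_filter=n in (2, 5, 6, 9, 10),
            use_lrko_alpha_star_filter=n in (2, 9, 10),
            restrict_stage2_to_stage1_significant=n >= 3,
            fdr_scope_stage1=scope,
            fdr_scope_stage2=scope,
            stage2_fdr_level=0.20 if n in (4, 6, 8, 10) else 0.05,
        )

    def fingerprint(self) -> str:
        return ";".join(f"{k}={v}" for k, v in sorted(asdict(self).items()))


@dataclass
class Report:
    table: pd.DataFrame
    filter_accounting: dict[str, int]
    config: PipelineConfig


def _stage1_alpha_star(d: SexStratifiedCounts, cfg: PipelineConfig) -> float:
    mid = cfg.stage1_method in ("MH_mid", "FE_mid")
    return mh_alpha_star(d, mid=mid)


def _stage2_alpha_star(d: SexStratifiedCounts) -> float:
    if d.male.total_a == 0 or d.female.total_a == 0:
        return 1.0
    total_ko = d.male.events_a + d.female.events_a
    return lrko_alpha_star(d.male.total_a, d.female.total_a, total_ko)


def _adjust_and_call(df: pd.DataFrame, pcol: str, scope: str, level: float,
                     legacy: Optional[float]):
    """Returns (adjusted p-values, call flags) over the rows of df."""
    ps = df[pcol].tolist()
    if legacy is not None:
        return [np.nan] * len(ps), [p < legacy for p in ps]
    if scope == "family":
        families: dict[str, dict[str, float]] = {}
        for _, row in df.iterrows():
            families.setdefault(row["family_id"], {})[row["dataset_id"]] = row[pcol]
        res = bb(FamilyLayout(families), level)
        adj = [res.adjusted_within_family[i] for i in df["dataset_id"]]
        call = [res.rejected[i] for i in df["dataset_id"]]
        return adj, call
    rej, padj = bh(ps, level)
    return padj, rej


def run_stage1(datasets: Sequence[SexStratifiedCounts],
               cfg: PipelineConfig) -> pd.DataFrame:
    """Stage-1 genotype testing with optional attainability filtering."""
    if not datasets:
        raise ValidationError("no data sets supplied")
    ids = [d.dataset_id for d in datasets]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate dataset ids")
    order = np.argsort(ids, kind="stable")
    rows = []
    for i in order:
        d = datasets[i]
        a1 = _stage1_alpha_star(d, cfg)
        a2 = _stage2_alpha_star(d)
        filtered = (cfg.use_mh_alpha_star_filter and not
                    (a1 < cfg.alpha_star_threshold_stage1))
        row = {
            "dataset_id": d.dataset_id, "line_id": d.line_id,
            "zygosity": d.zygosity, "trait_id": d.trait_id,
            "family_id": d.family_id,
            "alpha_star_stage1": a1, "alpha_star_stage2": a2,
            "stage1_filtered": filtered,
            "stage1_p": np.nan, "stage1_p_adj": np.nan, "stage1_call": False,
            "stage1_converged": True,
            "effect_estimate": np.nan, "effect_lower": np.nan,
            "effect_upper": np.nan,
            "disposition": "filtered_stage1" if filtered else "tested_stage1",
        }
        if not filtered:
            try:
                r = STAGE1_METHODS[cfg.stage1_method](d)
                row["stage1_p"] = r.p_value
                row["stage1_converged"] = r.converged
            except ValidationError as e:
                row["disposition"] = f"stage1_error: {e}"
            try:
                eff = sex_averaged_effect(d)
                row["effect_estimate"] = eff.estimate
                row["effect_lower"] = eff.lower
                row["effect_upper"] = eff.upper
            except ValidationError:
                pass
        rows.append(row)
    df = pd.DataFrame(rows)
    tested = df["stage1_p"].notna()
    if tested.any():
        adj, call = _adjust_and_call(df[tested], "stage1_p",
                                     cfg.fdr_scope_stage1,
                                     cfg.stage1_fdr_level,
                                     cfg.legacy_fixed_threshold)
        df.loc[tested, "stage1_p_adj"] = adj
        df.loc[tested, "stage1_call"] = call
    return df


def run_stage2(stage1_rows: pd.DataFrame,
               datasets: Sequence[SexStratifiedCounts],
               cfg: PipelineConfig) -> pd.DataFrame:
    """Stage-2 sexual-dimorphism testing on the stage-1 candidate set."""
    by_id = {d.dataset_id: d for d in datasets}
    df = stage1_rows.copy()
    for col, default in [("stage2_candidate", False), ("stage2_filtered", False),
                         ("stage2_p", np.nan), ("stage2_p_adj", np.nan),
                         ("stage2_call", False), ("stage2_converged", True),
                         ("ko_diff_estimate", np.nan), ("ko_diff_lower", np.nan),
                         ("ko_diff_upper", np.nan)]:
        df[col] = default

    if cfg.restrict_stage2_to_stage1_significant:
        candidates = df["stage1_call"].astype(bool)
    else:
        candidates = ~df["stage1_filtered"].astype(bool) & df["stage1_p"].notna()
    df["stage2_candidate"] = candidates

    for idx, row in df[candidates].iterrows():
        d = by_id[row["dataset_id"]]
        if cfg.use_lrko_alpha_star_filter and not (
                row["alpha_star_stage2"] < cfg.alpha_star_threshold_stage2):
            df.loc[idx, "stage2_filtered"] = True
            df.loc[idx, "disposition"] = "filtered_stage2"
            continue
        try:
            r = STAGE2_METHODS[cfg.stage2_method](d)
            df.loc[idx, "stage2_p"] = r.p_value
            df.loc[idx, "stage2_converged"] = r.converged
            df.loc[idx, "disposition"] = "tested_stage2"
        except ValidationError as e:
            df.loc[idx, "disposition"] = f"stage2_error: {e}"
            continue
        try:
            eff = ko_sex_difference(d)
            df.loc[idx, "ko_diff_estimate"] = eff.estimate
            df.loc[idx, "ko_diff_lower"] = eff.lower
            df.loc[idx, "ko_diff_upper"] = eff.upper
        except ValidationError:
            pass

    tested = df["stage2_p"].notna()
    if tested.any():
        adj, call = _adjust_and_call(df[tested], "stage2_p",
                                     cfg.fdr_scope_stage2,
                                     cfg.stage2_fdr_level,
                                     cfg.legacy_fixed_threshold)
        df.loc[tested, "stage2_p_adj"] = adj
        df.loc[tested, "stage2_call"] = call
        df.loc[tested & df["stage2_call"], "disposition"] = "called_stage2"
    return df


def run_pipeline(datasets: Sequence[SexStratifiedCounts],
                 cfg: Optional[PipelineConfig] = None) -> Report:
    """Run both stages and assemble the report with filter accounting."""
    cfg = cfg or PipelineConfig()
    s1 = run_stage1(datasets, cfg)
    table = run_stage2(s1, datasets, cfg)
    accounting = {
        "n_input": len(table),
        "n_filtered_stage1": int(table["stage1_filtered"].sum()),
        "n_tested_stage1": int(table["stage1_p"].notna().sum()),
        "n_called_stage1": int(table["stage1_call"].sum()),
        "n_candidates_stage2": int(table["stage2_candidate"].sum()),
        "n_filtered_stage2": int(table["stage2_filtered"].sum()),
        "n_tested_stage2": int(table["stage2_p"].notna().sum()),
        "n_called_stage2": int(table["stage2_call"].sum()),
    }
    return Report(table=table, filter_accounting=accounting, config=cfg)
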