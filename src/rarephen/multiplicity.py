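"""False discovery rate control: flat BH and the two-step within-family
(Benjamini-Bogomolov) procedure.

A "family" groups the hypotheses of one gene x zygosity.  The BB procedure
first selects families with at least one within-family BH discovery at
level q, then re-tests only the R selected families at the selection-
adjusted level R*q/m (m = number of families), controlling an average FDR
over families.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .tables import ValidationError

__all__ = ["FamilyLayout", "bh", "bb", "BBResult"]


def _validate_pvals(pvals) -> np.ndarray:
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value list")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    return p


def bh(pvals, q: float = 0.05) -> tuple[list[bool], list[float]]:
    """Benjamini-Hochberg step-up procedure.

    Returns (rejection flags, BH-adjusted p-values).  Rejects the k-hat
    smallest p-values where k-hat = max{k : p_(k) <= k q / m}.
    """
    if not (0 < q < 1):
        raise ValidationError("q must lie in (0, 1)")
    p = _validate_pvals(pvals)
    reject, padj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return [bool(r) for r in reject], [float(x) for x in padj]


@dataclass(frozen=True)
class FamilyLayout:
    """Hypotheses partitioned into families (gene x zygosity)."""

    families: dict[str, dict[str, float]]  # family id -> {hypothesis id: p}

    def __post_init__(self) -> None:
        if not self.families:
            raise ValidationError("layout must contain at least one family")
        seen: set[str] = set()
        for fam, members in self.families.items():
            if not members:
                raise ValidationError(f"family {fam!r} is empty")
            dup = seen & set(members)
            if dup:
                raise ValidationError(f"hypotheses in multiple families: {dup}")
            seen |= set(members)
            _validate_pvals(members.values())


@dataclass
class BBResult:
    n_selected_families: int
    selected_families: list[str]
    final_level: float
    rejected: dict[str, bool] = field(default_factory=dict)
    adjusted_within_family: dict[str, float] = field(default_factory=dict)


def bb(layout: FamilyLayout, q: float = 0.05) -> BBResult:
    """Benjamini-Bogomolov two-step average-FDR-over-families procedure.

    Step 1 runs BH at level q inside every family and selects the R families
    with at least one rejection.  Step 2 re-runs within-family BH at level
    R*q/m inside the selected families only; those rejections are final.
    """
    if not (0 < q < 1):
        raise ValidationError("q must lie in (0, 1)")
    m = len(layout.families)
    selected = []
    for fam, members in sorted(layout.families.items()):
        rej, _ = bh(list(members.values()), q)
        if any(rej):
            selected.append(fam)
    r = len(selected)
    final_level = r * q / m
    result = BBResult(n_selected_families=r, selected_families=selected,
                      final_level=final_level)
    for fam, members in sorted(layout.families.items()):
        ids = sorted(members)  # stable tie-break by hypothesis id
        ps = [members[h] for h in ids]
        _, padj = bh(ps, q)
        for h, a in zip(ids, padj):
            result.adjusted_within_family[h] = a
        if fam in selected and final_level > 0:
            rej, _ = bh(ps, final_level)
        else:
            rej = [False] * len(ids)
        for h, flag in zip(ids, rej):
            result.rejected[h] = flag
    return result
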