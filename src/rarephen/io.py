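"""Readers, writers and validation for phenotype record files.

Two delimited-text layouts are accepted (comma or tab, sniffed):

per-animal
    animal_id, line_id, zygosity, sex, group, trait_id, outcome[, batch_date]
    One row per animal x trait; outcomes are 0 (as expected) / 1 (abnormal).

aggregated
    line_id, zygosity, trait_id, sex, group, total, abnormal
    Pre-summed counts, one row per cell.

Counts are the internal currency: per-animal input is aggregated at the
door into one :class:`SexStratifiedCounts` per line x zygosity x trait, and
control animals are pooled across batches (batch labels are only retained
by the batch screen).  Malformed rows are rejected with their line numbers.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Sequence

import pandas as pd

from .tables import SexStratifiedCounts, TwoByTwo, ValidationError

__all__ = ["read_records", "write_datasets", "write_report", "read_per_animal_frame"]

_SEX = {"m": "M", "male": "M", "f": "F", "female": "F"}
_GROUP = {"control": "control", "wt": "control", "wild-type": "control",
          "wildtype": "control", "knockout": "knockout", "ko": "knockout"}


def _read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                     skip_blank_lines=True, comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    return df


def _norm_sex(token: str, row: int) -> str:
    s = _SEX.get(str(token).strip().lower())
    if s is None:
        raise ValidationError(f"row {row}: unknown sex token {token!r} "
                              "(expected M/F/Male/Female)")
    return s


def _norm_group(token: str, row: int) -> str:
    g = _GROUP.get(str(token).strip().lower())
    if g is None:
        raise ValidationError(f"row {row}: unknown group token {token!r} "
                              "(expected control/knockout)")
    return g


def _int_field(token, name: str, row: int) -> int:
    try:
        v = int(str(token).strip())
    except (TypeError, ValueError):
        raise ValidationError(f"row {row}: {name} must be an integer, "
                              f"got {token!r}") from None
    if v < 0:
        raise ValidationError(f"row {row}: {name} must be non-negative")
    return v


def read_per_animal_frame(path) -> pd.DataFrame:
    """Per-animal file as a validated DataFrame (keeps batch labels)."""
    df = _read_table(path)
    required = ["animal_id", "line_id", "zygosity", "sex", "group",
                "trait_id", "outcome"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"missing columns: {missing}")
    out = df.copy()
    rows = df.index + 2  # header is line 1
    out["sex"] = [_norm_sex(s, r) for s, r in zip(df["sex"], rows)]
    out["group"] = [_norm_group(g, r) for g, r in zip(df["group"], rows)]
    outcomes = [_int_field(o, "outcome", r) for o, r in zip(df["outcome"], rows)]
    if any(o not in (0, 1) for o in outcomes):
        bad = next(r for o, r in zip(outcomes, rows) if o not in (0, 1))
        raise ValidationError(f"row {bad}: outcome must be 0 or 1")
    out["outcome"] = outcomes
    dup = out.duplicated(subset=["animal_id", "trait_id"])
    if dup.any():
        raise ValidationError(
            f"row {rows[dup.argmax()]}: duplicate animal_id x trait_id")
    if "batch_date" not in out.columns:
        out["batch_date"] = ""
    return out


def _datasets_from_aggregated(df: pd.DataFrame) -> list[SexStratifiedCounts]:
    required = ["line_id", "zygosity", "trait_id", "sex", "group", "total",
                "abnormal"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"missing columns: {missing}")
    rows = df.index + 2
    df = df.copy()
    df["sex"] = [_norm_sex(s, r) for s, r in zip(df["sex"], rows)]
    df["group"] = [_norm_group(g, r) for g, r in zip(df["group"], rows)]
    df["total"] = [_int_field(t, "total", r) for t, r in zip(df["total"], rows)]
    df["abnormal"] = [_int_field(a, "abnormal", r)
                      for a, r in zip(df["abnormal"], rows)]
    for a, t, r in zip(df["abnormal"], df["total"], rows):
        if a > t:
            raise ValidationError(f"row {r}: abnormal ({a}) exceeds total ({t})")
    datasets = []
    for (line, zyg, trait), grp in df.groupby(
            ["line_id", "zygosity", "trait_id"], sort=True):
        cells = {}
        for _, row in grp.iterrows():
            key = (row["sex"], row["group"])
            if key in cells:
                cells[key] = (cells[key][0] + row["abnormal"],
                              cells[key][1] + row["total"])
            else:
                cells[key] = (row["abnormal"], row["total"])
        def cell(sex, group):
            return cells.get((sex, group), (0, 0))
        km, nm = cell("M", "knockout")
        kwm, nwm = cell("M", "control")
        kf, nf = cell("F", "knockout")
        kwf, nwf = cell("F", "control")
        datasets.append(SexStratifiedCounts(
            male=TwoByTwo(km, nm, kwm, nwm),
            female=TwoByTwo(kf, nf, kwf, nwf),
            line_id=str(line), zygosity=str(zyg), trait_id=str(trait)))
    return datasets


def read_records(path, fmt: str = "auto") -> list[SexStratifiedCounts]:
    """Read a records file into sex-stratified count tables.

    ``fmt`` is ``per-animal``, ``aggregated`` or ``auto`` (decided from the
    header).  Per-animal control data are pooled across batches.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    df = _read_table(path)
    if fmt == "auto":
        fmt = "per-animal" if "animal_id" in df.columns else "aggregated"
    if fmt == "aggregated":
        return _datasets_from_aggregated(df)
    if fmt != "per-animal":
        raise ValidationError(f"unknown format {fmt!r}")
    animals = read_per_animal_frame(path)
    agg = (animals.groupby(["line_id", "zygosity", "trait_id", "sex", "group"])
           .agg(total=("outcome", "size"), abnormal=("outcome", "sum"))
           .reset_index())
    return _datasets_from_aggregated(agg)


def write_datasets(datasets: Sequence[SexStratifiedCounts], path) -> None:
    """Write count tables in the aggregated layout (round-trips exactly)."""
    rows = []
    for d in sorted(datasets, key=lambda x: x.dataset_id):
        for sex, t in (("M", d.male), ("F", d.female)):
            rows.append((d.line_id, d.zygosity, d.trait_id, sex, "knockout",
                         t.total_a, t.events_a))
            rows.append((d.line_id, d.zygosity, d.trait_id, sex, "control",
                         t.total_b, t.events_b))
    pd.DataFrame(rows, columns=["line_id", "zygosity", "trait_id", "sex",
                                "group", "total", "abnormal"]
                 ).to_csv(path, sep="\t", index=False)


def write_report(rows: pd.DataFrame, path, config_fingerprint: str = "") -> None:
    """Write the pipeline report as TSV with a config fingerprint header."""
    if rows is None or len(rows) == 0:
        raise ValidationError("refusing to write an empty report")
    buf = _io.StringIO()
    rows.to_csv(buf, sep="\t", index=False, float_format="%.17g")
    with open(path, "w") as fh:
        if config_fingerprint:
            fh.write(f"# config: {config_fingerprint}\n")
        fh.write(buf.getvalue())


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#",
                       float_precision="round_trip")
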