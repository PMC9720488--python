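"""Readers and writers for the pipeline's plain-text formats.

Native formats are CSV/TSV: pedigree CSV (``animal,sire,dam,sex,hatch_week``
with ``0`` for an unknown parent), genotype matrix TSV (rows = individuals,
entries 0/1/2/NA) plus a SNP-map TSV, egg-log CSV (``hen,day,eggs``), NAb
CSV, and relationship matrices as TSV with an id header. A PLINK text
``.ped``/``.map`` dialect is accepted for genotypes. Configuration files
are YAML.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinship import RelationshipMatrix
from .simulate import (
    MISSING_CALL,
    EggLogSet,
    GenotypePanel,
    Pedigree,
    SimulationConfig,
)

__all__ = [
    "read_pedigree", "write_pedigree",
    "read_genotypes", "write_genotypes", "read_plink_text",
    "read_egg_logs", "write_egg_logs",
    "read_nab", "write_nab",
    "read_matrix", "write_matrix",
    "load_config", "dump_config",
    "write_json",
]

PEDIGREE_COLUMNS = ["animal", "sire", "dam", "sex", "hatch_week"]


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    out = ped.table.copy()
    for c in ("sire", "dam"):
        out[c] = out[c].replace("", "0")
    cols = PEDIGREE_COLUMNS + [c for c in out.columns if c not in PEDIGREE_COLUMNS]
    out[cols].to_csv(path, index=False)


def _topological_order(table: pd.DataFrame) -> pd.DataFrame:
    """Reorder records parents-first; raise on cycles or unknown-but-named
    parents referencing animals absent from the file."""
    ids = set(table["animal"])
    dup = table["animal"][table["animal"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate animal id {dup.iloc[0]!r}")
    for c in ("sire", "dam"):
        bad = table.loc[(table[c] != "") & ~table[c].isin(ids), c]
        if len(bad):
            raise ValueError(f"{c} {bad.iloc[0]!r} is not listed as an animal")
    pos = {a: i for i, a in enumerate(table["animal"])}
    placed: dict[str, int] = {}
    order: list[int] = []
    state: dict[str, int] = {}

    def visit(a: str) -> None:
        if state.get(a) == 2:
            return
        if state.get(a) == 1:
            raise ValueError(f"pedigree cycle involving {a!r}")
        state[a] = 1
        row = table.iloc[pos[a]]
        for p in (row["sire"], row["dam"]):
            if p:
                visit(p)
        state[a] = 2
        placed[a] = len(order)
        order.append(pos[a])

    import sys
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, len(table) * 2 + 100))
    try:
        for a in table["animal"]:
            visit(a)
    finally:
        sys.setrecursionlimit(old)
    return table.iloc[order].reset_index(drop=True)


def read_pedigree(path: str | Path) -> Pedigree:
    table = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in PEDIGREE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"pedigree file lacks columns {missing}")
    for c in ("sire", "dam"):
        table[c] = table[c].replace("0", "")
    table["hatch_week"] = table["hatch_week"].astype(int)
    for extra in ("family", "row"):
        if extra in table.columns:
            table[extra] = pd.to_numeric(table[extra]).astype(int)
    table = _topological_order(table)
    return Pedigree(table)


def write_genotypes(panel: GenotypePanel, matrix_path: str | Path, map_path: str | Path) -> None:
    calls = panel.calls.astype(object)
    calls[panel.calls == MISSING_CALL] = "NA"
    df = pd.DataFrame(calls, index=pd.Index(panel.ids, name="id"),
                      columns=panel.snp_map["snp_id"])
    df.to_csv(matrix_path, sep="\t")
    cols = ["snp_id", "chromosome", "position_bp"] + (
        ["founder_freq"] if "founder_freq" in panel.snp_map.columns else []
    )
    panel.snp_map[cols].to_csv(map_path, sep="\t", index=False)


def read_genotypes(matrix_path: str | Path, map_path: str | Path) -> GenotypePanel:
    df = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str)
    snp_map = pd.read_csv(map_path, sep="\t", dtype={"chromosome": str})
    if list(df.columns) != list(snp_map["snp_id"]):
        raise ValueError("genotype matrix columns do not match SNP map order")
    raw = df.to_numpy()
    calls = np.full(raw.shape, MISSING_CALL, dtype=np.int8)
    valid = {"0": 0, "1": 1, "2": 2, "NA": MISSING_CALL, "nan": MISSING_CALL}
    for (i, j), v in np.ndenumerate(raw):
        v = str(v)
        if v not in valid:
            raise ValueError(
                f"invalid genotype code {v!r} at row {df.index[i]!r}, "
                f"column {df.columns[j]!r}"
            )
        calls[i, j] = valid[v]
    return GenotypePanel(list(df.index), snp_map, calls)


def read_plink_text(ped_path: str | Path, map_path: str | Path) -> GenotypePanel:
    """PLINK text dialect: ``.map`` (chrom, snp, cM, pos) and ``.ped``
    (FID IID PAT MAT SEX PHENO + two allele columns per SNP, '0' missing).
    Calls count copies of the alphabetically later allele at each SNP."""
    smap = pd.read_csv(map_path, sep=r"\s+", header=None,
                       names=["chromosome", "snp_id", "cm", "position_bp"],
                       dtype={"chromosome": str})
    m = len(smap)
    ids, rows = [], []
    for line in Path(ped_path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * m:
            raise ValueError(
                f".ped line for {parts[1] if len(parts) > 1 else '?'} has "
                f"{len(parts) - 6} allele fields, expected {2 * m}"
            )
        ids.append(parts[1])
        rows.append(parts[6:])
    alleles = np.array(rows, dtype=object).reshape(len(ids), m, 2)
    calls = np.full((len(ids), m), MISSING_CALL, dtype=np.int8)
    for j in range(m):
        a = alleles[:, j, :]
        present = sorted({x for x in a.ravel() if x != "0"})
        counted = present[-1] if present else None
        ok = (a != "0").all(axis=1)
        if counted is not None:
            calls[ok, j] = (a[ok] == counted).sum(axis=1)
    out_map = smap[["snp_id", "chromosome", "position_bp"]].copy()
    return GenotypePanel(ids, out_map, calls)


def write_egg_logs(logs: EggLogSet, path: str | Path) -> None:
    rec = logs.records.copy()
    last = logs.last_day.rename("last_day")
    rec = rec.merge(last, left_on="hen", right_index=True)
    rec.to_csv(path, index=False)


def read_egg_logs(path: str | Path) -> EggLogSet:
    df = pd.read_csv(path)
    for c in ("hen", "day", "eggs"):
        if c not in df.columns:
            raise ValueError(f"egg log lacks column {c!r}")
    if "last_day" in df.columns:
        last = df.groupby("hen")["last_day"].first()
    else:
        last = df.groupby("hen")["day"].max()
    bad = df[df["day"] > last.reindex(df["hen"]).to_numpy()]
    if len(bad):
        raise ValueError(f"record after last_day_alive for hen {bad.iloc[0]['hen']!r}")
    return EggLogSet(df[["hen", "day", "eggs"]].copy(), last.rename("last_day"))


def write_nab(nab: pd.DataFrame, path: str | Path) -> None:
    nab.to_csv(path, index=False)


def read_nab(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for c in ("hen", "isotype", "titer", "plate", "age_class"):
        if c not in df.columns:
            raise ValueError(f"NAb table lacks column {c!r}")
    return df


def write_matrix(mat: RelationshipMatrix, path: str | Path) -> None:
    pd.DataFrame(mat.matrix, index=pd.Index(mat.ids, name=mat.kind),
                 columns=mat.ids).to_csv(path, sep="\t")


def read_matrix(path: str | Path, kind: str | None = None) -> RelationshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    kind = kind or str(df.index.name or "pedigree_A")
    return RelationshipMatrix(list(df.columns), df.to_numpy(dtype=float), kind)


def load_config(path: str | Path) -> SimulationConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    if "age_effects" in raw:
        raw["age_effects"] = {int(k): float(v) for k, v in raw["age_effects"].items()}
    if "hatch_week_props" in raw:
        raw["hatch_week_props"] = tuple(raw["hatch_week_props"])
    cfg = SimulationConfig(**raw)
    cfg.validate()
    return cfg


def dump_config(config: SimulationConfig, path: str | Path) -> None:
    d = dataclasses.asdict(config)
    d["hatch_week_props"] = list(d["hatch_week_props"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def write_json(obj: dict, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default, allow_nan=True))
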