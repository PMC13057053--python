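"""Delimited-text readers and report writers.

Conventions: CSV in (comma-separated, header row, ``NA`` for missing),
TSV reports out.  Report views round floats to 2 decimals; every report
writer also emits a full-precision twin with the ``.full.tsv`` suffix.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataWarning, InvalidInputError, ParseError
from .germination import GerminationTimeCourse, SeedlingRecord, TraitTable
from .qtl import Chromosome, GeneticMap, GenotypeMatrix, Marker, QtlCall

NA = "NA"


def read_genetic_map(path: str | Path) -> GeneticMap:
    """Read a ``chrom,marker,pos_cM`` CSV; markers sorted within chromosome."""
    df = pd.read_csv(path, dtype={"chrom": str, "marker": str},
                     float_precision="round_trip")
    required = {"chrom", "marker", "pos_cM"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: expected header chrom,marker,pos_cM")
    pos = pd.to_numeric(df["pos_cM"], errors="coerce")
    bad = df.index[pos.isna() | (pos < 0)]
    if len(bad):
        raise ParseError(
            f"{path}: non-numeric or negative position at line {bad[0] + 2}")
    if df["marker"].duplicated().any():
        dup = df.loc[df["marker"].duplicated(), "marker"].iloc[0]
        raise ParseError(f"{path}: duplicate marker name {dup!r}")
    df["pos_cM"] = pos
    chroms = []
    for name in dict.fromkeys(df["chrom"]):
        sub = df[df["chrom"] == name].sort_values("pos_cM", kind="stable")
        chroms.append(Chromosome(
            str(name), [Marker(str(r.marker), float(r.pos_cM))
                        for r in sub.itertuples()]))
    return GeneticMap(chroms)


def write_genetic_map(gmap: GeneticMap, path: str | Path) -> None:
    gmap.frame().to_csv(path, index=False)


_CODE = {"A": 1.0, "B": -1.0, NA: np.nan}


def read_genotypes(path: str | Path, gmap: GeneticMap) -> GenotypeMatrix:
    """Read a lines x markers CSV of A/B/NA calls, aligned to the map order.

    The first column holds line ids.  Columns absent from the map are
    dropped with a warning; heterozygote codes are rejected (DH lines are
    fully homozygous).
    """
    df = pd.read_csv(path, index_col=0, dtype=str)
    unknown = [c for c in df.columns if c not in set(gmap.marker_names)]
    if unknown:
        warnings.warn(
            f"{len(unknown)} genotype columns not in map dropped "
            f"(first: {unknown[0]!r})", DataWarning)
        df = df.drop(columns=unknown)
    bad = set(np.unique(df.fillna(NA).to_numpy())) - set(_CODE)
    if bad:
        raise ParseError(
            f"{path}: genotype code(s) {sorted(bad)} are not A/B/{NA}; "
            "doubled-haploid lines cannot carry heterozygote calls")
    ordered = [m for m in gmap.marker_names if m in df.columns]
    codes = df[ordered].fillna(NA).apply(lambda s: s.map(_CODE)).to_numpy(dtype=float)
    return GenotypeMatrix([str(i) for i in df.index], ordered, codes)


def write_genotypes(geno: GenotypeMatrix, path: str | Path) -> None:
    back = np.full(geno.codes.shape, NA, dtype=object)
    back[geno.codes == 1.0] = "A"
    back[geno.codes == -1.0] = "B"
    pd.DataFrame(back, index=pd.Index(geno.line_ids, name="line"),
                 columns=geno.marker_names).to_csv(path)


def read_germination(path: str | Path) -> list[GerminationTimeCourse]:
    """Read dishes from a ``genotype,treatment,replicate,total_seeds,d1..`` CSV."""
    df = pd.read_csv(path)
    day_cols = sorted(
        (c for c in df.columns if c.startswith("d") and c[1:].isdigit()),
        key=lambda c: int(c[1:]))
    if not day_cols:
        raise ParseError(f"{path}: no daily-count columns (d1, d2, ...)")
    return [
        GerminationTimeCourse(
            genotype_id=str(r.genotype), treatment=str(r.treatment),
            replicate=int(r.replicate), total_seeds=int(r.total_seeds),
            daily_counts=tuple(int(getattr(r, c)) for c in day_cols))
        for r in df.itertuples()
    ]


def read_seedlings(path: str | Path) -> list[SeedlingRecord]:
    """Read a ``genotype,treatment,replicate,fw_g,sl_cm,rl_cm,rno`` CSV."""
    df = pd.read_csv(path)
    return [
        SeedlingRecord(
            genotype_id=str(r.genotype), treatment=str(r.treatment),
            replicate=int(r.replicate), fresh_weight=float(r.fw_g),
            shoot_length=float(r.sl_cm), root_length=float(r.rl_cm),
            root_number=int(r.rno))
        for r in df.itertuples()
    ]


def write_trait_table(traits: TraitTable, path: str | Path) -> None:
    traits.data.to_csv(path, na_rep=NA)


def read_trait_table(path: str | Path) -> TraitTable:
    df = pd.read_csv(path, index_col=0, na_values=[NA])
    return TraitTable(df)


def _write_report(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    path = Path(path)
    rounded = df.copy()
    for c in rounded.columns:
        if pd.api.types.is_float_dtype(rounded[c]):
            rounded[c] = rounded[c].round(2)
    rounded.to_csv(path, sep="\t", index=index, na_rep=NA)
    full = path.with_suffix(".full.tsv")
    df.to_csv(full, sep="\t", index=index, na_rep=NA)


def qtl_frame(calls: list[QtlCall]) -> pd.DataFrame:
    cols = ["qtl", "trait", "chrom", "pos", "left_marker", "right_marker",
            "lod", "pve", "add", "ci_left", "ci_right", "environment", "strength"]
    rows = [
        (c.qtl_id, c.trait, c.chrom, c.peak_pos, c.left_marker, c.right_marker,
         c.lod, c.pve, c.add, c.ci_left, c.ci_right, c.environment, c.strength)
        for c in calls
    ]
    return pd.DataFrame(rows, columns=cols)


def write_qtl_report(calls: list[QtlCall], path: str | Path) -> None:
    """TSV mirroring the published QTL table column order (+ strength)."""
    _write_report(qtl_frame(calls), path)


def read_qtl_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA])


def write_map_summary(summary: pd.DataFrame, path: str | Path) -> None:
    _write_report(summary, path)


def write_anova_report(per_trait: dict[str, "object"], path: str | Path) -> None:
    """One row per trait: genotype and replicate F (+ codes), MS error, h2 %."""
    rows = []
    for trait, res in per_trait.items():
        t = res.table
        rows.append({
            "trait": trait,
            "F_G": t.loc["genotype", "f"],
            "sig_G": t.loc["genotype", "sig"],
            "F_R": t.loc["replicate", "f"],
            "sig_R": t.loc["replicate", "sig"],
            "MS_error": t.loc["error", "ms"],
            "h2_pct": 100.0 * res.h2_entry_mean,
        })
    _write_report(pd.DataFrame(rows), path)


def load_directions_yaml(path: str | Path) -> dict[str, str]:
    """Read a ``directions: {TRAIT: increase|decrease}`` YAML block."""
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    directions = doc.get("directions", doc)
    if not isinstance(directions, dict):
        raise ParseError(f"{path}: expected a mapping of trait -> direction")
    for k, v in directions.items():
        if v not in ("increase", "decrease"):
            raise InvalidInputError(f"direction for {k!r} must be increase/decrease")
    return dict(directions)
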