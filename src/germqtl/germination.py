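"""Germination and seedling-establishment indices from daily count data.

A dish holds ``total_seeds`` seeds (20 in the standard assay) scored once a
day for ``n_days`` days (12 in the standard assay); ``daily_counts[g-1]`` is
the number of seeds that germinated *on* day ``g``.  From these counts the
classic germination battery is computed:

==========  =====================================================
FG, IG      final / initial germination percentage
MGT, MGR    mean germination time (days) and its reciprocal
GP          germination pace, 100/MGT (identical to 100*MGR)
U           uncertainty: Shannon entropy (bits) of germination days
Z           synchrony: fraction of germinating-seed pairs sharing a day
CVt         coefficient of variation of germination time (percent)
SVI         seed vigor index, seedling length (cm) x FG%
==========  =====================================================

Seedling measurements (fresh weight, shoot/root length, root number) feed
the per-treatment trait table together with drought-tolerance indices
(DTI = 100 * drought/control) and absolute reductions (control - drought),
computed per genotype on replicate means, pairing drought with control
within the unprimed (D vs C) and nano-primed (DN vs CN) arms.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import DataWarning, InvalidInputError, undefined

TREATMENTS = ("C", "D", "CN", "DN")
Treatment = Literal["C", "D", "CN", "DN"]

#: Per-treatment trait abbreviations, in report order.
PER_TREATMENT_TRAITS = (
    "FG", "IG", "GP", "MGT", "MGR", "U", "Z", "CVt", "SVI",
    "FW", "SL", "RL", "RNo", "SRR",
)
#: Traits contrasted between drought and control arms.
CONTRAST_BASES = ("FW", "SL", "RL", "RNo")
DTI_TRAITS = tuple(f"{b}DTI" for b in CONTRAST_BASES)
REDUCTION_TRAITS = tuple(f"R{b}" for b in CONTRAST_BASES)

#: Traits where *smaller* is better for a drought-tolerant ideotype:
#: slow/erratic germination (MGT, U, CVt) and the four absolute reductions.
DECREASE_TRAITS = frozenset({"MGT", "U", "CVt", "RFW", "RSL", "RRL", "RRNo"})


@dataclass(frozen=True)
class GerminationTimeCourse:
    """Daily newly-germinated counts for one dish (genotype x treatment x rep)."""

    genotype_id: str
    treatment: Treatment
    replicate: int
    daily_counts: tuple[int, ...]
    total_seeds: int = 20

    def __post_init__(self) -> None:
        if self.total_seeds <= 0:
            raise InvalidInputError("total_seeds must be a positive integer")
        if self.replicate <= 0:
            raise InvalidInputError("replicate must be a positive integer")
        if self.treatment not in TREATMENTS:
            raise InvalidInputError(f"unknown treatment {self.treatment!r}")
        counts = tuple(int(c) for c in self.daily_counts)
        if len(counts) < 1:
            raise InvalidInputError("daily_counts needs at least one day")
        if any(c < 0 for c in counts):
            raise InvalidInputError("daily counts must be non-negative")
        if sum(counts) > self.total_seeds:
            raise InvalidInputError(
                f"{sum(counts)} germinated seeds exceed dish total {self.total_seeds}"
            )
        object.__setattr__(self, "daily_counts", counts)

    @property
    def n_germinated(self) -> int:
        return sum(self.daily_counts)

    @property
    def n_days(self) -> int:
        return len(self.daily_counts)

    def germination_days(self) -> list[int]:
        """Expand counts to one 1-based day index per germinated seed."""
        return [g for g, n in enumerate(self.daily_counts, start=1) for _ in range(n)]


@dataclass(frozen=True)
class SeedlingRecord:
    """End-of-assay seedling measurements for one dish."""

    genotype_id: str
    treatment: Treatment
    replicate: int
    fresh_weight: float  # g
    shoot_length: float  # cm
    root_length: float  # cm
    root_number: int

    def __post_init__(self) -> None:
        for name in ("fresh_weight", "shoot_length", "root_length", "root_number"):
            v = getattr(self, name)
            if not math.isnan(v) and v < 0:
                raise InvalidInputError(f"{name} must be >= 0, got {v}")


def germination_percentages(tc: GerminationTimeCourse) -> tuple[float, float]:
    """Final and initial germination percentage (day n_days resp. day 1)."""
    fg = 100.0 * tc.n_germinated / tc.total_seeds
    ig = 100.0 * tc.daily_counts[0] / tc.total_seeds
    return fg, ig


def germination_timing(
    tc: GerminationTimeCourse, strict: bool = False
) -> tuple[float, float, float, float]:
    """MGT (days), MGR (1/days), GP (percent) and CVt (percent).

    GP = 100*N / sum(n_g * g) = 100/MGT, so GP == 100*MGR identically.
    CVt uses the sample (N-1) standard deviation of individual germination
    days; with a single germinated seed it is undefined.
    """
    counts = np.asarray(tc.daily_counts, dtype=float)
    n = counts.sum()
    if n == 0:
        nan = undefined(
            f"no germinated seed in dish {tc.genotype_id}/{tc.treatment}/r{tc.replicate};"
            " MGT/MGR/GP/CVt undefined", strict)
        return nan, nan, nan, nan
    days = np.arange(1, tc.n_days + 1, dtype=float)
    mgt = float((counts * days).sum() / n)
    mgr = 1.0 / mgt
    gp = 100.0 * mgr
    if n < 2:
        cvt = undefined(
            f"single germinated seed in dish {tc.genotype_id}/{tc.treatment}/"
            f"r{tc.replicate}; CVt undefined", strict)
    else:
        # sample variance of the N individual days, without expanding per seed
        ss = float((counts * (days - mgt) ** 2).sum())
        cvt = 100.0 * math.sqrt(ss / (n - 1)) / mgt
    return mgt, mgr, gp, cvt


def germination_information(
    tc: GerminationTimeCourse, strict: bool = False
) -> tuple[float, float]:
    """Uncertainty U (bits) and synchrony Z of the germination process.

    U is the Shannon entropy of the day-of-germination distribution over
    days with at least one event; Z is the fraction of germinated-seed
    pairs that germinated on the same day.  U = 0 and Z = 1 exactly when
    all germination falls on a single day.
    """
    counts = np.asarray(tc.daily_counts, dtype=float)
    n = counts.sum()
    if n == 0:
        nan = undefined(
            f"no germinated seed in dish {tc.genotype_id}/{tc.treatment}/"
            f"r{tc.replicate}; U and Z undefined", strict)
        return nan, nan
    pos = counts[counts > 0]
    f = pos / n
    u = float(-(f * np.log2(f)).sum())
    if n < 2:
        z = undefined(
            f"fewer than two germinated seeds in dish {tc.genotype_id}/"
            f"{tc.treatment}/r{tc.replicate}; Z undefined", strict)
    else:
        z = float((pos * (pos - 1) / 2).sum() / (n * (n - 1) / 2))
    return u, z


def seed_vigor_index(seedling_length: float, fg_pct: float) -> float:
    """SVI = seedling length (cm) x final germination percentage."""
    if seedling_length < 0 or fg_pct < 0:
        raise InvalidInputError("seedling length and FG% must be >= 0")
    return seedling_length * fg_pct


def stress_indices(
    control_value: float, drought_value: float, strict: bool = False
) -> tuple[float, float]:
    """Drought-tolerance index (100*drought/control) and reduction (control-drought)."""
    reduction = control_value - drought_value
    if control_value == 0:
        dti = undefined("control mean is zero; DTI undefined", strict)
    else:
        dti = 100.0 * drought_value / control_value
    return dti, reduction


@dataclass
class TraitTable:
    """Genotype x trait matrix with per-trait selection direction.

    ``data`` has genotypes as the index and treatment-suffixed trait
    abbreviations (``MGT_D``, ``FWDTI_DN`` ...) as columns; ``directions``
    maps every column to ``"increase"`` or ``"decrease"``.
    """

    data: pd.DataFrame
    directions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in self.data.columns if c not in self.directions]
        if missing:
            self.directions.update(default_directions(missing))

    @property
    def genotype_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def trait_names(self) -> list[str]:
        return list(self.data.columns)


def default_directions(columns: Iterable[str]) -> dict[str, str]:
    """Direction map from base-trait conventions (MGT/U/CVt/R* decrease)."""
    out = {}
    for col in columns:
        base = col.rsplit("_", 1)[0]
        out[col] = "decrease" if base in DECREASE_TRAITS else "increase"
    return out


def trait_columns_for(treatments: Sequence[str]) -> list[str]:
    """Expected trait-table columns for the supplied treatments.

    Per-treatment traits get one column per treatment; DTI/reduction
    contrasts appear as ``_D`` (D vs C) and/or ``_DN`` (DN vs CN) whenever
    both arm members are present.
    """
    cols = [f"{t}_{tr}" for t in PER_TREATMENT_TRAITS for tr in treatments]
    for stress, ctrl in (("D", "C"), ("DN", "CN")):
        if stress in treatments and ctrl in treatments:
            cols += [f"{t}_{stress}" for t in DTI_TRAITS + REDUCTION_TRAITS]
    return cols


def _dish_traits(tc: GerminationTimeCourse, rec: SeedlingRecord | None,
                 svi_length: str, strict: bool) -> dict[str, float]:
    fg, ig = germination_percentages(tc)
    mgt, mgr, gp, cvt = germination_timing(tc, strict=strict)
    u, z = germination_information(tc, strict=strict)
    row = {"FG": fg, "IG": ig, "GP": gp, "MGT": mgt, "MGR": mgr,
           "U": u, "Z": z, "CVt": cvt}
    if rec is not None:
        row["FW"] = rec.fresh_weight
        row["SL"] = rec.shoot_length
        row["RL"] = rec.root_length
        row["RNo"] = float(rec.root_number)
        row["SRR"] = (rec.shoot_length / rec.root_length
                      if rec.root_length > 0
                      else undefined("zero root length; SRR undefined", strict))
        length = (rec.shoot_length if svi_length == "shoot"
                  else rec.shoot_length + rec.root_length)
        row["SVI"] = seed_vigor_index(length, fg)
    else:
        row.update({k: float("nan") for k in ("FW", "SL", "RL", "RNo", "SRR", "SVI")})
    return row


def per_dish_trait_frame(
    time_courses: Iterable[GerminationTimeCourse],
    seedling_records: Iterable[SeedlingRecord] = (),
    svi_length: str = "total",
    strict: bool = False,
) -> pd.DataFrame:
    """Un-averaged per-dish traits, indexed by (genotype, treatment, replicate).

    This is the input the per-treatment ANOVA needs (one observation per
    genotype x replicate cell within each treatment).
    """
    recs = {(r.genotype_id, r.treatment, r.replicate): r for r in seedling_records}
    rows = {}
    for tc in time_courses:
        rec = recs.get((tc.genotype_id, tc.treatment, tc.replicate))
        rows[(tc.genotype_id, tc.treatment, tc.replicate)] = _dish_traits(
            tc, rec, svi_length, strict)
    df = pd.DataFrame(rows).T
    df.index.names = ["genotype", "treatment", "replicate"]
    return df


def assemble_trait_table(
    time_courses: Iterable[GerminationTimeCourse],
    seedling_records: Iterable[SeedlingRecord] = (),
    svi_length: str = "total",
    strict: bool = False,
) -> TraitTable:
    """Replicate-averaged trait table over all supplied treatments.

    Germination indices are computed per dish and averaged over replicates
    within genotype x treatment; DTI and reduction contrasts are then taken
    on those replicate means, D against C and DN against CN.  ``svi_length``
    selects whether SVI uses total (shoot+root, default) or shoot-only
    seedling length.
    """
    if svi_length not in ("total", "shoot"):
        raise InvalidInputError("svi_length must be 'total' or 'shoot'")
    recs = {(r.genotype_id, r.treatment, r.replicate): r for r in seedling_records}
    rows = []
    for tc in time_courses:
        rec = recs.get((tc.genotype_id, tc.treatment, tc.replicate))
        row = _dish_traits(tc, rec, svi_length, strict)
        row["genotype"] = tc.genotype_id
        row["treatment"] = tc.treatment
        rows.append(row)
    if not rows:
        raise InvalidInputError("no germination time courses supplied")
    long = pd.DataFrame(rows)
    means = long.groupby(["genotype", "treatment"], sort=False).mean()

    treatments = [t for t in TREATMENTS if t in set(long["treatment"])]
    genotypes = list(dict.fromkeys(long["genotype"]))
    wide = pd.DataFrame(index=pd.Index(genotypes, name="genotype"))
    for trait, tr in itertools.product(PER_TREATMENT_TRAITS, treatments):
        col = means.loc[(slice(None), tr), trait].droplevel("treatment")
        wide[f"{trait}_{tr}"] = col.reindex(genotypes)

    for stress, ctrl in (("D", "C"), ("DN", "CN")):
        if stress not in treatments or ctrl not in treatments:
            if stress in treatments:
                warnings.warn(
                    f"treatment pair ({stress}, {ctrl}) incomplete; "
                    "DTI/reduction columns skipped for this arm", DataWarning)
            continue
        for base in CONTRAST_BASES:
            c = wide[f"{base}_{ctrl}"]
            d = wide[f"{base}_{stress}"]
            dti = pd.Series(
                [stress_indices(cv, dv, strict=strict)[0] if cv == cv else float("nan")
                 for cv, dv in zip(c, d)], index=wide.index)
            wide[f"{base}DTI_{stress}"] = dti
            wide[f"R{base}_{stress}"] = c - d

    order = trait_columns_for(treatments)
    wide = wide[[c for c in order if c in wide.columns]]
    return TraitTable(data=wide, directions=default_directions(wide.columns))
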