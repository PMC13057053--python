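"""Seeded synthetic doubled-haploid drought / nano-priming datasets.

The generator reproduces the statistical structure the pipeline assumes,
so that every stage can be exercised end to end without the unreleased
experimental data:

* a linkage map on the published 21-chromosome template (3,567 SNPs,
  3,150.71 cM) with uniform marker placement per chromosome;
* DH genotypes as single recombinant gametes: the first marker of each
  chromosome is +1/-1 with probability 1/2 and each subsequent marker
  flips with the Kosambi recombination fraction of its interval
  (intervals independent, no interference beyond the map function);
* seedling phenotypes from the replicated mixed model
  ``y = mu_t + sum_q a_q(t) x_q + polygene_i + rep_j + eps_ijr`` with a
  per-trait polygenic line effect (partly shared through a common "vigor"
  component, emulating the strong trait correlations of real assays),
  planted additive QTL effects that may differ by treatment, and dish
  error;
* per-seed germination: each seed fails with a treatment-specific
  probability, otherwise germinates on ``round(N(line day, per-seed SD))``
  truncated to the scoring window.  Drought raises the mean day and the
  failure probability; nano-priming moves both part of the way back, so
  that computed DTIs fall below 100 and reductions are positive on
  average, with the primed arm intermediate.

Alongside the data the generator returns the realized quantities a
recovery test needs: entry-mean heritability and per-QTL PVE computed
from the generated components.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .germination import GerminationTimeCourse, SeedlingRecord
from .published import LINKAGE_MAP_SUMMARY
from .qtl import Chromosome, GeneticMap, GenotypeMatrix, Marker, kosambi

#: Default map template: the published 21-chromosome geometry.
DEFAULT_MAP_SPEC: list[tuple[str, float, int]] = [
    (name, length, count) for name, count, length in LINKAGE_MAP_SUMMARY
]


@dataclass(frozen=True)
class QtlSpec:
    """One planted additive QTL: position and per-treatment effect size."""

    chrom: str
    pos: float  # cM; snapped to the nearest simulated marker
    trait: str
    effects: dict[str, float]  # treatment -> additive effect a (trait units)


@dataclass(frozen=True)
class TraitSpec:
    """Generative parameters of one seedling trait."""

    mu: float
    sigma2_g: float       # polygenic line variance
    sigma2_gr: float      # dish (replicate x line) error variance
    treatment_shift: dict[str, float] = field(default_factory=dict)
    vigor_weight: float = 0.0  # loading on the shared line "vigor" factor


@dataclass(frozen=True)
class GermSpec:
    """Generative parameters of the per-seed germination-time model."""

    baseline_day: float = 3.0          # mean germination day under control
    genotype_sd: float = 0.6           # SD of line-level day shifts
    seed_sd: float = 1.0               # per-seed SD around the line mean
    treatment_delay: dict[str, float] = field(
        default_factory=lambda: {"C": 0.0, "CN": -0.2, "D": 2.0, "DN": 1.2})
    fail_prob: dict[str, float] = field(
        default_factory=lambda: {"C": 0.05, "CN": 0.04, "D": 0.25, "DN": 0.15})
    n_days: int = 12
    seeds_per_dish: int = 20
    vigor_weight: float = -0.3         # high-vigor lines germinate earlier


def _default_qtls() -> list[QtlSpec]:
    # Planted effects sized for PVE in the published 3-22 % band given the
    # default trait variances (see docs/methods.md).
    return [
        QtlSpec("2A", 85.0, "SL",
                {"C": 0.45, "D": 0.85, "CN": 0.45, "DN": 0.65}),
        QtlSpec("3B", 102.0, "FW",
                {"C": 0.015, "D": 0.035, "CN": 0.015, "DN": 0.030}),
        QtlSpec("1A", 111.0, "RNo",
                {"C": 0.20, "D": 0.45, "CN": 0.20, "DN": 0.40}),
        QtlSpec("2B", 168.0, "germ_day",
                {"C": -0.10, "D": -0.30, "CN": -0.10, "DN": -0.25}),
    ]


def _default_traits() -> dict[str, TraitSpec]:
    return {
        "SL": TraitSpec(mu=10.0, sigma2_g=2.5, sigma2_gr=0.75,
                        treatment_shift={"C": 0.0, "CN": 0.3, "D": -3.0, "DN": -2.0},
                        vigor_weight=0.8),
        "RL": TraitSpec(mu=9.0, sigma2_g=2.0, sigma2_gr=0.8,
                        treatment_shift={"C": 0.0, "CN": 0.2, "D": 0.8, "DN": 1.2},
                        vigor_weight=0.6),
        "FW": TraitSpec(mu=0.55, sigma2_g=0.004, sigma2_gr=0.0012,
                        treatment_shift={"C": 0.0, "CN": 0.01, "D": -0.12, "DN": -0.08},
                        vigor_weight=0.03),
        "RNo": TraitSpec(mu=5.0, sigma2_g=0.5, sigma2_gr=0.25,
                         treatment_shift={"C": 0.0, "CN": 0.1, "D": -1.0, "DN": -0.6},
                         vigor_weight=0.3),
    }


@dataclass
class SimConfig:
    """Complete description of one synthetic experiment."""

    seed: int = 0
    n_lines: int = 63
    n_reps: int = 3
    treatments: tuple[str, ...] = ("C", "D", "CN", "DN")
    map_spec: list[tuple[str, float, int]] = field(
        default_factory=lambda: list(DEFAULT_MAP_SPEC))
    qtl_spec: list[QtlSpec] = field(default_factory=_default_qtls)
    trait_spec: dict[str, TraitSpec] = field(default_factory=_default_traits)
    germ_spec: GermSpec = field(default_factory=GermSpec)

    def __post_init__(self) -> None:
        if self.n_lines < 2 or self.n_reps < 1:
            raise InvalidInputError("need >= 2 lines and >= 1 replicate")
        lengths = {name: length for name, length, _ in self.map_spec}
        for q in self.qtl_spec:
            if q.chrom not in lengths:
                raise InvalidInputError(f"QTL chromosome {q.chrom!r} not in map")
            if not 0 <= q.pos <= lengths[q.chrom]:
                raise InvalidInputError(
                    f"QTL position {q.pos} outside chromosome {q.chrom}")


def simulate_map(config: SimConfig, rng: np.random.Generator | None = None
                 ) -> GeneticMap:
    """Uniformly placed markers; first at 0, last at the chromosome length."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    chroms = []
    for name, length, n_markers in config.map_spec:
        if n_markers < 2 and length > 0:
            raise InvalidInputError(
                f"{name}: need >= 2 markers on a chromosome of positive length")
        inner = np.sort(rng.uniform(0.0, length, size=max(n_markers - 2, 0)))
        pos = np.concatenate([[0.0], inner, [length]])
        markers = [Marker(f"{name}_M{i + 1}", float(p))
                   for i, p in enumerate(pos)]
        chroms.append(Chromosome(name, markers))
    return GeneticMap(chroms)


def simulate_dh_genotypes(
    gmap: GeneticMap, n_lines: int, seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """One recombinant gamete per line via interval-wise Kosambi flips."""
    rng = np.random.default_rng(seed) if rng is None else rng
    blocks = []
    for chrom in gmap.chromosomes:
        pos = chrom.positions
        m = len(pos)
        start = rng.choice([-1.0, 1.0], size=(n_lines, 1))
        if m == 1:
            blocks.append(start)
            continue
        r = np.array([kosambi(d, "d_to_r") for d in np.diff(pos)])
        flips = rng.random((n_lines, m - 1)) < r
        signs = np.cumprod(np.where(flips, -1.0, 1.0), axis=1)
        blocks.append(np.concatenate([start, start * signs], axis=1))
    codes = np.concatenate(blocks, axis=1)
    line_ids = [f"L{i + 1:03d}" for i in range(n_lines)]
    return GenotypeMatrix(line_ids, gmap.marker_names, codes)


def _nearest_marker(gmap: GeneticMap, chrom: str, pos: float) -> str:
    for c in gmap.chromosomes:
        if c.name == chrom:
            i = int(np.argmin(np.abs(c.positions - pos)))
            return c.markers[i].name
    raise InvalidInputError(f"chromosome {chrom!r} not in map")


def simulate_phenotypes(
    geno: GenotypeMatrix,
    gmap: GeneticMap,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Replicated seedling traits plus line-level germination-day means.

    Returns ``(seedlings, germ_days, truth)``: a long table of per-dish
    FW/SL/RL/RNo values, a line x treatment table of mean germination
    days, and a ``truth`` dict with planted markers, realized per-QTL PVE
    (share of line-mean variance, per treatment) and realized entry-mean
    heritability per trait and treatment.
    """
    n = len(geno.line_ids)
    col = {m: i for i, m in enumerate(geno.marker_names)}
    qtl_marker = {id(q): _nearest_marker(gmap, q.chrom, q.pos) for q in config.qtl_spec}

    vigor = rng.normal(0.0, 1.0, size=n)  # shared line factor
    truth: dict = {"qtls": [], "h2_entry_mean": {}, "pve": {}}
    for q in config.qtl_spec:
        truth["qtls"].append({
            "chrom": q.chrom, "pos": q.pos, "trait": q.trait,
            "marker": qtl_marker[id(q)], "effects": dict(q.effects)})

    rows = []
    germ_cols = {}
    gs = config.germ_spec
    germ_poly = rng.normal(0.0, gs.genotype_sd, size=n)

    genetic_value: dict[tuple[str, str], np.ndarray] = {}
    for trait, spec in config.trait_spec.items():
        poly = rng.normal(0.0, np.sqrt(spec.sigma2_g), size=n)
        line_g = spec.vigor_weight * vigor + poly
        for tr in config.treatments:
            qtl_part = np.zeros(n)
            for q in config.qtl_spec:
                if q.trait == trait:
                    x = geno.codes[:, col[qtl_marker[id(q)]]]
                    qtl_part += q.effects.get(tr, 0.0) * np.nan_to_num(x)
            genetic_value[(trait, tr)] = (
                spec.mu + spec.treatment_shift.get(tr, 0.0) + line_g + qtl_part)

    rep_effects = {
        (trait, tr): rng.normal(0.0, 0.05 * np.sqrt(spec.sigma2_gr),
                                size=config.n_reps)
        for trait, spec in config.trait_spec.items() for tr in config.treatments}

    for tr in config.treatments:
        germ_mean = (gs.baseline_day + gs.treatment_delay.get(tr, 0.0)
                     + germ_poly + gs.vigor_weight * vigor)
        for q in config.qtl_spec:
            if q.trait == "germ_day":
                x = geno.codes[:, col[qtl_marker[id(q)]]]
                germ_mean = germ_mean + q.effects.get(tr, 0.0) * np.nan_to_num(x)
        germ_cols[tr] = np.clip(germ_mean, 1.0, gs.n_days)

        for j in range(config.n_reps):
            dish = {
                trait: genetic_value[(trait, tr)]
                + rep_effects[(trait, tr)][j]
                + rng.normal(0.0, np.sqrt(spec.sigma2_gr), size=n)
                for trait, spec in config.trait_spec.items()
            }
            def cell(trait: str, i: int) -> float:
                return max(dish[trait][i], 0.0) if trait in dish else 0.0

            for i, line in enumerate(geno.line_ids):
                rows.append({
                    "genotype": line, "treatment": tr, "replicate": j + 1,
                    "fw_g": cell("FW", i),
                    "sl_cm": cell("SL", i),
                    "rl_cm": cell("RL", i),
                    "rno": int(round(cell("RNo", i))),
                })

    for trait, spec in config.trait_spec.items():
        for tr in config.treatments:
            gvar = float(np.var(genetic_value[(trait, tr)], ddof=1))
            h2 = gvar / (gvar + spec.sigma2_gr / config.n_reps)
            truth["h2_entry_mean"][f"{trait}_{tr}"] = h2
    for q, rec in zip(config.qtl_spec, truth["qtls"]):
        if q.trait == "germ_day":
            continue
        spec = config.trait_spec[q.trait]
        for tr in config.treatments:
            gvar = float(np.var(genetic_value[(q.trait, tr)], ddof=1))
            a = q.effects.get(tr, 0.0)
            x = geno.codes[:, col[rec["marker"]]]
            qvar = a * a * float(np.var(np.nan_to_num(x), ddof=1))
            rec.setdefault("realized_pve", {})[tr] = (
                100.0 * qvar / (gvar + spec.sigma2_gr / config.n_reps))

    seedlings = pd.DataFrame(rows)
    germ_days = pd.DataFrame(germ_cols, index=pd.Index(geno.line_ids, name="genotype"))
    return seedlings, germ_days, truth


def simulate_germination(
    config: SimConfig,
    germ_days: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-dish daily germination counts from the per-seed time model."""
    gs = config.germ_spec
    rows = []
    for tr in config.treatments:
        p_fail = gs.fail_prob.get(tr, 0.0)
        for line in germ_days.index:
            mean_day = germ_days.loc[line, tr]
            for j in range(config.n_reps):
                germinates = rng.random(gs.seeds_per_dish) >= p_fail
                days = np.clip(
                    np.rint(rng.normal(mean_day, gs.seed_sd, size=gs.seeds_per_dish)),
                    1, gs.n_days).astype(int)
                counts = np.bincount(days[germinates], minlength=gs.n_days + 1)[1:]
                rows.append({"genotype": line, "treatment": tr, "replicate": j + 1,
                             "total_seeds": gs.seeds_per_dish,
                             **{f"d{d + 1}": int(c) for d, c in enumerate(counts)}})
    return pd.DataFrame(rows)


@dataclass
class SimDataset:
    """One complete synthetic experiment plus its generative truth."""

    config: SimConfig
    gmap: GeneticMap
    geno: GenotypeMatrix
    seedlings: pd.DataFrame   # genotype treatment replicate fw_g sl_cm rl_cm rno
    germination: pd.DataFrame  # genotype treatment replicate total_seeds d1..d12
    truth: dict

    def time_courses(self) -> list[GerminationTimeCourse]:
        day_cols = [c for c in self.germination.columns if c.startswith("d")]
        return [
            GerminationTimeCourse(
                genotype_id=row.genotype, treatment=row.treatment,
                replicate=int(row.replicate), total_seeds=int(row.total_seeds),
                daily_counts=tuple(int(getattr(row, c)) for c in day_cols))
            for row in self.germination.itertuples()
        ]

    def seedling_records(self) -> list[SeedlingRecord]:
        return [
            SeedlingRecord(
                genotype_id=row.genotype, treatment=row.treatment,
                replicate=int(row.replicate), fresh_weight=float(row.fw_g),
                shoot_length=float(row.sl_cm), root_length=float(row.rl_cm),
                root_number=int(row.rno))
            for row in self.seedlings.itertuples()
        ]

    def write(self, out_dir: str | Path) -> None:
        from .io import write_genotypes, write_genetic_map

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_genetic_map(self.gmap, out / "map.csv")
        write_genotypes(self.geno, out / "genotypes.csv")
        self.germination.to_csv(out / "germination.csv", index=False)
        self.seedlings.to_csv(out / "seedlings.csv", index=False)
        (out / "truth.json").write_text(json.dumps(self.truth, indent=2))


def simulate_dataset(config: SimConfig | None = None) -> SimDataset:
    """Run the full generator under one seed; byte-identical per config."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    gmap = simulate_map(config, rng)
    geno = simulate_dh_genotypes(gmap, config.n_lines, rng=rng)
    seedlings, germ_days, truth = simulate_phenotypes(geno, gmap, config, rng)
    germination = simulate_germination(config, germ_days, rng)
    truth["config"] = {
        "seed": config.seed, "n_lines": config.n_lines, "n_reps": config.n_reps,
        "treatments": list(config.treatments)}
    return SimDataset(config, gmap, geno, seedlings, germination, truth)
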