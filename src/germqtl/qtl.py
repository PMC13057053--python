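"""Single-marker QTL analysis for doubled-haploid populations.

Doubled haploids carry one of the two parental alleles at every locus, so
genotypes are coded +1 (first parent) / -1 (second parent) and a
single-marker test is the least-squares fit ``y = mu + a*x``:

* ``add``  -- the slope ``a``, i.e. half the difference between the two
  homozygous class means (positive: first-parent allele raises the trait);
* ``lod``  -- (n/2) * log10(SS_total / SS_residual), the Gaussian
  likelihood-ratio form of the marker test;
* ``pve``  -- 100 * R^2 = 100 * (1 - SS_res/SS_tot), linked to the LOD by
  pve = 100 * (1 - 10^(-2*lod/n)).

Genome-wide significance comes from permutation of the phenotype across
lines (empirical (1-alpha) quantile of the per-permutation maximum LOD,
type-7 interpolation), support intervals from the 1-LOD-drop rule with
linear interpolation between markers, and QTL strength classes follow
PVE >= 20 (very strong), 10-20 (major), below (minor).

The module also provides the Kosambi map-function pair and the per-
chromosome / per-genome linkage-map summary (A/B/D genome rollups report
the sum of per-chromosome marker densities, the convention used in
published wheat map summaries; the markers-per-cM ratio is available as an
alternative).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataWarning, InvalidInputError

ENVIRONMENT_LABELS = {
    "C": "Control",
    "D": "Drought",
    "CN": "Control and Nano",
    "DN": "Drought and Nano",
}


# ---------------------------------------------------------------- map types

@dataclass(frozen=True)
class Marker:
    name: str
    pos: float  # cM


@dataclass
class Chromosome:
    name: str
    markers: list[Marker]

    @property
    def length(self) -> float:
        return self.markers[-1].pos if self.markers else 0.0

    @property
    def positions(self) -> np.ndarray:
        return np.array([m.pos for m in self.markers])


@dataclass
class GeneticMap:
    """Ordered marker positions (cM) on named chromosomes."""

    chromosomes: list[Chromosome]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for chrom in self.chromosomes:
            pos = [m.pos for m in chrom.markers]
            if any(p < 0 for p in pos):
                raise InvalidInputError(f"negative position on {chrom.name}")
            if any(b < a for a, b in zip(pos, pos[1:])):
                raise InvalidInputError(f"markers out of order on {chrom.name}")
            for m in chrom.markers:
                if m.name in seen:
                    raise InvalidInputError(f"duplicate marker name {m.name!r}")
                seen.add(m.name)

    @property
    def marker_names(self) -> list[str]:
        return [m.name for c in self.chromosomes for m in c.markers]

    @property
    def n_markers(self) -> int:
        return sum(len(c.markers) for c in self.chromosomes)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c.name, m.name, m.pos) for c in self.chromosomes for m in c.markers],
            columns=["chrom", "marker", "pos_cM"],
        )


@dataclass
class GenotypeMatrix:
    """DH genotypes: lines x markers, entries +1 / -1 / NaN (missing)."""

    line_ids: list[str]
    marker_names: list[str]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.shape != (len(self.line_ids), len(self.marker_names)):
            raise InvalidInputError("codes shape does not match line/marker lists")
        ok = np.isnan(self.codes) | (self.codes == 1) | (self.codes == -1)
        if not ok.all():
            raise InvalidInputError(
                "DH genotypes must be +1/-1/missing (no heterozygotes)")


# ------------------------------------------------------------- map function

def kosambi(value: float, mode: str) -> float:
    """Kosambi map function, centiMorgan interface.

    ``r_to_d``: recombination fraction r in [0, 0.5) -> map distance in cM,
    d = 25 * ln((1+2r)/(1-2r)).  ``d_to_r``: cM -> r = 0.5 * tanh(2d),
    with d in Morgans.  The two are exact inverses.
    """
    if mode == "r_to_d":
        r = float(value)
        if not 0 <= r < 0.5:
            raise InvalidInputError("recombination fraction must be in [0, 0.5)")
        return 100.0 * 0.25 * math.log((1 + 2 * r) / (1 - 2 * r))
    if mode == "d_to_r":
        d_cm = float(value)
        if d_cm < 0:
            raise InvalidInputError("map distance must be >= 0")
        return 0.5 * math.tanh(2 * d_cm / 100.0)
    raise InvalidInputError(f"unknown mode {mode!r}")


# -------------------------------------------------------------------- scan

@dataclass
class ScanResult:
    """Per-marker LOD / PVE / additive-effect profile."""

    records: pd.DataFrame  # marker chrom pos_cM n lod pve add
    threshold_used: float | None = None
    skipped: list[str] = field(default_factory=list)  # monomorphic markers

    def per_chromosome(self, chrom: str) -> pd.DataFrame:
        return self.records[self.records["chrom"] == chrom].reset_index(drop=True)


def _marker_stats(x: np.ndarray, y: np.ndarray) -> tuple[int, float, float, float]:
    """(n, ss_tot, ss_res, slope) of y = mu + a*x over complete pairs."""
    ok = ~np.isnan(x)
    n = int(ok.sum())
    xi, yi = x[ok], y[ok]
    sxx = float(((xi - xi.mean()) ** 2).sum())
    ss_tot = float(((yi - yi.mean()) ** 2).sum())
    if sxx == 0:
        return n, ss_tot, float("nan"), float("nan")
    slope = float(((xi - xi.mean()) * (yi - yi.mean())).sum() / sxx)
    ss_res = max(ss_tot - slope ** 2 * sxx, 0.0)
    return n, ss_tot, ss_res, slope


def lod_to_pve(lod: float | np.ndarray, n: int | np.ndarray) -> float | np.ndarray:
    """PVE (%) implied by a LOD score at sample size n."""
    return 100.0 * (1.0 - 10.0 ** (-2.0 * np.asarray(lod, dtype=float) / n))


def single_marker_scan(
    geno: GenotypeMatrix,
    gmap: GeneticMap,
    phenotype: np.ndarray | pd.Series,
    min_lines: int = 10,
    lod_ceiling: float = 50.0,
) -> ScanResult:
    """Marker-by-marker regression scan of a per-line phenotype.

    Lines with missing phenotype are dropped globally; missing genotypes
    are dropped per marker (pairwise deletion).  Monomorphic markers, or
    markers with fewer than ``min_lines`` usable lines, are skipped and
    listed in ``ScanResult.skipped``.  A perfect fit (SS_res = 0) reports
    ``lod_ceiling`` instead of infinity.
    """
    y = np.asarray(
        phenotype.reindex(geno.line_ids) if isinstance(phenotype, pd.Series)
        else phenotype, dtype=float)
    if y.shape != (len(geno.line_ids),):
        raise InvalidInputError("phenotype length does not match line count")
    keep = ~np.isnan(y)
    y = y[keep]
    codes = geno.codes[keep]

    map_frame = gmap.frame()
    col = {m: i for i, m in enumerate(geno.marker_names)}
    rows, skipped = [], []
    for chrom, marker, pos in map_frame.itertuples(index=False):
        if marker not in col:
            skipped.append(marker)
            continue
        x = codes[:, col[marker]]
        n, ss_tot, ss_res, slope = _marker_stats(x, y)
        classes = np.unique(x[~np.isnan(x)])
        if n < min_lines or len(classes) < 2:
            skipped.append(marker)
            continue
        if ss_tot == 0:
            lod, pve = 0.0, 0.0
        elif ss_res == 0:
            lod, pve = lod_ceiling, 100.0
        else:
            lod = (n / 2.0) * math.log10(ss_tot / ss_res)
            pve = 100.0 * (1.0 - ss_res / ss_tot)
        rows.append((marker, chrom, pos, n, lod, pve, slope))
    records = pd.DataFrame(
        rows, columns=["marker", "chrom", "pos_cM", "n", "lod", "pve", "add"])
    return ScanResult(records=records, skipped=skipped)


def permutation_threshold(
    geno: GenotypeMatrix,
    gmap: GeneticMap,
    phenotype: np.ndarray | pd.Series,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    min_lines: int = 10,
) -> float:
    """Genome-wide LOD threshold: (1-alpha) quantile of permutation maxima.

    The phenotype vector is permuted across lines ``n_perm`` times with a
    seeded generator; each permutation records the maximum LOD over all
    markers.  The quantile uses linear (type-7) interpolation.  With
    complete genotype data the permutations are evaluated in one
    vectorized correlation product; otherwise each permutation re-runs the
    scan.
    """
    if n_perm < 100:
        raise InvalidInputError("need at least 100 permutations")
    rng = np.random.default_rng(seed)
    y = np.asarray(
        phenotype.reindex(geno.line_ids) if isinstance(phenotype, pd.Series)
        else phenotype, dtype=float)
    keep = ~np.isnan(y)
    y = y[keep]
    codes = geno.codes[keep]
    n = len(y)
    if y.std() == 0:
        return 0.0

    in_map = set(gmap.marker_names)
    cols = [i for i, m in enumerate(geno.marker_names) if m in in_map]
    x = codes[:, cols]
    poly = np.array([len(np.unique(c[~np.isnan(c)])) == 2 for c in x.T])
    x = x[:, poly]

    if not np.isnan(x).any():
        xs = (x - x.mean(axis=0)) / x.std(axis=0)
        perms = np.empty((n, n_perm))
        for j in range(n_perm):
            perms[:, j] = rng.permutation(y)
        ys = (perms - perms.mean(axis=0)) / perms.std(axis=0)
        r2 = ((xs.T @ ys) / n) ** 2  # markers x perms
        r2max = r2.max(axis=0)
        max_lods = np.where(
            r2max >= 1.0, np.inf, -(n / 2.0) * np.log10(1.0 - r2max))
    else:
        sub_geno = GenotypeMatrix(
            [l for l, k in zip(geno.line_ids, keep) if k],  # noqa: E741
            geno.marker_names, codes)
        max_lods = np.empty(n_perm)
        for j in range(n_perm):
            res = single_marker_scan(
                sub_geno, gmap, rng.permutation(y), min_lines=min_lines)
            max_lods[j] = res.records["lod"].max() if len(res.records) else 0.0
    return float(np.quantile(max_lods, 1.0 - alpha))


# ------------------------------------------------- intervals and QTL calls

def support_interval(
    scan: ScanResult, peak_marker: str, drop: float = 1.0
) -> tuple[float, float]:
    """LOD-drop support interval around a peak, linearly interpolated.

    Walk outward from the peak until the profile falls below
    ``peak_lod - drop``; the boundary is interpolated between the last
    marker above the cut and the first below, and truncated at the
    chromosome ends.
    """
    rec = scan.records
    hit = rec[rec["marker"] == peak_marker]
    if hit.empty:
        raise InvalidInputError(f"marker {peak_marker!r} not in scan")
    chrom = hit["chrom"].iloc[0]
    prof = scan.per_chromosome(chrom)
    idx = int(prof.index[prof["marker"] == peak_marker][0])
    cut = float(prof.loc[idx, "lod"]) - drop
    pos = prof["pos_cM"].to_numpy()
    lod = prof["lod"].to_numpy()

    left = pos[idx]
    for i in range(idx - 1, -1, -1):
        if lod[i] < cut:
            frac = (lod[i + 1] - cut) / (lod[i + 1] - lod[i])
            left = pos[i + 1] + frac * (pos[i] - pos[i + 1])
            break
        left = pos[i]
    right = pos[idx]
    for i in range(idx + 1, len(prof)):
        if lod[i] < cut:
            frac = (lod[i - 1] - cut) / (lod[i - 1] - lod[i])
            right = pos[i - 1] + frac * (pos[i] - pos[i - 1])
            break
        right = pos[i]
    return float(left), float(right)


@dataclass
class QtlCall:
    """One merged QTL record, mirroring the published report columns."""

    qtl_id: str
    trait: str
    chrom: str
    peak_pos: float
    left_marker: str
    right_marker: str
    lod: float
    pve: float
    add: float
    ci_left: float
    ci_right: float
    environment: str
    strength: str


def classify_strength(pve: float) -> str:
    """very_strong (PVE >= 20), major (10 <= PVE < 20), else minor."""
    if pve >= 20.0:
        return "very_strong"
    if pve >= 10.0:
        return "major"
    return "minor"


def call_qtls(
    scan: ScanResult,
    threshold: float,
    trait: str,
    environment: str,
    gmap: GeneticMap,
    drop: float = 1.0,
) -> list[QtlCall]:
    """Merge significant markers into QTLs and classify them.

    Markers with LOD > threshold are grouped per chromosome; markers whose
    ``drop``-LOD support intervals overlap collapse into one QTL reported
    at the highest-LOD marker.  Flanking markers are the map neighbours
    bracketing the peak (the peak marker itself at chromosome ends).
    """
    env_code = environment if environment in ENVIRONMENT_LABELS else {
        v: k for k, v in ENVIRONMENT_LABELS.items()}.get(environment)
    if env_code is None:
        raise InvalidInputError(f"unknown environment {environment!r}")
    calls: list[QtlCall] = []
    for chrom_obj in gmap.chromosomes:
        prof = scan.per_chromosome(chrom_obj.name)
        sig = prof[prof["lod"] > threshold]
        if sig.empty:
            continue
        intervals = {
            row.marker: support_interval(scan, row.marker, drop)
            for row in sig.itertuples()
        }
        # merge significant markers whose support intervals overlap
        items = sorted(sig.itertuples(), key=lambda r: r.pos_cM)
        clusters: list[list] = [[items[0]]]
        cur_right = intervals[items[0].marker][1]
        for row in items[1:]:
            lo, hi = intervals[row.marker]
            if lo <= cur_right:
                clusters[-1].append(row)
                cur_right = max(cur_right, hi)
            else:
                clusters.append([row])
                cur_right = hi
        for cluster in clusters:
            peak = max(cluster, key=lambda r: r.lod)
            ci_left = min(intervals[r.marker][0] for r in cluster)
            ci_right = max(intervals[r.marker][1] for r in cluster)
            names = [m.name for m in chrom_obj.markers]
            i = names.index(peak.marker)
            left_m = names[i - 1] if i > 0 else names[i]
            right_m = names[i + 1] if i + 1 < len(names) else names[i]
            calls.append(QtlCall(
                qtl_id=f"Q{trait}_{env_code}{chrom_obj.name}",
                trait=trait,
                chrom=chrom_obj.name,
                peak_pos=float(peak.pos_cM),
                left_marker=left_m,
                right_marker=right_m,
                lod=float(peak.lod),
                pve=float(peak.pve),
                add=float(peak.add),
                ci_left=ci_left,
                ci_right=ci_right,
                environment=ENVIRONMENT_LABELS[env_code],
                strength=classify_strength(float(peak.pve)),
            ))
    return calls


# ------------------------------------------------------------- map summary

def map_summary(
    gmap: GeneticMap | None = None,
    counts_lengths: list[tuple[str, int, float]] | None = None,
    rollup: str = "density_sum",
) -> pd.DataFrame:
    """Per-chromosome and per-genome linkage-map summary.

    Accepts either a :class:`GeneticMap` or pre-tabulated (chromosome,
    marker count, length) triples.  Chromosomes are grouped into the A/B/D
    wheat genomes by their name suffix.  ``rollup`` chooses the genome /
    total density convention: ``density_sum`` (default) adds the unrounded
    per-chromosome densities; ``ratio`` reports total markers / total cM.
    """
    if rollup not in ("density_sum", "ratio"):
        raise InvalidInputError("rollup must be 'density_sum' or 'ratio'")
    if (gmap is None) == (counts_lengths is None):
        raise InvalidInputError("pass exactly one of gmap / counts_lengths")
    if gmap is not None:
        counts_lengths = [
            (c.name, len(c.markers), c.length) for c in gmap.chromosomes]

    rows = []
    for name, count, length in counts_lengths:
        if length == 0:
            warnings.warn(f"zero-length chromosome {name}; density undefined",
                          DataWarning)
            density = float("nan")
        else:
            density = count / length
        rows.append({"group": name, "kind": "chromosome", "n_markers": count,
                     "length_cM": length, "density": density})
    chrom_df = pd.DataFrame(rows)

    def _roll(label: str, members: pd.DataFrame) -> dict:
        dens = (members["density"].sum() if rollup == "density_sum"
                else members["n_markers"].sum() / members["length_cM"].sum())
        return {"group": label, "kind": "genome" if label != "Total" else "total",
                "n_markers": int(members["n_markers"].sum()),
                "length_cM": float(members["length_cM"].sum()),
                "density": float(dens)}

    genome_rows = []
    for genome in ("A", "B", "D"):
        members = chrom_df[chrom_df["group"].str.endswith(genome)]
        if len(members):
            genome_rows.append(_roll(genome, members))
    genome_rows.append(_roll("Total", chrom_df))
    return pd.concat([chrom_df, pd.DataFrame(genome_rows)], ignore_index=True)
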