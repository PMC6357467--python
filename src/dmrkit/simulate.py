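"""Synthetic low-coverage WGBS cohorts with planted differential methylation.

The generator emulates the statistical structure of a whole-genome
bisulfite study of a liver disease cohort: CpG sites laid down as a
renewal process along toy chromosomes, a bimodal methylation landscape
(CpG-island-like sites low, background high), negative-binomial read
coverage, beta-binomial inter-sample dispersion, group structure with
planted differentially methylated regions of known location and effect,
covariates, and annotation tracks (enhancer-like interval sets, a
TSS/gene-model table, a drug-target table) with a controllable enrichment
of the planted regions. Everything is deterministic given the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import MethylationMatrix, write_cytosine_report
from .regions import RegionSet

DEFAULT_CHROMOSOMES = [("chr1", 5_000_000), ("chr2", 5_000_000)]


@dataclass
class PlantedDMR:
    """A region whose methylation is shifted in the affected groups.

    ``delta`` is a signed shift on the proportion scale, applied to the
    per-CpG baseline and clipped to [0.01, 0.99]. The magnitude scale of
    interest is 0.1-0.4, bracketing the percent differences reported for
    genome-wide-significant regions in liver disease methylome studies.
    """

    chrom: str
    start: int
    end: int
    delta: float
    affected_groups: tuple[str, ...] = ("WD",)
    n_cpgs: int = 5

    def __post_init__(self):
        if abs(self.delta) > 0.5:
            raise ValueError("|delta| must be <= 0.5")
        if self.start < 0 or self.start >= self.end:
            raise ValueError("invalid planted region coordinates")
        if self.n_cpgs < 5:
            raise ValueError("planted regions need n_cpgs >= 5")


@dataclass
class SimulationConfig:
    seed: int = 0
    chromosomes: list[tuple[str, int]] = field(default_factory=lambda: list(DEFAULT_CHROMOSOMES))
    cpg_island_fraction: float = 0.2
    mean_cpg_spacing: int = 200
    mean_coverage: float = 8.0
    coverage_dispersion: float = 3.0
    beta_precision: float = 30.0
    n_per_group: dict[str, int] = field(default_factory=lambda: {"WD": 10, "HC": 10})
    planted_dmrs: list[PlantedDMR] = field(default_factory=list)
    covariate_spec: dict | None = None
    confounded_fibrosis: bool = False

    def __post_init__(self):
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be > 0")
        if self.beta_precision <= 0:
            raise ValueError("beta_precision must be > 0")
        if self.coverage_dispersion <= 0:
            raise ValueError("coverage_dispersion must be > 0")
        if not (0 <= self.cpg_island_fraction <= 1):
            raise ValueError("cpg_island_fraction must be a proportion")
        if any(n < 0 for n in self.n_per_group.values()):
            raise ValueError("group sizes must be >= 0")
        names = list(self.n_per_group)
        if len(set(names)) != len(names):
            raise ValueError("group names must be unique")


@dataclass
class CpGLandscape:
    chrom: np.ndarray
    pos: np.ndarray
    baseline: np.ndarray
    island: np.ndarray
    chrom_lengths: dict[str, int]

    @property
    def n_cpgs(self) -> int:
        return len(self.pos)

    def region_indices(self, chrom: str, start: int, end: int) -> np.ndarray:
        mask = self.chrom == chrom
        idx = np.flatnonzero(mask)
        sub = self.pos[idx]
        lo = np.searchsorted(sub, start, side="left")
        hi = np.searchsorted(sub, end, side="left")
        return idx[lo:hi]


@dataclass
class TruthSet:
    """Ground truth: planted regions with realized shifts plus the
    annotation enrichment plan used by :func:`simulate_region_annotations`."""

    planted: list[dict]
    annotation_plan: dict = field(default_factory=dict)

    def planted_regions(self, groups: Sequence[str] | None = None) -> RegionSet:
        rows = [
            p
            for p in self.planted
            if groups is None or tuple(p["affected_groups"]) == tuple(groups)
        ]
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "delta", "affected_groups",
                                         "n_cpgs_covered", "realized_shift"])
        return RegionSet(df[["chrom", "start", "end", "delta"]].assign(
            direction=np.where(df["delta"] > 0, "hyper", "hypo")) if len(df) else
            pd.DataFrame(columns=["chrom", "start", "end", "delta", "direction"]),
            name="planted")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"planted": self.planted, "annotation_plan": self.annotation_plan},
                       indent=1, default=str)
        )


def simulate_cpg_landscape(config: SimulationConfig, rng: np.random.Generator | None = None) -> CpGLandscape:
    """Lay down CpG positions and a bimodal baseline methylation level.

    Inter-CpG gaps are geometric with the configured mean spacing, so the
    CpG count per chromosome is a renewal count. Island membership is
    assigned in blocks of ~20 consecutive CpGs; island CpGs draw their
    baseline from a low mode (mean ~0.2), background CpGs from a high
    mode (mean ~0.8).
    """
    rng = rng or np.random.default_rng(config.seed)
    chroms, poss = [], []
    for name, length in config.chromosomes:
        est = max(16, int(2.5 * length / config.mean_cpg_spacing))
        gaps = rng.geometric(1.0 / config.mean_cpg_spacing, size=est)
        pos = np.cumsum(gaps)
        pos = pos[pos < length - 1]
        if len(pos) < 2:
            raise ValueError(
                f"chromosome {name!r} too short ({length} bp) for CpG spacing "
                f"{config.mean_cpg_spacing}"
            )
        chroms.append(np.full(len(pos), name, dtype=object))
        poss.append(pos.astype(np.int64))
    chrom = np.concatenate(chroms)
    pos = np.concatenate(poss)
    n = len(pos)

    block = 20
    n_blocks = (n + block - 1) // block
    island_block = rng.random(n_blocks) < config.cpg_island_fraction
    island = np.repeat(island_block, block)[:n]
    baseline = np.where(island, rng.beta(2.0, 8.0, size=n), rng.beta(8.0, 2.0, size=n))
    return CpGLandscape(
        chrom=chrom, pos=pos, baseline=baseline, island=island,
        chrom_lengths=dict(config.chromosomes),
    )


def plant_dmr_truth(
    landscape: CpGLandscape, specs: Sequence[PlantedDMR]
) -> TruthSet:
    """Record planted regions and their realized (post-clipping) shifts.

    Specs must be non-overlapping, lie inside the landscape, and cover at
    least their requested number of simulated CpGs.
    """
    by_chrom: dict[str, list[PlantedDMR]] = {}
    for spec in specs:
        if spec.chrom not in landscape.chrom_lengths:
            raise ValueError(f"planted region on unknown chromosome {spec.chrom!r}")
        if spec.end > landscape.chrom_lengths[spec.chrom]:
            raise ValueError(f"planted region {spec.chrom}:{spec.start}-{spec.end} out of bounds")
        by_chrom.setdefault(spec.chrom, []).append(spec)
    for chrom, group in by_chrom.items():
        ordered = sorted(group, key=lambda s: s.start)
        for prev, nxt in zip(ordered, ordered[1:]):
            if nxt.start < prev.end:
                raise ValueError(
                    f"planted regions overlap on {chrom}: "
                    f"[{prev.start},{prev.end}) and [{nxt.start},{nxt.end})"
                )
    planted = []
    for spec in specs:
        idx = landscape.region_indices(spec.chrom, spec.start, spec.end)
        if len(idx) < spec.n_cpgs:
            raise ValueError(
                f"planted region {spec.chrom}:{spec.start}-{spec.end} covers only "
                f"{len(idx)} CpGs (< {spec.n_cpgs})"
            )
        base = np.clip(landscape.baseline[idx], 0.01, 0.99)
        shifted = np.clip(base + spec.delta, 0.01, 0.99)
        planted.append(
            {
                "chrom": spec.chrom,
                "start": int(spec.start),
                "end": int(spec.end),
                "delta": float(spec.delta),
                "affected_groups": list(spec.affected_groups),
                "n_cpgs_covered": int(len(idx)),
                "realized_shift": float(np.mean(shifted - base)),
            }
        )
    return TruthSet(planted=planted)


def choose_planted_regions(
    landscape: CpGLandscape,
    n_regions: int,
    deltas: Sequence[float],
    n_cpgs: int = 10,
    affected_groups: tuple[str, ...] = ("WD",),
    rng: np.random.Generator | None = None,
) -> list[PlantedDMR]:
    """Pick ``n_regions`` well-separated runs of ``n_cpgs`` consecutive CpGs
    and turn them into planted specs (cycling through ``deltas``).

    Guarantees every planted region covers exactly ``n_cpgs`` simulated
    CpGs regardless of the random CpG spacing. Placement is
    baseline-aware so the full shift is realizable after clipping:
    positive shifts land on low-methylation runs (the island-like mode,
    as when normally unmethylated regulatory regions gain methylation)
    and negative shifts on high-methylation background runs.
    """
    rng = rng or np.random.default_rng(0)
    n_total = landscape.n_cpgs
    if n_regions * 3 * n_cpgs > n_total:
        raise ValueError("landscape too small for the requested planted regions")
    stride = n_total // n_regions
    specs: list[PlantedDMR] = []
    for r in range(n_regions):
        delta = float(deltas[r % len(deltas)])
        lo = r * stride
        hi = min(n_total, lo + stride) - n_cpgs
        if hi <= lo:
            continue
        candidates = list(range(lo, hi, max(1, n_cpgs // 2)))
        best, best_score = None, -np.inf
        for i0 in candidates:
            i1 = i0 + n_cpgs
            if landscape.chrom[i0] != landscape.chrom[i1 - 1]:
                continue
            base = float(landscape.baseline[i0:i1].mean())
            headroom = (1.0 - base) if delta > 0 else base
            if best is None or headroom > best_score:
                best, best_score = i0, headroom
        if best is None or best_score < abs(delta):
            continue  # no run with enough headroom in this stride
        i0, i1 = best, best + n_cpgs
        specs.append(
            PlantedDMR(
                chrom=str(landscape.chrom[i0]),
                start=int(landscape.pos[i0]),
                end=int(landscape.pos[i1 - 1]) + 2,
                delta=delta,
                affected_groups=affected_groups,
                n_cpgs=n_cpgs,
            )
        )
    return specs


def group_mean_methylation(
    landscape: CpGLandscape, truth: TruthSet, group: str
) -> np.ndarray:
    """Per-CpG mean methylation for one group: baseline plus any planted
    shift affecting the group, clipped to [0.01, 0.99]."""
    mu = np.clip(landscape.baseline, 0.01, 0.99).copy()
    for p in truth.planted:
        if group in p["affected_groups"]:
            idx = landscape.region_indices(p["chrom"], p["start"], p["end"])
            mu[idx] = np.clip(mu[idx] + p["delta"], 0.01, 0.99)
    return mu


def default_covariate_spec(confounded_fibrosis: bool = False) -> dict:
    """Distributions for demographic/histology covariates per group.

    By default covariates are independent of group (so association screens
    should be null); the confounding switch skews the fibrosis stage in
    the case group, emulating the real cohort where cases present more
    advanced fibrosis.
    """
    fib_case = [0.05, 0.1, 0.2, 0.3, 0.35] if confounded_fibrosis else [0.2] * 5
    return {
        "age": {"*": ("normal", 44.0, 12.0, 22.0, 72.0)},
        "sex": {"*": ("choice", ["F", "M"], [0.5, 0.5])},
        "bmi": {"*": ("normal", 28.0, 5.0, 17.0, 45.0)},
        "fibrosis": {"WD": ("choice", [0, 1, 2, 3, 4], fib_case),
                     "*": ("choice", [0, 1, 2, 3, 4], [0.2] * 5)},
        "inflammation": {"*": ("choice", [0, 1, 2, 3], [0.4, 0.3, 0.2, 0.1])},
        "steatosis": {"*": ("choice", [0, 1, 2, 3], [0.4, 0.3, 0.2, 0.1])},
    }


def _draw_covariate(spec_entry: dict, group: str, rng: np.random.Generator):
    kind = spec_entry.get(group, spec_entry.get("*"))
    if kind is None:
        return np.nan
    if kind[0] == "normal":
        _, mean, sd, lo, hi = kind
        return float(np.clip(rng.normal(mean, sd), lo, hi))
    if kind[0] == "choice":
        _, values, probs = kind
        return values[rng.choice(len(values), p=np.asarray(probs) / np.sum(probs))]
    raise ValueError(f"unknown covariate distribution {kind[0]!r}")


@dataclass
class Cohort:
    matrix: MethylationMatrix
    sample_sheet: pd.DataFrame
    config: SimulationConfig


def simulate_cohort(
    landscape: CpGLandscape,
    truth: TruthSet,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> Cohort:
    """Draw per-sample counts: coverage ~ NB, proportion ~ Beta, counts ~
    Binomial(coverage, proportion). Covariates follow the covariate spec."""
    rng = rng or np.random.default_rng(config.seed + 1)
    n = landscape.n_cpgs
    r = config.coverage_dispersion
    p_nb = r / (r + config.mean_coverage)
    phi = config.beta_precision
    cov_spec = config.covariate_spec or default_covariate_spec(config.confounded_fibrosis)

    samples, groups = [], []
    meth_cols, total_cols = [], []
    sheet_rows = []
    for group, count in config.n_per_group.items():
        mu = group_mean_methylation(landscape, truth, group)
        a, b = mu * phi, (1 - mu) * phi
        for k in range(count):
            sid = f"{group}_{k + 1:02d}"
            coverage = rng.negative_binomial(r, p_nb, size=n)
            props = rng.beta(a, b)
            meth = rng.binomial(coverage, props)
            meth_cols.append(meth)
            total_cols.append(coverage)
            samples.append(sid)
            groups.append(group)
            row = {"sample": sid, "group": group if group in ("HC", "DC", "WD") else np.nan,
                   "phenotype": group if group in ("WDH", "WDN") else np.nan}
            for cov_name, entry in cov_spec.items():
                row[cov_name] = _draw_covariate(entry, group, rng)
            sheet_rows.append(row)

    matrix = MethylationMatrix(
        chrom=landscape.chrom,
        pos=landscape.pos,
        meth=np.column_stack(meth_cols) if meth_cols else np.zeros((n, 0), np.int64),
        total=np.column_stack(total_cols) if total_cols else np.zeros((n, 0), np.int64),
        samples=samples,
    )
    sheet = pd.DataFrame(sheet_rows)
    if sheet["group"].isna().all():
        sheet = sheet.drop(columns=["group"])
    if "phenotype" in sheet.columns and sheet["phenotype"].isna().all():
        sheet = sheet.drop(columns=["phenotype"])
    return Cohort(matrix=matrix, sample_sheet=sheet, config=config)


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Write per-sample cytosine reports and the sample sheet.

    Byte-identical for identical config and seed. Returns the directory.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    m = cohort.matrix
    files = []
    for j, sid in enumerate(m.samples):
        df = pd.DataFrame(
            {"chrom": m.chrom, "pos": m.pos, "strand": "+",
             "meth": m.meth[:, j], "unmeth": m.total[:, j] - m.meth[:, j]}
        )
        path = outdir / f"{sid}.CpG_report.txt"
        write_cytosine_report(df, path)
        files.append(path.name)  # relative: keeps the sheet portable
    sheet = cohort.sample_sheet.copy()
    sheet["file"] = files
    sheet.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    return outdir


def _random_intervals(
    rng: np.random.Generator, chrom_lengths: dict[str, int], n: int, length: int
) -> list[tuple[str, int, int]]:
    names = list(chrom_lengths)
    sizes = np.array([chrom_lengths[c] for c in names], dtype=float)
    out = []
    for _ in range(n):
        c = names[rng.choice(len(names), p=sizes / sizes.sum())]
        start = int(rng.integers(0, max(1, chrom_lengths[c] - length)))
        out.append((c, start, start + length))
    return out


def simulate_region_annotations(
    landscape: CpGLandscape,
    truth: TruthSet,
    config: SimulationConfig,
    enrichment_factor: float = 10.0,
    base_rate: float = 0.2,
    interval_length: int = 1000,
    genes_per_mb: float = 10.0,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, RegionSet], pd.DataFrame, pd.DataFrame]:
    """Annotation stand-ins with a known enrichment of planted regions.

    The ``enhancer_like`` set is built from genome-wide random intervals
    whose density makes a ~1 kb region overlap with probability
    ``base_rate``, topped up so that planted hypermethylated regions are
    covered at ``enrichment_factor`` times that rate (factor 1 adds no
    preference). ``null_1``/``null_2`` are matched random sets. Also
    returns a TSS/gene-model table and a drug-target table in which one
    drug ("TARGETED_DRUG") targets the genes nearest the planted regions.
    """
    if enrichment_factor < 1:
        raise ValueError("enrichment_factor must be >= 1")
    rng = rng or np.random.default_rng(config.seed + 2)
    genome = sum(landscape.chrom_lengths.values())
    lam = -np.log(max(1e-12, 1.0 - base_rate)) / (2.0 * interval_length)
    n_random = int(round(lam * genome))

    annotations: dict[str, RegionSet] = {}
    for name in ("enhancer_like", "null_1", "null_2"):
        ivs = _random_intervals(rng, landscape.chrom_lengths, n_random, interval_length)
        if name == "enhancer_like":
            p_extra = min(1.0, (enrichment_factor - 1.0) * base_rate)
            for p in truth.planted:
                if p["delta"] > 0 and rng.random() < p_extra:
                    center = (p["start"] + p["end"]) // 2
                    ivs.append((p["chrom"], max(0, center - interval_length // 2),
                                center + interval_length // 2))
        df = pd.DataFrame(ivs, columns=["chrom", "start", "end"])
        annotations[name] = RegionSet(df, name=name)

    tss_table = _simulate_gene_models(landscape, genes_per_mb, rng)
    drug_table = _simulate_drug_table(truth, tss_table, rng)
    truth.annotation_plan = {
        "enriched_set": "enhancer_like",
        "enrichment_factor": enrichment_factor,
        "base_rate": base_rate,
        "direction": "hyper",
        "targeted_drug": "TARGETED_DRUG",
    }
    return annotations, tss_table, drug_table


def _simulate_gene_models(
    landscape: CpGLandscape, genes_per_mb: float, rng: np.random.Generator
) -> pd.DataFrame:
    rows = []
    i = 0
    for chrom, length in landscape.chrom_lengths.items():
        spacing = int(1_000_000 / genes_per_mb)
        for anchor in range(spacing // 2, length - 60_000, spacing):
            tss_jitter = int(rng.integers(-spacing // 5, spacing // 5))
            strand = "+" if rng.random() < 0.5 else "-"
            span = int(rng.integers(5_000, 50_000))
            if strand == "+":
                start = max(0, anchor + tss_jitter)
                end = min(length, start + span)
                tss = start
            else:
                end = min(length, anchor + tss_jitter + span)
                start = max(0, end - span)
                tss = end - 1
            n_exons = int(rng.integers(3, 9))
            cuts = np.sort(rng.integers(start + 1, end - 1, size=2 * (n_exons - 1)))
            bounds = np.concatenate(([start], cuts, [end]))
            exons = [(int(bounds[2 * k]), int(bounds[2 * k + 1])) for k in range(n_exons)]
            exons = [(s, e) for s, e in exons if e > s]
            rows.append(
                {"gene": f"GENE_{i:04d}", "chrom": chrom, "strand": strand, "tss": int(tss),
                 "start": int(start), "end": int(end),
                 "exons": ";".join(f"{s}-{e}" for s, e in exons)}
            )
            i += 1
    return pd.DataFrame(rows)


def _simulate_drug_table(
    truth: TruthSet, tss_table: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    from .annotation import nearest_genes

    universe = list(tss_table["gene"])
    rows = []
    for k in range(10):
        n_targets = min(int(rng.integers(5, 16)), len(universe))
        for g in rng.choice(len(universe), size=n_targets, replace=False):
            rows.append({"drug": f"DRUG_{k:02d}", "gene": universe[g]})
    planted_df = pd.DataFrame(truth.planted)
    if len(planted_df):
        hits = nearest_genes(planted_df, tss_table, k=1)
        for g in sorted(set(hits["gene"])):
            rows.append({"drug": "TARGETED_DRUG", "gene": g})
    return pd.DataFrame(rows, columns=["drug", "gene"])


def simulate_phenotype_table(
    n_regions: int = 2860,
    n_informative: int = 44,
    delta: float = 0.2,
    n_per_class: dict[str, int] | None = None,
    coverage_per_region: int = 80,
    region_precision: float = 10.0,
    seed: int = 0,
    base: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    sample_prefix: str = "",
) -> tuple[pd.DataFrame, pd.Series]:
    """Region x sample percent-methylation table with a planted phenotype
    effect in the first ``n_informative`` regions (shift applied to the
    WDH class).

    ``region_precision`` is the beta precision of a subject's region-level
    methylation around the region mean. It is deliberately much smaller
    than the per-CpG dispersion used for count simulation: within a region
    a subject's CpGs are strongly correlated, so averaging them does not
    shrink inter-individual variance, and region percent methylation in
    blood typically varies by 10-20 points between subjects. The default
    (10, giving ~0.17 sd at intermediate methylation) makes a 0.2 shift a
    realistically noisy single-region signal.

    Pass ``base`` (per-region mean methylation) to generate an
    independent cohort over the *same* regions as an earlier call.
    """
    rng = rng or np.random.default_rng(seed)
    n_per_class = n_per_class or {"WDH": 20, "WDN": 20}
    if base is None:
        base = rng.uniform(0.2, 0.8, size=n_regions)
    informative = np.zeros(n_regions, dtype=bool)
    informative[:n_informative] = True
    cols, labels = [], []
    for cls, count in n_per_class.items():
        mu = np.where(informative & (cls == "WDH"), np.clip(base + delta, 0.01, 0.99), base)
        mu = np.clip(mu, 0.01, 0.99)
        for k in range(count):
            props = rng.beta(mu * region_precision, (1 - mu) * region_precision)
            cov = np.maximum(1, rng.poisson(coverage_per_region, size=n_regions))
            meth = rng.binomial(cov, props)
            cols.append(100.0 * meth / cov)
            labels.append(cls)
    index = pd.Index([f"region_{i:04d}" for i in range(n_regions)], name="region")
    samples = [
        f"{sample_prefix}{cls}_{i:02d}" for cls, count in n_per_class.items() for i in range(count)
    ]
    table = pd.DataFrame(np.column_stack(cols), index=index, columns=samples)
    return table, pd.Series(labels, index=samples, name="phenotype")


def simulate_phenotype_cohorts(
    n_regions: int = 2860,
    n_informative: int = 44,
    delta: float = 0.2,
    n_train_per_class: dict[str, int] | None = None,
    n_test_per_class: dict[str, int] | None = None,
    region_precision: float = 10.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, pd.Series]:
    """Training and independent test cohorts over one shared set of regions.

    The test cohort draws new subjects from the same per-region means, as
    when a biomarker panel trained on one patient cohort is evaluated on
    a later one.
    """
    rng = np.random.default_rng(seed)
    base = rng.uniform(0.2, 0.8, size=n_regions)
    train = simulate_phenotype_table(
        n_regions, n_informative, delta, n_train_per_class or {"WDH": 20, "WDN": 20},
        region_precision=region_precision, base=base, rng=rng,
    )
    test = simulate_phenotype_table(
        n_regions, n_informative, delta, n_test_per_class or {"WDH": 5, "WDN": 5},
        region_precision=region_precision, base=base, rng=rng, sample_prefix="test_",
    )
    return train[0], train[1], test[0], test[1]
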