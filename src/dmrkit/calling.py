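"""Differentially methylated region calling between two sample groups.

The statistic is a coverage-weighted smoothed difference of pooled
methylation proportions. Candidate regions are maximal same-sign runs of
CpGs whose smoothed difference clears a cutoff; each candidate is scored
by its area (sum of smoothed differences). Significance comes from label
permutation: the same smoothing and segmentation are re-run under every
permuted labelling, the resulting candidate areas form a pooled empirical
null for per-region p-values, and the per-permutation maximum |area| gives
the family-wise error rate (strong control via the max-statistic).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from statsmodels.stats.multitest import multipletests

from .io import MethylationMatrix
from .regions import RegionSet

logger = logging.getLogger(__name__)


@dataclass
class DMRCallingParams:
    """Tuning parameters of the region caller.

    cutoff
        Minimum |smoothed difference| (proportion scale) for a CpG to seed
        or extend a candidate run.
    min_cpgs
        Minimum CpGs per candidate region.
    max_gap
        Maximum bp between consecutive CpGs inside one region; smoothing
        windows never bridge larger gaps either.
    window_bp
        Half-width of the weighted smoothing window.
    n_perm
        Requested label permutations; when fewer distinct assignments
        exist they are enumerated exactly once each.
    """

    cutoff: float = 0.10
    min_cpgs: int = 5
    max_gap: int = 1000
    window_bp: int = 500
    n_perm: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.cutoff < 1):
            raise ValueError("cutoff must be in (0, 1)")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


@dataclass
class DifferenceTrack:
    """Per-CpG group difference with pooled counts and smoothing weights."""

    chrom: np.ndarray
    pos: np.ndarray
    d: np.ndarray  # pooled proportion(A) - pooled proportion(B)
    w: np.ndarray  # sqrt(total coverage across both groups)
    ma: np.ndarray
    ta: np.ndarray
    mb: np.ndarray
    tb: np.ndarray
    s: np.ndarray | None = None  # smoothed difference, set by smooth_difference

    @property
    def n_cpgs(self) -> int:
        return len(self.pos)


@dataclass
class PermutationNull:
    """Empirical null from label permutations.

    ``areas`` pools the candidate areas detected in every permutation;
    ``max_abs`` holds each permutation's maximum |area| (0 when a
    permutation produced no candidate region).
    """

    n_perm: int
    areas: np.ndarray
    max_abs: np.ndarray
    enumerated: bool


@dataclass
class DMRResult:
    """Full output of one pairwise comparison."""

    candidates: pd.DataFrame
    track: DifferenceTrack
    null: PermutationNull | None
    params: DMRCallingParams
    group_a: str
    group_b: str

    def significant(self, alpha: float = 0.05, criterion: str = "fwer") -> pd.DataFrame:
        from .consensus import filter_significant

        return filter_significant(self.candidates, alpha=alpha, criterion=criterion)

    def to_region_set(self, name: str = "") -> RegionSet:
        return RegionSet(self.candidates, name=name or f"{self.group_a}_vs_{self.group_b}")


def group_methylation_difference(
    matrix: MethylationMatrix,
    group_a_ids: Sequence[str],
    group_b_ids: Sequence[str],
) -> DifferenceTrack:
    """Pooled-proportion difference per CpG, case (A) minus reference (B).

    Pooling is coverage-weighted: within each group the proportion is
    total methylated reads over total reads. CpGs without coverage in
    either group are excluded (counted in the log).
    """
    if len(group_a_ids) < 2 or len(group_b_ids) < 2:
        raise ValueError("each group needs >= 2 samples")
    if set(group_a_ids) & set(group_b_ids):
        raise ValueError("group sample ids overlap")
    ia = matrix.sample_index(group_a_ids)
    ib = matrix.sample_index(group_b_ids)
    ma = matrix.meth[:, ia].sum(axis=1)
    ta = matrix.total[:, ia].sum(axis=1)
    mb = matrix.meth[:, ib].sum(axis=1)
    tb = matrix.total[:, ib].sum(axis=1)
    keep = (ta > 0) & (tb > 0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("excluding %d CpGs with zero coverage in a group", n_dropped)
    d = ma[keep] / ta[keep] - mb[keep] / tb[keep]
    w = np.sqrt((ta + tb)[keep].astype(float))
    return DifferenceTrack(
        chrom=np.asarray(matrix.chrom)[keep],
        pos=matrix.pos[keep],
        d=d,
        w=w,
        ma=ma[keep],
        ta=ta[keep],
        mb=mb[keep],
        tb=tb[keep],
    )


def _block_ids(chrom: np.ndarray, pos: np.ndarray, max_gap: int) -> np.ndarray:
    """Integer block label per CpG; blocks break at chromosome changes and
    at inter-CpG gaps larger than ``max_gap``."""
    n = len(pos)
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    brk = np.zeros(n, dtype=bool)
    brk[1:] = (chrom[1:] != chrom[:-1]) | (np.diff(pos) > max_gap)
    return np.cumsum(brk)


def build_smoother(
    pos: np.ndarray, blocks: np.ndarray, w: np.ndarray, window_bp: int
) -> sp.csr_matrix:
    """Sparse row-stochastic smoother ``M`` with ``s = M @ d``.

    Row i averages ``d`` over CpGs of the same block within ``window_bp``
    of CpG i, weighted by ``w``.
    """
    n = len(pos)
    lo = np.empty(n, dtype=np.int64)
    hi = np.empty(n, dtype=np.int64)
    # per-block searchsorted keeps windows from bridging blocks
    bounds = np.concatenate(([0], np.flatnonzero(np.diff(blocks)) + 1, [n]))
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        sub = pos[b0:b1]
        lo[b0:b1] = b0 + np.searchsorted(sub, sub - window_bp, side="left")
        hi[b0:b1] = b0 + np.searchsorted(sub, sub + window_bp, side="right")
    counts = hi - lo
    indptr = np.concatenate(([0], np.cumsum(counts)))
    indices = np.concatenate([np.arange(a, b) for a, b in zip(lo, hi)]) if n else np.zeros(0, int)
    data = w[indices].astype(float)
    row_sums = np.add.reduceat(data, indptr[:-1]) if n else np.zeros(0)
    data /= np.repeat(row_sums, counts)
    return sp.csr_matrix((data, indices, indptr), shape=(n, n))


def smooth_difference(
    track: DifferenceTrack, window_bp: int = 500, max_gap: int = 1000
) -> DifferenceTrack:
    """Fill ``track.s`` with the windowed coverage-weighted mean of ``d``."""
    blocks = _block_ids(track.chrom, track.pos, max_gap)
    M = build_smoother(track.pos, blocks, track.w, window_bp)
    track.s = M @ track.d
    return track


def _segment(
    s: np.ndarray, blocks: np.ndarray, cutoff: float, min_cpgs: int
) -> tuple[np.ndarray, np.ndarray]:
    """Maximal same-sign runs with |s| >= cutoff inside one block.

    Returns (starts, ends) as CpG index ranges, half-open, only runs with
    at least ``min_cpgs`` CpGs.
    """
    sig = np.abs(s) >= cutoff
    idx = np.flatnonzero(sig)
    if idx.size == 0:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64)
    sgn = s[idx] > 0
    brk = (np.diff(idx) != 1) | (sgn[1:] != sgn[:-1]) | (blocks[idx[1:]] != blocks[idx[:-1]])
    run_start = np.concatenate(([0], np.flatnonzero(brk) + 1))
    run_end = np.concatenate((np.flatnonzero(brk), [idx.size - 1])) + 1
    starts = idx[run_start]
    ends = idx[run_end - 1] + 1
    keep = (ends - starts) >= min_cpgs
    return starts[keep], ends[keep]


def detect_candidate_regions(
    track: DifferenceTrack,
    cutoff: float = 0.10,
    min_cpgs: int = 5,
    max_gap: int = 1000,
) -> pd.DataFrame:
    """Segment the smoothed track into candidate regions.

    A region's coordinates span its first CpG to two bases past its last
    CpG (covering the final CpG dyad, half-open).
    """
    if track.s is None:
        raise ValueError("run smooth_difference first")
    if not (0 < cutoff < 1):
        raise ValueError("cutoff must be in (0, 1)")
    blocks = _block_ids(track.chrom, track.pos, max_gap)
    starts, ends = _segment(track.s, blocks, cutoff, min_cpgs)
    return pd.DataFrame(
        {
            "chrom": track.chrom[starts] if len(starts) else np.array([], dtype=object),
            "start": track.pos[starts] if len(starts) else np.array([], dtype=np.int64),
            "end": track.pos[ends - 1] + 2 if len(starts) else np.array([], dtype=np.int64),
            "idx_start": starts,
            "idx_end": ends,
        }
    )


def score_regions(candidates: pd.DataFrame, track: DifferenceTrack) -> pd.DataFrame:
    """Attach area statistic, percent difference, CpG count and direction."""
    out = candidates.copy()
    areas = np.empty(len(out))
    diffs = np.empty(len(out))
    for r, (i0, i1) in enumerate(zip(out["idx_start"], out["idx_end"])):
        sl = slice(int(i0), int(i1))
        areas[r] = track.s[sl].sum()
        pa = track.ma[sl].sum() / track.ta[sl].sum()
        pb = track.mb[sl].sum() / track.tb[sl].sum()
        diffs[r] = 100.0 * (pa - pb)
    out["n_cpgs"] = (out["idx_end"] - out["idx_start"]).astype(int)
    out["area"] = areas
    out["meth_diff_pct"] = diffs
    out["direction"] = np.where(diffs > 0, "hyper", "hypo")
    return out


def _distinct_assignments(n: int, n_a: int) -> int:
    return math.comb(n, n_a)


def permutation_test(
    matrix: MethylationMatrix,
    candidates: pd.DataFrame,
    group_a_ids: Sequence[str],
    group_b_ids: Sequence[str],
    n_perm: int = 1000,
    seed: int = 0,
    params: DMRCallingParams | None = None,
    batch_size: int = 128,
) -> tuple[pd.DataFrame, PermutationNull]:
    """Label-permutation empirical p-values and FWER for scored candidates.

    Every permutation preserves group sizes; when the number of distinct
    assignments is at most ``n_perm`` they are all enumerated exactly once.
    For each permuted labelling the smoothed difference is recomputed and
    segmented with the observed parameters; the detected candidate areas
    are pooled across regions and permutations for ``p_emp``, and the
    per-permutation maximum |area| yields ``fwer``. Ties count as
    exceedances and the add-one estimator is used throughout, so no
    reported p is ever zero. ``q`` is Benjamini-Hochberg over ``p_emp``.
    """
    params = params or DMRCallingParams()
    n_a, n_b = len(group_a_ids), len(group_b_ids)
    if n_a < 2 and n_b < 2:
        raise ValueError("cannot permute: both groups have a single sample")
    ids = list(group_a_ids) + list(group_b_ids)
    idx_all = matrix.sample_index(ids)
    meth = matrix.meth[:, idx_all].astype(float)
    total = matrix.total[:, idx_all].astype(float)

    # observed track geometry is reused for every permutation: the weights
    # depend only on the pooled coverage of the union, which is label-free
    keep = (total[:, :n_a].sum(axis=1) > 0) & (total[:, n_a:].sum(axis=1) > 0)
    meth, total = meth[keep], total[keep]
    chrom = np.asarray(matrix.chrom)[keep]
    pos = matrix.pos[keep]
    w = np.sqrt(total.sum(axis=1))
    blocks = _block_ids(chrom, pos, params.max_gap)
    M = build_smoother(pos, blocks, w, params.window_bp)
    msum = meth.sum(axis=1, keepdims=True)
    tsum = total.sum(axis=1, keepdims=True)

    n_samples = len(ids)
    n_distinct = _distinct_assignments(n_samples, n_a)
    rng = np.random.default_rng(seed)
    if n_distinct <= n_perm:
        assign = np.zeros((n_samples, n_distinct), dtype=float)
        for k, comb in enumerate(combinations(range(n_samples), n_a)):
            assign[list(comb), k] = 1.0
        enumerated = True
    else:
        assign = np.zeros((n_samples, n_perm), dtype=float)
        for k in range(n_perm):
            assign[rng.permutation(n_samples)[:n_a], k] = 1.0
        enumerated = False
    n_used = assign.shape[1]

    null_areas: list[np.ndarray] = []
    max_abs = np.zeros(n_used)
    for b0 in range(0, n_used, batch_size):
        A = assign[:, b0 : b0 + batch_size]
        ta = total @ A
        ma = meth @ A
        tb = tsum - ta
        mb = msum - ma
        with np.errstate(invalid="ignore", divide="ignore"):
            d = ma / ta - mb / tb
        d[~np.isfinite(d)] = 0.0
        s = M @ d
        for c in range(s.shape[1]):
            st, en = _segment(s[:, c], blocks, params.cutoff, params.min_cpgs)
            if st.size:
                cs = np.concatenate(([0.0], np.cumsum(s[:, c])))
                areas = cs[en] - cs[st]
                null_areas.append(areas)
                max_abs[b0 + c] = np.abs(areas).max()

    pooled = np.abs(np.concatenate(null_areas)) if null_areas else np.zeros(0)
    pooled.sort()
    max_sorted = np.sort(max_abs)

    obs = np.abs(candidates["area"].to_numpy(float))
    # ties count as exceedances: #{null >= obs} via searchsorted on left side
    exceed = pooled.size - np.searchsorted(pooled, obs, side="left")
    p_emp = (1.0 + exceed) / (1.0 + pooled.size)
    exceed_max = max_sorted.size - np.searchsorted(max_sorted, obs, side="left")
    fwer = (1.0 + exceed_max) / (1.0 + n_used)
    out = candidates.copy()
    out["p_emp"] = p_emp
    out["fwer"] = fwer
    out["q"] = multipletests(p_emp, method="fdr_bh")[1] if len(out) else p_emp
    null = PermutationNull(
        n_perm=n_used, areas=pooled, max_abs=max_abs, enumerated=enumerated
    )
    return out, null


def call_dmrs(
    matrix: MethylationMatrix,
    sample_sheet: pd.DataFrame,
    group_a: str,
    group_b: str,
    params: DMRCallingParams | None = None,
    label_column: str | None = None,
) -> DMRResult:
    """End-to-end two-group DMR call.

    ``group_a`` is the case (positive percent difference = hypermethylated
    in A); ``group_b`` the reference. Returns scored candidates with
    empirical p, FWER and BH q -- the full candidate list doubles as the
    enrichment background universe.
    """
    params = params or DMRCallingParams()
    col = label_column or ("group" if "group" in sample_sheet.columns else "phenotype")
    labels = sample_sheet[col]
    ids_a = list(sample_sheet.loc[labels == group_a, "sample"])
    ids_b = list(sample_sheet.loc[labels == group_b, "sample"])
    if not ids_a or not ids_b:
        raise ValueError(f"groups {group_a!r}/{group_b!r} not found in column {col!r}")
    track = group_methylation_difference(matrix, ids_a, ids_b)
    smooth_difference(track, window_bp=params.window_bp, max_gap=params.max_gap)
    cands = detect_candidate_regions(
        track, cutoff=params.cutoff, min_cpgs=params.min_cpgs, max_gap=params.max_gap
    )
    cands = score_regions(cands, track)
    if len(cands):
        cands, null = permutation_test(
            matrix, cands, ids_a, ids_b, n_perm=params.n_perm, seed=params.seed, params=params
        )
    else:
        for col_ in ("p_emp", "fwer", "q"):
            cands[col_] = np.zeros(0)
        null = None
    cands.insert(0, "name", [f"{group_a}_vs_{group_b}_{i}" for i in range(len(cands))])
    return DMRResult(
        candidates=cands, track=track, null=null, params=params, group_a=group_a, group_b=group_b
    )


def region_sample_methylation(
    matrix: MethylationMatrix, regions: RegionSet | pd.DataFrame
) -> pd.DataFrame:
    """Percent methylation per region per sample (region x sample table).

    Each cell is ``100 * sum(meth) / sum(total)`` over the region's CpGs
    for that sample; samples with zero coverage in a region get NaN.
    """
    df = regions.df if isinstance(regions, RegionSet) else regions
    n_r = len(df)
    meth = np.zeros((n_r, matrix.n_samples))
    total = np.zeros((n_r, matrix.n_samples))
    for r, (chrom, start, end) in enumerate(zip(df["chrom"], df["start"], df["end"])):
        sl = matrix.region_slice(str(chrom), int(start), int(end))
        meth[r] = matrix.meth[sl].sum(axis=0)
        total[r] = matrix.total[sl].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * meth / total
    index = (
        df["name"]
        if "name" in df.columns
        else pd.Index([f"{c}:{s}-{e}" for c, s, e in zip(df["chrom"], df["start"], df["end"])])
    )
    return pd.DataFrame(pct, index=pd.Index(index, name="region"), columns=matrix.samples)


def dmrs_to_bed_frame(dmrs: pd.DataFrame) -> pd.DataFrame:
    """BED6+ report rows: score is -10*log10(p_emp) capped at 1000 and the
    percent difference is rounded to an integer (full precision is kept
    only internally)."""
    out = pd.DataFrame(
        {
            "chrom": dmrs["chrom"],
            "start": dmrs["start"].astype(int),
            "end": dmrs["end"].astype(int),
            "name": dmrs.get("name", pd.Series(range(len(dmrs)), index=dmrs.index).astype(str)),
            "score": np.minimum(1000, (-10 * np.log10(dmrs["p_emp"])).round()).astype(int)
            if "p_emp" in dmrs
            else 0,
            "strand": ".",
            "n_cpgs": dmrs["n_cpgs"].astype(int),
            "area": dmrs["area"].round(4),
            "meth_diff_pct": dmrs["meth_diff_pct"].round().astype(int),
        }
    )
    for col in ("p_emp", "fwer", "q"):
        if col in dmrs.columns:
            out[col] = dmrs[col]
    return out
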