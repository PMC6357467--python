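"""Disease-specific consensus DMR logic and region-set algebra.

The consensus signature keeps regions from an anchor comparison
(case vs healthy control) that are supported, with the same direction,
by the case vs disease-control comparison, and that do not overlap any
region separating the two control groups. Overlap means >= 1 bp under
half-open semantics.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .regions import RegionSet


def _ensure_frame(regions) -> pd.DataFrame:
    return regions.df if isinstance(regions, RegionSet) else regions


def intersect_directional(set_a, set_b) -> pd.DataFrame:
    """Regions of A overlapping a same-direction region of B (A kept)."""
    a = _ensure_frame(set_a)
    b = _ensure_frame(set_b)
    keep = np.zeros(len(a), dtype=bool)
    for direction in ("hyper", "hypo"):
        a_mask = (a["direction"] == direction).to_numpy()
        if not a_mask.any():
            continue
        b_sub = b[b["direction"] == direction]
        if b_sub.empty:
            continue
        sub = RegionSet(a[a_mask])
        hits = sub.overlaps_any(RegionSet(b_sub))
        # RegionSet sorts rows; map back through the sorted order
        order = a[a_mask].sort_values(["chrom", "start", "end"], kind="mergesort").index
        keep[a.index.get_indexer(order[hits])] = True
    out = a[keep].copy()
    out["supported_by"] = set_b.name if isinstance(set_b, RegionSet) else "required"
    return out


def subtract_regions(set_a, exclusion) -> pd.DataFrame:
    """Drop regions of A overlapping the exclusion set (any direction)."""
    a = _ensure_frame(set_a)
    excl = _ensure_frame(exclusion)
    if excl.empty or a.empty:
        return a.copy()
    sorted_a = a.sort_values(["chrom", "start", "end"], kind="mergesort")
    hits = RegionSet(sorted_a).overlaps_any(RegionSet(excl))
    drop = np.zeros(len(a), dtype=bool)
    drop[a.index.get_indexer(sorted_a.index[hits])] = True
    return a[~drop].copy()


def wd_specific_consensus(
    dmrs_case_hc: pd.DataFrame,
    dmrs_case_dc: pd.DataFrame,
    dmrs_dc_hc: pd.DataFrame,
) -> pd.DataFrame:
    """Case-specific signature from three pairwise comparisons.

    Keep case-vs-HC regions overlapping a same-direction case-vs-DC
    region, then drop any that overlap a DC-vs-HC region. The anchor
    (case vs HC) record is the representative; hyper/hypo counts are
    available from its ``direction`` column.
    """
    supported = intersect_directional(dmrs_case_hc, dmrs_case_dc)
    return subtract_regions(supported, dmrs_dc_hc)


def filter_significant(
    dmr_set: pd.DataFrame, alpha: float = 0.05, criterion: str = "fwer"
) -> pd.DataFrame:
    """Rows whose ``criterion`` value is strictly below ``alpha`` (stable order)."""
    if criterion not in ("fwer", "q"):
        raise ValueError("criterion must be 'fwer' or 'q'")
    if criterion not in dmr_set.columns:
        raise KeyError(f"column {criterion!r} missing from DMR table")
    return dmr_set[dmr_set[criterion] < alpha].copy()


def overlap_regions(set_a, set_b) -> tuple[int, pd.DataFrame]:
    """Count and return the regions of A overlapping >=1 region of B."""
    a = _ensure_frame(set_a)
    if a.empty:
        return 0, a.copy()
    sorted_a = a.sort_values(["chrom", "start", "end"], kind="mergesort")
    hits = RegionSet(sorted_a).overlaps_any(RegionSet(_ensure_frame(set_b)))
    keep = np.zeros(len(a), dtype=bool)
    keep[a.index.get_indexer(sorted_a.index[hits])] = True
    return int(keep.sum()), a[keep].copy()


def consensus_background(candidates: pd.DataFrame, consensus: pd.DataFrame) -> pd.DataFrame:
    """Enrichment background: anchor candidates minus the consensus regions
    (matched by exact coordinates)."""
    keys = set(zip(consensus["chrom"], consensus["start"], consensus["end"]))
    mask = [
        (c, s, e) not in keys
        for c, s, e in zip(candidates["chrom"], candidates["start"], candidates["end"])
    ]
    return candidates[np.asarray(mask)].copy()


def load_reference_dmr_table() -> pd.DataFrame:
    """The packaged reference table of 18 genome-wide-significant Wilson
    disease liver DMRs (coordinates, CpG count, percent difference, FWER
    and nearest-gene annotations), used as a worked example and fixture.

    FWER values printed as ``<0.001`` are stored as 0.0005 so that strict
    threshold filters behave as the printed table implies.
    """
    with resources.files("dmrkit.data").joinpath("wd_liver_dmrs_fwer.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    df["fwer"] = df["fwer"].replace("<0.001", "0.0005").astype(float)
    return df
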