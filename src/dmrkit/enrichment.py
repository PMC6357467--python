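"""Region-set and gene-set enrichment.

The enrichment unit is the region: a query region either overlaps an
annotation set (>= 1 bp) or it does not, and the query's overlap rate is
compared with that of a disjoint background region universe through a
two-sided Fisher exact test. This mirrors locus-overlap analysis of
chromatin states and ChIP-seq peak collections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .calling import region_sample_methylation
from .io import MethylationMatrix
from .regions import RegionSet

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    """One query/annotation 2x2 comparison.

    ``a`` query regions overlap the annotation, ``b`` do not; ``c``/``d``
    likewise for the background. The odds ratio is ``(a*d)/(b*c)`` with a
    Haldane-Anscombe 0.5 added to every cell iff any cell is zero
    (``haldane`` flags when that happened).
    """

    annotation: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p: float
    q: float = np.nan
    haldane: bool = False

    @property
    def fraction_query_overlapping(self) -> float:
        return self.a / (self.a + self.b)


def _odds_ratio(a: int, b: int, c: int, d: int) -> tuple[float, bool]:
    if min(a, b, c, d) == 0:
        a2, b2, c2, d2 = (x + 0.5 for x in (a, b, c, d))
        return (a2 * d2) / (b2 * c2), True
    return (a * d) / (b * c), False


def fisher_region_enrichment(
    query: RegionSet, background: RegionSet, annotation: RegionSet
) -> EnrichmentResult:
    """Two-sided Fisher exact test of annotation overlap, query vs background.

    The query and background universes must be disjoint region sets (same
    coordinates may not appear in both).
    """
    if len(query) == 0 or len(background) == 0:
        raise ValueError("query and background must be non-empty")
    if query.keys() & background.keys():
        raise ValueError("query and background share regions; universes must be disjoint")
    a = query.count_overlapping(annotation)
    b = len(query) - a
    c = background.count_overlapping(annotation)
    d = len(background) - c
    odds, haldane = _odds_ratio(a, b, c, d)
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return EnrichmentResult(
        annotation=annotation.name, a=a, b=b, c=c, d=d, odds_ratio=odds, p=p, haldane=haldane
    )


def enrichment_panel(
    query: RegionSet, background: RegionSet, annotation_collection: dict[str, RegionSet]
) -> pd.DataFrame:
    """Run the Fisher test against every annotation, BH-correct, sort by q."""
    results = []
    for name, ann in annotation_collection.items():
        res = fisher_region_enrichment(query, background, ann)
        res.annotation = name
        results.append(res)
    ps = [r.p for r in results]
    qs = multipletests(ps, method="fdr_bh")[1] if results else []
    for r, q in zip(results, qs):
        r.q = q
    df = pd.DataFrame(
        {
            "annotation": [r.annotation for r in results],
            "a": [r.a for r in results],
            "b": [r.b for r in results],
            "c": [r.c for r in results],
            "d": [r.d for r in results],
            "fraction_query": [r.fraction_query_overlapping for r in results],
            "odds_ratio": [r.odds_ratio for r in results],
            "p": ps,
            "q": qs,
            "haldane": [r.haldane for r in results],
        }
    )
    return df.sort_values("q", kind="mergesort").reset_index(drop=True)


def tf_cooccurrence(
    query: RegionSet, peak_sets: dict[str, RegionSet]
) -> tuple[pd.DataFrame, int, pd.DataFrame]:
    """Overlap membership of each query region across k peak sets.

    Returns the boolean membership table (regions x factors), the number
    of regions overlapping all k factors, and the pairwise Fisher
    enrichment between factor memberships.
    """
    names = list(peak_sets)
    member = pd.DataFrame(
        {name: query.overlaps_any(peak_sets[name]) for name in names},
        index=pd.RangeIndex(len(query)),
    )
    all_count = int(member.all(axis=1).sum()) if names else 0
    rows = []
    for i, fa in enumerate(names):
        for fb in names[i + 1 :]:
            x, y = member[fa].to_numpy(), member[fb].to_numpy()
            a = int((x & y).sum())
            b = int((x & ~y).sum())
            c = int((~x & y).sum())
            d = int((~x & ~y).sum())
            odds, haldane = _odds_ratio(a, b, c, d)
            _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            rows.append(
                {"factor_a": fa, "factor_b": fb, "both": a, "odds_ratio": odds, "p": p,
                 "haldane": haldane}
            )
    pairwise = pd.DataFrame(rows, columns=["factor_a", "factor_b", "both", "odds_ratio", "p", "haldane"])
    return member, all_count, pairwise


def gene_set_overlap(
    genes_a: set[str], genes_b: set[str], universe: set[str]
) -> tuple[int, float]:
    """Hypergeometric upper-tail p for the overlap of two gene sets.

    With ``N = |universe|``, ``K = |A|`` successes and ``n = |B|`` draws,
    ``p = P(X >= |A & B|)``.
    """
    genes_a, genes_b, universe = set(genes_a), set(genes_b), set(universe)
    if not genes_a <= universe or not genes_b <= universe:
        raise ValueError("gene sets must be subsets of the universe")
    x = len(genes_a & genes_b)
    p = float(sps.hypergeom.sf(x - 1, len(universe), len(genes_a), len(genes_b)))
    return x, min(1.0, p)


def celltype_promoter_screen(
    matrix: MethylationMatrix,
    dmrs: RegionSet,
    promoter_sets: dict[str, RegionSet],
    sample_sheet: pd.DataFrame,
    group_a: str,
    group_b: str,
    label_column: str = "group",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cell-composition confound screen against cell-type-specific promoters.

    Returns (i) per promoter set, the fraction of DMRs overlapping it, and
    (ii) a per-promoter Welch two-sample t-test of region percent
    methylation between the two groups, with the fraction of promoters at
    nominal p < 0.05 attached per set. A small overlap fraction and a
    near-nominal positive rate argue against cell-type shifts driving the
    DMR signal.
    """
    labels = sample_sheet.set_index("sample")[label_column]
    ids_a = [s for s in matrix.samples if labels.get(s) == group_a]
    ids_b = [s for s in matrix.samples if labels.get(s) == group_b]
    overlap_rows = []
    test_rows = []
    for name, proms in promoter_sets.items():
        frac = dmrs.count_overlapping(proms) / len(dmrs) if len(dmrs) else 0.0
        table = region_sample_methylation(matrix, proms)
        for region, values in table.iterrows():
            ya = values[ids_a].to_numpy(float)
            yb = values[ids_b].to_numpy(float)
            ya, yb = ya[~np.isnan(ya)], yb[~np.isnan(yb)]
            if len(ya) < 2 or len(yb) < 2:
                stat, p = np.nan, np.nan
            else:
                stat, p = sps.ttest_ind(ya, yb, equal_var=False)
            test_rows.append({"set": name, "promoter": region, "t": stat, "p": p})
        sub = [r for r in test_rows if r["set"] == name and not np.isnan(r["p"])]
        nominal = float(np.mean([r["p"] < 0.05 for r in sub])) if sub else np.nan
        overlap_rows.append(
            {"set": name, "n_promoters": len(proms), "dmr_overlap_fraction": frac,
             "fraction_nominal_p05": nominal}
        )
    return pd.DataFrame(overlap_rows), pd.DataFrame(test_rows)
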