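"""Nearest-gene assignment, position categories, drug-target enrichment.

Gene models are single-TSS toy records: name, chromosome, strand, TSS,
gene span and exon intervals. Distances to the TSS are measured from the
nearest edge of the region (0 when the region covers the TSS point) and
signed by gene strand: negative = upstream of the TSS.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

GENE_MODEL_COLUMNS = ["gene", "chrom", "strand", "tss", "start", "end", "exons"]


def read_gene_models(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str, "exons": str})
    missing = [c for c in GENE_MODEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gene model table lacks columns: {missing}")
    return df


def write_gene_models(models: pd.DataFrame, path) -> None:
    models[GENE_MODEL_COLUMNS].to_csv(path, sep="\t", index=False)


def parse_exons(exons: str) -> list[tuple[int, int]]:
    if not isinstance(exons, str) or not exons:
        return []
    out = []
    for part in exons.split(";"):
        s, e = part.split("-")
        out.append((int(s), int(e)))
    return out


def _edge_distance(start: int, end: int, tss: int) -> int:
    """Unsigned bp from the region's nearest base to the TSS point; 0 when
    the region covers the TSS (half-open region)."""
    if start <= tss < end:
        return 0
    if tss < start:
        return start - tss
    return tss - (end - 1)


def _signed_kb(start: int, end: int, gene: pd.Series) -> float:
    dist = _edge_distance(int(start), int(end), int(gene["tss"]))
    if dist == 0:
        return 0.0
    mid = (start + end) / 2
    left_of_tss = mid < gene["tss"]
    upstream = left_of_tss if gene["strand"] == "+" else not left_of_tss
    return round((-dist if upstream else dist) / 1000.0, 1)


def position_category(dmr, gene_model: pd.Series) -> str:
    """Classify a region relative to one gene.

    TSS when the region covers the TSS point; otherwise the region
    midpoint decides Exon/Intron (inside the gene span) or the
    strand-aware Upstream/Downstream side.
    """
    start, end = int(dmr["start"]), int(dmr["end"])
    tss = int(gene_model["tss"])
    if start <= tss < end:
        return "TSS"
    mid = (start + end) // 2
    if int(gene_model["start"]) <= mid < int(gene_model["end"]):
        for es, ee in parse_exons(gene_model["exons"]):
            if es <= mid < ee:
                return "Exon"
        return "Intron"
    left = mid < tss
    if gene_model["strand"] == "+":
        return "Upstream" if left else "Downstream"
    return "Downstream" if left else "Upstream"


def nearest_genes(dmrs: pd.DataFrame, gene_models: pd.DataFrame, k: int = 2) -> pd.DataFrame:
    """The k genes with the closest TSS for each region.

    Ties in TSS distance are broken by gene name. Chromosomes without any
    gene model yield no assignment (warned once per chromosome).
    """
    by_chrom = {str(c): sub.reset_index(drop=True) for c, sub in gene_models.groupby("chrom")}
    rows = []
    warned: set[str] = set()
    for i, dmr in dmrs.iterrows():
        chrom = str(dmr["chrom"])
        genes = by_chrom.get(chrom)
        if genes is None or genes.empty:
            if chrom not in warned:
                logger.warning("no gene models on %s; regions there left unassigned", chrom)
                warned.add(chrom)
            continue
        dists = np.array(
            [_edge_distance(int(dmr["start"]), int(dmr["end"]), int(t)) for t in genes["tss"]]
        )
        order = sorted(range(len(genes)), key=lambda j: (dists[j], genes["gene"].iloc[j]))
        for rank, j in enumerate(order[:k]):
            gene = genes.iloc[j]
            rows.append(
                {
                    "dmr": dmr.get("name", f"{chrom}:{dmr['start']}-{dmr['end']}"),
                    "chrom": chrom,
                    "start": int(dmr["start"]),
                    "end": int(dmr["end"]),
                    "rank": rank + 1,
                    "gene": gene["gene"],
                    "distance_kb": _signed_kb(int(dmr["start"]), int(dmr["end"]), gene),
                    "category": position_category(dmr, gene),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["dmr", "chrom", "start", "end", "rank", "gene", "distance_kb", "category"],
    )


def drug_interaction_enrichment(
    dmr_genes: set[str], drug_gene_table: pd.DataFrame, universe: set[str]
) -> pd.DataFrame:
    """Per-drug one-sided enrichment of DMR genes among drug targets.

    For each drug the 2x2 table compares DMR genes with the rest of the
    universe against target membership; ``p`` is the hypergeometric upper
    tail and ``q`` the BH adjustment across drugs. Drugs with no target in
    the universe are skipped with a warning.
    """
    dmr_genes = set(dmr_genes) & set(universe)
    n_universe = len(universe)
    rows = []
    for drug, sub in drug_gene_table.groupby("drug"):
        targets = set(sub["gene"]) & set(universe)
        if not targets:
            logger.warning("drug %r has no targets in the universe; skipped", drug)
            continue
        x = len(dmr_genes & targets)
        p = float(sps.hypergeom.sf(x - 1, n_universe, len(targets), len(dmr_genes)))
        rows.append(
            {"drug": drug, "n_targets": len(targets), "overlap": x,
             "overlap_genes": ",".join(sorted(dmr_genes & targets)), "p": min(1.0, p)}
        )
    df = pd.DataFrame(rows, columns=["drug", "n_targets", "overlap", "overlap_genes", "p"])
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
        df = df.sort_values(["p", "drug"], kind="mergesort").reset_index(drop=True)
    else:
        df["q"] = []
    return df
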