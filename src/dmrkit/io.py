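"""Reading and writing methylation count data and interval files.

Cytosine reports follow the Bismark coordinate convention (1-based
positions); everything held in memory is 0-based half-open. BED output is
0-based half-open throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .regions import RegionSet

logger = logging.getLogger(__name__)

GROUP_VOCABULARY = {"HC", "DC", "WD"}
PHENOTYPE_VOCABULARY = {"WDH", "WDN"}

REPORT_COLUMNS = ["chrom", "pos", "strand", "meth", "unmeth", "context", "tri"]


def read_cytosine_report(path: str | Path) -> pd.DataFrame:
    """Parse a Bismark-style cytosine report.

    Expected TSV columns: chromosome, 1-based position, strand,
    methylated count, unmethylated count, context, trinucleotide.
    Positions are converted to 0-based on read.

    Raises
    ------
    ValueError
        On a malformed line, naming its 1-based line number.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            names=REPORT_COLUMNS,
            dtype={"chrom": str, "strand": str, "context": str, "tri": str},
            header=None,
            comment="#",
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=REPORT_COLUMNS)
    if df.empty:
        logger.warning("cytosine report %s is empty", path)
        return pd.DataFrame(columns=["chrom", "pos", "strand", "meth", "unmeth"])
    for col in ("pos", "meth", "unmeth"):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() | (values != np.floor(values.fillna(0)))
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ValueError(f"{path}: non-integer {col!r} field at line {line}")
        df[col] = values.astype(np.int64)
    neg = (df["meth"] < 0) | (df["unmeth"] < 0) | (df["pos"] < 1)
    if neg.any():
        line = int(np.flatnonzero(neg.to_numpy())[0]) + 1
        raise ValueError(f"{path}: negative count or position at line {line}")
    df["pos"] = df["pos"] - 1  # to 0-based
    return df[["chrom", "pos", "strand", "meth", "unmeth"]]


def write_cytosine_report(df: pd.DataFrame, path: str | Path) -> None:
    """Write records (0-based ``pos``) back to the 1-based report format."""
    out = df.copy()
    out["pos"] = out["pos"].astype(np.int64) + 1
    if "context" not in out.columns:
        out["context"] = "CpG"
    if "tri" not in out.columns:
        out["tri"] = "CGN"
    out[REPORT_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def destrand_cpgs(records: pd.DataFrame) -> pd.DataFrame:
    """Merge CpG dyads into single strand-free CpG units.

    A plus-strand cytosine at position ``p`` and a minus-strand cytosine at
    ``p + 1`` on the same chromosome are the two halves of one CpG; their
    counts are summed and reported at ``p``. Unpaired records are kept as-is
    (minus-strand singletons are shifted to the plus-strand coordinate
    ``p - 1`` so downstream coordinates are uniform).
    """
    if records.empty:
        return pd.DataFrame(columns=["chrom", "pos", "meth", "total"])
    rec = records.copy()
    rec["total"] = rec["meth"] + rec["unmeth"]
    minus = rec["strand"] == "-"
    # anchor every record at the + strand C of its dyad
    rec.loc[minus, "pos"] = rec.loc[minus, "pos"] - 1
    merged = (
        rec.groupby(["chrom", "pos"], sort=True, as_index=False)[["meth", "total"]]
        .sum()
        .astype({"meth": np.int64, "total": np.int64})
    )
    return merged


@dataclass
class MethylationMatrix:
    """Per-CpG methylated/total counts across samples.

    ``chrom``/``pos`` give the 0-based plus-strand cytosine coordinate of
    each destranded CpG, sorted by (chrom, pos) with chromosomes grouped.
    ``meth`` and ``total`` are ``(n_cpgs, n_samples)`` integer arrays with
    one column per sample-sheet row, in sheet order.
    """

    chrom: np.ndarray
    pos: np.ndarray
    meth: np.ndarray
    total: np.ndarray
    samples: list[str]
    _chrom_slices: dict[str, tuple[int, int]] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if np.any(self.meth > self.total):
            raise ValueError("methylated count exceeds total coverage")
        if self._chrom_slices is None:
            slices: dict[str, tuple[int, int]] = {}
            chroms = np.asarray(self.chrom)
            if len(chroms):
                change = np.flatnonzero(chroms[1:] != chroms[:-1]) + 1
                bounds = np.concatenate(([0], change, [len(chroms)]))
                for b0, b1 in zip(bounds[:-1], bounds[1:]):
                    name = str(chroms[b0])
                    if name in slices:
                        raise ValueError(f"chromosome {name} not contiguous; sort input")
                    slices[name] = (int(b0), int(b1))
            self._chrom_slices = slices

    @property
    def n_cpgs(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in ids], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in matrix") from None

    def region_slice(self, chrom: str, start: int, end: int) -> slice:
        """Index slice of CpGs whose position lies in ``[start, end)``."""
        if chrom not in self._chrom_slices:
            return slice(0, 0)
        b0, b1 = self._chrom_slices[chrom]
        sub = self.pos[b0:b1]
        lo = int(np.searchsorted(sub, start, side="left"))
        hi = int(np.searchsorted(sub, end, side="left"))
        return slice(b0 + lo, b0 + hi)

    def to_frame(self) -> pd.DataFrame:
        data = {"chrom": self.chrom, "pos": self.pos}
        for j, s in enumerate(self.samples):
            data[f"{s}.meth"] = self.meth[:, j]
            data[f"{s}.total"] = self.total[:, j]
        return pd.DataFrame(data)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "MethylationMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        samples = [c[:-5] for c in df.columns if c.endswith(".meth")]
        meth = df[[f"{s}.meth" for s in samples]].to_numpy(np.int64)
        total = df[[f"{s}.total" for s in samples]].to_numpy(np.int64)
        return cls(
            chrom=df["chrom"].to_numpy(),
            pos=df["pos"].to_numpy(np.int64),
            meth=meth,
            total=total,
            samples=samples,
        )


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a TSV sample sheet and validate ids and group labels.

    Relative entries in the ``file`` column are resolved against the
    sheet's own directory.
    """
    path = Path(path)
    sheet = pd.read_csv(path, sep="\t", dtype={"sample": str})
    if "file" in sheet.columns:
        sheet["file"] = [
            str(f) if Path(str(f)).is_absolute() else str(path.parent / str(f))
            for f in sheet["file"]
        ]
    return validate_sample_sheet(sheet)


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    if "sample" not in sheet.columns:
        raise ValueError("sample sheet needs a 'sample' column")
    if sheet["sample"].duplicated().any():
        dup = sheet.loc[sheet["sample"].duplicated(), "sample"].iloc[0]
        raise ValueError(f"duplicate sample id {dup!r}")
    if "group" in sheet.columns:
        unknown = set(sheet["group"].dropna()) - GROUP_VOCABULARY
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")
    if "phenotype" in sheet.columns:
        unknown = set(sheet["phenotype"].dropna()) - PHENOTYPE_VOCABULARY
        if unknown:
            raise ValueError(f"unknown phenotype labels: {sorted(unknown)}")
    return sheet


def build_methylation_matrix(
    sample_sheet: pd.DataFrame,
    min_coverage: int = 1,
    min_fraction: float = 1.0,
    destrand: bool = True,
    reports: dict[str, pd.DataFrame] | None = None,
) -> MethylationMatrix:
    """Assemble the analysis-ready CpG x sample count matrix.

    A CpG is retained when its total coverage is ``>= min_coverage`` in at
    least ``min_fraction`` of the samples of *every* group (default: every
    sample has at least one read). ``reports`` may supply pre-parsed records
    keyed by sample id; otherwise each sheet row's ``file`` is read.
    """
    validate_sample_sheet(sample_sheet)
    per_sample: dict[str, pd.DataFrame] = {}
    for _, row in sample_sheet.iterrows():
        sid = row["sample"]
        if reports is not None and sid in reports:
            rec = reports[sid]
        else:
            if "file" not in sample_sheet.columns or pd.isna(row.get("file")):
                raise FileNotFoundError(f"sample {sid!r} has no report file")
            fp = Path(row["file"])
            if not fp.exists():
                raise FileNotFoundError(f"sample {sid!r}: report {fp} not found")
            rec = read_cytosine_report(fp)
        merged = destrand_cpgs(rec) if destrand else _stranded_passthrough(rec)
        per_sample[sid] = merged.set_index(["chrom", "pos"])[["meth", "total"]]

    samples = list(sample_sheet["sample"])
    union = None
    for sid in samples:
        idx = per_sample[sid].index
        union = idx if union is None else union.union(idx)
    union = union.sortlevel()[0] if union is not None else pd.MultiIndex.from_arrays([[], []])

    n = len(union)
    meth = np.zeros((n, len(samples)), dtype=np.int64)
    total = np.zeros_like(meth)
    for j, sid in enumerate(samples):
        sub = per_sample[sid].reindex(union)
        meth[:, j] = sub["meth"].fillna(0).to_numpy(np.int64)
        total[:, j] = sub["total"].fillna(0).to_numpy(np.int64)

    if min_coverage > 0 and n:
        groups = (
            sample_sheet["group"]
            if "group" in sample_sheet.columns
            else pd.Series(["all"] * len(samples))
        )
        keep = np.ones(n, dtype=bool)
        for g in pd.unique(groups.dropna()):
            cols = np.flatnonzero((groups == g).to_numpy())
            frac_ok = (total[:, cols] >= min_coverage).mean(axis=1)
            keep &= frac_ok >= min_fraction
        dropped = int((~keep).sum())
        if dropped:
            logger.info("coverage filter dropped %d of %d CpGs", dropped, n)
        meth, total = meth[keep], total[keep]
        union = union[keep]

    chrom = np.array([c for c, _ in union], dtype=object)
    pos = np.array([p for _, p in union], dtype=np.int64)
    return MethylationMatrix(chrom=chrom, pos=pos, meth=meth, total=total, samples=samples)


def _stranded_passthrough(rec: pd.DataFrame) -> pd.DataFrame:
    out = rec.copy()
    out["total"] = out["meth"] + out["unmeth"]
    return (
        out.groupby(["chrom", "pos"], sort=True, as_index=False)[["meth", "total"]].sum()
    )


def read_bed(path: str | Path, name: str | None = None) -> RegionSet:
    """Read BED3+ into a :class:`RegionSet` (0-based half-open, validated)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=range(3))
    extra = ["name", "score", "strand", "n_cpgs", "area", "meth_diff_pct", "p_emp", "fwer", "q"]
    cols = ["chrom", "start", "end"] + extra[: max(0, df.shape[1] - 3)]
    df.columns = cols[: df.shape[1]]
    if len(df):
        bad = df["start"].astype(np.int64) >= df["end"].astype(np.int64)
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ValueError(f"{path}: start >= end at line {line}")
    return RegionSet(df, name=name or path.stem)


def write_bed(regions: RegionSet, path: str | Path, columns: list[str] | None = None) -> None:
    """Write a RegionSet as BED3+ (sorted; extra columns appended in order)."""
    df = regions.df.sort_values(["chrom", "start", "end"], kind="mergesort")
    cols = ["chrom", "start", "end"] + (
        columns if columns is not None else [c for c in df.columns if c not in ("chrom", "start", "end")]
    )
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(
    chrom: np.ndarray, pos: np.ndarray, values: np.ndarray, path: str | Path, span: int = 2
) -> None:
    """Write per-CpG values (e.g. a smoothed difference track) as bedGraph."""
    df = pd.DataFrame(
        {"chrom": chrom, "start": pos, "end": np.asarray(pos) + span, "value": values}
    )
    df.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")
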