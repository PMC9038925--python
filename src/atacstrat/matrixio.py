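"""Peak-set handling, count normalisation, QC and genomic annotation.

Coordinates are BED-style throughout: 0-based, half-open ``[start, end)``.
A :class:`PeakSet` is the universe that every matrix in the package indexes
into; a :class:`CountMatrix` carries raw read counts per peak and sample
together with the derived CPM and log2(CPM+1) layers used by clustering,
linkage and motif scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "PeakSet",
    "CountMatrix",
    "GeneAnnotation",
    "merge_peak_calls",
    "cpm_normalize",
    "replicate_qc",
    "presence_histogram",
    "annotate_peaks",
    "classify_genomic_features",
    "presence_from_counts",
    "read_bed",
    "write_bed",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_genes_tsv",
    "write_genes_tsv",
]

# Promoter and distal-regulatory-element windows (bp, strand-oriented
# offsets from the TSS).  Promoter: [-1000, +100].  DRE: 3 kb < |d| <= 500 kb.
PROMOTER_WINDOW = (-1000, 100)
DRE_WINDOW = (3000, 500_000)

#: Priority order used when a peak overlaps several genomic features.
FEATURE_PRIORITY = ("TSS", "TTS", "5'UTR", "3'UTR", "exon", "intron", "intergenic")


@dataclass
class PeakSet:
    """Sorted set of genomic intervals with stable, unique identifiers."""

    df: pd.DataFrame  # columns: chrom, start, end, peak_id

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)
        required = ["chrom", "start", "end", "peak_id"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"PeakSet missing columns: {missing}")
        bad = df["start"] >= df["end"]
        if bad.any():
            ids = df.loc[bad, "peak_id"].tolist()
            raise ValueError(f"malformed intervals (start >= end) for peaks: {ids}")
        if df["peak_id"].duplicated().any():
            dup = df.loc[df["peak_id"].duplicated(), "peak_id"].unique().tolist()
            raise ValueError(f"duplicate peak ids: {dup}")
        self.df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
            drop=True
        )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def peak_ids(self) -> pd.Index:
        return pd.Index(self.df["peak_id"])

    def midpoints(self) -> np.ndarray:
        """Integer midpoint per peak, floor((start + end) / 2)."""
        return ((self.df["start"].to_numpy() + self.df["end"].to_numpy()) // 2).astype(
            np.int64
        )

    @classmethod
    def from_arrays(cls, chrom, start, end, peak_id=None) -> "PeakSet":
        n = len(start)
        if peak_id is None:
            peak_id = [f"peak{i:06d}" for i in range(n)]
        return cls(
            pd.DataFrame(
                {"chrom": chrom, "start": start, "end": end, "peak_id": peak_id}
            )
        )


@dataclass
class CountMatrix:
    """Peak x sample counts with CPM and log2(CPM+1) layers."""

    raw: pd.DataFrame  # peaks x samples, non-negative
    cpm: pd.DataFrame = field(default=None)
    logcpm: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        if (self.raw.to_numpy() < 0).any():
            raise ValueError("raw counts must be non-negative")
        if self.cpm is None:
            self.cpm, self.logcpm = _cpm_layers(self.raw)

    @property
    def peak_ids(self) -> pd.Index:
        return self.raw.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.raw.columns


@dataclass
class GeneAnnotation:
    """Per-gene annotation: TSS, strand, optional gene-model intervals.

    ``exons``, ``utr5``, ``utr3`` are lists of (start, end) half-open
    intervals; ``tts`` is the transcription termination site.  Only the
    TSS and strand are required for nearest-gene annotation.
    """

    df: pd.DataFrame  # columns: gene_id, chrom, strand, tss [, tts, exons, utr5, utr3]

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)
        required = ["gene_id", "chrom", "strand", "tss"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"GeneAnnotation missing columns: {missing}")
        if not df["strand"].isin(["+", "-"]).all():
            raise ValueError("strand must be '+' or '-'")
        if df["gene_id"].duplicated().any():
            raise ValueError("duplicate gene ids")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# peak-call merging


def merge_peak_calls(per_sample_peaks, sample_ids=None):
    """Union-merge per-sample peak calls (bedtools-merge semantics).

    Overlapping or bookended intervals (sharing >= 1 bp or touching) are
    merged.  Returns the merged :class:`PeakSet` and a binary presence
    DataFrame: ``presence.loc[peak, sample] == 1`` iff that sample
    contributed at least one interval overlapping the merged peak.
    """
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(len(per_sample_peaks))]
    if len(sample_ids) != len(per_sample_peaks):
        raise ValueError("sample_ids length mismatch")
    rows = []
    for j, ps in enumerate(per_sample_peaks):
        d = ps.df
        rows.append(
            pd.DataFrame(
                {"chrom": d["chrom"], "start": d["start"], "end": d["end"], "sample": j}
            )
        )
    allint = pd.concat(rows, ignore_index=True).sort_values(
        ["chrom", "start", "end"], kind="mergesort"
    )

    merged_chrom, merged_start, merged_end = [], [], []
    presence_rows = []
    cur = None  # (chrom, start, end, set_of_samples)
    for chrom, start, end, samp in allint.itertuples(index=False):
        if cur is not None and chrom == cur[0] and start <= cur[2]:
            cur = (chrom, cur[1], max(cur[2], end), cur[3] | {samp})
        else:
            if cur is not None:
                merged_chrom.append(cur[0])
                merged_start.append(cur[1])
                merged_end.append(cur[2])
                presence_rows.append(cur[3])
            cur = (chrom, start, end, {samp})
    if cur is not None:
        merged_chrom.append(cur[0])
        merged_start.append(cur[1])
        merged_end.append(cur[2])
        presence_rows.append(cur[3])

    n = len(merged_chrom)
    peaks = PeakSet.from_arrays(merged_chrom, merged_start, merged_end)
    presence = np.zeros((n, len(per_sample_peaks)), dtype=np.int8)
    for i, samples in enumerate(presence_rows):
        for j in samples:
            presence[i, j] = 1
    presence_df = pd.DataFrame(
        presence, index=peaks.peak_ids, columns=list(sample_ids)
    )
    return peaks, presence_df


# ---------------------------------------------------------------------------
# normalisation and QC


def _cpm_layers(raw: pd.DataFrame):
    mat = raw.to_numpy(dtype=float)
    totals = mat.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} sample(s) have zero total counts; "
            "their CPM columns are set to zero",
            stacklevel=3,
        )
    safe = np.where(zero, 1.0, totals)
    cpm = mat / safe * 1e6
    cpm[:, zero] = 0.0
    cpm_df = pd.DataFrame(cpm, index=raw.index, columns=raw.columns)
    logcpm_df = pd.DataFrame(
        np.log2(cpm + 1.0), index=raw.index, columns=raw.columns
    )
    return cpm_df, logcpm_df


def cpm_normalize(raw: pd.DataFrame) -> CountMatrix:
    """Counts-per-million normalisation with a log2(CPM+1) layer.

    Each column is scaled to sum to 10^6 (columns with zero total stay
    zero and trigger a warning).
    """
    return CountMatrix(raw=raw)


def replicate_qc(logcpm: pd.DataFrame, replicate_pairs, threshold: float = 0.8):
    """Pearson correlation per technical-replicate pair on log2(CPM+1).

    Pairs with an undefined correlation (constant column) are reported
    with ``r = NaN``; pairs below ``threshold`` are flagged.
    """
    records = []
    for a, b in replicate_pairs:
        if a not in logcpm.columns or b not in logcpm.columns:
            raise KeyError(f"replicate pair ({a}, {b}) references unknown sample")
        x = logcpm[a].to_numpy(dtype=float)
        y = logcpm[b].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(x, y)[0, 1])
        records.append(
            {"sample_a": a, "sample_b": b, "r": r, "below_threshold": not (r >= threshold)}
        )
    return pd.DataFrame.from_records(records)


def presence_histogram(presence) -> pd.Series:
    """Number of peaks present in exactly n samples, n = 1..N.

    The histogram sums to the number of peaks with at least one presence.
    """
    mat = np.asarray(presence, dtype=np.int64)
    if not np.isin(mat, (0, 1)).all():
        raise ValueError("presence matrix must be binary")
    n_samples = mat.shape[1]
    counts = np.bincount(mat.sum(axis=1), minlength=n_samples + 1)[1:]
    return pd.Series(counts, index=pd.RangeIndex(1, n_samples + 1, name="n_samples"))


def presence_from_counts(raw: pd.DataFrame, threshold: float = 1) -> pd.DataFrame:
    """Presence from a count matrix: count >= threshold (default 1 read).

    Stand-in for per-sample peak calls when only the merged matrix exists.
    """
    return (raw.round() >= threshold).astype(np.int8)


# ---------------------------------------------------------------------------
# annotation


def _signed_distance(mid, tss, strand):
    d = mid - tss
    return d if strand == "+" else -d


def _region_class(distance: int) -> str:
    if PROMOTER_WINDOW[0] <= distance <= PROMOTER_WINDOW[1]:
        return "promoter"
    if DRE_WINDOW[0] < abs(distance) <= DRE_WINDOW[1]:
        return "DRE"
    return "other"


def annotate_peaks(peaks: PeakSet, genes: GeneAnnotation) -> pd.DataFrame:
    """Nearest-gene annotation with promoter/DRE/other classification.

    Distance runs from the peak midpoint to the gene TSS, signed in the
    gene's transcriptional orientation (downstream positive).  The nearest
    gene minimises |distance|; ties go to the lexicographically smaller
    gene_id.  Peaks farther than 500 kb from any TSS (or on a gene-free
    chromosome) are classed "other".
    """
    if len(genes) == 0:
        warnings.warn("empty gene annotation: all peaks classed 'other'", stacklevel=2)
        return pd.DataFrame(
            {
                "nearest_gene_id": pd.NA,
                "distance": pd.NA,
                "region_class": "other",
            },
            index=peaks.peak_ids,
        )

    by_chrom = {}
    for chrom, sub in genes.df.groupby("chrom"):
        sub = sub.sort_values(["tss", "gene_id"], kind="mergesort")
        by_chrom[chrom] = (
            sub["tss"].to_numpy(dtype=np.int64),
            sub["gene_id"].to_numpy(),
            sub["strand"].to_numpy(),
        )

    mids = peaks.midpoints()
    out_gene, out_dist, out_class = [], [], []
    for (chrom, mid) in zip(peaks.df["chrom"].to_numpy(), mids):
        if chrom not in by_chrom:
            out_gene.append(pd.NA)
            out_dist.append(pd.NA)
            out_class.append("other")
            continue
        tss_arr, gid_arr, strand_arr = by_chrom[chrom]
        idx = np.searchsorted(tss_arr, mid)
        lo = max(idx - 1, 0)
        hi = min(idx + 1, len(tss_arr) - 1)
        cand = range(lo, hi + 1)
        best = min(
            cand, key=lambda i: (abs(int(mid) - int(tss_arr[i])), str(gid_arr[i]))
        )
        d = _signed_distance(int(mid), int(tss_arr[best]), strand_arr[best])
        out_gene.append(gid_arr[best])
        out_dist.append(d)
        out_class.append(_region_class(d))
    return pd.DataFrame(
        {"nearest_gene_id": out_gene, "distance": out_dist, "region_class": out_class},
        index=peaks.peak_ids,
    )


def _promoter_interval(tss: int, strand: str, window=PROMOTER_WINDOW):
    lo, hi = window
    if strand == "+":
        return tss + lo, tss + hi + 1
    return tss - hi, tss - lo + 1


def classify_genomic_features(
    peaks: PeakSet,
    genes: GeneAnnotation,
    tss_window=PROMOTER_WINDOW,
    tts_window=(-100, 100),
) -> pd.Series:
    """Seven-feature classification of peaks against gene models.

    Features in priority order: TSS > TTS > 5'UTR > 3'UTR > exon > intron
    > intergenic.  The TSS window equals the promoter window (strand
    oriented); the TTS window defaults to +/-100 bp around ``tts``.  A
    peak overlapping several features by >= 1 bp takes the highest
    priority one; a peak touching nothing is intergenic.
    """
    trees = {name: {} for name in FEATURE_PRIORITY[:-1]}

    def _add(feature, chrom, start, end):
        if end <= start:
            return
        trees[feature].setdefault(chrom, IntervalTree()).addi(start, end)

    for row in genes.df.itertuples(index=False):
        chrom, strand, tss = row.chrom, row.strand, int(row.tss)
        _add("TSS", chrom, *_promoter_interval(tss, strand, tss_window))
        tts = getattr(row, "tts", None)
        exons = getattr(row, "exons", None) or []
        utr5 = getattr(row, "utr5", None) or []
        utr3 = getattr(row, "utr3", None) or []
        if tts is not None and not pd.isna(tts):
            tts = int(tts)
            _add("TTS", chrom, tts + tts_window[0], tts + tts_window[1] + 1)
        for s, e in utr5:
            _add("5'UTR", chrom, int(s), int(e))
        for s, e in utr3:
            _add("3'UTR", chrom, int(s), int(e))
        span_points = [tss] + ([tts] if tts is not None and not pd.isna(tts) else [])
        for s, e in exons:
            _add("exon", chrom, int(s), int(e))
            span_points += [int(s), int(e)]
        if exons:
            _add("intron", chrom, min(span_points), max(span_points))

    out = []
    for chrom, start, end in zip(
        peaks.df["chrom"], peaks.df["start"], peaks.df["end"]
    ):
        label = "intergenic"
        for feature in FEATURE_PRIORITY[:-1]:
            tree = trees[feature].get(chrom)
            if tree is not None and tree.overlap(int(start), int(end)):
                label = feature
                break
        out.append(label)
    return pd.Series(out, index=peaks.peak_ids, name="feature_class")


# ---------------------------------------------------------------------------
# readers / writers (plain text only)


def write_bed(peaks: PeakSet, path) -> None:
    peaks.df[["chrom", "start", "end", "peak_id"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed(path) -> PeakSet:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "peak_id"],
        dtype={"chrom": str},
        usecols=[0, 1, 2, 3],
    )
    return PeakSet(df)


def write_matrix_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="feature_id", float_format="%.17g")


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="feature_id")


def _fmt_intervals(intervals) -> str:
    if intervals is None or (isinstance(intervals, float) and pd.isna(intervals)):
        return ""
    return ",".join(f"{int(s)}-{int(e)}" for s, e in intervals)


def _parse_intervals(text):
    if text is None or (isinstance(text, float) and pd.isna(text)) or text == "":
        return []
    return [tuple(int(v) for v in part.split("-")) for part in str(text).split(",")]


def write_genes_tsv(genes: GeneAnnotation, path) -> None:
    df = genes.df.copy()
    for col in ("exons", "utr5", "utr3"):
        if col in df.columns:
            df[col] = df[col].map(_fmt_intervals)
    df.to_csv(path, sep="\t", index=False)


def read_genes_tsv(path) -> GeneAnnotation:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    for col in ("exons", "utr5", "utr3"):
        if col in df.columns:
            df[col] = df[col].map(_parse_intervals)
    return GeneAnnotation(df)
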