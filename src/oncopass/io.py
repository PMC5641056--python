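"""Reading the standard inputs and mapping copy-number segments to genes.

Segmentation comes in the common SEG dialect (tab-separated, columns
``Sample Chromosome Start End Num_Probes Segment_Mean``, 1-based inclusive
coordinates); gene coordinates come as BED (0-based half-open). Segment
means are log-ratios of tumor vs. reference copy number. A gene's
copy-number value in a sample is the length-weighted mean of the segment
means over the bases of the gene body covered by segments in that sample;
uncovered genes are missing and excluded pairwise downstream.

Gain and loss calls follow percentile rules on the per-gene log-ratio
distribution across patients: gain when the 90th percentile exceeds 0.50,
loss when the 10th percentile is below −0.50 (strict inequalities).
Constitutively silent genes are removed by requiring more than 30
normalized counts in at least 10% of samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import OmicCohort

logger = logging.getLogger(__name__)

__all__ = [
    "CopyNumberSegment",
    "GeneCNVCall",
    "read_seg",
    "write_seg",
    "read_gene_bed",
    "write_gene_bed",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_clinical",
    "read_probe_map",
    "map_segments_to_genes",
    "call_gain_loss",
    "call_gain_loss_matrix",
    "filter_expressed",
    "read_cohort",
]

SEG_COLUMNS = ["Sample", "Chromosome", "Start", "End", "Num_Probes", "Segment_Mean"]

GAIN_THRESHOLD = 0.50
LOSS_THRESHOLD = -0.50


@dataclass(frozen=True)
class CopyNumberSegment:
    """One contiguous segment of constant copy-number log-ratio.

    Coordinates are stored 0-based half-open; SEG files on disk are 1-based
    inclusive and converted on read/write.
    """

    sample: str
    chromosome: str
    start: int
    end: int
    segment_mean: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"segment start must be < end ({self.start}, {self.end})")
        if not math.isfinite(self.segment_mean):
            raise ValueError("segment mean must be finite")


@dataclass(frozen=True)
class GeneCNVCall:
    """Gain/loss status of one gene from its cross-patient CNV percentiles.

    ``status`` is ``gain`` (90th percentile > 0.50), ``loss`` (10th
    percentile < −0.50), ``neither``, or ``both`` — the flagged error state
    when a bimodal gene triggers both rules. ``percentile_stat`` is the
    percentile value that triggered the call (NaN for neither).
    """

    gene: str
    status: str
    percentile_stat: float
    p90: float
    p10: float


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_seg(path: str | Path) -> pd.DataFrame:
    """Read a SEG file into a segment table with 0-based half-open coords."""
    df = pd.read_csv(path, sep="\t", dtype={"Sample": str, "Chromosome": str})
    missing = [c for c in SEG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"SEG file missing columns: {missing}")
    out = pd.DataFrame(
        {
            "sample": df["Sample"],
            "chromosome": df["Chromosome"],
            "start": df["Start"].astype(np.int64) - 1,  # to 0-based half-open
            "end": df["End"].astype(np.int64),
            "segment_mean": df["Segment_Mean"].astype(float),
        }
    )
    if (out["start"] >= out["end"]).any():
        raise ValueError("SEG file contains empty or inverted segments")
    if not np.isfinite(out["segment_mean"]).all():
        raise ValueError("SEG file contains non-finite segment means")
    return out


def write_seg(segments: pd.DataFrame, path: str | Path) -> None:
    """Write a 0-based half-open segment table as a 1-based inclusive SEG file."""
    df = pd.DataFrame(
        {
            "Sample": segments["sample"],
            "Chromosome": segments["chromosome"],
            "Start": segments["start"].astype(np.int64) + 1,
            "End": segments["end"].astype(np.int64),
            "Num_Probes": segments.get(
                "num_probes", pd.Series(0, index=segments.index)
            ),
            "Segment_Mean": segments["segment_mean"].map(lambda v: f"{v:.12g}"),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_gene_bed(path: str | Path) -> pd.DataFrame:
    """Read gene coordinates from BED (chrom, start, end, name; 0-based)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2, 3],
        names=["chromosome", "start", "end", "gene"],
        dtype={"chromosome": str, "gene": str},
    )
    return df.set_index("gene")[["chromosome", "start", "end"]]


def write_gene_bed(genes: pd.DataFrame, path: str | Path) -> None:
    out = genes.reset_index()
    out = out[["chromosome", "start", "end", out.columns[0]]]
    out.to_csv(path, sep="\t", header=False, index=False)


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read a feature × sample TSV whose header row holds sample IDs."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", float_format="%.10g")


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    df = df.set_index("sample")[["time_days", "event"]]
    df["time_days"] = df["time_days"].astype(float)
    df["event"] = df["event"].astype(int)
    return df


def read_probe_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"probe": str, "gene": str})
    if not {"probe", "gene"}.issubset(df.columns):
        raise ValueError("probe map requires 'probe' and 'gene' columns")
    return df


# ---------------------------------------------------------------------------
# segment → gene mapping
# ---------------------------------------------------------------------------

def map_segments_to_genes(
    segments: pd.DataFrame, genes: pd.DataFrame
) -> pd.DataFrame:
    """Length-weighted gene-level CNV matrix from a segment table.

    For every (gene, sample), the value is the mean of segment log-ratios
    weighted by the number of gene-body bases each segment covers; genes
    with no covered base in a sample are NaN. Overlapping segments within
    one sample on one chromosome are rejected.

    Parameters
    ----------
    segments : DataFrame
        Columns ``sample, chromosome, start, end, segment_mean`` with
        0-based half-open coordinates (as produced by :func:`read_seg`).
    genes : DataFrame
        Indexed by gene name, columns ``chromosome, start, end`` (0-based
        half-open).

    Returns
    -------
    DataFrame
        genes × samples matrix of log-ratios, row order following ``genes``.
    """
    samples = list(dict.fromkeys(segments["sample"]))
    sample_idx = {s: j for j, s in enumerate(samples)}
    n_genes, n_samples = len(genes), len(samples)
    wsum = np.zeros((n_genes, n_samples))
    cov = np.zeros((n_genes, n_samples))

    gene_chroms = set(genes["chromosome"])
    seg_chroms = set(segments["chromosome"])
    for absent in sorted(gene_chroms - seg_chroms):
        logger.warning(
            "chromosome %s has genes but no segmentation; rows will be missing",
            absent,
        )

    # per-chromosome gene layout, sorted by start for binary search
    gene_pos = {g: i for i, g in enumerate(genes.index)}
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, int]] = {}
    for chrom, sub in genes.groupby("chromosome", sort=False):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy(np.int64)
        ends = sub["end"].to_numpy(np.int64)
        rows = np.array([gene_pos[g] for g in sub.index])
        max_len = int((ends - starts).max()) if len(sub) else 0
        by_chrom[str(chrom)] = (starts, ends, rows, max_len)

    for (sample, chrom), seg in segments.groupby(["sample", "chromosome"], sort=False):
        seg = seg.sort_values("start")
        s_start = seg["start"].to_numpy(np.int64)
        s_end = seg["end"].to_numpy(np.int64)
        if np.any(s_start[1:] < s_end[:-1]):
            raise ValueError(
                f"overlapping segments for sample {sample!r} on chromosome {chrom!r}"
            )
        layout = by_chrom.get(str(chrom))
        if layout is None:
            continue
        g_start, g_end, g_rows, max_len = layout
        j = sample_idx[sample]
        for s0, s1, mean in zip(s_start, s_end, seg["segment_mean"].to_numpy(float)):
            # candidate genes: start < s1 and end > s0; genes sorted by start,
            # so scan the index window [searchsorted(s0 - max_len), searchsorted(s1))
            hi = int(np.searchsorted(g_start, s1, side="left"))
            lo = int(np.searchsorted(g_start, s0 - max_len, side="left"))
            if lo >= hi:
                continue
            ov = np.minimum(g_end[lo:hi], s1) - np.maximum(g_start[lo:hi], s0)
            keep = ov > 0
            rows = g_rows[lo:hi][keep]
            bases = ov[keep].astype(float)
            wsum[rows, j] += bases * mean
            cov[rows, j] += bases

    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(cov > 0, wsum / np.where(cov > 0, cov, 1.0), np.nan)
    return pd.DataFrame(values, index=genes.index, columns=samples)


# ---------------------------------------------------------------------------
# gain/loss calls and expression filter
# ---------------------------------------------------------------------------

def call_gain_loss(cnv_row: np.ndarray | pd.Series, gene: str = "") -> GeneCNVCall:
    """Classify one gene as CNV gain / loss / neither from patient percentiles.

    Gain: 90th percentile of the cross-patient log-ratios > 0.50.
    Loss: 10th percentile < −0.50. Percentiles use linear interpolation
    between order statistics; inequalities are strict. Requires at least
    10 non-missing values.
    """
    vals = np.asarray(cnv_row, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 10:
        raise ValueError("need >= 10 non-missing CNV values for a gain/loss call")
    p90 = float(np.percentile(vals, 90))
    p10 = float(np.percentile(vals, 10))
    is_gain = p90 > GAIN_THRESHOLD
    is_loss = p10 < LOSS_THRESHOLD
    if is_gain and is_loss:
        return GeneCNVCall(gene, "both", float("nan"), p90, p10)
    if is_gain:
        return GeneCNVCall(gene, "gain", p90, p90, p10)
    if is_loss:
        return GeneCNVCall(gene, "loss", p10, p90, p10)
    return GeneCNVCall(gene, "neither", float("nan"), p90, p10)


def call_gain_loss_matrix(cnv: pd.DataFrame) -> pd.DataFrame:
    """Vectorized gain/loss calls for every gene row of a CNV matrix.

    Genes with fewer than 10 non-missing values get status ``insufficient``.
    """
    vals = cnv.to_numpy(float)
    n_ok = np.isfinite(vals).sum(axis=1)
    with np.errstate(all="ignore"):
        p90 = np.nanpercentile(vals, 90, axis=1)
        p10 = np.nanpercentile(vals, 10, axis=1)
    status = np.full(len(cnv), "neither", dtype=object)
    gain = p90 > GAIN_THRESHOLD
    loss = p10 < LOSS_THRESHOLD
    status[gain] = "gain"
    status[loss] = "loss"
    status[gain & loss] = "both"
    status[n_ok < 10] = "insufficient"
    return pd.DataFrame(
        {"status": status, "p90": p90, "p10": p10}, index=cnv.index
    )


def filter_expressed(
    expression: pd.DataFrame,
    min_count: float = 30.0,
    min_fraction: float = 0.10,
) -> pd.Index:
    """Genes expressed above ``min_count`` in at least ``min_fraction`` of samples.

    A gene is retained iff the number of samples with normalized count
    strictly greater than ``min_count`` is at least
    ``ceil(min_fraction * n_samples)``.
    """
    if expression.size == 0:
        raise ValueError("empty expression matrix")
    n_required = math.ceil(min_fraction * expression.shape[1])
    n_above = (expression.to_numpy(float) > min_count).sum(axis=1)
    return expression.index[n_above >= n_required]


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def read_cohort(
    directory: str | Path,
    seg: str = "segments.seg",
    expr: str = "expression.tsv",
    meth: str = "methylation.tsv",
    probes: str = "probes.tsv",
    clinical: str = "clinical.tsv",
    genes: str = "genes.bed",
) -> OmicCohort:
    """Assemble an :class:`OmicCohort` from a directory of standard files.

    Layers whose file is absent are left unset; the segmentation is mapped
    to gene level with :func:`map_segments_to_genes`. All present layers
    are reindexed to the sample ordering of the first layer found.
    """
    d = Path(directory)
    gene_df = read_gene_bed(d / genes) if (d / genes).exists() else None

    cnv = None
    if (d / seg).exists():
        if gene_df is None:
            raise ValueError("segmentation requires a gene coordinate BED")
        cnv = map_segments_to_genes(read_seg(d / seg), gene_df)

    expression = read_matrix_tsv(d / expr) if (d / expr).exists() else None
    methylation = read_matrix_tsv(d / meth) if (d / meth).exists() else None
    probe_map = read_probe_map(d / probes) if (d / probes).exists() else None
    clin = read_clinical(d / clinical) if (d / clinical).exists() else None

    samples = None
    for layer in (cnv, expression, methylation):
        if layer is not None:
            samples = list(layer.columns)
            break
    if samples is not None:
        if cnv is not None:
            cnv = cnv[samples]
        if expression is not None:
            expression = expression[samples]
        if methylation is not None:
            methylation = methylation[samples]
        if clin is not None:
            clin = clin.loc[samples]

    return OmicCohort(
        cnv=cnv,
        expression=expression,
        methylation=methylation,
        probe_map=probe_map,
        clinical=clin,
        genes=gene_df,
    )
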