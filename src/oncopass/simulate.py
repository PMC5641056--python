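"""Synthetic multi-omic tumor cohorts with planted dosage effects.

The generator emulates the four-layer structure of an SNP-array +
RNA-seq + methylation-array + clinical cohort:

* **Copy number** — each sample carries, per driver locus and with
  probability ``amp_frequency``, an amplified segment centered on the
  driver. The segment extends a geometrically distributed number of genes
  to each side (mean ``segment_decay``), so co-amplification correlation
  decays with distance from the driver. Amplified segment means are drawn
  from Normal(0.8, 0.1); the background is segmented noise
  Normal(0, ``cnv_noise_sd``).
* **Expression** — log2(count+1) = baseline + slope·CNV + Normal(0, 0.3),
  with slope ``dosage_slope`` for CR-high genes and 0 for CR-low genes:
  CR-high expression follows gene dosage, CR-low expression ignores it.
* **Methylation** — one probe per gene;
  beta = inverse-logit(logit(b0) + methyl_compensation·k·CNV + noise)
  with k > 0 for amplified CR-low genes (hypermethylation on copy gain,
  the compensation mechanism) and k < 0 for CR-high genes
  (hypomethylation on gain).
* **Survival** — exponential proportional hazards on the standardized
  log2 expression of a small designated set of outcome genes, with
  coefficients ``hazard_coef_crhigh`` / ``hazard_coef_crlow`` and
  independent exponential censoring calibrated so a baseline subject is
  censored with probability ``censor_rate``.

Every draw flows from one seeded generator, so cohorts are bit-identical
given the same config.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import OmicCohort
from . import io as opio

__all__ = ["SimulationConfig", "GroundTruth", "simulate_cohort", "write_cohort"]

GENE_SPACING = 100_000  # bp between gene starts on the synthetic grid
GENE_LENGTH = 10_000  # bp per gene body
AMP_MEAN = 0.8  # mean amplified segment log-ratio
AMP_SD = 0.1
EXPR_NOISE_SD = 0.3  # sd of log2 expression noise
METH_LOGIT_NOISE_SD = 0.2
METH_K = 2.0  # |k|, logit-scale CN→beta coupling for labelled genes
BASELINE_HAZARD = 1.0 / 1000.0  # events per day for a baseline subject
N_OUTCOME_PER_CLASS = 5


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic cohort.

    ``driver_loci`` are (chromosome index, gene index within chromosome)
    pairs; ``segment_decay`` is the expected amplified half-length in genes;
    ``cr_low_fraction`` is the fraction of amplicon genes whose expression
    is uncoupled from copy number.
    """

    n_samples: int = 300
    n_genes: int = 2000
    n_chromosomes: int = 10
    driver_loci: tuple[tuple[int, int], ...] = ((0, 100), (3, 60), (7, 140))
    amp_frequency: float = 0.3
    segment_decay: float = 40.0
    cnv_noise_sd: float = 0.1
    cr_low_fraction: float = 0.3
    dosage_slope: float = 1.0
    methyl_compensation: float = 1.0
    hazard_coef_crhigh: float = 0.5
    hazard_coef_crlow: float = -0.5
    censor_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_genes < 1 or self.n_chromosomes < 1:
            raise ValueError("n_samples, n_genes, n_chromosomes must be positive")
        for name in ("amp_frequency", "cr_low_fraction", "censor_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not (0.0 <= self.methyl_compensation <= 1.0):
            raise ValueError("methyl_compensation must lie in [0, 1]")
        if self.segment_decay <= 0 or self.cnv_noise_sd <= 0:
            raise ValueError("segment_decay and cnv_noise_sd must be > 0")
        for name in ("dosage_slope", "hazard_coef_crhigh", "hazard_coef_crlow"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        per_chrom = self._genes_per_chromosome()
        for chrom, pos in self.driver_loci:
            if not (0 <= chrom < self.n_chromosomes):
                raise ValueError(f"driver chromosome {chrom} outside grid")
            if not (0 <= pos < per_chrom[chrom]):
                raise ValueError(
                    f"driver position {pos} exceeds genes on chromosome {chrom}"
                )

    def _genes_per_chromosome(self) -> list[int]:
        base, extra = divmod(self.n_genes, self.n_chromosomes)
        return [base + (1 if c < extra else 0) for c in range(self.n_chromosomes)]


@dataclass
class GroundTruth:
    """Planted per-gene truth for parameter-recovery tests.

    ``table`` is indexed by gene with columns ``label`` (CR-high / CR-low /
    neutral), ``dosage_slope``, ``hazard_coef`` and ``methyl_compensated``;
    ``outcome_genes`` lists the genes whose expression drives survival.
    """

    table: pd.DataFrame
    outcome_genes: list[str] = field(default_factory=list)

    @property
    def labels(self) -> pd.Series:
        return self.table["label"]

    def amplicon_genes(self) -> pd.Index:
        return self.table.index[self.table["label"] != "neutral"]


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def _inv_logit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _gene_layout(config: SimulationConfig) -> pd.DataFrame:
    per_chrom = config._genes_per_chromosome()
    rows = []
    g = 0
    for c, n in enumerate(per_chrom):
        for i in range(n):
            start = i * GENE_SPACING
            rows.append((f"G{g:05d}", f"chr{c + 1}", start, start + GENE_LENGTH))
            g += 1
    return pd.DataFrame(
        rows, columns=["gene", "chromosome", "start", "end"]
    ).set_index("gene")


def simulate_cohort(config: SimulationConfig) -> tuple[OmicCohort, GroundTruth]:
    """Generate one cohort and its planted ground truth.

    Returns the cohort (all four layers populated) and a
    :class:`GroundTruth` giving each gene's class, true dosage slope, true
    hazard coefficient and methylation-compensation flag.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_layout(config)
    per_chrom = config._genes_per_chromosome()
    chrom_offsets = np.concatenate([[0], np.cumsum(per_chrom)])
    n_g, n_s = config.n_genes, config.n_samples
    samples = [f"S{j:04d}" for j in range(n_s)]

    # ---- planted classes ---------------------------------------------------
    window = int(round(config.segment_decay))
    amplicon = np.zeros(n_g, dtype=bool)
    driver_global = []
    for chrom, pos in config.driver_loci:
        g0 = int(chrom_offsets[chrom] + pos)
        driver_global.append(g0)
        lo = max(chrom_offsets[chrom], g0 - window)
        hi = min(chrom_offsets[chrom + 1], g0 + window + 1)
        amplicon[lo:hi] = True

    labels = np.full(n_g, "neutral", dtype=object)
    amp_idx = np.flatnonzero(amplicon)
    is_low = rng.random(amp_idx.size) < config.cr_low_fraction
    labels[amp_idx[is_low]] = "CR-low"
    labels[amp_idx[~is_low]] = "CR-high"

    slopes = np.where(labels == "CR-high", config.dosage_slope, 0.0)
    meth_k = np.zeros(n_g)
    meth_k[labels == "CR-low"] = METH_K  # hypermethylate on gain
    meth_k[labels == "CR-high"] = -METH_K  # hypomethylate on gain

    # ---- copy number: per-sample piecewise-constant gene values ------------
    cnv = np.empty((n_g, n_s))
    for j in range(n_s):
        for c in range(config.n_chromosomes):
            lo, hi = int(chrom_offsets[c]), int(chrom_offsets[c + 1])
            n_here = hi - lo
            # background blocks: Poisson number of breakpoints, one noise
            # value per block so the background itself is segmented
            n_breaks = min(int(rng.poisson(2)), max(n_here - 1, 0))
            if n_breaks > 0:
                cuts = np.sort(
                    rng.choice(np.arange(1, n_here), size=n_breaks, replace=False)
                )
            else:
                cuts = np.array([], dtype=int)
            bounds = np.concatenate([[0], cuts, [n_here]])
            vals = rng.normal(0.0, config.cnv_noise_sd, size=len(bounds) - 1)
            row = np.repeat(vals, np.diff(bounds))
            cnv[lo:hi, j] = row
        # amplified segments overlaying the background
        for (chrom, pos), g0 in zip(config.driver_loci, driver_global):
            if rng.random() < config.amp_frequency:
                left = int(rng.geometric(1.0 / config.segment_decay))
                right = int(rng.geometric(1.0 / config.segment_decay))
                amp = rng.normal(AMP_MEAN, AMP_SD)
                a_lo = max(int(chrom_offsets[chrom]), g0 - left)
                a_hi = min(int(chrom_offsets[chrom + 1]), g0 + right + 1)
                cnv[a_lo:a_hi, j] = amp
            else:
                # keep the stream aligned so per-sample draws stay comparable
                rng.geometric(1.0 / config.segment_decay)
                rng.geometric(1.0 / config.segment_decay)
                rng.normal(AMP_MEAN, AMP_SD)

    # ---- expression --------------------------------------------------------
    baseline = rng.uniform(6.0, 10.0, size=n_g)
    log_expr = (
        baseline[:, None]
        + slopes[:, None] * cnv
        + rng.normal(0.0, EXPR_NOISE_SD, size=(n_g, n_s))
    )
    counts = np.maximum(np.exp2(log_expr) - 1.0, 0.0)

    # ---- methylation (one probe per gene) ----------------------------------
    b0 = rng.uniform(0.3, 0.7, size=n_g)
    logit_beta = (
        _logit(b0)[:, None]
        + config.methyl_compensation * meth_k[:, None] * cnv
        + rng.normal(0.0, METH_LOGIT_NOISE_SD, size=(n_g, n_s))
    )
    betas = _inv_logit(logit_beta)
    probes = [f"cg{i:05d}" for i in range(n_g)]
    probe_map = pd.DataFrame({"probe": probes, "gene": genes.index})

    # ---- survival ----------------------------------------------------------
    hazard_coef = np.zeros(n_g)
    high_pool = np.flatnonzero(labels == "CR-high")
    low_pool = np.flatnonzero(labels == "CR-low")
    outcome: list[int] = []
    if high_pool.size:
        pick = rng.choice(
            high_pool, size=min(N_OUTCOME_PER_CLASS, high_pool.size), replace=False
        )
        hazard_coef[pick] = config.hazard_coef_crhigh
        outcome.extend(pick.tolist())
    if low_pool.size:
        pick = rng.choice(
            low_pool, size=min(N_OUTCOME_PER_CLASS, low_pool.size), replace=False
        )
        hazard_coef[pick] = config.hazard_coef_crlow
        outcome.extend(pick.tolist())

    lp = np.zeros(n_s)
    for g in outcome:
        z = log_expr[g] - log_expr[g].mean()
        sd = z.std()
        if sd > 0:
            lp += hazard_coef[g] * z / sd
    event_time = rng.exponential(1.0, size=n_s) / (BASELINE_HAZARD * np.exp(lp))
    if config.censor_rate > 0.0:
        censor_hazard = BASELINE_HAZARD * config.censor_rate / (1.0 - config.censor_rate)
        censor_time = rng.exponential(1.0 / censor_hazard, size=n_s)
    else:
        censor_time = np.full(n_s, np.inf)
    time_days = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    cohort = OmicCohort(
        cnv=pd.DataFrame(cnv, index=genes.index, columns=samples),
        expression=pd.DataFrame(counts, index=genes.index, columns=samples),
        methylation=pd.DataFrame(betas, index=probes, columns=samples),
        probe_map=probe_map,
        clinical=pd.DataFrame(
            {"time_days": time_days, "event": event},
            index=pd.Index(samples, name="sample"),
        ),
        genes=genes,
    )
    truth = GroundTruth(
        table=pd.DataFrame(
            {
                "label": labels,
                "dosage_slope": slopes,
                "hazard_coef": hazard_coef,
                "methyl_compensated": labels == "CR-low",
            },
            index=genes.index,
        ),
        outcome_genes=[genes.index[g] for g in outcome],
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def _segments_from_gene_cnv(cnv: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Rebuild a segment table from gene-level values.

    Consecutive genes (in coordinate order) with identical values collapse
    into one segment spanning their gene bodies; mapping the result back
    through the length-weighted averager reproduces the matrix exactly.
    """
    records = []
    for chrom, sub in genes.groupby("chromosome", sort=False):
        sub = sub.sort_values("start")
        vals = cnv.loc[sub.index].to_numpy(float)
        starts = sub["start"].to_numpy(np.int64)
        ends = sub["end"].to_numpy(np.int64)
        for j, sample in enumerate(cnv.columns):
            col = vals[:, j]
            i = 0
            while i < len(col):
                if not np.isfinite(col[i]):
                    i += 1
                    continue
                k = i
                while k + 1 < len(col) and col[k + 1] == col[i]:
                    k += 1
                records.append(
                    (sample, chrom, int(starts[i]), int(ends[k]), float(col[i]))
                )
                i = k + 1
    df = pd.DataFrame(
        records, columns=["sample", "chromosome", "start", "end", "segment_mean"]
    )
    return df.sort_values(["sample", "chromosome", "start"], ignore_index=True)


def write_cohort(cohort: OmicCohort, directory: str | Path) -> dict[str, Path]:
    """Write a cohort as the standard file set readable by :func:`oncopass.io.read_cohort`.

    Emits SEG segmentation (synthesized from the gene-level matrix),
    expression and beta TSVs, probe map, clinical table and gene BED.
    Returns the mapping of layer name to written path.
    """
    if cohort.n_samples == 0:
        raise ValueError("cannot write a cohort with zero samples")
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    if cohort.cnv is not None:
        if cohort.genes is None:
            raise ValueError("writing segmentation requires gene coordinates")
        seg = _segments_from_gene_cnv(cohort.cnv, cohort.genes)
        opio.write_seg(seg, d / "segments.seg")
        written["segments"] = d / "segments.seg"
    if cohort.genes is not None:
        opio.write_gene_bed(cohort.genes, d / "genes.bed")
        written["genes"] = d / "genes.bed"
    if cohort.expression is not None:
        opio.write_matrix_tsv(cohort.expression, d / "expression.tsv")
        written["expression"] = d / "expression.tsv"
    if cohort.methylation is not None:
        opio.write_matrix_tsv(cohort.methylation, d / "methylation.tsv")
        written["methylation"] = d / "methylation.tsv"
        cohort.probe_map.to_csv(d / "probes.tsv", sep="\t", index=False)
        written["probes"] = d / "probes.tsv"
    if cohort.clinical is not None:
        clin = cohort.clinical.copy()
        clin.index.name = "sample"
        clin.to_csv(d / "clinical.tsv", sep="\t", float_format="%.10g")
        written["clinical"] = d / "clinical.tsv"
    return written
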