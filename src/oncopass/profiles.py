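"""Genome-wide co-amplification and co-expression profiles of an index oncogene.

For an index oncogene (e.g. *ERBB2*, *MYC*, *CCND1*), its **co-amplification
profile** is the vector of Pearson correlations between its copy-number
log-ratio and every other gene's copy number across samples; its
**co-expression profile** correlates the index copy number with every
gene's mRNA instead. High concordance between the two profiles means that
the transcriptome changes accompanying the amplification are largely
carried by co-amplified passenger genes rather than downstream signaling.
The enrichment statistic quantifies this: among genes overexpressed in
index-amplified samples, how many are also co-amplified, with an
upper-tail hypergeometric P-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import (
    MIN_PAIRED,
    log2_counts,
    pearson_pairwise,
    pearson_vector_matrix,
    t_statistic,
)
from .cohort import OmicCohort

__all__ = [
    "GeneProfile",
    "EnrichmentResult",
    "association_profile",
    "profile_concordance",
    "coamplification_enrichment",
]

GAIN_SAMPLE_THRESHOLD = 0.5  # sample counted as index-gain when CNV log-ratio > 0.5


def hypergeom_upper_tail(
    n_overlap: int, n_population: int, n_coamplified: int, n_overexpressed: int
) -> float:
    """P(X >= n_overlap) for X ~ Hypergeometric(population, successes, draws)."""
    p = float(
        stats.hypergeom.sf(
            n_overlap - 1, n_population, n_coamplified, n_overexpressed
        )
    )
    return min(p, 1.0)


@dataclass
class GeneProfile:
    """Per-gene association of one index gene's CNV with an omic layer.

    ``values`` is indexed by gene; ``statistic_kind`` is ``pearson_r`` or
    ``t_statistic`` (the correlation t, t = r·sqrt((n−2)/(1−r²))).
    """

    index_gene: str
    level: str  # DNA | mRNA | methylation
    values: pd.Series
    statistic_kind: str = "pearson_r"


@dataclass
class EnrichmentResult:
    """Overlap of co-amplified and index-associated overexpressed genes."""

    n_population: int
    n_coamplified: int
    n_overexpressed: int
    n_overlap: int
    fraction: float
    p_value: float
    flagged: bool = False  # True when the overexpressed set is empty


def association_profile(
    cohort: OmicCohort,
    index_gene: str,
    level: str = "DNA",
    statistic: str = "pearson_r",
    gene_set: pd.Index | None = None,
) -> GeneProfile:
    """Correlate the index gene's CNV with every gene row of one layer.

    ``level`` selects the target layer: ``DNA`` (copy number), ``mRNA``
    (log2(count+1) expression) or ``methylation`` (betas, per probe).
    Genes with zero variance or fewer than 10 paired observations are NaN.
    """
    cohort.require("cnv")
    if index_gene not in cohort.cnv.index:
        raise KeyError(f"index gene {index_gene!r} not in CNV matrix")
    x = cohort.cnv.loc[index_gene].to_numpy(float)
    finite = x[np.isfinite(x)]
    if finite.size < MIN_PAIRED or np.all(finite == finite[0]):
        raise ValueError(f"index gene {index_gene!r} has constant or missing CNV")

    if level == "DNA":
        target = cohort.cnv
    elif level == "mRNA":
        cohort.require("expression")
        target = cohort.expression
    elif level == "methylation":
        cohort.require("methylation")
        target = cohort.methylation
    else:
        raise ValueError(f"unknown level {level!r}")
    if gene_set is not None:
        target = target.loc[target.index.intersection(gene_set)]

    m = target.to_numpy(float)
    if level == "mRNA":
        m = log2_counts(m)
    r = pearson_vector_matrix(x, m)
    values = pd.Series(r, index=target.index, name=f"{index_gene}:{level}")
    if statistic == "t_statistic":
        n = (np.isfinite(m) & np.isfinite(x)[None, :]).sum(axis=1)
        values = pd.Series(
            t_statistic(values.to_numpy(), n), index=target.index, name=values.name
        )
    elif statistic != "pearson_r":
        raise ValueError(f"unknown statistic {statistic!r}")
    return GeneProfile(index_gene, level, values, statistic)


def profile_concordance(p_dna: GeneProfile, p_mrna: GeneProfile) -> float:
    """Pearson correlation across genes of two profiles, index gene excluded."""
    shared = p_dna.values.index.intersection(p_mrna.values.index)
    shared = shared.drop(
        [g for g in {p_dna.index_gene, p_mrna.index_gene} if g in shared]
    )
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared genes between profiles")
    return pearson_pairwise(
        p_dna.values.loc[shared].to_numpy(),
        p_mrna.values.loc[shared].to_numpy(),
        min_n=3,
    )


def coamplification_enrichment(
    cohort: OmicCohort,
    index_gene: str,
    overexpr_alpha: float = 0.001,
    coamp_r_threshold: float = 0.4,
    scope: str = "genome",
    gene_set: pd.Index | None = None,
) -> EnrichmentResult:
    """Hypergeometric enrichment of co-amplified genes among overexpressed ones.

    Samples are split by index-gene CNV > 0.5 (gain) vs the rest.
    Overexpressed genes differ in log2 expression between the two groups by
    Welch's t-test at P < ``overexpr_alpha`` with the higher mean in gain
    samples. Co-amplified genes have DNA-profile r > ``coamp_r_threshold``.
    ``scope='trans_only'`` drops genes on the index gene's chromosome.
    """
    cohort.require("cnv", "expression")
    x = cohort.cnv.loc[index_gene].to_numpy(float)
    gain = np.isfinite(x) & (x > GAIN_SAMPLE_THRESHOLD)
    rest = np.isfinite(x) & ~gain
    if gain.sum() < 10:
        raise ValueError(
            f"index gene {index_gene!r} has fewer than 10 copy-gain samples"
        )

    universe = cohort.expression.index.intersection(cohort.cnv.index)
    if gene_set is not None:
        universe = universe.intersection(gene_set)
    universe = universe.drop(index_gene) if index_gene in universe else universe
    if scope == "trans_only":
        if cohort.genes is None:
            raise ValueError("trans_only scope requires gene coordinates")
        chrom = cohort.genes.loc[index_gene, "chromosome"]
        same = cohort.genes.index[cohort.genes["chromosome"] == chrom]
        universe = universe.drop(universe.intersection(same))
    elif scope != "genome":
        raise ValueError(f"unknown scope {scope!r}")

    expr = log2_counts(cohort.expression.loc[universe].to_numpy(float))
    with np.errstate(all="ignore"):
        t, p = stats.ttest_ind(
            expr[:, gain], expr[:, rest], axis=1, equal_var=False
        )
    over = pd.Index(universe[(p < overexpr_alpha) & (t > 0)])

    dna = association_profile(cohort, index_gene, level="DNA", gene_set=universe)
    coamp = dna.values.index[dna.values > coamp_r_threshold]

    n_pop, n_co, n_over = len(universe), len(coamp), len(over)
    n_overlap = len(over.intersection(coamp))
    if n_over == 0:
        return EnrichmentResult(n_pop, n_co, 0, 0, float("nan"), 1.0, flagged=True)
    p_val = hypergeom_upper_tail(n_overlap, n_pop, n_co, n_over)
    return EnrichmentResult(
        n_pop, n_co, n_over, n_overlap, n_overlap / n_over, p_val
    )
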