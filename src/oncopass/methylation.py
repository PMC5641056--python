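"""CNV–methylation coupling and its coherence with CNV–mRNA coupling.

Copy-number gains of dosage-coupled (CR-high) genes tend to come with
beta-value losses (the added copies are unmethylated), while gains of
dosage-uncoupled (CR-low) genes come with beta gains — hypermethylation
that suppresses the extra copies. Coherence between per-gene CNV–beta and
CNV–mRNA correlations is summarized with a Spearman rank correlation and
an ordinary least-squares slope; a negative relationship is the signature
of methylation-mediated compensation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import MIN_PAIRED, pearson_pairwise
from .cohort import OmicCohort

__all__ = [
    "MethylationCoupling",
    "BetaComparison",
    "cnv_methylation_correlation",
    "coherence",
    "beta_gain_vs_2N",
]

GAIN_CUTOFF = 0.5  # sample-level copy-gain call on the log-ratio scale
MIN_GROUP = 5


@dataclass
class MethylationCoupling:
    """Per-gene CNV–beta correlations under a stated probe policy.

    ``table`` is indexed by gene with columns ``cnv_meth_r``, ``best_probe``
    and ``n_probes``; ``probe_policy`` records how multi-probe genes were
    summarized.
    """

    table: pd.DataFrame
    probe_policy: str


@dataclass
class BetaComparison:
    """Beta values in copy-gain vs copy-neutral (2N) samples for one probe."""

    gene: str
    probe: str
    beta_2N_median: float
    beta_2N_iqr: tuple[float, float]
    beta_gain_median: float
    beta_gain_iqr: tuple[float, float]
    n_2N: int
    n_gain: int
    direction: str  # hyper | hypo | none
    p_value: float


def cnv_methylation_correlation(
    cohort: OmicCohort,
    gene_set: pd.Index | None = None,
    probe_policy: str = "best_abs",
) -> MethylationCoupling:
    """Pearson r of each gene's CNV against its methylation probes.

    Probe policies for genes with several probes:

    * ``best_abs`` — keep the probe with the largest \\|r\\|;
    * ``mean_beta`` — average betas across the gene's probes first;
    * ``per_probe`` — one record per probe (table indexed by gene, one
      row per probe).

    Genes without mapped probes are excluded; all policies agree exactly
    for single-probe genes.
    """
    cohort.require("cnv", "methylation")
    if probe_policy not in ("best_abs", "mean_beta", "per_probe"):
        raise ValueError(f"unknown probe policy {probe_policy!r}")
    pm = cohort.probe_map
    genes = cohort.cnv.index
    if gene_set is not None:
        genes = genes.intersection(gene_set)
    pm = pm[pm["gene"].isin(genes) & pm["probe"].isin(cohort.methylation.index)]

    rows = []
    for gene, sub in pm.groupby("gene", sort=False):
        x = cohort.cnv.loc[gene].to_numpy(float)
        probes = list(sub["probe"])
        if probe_policy == "mean_beta":
            beta = cohort.methylation.loc[probes].to_numpy(float).mean(axis=0)
            r = pearson_pairwise(x, beta)
            if np.isfinite(r):
                rows.append((gene, r, ";".join(probes), len(probes)))
            continue
        per_probe = [
            (p, pearson_pairwise(x, cohort.methylation.loc[p].to_numpy(float)))
            for p in probes
        ]
        per_probe = [(p, r) for p, r in per_probe if np.isfinite(r)]
        if not per_probe:
            continue
        if probe_policy == "per_probe":
            rows.extend((gene, r, p, len(probes)) for p, r in per_probe)
        else:  # best_abs
            p, r = max(per_probe, key=lambda pr: abs(pr[1]))
            rows.append((gene, r, p, len(probes)))

    table = pd.DataFrame(
        rows, columns=["gene", "cnv_meth_r", "best_probe", "n_probes"]
    ).set_index("gene")
    return MethylationCoupling(table, probe_policy)


def coherence(
    meth_r: pd.Series, mrna_r: pd.Series
) -> tuple[float, float]:
    """Spearman rho and OLS slope of CNV–beta r on CNV–mRNA r across genes.

    Returns ``(spearman_rho, ols_slope)`` over genes present and finite in
    both series; requires at least 10 such genes.
    """
    shared = meth_r.index.intersection(mrna_r.index)
    x = mrna_r.loc[shared].to_numpy(float)
    y = meth_r.loc[shared].to_numpy(float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < MIN_PAIRED:
        raise ValueError("need at least 10 genes with both correlations")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("degenerate variance in coherence inputs")
    rho = float(stats.spearmanr(x, y).statistic)
    slope = float(np.polyfit(x, y, 1)[0])
    return rho, slope


def beta_gain_vs_2N(
    cohort: OmicCohort,
    gene: str,
    probe: str | None = None,
    side: str = "gain",
    alpha: float = 0.05,
) -> BetaComparison:
    """Compare a probe's betas between copy-altered and copy-neutral samples.

    ``side='gain'`` contrasts samples with gene CNV > 0.5 against 2N
    samples (\\|CNV\\| ≤ 0.5); ``side='loss'`` uses CNV < −0.5 instead. A
    two-sided Mann–Whitney test decides the direction: ``hyper`` when the
    altered group's median beta is higher at p < ``alpha``, ``hypo`` when
    lower, ``none`` otherwise. Both groups need at least 5 samples.
    """
    cohort.require("cnv", "methylation")
    if probe is None:
        sub = cohort.probe_map[cohort.probe_map["gene"] == gene]
        if sub.empty:
            raise ValueError(f"gene {gene!r} has no mapped probes")
        probe = str(sub["probe"].iloc[0])
    x = cohort.cnv.loc[gene].to_numpy(float)
    beta = cohort.methylation.loc[probe].to_numpy(float)
    ok = np.isfinite(x) & np.isfinite(beta)
    x, beta = x[ok], beta[ok]
    if side == "gain":
        altered = x > GAIN_CUTOFF
    elif side == "loss":
        altered = x < -GAIN_CUTOFF
    else:
        raise ValueError(f"unknown side {side!r}")
    neutral = np.abs(x) <= GAIN_CUTOFF
    b_alt, b_2n = beta[altered], beta[neutral]
    if b_alt.size < MIN_GROUP or b_2n.size < MIN_GROUP:
        raise ValueError(
            f"need >= {MIN_GROUP} samples per group "
            f"(altered={b_alt.size}, 2N={b_2n.size})"
        )
    # exact null when group sizes permit and betas carry no ties
    no_ties = len(np.unique(np.concatenate([b_alt, b_2n]))) == b_alt.size + b_2n.size
    method = "exact" if (no_ties and max(b_alt.size, b_2n.size) <= 25) else "asymptotic"
    res = stats.mannwhitneyu(b_alt, b_2n, alternative="two-sided", method=method)
    med_alt, med_2n = float(np.median(b_alt)), float(np.median(b_2n))
    if res.pvalue < alpha and med_alt > med_2n:
        direction = "hyper"
    elif res.pvalue < alpha and med_alt < med_2n:
        direction = "hypo"
    else:
        direction = "none"
    q = lambda b: (float(np.percentile(b, 25)), float(np.percentile(b, 75)))
    return BetaComparison(
        gene=gene,
        probe=probe,
        beta_2N_median=med_2n,
        beta_2N_iqr=q(b_2n),
        beta_gain_median=med_alt,
        beta_gain_iqr=q(b_alt),
        n_2N=int(b_2n.size),
        n_gain=int(b_alt.size),
        direction=direction,
        p_value=float(res.pvalue),
    )
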