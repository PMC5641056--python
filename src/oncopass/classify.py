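"""CR-high / CR-low classification from the bimodal dosage-correlation density.

Across frequently copy-number-altered genes, the distribution of each
gene's own CNV–mRNA Pearson correlation is bimodal: one mode of genes
whose expression tracks dosage (CR-high) and one of genes whose
expression is uncoupled from it (CR-low). The class boundary is placed at
the valley between the two hills of a Gaussian kernel density estimate,
which in practice lands near r = 0.4; when the density is not clearly
bimodal the classifier falls back to that fixed cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import log2_counts, pearson_rowwise
from .cohort import OmicCohort

logger = logging.getLogger(__name__)

__all__ = [
    "CRClassification",
    "per_gene_dosage_correlation",
    "find_valley_cutoff",
    "classify",
]

FALLBACK_CUTOFF = 0.4
VALLEY_WINDOW = (0.0, 0.8)  # admissible valley locations
KDE_GRID_SIZE = 512
MIN_VALUES_FOR_VALLEY = 50


@dataclass
class CRClassification:
    """Per-gene coupling labels with the fitted cutoff.

    ``table`` is indexed by gene with columns ``cnv_mrna_r`` and ``label``
    (CR-high / CR-low / excluded). ``cutoff_source`` records whether the
    cutoff came from the density valley or the fixed fallback.
    """

    table: pd.DataFrame
    cutoff: float
    cutoff_source: str

    @property
    def labels(self) -> pd.Series:
        return self.table["label"]

    def genes(self, label: str) -> pd.Index:
        return self.table.index[self.table["label"] == label]


def per_gene_dosage_correlation(
    cohort: OmicCohort, gene_set: pd.Index | None = None
) -> pd.Series:
    """Pearson r of each gene's own CNV against its own log2(count+1) expression.

    Genes absent from either layer, constant, or with fewer than 10 paired
    observations come back NaN.
    """
    cohort.require("cnv", "expression")
    genes = cohort.cnv.index.intersection(cohort.expression.index)
    if gene_set is not None:
        genes = genes.intersection(gene_set)
    cnv = cohort.cnv.loc[genes].to_numpy(float)
    expr = log2_counts(cohort.expression.loc[genes].to_numpy(float))
    r = pearson_rowwise(cnv, expr)
    return pd.Series(r, index=genes, name="cnv_mrna_r")


def find_valley_cutoff(
    r_values: np.ndarray | pd.Series, fallback: float = FALLBACK_CUTOFF
) -> tuple[float, str]:
    """Locate the density valley between the two hills of the r distribution.

    A Gaussian KDE (Silverman bandwidth) is evaluated on a 512-point grid
    over [−1, 1]; the two highest local maxima are found and the cutoff is
    the grid point of minimum density strictly between them. If the
    density has fewer than two local maxima, or the valley falls outside
    the admissible window [0.0, 0.8], the fixed fallback is returned with
    ``source='fallback'``.
    """
    vals = np.asarray(r_values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < MIN_VALUES_FOR_VALLEY:
        raise ValueError("need at least 50 correlation values to fit a cutoff")

    grid = np.linspace(-1.0, 1.0, KDE_GRID_SIZE)
    kde = stats.gaussian_kde(vals, bw_method="silverman")
    density = kde(grid)

    interior = np.flatnonzero(
        (density[1:-1] > density[:-2]) & (density[1:-1] >= density[2:])
    ) + 1
    if interior.size < 2:
        logger.warning("density not bimodal; using fallback cutoff %.2f", fallback)
        return fallback, "fallback"
    top_two = interior[np.argsort(density[interior])][-2:]
    left, right = int(top_two.min()), int(top_two.max())
    if right - left < 2:
        return fallback, "fallback"
    between = slice(left + 1, right)
    cutoff = float(grid[between][np.argmin(density[between])])
    # window check tolerates one grid step so a valley exactly at a bound
    # (e.g. 0 for a symmetric density) is not spuriously rejected
    step = grid[1] - grid[0]
    if not (VALLEY_WINDOW[0] - step <= cutoff <= VALLEY_WINDOW[1] + step):
        logger.warning(
            "valley at %.3f outside admissible window; using fallback %.2f",
            cutoff,
            fallback,
        )
        return fallback, "fallback"
    return cutoff, "valley"


def classify(
    r_values: pd.Series, cutoff: float | None = None, fallback: float = FALLBACK_CUTOFF
) -> CRClassification:
    """Label genes CR-high (r strictly above the cutoff) or CR-low (r ≤ cutoff).

    With ``cutoff=None`` the valley cutoff is fitted from the values first.
    Ties at the cutoff go to CR-low; missing r gives ``excluded``.
    """
    if cutoff is None:
        cutoff, source = find_valley_cutoff(r_values, fallback=fallback)
    else:
        if not np.isfinite(cutoff):
            raise ValueError("cutoff must be finite")
        source = "fixed"
    r = pd.Series(r_values).astype(float)
    label = np.where(r > cutoff, "CR-high", "CR-low")
    label = np.where(np.isfinite(r), label, "excluded")
    table = pd.DataFrame({"cnv_mrna_r": r, "label": label}, index=r.index)
    return CRClassification(table, float(cutoff), source)
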