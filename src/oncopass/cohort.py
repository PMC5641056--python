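"""Aligned multi-omic cohort container.

An :class:`OmicCohort` holds gene-level copy number (log-ratio), expression
(normalized counts), methylation (probe-level beta values with a probe→gene
map), clinical outcomes and gene coordinates for one tumor cohort, with a
single shared sample ordering across all layers that are present.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["OmicCohort"]


@dataclass
class OmicCohort:
    """Gene × sample multi-omic matrices plus clinical outcomes.

    Parameters
    ----------
    cnv : DataFrame or None
        Gene-level copy-number log-ratios, genes in rows, samples in columns.
        Missing values (NaN) mark gene/sample pairs with no segment coverage.
    expression : DataFrame or None
        Normalized counts (non-negative), genes × samples.
    methylation : DataFrame or None
        Beta values in [0, 1], probes × samples.
    probe_map : DataFrame or None
        Columns ``probe`` and ``gene`` (optionally ``position``); maps
        methylation probes to genes. Required when ``methylation`` is set.
    clinical : DataFrame or None
        Indexed by sample, columns ``time_days`` (positive) and ``event``
        (0/1).
    genes : DataFrame or None
        Indexed by gene, columns ``chromosome``, ``start``, ``end``
        (0-based half-open).
    """

    cnv: pd.DataFrame | None = None
    expression: pd.DataFrame | None = None
    methylation: pd.DataFrame | None = None
    probe_map: pd.DataFrame | None = None
    clinical: pd.DataFrame | None = None
    genes: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- layer bookkeeping -------------------------------------------------
    @property
    def samples(self) -> list[str]:
        for layer in (self.cnv, self.expression, self.methylation):
            if layer is not None:
                return list(layer.columns)
        if self.clinical is not None:
            return list(self.clinical.index)
        return []

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def validate(self) -> None:
        """Check cross-layer sample alignment and per-layer value ranges."""
        samples = self.samples
        for name in ("cnv", "expression", "methylation"):
            layer = getattr(self, name)
            if layer is not None and list(layer.columns) != samples:
                raise ValueError(
                    f"sample columns of layer {name!r} do not match the "
                    "cohort sample ordering"
                )
        if self.clinical is not None:
            if list(self.clinical.index) != samples and samples:
                raise ValueError("clinical sample index does not match matrix columns")
            t = self.clinical["time_days"].to_numpy(float)
            e = self.clinical["event"].to_numpy(float)
            if np.any(t <= 0):
                raise ValueError("survival times must be positive")
            if not np.isin(e, (0.0, 1.0)).all():
                raise ValueError("event indicator must be 0 or 1")
        if self.methylation is not None:
            vals = self.methylation.to_numpy(float)
            finite = vals[np.isfinite(vals)]
            if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
                raise ValueError("methylation betas must lie in [0, 1]")
            if self.probe_map is None:
                raise ValueError("methylation layer requires a probe_map")
        if self.expression is not None:
            vals = self.expression.to_numpy(float)
            finite = vals[np.isfinite(vals)]
            if finite.size and finite.min() < 0.0:
                raise ValueError("expression counts must be non-negative")

    def require(self, *layers: str) -> None:
        """Raise a clean error naming any requested layer that is absent."""
        for name in layers:
            if getattr(self, name) is None:
                raise ValueError(f"cohort is missing required layer {name!r}")
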