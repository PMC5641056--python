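"""End-to-end orchestration: ingest → filter → calls → classify → downstream.

A :class:`RunConfig` holds every input path and threshold with the
standard defaults baked in (gain at 90th percentile > 0.50, loss at 10th
percentile < −0.50, expression filter at > 30 counts in ≥ 10% of samples,
CR pivot 0.4, overexpression alpha 0.001, Cox z band ±2).
:func:`run_pipeline` executes the enabled stages in order, writes one TSV
per stage plus a JSON manifest (config, config hash, seed, package
version) and a log, and halts on a stage failure with the stage name,
keeping the outputs already written.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import classify as classify_genes
from .classify import per_gene_dosage_correlation
from . import io as opio
from . import methylation as methmod
from . import netflux as nfmod
from . import profiles as profmod
from . import survival as survmod
from .cohort import OmicCohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Declarative pipeline configuration with the standard thresholds."""

    input_dir: str = "."
    out_dir: str = "run"
    gain_threshold: float = 0.50
    loss_threshold: float = -0.50
    expr_min_count: float = 30.0
    expr_min_fraction: float = 0.10
    cr_pivot: float = 0.4
    cutoff_mode: str = "valley"  # valley | fixed
    cr_scope: str = "gain"  # gain | loss | all
    overexpr_alpha: float = 0.001
    cox_z_cut: float = 2.0
    restart: float = 0.05
    n_permutations: int = 1000
    seed: int = 0
    index_genes: list[str] = field(default_factory=list)
    network_file: str | None = None
    gmt_file: str | None = None
    probe_policy: str = "best_abs"
    stages: list[str] = field(
        default_factory=lambda: [
            "filter",
            "calls",
            "dosage",
            "classify",
            "profiles",
            "methylation",
            "survival",
            "netflux",
        ]
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def run_pipeline(
    config: RunConfig, cohort: OmicCohort | None = None
) -> Path:
    """Run the enabled stages and return the output directory.

    ``cohort`` may be passed directly (e.g. a simulated one); otherwise it
    is read from ``config.input_dir``. Stage outputs are TSVs with a fixed
    numeric format so identical configs and seeds give byte-identical runs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("oncopass")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    stage = "ingest"
    try:
        if cohort is None:
            cohort = opio.read_cohort(config.input_dir)
        logger.info("ingested cohort with %d samples", cohort.n_samples)

        retained = None
        if "filter" in config.stages:
            stage = "filter"
            cohort.require("expression")
            retained = opio.filter_expressed(
                cohort.expression, config.expr_min_count, config.expr_min_fraction
            )
            pd.DataFrame(index=retained).to_csv(out / "retained_genes.tsv", sep="\t")
            logger.info("retained %d expressed genes", len(retained))

        calls = None
        if "calls" in config.stages:
            stage = "calls"
            cohort.require("cnv")
            calls = opio.call_gain_loss_matrix(cohort.cnv)
            _write(calls, out / "gain_loss_calls.tsv")

        dosage_r = None
        if "dosage" in config.stages:
            stage = "dosage"
            dosage_r = per_gene_dosage_correlation(cohort, gene_set=retained)
            _write(dosage_r.to_frame(), out / "dosage_correlation.tsv")

        cr = None
        if "classify" in config.stages and dosage_r is not None:
            stage = "classify"
            scope_r = dosage_r
            if calls is not None and config.cr_scope in ("gain", "loss"):
                in_scope = calls.index[calls["status"] == config.cr_scope]
                scope_r = dosage_r.loc[dosage_r.index.intersection(in_scope)]
            cutoff = None if config.cutoff_mode == "valley" else config.cr_pivot
            cr = classify_genes(scope_r, cutoff=cutoff, fallback=config.cr_pivot)
            tbl = cr.table.copy()
            tbl["cutoff"] = cr.cutoff
            tbl["cutoff_source"] = cr.cutoff_source
            _write(tbl, out / "cr_classification.tsv")
            logger.info(
                "CR cutoff %.4f (%s); %d CR-high / %d CR-low",
                cr.cutoff,
                cr.cutoff_source,
                (cr.labels == "CR-high").sum(),
                (cr.labels == "CR-low").sum(),
            )

        if "profiles" in config.stages and config.index_genes:
            stage = "profiles"
            prof_rows, enrich_rows = [], []
            for g in config.index_genes:
                p_dna = profmod.association_profile(
                    cohort, g, "DNA", gene_set=retained
                )
                p_rna = profmod.association_profile(
                    cohort, g, "mRNA", gene_set=retained
                )
                conc = profmod.profile_concordance(p_dna, p_rna)
                enr = profmod.coamplification_enrichment(
                    cohort,
                    g,
                    overexpr_alpha=config.overexpr_alpha,
                    coamp_r_threshold=config.cr_pivot,
                    gene_set=retained,
                )
                prof_rows.append(
                    pd.DataFrame(
                        {"dna_r": p_dna.values, "mrna_r": p_rna.values}
                    ).assign(index_gene=g)
                )
                enrich_rows.append(
                    {
                        "index_gene": g,
                        "concordance": conc,
                        "n_population": enr.n_population,
                        "n_coamplified": enr.n_coamplified,
                        "n_overexpressed": enr.n_overexpressed,
                        "n_overlap": enr.n_overlap,
                        "fraction": enr.fraction,
                        "p_value": enr.p_value,
                    }
                )
            _write(pd.concat(prof_rows), out / "profiles.tsv")
            _write(pd.DataFrame(enrich_rows).set_index("index_gene"),
                   out / "enrichment.tsv")

        if "methylation" in config.stages:
            stage = "methylation"
            cohort.require("methylation")
            coupling = methmod.cnv_methylation_correlation(
                cohort,
                gene_set=cr.table.index if cr is not None else retained,
                probe_policy=config.probe_policy,
            )
            _write(coupling.table, out / "methylation_coupling.tsv")
            if cr is not None:
                rho, slope = methmod.coherence(
                    coupling.table["cnv_meth_r"], cr.table["cnv_mrna_r"]
                )
                pd.DataFrame(
                    {"spearman_rho": [rho], "ols_slope": [slope]}
                ).to_csv(out / "coherence.tsv", sep="\t", index=False,
                         float_format=FLOAT_FMT)
                logger.info("coherence rho=%.4f slope=%.4f", rho, slope)

        if "survival" in config.stages:
            stage = "survival"
            cohort.require("clinical")
            gene_set = cr.table.index if cr is not None else retained
            cox = survmod.cox_per_gene(cohort, gene_set=gene_set)
            _write(cox, out / "cox_screen.tsv")
            if cr is not None:
                summary = survmod.stratify_by_cr(cox, cr.table, config.cox_z_cut)
                rows = []
                for name, g in summary.groups.items():
                    row = {"group": name}
                    row.update(g or {"n": 0})
                    rows.append(row)
                strat = pd.DataFrame(rows).set_index("group")
                strat["spearman_rho"] = summary.spearman_rho
                _write(strat, out / "cox_stratified.tsv")

        if (
            "netflux" in config.stages
            and config.network_file
            and config.gmt_file
            and cr is not None
        ):
            stage = "netflux"
            network = nfmod.read_edge_list(config.network_file)
            pathways = nfmod.read_gmt(config.gmt_file)
            values = nfmod.transform_cr_values(
                cr.table["cnv_mrna_r"].dropna(), pivot=config.cr_pivot
            )
            node_flux, edge_flux = nfmod.stationary_flux(
                network, values, restart=config.restart
            )
            results = nfmod.pathway_flux(
                node_flux,
                edge_flux,
                pathways,
                n_permutations=config.n_permutations,
                seed=config.seed,
            )
            df = pd.DataFrame(
                [
                    {
                        "pathway": r.pathway,
                        "n_members": r.n_members_in_network,
                        "flux_score": r.flux_score,
                        "null_mean": r.null_mean,
                        "null_sd": r.null_sd,
                        "z": r.z,
                    }
                    for r in results
                ]
            ).set_index("pathway")
            _write(df, out / "pathway_flux.tsv")
    except Exception as exc:
        root.removeHandler(handler)
        handler.close()
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    root.removeHandler(handler)
    handler.close()
    return out
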