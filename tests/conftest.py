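import numpy as np
import pandas as pd
import pytest

from oncopass import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_sim():
    """A 100-sample, 400-gene cohort with planted classes (seeded)."""
    cfg = SimulationConfig(
        seed=11,
        n_samples=100,
        n_genes=400,
        n_chromosomes=4,
        driver_loci=((0, 50), (2, 40)),
        segment_decay=25.0,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def recovery_sim():
    """A 300-sample cohort sized for parameter-recovery checks."""
    cfg = SimulationConfig(seed=7, n_samples=300)
    return simulate_cohort(cfg)


def brute_force_gene_cnv(segments: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Per-base averaging oracle for segment→gene mapping (small fixtures only)."""
    samples = list(dict.fromkeys(segments["sample"]))
    out = np.full((len(genes), len(samples)), np.nan)
    for gi, (gene, row) in enumerate(genes.iterrows()):
        for si, sample in enumerate(samples):
            total, covered = 0.0, 0
            sub = segments[
                (segments["sample"] == sample)
                & (segments["chromosome"] == row["chromosome"])
            ]
            for base in range(int(row["start"]), int(row["end"])):
                hit = sub[(sub["start"] <= base) & (base < sub["end"])]
                if len(hit):
                    total += float(hit["segment_mean"].iloc[0])
                    covered += 1
            if covered:
                out[gi, si] = total / covered
    return pd.DataFrame(out, index=genes.index, columns=samples)
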