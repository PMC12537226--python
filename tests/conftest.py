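"""Shared fixtures: hand-built pedigrees and reusable simulated scenarios."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rhdocall import (
    PedigreeGenotypes,
    PlasmaCounts,
    Region,
    RunConfig,
    SampleRoles,
    SimulationConfig,
)


def make_ped(genotypes: list[tuple[int, int, int]], chrom: str = "chr6",
             start: int = 32_000_000, step: int = 100) -> PedigreeGenotypes:
    """Build a PedigreeGenotypes from (father, mother, sibling) ref counts."""
    n = len(genotypes)
    bases = ["A", "C", "G", "T"]
    rows = []
    for i, (gf, gm, gs) in enumerate(genotypes):
        rows.append(
            {
                "chrom": chrom,
                "pos": start + i * step,
                "ref": bases[i % 4],
                "alt": bases[(i + 1) % 4],
                "father": gf,
                "mother": gm,
                "sibling": gs,
            }
        )
    return PedigreeGenotypes(pd.DataFrame(rows))


def make_plasma(ped: PedigreeGenotypes, ref_depth, alt_depth) -> PlasmaCounts:
    df = ped.df[["chrom", "pos", "ref", "alt"]].copy()
    df["ref_depth"] = np.asarray(ref_depth, dtype=int)
    df["alt_depth"] = np.asarray(alt_depth, dtype=int)
    return PlasmaCounts(df)


@pytest.fixture
def run_config() -> RunConfig:
    return RunConfig(
        samples=SampleRoles(father="FATHER", mother="MOTHER", sibling="SIBLING"),
        region=Region(chrom="chr6", start=31_000_000, end=34_000_000),
        flank_bp=0,
    )


@pytest.fixture(scope="session")
def default_scenario():
    """One shared end-to-end run under the study conditions."""
    from rhdocall import run_scenario

    return run_scenario(SimulationConfig(n_snps=2000, seed=12345))


@pytest.fixture
def sim_cfg():
    def _make(**kwargs) -> SimulationConfig:
        kwargs.setdefault("seed", 0)
        return SimulationConfig(**kwargs)

    return _make
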