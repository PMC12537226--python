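"""End-to-end analysis: phase -> classify -> dosage -> ff -> call."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .config import RunConfig
from .core import PedigreeGenotypes, PlasmaCounts
from .fetal_fraction import FetalFractionEstimate, estimate_ff, select_ff_loci
from .informative import DosageTable, classify_informative_snps, compute_dc, subtype_summary
from .phasing import PhasedHaplotypes, phase_quartet
from .rhdo import RhdoCall, call_inheritance


@dataclass
class AnalysisResult:
    """Everything one RHDO run produces."""

    phased: PhasedHaplotypes = field(repr=False)
    snps: pd.DataFrame = field(repr=False)
    counts_summary: pd.DataFrame = field(repr=False)
    dosage: DosageTable = field(repr=False)
    ff: FetalFractionEstimate
    calls: list[RhdoCall]

    def call_for(self, parent: str) -> RhdoCall:
        return next(c for c in self.calls if c.parent == parent)


def analyze(
    ped: PedigreeGenotypes,
    plasma: PlasmaCounts,
    config: RunConfig,
    ff_override: Optional[float] = None,
) -> AnalysisResult:
    """Run the full RHDO pipeline on in-memory inputs.

    ``ff_override`` substitutes an externally known fetal fraction for the
    opposite-homozygote estimate (e.g. from an orthogonal assay).
    """
    phased = phase_quartet(ped, config)
    snps = classify_informative_snps(phased)
    dosage = compute_dc(
        snps,
        plasma,
        min_depth=config.min_depth,
        outlier_dc_bound=config.outlier_dc_bound,
        outlier_min_depth=config.outlier_min_depth,
    )
    if ff_override is not None:
        ff = FetalFractionEstimate(
            ff=float(ff_override),
            n_loci=0,
            per_locus=pd.DataFrame(),
            flagged=not (0.01 <= ff_override <= 0.5),
            note="externally supplied fetal fraction",
        )
    else:
        ff = estimate_ff(select_ff_loci(ped), plasma, config)
    calls = call_inheritance(dosage, ff.ff, config)
    return AnalysisResult(
        phased=phased,
        snps=snps,
        counts_summary=subtype_summary(snps),
        dosage=dosage,
        ff=ff,
        calls=calls,
    )
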