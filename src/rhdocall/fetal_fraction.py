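"""Fetal-fraction estimation from opposite-homozygote parental loci.

Where the parents are homozygous for different alleles the fetus is an
obligate heterozygote and the paternal allele is absent from the maternal
genome, so its plasma depth ``a`` is purely fetal. With ``b`` the depth of
the allele shared by fetus and mother, each locus yields

    ff_locus = 2 * a / (a + b)

and the run-level estimate is the median across usable loci (depth filter
applied), a robust choice against isolated mapping artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import FetalFractionError, PedigreeGenotypes, PlasmaCounts, join_on_sites
from .config import RunConfig


def select_ff_loci(ped: PedigreeGenotypes) -> pd.DataFrame:
    """Sites where mother and father are opposite homozygotes.

    Returns the site columns plus ``paternal_is_ref`` (True when the
    fetus-specific paternal allele is the reference base).
    """
    gm = ped.genotype("mother")
    gf = ped.genotype("father")
    opp = ((gm == 0) & (gf == 2)) | ((gm == 2) & (gf == 0))
    out = ped.df.loc[opp, ["chrom", "pos", "ref", "alt"]].copy()
    out["paternal_is_ref"] = (gf[opp] == 2)
    return out.reset_index(drop=True)


@dataclass
class FetalFractionEstimate:
    """Aggregated fetal fraction with per-locus detail."""

    ff: float
    n_loci: int
    per_locus: pd.DataFrame = field(repr=False)
    flagged: bool = False
    note: str | None = None

    def to_tsv(self, path: str | Path) -> None:
        self.per_locus.to_csv(path, sep="\t", index=False)


def estimate_ff(
    loci: pd.DataFrame, counts: PlasmaCounts, config: RunConfig
) -> FetalFractionEstimate:
    """Median per-locus fetal fraction over usable opposite-homozygote loci.

    Raises :class:`FetalFractionError` when fewer than ``min_ff_loci``
    loci pass the depth filter. Estimates outside (0.01, 0.5) are flagged
    but returned: biologically implausible values usually indicate sample
    or pipeline problems and deserve inspection rather than silence.
    """
    merged = join_on_sites(loci, counts)
    depth = merged["ref_depth"] + merged["alt_depth"]
    merged = merged[depth >= config.min_depth].copy()
    if len(merged) < config.min_ff_loci:
        raise FetalFractionError(
            f"fetal fraction not estimable: {len(merged)} usable loci "
            f"< min_ff_loci={config.min_ff_loci}"
        )
    pat_ref = merged["paternal_is_ref"].to_numpy(dtype=bool)
    a = np.where(pat_ref, merged["ref_depth"], merged["alt_depth"]).astype(float)
    b = np.where(pat_ref, merged["alt_depth"], merged["ref_depth"]).astype(float)
    merged["ff_locus"] = 2.0 * a / (a + b)

    ff = float(np.median(merged["ff_locus"]))
    flagged = not (0.01 <= ff <= 0.5)
    note = None
    if flagged:
        note = f"estimate {ff:.4f} outside plausible range (0.01, 0.5)"
    return FetalFractionEstimate(
        ff=ff, n_loci=len(merged), per_locus=merged.reset_index(drop=True),
        flagged=flagged, note=note,
    )
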