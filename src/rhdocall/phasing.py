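"""Quartet phasing of the four parental haplotypes.

The unaffected, noncarrier sibling anchors the haplotype labels: at every
site, the allele the sibling received from a parent is assigned to that
parent's wild-type haplotype (HM2 maternally, HF2 paternally), and the
parent's other allele to the pathogenic haplotype (HM1 / HF1). A site is
phased only when the decomposition of the sibling genotype into one maternal
plus one paternal allele is unique given the parental genotypes; sites with
several valid decompositions are ambiguous, sites with none are Mendelian
errors, and no statistical or population phasing is attempted.

Haplotype alleles are encoded as reference-allele indicators: 1 = ref,
0 = alt, -1 = unknown.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from .core import MISSING, InputError, PhasingError, PedigreeGenotypes

HAPLOTYPES = ("hm1", "hm2", "hf1", "hf2")
STATUSES = ("phased", "ambiguous", "mendelian_error", "missing")

_STATUS_CODE = {s: i for i, s in enumerate(STATUSES)}


def _allele_pair(g: int) -> tuple[int, int]:
    """Unordered allele pair (as ref-indicators) of a ref-count genotype."""
    return ((0, 0), (0, 1), (1, 1))[g]


def decompose_sibling(gf: int, gm: int, gs: int) -> list[tuple[int, int]]:
    """All (maternal, paternal) transmitted-allele pairs explaining gs.

    Each element of a pair is a ref-indicator (1 = ref allele). This is the
    elementary transmission rule; :func:`phase_quartet` applies its
    tabulated form to every site.
    """
    out = set()
    for m in set(_allele_pair(gm)):
        for f in set(_allele_pair(gf)):
            if m + f == gs:
                out.add((m, f))
    return sorted(out)


@lru_cache(maxsize=1)
def _transmission_table() -> np.ndarray:
    """Lookup [gf, gm, gs] -> (status_code, hm1, hm2, hf1, hf2)."""
    tbl = np.full((3, 3, 3, 5), MISSING, dtype=np.int8)
    for gf in range(3):
        for gm in range(3):
            for gs in range(3):
                dec = decompose_sibling(gf, gm, gs)
                if len(dec) == 0:
                    tbl[gf, gm, gs, 0] = _STATUS_CODE["mendelian_error"]
                elif len(dec) > 1:
                    tbl[gf, gm, gs, 0] = _STATUS_CODE["ambiguous"]
                else:
                    m, f = dec[0]
                    # sibling-transmitted allele -> wild-type haplotype
                    tbl[gf, gm, gs] = (
                        _STATUS_CODE["phased"],
                        gm - m,  # hm1: mother's other allele
                        m,       # hm2
                        gf - f,  # hf1: father's other allele
                        f,       # hf2
                    )
    return tbl


@dataclass
class PhasedHaplotypes:
    """Per-site alleles of HM1/HM2/HF1/HF2 with a phasing status.

    ``df`` columns: chrom, pos, ref, alt, hm1, hm2, hf1, hf2, status.
    Haplotype columns are ref-indicators (1/0) or -1 where unknown
    (ambiguous, Mendelian-error or missing sites).
    """

    df: pd.DataFrame

    @property
    def n_phased(self) -> int:
        return int((self.df["status"] == "phased").sum())

    def haplotype(self, name: str) -> np.ndarray:
        if name.lower() not in HAPLOTYPES:
            raise InputError(f"unknown haplotype {name!r}")
        return self.df[name.lower()].to_numpy(dtype=np.int8)

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def phase_quartet(ped: PedigreeGenotypes, config=None) -> PhasedHaplotypes:
    """Phase every site of a quartet genotype table.

    Deterministic given genotypes. Sites with any missing genotype are
    marked ``missing``. Raises :class:`PhasingError` when no site at all
    can be phased.
    """
    gf = ped.genotype("father")
    gm = ped.genotype("mother")
    gs = ped.genotype("sibling")
    n = len(gf)

    status = np.full(n, _STATUS_CODE["missing"], dtype=np.int8)
    haps = np.full((n, 4), MISSING, dtype=np.int8)

    ok = (gf >= 0) & (gm >= 0) & (gs >= 0)
    if ok.any():
        tbl = _transmission_table()
        rows = tbl[gf[ok], gm[ok], gs[ok]]
        status[ok] = rows[:, 0]
        haps[ok] = rows[:, 1:]

    df = ped.df[["chrom", "pos", "ref", "alt"]].copy()
    for i, h in enumerate(HAPLOTYPES):
        df[h] = haps[:, i]
    df["status"] = pd.Categorical.from_codes(status, categories=list(STATUSES))

    phased = PhasedHaplotypes(df)
    if phased.n_phased == 0:
        raise PhasingError("insufficient phasing information: 0 phaseable sites")
    return phased


@dataclass
class HaplotypeIdentity:
    """Pairwise allele identity between two haplotypes over shared sites."""

    n_compared: int
    n_identical: int

    @property
    def fraction(self) -> float:
        return self.n_identical / self.n_compared


def haplotype_identity(hap_a: np.ndarray, hap_b: np.ndarray) -> HaplotypeIdentity:
    """Fraction of sites (known in both haplotypes) carrying equal alleles."""
    a = np.asarray(hap_a)
    b = np.asarray(hap_b)
    if a.shape != b.shape:
        raise InputError("haplotypes must cover the same site set")
    known = (a != MISSING) & (b != MISSING)
    n = int(known.sum())
    if n == 0:
        raise InputError("identity undefined: no site known in both haplotypes")
    return HaplotypeIdentity(n_compared=n, n_identical=int((a[known] == b[known]).sum()))
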