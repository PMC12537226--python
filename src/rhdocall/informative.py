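"""Informative-SNP classification and per-site dosage change.

An informative SNP is heterozygous in one parent and homozygous in the
other. Maternal-informative sites (mother het, father hom) are Type 1 when
the father's homozygous allele matches the maternal pathogenic haplotype
HM1 (marker allele = HM1's allele) and Type 2 when it matches HM2 (marker =
HM2's allele). Paternal-informative sites (father het, mother hom) are
Type 3 when the mother's allele matches HF2 (marker = HF1's allele) and
Type 4 when it matches HF1 (marker = HF2's allele). The marker allele is
the one whose plasma frequency rises by ff/2 when the type's haplotype is
inherited by the fetus; each type is further stratified into a ``_ref`` or
``_alt`` subtype according to whether the marker allele is the reference
or the alternative base.

The dosage change (DC) of a site is the observed plasma reference-allele
frequency minus its fetus-independent baseline — the maternal
reference-allele dosage g_mother/2 (0.5 for Types 1–2; 0 or 1 for
Types 3–4). When the type's haplotype is inherited the expected DC is
+ff/2 at ref-marker sites and -ff/2 at alt-marker sites; otherwise 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import InputError, PlasmaCounts, join_on_sites
from .phasing import PhasedHaplotypes

#: marker-allele encoding: 1 = reference, 0 = alternative
REF, ALT = 1, 0

SNP_TYPES = (1, 2, 3, 4)
#: pathogenic-linked vs wild-type-linked types, per parent
PARENT_TYPES = {"maternal": (1, 2), "paternal": (3, 4)}


def classify_site(hm1: int, hm2: int, hf1: int, hf2: int) -> tuple[int, int] | None:
    """Classify one phased site; returns (snp_type, marker_allele) or None.

    Raises if any haplotype allele is unknown (unphased site).
    """
    if min(hm1, hm2, hf1, hf2) < 0:
        raise InputError("cannot classify an unphased site")
    if hm1 != hm2 and hf1 == hf2:  # maternal-informative
        return (1, hm1) if hf1 == hm1 else (2, hm2)
    if hf1 != hf2 and hm1 == hm2:  # paternal-informative
        return (3, hf1) if hm1 == hf2 else (4, hf2)
    return None


def classify_informative_snps(phased: PhasedHaplotypes) -> pd.DataFrame:
    """Classify all phased sites into informative SNP types and subtypes.

    Returns a table with columns chrom, pos, ref, alt, snp_type,
    marker_allele (1=ref/0=alt), subtype ("typeN_ref"/"typeN_alt") and
    baseline_e0 (expected plasma ref frequency absent inheritance of the
    type's haplotype). Non-informative phased sites are excluded; sites
    that are not phased do not enter classification at all.
    """
    df = phased.df
    ph = df[df["status"] == "phased"]
    hm1 = ph["hm1"].to_numpy()
    hm2 = ph["hm2"].to_numpy()
    hf1 = ph["hf1"].to_numpy()
    hf2 = ph["hf2"].to_numpy()

    mat = (hm1 != hm2) & (hf1 == hf2)
    pat = (hf1 != hf2) & (hm1 == hm2)

    snp_type = np.zeros(len(ph), dtype=np.int8)
    marker = np.full(len(ph), -1, dtype=np.int8)

    t1 = mat & (hf1 == hm1)
    t2 = mat & (hf1 == hm2)
    t3 = pat & (hm1 == hf2)
    t4 = pat & (hm1 == hf1)
    for t, mask, mk in ((1, t1, hm1), (2, t2, hm2), (3, t3, hf1), (4, t4, hf2)):
        snp_type[mask] = t
        marker[mask] = mk[mask]

    out = ph[["chrom", "pos", "ref", "alt"]].copy()
    out["snp_type"] = snp_type
    out["marker_allele"] = marker
    out["baseline_e0"] = (hm1 + hm2) / 2.0
    out = out[out["snp_type"] > 0].reset_index(drop=True)
    out["subtype"] = [
        f"type{t}_{'ref' if m == REF else 'alt'}"
        for t, m in zip(out["snp_type"], out["marker_allele"])
    ]
    return out


def ref_share_pct(n_ref: int, n_alt: int) -> float:
    """Percentage of a type's loci whose marker is the reference allele."""
    total = n_ref + n_alt
    if total == 0:
        return float("nan")
    return 100.0 * n_ref / total


def subtype_summary(snps: pd.DataFrame) -> pd.DataFrame:
    """Per-type counts of ref/alt subtypes and the ref share in percent.

    An empty type yields NaN for the share (reported as missing).
    """
    rows = []
    for t in SNP_TYPES:
        sub = snps[snps["snp_type"] == t]
        n_ref = int((sub["marker_allele"] == REF).sum())
        n_alt = int((sub["marker_allele"] == ALT).sum())
        rows.append(
            {
                "snp_type": t,
                "n_ref": n_ref,
                "n_alt": n_alt,
                "n_total": n_ref + n_alt,
                "ref_share_pct": ref_share_pct(n_ref, n_alt),
            }
        )
    return pd.DataFrame(rows).set_index("snp_type")


@dataclass
class DosageTable:
    """Per-site dosage observations plus exclusion bookkeeping.

    ``df`` adds to the informative-SNP columns: ref_depth, alt_depth,
    depth, ref_freq and dc (= ref_freq - baseline_e0).
    """

    df: pd.DataFrame
    n_excluded_depth: int
    n_excluded_outlier: int
    n_unmatched: int

    def of_type(self, snp_type: int) -> pd.DataFrame:
        return self.df[self.df["snp_type"] == snp_type]

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def compute_dc(
    snps: pd.DataFrame,
    counts: PlasmaCounts,
    *,
    min_depth: int = 50,
    outlier_dc_bound: float = 0.5,
    outlier_min_depth: int = 100,
) -> DosageTable:
    """Join informative SNPs with plasma counts and compute per-site DC.

    Sites below ``min_depth`` total plasma reads are excluded, as are
    apparent-artifact sites with |dc| > ``outlier_dc_bound`` at depth >=
    ``outlier_min_depth``; both exclusions are counted in the result.
    """
    merged = join_on_sites(snps, counts)
    n_unmatched = len(snps) - len(merged)
    depth = (merged["ref_depth"] + merged["alt_depth"]).to_numpy(dtype=np.int64)
    merged["depth"] = depth

    low = depth < min_depth
    n_excl_depth = int(low.sum())
    merged = merged[~low].copy()

    merged["ref_freq"] = merged["ref_depth"] / merged["depth"]
    merged["dc"] = merged["ref_freq"] - merged["baseline_e0"]

    outlier = (merged["dc"].abs() > outlier_dc_bound) & (
        merged["depth"] >= outlier_min_depth
    )
    n_excl_out = int(outlier.sum())
    merged = merged[~outlier].reset_index(drop=True)

    return DosageTable(
        df=merged,
        n_excluded_depth=n_excl_depth,
        n_excluded_outlier=n_excl_out,
        n_unmatched=n_unmatched,
    )
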