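"""Reading and writing the standard formats around the pipeline.

Quartet genotypes come from a multi-sample VCF 4.x (read with cyvcf2);
plasma allele depths from a TSV dialect (tab-separated, header line,
columns chrom, pos, ref, alt, ref_depth, alt_depth) or from a
single-sample VCF carrying per-allele depths (AD). Results go out as a
JSON report plus a per-type TSV; both re-parse losslessly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import (
    MISSING,
    ROLES,
    InputError,
    ConfigError,
    PedigreeGenotypes,
    PlasmaCounts,
    validate_site_table,
)
from .config import RunConfig

logger = logging.getLogger(__name__)

PLASMA_COLUMNS = ["chrom", "pos", "ref", "alt", "ref_depth", "alt_depth"]


def _ref_count(genotype: list) -> int:
    """cyvcf2 genotype [a0, a1, phased] -> reference-allele count or -1."""
    alleles = genotype[:-1]
    if len(alleles) != 2 or any(a < 0 for a in alleles):
        return MISSING
    return int(sum(a == 0 for a in alleles))


def read_quartet_vcf(path: str | Path, config: RunConfig) -> PedigreeGenotypes:
    """Read father/mother/sibling genotypes for the configured region.

    Keeps biallelic SNVs within ``region ± flank_bp``; multiallelic,
    symbolic and indel records are skipped with a logged count. Missing
    genotypes are preserved as missing. An unsorted VCF is an error.
    """
    vcf = VCF(str(path))
    sample_index = {}
    for role in ROLES:
        name = getattr(config.samples, role)
        if name not in vcf.samples:
            raise ConfigError(
                f"sample {name!r} (role {role}) not found in {path}; "
                f"VCF samples: {vcf.samples}"
            )
        sample_index[role] = vcf.samples.index(name)

    region = config.region
    lo = max(1, region.start - config.flank_bp)
    hi = region.end + config.flank_bp

    rows = []
    n_skipped = 0
    last_pos = None
    last_chrom = None
    for var in vcf:
        if var.CHROM == last_chrom and var.POS < last_pos:
            raise InputError(f"unsorted VCF: {var.CHROM}:{var.POS} after {last_pos}")
        last_chrom, last_pos = var.CHROM, var.POS
        if var.CHROM != region.chrom or not (lo <= var.POS <= hi):
            continue
        if (
            len(var.ALT) != 1
            or len(var.REF) != 1
            or len(var.ALT[0]) != 1
            or var.ALT[0] not in "ACGT"
            or var.REF not in "ACGT"
        ):
            n_skipped += 1
            continue
        gts = var.genotypes
        rows.append(
            {
                "chrom": var.CHROM,
                "pos": var.POS,
                "ref": var.REF,
                "alt": var.ALT[0],
                **{role: _ref_count(gts[idx]) for role, idx in sample_index.items()},
            }
        )
    if n_skipped:
        logger.info("skipped %d non-biallelic/non-SNV records", n_skipped)
    if not rows:
        raise InputError(
            f"no biallelic SNVs in {region.chrom}:{lo}-{hi} of {path}"
        )
    df = pd.DataFrame(rows).sort_values(["chrom", "pos"]).reset_index(drop=True)
    return PedigreeGenotypes(df)


def write_quartet_vcf(
    ped: PedigreeGenotypes, path: str | Path, config: RunConfig
) -> None:
    """Write quartet genotypes as a minimal sorted VCF 4.2."""
    names = [getattr(config.samples, role) for role in ROLES]
    gt_map = {2: "0/0", 1: "0/1", 0: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(ped.df["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(names)
            + "\n"
        )
        for row in ped.df.itertuples(index=False):
            gts = "\t".join(gt_map[getattr(row, role)] for role in ROLES)
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_plasma_counts(path: str | Path) -> PlasmaCounts:
    """Read plasma allele depths from TSV (canonical) or VCF-with-AD."""
    path = Path(path)
    if path.suffix in {".vcf", ".gz", ".bcf"}:
        return _read_plasma_vcf(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    missing = [c for c in PLASMA_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"plasma TSV {path} missing columns {missing}")
    df = df[PLASMA_COLUMNS]
    n_zero = int(((df["ref_depth"] + df["alt_depth"]) == 0).sum())
    if n_zero:
        logger.info("%d plasma sites have total depth 0 (kept, flagged)", n_zero)
    return PlasmaCounts(df)


def _read_plasma_vcf(path: Path) -> PlasmaCounts:
    vcf = VCF(str(path))
    if len(vcf.samples) < 1:
        raise InputError(f"plasma VCF {path} has no sample column")
    rows = []
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            continue
        ad = var.format("AD")
        if ad is None:
            raise InputError(f"plasma VCF {path} lacks AD format field")
        ref_d, alt_d = int(ad[0][0]), int(ad[0][1])
        rows.append(
            {
                "chrom": var.CHROM,
                "pos": var.POS,
                "ref": var.REF,
                "alt": var.ALT[0],
                "ref_depth": max(ref_d, 0),
                "alt_depth": max(alt_d, 0),
            }
        )
    return PlasmaCounts(pd.DataFrame(rows, columns=PLASMA_COLUMNS))


def write_plasma_counts(counts: PlasmaCounts, path: str | Path) -> None:
    """Write plasma depths in the canonical TSV dialect."""
    counts.df[PLASMA_COLUMNS].to_csv(path, sep="\t", index=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_report(calls, ff, counts_summary: pd.DataFrame, path: str | Path) -> dict:
    """Write the machine-readable result report.

    ``path`` names the JSON file; a sibling TSV (same stem, ``.tsv``) holds
    one row per parent x analysed type. Returns the report dict.
    """
    path = Path(path)
    report = {
        "fetal_fraction": {
            "ff": ff.ff,
            "n_loci": ff.n_loci,
            "flagged": ff.flagged,
            "note": ff.note,
        },
        "snp_counts": {
            f"type{t}_{sub}": int(counts_summary.loc[t, f"n_{sub}"])
            for t in counts_summary.index
            for sub in ("ref", "alt")
        },
        "calls": [c.to_dict() for c in calls],
    }
    with open(path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=2)
        fh.write("\n")

    rows = []
    for call in calls:
        for t, m in sorted(call.models.items()):
            label = call.call
            if not m.computable:
                label = "no-call (insufficient SNPs)"
            rows.append(
                {
                    "parent": call.parent,
                    "snp_type": t,
                    "n_ref": m.n_ref,
                    "n_alt": m.n_alt,
                    "d_stat": m.d_stat,
                    "sigma": m.sigma,
                    "log10_bf": m.log10_bf,
                    "computable": m.computable,
                    "combined_log10_bf": call.combined_log10_bf,
                    "call": label,
                }
            )
    pd.DataFrame(rows).to_csv(path.with_suffix(".tsv"), sep="\t", index=False)
    return report


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_truth_json(truth, path: str | Path) -> None:
    """Serialize a simulation's generative truth for fixture triples."""
    payload = {
        "config": truth.config.model_dump(),
        "maternal_inherited": truth.config.maternal_inherited,
        "paternal_inherited": truth.config.paternal_inherited,
        "haplotypes": {
            h: truth.df[h].astype(int).tolist() for h in ("hm1", "hm2", "hf1", "hf2")
        },
        "pos": truth.df["pos"].astype(int).tolist(),
    }
    with open(path, "w") as fh:
        json.dump(_jsonable(payload), fh)
        fh.write("\n")
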