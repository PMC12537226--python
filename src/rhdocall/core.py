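"""Core site tables and exceptions shared by every pipeline stage.

All coordinates are 1-based inclusive (VCF convention). Genotypes are stored
as reference-allele counts in {0, 1, 2}, with -1 for missing. Joins between
the genotype table and the plasma-count table are always exact on
(chrom, pos, ref, alt), never positional-only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: sentinel for a missing genotype / unknown haplotype allele
MISSING = -1

#: pedigree roles, in canonical column order
ROLES = ("father", "mother", "sibling")

#: the exact-join key between genotype and plasma tables
SITE_KEY = ["chrom", "pos", "ref", "alt"]

_BASES = frozenset("ACGT")


class RhdoError(Exception):
    """Base class for all package errors."""


class ConfigError(RhdoError):
    """Invalid or inconsistent run configuration."""


class InputError(RhdoError):
    """Malformed or inconsistent input data."""


class PhasingError(RhdoError):
    """Quartet phasing cannot proceed (e.g. zero phaseable sites)."""


class FetalFractionError(RhdoError):
    """Fetal fraction not estimable from the available loci."""


def validate_site_table(df: pd.DataFrame) -> None:
    """Validate the shared site-table contract.

    Requires columns chrom/pos/ref/alt, 1-based positions, single-base
    biallelic ref != alt, and strictly increasing position within each
    contiguous chromosome block.
    """
    for col in SITE_KEY:
        if col not in df.columns:
            raise InputError(f"site table missing column {col!r}")
    if len(df) == 0:
        return
    if (df["pos"] < 1).any():
        raise InputError("positions must be >= 1 (1-based convention)")
    ref = df["ref"].astype(str)
    alt = df["alt"].astype(str)
    if not ((ref.str.len() == 1) & (alt.str.len() == 1)).all():
        raise InputError("only single-base SNVs are supported")
    bad = ~(ref.isin(_BASES) & alt.isin(_BASES))
    if bad.any():
        row = df[bad].iloc[0]
        raise InputError(f"non-ACGT allele at {row['chrom']}:{row['pos']}")
    if (ref == alt).any():
        row = df[ref == alt].iloc[0]
        raise InputError(f"ref == alt at {row['chrom']}:{row['pos']}")
    # strictly increasing pos within chromosome, chromosomes contiguous
    chrom = df["chrom"].to_numpy()
    pos = df["pos"].to_numpy()
    same = chrom[1:] == chrom[:-1]
    if (same & (pos[1:] <= pos[:-1])).any():
        raise InputError("sites not strictly sorted by (chrom, pos)")
    seen: set[str] = set()
    last = None
    for c in chrom:
        if c != last:
            if c in seen:
                raise InputError(f"chromosome {c} appears in two blocks")
            seen.add(c)
            last = c


@dataclass
class PedigreeGenotypes:
    """Quartet genotype table.

    ``df`` columns: chrom, pos, ref, alt, father, mother, sibling.
    Role columns hold reference-allele counts in {0, 1, 2} or -1 (missing).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        validate_site_table(self.df)
        for role in ROLES:
            if role not in self.df.columns:
                raise InputError(f"genotype table missing role column {role!r}")
            g = self.df[role].to_numpy()
            if not np.isin(g, (-1, 0, 1, 2)).all():
                raise InputError(f"{role} genotypes must be in {{-1,0,1,2}}")
        self.df = self.df.reset_index(drop=True)

    @property
    def n_sites(self) -> int:
        return len(self.df)

    def genotype(self, role: str) -> np.ndarray:
        return self.df[role].to_numpy(dtype=np.int8)

    def equals(self, other: "PedigreeGenotypes") -> bool:
        cols = SITE_KEY + list(ROLES)
        a = self.df[cols].reset_index(drop=True)
        b = other.df[cols].reset_index(drop=True)
        return a.equals(b.astype(a.dtypes.to_dict()))


@dataclass
class PlasmaCounts:
    """Per-SNP cfDNA allele depths from maternal plasma.

    ``df`` columns: chrom, pos, ref, alt, ref_depth, alt_depth. Rows with
    total depth 0 are retained (flagged downstream by the depth filter).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        validate_site_table(self.df)
        for col in ("ref_depth", "alt_depth"):
            if col not in self.df.columns:
                raise InputError(f"plasma table missing column {col!r}")
            d = self.df[col].to_numpy()
            if (d < 0).any():
                row = self.df[self.df[col] < 0].iloc[0]
                raise InputError(
                    f"negative {col} at {row['chrom']}:{row['pos']}"
                )
        self.df = self.df.reset_index(drop=True)

    @property
    def n_sites(self) -> int:
        return len(self.df)

    def equals(self, other: "PlasmaCounts") -> bool:
        cols = SITE_KEY + ["ref_depth", "alt_depth"]
        a = self.df[cols].reset_index(drop=True)
        b = other.df[cols].reset_index(drop=True)
        return a.equals(b.astype(a.dtypes.to_dict()))


def join_on_sites(sites: pd.DataFrame, plasma: PlasmaCounts) -> pd.DataFrame:
    """Inner-join a site table with plasma counts, exact on the full key.

    A (chrom, pos) match whose ref/alt disagree is an error naming the
    site — allele identity is part of the join contract.
    """
    merged = sites.merge(
        plasma.df, on=["chrom", "pos"], how="inner", suffixes=("", "_plasma")
    )
    bad = (merged["ref"] != merged["ref_plasma"]) | (
        merged["alt"] != merged["alt_plasma"]
    )
    if bad.any():
        row = merged[bad].iloc[0]
        raise InputError(
            f"ref/alt mismatch at {row['chrom']}:{row['pos']}: genotypes "
            f"{row['ref']}>{row['alt']} vs plasma "
            f"{row['ref_plasma']}>{row['alt_plasma']}"
        )
    return merged.drop(columns=["ref_plasma", "alt_plasma"])
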