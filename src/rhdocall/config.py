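"""Run configuration: sample roles, target region, filters and thresholds.

The YAML config file is the source of truth for a run; CLI flags override
individual keys. Thresholds here are deliberately conservative defaults for
targeted-capture cfDNA data and are all user-configurable.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, ValidationError, model_validator

from .core import ConfigError


class Region(BaseModel):
    """Pathogenic target region, 1-based inclusive."""

    chrom: str
    start: int = Field(ge=1)
    end: int = Field(ge=1)

    @model_validator(mode="after")
    def _ordered(self) -> "Region":
        if self.start > self.end:
            raise ValueError("region start must be <= end")
        return self


class SampleRoles(BaseModel):
    """VCF sample names for the three pedigree roles."""

    father: str
    mother: str
    sibling: str


class RunConfig(BaseModel):
    """Full analysis configuration.

    Attributes
    ----------
    samples:
        VCF sample-name mapping for father, mother and the unaffected
        (noncarrier) sibling used as the phasing anchor.
    region:
        Pathogenic locus region; SNPs within ``flank_bp`` of it are analysed.
    mother_is_carrier, father_is_carrier:
        Carrier-status assertions. The pathogenic variant itself (often a
        structural allele invisible to SNP logic) enters the analysis only
        through these assertions.
    min_depth:
        Minimum plasma depth for a site to contribute to dosage statistics
        or fetal-fraction estimation (reads).
    min_ff_loci:
        Minimum usable opposite-homozygote loci for a fetal-fraction
        estimate.
    min_subgroup_snps:
        Minimum SNPs per ref/alt subgroup (or per type, classic mode) for a
        Bayes factor to be computable.
    log10_bf_threshold:
        |combined log10 BF| at or above which an inheritance call is made.
    outlier_dc_bound, outlier_min_depth:
        A site with |dosage change| > bound at depth >= outlier_min_depth is
        excluded as a genotyping/mapping artifact.
    block_size:
        Optional fixed SNP count per analysis block; None = single block
        over the whole region.
    """

    samples: SampleRoles
    region: Region
    flank_bp: int = Field(default=1_000_000, ge=0)
    mother_is_carrier: bool = True
    father_is_carrier: bool = True
    min_depth: int = Field(default=50, ge=1)
    min_ff_loci: int = Field(default=20, ge=1)
    min_subgroup_snps: int = Field(default=10, ge=1)
    log10_bf_threshold: float = Field(default=2.0, gt=0)
    outlier_dc_bound: float = Field(default=0.5, gt=0)
    outlier_min_depth: int = Field(default=100, ge=1)
    block_size: Optional[int] = Field(default=None, ge=2)
    seed: Optional[int] = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            with open(path) as fh:
                data = yaml.safe_load(fh)
            return cls.model_validate(data)
        except (ValidationError, yaml.YAMLError) as exc:
            raise ConfigError(f"invalid run config {path}: {exc}") from exc

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)
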