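"""Synthetic pedigree and plasma generator with known generative truth.

The generator reproduces the statistical structure the method assumes: four
parental haplotypes drawn from a population reference-allele frequency,
with the paternal pathogenic haplotype HF1 copying the maternal pathogenic
haplotype HM1 site-wise with a configurable identity probability (the
regime of interest is near-identical pathogenic haplotypes, ~0.98); a
noncarrier sibling who received HM2 and HF2; a fetal inheritance truth; and
plasma read counts that are binomial around the maternal/fetal mixture
frequency

    p = (1 - ff) * g_mother/2 + ff * g_fetus/2,

optionally skewed by a multiplicative reference-allele capture-enrichment
factor beta, p' = p (1 + beta) / (1 + p beta). Depth is Poisson. Genotypes
are emitted error-free: parental gDNA is sequenced deeply in practice, and
genotype-error robustness is a phasing concern, exercised separately by
injecting flips.

Capture assays for this application carry a dedicated panel of common SNPs
for fetal-fraction estimation, unlinked to the pathogenic haplotypes. The
generator emulates the usable part of such a panel: ``n_ff_snps`` extra
sites at which the parents are opposite homozygotes by construction
(which parent is ref-homozygous is random). These sites are appended after
the target SNPs, flagged ``is_ff_panel`` in the truth table, and can never
be informative SNPs (both parents homozygous), so they do not perturb the
type counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .core import ConfigError, PedigreeGenotypes, PlasmaCounts
from .config import Region, RunConfig, SampleRoles

_BASES = np.array(list("ACGT"))


class SimulationConfig(BaseModel):
    """Generative-truth description of one synthetic pedigree + plasma run.

    ``hm1_hf1_identity`` is the per-site probability that HF1 copies HM1's
    allele; ``capture_bias_beta`` the multiplicative ref-read enrichment.
    The same seed always yields byte-identical outputs.
    """

    n_snps: int = Field(default=2000, ge=1)
    n_ff_snps: int = Field(default=200, ge=0)
    ref_allele_freq: Union[float, Sequence[float]] = 0.5
    hm1_hf1_identity: float = Field(default=0.9797, ge=0.0, le=1.0)
    ff_true: float = Field(default=0.10, gt=0.0, le=0.5)
    plasma_depth_mean: float = Field(default=1000.0, gt=0.0)
    capture_bias_beta: float = Field(default=0.0, ge=-0.9)
    maternal_inherited: Literal["HM1", "HM2"] = "HM1"
    paternal_inherited: Literal["HF1", "HF2"] = "HF2"
    chrom: str = "chr6"
    start_pos: int = Field(default=31_000_000, ge=1)
    pos_step: int = Field(default=1000, ge=1)
    seed: int = 0

    @model_validator(mode="after")
    def _freq_valid(self) -> "SimulationConfig":
        p = np.atleast_1d(np.asarray(self.ref_allele_freq, dtype=float))
        if ((p < 0) | (p > 1)).any():
            raise ValueError("ref_allele_freq must lie in [0, 1]")
        if p.size not in (1, self.n_snps):
            raise ValueError("per-site ref_allele_freq must have length n_snps")
        return self

    def run_config(self) -> RunConfig:
        """A RunConfig whose region covers every simulated site."""
        end = self.start_pos + (self.n_snps + self.n_ff_snps - 1) * self.pos_step
        return RunConfig(
            samples=SampleRoles(father="FATHER", mother="MOTHER", sibling="SIBLING"),
            region=Region(chrom=self.chrom, start=self.start_pos, end=end),
            flank_bp=0,
            seed=self.seed,
        )


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per stage from the one user seed
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(stream,)))


@dataclass
class SimulatedTruth:
    """Per-site generative truth backing one simulated run.

    ``df`` columns: chrom, pos, ref, alt; hm1/hm2/hf1/hf2 (ref-indicators);
    fetal_m, fetal_f (transmitted alleles per truth); p_plasma (mixture ref
    frequency) and p_biased (after capture enrichment).
    """

    df: pd.DataFrame = field(repr=False)
    config: SimulationConfig

    def haplotype(self, name: str, *, target_only: bool = False) -> np.ndarray:
        col = self.df[name.lower()]
        if target_only:
            col = col[~self.df["is_ff_panel"]]
        return col.to_numpy(dtype=np.int8)

    @property
    def target_mask(self) -> np.ndarray:
        return (~self.df["is_ff_panel"]).to_numpy()


def simulate_quartet(cfg: SimulationConfig) -> tuple[SimulatedTruth, PedigreeGenotypes]:
    """Draw the four parental haplotypes and emit unphased quartet genotypes.

    HM1, HM2 and HF2 are independent Bernoulli(ref_allele_freq) draws per
    site; HF1 copies HM1 with probability ``hm1_hf1_identity`` and is an
    independent population draw otherwise. The sibling carries HM2 + HF2
    (noncarrier); fetal transmitted alleles follow the configured truth.
    """
    rng = _rng(cfg, 0)
    nt = cfg.n_snps
    nf = cfg.n_ff_snps
    n = nt + nf
    p = np.broadcast_to(
        np.atleast_1d(np.asarray(cfg.ref_allele_freq, dtype=float)), (nt,)
    )

    hm1 = (rng.random(nt) < p).astype(np.int8)
    hm2 = (rng.random(nt) < p).astype(np.int8)
    hf2 = (rng.random(nt) < p).astype(np.int8)
    copy = rng.random(nt) < cfg.hm1_hf1_identity
    hf1 = np.where(copy, hm1, (rng.random(nt) < p).astype(np.int8)).astype(np.int8)

    # fetal-fraction panel: parents opposite homozygotes by construction
    mother_ref = rng.random(nf) < 0.5
    fm = np.where(mother_ref, 1, 0).astype(np.int8)
    ff_pat = (1 - fm).astype(np.int8)
    hm1 = np.concatenate([hm1, fm])
    hm2 = np.concatenate([hm2, fm])
    hf1 = np.concatenate([hf1, ff_pat])
    hf2 = np.concatenate([hf2, ff_pat])
    is_ff_panel = np.concatenate(
        [np.zeros(nt, dtype=bool), np.ones(nf, dtype=bool)]
    )

    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4

    fetal_m = hm1 if cfg.maternal_inherited == "HM1" else hm2
    fetal_f = hf1 if cfg.paternal_inherited == "HF1" else hf2

    g_mother = hm1 + hm2
    p_plasma = (1 - cfg.ff_true) * g_mother / 2.0 + cfg.ff_true * (
        fetal_m + fetal_f
    ) / 2.0
    beta = cfg.capture_bias_beta
    p_biased = p_plasma * (1 + beta) / (1 + p_plasma * beta)

    pos = cfg.start_pos + cfg.pos_step * np.arange(n)
    df = pd.DataFrame(
        {
            "chrom": cfg.chrom,
            "pos": pos,
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
            "hm1": hm1,
            "hm2": hm2,
            "hf1": hf1,
            "hf2": hf2,
            "fetal_m": fetal_m,
            "fetal_f": fetal_f,
            "p_plasma": p_plasma,
            "p_biased": p_biased,
            "is_ff_panel": is_ff_panel,
        }
    )
    truth = SimulatedTruth(df=df, config=cfg)

    ped = PedigreeGenotypes(
        pd.DataFrame(
            {
                "chrom": cfg.chrom,
                "pos": pos,
                "ref": df["ref"],
                "alt": df["alt"],
                "father": (hf1 + hf2).astype(np.int8),
                "mother": g_mother.astype(np.int8),
                "sibling": (hm2 + hf2).astype(np.int8),
            }
        )
    )
    return truth, ped


def simulate_plasma(truth: SimulatedTruth, cfg: Optional[SimulationConfig] = None) -> PlasmaCounts:
    """Draw plasma depths (Poisson) and ref counts (binomial at p_biased)."""
    cfg = cfg or truth.config
    rng = _rng(cfg, 1)
    n = len(truth.df)
    depth = rng.poisson(cfg.plasma_depth_mean, size=n)
    ref_depth = rng.binomial(depth, truth.df["p_biased"].to_numpy())
    return PlasmaCounts(
        pd.DataFrame(
            {
                "chrom": truth.df["chrom"],
                "pos": truth.df["pos"],
                "ref": truth.df["ref"],
                "alt": truth.df["alt"],
                "ref_depth": ref_depth,
                "alt_depth": depth - ref_depth,
            }
        )
    )


@dataclass
class ScenarioResult:
    """End-to-end result of one simulated scenario, with truth comparison."""

    truth: SimulatedTruth
    ped: PedigreeGenotypes
    plasma: PlasmaCounts
    analysis: "AnalysisResult"
    expected_calls: dict[str, str]
    maternal_correct: bool
    paternal_correct: bool


def expected_call(cfg: SimulationConfig, parent: str) -> str:
    if parent == "maternal":
        return (
            "pathogenic_inherited"
            if cfg.maternal_inherited == "HM1"
            else "wildtype_inherited"
        )
    return (
        "pathogenic_inherited"
        if cfg.paternal_inherited == "HF1"
        else "wildtype_inherited"
    )


def run_scenario(
    cfg: SimulationConfig, run_config: Optional[RunConfig] = None
) -> ScenarioResult:
    """simulate -> phase -> classify -> ff-estimate -> call, plus truth flags."""
    from .pipeline import analyze  # late import to avoid a cycle

    truth, ped = simulate_quartet(cfg)
    plasma = simulate_plasma(truth, cfg)
    rc = run_config or cfg.run_config()
    analysis = analyze(ped, plasma, rc)
    expected = {p: expected_call(cfg, p) for p in ("maternal", "paternal")}
    got = {c.parent: c.call for c in analysis.calls}
    return ScenarioResult(
        truth=truth,
        ped=ped,
        plasma=plasma,
        analysis=analysis,
        expected_calls=expected,
        maternal_correct=got["maternal"] == expected["maternal"],
        paternal_correct=got["paternal"] == expected["paternal"],
    )
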