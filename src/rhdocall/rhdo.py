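"""Bayes-factor inference of fetal haplotype inheritance.

Two routes are provided. The classic route contrasts the dosage signal of a
type with that of its partner type on the other parental haplotype
(Type 1 vs 2 maternally, 3 vs 4 paternally); it fails when one type has
too few SNPs, as happens when the parents' pathogenic haplotypes are
nearly identical. The split route instead contrasts the ref-marker and
alt-marker subgroups *within one type*: when the type's haplotype is
inherited, the reference-allele frequency rises by ff/2 at ref-marker
sites and falls by ff/2 at alt-marker sites, so the subgroup-mean DC
difference is centred on ff under H1 ("type's haplotype inherited") and on
0 under H2. Because both subgroups use reference-allele frequencies, a
capture-induced shift common to all sites cancels in the difference.

The sampling model for the difference-of-subgroup-means statistic D is
Gaussian with variance propagated from per-site binomial read sampling:
var(D) = sum_ref v_i / n_ref^2 + sum_alt v_i / n_alt^2, where
v_i = p_i (1 - p_i) / depth_i. The binomial variance is evaluated at the
midpoint of each site's H1 and H2 expected frequencies (baseline ± ff/4),
which is strictly inside (0, 1) for every type — evaluating at the H2
baseline alone would degenerate to zero variance at paternal-informative
sites, whose baseline is 0 or 1. The Bayes factor is the ratio of the two
Gaussian densities at the observed D, computed in log space and clamped to
|log10 BF| <= 300.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .core import InputError
from .config import RunConfig
from .informative import PARENT_TYPES, REF, DosageTable

#: |log10 BF| clamp; 1e±300 brackets the double-precision underflow boundary
LOG10_BF_CLAMP = 300.0

_LN10 = math.log(10.0)


def gaussian_log10_bf(d: float, mu_h1: float, mu_h2: float, sigma: float) -> float:
    """log10 of N(d; mu_h1, sigma) / N(d; mu_h2, sigma), clamped to ±300."""
    if sigma <= 0:
        raise InputError("sigma must be positive")
    ln_bf = ((d - mu_h2) ** 2 - (d - mu_h1) ** 2) / (2.0 * sigma**2)
    return float(np.clip(ln_bf / _LN10, -LOG10_BF_CLAMP, LOG10_BF_CLAMP))


@dataclass
class BfModel:
    """One type's Bayes-factor computation (split or classic route).

    H1 = "the fetus inherited the haplotype this type marks";
    H2 = "it inherited the other haplotype of the same parent".
    ``d_stat`` is the difference of subgroup (or type) mean DCs on the
    reference-allele scale for the split route, or on the marker-allele
    scale for the classic route.
    """

    snp_type: int
    method: str  # "split" | "classic"
    n_ref: int
    n_alt: int
    computable: bool
    reason: Optional[str] = None
    d_stat: Optional[float] = None
    mu_h1: Optional[float] = None
    mu_h2: Optional[float] = None
    sigma: Optional[float] = None
    log10_bf: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "snp_type": self.snp_type,
            "method": self.method,
            "n_ref": self.n_ref,
            "n_alt": self.n_alt,
            "computable": self.computable,
            "reason": self.reason,
            "d_stat": self.d_stat,
            "mu_h1": self.mu_h1,
            "mu_h2": self.mu_h2,
            "sigma": self.sigma,
            "log10_bf": self.log10_bf,
        }


def _check_ff(ff: float) -> None:
    if not (0.0 < ff <= 0.5):
        raise InputError(f"fetal fraction {ff} outside (0, 0.5]")


def _site_variances(obs: pd.DataFrame, ff: float) -> np.ndarray:
    """Per-site binomial variance of ref_freq at the H1/H2 midpoint."""
    sign = np.where(obs["marker_allele"].to_numpy() == REF, 1.0, -1.0)
    p_mid = obs["baseline_e0"].to_numpy() + sign * ff / 4.0
    return p_mid * (1.0 - p_mid) / obs["depth"].to_numpy()


def split_bf(
    obs: pd.DataFrame,
    ff: float,
    *,
    min_subgroup_snps: int = 10,
    snp_type: Optional[int] = None,
) -> BfModel:
    """Single-type BF from the ref-vs-alt subgroup mean DC difference.

    ``obs`` must hold dosage observations of exactly one SNP type (an empty
    table is allowed with ``snp_type`` given, and is not computable). Under
    H1 the statistic is centred on +ff, under H2 on 0.
    """
    _check_ff(ff)
    types = obs["snp_type"].unique()
    if len(types) > 1 or (len(types) == 1 and snp_type not in (None, int(types[0]))):
        raise InputError("split_bf expects observations of exactly one SNP type")
    if len(types) == 0 and snp_type is None:
        raise InputError("empty observation table needs an explicit snp_type")
    t = int(types[0]) if len(types) else int(snp_type)
    ref = obs[obs["marker_allele"] == REF]
    alt = obs[obs["marker_allele"] != REF]
    n_ref, n_alt = len(ref), len(alt)
    if min(n_ref, n_alt) < min_subgroup_snps:
        return BfModel(
            snp_type=t, method="split", n_ref=n_ref, n_alt=n_alt,
            computable=False,
            reason=(
                f"type not computable: subgroup sizes ref={n_ref}, alt={n_alt} "
                f"< min_subgroup_snps={min_subgroup_snps}"
            ),
        )
    d = float(ref["dc"].mean() - alt["dc"].mean())
    var = float(
        _site_variances(ref, ff).sum() / n_ref**2
        + _site_variances(alt, ff).sum() / n_alt**2
    )
    sigma = math.sqrt(var)
    mu_h1, mu_h2 = ff, 0.0
    return BfModel(
        snp_type=t, method="split", n_ref=n_ref, n_alt=n_alt, computable=True,
        d_stat=d, mu_h1=mu_h1, mu_h2=mu_h2, sigma=sigma,
        log10_bf=gaussian_log10_bf(d, mu_h1, mu_h2, sigma),
    )


def _oriented_dc(obs: pd.DataFrame) -> np.ndarray:
    """DC on the marker-allele scale: dc if marker is ref, else -dc."""
    sign = np.where(obs["marker_allele"].to_numpy() == REF, 1.0, -1.0)
    return sign * obs["dc"].to_numpy()


def classic_bf(
    obs_type: pd.DataFrame,
    obs_partner: pd.DataFrame,
    ff: float,
    *,
    min_subgroup_snps: int = 10,
) -> BfModel:
    """Two-type BF from the between-type mean marker-dosage difference.

    H1 = "the haplotype of the first type is inherited"; the statistic is
    centred on +ff/2 under H1 and -ff/2 under H2. Requires both types to
    reach ``min_subgroup_snps`` — the route that fails when one haplotype
    carries almost no informative SNPs.
    """
    _check_ff(ff)
    t = int(obs_type["snp_type"].iloc[0]) if len(obs_type) else 0
    n_a, n_b = len(obs_type), len(obs_partner)
    if min(n_a, n_b) < min_subgroup_snps:
        return BfModel(
            snp_type=t, method="classic", n_ref=n_a, n_alt=n_b, computable=False,
            reason=(
                f"type not computable: type sizes {n_a} and {n_b} "
                f"< min_subgroup_snps={min_subgroup_snps}"
            ),
        )
    d = float(_oriented_dc(obs_type).mean() - _oriented_dc(obs_partner).mean())
    var = float(
        _site_variances(obs_type, ff).sum() / n_a**2
        + _site_variances(obs_partner, ff).sum() / n_b**2
    )
    sigma = math.sqrt(var)
    mu_h1, mu_h2 = ff / 2.0, -ff / 2.0
    return BfModel(
        snp_type=t, method="classic", n_ref=n_a, n_alt=n_b, computable=True,
        d_stat=d, mu_h1=mu_h1, mu_h2=mu_h2, sigma=sigma,
        log10_bf=gaussian_log10_bf(d, mu_h1, mu_h2, sigma),
    )


@dataclass
class RhdoCall:
    """Per-parent inheritance call.

    ``combined_log10_bf`` is oriented pathogenic-vs-wild-type: the log10 BF
    of the pathogenic-linked type (1 or 3) minus that of the wild-type-
    linked type (2 or 4), over whichever types are computable. Positive
    values favour inheritance of the pathogenic haplotype.
    """

    parent: str  # "maternal" | "paternal"
    models: dict[int, BfModel] = field(repr=False)
    combined_log10_bf: Optional[float] = None
    call: str = "no_call"
    reason: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "parent": self.parent,
            "call": self.call,
            "combined_log10_bf": self.combined_log10_bf,
            "reason": self.reason,
            "types": {str(t): m.to_dict() for t, m in self.models.items()},
        }


def call_parent(
    parent: str, models: dict[int, BfModel], *, log10_bf_threshold: float = 2.0
) -> RhdoCall:
    """Combine a parent's per-type BFs into a three-way inheritance call."""
    path_type, wt_type = PARENT_TYPES[parent]
    path_m = models.get(path_type)
    wt_m = models.get(wt_type)
    usable = [m for m in (path_m, wt_m) if m is not None and m.computable]
    if not usable:
        return RhdoCall(
            parent=parent, models=models,
            reason="no computable informative SNP type for this parent",
        )
    combined = 0.0
    if path_m is not None and path_m.computable:
        combined += path_m.log10_bf
    if wt_m is not None and wt_m.computable:
        combined -= wt_m.log10_bf
    combined = float(np.clip(combined, -LOG10_BF_CLAMP, LOG10_BF_CLAMP))
    if combined >= log10_bf_threshold:
        call = "pathogenic_inherited"
    elif combined <= -log10_bf_threshold:
        call = "wildtype_inherited"
    else:
        call = "no_call"
    reason = None
    if call == "no_call":
        reason = (
            f"|combined log10 BF| = {abs(combined):.3g} below threshold "
            f"{log10_bf_threshold}"
        )
    return RhdoCall(
        parent=parent, models=models, combined_log10_bf=combined,
        call=call, reason=reason,
    )


def call_inheritance(
    dosage: DosageTable, ff: float, config: RunConfig
) -> list[RhdoCall]:
    """Split-route BFs for all four types, combined into per-parent calls.

    Optional fixed-SNP-count blocking (``config.block_size``): each type's
    observations are cut into consecutive position-ordered blocks, a BF is
    computed per block, and the type's log10 BF is the sum over computable
    blocks (independent-evidence combination).
    """
    calls = []
    for parent, (t_path, t_wt) in PARENT_TYPES.items():
        models: dict[int, BfModel] = {}
        for t in (t_path, t_wt):
            obs = dosage.of_type(t)
            if config.block_size is None:
                models[t] = split_bf(
                    obs, ff, min_subgroup_snps=config.min_subgroup_snps,
                    snp_type=t,
                )
            else:
                models[t] = blocked_split_bf(
                    obs, ff, block_size=config.block_size,
                    min_subgroup_snps=config.min_subgroup_snps, snp_type=t,
                )
        calls.append(
            call_parent(
                parent, models, log10_bf_threshold=config.log10_bf_threshold
            )
        )
    return calls


def blocked_split_bf(
    obs: pd.DataFrame,
    ff: float,
    *,
    block_size: int,
    min_subgroup_snps: int = 10,
    snp_type: Optional[int] = None,
) -> BfModel:
    """Split BF over fixed-SNP-count blocks, log10 BFs summed across blocks.

    Blocks inherit the per-block subgroup minimum; a type is computable
    when at least one block is. Summary fields (d_stat, sigma) are taken
    from the whole-region statistic for reporting.
    """
    whole = split_bf(obs, ff, min_subgroup_snps=min_subgroup_snps, snp_type=snp_type)
    obs = obs.sort_values(["chrom", "pos"])
    total = 0.0
    n_blocks = 0
    for start in range(0, len(obs), block_size):
        block = obs.iloc[start : start + block_size]
        m = split_bf(block, ff, min_subgroup_snps=min_subgroup_snps, snp_type=snp_type)
        if m.computable:
            total += m.log10_bf
            n_blocks += 1
    if n_blocks == 0:
        whole.computable = False
        whole.log10_bf = None
        whole.reason = "type not computable: no block met subgroup minima"
        return whole
    whole.log10_bf = float(np.clip(total, -LOG10_BF_CLAMP, LOG10_BF_CLAMP))
    whole.reason = f"sum over {n_blocks} blocks of {block_size} SNPs"
    return whole
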