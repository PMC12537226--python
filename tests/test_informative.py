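"""Informative-SNP typing, ref/alt subtypes and per-site dosage change."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from rhdocall import (
    InputError,
    PlasmaCounts,
    SimulationConfig,
    classify_informative_snps,
    compute_dc,
    phase_quartet,
    ref_share_pct,
    simulate_plasma,
    simulate_quartet,
    subtype_summary,
)
from rhdocall.informative import classify_site

from conftest import make_ped, make_plasma

TYPE_HAPLOTYPE = {1: "hm1", 2: "hm2", 3: "hf1", 4: "hf2"}


def mixture_ref_freq(hm1, hm2, hf1, hf2, fetal_m, fetal_f, ff):
    """Expected plasma ref frequency for a site, straight from the mixture."""
    return (1 - ff) * (hm1 + hm2) / 2 + ff * (fetal_m + fetal_f) / 2


@pytest.mark.parametrize(
    "haps,expect",
    [
        # mother het (HM1=alt, HM2=ref), father hom-alt -> Type 1, marker alt
        ((0, 1, 0, 0), (1, 0)),
        # father het (HF1=ref, HF2=alt), mother hom-ref -> Type 4, marker alt
        ((1, 1, 1, 0), (4, 0)),
        # mother het, father hom matching HM2 -> Type 2, marker = HM2 allele
        ((1, 0, 0, 0), (2, 0)),
        # father het, mother hom matching HF2 -> Type 3, marker = HF1 allele
        ((0, 0, 1, 0), (3, 1)),
        # both parents heterozygous: excluded
        ((1, 0, 1, 0), None),
        # both parents homozygous: excluded
        ((1, 1, 0, 0), None),
    ],
)
def test_classification_rule(haps, expect):
    assert classify_site(*haps) == expect


def test_classify_rejects_unphased_site():
    with pytest.raises(InputError):
        classify_site(-1, 1, 0, 0)


def test_classification_agrees_with_dosage_first_principles():
    """Exhaustive check over all 16 haplotype configurations: a site is
    assigned type N with marker allele M exactly when, by mixture
    arithmetic, M's plasma frequency rises by ff/2 when the fetus inherits
    type N's haplotype and is unchanged when it inherits the other one."""
    ff = 0.1
    for hm1, hm2, hf1, hf2 in itertools.product((0, 1), repeat=4):
        got = classify_site(hm1, hm2, hf1, hf2)
        # informative = exactly one parent heterozygous
        informative = (hm1 != hm2) != (hf1 != hf2)
        if not informative:
            assert got is None
            continue
        assert got is not None
        snp_type, marker = got
        hap = TYPE_HAPLOTYPE[snp_type]
        alleles = {"hm1": hm1, "hm2": hm2, "hf1": hf1, "hf2": hf2}
        assert marker == alleles[hap]
        # inherit the type's haplotype vs the parent's other haplotype
        if hap.startswith("hm"):
            inherit = dict(fetal_m=alleles[hap], fetal_f=hf1)
            other = dict(fetal_m=alleles["hm2" if hap == "hm1" else "hm1"], fetal_f=hf1)
        else:
            inherit = dict(fetal_m=hm1, fetal_f=alleles[hap])
            other = dict(fetal_m=hm1, fetal_f=alleles["hf2" if hap == "hf1" else "hf1"])
        base = (hm1 + hm2) / 2
        f_in = mixture_ref_freq(hm1, hm2, hf1, hf2, ff=ff, **inherit)
        f_out = mixture_ref_freq(hm1, hm2, hf1, hf2, ff=ff, **other)
        sign = 1.0 if marker == 1 else -1.0
        assert f_in - base == pytest.approx(sign * ff / 2)
        assert f_out - base == pytest.approx(0.0)


def test_identical_pathogenic_haplotypes_leave_no_type2_or_type3():
    """The degenerate regime taken to its limit: HM1 == HF1 everywhere."""
    _, ped = simulate_quartet(
        SimulationConfig(n_snps=2000, hm1_hf1_identity=1.0, seed=3)
    )
    snps = classify_informative_snps(phase_quartet(ped))
    counts = snps["snp_type"].value_counts()
    assert counts.get(2, 0) == 0
    assert counts.get(3, 0) == 0
    assert counts.get(1, 0) > 100 and counts.get(4, 0) > 100


def enumerate_type_probabilities(identity: float, p: float) -> dict[int, float]:
    """Oracle: per-site type probabilities by enumeration over the
    generative haplotype configurations (HM1, HM2, HF2 independent
    Bernoulli(p); HF1 copies HM1 w.p. identity, else independent draw)."""
    probs = {1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0}
    for hm1, hm2, hf2 in itertools.product((0, 1), repeat=3):
        base = (
            (p if hm1 else 1 - p) * (p if hm2 else 1 - p) * (p if hf2 else 1 - p)
        )
        for hf1 in (0, 1):
            w = identity * (1.0 if hf1 == hm1 else 0.0) + (1 - identity) * (
                p if hf1 else 1 - p
            )
            got = classify_site(hm1, hm2, hf1, hf2)
            if got is not None:
                probs[got[0]] += base * w
    return probs


def test_scarce_type2_type3_counts_match_enumeration():
    """Under 0.98 identity the Type 2 + Type 3 count is binomial around the
    enumerated per-site probability."""
    n = 2000
    cfg = SimulationConfig(n_snps=n, hm1_hf1_identity=0.98, seed=21)
    _, ped = simulate_quartet(cfg)
    snps = classify_informative_snps(phase_quartet(ped))
    counts = snps["snp_type"].value_counts()
    probs = enumerate_type_probabilities(0.98, 0.5)
    p23 = probs[2] + probs[3]
    observed = counts.get(2, 0) + counts.get(3, 0)
    se = np.sqrt(n * p23 * (1 - p23))
    assert abs(observed - n * p23) <= 3 * se
    # and the common types are where the enumeration puts them too
    for t in (1, 4):
        se_t = np.sqrt(n * probs[t] * (1 - probs[t]))
        assert abs(counts.get(t, 0) - n * probs[t]) <= 3 * se_t


def test_baseline_always_half_the_maternal_ref_count():
    _, ped = simulate_quartet(SimulationConfig(n_snps=1000, seed=5))
    phased = phase_quartet(ped)
    snps = classify_informative_snps(phased)
    merged = snps.merge(ped.df, on=["chrom", "pos", "ref", "alt"])
    assert np.allclose(merged["baseline_e0"], merged["mother"] / 2.0)
    # types 1-2 maternal het; types 3-4 maternal hom
    assert (merged.loc[merged["snp_type"].isin((1, 2)), "baseline_e0"] == 0.5).all()
    assert merged.loc[merged["snp_type"].isin((3, 4)), "baseline_e0"].isin((0.0, 1.0)).all()


def test_subtype_summary_shares():
    snps = pd.DataFrame(
        {
            "snp_type": [1] * 227 + [4] * 4,
            "marker_allele": [1] * 23 + [0] * 204 + [1, 1, 0, 0],
        }
    )
    summary = subtype_summary(snps)
    assert summary.loc[1, "n_ref"] == 23 and summary.loc[1, "n_alt"] == 204
    assert round(summary.loc[1, "ref_share_pct"], 2) == 10.13
    assert summary.loc[4, "ref_share_pct"] == 50.00
    assert np.isnan(summary.loc[2, "ref_share_pct"])  # empty type -> missing
    assert np.isnan(ref_share_pct(0, 0))


def test_dc_arithmetic_and_filters(run_config):
    ped = make_ped([(2, 1, 2), (0, 1, 1), (1, 2, 2), (2, 1, 2)])
    phased = phase_quartet(ped)
    snps = classify_informative_snps(phased)
    plasma = make_plasma(ped, ref_depth=[55, 95, 20, 600], alt_depth=[45, 5, 10, 400])
    table = compute_dc(snps, plasma, min_depth=50, outlier_dc_bound=0.08)
    by_pos = table.df.set_index("pos")
    # baseline 0.5, 55/45 -> dc = +0.05
    assert by_pos.loc[32_000_000, "dc"] == pytest.approx(0.05)
    # depth 30 < min_depth -> excluded
    assert table.n_excluded_depth == 1
    # |dc| beyond the sanity bound at depth >= 100 -> outliers excluded
    assert table.n_excluded_outlier == 2
    assert 32_000_100 not in by_pos.index
    assert 32_000_300 not in by_pos.index
    assert len(table.df) == 1


def test_dc_against_hom_ref_baseline():
    # mother hom-ref (baseline 1.0), father het: paternal-informative site
    ped = make_ped([(1, 2, 2), (2, 1, 2)])
    snps = classify_informative_snps(phase_quartet(ped))
    plasma = make_plasma(ped, ref_depth=[95, 50], alt_depth=[5, 50])
    table = compute_dc(snps, plasma, min_depth=10)
    row = table.df[table.df["baseline_e0"] == 1.0].iloc[0]
    assert row["dc"] == pytest.approx(-0.05)


def test_mean_dc_is_half_fetal_fraction_when_inherited():
    """Generative check of the dosage model: for type1_ref sites with the
    maternal pathogenic haplotype inherited, mean DC -> +ff/2."""
    cfg = SimulationConfig(
        n_snps=1000, ff_true=0.10, plasma_depth_mean=10_000,
        maternal_inherited="HM1", seed=17,
    )
    truth, ped = simulate_quartet(cfg)
    plasma = simulate_plasma(truth, cfg)
    snps = classify_informative_snps(phase_quartet(ped))
    table = compute_dc(snps, plasma, min_depth=50)
    sub = table.df[(table.df["snp_type"] == 1) & (table.df["marker_allele"] == 1)]
    assert len(sub) > 100
    se = sub["dc"].std() / np.sqrt(len(sub))
    assert abs(sub["dc"].mean() - 0.05) < 3 * se
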