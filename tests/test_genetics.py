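"""Genotype QC and PRS scoring, each checked against an independent
brute-force oracle."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gdrisk.genetics import (GenotypeMatrix, VariantWeight, compute_prs,
                             filter_imputed, hwe_exact_p, qc_filter_samples,
                             qc_filter_variants, quartile_bins,
                             read_dosage_tsv, read_vcf, read_weights,
                             write_dosage_tsv, write_vcf, write_weights)


def make_matrix(dosages, typed=True, info=None, probs=None, rsids=None):
    dosages = np.asarray(dosages, dtype=float)
    m, n = dosages.shape
    variants = pd.DataFrame({
        "rsid": rsids or [f"rs{i}" for i in range(m)],
        "chrom": ["1"] * m,
        "pos": np.arange(1, m + 1),
        "ref": ["A"] * m,
        "alt": ["G"] * m,
        "typed": typed if np.iterable(typed) else [typed] * m,
        "info": info if info is not None else [np.nan] * m,
    })
    hard = np.where(np.isnan(dosages), -1, np.rint(dosages)).astype(np.int8)
    return GenotypeMatrix(
        samples=[f"s{j}" for j in range(n)], variants=variants, dosages=dosages,
        hard_calls=hard, genotype_probs=probs,
    )


# ---------------------------------------------------------------------------
# HWE exact test vs full enumeration


def hwe_enumeration_p(n_het, n_hom1, n_hom2):
    """Oracle: enumerate every genotype configuration with the observed
    allele counts and sum exact conditional probabilities no larger than
    the observed one."""
    n = n_het + n_hom1 + n_hom2
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0

    def log_prob(het):
        hom_r = (n_rare - het) // 2
        hom_c = n - het - hom_r
        return (math.lgamma(n + 1) - math.lgamma(hom_r + 1) - math.lgamma(het + 1)
                - math.lgamma(hom_c + 1) + het * math.log(2)
                + math.lgamma(n_rare + 1) + math.lgamma(2 * n - n_rare + 1)
                - math.lgamma(2 * n + 1))

    hets = [h for h in range(n_rare % 2, n_rare + 1, 2) if (n_rare - h) // 2 + h <= n]
    probs = {h: math.exp(log_prob(h)) for h in hets}
    p_obs = probs[n_het]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))


@pytest.mark.parametrize("het,hom1,hom2", [
    (10, 5, 5), (0, 10, 10), (20, 0, 0), (3, 40, 2), (57, 14, 50),
    (1, 1, 1), (0, 100, 0), (12, 12, 0),
])
def test_hwe_exact_matches_enumeration(het, hom1, hom2):
    assert hwe_exact_p(het, hom1, hom2) == pytest.approx(
        hwe_enumeration_p(het, hom1, hom2), rel=1e-9)


@given(het=st.integers(0, 40), hom1=st.integers(0, 40), hom2=st.integers(0, 40))
@settings(max_examples=150, deadline=None)
def test_hwe_exact_matches_enumeration_random(het, hom1, hom2):
    if het + hom1 + hom2 == 0:
        return
    p = hwe_exact_p(het, hom1, hom2)
    assert 0.0 <= p <= 1.0
    assert p == pytest.approx(hwe_enumeration_p(het, hom1, hom2), rel=1e-9)


# ---------------------------------------------------------------------------
# variant QC


def test_variant_missingness_threshold():
    # 3 missing calls in 100 samples -> missingness 0.03 > 0.02 -> removed
    rng = np.random.default_rng(0)
    row = rng.binomial(2, 0.4, 100).astype(float)
    row[:3] = np.nan
    clean = rng.binomial(2, 0.4, 100).astype(float)
    g = make_matrix(np.vstack([row, clean]))
    kept, fate = qc_filter_variants(g)
    assert list(kept.variants["rsid"]) == ["rs1"]
    assert fate.loc[0, "reason"] == "missingness"


def test_monomorphic_variant_removed():
    balanced = np.tile([0.0, 1.0, 2.0, 1.0], 15)  # HW proportions at freq 0.5
    g = make_matrix(np.vstack([np.zeros(60), balanced]))
    kept, fate = qc_filter_variants(g)
    assert "maf" in fate.loc[0, "reason"]
    assert list(kept.variants["rsid"]) == ["rs1"]


def test_variant_qc_matches_brute_force():
    """Survivors of a 20-variant matrix with injected violations equal a
    direct evaluation of the three predicates."""
    rng = np.random.default_rng(42)
    m, n = 20, 200
    dos = rng.binomial(2, rng.uniform(0.05, 0.5, size=(m, 1)), size=(m, n)).astype(float)
    dos[2, :7] = np.nan                      # missingness 0.035
    dos[5] = 0.0                             # monomorphic
    dos[8] = np.tile([0.0, 2.0], n // 2)     # het deficit -> HWE failure
    g = make_matrix(dos)
    kept, fate = qc_filter_variants(g)

    survivors = []
    for i in range(m):
        row = dos[i]
        miss = np.mean(np.isnan(row))
        p = np.nanmean(row) / 2
        maf = min(p, 1 - p)
        hwe = hwe_enumeration_p(int(np.sum(row == 1)), int(np.sum(row == 0)),
                                int(np.sum(row == 2)))
        if miss <= 0.02 and maf >= 0.01 and hwe >= 1e-6:
            survivors.append(f"rs{i}")
    assert list(kept.variants["rsid"]) == survivors
    assert not fate.loc[[2, 5, 8], "kept"].any()


# ---------------------------------------------------------------------------
# sample QC


def test_sample_call_rate_threshold():
    rng = np.random.default_rng(1)
    dos = rng.binomial(2, 0.5, size=(100, 60)).astype(float)
    dos[:5, 0] = np.nan   # call rate 0.95 -> removed
    g = make_matrix(dos)
    kept, fate = qc_filter_samples(g)
    assert "s0" not in kept.samples
    assert fate.loc[0, "call_rate"] == pytest.approx(0.95)
    assert not fate.loc[0, "kept"]
    # the fully typed samples with ordinary heterozygosity survive
    assert kept.n_samples >= 55


def test_fhet_closed_form_on_constructed_genotypes():
    """All-homozygous sample at MAF-0.5 loci has F_het ~ 1 and is removed;
    an all-het sample has F_het ~ 1 - 1/E(het) per locus < -0.2."""
    m = 50
    homo = np.tile([0.0, 2.0], m // 2)          # no hets, freq 0.5
    het = np.ones(m)                            # all hets
    balanced = np.tile([0.0, 1.0, 2.0, 1.0], m // 4 + 1)[:m]
    dos = np.column_stack([homo, het, balanced, balanced])
    g = make_matrix(dos)
    fhet = g.sample_fhet()
    p = g.alt_allele_freq()
    exp_het = float(np.sum(2 * p * (1 - p)))
    assert fhet[0] == pytest.approx(1.0)                       # zero observed hets
    assert fhet[1] == pytest.approx(1.0 - m / exp_het)
    kept, fate = qc_filter_samples(g)
    assert "s0" not in kept.samples and "s1" not in kept.samples


def test_fhet_zero_sample_retained():
    # Latin-square genotype blocks: every variant sees dosages {0,1,2,1}
    # across the 4 samples, so each sample's observed het equals the HW
    # expectation exactly and F_het = 0
    block = np.array([[0, 1, 2, 1], [1, 0, 1, 2], [2, 1, 0, 1], [1, 2, 1, 0]], float)
    dos = np.tile(block, (10, 1))
    g = make_matrix(dos)
    fhet = g.sample_fhet()
    assert np.allclose(fhet, 0.0)
    kept, _ = qc_filter_samples(g)
    assert kept.n_samples == 4


# ---------------------------------------------------------------------------
# imputed-variant filter


def test_filter_imputed_drops_low_info_and_masks_low_prob():
    rng = np.random.default_rng(3)
    dos = rng.binomial(2, 0.3, size=(3, 50)).astype(float)
    probs = np.full((3, 50), 0.99)
    probs[1, :10] = 0.5   # low-confidence calls on the imputed rs1
    g = make_matrix(dos, typed=[False, False, True],
                    info=[0.05, 0.9, np.nan], probs=probs)
    kept, fate = filter_imputed(g)
    assert "info" in fate.loc[0, "reason"]          # INFO 0.05 <= 0.1 dropped
    assert fate.loc[2, "kept"]                      # typed variant untouched
    i1 = list(kept.variants["rsid"]).index("rs1")
    assert np.isnan(kept.dosages[i1, :10]).all()    # masked calls
    assert not np.isnan(kept.dosages[i1, 10:]).any()


def test_filter_imputed_requires_metadata():
    dos = np.ones((1, 10))
    g = make_matrix(dos, typed=[False], info=[np.nan],
                    probs=np.full((1, 10), 0.99))
    with pytest.raises(ValueError, match="INFO"):
        filter_imputed(g)


def test_filter_imputed_matches_brute_force():
    rng = np.random.default_rng(9)
    m, n = 15, 80
    dos = rng.binomial(2, rng.uniform(0.05, 0.5, (m, 1)), (m, n)).astype(float)
    typed = rng.random(m) < 0.4
    info = np.where(typed, np.nan, rng.uniform(0, 1, m))
    probs = rng.uniform(0.6, 1.0, (m, n))
    g = make_matrix(dos, typed=typed.tolist(), info=info.tolist(), probs=probs)
    kept, fate = filter_imputed(g)
    expect = []
    for i in range(m):
        if typed[i]:
            expect.append(f"rs{i}")
            continue
        masked = np.where(probs[i] <= 0.80, np.nan, dos[i])
        p = np.nanmean(masked) / 2
        maf = min(p, 1 - p) if not np.isnan(p) else np.nan
        if info[i] > 0.1 and maf > 0.005:
            expect.append(f"rs{i}")
    assert list(kept.variants["rsid"]) == expect


# ---------------------------------------------------------------------------
# PRS


def test_prs_hand_arithmetic():
    g = make_matrix(np.array([[2.0], [1.0]]))
    w = [VariantWeight("rs0", "G", "A", 0.1), VariantWeight("rs1", "G", "A", 0.2)]
    scores, report = compute_prs(g, w)
    assert scores.iloc[0] == pytest.approx(0.4)
    assert report["n_matched"] == 2 and report["n_flipped"] == 0


def test_prs_zero_effect_alleles():
    g = make_matrix(np.zeros((4, 2)))
    w = [VariantWeight(f"rs{i}", "G", "A", 0.3) for i in range(4)]
    scores, _ = compute_prs(g, w)
    assert np.allclose(scores, 0.0)


def test_prs_matches_brute_force_loop():
    """84 random weights, random dosages with some missing: scores equal an
    independent per-sample accumulation including the 2*EAF fallback."""
    rng = np.random.default_rng(11)
    m, n = 84, 60
    dos = rng.binomial(2, rng.uniform(0.1, 0.9, (m, 1)), (m, n)).astype(float)
    dos[rng.random((m, n)) < 0.02] = np.nan
    g = make_matrix(dos)
    betas = rng.normal(0.1, 0.05, m)
    flip = rng.random(m) < 0.5
    w = [VariantWeight(f"rs{i}",
                       "A" if flip[i] else "G",
                       "G" if flip[i] else "A",
                       float(betas[i])) for i in range(m)]
    scores, report = compute_prs(g, w)
    assert report["n_flipped"] == int(flip.sum())

    expect = np.zeros(n)
    for i in range(m):
        d = dos[i].copy()
        if flip[i]:
            d = 2.0 - d
        eaf = np.nanmean(d) / 2.0
        d[np.isnan(d)] = 2.0 * eaf
        expect += betas[i] * d
    assert np.allclose(scores.to_numpy(), expect)


def test_prs_linear_in_beta():
    rng = np.random.default_rng(2)
    dos = rng.binomial(2, 0.4, (10, 20)).astype(float)
    g = make_matrix(dos)
    w1 = [VariantWeight(f"rs{i}", "G", "A", 0.1 + 0.01 * i) for i in range(10)]
    w2 = [VariantWeight(v.rsid, v.effect_allele, v.other_allele, 2 * v.beta) for v in w1]
    s1, _ = compute_prs(g, w1)
    s2, _ = compute_prs(g, w2)
    assert np.allclose(2 * s1.to_numpy(), s2.to_numpy())


def test_prs_allele_flip_identity():
    """Swapping effect/other allele with negated beta shifts every score by
    exactly -2*beta per variant (dosage(other) = 2 - dosage(effect))."""
    rng = np.random.default_rng(4)
    dos = rng.binomial(2, 0.3, (6, 15)).astype(float)
    g = make_matrix(dos)
    w = [VariantWeight(f"rs{i}", "G", "A", 0.2) for i in range(6)]
    wf = [VariantWeight(v.rsid, "A", "G", -v.beta) for v in w]
    s, _ = compute_prs(g, w)
    sf, _ = compute_prs(g, wf)
    assert np.allclose(s.to_numpy(), sf.to_numpy() + 2 * sum(v.beta for v in w))


def test_prs_low_match_raises():
    g = make_matrix(np.ones((2, 3)))
    w = [VariantWeight(f"rsX{i}", "G", "A", 0.1) for i in range(10)]
    with pytest.raises(ValueError, match="matched"):
        compute_prs(g, w)


def test_prs_palindromic_warns():
    g = make_matrix(np.ones((1, 3)))
    g.variants.loc[0, ["ref", "alt"]] = ["A", "T"]
    with pytest.warns(UserWarning, match="strand-ambiguous"):
        compute_prs(g, [VariantWeight("rs0", "T", "A", 0.1)])


# ---------------------------------------------------------------------------
# quartiles


def test_quartiles_symmetric_case():
    bins = quartile_bins(pd.Series(np.arange(1.0, 9.0)))
    assert list(bins["quartile"]) == ["Q1", "Q1", "Q2", "Q2", "Q3", "Q3", "Q4", "Q4"]
    assert bins["top25"].sum() == 2 and bins["bottom25"].sum() == 2


def test_quartiles_constant_scores_warn():
    with pytest.warns(UserWarning, match="constant"):
        bins = quartile_bins(np.full(10, 3.3))
    assert (bins["quartile"] == "Q1").all()


def test_quartiles_match_sort_and_split():
    rng = np.random.default_rng(8)
    s = rng.normal(size=1000)
    bins = quartile_bins(s)
    occupancy = bins["quartile"].value_counts()
    assert all(abs(occupancy[q] - 250) <= 1 for q in ["Q1", "Q2", "Q3", "Q4"])
    # brute-force: quartile by comparing against the sorted percentile cuts
    cuts = np.quantile(s, [0.25, 0.5, 0.75])
    expect = 1 + np.sum(s[:, None] > cuts, axis=1)
    assert (bins["quartile"].str[1].astype(int).to_numpy() == expect).all()


def test_quartile_tie_at_cut_goes_low():
    s = np.array([0, 0, 0, 1, 2, 3, 4, 5.0])   # 25th percentile is 0
    bins = quartile_bins(s)
    assert (bins["quartile"][:3] == "Q1").all()


# ---------------------------------------------------------------------------
# I/O round trips


def test_dosage_tsv_round_trip(tmp_path):
    rng = np.random.default_rng(6)
    dos = rng.binomial(2, 0.4, (5, 8)).astype(float)
    dos[0, 0] = np.nan
    g = make_matrix(dos)
    p = tmp_path / "dos.tsv"
    write_dosage_tsv(g, p)
    back = read_dosage_tsv(p)
    assert back.samples == g.samples
    assert np.allclose(back.dosages, g.dosages, equal_nan=True)


def test_vcf_round_trip(tmp_path):
    rng = np.random.default_rng(7)
    dos = rng.binomial(2, 0.5, (4, 6)).astype(float)
    dos[1, 2] = np.nan
    g = make_matrix(dos, typed=[True, True, False, False],
                    info=[np.nan, np.nan, 0.8, 0.95])
    p = tmp_path / "toy.vcf"
    write_vcf(g, p)
    back = read_vcf(p)
    assert back.samples == g.samples
    assert list(back.variants["rsid"]) == list(g.variants["rsid"])
    assert np.allclose(back.dosages, g.dosages, equal_nan=True)
    assert list(back.variants["typed"]) == [True, True, False, False]
    assert back.variants["info"].iloc[2] == pytest.approx(0.8)


def test_weights_tsv_round_trip(tmp_path):
    w = [VariantWeight("rs1", "A", "G", 0.12, 0.9), VariantWeight("rs2", "C", "T", -0.05)]
    p = tmp_path / "w.tsv"
    write_weights(w, p)
    back = read_weights(p)
    assert back[0] == w[0]
    assert back[1].beta == pytest.approx(-0.05) and back[1].info is None
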