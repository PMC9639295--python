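import numpy as np
import pandas as pd
import pytest

from reqtlkit.expression import ExpressionPair
from reqtlkit.genotypes import GenotypeMatrix, pairwise_r2
from reqtlkit.reqtl import (
    call_reqtls,
    classify_regenes,
    detect_heo_egenes,
    fit_interaction_lmm,
    fits_to_frame,
    rescan_flanking,
    select_candidates,
    InteractionFit,
)

from .oracles import diff_ols


def toy_genotypes(dosage_cols, positions=None):
    dosage = np.column_stack(dosage_cols).astype(float)
    m = dosage.shape[1]
    positions = positions or [(j + 1) * 1000 for j in range(m)]
    variants = pd.DataFrame(
        {
            "id": [f"v{j}" for j in range(m)],
            "chrom": "1",
            "pos": positions,
            "ref": "A",
            "alt": "T",
            "is_indel": False,
        }
    )
    return GenotypeMatrix(
        [f"s{i}" for i in range(dosage.shape[0])], variants, dosage
    )


def cis_hits(rows):
    return pd.DataFrame(rows, columns=["gene_id", "variant_id", "p", "klass"])


class TestSelectCandidates:
    def test_identical_top_yields_single_candidate(self, rng):
        G = toy_genotypes([rng.choice([0.0, 2.0], 20) for _ in range(2)])
        hc = cis_hits([("gA", "v0", 1e-8, "cis")])
        hh = cis_hits([("gA", "v0", 1e-6, "cis")])
        out = select_candidates(hc, hh, G)
        assert len(out) == 1
        assert out.iloc[0]["selection_rule"] == "identical_top"

    def test_single_condition_rule(self, rng):
        G = toy_genotypes([rng.choice([0.0, 2.0], 20)])
        hc = cis_hits([("gA", "v0", 1e-8, "cis")])
        hh = cis_hits([])
        out = select_candidates(hc, hh, G)
        assert out.iloc[0]["selection_rule"] == "single_condition"

    def test_high_ld_picks_one_low_ld_keeps_both(self):
        rng = np.random.default_rng(123)
        base = np.repeat([0.0, 2.0], 20)
        partner = base.copy()
        partner[:2] = 2 - partner[:2]  # high but imperfect LD
        indep = rng.permutation(base)
        assert pairwise_r2(base, partner) > 0.8
        assert pairwise_r2(base, indep) <= 0.8
        G = toy_genotypes([base, partner, indep])
        hc = cis_hits([("gA", "v0", 1e-9, "cis"), ("gB", "v0", 1e-9, "cis")])
        hh = cis_hits([("gA", "v1", 1e-9, "cis"), ("gB", "v2", 1e-9, "cis")])
        out = select_candidates(hc, hh, G, r2_ld=0.8, seed=0).set_index("gene_id")
        assert out.loc["gA", "selection_rule"] == "high_ld_pick"
        assert (out.loc[["gB"], "selection_rule"] == "low_ld_both").all()
        assert len(out.loc[["gB"]]) == 2

    def test_ld_boundary_exactly_r2_keeps_both(self, rng):
        a = rng.choice([0.0, 2.0], 30)
        b = rng.choice([0.0, 2.0], 30)
        G = toy_genotypes([a, b])
        r2 = pairwise_r2(a, b)
        hc = cis_hits([("gA", "v0", 1e-9, "cis")])
        hh = cis_hits([("gA", "v1", 1e-9, "cis")])
        # r^2 exactly at the threshold -> "<= r2_ld" -> both retained
        out = select_candidates(hc, hh, G, r2_ld=r2, seed=0)
        assert len(out) == 2 and set(out["selection_rule"]) == {"low_ld_both"}

    def test_deterministic_given_seed(self, rng):
        base = rng.choice([0.0, 2.0], 40)
        G = toy_genotypes([base, base.copy()])
        hc = cis_hits([("gA", "v0", 1e-9, "cis")])
        hh = cis_hits([("gA", "v1", 1e-9, "cis")])
        a = select_candidates(hc, hh, G, seed=5)
        b = select_candidates(hc, hh, G, seed=5)
        pd.testing.assert_frame_equal(a, b)


def paired_gene_data(n=80, theta=1.2, ncov=4, seed=0, maf=0.4):
    rng = np.random.default_rng(seed)
    d = rng.choice([0.0, 2.0], size=n, p=[1 - maf, maf])
    cov = rng.normal(size=(n, ncov))
    g = rng.normal(0, 0.3, size=n)
    yc = 1.0 + 0.4 * d + cov @ np.full(ncov, 0.2) + g + rng.normal(0, 0.4, n)
    yh = 1.5 + (0.4 + theta) * d + cov @ np.full(ncov, -0.1) + g + rng.normal(0, 0.4, n)
    return yc, yh, d, cov


class TestFitInteractionLmm:
    def test_matches_difference_ols_oracle(self):
        # condition-invariant covariates: the mixed model collapses to OLS on
        # within-genotype differences with df = n - (ncov + 2)
        for seed in range(5):
            yc, yh, d, cov = paired_gene_data(seed=seed)
            fit = fit_interaction_lmm(yc, yh, d, cov)
            b, se, df, tval, p = diff_ols(yc, yh, d, cov)
            assert fit.beta_interaction == pytest.approx(b, rel=1e-6)
            assert fit.se == pytest.approx(se, rel=1e-6)
            assert fit.df_satterthwaite == pytest.approx(df, rel=1e-6)
            assert fit.p_raw == pytest.approx(p, rel=1e-4, abs=1e-300)

    def test_planted_positive_interaction_sign(self):
        signs = []
        for seed in range(50):
            yc, yh, d, cov = paired_gene_data(theta=1.5, seed=seed)
            signs.append(fit_interaction_lmm(yc, yh, d, cov).beta_interaction > 0)
        assert np.mean(signs) >= 0.99

    def test_incomplete_pairs_dropped(self):
        yc, yh, d, cov = paired_gene_data(n=30, seed=2)
        yc2 = yc.copy()
        yc2[:3] = np.nan
        fit = fit_interaction_lmm(yc2, yh, d, cov)
        assert fit.n_genotypes == 27

    def test_constant_dosage_rejected(self):
        yc, yh, d, cov = paired_gene_data(n=20, seed=3)
        with pytest.raises(ValueError, match="constant"):
            fit_interaction_lmm(yc, yh, np.zeros_like(d), cov)

    def test_condition_varying_covariates_accepted(self):
        yc, yh, d, cov = paired_gene_data(n=40, seed=4)
        cov2 = np.vstack([cov, cov + np.random.default_rng(0).normal(0, 0.1, cov.shape)])
        fit = fit_interaction_lmm(yc, yh, d, cov2)
        assert np.isfinite(fit.p_raw) and fit.df_satterthwaite > 0


class TestCallReqtls:
    def _fits(self, ps):
        return [
            InteractionFit(f"g{i}", f"v{i}", 1.0, 0.1, 88.0, p, 80)
            for i, p in enumerate(ps)
        ]

    def test_bonferroni_boundary_not_called(self):
        m = 15588
        ps = [0.01 / m] + [0.5] * (m - 1)
        out = call_reqtls(fits_to_frame(self._fits(ps)), alpha=0.01)
        assert out.loc[0, "p_bonf"] == pytest.approx(0.01)
        assert not out.loc[0, "is_reqtl"]  # strict <

    def test_strong_signal_called(self):
        ps = [1e-9] + [0.5] * 999
        out = call_reqtls(fits_to_frame(self._fits(ps)), alpha=0.01)
        assert out.loc[0, "p_bonf"] == pytest.approx(1e-6)
        assert bool(out.loc[0, "is_reqtl"]) and bool(out.loc[0, "is_gene_reqtl"])

    def test_two_passing_candidates_resolve_to_smaller_p(self):
        fits = [
            InteractionFit("gA", "v1", 1.0, 0.1, 88.0, 1e-9, 80),
            InteractionFit("gA", "v2", 1.0, 0.1, 88.0, 1e-12, 80),
            InteractionFit("gB", "v3", 1.0, 0.1, 88.0, 0.9, 80),
        ]
        out = call_reqtls(fits_to_frame(fits), alpha=0.01).set_index("variant_id")
        assert bool(out.loc["v2", "is_gene_reqtl"])
        assert not bool(out.loc["v1", "is_gene_reqtl"])
        assert bool(out.loc["v1", "is_reqtl"])


def pair_from_cpm(cpm_c, cpm_h, genes, samples):
    # counts chosen so realized CPM equals the requested matrix
    return ExpressionPair(
        genes, samples, cpm_c, cpm_h, cpm_control=cpm_c, cpm_heat=cpm_h
    )


def allele_pair(L_ref, L_alt, n_ref=6, n_alt=6, base=100.0):
    """One gene whose ref/alt homozygous groups respond with L_ref / L_alt."""
    d = np.array([0.0] * n_ref + [2.0] * n_alt)
    cpm_c = np.full((1, n_ref + n_alt), base)
    cpm_h = np.concatenate(
        [
            np.full(n_ref, (base + 1) * 2.0**L_ref - 1),
            np.full(n_alt, (base + 1) * 2.0**L_alt - 1),
        ]
    )[None, :]
    samples = [f"s{i}" for i in range(n_ref + n_alt)]
    pair = pair_from_cpm(cpm_c, cpm_h, ["gA"], samples)
    G = toy_genotypes([d])
    calls = pd.DataFrame({"gene_id": ["gA"], "variant_id": ["v0"]})
    return calls, pair, G


class TestClassifyRegenes:
    @pytest.mark.parametrize(
        "L_ref,L_alt,expected",
        [
            (2.0, 0.5, "RefHeat"),
            (-0.2, -1.4, "AltControl"),
            (-2.0, 0.3, "RefControl"),
            (0.1, 1.8, "AltHeat"),
        ],
    )
    def test_category_definitions(self, L_ref, L_alt, expected):
        calls, pair, G = allele_pair(L_ref, L_alt)
        out = classify_regenes(calls, pair, G)
        assert out.iloc[0]["category"] == expected
        assert out.iloc[0]["L_ref"] == pytest.approx(L_ref, abs=1e-9)
        assert out.iloc[0]["L_alt"] == pytest.approx(L_alt, abs=1e-9)

    def test_exact_tie_is_ambiguous(self):
        calls, pair, G = allele_pair(1.0, -1.0)
        out = classify_regenes(calls, pair, G)
        assert out.iloc[0]["category"] == "ambiguous"

    def test_small_group_skipped(self):
        calls, pair, G = allele_pair(2.0, 0.5, n_ref=2)
        out = classify_regenes(calls, pair, G)
        assert out.iloc[0]["category"] == "skipped_small_group"

    def test_allele_swap_invariance(self):
        # relabel ref<->alt (d -> 2-d): prefix flips, suffix unchanged
        calls, pair, G = allele_pair(2.0, 0.5)
        out1 = classify_regenes(calls, pair, G)
        G2 = GenotypeMatrix(G.samples, G.variants.copy(), 2.0 - G.dosage)
        out2 = classify_regenes(calls, pair, G2)
        assert out1.iloc[0]["category"] == "RefHeat"
        assert out2.iloc[0]["category"] == "AltHeat"


class TestDetectHeoEgenes:
    def test_requires_cis_hit_and_classifies_by_heat_median(self):
        d = np.array([0.0] * 5 + [2.0] * 5)
        cpm_c = np.zeros((1, 10))
        cpm_h = np.concatenate([np.full(5, 12.0), np.full(5, 3.0)])[None, :]
        pair = pair_from_cpm(cpm_c, cpm_h, ["gH"], [f"s{i}" for i in range(10)])
        G = toy_genotypes([d])
        hits = pd.DataFrame(
            {
                "gene_id": ["gH"],
                "variant_id": ["v0"],
                "p": [1e-7],
                "klass": ["cis"],
                "distance_bp": [100],
            }
        )
        out = detect_heo_egenes({"gH"}, hits, pair, G)
        assert out.iloc[0]["category"] == "RefHeat"
        no_hit = detect_heo_egenes({"gH"}, hits[hits.gene_id != "gH"], pair, G)
        assert len(no_hit) == 0


class TestRescanFlanking:
    def test_window_boundary_inclusive(self, rng):
        n = 40
        d1 = rng.choice([0.0, 2.0], n)
        d2 = rng.choice([0.0, 2.0], n)
        d3 = rng.choice([0.0, 2.0], n)
        G = toy_genotypes([d1, d2, d3], positions=[4000, 5001, 12001])
        gene = pd.Series(
            {"gene_id": "gA", "chrom": "1", "start": 5000, "end": 11000,
             "strand": "+", "tss": 5000, "tts": 11000}
        )
        yc, yh, _, cov = paired_gene_data(n=n, seed=1)
        out = rescan_flanking(gene, G, yc, yh, cov, flank_bp=1000)
        # v0 at start-1000 exactly -> included; v2 at end+1001 -> excluded
        assert set(out["variant_id"]) == {"v0", "v1"}

    def test_reproduces_direct_fit(self, rng):
        n = 40
        d = rng.choice([0.0, 2.0], n)
        G = toy_genotypes([d], positions=[5500])
        gene = pd.Series(
            {"gene_id": "gA", "chrom": "1", "start": 5000, "end": 6000,
             "strand": "+", "tss": 5000, "tts": 6000}
        )
        yc, yh, _, cov = paired_gene_data(n=n, seed=2)
        out = rescan_flanking(gene, G, yc, yh, cov)
        direct = fit_interaction_lmm(yc, yh, d, cov)
        assert out.iloc[0]["p_raw"] == pytest.approx(direct.p_raw, rel=1e-12)
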