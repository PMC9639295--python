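import numpy as np
import pandas as pd
import pytest

from reqtlkit.footprints import (
    REPLICATE_COLUMNS,
    assign_footprints,
    center_fragments,
    differential_occupancy,
    enrichment_vs_background,
    inside_outside_comparison,
    relative_position,
    top_variant_overlap,
)
from reqtlkit.stats import fisher_exact

from .oracles import fisher_greater


def frags(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def fp_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "status"])


def gene_row(gene_id="gA", chrom="1", start=10_000, end=12_000, strand="+"):
    tss, tts = (start, end) if strand == "+" else (end, start)
    return pd.Series(
        {"gene_id": gene_id, "chrom": chrom, "start": start, "end": end,
         "strand": strand, "tss": tss, "tts": tts}
    )


def genes_frame(rows):
    return pd.DataFrame([gene_row(**r) for r in rows])


class TestCenterFragments:
    def test_odd_length_forced_window(self):
        out = center_fragments(frags([("1", 100, 131)]), seed=0)
        assert (out.loc[0, "start"], out.loc[0, "end"]) == (105, 125)

    def test_length_81_dropped(self):
        out = center_fragments(frags([("1", 0, 81)]), seed=0)
        assert len(out) == 0

    def test_length_80_retained(self):
        out = center_fragments(frags([("1", 0, 80)]), seed=0)
        assert len(out) == 1

    def test_even_length_two_centers_reproducible(self):
        f = frags([("1", 100, 130)])
        results = {tuple(center_fragments(f, seed=s).iloc[0][["start", "end"]])
                   for s in range(20)}
        assert results <= {(104, 124), (105, 125)}
        assert len(results) == 2  # both centers occur over seeds
        a = center_fragments(f, seed=3)
        b = center_fragments(f, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_outputs_exactly_20bp_within_bounds(self):
        rng = np.random.default_rng(11)
        rows = [("1", 500, 520)]  # exactly 20 bp: clamp must bind
        for _ in range(200):
            s = int(rng.integers(0, 10_000))
            rows.append(("1", s, s + int(rng.integers(20, 81))))
        out = center_fragments(frags(rows), seed=1)
        width = out["end"] - out["start"]
        assert (width == 20).all()
        merged = out.join(frags(rows), rsuffix="_orig")
        assert (out["start"] >= merged["start_orig"]).all()
        assert (out["end"] <= merged["end_orig"]).all()


def rep_fp(counts, chrom="1"):
    rows = []
    for i, c in enumerate(counts):
        rows.append({"chrom": chrom, "start": 100 * i, "end": 100 * i + 34,
                     **dict(zip(REPLICATE_COLUMNS, c))})
    return pd.DataFrame(rows)


class TestDifferentialOccupancy:
    def test_identical_replicates_all_stable(self):
        fp = rep_fp([[50, 55, 60, 50, 55, 60]] * 5 + [[10, 12, 9, 10, 12, 9]] * 5)
        out = differential_occupancy(fp)
        assert (out["status"] == "stable").all()

    def test_planted_fourfold_recovered(self, rng):
        rows = []
        truth = []
        for _ in range(150):
            base = rng.uniform(30, 100)
            enriched = rng.uniform() < 0.3
            fold = 4.0 if enriched else 1.0
            rows.append(
                list(rng.poisson(base, 3)) + list(rng.poisson(base * fold, 3))
            )
            truth.append(enriched)
        out = differential_occupancy(rep_fp(rows))
        truth = np.array(truth)
        called = (out["status"] == "heat_enriched").to_numpy()
        assert called[truth].mean() >= 0.8
        assert called[~truth].mean() <= 0.1

    def test_label_swap_symmetry(self, rng):
        rows = [list(rng.poisson(50, 3)) + list(rng.poisson(200, 3)) for _ in range(40)]
        fp = rep_fp(rows)
        out1 = differential_occupancy(fp)
        swapped = fp.rename(
            columns={"control_1": "heat_1", "control_2": "heat_2",
                     "control_3": "heat_3", "heat_1": "control_1",
                     "heat_2": "control_2", "heat_3": "control_3"}
        )
        out2 = differential_occupancy(swapped)
        flip = {"heat_enriched": "heat_depleted", "heat_depleted": "heat_enriched",
                "stable": "stable"}
        assert (out1["status"].map(flip) == out2["status"]).all()

    def test_missing_replicates_rejected(self):
        with pytest.raises(ValueError, match="statuses"):
            differential_occupancy(fp_frame([("1", 0, 34, "stable")]))


class TestAssignFootprints:
    def test_flank_boundary_no_shared_base(self):
        # gene body BED [9999, 12000); 2-kb flank starts at 7999.
        # footprint ending exactly at 7999 (half-open) shares no base
        genes = genes_frame([{}])
        fp = fp_frame([("1", 7965, 7999, "stable"), ("1", 7965, 8000, "stable")])
        out = assign_footprints(fp, genes)
        assigned = out.iloc[0]["footprints_flank"]
        assert list(assigned) == [1]

    def test_minus_strand_promoter_downstream_in_genomic_coords(self):
        genes = genes_frame([{"strand": "-"}])  # TSS at end=12000
        fp = fp_frame([("1", 12500, 12534, "stable"), ("1", 9000, 9034, "stable")])
        out = assign_footprints(fp, genes)
        assert list(out.iloc[0]["footprints_promoter"]) == [0]

    def test_generated_promoter_footprints_assigned_to_intended_gene(self, cohort):
        G, genes, _, truth, fp = cohort
        out = assign_footprints(fp, genes).set_index("gene_id")
        gmeta = genes.set_index("gene_id")
        checked = 0
        for row in fp.itertuples():
            g = gmeta.loc[row.intended_gene]
            # restrict to footprints fully inside the strand-aware promoter
            if g.strand == "+":
                lo, hi = g.tss - 1 - 2000, g.tss - 1
            else:
                lo, hi = g.tss, g.tss + 2000
            if lo <= row.start and row.end <= hi:
                assert row.Index in set(out.loc[row.intended_gene, "footprints_promoter"])
                checked += 1
        assert checked > 20

    def test_translation_invariance(self):
        genes = genes_frame([{}, {"gene_id": "gB", "start": 50_000, "end": 51_000}])
        fp = fp_frame(
            [("1", 9000, 9034, "heat_enriched"), ("1", 49_500, 49_534, "stable")]
        )
        base = assign_footprints(fp, genes)
        shift = 7_345
        genes2 = genes.copy()
        for c in ("start", "end", "tss", "tts"):
            genes2[c] += shift
        fp2 = fp.copy()
        fp2[["start", "end"]] += shift
        moved = assign_footprints(fp2, genes2)
        for col in ("footprints_flank", "footprints_promoter", "footprints_gene_body"):
            for a, b in zip(base[col], moved[col]):
                assert list(a) == list(b)
        assert base["has_heat_enriched"].tolist() == moved["has_heat_enriched"].tolist()


class TestEnrichment:
    def test_equal_presence_rates_not_enriched(self):
        assignments = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(40)],
             "has_heat_enriched": [i % 2 == 0 for i in range(40)]}
        )
        up = {f"g{i}" for i in range(20)}
        bg = {f"g{i}" for i in range(20, 40)}
        _, p = enrichment_vs_background(assignments, up, bg)
        assert p >= 0.5

    def test_table_matches_fisher_oracle(self):
        assignments = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(200)],
             "has_heat_enriched": [i < 30 or (100 <= i < 110) for i in range(200)]}
        )
        up = {f"g{i}" for i in range(100)}
        bg = {f"g{i}" for i in range(100, 200)}
        table, p = enrichment_vs_background(assignments, up, bg)
        np.testing.assert_array_equal(table, [[30, 70], [10, 90]])
        assert p == pytest.approx(fisher_greater(table), rel=1e-10)
        assert p == pytest.approx(fisher_exact(table, "greater"), rel=1e-12)

    def test_overlapping_sets_rejected(self):
        assignments = pd.DataFrame({"gene_id": ["g1"], "has_heat_enriched": [True]})
        with pytest.raises(ValueError, match="disjoint"):
            enrichment_vs_background(assignments, {"g1"}, {"g1"})


def rescan_results(rows):
    return pd.DataFrame(rows, columns=["variant_id", "pos", "p_raw"])


class TestTopVariantOverlap:
    def test_causal_top_variant_inside_flagged(self):
        genes = genes_frame([{}])
        fp = fp_frame([("1", 10_499, 10_534, "heat_enriched")])
        res = {"gA": rescan_results([("v1", 10_500, 1e-9), ("v2", 11_000, 0.5)])}
        flags, props = top_variant_overlap(res, fp, genes)
        assert bool(flags.iloc[0]["flagged"])
        assert props.iloc[0]["proportion"] == 1.0

    def test_variant_at_interval_end_not_inside(self):
        genes = genes_frame([{}])
        # interval [10499, 10534): 1-based position 10535 maps to 0-based 10534
        fp = fp_frame([("1", 10_499, 10_534, "heat_enriched")])
        res = {"gA": rescan_results([("v1", 10_535, 1e-9)])}
        flags, _ = top_variant_overlap(res, fp, genes)
        assert not bool(flags.iloc[0]["flagged"])

    def test_status_filter_excludes_stable(self):
        genes = genes_frame([{}])
        fp = fp_frame([("1", 10_499, 10_534, "stable")])
        res = {"gA": rescan_results([("v1", 10_500, 1e-9)])}
        flags, _ = top_variant_overlap(res, fp, genes)
        assert not bool(flags.iloc[0]["flagged"])

    def test_only_top_k_considered(self):
        genes = genes_frame([{}])
        fp = fp_frame([("1", 10_499, 10_534, "heat_enriched")])
        res = {
            "gA": rescan_results(
                [("v1", 11_000, 1e-9), ("v2", 11_100, 1e-8), ("v3", 11_200, 1e-7),
                 ("v4", 10_500, 1e-2)]  # inside, but ranked 4th
            )
        }
        flags, _ = top_variant_overlap(res, fp, genes, top_k=3)
        assert not bool(flags.iloc[0]["flagged"])


class TestInsideOutside:
    def test_identical_values_p_one(self):
        genes = genes_frame([{}])
        fp = fp_frame([("1", 10_000, 11_000, "heat_enriched")])
        res = {"gA": rescan_results(
            [("v1", 10_500, 1e-4), ("v2", 10_600, 1e-4), ("v3", 13_000, 1e-4),
             ("v4", 13_100, 1e-4)]
        )}
        out = inside_outside_comparison(res, fp, genes)
        assert out.iloc[0]["p"] >= 0.999
        assert out.iloc[0]["n_in"] == 2 and out.iloc[0]["n_out"] == 2

    def test_complete_separation_three_vs_three(self):
        genes = genes_frame([{}])
        fp = fp_frame([("1", 10_000, 11_000, "heat_enriched")])
        res = {"gA": rescan_results(
            [("v1", 10_100, 1e-9), ("v2", 10_200, 1e-8), ("v3", 10_300, 1e-7),
             ("v4", 13_000, 1e-2), ("v5", 13_100, 1e-1), ("v6", 13_200, 0.5)]
        )}
        out = inside_outside_comparison(res, fp, genes)
        assert out.iloc[0]["p"] == pytest.approx(0.1)
        assert out.iloc[0]["median_in"] > out.iloc[0]["median_out"]

    def test_empty_side_not_computable(self):
        genes = genes_frame([{}])
        fp = fp_frame([("1", 10_000, 11_000, "heat_enriched")])
        res = {"gA": rescan_results([("v1", 10_100, 1e-9)])}
        out = inside_outside_comparison(res, fp, genes)
        assert np.isnan(out.iloc[0]["p"])


class TestRelativePosition:
    def test_midpoint_at_tss_is_genic(self):
        g = gene_row()
        d_tss, _, klass = relative_position(10_000, g)
        assert d_tss == 0 and klass == "genic"

    def test_plus_strand_proximal_upstream(self):
        g = gene_row()
        d_tss, _, klass = relative_position(9_500, g)
        assert d_tss == -500 and klass == "proximal_upstream"

    def test_minus_strand_mirror(self):
        g = gene_row(strand="-")  # TSS at 12000
        d_tss, _, klass = relative_position(12_500, g)
        assert d_tss == -500 and klass == "proximal_upstream"

    def test_distal_downstream(self):
        g = gene_row()
        _, d_tts, klass = relative_position(15_000, g)
        assert d_tts == 3_000 and klass == "distal_downstream"

    def test_chromosome_mismatch_rejected(self):
        with pytest.raises(ValueError, match="chromosome"):
            relative_position(10_000, gene_row(), chrom="2")
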