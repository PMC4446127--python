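import numpy as np
import pandas as pd
import pytest

from promdir import directionality as dr
from promdir.cage import count_tags_table
from promdir.genome_io import GeneModel, GenomicInterval


def cl(start, end, strand, name="."):
    return GenomicInterval("c", start, end, name=name, score=1.0, strand=strand)


def tss_cluster(gene):
    return cl(gene.tss - 2, gene.tss + 3, gene.strand, name=gene.gene_id)


class TestCallActive:
    def test_overlapping_cluster_distance_zero(self):
        g = GeneModel("g", "c", "+", 5000)
        assert dr.call_active([g], [cl(5003, 5040, "+")]) == {"g"}

    def test_distance_eleven_is_inactive(self):
        g = GeneModel("g", "c", "+", 5000)
        assert dr.call_active([g], [cl(5011, 5040, "+")]) == set()
        assert dr.call_active([g], [cl(5010, 5040, "+")]) == {"g"}

    def test_strand_must_match(self):
        g = GeneModel("g", "c", "+", 5000)
        assert dr.call_active([g], [cl(4995, 5005, "-")]) == set()

    def test_generated_genes_are_all_active(self, small_sim):
        active = dr.call_active(small_sim.genes, small_sim.cage_clusters)
        assert active == {g.gene_id for g in small_sim.genes}


class TestAnnotate:
    def test_opposite_gene_within_1kb_makes_both_ensembl_bi(self):
        a = GeneModel("a", "c", "+", 5000)
        b = GeneModel("b", "c", "-", 5600)
        ann = dr.annotate([a, b], [tss_cluster(a), tss_cluster(b)])
        assert ann.loc["a", "class_ensembl"] == "bi"
        assert ann.loc["b", "class_ensembl"] == "bi"
        # each TSS cluster is also the other's opposite-strand CAGE evidence
        assert ann.loc["a", "class_combined"] == "bi"

    def test_disagreement_is_excluded(self):
        g = GeneModel("g", "c", "+", 5000)
        clusters = [tss_cluster(g), cl(4001, 4010, "-")]  # distance 991
        ann = dr.annotate([g], clusters)
        assert ann.loc["g", "class_cage"] == "bi"
        assert ann.loc["g", "class_ensembl"] == "uni"
        assert ann.loc["g", "class_combined"] == "excluded"

    def test_inactive_gene_is_na_everywhere(self):
        g = GeneModel("g", "c", "+", 5000)
        ann = dr.annotate([g], [])
        assert not ann.loc["g", "active"]
        assert ann.loc["g", "class_combined"] == "n/a"

    def test_combined_implies_both_rules(self, small_sim):
        ann = dr.annotate(small_sim.genes, small_sim.cage_clusters)
        for cls in ("uni", "bi"):
            sub = ann[ann["class_combined"] == cls]
            assert (sub["class_ensembl"] == cls).all()
            assert (sub["class_cage"] == cls).all()

    def test_strand_mirror_invariance(self, small_sim):
        """Reflecting the genome and flipping strands keeps all labels."""
        sim = small_sim
        L = sim.chrom_lengths[sim.config.chrom]
        flip = {"+": "-", "-": "+"}
        genes = [GeneModel(g.gene_id, g.chrom, flip[g.strand], L - 1 - g.tss)
                 for g in sim.genes]
        clusters = [GenomicInterval(c.chrom, L - c.end, L - c.start, c.name,
                                    c.score, flip[c.strand])
                    for c in sim.cage_clusters]
        ann = dr.annotate(sim.genes, sim.cage_clusters)
        mirrored = dr.annotate(genes, clusters)
        pd.testing.assert_frame_equal(
            ann[["active", "class_ensembl", "class_cage", "class_combined"]],
            mirrored[["active", "class_ensembl", "class_cage",
                      "class_combined"]])

    def test_recovers_planted_classes(self, small_sim):
        ann = dr.annotate(small_sim.genes, small_sim.cage_clusters)
        truth = small_sim.truth.set_index("gene_id")["true_class"]
        recovery = (ann["class_combined"] == truth).mean()
        assert recovery >= 0.95


class TestAgreement:
    @pytest.mark.parametrize("ens,cage,expected", [
        (["uni"] * 4, ["uni"] * 4, 100.0),
        (["uni"] * 4, ["bi"] * 4, 0.0),
        (["uni"] * 8 + ["bi"] * 2, ["uni"] * 6 + ["bi"] * 4, 80.0),
    ])
    def test_ratio_definition(self, ens, cage, expected):
        ann = pd.DataFrame({
            "active": True, "class_ensembl": ens, "class_cage": cage,
        }, index=[f"g{i}" for i in range(len(ens))])
        assert dr.agreement(ann) == pytest.approx(expected)

    def test_no_active_genes_is_missing(self):
        ann = pd.DataFrame({"active": [False], "class_ensembl": ["n/a"],
                            "class_cage": ["n/a"]}, index=["g"])
        assert np.isnan(dr.agreement(ann))


def make_annotation(active, classes):
    return pd.DataFrame({
        "active": active,
        "class_combined": [c if a else "n/a" for a, c in zip(active, classes)],
    }, index=[f"g{i}" for i in range(len(active))])


class TestCrossSampleConsistency:
    def test_identical_annotations_fully_consistent(self):
        a = make_annotation([True, True, False], ["uni", "bi", "uni"])
        hist, labels = dr.cross_sample_consistency([a, a.copy()])
        assert hist.loc[2] == 2 and hist.loc[0] == 1
        assert set(labels) == {"uni", "bi"}

    def test_conflicting_gene_is_mixed(self):
        a = make_annotation([True], ["bi"])
        b = make_annotation([True], ["uni"])
        _, labels = dr.cross_sample_consistency([a, b])
        assert labels.loc["g0"] == "mixed"

    def test_mismatched_universe_raises(self):
        a = make_annotation([True], ["uni"])
        b = make_annotation([True, True], ["uni", "uni"])
        with pytest.raises(ValueError, match="universe"):
            dr.cross_sample_consistency([a, b])

    def test_planted_shared_activity(self, small_sim):
        """Subsampled activity keeps directionality consistent across samples."""
        from promdir.synthetic import subsample_activity
        sim = small_sim
        anns = []
        for s in (1, 2):
            clusters, _ = subsample_activity(sim, 0.7, seed=s)
            anns.append(dr.annotate(sim.genes, clusters))
        hist, labels = dr.cross_sample_consistency(anns)
        assert hist.sum() == len(sim.genes)
        # genes active in both samples keep their planted class
        truth = sim.truth.set_index("gene_id")["true_class"]
        both = labels[labels != "mixed"]
        assert (both == truth.loc[both.index]).mean() >= 0.95


class TestUpstreamAltTss:
    def test_upstream_cluster_disqualifies(self):
        g = GeneModel("g", "c", "+", 5000)
        clusters = [tss_cluster(g), cl(4495, 4506, "+")]  # at tss-500
        assert dr.filter_no_upstream_alt_tss([g], clusters) == []

    def test_own_tss_cluster_does_not_disqualify(self):
        g = GeneModel("g", "c", "+", 5000)
        assert dr.filter_no_upstream_alt_tss([g], [tss_cluster(g)]) == ["g"]

    def test_downstream_cluster_does_not_disqualify(self):
        g = GeneModel("g", "c", "+", 5000)
        clusters = [tss_cluster(g), cl(5495, 5506, "+")]
        assert dr.filter_no_upstream_alt_tss([g], clusters) == ["g"]

    def test_minus_strand_mirrors(self):
        g = GeneModel("g", "c", "-", 5000)
        upstream = cl(5495, 5506, "-")  # higher coordinate = upstream for '-'
        assert dr.filter_no_upstream_alt_tss([g], [tss_cluster(g), upstream]) == []

    def test_matches_brute_force_on_random_placements(self, rng):
        genes = [GeneModel(f"g{i}", "c", "+" if i % 2 else "-",
                           int(5000 + i * 4000)) for i in range(10)]
        clusters = []
        for _ in range(60):
            s = int(rng.integers(1000, 45000))
            strand = "+" if rng.random() < 0.5 else "-"
            clusters.append(cl(s, s + int(rng.integers(1, 30)), strand))
        got = set(dr.filter_no_upstream_alt_tss(genes, clusters))
        expected = set()
        for g in genes:
            bad = False
            for c in clusters:
                if c.strand != g.strand:
                    continue
                for pos in range(c.start, c.end):
                    u = g.tss - pos if g.strand == "+" else pos - g.tss
                    if 10 < u <= 1000:
                        bad = True
            if not bad:
                expected.add(g.gene_id)
        assert got == expected

    def test_generator_alt_tss_flags_recovered(self, small_sim):
        sim = small_sim
        truth = sim.truth.set_index("gene_id")
        uni = [g for g in sim.genes
               if truth.loc[g.gene_id, "true_class"] == "uni"]
        kept = set(dr.filter_no_upstream_alt_tss(uni, sim.cage_clusters))
        for g in uni:
            assert (g.gene_id not in kept) == truth.loc[g.gene_id, "alt_tss"]
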