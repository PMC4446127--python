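import itertools

import numpy as np
import pandas as pd
import pytest

from promdir import motifs
from promdir.footprints import SignalMatrix
from promdir.genome_io import GeneModel
from promdir.motifs import (
    PWM,
    SequenceRegion,
    correlation_matrix,
    ctcf_group,
    encode,
    exact_score_tail,
    motif_coverage,
    pvalue_lookup,
    read_jaspar,
    scan,
    write_jaspar,
)


def toy_pwm(consensus="ACGT", major=20, minor=2):
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    counts = np.full((4, len(consensus)), minor, dtype=float)
    for j, b in enumerate(consensus):
        counts[code[b], j] = major
    return PWM(counts)


def region(seq, chrom="c", start=0):
    return SequenceRegion(chrom, start, encode(seq))


def revcomp(s):
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


class TestPWM:
    def test_consensus_and_jaspar_round_trip(self, tmp_path):
        pwm = toy_pwm("ACGTAC")
        assert pwm.consensus() == "ACGTAC"
        p = tmp_path / "m.pcm"
        write_jaspar(p, pwm.counts, name="toy")
        name, counts = read_jaspar(p)
        assert name == "toy"
        assert np.array_equal(counts, pwm.counts)

    def test_consensus_maximizes_log_odds(self):
        pwm = toy_pwm("ACGT")
        lom = pwm.log_odds_int
        best = sum(int(lom[:, j].max()) for j in range(4))
        scores, valid = motifs._window_scores(encode("ACGT"), lom)
        assert valid.all() and scores[0] == best


class TestExactPValues:
    @pytest.mark.parametrize("consensus", ["ACG", "GGTACC"])
    def test_dp_matches_full_kmer_enumeration(self, consensus):
        """Exact tail probabilities equal brute-force enumeration of 4^L k-mers."""
        pwm = toy_pwm(consensus)
        lom = pwm.log_odds_int
        L = pwm.length
        min_score, tail = exact_score_tail(pwm)
        # enumerate every k-mer score under the uniform background
        all_scores = sorted(
            sum(int(lom[b, j]) for j, b in enumerate(kmer))
            for kmer in itertools.product(range(4), repeat=L))
        for s in {all_scores[0], all_scores[len(all_scores) // 2],
                  all_scores[-1]}:
            expected = sum(1 for x in all_scores if x >= s) / 4 ** L
            got = pvalue_lookup(min_score, tail, np.array([s]))[0]
            assert got == pytest.approx(expected, rel=1e-9)

    def test_max_score_pvalue_counts_maximal_kmers(self):
        pwm = toy_pwm("ACG")
        min_score, tail = exact_score_tail(pwm)
        lom = pwm.log_odds_int
        max_s = sum(int(lom[:, j].max()) for j in range(3))
        n_max = 1  # a single consensus trimer attains the maximum
        p = pvalue_lookup(min_score, tail, np.array([max_s]))[0]
        assert p == pytest.approx(n_max / 64)


class TestScan:
    def test_consensus_hit_found_on_both_strand_representations(self):
        pwm = toy_pwm("ACGTACGT")
        bg = "".join("ACGT"[i % 4] for i in range(0, 400, 7))  # scrambles
        seq = "TTTTGGGG" * 40 + "ACGTACGT" + "TTTTGGGG" * 40
        hits = scan(pwm, [region(seq)], q_threshold=0.05,
                    background=np.full(4, 0.25))
        plus = hits[hits["strand"] == "+"]
        assert (plus["start"] == 320).any()

    def test_reverse_complement_symmetry(self):
        pwm = toy_pwm("ACGGTC")
        seq = "TGCATGCAACGGTCTGCATGCATGCA"
        fwd = scan(pwm, [region(seq)], 1.0, np.full(4, 0.25))
        rev = scan(pwm, [region(revcomp(seq))], 1.0, np.full(4, 0.25))
        n = len(seq)
        mapped = sorted(
            (n - int(r.end), "-" if r.strand == "+" else "+",
             round(r.score, 6))
            for r in rev.itertuples())
        orig = sorted((int(r.start), r.strand, round(r.score, 6))
                      for r in fwd.itertuples())
        assert mapped == orig

    def test_short_sequence_gives_no_windows(self):
        pwm = toy_pwm("ACGTAC")
        assert len(scan(pwm, [region("ACG")], 1.0, np.full(4, 0.25))) == 0

    def test_n_windows_are_skipped(self):
        pwm = toy_pwm("ACGT")
        hits = scan(pwm, [region("NNACGTNN")], 1.0, np.full(4, 0.25))
        # only windows free of N are scanned: starts 2..2 (span 2-6)
        assert set(hits["start"]) <= {2}

    def test_bh_qvalues_match_step_up_rule(self, rng):
        """q <= alpha selection equals the brute-force BH step-up."""
        pwm = toy_pwm("ACGTA", major=10, minor=3)
        seq = "".join(rng.choice(list("ACGT"), size=3000))
        hits = scan(pwm, [region(seq)], q_threshold=1.0,
                    background=np.full(4, 0.25))
        p = np.sort(hits["p"].to_numpy())
        alpha = 0.4
        m = 2 * (3000 - 5 + 1)
        thresh = 0.0
        for k in range(len(p), 0, -1):
            if p[k - 1] <= alpha * k / m:
                thresh = p[k - 1]
                break
        brute = set(hits.index[hits["p"] <= thresh])
        step = set(hits.index[hits["q"] <= alpha])
        assert brute == step


class TestMotifCoverage:
    def gene(self, strand="+", tss=5000):
        return GeneModel("g", "c", strand, tss)

    def hits_at(self, starts, length=19, strand="+"):
        return pd.DataFrame({
            "chrom": "c", "start": starts,
            "end": [s + length for s in starts], "strand": strand,
        })

    def test_concentrated_hits_give_their_center(self):
        g = self.gene()
        # 19-bp hits centered at tss-81, jittered ±15 so the smoothed
        # profile is strictly unimodal
        rng = np.random.default_rng(0)
        centers = 5000 - 81 + rng.integers(-15, 16, size=400)
        hits = self.hits_at([int(c) - 9 for c in centers])
        _, _, site = motif_coverage(hits, [g])
        assert abs(site - (-81)) <= 3

    def test_single_hit_plateau_tie_breaks_toward_tss(self):
        """A 1-bp delta at -81 smooths to a flat plateau; the documented
        tie-break picks the plateau edge closest to the TSS (-61)."""
        g = self.gene()
        hits = self.hits_at([5000 - 81], length=1)
        _, smoothed, site = motif_coverage(hits, [g])
        assert site == -61

    def test_no_hits_site_undefined(self):
        raw, smoothed, site = motif_coverage(self.hits_at([]), [self.gene()])
        assert site is None and raw.sum() == 0

    def test_minus_strand_gene_mirrors_relative_positions(self):
        gp = GeneModel("p", "c", "+", 5000)
        gm = GeneModel("m", "c", "-", 5000)
        hits = self.hits_at([5000 - 90])  # spans -90..-72 for the + gene
        raw_p, _, _ = motif_coverage(hits, [gp])
        raw_m, _, _ = motif_coverage(hits, [gm])
        assert np.array_equal(raw_p, raw_m[::-1])

    def test_per_start_mode_counts_five_prime_base(self):
        g = self.gene()
        hits = self.hits_at([5000 - 90], strand="-")
        raw, _, _ = motif_coverage(hits, [g], per_base=False)
        # 5'-most base of a minus-strand hit is its highest coordinate
        assert raw.sum() == 1
        assert raw[1000 - 90 + 18] == 1


class TestCtcfGroup:
    def make_matrix(self, ids, total):
        vals = np.zeros((len(ids), 2001))
        for i, t in enumerate(total):
            vals[i, 900:1100] = t / 200.0  # row sums to t
        return SignalMatrix(vals, ids, 1000)

    def test_boundary_inclusive(self):
        g = GeneModel("g", "c", "+", 5000)
        # hit 5' base at -180 = site(-80) - 100: inclusive
        hits = pd.DataFrame({"chrom": ["c"], "start": [5000 - 180],
                             "end": [5000 - 161], "strand": ["+"]})
        mat = self.make_matrix(["g"], [100 * 147])
        grp = ctcf_group([g], hits, -80, mat)
        assert grp["g"] == "CTCF"

    def test_distance_101_is_excluded(self):
        g = GeneModel("g", "c", "+", 5000)
        hits = pd.DataFrame({"chrom": ["c"], "start": [5000 - 181],
                             "end": [5000 - 162], "strand": ["+"]})
        mat = self.make_matrix(["g"], [100 * 147])
        assert ctcf_group([g], hits, -80, mat)["g"] == "Non-CTCF"

    def test_read_count_rule(self):
        g = GeneModel("g", "c", "+", 5000)
        hits = pd.DataFrame({"chrom": ["c"], "start": [5000 - 85],
                             "end": [5000 - 66], "strand": ["+"]})
        low = self.make_matrix(["g"], [99 * 147])
        high = self.make_matrix(["g"], [100 * 147])
        assert ctcf_group([g], hits, -80, low)["g"] == "Non-CTCF"
        assert ctcf_group([g], hits, -80, high)["g"] == "CTCF"

    def test_planted_group_recovery(self, default_sim):
        """Pipeline-level CTCF group recovers the planted peak+motif genes."""
        from promdir import footprints
        from promdir.genome_io import build_coverage

        sim = default_sim
        truth = sim.truth.set_index("gene_id")
        uni = [g for g in sim.genes
               if truth.loc[g.gene_id, "true_class"] == "uni"]
        regions = motifs.regions_from_genes(sim.sequences, sim.genes)
        hits = scan(PWM(sim.pcm), regions)
        _, _, site = motif_coverage(hits, uni)
        track = build_coverage(sim.chip_reads["CTCF"], sim.chrom_lengths)
        mat = footprints.window_matrix(track, uni)
        grp = ctcf_group(uni, hits, site, mat)
        planted = (truth.loc[grp.index, "ctcf_peak"]
                   & truth.loc[grp.index, "motif"])
        assert ((grp == "CTCF") == planted).mean() >= 0.95


class TestCorrelationMatrix:
    def frame(self, up, down):
        return pd.DataFrame({"upstream": up, "downstream": down},
                            index=[f"g{i}" for i in range(len(up))])

    def test_perfect_positive_and_negative(self):
        x = pd.Series([1.0, 2, 3, 4], index=[f"g{i}" for i in range(4)])
        sums = {"M": self.frame(2 * x.values, -x.values + 10)}
        groups = pd.Series("CTCF", index=x.index)
        out = correlation_matrix(x, sums, groups)
        up = out[(out["mark"] == "M") & (out["side"] == "upstream")]
        down = out[(out["mark"] == "M") & (out["side"] == "downstream")]
        assert up["r"].iloc[0] == pytest.approx(1.0)
        assert down["r"].iloc[0] == pytest.approx(-1.0)

    def test_zero_variance_is_missing(self):
        x = pd.Series([1.0, 2, 3], index=list("abc"))
        sums = {"M": pd.DataFrame({"upstream": [5.0, 5, 5],
                                   "downstream": [1.0, 2, 4]},
                                  index=list("abc"))}
        out = correlation_matrix(x, sums, pd.Series("G", index=x.index))
        up = out[out["side"] == "upstream"]["r"].iloc[0]
        assert np.isnan(up)

    def test_small_group_rejected(self):
        x = pd.Series([1.0, 2], index=list("ab"))
        sums = {"M": pd.DataFrame({"upstream": [1.0, 2],
                                   "downstream": [1.0, 2]}, index=list("ab"))}
        with pytest.raises(ValueError, match="fewer than 3"):
            correlation_matrix(x, sums, pd.Series("G", index=x.index))

    def test_independent_noise_is_near_zero(self, rng):
        n = 1000
        idx = [f"g{i}" for i in range(n)]
        x = pd.Series(rng.normal(size=n), index=idx)
        sums = {"M": pd.DataFrame({"upstream": rng.normal(size=n),
                                   "downstream": rng.normal(size=n)},
                                  index=idx)}
        out = correlation_matrix(x, sums, pd.Series("G", index=idx))
        assert (out["r"].abs() < 0.1).all()
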