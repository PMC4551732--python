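"""Region partition, window rates, SNP-free segments, mixture EM, codon logic."""

import numpy as np
import pytest

from lepcompgen import snpdist, synthio
from lepcompgen.io import GeneModel, ScaffoldRecord, SnpRecord, revcomp
from lepcompgen.snpdist import CODON_TABLE


def _scaffold(n=10_000, seed=0):
    rng = np.random.default_rng(seed)
    return ScaffoldRecord("s1", "".join(rng.choice(list("ACGT"), size=n)))


class TestPartitionRegions:
    def test_single_gene_splits_scaffold(self):
        scf = _scaffold()
        g = GeneModel("g1", "s1", 1000, 1300, "+", [(1000, 1300)])
        part = snpdist.partition_regions([g], [], [scf], [("s1", 0, 10_000)])
        assert part.total_length("exon") == 300
        assert part.total_length("intergenic") == 9700

    def test_repeat_overlapping_exon_counts_as_exon(self):
        scf = _scaffold()
        g = GeneModel("g1", "s1", 1000, 1300, "+", [(1000, 1300)])
        part = snpdist.partition_regions(
            [g], [("s1", 1100, 1400)], [scf], [("s1", 0, 10_000)]
        )
        assert part.total_length("exon") == 300
        assert part.total_length("repeat") == 100  # only the non-exon tail

    def test_class_lengths_sum_to_diploid_length(self):
        scf = _scaffold()
        genes = [
            GeneModel("g1", "s1", 500, 2000, "+", [(500, 800), (1500, 1800)]),
            GeneModel("g2", "s1", 4000, 4600, "-", [(4000, 4600)]),
        ]
        repeats = [("s1", 700, 3000), ("s1", 9000, 9500)]
        diploid = [("s1", 100, 6000), ("s1", 8000, 9800)]
        part = snpdist.partition_regions(genes, repeats, [scf], diploid)
        total = sum(part.total_length(c) for c in part.CLASS_ORDER)
        assert total == (6000 - 100) + (9800 - 8000)

    def test_unknown_scaffold_rejected(self):
        g = GeneModel("g1", "sX", 0, 10, "+", [])
        with pytest.raises(ValueError, match="unknown scaffold"):
            snpdist.partition_regions([g], [], [_scaffold()], [("s1", 0, 100)])


class TestWindowRates:
    def _part(self, length=5000):
        scf = ScaffoldRecord("s1", "A" * length)
        return snpdist.partition_regions([], [], [scf], [("s1", 0, length)])

    def test_rate_of_ten_snps_in_window(self):
        part = self._part(1000)
        snps = [SnpRecord("s1", 10 * i, "A", "T") for i in range(1, 11)]
        track = snpdist.window_rates(snps, part, window=1000, step=1000)
        assert track == [("s1", 0, 0.01, "intergenic")]

    def test_short_interval_emits_nothing(self):
        part = self._part(500)
        assert snpdist.window_rates([], part, window=1000) == []

    def test_nonoverlapping_windows_conserve_snp_count(self):
        part = self._part(5000)
        rng = np.random.default_rng(3)
        pos = rng.choice(5000, size=120, replace=False)
        snps = [SnpRecord("s1", int(p), "A", "T") for p in pos]
        track = snpdist.window_rates(snps, part, window=1000, step=1000)
        covered = sum(r * 1000 for _, _, r, _ in track)
        n_in_span = sum(1 for p in pos if p < 5000)
        assert covered == n_in_span


class TestSnpFreeSegments:
    def test_interval_without_snps_is_one_segment(self):
        segs, mx = snpdist.snp_free_segments([], [("s1", 0, 5000)])
        assert segs == [("s1", 0, 5000)] and mx == 5000

    def test_snp_splits_interval_excluding_position(self):
        snps = [SnpRecord("s1", 2000, "A", "T")]
        segs, mx = snpdist.snp_free_segments(snps, [("s1", 0, 5000)], min_len=1000)
        assert segs == [("s1", 0, 2000), ("s1", 2001, 5000)]
        assert mx == 2999

    def test_planted_free_blocks_recovered(self, small_diploid):
        t = small_diploid
        snps = [SnpRecord("hap1", p, t.hap1[p], t.hap2[p]) for p in sorted(t.snp_positions)]
        diploid = [("hap1", 0, t.length)]
        segs, _ = snpdist.snp_free_segments(snps, diploid, min_len=1000)
        for s, e, cls in t.block_table:
            if cls == "free" and e - s >= 1000:
                assert any(ss <= s and e <= se for _, ss, se in segs)


class TestMixture:
    def test_single_component_recovery_and_selection(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0.024, 0.004, 5000)
        f1, f2 = snpdist.fit_mixture(x, 1), snpdist.fit_mixture(x, 2)
        assert snpdist.select_model(f1, f2).n_components == 1
        assert f1.means[0] == pytest.approx(0.024, abs=0.001)

    def test_two_component_recovery(self):
        rng = np.random.default_rng(13)
        x = np.concatenate(
            [rng.normal(0.0035, 0.001, 2500), rng.normal(0.025, 0.004, 2500)]
        )
        f1, f2 = snpdist.fit_mixture(x, 1), snpdist.fit_mixture(x, 2)
        chosen = snpdist.select_model(f1, f2)
        assert chosen.n_components == 2
        assert chosen.means[0] == pytest.approx(0.0035, rel=0.2)
        assert chosen.means[1] == pytest.approx(0.025, rel=0.2)
        assert chosen.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert f2.loglik >= f1.loglik  # nested models

    def test_agrees_with_sklearn(self):
        """Independent oracle: sklearn's EM finds the same two components."""
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(17)
        x = np.concatenate(
            [rng.normal(0.004, 0.001, 2000), rng.normal(0.024, 0.004, 2000)]
        )
        ours = snpdist.fit_mixture(x, 2)
        gm = GaussianMixture(2, covariance_type="spherical", tol=1e-8, random_state=0)
        gm.fit(x.reshape(-1, 1))
        ref_means = np.sort(gm.means_.ravel())
        assert ours.means == pytest.approx(ref_means, rel=0.02)

    def test_degenerate_input_rejected_for_two_components(self):
        with pytest.raises(ValueError, match="degenerate"):
            snpdist.fit_mixture(np.full(100, 0.01), 2)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            snpdist.fit_mixture(np.arange(10, dtype=float), 1)


def _gene_with_cds(seq, start, strand="+"):
    scf = ScaffoldRecord("s1", seq)
    g = GeneModel("g1", "s1", start, start + 6, strand, [(start, start + 6)])
    return scf, g


class TestClassifySnpEffect:
    def test_plus_strand_nonsynonymous(self):
        scf, g = _gene_with_cds("ATGAAA", 0)
        # ATG -> ATA: M -> I
        snp = SnpRecord("s1", 2, "G", "A")
        assert snpdist.classify_snp_effect(snp, g, scf.sequence) == "nonsynonymous"

    def test_plus_strand_synonymous(self):
        scf, g = _gene_with_cds("GCTAAA", 0)
        # GCT -> GCC: A -> A
        snp = SnpRecord("s1", 2, "T", "C")
        assert snpdist.classify_snp_effect(snp, g, scf.sequence) == "synonymous"

    def test_noncoding_outside_cds(self):
        seq = "TTTATGAAATTT"
        scf = ScaffoldRecord("s1", seq)
        g = GeneModel("g1", "s1", 3, 12, "+", [(3, 9)])
        snp = SnpRecord("s1", 10, seq[10], "C" if seq[10] != "C" else "G")
        assert snpdist.classify_snp_effect(snp, g, scf.sequence) == "noncoding"

    def test_ref_mismatch_rejected(self):
        scf, g = _gene_with_cds("ATGAAA", 0)
        snp = SnpRecord("s1", 0, "C", "T")  # scaffold has A
        with pytest.raises(ValueError, match="disagrees"):
            snpdist.classify_snp_effect(snp, g, scf.sequence)

    def test_minus_strand_consistency_with_plus(self):
        """A SNP on a minus-strand gene classifies like its reverse complement
        on the equivalent plus-strand gene."""
        coding = "ATGGCTAAA"  # M A K
        genome_minus = revcomp(coding)
        scf = ScaffoldRecord("s1", genome_minus)
        g = GeneModel("g1", "s1", 0, 9, "-", [(0, 9)])
        # mutate codon GCT (A) -> GTT (V): coding pos 4 C->T;
        # genome coordinate = 9-1-4 = 4, bases complemented
        snp = SnpRecord("s1", 4, revcomp("C"), revcomp("T"))
        assert snpdist.classify_snp_effect(snp, g, scf.sequence) == "nonsynonymous"

    def test_exhaustive_codon_oracle(self):
        """All 576 single-base codon changes match brute-force translation."""
        mismatches = 0
        for codon in CODON_TABLE:
            for off in range(3):
                for alt in "ACGT":
                    if alt == codon[off]:
                        continue
                    scf, g = _gene_with_cds(codon + "AAA", 0)
                    snp = SnpRecord("s1", off, codon[off], alt)
                    got = snpdist.classify_snp_effect(snp, g, scf.sequence)
                    mutant = codon[:off] + alt + codon[off + 1 :]
                    want = (
                        "synonymous"
                        if CODON_TABLE[codon] == CODON_TABLE[mutant]
                        else "nonsynonymous"
                    )
                    mismatches += got != want
        assert mismatches == 0

    def test_codon_table_matches_biopython(self):
        """Cross-check the hard-coded genetic code against Biopython."""
        from Bio.Seq import Seq

        for codon, aa in CODON_TABLE.items():
            assert str(Seq(codon).translate()) == aa


class TestSubstitutionProfiles:
    def test_profiles_and_disorder_mask(self):
        seq = "ATGGCTAAATTTGGG"  # 5 codons: M A K F G
        scf = ScaffoldRecord("s1", seq)
        g = GeneModel("g1", "s1", 0, 15, "+", [(0, 15)])
        snps = [
            SnpRecord("s1", 4, "C", "T"),   # GCT->GTT nonsyn, aa 1
            SnpRecord("s1", 5, "T", "C"),   # GCT->GCC syn
            SnpRecord("s1", 9, "T", "C"),   # TTT->CTT nonsyn, aa 3
        ]
        masks = {"g1": [(1, 2)]}  # aa 1 disordered
        (prof,) = snpdist.substitution_profiles(snps, [g], {"s1": seq}, masks)
        assert prof.length == 5
        assert prof.substitution_count == 2
        assert prof.ordered_count == 1  # aa 1 masked out
        assert prof.ordered_length + prof.disordered_length == prof.length

    def test_zero_nonsyn_snps(self):
        seq = "ATGGCTAAA"
        g = GeneModel("g1", "s1", 0, 9, "+", [(0, 9)])
        (prof,) = snpdist.substitution_profiles([], [g], {"s1": seq})
        assert prof.substitution_count == 0


def test_coding_rate_below_noncoding_on_constrained_genomes():
    """Sign test: genomes simulated with purifying selection on exons show a
    lower exonic than intergenic SNP rate in every replicate."""
    wins = 0
    n_seeds = 6
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        L = 40_000
        seq = "".join(rng.choice(list("ACGT"), size=L))
        scf = ScaffoldRecord("s1", seq)
        # exons every 4 kb; exonic SNP rate 0.4x the intergenic rate
        genes = [
            GeneModel(f"g{i}", "s1", s, s + 1200, "+", [(s, s + 1200)])
            for i, s in enumerate(range(0, L - 1200, 4000))
        ]
        exonic = np.zeros(L, dtype=bool)
        for g in genes:
            exonic[g.start : g.end] = True
        rate = np.where(exonic, 0.008, 0.02)
        pos = np.nonzero(rng.random(L) < rate)[0]
        snps = [SnpRecord("s1", int(p), seq[p], "A" if seq[p] != "A" else "C") for p in pos]
        part = snpdist.partition_regions(genes, [], [scf], [("s1", 0, L)])
        track = snpdist.window_rates(snps, part, window=1000, step=500)
        ex = [r for _, _, r, c in track if c == "exon"]
        ig = [r for _, _, r, c in track if c == "intergenic"]
        wins += np.mean(ex) < np.mean(ig)
    assert wins == n_seeds
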