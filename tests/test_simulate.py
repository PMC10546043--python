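"""Digestion simulator: genome/profile generation, fragment geometry,
read generation, and the printed geometric anchors."""

import numpy as np
import pytest

import fmlseq as f
from conftest import complete_digestion, make_palindrome_genome


class TestGenerateGenome:
    def test_seed_determinism_and_alphabet(self):
        g1 = f.generate_genome(1000, seed=7)
        g2 = f.generate_genome(1000, seed=7)
        assert g1 == g2
        seq = next(iter(g1.values()))
        assert len(seq) == 1000 and set(seq) <= set("ACGT")

    def test_minimum_length(self):
        with pytest.raises(ValueError):
            f.generate_genome(99)
        assert len(f.generate_genome(100, seed=1)["chrS"]) == 100

    def test_cpg_enrichment(self):
        def cpg_freq(e):
            seq = f.generate_genome(200_000, cpg_enrichment=e, seed=5)["chrS"]
            return seq.count("CG") / (len(seq) - 1)

        f0, f2, f8 = cpg_freq(0.0), cpg_freq(2.0), cpg_freq(8.0)
        assert f0 < f2 < f8
        # at zero enrichment, CpG frequency ~ product of mononucleotide freqs
        seq = f.generate_genome(200_000, cpg_enrichment=0.0, seed=5)["chrS"]
        pc = seq.count("C") / len(seq)
        pg = seq.count("G") / len(seq)
        assert f0 == pytest.approx(pc * pg, rel=0.1)


class TestGenerateProfile:
    def test_extreme_modes(self, random_sites):
        up = f.generate_profile(random_sites, mode="all_methylated")
        down = f.generate_profile(random_sites, mode="all_unmethylated")
        assert set(up.fractions.values()) == {1.0}
        assert set(down.fractions.values()) == {0.0}
        assert len(up) == len(random_sites)

    def test_beta_reproducible_mean(self, random_sites):
        p1 = f.generate_profile(random_sites, mode="beta", a=2, b=2, seed=9)
        p2 = f.generate_profile(random_sites, mode="beta", a=2, b=2, seed=9)
        assert p1.fractions == p2.fractions
        vals = np.array(list(p1.fractions.values()))
        # Beta(2,2): mean 0.5, sd ~0.224; symmetric CpGs halve the effective n
        se = vals.std() / np.sqrt(len(vals) / 2)
        assert abs(vals.mean() - 0.5) < 3 * se

    def test_symmetric_cpg_pairing(self, random_sites):
        prof = f.generate_profile(random_sites, mode="beta", seed=3)
        for s in random_sites:
            if s.strand == "+":
                partner = (s.chrom, s.mc_pos + 1, "-")
                if partner in prof.fractions:
                    assert prof.fractions[partner] == prof.fraction_of(s)

    def test_table_validation(self, random_sites):
        with pytest.raises(ValueError):
            f.generate_profile(random_sites, mode="table",
                               fraction_table={("chrS", 1, "+"): 1.5})
        with pytest.raises(ValueError):
            f.MethylationProfile({("chrS", 1, "+"): -0.1})


class TestSimConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            f.SimConfig(digestion_prob=1.5)
        with pytest.raises(ValueError):
            f.SimConfig(read_length=10)


class TestDigest:
    def test_palindrome_32bp_insert(self, palindrome_genome):
        sites = f.scan_motifs(palindrome_genome, pattern="CGNR")
        frags, _, _ = complete_digestion(palindrome_genome, sites)
        lig = [fr for fr in frags if fr.ligatable]
        assert len(lig) == 1
        assert (lig[0].start, lig[0].end) == (85, 117)
        assert lig[0].length == 32

    def test_geometry_anchor_constants(self):
        assert f.minimum_flanking_insert() == 21
        assert f.palindromic_insert_length() == 32

    def test_unmethylated_yields_no_library(self, random_genome, random_sites):
        profile = f.generate_profile(random_sites, mode="all_unmethylated")
        frags = f.digest(random_genome, profile, config=f.SimConfig(n_copies=3, seed=1),
                         sites=random_sites)
        assert all(not fr.ligatable for fr in frags)

    def test_zero_digestion_prob(self, random_genome, random_sites):
        profile = f.generate_profile(random_sites, mode="all_methylated")
        cfg = f.SimConfig(n_copies=3, digestion_prob=0.0, seed=1)
        frags = f.digest(random_genome, profile, config=cfg, sites=random_sites)
        assert all(not fr.ligatable for fr in frags)

    def test_length_conservation_per_copy(self, random_genome, random_sites):
        """Fill-in duplicates each cut's 4-nt overhang into both flanking
        fragments, so per copy: sum(lengths) == contig + 4 * n_cuts."""
        profile = f.generate_profile(random_sites, mode="beta", seed=2)
        cfg = f.SimConfig(n_copies=4, digestion_prob=0.7, seed=2)
        frags = f.digest(random_genome, profile, config=cfg, sites=random_sites)
        contig_len = len(random_genome["chrS"])
        for copy_id in range(cfg.n_copies):
            copy = [fr for fr in frags if fr.copy_id == copy_id]
            n_cuts = len(copy) - 1
            assert sum(fr.length for fr in copy) == contig_len + 4 * n_cuts

    def test_fragment_count_monotone_in_digestion_prob(self, random_genome, random_sites):
        profile = f.generate_profile(random_sites, mode="beta", seed=4)
        counts = []
        for prob in (0.2, 0.5, 0.9):
            cfg = f.SimConfig(n_copies=10, digestion_prob=prob, seed=6)
            frags = f.digest(random_genome, profile, config=cfg, sites=random_sites,
                             rng=np.random.default_rng(6))
            counts.append(sum(fr.ligatable for fr in frags))
        assert counts[0] < counts[1] < counts[2]


class TestFragmentsToReads:
    def _one_fragment(self, genome):
        sites = f.scan_motifs(genome, pattern="CGNR")
        frags, cfg, rng = complete_digestion(genome, sites)
        return [fr for fr in frags if fr.ligatable], cfg, rng

    def test_read_coordinates_and_sequences(self, palindrome_genome):
        lig, cfg, rng = self._one_fragment(palindrome_genome)
        pairs = f.fragments_to_reads(palindrome_genome, lig, cfg, rng=rng)
        (p,) = pairs
        seq = palindrome_genome["chrP"]
        assert (p.start, p.end) == (85, 117)
        assert p.seq1 == seq[85:117][: cfg.read_length]
        assert p.seq2 == f.reverse_complement(seq[85:117])[: cfg.read_length]
        # read 2's 5' base sits at the insert's rightmost coordinate, 116
        assert p.end - 1 == 116

    def test_adapter_dimer_rate_one(self, palindrome_genome):
        lig, _, _ = self._one_fragment(palindrome_genome)
        cfg = f.SimConfig(n_copies=1, adapter_dimer_rate=1.0, seed=0)
        pairs = f.fragments_to_reads(palindrome_genome, lig * 10, cfg)
        assert len(pairs) == 10
        assert all(p.is_dimer and p.insert_len == 4 for p in pairs)

    def test_insert_size_filter(self, palindrome_genome):
        lig, _, _ = self._one_fragment(palindrome_genome)  # one 32-bp insert
        cfg = f.SimConfig(n_copies=1, adapter_dimer_rate=0.0, insert_min=30, seed=0)
        assert len(f.fragments_to_reads(palindrome_genome, lig, cfg)) == 1
        cfg = f.SimConfig(n_copies=1, adapter_dimer_rate=0.0, insert_min=33, seed=0)
        assert f.fragments_to_reads(palindrome_genome, lig, cfg) == []


class TestInsertHistogram:
    def test_examples(self, palindrome_genome):
        sites = f.scan_motifs(palindrome_genome, pattern="CGNR")
        frags, _, _ = complete_digestion(palindrome_genome, sites)
        lig = [fr for fr in frags if fr.ligatable]
        assert f.insert_length_histogram(lig) == {32: 1}
        assert f.insert_length_histogram([]) == {}
        assert f.insert_length_histogram([5, 5, 7]) == {5: 2, 7: 1}

    def test_palindrome_array_mode_at_32(self):
        """A genome of repeated well-separated palindromic CpGs digested
        completely has its insert-length mode at 32 bp."""
        seq = []
        for _ in range(30):
            seq.extend("A" * 60)
            seq.extend("TACGAG")
        seq.extend("A" * 60)
        genome = {"chrR": "".join(seq)}
        sites = f.scan_motifs(genome, pattern="CGNR")
        frags, _, _ = complete_digestion(genome, sites, n_copies=5, seed=8)
        hist = f.insert_length_histogram([fr for fr in frags if fr.ligatable])
        assert max(hist, key=hist.get) == 32
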