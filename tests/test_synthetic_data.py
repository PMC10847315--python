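import math

import numpy as np
import pytest

from hlasplice import scenarios as sc
from hlasplice import synthetic_data as sd
from hlasplice.gene_model import pyrimidine_fraction


class TestFixtureAlleles:
    def test_null_analog_carries_a_at_781_others_g(self, bundle):
        for name, allele in bundle.alleles.items():
            base = allele.sequence[sd.ALT_E3_MINUS2 - 1]
            assert base == ("A" if name == sd.NULL_ALLELE else "G")

    def test_both_cryptic_acceptors_end_in_ag(self, bundle):
        null = bundle.alleles[sd.NULL_ALLELE]
        assert null.subseq(781, 782) == "AG"
        for allele in bundle.alleles.values():
            assert allele.subseq(2518, 2519) == "AG"

    def test_cryptic_intron5_acceptor_is_18nt_upstream_of_exon6(self, bundle):
        assert bundle.gene_model.exon(6)[0] - sd.INTRON5_CRYPTIC == 18

    def test_acceptor_context_composition(self, bundle):
        for allele in bundle.alleles.values():
            assert pyrimidine_fraction(allele, sd.G_RICH_RANGE) <= 0.2
            assert pyrimidine_fraction(allele, sd.PYR_RICH_RANGE) >= 0.8

    def test_exon_end_contexts_shared_across_alleles(self, bundle):
        gm = bundle.gene_model
        alleles = list(bundle.alleles.values())
        for end, tlen in sd.TAG_LENGTHS.items():
            s, e = gm.exon(end)
            tags = {a.subseq(e - tlen + 1, e) for a in alleles}
            assert len(tags) == 1
            wlen = sd.WINDOW_LENGTHS[end]
            windows = {a.subseq(e + 1, e + wlen) for a in alleles}
            assert len(windows) == 1

    def test_discriminators_private_to_their_allele(self, bundle):
        for name, discs in bundle.discriminators.items():
            own = bundle.alleles[name].sequence
            for d in discs[:5]:
                assert own.count(d) == 1
                for other, allele in bundle.alleles.items():
                    if other != name:
                        assert d not in allele.sequence

    def test_same_seed_reproduces_identical_sequences(self):
        b1 = sd.make_fixture_alleles(3)
        b2 = sd.make_fixture_alleles(3)
        assert all(
            b1.alleles[n].sequence == b2.alleles[n].sequence for n in b1.alleles
        )
        assert b1.discriminators == b2.discriminators


class TestSplicePrograms:
    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(sd.SpliceProgramError):
            sd.SpliceProgram({2: {sd.CANONICAL: 0.5, sd.UNSPLICED: 0.4}})

    def test_degenerate_program_yields_single_isoform(self, bundle):
        counts = sd.sample_isoforms(sd.SpliceProgram({}), 500, 1, bundle.gene_model)
        assert sum(counts.values()) == 500
        (iso, n), = counts.items()
        assert n == 500
        assert all(out == sd.CANONICAL for _, out in iso.chain)

    def test_forced_intron_retention_retains_intron_2(self, bundle):
        program = sd.SpliceProgram({2: {sd.UNSPLICED: 1.0}})
        counts = sd.sample_isoforms(program, 10, 1, bundle.gene_model)
        intron2 = bundle.alleles["C0303"].intron_seq(2)
        for iso in counts:
            assert intron2 in sd.transcribe(bundle.alleles["C0303"], iso)

    def test_sampling_follows_binomial_law(self, bundle):
        n = 10000
        program = sd.SpliceProgram(
            {2: {sd.alternate_acceptor(sd.ALT_E3_ACCEPTOR): 0.5, sd.CANONICAL: 0.5}}
        )
        counts = sd.sample_isoforms(program, n, 123, bundle.gene_model)
        alt = sum(
            c
            for iso, c in counts.items()
            if iso.outcome_at(2).kind == "alternate_acceptor"
        )
        assert abs(alt - n / 2) <= 3 * math.sqrt(n * 0.25)


class TestTranscription:
    def test_canonical_chain_concatenates_all_exons(self, bundle):
        allele = bundle.alleles["C0303"]
        iso = sd.IsoformSpec(tuple((d, sd.CANONICAL) for d in range(1, 8)))
        assert sd.transcribe(allele, iso) == "".join(
            allele.exon_seq(i) for i in range(1, 9)
        )

    def test_alternate_exon3_transcript_lacks_719_to_782(self, bundle):
        allele = bundle.alleles[sd.NULL_ALLELE]
        chain = [(1, sd.CANONICAL), (2, sd.alternate_acceptor(783))]
        chain += [(d, sd.CANONICAL) for d in range(3, 8)]
        rna = sd.transcribe(allele, sd.IsoformSpec(tuple(chain)))
        canonical = sd.transcribe(
            allele, sd.IsoformSpec(tuple((d, sd.CANONICAL) for d in range(1, 8)))
        )
        assert len(canonical) - len(rna) == 783 - 719  # 64 nt shorter
        assert allele.subseq(719, 738) not in rna
        assert allele.subseq(783, 802) in rna

    def test_exon5_skip_joins_exon4_to_exon6(self, bundle):
        allele = bundle.alleles["C0801"]
        chain = ((1, sd.CANONICAL), (2, sd.CANONICAL), (3, sd.CANONICAL),
                 (4, sd.skip_to_exon(6)), (6, sd.CANONICAL), (7, sd.CANONICAL))
        rna = sd.transcribe(allele, sd.IsoformSpec(chain))
        junction = allele.exon_seq(4)[-10:] + allele.exon_seq(6)[:10]
        assert junction in rna
        assert allele.exon_seq(5) not in rna


class TestExpressionModel:
    def _counts(self, bundle):
        gm = bundle.gene_model
        canonical = sd.IsoformSpec(tuple((d, sd.CANONICAL) for d in range(1, 8)))
        alt = sd.IsoformSpec(
            ((1, sd.CANONICAL), (2, sd.alternate_acceptor(783)))
            + tuple((d, sd.CANONICAL) for d in range(3, 8))
        )
        return {canonical: 90, alt: 10}, {canonical: False, alt: True}

    def test_factor_one_keeps_counts(self, bundle):
        counts, flags = self._counts(bundle)
        assert sd.apply_expression_model(counts, flags, 1.0) == {
            k: float(v) for k, v in counts.items()
        }

    def test_all_ptc_pool_scales_total(self, bundle):
        counts, _ = self._counts(bundle)
        flags = {k: True for k in counts}
        weights = sd.apply_expression_model(counts, flags, 0.1)
        assert sum(weights.values()) == pytest.approx(0.1 * sum(counts.values()))

    def test_invalid_factor_rejected(self, bundle):
        counts, flags = self._counts(bundle)
        for bad in (0.0, -1.0, 1.5):
            with pytest.raises(ValueError):
                sd.apply_expression_model(counts, flags, bad)


class TestReadSimulation:
    def test_pair_count_conservation_and_truth_rows(self, bundle):
        spec = sc.sample2_spec(n_read_pairs=1000, seed=5)
        alleles = {n: bundle.alleles[n] for n in spec.abundances}
        pairs, truth = sd.simulate_read_pairs(sd.steady_state_pool(alleles, spec), spec)
        assert len(pairs) == 1000
        assert len(truth) == 1000
        assert all(len(r1) == spec.read_length == len(r2) for _, r1, r2 in pairs)

    def test_single_transcript_pool_names_that_transcript(self, bundle):
        spec = sc.sample1_spec(n_read_pairs=50, seed=5)
        allele = bundle.alleles["C0801"]
        iso = sd.IsoformSpec(tuple((d, sd.CANONICAL) for d in range(1, 8)))
        pool = [sd.TranscriptRecord("only", "C0801", iso, sd.transcribe(allele, iso), 1.0)]
        _, truth = sd.simulate_read_pairs(pool, spec)
        assert set(truth["transcript_id"]) == {"only"}

    def test_same_seed_gives_identical_fastq_bytes(self, bundle, tmp_path):
        spec = sc.sample2_spec(n_read_pairs=300, seed=9)
        alleles = {n: bundle.alleles[n] for n in spec.abundances}
        pool = sd.steady_state_pool(alleles, spec)
        for tag in ("a", "b"):
            pairs, _ = sd.simulate_read_pairs(pool, spec)
            sd.write_paired_fastq(pairs, tmp_path / f"{tag}_1.fq", tmp_path / f"{tag}_2.fq")
        assert (tmp_path / "a_1.fq").read_bytes() == (tmp_path / "b_1.fq").read_bytes()
        assert (tmp_path / "a_2.fq").read_bytes() == (tmp_path / "b_2.fq").read_bytes()

    def test_mate2_is_reverse_complement_of_fragment_end(self, bundle):
        spec = sc.sample2_spec(n_read_pairs=20, seed=11)
        alleles = {n: bundle.alleles[n] for n in spec.abundances}
        pool = sd.steady_state_pool(alleles, spec)
        seqs = {t.transcript_id: t.sequence for t in pool}
        pairs, truth = sd.simulate_read_pairs(pool, spec)
        for (_, r1, r2), (_, row) in zip(pairs, truth.iterrows()):
            frag = seqs[row["transcript_id"]][row["start"] - 1 : row["start"] - 1 + row["fragment_len"]]
            assert r1 == frag[: spec.read_length]
            assert r2 == sd.reverse_complement(frag[-spec.read_length :])

    def test_empty_pool_rejected(self, bundle):
        with pytest.raises(ValueError):
            sd.simulate_read_pairs([], sc.sample1_spec(n_read_pairs=10))


class TestCrSimulation:
    def test_perfect_doubling_steps_cr_by_one(self):
        spec = sd.CrSimSpec(
            templates={("s", "hla"): 1e-4}, amplification={"hla": 2.0}
        )
        cr = sd.simulate_cr(spec)["cr"].to_numpy()
        assert np.allclose(np.diff(cr), 1.0)

    def test_twofold_template_ratio_shifts_cr_by_one(self):
        spec = sd.CrSimSpec(
            templates={("a", "hla"): 2e-4, ("b", "hla"): 1e-4},
            amplification={"hla": 2.0},
        )
        table = sd.simulate_cr(spec)
        a = table[table["sample"] == "a"]["cr"].to_numpy()
        b = table[table["sample"] == "b"]["cr"].to_numpy()
        assert np.allclose(b - a, 1.0)

    def test_spacing_matches_closed_form_for_a_1p9(self):
        spec = sd.CrSimSpec(
            templates={("s", "hla"): 1e-4}, amplification={"hla": 1.9}
        )
        cr = sd.simulate_cr(spec)["cr"].to_numpy()
        assert np.allclose(np.diff(cr), np.log(2) / np.log(1.9))

    def test_amplification_at_most_one_rejected(self):
        with pytest.raises(ValueError):
            sd.CrSimSpec(templates={("s", "hla"): 1e-4}, amplification={"hla": 1.0})
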