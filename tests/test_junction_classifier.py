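import numpy as np
import pytest

from hlasplice import junction_classifier as jc
from hlasplice import scenarios as sc
from hlasplice import synthetic_data as sd

from conftest import cell


@pytest.fixture(scope="module")
def tags(bundle):
    return jc.build_tags(bundle.gene_model, bundle.alleles)


@pytest.fixture(scope="module")
def refs(bundle):
    return {
        n: jc.build_junction_references(bundle.gene_model, a)
        for n, a in bundle.alleles.items()
    }


def _sense_read(allele, exon_end, window_source, pad=10):
    """A sense-strand read holding the exon-end tag followed by a window."""
    gm = allele.gene_model
    s, e = gm.exon(exon_end)
    tag = allele.subseq(e - sd.TAG_LENGTHS[exon_end] + 1, e)
    return "A" * pad + tag + window_source


class TestTags:
    def test_tag_lengths_follow_the_scheme(self, bundle, tags):
        for end, tlen in sd.TAG_LENGTHS.items():
            for tag in tags.tags[end]:
                assert len(tag) == tlen

    def test_exon2_tag_is_last_60_bases_of_exon_2(self, bundle, tags):
        allele = next(iter(bundle.alleles.values()))
        s, e = bundle.gene_model.exon(2)
        assert allele.subseq(e - 59, e) in tags.tags[2]

    def test_locally_identical_alleles_share_one_tag_entry(self, bundle, tags):
        # all four fixture alleles share every exon-end context
        for end in sd.TAG_LENGTHS:
            assert len(tags.tags[end]) == 1
            (names,) = tags.tags[end].values()
            assert names == frozenset(bundle.alleles)

    def test_exon_shorter_than_tag_rejected(self, bundle):
        from hlasplice.gene_model import Allele, build_gene_model

        gm = build_gene_model([(1, 30), (41, 100)])
        allele = Allele("x", "A" * 120, gm)
        with pytest.raises(jc.ClassifierError):
            jc.build_tags(gm, {"x": allele})


class TestReferences:
    def test_exon2_end_references(self, bundle, refs):
        allele = bundle.alleles["C0303"]
        table = refs["C0303"][2]
        canonical = allele.exon_seq(3)[:20]
        unspliced = allele.intron_seq(2)[:20]
        assert table[canonical] == sd.CANONICAL
        assert table[unspliced] == sd.UNSPLICED

    def test_exon4_end_skip_reference_is_exon6_start(self, bundle, refs):
        allele = bundle.alleles["C0303"]
        assert refs["C0303"][4][allele.exon_seq(6)[:20]] == sd.skip_to_exon(6)

    def test_reference_collision_yields_unclassified(self, bundle):
        allele = bundle.alleles["C0303"]
        window = allele.exon_seq(3)[:20]
        collided = {window: None}
        assert jc.classify_window(window, collided, allele, 2) is None


class TestScan:
    def test_tag_followed_by_window_is_hit(self, bundle, tags):
        allele = bundle.alleles["C0303"]
        read = _sense_read(allele, 2, allele.exon_seq(3)[:25])
        hits = jc.scan_read_pair((read, "A" * len(read)), tags)
        assert (2, allele.exon_seq(3)[:20]) in hits

    def test_tag_at_read_end_has_no_window_and_is_dropped(self, bundle, tags):
        allele = bundle.alleles["C0303"]
        s, e = bundle.gene_model.exon(2)
        read = "A" * 40 + allele.subseq(e - 59, e)  # tag is the final 60 bases
        assert jc.scan_read_pair((read, "C" * len(read)), tags) == []

    def test_reverse_strand_tag_found_after_reverse_complement(self, bundle, tags):
        allele = bundle.alleles["C0303"]
        read = _sense_read(allele, 2, allele.exon_seq(3)[:25])
        rc = sd.reverse_complement(read)
        hits = jc.scan_read_pair(("T" * len(read), rc), tags)
        assert (2, allele.exon_seq(3)[:20]) in hits

    def test_classification_symmetric_across_mates(self, bundle, tags):
        allele = bundle.alleles["C0303"]
        read = _sense_read(allele, 4, allele.exon_seq(5)[:25])
        via_mate1 = jc.scan_read_pair((read, "A" * 100), tags)
        via_mate2 = jc.scan_read_pair(("A" * 100, sd.reverse_complement(read)), tags)
        assert via_mate1 == via_mate2 != []


class TestClassifyWindow:
    def test_canonical_window(self, bundle, refs):
        allele = bundle.alleles["C0303"]
        out = jc.classify_window(allele.exon_seq(3)[:20], refs["C0303"][2], allele, 2)
        assert out == sd.CANONICAL

    def test_alternate_exon3_window_on_null_analog(self, bundle, refs):
        null = bundle.alleles[sd.NULL_ALLELE]
        window = null.subseq(783, 802)
        out = jc.classify_window(window, refs[sd.NULL_ALLELE][2], null, 2)
        assert out == sd.alternate_acceptor(783)

    def test_same_window_not_rescued_without_preceding_ag(self, bundle, refs):
        # the comparator carries G at 781, so no AG precedes position 783
        comp = bundle.alleles["C0801"]
        window = comp.subseq(783, 802)
        assert jc.classify_window(window, refs["C0801"][2], comp, 2) is None

    def test_cryptic_intron5_window_from_exon4_and_exon5_ends(self, bundle, refs):
        null = bundle.alleles[sd.NULL_ALLELE]
        window = null.subseq(2520, 2539)
        for end in (4, 5):
            out = jc.classify_window(window, refs[sd.NULL_ALLELE][end], null, end)
            assert out == sd.alternate_acceptor(2520)

    def test_random_window_is_unclassified(self, bundle, refs):
        allele = bundle.alleles["C0303"]
        assert jc.classify_window("ACGT" * 5, refs["C0303"][2], allele, 2) is None


class TestAssignAllele:
    def test_unique_discriminator_assigns(self, bundle):
        discs = {n: bundle.discriminators[n] for n in ("C0323N", "C0801")}
        read = "A" * 20 + discs["C0323N"][0] + "C" * 20
        assert jc.assign_allele((read, "T" * 50), discs) == "C0323N"

    def test_no_discriminator_is_ambiguous(self, bundle):
        discs = {n: bundle.discriminators[n] for n in ("C0323N", "C0801")}
        assert jc.assign_allele(("A" * 60, "C" * 60), discs) is None

    def test_chimeric_pair_with_both_discriminators_is_ambiguous(self, bundle):
        discs = {n: bundle.discriminators[n] for n in ("C0323N", "C0801")}
        read = discs["C0323N"][0] + "AAAA" + discs["C0801"][0]
        assert jc.assign_allele((read, "T" * 30), discs) is None

    def test_shared_discriminator_is_a_configuration_error(self):
        with pytest.raises(jc.ClassifierError):
            jc.assign_allele(("A" * 30, "C" * 30), {"x": ["ACGTACGTAC"], "y": ["ACGTACGTAC"]})


class TestTabulate:
    def test_all_canonical_gives_proportion_one(self):
        import pandas as pd

        calls = pd.DataFrame(
            {
                "read_id": [f"r{i}" for i in range(100)],
                "allele": ["a"] * 100,
                "exon_end": [2] * 100,
                "category": ["canonical"] * 100,
                "window": ["x"] * 100,
            }
        )
        table = jc.tabulate(calls)
        assert table["proportion"].iloc[0] == 1.0

    def test_rare_category_flagged_suppressed_at_half_percent(self):
        import pandas as pd

        cats = ["canonical"] * 999 + ["alternate_acceptor:783"]
        calls = pd.DataFrame(
            {
                "read_id": [f"r{i}" for i in range(1000)],
                "allele": ["a"] * 1000,
                "exon_end": [2] * 1000,
                "category": cats,
                "window": ["x"] * 1000,
            }
        )
        table = jc.tabulate(calls)
        rare = table[table["category"] == "alternate_acceptor:783"]
        assert bool(rare["suppressed"].iloc[0])
        common = table[table["category"] == "canonical"]
        assert not bool(common["suppressed"].iloc[0])

    def test_proportions_sum_to_one_per_exon_end(self, sample2_run):
        table = sample2_run["table"]
        for (_, _), sub in table.groupby(["allele", "exon_end"]):
            assert sub["proportion_all"].sum() == pytest.approx(1.0, abs=1e-9)
            classifiable = sub[sub["category"] != jc.UNCLASSIFIED]
            if not classifiable.empty:
                assert classifiable["proportion"].sum() == pytest.approx(1.0, abs=1e-9)


class TestEndToEnd:
    def test_every_call_matches_generator_truth(self, sample2_run):
        """Oracle equivalence: on error-free reads, classification agrees with
        the generator truth for every (pair, exon end) hit."""
        calls = sample2_run["calls"]
        truth = sample2_run["truth"].set_index("read_id")
        iso_by_tid = {t.transcript_id: t.isoform for t in sample2_run["pool"]}
        allele_by_rid = truth["allele"]
        tid_by_rid = truth["transcript_id"]

        checked = 0
        for rid, group, end, category in calls[
            ["read_id", "allele", "exon_end", "category"]
        ].itertuples(index=False):
            if group != jc.AMBIGUOUS:
                assert group == allele_by_rid[rid]
            expected = iso_by_tid[tid_by_rid[rid]].outcome_at(end)
            assert category == (expected.label if expected else jc.UNCLASSIFIED)
            checked += 1
        assert checked == len(calls) > 10000

    def test_recovery_of_program_probabilities_within_3_sigma(self, sample2_run):
        """Classified proportions recover the splice-program probabilities."""
        program_truth = {
            (sd.NULL_ALLELE, 2, f"alternate_acceptor:{sd.ALT_E3_ACCEPTOR}"): sc.NULL_E2_ALT,
            (sd.NULL_ALLELE, 2, "canonical"): sc.NULL_E2_CANONICAL,
            (sd.NULL_ALLELE, 4, "skip_to_exon:6"): sc.NULL_E4_SKIP,
            (sd.NULL_ALLELE, 5, "unspliced"): sc.NULL_E5_UNSPLICED,
            (sc.COMPARATOR_ALLELE, 5, "canonical"): sc.COMPARATOR_E5_CANONICAL,
            (sc.COMPARATOR_ALLELE, 2, "unspliced"): 0.25,
        }
        for (allele, end, category), p in program_truth.items():
            est, n = cell(sample2_run["table"], allele, end, category)
            assert n > 100
            assert abs(est - p) <= 3 * np.sqrt(p * (1 - p) / n), (allele, end, category)

    def test_fastq_round_trip_preserves_calls(self, bundle, tmp_path):
        spec = sc.sample2_spec(n_read_pairs=500, seed=8)
        alleles = {n: bundle.alleles[n] for n in spec.abundances}
        pairs, _ = sd.simulate_read_pairs(sd.steady_state_pool(alleles, spec), spec)
        sd.write_paired_fastq(pairs, tmp_path / "r1.fq", tmp_path / "r2.fq")
        back = jc.read_paired_fastq(tmp_path / "r1.fq", tmp_path / "r2.fq")
        direct = jc.classify_pairs(pairs, bundle.gene_model, alleles)
        loaded = jc.classify_pairs(back, bundle.gene_model, alleles)
        assert direct.equals(loaded)
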