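"""Assay representation, priming-site scan, amplicon extraction, specificity."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zfsex.sequences import (
    DEFAULT_ASSAY,
    AmbiguousTemplateError,
    AssayDefinition,
    NucleotideSequence,
    SequenceError,
    extract_amplicon,
    find_priming_site,
    hamming_distance,
    specificity_screen,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=40)


class TestNucleotideSequence:
    def test_rejects_empty_and_illegal(self):
        with pytest.raises(SequenceError):
            NucleotideSequence("")
        with pytest.raises(SequenceError):
            NucleotideSequence("ACGU")
        with pytest.raises(SequenceError):
            NucleotideSequence("ACGN")  # ambiguity needs opt-in
        assert str(NucleotideSequence("ACGN", allow_ambiguity=True)) == "ACGN"

    def test_lowercase_normalized(self):
        assert str(NucleotideSequence("acgt")) == "ACGT"

    @given(dna)
    @settings(max_examples=50, deadline=None)
    def test_reverse_complement_involution(self, s):
        seq = NucleotideSequence(s)
        assert str(seq.reverse_complement().reverse_complement()) == s

    def test_default_assay_sequences(self):
        a = DEFAULT_ASSAY
        assert str(a.forward_primer) == "ACAAAATGGTGCATAAGGAAAAG"
        assert str(a.reverse_primer) == "CTCAGCTGTCTCGTATTCACA"
        assert str(a.probe_x) == "AGCCAACAAAATG"
        assert str(a.probe_y) == "ATCCAGCAAAATG"
        assert len(a.probe_x) == len(a.probe_y) == 13
        assert a.dye_x == "VIC" and a.dye_y == "FAM"

    def test_assay_invariants_enforced(self):
        with pytest.raises(ValueError):
            AssayDefinition(
                forward_primer=NucleotideSequence("ACGT"),
                reverse_primer=NucleotideSequence("ACGT"),
                probe_x=NucleotideSequence("AAA"),
                probe_y=NucleotideSequence("AAAA"),
            )
        with pytest.raises(ValueError):
            AssayDefinition(
                forward_primer=NucleotideSequence("ACGT"),
                reverse_primer=NucleotideSequence("ACGT"),
                probe_x=NucleotideSequence("AAA"),
                probe_y=NucleotideSequence("TTT"),
                dye_x="FAM", dye_y="FAM",
            )


class TestHammingDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("AGCCAACAAAATG", "ATCCAGCAAAATG", 2),  # the two allele probes
            ("ACGT", "ACGT", 0),
            ("AAA", "TTT", 3),
        ],
    )
    def test_examples(self, a, b, expected):
        assert hamming_distance(a, b) == expected

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            hamming_distance("AA", "AAA")

    @given(st.integers(1, 20).flatmap(
        lambda n: st.tuples(*[st.text("ACGT", min_size=n, max_size=n)] * 3)))
    @settings(max_examples=100, deadline=None)
    def test_metric_properties(self, triple):
        a, b, c = triple
        assert hamming_distance(a, b) == hamming_distance(b, a)
        assert (hamming_distance(a, b) == 0) == (a == b)
        assert hamming_distance(a, c) <= hamming_distance(a, b) + hamming_distance(b, c)


class TestFindPrimingSite:
    def test_exact_embedding(self, assay):
        ref = NucleotideSequence("TTTT" + str(assay.forward_primer) + "GGGG")
        sites = find_priming_site(ref, assay.forward_primer)
        qualifying = [s for s in sites if s.qualifies and s.mismatches == 0]
        assert len(qualifying) == 1
        site = qualifying[0]
        assert (site.position, site.strand) == (4, "+")
        assert site.terminal_match

    def test_terminal_3prime_anchor_blocks_human_like_state(self, assay):
        # human-like template: final 3' G of the forward primer replaced by A
        primer = str(assay.forward_primer)
        ref = NucleotideSequence("TT" + primer[:-1] + "A" + "CCCC")
        sites = find_priming_site(ref, assay.forward_primer, max_mismatches=2)
        assert all(not s.qualifies for s in sites)
        candidates = [s for s in sites if s.mismatches == 1]
        assert candidates and not candidates[0].terminal_match

    def test_over_mismatch_budget_empty(self, assay):
        primer = str(assay.forward_primer)
        mutated = "TTT" + primer[:5] + "CCC" + primer[8:]  # 3 internal mismatches
        sites = find_priming_site(NucleotideSequence(mutated), assay.forward_primer,
                                  max_mismatches=2)
        assert sites == []

    def test_errors(self, assay):
        with pytest.raises(SequenceError):
            find_priming_site(NucleotideSequence("ACG"), assay.forward_primer)

    def test_reverse_complement_symmetry(self, assay):
        ref = NucleotideSequence("TTTT" + str(assay.forward_primer) + "GGGGCA")
        rc = ref.reverse_complement()
        fwd_sites = find_priming_site(ref, assay.forward_primer)
        rc_sites = find_priming_site(rc, assay.forward_primer)
        L = len(assay.forward_primer)
        mirrored = sorted(
            (len(ref) - (s.position + L), {"+": "-", "-": "+"}[s.strand],
             s.mismatches, s.terminal_match)
            for s in fwd_sites
        )
        observed = sorted(
            (s.position, s.strand, s.mismatches, s.terminal_match) for s in rc_sites
        )
        assert mirrored == observed


class TestExtractAmplicon:
    def test_constructed_74bp(self, assay, elephantine_reference):
        hit = extract_amplicon(elephantine_reference, assay)
        assert hit is not None
        amplicon, length = hit
        assert length == 74
        assert length == (len(assay.forward_primer) + 30 + len(assay.reverse_primer))
        assert str(amplicon).startswith(str(assay.forward_primer))

    def test_missing_reverse_site(self, assay):
        ref = NucleotideSequence("AAAA" + str(assay.forward_primer) + "C" * 40)
        assert extract_amplicon(ref, assay) is None

    def test_two_forward_sites_ambiguous(self, assay, elephantine_reference):
        doubled = NucleotideSequence(
            str(assay.forward_primer) + "TTTT" + str(elephantine_reference)
        )
        with pytest.raises(AmbiguousTemplateError):
            extract_amplicon(doubled, assay)

    def test_reverse_complemented_template(self, assay, elephantine_reference):
        hit = extract_amplicon(elephantine_reference.reverse_complement(), assay)
        assert hit is not None
        _, length = hit
        assert length == 74


class TestSpecificityScreen:
    def test_panel(self, assay, elephantine_reference):
        primer = str(assay.forward_primer)
        human_like = NucleotideSequence(
            primer[:-1] + "A"  # 3' terminal A, as in humans
            + str(assay.probe_x) + "GATCGATCGATCGATCG"
            + str(assay.reverse_primer.reverse_complement())
        )
        # canid-ZFY-like: amplifiable (3' G) but one probe-range mismatch
        probe_mut = "T" + str(assay.probe_y)[1:]
        assert probe_mut != str(assay.probe_y)
        canid_like = NucleotideSequence(
            primer + probe_mut + "GATCGATCGATCGATCG"
            + str(assay.reverse_primer.reverse_complement())
        )
        rows = specificity_screen(assay, [
            ("Loxodonta", "ZFX", elephantine_reference),
            ("Homo", "ZFX", human_like),
            ("Canis", "ZFY", canid_like),
        ])
        lox, homo, canis = rows
        assert (lox.amplifiable, lox.probe_x_binds, lox.probe_y_binds) == (True, True, False)
        assert homo.amplifiable is False
        assert (canis.amplifiable, canis.probe_x_binds, canis.probe_y_binds) == (True, False, False)

    def test_empty_panel_rejected(self, assay):
        with pytest.raises(ValueError):
            specificity_screen(assay, [])

    def test_ambiguity_codes_never_support_probe_binding(self, assay):
        # template where the X-probe window carries an N: compatible for
        # priming scans but conservative (no binding) for the probe
        probe_with_n = "N" + str(assay.probe_x)[1:]
        ref = NucleotideSequence(
            str(assay.forward_primer) + probe_with_n + "GATCGATCGATCGATCG"
            + str(assay.reverse_primer.reverse_complement()),
            allow_ambiguity=True,
        )
        rows = specificity_screen(assay, [("Taxon", "X", ref)])
        assert rows[0].amplifiable is True
        assert rows[0].probe_x_binds is False
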