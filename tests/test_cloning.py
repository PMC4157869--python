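import logging

import numpy as np
import pytest

from pollenkit import (
    DNAMolecule,
    Enzyme,
    MoleculeEnd,
    PrimerPair,
    REGISTRY,
    ValidationError,
    a_tail,
    digest,
    in_silico_pcr,
    ligate,
    make_t_vector,
    reverse_complement,
    scan_sites,
    verify_orientation,
)
from pollenkit.cloning import (
    BLUNT,
    FIVE_PRIME,
    THREE_PRIME,
    ends_compatible,
    molecule_to_record,
    record_to_molecule,
)
from pollenkit.synthetic_data import AHDI_SITE_FWD, random_dna

AHDI = REGISTRY["AhdI"]
HINDIII = REGISTRY["HindIII"]
XCMI = REGISTRY["XcmI"]

# AhdI-free filler (contains neither GAC nor GTC in any frame)
CLEAN = "ACCT" * 40


def top_strand_total(fragments):
    return sum(len(f.sequence) for f in fragments)


class TestRegistry:
    def test_patterns_are_their_own_reverse_complement(self):
        for enz in REGISTRY.values():
            assert reverse_complement(enz.recognition) == enz.recognition

    def test_ahdi_cut_geometry_gives_one_nt_3prime_overhang(self):
        assert AHDI.top_cut - AHDI.bottom_cut == 1
        assert AHDI.overhang_length == 1

    def test_cut_outside_site_rejected(self):
        with pytest.raises(ValidationError):
            Enzyme("Bad", "GACNNNNNGTC", 11, 5)


class TestScanSites:
    def test_xcmi_degenerate_instance(self):
        # CCANNNNTNNNNTGG instantiated with concrete bases
        mol = DNAMolecule("TT" + "CCAGGGGTAAAATGG" + "TT")
        hits = scan_sites(mol, XCMI)
        assert [(h.position, h.matched) for h in hits] == [(3, "CCAGGGGTAAAATGG")]

    def test_no_match_without_g(self):
        assert scan_sites(DNAMolecule("ACTACTACTACTACT"), AHDI) == []

    def test_overlapping_matches_all_reported(self):
        # two AhdI matches sharing sequence: GAC..GTC twice, offset 3
        mol = DNAMolecule("GACGACAAGTCGTC")
        assert [h.position for h in scan_sites(mol, AHDI)] == [1, 4]

    def test_circular_origin_spanning_site_matches_rotation_oracle(self):
        seq = "GTC" + CLEAN[:30] + "GACAATAA"  # site GACAATAAGTC wraps the origin
        mol = DNAMolecule(seq, "circular")
        hits = scan_sites(mol, AHDI)
        # oracle: scan every rotation linearly and map positions back
        oracle = set()
        n = len(seq)
        for k in range(n):
            rot = seq[k:] + seq[:k]
            for h in scan_sites(DNAMolecule(rot), AHDI):
                oracle.add((h.position - 1 + k) % n + 1)
        assert {h.position for h in hits} == oracle
        assert len(hits) == 1


class TestDigest:
    def test_printed_site_leaves_3prime_t_overhang(self):
        up, down = digest(DNAMolecule("AAAA" + AHDI_SITE_FWD + "CCCC"), AHDI)
        assert up.right_end == MoleculeEnd("T", THREE_PRIME)
        assert up.sequence.endswith("GACAAT")
        assert down.left_end == MoleculeEnd("A", THREE_PRIME)
        assert down.sequence.startswith("AAGTC")

    def test_hindiii_leaves_5prime_agct_overhangs(self):
        up, down = digest(DNAMolecule("TTTT" + "AAGCTT" + "GGGG"), HINDIII)
        assert up.right_end == MoleculeEnd("AGCT", FIVE_PRIME)
        assert down.left_end == MoleculeEnd("AGCT", FIVE_PRIME)
        assert down.sequence.startswith("AGCTT")

    def test_no_sites_returns_molecule_unchanged(self):
        mol = DNAMolecule(CLEAN)
        assert digest(mol, AHDI) == [mol]

    def test_plasmid_two_fragments_conserve_length(self, plasmid):
        frags = digest(plasmid, AHDI)
        assert len(frags) == 2
        assert top_strand_total(frags) == len(plasmid.sequence)

    def test_linear_k_sites_give_k_plus_one_fragments(self):
        mol = DNAMolecule(CLEAN + AHDI_SITE_FWD + CLEAN + AHDI_SITE_FWD + CLEAN)
        frags = digest(mol, AHDI)
        assert len(frags) == 3
        assert top_strand_total(frags) == len(mol.sequence)

    def test_conflicting_cut_regions_rejected(self):
        wide = Enzyme("Wide", "AANNTT", 5, 1)
        with pytest.raises(ValidationError):
            digest(DNAMolecule("CCC" + "AAAATTTT" + "CCC"), wide)

    def test_strand_symmetry(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            seq = random_dna(rng, 80) + AHDI_SITE_FWD + random_dna(rng, 80)
            mol = DNAMolecule(seq)
            fwd = digest(mol, AHDI)
            rev = digest(mol.reverse_complement(), AHDI)
            flipped = [f.reverse_complement() for f in reversed(rev)]
            assert [f.sequence for f in flipped] == [f.sequence for f in fwd]
            assert [(f.left_end, f.right_end) for f in flipped] == [
                (f.left_end, f.right_end) for f in fwd
            ]


class TestTVector:
    def test_inverted_sites_give_3prime_t_both_ends(self, plasmid):
        tv = make_t_vector(plasmid)
        assert tv.left_end == MoleculeEnd("T", THREE_PRIME)
        assert tv.right_end == MoleculeEnd("T", THREE_PRIME)
        frags = digest(plasmid, AHDI)
        assert len(tv.sequence) == max(len(f.sequence) for f in frags)

    def test_same_orientation_sites_rejected(self):
        same = DNAMolecule(
            AHDI_SITE_FWD + CLEAN + AHDI_SITE_FWD + CLEAN * 2, "circular"
        )
        with pytest.raises(ValidationError, match="not a T-vector"):
            make_t_vector(same)

    def test_wrong_site_count_rejected(self):
        one = DNAMolecule(AHDI_SITE_FWD + CLEAN, "circular")
        with pytest.raises(ValidationError, match="2"):
            make_t_vector(one)

    def test_linear_input_rejected(self):
        with pytest.raises(ValidationError):
            make_t_vector(DNAMolecule(AHDI_SITE_FWD + CLEAN))


class TestATailAndLigate:
    def test_a_tail_adds_single_3prime_a_each_end(self):
        blunt = DNAMolecule("G" * 100)
        tailed = a_tail(blunt)
        assert tailed.left_end == MoleculeEnd("A", THREE_PRIME)
        assert tailed.right_end == MoleculeEnd("A", THREE_PRIME)
        assert len(tailed.sequence) == 101  # top strand gains its 3' A

    def test_double_tailing_rejected(self):
        tailed = a_tail(DNAMolecule("G" * 50))
        with pytest.raises(ValidationError):
            a_tail(tailed)

    def test_t_vector_plus_a_tailed_insert_gives_two_orientations(self, plasmid):
        tv = make_t_vector(plasmid)
        insert = a_tail(DNAMolecule(random_dna(np.random.default_rng(1), 400)))
        products = ligate(tv, insert)
        assert len(products) == 2
        assert all(p.is_circular for p in products)
        # every overhang base counted exactly once
        assert all(
            len(p.sequence) == len(tv.sequence) + len(insert.sequence)
            for p in products
        )
        assert products[0].sequence != products[1].sequence

    def test_blunt_insert_does_not_ligate_into_t_vector(self, plasmid):
        tv = make_t_vector(plasmid)
        assert ligate(tv, DNAMolecule("G" * 60)) == []

    def test_single_site_digest_religation_is_a_rotation(self):
        circ = DNAMolecule("CCCC" + AHDI_SITE_FWD + CLEAN, "circular")
        (fragment,) = digest(circ, AHDI)
        (religated,) = ligate(fragment)
        assert len(religated.sequence) == len(circ.sequence)
        assert religated.sequence in circ.sequence + circ.sequence

    def test_end_compatibility_rule(self):
        t = MoleculeEnd("T", THREE_PRIME)
        a = MoleculeEnd("A", THREE_PRIME)
        agct = MoleculeEnd("AGCT", FIVE_PRIME)
        assert ends_compatible(t, a) and ends_compatible(a, t)
        assert not ends_compatible(t, t)
        assert ends_compatible(agct, agct)  # palindromic 5' overhang
        assert not ends_compatible(t, agct)


class TestConservationProperty:
    def test_random_molecules_conserve_bases_and_recircularize(self):
        rng = np.random.default_rng(7)
        enzymes = [AHDI, HINDIII, XCMI]
        for i in range(60):
            enz = enzymes[i % 3]
            topology = "circular" if i % 2 else "linear"
            seq = random_dna(rng, int(rng.integers(200, 800)))
            mol = DNAMolecule(seq, topology)
            frags = digest(mol, enz)
            assert top_strand_total(frags) == len(seq)
            sites = scan_sites(mol, enz)
            expected = len(sites) + (0 if topology == "circular" else 1)
            assert len(frags) == max(expected, 1)
            if topology == "circular" and len(sites) == 1:
                (rejoined,) = ligate(frags[0])
                assert rejoined.sequence in seq + seq


class TestInSilicoPCR:
    def test_direct_construction(self):
        rng = np.random.default_rng(3)
        f = random_dna(rng, 20)
        r = random_dna(rng, 20)
        template = DNAMolecule("TT" + f + random_dna(rng, 100) + reverse_complement(r) + "AA")
        (amp,) = in_silico_pcr(template, PrimerPair(f, r))
        assert len(amp.sequence) == 140
        assert amp.sequence.startswith(f)
        assert amp.sequence.endswith(reverse_complement(r))

    def test_missing_forward_primer_gives_no_amplicon(self):
        template = DNAMolecule("A" * 200)
        assert in_silico_pcr(template, PrimerPair("C" * 20, "T" * 20)) == []

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(9)
        for topology in ("linear", "circular"):
            seq = random_dna(rng, 1500)
            f, r_rc = seq[100:120], seq[800:820]
            template = DNAMolecule(seq, topology)
            primers = PrimerPair(f, reverse_complement(r_rc))
            got = {(a.sequence) for a in in_silico_pcr(template, primers)}
            space = seq + seq[: len(seq) - 1] if topology == "circular" else seq
            oracle = set()
            for i in range(len(seq) if topology == "circular" else len(space)):
                if space[i:i + 20] != f:
                    continue
                for j in range(i, len(space) - 19):
                    if space[j:j + 20] == r_rc and j + 20 - i <= len(seq):
                        oracle.add(space[i:j + 20])
            assert got == oracle and got

    def test_short_primers_rejected(self):
        with pytest.raises(ValidationError):
            PrimerPair("ACGTACGT", "ACGTACGTACGTACG")


class TestOrientation:
    def test_exactly_one_product_is_correct(self, plasmid):
        tv = make_t_vector(plasmid)
        rng = np.random.default_rng(21)
        insert = a_tail(DNAMolecule(random_dna(rng, 600), name="prom"))
        products = ligate(tv, insert)
        reporter = next(iv for label, iv in tv.annotations if label == "reporter")
        rev = reverse_complement(tv.sequence[reporter.start + 29: reporter.start + 49])
        fwd = insert.sequence[:20]
        verdicts = verify_orientation(products, rev, fwd)
        assert sorted(verdicts.values()) == ["correct", "reversed"]

    def test_correct_amplicon_ends_inside_reporter(self, plasmid):
        tv = make_t_vector(plasmid)
        insert = a_tail(DNAMolecule(random_dna(np.random.default_rng(2), 300)))
        products = ligate(tv, insert)
        reporter = next(iv for label, iv in tv.annotations if label == "reporter")
        rev = reverse_complement(tv.sequence[reporter.start + 29: reporter.start + 49])
        fwd = insert.sequence[:20]
        for product in products:
            amps = in_silico_pcr(product, PrimerPair(fwd, rev))
            if len(amps) == 1:
                # the amplicon terminates with the reporter-internal segment
                assert amps[0].sequence.endswith(reverse_complement(rev))

    def test_absent_reporter_primer_warns_and_classifies_reversed(
        self, plasmid, caplog
    ):
        tv = make_t_vector(plasmid)
        insert = a_tail(DNAMolecule(random_dna(np.random.default_rng(4), 300)))
        products = ligate(tv, insert)
        with caplog.at_level(logging.WARNING, logger="pollenkit.cloning"):
            verdicts = verify_orientation(products, "T" * 20, insert.sequence[:20])
        assert set(verdicts.values()) == {"reversed"}
        assert any("reporter" in rec.message for rec in caplog.records)


class TestBiopythonCrossCheck:
    """Bio.Restriction as an independent oracle for site positions and
    overhang geometry (it is never used by the implementation)."""

    @pytest.mark.parametrize("name", ["AhdI", "HindIII", "XcmI", "NcoI", "SpeI"])
    def test_site_positions_match(self, name):
        from Bio import Restriction
        from Bio.Seq import Seq

        bio_enz = getattr(Restriction, name)
        our_enz = REGISTRY[name]
        rng = np.random.default_rng(sum(ord(c) for c in name))
        for _ in range(5):
            seq = random_dna(rng, 400)
            ins = int(rng.integers(0, 380))
            seq = seq[:ins] + our_enz.recognition.replace("N", "G") + seq[ins:]
            ours = {h.position for h in scan_sites(DNAMolecule(seq), our_enz)}
            # Bio.Restriction reports the first base after the top-strand cut
            theirs = {
                cut - bio_enz.charac[0] for cut in bio_enz.search(Seq(seq))
            }
            assert ours == theirs and ours

    def test_overhang_geometry_matches(self):
        from Bio.Restriction import AhdI as BioAhdI, HindIII as BioHindIII

        assert AHDI.top_cut - AHDI.bottom_cut == BioAhdI.ovhg  # +1 = 3', 1 nt
        assert HINDIII.top_cut - HINDIII.bottom_cut == BioHindIII.ovhg  # -4 = 5'


def test_molecule_fasta_round_trip(plasmid):
    tv = make_t_vector(plasmid)
    for mol in (plasmid, tv, a_tail(DNAMolecule("G" * 30))):
        rec = molecule_to_record(mol, "m")
        back = record_to_molecule(rec)
        assert back.sequence == mol.sequence
        assert back.topology == mol.topology
        assert back.left_end == mol.left_end
        assert back.right_end == mol.right_end
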