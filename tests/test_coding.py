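import numpy as np
import pytest
from Bio.SeqUtils import molecular_weight

from hml2profiler.coding import (
    annotate_domains,
    predict_spliced_protein,
    protein_mass,
    scan_env_orfs,
)
from hml2profiler.splicing import call_splice
from hml2profiler import simulate as S

from .oracles import oracle_translate

STOP_SWAP = {"A": "C", "C": "A", "G": "T", "T": "G"}


@pytest.fixture(scope="module")
def canonical(family):
    """The canonical type-2 locus, its CDS, and the family's coding context."""
    locus = family.registry.records[family.registry.canonical_env_reference]
    return {
        "locus": locus,
        "cds": family.references["env_cds"],
        "dm": family.domain_map,
        "indel": family.indel_aa_interval,
    }


def _scan(canonical, sequence, ptype):
    return scan_env_orfs(
        sequence,
        canonical["cds"],
        ptype,
        domain_map=canonical["dm"],
        indel_aa_interval=canonical["indel"],
    )


class TestProteinMass:
    def test_empty_chain_is_one_water(self):
        assert protein_mass("") == pytest.approx(0.018, abs=5e-4)

    def test_single_glycine(self):
        assert protein_mass("G") == pytest.approx(0.075, abs=5e-4)

    def test_cross_checked_against_biopython(self, family):
        """Independent average-mass oracle over the canonical Env protein."""
        env = family.references["env"]
        expected = molecular_weight(env, seq_type="protein") / 1000.0
        assert protein_mass(env) == pytest.approx(expected, rel=1e-4)

    def test_unknown_residue_raises(self):
        with pytest.raises(ValueError, match="unknown residue"):
            protein_mass("GX")

    def test_mass_strictly_increases_with_length(self):
        masses = [protein_mass("G" * n) for n in range(1, 6)]
        assert masses == sorted(masses) and len(set(masses)) == 5


class TestScanEnvOrfs:
    def test_full_length_env_on_canonical_type2(self, canonical):
        orfs = _scan(canonical, canonical["locus"].sequence, 2)
        full = [o for o in orfs if o.orf_class == "full_length_env"]
        assert len(full) == 1
        orf = full[0]
        assert orf.aa_length == 699
        assert orf.alignment_to_canonical == (1, 699)
        assert orf.predicted_mass_kDa == pytest.approx(79, rel=0.15)

    def test_reported_sequences_equal_independent_translation(self, canonical):
        seq = canonical["locus"].sequence
        for orf in _scan(canonical, seq, 2):
            nt = seq[orf.nt_span[0] : orf.nt_span[1]]
            assert oracle_translate(nt) == orf.aa_sequence
            assert orf.aa_length * 3 == orf.nt_span[1] - orf.nt_span[0]
            assert "*" not in orf.aa_sequence

    def test_no_reported_orf_is_extendable(self, canonical):
        seq = canonical["locus"].sequence
        for orf in _scan(canonical, seq, 2):
            s, e = orf.nt_span
            if s >= 3:
                assert oracle_translate(seq[s - 3 : s]) == "*"
            if e + 3 <= len(seq):
                assert oracle_translate(seq[e : e + 3]) == "*"

    def test_premature_stop_yields_su_om_fragment(self, canonical):
        """A stop planted at Env codon 264 splits off a 263-aa SU/OM fragment."""
        seq = list(canonical["locus"].sequence)
        stop_at = S.ENV_START + 3 * 263  # codon 264
        seq[stop_at : stop_at + 3] = list("TAA")
        orfs = _scan(canonical, "".join(seq), 2)
        frag = [o for o in orfs if o.alignment_to_canonical == (1, 263)]
        assert len(frag) == 1
        assert frag[0].orf_class == "SU_OM_fragment"
        assert frag[0].aa_length == 263
        assert not any(o.orf_class == "full_length_env" for o in orfs)

    def test_type1_env_classification(self, family, canonical):
        t1 = S.pristine_type1(family)
        orfs = _scan(canonical, t1.sequence, 1)
        t1_env = [o for o in orfs if o.orf_class == "type1_env"]
        assert len(t1_env) == 1
        assert t1_env[0].alignment_to_canonical[1] == 699
        assert t1_env[0].alignment_to_canonical[0] >= canonical["indel"][1] - 2
        assert not any(o.orf_class == "full_length_env" for o in orfs)

    def test_full_length_reported_only_for_type2(self, canonical):
        """The same sequence declared type 1 must not class full_length_env."""
        orfs = _scan(canonical, canonical["locus"].sequence, 1)
        assert not any(o.orf_class == "full_length_env" for o in orfs)

    def test_upstream_in_frame_extension_is_a_fusion(self, canonical):
        """An ORF reaching 830 aa upstream of a 139-aa env portion mirrors the
        long gag/pol-env fusion case (969 aa total)."""
        rng = np.random.default_rng(31)
        cds = canonical["cds"]
        env_tail = cds[3 * 560 : 3 * 699]  # canonical aa 561-699, in frame
        upstream = S._random_nonstop_codons(rng, 830)
        locus = (
            "".join(rng.choice(list("ACGT"), size=90))
            + "TAA" + upstream + env_tail + "TAA"
            + "".join(rng.choice(list("ACGT"), size=90))
        )
        orfs = scan_env_orfs(
            locus, cds, 1, domain_map=canonical["dm"], indel_aa_interval=canonical["indel"]
        )
        fusion = [o for o in orfs if o.orf_class == "pol_env_fusion"]
        assert len(fusion) == 1
        assert fusion[0].aa_length == 969
        assert fusion[0].env_overlap_aa == 139
        assert fusion[0].upstream_extension_aa == 830


class TestAnnotateDomains:
    def test_full_length_env_yields_three_products(self, canonical):
        orfs = _scan(canonical, canonical["locus"].sequence, 2)
        full = next(o for o in orfs if o.orf_class == "full_length_env")
        products = annotate_domains(full, canonical["dm"])
        assert [p.name for p in products] == ["SP", "SU_OM", "TM"]
        sp, su, tm = products
        assert sp.canonical_span == (1, 96)
        assert len(sp.aa_sequence) == 96
        assert tm.predicted_mass_kDa == pytest.approx(26, rel=0.15)
        assert su.predicted_mass_kDa == pytest.approx(41, rel=0.15)

    def test_internal_span_has_no_signal_peptide(self, canonical):
        orfs = _scan(canonical, canonical["locus"].sequence, 2)
        full = next(o for o in orfs if o.orf_class == "full_length_env")
        # restrict the ORF artificially to aa 120-436
        full.alignment_to_canonical = (120, 436)
        full.aa_sequence = full.aa_sequence[119:436]
        full.upstream_extension_aa = 0
        products = annotate_domains(full, canonical["dm"])
        assert [p.name for p in products] == ["SU_OM"]

    def test_product_sequences_are_orf_substrings(self, canonical):
        orfs = _scan(canonical, canonical["locus"].sequence, 2)
        full = next(o for o in orfs if o.orf_class == "full_length_env")
        for product in annotate_domains(full, canonical["dm"]):
            assert product.aa_sequence in full.aa_sequence


class TestPredictSplicedProtein:
    def _call(self, family, name):
        v = S.make_variant_reads(family)[name]
        call = call_splice(
            v["read"], v["locus"].sequence, v["annotation"], v["locus"].provirus_type
        )
        return v, call

    def test_canonical_rec(self, family):
        v, call = self._call(family, "rec")
        p = predict_spliced_protein(v["locus"].sequence, call, v["annotation"], family.references)
        assert p.protein_class == "Rec"
        assert p.aa_sequence == family.references["rec"]

    def test_canonical_np9(self, family):
        v, call = self._call(family, "np9")
        p = predict_spliced_protein(v["locus"].sequence, call, v["annotation"], family.references)
        assert p.protein_class == "Np9"

    def test_alternative_acceptor_truncates_rec_by_17_aa(self, family):
        v, call = self._call(family, "np9_like_alt")
        p = predict_spliced_protein(v["locus"].sequence, call, v["annotation"], family.references)
        assert p.protein_class == "Rec_truncated"
        rec = family.references["rec"]
        assert p.aa_sequence == rec[: len(rec) - 17]
        assert "17 aa" in p.truncation_note

    def test_rec_truncated_is_a_proper_prefix(self, family):
        v, call = self._call(family, "np9_like_alt")
        p = predict_spliced_protein(v["locus"].sequence, call, v["annotation"], family.references)
        assert family.references["rec"].startswith(p.aa_sequence)
        assert len(p.aa_sequence) < len(family.references["rec"])

    def test_retrocopy_stop_at_codon_19_encodes_nothing(self, family):
        retro = family.registry.records["locus_retro"]
        ann = family.annotations["locus_retro"]
        call = call_splice(S.rec_np9_product(retro, ann), retro.sequence, ann, 2)
        p = predict_spliced_protein(retro.sequence, call, ann, family.references)
        assert p.protein_class == "none"
        assert p.stop_position == 19

    def test_unknown_call_is_a_precondition_violation(self, family):
        from hml2profiler.splicing import SpliceCall

        bad = SpliceCall(read_id="r", locus_id="x", transcript_class="unknown")
        with pytest.raises(ValueError):
            predict_spliced_protein("ATG", bad, None, family.references)
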