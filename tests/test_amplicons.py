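import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hml2profiler._align import count_differences, revcomp
from hml2profiler.amplicons import (
    AmpliconDefinition,
    Primer,
    PrimerSet,
    classify_provirus_type,
    diagnostic_sites,
    difference_matrix,
    extract_amplicons,
    indistinguishable_groups,
    match_primers,
)
from hml2profiler.registry import LocusRecord, LocusRegistry
from hml2profiler import simulate as S

from .oracles import gotoh_score, oracle_primer_scan

FWD = "ACGTACGGTTCAGACCTAGC"
REV = "CCTGAGTACGGATCAGTCCA"  # site on the + strand; primer is its revcomp


def _rand(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _primer_set(max_mismatches=0):
    return PrimerSet(
        name="toy",
        forward=(Primer(FWD),),
        reverse=(Primer(revcomp(REV)),),
        max_mismatches=max_mismatches,
    )


class TestMatchPrimers:
    def test_planted_sites_600_apart(self):
        rng = np.random.default_rng(0)
        seq = _rand(rng, 100) + FWD + _rand(rng, 600) + REV + _rand(rng, 100)
        intervals = match_primers(seq, _primer_set())
        assert intervals == [(100, 100 + 20 + 600 + 20)]

    def test_mismatch_tolerance_is_respected(self):
        rng = np.random.default_rng(1)
        fwd_1mm = "T" + FWD[1:]
        seq = _rand(rng, 50) + fwd_1mm + _rand(rng, 300) + REV + _rand(rng, 50)
        assert match_primers(seq, _primer_set(max_mismatches=1)) == [(50, 50 + 20 + 300 + 20)]
        assert match_primers(seq, _primer_set(max_mismatches=0)) == []

    def test_reverse_strand_amplicons_are_found(self):
        rng = np.random.default_rng(2)
        seq = _rand(rng, 50) + FWD + _rand(rng, 200) + REV + _rand(rng, 50)
        assert match_primers(revcomp(seq), _primer_set()) == [(50, 50 + 20 + 200 + 20)]

    def test_agrees_with_naive_sliding_window_oracle(self):
        """All-pairs scan equals the brute-force oracle on random 2-kb loci."""
        rng = np.random.default_rng(3)
        pset = PrimerSet(
            name="mix",
            forward=(Primer(FWD, 5.0), Primer("G" + FWD[1:], 1.0)),
            reverse=(Primer(revcomp(REV)),),
            max_mismatches=1,
        )
        for trial in range(50):
            seq = list(_rand(rng, 2000))
            # plant 0-2 forward and reverse sites at random positions
            for site in (FWD, REV):
                for _ in range(int(rng.integers(0, 3))):
                    p = int(rng.integers(0, 2000 - 20))
                    seq[p : p + 20] = list(site)
            seq = "".join(seq)
            expected = oracle_primer_scan(
                seq, [p.sequence for p in pset.forward], [p.sequence for p in pset.reverse], 1
            )
            assert match_primers(seq, pset) == expected


class TestExtractAmplicons:
    def test_full_coverage_of_the_synthetic_family(self, family, gag_profile):
        reference = {r.locus_id for r in family.registry if r.provenance == "reference"}
        assert set(gag_profile.sequences) == reference
        # the retrocopy lost its gag region together with the intron
        assert gag_profile.absent == {"locus_retro": "no forward primer match"}

    def test_deleting_the_forward_site_reports_a_reason(self, family):
        rec = family.registry.records["locus01"]
        damaged = LocusRecord(
            locus_id="damaged",
            sequence=rec.sequence[: S.GAG_F_SITE[0]] + rec.sequence[S.GAG_R_SITE[1] :],
            provirus_type=2,
        )
        registry = LocusRegistry.from_records([damaged], "damaged")
        profile = extract_amplicons(registry, family.definitions["gag"])
        assert profile.sequences == {}
        assert "no forward primer match" in profile.absent["damaged"]

    def test_type1_and_type2_products_differ_by_the_indel(self, family, env_profile):
        lengths = {
            rec.locus_id: len(env_profile.sequences[rec.locus_id])
            for rec in family.registry
            if rec.locus_id in env_profile.sequences
        }
        by_type = {1: set(), 2: set()}
        for rec in family.registry:
            if rec.locus_id in lengths:
                by_type[rec.provirus_type].add(lengths[rec.locus_id])
        assert by_type[2] == {620}
        assert by_type[1] == {620 - 292}


@pytest.fixture(scope="module")
def ref5(family):
    return family.ancestor[S.ENV_START : S.ENV600_R_SITE[1]]


class TestClassifyProvirusType:
    def test_type2_self_classification(self, ref5):
        assert classify_provirus_type(ref5, ref5) == 2

    def test_excising_the_segment_gives_type1(self, family, ref5):
        seg = (S.SEGMENT[0] - S.ENV_START, S.SEGMENT[1] - S.ENV_START)
        type1 = ref5[: seg[0]] + ref5[seg[1] :]
        assert classify_provirus_type(type1, ref5) == 1

    @pytest.mark.parametrize("extra,expected", [(0, 1), (8, 1), (28, "unknown")])
    def test_deletion_length_tolerance_boundaries(self, ref5, family, extra, expected):
        """292 +/- 10 nt counts as the type-1 deletion; larger is unknown."""
        seg = (S.SEGMENT[0] - S.ENV_START, S.SEGMENT[1] - S.ENV_START)
        mutant = ref5[: seg[0]] + ref5[seg[1] + extra :]
        assert classify_provirus_type(mutant, ref5) == expected

    def test_reinserting_the_segment_flips_the_call(self, family, ref5):
        seg = (S.SEGMENT[0] - S.ENV_START, S.SEGMENT[1] - S.ENV_START)
        segment = ref5[seg[0] : seg[1]]
        type1 = ref5[: seg[0]] + ref5[seg[1] :]
        assert classify_provirus_type(type1, ref5) == 1
        restored = type1[: seg[0]] + segment + type1[seg[0] :]
        assert classify_provirus_type(restored, ref5) == 2

    def test_short_input_is_an_error(self, ref5):
        with pytest.raises(ValueError, match="too short"):
            classify_provirus_type("ACGT" * 20, ref5)


class TestDifferenceMatrix:
    def test_identical_sequences_give_zero(self):
        m = difference_matrix({"a": "ACGTACGT" * 20, "b": "ACGTACGT" * 20})
        assert m.loc["a", "b"] == 0

    def test_substitutions_plus_one_long_gap_count_as_events(self):
        rng = np.random.default_rng(5)
        base = _rand(rng, 600)
        other = list(base)
        for pos in (50, 450, 550):  # outside the deleted segment
            other[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[other[pos]]
        other = "".join(other[:100] + other[100 + 292 :])  # 3 subs + one 292-nt gap
        assert count_differences(base, other) == 4
        m = difference_matrix({"a": base, "b": other})
        assert m.loc["a", "b"] == 4

    def test_score_matches_independent_affine_gap_oracle(self):
        """The alignment underlying the counts is optimal (Gotoh check)."""
        from hml2profiler._align import _GLOBAL

        rng = np.random.default_rng(6)
        for _ in range(8):
            a = _rand(rng, 120)
            b = list(a)
            for pos in rng.choice(120, size=4, replace=False):
                b[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[b[pos]]
            b = "".join(b)
            assert _GLOBAL.align(a, b)[0].score == pytest.approx(gotoh_score(a, b))

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.data())
    def test_symmetry_zero_iff_identical(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        a = _rand(rng, 80)
        n_mut = data.draw(st.integers(0, 6))
        b = list(a)
        for pos in rng.choice(80, size=n_mut, replace=False):
            b[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[b[pos]]
        b = "".join(b)
        d_ab, d_ba = count_differences(a, b), count_differences(b, a)
        assert d_ab == d_ba >= 0
        assert (d_ab == 0) == (a == b)

    def test_family_matrix_matches_planted_truth(self, family, gag_profile):
        """For indel-free loci, matrix entries equal planted substitution diffs."""
        truth = family.truth
        alleles = {}
        for locus_id in gag_profile.locus_ids:
            events = truth.loc[locus_id, "substitutions"]
            alleles[locus_id] = {}
            for e in events.split(";") if events else []:
                pos, new = int(e[:-3]), e[-1]  # "123A>G"
                if S.GAG_F_SITE[0] <= pos < S.GAG_R_SITE[1]:
                    alleles[locus_id][pos] = new
        matrix = gag_profile.difference_matrix
        ids = [l for l in gag_profile.locus_ids]
        for i in ids[:6]:
            for j in ids[:6]:
                if i >= j:
                    continue
                positions = set(alleles[i]) | set(alleles[j])
                expected = sum(
                    1 for p in positions if alleles[i].get(p) != alleles[j].get(p)
                )
                assert matrix.loc[i, j] == expected


class TestDiagnosticSites:
    def test_private_substitutions_are_flagged(self):
        rng = np.random.default_rng(7)
        base = _rand(rng, 200)
        seqs = {}
        planted = {"a": 30, "b": 90, "c": 150}
        for name, pos in planted.items():
            s = list(base)
            s[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[s[pos]]
            seqs[name] = "".join(s)
        profile = S.AmpliconProfile(
            amplicon=AmpliconDefinition("toy", _primer_set(), {1: (1, 10_000)}),
            sequences=seqs,
        )
        sites = diagnostic_sites(profile)
        assert {s.column for s in sites} == set(planted.values())
        assert all(s.private for s in sites)
        assert {s.private_locus for s in sites} == set(planted)

    def test_brute_force_column_scan_agrees(self, gag_profile):
        rows = gag_profile.alignment_rows()
        ids = list(rows)
        length = len(rows[gag_profile.anchor])
        expected = [
            col
            for col in range(length)
            if len({rows[i][col] for i in ids}) > 1
        ]
        assert [s.column for s in diagnostic_sites(gag_profile)] == expected

    def test_identical_pair_is_reported_indistinguishable(self, family, gag_profile):
        groups = indistinguishable_groups(gag_profile)
        assert groups == [frozenset({"locus19", "locus20"})]
        sites = diagnostic_sites(gag_profile)
        # no column separates the pair
        assert all(s.bases["locus19"] == s.bases["locus20"] for s in sites)


class TestPrimerConfig:
    def test_packaged_defaults_carry_published_reverse_primers(self):
        from hml2profiler.amplicons import load_primer_config

        definitions = load_primer_config()
        # the env600nt set lacks forward primers (published elsewhere) and is
        # therefore returned incomplete rather than silently guessed
        assert definitions["env600nt"] is None
        import yaml
        from importlib import resources

        with resources.files("hml2profiler").joinpath("data", "primers.yaml").open() as fh:
            raw = yaml.safe_load(fh)
        reverse = raw["primer_sets"]["env600nt"]["reverse"]
        assert len(reverse) == 6
        assert reverse[0]["sequence"].startswith("ATTTACCCGTGGCCTGAGTG"[:10])
        assert [p["ratio"] for p in reverse] == [5, 1, 1, 1, 1, 1]

    def test_complete_config_round_trips_to_definitions(self, tmp_path):
        from hml2profiler.amplicons import load_primer_config

        cfg = tmp_path / "primers.yaml"
        cfg.write_text(
            "primer_sets:\n"
            "  toy:\n"
            "    max_mismatches: 1\n"
            "    forward: [{sequence: ACGTACGGTTCAGACCTAGC, ratio: 5}]\n"
            "    reverse: [{sequence: TGGACTGATCCGTACTCAGG, ratio: 1}]\n"
            "amplicon_definitions:\n"
            "  toy:\n"
            "    expected_lengths: {1: [100, 900], 2: [100, 900]}\n"
        )
        definitions = load_primer_config(cfg)
        toy = definitions["toy"]
        assert toy.primer_set.max_mismatches == 1
        assert toy.expected_lengths == {1: (100, 900), 2: (100, 900)}
        assert toy.length_ok(500) and not toy.length_ok(950)


class TestRegistryTypeCheck:
    def test_declared_types_match_sequence_classification(self, family):
        from hml2profiler.registry import check_provirus_types

        ref5 = family.ancestor[S.ENV_START : S.ENV600_R_SITE[1]]
        assert check_provirus_types(family.registry, ref5) == {}

    def test_mislabelled_type_triggers_a_warning(self, family):
        from hml2profiler.registry import LocusRegistry, LocusRecord, check_provirus_types

        rec = family.registry.records["locus01"]
        wrong = LocusRecord(
            locus_id="wrong", sequence=rec.sequence, provirus_type=1
        )
        registry = LocusRegistry.from_records([wrong], "wrong")
        ref5 = family.ancestor[S.ENV_START : S.ENV600_R_SITE[1]]
        with pytest.warns(UserWarning, match="wrong"):
            mismatches = check_provirus_types(registry, ref5)
        assert mismatches == {"wrong": (1, 2)}
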