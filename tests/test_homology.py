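"""Aligner correctness and the marker-detection decision rules."""

import numpy as np
import pytest

from halonitro.errors import AmbiguityError, ConfigError, ContextError
from halonitro.homology import (
    MarkerHit,
    MarkerProfile,
    ReferencePanel,
    build_profiles,
    global_align,
    scan_proteome,
    type_nir,
    verify_nar_context,
)
from halonitro.seqio import GeneOrder, SequenceRecord
from halonitro.synthetic_data import generate_reference_panel, mutate_to_identity

from oracles import gotoh_oracle, identity_oracle


class TestGlobalAlign:
    def test_identical_sequences(self):
        res = global_align("MKVL", "MKVL")
        assert res.percent_identity == 1.0
        assert res.matches == 4
        assert res.alignment_length == 4

    def test_single_substitution(self):
        res = global_align("MKVL", "MAVL")
        assert res.percent_identity == 0.75

    def test_internal_gap_matches_oracle(self):
        a, b = "MKVLAAAQWE", "MKVLAAQWE"
        res = global_align(a, b)
        score, oa, ob = gotoh_oracle(a, b)
        assert res.score == pytest.approx(score)
        assert (res.aligned_query, res.aligned_subject) == (oa, ob)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ConfigError):
            global_align("", "MKVL")

    def test_symmetry_of_identity(self, rng):
        for _ in range(30):
            a = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=int(rng.integers(5, 40))))
            b = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=int(rng.integers(5, 40))))
            assert global_align(a, b).percent_identity == pytest.approx(
                global_align(b, a).percent_identity
            )

    def test_score_matches_biopython(self, rng):
        """Independent cross-check of the optimal score against the
        Needleman-Wunsch implementation in Biopython."""
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1.0
        aligner.mismatch_score = 0.0
        aligner.open_gap_score = -10.0
        aligner.extend_gap_score = -1.0
        for _ in range(40):
            a = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=int(rng.integers(5, 60))))
            b = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=int(rng.integers(5, 60))))
            assert global_align(a, b).score == pytest.approx(aligner.score(a, b))

    def test_terminal_overhang_excluded_from_identity(self):
        # fragment vs full length: overhang columns must not dilute identity
        res = global_align("KVLA", "MMMMKVLAMMMM", gap_open=-1, gap_extend=-0.5)
        assert res.percent_identity == 1.0
        assert res.alignment_length == 4


class TestScanProteome:
    def test_homolog_at_70_percent_accepted(self, panel):
        ref = panel.members["NirK"][0]
        prot = [SequenceRecord("p1", mutate_to_identity(ref.residues, 0.70, seed=1))]
        hits = scan_proteome("sp", prot, panel)
        nirk = [h for h in hits if h.enzyme == "NirK"][0]
        assert nirk.accepted
        assert nirk.percent_identity == pytest.approx(0.70, abs=0.02)

    def test_boundary_exactly_65_percent_accepted(self, panel):
        # NirK panel length 300 -> exactly 105 mutations gives 195/300 = 0.65
        ref = panel.members["NirK"][0]
        mutant = mutate_to_identity(ref.residues, 0.65, seed=5)
        assert sum(x != y for x, y in zip(mutant, ref.residues)) == 105
        hits = scan_proteome("sp", [SequenceRecord("p1", mutant)], panel)
        nirk = [h for h in hits if h.enzyme == "NirK"][0]
        assert nirk.percent_identity == pytest.approx(0.65)
        assert nirk.accepted  # "at least 65%": inclusive threshold

    def test_decoy_reported_but_not_accepted(self, panel):
        ref = panel.members["Nor"][0]
        prot = [SequenceRecord("p1", mutate_to_identity(ref.residues, 0.30, seed=2))]
        hits = scan_proteome("sp", prot, panel)
        nor = [h for h in hits if h.enzyme == "Nor"][0]
        assert not nor.accepted
        assert nor.percent_identity == pytest.approx(0.30, abs=0.02)

    def test_below_threshold_mutant_yields_no_accepted_hit(self, panel):
        ref = panel.members["NarG"][0]
        prot = [SequenceRecord("p1", mutate_to_identity(ref.residues, 0.50, seed=3))]
        hits = scan_proteome("sp", prot, panel, threshold=0.65)
        assert not any(h.accepted for h in hits)

    def test_threshold_monotonicity(self, panel):
        prot = [
            SequenceRecord(
                f"p{i}", mutate_to_identity(panel.members[fam][0].residues, ident, seed=i)
            )
            for i, (fam, ident) in enumerate(
                [("NarG", 0.9), ("NirK", 0.7), ("Nor", 0.66), ("NosZ", 0.5)]
            )
        ]
        accepted = {}
        for thr in (0.45, 0.65, 0.75, 0.95):
            hits = scan_proteome("sp", prot, panel, threshold=thr)
            accepted[thr] = {h.enzyme for h in hits if h.accepted}
        assert accepted[0.95] <= accepted[0.75] <= accepted[0.65] <= accepted[0.45]

    def test_output_invariant_to_proteome_order(self, panel, rng):
        prot = [
            SequenceRecord(f"p{i}", mutate_to_identity(panel.members["NosZ"][0].residues, 0.8, seed=i))
            for i in range(4)
        ]
        hits_fwd = scan_proteome("sp", prot, panel)
        hits_rev = scan_proteome("sp", prot[::-1], panel)
        assert [(h.enzyme, h.protein_id, h.percent_identity) for h in hits_fwd] == [
            (h.enzyme, h.protein_id, h.percent_identity) for h in hits_rev
        ]

    def test_empty_proteome_warns(self, panel):
        with pytest.warns(UserWarning):
            assert scan_proteome("sp", [], panel) == []


def _hit(enzyme, pid, identity=0.9, accepted=True):
    return MarkerHit(
        species="sp",
        enzyme=enzyme,
        protein_id=pid,
        subject_id=f"ref_{enzyme}_1",
        percent_identity=identity,
        matches=int(identity * 100),
        alignment_length=100,
        accepted=accepted,
    )


class TestNarContext:
    @pytest.mark.parametrize(
        "narh_pos,window,expected",
        [(6, 2, True), (7, 2, True), (8, 2, False), (8, 3, True), (3, 2, True)],
    )
    def test_window_semantics_on_toy_replicon(self, narh_pos, window, expected):
        """All placements of narH around narG at position 5 on a 10-gene replicon."""
        genes = [("chr", i, f"g{i}") for i in range(10)]
        order = GeneOrder("sp", genes)
        hits = [_hit("NarG", "g5"), _hit("NarH", f"g{narh_pos}")]
        assert verify_nar_context("sp", hits, order, window=window) is expected

    def test_narh_on_other_replicon_fails(self):
        order = GeneOrder("sp", [("chr", 0, "g0"), ("pHV", 0, "h0")])
        hits = [_hit("NarG", "g0"), _hit("NarH", "h0")]
        assert verify_nar_context("sp", hits, order) is False

    def test_missing_narg_gene_is_error_not_false(self):
        order = GeneOrder("sp", [("chr", 0, "other")])
        hits = [_hit("NarG", "gX"), _hit("NarH", "other")]
        with pytest.raises(ContextError):
            verify_nar_context("sp", hits, order)


class TestTypeNir:
    def test_nirk_hit(self):
        assert type_nir([_hit("NirK", "p1")]) == "NirK"

    def test_absent(self):
        assert type_nir([_hit("Nor", "p1")]) == "absent"
        assert type_nir([_hit("NirK", "p1", accepted=False)]) == "absent"

    def test_same_protein_both_types_is_ambiguous(self):
        with pytest.raises(AmbiguityError):
            type_nir([_hit("NirK", "p1"), _hit("NirS", "p1")])


class TestBuildProfiles:
    def test_accepted_narg_without_context_gives_nar_false(self, panel):
        """A species with NarG but no adjacent narH is not scored as a
        nitrate reducer (canonical Nar requires the operon partner)."""
        narg = SequenceRecord("sp_p01", mutate_to_identity(panel.members["NarG"][0].residues, 0.9, 1))
        order = GeneOrder("sp", [("chr", 0, "sp_p01")])
        hits = {"sp": scan_proteome("sp", [narg], panel)}
        profiles = build_profiles(hits, {"sp": order}, {"sp": ("FamA", True)})
        assert profiles[0].nar is False

    def test_full_profile_when_all_accepted_and_adjacent(self, panel):
        seqs = {
            "NarG": "sp_p01",
            "NarH": "sp_p02",
            "NirK": "sp_p03",
            "Nor": "sp_p04",
            "NosZ": "sp_p05",
        }
        prot = [
            SequenceRecord(pid, mutate_to_identity(panel.members[fam][0].residues, 0.9, i))
            for i, (fam, pid) in enumerate(seqs.items())
        ]
        order = GeneOrder("sp", [("chr", i, pid) for i, pid in enumerate(seqs.values())])
        hits = {"sp": scan_proteome("sp", prot, panel)}
        profile = build_profiles(hits, {"sp": order}, {"sp": ("FamA", True)})[0]
        assert (profile.nar, profile.nir, profile.nir_type, profile.nor, profile.nos) == (
            True,
            True,
            "NirK",
            True,
            True,
        )

    def test_no_genome_species_excluded(self):
        profiles = build_profiles({}, {}, {"sp": ("FamA", False)})
        assert profiles == []


class TestPipelineRecovery:
    def test_detected_profiles_match_ground_truth(self, small_community):
        """Detection on a synthetic community recovers every true profile
        (identity_true=0.85, identity_decoy=0.30, threshold 0.65)."""
        com = small_community
        hits = {sp: scan_proteome(sp, prot, com.panel) for sp, prot in com.proteomes.items()}
        profiles = build_profiles(hits, com.gene_orders, com.taxonomy)
        assert len(profiles) == 12
        for p in profiles:
            t = com.truth.profiles[p.species]
            assert (p.nar, p.nir, p.nir_type, p.nor, p.nos) == (
                t.nar,
                t.nir,
                t.nir_type,
                t.nor,
                t.nos,
            ), p.species

    def test_no_species_typed_nirs_when_seeded_from_nirk(self, small_community):
        """All planted nitrite reductases derive from the NirK panel, so
        no species may be typed NirS."""
        com = small_community
        hits = {sp: scan_proteome(sp, prot, com.panel) for sp, prot in com.proteomes.items()}
        profiles = build_profiles(hits, com.gene_orders, com.taxonomy)
        assert sum(p.nir_type == "NirS" for p in profiles) == 0


class TestPanelContrast:
    def test_nirk_nirs_panel_identity_below_40_percent(self, panel):
        """NirK and NirS references must be mutually distinguishable."""
        res = global_align(panel.members["NirK"][0], panel.members["NirS"][0])
        assert res.percent_identity < 0.40
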