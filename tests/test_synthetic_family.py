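"""Generator truths: divergence statistics, engineered deletion, contexts."""

import numpy as np
import pytest

from hml2kit.catalogue import catalogue_to_fasta_string
from hml2kit.synthetic_family import (
    ALT_TSS_IN_R,
    FRAGMENT_LTR_LEN,
    POL_ENV_DELETION_LEN,
    U3_R_BORDER,
    UPSTREAM_LTR_GAP,
    FamilySpec,
    HostContext,
    PlanEntry,
    apply_type1_deletion,
    build_host_contexts,
    generate_family,
    make_truth_profile,
    mutate,
)


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def test_zero_divergence_descendant_equals_ancestor(single_provirus):
    catalogue, ancestry = single_provirus
    assert catalogue.get("P0").seq == ancestry.ancestor_seq


def test_type1_member_is_292_shorter_than_type2(study_family):
    catalogue, _ = study_family
    assert len(catalogue.get("Hs_03")) == len(catalogue.get("Hs_01")) - POL_ENV_DELETION_LEN
    assert catalogue.get("Hs_03").provirus_type == "type1"


def test_substitution_count_within_3_sd_of_binomial():
    d = 0.02
    spec = FamilySpec(
        divergences={"X": d}, duplicate_pairs=[], type1_members=(),
        hypermutated_members=(), solo_ltr_count=0, seed=99,
    )
    catalogue, ancestry = generate_family(spec)
    L = len(ancestry.ancestor_seq)
    observed = _hamming(catalogue.get("X").seq, ancestry.ancestor_seq)
    sd = np.sqrt(L * d * (1 - d))
    assert abs(observed - L * d) <= 3 * sd


def test_duplicate_pair_intra_divergence(study_family):
    catalogue, _ = study_family
    a, b = catalogue.get("HsDupA").seq, catalogue.get("HsDupB").seq
    assert a == b  # declared intra-pair divergence of the study family is 0


@pytest.mark.parametrize("intra", [0.004, 0.01])
def test_duplicate_pair_hamming_tracks_requested_divergence(intra):
    spec = FamilySpec(
        divergences={}, duplicate_pairs=[("d1", "d2", 0.002, intra)],
        type1_members=(), hypermutated_members=(), solo_ltr_count=0, seed=5,
    )
    catalogue, _ = generate_family(spec)
    a, b = catalogue.get("d1").seq, catalogue.get("d2").seq
    L = len(a)
    # each member mutated intra/2 from the pair parent; double hits shrink
    # the realized distance slightly, so allow 3 SD around the target
    observed = _hamming(a, b) / L
    sd = np.sqrt(intra * (1 - intra) / L)
    assert abs(observed - intra) <= 3 * sd + 2 * (intra / 2) ** 2


def test_same_seed_gives_byte_identical_catalogue():
    out = [catalogue_to_fasta_string(generate_family(FamilySpec(seed=42))[0]) for _ in range(2)]
    assert out[0] == out[1]


def test_hypermutation_replaces_only_g_with_a(study_family):
    catalogue, ancestry = study_family
    spec_h = FamilySpec(seed=7)
    # regenerate without hypermutation to obtain the pre-hypermutation sequence
    spec_h.hypermutated_members = ()
    plain = generate_family(spec_h)[0].get("Hs_05").seq
    hyper = catalogue.get("Hs_05").seq
    changed = [(x, y) for x, y in zip(plain, hyper) if x != y]
    assert changed and all(x == "G" and y == "A" for x, y in changed)
    n_g = plain.count("G")
    assert abs(len(changed) - 0.3 * n_g) <= 3 * np.sqrt(n_g * 0.3 * 0.7)


def test_solo_ltr_is_u3_r_of_5ltr_plus_u5_of_3ltr(study_family):
    catalogue, ancestry = study_family
    solo = catalogue.get("solo_01")
    donor = catalogue.get(ancestry.elements["solo_01"].solo_donor)
    assert solo.seq[:870] == donor.seq[:870]  # U3+R of the 5' LTR
    assert solo.seq[870:] == donor.seq[-98:]  # U5 of the 3' LTR
    assert len(solo) == 968


def test_apply_type1_deletion_on_type2_element(single_provirus):
    catalogue, ancestry = single_provirus
    elem = catalogue.get("P0")
    ann = catalogue.annotations["P0"]
    t1, t1_ann = apply_type1_deletion(elem, ann)
    assert len(t1) == len(elem) - POL_ENV_DELETION_LEN
    env0 = ann.span("env")
    env1 = t1_ann.span("env")
    assert env1[0] == env0[0]  # deletion starts at the boundary
    assert env1[1] == env0[1] - POL_ENV_DELETION_LEN


def test_deletion_past_sequence_end_is_error(single_provirus):
    catalogue, _ = single_provirus
    elem = catalogue.get("P0")
    ann = catalogue.annotations["P0"]
    with pytest.raises(ValueError, match="past sequence end"):
        apply_type1_deletion(elem, ann, deletion_len=10_000)


def test_mutate_rejects_bad_divergence():
    with pytest.raises(ValueError):
        mutate("ACGT", 1.5, np.random.default_rng(0))


class TestHostContexts:
    def test_isolated_scenario_has_empty_flanks(self, study_family):
        catalogue, ancestry = study_family
        ctx = build_host_contexts(catalogue, {"Hs_02": "isolated"}, seed=1, ancestry=ancestry)
        ec = ctx.get("Hs_02")
        assert ec.up_flank == "" and ec.down_flank == ""

    def test_upstream_fragment_sits_551_bp_upstream(self, study_family):
        catalogue, ancestry = study_family
        ctx = build_host_contexts(
            catalogue, {"5B_01": "upstream_fragmentary_ltr"}, seed=1, ancestry=ancestry
        )
        ec = ctx.get("5B_01")
        frag_start, frag_end = ec.fragment_span_in_up
        gap = len(ec.up_flank) - frag_end
        assert gap == UPSTREAM_LTR_GAP
        assert frag_end - frag_start + 1 == FRAGMENT_LTR_LEN

    def test_chimeric_junction_is_gt_ag_in_dna_sense(self, study_family):
        catalogue, ancestry = study_family
        ctx = build_host_contexts(
            catalogue, {"5B_01": "upstream_fragmentary_ltr"}, seed=1, ancestry=ancestry
        )
        ec = ctx.get("5B_01")
        donor_intron = ec.up_flank[ec.donor_end_in_up : ec.donor_end_in_up + 2]
        elem = catalogue.get("5B_01")
        acc = ec.acceptor_start_in_elem
        acceptor_intron = elem.seq[acc - 3 : acc - 1]
        assert donor_intron == "GT"
        assert acceptor_intron == "AG"


class TestTruthProfile:
    def test_single_transcript_gets_fraction_one(self, single_provirus):
        catalogue, _ = single_provirus
        plan = {"P0": PlanEntry(0.7, 1.0, "ltr_driven")}
        truth = make_truth_profile(catalogue, HostContext(contexts={}), plan)
        assert truth.fractions("cell") == {"tx_P0": 1.0}

    def test_ltr_driven_tss_is_u3_r_border(self, single_provirus):
        catalogue, _ = single_provirus
        plan = {"P0": PlanEntry(1.0, 1.0, "ltr_driven")}
        truth = make_truth_profile(catalogue, HostContext(contexts={}), plan)
        (tx,) = truth.transcripts
        assert tx.exons[0][0] == U3_R_BORDER

    def test_chimeric_exon1_starts_at_alt_tss_in_fragment_r(self, study_family):
        catalogue, ancestry = study_family
        ctx = build_host_contexts(
            catalogue, {"5B_01": "upstream_fragmentary_ltr"}, seed=1, ancestry=ancestry
        )
        plan = {"5B_01": PlanEntry(1.0, 1.0, "upstream_ltr_chimeric")}
        truth = make_truth_profile(catalogue, ctx, plan)
        (tx,) = truth.transcripts
        frag_start = ctx.get("5B_01").fragment_span_in_up[0]
        assert tx.exons[0][0] == frag_start + ALT_TSS_IN_R - 1

    def test_zero_packaging_locus_absent_from_virion_truth(self, study_family):
        catalogue, _ = study_family
        plan = {
            "Hs_01": PlanEntry(0.5, 1.0),
            "5B_02": PlanEntry(0.5, 0.0),
        }
        truth = make_truth_profile(catalogue, HostContext(contexts={}), plan)
        virion = truth.element_fractions("virion")
        assert virion["5B_02"] == 0.0
        assert virion["Hs_01"] == 1.0

    def test_fraction_sums_are_normalized(self, study_family):
        catalogue, ancestry = study_family
        from hml2kit.synthetic_family import default_sample_plan, default_scenarios

        plan = default_sample_plan()
        ctx = build_host_contexts(catalogue, default_scenarios(plan), seed=2, ancestry=ancestry)
        truth = make_truth_profile(catalogue, ctx, plan)
        for sample in ("cell", "virion"):
            assert sum(truth.fractions(sample).values()) == pytest.approx(1.0)
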