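"""Aligner completeness (vs brute force), pairing semantics, SAM output."""

import numpy as np
import pysam
import pytest

from hml2kit.aligner import (
    AlignParams,
    align_pair,
    align_pairs,
    align_spliced,
    brute_force_hits,
    build_index,
    read_sam,
    write_sam,
)
from hml2kit.catalogue import Catalogue, Element, revcomp
from hml2kit.readsim import ReadPair, simulate_library, cell_library
from hml2kit.synthetic_family import mutate, random_dna


def _pair_from(seq: str, pos: int, insert: int, read_len: int, rid="p") -> ReadPair:
    frag = seq[pos : pos + insert]
    m2 = frag[:read_len]
    m1 = revcomp(frag[-read_len:])
    return ReadPair(rid, m1, "F" * len(m1), m2, "F" * len(m2))


def test_single_element_prefix_read_hits_position_one(rng):
    cat = Catalogue()
    cat.add(Element(id="e", elem_class="provirus", seq=random_dna(2000, rng)))
    idx = build_index(cat)
    hits = idx.align_mate(cat.get("e").seq[:120], 2)
    assert [(h.element_id, h.start, h.strand, h.mismatches) for h in hits] == [("e", 1, "+", 0)]


def test_reverse_complement_query_found_on_minus_strand(rng):
    cat = Catalogue()
    cat.add(Element(id="e", elem_class="provirus", seq=random_dna(2000, rng)))
    idx = build_index(cat)
    read = revcomp(cat.get("e").seq[500:620])
    hits = idx.align_mate(read, 2)
    assert hits == brute_force_hits(cat, read, 2)
    assert hits[0].strand == "-" and hits[0].start == 501


def test_seeded_search_matches_brute_force_with_planted_mismatches(toy_catalogue, rng):
    idx = build_index(toy_catalogue)
    elems = list(toy_catalogue)
    for t in range(60):
        elem = elems[t % 3]
        pos = int(rng.integers(0, len(elem) - 120))
        read = mutate(elem.seq[pos : pos + 120], 0.01, rng)
        if t % 2:
            read = revcomp(read)
        assert idx.align_mate(read, 2) == brute_force_hits(toy_catalogue, read, 2)


def test_symmetry_under_pair_reverse_complement(toy_catalogue, rng):
    idx = build_index(toy_catalogue)
    elem = toy_catalogue.get("lone")
    pair = _pair_from(elem.seq, 100, 400, 150)
    # swap mates and reverse complement both: same fragment, other strand
    swapped = ReadPair("p", pair.seq2, pair.qual2, pair.seq1, pair.qual1)
    a1 = align_pair(pair, idx, 2, (150, 500))
    a2 = align_pair(swapped, idx, 2, (150, 500))
    locs1 = {(l.element_id, l.start, l.end) for l in a1.locations}
    locs2 = {(l.element_id, l.start, l.end) for l in a2.locations}
    assert locs1 == locs2
    assert {l.ts_strand for l in a1.locations} == {"+"}
    assert {l.ts_strand for l in a2.locations} == {"-"}


def test_raising_mismatch_budget_never_removes_locations(toy_catalogue, rng):
    idx = build_index(toy_catalogue)
    elem = toy_catalogue.get("parA")
    for t in range(20):
        pos = int(rng.integers(0, len(elem) - 500))
        pair = _pair_from(mutate(elem.seq, 0.005, rng), pos, 450, 150, rid=f"p{t}")
        locs = {}
        for mm in (0, 1, 2):
            a = align_pair(pair, idx, mm, (150, 600))
            locs[mm] = {(l.element_id, l.start, l.end) for l in a.locations}
        assert locs[0] <= locs[1] <= locs[2]


@pytest.fixture()
def duplicate_catalogue(rng):
    cat = Catalogue()
    base = random_dna(5000, rng)
    cat.add(Element(id="dupA", elem_class="provirus", seq=base))
    cat.add(Element(id="dupB", elem_class="provirus", seq=base))
    return cat


def test_identical_duplicate_pair_gives_multi_mapq_1(duplicate_catalogue):
    idx = build_index(duplicate_catalogue)
    pair = _pair_from(duplicate_catalogue.get("dupA").seq, 3000, 450, 250)
    a = align_pair(pair, idx, 2, (250, 600))
    assert not a.unique
    assert a.mapq == 1
    assert {l.element_id for l in a.locations} == {"dupA", "dupB"}


def test_unique_means_only_location_within_budget(rng):
    """A perfect hit plus a 2-mismatch hit elsewhere is still a multi-read."""
    cat = Catalogue()
    base = random_dna(3000, rng)
    # plant exactly 2 diagnostic differences within one read window
    arr = list(base)
    arr[1500] = "A" if arr[1500] != "A" else "C"
    arr[1510] = "A" if arr[1510] != "A" else "C"
    cat.add(Element(id="orig", elem_class="provirus", seq=base))
    cat.add(Element(id="near", elem_class="provirus", seq="".join(arr)))
    idx = build_index(cat)
    pair = _pair_from(base, 1450, 300, 150)
    a = align_pair(pair, idx, 2, (150, 400))
    assert len(a.locations) == 2 and not a.unique
    # with a 1-mismatch budget the diagnostic sites disambiguate the pair
    a1 = align_pair(pair, idx, 1, (150, 400))
    assert a1.unique and a1.locations[0].element_id == "orig"


def test_discordant_only_pairs_are_unaligned(rng):
    cat = Catalogue()
    cat.add(Element(id="e", elem_class="provirus", seq=random_dna(3000, rng)))
    idx = build_index(cat)
    seq = cat.get("e").seq
    # both mates forward strand: no FR combination exists
    m2 = seq[100:250]
    m1 = seq[600:750]
    pair = ReadPair("d", m1, "F" * 150, m2, "F" * 150)
    a = align_pair(pair, idx, 2, (150, 2000))
    assert not a.aligned


class TestSplicedAlignment:
    @pytest.fixture()
    def chimera(self):
        from hml2kit.synthetic_family import mechanism_demo

        cat, ctx, truth, aug, placements = mechanism_demo(seed=3)
        tx = next(t for t in truth.transcripts if t.mechanism == "upstream_ltr_chimeric")
        return aug, ctx, tx

    def test_exonic_read_is_never_split(self, chimera):
        aug, ctx, tx = chimera
        idx = build_index(aug)
        pair = _pair_from(tx.seq, 400, 300, 150)  # fully inside exon 2
        a = align_spliced(pair, idx, 2, (150, 500))
        assert a.aligned and a.junction is None

    def test_junction_positions_recovered_for_spanning_reads(self, chimera):
        aug, ctx, tx = chimera
        idx = build_index(aug)
        ec = ctx.get("mech_chimera")
        exon1_len = len(ec.up_flank) and (ec.donor_end_in_up - (tx.exons[0][0] - 1))
        true_donor = ec.donor_end_in_up
        true_acceptor = tx.exons[1][0]
        n_ok = 0
        for i in range(50):
            offset = exon1_len - 100 + i  # junction inside mate 2
            pair = _pair_from(tx.seq, offset, 400, 150, rid=f"jx{i}")
            a = align_spliced(pair, idx, 2, (100, 500))
            if a.junction is not None:
                assert a.junction.donor_end == true_donor
                assert a.junction.acceptor_start == true_acceptor
                assert a.junction.gt_ag
                n_ok += 1
        assert n_ok == 50


class TestSamOutput:
    def test_unique_pair_writes_two_mapq50_records(self, toy_catalogue, tmp_path):
        idx = build_index(toy_catalogue)
        elem = toy_catalogue.get("lone")
        pair = _pair_from(elem.seq, 100, 400, 150, rid="u1")
        a = align_pair(pair, idx, 2, (150, 500))
        sam = tmp_path / "one.sam"
        write_sam([(pair, a)], toy_catalogue, sam)
        records = [l for l in sam.read_text().splitlines() if not l.startswith("@")]
        assert len(records) == 2
        assert all(r.split("\t")[4] == "50" for r in records)
        assert all("NH:i:1" in r for r in records)

    def test_multi_pair_writes_secondary_records(self, duplicate_catalogue, tmp_path):
        catalogue = duplicate_catalogue
        idx = build_index(catalogue)
        pair = _pair_from(catalogue.get("dupA").seq, 3000, 450, 250, rid="m1")
        a = align_pair(pair, idx, 2, (250, 600))
        sam = tmp_path / "multi.sam"
        write_sam([(pair, a)], catalogue, sam)
        records = [l for l in sam.read_text().splitlines() if not l.startswith("@")]
        assert len(records) == 4
        assert sum(1 for r in records if int(r.split("\t")[1]) & 0x100) == 2
        assert all("NH:i:2" in r for r in records)
        assert all(r.split("\t")[4] == "1" for r in records)

    def test_sam_parses_cleanly_with_pysam(self, toy_catalogue, tmp_path, rng):
        idx = build_index(toy_catalogue)
        pairs = []
        for t in range(30):
            elem = list(toy_catalogue)[t % 3]
            pos = int(rng.integers(0, len(elem) - 400))
            pairs.append(_pair_from(elem.seq, pos, 400, 150, rid=f"r{t}"))
        sam = tmp_path / "batch.sam"
        items = list(align_pairs(pairs, idx, AlignParams(insert_bounds=(150, 500))))
        write_sam(items, toy_catalogue, sam)
        with pysam.AlignmentFile(str(sam), "r") as fh:
            n = sum(1 for _ in fh)
        assert n >= 60

    def test_read_sam_round_trips_locations(self, toy_catalogue, tmp_path, rng):
        idx = build_index(toy_catalogue)
        pairs = []
        for t in range(20):
            elem = list(toy_catalogue)[t % 3]
            pos = int(rng.integers(0, len(elem) - 400))
            pairs.append(_pair_from(elem.seq, pos, 400, 150, rid=f"r{t:02d}"))
        sam = tmp_path / "rt.sam"
        items = list(align_pairs(pairs, idx, AlignParams(insert_bounds=(150, 500))))
        write_sam(items, toy_catalogue, sam)
        recovered = {a.read_id: a for a in read_sam(sam)}
        for _pair, orig in items:
            back = recovered[orig.read_id]
            assert {(l.element_id, l.start, l.end, l.ts_strand) for l in back.locations} == {
                (l.element_id, l.start, l.end, l.ts_strand) for l in orig.locations
            }


def test_query_too_short_for_seeds_raises(toy_catalogue):
    idx = build_index(toy_catalogue, seed_len=20)
    with pytest.raises(ValueError, match="too short"):
        idx.align_mate("ACGT" * 10, 2)  # 40 b / 3 seeds < 20


def test_seed_len_below_12_rejected(toy_catalogue):
    with pytest.raises(ValueError, match=">= 12"):
        build_index(toy_catalogue, seed_len=8)
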