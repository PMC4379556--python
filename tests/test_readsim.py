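"""Read simulation statistics, FASTQ round trip and trimming policy."""

import numpy as np
import pytest

from hml2kit.catalogue import revcomp
from hml2kit.readsim import (
    LibraryParams,
    ReadPair,
    cell_library,
    read_fastq_pair,
    simulate_library,
    simulate_uniform,
    trim_reads,
    write_fastq_pair,
)
from hml2kit.synthetic_family import HostContext, PlanEntry, make_truth_profile


@pytest.fixture()
def one_transcript_truth(single_provirus):
    catalogue, _ = single_provirus
    plan = {"P0": PlanEntry(1.0, 1.0, "ltr_driven")}
    return make_truth_profile(catalogue, HostContext(contexts={}), plan)


def test_zero_fragments_yields_empty_but_valid_fastq(one_transcript_truth, tmp_path):
    pairs, report = simulate_library(
        one_transcript_truth, "cell", cell_library(n_fragments=0, seed=1)
    )
    assert pairs == []
    assert report.n_simulated == 0
    write_fastq_pair(pairs, tmp_path / "a_1.fq", tmp_path / "a_2.fq")
    assert (tmp_path / "a_1.fq").read_text() == ""


def test_error_free_mates_are_exact_transcript_substrings(one_transcript_truth):
    pairs, _ = simulate_library(
        one_transcript_truth, "cell", cell_library(n_fragments=200, seed=1, error_rate=0.0)
    )
    tx = one_transcript_truth.transcripts[0].seq
    for p in pairs:
        # FR orientation: mate 2 is transcript sense, mate 1 reverse complement
        assert p.seq2 in tx
        assert revcomp(p.seq1) in tx


def test_fragment_counts_follow_multinomial_weights(single_provirus):
    catalogue, _ = single_provirus
    # two transcripts over the same element, equal length, fractions 0.8/0.2
    plan = {"P0": PlanEntry(1.0, 1.0, "ltr_driven")}
    truth = make_truth_profile(catalogue, HostContext(contexts={}), plan)
    t0 = truth.transcripts[0]
    t1 = type(t0)(
        id="tx_alt", element_id="P0", record_id="P0", exons=t0.exons, strand="+",
        mechanism="ltr_driven", cell_fraction=0.0, virion_fraction=0.0, seq=t0.seq,
    )
    t0.cell_fraction, t1.cell_fraction = 0.8, 0.2
    truth.transcripts.append(t1)
    pairs, report = simulate_library(truth, "cell", cell_library(n_fragments=10_000, seed=2))
    n0 = report.fragments_per_transcript["tx_P0"]
    sd = np.sqrt(10_000 * 0.8 * 0.2)
    assert abs(n0 - 8000) <= 3 * sd


def test_truth_rows_match_simulated_pairs(one_transcript_truth, tmp_path):
    pairs, _ = simulate_library(one_transcript_truth, "cell", cell_library(500, seed=3))
    n = write_fastq_pair(pairs, tmp_path / "x_1.fq", tmp_path / "x_2.fq", tmp_path / "t.tsv")
    rows = (tmp_path / "t.tsv").read_text().strip().splitlines()
    assert len(rows) - 1 == n == 500


def test_same_seed_gives_identical_fastq_bytes(one_transcript_truth, tmp_path):
    blobs = []
    for run in range(2):
        pairs, _ = simulate_library(one_transcript_truth, "cell", cell_library(300, seed=9))
        f1, f2 = tmp_path / f"r{run}_1.fq", tmp_path / f"r{run}_2.fq"
        write_fastq_pair(pairs, f1, f2)
        blobs.append(f1.read_bytes() + f2.read_bytes())
    assert blobs[0] == blobs[1]


def test_short_transcript_skipped_with_warning(single_provirus):
    catalogue, _ = single_provirus
    plan = {"P0": PlanEntry(1.0, 1.0, "ltr_driven")}
    truth = make_truth_profile(catalogue, HostContext(contexts={}), plan)
    truth.transcripts[0].seq = truth.transcripts[0].seq[:50]  # below min insert
    with pytest.warns(UserWarning, match="shorter than min insert"):
        pairs, report = simulate_library(truth, "cell", cell_library(100, seed=1))
    assert pairs == []
    assert report.skipped_transcripts == ["tx_P0"]


class TestSimulateUniform:
    def test_fragment_count_formula(self, single_provirus):
        catalogue, _ = single_provirus
        elem = catalogue.get("P0")
        elem5k = type(elem)(id="half", elem_class="provirus", seq=elem.seq[:5000])
        pairs = simulate_uniform(elem5k, depth=20, read_len=250, seed=1)
        assert len(pairs) == 200  # 20 * 5000 / (2 * 250)

    def test_depth_zero_means_no_fragments(self, single_provirus):
        catalogue, _ = single_provirus
        assert simulate_uniform(catalogue.get("P0"), depth=0, seed=1) == []

    def test_element_shorter_than_read_is_error(self, rng):
        from hml2kit.catalogue import Element
        from hml2kit.synthetic_family import random_dna

        short = Element(id="s", elem_class="provirus", seq=random_dna(100, rng))
        with pytest.raises(ValueError, match="shorter than read length"):
            simulate_uniform(short, read_len=250)

    def test_coverage_close_to_target_depth(self, single_provirus):
        catalogue, _ = single_provirus
        elem = catalogue.get("P0")  # 9.5 kb
        pairs = simulate_uniform(elem, depth=20, read_len=250, seed=4)
        cov = np.zeros(len(elem))
        for p in pairs:
            _tx, s, e, _strand = p.truth
            cov[s - 1 : e] += 1
        assert abs(cov.mean() - 20) / 20 < 0.2


class TestTrimming:
    def _write(self, tmp_path, pairs):
        f1, f2 = tmp_path / "in_1.fq", tmp_path / "in_2.fq"
        write_fastq_pair(pairs, f1, f2)
        return f1, f2

    def test_clean_reads_pass_unchanged(self, tmp_path):
        pairs = [ReadPair("r1", "ACGT" * 30, "F" * 120, "TGCA" * 30, "F" * 120)]
        f1, f2 = self._write(tmp_path, pairs)
        o1, o2 = tmp_path / "o_1.fq", tmp_path / "o_2.fq"
        report = trim_reads(f1, f2, o1, o2)
        assert report.kept_pairs == 1
        assert o1.read_bytes() == f1.read_bytes()
        assert o2.read_bytes() == f2.read_bytes()

    def test_adapter_removed_by_exact_3prime_overlap(self, tmp_path):
        adapter = "AGATCGGAAGAGC"
        body = "ACGT" * 30
        pairs = [
            ReadPair("r1", body + adapter, "F" * (120 + 13), body, "F" * 120)
        ]
        f1, f2 = self._write(tmp_path, pairs)
        o1, o2 = tmp_path / "o_1.fq", tmp_path / "o_2.fq"
        report = trim_reads(f1, f2, o1, o2, adapters=(adapter,))
        assert report.kept_pairs == 1
        out_seq = o1.read_text().splitlines()[1]
        assert out_seq == body

    def test_pair_dropped_when_one_mate_trims_below_min_len(self, tmp_path):
        # mate 1 has low-quality tail starting at base 99 -> trimmed to 99 < 100
        good = "F" * 120
        bad = "F" * 99 + "#" * 21
        pairs = [
            ReadPair("r1", "ACGT" * 30, bad, "TGCA" * 30, good),
            ReadPair("r2", "ACGT" * 30, good, "TGCA" * 30, good),
        ]
        f1, f2 = self._write(tmp_path, pairs)
        o1, o2 = tmp_path / "o_1.fq", tmp_path / "o_2.fq"
        report = trim_reads(f1, f2, o1, o2, qual_threshold=25, min_len=100)
        assert report.input_pairs == 2
        assert report.kept_pairs == 1
        assert report.dropped_pairs == 1
        assert o1.read_text().count("@") == 1

    def test_mate_id_mismatch_reports_record_index(self, tmp_path):
        f1, f2 = tmp_path / "a_1.fq", tmp_path / "a_2.fq"
        f1.write_text("@x/1\nACGT\n+\nFFFF\n")
        f2.write_text("@y/2\nACGT\n+\nFFFF\n")
        with pytest.raises(ValueError, match="record 0"):
            list(read_fastq_pair(f1, f2))


def test_unstranded_library_mixes_mate_orientations(one_transcript_truth):
    from hml2kit.readsim import virion_library

    pairs, _ = simulate_library(
        one_transcript_truth, "virion", virion_library(400, seed=6, error_rate=0.0)
    )
    tx = one_transcript_truth.transcripts[0].seq
    sense2 = sum(p.seq2 in tx for p in pairs)
    # about half the fragments should have mate 2 on the transcript sense
    assert 0.35 < sense2 / len(pairs) < 0.65


def test_insert_bounds_validated():
    with pytest.raises(ValueError, match="insert_min <= insert_mean <= insert_max"):
        LibraryParams(insert_mean=50.0)
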