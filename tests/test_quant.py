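"""Counting modes, EM rescue against a maximum-likelihood oracle, FPKM."""

import math

import numpy as np
import pandas as pd
import pytest

from hml2kit.catalogue import Catalogue, Element
from hml2kit.quant import (
    CountTable,
    LocationClasses,
    _em_rescue,
    collect_location_classes,
    compare_modes,
    compute_expression,
    count_fragments,
    em_log_likelihood,
    target_lengths,
)
from collections import Counter


def _classes(spec: dict[tuple, int]) -> LocationClasses:
    c = Counter({k: v for k, v in spec.items()})
    return LocationClasses(classes=c, n_pairs=sum(spec.values()))


def test_unique_pairs_count_fully_in_every_mode():
    classes = _classes({("A",): 10})
    lengths = {"A": 1000}
    for mode in ("unfiltered_uniform", "unique_only", "em_rescue"):
        table = count_fragments(classes, mode, lengths=lengths)
        assert table.counts == {"A": 10.0}


def test_five_location_pair_contributes_twenty_percent_each():
    classes = _classes({tuple("ABCDE"): 1})
    table = count_fragments(classes, "unfiltered_uniform")
    assert table.counts == {k: pytest.approx(0.2) for k in "ABCDE"}


def test_unique_only_discards_multi_pairs():
    classes = _classes({("A",): 5, ("A", "B"): 7})
    table = count_fragments(classes, "unique_only")
    assert table.counts == {"A": 5.0}
    assert table.n_counted == 5


@pytest.mark.parametrize("mode", ["unfiltered_uniform", "unique_only", "em_rescue"])
def test_conservation_sum_equals_counted_pairs(mode):
    classes = _classes({("A",): 50, ("B",): 30, ("A", "B"): 100, ("A", "B", "C"): 33})
    lengths = {"A": 1000, "B": 1000, "C": 2000}
    table = count_fragments(classes, mode, lengths=lengths)
    assert math.isclose(sum(table.counts.values()), table.n_counted, abs_tol=1e-9)


def test_em_matches_maximum_likelihood_grid_search():
    """Two identical-body elements with 90:10 unique flank signal sharing 100
    multi-pairs: EM allocation must match the ML of the two-component
    multinomial within 1% (brute-force grid over the shared-mass split)."""
    classes = _classes({("A",): 90, ("B",): 10, ("A", "B"): 100})
    lengths = {"A": 10_000, "B": 10_000}
    table = count_fragments(classes, "em_rescue", lengths=lengths)

    def loglik(x):  # x = share of the 100 multi-pairs allocated to A
        ca, cb = 90 + x, 10 + (100 - x)
        tot = ca + cb
        ra, rb = ca / tot / lengths["A"], cb / tot / lengths["B"]
        return 90 * math.log(ra) + 10 * math.log(rb) + 100 * math.log(ra + rb)

    grid = np.linspace(0, 100, 100_001)
    best = grid[int(np.argmax([loglik(x) for x in grid]))]
    assert table.counts["A"] == pytest.approx(90 + best, rel=0.01)
    assert table.counts["B"] == pytest.approx(110 - best, rel=0.01)
    # the shared mass should land close to the 90:10 unique evidence
    assert 85 <= best <= 95


def test_em_log_likelihood_non_decreasing_over_iterations():
    classes = _classes({("A",): 60, ("B",): 10, ("A", "B"): 100, ("B", "C"): 40})
    lengths = {"A": 5000, "B": 8000, "C": 3000}
    lls = []
    for k in range(1, 12):
        counts = _em_rescue(classes, lengths, max_iter=k)
        lls.append(em_log_likelihood(classes, counts, lengths))
    assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))


def test_em_mass_never_negative():
    classes = _classes({("A", "B"): 100, ("C",): 1})
    lengths = {"A": 1000, "B": 9000, "C": 100}
    table = count_fragments(classes, "em_rescue", lengths=lengths)
    assert all(v >= 0 for v in table.counts.values())


def test_plus_stranded_counts_only_sense_pairs(toy_catalogue, rng):
    from hml2kit.aligner import align_pair, build_index
    from tests.test_aligner import _pair_from

    idx = build_index(toy_catalogue)
    elem = toy_catalogue.get("lone")
    fwd = _pair_from(elem.seq, 100, 400, 150, rid="f")
    rev_pair = _pair_from(elem.seq, 100, 400, 150, rid="r")
    rev = type(rev_pair)(rev_pair.id, rev_pair.seq2, rev_pair.qual2, rev_pair.seq1, rev_pair.qual1)
    alns = [align_pair(p, idx, 2, (150, 500)) for p in (fwd, rev)]
    plus = collect_location_classes(alns, "plus_stranded")
    both = collect_location_classes(alns, "unstranded")
    assert plus.n_pairs == 1
    assert both.n_pairs == 2


def test_unknown_element_in_alignment_is_error(toy_catalogue):
    from hml2kit.aligner import Hit, Location, PairAlignment

    h = Hit("ghost", 1, "+", 0)
    loc = Location("ghost", 1, 100, "+", 0, h, h)
    aln = PairAlignment(read_id="x", locations=(loc,))
    with pytest.raises(ValueError, match="ghost"):
        collect_location_classes([aln], known_ids={e.id for e in toy_catalogue})


class TestExpression:
    def _catalogue(self, lengths):
        cat = Catalogue()
        for eid, L in lengths.items():
            cat.add(Element(id=eid, elem_class="provirus", seq="A" * L))
        return cat

    def test_fpkm_formula(self):
        cat = self._catalogue({"A": 10_000})
        table = CountTable({"A": 10.0}, "unique_only", "unstranded", n_counted=1_000_000)
        df = compute_expression(table, cat)
        assert df.loc[0, "fpkm"] == pytest.approx(1.0)

    def test_single_expressed_element_gets_abundance_100(self):
        cat = self._catalogue({"A": 10_000, "B": 5000})
        table = CountTable({"A": 42.0}, "unique_only", "unstranded", n_counted=42)
        df = compute_expression(table, cat).set_index("element_id")
        assert df.loc["A", "abundance_pct"] == pytest.approx(100.0)
        assert df.loc["B", "abundance_pct"] == pytest.approx(0.0)

    def test_abundance_is_normalized_fpkm(self):
        cat = self._catalogue({"A": 1000, "B": 1000, "C": 1000})
        table = CountTable(
            {"A": 20.0, "B": 20.0, "C": 40.0}, "unique_only", "unstranded", n_counted=80
        )
        df = compute_expression(table, cat).set_index("element_id")
        assert list(df["abundance_pct"]) == pytest.approx([25.0, 25.0, 50.0])

    def test_solo_ltr_excluded_from_family_denominator(self):
        cat = Catalogue()
        cat.add(Element(id="P", elem_class="provirus", seq="A" * 1000))
        cat.add(Element(id="S", elem_class="solo_ltr", seq="A" * 1000))
        table = CountTable({"P": 10.0, "S": 10.0}, "unique_only", "unstranded", n_counted=20)
        df = compute_expression(table, cat).set_index("element_id")
        assert df.loc["P", "abundance_pct"] == pytest.approx(100.0)
        assert np.isnan(df.loc["S", "abundance_pct"])

    def test_all_zero_family_warns_and_reports_na(self):
        cat = self._catalogue({"A": 1000})
        table = CountTable({}, "unique_only", "unstranded", n_counted=5)
        with pytest.warns(UserWarning, match="abundance undefined"):
            df = compute_expression(table, cat)
        assert np.isnan(df.loc[0, "abundance_pct"])

    def test_zero_n_is_error(self):
        cat = self._catalogue({"A": 1000})
        table = CountTable({}, "unique_only", "unstranded", n_counted=0)
        with pytest.raises(ValueError, match="FPKM undefined"):
            compute_expression(table, cat)


class TestCompareModes:
    def _records(self, fpkm_unf, fpkm_unq):
        rows_unf, rows_unq = [], []
        total_unf, total_unq = sum(fpkm_unf.values()), sum(fpkm_unq.values())
        for eid in fpkm_unf:
            rows_unf.append(
                {"element_id": eid, "elem_class": "provirus", "fpkm": fpkm_unf[eid],
                 "abundance_pct": 100 * fpkm_unf[eid] / total_unf}
            )
            rows_unq.append(
                {"element_id": eid, "elem_class": "provirus", "fpkm": fpkm_unq[eid],
                 "abundance_pct": 100 * fpkm_unq[eid] / total_unq if total_unq else np.nan}
            )
        return {"unfiltered_uniform": pd.DataFrame(rows_unf), "unique_only": pd.DataFrame(rows_unq)}

    def test_silent_near_identical_paralog_is_flagged(self):
        # emulates a locus incorrectly assigned 2.5% of reads that drops to
        # 0.07% after unique filtering
        records = self._records(
            {"hot": 97.5, "ghost": 2.5}, {"hot": 99.93, "ghost": 0.07}
        )
        df = compare_modes(records).set_index("element_id")
        assert bool(df.loc["ghost", "flagged_misassigned"])
        assert not bool(df.loc["hot", "flagged_misassigned"])

    def test_element_without_paralogs_ratio_one_unflagged(self):
        records = self._records({"a": 50.0, "b": 50.0}, {"a": 50.0, "b": 50.0})
        df = compare_modes(records).set_index("element_id")
        assert df.loc["a", "ratio_unique_unfiltered"] == pytest.approx(1.0)
        assert not df["flagged_misassigned"].any()

    def test_needs_two_modes(self):
        with pytest.raises(ValueError, match="two modes"):
            compare_modes({"unique_only": pd.DataFrame()})


def test_target_lengths_include_flank_buckets(study_family):
    catalogue, ancestry = study_family
    from hml2kit.synthetic_family import build_host_contexts

    ctx = build_host_contexts(catalogue, {"Hs_01": "intronic"}, seed=0, ancestry=ancestry)
    _aug, placements = ctx.augmented_catalogue(catalogue)
    lengths = target_lengths(catalogue, placements)
    assert lengths["Hs_01"] == len(catalogue.get("Hs_01"))
    assert lengths["Hs_01#flank"] == 4000
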