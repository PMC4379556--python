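"""Complete mismatch-bounded alignment of read pairs against the catalogue.

The aligner enumerates *every* ungapped full-length placement of each mate
with at most ``per_mate_mm`` mismatches (default 2), on both strands of every
catalogue record.  Completeness is guaranteed by the pigeonhole principle:
a mate with at most m mismatches is cut into m+1 non-overlapping segments, at
least one of which must match the reference exactly, and each segment is
looked up through an exact k-mer table.  Candidate placements are then
verified by direct mismatch counting.

A pair is *unique* iff exactly one concordant location exists within the
budget -- not merely one best location -- a conservative reading of the
TopHat-style MAPQ-50 convention: a perfect hit plus a 2-mismatch hit
elsewhere still makes the pair a multi-read.  Multi-mapped pairs get MAPQ 1
(any value below 50 passes the downstream ``view -q 50`` filter identically).

N bases count as mismatches everywhere, including against another N.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, NamedTuple

import numpy as np

from .catalogue import Catalogue, revcomp

DEFAULT_MM = 2
UNIQUE_MAPQ = 50
MULTI_MAPQ = 1


class Hit(NamedTuple):
    element_id: str
    start: int  # 1-based leftmost position on the element's + strand
    strand: str  # strand the mate sequence matches
    mismatches: int


class Location(NamedTuple):
    """One concordant placement of a pair: fragment span plus mate hits."""

    element_id: str
    start: int  # fragment leftmost base, 1-based
    end: int  # fragment rightmost base, 1-based
    ts_strand: str  # inferred transcript strand (strand of mate 2)
    mismatches: int
    hit1: Hit
    hit2: Hit


class SpliceJunction(NamedTuple):
    element_id: str
    donor_end: int  # last exon-1 base, 1-based
    acceptor_start: int  # first exon-2 base, 1-based
    split: int  # read offset of the junction (bases in exon 1)
    gt_ag: bool
    mismatches: int


@dataclass
class PairAlignment:
    read_id: str
    locations: tuple[Location, ...] = ()
    junction: SpliceJunction | None = None
    spliced_mate: int | None = None  # 1 or 2 when a mate was split-aligned

    @property
    def aligned(self) -> bool:
        return bool(self.locations)

    @property
    def unique(self) -> bool:
        return len(self.locations) == 1

    @property
    def mapq(self) -> int:
        if not self.locations:
            return 0
        return UNIQUE_MAPQ if self.unique else MULTI_MAPQ

    @property
    def nh(self) -> int:
        return len(self.locations)


def _encode_ref(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    arr[arr == ord("N")] = 0  # sentinel: never equal to a query base
    return arr


def _encode_query(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    arr[arr == ord("N")] = 1  # distinct sentinel: N vs N is a mismatch
    return arr


class CatalogueIndex:
    """Exact k-mer lookup over the + strand of every catalogue record.

    Minus-strand hits are found by querying the reverse complement of the
    mate.  Tables for additional seed lengths (e.g. splice anchors) are built
    lazily and cached.
    """

    def __init__(self, catalogue: Catalogue, seed_len: int = 20):
        if seed_len < 12:
            raise ValueError("seed_len must be >= 12")
        self.seed_len = seed_len
        self.catalogue = catalogue
        self.ids = [e.id for e in catalogue]
        self.seq_bytes = {e.id: e.seq.encode() for e in catalogue}
        self.ref = {e.id: _encode_ref(e.seq) for e in catalogue}
        self._tables: dict[int, dict[bytes, list[tuple[str, int]]]] = {}

    def table(self, k: int) -> dict[bytes, list[tuple[str, int]]]:
        tab = self._tables.get(k)
        if tab is None:
            tab = {}
            for eid in self.ids:
                sb = self.seq_bytes[eid]
                for i in range(len(sb) - k + 1):
                    tab.setdefault(sb[i : i + k], []).append((eid, i))
            self._tables[k] = tab
        return tab

    # ------------------------------------------------------------ queries

    def _candidates(self, qbytes: bytes, mm: int) -> set[tuple[str, int]]:
        L = len(qbytes)
        p = mm + 1
        step = L // p
        if step < self.seed_len:
            raise ValueError(
                f"mate length {L} too short for {p} seeds of length >= {self.seed_len}"
            )
        tab = self.table(self.seed_len)
        cands: set[tuple[str, int]] = set()
        for j in range(p):
            off = j * step
            seed = qbytes[off : off + self.seed_len]
            for eid, pos in tab.get(seed, ()):
                start = pos - off
                if start >= 0:
                    cands.add((eid, start))
        return cands

    def align_mate(self, seq: str, mm: int = DEFAULT_MM) -> list[Hit]:
        """All placements of one mate with <= mm mismatches, both strands."""
        hits: list[Hit] = []
        L = len(seq)
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            q = _encode_query(s)
            for eid, start in self._candidates(s.encode(), mm):
                ref = self.ref[eid]
                if start + L > ref.size:
                    continue
                n_mm = int(np.count_nonzero(ref[start : start + L] != q))
                if n_mm <= mm:
                    hits.append(Hit(eid, start + 1, strand, n_mm))
        hits.sort(key=lambda h: (h.element_id, h.start, h.strand))
        return hits


def build_index(catalogue: Catalogue, seed_len: int = 20) -> CatalogueIndex:
    return CatalogueIndex(catalogue, seed_len=seed_len)


def align_pair(
    pair,
    index: CatalogueIndex,
    per_mate_mm: int = DEFAULT_MM,
    insert_bounds: tuple[int, int] = (50, 1200),
    orientation: str = "FR",
) -> PairAlignment:
    """Enumerate all concordant locations of a read pair.

    Concordant means: same element, mates on opposite strands in FR
    orientation (the + strand mate leftmost), implied insert within bounds.
    Discordant-only pairs are reported unaligned.  Mismatch ties are never
    broken; every location within the budget is reported.
    """
    if orientation != "FR":
        raise ValueError("only FR orientation is supported")
    hits1 = index.align_mate(pair.seq1, per_mate_mm)
    hits2 = index.align_mate(pair.seq2, per_mate_mm)
    return _pair_from_hits(pair, hits1, hits2, len(pair.seq1), len(pair.seq2), insert_bounds)


def _pair_from_hits(
    pair, hits1, hits2, len1: int, len2: int, insert_bounds
) -> PairAlignment:
    lo, hi = insert_bounds
    locations = []
    by_elem: dict[str, list[Hit]] = {}
    for h in hits2:
        by_elem.setdefault(h.element_id, []).append(h)
    for h1 in hits1:
        for h2 in by_elem.get(h1.element_id, ()):
            if h1.strand == h2.strand:
                continue
            fw, rv = (h1, h2) if h1.strand == "+" else (h2, h1)
            fw_len = len1 if fw is h1 else len2
            rv_len = len2 if rv is h2 else len1
            if fw.start > rv.start:
                continue  # RF orientation: discordant
            frag_start = fw.start
            frag_end = rv.start + rv_len - 1
            insert = frag_end - frag_start + 1
            if insert < max(lo, fw_len) or insert > hi:
                continue
            locations.append(
                Location(
                    element_id=h1.element_id,
                    start=frag_start,
                    end=frag_end,
                    ts_strand=h2.strand,
                    mismatches=h1.mismatches + h2.mismatches,
                    hit1=h1,
                    hit2=h2,
                )
            )
    locations.sort(key=lambda x: (x.element_id, x.start, x.ts_strand))
    return PairAlignment(read_id=pair.id, locations=tuple(locations))


# --------------------------------------------------------------------------
# Spliced (single-split) alignment
# --------------------------------------------------------------------------


def _splice_mate(
    seq: str, index: CatalogueIndex, min_segment: int = 20, segment_mm: int = 1
) -> list[SpliceJunction]:
    """Single-split placements of one mate on the + strand of one record.

    Both segments must be >= min_segment bases with <= segment_mm mismatches
    each.  Among feasible split offsets the first satisfying GT-AG intron
    dinucleotides is preferred; otherwise the maximal donor extension is
    reported with ``gt_ag=False``.
    """
    L = len(seq)
    if L < 2 * min_segment:
        return []
    q = _encode_query(seq)
    tab = index.table(min_segment)
    donor: list[tuple[str, int, int, np.ndarray]] = []  # (eid, pos0, max_prefix, cum)
    for eid, pos in tab.get(seq[:min_segment].encode(), ()):
        ref = index.ref[eid]
        span = min(L, ref.size - pos)
        diff = (ref[pos : pos + span] != q[:span]).astype(np.int32)
        cum = np.cumsum(diff)
        max_prefix = int(np.searchsorted(cum, segment_mm + 1))
        if max_prefix >= min_segment:
            donor.append((eid, pos, min(max_prefix, span), cum))
    acceptor: list[tuple[str, int, int]] = []  # (eid, base0, min_start_offset)
    for eid, pos in tab.get(seq[-min_segment:].encode(), ()):
        ref = index.ref[eid]
        base0 = pos - (L - min_segment)  # ref pos aligned to read offset 0
        j0 = max(0, -base0)
        diff = (ref[base0 + j0 : base0 + L] != q[j0:]).astype(np.int32)
        # cumulative mismatches from the right; min read offset keeping <= budget
        rcum = np.cumsum(diff[::-1])
        max_suffix = int(np.searchsorted(rcum, segment_mm + 1))
        if max_suffix >= min_segment:
            acceptor.append((eid, base0, L - max_suffix))
    out: dict[tuple, SpliceJunction] = {}
    for eid, dpos, dmax, dcum in donor:
        ref_b = index.seq_bytes[eid]
        for aeid, abase, amin in acceptor:
            if aeid != eid:
                continue
            s_lo = max(amin, min_segment)
            s_hi = min(dmax, L - min_segment)
            if s_lo > s_hi:
                continue
            chosen = None
            for s in range(s_lo, s_hi + 1):
                donor_end = dpos + s  # 1-based last exon-1 base
                acc_start = abase + s + 1  # 1-based first exon-2 base
                if acc_start - donor_end <= 2:
                    continue  # no real intron
                gt = ref_b[donor_end : donor_end + 2] == b"GT"
                ag = ref_b[acc_start - 3 : acc_start - 1] == b"AG"
                if gt and ag:
                    chosen = (s, donor_end, acc_start, True)
                    break
            if chosen is None:
                s = s_hi
                donor_end = dpos + s
                acc_start = abase + s + 1
                if acc_start - donor_end <= 2:
                    continue
                chosen = (s, donor_end, acc_start, False)
            s, donor_end, acc_start, gtag = chosen
            n_mm = int(dcum[s - 1]) + int(
                np.count_nonzero(
                    index.ref[eid][acc_start - 1 : acc_start - 1 + (L - s)] != q[s:]
                )
            )
            jx = SpliceJunction(eid, donor_end, acc_start, s, gtag, n_mm)
            key = (eid, donor_end, acc_start)
            if key not in out or n_mm < out[key].mismatches:
                out[key] = jx
    return sorted(out.values(), key=lambda j: (j.element_id, j.donor_end, j.acceptor_start))


def align_spliced(
    pair,
    index: CatalogueIndex,
    per_mate_mm: int = DEFAULT_MM,
    insert_bounds: tuple[int, int] = (50, 1200),
    min_segment: int = 20,
    segment_mm: int = 1,
) -> PairAlignment:
    """Rescue a pair whose mates failed full-length alignment via one split.

    One mate must anchor with a full-length hit; the other is split-aligned
    on the + strand of the same record.  Falls back to an unaligned result.
    Reads fully contained in one exon are handled by ``align_pair`` and are
    never split here.
    """
    hits1 = index.align_mate(pair.seq1, per_mate_mm)
    hits2 = index.align_mate(pair.seq2, per_mate_mm)
    full = _pair_from_hits(pair, hits1, hits2, len(pair.seq1), len(pair.seq2), insert_bounds)
    if full.aligned:
        return full
    lo, hi = insert_bounds
    # A + strand transcript puts mate 2 sense-forward and mate 1 on the -
    # strand, so a junction read on mate 1 is split-aligned as its reverse
    # complement; the other mate must anchor on the opposite strand.
    attempts = (
        (2, pair.seq2, hits1, len(pair.seq1), "-"),
        (1, revcomp(pair.seq1), hits2, len(pair.seq2), "+"),
    )
    for spliced_mate, sseq, anchor_hits, anchor_len, need_strand in attempts:
        if not anchor_hits:
            continue
        junctions = _splice_mate(sseq, index, min_segment, segment_mm)
        locations = []
        chosen_junction = None
        for jx in junctions:
            exon1_start = jx.donor_end - jx.split + 1
            exon2_end = jx.acceptor_start + (len(sseq) - jx.split) - 1
            for ah in anchor_hits:
                if ah.element_id != jx.element_id or ah.strand != need_strand:
                    continue
                if need_strand == "-":
                    frag_start, frag_end = exon1_start, ah.start + anchor_len - 1
                    if frag_end < exon2_end:
                        continue
                    span = frag_end - jx.acceptor_start + 1
                else:
                    frag_start, frag_end = ah.start, exon2_end
                    if frag_start > exon1_start:
                        continue
                    span = jx.donor_end - frag_start + 1
                if not (lo <= span <= hi):
                    continue
                h_sp = Hit(
                    jx.element_id, exon1_start, "+" if spliced_mate == 2 else "-", jx.mismatches
                )
                hit1, hit2 = (ah, h_sp) if spliced_mate == 2 else (h_sp, ah)
                locations.append(
                    Location(
                        element_id=jx.element_id,
                        start=frag_start,
                        end=frag_end,
                        ts_strand="+",
                        mismatches=jx.mismatches + ah.mismatches,
                        hit1=hit1,
                        hit2=hit2,
                    )
                )
                chosen_junction = jx
        if locations:
            locations.sort(key=lambda x: (x.element_id, x.start))
            return PairAlignment(
                read_id=pair.id,
                locations=tuple(locations),
                junction=chosen_junction,
                spliced_mate=spliced_mate,
            )
    # short inserts make the mates overlap, so both can cross the junction:
    # split-align both and require them to support the same junction
    jx2 = _splice_mate(pair.seq2, index, min_segment, segment_mm)
    if jx2:
        jx1 = _splice_mate(revcomp(pair.seq1), index, min_segment, segment_mm)
        shared = {
            (j.element_id, j.donor_end, j.acceptor_start): j for j in jx2
        }
        locations = []
        chosen_junction = None
        for j1 in jx1:
            j2 = shared.get((j1.element_id, j1.donor_end, j1.acceptor_start))
            if j2 is None:
                continue
            e1_start = min(j1.donor_end - j1.split, j2.donor_end - j2.split) + 1
            e2_end = max(
                j1.acceptor_start + (len(pair.seq1) - j1.split),
                j2.acceptor_start + (len(pair.seq2) - j2.split),
            ) - 1
            h1 = Hit(j1.element_id, j1.donor_end - j1.split + 1, "-", j1.mismatches)
            h2 = Hit(j2.element_id, j2.donor_end - j2.split + 1, "+", j2.mismatches)
            locations.append(
                Location(
                    element_id=j1.element_id,
                    start=e1_start,
                    end=e2_end,
                    ts_strand="+",
                    mismatches=j1.mismatches + j2.mismatches,
                    hit1=h1,
                    hit2=h2,
                )
            )
            chosen_junction = j2
        if locations:
            locations.sort(key=lambda x: (x.element_id, x.start))
            return PairAlignment(
                read_id=pair.id,
                locations=tuple(locations),
                junction=chosen_junction,
                spliced_mate=2,
            )
    return full


# --------------------------------------------------------------------------
# Streaming driver and SAM output
# --------------------------------------------------------------------------


@dataclass
class AlignParams:
    per_mate_mm: int = DEFAULT_MM
    insert_bounds: tuple[int, int] = (50, 1200)
    spliced: bool = True
    min_segment: int = 20
    segment_mm: int = 1


def align_pairs(
    pairs: Iterable,
    index: CatalogueIndex,
    params: AlignParams | None = None,
) -> Iterator[tuple[object, PairAlignment]]:
    """Align a stream of read pairs; splice rescue only for unaligned pairs."""
    params = params or AlignParams()
    for pair in pairs:
        try:
            aln = align_pair(pair, index, params.per_mate_mm, params.insert_bounds)
        except ValueError:
            aln = PairAlignment(read_id=pair.id)
        if not aln.aligned and params.spliced:
            try:
                aln = align_spliced(
                    pair, index, params.per_mate_mm, params.insert_bounds,
                    params.min_segment, params.segment_mm,
                )
            except ValueError:
                pass
        yield pair, aln


def write_sam(items: Iterable[tuple[object, PairAlignment]], catalogue: Catalogue, path) -> int:
    """Write alignments as SAM 1.x with NH and NM tags.

    One primary record per mate for the first location, secondary (0x100)
    records for the rest; MAPQ 50 for unique pairs, 1 for multi-mapped, so
    the downstream unique-only filter is exactly ``MAPQ >= 50``.
    """
    n = 0
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for elem in catalogue:
            fh.write(f"@SQ\tSN:{elem.id}\tLN:{len(elem)}\n")
        fh.write("@PG\tID:hml2kit\tPN:hml2kit\n")
        for pair, aln in items:
            n += 1
            if not aln.aligned:
                fh.write(
                    f"{aln.read_id}\t77\t*\t0\t0\t*\t*\t0\t0\t{pair.seq1}\t{pair.qual1}\n"
                    f"{aln.read_id}\t141\t*\t0\t0\t*\t*\t0\t0\t{pair.seq2}\t{pair.qual2}\n"
                )
                continue
            nh = aln.nh
            mapq = aln.mapq
            for li, loc in enumerate(aln.locations):
                secondary = 0x100 if li else 0
                tlen = loc.end - loc.start + 1
                for mate_no, hit, seq, qual in (
                    (1, loc.hit1, pair.seq1, pair.qual1),
                    (2, loc.hit2, pair.seq2, pair.qual2),
                ):
                    flag = 0x1 | 0x2 | secondary
                    flag |= 0x40 if mate_no == 1 else 0x80
                    if hit.strand == "-":
                        flag |= 0x10
                    other = loc.hit2 if mate_no == 1 else loc.hit1
                    if other.strand == "-":
                        flag |= 0x20
                    if hit.strand == "-":
                        out_seq, out_qual = revcomp(seq), qual[::-1]
                    else:
                        out_seq, out_qual = seq, qual
                    if secondary:
                        out_seq, out_qual = "*", "*"
                    mate_len = len(seq)
                    if aln.junction is not None and aln.spliced_mate == mate_no:
                        jx = aln.junction
                        intron = jx.acceptor_start - jx.donor_end - 1
                        cigar = f"{jx.split}M{intron}N{mate_len - jx.split}M"
                    else:
                        cigar = f"{mate_len}M"
                    sign = 1 if hit.start == loc.start else -1
                    fh.write(
                        f"{aln.read_id}\t{flag}\t{loc.element_id}\t{hit.start}\t{mapq}\t"
                        f"{cigar}\t=\t{other.start}\t{sign * tlen}\t{out_seq}\t{out_qual}\t"
                        f"NH:i:{nh}\tNM:i:{hit.mismatches}\n"
                    )
    return n


def read_sam(path) -> Iterator[PairAlignment]:
    """Reconstruct pair alignments from a SAM file written by ``write_sam``.

    Mate records are paired in file order (two consecutive records per
    location); fragment spans are recovered from TLEN, mismatch counts from
    NM, splice junctions from N operations in the CIGAR.
    """
    pending: dict[str, list] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            cols = line.rstrip("\n").split("\t")
            qname, flag = cols[0], int(cols[1])
            if flag & 0x4:
                if qname not in pending:
                    pending[qname] = []
                    order.append(qname)
                continue
            tags = {c.split(":", 1)[0]: c.rsplit(":", 1)[1] for c in cols[11:]}
            rec = {
                "flag": flag,
                "rname": cols[2],
                "pos": int(cols[3]),
                "cigar": cols[5],
                "tlen": int(cols[8]),
                "nm": int(tags.get("NM", 0)),
            }
            if qname not in pending:
                pending[qname] = []
                order.append(qname)
            pending[qname].append(rec)
    for qname in order:
        recs = pending[qname]
        locations = []
        junction = None
        spliced_mate = None
        for i in range(0, len(recs) - 1, 2):
            r1, r2 = recs[i], recs[i + 1]
            if r1["flag"] & 0x80:
                r1, r2 = r2, r1
            h1 = Hit(r1["rname"], r1["pos"], "-" if r1["flag"] & 0x10 else "+", r1["nm"])
            h2 = Hit(r2["rname"], r2["pos"], "-" if r2["flag"] & 0x10 else "+", r2["nm"])
            start = min(r1["pos"], r2["pos"])
            end = start + abs(r1["tlen"]) - 1
            locations.append(
                Location(r1["rname"], start, end, h2.strand, r1["nm"] + r2["nm"], h1, h2)
            )
            for mate_no, r in ((1, r1), (2, r2)):
                if "N" in r["cigar"]:
                    left, rest = r["cigar"].split("M", 1)
                    intron = int(rest.split("N", 1)[0])
                    donor_end = r["pos"] + int(left) - 1
                    junction = SpliceJunction(
                        r["rname"], donor_end, donor_end + intron + 1, int(left), False, r["nm"]
                    )
                    spliced_mate = mate_no
        yield PairAlignment(
            read_id=qname,
            locations=tuple(locations),
            junction=junction,
            spliced_mate=spliced_mate,
        )


def brute_force_hits(catalogue: Catalogue, seq: str, mm: int = DEFAULT_MM) -> list[Hit]:
    """Oracle: scan every position of every record on both strands.

    O(reads x positions); used to certify the seeded search's completeness on
    small instances.  Kept in the package so tests and users can audit any
    alignment.
    """
    hits = []
    L = len(seq)
    for elem in catalogue:
        ref = _encode_ref(elem.seq)
        if ref.size < L:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(ref, L)
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            q = _encode_query(s)
            counts = (windows != q).sum(axis=1)
            for pos in np.flatnonzero(counts <= mm):
                hits.append(Hit(elem.id, int(pos) + 1, strand, int(counts[pos])))
    hits.sort(key=lambda h: (h.element_id, h.start, h.strand))
    return hits
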