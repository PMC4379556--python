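"""Paired-end read simulation and trimming.

Two samplers are provided: a library emulator that draws fragments from a
truth profile (multinomial over transcripts with molar-fraction x length
weighting, truncated-normal insert sizes, FR orientation, optional dUTP
strandedness, i.i.d. substitution errors) and a uniform per-element sampler
used for mappability assessment (error-free 250 b paired reads to a target
depth).  A fixed seed yields byte-identical FASTQ output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .catalogue import Element

BASE_QUAL = 37  # constant Phred quality of simulated bases
ERROR_QUAL = 12  # penalized quality written at substituted positions
_Q_CHAR = chr(33 + BASE_QUAL)
_E_CHAR = chr(33 + ERROR_QUAL)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP_LUT = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP_LUT[_a] = _b
_IDX_LUT = np.zeros(256, dtype=np.uint8)
for _i, _a in enumerate(b"ACGT"):
    _IDX_LUT[_a] = _i


@dataclass
class ReadPair:
    id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str
    # (transcript_id, fragment start, fragment end, transcript strand)
    truth: tuple[str, int, int, str] | None = None


@dataclass
class LibraryParams:
    """Sequencing-library emulation parameters.

    Defaults model a stranded total-RNA MiSeq cell library: 250 b reads,
    insert mean 180 (range 98-522), dUTP chemistry.  ``virion_library()`` switches to
    the virion values (mean 200, range 100-568, unstranded).
    """

    read_len: int = 250
    insert_mean: float = 180.0
    insert_sd: float = 60.0
    insert_min: int = 98
    insert_max: int = 522
    error_rate: float = 0.005
    stranded: bool = True
    n_fragments: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.insert_min <= self.insert_mean <= self.insert_max:
            raise ValueError("need insert_min <= insert_mean <= insert_max")
        if self.error_rate < 0 or self.error_rate >= 1:
            raise ValueError("error_rate must be in [0, 1)")


def cell_library(n_fragments: int = 100_000, seed: int = 0, **kw) -> LibraryParams:
    return LibraryParams(n_fragments=n_fragments, seed=seed, **kw)


def virion_library(n_fragments: int = 100_000, seed: int = 0, **kw) -> LibraryParams:
    defaults = dict(
        insert_mean=200.0, insert_sd=65.0, insert_min=100, insert_max=568, stranded=False
    )
    defaults.update(kw)
    return LibraryParams(n_fragments=n_fragments, seed=seed, **defaults)


def _truncated_normal(
    rng: np.random.Generator, n: int, mean: float, sd: float, lo: int, hi: int
) -> np.ndarray:
    """Integer inserts from a normal truncated (by resampling) to [lo, hi]."""
    out = np.rint(rng.normal(mean, sd, size=n)).astype(np.int64)
    for _ in range(100):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = np.rint(rng.normal(mean, sd, size=int(bad.sum()))).astype(np.int64)
    return np.clip(out, lo, hi)


def _pairs_from_fragments(
    t_seq: str,
    starts: np.ndarray,
    inserts: np.ndarray,
    read_len: int,
    error_rate: float,
    rng: np.random.Generator,
    id_prefix: str,
    id_start: int,
    tx_id: str,
    unstranded: bool,
) -> list[ReadPair]:
    """Realize FR read pairs for fragments [start, start+insert-1] (1-based).

    dUTP fr-firststrand convention: mate 2 carries the transcript-sense
    sequence from the fragment 5' end, mate 1 the reverse complement of the
    fragment 3' end.  In unstranded mode the two files are swapped for a
    random half of the fragments.  Mates shorter than the read length (insert
    < read_len) are emitted at the insert length.
    """
    n = starts.size
    pairs: list[ReadPair] = []
    if n == 0:
        return pairs
    t_arr = np.frombuffer(t_seq.encode(), dtype=np.uint8)
    comp = _COMP_LUT[t_arr]
    col = np.arange(read_len)
    chunk = 20_000
    flip_all = (
        rng.random(n) < 0.5 if unstranded else np.zeros(n, dtype=bool)
    )
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        st = starts[lo:hi]
        ins = inserts[lo:hi]
        m = st.size
        mlen = np.minimum(ins, read_len)
        valid = col[None, :] < mlen[:, None]
        # mate 2: sense strand, fragment 5' end
        idx2 = np.clip((st - 1)[:, None] + col[None, :], 0, t_arr.size - 1)
        mat2 = t_arr[idx2]
        # mate 1: reverse complement of the fragment 3' end, built reversed
        end0 = st + ins - 2  # 0-based index of the fragment's last base
        idx1 = np.clip(end0[:, None] - col[None, :], 0, t_arr.size - 1)
        mat1 = comp[idx1]
        q2 = np.full((m, read_len), ord(_Q_CHAR), dtype=np.uint8)
        q1 = np.full((m, read_len), ord(_Q_CHAR), dtype=np.uint8)
        if error_rate > 0:
            for mat, q in ((mat2, q2), (mat1, q1)):
                emask = (rng.random((m, read_len)) < error_rate) & valid
                k = int(emask.sum())
                if k:
                    shift = rng.integers(1, 4, size=k).astype(np.uint8)
                    mat[emask] = _BASES[(_IDX_LUT[mat[emask]] + shift) % 4]
                    q[emask] = ord(_E_CHAR)
        for i in range(m):
            L = int(mlen[i])
            s1 = mat1[i, :L].tobytes().decode()
            s2 = mat2[i, :L].tobytes().decode()
            c1 = q1[i, :L].tobytes().decode()
            c2 = q2[i, :L].tobytes().decode()
            if flip_all[lo + i]:
                s1, s2, c1, c2 = s2, s1, c2, c1
            pairs.append(
                ReadPair(
                    id=f"{id_prefix}{id_start + lo + i:07d}",
                    seq1=s1,
                    qual1=c1,
                    seq2=s2,
                    qual2=c2,
                    truth=(tx_id, int(starts[lo + i]), int(starts[lo + i] + inserts[lo + i] - 1), "+"),
                )
            )
    return pairs


@dataclass
class LibraryReport:
    sample: str
    n_requested: int
    n_simulated: int
    fragments_per_transcript: dict[str, int] = field(default_factory=dict)
    skipped_transcripts: list[str] = field(default_factory=list)


def simulate_library(truth, sample: str, params: LibraryParams) -> tuple[list[ReadPair], LibraryReport]:
    """Draw a paired-end library from a truth profile (in memory).

    Fragment counts per transcript are Multinomial(n, fraction x length); the
    length weighting makes molar fractions correspond to FPKM downstream.
    Transcripts shorter than the minimum insert are skipped with a warning.
    """
    fractions = truth.fractions(sample)
    txs = [t for t in truth.transcripts if fractions[t.id] > 0]
    usable = []
    report = LibraryReport(sample=sample, n_requested=params.n_fragments, n_simulated=0)
    for t in txs:
        if len(t) < params.insert_min:
            warnings.warn(
                f"transcript {t.id} ({len(t)} b) shorter than min insert; skipped",
                stacklevel=2,
            )
            report.skipped_transcripts.append(t.id)
        else:
            usable.append(t)
    rng = np.random.default_rng(params.seed)
    if not usable or params.n_fragments == 0:
        return [], report
    weights = np.array([fractions[t.id] * len(t) for t in usable], dtype=float)
    probs = weights / weights.sum()
    counts = rng.multinomial(params.n_fragments, probs)
    pairs: list[ReadPair] = []
    serial = 0
    for t, m in zip(usable, counts):
        report.fragments_per_transcript[t.id] = int(m)
        if m == 0:
            continue
        hi = min(params.insert_max, len(t))
        inserts = _truncated_normal(rng, int(m), params.insert_mean, params.insert_sd,
                                    params.insert_min, hi)
        starts = rng.integers(1, len(t) - inserts + 2)
        pairs.extend(
            _pairs_from_fragments(
                t.seq, starts, inserts, params.read_len, params.error_rate, rng,
                id_prefix=f"{sample}_", id_start=serial, tx_id=t.id,
                unstranded=not params.stranded,
            )
        )
        serial += int(m)
    report.n_simulated = len(pairs)
    return pairs, report


def simulate_uniform(
    element: Element,
    depth: float = 20.0,
    read_len: int = 250,
    error_rate: float = 0.0,
    insert: int | None = None,
    paired: bool = True,
    seed: int = 0,
) -> list[ReadPair]:
    """Uniform paired reads over one element to a target depth (default 20X).

    n_fragments = ceil(depth * len / (2 * read_len)); fragment starts are
    uniform along the element.  ``paired=False`` keeps the pair format but
    makes the mates fully overlap (insert = read_len), so per-placement
    uniqueness matches a single-end read of length ``read_len``.
    """
    L = len(element)
    if L < read_len:
        raise ValueError(f"element {element.id} ({L} b) shorter than read length {read_len}")
    n = math.ceil(depth * L / (2 * read_len))
    if n == 0:
        return []
    if insert is None:
        insert = read_len if not paired else min(2 * read_len, L)
    insert = min(insert, L)
    rng = np.random.default_rng(seed)
    starts = rng.integers(1, L - insert + 2, size=n)
    inserts = np.full(n, insert, dtype=np.int64)
    return _pairs_from_fragments(
        element.seq, starts, inserts, read_len, error_rate, rng,
        id_prefix=f"sim_{element.id}_", id_start=0, tx_id=element.id, unstranded=False,
    )


# --------------------------------------------------------------------------
# FASTQ I/O
# --------------------------------------------------------------------------


def write_fastq_pair(pairs, fq1_path, fq2_path, truth_path=None) -> int:
    """Write mate FASTQ files (Phred+33, ids suffixed /1 and /2) + truth TSV."""
    n = 0
    truth_fh = open(truth_path, "w") if truth_path else None
    try:
        if truth_fh:
            truth_fh.write("read_id\ttranscript_id\tfrag_start\tfrag_end\tstrand\n")
        with open(fq1_path, "w") as f1, open(fq2_path, "w") as f2:
            for p in pairs:
                f1.write(f"@{p.id}/1\n{p.seq1}\n+\n{p.qual1}\n")
                f2.write(f"@{p.id}/2\n{p.seq2}\n+\n{p.qual2}\n")
                if truth_fh and p.truth:
                    tx, s, e, strand = p.truth
                    truth_fh.write(f"{p.id}\t{tx}\t{s}\t{e}\t{strand}\n")
                n += 1
    finally:
        if truth_fh:
            truth_fh.close()
    return n


def read_fastq_pair(fq1_path, fq2_path):
    """Iterate ReadPairs from two mate FASTQ files (ids must correspond)."""
    it1 = FastqGeneralIterator(str(fq1_path))
    it2 = FastqGeneralIterator(str(fq2_path))
    for idx, ((t1, s1, q1), (t2, s2, q2)) in enumerate(zip(it1, it2)):
        rid1 = t1.split()[0].removesuffix("/1")
        rid2 = t2.split()[0].removesuffix("/2")
        if rid1 != rid2:
            raise ValueError(f"mate id mismatch at record {idx}: {rid1!r} vs {rid2!r}")
        yield ReadPair(id=rid1, seq1=s1, qual1=q1, seq2=s2, qual2=q2)


# --------------------------------------------------------------------------
# Trimming
# --------------------------------------------------------------------------


@dataclass
class TrimReport:
    input_pairs: int = 0
    kept_pairs: int = 0
    dropped_pairs: int = 0

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("input_pairs\tkept_pairs\tdropped_pairs\n")
            fh.write(f"{self.input_pairs}\t{self.kept_pairs}\t{self.dropped_pairs}\n")


def _trim_adapter(seq: str, qual: str, adapters, min_overlap: int = 10) -> tuple[str, str]:
    for adapter in adapters:
        if len(adapter) >= min_overlap:
            idx = seq.find(adapter)
            if idx >= 0:
                return seq[:idx], qual[:idx]
        # partial 3' overlap: read suffix equals adapter prefix
        max_ov = min(len(seq), len(adapter))
        for ov in range(max_ov, min_overlap - 1, -1):
            if seq.endswith(adapter[:ov]):
                return seq[: len(seq) - ov], qual[: len(qual) - ov]
    return seq, qual


def _trim_quality(seq: str, qual: str, threshold: float, window: int = 4) -> tuple[str, str]:
    if len(seq) < window:
        return seq, qual
    q = np.frombuffer(qual.encode(), dtype=np.uint8).astype(np.int32) - 33
    means = np.convolve(q, np.ones(window) / window, mode="valid")
    bad = np.flatnonzero(means < threshold)
    if bad.size:
        cut = int(bad[0])
        return seq[:cut], qual[:cut]
    return seq, qual


def _trim_one(seq: str, qual: str, threshold: float, min_len: int, adapters) -> tuple[str, str] | None:
    seq, qual = _trim_adapter(seq, qual, adapters)
    seq, qual = _trim_quality(seq, qual, threshold)
    if len(seq) < min_len:
        return None
    return seq, qual


def trim_reads(
    fq1_in,
    fq2_in,
    fq1_out,
    fq2_out,
    qual_threshold: float = 25.0,
    min_len: int = 100,
    adapters: tuple[str, ...] = (),
) -> TrimReport:
    """Adapter + sliding-window quality trimming of a paired FASTQ set.

    Policy: exact adapter match (or >=10 b exact 3' overlap) is removed, then
    3' bases are cut from the first 4-base window whose mean quality falls
    below the threshold; a pair is kept only when both mates remain at least
    ``min_len`` bases (Q < 25 / 100 b defaults).
    """
    report = TrimReport()
    with open(fq1_out, "w") as o1, open(fq2_out, "w") as o2:
        for pair in read_fastq_pair(fq1_in, fq2_in):
            report.input_pairs += 1
            r1 = _trim_one(pair.seq1, pair.qual1, qual_threshold, min_len, adapters)
            r2 = _trim_one(pair.seq2, pair.qual2, qual_threshold, min_len, adapters)
            if r1 is None or r2 is None:
                report.dropped_pairs += 1
                continue
            report.kept_pairs += 1
            o1.write(f"@{pair.id}/1\n{r1[0]}\n+\n{r1[1]}\n")
            o2.write(f"@{pair.id}/2\n{r2[0]}\n+\n{r2[1]}\n")
    return report
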