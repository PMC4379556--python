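"""Structural annotation: ORFs, type 1/2 classification, promoter motifs.

ORF discovery is a plain three-frame plus-strand scan (proviral genes are
sense-encoded); the longest ATG-initiated ORF overlapping at least half of an
annotated gene span is assigned to that gene and called full-length when it
reaches 95% of the reference protein length, truncated otherwise, absent
when no ORF qualifies.

Type 1 proviruses are recognized by the 292-bp deletion at the pol-env
boundary: two 30-bp anchors from a type-2 boundary reference are placed in
the element and the inferred deletion length is the difference of the
inter-anchor spans.  Deletions in [250, 330] bp are type 1; [-10, 10] is
type 2; unplaceable anchors give "unknown" (e.g. a solo LTR lacking the
boundary region entirely).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalogue import Annotation, Catalogue, Element, Span
from .motifs import PROMOTER_MOTIFS

GENES = ("gag", "pro", "pol", "env")

# reference protein lengths (aa, excluding stop) of the intact family layout
REFERENCE_PROTEIN_LENGTHS = {"gag": 666, "pro": 259, "pol": 799, "env": 599}

TYPE1_DELETION_RANGE = (250, 330)
TYPE2_DELETION_RANGE = (-10, 10)

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class OrfCall:
    element_id: str
    gene: str
    span: Span | None  # ORF span including the stop codon; None when absent
    length_aa: int
    status: str  # full_length | truncated | absent


@dataclass
class MotifHit:
    name: str
    canonical_seq: str
    canonical_pos: int
    found_pos: int | None
    mismatches: int | None
    status: str  # canonical | mutated | missing


def _scan_orfs(seq: str) -> list[tuple[int, int, int]]:
    """All maximal ATG-initiated ORFs on the + strand.

    Returns (start, end, length_aa) with 1-based inclusive spans covering the
    stop codon; ORFs lacking a stop before the sequence end are ignored.
    """
    orfs = []
    n = len(seq)
    for frame in range(3):
        start: int | None = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if codon in _STOPS:
                if start is not None:
                    orfs.append((start + 1, i + 3, (i - start) // 3))
                    start = None
            elif codon == "ATG" and start is None:
                start = i
    return orfs


def find_orfs(
    element: Element,
    annotation: Annotation,
    reference_lengths: dict[str, int] | None = None,
) -> list[OrfCall]:
    """Assign the longest qualifying ORF to each annotated gene."""
    reference_lengths = reference_lengths or REFERENCE_PROTEIN_LENGTHS
    orfs = _scan_orfs(element.seq)
    calls = []
    for gene in GENES:
        span = annotation.span(gene) if annotation else None
        if span is None:
            continue
        gs, ge = span
        gene_len = ge - gs + 1
        best = None
        for os_, oe, aa in orfs:
            overlap = min(oe, ge) - max(os_, gs) + 1
            if overlap < 0.5 * gene_len:
                continue
            if best is None or aa > best[2]:
                best = (os_, oe, aa)
        if best is None:
            calls.append(OrfCall(element.id, gene, None, 0, "absent"))
            continue
        ref = reference_lengths[gene]
        status = "full_length" if best[2] >= 0.95 * ref else "truncated"
        calls.append(OrfCall(element.id, gene, (best[0], best[1]), best[2], status))
    return calls


def _place_anchor(elem_arr: np.ndarray, anchor: str, max_mm: int) -> tuple[int, int] | None:
    """Best placement (0-based pos, mismatches) of a short anchor, or None."""
    a = np.frombuffer(anchor.encode(), dtype=np.uint8)
    if elem_arr.size < a.size:
        return None
    windows = np.lib.stride_tricks.sliding_window_view(elem_arr, a.size)
    counts = (windows != a).sum(axis=1)
    pos = int(np.argmin(counts))
    if int(counts[pos]) > max_mm:
        return None
    return pos, int(counts[pos])


def classify_type(
    element: Element,
    boundary_reference: str,
    window: int = 600,
    anchor_len: int = 30,
    anchor_mm: int = 3,
) -> tuple[str, int | None]:
    """Classify an element as type 1 / type 2 / unknown at the pol-env boundary.

    ``boundary_reference`` is a type-2 sequence centered on the boundary; its
    first and last ``anchor_len`` bases are anchored in the element and the
    deletion length is the shrinkage of the inter-anchor span.
    """
    ref = boundary_reference[:window]
    if len(ref) < 2 * anchor_len + 1:
        raise ValueError("boundary reference shorter than two anchors")
    left, right = ref[:anchor_len], ref[-anchor_len:]
    elem_arr = np.frombuffer(element.seq.encode(), dtype=np.uint8)
    p1 = _place_anchor(elem_arr, left, anchor_mm)
    if p1 is None:
        return "unknown", None
    # the right anchor must land after the left one
    tail = elem_arr[p1[0] + anchor_len :]
    p2 = _place_anchor(tail, right, anchor_mm)
    if p2 is None:
        return "unknown", None
    ref_inner = len(ref) - 2 * anchor_len
    elem_inner = p2[0]
    deletion = ref_inner - elem_inner
    if TYPE1_DELETION_RANGE[0] <= deletion <= TYPE1_DELETION_RANGE[1]:
        return "type1", deletion
    if TYPE2_DELETION_RANGE[0] <= deletion <= TYPE2_DELETION_RANGE[1]:
        return "type2", deletion
    return "unknown", deletion


def classify_catalogue_types(
    catalogue: Catalogue, boundary_reference: str, **kw
) -> pd.DataFrame:
    rows = []
    for elem in catalogue:
        ptype, deletion = classify_type(elem, boundary_reference, **kw)
        rows.append({"element_id": elem.id, "provirus_type": ptype, "deletion_len": deletion})
    return pd.DataFrame(rows)


def allocate_orf_abundance(
    expression: pd.DataFrame, orf_calls: list[OrfCall]
) -> pd.DataFrame:
    """Allocate per-element relative abundance to each gene's ORF status.

    The full cellular abundance of an element is credited to every gene for
    which it carries an ORF (the maximum probability of that ORF being
    expressed); elements with no ORF at all accumulate under "none".  The
    allocation is intentionally non-exclusive, so per-gene totals can jointly
    exceed 100%.  Splicing is not considered.
    """
    abundance = {
        r.element_id: (0.0 if pd.isna(r.abundance_pct) else float(r.abundance_pct))
        for r in expression.itertuples()
        if r.elem_class == "provirus"
    }
    by_elem: dict[str, list[OrfCall]] = {}
    for call in orf_calls:
        by_elem.setdefault(call.element_id, []).append(call)
    rows = []
    for gene in GENES:
        full = trunc = 0.0
        for eid, a in abundance.items():
            for call in by_elem.get(eid, []):
                if call.gene != gene:
                    continue
                if call.status == "full_length":
                    full += a
                elif call.status == "truncated":
                    trunc += a
        rows.append(
            {"gene": gene, "full_length_pct": full, "truncated_pct": trunc,
             "any_orf_pct": full + trunc}
        )
    none_total = 0.0
    for eid, a in abundance.items():
        calls = by_elem.get(eid, [])
        if not calls or all(c.status == "absent" for c in calls):
            none_total += a
    rows.append(
        {"gene": "none", "full_length_pct": 0.0, "truncated_pct": 0.0,
         "any_orf_pct": none_total}
    )
    return pd.DataFrame(rows)


def scan_promoter_motifs(
    ltr_seq: str,
    motif_catalogue: tuple[tuple[str, int, str], ...] = PROMOTER_MOTIFS,
    max_mm: int = 3,
    positional_window: int = 15,
) -> tuple[list[MotifHit], dict[str, int]]:
    """Scan an LTR for the eight canonical promoter-element motifs.

    Each motif is searched within +/-``positional_window`` of its canonical
    position; the best hit (fewest mismatches, then closest to the canonical
    position) is classified canonical (0 mm), mutated (1..max_mm mm) or
    missing.  Returns hits plus a summary whose three counts always total
    the catalogue size.
    """
    hits: list[MotifHit] = []
    n_canonical = n_mutated = n_missing = 0
    for name, pos, motif in motif_catalogue:
        best: tuple[int, int, int] | None = None  # (mm, |delta|, position)
        for p in range(pos - positional_window, pos + positional_window + 1):
            if p < 1 or p + len(motif) - 1 > len(ltr_seq):
                continue
            window = ltr_seq[p - 1 : p - 1 + len(motif)]
            mm = sum(1 for a, b in zip(window, motif) if a != b)
            cand = (mm, abs(p - pos), p)
            if best is None or cand < best:
                best = cand
        if best is None or best[0] > max_mm:
            hits.append(MotifHit(name, motif, pos, None, None, "missing"))
            n_missing += 1
        elif best[0] == 0:
            hits.append(MotifHit(name, motif, pos, best[2], 0, "canonical"))
            n_canonical += 1
        else:
            hits.append(MotifHit(name, motif, pos, best[2], best[0], "mutated"))
            n_mutated += 1
    summary = {"n_canonical": n_canonical, "n_mutated": n_mutated, "n_missing": n_missing}
    return hits, summary
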