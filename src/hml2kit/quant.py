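"""Fragment counting and FPKM / relative-abundance computation.

Three analysis modes cover the standard multi-read policies:

``unfiltered_uniform``
    every pair contributes 1/k of a fragment to each of its k locations
    (a pair mapping to five locations assigns 20% of a read to each);
``unique_only``
    pairs with more than one concordant location are discarded (the
    MAPQ-50 filter);
``em_rescue``
    multi-mapped pairs are reallocated iteratively in proportion to the
    current per-base abundance of their candidate loci (multi-read
    correction), starting from the uniform allocation.

FPKM is F_i = c_i x 10^9 / (L_i x N) with L_i the element length in bases
and N the number of fragments counted in the mode's own filtered alignment.
Relative abundance is a_i = 100 x F_i / sum of F_j over family proviruses;
solo LTRs and host records receive an FPKM but never enter the denominator.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .catalogue import Catalogue
from .synthetic_family import Placement

MODES = ("unfiltered_uniform", "unique_only", "em_rescue")
STRAND_MODES = ("plus_stranded", "unstranded")

EM_TOL = 1e-6
EM_MAX_ITER = 200

FLANK_SUFFIX = "#flank"


@dataclass
class CountTable:
    """Per-target fragment mass under one analysis mode.

    ``counts`` may contain per-locus flank buckets (``<id>#flank``) when a
    placement map restricts element attribution to the element span; those
    buckets count toward N but are not elements.
    """

    counts: dict[str, float]
    mode: str
    strand_mode: str
    n_counted: int  # fragments contributing to `counts` (the conservation sum)

    @property
    def N(self) -> int:
        return self.n_counted


@dataclass
class LocationClasses:
    """Pairs collapsed into equivalence classes by their attributed targets."""

    classes: Counter  # tuple(sorted target ids, with multiplicity) -> n pairs
    n_pairs: int = 0

    def unique_counts(self) -> dict[str, float]:
        return {cls[0]: float(n) for cls, n in self.classes.items() if len(cls) == 1}


def _attribute(loc, placements: dict[str, Placement] | None) -> str:
    if placements is None:
        return loc.element_id
    place = placements.get(loc.element_id)
    if place is None:
        return loc.element_id
    elem_lo, elem_hi = place.offset + 1, place.offset + place.elem_len
    if loc.end >= elem_lo and loc.start <= elem_hi:
        return loc.element_id
    return loc.element_id + FLANK_SUFFIX


def collect_location_classes(
    alignments: Iterable,
    strand_mode: str = "unstranded",
    placements: dict[str, Placement] | None = None,
    known_ids: set[str] | None = None,
) -> LocationClasses:
    """Reduce pair alignments to (location multiset -> pair count) classes."""
    if strand_mode not in STRAND_MODES:
        raise ValueError(f"unknown strand mode {strand_mode!r}")
    classes: Counter = Counter()
    n = 0
    for aln in alignments:
        locs = aln.locations if hasattr(aln, "locations") else aln
        if not locs:
            continue
        if strand_mode == "plus_stranded":
            locs = [l for l in locs if l.ts_strand == "+"]
            if not locs:
                continue
        if known_ids is not None:
            for l in locs:
                if l.element_id not in known_ids:
                    raise ValueError(f"alignment references unknown element {l.element_id!r}")
        key = tuple(sorted(_attribute(l, placements) for l in locs))
        classes[key] += 1
        n += 1
    return LocationClasses(classes=classes, n_pairs=n)


def em_log_likelihood(classes: LocationClasses, counts: dict[str, float], lengths: dict[str, int]) -> float:
    """Multinomial-over-locations log-likelihood of an allocation."""
    total = sum(counts.values())
    if total <= 0:
        return float("-inf")
    ll = 0.0
    for cls, n in classes.classes.items():
        rate = sum((counts.get(i, 0.0) / total) / lengths[i] for i in cls)
        ll += n * math.log(rate) if rate > 0 else float("-inf")
    return ll


def _em_rescue(
    classes: LocationClasses,
    lengths: dict[str, int],
    max_iter: int = EM_MAX_ITER,
    tol: float = EM_TOL,
) -> dict[str, float]:
    unique = classes.unique_counts()
    multi = [(cls, n) for cls, n in classes.classes.items() if len(cls) > 1]
    # initialize from the uniform allocation
    counts: dict[str, float] = dict(unique)
    for cls, n in multi:
        share = n / len(cls)
        for i in cls:
            counts[i] = counts.get(i, 0.0) + share
    for _ in range(max_iter):
        new = dict(unique)
        for cls, n in multi:
            weights = [counts.get(i, 0.0) / lengths[i] for i in cls]
            denom = sum(weights)
            if denom <= 0:
                share = n / len(cls)
                for i in cls:
                    new[i] = new.get(i, 0.0) + share
            else:
                for i, w in zip(cls, weights):
                    new[i] = new.get(i, 0.0) + n * w / denom
        max_rel = 0.0
        for i, v in new.items():
            old = counts.get(i, 0.0)
            ref = max(old, 1e-12)
            max_rel = max(max_rel, abs(v - old) / ref)
        counts = new
        if max_rel < tol:
            break
    return counts


def count_fragments(
    alignments: Iterable,
    mode: str,
    strand_mode: str = "unstranded",
    lengths: dict[str, int] | None = None,
    placements: dict[str, Placement] | None = None,
    known_ids: set[str] | None = None,
) -> CountTable:
    """Count fragment mass per target under one mode.

    ``alignments`` may be an iterable of PairAlignments or a pre-collected
    ``LocationClasses``.  ``lengths`` (target id -> bases) is required for
    ``em_rescue``.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if isinstance(alignments, LocationClasses):
        classes = alignments
    else:
        classes = collect_location_classes(alignments, strand_mode, placements, known_ids)
    if mode == "unique_only":
        counts = classes.unique_counts()
        n_counted = int(sum(counts.values()))
    elif mode == "unfiltered_uniform":
        counts = {}
        for cls, n in classes.classes.items():
            share = n / len(cls)
            for i in cls:
                counts[i] = counts.get(i, 0.0) + share
        n_counted = classes.n_pairs
    else:
        if lengths is None:
            raise ValueError("em_rescue requires target lengths")
        counts = _em_rescue(classes, lengths)
        n_counted = classes.n_pairs
    return CountTable(counts=counts, mode=mode, strand_mode=strand_mode, n_counted=n_counted)


def target_lengths(
    catalogue: Catalogue, placements: dict[str, Placement] | None = None
) -> dict[str, int]:
    """Element lengths plus flank-bucket lengths for EM and FPKM."""
    out = {e.id: len(e) for e in catalogue}
    if placements:
        for eid, place in placements.items():
            out[eid] = place.elem_len
            flank = place.locus_len - place.elem_len
            if flank > 0:
                out[eid + FLANK_SUFFIX] = flank
    return out


def compute_expression(
    counts: CountTable,
    catalogue: Catalogue,
    lengths: dict[str, int] | None = None,
    N: int | None = None,
) -> pd.DataFrame:
    """Per-element FPKM and family relative abundance (percent).

    ``N`` defaults to the mode's own counted-fragment total (Cufflinks run on
    the filtered alignment); pass the unfiltered total to put several modes on
    a common FPKM scale, mirroring genome-wide normalization where N barely
    changes across filters.  Relative abundance is N-invariant either way.
    Flank buckets contribute to N but are not reported.  When every family
    provirus has zero FPKM the abundance column is NA with a warning.
    """
    N = counts.N if N is None else N
    if N <= 0:
        raise ValueError("no counted fragments; FPKM undefined")
    lengths = lengths or target_lengths(catalogue)
    rows = []
    for elem in catalogue:
        c = counts.counts.get(elem.id, 0.0)
        L = lengths[elem.id]
        fpkm = c * 1e9 / (L * N)
        rows.append(
            {
                "element_id": elem.id,
                "elem_class": elem.elem_class,
                "mode": counts.mode,
                "strand_mode": counts.strand_mode,
                "fragments": c,
                "fpkm": fpkm,
            }
        )
    df = pd.DataFrame(rows)
    family = df["elem_class"] == "provirus"
    total = df.loc[family, "fpkm"].sum()
    if total > 0:
        df["abundance_pct"] = np.where(family, 100.0 * df["fpkm"] / total, np.nan)
    else:
        warnings.warn("all family FPKM are zero; relative abundance undefined", stacklevel=2)
        df["abundance_pct"] = np.nan
    return df


def compare_modes(
    records_by_mode: dict[str, pd.DataFrame],
    unfiltered: str = "unfiltered_uniform",
    unique: str = "unique_only",
    unfiltered_abundance_min: float = 0.5,
    unique_abundance_max: float = 0.1,
) -> pd.DataFrame:
    """Side-by-side FPKM per mode with a "likely misassigned" flag.

    A locus is flagged when the unfiltered analysis gives it at least
    ``unfiltered_abundance_min`` percent of family expression but the
    unique-only analysis at most ``unique_abundance_max`` percent -- the
    drop-off signature of signal misaligned from a closely related locus.
    """
    if len(records_by_mode) < 2:
        raise ValueError("need at least two modes to compare")
    base = None
    for mode, df in records_by_mode.items():
        sub = df[["element_id", "elem_class", "fpkm", "abundance_pct"]].rename(
            columns={"fpkm": f"fpkm_{mode}", "abundance_pct": f"abundance_{mode}"}
        )
        base = sub if base is None else base.merge(sub, on=["element_id", "elem_class"])
    unf_f, unq_f = f"fpkm_{unfiltered}", f"fpkm_{unique}"
    with np.errstate(divide="ignore", invalid="ignore"):
        base["ratio_unique_unfiltered"] = np.where(
            base[unf_f] > 0, base[unq_f] / base[unf_f], np.nan
        )
    base["flagged_misassigned"] = (
        (base[f"abundance_{unfiltered}"] >= unfiltered_abundance_min)
        & (base[f"abundance_{unique}"].fillna(0.0) <= unique_abundance_max)
    )
    return base
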