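"""Synthetic HML-2 paralog families with known ground truth.

No public read set exists at locus resolution with known per-locus truth
for this repeat family, so the quantification, mappability, mechanism and
packaging modules are exercised end-to-end on a simulated paralog family
reproducing the statistical structure the analysis has to cope with:

* a divergence gradient from "just integrated" near-identical loci (LTR Hs
  like) down to ~8% diverged ancient loci (LTR 5B like),
* a post-integration duplicate pair (near- or fully identical members),
* type-1 proviruses carrying the diagnostic 292-bp deletion at the pol-env
  boundary,
* solo-LTR recombinants (5' LTR U3+R fused to 3' LTR U5),
* APOBEC3G-style plus-strand G-to-A hypermutated members, and
* host-context scenarios (divergent neighbor gene, intronic residence,
  upstream fragmentary LTR driving a spliced chimera, antisense neighbor)
  with distinct cell and virion abundance truths.

Evolution is substitution-only (Jukes-Cantor-like: uniform across positions
and target bases); the only indels are the engineered pol-env deletion and the
solo-LTR recombination.  This keeps p-distances interpretable and allows a
gap-free natural alignment of equal-age features (e.g. 5' LTRs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .catalogue import Annotation, Catalogue, Element, Span, revcomp
from .motifs import (
    ALT_TSS_IN_R,
    LTR_LEN,
    PROMOTER_MOTIFS,
    R_SPAN,
    U3_R_BORDER,
    U3_SPAN,
    U5_SPAN,
)

# Chimeric splice geometry (ancestor coordinates): the donor exon of the
# upstream fragmentary LTR ends at 1074 (gag leader) with a GT intron start at
# 1075, and the acceptor exon of the provirus starts at 1018 with an AG intron
# end at 1016-1017.
CHIMERA_DONOR_END = 1074
CHIMERA_ACCEPTOR_START = 1018
UPSTREAM_LTR_GAP = 551
FRAGMENT_LTR_LEN = 1118  # LTR plus enough gag leader to cover the donor site

POL_ENV_DELETION_LEN = 292

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS and a + b + c != "ATG"
]

SCENARIOS = (
    "isolated",
    "divergent_neighbor_gene",
    "intronic",
    "upstream_fragmentary_ltr",
    "antisense_neighbor",
)
MECHANISMS = (
    "ltr_driven",
    "read_through",
    "intronic_passenger",
    "upstream_ltr_chimeric",
    "antisense",
)


def _arr(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8).copy()


def _str(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def random_dna(length: int, rng: np.random.Generator) -> str:
    return _str(_BASES[rng.integers(0, 4, size=length)])


def mutate(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute each position independently with probability ``divergence``.

    Replacement bases are uniform over the three alternatives, so every
    substitution changes the base (no silent resampling).
    """
    if not 0.0 <= divergence <= 1.0:
        raise ValueError(f"divergence must be in [0, 1], got {divergence}")
    if divergence == 0.0:
        return seq
    arr = _arr(seq)
    idx = np.searchsorted(_BASES, arr)  # catalogue sequences are ACGT-only here
    hit = rng.random(arr.size) < divergence
    shift = rng.integers(1, 4, size=int(hit.sum()))
    idx[hit] = (idx[hit] + shift) % 4
    return _str(_BASES[idx])


def hypermutate(seq: str, fraction: float, rng: np.random.Generator) -> str:
    """Plus-strand G->A hypermutation: replace ``fraction`` of G's with A."""
    arr = _arr(seq)
    gs = np.flatnonzero(arr == ord("G"))
    hit = gs[rng.random(gs.size) < fraction]
    arr[hit] = ord("A")
    return _str(arr)


# --------------------------------------------------------------------------
# Family specification
# --------------------------------------------------------------------------


def _study_divergences() -> dict[str, float]:
    """Per-element divergence of the default study family (vs the ancestor).

    Spans the recent "LTR Hs"-like through diverged "5B"-like range; the
    identical duplicate pair is declared separately in ``duplicate_pairs``.
    """
    return {
        "Hs_01": 0.002,
        "Hs_02": 0.004,
        "Hs_03": 0.006,
        "Hs_04": 0.008,
        "Hs_05": 0.010,
        "5A_01": 0.015,
        "5A_02": 0.020,
        "5B_01": 0.030,
        "5B_02": 0.050,
        "5B_03": 0.080,
    }


@dataclass
class FamilySpec:
    """Parameters of a synthetic family; a fixed seed gives identical output."""

    ancestor_len: int = 9500
    ltr_len: int = LTR_LEN
    leader_len: int = 250
    gene_lengths: dict[str, int] = field(
        default_factory=lambda: {"gag": 2001, "pro": 780, "pol": 2400, "env": 1800}
    )
    divergences: dict[str, float] = field(default_factory=_study_divergences)
    # (id_a, id_b, divergence of the pair's parent vs ancestor, intra-pair divergence)
    duplicate_pairs: list[tuple[str, str, float, float]] = field(
        default_factory=lambda: [("HsDupA", "HsDupB", 0.002, 0.0)]
    )
    type1_members: tuple[str, ...] = ("Hs_03", "5A_01")
    solo_ltr_count: int = 2
    hypermutated_members: tuple[str, ...] = ("Hs_05",)
    hyper_fraction: float = 0.3
    deletion_len: int = POL_ENV_DELETION_LEN
    seed: int = 0

    def all_provirus_ids(self) -> list[str]:
        ids = list(self.divergences)
        for a, b, _d, _i in self.duplicate_pairs:
            ids.extend((a, b))
        return ids

    def validate(self) -> None:
        for eid, d in self.divergences.items():
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"divergence for {eid} outside [0, 1]: {d}")
        ids = self.all_provirus_ids()
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate element ids in family spec")
        for eid in list(self.type1_members) + list(self.hypermutated_members):
            if eid not in ids:
                raise ValueError(f"spec references unknown element {eid!r}")
        interior = self.ancestor_len - 2 * self.ltr_len
        needed = self.leader_len + sum(self.gene_lengths.values())
        if needed > interior:
            raise ValueError("gene layout does not fit between the LTRs")


@dataclass
class ElementAncestry:
    parent: str  # "ancestor" or a duplicate-pair parent tag
    divergence: float
    deletion: Span | None = None  # (start, length) in pre-deletion coordinates
    solo_donor: str | None = None
    hypermutated: bool = False


@dataclass
class Ancestry:
    """Generator-side truth: ancestor sequence, layout, per-element history."""

    ancestor_seq: str
    layout: list[tuple[str, Span, str]]
    elements: dict[str, ElementAncestry] = field(default_factory=dict)

    def layout_span(self, name: str) -> Span:
        for nm, sp, _ in self.layout:
            if nm == name:
                return sp
        raise KeyError(name)

    def boundary_reference(self, window: int = 600) -> str:
        """Type-2 pol-env boundary region of the ancestor (classify_type input).

        Asymmetric around the boundary: the downstream side must extend past
        the longest recognizable deletion (330 bp) so the right anchor lands
        beyond it in type-1 elements.
        """
        env_start = self.layout_span("env")[0]
        after = max(window - 250, 350)
        return self.ancestor_seq[env_start - 1 - (window - after) : env_start - 1 + after]


def _build_canonical_ltr(rng: np.random.Generator) -> str:
    ltr = _arr(random_dna(LTR_LEN, rng))
    for _name, pos, motif in PROMOTER_MOTIFS:
        ltr[pos - 1 : pos - 1 + len(motif)] = _arr(motif)
    return _str(ltr)


def _random_orf(length: int, rng: np.random.Generator) -> str:
    """ATG + stop-free random codons + TAA; ``length`` must be divisible by 3."""
    if length % 3 != 0 or length < 6:
        raise ValueError("ORF length must be a multiple of 3 and >= 6")
    n_codons = length // 3 - 2
    body = "".join(rng.choice(_CODONS) for _ in range(n_codons))
    return "ATG" + body + "TAA"


def build_ancestor(spec: FamilySpec, rng: np.random.Generator) -> tuple[str, list]:
    """Construct the family ancestor with identical LTRs and intact ORFs."""
    spec.validate()
    seq = _arr(random_dna(spec.ancestor_len, rng))
    ltr = _build_canonical_ltr(rng)
    # identical 5' and 3' LTRs: intra-element LTR divergence is zero at age 0
    seq[: spec.ltr_len] = _arr(ltr)
    seq[spec.ancestor_len - spec.ltr_len :] = _arr(ltr)

    layout: list[tuple[str, Span, str]] = []
    for name, (s, e) in (("U3", U3_SPAN), ("R", R_SPAN), ("U5", U5_SPAN)):
        layout.append((name, (s, e), "+"))
    pos = spec.ltr_len + 1
    layout.append(("leader", (pos, pos + spec.leader_len - 1), "+"))
    pos += spec.leader_len
    for gene in ("gag", "pro", "pol", "env"):
        glen = spec.gene_lengths[gene]
        orf = _random_orf(glen, rng)
        seq[pos - 1 : pos - 1 + glen] = _arr(orf)
        layout.append((gene, (pos, pos + glen - 1), "+"))
        pos += glen
    # splice acceptor (AG|exon at 1018) and chimeric donor (exon|GT at 1075)
    # in the gag leader, matching the canonical junction geometry
    seq[CHIMERA_ACCEPTOR_START - 3 : CHIMERA_ACCEPTOR_START - 1] = _arr("AG")
    seq[CHIMERA_DONOR_END : CHIMERA_DONOR_END + 2] = _arr("GT")
    return _str(seq), layout


def _ltr_group_for(divergence: float) -> str:
    if divergence <= 0.012:
        return "Hs"
    if divergence <= 0.04:
        return "5A"
    return "5B"


def _apply_deletion(
    seq: str, layout: list[tuple[str, Span, str]], start: int, length: int
) -> tuple[str, list[tuple[str, Span, str]]]:
    """Remove ``length`` bases starting at 1-based ``start``; remap features."""
    if start + length - 1 > len(seq):
        raise ValueError(
            f"deletion window [{start}, {start + length - 1}] extends past sequence end {len(seq)}"
        )
    out_seq = seq[: start - 1] + seq[start - 1 + length :]
    del_end = start + length - 1
    remapped = []
    for name, (s, e), strand in layout:
        if s >= start and e <= del_end:
            continue  # feature entirely deleted
        if s < start <= e <= del_end:
            ns, ne = s, start - 1
        elif start <= s <= del_end < e:
            ns, ne = start, e - length
        elif s < start and e > del_end:
            ns, ne = s, e - length
        elif s > del_end:
            ns, ne = s - length, e - length
        else:
            ns, ne = s, e
        if ne >= ns:
            remapped.append((name, (ns, ne), strand))
    return out_seq, remapped


def _element_from(
    eid: str,
    seq: str,
    layout: list[tuple[str, Span, str]],
    spec: FamilySpec,
    *,
    elem_class: str = "provirus",
    ltr_group: str = "unknown",
    provirus_type: str = "unknown",
) -> tuple[Element, Annotation]:
    spans = {name: sp for name, sp, _ in layout}
    ltr5 = (1, spec.ltr_len)
    ltr3 = None
    if elem_class == "provirus":
        # the 3' LTR is the trailing ltr_len bases (deletions never reach it)
        ltr3 = (len(seq) - spec.ltr_len + 1, len(seq))
    elem = Element(
        id=eid,
        elem_class=elem_class,
        seq=seq,
        ltr5_span=ltr5,
        ltr3_span=ltr3,
        ltr_group=ltr_group,
        provirus_type=provirus_type,
    )
    ann = Annotation(element_id=eid, features=list(layout))
    del spans
    return elem, ann


def apply_type1_deletion(
    element: Element,
    annotation: Annotation,
    deletion_len: int = POL_ENV_DELETION_LEN,
) -> tuple[Element, Annotation]:
    """Turn a type-2 provirus into a type-1 by deleting ``deletion_len``
    contiguous bases starting at the annotated pol-env boundary (the first
    base of env), remapping the annotation through the deletion."""
    env = annotation.span("env")
    if env is None:
        raise ValueError(f"element {element.id} has no annotated env span")
    seq, layout = _apply_deletion(element.seq, annotation.features, env[0], deletion_len)
    ltr_len = (
        element.ltr5_span[1] - element.ltr5_span[0] + 1 if element.ltr5_span else None
    )
    new_elem = Element(
        id=element.id,
        elem_class=element.elem_class,
        seq=seq,
        ltr5_span=element.ltr5_span,
        ltr3_span=(len(seq) - ltr_len + 1, len(seq)) if ltr_len else None,
        ltr_group=element.ltr_group,
        age_mya=element.age_mya,
        provirus_type="type1",
    )
    return new_elem, Annotation(element_id=element.id, features=layout)


def generate_family(spec: FamilySpec | None = None) -> tuple[Catalogue, Ancestry]:
    """Generate a catalogue and its ancestry record from a family spec.

    Descendants are the ancestor with Binomial(len, divergence) substituted
    positions; type-1 members then lose exactly ``spec.deletion_len``
    contiguous bases starting at the annotated pol-env boundary (the first
    base of env); solo LTRs fuse a donor's 5' LTR U3+R to its 3' LTR U5.
    """
    spec = spec or FamilySpec()
    rng = np.random.default_rng(spec.seed)
    ancestor, layout = build_ancestor(spec, rng)
    ancestry = Ancestry(ancestor_seq=ancestor, layout=layout)
    catalogue = Catalogue()

    members: list[tuple[str, str, ElementAncestry]] = []  # (id, seq, record)
    for eid, d in spec.divergences.items():
        members.append((eid, mutate(ancestor, d, rng), ElementAncestry("ancestor", d)))
    for a, b, d_parent, intra in spec.duplicate_pairs:
        parent = mutate(ancestor, d_parent, rng)
        tag = f"dup({a},{b})"
        for eid in (a, b):
            members.append(
                (eid, mutate(parent, intra / 2.0, rng), ElementAncestry(tag, d_parent))
            )

    env_start = ancestry.layout_span("env")[0]
    for eid, seq, record in members:
        elem_layout = list(layout)
        if eid in spec.hypermutated_members:
            seq = hypermutate(seq, spec.hyper_fraction, rng)
            record.hypermutated = True
        ptype = "type2"
        if eid in spec.type1_members:
            seq, elem_layout = _apply_deletion(seq, elem_layout, env_start, spec.deletion_len)
            record.deletion = (env_start, spec.deletion_len)
            ptype = "type1"
        group = _ltr_group_for(record.divergence)
        elem, ann = _element_from(
            eid, seq, elem_layout, spec, ltr_group=group, provirus_type=ptype
        )
        catalogue.add(elem, ann)
        ancestry.elements[eid] = record

    donors = [eid for eid, _s, _r in members]
    for i in range(spec.solo_ltr_count):
        donor_id = donors[i % len(donors)]
        donor = catalogue.get(donor_id)
        u3r = donor.subseq((donor.ltr5_span[0], donor.ltr5_span[0] + R_SPAN[1] - 1))
        l3 = donor.ltr3_span
        u5 = donor.subseq((l3[0] + U5_SPAN[0] - 1, l3[1]))
        solo_id = f"solo_{i + 1:02d}"
        seq = u3r + u5
        elem = Element(
            id=solo_id,
            elem_class="solo_ltr",
            seq=seq,
            ltr5_span=(1, len(seq)),
            ltr_group=donor.ltr_group,
        )
        ann = Annotation(
            element_id=solo_id,
            features=[("U3", U3_SPAN, "+"), ("R", R_SPAN, "+"), ("U5", U5_SPAN, "+")],
        )
        catalogue.add(elem, ann)
        ancestry.elements[solo_id] = ElementAncestry(
            parent=donor_id, divergence=ancestry.elements[donor_id].divergence,
            solo_donor=donor_id,
        )
    return catalogue, ancestry


def aligned_ltr_fasta(catalogue: Catalogue) -> dict[str, str]:
    """5' LTR sequences for tree building; equal-length under the family's
    substitution-only evolution, so they form a natural gap-free alignment."""
    out = {}
    for elem in catalogue:
        if elem.ltr5_span is not None and elem.elem_class != "host_gene":
            out[elem.id] = elem.subseq(elem.ltr5_span)
    return out


def aligned_provirus_alignment(catalogue: Catalogue, ancestry: Ancestry) -> dict[str, str]:
    """Full-provirus alignment with '-' restored at engineered deletions."""
    out = {}
    for elem in catalogue:
        if elem.elem_class != "provirus":
            continue
        rec = ancestry.elements[elem.id]
        seq = elem.seq
        if rec.deletion is not None:
            start, length = rec.deletion
            seq = seq[: start - 1] + "-" * length + seq[start - 1 :]
        out[elem.id] = seq
    return out


# --------------------------------------------------------------------------
# Host contexts
# --------------------------------------------------------------------------


@dataclass
class NeighborGene:
    name: str
    span_in_locus: Span  # filled when the locus is assembled
    strand: str


@dataclass
class ElementContext:
    element_id: str
    scenario: str
    up_flank: str = ""
    down_flank: str = ""
    neighbor: NeighborGene | None = None
    # upstream fragmentary LTR bookkeeping (up_flank coordinates)
    fragment_span_in_up: Span | None = None
    donor_end_in_up: int | None = None  # last exon-1 base, up_flank coords
    acceptor_start_in_elem: int | None = None  # first exon-2 base, element coords


@dataclass
class Placement:
    offset: int  # number of upstream-flank bases before element position 1
    elem_len: int
    locus_len: int


@dataclass
class HostContext:
    """Per-element genomic surroundings used by mechanism-aware analyses."""

    flank_len: int = 2000
    contexts: dict[str, ElementContext] = field(default_factory=dict)

    def get(self, element_id: str) -> ElementContext | None:
        return self.contexts.get(element_id)

    def augmented_catalogue(self, catalogue: Catalogue) -> tuple[Catalogue, dict[str, Placement]]:
        """Reference where each contexted element becomes a flanked locus record.

        Record ids are unchanged; a placement map gives the element's offset
        inside its record so coordinates can be projected back.
        """
        aug = Catalogue()
        placements: dict[str, Placement] = {}
        for elem in catalogue:
            ctx = self.contexts.get(elem.id)
            up = ctx.up_flank if ctx else ""
            down = ctx.down_flank if ctx else ""
            seq = up + elem.seq + down
            off = len(up)
            shifted = Element(
                id=elem.id,
                elem_class=elem.elem_class,
                seq=seq,
                ltr5_span=(elem.ltr5_span[0] + off, elem.ltr5_span[1] + off)
                if elem.ltr5_span
                else None,
                ltr3_span=(elem.ltr3_span[0] + off, elem.ltr3_span[1] + off)
                if elem.ltr3_span
                else None,
                ltr_group=elem.ltr_group,
                provirus_type=elem.provirus_type,
            )
            ann = catalogue.annotations.get(elem.id)
            shifted_ann = None
            if ann is not None:
                shifted_ann = Annotation(
                    element_id=elem.id,
                    features=[(n, (s + off, e + off), st) for n, (s, e), st in ann.features],
                )
            aug.add(shifted, shifted_ann)
            placements[elem.id] = Placement(offset=off, elem_len=len(elem), locus_len=len(seq))
        return aug, placements


def _find_acceptor(elem_seq: str, preferred: int = CHIMERA_ACCEPTOR_START) -> int:
    """First exon-2 base: position after an AG dinucleotide nearest ``preferred``.

    Descendant mutation can destroy the canonical AG at 1016-1017, so the
    nearest AG within +/-25 bp is used and recorded as the locus's truth.
    """
    best = None
    for delta in sorted(range(-25, 26), key=abs):
        pos = preferred + delta  # candidate exon-2 start (1-based)
        if pos < 3 or pos + 1 > len(elem_seq):
            continue
        if elem_seq[pos - 3 : pos - 1] == "AG":
            best = pos
            break
    if best is None:
        raise ValueError("no AG acceptor near the canonical leader position")
    return best


def build_host_contexts(
    catalogue: Catalogue,
    scenarios: dict[str, str],
    seed: int = 0,
    flank_len: int = 2000,
    ancestry: Ancestry | None = None,
) -> HostContext:
    """Emit flank and neighbor sequences for each requested scenario.

    ``upstream_fragmentary_ltr`` places a recent-LTR fragment exactly 551 bp
    upstream of the element with a GT splice donor after fragment position
    1074 and an AG acceptor in the element's gag leader, so the chimeric
    junction obeys GT-AG in DNA sense.
    """
    rng = np.random.default_rng(seed)
    ctx = HostContext(flank_len=flank_len)
    for eid, scenario in scenarios.items():
        elem = catalogue.get(eid)
        if scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {scenario!r}")
        ec = ElementContext(element_id=eid, scenario=scenario)
        if scenario == "isolated":
            pass
        elif scenario == "divergent_neighbor_gene":
            ec.up_flank = random_dna(flank_len, rng)
            ec.down_flank = random_dna(flank_len, rng)
            ec.neighbor = NeighborGene(name=f"{eid}_nb", span_in_locus=(201, 1700), strand="-")
        elif scenario == "intronic":
            ec.up_flank = random_dna(flank_len, rng)
            ec.down_flank = random_dna(flank_len, rng)
            locus_len = flank_len * 2 + len(elem)
            ec.neighbor = NeighborGene(name=f"{eid}_host", span_in_locus=(1, locus_len), strand="+")
        elif scenario == "upstream_fragmentary_ltr":
            if ancestry is None:
                raise ValueError("upstream_fragmentary_ltr scenario needs the family ancestry")
            frag = mutate(ancestry.ancestor_seq[:FRAGMENT_LTR_LEN], 0.002, rng)
            # re-plant the GT donor in case mutation hit it
            frag = frag[:CHIMERA_DONOR_END] + "GT" + frag[CHIMERA_DONOR_END + 2 :]
            pad = max(0, flank_len - FRAGMENT_LTR_LEN - UPSTREAM_LTR_GAP)
            ec.up_flank = random_dna(pad, rng) + frag + random_dna(UPSTREAM_LTR_GAP, rng)
            ec.down_flank = random_dna(flank_len, rng)
            ec.fragment_span_in_up = (pad + 1, pad + FRAGMENT_LTR_LEN)
            ec.donor_end_in_up = pad + CHIMERA_DONOR_END
            ec.acceptor_start_in_elem = _find_acceptor(elem.seq)
        elif scenario == "antisense_neighbor":
            ec.up_flank = random_dna(flank_len, rng)
            ec.down_flank = random_dna(flank_len, rng)
            ec.neighbor = NeighborGene(name=f"{eid}_as", span_in_locus=(0, 0), strand="-")
        ctx.contexts[eid] = ec
    return ctx


# --------------------------------------------------------------------------
# Truth profiles
# --------------------------------------------------------------------------


@dataclass
class Transcript:
    id: str
    element_id: str  # primary element (or neighbor tag for host transcripts)
    record_id: str  # reference record the exons live on
    exons: list[Span]  # record coordinates, 1-based inclusive, 5'->3' in DNA sense
    strand: str
    mechanism: str
    cell_fraction: float
    virion_fraction: float
    seq: str  # realized transcript sequence (sense strand of the transcript)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class TruthProfile:
    """Molar transcript fractions for the cell and virion samples."""

    transcripts: list[Transcript] = field(default_factory=list)

    def fractions(self, sample: str) -> dict[str, float]:
        if sample not in ("cell", "virion"):
            raise ValueError("sample must be 'cell' or 'virion'")
        attr = "cell_fraction" if sample == "cell" else "virion_fraction"
        return {t.id: getattr(t, attr) for t in self.transcripts}

    def element_fractions(self, sample: str) -> dict[str, float]:
        out: dict[str, float] = {}
        for t in self.transcripts:
            out[t.element_id] = out.get(t.element_id, 0.0) + self.fractions(sample)[t.id]
        return out

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "transcript_id\telement_id\trecord_id\texons\tstrand\tmechanism"
                "\tcell_fraction\tvirion_fraction\n"
            )
            for t in self.transcripts:
                exons = ",".join(f"{s}-{e}" for s, e in t.exons)
                fh.write(
                    f"{t.id}\t{t.element_id}\t{t.record_id}\t{exons}\t{t.strand}"
                    f"\t{t.mechanism}\t{t.cell_fraction:.6g}\t{t.virion_fraction:.6g}\n"
                )


@dataclass
class PlanEntry:
    """Per-element expression plan: cell molar fraction, packaging efficiency
    (virion weight multiplier; 0 means never packaged), and mechanism."""

    cell_fraction: float
    packaging: float = 1.0
    mechanism: str = "ltr_driven"


def default_sample_plan() -> dict[str, PlanEntry]:
    """Study conditions for the default family: two dominant loci, a strongly
    expressed but packaging-incompetent ancient locus (66-fold depleted in
    virions), one cell-only locus, a silent duplicate twin, and one locus per
    transcription mechanism."""
    return {
        "Hs_01": PlanEntry(0.22, 3.0, "ltr_driven"),
        "Hs_02": PlanEntry(0.13, 2.0),
        "Hs_03": PlanEntry(0.06, 2.5),
        "Hs_04": PlanEntry(0.06, 0.0, "antisense"),
        "Hs_05": PlanEntry(0.05, 1.0),
        "HsDupA": PlanEntry(0.05, 2.0),
        "HsDupB": PlanEntry(0.0, 0.0),
        "5A_01": PlanEntry(0.04, 0.5),
        "5A_02": PlanEntry(0.0, 0.0),
        "5B_01": PlanEntry(0.25, 0.004, "upstream_ltr_chimeric"),
        "5B_02": PlanEntry(0.01, 0.0, "intronic_passenger"),
        "5B_03": PlanEntry(0.12, 0.3, "read_through"),
        "solo_01": PlanEntry(0.01, 0.2),
        "solo_02": PlanEntry(0.0, 0.0),
    }


def default_scenarios(plan: dict[str, PlanEntry] | None = None) -> dict[str, str]:
    """Host-context scenario per element, derived from the plan's mechanisms."""
    plan = plan or default_sample_plan()
    mech_to_scenario = {
        "ltr_driven": "isolated",
        "read_through": "divergent_neighbor_gene",
        "intronic_passenger": "intronic",
        "upstream_ltr_chimeric": "upstream_fragmentary_ltr",
        "antisense": "antisense_neighbor",
    }
    out = {}
    for eid, entry in plan.items():
        scen = mech_to_scenario[entry.mechanism]
        if scen != "isolated":
            out[eid] = scen
    # the dominant LTR-driven locus sits next to a divergent neighbor gene,
    # the configuration in which native-LTR transcription is diagnosable
    if "Hs_01" in plan:
        out["Hs_01"] = "divergent_neighbor_gene"
    return out


def _transcript_seq(record_seq: str, exons: list[Span], strand: str) -> str:
    parts = [record_seq[s - 1 : e] for s, e in exons]
    seq = "".join(parts)
    return seq if strand == "+" else revcomp(seq)


def make_truth_profile(
    catalogue: Catalogue,
    contexts: HostContext,
    sample_plan: dict[str, PlanEntry],
    seed: int = 0,
) -> TruthProfile:
    """Realize transcripts from the plan against the contexted reference.

    LTR-driven transcripts start at the U3-R border of the 5' LTR (position
    793 of a canonical LTR); read-through transcripts run from the locus start
    through the element; intronic passengers span the whole pre-mRNA locus;
    chimeric transcripts splice the upstream fragment's R region into the
    element's gag leader; antisense transcripts are reverse-complement spans.
    The virion profile reweights the cell profile by per-element packaging
    efficiency.  Fractions are always renormalized (with a warning when the
    input cell fractions deviate from 1 by more than 1%).
    """
    del seed  # deterministic given plan + contexts; kept for interface stability
    aug, placements = contexts.augmented_catalogue(catalogue)
    transcripts: list[Transcript] = []
    for eid, entry in sample_plan.items():
        if entry.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {entry.mechanism!r}")
        if entry.cell_fraction < 0 or entry.packaging < 0:
            raise ValueError("fractions and packaging efficiencies must be >= 0")
        if entry.cell_fraction == 0 and entry.packaging == 0:
            continue
        elem = catalogue.get(eid)
        record = aug.get(eid)
        place = placements[eid]
        off = place.offset
        mech = entry.mechanism
        if mech == "ltr_driven":
            tss = off + (U3_R_BORDER if elem.ltr5_span else 1)
            exons = [(tss, off + place.elem_len)]
            strand = "+"
        elif mech == "read_through":
            exons = [(1, off + place.elem_len)]
            strand = "+"
        elif mech == "intronic_passenger":
            exons = [(1, place.locus_len)]
            strand = "+"
        elif mech == "upstream_ltr_chimeric":
            ctx = contexts.get(eid)
            if ctx is None or ctx.scenario != "upstream_fragmentary_ltr":
                raise ValueError(f"{eid}: chimeric mechanism needs an upstream_fragmentary_ltr context")
            frag_start = ctx.fragment_span_in_up[0]
            exon1 = (frag_start + ALT_TSS_IN_R - 1, ctx.donor_end_in_up)
            exon2 = (off + ctx.acceptor_start_in_elem, off + place.elem_len)
            exons = [exon1, exon2]
            strand = "+"
        else:  # antisense
            exons = [(off + 1, place.locus_len)]
            strand = "-"
        seq = _transcript_seq(record.seq, exons, strand)
        transcripts.append(
            Transcript(
                id=f"tx_{eid}",
                element_id=eid,
                record_id=eid,
                exons=exons,
                strand=strand,
                mechanism=mech,
                cell_fraction=entry.cell_fraction,
                virion_fraction=entry.cell_fraction * entry.packaging,
                seq=seq,
            )
        )
        # neighbor transcript for the divergent-orientation neighbor gene:
        # minus-strand mRNA confined to the upstream flank
        ctx = contexts.get(eid)
        if ctx and ctx.neighbor and ctx.scenario == "divergent_neighbor_gene":
            nb = ctx.neighbor
            nb_exons = [nb.span_in_locus]
            nb_seq = _transcript_seq(record.seq, nb_exons, nb.strand)
            transcripts.append(
                Transcript(
                    id=f"tx_{nb.name}",
                    element_id=nb.name,
                    record_id=eid,
                    exons=nb_exons,
                    strand=nb.strand,
                    mechanism="read_through",
                    cell_fraction=entry.cell_fraction * 0.5,
                    virion_fraction=0.0,
                    seq=nb_seq,
                )
            )

    plan_sum = sum(e.cell_fraction for e in sample_plan.values())
    if abs(plan_sum - 1.0) > 0.01:
        warnings.warn(
            f"plan cell fractions sum to {plan_sum:.4g}; renormalizing to 1", stacklevel=2
        )
    cell_sum = sum(t.cell_fraction for t in transcripts)
    if cell_sum <= 0:
        raise ValueError("sample plan yields no expressed transcripts")
    vir_sum = sum(t.virion_fraction for t in transcripts)
    for t in transcripts:
        t.cell_fraction /= cell_sum
        t.virion_fraction = t.virion_fraction / vir_sum if vir_sum > 0 else 0.0
    return TruthProfile(transcripts=transcripts)


def mechanism_demo(seed: int = 0, flank_len: int = 2000):
    """Five-locus demonstration family, one locus per transcription mechanism.

    Returns (catalogue, contexts, truth, augmented catalogue, placements).
    Loci are well diverged (5% each from the ancestor, ~10% pairwise) so that
    unique alignment is unambiguous even against the recent fragmentary LTR
    of the chimera context, and classification reflects coverage shape, not
    mappability.
    """
    spec = FamilySpec(
        divergences={
            "mech_ltr": 0.05,
            "mech_rt": 0.05,
            "mech_intron": 0.05,
            "mech_chimera": 0.05,
            "mech_anti": 0.05,
        },
        duplicate_pairs=[],
        type1_members=(),
        hypermutated_members=(),
        solo_ltr_count=0,
        seed=seed,
    )
    catalogue, ancestry = generate_family(spec)
    scenarios = {
        "mech_ltr": "divergent_neighbor_gene",
        "mech_rt": "divergent_neighbor_gene",
        "mech_intron": "intronic",
        "mech_chimera": "upstream_fragmentary_ltr",
        "mech_anti": "antisense_neighbor",
    }
    contexts = build_host_contexts(
        catalogue, scenarios, seed=seed + 1, flank_len=flank_len, ancestry=ancestry
    )
    plan = {
        "mech_ltr": PlanEntry(0.2, 1.0, "ltr_driven"),
        "mech_rt": PlanEntry(0.2, 1.0, "read_through"),
        "mech_intron": PlanEntry(0.2, 1.0, "intronic_passenger"),
        "mech_chimera": PlanEntry(0.2, 1.0, "upstream_ltr_chimeric"),
        "mech_anti": PlanEntry(0.2, 1.0, "antisense"),
    }
    truth = make_truth_profile(catalogue, contexts, plan)
    aug, placements = contexts.augmented_catalogue(catalogue)
    return catalogue, contexts, truth, aug, placements
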