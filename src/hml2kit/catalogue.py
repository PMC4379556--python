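"""Element catalogue: the alignment reference for locus-resolution ERV analysis.

The catalogue treats every HML-2 element (provirus, solo LTR, fragmentary LTR,
or host-gene decoy) as an independent reference sequence -- a "chromosome" of
its own -- so that read pairs can be assigned to individual loci rather than to
the family as a whole.  Coordinates are 1-based inclusive throughout the
package; conversion to 0-based half-open happens only inside format writers.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

Span = tuple[int, int]  # 1-based inclusive

ELEMENT_CLASSES = ("provirus", "solo_ltr", "fragmentary_ltr", "host_gene")
LTR_GROUPS = ("Hs", "5A", "5B", "unknown")
PROVIRUS_TYPES = ("type1", "type2", "unknown")
FEATURE_NAMES = ("gag", "pro", "pol", "env", "U3", "R", "U5", "leader")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


class CatalogueError(ValueError):
    """Malformed catalogue input (duplicate ids, out-of-bounds features...)."""


@dataclass
class Element:
    """One catalogue sequence with its LTR structure and classification.

    ``ltr5_span``/``ltr3_span`` are 1-based inclusive intervals in element
    coordinates.  ``age_mya`` is contextual only; divergence from the family
    ancestor is the operative age measure elsewhere in the package.
    """

    id: str
    elem_class: str
    seq: str
    ltr5_span: Span | None = None
    ltr3_span: Span | None = None
    ltr_group: str = "unknown"
    age_mya: float | None = None
    provirus_type: str = "unknown"

    def __post_init__(self) -> None:
        if not self.id:
            raise CatalogueError("element id must be nonempty")
        if self.elem_class not in ELEMENT_CLASSES:
            raise CatalogueError(f"unknown element class {self.elem_class!r}")
        if self.ltr_group not in LTR_GROUPS:
            raise CatalogueError(f"unknown LTR group {self.ltr_group!r}")
        if self.provirus_type not in PROVIRUS_TYPES:
            raise CatalogueError(f"unknown provirus type {self.provirus_type!r}")
        self.seq = self.seq.upper().replace("U", "T")
        if set(self.seq) - set("ACGTN"):
            bad = sorted(set(self.seq) - set("ACGTN"))
            raise CatalogueError(f"element {self.id}: non-DNA characters {bad}")
        for name, span in (("ltr5_span", self.ltr5_span), ("ltr3_span", self.ltr3_span)):
            if span is not None:
                s, e = span
                if not (1 <= s <= e <= len(self.seq)):
                    raise CatalogueError(
                        f"element {self.id}: {name} {span} outside [1, {len(self.seq)}]"
                    )
        if self.ltr5_span and self.ltr3_span and not self.ltr5_span[1] < self.ltr3_span[0]:
            raise CatalogueError(f"element {self.id}: 5' LTR must precede 3' LTR")
        if self.age_mya is not None and self.age_mya < 0:
            raise CatalogueError(f"element {self.id}: negative age")

    def __len__(self) -> int:
        return len(self.seq)

    def subseq(self, span: Span) -> str:
        """Subsequence over a 1-based inclusive span, element-sense strand."""
        s, e = span
        return self.seq[s - 1 : e]


@dataclass
class Annotation:
    """Per-element feature list: (name, 1-based inclusive span, strand)."""

    element_id: str
    features: list[tuple[str, Span, str]] = field(default_factory=list)

    def spans(self, name: str) -> list[Span]:
        return [sp for nm, sp, _ in self.features if nm == name]

    def span(self, name: str) -> Span | None:
        got = self.spans(name)
        return got[0] if got else None


@dataclass
class Catalogue:
    """Ordered element collection plus their annotations, keyed by element id."""

    elements: dict[str, Element] = field(default_factory=dict)
    annotations: dict[str, Annotation] = field(default_factory=dict)

    def add(self, element: Element, annotation: Annotation | None = None) -> None:
        if element.id in self.elements:
            raise CatalogueError(f"duplicate element id {element.id!r}")
        self.elements[element.id] = element
        if annotation is not None:
            self.attach(annotation)

    def attach(self, annotation: Annotation) -> None:
        elem = self.elements.get(annotation.element_id)
        if elem is None:
            raise CatalogueError(f"annotation references unknown element {annotation.element_id!r}")
        for name, (s, e), _strand in annotation.features:
            if not (1 <= s <= e <= len(elem)):
                raise CatalogueError(
                    f"element {elem.id}: feature {name} span ({s}, {e}) outside sequence bounds"
                )
        self.annotations[annotation.element_id] = annotation

    def __iter__(self):
        return iter(self.elements.values())

    def __len__(self) -> int:
        return len(self.elements)

    def __contains__(self, element_id: str) -> bool:
        return element_id in self.elements

    def get(self, element_id: str) -> Element:
        try:
            return self.elements[element_id]
        except KeyError:
            raise CatalogueError(f"unknown element {element_id!r}") from None

    def family_ids(self) -> list[str]:
        """Ids of family proviruses (the relative-abundance denominator)."""
        return [e.id for e in self if e.elem_class == "provirus"]

    # ------------------------------------------------------------------ I/O

    def write(self, fasta_path: str | Path, gtf_path: str | Path) -> None:
        write_catalogue(self, fasta_path, gtf_path)


def _element_description(elem: Element) -> str:
    parts = [f"class={elem.elem_class}", f"ltr_group={elem.ltr_group}", f"type={elem.provirus_type}"]
    if elem.age_mya is not None:
        parts.append(f"age_mya={elem.age_mya:g}")
    return " ".join(parts)


def _parse_description(desc: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for token in desc.split():
        if "=" in token:
            k, v = token.split("=", 1)
            out[k] = v
    return out


def write_catalogue(catalogue: Catalogue, fasta_path: str | Path, gtf_path: str | Path) -> None:
    """Write multi-FASTA (wrapped at 60 columns) and GTF 2.2 feature lines.

    LTR spans are serialized as ``ltr5``/``ltr3`` features alongside the gene
    and LTR-region features so that a load/write/load round trip is identity.
    """
    records = []
    for elem in catalogue:
        records.append(
            SeqRecord(Seq(elem.seq), id=elem.id, description=_element_description(elem))
        )
    with open(fasta_path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=60)
        writer.write_file(records)
    with open(gtf_path, "w") as handle:
        for elem in catalogue:
            rows: list[tuple[str, Span, str]] = []
            if elem.ltr5_span:
                rows.append(("ltr5", elem.ltr5_span, "+"))
            if elem.ltr3_span:
                rows.append(("ltr3", elem.ltr3_span, "+"))
            ann = catalogue.annotations.get(elem.id)
            if ann:
                rows.extend(ann.features)
            for name, (s, e), strand in rows:
                attrs = f'element_id "{elem.id}"; feature_name "{name}";'
                handle.write(
                    f"{elem.id}\thml2kit\t{name}\t{s}\t{e}\t.\t{strand}\t.\t{attrs}\n"
                )


def load_catalogue(fasta_path: str | Path, gtf_path: str | Path | None = None) -> Catalogue:
    """Load a catalogue from multi-FASTA plus optional GTF annotations.

    Sequences are uppercased and U is normalized to T.  Duplicate FASTA ids
    and GTF features outside sequence bounds are hard errors.
    """
    catalogue = Catalogue()
    meta: dict[str, dict[str, str]] = {}
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        desc = record.description
        if desc.startswith(record.id):
            desc = desc[len(record.id) :].strip()
        fields = _parse_description(desc)
        meta[record.id] = fields
        elem = Element(
            id=record.id,
            elem_class=fields.get("class", "provirus"),
            seq=str(record.seq),
            ltr_group=fields.get("ltr_group", "unknown"),
            age_mya=float(fields["age_mya"]) if "age_mya" in fields else None,
            provirus_type=fields.get("type", "unknown"),
        )
        catalogue.add(elem)
    if gtf_path is not None:
        feats: dict[str, list[tuple[str, Span, str]]] = {}
        with open(gtf_path) as handle:
            for lineno, line in enumerate(handle, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                cols = line.split("\t")
                if len(cols) != 9:
                    raise CatalogueError(f"{gtf_path}:{lineno}: expected 9 GTF columns")
                seqname, _src, feature, start, end, _score, strand, _frame, _attrs = cols
                if seqname not in catalogue:
                    raise CatalogueError(
                        f"{gtf_path}:{lineno}: feature for unknown element {seqname!r}"
                    )
                span = (int(start), int(end))
                elem = catalogue.get(seqname)
                if not (1 <= span[0] <= span[1] <= len(elem)):
                    raise CatalogueError(
                        f"element {seqname}: feature {feature} span {span} outside sequence bounds"
                    )
                feats.setdefault(seqname, []).append((feature, span, strand))
        for element_id, rows in feats.items():
            elem = catalogue.elements[element_id]
            plain = []
            for name, span, strand in rows:
                if name == "ltr5":
                    elem.ltr5_span = span
                elif name == "ltr3":
                    elem.ltr3_span = span
                else:
                    plain.append((name, span, strand))
            # re-validate LTR ordering after attachment
            if elem.ltr5_span and elem.ltr3_span and not elem.ltr5_span[1] < elem.ltr3_span[0]:
                raise CatalogueError(f"element {elem.id}: 5' LTR must precede 3' LTR")
            catalogue.attach(Annotation(element_id=element_id, features=plain))
    return catalogue


def extract_ltr(catalogue: Catalogue, element_id: str, which: str = "5prime") -> str:
    """Extract an element's 5' or 3' LTR sequence (element-sense strand).

    For a solo LTR -- where the whole record *is* the LTR -- either choice
    returns the annotated (or full) sequence.  Raises a distinct error for an
    unknown element versus a known element lacking the requested annotation.
    """
    if which not in ("5prime", "3prime"):
        raise ValueError(f"which must be '5prime' or '3prime', got {which!r}")
    elem = catalogue.get(element_id)  # raises for unknown element
    span = elem.ltr5_span if which == "5prime" else elem.ltr3_span
    if span is None:
        if elem.elem_class in ("solo_ltr", "fragmentary_ltr"):
            return elem.seq
        raise CatalogueError(
            f"element {element_id} has no {'5' if which == '5prime' else '3'}' LTR annotation"
        )
    return elem.subseq(span)


def catalogue_to_fasta_string(catalogue: Catalogue) -> str:
    """Catalogue FASTA as an in-memory string (used for byte-level checks)."""
    buf = io.StringIO()
    writer = SeqIO.FastaIO.FastaWriter(buf, wrap=60)
    writer.write_file(
        [SeqRecord(Seq(e.seq), id=e.id, description=_element_description(e)) for e in catalogue]
    )
    return buf.getvalue()
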