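"""Canonical HML-2 LTR coordinate frame and promoter-motif catalogue.

The canonical LTR is 968 bp with U3 at 1-792, R at 793-870 and U5 at
871-968.  Position 793 (the U3-R border) is the canonical transcription
start site; 826 is the alternative start observed mid-R for the fragmentary
upstream LTR.  The promoter-element catalogue lists the eight canonical
motif instances (GA-rich motif, three E boxes, two GC boxes, TATA box and
initiator) by name, canonical start position and canonical sequence.
"""

from __future__ import annotations

Span = tuple[int, int]

LTR_LEN = 968
U3_SPAN: Span = (1, 792)
R_SPAN: Span = (793, 870)
U5_SPAN: Span = (871, 968)
U3_R_BORDER = 793
ALT_TSS_IN_R = 826

# (name, canonical 1-based start, canonical sequence) -- eight instances
PROMOTER_MOTIFS: tuple[tuple[str, int, str], ...] = (
    ("GA", 379, "GGGAAGGG"),
    ("E1", 465, "TTGCAGTTGAGA"),
    ("E2", 485, "AGGCATCTGTCT"),
    ("GC2", 602, "GGCGG"),
    ("GC1", 759, "CCCCC"),
    ("TATA", 790, "AATAAATA"),
    ("Inr", 807, "CTCAGA"),
    ("E3", 832, "CTCCATATGCTG"),
)
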