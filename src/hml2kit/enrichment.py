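"""Cell-versus-virion packaging enrichment of relative abundances.

For each element the virion/cell abundance ratio r = a_virion / a_cell sorts
loci into increased, decreased or similar packaging categories.  Loci
undetected in one sample are floored at 0.01% for the ratio (and flagged
cell_only / virion_only); raw values are used whenever both are detected.
Fold change text truncates to a whole number at 10-fold and above -- e.g.
abundances of 25.32% in cells and 0.38% in virions report a 66-fold
decrease -- and the exact ratio is always emitted alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

DEFAULT_FLOOR = 0.01  # percent
DEFAULT_BAND = (0.5, 2.0)


@dataclass
class ProfileComparison:
    element_id: str
    a_cell: float
    a_virion: float
    r: float
    category: str  # increased | decreased | similar | cell_only | virion_only
    fold_text: str
    cell_detected: bool
    virion_detected: bool


def _fold_text(r: float) -> str:
    if r == 1.0:
        return "1.0-fold change"
    fold = max(r, 1.0 / r)
    direction = "increase" if r > 1.0 else "decrease"
    if fold >= 10.0:
        return f"{math.floor(fold)}-fold {direction}"
    return f"{fold:.1f}-fold {direction}"


def _detected(value) -> bool:
    return value is not None and not pd.isna(value) and value > 0.0


def compare_profiles(
    cell: dict[str, float] | pd.DataFrame,
    virion: dict[str, float] | pd.DataFrame,
    floor: float = DEFAULT_FLOOR,
    similar_band: tuple[float, float] = DEFAULT_BAND,
) -> list[ProfileComparison]:
    """Compare per-element relative abundance between samples.

    Inputs are element -> abundance-percent mappings (or expression frames
    with ``element_id``/``abundance_pct`` columns, from which provirus rows
    are taken).  Elements undetected in both samples are omitted.
    """
    a_cell = _as_dict(cell)
    a_virion = _as_dict(virion)
    lo, hi = similar_band
    out: list[ProfileComparison] = []
    for eid in dict.fromkeys(list(a_cell) + list(a_virion)):
        c_raw, v_raw = a_cell.get(eid), a_virion.get(eid)
        c_det, v_det = _detected(c_raw), _detected(v_raw)
        if not c_det and not v_det:
            continue
        c = float(c_raw) if c_det else floor
        v = float(v_raw) if v_det else floor
        r = v / c
        if not v_det:
            category = "cell_only"
        elif not c_det:
            category = "virion_only"
        elif r > hi:
            category = "increased"
        elif r < lo:
            category = "decreased"
        else:
            category = "similar"
        out.append(
            ProfileComparison(
                element_id=eid,
                a_cell=c,
                a_virion=v,
                r=r,
                category=category,
                fold_text=_fold_text(r),
                cell_detected=c_det,
                virion_detected=v_det,
            )
        )
    return out


def _as_dict(profile) -> dict[str, float]:
    if isinstance(profile, pd.DataFrame):
        sub = profile
        if "elem_class" in sub.columns:
            sub = sub[sub["elem_class"] == "provirus"]
        return dict(zip(sub["element_id"], sub["abundance_pct"]))
    return dict(profile)


def comparisons_frame(comparisons: list[ProfileComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "element_id": c.element_id,
                "a_cell": c.a_cell,
                "a_virion": c.a_virion,
                "ratio_virion_cell": c.r,
                "category": c.category,
                "fold_text": c.fold_text,
                "cell_detected": c.cell_detected,
                "virion_detected": c.virion_detected,
            }
            for c in comparisons
        ]
    )
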