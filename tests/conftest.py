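"""Shared fixtures: generated catalogues and small simulated libraries."""

from __future__ import annotations

import numpy as np
import pytest

from hml2kit.catalogue import Catalogue, Element
from hml2kit.synthetic_family import FamilySpec, generate_family, random_dna


@pytest.fixture(scope="session")
def study_family():
    """The default 12-provirus + 2 solo-LTR family, fixed seed."""
    return generate_family(FamilySpec(seed=7))


@pytest.fixture(scope="session")
def single_provirus():
    """One age-0 provirus: identical to the ancestor, all ORFs intact."""
    spec = FamilySpec(
        divergences={"P0": 0.0},
        duplicate_pairs=[],
        type1_members=(),
        hypermutated_members=(),
        solo_ltr_count=0,
        seed=3,
    )
    return generate_family(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_catalogue(rng):
    """Three 4-kb elements: two 2%-diverged paralogs plus one unrelated."""
    cat = Catalogue()
    base = random_dna(4000, rng)
    from hml2kit.synthetic_family import mutate

    cat.add(Element(id="parA", elem_class="provirus", seq=base))
    cat.add(Element(id="parB", elem_class="provirus", seq=mutate(base, 0.02, rng)))
    cat.add(Element(id="lone", elem_class="provirus", seq=random_dna(4000, rng)))
    return cat
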