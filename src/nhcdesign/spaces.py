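"""Bundled default fragment space and reference ligand builders.

The default space spans imidazolidin-2-ylidene (saturated NHC) ligands
with aromatic N-substituents required to be identical on both nitrogen
atoms, ortho/para aryl substitution, and symmetric backbone alkylation
(the substitution pattern on C4 equals that on C5).  It is a stand-in
exploring the same chemistry axes as published de novo NHC designs, not
a reproduction of any deposited space.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .fragments import FragmentSpace, LigandGraph, cap_remaining, grow, load_fragment_space

__all__ = ["default_space", "data_path", "anchor_ligands", "build_nhc"]


def data_path(*parts: str) -> Path:
    return Path(resources.files("nhcdesign").joinpath("data", *parts))


def default_space() -> FragmentSpace:
    root = data_path("default_space")
    return load_fragment_space([root / "fragments.sdf"], root / "rules.yaml")


def build_nhc(
    space: FragmentSpace,
    ortho: tuple[str | None, str | None] = (None, None),
    para: str | None = None,
    backbone: tuple[str | None, str | None] = (None, None),
) -> LigandGraph:
    """Assemble an NHC ligand of the default space from substituent names.

    ``ortho``/``para`` decorate the (shared) N-aryl phenyl; ``backbone``
    fills the two symmetric backbone slot pairs.  ``None`` means
    hydrogen.  Returns a complete (fully capped) ligand.
    """
    lig = LigandGraph.empty(space)
    lig = grow(lig, ("naryl", ()), "phenyl")
    for path, name in zip(((1,), (2,)), ortho):
        if name:
            lig = grow(lig, ("naryl", path), name)
    if para:
        lig = grow(lig, ("naryl", (3,)), para)
    for group, name in zip(("backbone_a", "backbone_b"), backbone):
        if name:
            lig = grow(lig, (group, ()), name)
    return cap_remaining(lig)


def anchor_ligands(space: FragmentSpace | None = None) -> dict[str, LigandGraph]:
    """The calibration anchor ligands, numbered as in the anchor table.

    9  -- mesityl N-aryls, one tert-butyl on each backbone carbon
    10 -- 2,6-diisopropylphenyl N-aryls, tetraethyl backbone
    11 -- mesityl N-aryls, unsubstituted backbone (the H2IMes carbene)
    12 -- 2,6-diisopropylphenyl N-aryls, unsubstituted backbone (SIPr)
    13 -- 2-tert-butylphenyl N-aryls, unsubstituted backbone (a stand-in
          for an additional known catalyst of the reference set)
    """
    space = space or default_space()
    mes = dict(ortho=("methyl", "methyl"), para="methyl")
    dipp = dict(ortho=("isopropyl", "isopropyl"))
    return {
        "9": build_nhc(space, backbone=("tert-butyl", None), **mes),
        "10": build_nhc(space, backbone=("ethyl", "ethyl"), **dipp),
        "11": build_nhc(space, **mes),
        "12": build_nhc(space, **dipp),
        "13": build_nhc(space, ortho=("tert-butyl", None)),
    }
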