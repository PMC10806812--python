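import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for spacegen helpers

from nhcdesign.energetics import default_surrogate
from nhcdesign.spaces import anchor_ligands


@pytest.fixture(scope="session")
def surrogate():
    """(space, substituent table, calibrated params) from bundled data."""
    return default_surrogate()


@pytest.fixture(scope="session")
def space(surrogate):
    return surrogate[0]


@pytest.fixture(scope="session")
def table(surrogate):
    return surrogate[1]


@pytest.fixture(scope="session")
def params(surrogate):
    return surrogate[2]


@pytest.fixture(scope="session")
def anchors(space):
    return anchor_ligands(space)


@pytest.fixture(scope="session")
def toy_space():
    """A small NHC-like space (~tens of constitutions) built from the
    bundled fragments but with trimmed libraries, for GA/exhaustive
    comparisons."""
    from nhcdesign.fragments import FragmentSpace
    from nhcdesign.spaces import default_space

    full = default_space()
    keep = {"imidazolidin-2-ylidene", "phenyl", "methyl", "tert-butyl"}
    return FragmentSpace(
        scaffolds=full.scaffolds,
        substituents=tuple(f for f in full.substituents if f.name in keep),
        cappings=full.cappings,
        compatibility=full.compatibility,
        symmetry_groups=full.symmetry_groups,
        site_classes=full.site_classes,
        default_capping=full.default_capping,
        mandatory_classes=full.mandatory_classes,
        hindered_rotation=full.hindered_rotation,
    )
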