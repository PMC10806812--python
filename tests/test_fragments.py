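"""Fragment space construction, growth, enumeration and canonical keys."""

import itertools

import numpy as np
import pytest
from rdkit import Chem

from nhcdesign.fragments import (
    AttachmentPoint,
    Fragment,
    FragmentSpace,
    FragmentSpaceError,
    LigandGraph,
    canonical_key,
    cap_remaining,
    constitution_smiles,
    enumerate_space,
    expand_configurations,
    grow,
    load_fragment_space,
    random_ligand,
)
from nhcdesign.spaces import build_nhc, data_path

from spacegen import PlainSpace, random_plain_space, oracle_count


class TestLoading:
    def test_bundled_space_loads_and_validates(self, space):
        assert {f.name for f in space.scaffolds} == {"imidazolidin-2-ylidene"}
        assert len(space.substituents) == 9
        assert space.mandatory_classes == {"n_aryl"}
        # toy inventory: 1 scaffold + substituents, several ap classes
        assert "ortho" in space.compatibility

    def test_unclosed_compatibility_map_rejected(self, space):
        broken = dict(space.compatibility)
        del broken["ortho"]
        with pytest.raises(FragmentSpaceError, match="unclosed compatibility"):
            FragmentSpace(
                scaffolds=space.scaffolds,
                substituents=space.substituents,
                cappings=space.cappings,
                compatibility=broken,
                symmetry_groups=space.symmetry_groups,
                mandatory_classes=space.mandatory_classes,
            )

    def test_malformed_ap_annotation_names_record(self, tmp_path):
        sdf = data_path("default_space", "fragments.sdf").read_text()
        bad = sdf.replace("1 n_aryl 1", "1 n_aryl")  # drop the bond order
        p = tmp_path / "bad.sdf"
        p.write_text(bad)
        with pytest.raises(FragmentSpaceError, match="malformed attachment point"):
            load_fragment_space([p], data_path("default_space", "rules.yaml"))

    def test_capping_fragment_ap_count_enforced(self):
        mol = Chem.MolFromSmiles("C")
        with pytest.raises(FragmentSpaceError, match="exactly 1"):
            Fragment(
                name="bad", mol=mol,
                aps=(AttachmentPoint(0, "x", 1), AttachmentPoint(0, "x", 1)),
                role="capping",
            )


class TestGrow:
    def test_symmetry_group_mirrors_n_aryl(self, space, table):
        lig = build_nhc(space, ortho=("methyl", "methyl"), para="methyl")
        smi = constitution_smiles(lig)
        # both N atoms bear mesityl: two identical aromatic rings
        assert smi.count("c1") + smi.count("c(") >= 2
        mol = lig.to_mol()
        assert len(mol.GetSubstructMatches(Chem.MolFromSmarts("c1ccccc1"))) == 2

    def test_backbone_pairing_installs_on_both_carbons(self, space):
        lig = build_nhc(space, backbone=("tert-butyl", None))
        mol = lig.to_mol()
        tbu = Chem.MolFromSmarts("CC(C)(C)[CX4;R]")
        assert len(mol.GetSubstructMatches(tbu)) == 2

    def test_occupied_site_rejected(self, space):
        lig = LigandGraph.empty(space)
        lig = grow(lig, ("naryl", ()), "phenyl")
        with pytest.raises(FragmentSpaceError, match="site occupied"):
            grow(lig, ("naryl", ()), "phenyl")

    def test_class_mismatch_rejected(self, space):
        lig = LigandGraph.empty(space)
        with pytest.raises(FragmentSpaceError, match="class mismatch"):
            grow(lig, ("backbone_a", ()), "phenyl")

    def test_grow_order_independent_keys(self, space):
        rng = np.random.default_rng(11)
        for _ in range(10):
            lig = random_ligand(space, rng)
            key = canonical_key(lig)
            # rebuild with permuted group assignment order
            groups = [g for g, _ in lig.assignments]
            for perm in itertools.islice(itertools.permutations(groups), 3):
                rebuilt = LigandGraph.empty(space)
                for g in perm:
                    rebuilt = rebuilt.with_assignment(g, lig.assignment(g))
                assert canonical_key(rebuilt) == key


class TestEnumeration:
    def test_default_space_counts(self, space):
        res = enumerate_space(space)
        assert res.count == 1890 and not res.truncated
        res2 = enumerate_space(space, collapse_configurations=False)
        # every hindered asymmetric-aryl constitution contributes a
        # second (anti) orientation: 15 asymmetric ortho pairs x 6 para
        # x 14 substituted backbone pairs
        assert res2.count == 1890 + 1260

    def test_collapse_never_exceeds_expanded(self, toy_space):
        a = enumerate_space(toy_space).count
        b = enumerate_space(toy_space, collapse_configurations=False).count
        assert a <= b

    def test_truncation_is_flagged(self, space):
        res = enumerate_space(space, limit=17)
        assert res.truncated and res.count == 17

    def test_cappings_only_space_single_constitution(self):
        scaffold = PlainSpace(
            scaffold=__import__("spacegen").PlainFragment(
                "scaf", [("C", 0), ("C", 0)], [(0, 1, 1)],
                [(0, "a", 1), (1, "a", 1)], "scaffold",
            ),
            substituents=[],
            groups={"g0": (0,), "g1": (1,)},
            compat={"a": {"s0"}},
        ).to_fragment_space()
        res = enumerate_space(scaffold)
        assert res.count == 1  # the fully H-capped scaffold

    def test_every_emitted_ligand_is_complete(self, toy_space):
        for lig in enumerate_space(toy_space).ligands:
            lig.validate()

    @pytest.mark.parametrize("seed", range(5))
    def test_count_matches_brute_force_oracle(self, seed):
        """Package enumeration (canonical-SMILES dedup) equals an
        independent graph-isomorphism oracle on random spaces."""
        rng = np.random.default_rng(1000 + seed)
        plain = random_plain_space(rng, max_constitutions=300)
        fs = plain.to_fragment_space()
        assert enumerate_space(fs).count == oracle_count(plain)


class TestConfigurations:
    def test_symmetric_aryl_single_configuration(self, space):
        lig = build_nhc(space, ortho=("methyl", "methyl"), para="methyl",
                        backbone=("tert-butyl", None))
        assert len(expand_configurations(lig)) == 1

    def test_unhindered_asymmetric_aryl_single_configuration(self, space):
        # no backbone substituent: rotation accessible, one candidate
        lig = build_nhc(space, ortho=("methyl", None))
        assert len(expand_configurations(lig)) == 1

    def test_hindered_asymmetric_aryl_two_configurations(self, space):
        lig = build_nhc(space, ortho=("tert-butyl", None),
                        backbone=("tert-butyl", None))
        configs = expand_configurations(lig)
        # 2x2 orientations collapse to syn/anti under the N<->N' swap
        # and the global flip
        assert len(configs) == 2
        keys = {canonical_key(c) for c in configs}
        assert len(keys) == 2
        prefixes = {k.split("|")[0] for k in keys}
        assert len(prefixes) == 1  # shared constitution prefix

    def test_orientation_orbits_match_brute_force(self, space):
        """Orbit collapse equals explicit enumeration over the
        automorphism group {site swap} x {global flip}."""
        lig = build_nhc(space, ortho=("tert-butyl", None),
                        backbone=("tert-butyl", None))
        labelings = list(itertools.product((0, 1), repeat=2))
        seen = []
        for lab in labelings:
            orbit = {lab, lab[::-1],
                     tuple(1 - b for b in lab), tuple(1 - b for b in lab[::-1])}
            if not any(o in seen for o in orbit):
                seen.append(lab)
        assert len(expand_configurations(lig)) == len(seen)


class TestOrbitCanonicalization:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        labels=st.lists(st.integers(0, 1), min_size=2, max_size=6),
        seed=st.integers(0, 10_000),
    )
    @settings(derandomize=True, max_examples=60)
    def test_canonical_form_invariant_under_group_action(self, labels, seed):
        """The orientation-orbit representative is unchanged by block
        permutations and the global flip (molecular automorphisms)."""
        from nhcdesign.fragments import _orbit_canonical

        labels = tuple(labels)
        rng = np.random.default_rng(seed)
        # random block structure over the sites
        cutpoints = sorted(
            rng.choice(range(1, len(labels)), size=min(2, len(labels) - 1), replace=False)
        )
        idx = list(range(len(labels)))
        blocks, prev = [], 0
        for c in [*cutpoints, len(labels)]:
            blocks.append(idx[prev:c])
            prev = c
        base = _orbit_canonical(labels, blocks)
        # flip
        assert _orbit_canonical(tuple(1 - b for b in labels), blocks) == base
        # permute within one block
        perm = list(labels)
        blk = blocks[int(rng.integers(len(blocks)))]
        shuffled = list(rng.permutation(blk))
        for i, j in zip(blk, shuffled):
            perm[i] = labels[j]
        assert _orbit_canonical(tuple(perm), blocks) == base
        # idempotence
        assert _orbit_canonical(base, blocks) == base


class TestCanonicalKey:
    def test_distinct_constitutions_distinct_keys(self, space):
        rng = np.random.default_rng(5)
        ligs, keys = [], []
        while len(ligs) < 30:
            lig = random_ligand(space, rng)
            k = canonical_key(lig)
            if k not in keys:
                ligs.append(lig)
                keys.append(k)
        # cross-check distinctness with RDKit isomorphism (substructure
        # match both ways on the assembled molecules)
        mols = [l.to_mol() for l in ligs]
        for i in range(len(mols)):
            for j in range(i + 1, len(mols)):
                same = mols[i].GetNumAtoms() == mols[j].GetNumAtoms() and mols[
                    i
                ].HasSubstructMatch(mols[j]) and mols[j].HasSubstructMatch(mols[i])
                assert not same, (keys[i], keys[j])

    def test_ortho_pair_order_is_not_a_new_constitution(self, space):
        a = build_nhc(space, ortho=("methyl", "tert-butyl"))
        b = build_nhc(space, ortho=("tert-butyl", "methyl"))
        assert canonical_key(a) == canonical_key(b)

    def test_cap_remaining_mandatory_site_errors(self, space):
        lig = LigandGraph.empty(space)
        with pytest.raises(FragmentSpaceError, match="mandatory"):
            cap_remaining(lig)
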