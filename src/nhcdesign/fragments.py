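"""Fragment spaces and ligand graphs for NHC ligand design.

A fragment space is a combinatorial definition of a ligand chemistry:
scaffolds, substituents and cappings (each an RDKit molecule carrying
annotated attachment points), a compatibility map saying which
attachment-point classes may bond to which, and symmetry groups --
named sets of scaffold attachment points that must carry identical
substituent subtrees (e.g. the two N atoms of an imidazolidin-2-ylidene,
which must bear the same aryl group).

A candidate ligand is a rooted tree of fragment instances
(:class:`LigandGraph`).  Its chemical identity is canonicalized through
the canonical SMILES of the assembled molecule, optionally suffixed with
an atropisomer-like configuration label for N-aryl groups whose rotation
is hindered by backbone substitution.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import yaml
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "AttachmentPoint",
    "Fragment",
    "FragmentSpace",
    "LigandGraph",
    "Subtree",
    "EnumerationResult",
    "FragmentSpaceError",
    "load_fragment_space",
    "grow",
    "cap_remaining",
    "enumerate_space",
    "expand_configurations",
    "canonical_key",
]

#: Wildcard attachment-point class carried by the built-in hydrogen capping.
WILDCARD_CLASS = "*"

HYDROGEN_NAME = "H"


class FragmentSpaceError(ValueError):
    """Raised for malformed libraries, rules, or illegal build steps."""


@dataclass(frozen=True)
class AttachmentPoint:
    """A substitutable position on a fragment.

    ``owner_atom`` indexes the atom (0-based) that currently carries an
    implicit hydrogen in the free fragment; attaching a partner fragment
    replaces that hydrogen by a bond of order ``bond_order``.
    """

    owner_atom: int
    ap_class: str
    bond_order: int = 1

    def __post_init__(self) -> None:
        if not self.ap_class:
            raise FragmentSpaceError("attachment point with empty ap_class")
        if self.bond_order not in (1, 2, 3):
            raise FragmentSpaceError(
                f"attachment point bond order must be 1-3, got {self.bond_order}"
            )


@dataclass(frozen=True)
class Fragment:
    """A molecular building block with annotated attachment points."""

    name: str
    mol: Chem.Mol = field(compare=False, repr=False)
    aps: tuple[AttachmentPoint, ...]
    role: str  # scaffold | substituent | capping

    def __post_init__(self) -> None:
        n = self.mol.GetNumAtoms()
        for ap in self.aps:
            if not (0 <= ap.owner_atom < n):
                raise FragmentSpaceError(
                    f"fragment {self.name!r}: attachment point atom "
                    f"{ap.owner_atom} out of range (fragment has {n} atoms)"
                )
        if self.role == "substituent" and not self.aps:
            raise FragmentSpaceError(
                f"substituent fragment {self.name!r} has no attachment point"
            )
        if self.role == "capping" and len(self.aps) != 1:
            raise FragmentSpaceError(
                f"capping fragment {self.name!r} must have exactly 1 "
                f"attachment point, has {len(self.aps)}"
            )
        if self.role not in ("scaffold", "substituent", "capping"):
            raise FragmentSpaceError(f"unknown fragment role {self.role!r}")


def _hydrogen_capping() -> Fragment:
    mol = Chem.MolFromSmiles("[H]", sanitize=False)
    mol.UpdatePropertyCache(strict=False)
    return Fragment(
        name=HYDROGEN_NAME,
        mol=mol,
        aps=(AttachmentPoint(0, WILDCARD_CLASS, 1),),
        role="capping",
    )


@dataclass(frozen=True)
class FragmentSpace:
    """A validated fragment space.

    ``symmetry_groups`` maps scaffold name -> group name -> tuple of
    scaffold AP indices.  Scaffold APs not claimed by any group are
    wrapped in implicit singleton groups named ``ap<i>``.
    ``site_classes`` maps ap_class -> a semantic site label used by the
    descriptor model and the hindered-rotation rule (``backbone``,
    ``ortho``, ``meta_para``, ``n_aryl``, ...).
    """

    scaffolds: tuple[Fragment, ...]
    substituents: tuple[Fragment, ...]
    cappings: tuple[Fragment, ...]
    compatibility: Mapping[str, frozenset[str]]
    symmetry_groups: Mapping[str, Mapping[str, tuple[int, ...]]]
    site_classes: Mapping[str, str] = field(default_factory=dict)
    default_capping: Mapping[str, str] = field(default_factory=dict)
    mandatory_classes: frozenset[str] = frozenset()
    hindered_rotation: bool = True

    # ------------------------------------------------------------------ #
    def __post_init__(self) -> None:
        names = [f.name for f in (*self.scaffolds, *self.substituents, *self.cappings)]
        if len(set(names)) != len(names):
            raise FragmentSpaceError("duplicate fragment names in libraries")
        for frag in (*self.substituents, *self.cappings):
            root = frag.aps[0]
            partners = {
                c for cs in self.compatibility.values() for c in cs
            }
            if root.ap_class not in partners and root.ap_class != WILDCARD_CLASS:
                raise FragmentSpaceError(
                    f"unclosed compatibility map: root ap_class "
                    f"{root.ap_class!r} of fragment {frag.name!r} is not an "
                    f"allowed partner of any site class"
                )
            for ap in frag.aps[1:]:
                if ap.ap_class not in self.compatibility:
                    raise FragmentSpaceError(
                        f"unclosed compatibility map: ap_class {ap.ap_class!r} "
                        f"of fragment {frag.name!r} has no entry"
                    )
        for sc in self.scaffolds:
            for ap in sc.aps:
                if ap.ap_class not in self.compatibility:
                    raise FragmentSpaceError(
                        f"unclosed compatibility map: scaffold ap_class "
                        f"{ap.ap_class!r} has no entry"
                    )
            groups = self.symmetry_groups.get(sc.name, {})
            seen: set[int] = set()
            for gname, members in groups.items():
                for idx in members:
                    if not (0 <= idx < len(sc.aps)):
                        raise FragmentSpaceError(
                            f"symmetry group {gname!r} references AP {idx} "
                            f"outside scaffold {sc.name!r}"
                        )
                    if idx in seen:
                        raise FragmentSpaceError(
                            f"scaffold AP {idx} appears in two symmetry groups"
                        )
                    seen.add(idx)
                classes = {sc.aps[i].ap_class for i in members}
                if len(classes) != 1:
                    raise FragmentSpaceError(
                        f"symmetry group {gname!r} mixes ap_classes {classes}"
                    )

    # ------------------------------------------------------------------ #
    def fragment(self, name: str) -> Fragment:
        for frag in (*self.scaffolds, *self.substituents, *self.cappings):
            if frag.name == name:
                return frag
        if name == HYDROGEN_NAME:
            return _hydrogen_capping()
        raise KeyError(name)

    def scaffold(self, name: str) -> Fragment:
        for frag in self.scaffolds:
            if frag.name == name:
                return frag
        raise KeyError(name)

    def groups_for(self, scaffold: str) -> dict[str, tuple[int, ...]]:
        """All slot groups of a scaffold, including implicit singletons."""
        sc = self.scaffold(scaffold)
        groups = dict(self.symmetry_groups.get(scaffold, {}))
        claimed = {i for m in groups.values() for i in m}
        for i in range(len(sc.aps)):
            if i not in claimed:
                groups[f"ap{i}"] = (i,)
        return groups

    def group_class(self, scaffold: str, group: str) -> str:
        sc = self.scaffold(scaffold)
        members = self.groups_for(scaffold)[group]
        return sc.aps[members[0]].ap_class

    def cappings_for(self, ap_class: str) -> tuple[Fragment, ...]:
        """Cappings usable at a site class; the default capping comes first.

        A class listed in ``mandatory_classes`` must carry a substituent,
        so no capping applies."""
        if ap_class in self.mandatory_classes:
            return ()
        allowed = self.compatibility.get(ap_class, frozenset())
        out = [
            c
            for c in self.cappings
            if c.aps[0].ap_class in allowed or c.aps[0].ap_class == WILDCARD_CLASS
        ]
        if not any(c.name == HYDROGEN_NAME for c in out):
            out.insert(0, _hydrogen_capping())
        default = self.default_capping.get(ap_class, HYDROGEN_NAME)
        out.sort(key=lambda c: c.name != default)
        return tuple(out)

    def substituents_for(self, ap_class: str) -> tuple[Fragment, ...]:
        allowed = self.compatibility.get(ap_class, frozenset())
        return tuple(
            s for s in self.substituents if any(ap.ap_class in allowed for ap in s.aps)
        )

    def root_ap_index(self, fragment: Fragment, ap_class: str) -> int:
        """Index of the AP through which ``fragment`` binds a site of
        ``ap_class``; raises on class mismatch."""
        allowed = self.compatibility.get(ap_class, frozenset())
        for i, ap in enumerate(fragment.aps):
            if ap.ap_class in allowed or ap.ap_class == WILDCARD_CLASS:
                return i
        raise FragmentSpaceError(
            f"class mismatch: fragment {fragment.name!r} has no attachment "
            f"point compatible with site class {ap_class!r}"
        )


# ---------------------------------------------------------------------- #
# Ligand graphs
# ---------------------------------------------------------------------- #


@dataclass(frozen=True)
class Subtree:
    """A fragment instance plus what is attached to its remaining APs.

    ``root_ap`` is the AP through which this instance binds its parent.
    ``children`` maps each *other* AP index to its subtree; an AP index
    missing from ``children`` is an open site.
    """

    fragment: str
    root_ap: int
    children: tuple[tuple[int, "Subtree"], ...] = ()

    def child(self, ap_index: int) -> Optional["Subtree"]:
        for i, st in self.children:
            if i == ap_index:
                return st
        return None

    def with_child(self, ap_index: int, st: "Subtree") -> "Subtree":
        items = dict(self.children)
        items[ap_index] = st
        return replace(self, children=tuple(sorted(items.items())))


Site = tuple[str, tuple[int, ...]]
"""Address of an attachment site: (group name, path of AP indices).

An empty path addresses the scaffold slot of the group itself; each
further element descends into the subtree through that AP index.
"""


@dataclass(frozen=True)
class LigandGraph:
    """A candidate ligand: scaffold plus one subtree per slot group.

    Because all members of a symmetry group share a single assignment,
    the symmetry constraint (identical subtrees on grouped sites) holds
    by construction, and any edit below a grouped site is mirrored
    automatically.
    """

    space: FragmentSpace = field(compare=False, repr=False)
    scaffold: str = "scaffold"
    assignments: tuple[tuple[str, Optional[Subtree]], ...] = ()
    config: tuple[int, ...] = ()

    # ------------------------------------------------------------------ #
    @classmethod
    def empty(cls, space: FragmentSpace, scaffold: Optional[str] = None) -> "LigandGraph":
        name = scaffold or space.scaffolds[0].name
        groups = sorted(space.groups_for(name))
        return cls(
            space=space,
            scaffold=name,
            assignments=tuple((g, None) for g in groups),
        )

    def assignment(self, group: str) -> Optional[Subtree]:
        for g, st in self.assignments:
            if g == group:
                return st
        raise KeyError(group)

    def with_assignment(self, group: str, st: Optional[Subtree]) -> "LigandGraph":
        items = dict(self.assignments)
        if group not in items:
            raise KeyError(group)
        items[group] = st
        return replace(self, assignments=tuple(sorted(items.items())))

    # ------------------------------------------------------------------ #
    def open_sites(self) -> list[Site]:
        """All unassigned sites, in deterministic (group, path) order."""
        out: list[Site] = []
        for group, st in self.assignments:
            if st is None:
                out.append((group, ()))
            else:
                out.extend(
                    (group, path) for path in _open_paths(self.space, st, ())
                )
        return out

    def is_complete(self) -> bool:
        return not self.open_sites()

    def validate(self) -> None:
        """Raise unless every site is assigned (bonded or capped)."""
        missing = self.open_sites()
        if missing:
            raise FragmentSpaceError(f"ligand has open sites: {missing[:4]}")

    # ------------------------------------------------------------------ #
    def to_mol(self) -> Chem.Mol:
        return _assemble(self)

    @property
    def key(self) -> str:
        return canonical_key(self)


def _open_paths(
    space: FragmentSpace, st: Subtree, prefix: tuple[int, ...]
) -> Iterable[tuple[int, ...]]:
    frag = space.fragment(st.fragment)
    assigned = dict(st.children)
    for i in range(len(frag.aps)):
        if i == st.root_ap:
            continue
        if i in assigned:
            yield from _open_paths(space, assigned[i], prefix + (i,))
        else:
            yield prefix + (i,)


def _site_class(space: FragmentSpace, ligand: LigandGraph, site: Site) -> str:
    group, path = site
    if not path:
        return space.group_class(ligand.scaffold, group)
    st = ligand.assignment(group)
    if st is None:
        raise FragmentSpaceError(f"site {site} unreachable: group slot empty")
    for ap_index in path[:-1]:
        nxt = st.child(ap_index)
        if nxt is None:
            raise FragmentSpaceError(f"site {site} unreachable: open intermediate AP")
        st = nxt
    return space.fragment(st.fragment).aps[path[-1]].ap_class


# ---------------------------------------------------------------------- #
# Building operations
# ---------------------------------------------------------------------- #


def grow(ligand: LigandGraph, site: Site, fragment: Fragment | str) -> LigandGraph:
    """Attach ``fragment`` at ``site``, mirroring across the symmetry group.

    Because grouped scaffold slots share one assignment, installing a
    fragment at any member installs the identical subtree at all of
    them atomically.
    """
    space = ligand.space
    frag = space.fragment(fragment) if isinstance(fragment, str) else fragment
    group, path = site
    ap_class = _site_class(space, ligand, site)
    root = space.root_ap_index(frag, ap_class)  # raises "class mismatch"
    new = Subtree(fragment=frag.name, root_ap=root)
    if not path:
        if ligand.assignment(group) is not None:
            raise FragmentSpaceError(f"site occupied: {site}")
        return ligand.with_assignment(group, new)
    st = ligand.assignment(group)
    updated = _install(st, path, new)
    return ligand.with_assignment(group, updated)


def _install(st: Subtree, path: tuple[int, ...], new: Subtree) -> Subtree:
    head, rest = path[0], path[1:]
    if not rest:
        if st.child(head) is not None:
            raise FragmentSpaceError(f"site occupied: AP {head} of {st.fragment}")
        return st.with_child(head, new)
    nxt = st.child(head)
    if nxt is None:
        raise FragmentSpaceError(f"unreachable site: AP {head} of {st.fragment} is open")
    return st.with_child(head, _install(nxt, rest, new))


def prune(ligand: LigandGraph, site: Site) -> LigandGraph:
    """Remove the subtree at ``site`` (all symmetry-group copies)."""
    group, path = site
    if not path:
        return ligand.with_assignment(group, None)
    st = ligand.assignment(group)
    return ligand.with_assignment(group, _remove(st, path))


def _remove(st: Subtree, path: tuple[int, ...]) -> Subtree:
    head, rest = path[0], path[1:]
    if not rest:
        items = dict(st.children)
        items.pop(head, None)
        return replace(st, children=tuple(sorted(items.items())))
    return st.with_child(head, _remove(st.child(head), rest))


def cap_remaining(ligand: LigandGraph) -> LigandGraph:
    """Fill every open site with its default capping (hydrogen unless
    overridden by the rules file)."""
    space = ligand.space
    while True:
        sites = ligand.open_sites()
        if not sites:
            return ligand
        for site in sites:
            ap_class = _site_class(space, ligand, site)
            caps = space.cappings_for(ap_class)
            if not caps:
                raise FragmentSpaceError(
                    f"site {site} of mandatory class {ap_class!r} is open and "
                    f"cannot be capped; install a substituent first"
                )
            ligand = grow(ligand, site, caps[0])


# ---------------------------------------------------------------------- #
# Molecule assembly and canonical keys
# ---------------------------------------------------------------------- #


def _add_bond(rw: Chem.RWMol, a: int, b: int, order: int) -> None:
    """Bond two atoms, consuming an explicit hydrogen count where one is
    recorded (implicit hydrogens adjust automatically on sanitization)."""
    rw.AddBond(a, b, _BOND_TYPES[order])
    for idx in (a, b):
        atom = rw.GetAtomWithIdx(idx)
        if atom.GetNumExplicitHs() > 0:
            atom.SetNumExplicitHs(max(0, atom.GetNumExplicitHs() - order))


def _assemble(ligand: LigandGraph) -> Chem.Mol:
    space = ligand.space
    sc = space.scaffold(ligand.scaffold)
    rw = Chem.RWMol(sc.mol)
    groups = space.groups_for(ligand.scaffold)

    def attach(parent_atom: int, bond_order: int, st: Subtree) -> None:
        frag = space.fragment(st.fragment)
        offset = rw.GetNumAtoms()
        rw.InsertMol(frag.mol)
        root_atom = offset + frag.aps[st.root_ap].owner_atom
        _add_bond(rw, parent_atom, root_atom, bond_order)
        for ap_index, child in st.children:
            ap = frag.aps[ap_index]
            attach(offset + ap.owner_atom, ap.bond_order, child)

    for group, st in ligand.assignments:
        if st is None:
            raise FragmentSpaceError(f"cannot assemble: group {group!r} unassigned")
        for ap_index in groups[group]:
            ap = sc.aps[ap_index]
            attach(ap.owner_atom, ap.bond_order, st)

    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return Chem.RemoveHs(mol)


_BOND_TYPES = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}


def constitution_smiles(ligand: LigandGraph) -> str:
    return Chem.MolToSmiles(ligand.to_mol())


def canonical_key(ligand: LigandGraph) -> str:
    """Build-order-independent identity string.

    The constitution prefix is the canonical SMILES of the assembled
    molecule; configurations of one constitution share the prefix and
    differ in the orientation suffix.
    """
    prefix = constitution_smiles(ligand)
    if ligand.config:
        bits = "".join(str(b) for b in ligand.config)
        return f"{prefix}|cfg:{bits}"
    return prefix


def subtree_key(space: FragmentSpace, st: Subtree, parent_order: int = 1) -> str:
    """Canonical SMILES of a subtree as a standalone radical-marked group."""
    rw = Chem.RWMol()
    star = rw.AddAtom(Chem.Atom(0))  # dummy marks the attachment vector

    def attach(parent_atom: int, order: int, sub: Subtree) -> None:
        frag = space.fragment(sub.fragment)
        offset = rw.GetNumAtoms()
        rw.InsertMol(frag.mol)
        _add_bond(rw, parent_atom, offset + frag.aps[sub.root_ap].owner_atom, order)
        for ap_index, child in sub.children:
            ap = frag.aps[ap_index]
            attach(offset + ap.owner_atom, ap.bond_order, child)

    attach(star, parent_order, st)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(Chem.RemoveHs(mol))


# ---------------------------------------------------------------------- #
# Enumeration
# ---------------------------------------------------------------------- #


@dataclass
class EnumerationResult:
    ligands: list[LigandGraph]
    count: int
    truncated: bool = False


def _complete_subtrees(
    space: FragmentSpace,
    ap_class: str,
    depth: int,
    max_depth: int,
    cache: dict[str, list[Subtree]],
) -> list[Subtree]:
    if ap_class in cache:
        return cache[ap_class]
    if depth > max_depth:
        raise FragmentSpaceError(
            f"fragment space recurses deeper than {max_depth} levels at "
            f"ap_class {ap_class!r}; the space is unbounded or max_depth too small"
        )
    options: list[Subtree] = []
    for cap in space.cappings_for(ap_class):
        options.append(Subtree(fragment=cap.name, root_ap=0))
    for sub in space.substituents_for(ap_class):
        root = space.root_ap_index(sub, ap_class)
        open_aps = [i for i in range(len(sub.aps)) if i != root]
        child_options = [
            _complete_subtrees(
                space, sub.aps[i].ap_class, depth + 1, max_depth, cache
            )
            for i in open_aps
        ]
        for combo in itertools.product(*child_options):
            options.append(
                Subtree(
                    fragment=sub.name,
                    root_ap=root,
                    children=tuple(sorted(zip(open_aps, combo))),
                )
            )
    cache[ap_class] = options
    return options


def enumerate_space(
    space: FragmentSpace,
    collapse_configurations: bool = True,
    limit: Optional[int] = None,
    max_depth: int = 8,
) -> EnumerationResult:
    """Enumerate every distinct ligand of the space exactly once.

    Distinctness is decided on the canonical key of the assembled
    molecule, so raw assignments that differ only by a molecular
    automorphism (e.g. swapping the two ortho positions of an N-aryl)
    collapse to one candidate.  The traversal is depth-first over
    library order, so the emitted stream is deterministic.

    When ``limit`` is hit the result is flagged ``truncated``; the count
    of a truncated result equals the number of ligands emitted.
    """
    out: list[LigandGraph] = []
    seen: set[str] = set()
    cache: dict[str, list[Subtree]] = {}
    truncated = False

    for sc in space.scaffolds:
        groups = sorted(space.groups_for(sc.name))
        per_group = [
            _complete_subtrees(space, space.group_class(sc.name, g), 0, max_depth, cache)
            for g in groups
        ]
        base = LigandGraph.empty(space, sc.name)
        for combo in itertools.product(*per_group):
            ligand = base
            for g, st in zip(groups, combo):
                ligand = ligand.with_assignment(g, st)
            if collapse_configurations:
                candidates = [ligand]
            else:
                candidates = expand_configurations(ligand)
            for cand in candidates:
                key = canonical_key(cand)
                if key in seen:
                    continue
                seen.add(key)
                out.append(cand)
                if limit is not None and len(out) >= limit:
                    truncated = True
                    break
            if truncated:
                break
        if truncated:
            break

    return EnumerationResult(ligands=out, count=len(out), truncated=truncated)


# ---------------------------------------------------------------------- #
# Configurations (hindered N-aryl rotation)
# ---------------------------------------------------------------------- #


def _is_default_capping(space: FragmentSpace, st: Subtree, ap_class: str) -> bool:
    caps = space.cappings_for(ap_class)
    return st.children == () and caps and st.fragment == caps[0].name


def _has_backbone_substituent(ligand: LigandGraph) -> bool:
    space = ligand.space
    for group, st in ligand.assignments:
        if st is None:
            continue
        ap_class = space.group_class(ligand.scaffold, group)
        if space.site_classes.get(ap_class) != "backbone":
            continue
        if not _is_default_capping(space, st, ap_class):
            return True
    return False


def _aryl_asymmetric(space: FragmentSpace, st: Subtree) -> bool:
    """True when the two ortho positions of an N-aryl subtree differ."""
    frag = space.fragment(st.fragment)
    ortho_keys = []
    for i, ap in enumerate(frag.aps):
        if i == st.root_ap:
            continue
        if space.site_classes.get(ap.ap_class) != "ortho":
            continue
        child = st.child(i)
        ortho_keys.append(subtree_key(space, child, ap.bond_order) if child else None)
    return len(ortho_keys) == 2 and ortho_keys[0] != ortho_keys[1]


def hindered_aryl_sites(ligand: LigandGraph) -> list[tuple[str, int]]:
    """(group, member index) pairs carrying a hindered asymmetric N-aryl.

    Rotation about the N-aryl bond is taken as hindered iff the backbone
    bears at least one non-hydrogen substituent; only then do asymmetric
    aryls (distinct ortho substituents) give isolable orientations.
    """
    space = ligand.space
    if not space.hindered_rotation or not _has_backbone_substituent(ligand):
        return []
    sites: list[tuple[str, int]] = []
    groups = space.groups_for(ligand.scaffold)
    for group, st in sorted(ligand.assignments):
        if st is None:
            continue
        ap_class = space.group_class(ligand.scaffold, group)
        if space.site_classes.get(ap_class) != "n_aryl":
            continue
        if _aryl_asymmetric(space, st):
            sites.extend((group, m) for m in range(len(groups[group])))
    return sites


def _orbit_canonical(labels: tuple[int, ...], blocks: list[list[int]]) -> tuple[int, ...]:
    """Minimal representative under per-block permutations and global flip.

    Members of one symmetry group hold identical subtrees on equivalent
    scaffold positions, so permuting their orientation labels is a
    molecular automorphism; flipping every label corresponds to turning
    the whole molecule over.
    """
    best = None
    for flip in (False, True):
        cur = tuple(1 - b for b in labels) if flip else labels
        canon = list(cur)
        for block in blocks:
            vals = sorted(canon[i] for i in block)
            for i, v in zip(block, vals):
                canon[i] = v
        t = tuple(canon)
        if best is None or t < best:
            best = t
    return best


def expand_configurations(ligand: LigandGraph) -> list[LigandGraph]:
    """All distinct N-aryl orientation configurations of a constitution.

    Returns the ligand itself (one configuration) when rotation is
    unhindered or every aryl is symmetric; otherwise enumerates binary
    orientation labels over the hindered sites and collapses duplicates
    related by molecular automorphisms (site swaps within a symmetry
    group, global flip).
    """
    sites = hindered_aryl_sites(ligand)
    if not sites:
        return [replace(ligand, config=())]
    blocks: dict[str, list[int]] = {}
    for pos, (group, _m) in enumerate(sites):
        blocks.setdefault(group, []).append(pos)
    block_list = list(blocks.values())
    reps: set[tuple[int, ...]] = set()
    for labels in itertools.product((0, 1), repeat=len(sites)):
        reps.add(_orbit_canonical(labels, block_list))
    return [replace(ligand, config=rep) for rep in sorted(reps)]


# ---------------------------------------------------------------------- #
# Random construction
# ---------------------------------------------------------------------- #


def random_subtree(
    space: FragmentSpace,
    ap_class: str,
    rng,
    depth: int = 0,
    max_depth: int = 8,
    p_substituent: float = 0.5,
) -> Subtree:
    """Draw a random complete subtree for a site class.

    With probability ``p_substituent`` a substituent is installed (its
    own sites filled recursively), otherwise a capping; at ``max_depth``
    only cappings are drawn so the draw always terminates.
    """
    caps = space.cappings_for(ap_class)
    subs = space.substituents_for(ap_class)
    if not caps and not subs:
        raise FragmentSpaceError(f"no fragment available for class {ap_class!r}")
    use_sub = bool(subs) and (
        not caps or (depth < max_depth and rng.random() < p_substituent)
    )
    if not use_sub:
        cap = caps[int(rng.integers(len(caps)))]
        return Subtree(fragment=cap.name, root_ap=0)
    sub = subs[int(rng.integers(len(subs)))]
    root = space.root_ap_index(sub, ap_class)
    children = []
    for i, ap in enumerate(sub.aps):
        if i == root:
            continue
        children.append(
            (i, random_subtree(space, ap.ap_class, rng, depth + 1, max_depth, p_substituent))
        )
    return Subtree(fragment=sub.name, root_ap=root, children=tuple(sorted(children)))


def random_ligand(space: FragmentSpace, rng, scaffold: Optional[str] = None) -> LigandGraph:
    """Draw a random complete ligand (one random subtree per slot group)."""
    name = scaffold or space.scaffolds[int(rng.integers(len(space.scaffolds)))].name
    ligand = LigandGraph.empty(space, name)
    for group in sorted(space.groups_for(name)):
        ap_class = space.group_class(name, group)
        ligand = ligand.with_assignment(group, random_subtree(space, ap_class, rng))
    return ligand


# ---------------------------------------------------------------------- #
# Library loading
# ---------------------------------------------------------------------- #

_AP_PROP = "ATTACHMENT_POINTS"
_ROLE_PROP = "ROLE"


def _parse_record(mol: Chem.Mol, path: str, index: int) -> Fragment:
    name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"record{index}"
    where = f"{path} record {index} ({name!r})"
    if not mol.HasProp(_ROLE_PROP):
        raise FragmentSpaceError(f"missing ROLE property in {where}")
    role = mol.GetProp(_ROLE_PROP).strip()
    aps: list[AttachmentPoint] = []
    if mol.HasProp(_AP_PROP):
        for line in mol.GetProp(_AP_PROP).splitlines():
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 3:
                raise FragmentSpaceError(
                    f"malformed attachment point line {line!r} in {where}: "
                    f"expected '<atom_index> <ap_class> <bond_order>'"
                )
            try:
                atom, order = int(parts[0]), int(parts[2])
            except ValueError as exc:
                raise FragmentSpaceError(
                    f"malformed attachment point line {line!r} in {where}: {exc}"
                ) from None
            aps.append(AttachmentPoint(atom, parts[1], order))
    try:
        return Fragment(name=name, mol=mol, aps=tuple(aps), role=role)
    except FragmentSpaceError as exc:
        raise FragmentSpaceError(f"{exc} (in {where})") from None


def load_fragment_space(
    library_files: Sequence[str | Path],
    rules: str | Path | Mapping,
) -> FragmentSpace:
    """Load SDF fragment libraries plus a YAML/JSON rules file.

    Each SDF record carries a ``ROLE`` property (scaffold / substituent /
    capping) and an ``ATTACHMENT_POINTS`` property with one line per AP:
    ``<atom_index> <ap_class> <bond_order>`` (0-based atom indices).
    """
    if isinstance(rules, (str, Path)):
        with open(rules) as fh:
            rules_data = yaml.safe_load(fh)
    else:
        rules_data = dict(rules)

    scaffolds: list[Fragment] = []
    substituents: list[Fragment] = []
    cappings: list[Fragment] = []
    for path in library_files:
        supplier = Chem.SDMolSupplier(str(path), removeHs=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                raise FragmentSpaceError(f"unparseable record {i} in {path}")
            frag = _parse_record(mol, str(path), i)
            {"scaffold": scaffolds, "substituent": substituents, "capping": cappings}[
                frag.role
            ].append(frag)
    if not scaffolds:
        raise FragmentSpaceError("no scaffold fragment in libraries")

    compat = {
        k: frozenset(v) for k, v in (rules_data.get("compatibility") or {}).items()
    }
    sym = {
        sc: {g: tuple(m) for g, m in groups.items()}
        for sc, groups in (rules_data.get("symmetry_groups") or {}).items()
    }
    return FragmentSpace(
        scaffolds=tuple(scaffolds),
        substituents=tuple(substituents),
        cappings=tuple(cappings),
        compatibility=compat,
        symmetry_groups=sym,
        site_classes=dict(rules_data.get("site_classes") or {}),
        default_capping=dict(rules_data.get("default_capping") or {}),
        mandatory_classes=frozenset(rules_data.get("mandatory_classes") or ()),
        hindered_rotation=bool(rules_data.get("hindered_rotation", True)),
    )
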