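"""Programmatic fragment spaces for tests, with a plain-graph twin
representation that independent oracles can consume."""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
from rdkit import Chem

from nhcdesign.fragments import AttachmentPoint, Fragment, FragmentSpace


@dataclass
class PlainFragment:
    """Toolkit-free fragment: atom/bond lists plus attachment points."""

    name: str
    atoms: list[tuple[str, int]]  # (element, formal charge)
    bonds: list[tuple[int, int, int]]  # (i, j, order)
    aps: list[tuple[int, str, int]]  # (atom, ap_class, bond order)
    role: str


def _mol_from_plain(pf: PlainFragment) -> Chem.Mol:
    rw = Chem.RWMol()
    for elem, charge in pf.atoms:
        a = Chem.Atom(elem)
        a.SetFormalCharge(charge)
        rw.AddAtom(a)
    orders = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}
    for i, j, o in pf.bonds:
        rw.AddBond(i, j, orders[o])
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return mol


@dataclass
class PlainSpace:
    scaffold: PlainFragment
    substituents: list[PlainFragment]
    groups: dict[str, tuple[int, ...]]
    compat: dict[str, set[str]]
    mandatory: set[str] = field(default_factory=set)

    def to_fragment_space(self) -> FragmentSpace:
        def conv(pf: PlainFragment) -> Fragment:
            return Fragment(
                name=pf.name,
                mol=_mol_from_plain(pf),
                aps=tuple(AttachmentPoint(a, c, o) for a, c, o in pf.aps),
                role=pf.role,
            )

        return FragmentSpace(
            scaffolds=(conv(self.scaffold),),
            substituents=tuple(conv(s) for s in self.substituents),
            cappings=(),
            compatibility={k: frozenset(v) for k, v in self.compat.items()},
            symmetry_groups={self.scaffold.name: dict(self.groups)},
            site_classes={},
            mandatory_classes=frozenset(self.mandatory),
        )


# ---------------------------------------------------------------------- #
# Independent brute-force enumeration oracle (networkx graphs)
# ---------------------------------------------------------------------- #


def _root_ap(pf: PlainFragment, site_class: str, compat) -> int:
    allowed = compat.get(site_class, set())
    for k, (_a, cls, _o) in enumerate(pf.aps):
        if cls in allowed:
            return k
    raise ValueError("no compatible AP")


def _subtree_options(space: PlainSpace, site_class: str, depth=0):
    """All complete plain subtrees for a site class: None is the
    hydrogen capping (allowed unless the class is mandatory)."""
    if depth > 8:
        raise RecursionError("unbounded space")
    options = [] if site_class in space.mandatory else [None]
    allowed = space.compat.get(site_class, set())
    for si, sub in enumerate(space.substituents):
        if not any(cls in allowed for _a, cls, _o in sub.aps):
            continue
        root = _root_ap(sub, site_class, space.compat)
        child_sites = [k for k in range(len(sub.aps)) if k != root]
        child_opts = [
            _subtree_options(space, sub.aps[k][1], depth + 1) for k in child_sites
        ]
        for combo in itertools.product(*child_opts):
            options.append((si, root, tuple(zip(child_sites, combo))))
    return options


def _build_graph(space: PlainSpace, assignment) -> nx.Graph:
    g = nx.Graph()
    counter = itertools.count()

    def add_fragment(pf: PlainFragment):
        idx = {}
        for a, (elem, charge) in enumerate(pf.atoms):
            n = next(counter)
            idx[a] = n
            g.add_node(n, elem=elem, charge=charge)
        for i, j, o in pf.bonds:
            g.add_edge(idx[i], idx[j], order=o)
        return idx

    sc_idx = add_fragment(space.scaffold)

    def install(parent_node: int, order: int, tree):
        if tree is None:
            return
        si, root, children = tree
        sub = space.substituents[si]
        idx = add_fragment(sub)
        g.add_edge(parent_node, idx[sub.aps[root][0]], order=order)
        for k, child in children:
            a, _cls, o = sub.aps[k]
            install(idx[a], o, child)

    for gname, members in space.groups.items():
        tree = assignment[gname]
        for ap_i in members:
            a, _cls, o = space.scaffold.aps[ap_i]
            install(sc_idx[a], o, tree)
    return g


def _iso(g1: nx.Graph, g2: nx.Graph) -> bool:
    nm = nx.isomorphism.categorical_node_match(["elem", "charge"], ["", 0])
    em = nx.isomorphism.categorical_edge_match("order", 1)
    return nx.is_isomorphic(g1, g2, node_match=nm, edge_match=em)


def oracle_count(space: PlainSpace) -> int:
    """Brute-force constitution count: enumerate every per-group
    assignment, build the molecular graph, deduplicate by graph
    isomorphism (bucketed by a Weisfeiler-Lehman hash)."""
    gnames = sorted(space.groups)
    per_group = [
        _subtree_options(space, space.scaffold.aps[space.groups[g][0]][1])
        for g in gnames
    ]
    buckets: dict[str, list[nx.Graph]] = {}
    count = 0
    for combo in itertools.product(*per_group):
        assignment = dict(zip(gnames, combo))
        g = _build_graph(space, assignment)
        h = nx.weisfeiler_lehman_graph_hash(
            g, node_attr="elem", edge_attr="order", iterations=3
        )
        bucket = buckets.setdefault(h, [])
        if not any(_iso(g, other) for other in bucket):
            bucket.append(g)
            count += 1
    return count


# ---------------------------------------------------------------------- #
# Randomized space generator
# ---------------------------------------------------------------------- #

_ELEMENTS = ["C", "N", "O"]


def random_plain_space(rng, max_constitutions: int = 600) -> PlainSpace:
    """A random small fragment space (chain scaffold with grouped and
    ungrouped sites, substituents with occasional second-level sites)."""
    while True:
        n_sc = int(rng.integers(2, 5))
        atoms = [("C", 0) for _ in range(n_sc)]
        bonds = [(i, i + 1, 1) for i in range(n_sc - 1)]
        n_classes = int(rng.integers(1, 3))
        classes = [f"c{i}" for i in range(n_classes)]
        aps = []
        for i in range(n_sc):
            for _slot in range(int(rng.integers(1, 3))):
                aps.append((i, classes[int(rng.integers(n_classes))], 1))
        if len(aps) < 2:
            continue
        # group a random pair of same-class APs
        groups: dict[str, tuple[int, ...]] = {}
        by_class: dict[str, list[int]] = {}
        for k, (_a, cls, _o) in enumerate(aps):
            by_class.setdefault(cls, []).append(k)
        gi = 0
        used = set()
        for cls, members in by_class.items():
            if len(members) >= 2 and rng.random() < 0.7:
                pair = tuple(members[:2])
                groups[f"g{gi}"] = pair
                used.update(pair)
                gi += 1
        for k in range(len(aps)):
            if k not in used:
                groups[f"g{gi}"] = (k,)
                gi += 1

        scaffold = PlainFragment("scaf", atoms, bonds, aps, "scaffold")
        subs = []
        sub_classes = {f"s{i}" for i in range(n_classes)}
        compat = {c: {f"s{i}" for i in range(n_classes)} for c in classes}
        n_subs = int(rng.integers(2, 5))
        _VAL = {"C": 4, "N": 3, "O": 2}
        for j in range(n_subs):
            n_at = int(rng.integers(1, 4))
            s_atoms = [(str(rng.choice(_ELEMENTS)), 0)]
            s_bonds = []
            spare = [_VAL[s_atoms[0][0]] - 1]  # root bond consumes one
            for a in range(1, n_at):
                parents = [i for i in range(a) if spare[i] >= 1]
                if not parents:
                    break
                elem = str(rng.choice(_ELEMENTS))
                parent = int(rng.choice(parents))
                s_atoms.append((elem, 0))
                s_bonds.append((parent, a, 1))
                spare[parent] -= 1
                spare.append(_VAL[elem] - 1)
            root_cls = f"s{int(rng.integers(n_classes))}"
            s_aps = [(0, root_cls, 1)]
            # occasional nested site taking only terminal substituents
            last = len(s_atoms) - 1
            if last > 0 and spare[last] >= 1 and rng.random() < 0.3:
                s_aps.append((last, "leaf", 1))
                compat.setdefault("leaf", set()).add("s_leaf")
            subs.append(PlainFragment(f"sub{j}", s_atoms, s_bonds, s_aps, "substituent"))
        if any(len(f.aps) > 1 for f in subs):
            subs.append(PlainFragment("leafsub", [("O", 0)], [], [(0, "s_leaf", 1)], "substituent"))

        space = PlainSpace(scaffold, subs, groups, compat)
        # bound the raw product size
        try:
            sizes = [
                len(_subtree_options(space, space.scaffold.aps[m[0]][1]))
                for m in groups.values()
            ]
        except (RecursionError, ValueError):
            continue
        raw = 1
        for s in sizes:
            raw *= s
        if 2 <= raw <= max_constitutions:
            return space
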