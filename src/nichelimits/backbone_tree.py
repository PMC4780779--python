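"""Working phylogenies: newick I/O, backbone collapse, polytomy grafting, VCV.

The working phylogeny is built from a resolved source tree by retaining only a
set of well-supported backbone clades (the backbone spec), discarding
within-clade resolution, and pasting taxa without sequence data into the
resulting polytomies. Terminal branch lengths of grafted taxa follow one of
three schemes:

* ``EQUAL`` (scheme 1): after grafting, *every* branch length is set to 1;
* ``GLOBAL_MEAN`` (scheme 2): the arithmetic mean of all terminal branch
  lengths in the reference (source) tree;
* ``CLADE_MEAN`` (scheme 3): the mean terminal branch length of the sampled
  members of the clade the taxon is grafted into.

Internal branch lengths of the backbone are kept from the source tree under
schemes 2 and 3. Trees are ``dendropy.Tree`` objects throughout; polytomies
are first-class and never resolved.

Backbone spec grammar (indented plain text; '#' starts a comment)::

    CladeName state=C4
      members: sp1, sp2
      NestedClade state=mixed
        members: sp3

Nesting follows indentation; ``members:`` lines list the species whose
*smallest* containing clade is the current one.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import IO, Mapping

import dendropy
import numpy as np
import pandas as pd

from .errors import MonophylyError, TreeError

log = logging.getLogger(__name__)


class BranchLengthScheme(Enum):
    EQUAL = 1
    GLOBAL_MEAN = 2
    CLADE_MEAN = 3


# ---------------------------------------------------------------------------
# Newick I/O


def parse_newick(source: str | IO[str]) -> dendropy.Tree:
    """Parse a rooted newick tree (polytomies allowed, internal labels kept)."""
    if not isinstance(source, str):
        source = source.read()
    if "(" not in source and "\n" not in source:
        with open(source, "r", encoding="utf-8") as fh:
            source = fh.read()
    try:
        tree = dendropy.Tree.get(
            data=source,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"newick parse error: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise TreeError(f"duplicate leaf label(s): {', '.join(sorted(dupes))}")
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node and node.edge.length is not None and node.edge.length < 0:
            raise TreeError("negative branch length")
    tree.is_rooted = True
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialise a tree to newick (round-trip partner of :func:`parse_newick`)."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip() + "\n"


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _clone(tree: dendropy.Tree) -> dendropy.Tree:
    # Round-trip through newick: guarantees an independent taxon namespace.
    return parse_newick(write_newick(tree))


def is_ultrametric(tree: dendropy.Tree, rel_tol: float = 1e-6) -> bool:
    depths = _node_depths(tree)
    tip_depths = [depths[leaf] for leaf in tree.leaf_node_iter()]
    span = max(tip_depths) - min(tip_depths)
    return span <= rel_tol * max(max(tip_depths), 1e-300)


def _node_depths(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    """Depth from the root node (the root's own edge does not count)."""
    depths: dict[dendropy.Node, float] = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        length = node.edge.length
        if length is None:
            raise TreeError(f"undefined branch length above node {node.label or node.taxon}")
        depths[node] = depths[node.parent_node] + length
    return depths


# ---------------------------------------------------------------------------
# Backbone specification


@dataclass
class BackboneClade:
    name: str
    state: str = "mixed"  # C3 | C4 | mixed — descriptive only
    members: list[str] = field(default_factory=list)
    children: list["BackboneClade"] = field(default_factory=list)

    def full_species_set(self) -> set[str]:
        s = set(self.members)
        for child in self.children:
            s |= child.full_species_set()
        return s

    def iter_clades(self):
        yield self
        for child in self.children:
            yield from child.iter_clades()


@dataclass
class BackboneSpec:
    roots: list[BackboneClade]

    def iter_clades(self):
        for r in self.roots:
            yield from r.iter_clades()

    def validate(self) -> None:
        names = [c.name for c in self.iter_clades()]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise TreeError(f"duplicate clade name(s) in backbone spec: {sorted(dupes)}")
        seen_roots: set[str] = set()
        for root in self.roots:
            s = root.full_species_set()
            overlap = seen_roots & s
            if overlap:
                raise TreeError(
                    f"species {sorted(overlap)} appear in more than one "
                    "sibling clade at the top level"
                )
            seen_roots |= s
        for clade in self.iter_clades():
            sets = [c.full_species_set() for c in clade.children] + [set(clade.members)]
            seen: set[str] = set()
            for s in sets:
                overlap = seen & s
                if overlap:
                    raise TreeError(
                        f"species {sorted(overlap)} appear in more than one "
                        f"sibling clade under {clade.name!r}"
                    )
                seen |= s


def parse_backbone_spec(source: str | IO[str]) -> BackboneSpec:
    """Parse the indented backbone-spec text format (see module docstring)."""
    if not isinstance(source, str):
        source = source.read()
    if "\n" not in source and "state=" not in source:
        with open(source, "r", encoding="utf-8") as fh:
            source = fh.read()
    roots: list[BackboneClade] = []
    stack: list[tuple[int, BackboneClade]] = []
    for lineno, raw in enumerate(source.split("\n"), 1):
        line = raw.split("#", 1)[0].rstrip()
        if not line.strip():
            continue
        indent = len(line) - len(line.lstrip())
        body = line.strip()
        if body.startswith("members:"):
            if not stack or indent <= stack[-1][0]:
                raise TreeError(f"line {lineno}: members line without a clade")
            names = [m.strip() for m in body[len("members:"):].split(",") if m.strip()]
            stack[-1][1].members.extend(names)
            continue
        parts = body.split()
        name = parts[0]
        state = "mixed"
        for p in parts[1:]:
            if p.startswith("state="):
                state = p[len("state="):]
            else:
                raise TreeError(f"line {lineno}: unrecognised token {p!r}")
        if state not in ("C3", "C4", "mixed"):
            raise TreeError(f"line {lineno}: invalid state {state!r}")
        clade = BackboneClade(name=name, state=state)
        while stack and stack[-1][0] >= indent:
            stack.pop()
        if stack:
            stack[-1][1].children.append(clade)
        else:
            roots.append(clade)
        stack.append((indent, clade))
    spec = BackboneSpec(roots)
    spec.validate()
    return spec


def write_backbone_spec(spec: BackboneSpec, dest: str | IO[str]) -> None:
    buf = io.StringIO()

    def emit(clade: BackboneClade, indent: int) -> None:
        pad = " " * indent
        buf.write(f"{pad}{clade.name} state={clade.state}\n")
        if clade.members:
            buf.write(f"{pad}  members: {', '.join(clade.members)}\n")
        for child in clade.children:
            emit(child, indent + 2)

    for r in spec.roots:
        emit(r, 0)
    if isinstance(dest, str):
        with open(dest, "w", encoding="utf-8") as fh:
            fh.write(buf.getvalue())
    else:
        dest.write(buf.getvalue())


def read_assignments(source: str | IO[str]) -> dict[str, str]:
    """Read the species→clade assignment CSV for taxa to be grafted."""
    df = pd.read_csv(source, dtype=str)
    if not {"species", "clade"} <= set(df.columns):
        raise TreeError("assignment table needs columns species,clade")
    return dict(zip(df["species"].str.strip(), df["clade"].str.strip()))


def write_assignments(assignments: Mapping[str, str], dest: str | IO[str]) -> None:
    pd.DataFrame(
        sorted(assignments.items()), columns=["species", "clade"]
    ).to_csv(dest, index=False)


# ---------------------------------------------------------------------------
# Collapse and graft


def collapse_to_backbone(tree: dendropy.Tree, spec: BackboneSpec) -> dendropy.Tree:
    """Collapse a resolved tree to the nesting structure of the backbone spec.

    Each retained clade becomes a (potentially polytomous) node whose stem is
    the branch subtending the MRCA of its sampled members in the source tree;
    sampled direct members become terminal children keeping their original
    branch lengths; within-clade resolution is discarded. A clade whose
    sampled members reduce to a single leaf has no MRCA node in the source:
    its stem is set to 0 and the terminal keeps its length.
    """
    spec.validate()
    leaves = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    taxon_of = {leaf.taxon.label: leaf.taxon for leaf in tree.leaf_node_iter()}

    out = dendropy.Tree()
    out.is_rooted = True

    def build(clade: BackboneClade, parent_out: dendropy.Node) -> None:
        full = clade.full_species_set()
        sampled = sorted(full & leaves.keys())
        if not sampled:
            raise TreeError(f"clade {clade.name!r} has no sampled members in the tree")
        if len(sampled) == 1:
            mrca = leaves[sampled[0]]
            stem = 0.0
        else:
            mrca = tree.mrca(taxa=[taxon_of[s] for s in sampled])
            under = {l.taxon.label for l in mrca.leaf_iter()}
            intruders = under - full
            if intruders:
                raise MonophylyError(clade.name, intruders)
            stem = mrca.edge.length if mrca.edge.length is not None else 0.0
        node = parent_out.new_child(edge_length=stem)
        node.label = clade.name
        for member in clade.members:
            if member in leaves:
                term_len = leaves[member].edge.length
                child = node.new_child(edge_length=term_len)
                child.taxon = out.taxon_namespace.require_taxon(label=member)
        for sub in clade.children:
            build(sub, node)

    for root_clade in spec.roots:
        build(root_clade, out.seed_node)
    return out


def _terminal_lengths(tree: dendropy.Tree) -> list[float]:
    out = []
    for leaf in tree.leaf_node_iter():
        if leaf.edge.length is None:
            raise TreeError(f"terminal {leaf.taxon.label} has no branch length")
        out.append(leaf.edge.length)
    return out


def graft_taxa(
    tree: dendropy.Tree,
    assignments: Mapping[str, str],
    scheme: BranchLengthScheme,
    reference_tree: dendropy.Tree | None = None,
    clade_mean_fallback: bool = False,
) -> dendropy.Tree:
    """Paste unsequenced taxa into backbone polytomies under a length scheme.

    Returns a new tree; the input is untouched. ``reference_tree`` supplies
    the terminal branch lengths for ``GLOBAL_MEAN`` (defaults to ``tree``
    itself). Under ``CLADE_MEAN``, a clade with no sampled terminal children
    is an error unless ``clade_mean_fallback`` allows falling back to the
    global mean.
    """
    out = _clone(tree)
    clade_nodes = {
        node.label: node
        for node in out.preorder_node_iter()
        if node.label and not node.is_leaf()
    }
    existing = set(leaf_labels(out))

    # Per-clade means of *sampled* terminal children, frozen before grafting.
    clade_means: dict[str, float | None] = {}
    for name, node in clade_nodes.items():
        lens = [c.edge.length for c in node.child_nodes() if c.is_leaf()]
        clade_means[name] = float(np.mean(lens)) if lens else None
    ref = reference_tree if reference_tree is not None else tree
    global_mean = float(np.mean(_terminal_lengths(ref)))

    for species, clade_name in assignments.items():
        if clade_name not in clade_nodes:
            raise TreeError(f"unknown clade {clade_name!r} for grafted taxon {species!r}")
        if species in existing:
            raise TreeError(f"taxon {species!r} is already a leaf of the tree")
        if scheme is BranchLengthScheme.EQUAL:
            length = 1.0
        elif scheme is BranchLengthScheme.GLOBAL_MEAN:
            length = global_mean
        else:  # CLADE_MEAN
            mean = clade_means[clade_name]
            if mean is None:
                if not clade_mean_fallback:
                    raise TreeError(
                        f"clade {clade_name!r} has no sampled terminals for CLADE_MEAN"
                    )
                mean = global_mean
            length = mean
        child = clade_nodes[clade_name].new_child(edge_length=length)
        child.taxon = out.taxon_namespace.require_taxon(label=species)
        existing.add(species)

    if scheme is BranchLengthScheme.EQUAL:
        for node in out.preorder_node_iter():
            if node is not out.seed_node:
                node.edge.length = 1.0
    return out


# ---------------------------------------------------------------------------
# Covariance and clade extraction


def vcv_from_tree(tree: dendropy.Tree) -> pd.DataFrame:
    """Phylogenetic covariance matrix: V[i,j] = root-to-MRCA(i,j) path length.

    The diagonal holds root-to-tip distances; the root's own edge, if any,
    does not contribute. Returned as a labelled, symmetric DataFrame.
    """
    depths = _node_depths(tree)
    leaves = list(tree.leaf_node_iter())
    labels = [l.taxon.label for l in leaves]
    index = {l: i for i, l in enumerate(labels)}
    n = len(leaves)
    V = np.zeros((n, n))
    # Preorder: deeper nodes overwrite, leaving each pair with its MRCA depth.
    for node in tree.preorder_node_iter():
        tips = np.array([index[l.taxon.label] for l in node.leaf_iter()])
        V[np.ix_(tips, tips)] = depths[node]
    return pd.DataFrame(V, index=labels, columns=labels)


def find_clade_node(tree: dendropy.Tree, clade_name: str) -> dendropy.Node:
    if tree.seed_node.label == clade_name:
        return tree.seed_node
    for node in tree.preorder_node_iter():
        if node.label == clade_name:
            return node
    raise TreeError(f"no internal node labelled {clade_name!r}")


def _subtree_newick(node: dendropy.Node) -> str:
    def rec(nd: dendropy.Node) -> str:
        if nd.is_leaf():
            s = nd.taxon.label
        else:
            s = "(" + ",".join(rec(c) for c in nd.child_nodes()) + ")"
            if nd.label:
                s += nd.label
        if nd.edge.length is not None:
            s += f":{nd.edge.length!r}"
        return s

    if node.is_leaf():
        raise TreeError("cannot extract a single leaf as a clade")
    inner = "(" + ",".join(rec(c) for c in node.child_nodes()) + ")"
    if node.label:
        inner += node.label
    return inner + ";"


def extract_clade(tree: dendropy.Tree, clade_name: str) -> dendropy.Tree:
    """Subtree rooted at the named internal node, with its stem dropped."""
    node = find_clade_node(tree, clade_name)
    return parse_newick(_subtree_newick(node))
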