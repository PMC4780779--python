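"""Building a working phylogeny: backbone collapse and taxon grafting.

Many species in a contrast analysis lack sequence data. Starting from a
resolved tree of the sequenced species, this example collapses it to named
backbone clades and grafts unsequenced taxa into their clades under the three
branch-length schemes: (1) every branch set to one, (2) grafted terminals get
the global mean terminal length, (3) grafted terminals get their clade's mean
terminal length.
"""

from nichelimits import (
    BranchLengthScheme,
    collapse_to_backbone,
    graft_taxa,
    parse_backbone_spec,
    parse_newick,
    vcv_from_tree,
    write_newick,
)

source = parse_newick(
    "(((a:0.2,b:0.2):0.3,(c:0.1,d:0.1,e:0.1):0.4):0.5,((f:0.3,g:0.3):0.2,h:0.5):0.5);"
)

backbone = parse_backbone_spec(
    """
    Andropogoneae state=C4
      members: a, b, c, d, e
    Paniceae state=mixed
      members: f, g, h
    """
)

working = collapse_to_backbone(source, backbone)
print("collapsed backbone:", write_newick(working))

# two field-collected species without sequences, assigned to clades
assignments = {"new_taxon_1": "Andropogoneae", "new_taxon_2": "Paniceae"}

for scheme in BranchLengthScheme:
    grafted = graft_taxa(working, assignments, scheme, reference_tree=source)
    new1 = next(
        l for l in grafted.leaf_node_iter() if l.taxon.label == "new_taxon_1"
    )
    print(f"scheme {scheme.name}: grafted terminal length {new1.edge.length:.3f}")

# the grafted tree yields the covariance structure used by the PGLS stage
grafted = graft_taxa(
    working, assignments, BranchLengthScheme.CLADE_MEAN, reference_tree=source
)
V = vcv_from_tree(grafted)
print("covariance of new_taxon_1 with its clade siblings:")
print(V.loc["new_taxon_1", ["a", "b", "f"]].round(3).to_string())
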