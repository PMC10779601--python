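"""Membership statistics of a target-module bipartite network.

Builds a small endophenotype-style module catalog, forms the gene<->module
membership network, and ranks both sides by degree — the module-side degree
is module size, the gene-side degree counts how many pathological processes
a gene participates in.
"""

from endoprox import GeneSet, ModuleCatalog, build_bipartite, top_by_degree

catalog = ModuleCatalog(
    modules=[
        GeneSet("inflammatory_response", frozenset({"TNF", "IL6", "NFKB1", "TLR4", "CASP3"}),
                category="neuron inflammation"),
        GeneSet("neuron_apoptosis", frozenset({"CASP3", "BAX", "BCL2", "TNF"}),
                category="neuron apoptosis"),
        GeneSet("amyloid_processing", frozenset({"APP", "BACE1", "PSEN1", "CASP3"}),
                category="amyloidosis"),
        GeneSet("unfolded_protein_response", frozenset({"ERN1", "ATF6", "XBP1"}),
                category="endoplasmic reticulum stress"),
    ],
    source="example",
)

net = build_bipartite(catalog)
print(
    f"bipartite network: {net.n_pairs} gene-module pairs, "
    f"{net.n_genes} genes, {net.n_modules} modules"
)
print("\nconservation check: sum of gene degrees =",
      sum(net.gene_degree.values()), "= number of pairs")

print("\nmodules by size (n = number of member genes):")
for name, deg in top_by_degree(net, "module"):
    print(f"  {name:28s} n = {deg}")

print("\ngenes in >= 2 modules (D = number of processes they touch):")
for gene, deg in top_by_degree(net, "gene", min_degree=2):
    print(f"  {gene:8s} D = {deg}")
print(
    "\nHigh-D genes are pleiotropic: they sit in several pathological\n"
    "processes at once and are natural multi-mechanism drug targets."
)
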