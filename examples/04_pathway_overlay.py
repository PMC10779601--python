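"""Overlay a drug-target set on pathway gene sets.

Intersects a toy target list with three signalling-pathway gene sets and
prints the per-pathway hit table (zero-hit pathways retained), the raw
material for an integrated pathway map.
"""

from endoprox import GeneSet, ModuleCatalog, pathway_overlay

targets = GeneSet(
    "drug_targets",
    frozenset({"AKT1", "CASP3", "TNF", "BACE1", "GSK3B"}),
)
pathways = ModuleCatalog(
    modules=[
        GeneSet("PI3K_AKT_signaling", frozenset({"PIK3CA", "AKT1", "GSK3B", "MTOR", "BCL2"}),
                category="apoptosis"),
        GeneSet("TNF_signaling", frozenset({"TNF", "TNFRSF1A", "CASP3", "NFKB1"}),
                category="neuroinflammation"),
        GeneSet("Notch_signaling", frozenset({"NOTCH1", "JAG1", "HES1"}),
                category="development"),
    ],
    source="example",
)

table = pathway_overlay(targets, pathways)
print(table.to_string(index=False))
print(
    "\nn_hits counts the drug's targets inside each pathway gene set;\n"
    "pathways with zero hits are kept so the full catalog remains visible."
)
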