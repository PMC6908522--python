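"""Over-representation of a gene list against TF -> target sets.

Builds a small GMT-style collection in which one transcription factor's
target set contains the whole query list; that TF must rank first.
"""

from coexmeta.datatypes import GeneSetCollection
from coexmeta.enrichment import enrich_collection

universe = [f"G{i:03d}" for i in range(100)]
query = universe[:8]  # the "winner" genes

collection = GeneSetCollection(sets={
    "TF_A_targets": ("targets of TF A", frozenset(universe[:12])),
    "TF_B_targets": ("targets of TF B", frozenset(universe[5:40])),
    "TF_C_targets": ("targets of TF C", frozenset(universe[50:])),
    "cell_cycle": ("cell cycle genes", frozenset(universe[2:20])),
})

table = enrich_collection(query, collection, universe)
print(table.to_string(index=False,
                      formatters={"p": "{:.3e}".format,
                                  "p_adj": "{:.3e}".format}))
# k of K targets overlap the n-gene list within the N-gene universe; p is the
# upper-tail hypergeometric probability and p_adj its BH correction. TF A,
# whose targets cover the whole list, dominates.
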