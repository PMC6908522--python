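"""Cross-study consensus: find genes deregulated the same way in most studies.

Runs SAM on a ten-study synthetic collection (6 lung-cancer + 4 other lung
disease) and applies the winner rule: same direction in >= 7 of 10 studies
including >= 5 of the 6 LC studies.
"""

import numpy as np

from coexmeta.consensus import direction_matrix, winner_genes, winner_support
from coexmeta.normalization import normalize_study
from coexmeta.sam import sam_analyze
from coexmeta.simulate import (SimulationConfig, gen_study_collection,
                               global_winner_truth)

config = SimulationConfig(n_genes=300, samples_per_group=20,
                          n_winner_up=15, n_winner_down=10,
                          n_blocks=3, block_size=15, seed=5)
collection = gen_study_collection(config)

seeds = np.random.SeedSequence(5).spawn(len(collection))
gene_results = {}
for (study, _), seed in zip(collection, seeds):
    res = sam_analyze(normalize_study(study), B=200, seed=seed)
    gene_results[study.study_id] = (res.table, study.disease_class)

table = direction_matrix(gene_results, q_threshold=0.01)
up, down = winner_genes(table, min_total=7, min_lc=5)
truth_up, truth_down = global_winner_truth(config)

print(f"direction matrix: {table.directions.shape[0]} genes x "
      f"{table.directions.shape[1]} studies")
print(f"winners: {len(up)} up + {len(down)} down "
      f"(planted: {len(truth_up)} up + {len(truth_down)} down)")
print(f"recovered exactly: {up == truth_up and down == truth_down}")
print("\nsupport counts of the first winners:")
print(winner_support(table).head(8).to_string())
# n_support / n_lc_support show in how many studies (and how many lung-cancer
# studies) each winner carries its direction — by the rule, >= 7 and >= 5.
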