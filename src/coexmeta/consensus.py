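"""Cross-study consensus: probe harmonization and the winner-gene rule.

Each study's probe-level calls are collapsed to gene level (representative
probe = maximum |d|), directions are assembled into a gene x study matrix
with entries in {+1, -1, 0}, and a gene is a "winner" in a direction when
it is deregulated that way in at least ``min_total`` of all studies
including at least ``min_lc`` of the lung-cancer studies. Under the
canonical 6 LC + 4 LD design with (7, 5) this forces at least one
other-lung-disease study when 6 LC support and at least two when 5 LC
support — the arithmetic reading of "one or two of other lung disease".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ConsensusError
from .sam import SamResult


@dataclass
class ConsensusTable:
    """Gene x study direction matrix with derived winner sets.

    ``directions`` holds {+1, -1, 0}; ``absent`` marks genes not measured on
    a study's platform (they contribute 0 support, i.e. non-support rather
    than missing-excluded).
    """

    directions: pd.DataFrame
    disease_class: pd.Series  # study -> {"LC", "LD"}
    absent: pd.DataFrame
    winner_up: set[str] = field(default_factory=set)
    winner_down: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        vals = self.directions.to_numpy()
        if not np.isin(vals, (-1, 0, 1)).all():
            raise ConsensusError("direction entries must be in {-1, 0, +1}")
        if self.winner_up & self.winner_down:
            raise ConsensusError("winner sets must be disjoint")

    @property
    def genes(self) -> list[str]:
        return list(self.directions.index)

    @property
    def studies(self) -> list[str]:
        return list(self.directions.columns)


def collapse_to_genes(sam: SamResult, probe_map: dict[str, str]) -> pd.DataFrame:
    """Collapse probe-level SAM results to gene level.

    Per gene the representative probe is the mapped probe with maximum |d|
    (ties break to the lexicographically smallest probe label); the gene
    inherits its row. Unmapped probes are dropped and counted in the
    ``n_dropped`` attribute of the returned frame.
    """
    table = sam.table
    mapped = [p for p in table.index if p in probe_map]
    if not mapped:
        raise ConsensusError(
            f"study {sam.study_id!r}: no probe in the result maps to a gene"
        )
    sub = table.loc[mapped].copy()
    sub["gene"] = [probe_map[p] for p in mapped]
    sub["_absd"] = sub["d"].abs()
    # pre-sorting by probe label makes the stable |d| sort break ties to the
    # lexicographically smallest probe
    sub = sub.sort_index(kind="stable").sort_values(
        ["gene", "_absd"], ascending=[True, False], kind="stable"
    )
    out = sub.groupby("gene", sort=True).head(1)
    out = out.set_index("gene").drop(columns=["_absd"])
    out.attrs["n_dropped"] = len(table) - len(mapped)
    return out


def direction_matrix(
    gene_results: dict[str, tuple[pd.DataFrame, str]],
    q_threshold: float = 0.01,
) -> ConsensusTable:
    """Assemble the gene x study direction matrix.

    ``gene_results`` maps study id to ``(gene-level table, disease_class)``;
    the table needs ``direction``, ``q`` and (optionally) ``called``
    columns. An entry is the direction when called at ``q_threshold``, else
    0; genes absent from a study's platform get 0 with the absent mask set.
    """
    if not gene_results:
        raise ConsensusError("need at least one study")
    studies = list(gene_results)
    if len(set(studies)) != len(studies):
        raise ConsensusError("duplicate study ids")
    universe = sorted(set().union(*(set(t.index) for t, _ in gene_results.values())))
    directions = pd.DataFrame(0, index=universe, columns=studies, dtype=int)
    absent = pd.DataFrame(True, index=universe, columns=studies, dtype=bool)
    classes = {}
    for sid, (table, cls) in gene_results.items():
        classes[sid] = cls
        called = (table["q"] < q_threshold) if "called" not in table else table["called"]
        signs = table["direction"].where(called, 0).astype(int)
        directions.loc[signs.index, sid] = signs
        absent.loc[table.index, sid] = False
    return ConsensusTable(
        directions=directions,
        disease_class=pd.Series(classes),
        absent=absent,
    )


def winner_genes(
    table: ConsensusTable, min_total: int = 7, min_lc: int = 5
) -> tuple[set[str], set[str]]:
    """Apply the consensus winner rule per direction.

    A gene wins in direction sigma iff it carries sigma in >= ``min_total``
    studies overall and in >= ``min_lc`` LC studies. Returns
    ``(winner_up, winner_down)`` and stores them on the table.
    """
    lc_cols = [s for s in table.studies if table.disease_class[s] == "LC"]
    if min_lc > len(lc_cols):
        raise ConfigurationError(
            f"min_lc={min_lc} exceeds the {len(lc_cols)} LC studies"
        )
    d = table.directions
    winners = {}
    for sigma, name in ((1, "up"), (-1, "down")):
        support = (d == sigma).sum(axis=1)
        lc_support = (d[lc_cols] == sigma).sum(axis=1)
        winners[name] = set(d.index[(support >= min_total) & (lc_support >= min_lc)])
    if winners["up"] & winners["down"]:
        raise ConsensusError(
            "a gene won in both directions; min_total must exceed half the "
            "number of studies to preclude this"
        )
    table.winner_up = winners["up"]
    table.winner_down = winners["down"]
    return winners["up"], winners["down"]


def winner_support(table: ConsensusTable) -> pd.DataFrame:
    """Support counts for each winner: direction, n_support, n_lc_support."""
    lc_cols = [s for s in table.studies if table.disease_class[s] == "LC"]
    rows = []
    for gene in sorted(table.winner_up | table.winner_down):
        sigma = 1 if gene in table.winner_up else -1
        row = table.directions.loc[gene]
        rows.append({
            "gene": gene,
            "direction": sigma,
            "n_support": int((row == sigma).sum()),
            "n_lc_support": int((row[lc_cols] == sigma).sum()),
        })
    return pd.DataFrame(rows, columns=["gene", "direction", "n_support",
                                       "n_lc_support"]).set_index("gene")
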