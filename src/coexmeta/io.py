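"""Readers and writers for every external format the pipeline touches.

Formats: expression TSV (header row of sample labels, first column feature
labels) plus a sample-annotation TSV (sample, group), GMT gene-set files,
two-column probe-map TSVs, and graph exports (SIF, GraphML, edge-list TSV).

All writers are deterministic: fixed ordering and fixed numeric formatting
(6 significant digits), so the same object always produces a byte-identical
file. Decimal separator is "." with no thousands separators; missing values
are encoded "NA".
"""

from __future__ import annotations

import logging
from pathlib import Path
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd

from .datatypes import ExpressionStudy, GeneSetCollection
from .errors import FormatError
from .network import GeneNetwork

logger = logging.getLogger(__name__)

NA = "NA"


def _fmt(x: float) -> str:
    if pd.isna(x):
        return NA
    return f"{x:.6g}"


# -- expression matrices -----------------------------------------------------

def write_expression_tsv(study: ExpressionStudy, matrix_path, annotation_path) -> None:
    """Write the matrix TSV and its sample-annotation sidecar."""
    with open(matrix_path, "w") as fh:
        fh.write("feature\t" + "\t".join(study.samples) + "\n")
        values = study.values.to_numpy(dtype=float)
        for i, feat in enumerate(study.features):
            fh.write(feat + "\t" + "\t".join(_fmt(v) for v in values[i]) + "\n")
    with open(annotation_path, "w") as fh:
        fh.write("sample\tgroup\tdisease_class\tstudy_id\tscale\n")
        for s in study.samples:
            fh.write(f"{s}\t{study.group[s]}\t{study.disease_class}\t"
                     f"{study.study_id}\t{study.scale}\n")


def read_expression_tsv(matrix_path, annotation_path) -> ExpressionStudy:
    """Read and validate an expression study from its two TSV files.

    Rows with any unparseable cell are rejected with their line numbers;
    label duplication, sample mismatch between the files and undersized
    groups raise :class:`FormatError` naming the offender.
    """
    matrix_path, annotation_path = Path(matrix_path), Path(annotation_path)
    with open(matrix_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise FormatError(f"{matrix_path}: header needs >= 2 columns")
        samples = header[1:]
        features, rows, bad_lines = [], [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                bad_lines.append(lineno)
                continue
            vals = []
            ok = True
            for cell in parts[1:]:
                if cell == NA:
                    vals.append(np.nan)
                    continue
                try:
                    vals.append(float(cell))
                except ValueError:
                    ok = False
                    break
            if not ok:
                bad_lines.append(lineno)
                continue
            features.append(parts[0])
            rows.append(vals)
    if bad_lines:
        raise FormatError(
            f"{matrix_path}: unparseable rows at lines {bad_lines[:10]}"
        )
    if len(set(samples)) != len(samples):
        raise FormatError(f"{matrix_path}: duplicate sample labels in header")
    if len(set(features)) != len(features):
        raise FormatError(f"{matrix_path}: duplicate feature labels")

    annot = pd.read_csv(annotation_path, sep="\t", dtype=str)
    for col in ("sample", "group"):
        if col not in annot.columns:
            raise FormatError(f"{annotation_path}: missing column {col!r}")
    extra = set(annot["sample"]) - set(samples)
    if extra:
        raise FormatError(
            f"{annotation_path}: sample not in matrix: {sorted(extra)[:5]}"
        )
    missing = set(samples) - set(annot["sample"])
    if missing:
        raise FormatError(
            f"{annotation_path}: matrix sample without annotation: "
            f"{sorted(missing)[:5]}"
        )
    annot = annot.set_index("sample")
    study_id = (annot["study_id"].iloc[0]
                if "study_id" in annot.columns else matrix_path.stem)
    disease_class = (annot["disease_class"].iloc[0]
                     if "disease_class" in annot.columns else "LC")
    scale = annot["scale"].iloc[0] if "scale" in annot.columns else "raw"
    return ExpressionStudy(
        study_id=study_id,
        disease_class=disease_class,
        values=pd.DataFrame(rows, index=features, columns=samples, dtype=float),
        group=annot["group"].loc[samples],
        scale=scale,
    )


# -- gene sets and probe maps ------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: name TAB description TAB gene... per line.

    Duplicate genes within a set are deduplicated; a line with fewer than 3
    fields or no genes is rejected with its line number. An empty file
    yields an empty collection with a logged warning.
    """
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno}: fewer than 3 fields")
            name, desc = parts[0], parts[1]
            genes = frozenset(g for g in parts[2:] if g)
            if not genes:
                raise FormatError(f"{path}: line {lineno}: set {name!r} empty")
            if name in sets:
                raise FormatError(f"{path}: line {lineno}: duplicate set {name!r}")
            sets[name] = (desc, genes)
    if not sets:
        logger.warning("%s: empty GMT file", path)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.names()):
            desc, genes = collection.sets[name]
            fh.write(name + "\t" + desc + "\t" + "\t".join(sorted(genes)) + "\n")


def read_probe_map(path) -> dict[str, str]:
    """Read a two-column probe -> gene TSV.

    Probes mapping to an empty or "NA" symbol are dropped and counted (the
    count is logged); duplicate probe rows with conflicting symbols raise.
    """
    mapping: dict[str, str] = {}
    conflicts: list[str] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}: line {lineno}: expected 2 columns")
            probe, gene = parts
            if gene in ("", NA):
                dropped += 1
                continue
            if probe in mapping and mapping[probe] != gene:
                conflicts.append(probe)
                continue
            mapping[probe] = gene
    if conflicts:
        raise FormatError(
            f"{path}: conflicting symbols for probes {sorted(set(conflicts))[:10]}"
        )
    if dropped:
        logger.info("%s: dropped %d probes with empty/NA symbols", path, dropped)
    return mapping


# -- graphs ------------------------------------------------------------------

def write_graph(network: GeneNetwork, fmt: str, path,
                similarity=None) -> None:
    """Write a network as SIF, GraphML or edge-list TSV.

    SIF lines are ``geneA TAB co TAB geneB`` with endpoints in lexicographic
    order, one undirected edge once. GraphML carries the threshold and,
    when a :class:`~coexmeta.network.SimilarityMatrix` is supplied, the
    ``|r|`` edge weights. For an empty network the node list is still
    emitted as ``#`` comment lines.
    """
    edges = sorted(network.edges)
    nodes = sorted(network.nodes)
    if fmt == "sif":
        with open(path, "w") as fh:
            for v in (nodes if not edges else []):
                fh.write(f"#node\t{v}\n")
            for a, b in edges:
                fh.write(f"{a}\tco\t{b}\n")
    elif fmt == "edge-tsv":
        with open(path, "w") as fh:
            fh.write("geneA\tgeneB\n")
            for v in (nodes if not edges else []):
                fh.write(f"#node\t{v}\n")
            for a, b in edges:
                fh.write(f"{a}\t{b}\n")
    elif fmt == "graphml":
        sim = similarity.frame() if similarity is not None else None
        thr = "" if network.threshold is None else _fmt(network.threshold)
        lines = [
            '<?xml version="1.0" encoding="UTF-8"?>',
            '<graphml xmlns="http://graphml.graphdrawing.org/xmlns">',
            '  <key id="w" for="edge" attr.name="abs_r" attr.type="double"/>',
            '  <key id="t" for="graph" attr.name="threshold" attr.type="double"/>',
            '  <graph edgedefault="undirected">',
        ]
        if thr:
            lines.append(f'    <data key="t">{thr}</data>')
        for v in nodes:
            lines.append(f'    <node id="{escape(v)}"/>')
        for a, b in edges:
            if sim is not None:
                w = _fmt(float(sim.loc[a, b]))
                lines.append(
                    f'    <edge source="{escape(a)}" target="{escape(b)}">'
                    f'<data key="w">{w}</data></edge>'
                )
            else:
                lines.append(f'    <edge source="{escape(a)}" target="{escape(b)}"/>')
        lines += ["  </graph>", "</graphml>", ""]
        with open(path, "w") as fh:
            fh.write("\n".join(lines))
    else:
        raise FormatError(f"unknown graph format {fmt!r}")


def read_edge_tsv(path) -> GeneNetwork:
    """Read an edge-list TSV back into a :class:`GeneNetwork`."""
    edges: set[tuple[str, str]] = set()
    nodes: set[str] = set()
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("geneA"):
            raise FormatError(f"{path}: missing edge-TSV header")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#node\t"):
                nodes.add(line.split("\t", 1)[1])
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}: line {lineno}: expected 2 columns")
            a, b = parts
            edges.add((a, b) if a < b else (b, a))
            nodes.update((a, b))
    return GeneNetwork(nodes=nodes, edges=edges)


def write_table(frame: pd.DataFrame, path, index_label: str | None = None) -> None:
    """Deterministic TSV export of a results table (6 significant digits)."""
    out = frame.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(_fmt)
    out.to_csv(path, sep="\t", index=index_label is not None,
               index_label=index_label)
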