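"""Readers and writers for the plain-text formats the tool consumes.

* networks: edge-list TSV/SIF-like, two whitespace-separated protein IDs per
  line (extra columns such as weights are ignored — the model is defined on
  unweighted networks);
* annotations: two-column TSV (protein, term) or GAF 2.x (DB Object ID and
  GO ID columns; hierarchy ignored; ``NOT``-qualified rows skipped);
* complex sets: one complex per line, tab-separated member IDs
  (CYC2008-style).

All readers de-duplicate and preserve first-appearance order, so runs are
byte-for-byte reproducible from fixed inputs.  Comment lines start with '#'.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .detection import ComplexSet
from .evaluation import ENRICHMENT_BIN_LABELS, EnrichmentTable, EvaluationReport
from .model import FunctionalProfile, PPINetwork

__all__ = [
    "read_network",
    "read_annotations",
    "read_complexes",
    "write_network",
    "write_annotations",
    "write_complexes",
    "write_report",
    "write_enrichment",
]

logger = logging.getLogger("gmftp")


def _data_lines(path: str | Path):
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_network(path: str | Path) -> PPINetwork:
    """Read an undirected, unweighted network from an edge list.

    Duplicate edges collapse; self-loops are dropped with a warning; columns
    beyond the first two (e.g. confidence weights) are ignored.
    """
    order: dict[str, int] = {}
    pairs: set[tuple[int, int]] = set()
    n_self = n_weighted = 0
    for lineno, line in _data_lines(path):
        tokens = line.split()
        if len(tokens) < 2:
            raise ValueError(f"{path}:{lineno}: expected at least 2 columns, got {len(tokens)}")
        a, b = tokens[0], tokens[1]
        if len(tokens) > 2:
            n_weighted += 1
        if a == b:
            n_self += 1
            continue
        for p in (a, b):
            if p not in order:
                order[p] = len(order)
        i, j = order[a], order[b]
        pairs.add((min(i, j), max(i, j)))
    if n_self:
        logger.warning("%s: dropped %d self-loop(s)", path, n_self)
    if n_weighted:
        logger.info("%s: ignored extra columns on %d line(s) (network treated as unweighted)",
                    path, n_weighted)
    if not pairs:
        raise ValueError(f"{path}: no edges found")
    n = len(order)
    a_mat = np.zeros((n, n), dtype=np.int8)
    for i, j in pairs:
        a_mat[i, j] = a_mat[j, i] = 1
    return PPINetwork(protein_ids=list(order), A=a_mat)


def _looks_like_gaf(path: str | Path) -> bool:
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            if raw.startswith("!"):
                return True
            if not raw.strip():
                continue
            return len(raw.rstrip("\n").split("\t")) >= 15
    return False


def read_annotations(path: str | Path, protein_ids: list[str]) -> FunctionalProfile:
    """Read a protein→term annotation table against a protein catalog.

    Accepts a two-column TSV or a GAF 2.x file (detected by its '!' header
    or its ≥15 tab-separated columns; DB Object ID and GO ID columns are
    used, rows with a NOT qualifier are skipped).  Proteins in the catalog
    but absent from the file get S_i = 0; annotations of unknown proteins
    are ignored with a logged count.
    """
    index = {p: i for i, p in enumerate(protein_ids)}
    gaf = _looks_like_gaf(path)
    terms: dict[str, int] = {}
    cells: set[tuple[int, int]] = set()
    annotated = np.zeros(len(protein_ids), dtype=np.int8)
    n_unknown = 0
    n_rows = 0
    for lineno, line in _data_lines(path):
        if gaf and line.startswith("!"):
            continue
        tokens = line.split("\t") if gaf else line.split()
        if gaf:
            if len(tokens) < 5:
                raise ValueError(f"{path}:{lineno}: malformed GAF row")
            if "NOT" in tokens[3].split("|"):
                continue
            protein, term = tokens[1], tokens[4]
        else:
            if len(tokens) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(tokens)}")
            protein, term = tokens[0], tokens[1]
        n_rows += 1
        i = index.get(protein)
        if i is None:
            n_unknown += 1
            continue
        if term not in terms:
            terms[term] = len(terms)
        cells.add((i, terms[term]))
        annotated[i] = 1
    if n_rows == 0:
        raise ValueError(f"{path}: no annotation rows found")
    if n_unknown:
        logger.info("%s: ignored %d annotation(s) of proteins absent from the network",
                    path, n_unknown)
    f_mat = np.zeros((len(protein_ids), len(terms)), dtype=np.int8)
    for i, c in cells:
        f_mat[i, c] = 1
    return FunctionalProfile(term_ids=list(terms), F=f_mat, S=annotated)


def read_complexes(path: str | Path, protein_ids: list[str]) -> ComplexSet:
    """Read one complex per line (tab- or space-separated member IDs).

    Members absent from the catalog are dropped with a logged count; blank
    lines are ignored.
    """
    index = {p: i for i, p in enumerate(protein_ids)}
    complexes: list[frozenset[int]] = []
    n_unknown = 0
    for _lineno, line in _data_lines(path):
        members = set()
        for token in line.split():
            i = index.get(token)
            if i is None:
                n_unknown += 1
            else:
                members.add(i)
        if members:
            complexes.append(frozenset(members))
    if not complexes:
        raise ValueError(f"{path}: no complexes found")
    if n_unknown:
        logger.info("%s: dropped %d member(s) absent from the catalog", path, n_unknown)
    return ComplexSet(complexes=complexes, n_proteins=len(protein_ids))


def write_network(net: PPINetwork, path: str | Path) -> None:
    """Write the edge list (tab-separated, i < j, row order)."""
    ei, ej = net.edges()
    with open(path, "w", encoding="utf-8") as fh:
        for i, j in zip(ei, ej):
            fh.write(f"{net.protein_ids[i]}\t{net.protein_ids[j]}\n")


def write_annotations(prof: FunctionalProfile, protein_ids: list[str],
                      path: str | Path) -> None:
    """Write the two-column (protein, term) association table."""
    fi, fc = np.nonzero(prof.F)
    with open(path, "w", encoding="utf-8") as fh:
        for i, c in zip(fi, fc):
            fh.write(f"{protein_ids[i]}\t{prof.term_ids[c]}\n")


def write_complexes(cs: ComplexSet, protein_ids: list[str], path: str | Path) -> None:
    """Write one complex per line, tab-separated member IDs (sorted by index)."""
    with open(path, "w", encoding="utf-8") as fh:
        for c in cs:
            fh.write("\t".join(protein_ids[i] for i in sorted(c)) + "\n")


def write_report(report: EvaluationReport, path: str | Path) -> None:
    """Write the evaluation metrics as a two-column TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("metric\tvalue\n")
        fh.write(f"FRAC\t{report.frac:.6f}\n")
        fh.write(f"MMR\t{report.mmr:.6f}\n")
        fh.write(f"ACC\t{report.acc:.6f}\n")
        # geometric-mean composite, not the literature's exact PR formula
        fh.write(f"PR(composite)\t{report.pr:.6f}\n")
        fh.write(f"n_predicted\t{report.n_predicted}\n")
        fh.write(f"coverage\t{report.coverage}\n")


def write_enrichment(table: EnrichmentTable, path: str | Path) -> None:
    """Write per-complex minimum P-values and the four bin counts."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("complex_index\tmin_p_value\n")
        for idx, p in enumerate(table.p_values):
            fh.write(f"{idx}\t{'NA' if np.isnan(p) else format(p, '.6g')}\n")
        fh.write("#bin\tcount\n")
        for label, count in zip(ENRICHMENT_BIN_LABELS, table.bin_counts):
            fh.write(f"#{label}\t{count}\n")
        fh.write(f"#unscored\t{table.n_unscored}\n")
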