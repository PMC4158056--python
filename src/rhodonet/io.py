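"""Plain-text file formats: TSV matrices, ortholog maps, GMT gene sets.

Every writer can prepend ``#``-prefixed comment lines (tool version, seed,
parameter digest); every reader skips them.  Missing cells are written as
``NA`` and read back as NaN, so matrix round-trips are exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import (
    ExprMatrix,
    GeneSetCollection,
    ModulePartition,
    OrthologMap,
    SampleSheet,
    ValidationError,
)


def format_header(seed=None, params_digest=None, **extra) -> list[str]:
    items = {"tool": f"rhodonet {__version__}"}
    if seed is not None:
        items["seed"] = seed
    if params_digest is not None:
        items["params"] = params_digest
    items.update(extra)
    return [f"# {k}={v}" for k, v in items.items()]


def _write_with_header(path, header_lines, body: str) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(line.rstrip("\n") + "\n")
        fh.write(body)


def _data_lines(path) -> list[tuple[int, str]]:
    """(1-based line number, content) for non-comment, non-blank lines."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped or stripped.startswith("#"):
                continue
            out.append((i, stripped))
    if not out:
        raise ValidationError(f"{path}: no data lines")
    return out


def read_expr_tsv(path, standardization: str = "raw") -> ExprMatrix:
    """Read a gene-by-condition TSV (first column gene id, header row of
    condition ids; empty cell or ``NA`` means missing)."""
    lines = _data_lines(path)
    lineno, header = lines[0]
    cols = header.split("\t")[1:]
    if not cols:
        raise ValidationError(f"{path}:{lineno}: header has no condition columns")
    genes, rows = [], []
    seen = {}
    for lineno, line in lines[1:]:
        parts = line.split("\t")
        if len(parts) != len(cols) + 1:
            raise ValidationError(
                f"{path}:{lineno}: expected {len(cols) + 1} fields, "
                f"got {len(parts)}"
            )
        gene = parts[0]
        if gene in seen:
            raise ValidationError(
                f"{path}:{lineno}: duplicate gene id {gene!r} "
                f"(first seen on line {seen[gene]})"
            )
        seen[gene] = lineno
        vals = []
        for j, cell in enumerate(parts[1:]):
            if cell in ("", "NA", "NaN", "nan"):
                vals.append(np.nan)
            else:
                try:
                    vals.append(float(cell))
                except ValueError:
                    raise ValidationError(
                        f"{path}:{lineno}: non-numeric cell {cell!r} in "
                        f"column {cols[j]!r}"
                    ) from None
        genes.append(gene)
        rows.append(vals)
    df = pd.DataFrame(rows, index=genes, columns=cols)
    return ExprMatrix(df, standardization=standardization)


def write_expr_tsv(expr: ExprMatrix, path, header_lines=None) -> None:
    body = expr.data.to_csv(sep="\t", na_rep="NA", index_label="gene",
                            lineterminator="\n")
    _write_with_header(path, header_lines, body)


def read_orthologs_tsv(path) -> OrthologMap:
    """Two-column TSV of (reference gene, test gene); one-to-one enforced."""
    pairs = []
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValidationError(
                f"{path}:{lineno}: expected 2 columns, got {len(parts)}"
            )
        pairs.append(parts)
    if pairs and pairs[0] in (["ref", "test"], ["reference", "test"]):
        pairs = pairs[1:]
    return OrthologMap(pd.DataFrame(pairs, columns=["ref", "test"]))


def write_orthologs_tsv(mapping: OrthologMap, path, header_lines=None) -> None:
    body = mapping.pairs.to_csv(sep="\t", index=False, lineterminator="\n")
    _write_with_header(path, header_lines, body)


def read_gmt(path) -> GeneSetCollection:
    """GMT: set name, description/category, then tab-separated gene ids."""
    sets, cats = {}, {}
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValidationError(
                f"{path}:{lineno}: GMT line needs a name, description and "
                "at least one gene"
            )
        name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        if not genes:
            raise ValidationError(f"{path}:{lineno}: gene set {name!r} is empty")
        if name in sets:
            raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
        sets[name] = set(genes)
        cats[name] = desc
    return GeneSetCollection(sets, cats)


def write_gmt(sets: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in sets.names():
            desc = sets.categories.get(name, "")
            genes = "\t".join(sorted(sets.sets[name]))
            fh.write(f"{name}\t{desc}\t{genes}\n")


def read_sample_sheet_tsv(path, probe_map_path=None) -> SampleSheet:
    """Sample sheet TSV: sample_id, condition_id, replicate."""
    rows = []
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValidationError(
                f"{path}:{lineno}: expected at least sample and condition"
            )
        rows.append(parts[:3] if len(parts) >= 3 else parts + ["1"])
    if rows and rows[0][0] in ("sample", "sample_id"):
        rows = rows[1:]
    df = pd.DataFrame(rows, columns=["sample", "condition", "replicate"])
    df = df.set_index("sample")
    probe_map = None
    if probe_map_path is not None:
        pm_rows = []
        for lineno, line in _data_lines(probe_map_path):
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValidationError(
                    f"{probe_map_path}:{lineno}: expected 2 columns"
                )
            pm_rows.append(parts)
        if pm_rows and pm_rows[0] in (["probe", "gene"], ["probe_id", "gene_id"]):
            pm_rows = pm_rows[1:]
        probe_map = pd.DataFrame(pm_rows, columns=["probe", "gene"])
    return SampleSheet(df, probe_map)


def read_scores_tsv(path) -> pd.Series:
    """Two-column TSV of (gene, numeric score)."""
    genes, vals = [], []
    for pos, (lineno, line) in enumerate(_data_lines(path)):
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValidationError(f"{path}:{lineno}: expected 2 columns")
        if pos == 0 and parts[0] in ("gene", "gene_id"):
            continue
        try:
            vals.append(float(parts[1]))
        except ValueError:
            raise ValidationError(
                f"{path}:{lineno}: non-numeric score {parts[1]!r}"
            ) from None
        genes.append(parts[0])
    s = pd.Series(vals, index=genes)
    if s.index.has_duplicates:
        raise ValidationError(f"{path}: duplicate gene ids in scores")
    return s


def write_scores_tsv(scores: pd.Series, path, header_lines=None) -> None:
    body = scores.rename("score").to_csv(sep="\t", index_label="gene",
                                         lineterminator="\n")
    _write_with_header(path, header_lines, body)


def read_partition_tsv(path) -> ModulePartition:
    genes, labels = [], []
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValidationError(f"{path}:{lineno}: expected >= 2 columns")
        if parts[0] in ("gene", "gene_id") and not labels:
            continue
        genes.append(parts[0])
        try:
            labels.append(int(parts[1]))
        except ValueError:
            raise ValidationError(
                f"{path}:{lineno}: non-integer module label {parts[1]!r}"
            ) from None
    return ModulePartition(pd.Series(labels, index=genes))


def write_partition_tsv(part: ModulePartition, path, header_lines=None) -> None:
    body = part.to_frame().to_csv(sep="\t", index_label="gene",
                                  lineterminator="\n")
    _write_with_header(path, header_lines, body)


def write_table_tsv(df: pd.DataFrame, path, header_lines=None,
                    index_label=None) -> None:
    body = df.to_csv(sep="\t", na_rep="NA", index_label=index_label,
                     lineterminator="\n")
    _write_with_header(path, header_lines, body)


def write_truth_json(truth, path) -> None:
    payload = {
        "module_of_gene": truth.module_of_gene,
        "preserved": {str(k): v for k, v in truth.preserved.items()},
        "ortholog_pairs": [list(p) for p in truth.ortholog_pairs],
        "packaged_module": truth.packaged_module,
        "module_of_gene_B": truth.module_of_gene_B,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
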