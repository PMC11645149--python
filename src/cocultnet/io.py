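"""Readers, writers and validated in-memory containers for every external
artifact: expression matrices with sample annotations, gene sets (GMT),
STRING-style interaction edge tables, and patient cohort tables.

All gene identifiers are uppercased HGNC-style symbols on load; set-valued
containers are order-free so that input row order never changes a downstream
statistic.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCALES = ("counts", "log2cpm")


# ---------------------------------------------------------------------------
# containers


@dataclass
class ExpressionMatrix:
    """Gene x sample expression with per-sample annotations.

    ``values`` is a genes-by-samples DataFrame; ``scale`` flags whether the
    entries are raw counts or log2(CPM + pseudocount); ``annotations`` is a
    sample-indexed DataFrame carrying at least a ``condition`` column.
    """

    values: pd.DataFrame
    scale: str
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids after load: {dups[:5]}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        vals = self.values.to_numpy()
        if not np.isfinite(vals).all():
            raise ValueError("expression matrix contains non-finite values")
        if self.scale == "counts" and (vals < 0).any():
            raise ValueError("counts-scale matrix contains negative values")
        missing = set(self.values.columns) - set(self.annotations.index)
        if missing:
            raise ValueError(f"samples missing annotation: {sorted(missing)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_where(self, **conditions: str) -> list[str]:
        """Sample ids whose annotation matches every key=value given."""
        ann = self.annotations.loc[self.sample_ids]
        mask = np.ones(len(ann), dtype=bool)
        for key, val in conditions.items():
            mask &= (ann[key] == val).to_numpy()
        return list(ann.index[mask])

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values[list(samples)], self.scale, self.annotations.loc[list(samples)]
        )


@dataclass(frozen=True)
class GeneSet:
    """A named set of uppercase gene symbols."""

    name: str
    genes: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        object.__setattr__(self, "genes", frozenset(g.upper() for g in self.genes))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def __iter__(self):
        return iter(sorted(self.genes))

    def intersection(self, other: "GeneSet", name: str | None = None) -> "GeneSet":
        return GeneSet(name or f"{self.name}&{other.name}", self.genes & other.genes)


@dataclass
class EdgeTable:
    """Undirected weighted interaction edges, deduplicated and loop-free.

    Edges are stored with node_a < node_b lexicographically; symmetric
    duplicates are merged keeping the maximum confidence.
    """

    edges: pd.DataFrame  # columns: node_a, node_b, confidence

    def __post_init__(self) -> None:
        df = self.edges.copy()
        if df.empty:
            self.edges = pd.DataFrame(columns=["node_a", "node_b", "confidence"])
            return
        df["node_a"] = df["node_a"].astype(str).str.upper()
        df["node_b"] = df["node_b"].astype(str).str.upper()
        conf = df["confidence"].to_numpy(dtype=float)
        if ((conf < 0) | (conf > 1)).any():
            raise ValueError("edge confidence outside [0, 1]")
        loops = df["node_a"] == df["node_b"]
        if loops.any():
            logger.warning("dropping %d self-loop edge(s)", int(loops.sum()))
            df = df[~loops]
        lo = np.minimum(df["node_a"], df["node_b"])
        hi = np.maximum(df["node_a"], df["node_b"])
        df = pd.DataFrame({"node_a": lo, "node_b": hi, "confidence": df["confidence"]})
        df = (
            df.groupby(["node_a", "node_b"], as_index=False)["confidence"]
            .max()
            .sort_values(["node_a", "node_b"], ignore_index=True)
        )
        self.edges = df

    def __len__(self) -> int:
        return len(self.edges)

    def nodes(self) -> set[str]:
        if self.edges.empty:
            return set()
        return set(self.edges["node_a"]) | set(self.edges["node_b"])

    def filter_confidence(self, min_confidence: float) -> "EdgeTable":
        return EdgeTable(self.edges[self.edges["confidence"] >= min_confidence])


@dataclass
class CohortTable:
    """Patient survival cohort: time-to-event, event indicator and expression.

    ``table`` is patient-indexed with columns ``time`` (months, >= 0),
    ``event`` (0/1) and one uppercase gene column per measured gene.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        for col in ("time", "event"):
            if col not in df.columns:
                raise ValueError(f"cohort table missing column {col!r}")
        if (df["time"].to_numpy(dtype=float) < 0).any():
            raise ValueError("negative survival time")
        ev = set(df["event"].unique().tolist())
        if not ev <= {0, 1}:
            raise ValueError(f"event indicator must be 0/1, saw {sorted(ev)}")
        gene_cols = [c for c in df.columns if c not in ("time", "event")]
        self.table = df.rename(columns={c: c.upper() for c in gene_cols})

    @property
    def genes(self) -> list[str]:
        return [c for c in self.table.columns if c not in ("time", "event")]

    @property
    def times(self) -> np.ndarray:
        return self.table["time"].to_numpy(dtype=float)

    @property
    def events(self) -> np.ndarray:
        return self.table["event"].to_numpy(dtype=int)

    def expression(self) -> pd.DataFrame:
        """Genes x patients expression matrix view."""
        return self.table[self.genes].T


# ---------------------------------------------------------------------------
# expression / annotation IO


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited text table, sniffing comma vs tab."""
    path = Path(path)
    with open(path) as fh:
        head = fh.readline()
    sep = "\t" if head.count("\t") >= head.count(",") else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def read_expression(
    path: str | Path, annotation_path: str | Path, scale: str = "counts"
) -> ExpressionMatrix:
    """Load an expression table (first column gene symbols, rest samples)
    plus its sample annotation table.

    Duplicate gene rows are collapsed — summed on the counts scale (library
    size is preserved), max-collapsed on the log scale (no double counting)
    — with a logged warning. Non-numeric cells and unannotated samples are
    hard errors naming the offending cell/sample.
    """
    raw = _read_table(path)
    raw.index = raw.index.astype(str).str.upper()
    for j, col in enumerate(raw.columns):
        numeric = pd.to_numeric(raw[col], errors="coerce")
        bad = numeric.isna() & raw[col].notna() | raw[col].isna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric expression value at gene {raw.index[i]!r}, "
                f"sample {col!r} (row {i + 1}, column {j + 1})"
            )
        raw[col] = numeric.astype(float)
    if raw.index.has_duplicates:
        n_dup = int(raw.index.duplicated().sum())
        how = "sum" if scale == "counts" else "max"
        logger.warning("collapsing %d duplicate gene row(s) by %s", n_dup, how)
        raw = raw.groupby(level=0).sum() if scale == "counts" else raw.groupby(level=0).max()
    ann = _read_table(annotation_path)
    ann.index = ann.index.astype(str)
    missing = [s for s in raw.columns if s not in ann.index]
    if missing:
        raise ValueError(f"samples missing annotation: {missing}")
    return ExpressionMatrix(raw, scale, ann)


def write_expression(
    mat: ExpressionMatrix, path: str | Path, annotation_path: str | Path | None = None
) -> None:
    mat.values.to_csv(path, sep="\t", float_format="%.6g", index_label="gene")
    if annotation_path is not None:
        mat.annotations.to_csv(annotation_path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: one gene set per line, ``name<TAB>description<TAB>genes...``.

    Duplicate genes within a line are deduplicated; a line with fewer than
    three fields is an error naming the line number.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: expected >=3 tab-separated fields")
            name, desc, *genes = fields
            genes = [g for g in genes if g.strip()]
            sets.append(GeneSet(name, frozenset(genes), desc))
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fields = [gs.name, gs.description or "na", *sorted(gs.genes)]
            if len(fields) == 2:  # empty set still needs a third (empty) field
                fields.append("")
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# STRING-style edge tables


def read_edge_table(path: str | Path, min_confidence: float = 0.0) -> EdgeTable:
    """Load a STRING-export-style edge list (protein1, protein2,
    combined_score).

    Scores are auto-detected: any score > 1 anywhere means the STRING
    0-1000 convention and the whole column is divided by 1000; otherwise
    scores are taken as already in [0, 1]. Edges below ``min_confidence``
    are dropped, symmetric duplicates merged (max confidence), self-loops
    dropped with a warning.
    """
    path = Path(path)
    with open(path) as fh:
        head = fh.readline()
    sep = "\t" if head.count("\t") >= head.count(",") else ","
    df = pd.read_csv(path, sep=sep)
    cols = {c.lower(): c for c in df.columns}
    try:
        a, b, s = cols["protein1"], cols["protein2"], cols["combined_score"]
    except KeyError as exc:
        raise ValueError(
            "edge table must have columns protein1/protein2/combined_score"
        ) from exc
    score = df[s].to_numpy(dtype=float)
    if (score > 1).any():
        score = score / 1000.0
    table = EdgeTable(
        pd.DataFrame({"node_a": df[a], "node_b": df[b], "confidence": score})
    )
    return table.filter_confidence(min_confidence)


def write_edge_table(table: EdgeTable, path: str | Path) -> None:
    out = table.edges.rename(
        columns={"node_a": "protein1", "node_b": "protein2", "confidence": "combined_score"}
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# cohorts


def read_cohort(path: str | Path) -> CohortTable:
    """Load a patient cohort CSV: patient_id, time, event, then gene columns."""
    df = pd.read_csv(path, index_col=0)
    return CohortTable(df)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    cohort.table.to_csv(path, float_format="%.6g", index_label="patient_id")


# ---------------------------------------------------------------------------
# config and run manifest


def read_config(path: str | Path) -> dict:
    """Load a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".json",):
        return json.loads(text)
    import yaml

    return yaml.safe_load(text)


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g", quoting=csv.QUOTE_MINIMAL)
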