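"""Readers and writers for OTU tables, sample metadata, and association networks.

File conventions follow common amplicon tooling: on disk an OTU table stores
OTUs as rows (BIOM orientation) with a header row of sample ids and an
optional trailing ``taxonomy`` column; in memory all matrices are oriented
samples x OTUs so that regression conventions stay natural.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx

log = logging.getLogger(__name__)

#: Host phenotype responses carried by a SampleFrame, in canonical order.
PHENOTYPES = ("Fat", "BMC", "Lean", "DMI", "Weight", "Weight+1", "NAFLD")

TREATMENTS = ("control", "STAT")
DIETS = ("NC", "HFD")
SEXES = ("M", "F")


class ParseError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass
class OtuTable:
    """Integer count table, samples x OTUs, with ids and optional taxonomy.

    Parameters
    ----------
    counts
        Non-negative integer matrix of shape ``(n_samples, n_otus)``.
    sample_ids, otu_ids
        Unique identifier lists matching the two axes.
    taxonomy
        Optional per-OTU lineage strings (``k__...;p__...;...``).
    """

    counts: np.ndarray
    sample_ids: list[str]
    otu_ids: list[str]
    taxonomy: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix (samples x OTUs)")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = np.round(self.counts).astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.otu_ids = [str(o) for o in self.otu_ids]
        n, p = self.counts.shape
        if len(self.sample_ids) != n or len(self.otu_ids) != p:
            raise ValueError("id lists inconsistent with counts shape")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.otu_ids)) != p:
            raise ValueError("duplicate OTU ids")
        if self.taxonomy is not None and len(self.taxonomy) != p:
            raise ValueError("taxonomy length must match number of OTUs")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        """Counts as a samples x OTUs DataFrame."""
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    def select_otus(self, mask_or_idx) -> "OtuTable":
        idx = np.arange(self.n_otus)[mask_or_idx]
        tax = [self.taxonomy[i] for i in idx] if self.taxonomy is not None else None
        return OtuTable(self.counts[:, idx], list(self.sample_ids),
                        [self.otu_ids[i] for i in idx], tax)

    def select_samples(self, mask_or_idx) -> "OtuTable":
        idx = np.arange(self.n_samples)[mask_or_idx]
        return OtuTable(self.counts[idx], [self.sample_ids[i] for i in idx],
                        list(self.otu_ids),
                        list(self.taxonomy) if self.taxonomy is not None else None)

    def phylum_labels(self) -> list[str]:
        """Phylum per OTU parsed from lineage strings; 'unknown' if absent."""
        if self.taxonomy is None:
            return ["unknown"] * self.n_otus
        out = []
        for lin in self.taxonomy:
            phylum = "unknown"
            for tok in str(lin).split(";"):
                tok = tok.strip()
                if tok.startswith("p__") and len(tok) > 3:
                    phylum = tok[3:]
            out.append(phylum)
        return out


@dataclass
class SampleFrame:
    """Per-sample metadata and host phenotype responses.

    Wraps a DataFrame indexed by sample id with the design columns
    ``subject_id``, ``week``, ``treatment`` (control/STAT), ``diet`` (NC/HFD),
    ``sex`` (M/F) and any subset of the phenotype columns in
    :data:`PHENOTYPES` plus ``glucose`` (mg/dL) and ``insulin`` (mU/L).
    Unknown columns are preserved as extras.
    """

    frame: pd.DataFrame
    extras: list[str] = field(default_factory=list)

    REQUIRED = ("subject_id", "week", "treatment", "diet", "sex")

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ParseError(f"metadata missing required columns: {missing}")
        if df.index.duplicated().any():
            raise ParseError("duplicate sample ids in metadata")
        dup = df.duplicated(subset=["subject_id", "week"])
        if dup.any():
            raise ParseError(
                f"duplicate (subject_id, week) pairs: {df.index[dup].tolist()}")
        for col, allowed in (("treatment", TREATMENTS), ("diet", DIETS), ("sex", SEXES)):
            bad = set(df[col].astype(str)) - set(allowed)
            if bad:
                raise ParseError(f"column {col!r} has invalid values {sorted(bad)}; "
                                 f"allowed: {allowed}")
        df["week"] = df["week"].astype(int)

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.frame.index]

    @property
    def subjects(self) -> np.ndarray:
        return self.frame["subject_id"].to_numpy()

    @property
    def weeks(self) -> np.ndarray:
        return self.frame["week"].to_numpy()

    def phenotype_matrix(self, names: list[str] | None = None) -> pd.DataFrame:
        """Phenotype responses as a samples x responses DataFrame."""
        if names is None:
            names = [c for c in PHENOTYPES if c in self.frame.columns]
        missing = [c for c in names if c not in self.frame.columns]
        if missing:
            raise KeyError(f"phenotypes not present: {missing}")
        return self.frame[names].astype(float)

    def aligned_to(self, table: OtuTable) -> "SampleFrame":
        """Reorder to the sample order of *table*, warning about mismatches."""
        missing = [s for s in table.sample_ids if s not in self.frame.index]
        if missing:
            raise ParseError(f"samples missing from metadata: {missing}")
        extra = [s for s in self.frame.index if s not in set(table.sample_ids)]
        if extra:
            warnings.warn(f"{len(extra)} metadata samples absent from OTU table: "
                          f"{extra[:5]}...", stacklevel=2)
        return SampleFrame(self.frame.loc[table.sample_ids].copy(), list(self.extras))


# ---------------------------------------------------------------------------
# OTU table IO
# ---------------------------------------------------------------------------

def read_otu_table(path, format: str = "tsv") -> OtuTable:
    """Read an OTU table from TSV or BIOM 1.0 JSON.

    TSV layout: optional '#' comment lines, a header line whose first token is
    ``#OTU ID`` (or any id label) followed by sample ids, one row per OTU with
    integer counts, and an optional final ``taxonomy`` column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        return _read_otu_tsv(path)
    if format == "biom-json":
        return _read_biom_json(path)
    raise ValueError(f"unknown format {format!r}")


def _read_otu_tsv(path: Path) -> OtuTable:
    header = None
    rows: list[tuple[int, list[str]]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#") and header is not None:
                continue
            if line.startswith("#") and not line.startswith("#OTU"):
                continue
            if header is None:
                header = line.lstrip("#").split("\t")
                continue
            rows.append((lineno, line.split("\t")))
    if header is None or not rows:
        raise ParseError(f"{path}: empty or header-only OTU table")
    has_tax = header[-1].strip().lower() == "taxonomy"
    sample_ids = header[1:-1] if has_tax else header[1:]
    ncol = len(header)
    otu_ids, taxonomy, counts = [], [], []
    for lineno, parts in rows:
        if len(parts) != ncol:
            raise ParseError(f"{path}:{lineno}: expected {ncol} fields, got {len(parts)}")
        otu_ids.append(parts[0])
        vals = parts[1:-1] if has_tax else parts[1:]
        if has_tax:
            taxonomy.append(parts[-1])
        try:
            row = [int(float(v)) for v in vals]
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric count ({exc})") from None
        if any(float(v) < 0 for v in vals):
            raise ParseError(f"{path}:{lineno}: negative count")
        counts.append(row)
    mat = np.asarray(counts, dtype=np.int64).T  # file is OTUs x samples
    try:
        return OtuTable(mat, sample_ids, otu_ids, taxonomy if has_tax else None)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None


def _read_biom_json(path: Path) -> OtuTable:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if not doc:
        raise ParseError(f"{path}: empty BIOM document")
    n_otus, n_samples = doc["shape"]
    otu_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    taxonomy = None
    if all(r.get("metadata") and "taxonomy" in r["metadata"] for r in doc["rows"]):
        taxonomy = []
        for r in doc["rows"]:
            t = r["metadata"]["taxonomy"]
            taxonomy.append(";".join(t) if isinstance(t, list) else str(t))
    mat = np.zeros((n_otus, n_samples), dtype=np.int64)
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = int(v)
    else:
        mat[:] = np.asarray(doc["data"], dtype=np.int64)
    return OtuTable(mat.T, sample_ids, otu_ids, taxonomy)


def write_otu_table(table: OtuTable, path) -> None:
    """Write TSV with OTUs as rows (round-trips through :func:`read_otu_table`)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        cols = ["#OTU ID", *table.sample_ids]
        if table.taxonomy is not None:
            cols.append("taxonomy")
        fh.write("\t".join(cols) + "\n")
        for j, oid in enumerate(table.otu_ids):
            row = [oid, *(str(int(c)) for c in table.counts[:, j])]
            if table.taxonomy is not None:
                row.append(table.taxonomy[j])
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Metadata IO
# ---------------------------------------------------------------------------

def read_metadata(path) -> SampleFrame:
    """Read per-sample metadata TSV keyed by sample id (first column)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    df.index = df.index.astype(str)
    df.index.name = None
    known = set(SampleFrame.REQUIRED) | set(PHENOTYPES) | {"glucose", "insulin"}
    extras = [c for c in df.columns if c not in known]
    return SampleFrame(df, extras)


def write_metadata(meta: SampleFrame, path) -> None:
    meta.frame.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Network IO
# ---------------------------------------------------------------------------

def write_network(graph: nx.Graph, path, format: str = "edge_tsv") -> None:
    """Write an association network.

    ``edge_tsv`` columns: otu_a, otu_b, sign, weight, stars_frequency.
    ``graphml`` carries the per-node ``phylum`` attribute.
    """
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(graph, path)
        return
    if format != "edge_tsv":
        raise ValueError(f"unknown network format {format!r}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("otu_a\totu_b\tsign\tweight\tstars_frequency\n")
        for u, v, d in graph.edges(data=True):
            fh.write(f"{u}\t{v}\t{d.get('sign', 1):+d}\t{d.get('weight', 0.0):.6g}"
                     f"\t{d.get('stars_frequency', float('nan')):.4g}\n")


def read_network(path) -> nx.Graph:
    """Read an edge TSV written by :func:`write_network`."""
    g = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ParseError(f"{path}: ragged edge row {parts}")
            u, v, sign, weight, freq = parts
            g.add_edge(u, v, sign=int(sign), weight=float(weight),
                       stars_frequency=float(freq))
    return g
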