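"""Data containers and plain-text file formats used across the pipeline.

All tables move between stages as TSV/CSV/JSON so each stage is independently
runnable and every artifact is diffable. Counts are features-by-samples with
feature ids as the first column and sample ids as the header row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "read_counts_tsv",
    "read_meta_tsv",
    "write_meta_tsv",
    "read_edges_tsv",
    "write_edges_tsv",
    "read_gmt",
    "write_gmt",
    "read_ct_csv",
    "write_ct_csv",
    "read_mirna_annotation",
    "write_mirna_annotation",
]

EDGE_COLUMNS = ["source", "target", "edge_type", "evidence", "source_db"]
CT_COLUMNS = ["sample", "assay", "replicate", "ct"]


@dataclass
class CountMatrix:
    """Integer feature-by-sample expression counts.

    Invariants: values are nonnegative integers, feature and sample ids are
    unique, and no sample column is entirely zero (normalization needs a
    positive library size).
    """

    values: np.ndarray
    feature_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("count matrix must be 2-dimensional")
        if not np.issubdtype(self.values.dtype, np.integer):
            if not np.allclose(self.values, np.round(self.values)):
                raise ValueError("counts must be integers")
            self.values = self.values.astype(np.int64)
        if (self.values < 0).any():
            raise ValueError("counts must be nonnegative")
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        n_feat, n_samp = self.values.shape
        if len(self.feature_ids) != n_feat or len(self.sample_ids) != n_samp:
            raise ValueError("id lists do not match matrix shape")
        if len(set(self.feature_ids)) != n_feat:
            raise ValueError("feature ids must be unique")
        if len(set(self.sample_ids)) != n_samp:
            raise ValueError("sample ids must be unique")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def library_sizes(self) -> np.ndarray:
        """Per-sample total counts."""
        return self.values.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(df.to_numpy(), list(df.index), list(df.columns))

    def subset_samples(self, samples: list[str]) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in samples]
        return CountMatrix(self.values[:, idx], list(self.feature_ids), list(samples))

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "feature"
        df.to_csv(path, sep="\t")


def read_counts_tsv(path: str | Path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix.from_frame(df)


def read_meta_tsv(path: str | Path) -> pd.DataFrame:
    """Sample metadata: index = sample id; must carry a 'group' column (BCR/BRF)."""
    meta = pd.read_csv(path, sep="\t", index_col=0)
    if "group" not in meta.columns:
        raise ValueError("metadata must have a 'group' column")
    return meta


def write_meta_tsv(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample")


def read_edges_tsv(path: str | Path) -> pd.DataFrame:
    edges = pd.read_csv(path, sep="\t")
    missing = [c for c in EDGE_COLUMNS[:3] if c not in edges.columns]
    if missing:
        raise ValueError(f"edge catalog missing columns: {missing}")
    for col in EDGE_COLUMNS[3:]:
        if col not in edges.columns:
            edges[col] = "n/a"
    return edges[EDGE_COLUMNS]


def write_edges_tsv(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False, columns=EDGE_COLUMNS)


def read_gmt(path: str | Path) -> dict[str, dict]:
    """Read a GMT gene-set file: set id <tab> description <tab> member ids..."""
    sets: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            set_id, desc = parts[0], parts[1]
            if set_id in sets:
                raise ValueError(f"duplicate set id {set_id!r}")
            members = [m for m in parts[2:] if m]
            if not members:
                raise ValueError(f"empty gene set {set_id!r}")
            sets[set_id] = {"name": desc, "members": members}
    return sets


def write_gmt(sets: dict[str, dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        for set_id, rec in sets.items():
            fh.write("\t".join([set_id, rec.get("name", set_id), *rec["members"]]) + "\n")


def read_ct_csv(path: str | Path) -> pd.DataFrame:
    ct = pd.read_csv(path)
    missing = [c for c in CT_COLUMNS if c not in ct.columns]
    if missing:
        raise ValueError(f"CT table missing columns: {missing}")
    return ct[CT_COLUMNS]


def write_ct_csv(ct: pd.DataFrame, path: str | Path) -> None:
    ct.to_csv(path, index=False, columns=CT_COLUMNS)


def read_mirna_annotation(path: str | Path) -> dict[str, list[str]]:
    """Two-column TSV mapping miRNA id -> pathway/set id; returns set -> miRNAs."""
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[1] < 2:
        raise ValueError("annotation table needs two columns (mirna, set_id)")
    out: dict[str, list[str]] = {}
    for mirna, set_id in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out.setdefault(str(set_id), [])
        if str(mirna) not in out[str(set_id)]:
            out[str(set_id)].append(str(mirna))
    return out


def write_mirna_annotation(annotation: dict[str, list[str]], path: str | Path) -> None:
    rows = [(m, s) for s, mirnas in annotation.items() for m in mirnas]
    pd.DataFrame(rows, columns=["mirna", "set_id"]).to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
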