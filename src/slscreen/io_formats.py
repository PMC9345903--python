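"""Readers and writers for the tabular and ontology files the pipeline touches.

Everything tabular is TSV: expression matrices (genes x samples), MAF-subset
mutation calls, clinical tables, drug catalogs and AUC matrices.  Ontology
structure comes in as an OBO subset (``is_a`` / ``part_of`` edges only) with
gene annotations in a three-column GAF subset.  Each reader validates what the
downstream analysis relies on (unique identifiers, controlled vocabularies,
acyclicity) and fails with a named error carrying row/column context.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "ExpressionMatrix",
    "MutationTable",
    "DrugCatalog",
    "DEFAULT_VARIANT_VOCABULARY",
    "read_expression",
    "write_expression",
    "read_maf_subset",
    "write_maf_subset",
    "read_clinical",
    "read_obo_subset",
    "read_gaf_subset",
    "read_drug_catalog",
    "write_drug_catalog",
    "read_auc_matrix",
    "write_results_tsv",
    "write_network_json",
    "read_network_json",
]


class ParseError(ValueError):
    """A file failed validation; the message names the offending row/column."""


# Controlled vocabulary for MAF Variant_Classification.  The list is
# configurable because upstream callers differ in dialect; unknown classes are
# retained as "Other" with a warning rather than dropped, since filtering is a
# cohort-preparation decision, not a parsing one.
DEFAULT_VARIANT_VOCABULARY = frozenset(
    {
        "Missense_Mutation",
        "Silent",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Translation_Start_Site",
        "Other",
    }
)


@dataclass
class ExpressionMatrix:
    """Expression values for genes x samples on a declared scale.

    ``scale_tag`` is ``"tpm"`` (non-negative, per-sample sum 1e6) or
    ``"log2tpm"`` (log2(TPM+1)).  ``sample_meta`` optionally carries
    ``tissue`` (tumor|normal), ``batch`` and ``pair_id`` columns indexed by
    sample.
    """

    values: pd.DataFrame  # genes x samples
    scale_tag: str = "tpm"
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.scale_tag not in ("tpm", "log2tpm"):
            raise ParseError(f"unknown scale_tag {self.scale_tag!r}")
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise ParseError(f"duplicate gene identifier {dup!r}")
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise ParseError(f"duplicate sample identifier {dup!r}")
        if not np.issubdtype(self.values.to_numpy().dtype, np.number):
            raise ParseError("non-numeric cell in expression matrix")
        if self.scale_tag == "tpm" and (self.values.to_numpy() < 0).any():
            g, s = np.argwhere(self.values.to_numpy() < 0)[0]
            raise ParseError(
                f"negative TPM at gene {idx[g]!r}, sample {cols[s]!r}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def to_log2(self) -> "ExpressionMatrix":
        """Return a log2(TPM+1)-scale copy (identity if already on it)."""
        if self.scale_tag == "log2tpm":
            return self
        return ExpressionMatrix(
            np.log2(self.values + 1.0), "log2tpm", self.sample_meta
        )


@dataclass
class MutationTable:
    """Long-format somatic mutation calls (sample, gene, classification)."""

    records: pd.DataFrame  # columns: sample, gene, variant_classification
    vocabulary: frozenset[str] = DEFAULT_VARIANT_VOCABULARY

    def __post_init__(self) -> None:
        need = {"sample", "gene", "variant_classification"}
        missing = need - set(self.records.columns)
        if missing:
            raise ParseError(f"mutation table missing column(s) {sorted(missing)}")
        if self.records[sorted(need)].isna().any().any():
            raise ParseError("mutation table contains null fields")
        bad = ~self.records["variant_classification"].isin(self.vocabulary)
        if bad.any():
            n = int(bad.sum())
            warnings.warn(
                f"{n} mutation record(s) with unknown classification retained as 'Other'",
                stacklevel=2,
            )
            self.records = self.records.copy()
            self.records.loc[bad, "variant_classification"] = "Other"

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class DrugCatalog:
    """Drug-target rows (drug_id, drug_name, target_gene), unique per (drug, target)."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"drug_id", "drug_name", "target_gene"}
        missing = need - set(self.records.columns)
        if missing:
            raise ParseError(f"drug catalog missing column(s) {sorted(missing)}")
        self.records = self.records.drop_duplicates(
            subset=["drug_id", "target_gene"]
        ).reset_index(drop=True)

    def targets_of(self, drug_id: str) -> list[str]:
        r = self.records
        return list(r.loc[r["drug_id"] == drug_id, "target_gene"])

    def drugs_for(self, gene: str) -> list[str]:
        r = self.records
        return list(r.loc[r["target_gene"] == gene, "drug_id"])

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# expression


def read_expression(
    path: str | Path,
    scale_tag: str = "tpm",
    sample_meta: pd.DataFrame | None = None,
) -> ExpressionMatrix:
    """Read a genes-x-samples TSV (header row = samples, first column = genes)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # malformed header / ragged rows
        raise ParseError(f"cannot parse expression TSV {path}: {exc}") from exc
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise ParseError(
                f"non-numeric cell in sample column {col!r}"
                f" (first offending gene {bad.index[0]!r})"
            )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    df.columns.name = None
    return ExpressionMatrix(df.astype(float), scale_tag, sample_meta)


def write_expression(em: ExpressionMatrix, path: str | Path) -> None:
    em.values.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# mutations & clinical


def read_maf_subset(
    path: str | Path, vocabulary: frozenset[str] = DEFAULT_VARIANT_VOCABULARY
) -> MutationTable:
    """Read the three MAF columns the pipeline needs; extra columns ignored.

    Required columns: ``Tumor_Sample_Barcode``, ``Hugo_Symbol``,
    ``Variant_Classification``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    rename = {
        "Tumor_Sample_Barcode": "sample",
        "Hugo_Symbol": "gene",
        "Variant_Classification": "variant_classification",
    }
    missing = set(rename) - set(df.columns)
    if missing:
        raise ParseError(f"MAF file missing column(s) {sorted(missing)}")
    df = df[list(rename)].rename(columns=rename)
    return MutationTable(df, vocabulary)


def write_maf_subset(mtab: MutationTable, path: str | Path) -> None:
    out = mtab.records.rename(
        columns={
            "sample": "Tumor_Sample_Barcode",
            "gene": "Hugo_Symbol",
            "variant_classification": "Variant_Classification",
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a clinical TSV with columns sample, time (years), event (0/1)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"sample", "time", "event"} - set(df.columns)
    if missing:
        raise ParseError(f"clinical table missing column(s) {sorted(missing)}")
    df["sample"] = df["sample"].astype(str)
    if (df["time"] <= 0).any():
        bad = df.loc[df["time"] <= 0, "sample"].iloc[0]
        raise ParseError(f"non-positive survival time for sample {bad!r}")
    if not df["event"].isin([0, 1]).all():
        raise ParseError("clinical event column must be 0/1")
    return df


# ---------------------------------------------------------------------------
# ontology


def read_obo_subset(path: str | Path) -> "nx.DiGraph":
    """Parse an OBO subset into a typed GO DAG.

    Only ``[Term]`` stanzas are read; the fields used are ``id``, ``name``,
    ``namespace``, ``is_a`` and ``relationship: part_of``.  Obsolete terms and
    other relationship types are ignored.  Edges point child -> parent with an
    ``etype`` attribute.  A cycle is a hard error naming one offending loop.
    """
    g = nx.DiGraph()
    ns_map = {
        "molecular_function": "MF",
        "cellular_component": "CC",
        "biological_process": "BP",
    }
    cur: dict | None = None
    stanzas: list[dict] = []

    def flush() -> None:
        if cur and not cur.get("obsolete") and "id" in cur:
            stanzas.append(dict(cur))

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line == "[Term]":
                flush()
                cur = {"parents": []}
            elif cur is None or not line or line.startswith("["):
                if line.startswith("[") and line != "[Term]":
                    flush()
                    cur = None
                continue
            elif line.startswith("id:"):
                cur["id"] = line[3:].strip()
            elif line.startswith("name:"):
                cur["name"] = line[5:].strip()
            elif line.startswith("namespace:"):
                cur["namespace"] = ns_map.get(line[10:].strip(), line[10:].strip())
            elif line.startswith("is_obsolete: true"):
                cur["obsolete"] = True
            elif line.startswith("is_a:"):
                parent = line[5:].strip().split("!")[0].strip()
                cur["parents"].append((parent, "is_a"))
            elif line.startswith("relationship:"):
                parts = line[13:].strip().split()
                if len(parts) >= 2 and parts[0] == "part_of":
                    cur["parents"].append((parts[1], "part_of"))
    flush()

    for st in stanzas:
        g.add_node(st["id"], namespace=st.get("namespace", ""), name=st.get("name", ""))
    for st in stanzas:
        for parent, etype in st["parents"]:
            if parent not in g:
                warnings.warn(f"edge to unknown term {parent!r} dropped", stacklevel=2)
                continue
            g.add_edge(st["id"], parent, etype=etype)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise ParseError(f"ontology contains a cycle: {cycle}")
    return g


def read_gaf_subset(path: str | Path, graph: "nx.DiGraph") -> dict:
    """Parse gene annotations (columns gene, term, aspect in {F,C,P}).

    Annotations to terms absent from ``graph`` are dropped; the total dropped
    count is emitted as a single warning.  Returns
    ``{gene: {"MF": set, "CC": set, "BP": set}}``.
    """
    aspect_map = {"F": "MF", "C": "CC", "P": "BP"}
    df = pd.read_csv(path, sep="\t", comment="!", dtype=str)
    missing = {"gene", "term", "aspect"} - set(df.columns)
    if missing:
        raise ParseError(f"GAF subset missing column(s) {sorted(missing)}")
    ann: dict[str, dict[str, set]] = {}
    dropped = 0
    for gene, term, aspect in df[["gene", "term", "aspect"]].itertuples(index=False):
        if aspect not in aspect_map:
            raise ParseError(f"unknown GAF aspect {aspect!r} for gene {gene!r}")
        if term not in graph:
            dropped += 1
            continue
        ann.setdefault(gene, {"MF": set(), "CC": set(), "BP": set()})
        ann[gene][aspect_map[aspect]].add(term)
    if dropped:
        warnings.warn(f"{dropped} annotation(s) to unknown terms dropped", stacklevel=2)
    return ann


# ---------------------------------------------------------------------------
# drugs


def read_drug_catalog(path: str | Path) -> DrugCatalog:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return DrugCatalog(df)


def write_drug_catalog(cat: DrugCatalog, path: str | Path) -> None:
    cat.records.to_csv(path, sep="\t", index=False)


def read_auc_matrix(path: str | Path) -> pd.DataFrame:
    """Read a CCL x compound AUC matrix; empty cells become NaN."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df.astype(float)


# ---------------------------------------------------------------------------
# results


def write_results_tsv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a result table with a stable, documented column order."""
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_network_json(network, path: str | Path) -> None:
    """Serialize a driver-target-drug network losslessly to JSON."""
    payload = {
        "nodes": [
            {"id": n, **d} for n, d in sorted(network.nodes(data=True))
        ],
        "edges": [
            {"source": u, "target": v, **d}
            for u, v, d in sorted(network.edges(data=True), key=lambda e: (e[0], e[1]))
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_network_json(path: str | Path) -> nx.DiGraph:
    with open(path) as fh:
        payload = json.load(fh)
    g = nx.DiGraph()
    for node in payload["nodes"]:
        node = dict(node)
        g.add_node(node.pop("id"), **node)
    for edge in payload["edges"]:
        edge = dict(edge)
        g.add_edge(edge.pop("source"), edge.pop("target"), **edge)
    return g
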