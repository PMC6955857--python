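"""Typed data model and readers/writers for community tables, trees, and metadata.

The central objects are:

* :class:`CommunityTable` — a samples × taxa matrix of integer read counts
  (the OTU table every downstream stage consumes),
* :class:`Phylogeny` — a rooted tree with branch lengths whose tips are the
  taxa, the source of patristic distances for phylogenetic turnover,
* a metadata table of per-sample covariates (subject, elevation, body site,
  host factors),
* :class:`DistanceMatrix` — a symmetric pairwise matrix with explicit ID
  order and a recorded metric name.

On-disk formats are plain TSV (OTU table: taxa as rows, samples as columns,
optional trailing ``taxonomy`` column) and Newick.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BODY_SITES = ("forehead", "opisthenar", "palm")
GENDERS = ("female", "male")

#: metadata columns that must be present in every metadata file
REQUIRED_METADATA_COLUMNS = ("sample_id", "subject_id", "elevation_m", "body_site")

#: optional host covariates, coerced to float when present
NUMERIC_METADATA_COLUMNS = ("elevation_m", "age", "height", "weight", "uv_uw_cm2")

DEFAULT_ELEVATION_CUTOFF_M = 3000.0

class FormatError(ValueError):
    """A structural problem in an input file (duplicate IDs, bad counts, ...)."""

# ---------------------------------------------------------------------------
# CommunityTable

@dataclass
class CommunityTable:
    """Samples × taxa matrix of non-negative integer counts.

    Parameters
    ----------
    counts
        DataFrame with sample IDs as the index and taxon IDs as columns.
        Values must be non-negative integers.
    taxonomy
        Optional map from taxon ID to a lineage string.
    """

    counts: pd.DataFrame
    taxonomy: dict[str, str] | None = None

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            raise FormatError("duplicate sample identifiers")
        if df.columns.has_duplicates:
            raise FormatError("duplicate taxon identifiers")
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise FormatError("non-numeric counts")
        if values.size:
            if np.any(values < 0):
                raise FormatError("negative counts")
            if not np.all(np.equal(np.mod(values, 1), 0)):
                raise FormatError("non-integral counts")
        self.counts = df.astype(np.int64)
        self.counts.index = self.counts.index.astype(str)
        self.counts.index.name = "sample_id"
        self.counts.columns = self.counts.columns.astype(str)
        self.counts.columns.name = None

    # -- accessors ----------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def matrix(self) -> np.ndarray:
        return self.counts.to_numpy()

    def relative_abundance(self) -> pd.DataFrame:
        """Row-normalized counts (a derived view; counts stay integral)."""
        totals = self.counts.sum(axis=1)
        if (totals == 0).any():
            raise ValueError("cannot normalise samples with zero total count")
        return self.counts.div(totals, axis=0)

    # -- subsetting ---------------------------------------------------------

    def select_samples(self, sample_ids) -> "CommunityTable":
        missing = set(sample_ids) - set(self.counts.index)
        if missing:
            raise KeyError(f"unknown sample ids: {sorted(missing)}")
        return CommunityTable(self.counts.loc[list(sample_ids)].copy(), self.taxonomy)

    def select_taxa(self, taxon_ids) -> "CommunityTable":
        missing = set(taxon_ids) - set(self.counts.columns)
        if missing:
            raise KeyError(f"unknown taxon ids: {sorted(missing)}")
        sub = self.counts[list(taxon_ids)].copy()
        empty = sub.sum(axis=1) == 0
        if empty.any():
            raise ValueError(
                f"{int(empty.sum())} samples empty after taxon selection"
            )
        tax = None
        if self.taxonomy is not None:
            tax = {t: self.taxonomy[t] for t in taxon_ids if t in self.taxonomy}
        return CommunityTable(sub, tax)

def read_community_table(path, orientation: str = "taxa_rows") -> CommunityTable:
    """Read a TSV OTU table.

    The default orientation has taxa as rows (first column = taxon ID) and
    samples as columns; a trailing ``taxonomy`` column is split off when
    present. Orientation is an explicit flag, never guessed from the header.
    """
    if orientation not in ("taxa_rows", "samples_rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise FormatError("duplicate identifiers in table")
    taxonomy = None
    if orientation == "taxa_rows" and df.columns.size and df.columns[-1].lower() == "taxonomy":
        taxonomy = df["taxonomy"].to_dict()
        df = df.drop(columns=["taxonomy"])
    try:
        numeric = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric count in table: {exc}") from exc
    if orientation == "taxa_rows":
        numeric = numeric.T
    numeric.index.name = "sample_id"
    numeric.columns.name = None
    return CommunityTable(numeric, taxonomy)

def write_community_table(table: CommunityTable, path) -> None:
    """Write a CommunityTable as TSV with taxa as rows and samples as columns."""
    out = table.counts.T.copy()
    out.index.name = "taxon_id"
    if table.taxonomy is not None:
        out["taxonomy"] = [table.taxonomy.get(t, "") for t in out.index]
    out.to_csv(path, sep="\t")

# ---------------------------------------------------------------------------
# Phylogeny

@dataclass
class Phylogeny:
    """Rooted tree with branch lengths; tips are taxon identifiers."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise FormatError("duplicate tip labels in tree")
        n_missing = 0
        for edge in self.tree.preorder_edge_iter():
            if edge.length is None:
                edge.length = 0.0
                n_missing += 1
            elif edge.length < 0:
                raise FormatError("negative branch length")
        if n_missing:
            logger.warning("%d missing branch lengths set to 0", n_missing)

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def patristic_matrix(self, taxa=None) -> tuple[list[str], np.ndarray]:
        """Pairwise tip-to-tip path-length distances.

        Returns the taxon order used and a symmetric matrix with zero
        diagonal. ``taxa`` restricts and orders the output.
        """
        pdm = self.tree.phylogenetic_distance_matrix()
        by_label = {t.label: t for t in self.tree.taxon_namespace if t.label}
        order = self.tip_labels if taxa is None else list(taxa)
        missing = [t for t in order if t not in by_label]
        if missing:
            raise KeyError(f"taxa not on tree: {missing[:5]}")
        n = len(order)
        dist = np.zeros((n, n))
        for i in range(n):
            ti = by_label[order[i]]
            for j in range(i + 1, n):
                d = pdm.patristic_distance(ti, by_label[order[j]])
                dist[i, j] = dist[j, i] = d
        return order, dist

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

def read_newick(path_or_string) -> Phylogeny:
    """Parse a Newick tree from a path or a literal Newick string."""
    src = str(path_or_string)
    try:
        if src.strip().startswith("("):
            tree = dendropy.Tree.get(data=src, schema="newick")
        else:
            tree = dendropy.Tree.get(path=src, schema="newick")
    except Exception as exc:  # dendropy raises schema-specific subclasses
        raise FormatError(f"could not parse Newick: {exc}") from exc
    return Phylogeny(tree)

def write_newick(phylogeny: Phylogeny, path) -> None:
    with open(path, "w") as fh:
        fh.write(phylogeny.to_newick() + "\n")

# ---------------------------------------------------------------------------
# Sample metadata

def _validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    for col in REQUIRED_METADATA_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"metadata missing required column {col!r}")
    if df["sample_id"].duplicated().any():
        raise FormatError("duplicate sample_id in metadata")
    df = df.copy()
    for col in NUMERIC_METADATA_COLUMNS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
    if (df["elevation_m"] <= 0).any():
        raise ValueError("elevation_m must be positive")
    bad_sites = set(df["body_site"]) - set(BODY_SITES)
    if bad_sites:
        raise ValueError(f"unknown body site(s): {sorted(bad_sites)}")
    return df.set_index("sample_id", drop=False)

def read_metadata(path) -> pd.DataFrame:
    """Read the per-sample metadata TSV; returns a frame indexed by sample_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return _validate_metadata(df)

def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index=False)

def metadata_from_records(records) -> pd.DataFrame:
    """Build a validated metadata frame from an iterable of dicts."""
    return _validate_metadata(pd.DataFrame.from_records(list(records)))

def assign_elevation_groups(
    metadata: pd.DataFrame, cutoff_m: float = DEFAULT_ELEVATION_CUTOFF_M
) -> dict[str, str]:
    """Partition samples into ``high``/``low`` elevation groups.

    A sample is ``high`` iff its elevation is >= ``cutoff_m`` (so a sample at
    exactly the cutoff is high). The default cutoff of 3000 m falls in the gap
    between the study design's 2690 m and 3110 m sites.
    """
    groups = {
        str(sid): ("high" if elev >= cutoff_m else "low")
        for sid, elev in zip(metadata["sample_id"], metadata["elevation_m"])
    }
    n_high = sum(1 for g in groups.values() if g == "high")
    logger.info("elevation groups: %d high / %d low (cutoff %.0f m)",
                n_high, len(groups) - n_high, cutoff_m)
    return groups

# ---------------------------------------------------------------------------
# DistanceMatrix

@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with explicit ID order."""

    ids: list[str]
    values: np.ndarray
    metric_name: str = "distance"

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        vals = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if vals.shape != (n, n):
            raise ValueError(f"matrix shape {vals.shape} does not match {n} ids")
        if len(set(self.ids)) != n:
            raise FormatError("duplicate ids in distance matrix")
        if not np.allclose(vals, vals.T, atol=1e-10, equal_nan=True):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(vals), 0.0, atol=1e-10):
            raise ValueError("distance matrix diagonal is not zero")
        self.values = (vals + vals.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy ``squareform`` order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def submatrix(self, ids) -> "DistanceMatrix":
        idx = {s: i for i, s in enumerate(self.ids)}
        missing = [s for s in ids if s not in idx]
        if missing:
            raise KeyError(f"ids not in matrix: {missing[:5]}")
        sel = [idx[s] for s in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(sel, sel)], self.metric_name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = self.metric_name
        df.to_csv(path, sep="\t")

def read_distance_matrix(path, metric_name: str | None = None) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    name = metric_name or (df.index.name or "distance")
    return DistanceMatrix(list(df.index.astype(str)), df.to_numpy(float), name)
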