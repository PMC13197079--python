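"""Readers and writers for the package's tabular and tree artifacts.

All delimited files are comma-separated with a header row, decimal points and
no thousands separators. Species order as read from file is canonical: every
matrix produced downstream (resamples, consensus, distances) is indexed in
that order.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "TraitTable",
    "CommunityTable",
    "read_trait_table",
    "read_community_table",
    "write_labels",
    "read_labels",
    "save_consensus",
    "load_consensus",
    "export_dendrogram_newick",
    "linkage_to_newick",
]

#: taxon label used when a trait table carries no taxon column
DEFAULT_TAXON = "all"


@dataclass
class TraitTable:
    """Complete species x trait matrix on natural-log scale.

    Parameters
    ----------
    species_ids : sequence of str
        Unique species identifiers, one per row.
    trait_names : sequence of str
        Trait column identifiers.
    values : (N, M) ndarray
        Log-scale trait values; no missing entries allowed. This tool models
        imputation *error*, not imputation itself, so matrices must be
        complete on input.
    taxon : sequence of str, optional
        Per-species coarse taxon label (e.g. "angiosperm"/"gymnosperm") used
        to select error pools. When omitted every species shares one label.
    """

    species_ids: np.ndarray
    trait_names: list[str]
    values: np.ndarray
    taxon: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.species_ids = np.asarray(self.species_ids, dtype=object)
        self.trait_names = list(self.trait_names)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("trait values must be a 2-D matrix")
        n, m = self.values.shape
        if n < 2:
            raise ValueError("a trait table needs at least 2 species")
        if m < 1 or len(self.trait_names) != m:
            raise ValueError(
                f"trait_names length {len(self.trait_names)} does not match "
                f"matrix width {m}"
            )
        if len(self.species_ids) != n:
            raise ValueError("species_ids length does not match matrix height")
        uniq, counts = np.unique(self.species_ids.astype(str), return_counts=True)
        if (counts > 1).any():
            dup = uniq[counts > 1][0]
            raise ValueError(f"duplicate species id {dup!r}")
        if not np.isfinite(self.values).all():
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"missing/non-finite trait value for species "
                f"{self.species_ids[i]!r}, trait {self.trait_names[j]!r}; "
                "complete matrices are required"
            )
        if self.taxon is not None:
            self.taxon = np.asarray(self.taxon, dtype=object)
            if len(self.taxon) != n:
                raise ValueError("taxon length does not match matrix height")

    @property
    def n_species(self) -> int:
        return self.values.shape[0]

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]

    def taxon_labels(self) -> np.ndarray:
        """Per-species taxon labels, defaulting to one shared label."""
        if self.taxon is None:
            return np.full(self.n_species, DEFAULT_TAXON, dtype=object)
        return self.taxon

    def to_dataframe(self, id_column: str = "species",
                     taxon_column: str = "taxon") -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.trait_names)
        df.insert(0, id_column, self.species_ids)
        if self.taxon is not None:
            df.insert(1, taxon_column, self.taxon)
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, id_column: str,
                       taxon_column: str | None = None) -> "TraitTable":
        trait_cols = [c for c in df.columns if c not in (id_column, taxon_column)]
        values = np.empty((len(df), len(trait_cols)), dtype=float)
        for j, col in enumerate(trait_cols):
            numeric = pd.to_numeric(df[col], errors="coerce")
            bad = numeric.isna() & df[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValueError(
                    f"non-numeric trait value {df[col].iloc[row]!r} at row "
                    f"{row}, column {col!r}"
                )
            if numeric.isna().any():
                row = int(np.flatnonzero(numeric.isna().to_numpy())[0])
                raise ValueError(
                    f"missing trait value at row {row}, column {col!r}"
                )
            values[:, j] = numeric.to_numpy()
        taxon = df[taxon_column].to_numpy() if taxon_column else None
        return cls(df[id_column].to_numpy(), trait_cols, values, taxon)

    def write_csv(self, path, id_column: str = "species",
                  taxon_column: str = "taxon") -> None:
        self.to_dataframe(id_column, taxon_column).to_csv(path, index=False)


@dataclass
class CommunityTable:
    """Sites x species presence-absence matrix (binary entries only)."""

    site_ids: np.ndarray
    species_ids: np.ndarray
    presence: np.ndarray

    def __post_init__(self) -> None:
        self.site_ids = np.asarray(self.site_ids, dtype=object)
        self.species_ids = np.asarray(self.species_ids, dtype=object)
        self.presence = np.asarray(self.presence)
        if self.presence.shape != (len(self.site_ids), len(self.species_ids)):
            raise ValueError("presence shape does not match site/species ids")
        if not np.isin(self.presence, (0, 1)).all():
            raise ValueError("presence matrix must contain only 0/1 entries")
        self.presence = self.presence.astype(np.int8)

    def species_at(self, site_index: int) -> np.ndarray:
        """Species ids present at one site (duplicate columns collapse)."""
        present = self.species_ids[self.presence[site_index] == 1]
        return np.unique(present.astype(str))


def read_trait_table(path, id_column: str = "species",
                     taxon_column: str | None = None) -> TraitTable:
    """Read a delimited species x trait table, preserving row order.

    Raises on duplicate ids, non-numeric trait cells and missing values; the
    error names the offending id or row/column.
    """
    df = pd.read_csv(path)
    if id_column not in df.columns:
        raise ValueError(f"id column {id_column!r} not found in {path}")
    return TraitTable.from_dataframe(df, id_column, taxon_column)


def read_community_table(path, site_column: str = "site") -> CommunityTable:
    df = pd.read_csv(path)
    if site_column not in df.columns:
        raise ValueError(f"site column {site_column!r} not found in {path}")
    species = [c for c in df.columns if c != site_column]
    return CommunityTable(df[site_column].to_numpy(), np.asarray(species, dtype=object),
                          df[species].to_numpy())


def write_labels(labels: Sequence[int], species_ids: Sequence, path) -> None:
    """Write a two-column (species_id, group) CSV; round-trips exactly."""
    labels = np.asarray(labels)
    species_ids = np.asarray(species_ids, dtype=object)
    if labels.size == 0:
        raise ValueError("empty label vector")
    if len(labels) != len(species_ids):
        raise ValueError(
            f"labels length {len(labels)} != species_ids length {len(species_ids)}"
        )
    pd.DataFrame({"species_id": species_ids, "group": labels.astype(int)}).to_csv(
        path, index=False
    )


def read_labels(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a labels CSV back as (species_ids, labels)."""
    df = pd.read_csv(path)
    return df["species_id"].to_numpy(), df["group"].to_numpy(dtype=int)


def _triangle_checksum(tri: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(tri).tobytes()).hexdigest()


def save_consensus(consensus, path, dtype=np.float32) -> None:
    """Store a consensus matrix as an HDF5 container.

    Only the strict upper triangle is stored (the diagonal is 1 by
    definition), as float32 by default: consensus entries are means of at
    most S*A Bernoulli indicators, so their resolution is 1/(S*A) and single
    precision loses nothing at practical ensemble sizes.
    """
    from .consensus import ConsensusMatrix  # local import avoids cycle

    if not isinstance(consensus, ConsensusMatrix):
        raise TypeError("save_consensus expects a ConsensusMatrix")
    values = consensus.values
    if not np.allclose(values, values.T, atol=1e-12):
        raise ValueError("consensus matrix must be symmetric")
    n = values.shape[0]
    iu = np.triu_indices(n, k=1)
    tri = values[iu].astype(dtype)
    with h5py.File(path, "w") as h5:
        h5.create_dataset("triangle", data=tri)
        h5.create_dataset(
            "species_ids",
            data=np.asarray([str(s) for s in consensus.species_ids], dtype="S"),
        )
        h5.attrs["n_species"] = n
        h5.attrs["n_samples_total"] = consensus.n_samples_total
        h5.attrs["checksum"] = _triangle_checksum(tri)


def load_consensus(path):
    """Load a consensus matrix saved by :func:`save_consensus`.

    The full symmetric matrix is reconstructed from the stored triangle with
    a unit diagonal; shape and checksum mismatches are hard errors.
    """
    from .consensus import ConsensusMatrix

    with h5py.File(path, "r") as h5:
        tri = h5["triangle"][...]
        species = np.asarray([s.decode() for s in h5["species_ids"][...]],
                             dtype=object)
        n = int(h5.attrs["n_species"])
        n_samples = int(h5.attrs["n_samples_total"])
        checksum = h5.attrs["checksum"]
    if tri.size != n * (n - 1) // 2 or len(species) != n:
        raise ValueError("consensus container shape mismatch")
    if _triangle_checksum(tri) != checksum:
        raise ValueError("consensus container checksum mismatch")
    values = np.ones((n, n), dtype=float)
    iu = np.triu_indices(n, k=1)
    values[iu] = tri
    values[(iu[1], iu[0])] = tri
    return ConsensusMatrix(values, n_samples, species)


def linkage_to_newick(linkage: np.ndarray, leaf_names: Sequence) -> str:
    """Render a scipy-style linkage matrix as a Newick string.

    Branch lengths are differences of merge heights: each node's branch is
    its parent's merge height minus its own (leaves sit at height 0). The
    consensus distance is a dissimilarity, not calibrated time, so these
    lengths are dendrogram heights rather than an ultrametric clock.
    """
    from scipy.cluster.hierarchy import to_tree

    names = [str(s) for s in leaf_names]
    if len(set(names)) != len(names):
        raise ValueError("leaf names must be unique for Newick export")
    forbidden = set("():;, \t\n")
    for name in names:
        if forbidden & set(name):
            raise ValueError(f"leaf name {name!r} contains Newick metacharacters")
    root = to_tree(np.asarray(linkage, dtype=float))

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{names[node.id]}:{length:.10g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    left = render(root.left, root.dist)
    right = render(root.right, root.dist)
    return f"({left},{right});"


def export_dendrogram_newick(linkage: np.ndarray, species_ids: Sequence,
                             path) -> None:
    """Write the dendrogram implied by ``linkage`` as a Newick file."""
    newick = linkage_to_newick(linkage, species_ids)
    with open(path, "w") as fh:
        fh.write(newick + "\n")
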