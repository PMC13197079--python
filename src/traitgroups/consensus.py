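"""Co-assignment consensus matrix and the derived consensus distance.

The ensemble of per-resample partitions is summarized by the consensus
matrix C: C[i, i'] is the fraction of ensemble label vectors in which
species i and i' share a group, with the diagonal fixed at 1. Treating
D = 1 - C as a dissimilarity lets ordinary hierarchical clustering act on
the ensemble. D is not guaranteed to satisfy the triangle inequality; Ward
linkage is applied to it regardless, which is standard consensus-clustering
practice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .gmm import EnsembleMember

__all__ = [
    "ConsensusMatrix",
    "ConsensusAccumulator",
    "accumulate_consensus",
    "consensus_to_distance",
    "max_consensus_se",
]


@dataclass
class ConsensusMatrix:
    """Symmetric N x N co-assignment proportion matrix with unit diagonal.

    Off-diagonal entries are integer multiples of 1/n_samples_total, where
    n_samples_total is S (argmax mode) or S*A (sampling mode).
    """

    values: np.ndarray
    n_samples_total: int
    species_ids: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("consensus matrix must be square")
        if self.species_ids is None:
            self.species_ids = np.arange(n).astype(object)
        else:
            self.species_ids = np.asarray(self.species_ids, dtype=object)
            if len(self.species_ids) != n:
                raise ValueError("species_ids length mismatch")

    @property
    def n_species(self) -> int:
        return self.values.shape[0]


class ConsensusAccumulator:
    """Streaming accumulation of co-assignment counts.

    One N x N co-occurrence matrix is held at a time, so peak memory is
    O(N^2) regardless of ensemble size. Accumulation is order-independent:
    parallel and serial runs over the same label vectors agree exactly.
    """

    def __init__(self, n_species: int, species_ids=None):
        if n_species < 2:
            raise ValueError("need at least 2 species")
        self.n_species = n_species
        self.species_ids = species_ids
        self._counts = np.zeros((n_species, n_species), dtype=np.float64)
        self._n_vectors = 0

    def add_labels(self, labels: np.ndarray) -> None:
        labels = np.asarray(labels)
        if labels.shape != (self.n_species,):
            raise ValueError(
                f"label vector length {labels.shape} does not match "
                f"N={self.n_species}"
            )
        self._counts += labels[:, None] == labels[None, :]
        self._n_vectors += 1

    def add_member(self, member: EnsembleMember) -> None:
        if not member.assignments:
            raise ValueError("ensemble member carries no assignments")
        for labels in member.assignments:
            self.add_labels(labels)

    def finalize(self) -> ConsensusMatrix:
        if self._n_vectors == 0:
            raise ValueError("no label vectors accumulated")
        values = self._counts / self._n_vectors
        np.fill_diagonal(values, 1.0)
        return ConsensusMatrix(values, self._n_vectors, self.species_ids)


def accumulate_consensus(members: Iterable[EnsembleMember],
                         species_ids=None) -> ConsensusMatrix:
    """Build the consensus matrix from an ensemble of members.

    All members must cover the same species in the same order; the entry for
    a pair is the fraction of label vectors in which the pair shares a
    group, and the diagonal is exactly 1.
    """
    members = list(members)
    if not members:
        raise ValueError("need at least one ensemble member")
    n = len(members[0].assignments[0])
    acc = ConsensusAccumulator(n, species_ids)
    for member in members:
        for labels in member.assignments:
            if len(labels) != n:
                raise ValueError("inconsistent species count across members")
        acc.add_member(member)
    return acc.finalize()


def consensus_to_distance(consensus: ConsensusMatrix) -> np.ndarray:
    """Elementwise D = 1 - C with an exactly zero diagonal."""
    d = 1.0 - consensus.values
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 1.0)


def max_consensus_se(n_samples_total: int) -> float:
    """Worst-case Monte-Carlo standard error of a consensus entry.

    Each entry is the mean of n Bernoulli indicators, so its standard error
    is at most sqrt(0.25 / n) — about 0.07 at 50 samples.
    """
    if n_samples_total < 1:
        raise ValueError("sample count must be positive")
    return float(np.sqrt(0.25 / n_samples_total))
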