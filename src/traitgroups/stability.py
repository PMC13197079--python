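"""Stability diagnostics for consensus partitions.

Three views of robustness: (i) per-species stability — the share of a
species' total consensus mass directed at its own final group; (ii) the
group-level consensus summary — mean within- and between-group consensus;
and (iii) an ensemble experiment contrasting the agreement (adjusted Rand
index) among single-resample mixture partitions with the agreement among
consensus partitions built from blocks of resamples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .consensus import ConsensusMatrix

__all__ = [
    "species_stability",
    "group_consensus_summary",
    "adjusted_rand_index",
    "StabilityExperimentResult",
    "stability_experiment",
]


def species_stability(consensus: ConsensusMatrix, labels: np.ndarray
                      ) -> np.ndarray:
    """stab_i = within-group consensus mass / total consensus mass.

    Sums C[i, i'] over the other members of i's group and divides by the sum
    over all other species. Values lie in [0, 1]; 1 means every resample
    that linked i to anyone linked it within its final group. Species with
    zero total off-diagonal consensus get NaN with a warning.
    """
    c = consensus.values
    labels = np.asarray(labels)
    n = c.shape[0]
    if len(labels) != n:
        raise ValueError("labels length does not match consensus size")
    same = labels[:, None] == labels[None, :]
    off = ~np.eye(n, dtype=bool)
    num = (c * (same & off)).sum(axis=1)
    den = (c * off).sum(axis=1)
    stab = np.full(n, np.nan)
    ok = den > 0
    stab[ok] = num[ok] / den[ok]
    if not ok.all():
        warnings.warn(
            f"{(~ok).sum()} species have zero off-diagonal consensus; "
            "stability undefined (NaN)"
        )
    return stab


def group_consensus_summary(consensus: ConsensusMatrix, labels: np.ndarray
                            ) -> np.ndarray:
    """K x K matrix of mean consensus within (diagonal) and between groups.

    Entry (k, k) averages C over unordered within-group pairs, excluding the
    unit diagonal; entry (k, k') averages over cross-group pairs. A
    singleton group has no within pair and gets NaN on its diagonal.
    """
    c = consensus.values
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    k = len(uniq)
    onehot = (labels[:, None] == uniq[None, :]).astype(float)
    counts = onehot.sum(axis=0)
    block_sums = onehot.T @ c @ onehot
    out = np.empty((k, k))
    for a in range(k):
        for b in range(k):
            if a == b:
                n_pairs = counts[a] * (counts[a] - 1)
                out[a, b] = (
                    (block_sums[a, a] - counts[a]) / n_pairs
                    if n_pairs > 0 else np.nan
                )
            else:
                out[a, b] = block_sums[a, b] / (counts[a] * counts[b])
    return out


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two partitions.

    Standard permutation-model ARI from the contingency table: 1 for
    identical partitions up to relabeling, expectation 0 under independent
    random labelings.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    n = len(a)
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    contingency = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(contingency, (ai, bi), 1)
    comb = lambda x: x * (x - 1) / 2.0
    sum_ij = comb(contingency).sum()
    sum_a = comb(contingency.sum(axis=1)).sum()
    sum_b = comb(contingency.sum(axis=0)).sum()
    total = comb(n)
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:  # both partitions trivial
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


@dataclass
class StabilityExperimentResult:
    """Pairwise-ARI samples for the two arms of the stability experiment."""

    single_run_ari: np.ndarray
    consensus_ari: np.ndarray
    single_run_labels: list[np.ndarray]
    consensus_labels: list[np.ndarray]

    @property
    def mean_single_run_ari(self) -> float:
        return float(self.single_run_ari.mean())

    @property
    def mean_consensus_ari(self) -> float:
        return float(self.consensus_ari.mean())

    @property
    def consensus_gain(self) -> float:
        """Mean ARI improvement from the consensus step."""
        return self.mean_consensus_ari - self.mean_single_run_ari


def _pairwise_ari(partitions: list[np.ndarray]) -> np.ndarray:
    return np.array([
        adjusted_rand_index(pa, pb) for pa, pb in combinations(partitions, 2)
    ])


def stability_experiment(model, n_runs: int, group_size: int,
                         seed: int = 0) -> StabilityExperimentResult:
    """Contrast single-run vs block-consensus partition agreement.

    Fits ``n_runs`` independent single-resample mixture partitions from the
    model's data and configuration, then splits the runs into consecutive
    blocks of ``group_size`` and derives one consensus partition per block
    with the full framework (accumulate, linkage, silhouette K-selection).
    Returns all pairwise ARIs within each arm. ``model`` is an (unfitted)
    :class:`~traitgroups.model.ConsensusClustering`.
    """
    if n_runs % group_size != 0:
        raise ValueError("n_runs must be divisible by group_size")
    from .consensus import ConsensusAccumulator, consensus_to_distance
    from .hierarchy import select_K, ward_linkage

    members = [model._fit_member(seed + s, s) for s in range(1, n_runs + 1)]
    single_labels = [m.assignments[0] for m in members]

    consensus_labels = []
    n_blocks = n_runs // group_size
    for block in range(n_blocks):
        acc = ConsensusAccumulator(model.trait_table.n_species)
        for m in members[block * group_size:(block + 1) * group_size]:
            acc.add_member(m)
        cons = acc.finalize()
        distance = consensus_to_distance(cons)
        linkage = ward_linkage(distance, model.linkage)
        k_max = min(model.k_range[1], model.trait_table.n_species)
        part = select_K(linkage, distance, range(model.k_range[0], k_max + 1))
        consensus_labels.append(part.labels)

    return StabilityExperimentResult(
        single_run_ari=_pairwise_ari(single_labels),
        consensus_ari=_pairwise_ari(consensus_labels),
        single_run_labels=single_labels,
        consensus_labels=consensus_labels,
    )
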