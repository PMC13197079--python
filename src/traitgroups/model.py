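"""Model/Results interface for the consensus-clustering framework.

:class:`ConsensusClustering` holds the data (a trait table and an error
model) together with the configuration; :meth:`ConsensusClustering.fit`
runs the full pipeline — resample, fit/select mixtures, assign, accumulate
the consensus matrix, Ward linkage, silhouette K-selection — and returns a
:class:`ConsensusClusteringResults` carrying the consensus matrix, the
final partition, per-resample diagnostics and stability measures, with a
``summary()`` table and writers for every artifact.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import hierarchy, io
from .consensus import (ConsensusAccumulator, ConsensusMatrix,
                        consensus_to_distance, max_consensus_se)
from .errors import ErrorModel, apply_robust_scale, robust_scale, sample_resample
from .gmm import EnsembleMember, assign_groups, select_G
from .io import TraitTable
from .stability import group_consensus_summary, species_stability

__all__ = ["ConsensusClustering", "ConsensusClusteringResults"]

logger = logging.getLogger("traitgroups")


class ConsensusClustering:
    """Consensus clustering of a trait table under an empirical error model.

    Parameters
    ----------
    trait_table : TraitTable
        Complete species x trait matrix (log scale).
    error_model : ErrorModel
        Taxon-nested pools of empirical prediction errors; must cover every
        taxon present in the table (union fallback covers missing traits).
    n_resamples : int
        Ensemble size S. Each resample perturbs every cell independently by
        a pool draw. Default 50, which bounds the Monte-Carlo standard
        error of any consensus entry by sqrt(0.25/50) ~ 0.07.
    assignment : {"argmax", "sample"}
        Per-resample group assignment: deterministic argmax of the
        responsibilities, or ``n_assignments`` categorical draws per
        resample.
    g_range : (int, int)
        Inclusive mixture-component search range per resample (default
        10-60).
    k_range : (int, int)
        Inclusive dendrogram cut range for silhouette selection (default
        2-120).
    scale : {"robust", "none"}
        Optional median/IQR scaling of each resample's columns.
    scale_refit : {"per_resample", "from_x"}
        Whether scaling parameters are re-estimated on every resample
        (default: each resample is treated as a full realization of the
        dataset) or frozen from the unperturbed table.
    linkage : {"ward", "average", "single", "complete"}
        Agglomerative criterion applied to the consensus distance.
    em_tol, em_restarts, reg_covar, em_max_iter
        EM convergence tolerance, restart count, covariance regularization
        jitter, and iteration cap.
    """

    def __init__(self, trait_table: TraitTable, error_model: ErrorModel, *,
                 n_resamples: int = 50, assignment: str = "argmax",
                 n_assignments: int = 10, g_range=(10, 60), k_range=(2, 120),
                 scale: str = "robust", scale_refit: str = "per_resample",
                 linkage: str = "ward", em_tol: float = 1e-3,
                 em_restarts: int = 3, reg_covar: float = 1e-6,
                 em_max_iter: int = 200):
        if assignment not in ("argmax", "sample"):
            raise ValueError(f"unknown assignment mode {assignment!r}")
        if scale not in ("robust", "none"):
            raise ValueError(f"unknown scaling mode {scale!r}")
        if scale_refit not in ("per_resample", "from_x"):
            raise ValueError(f"unknown scale_refit mode {scale_refit!r}")
        if n_resamples < 1:
            raise ValueError("need at least one resample")
        g_range = (int(g_range[0]), int(g_range[1]))
        k_range = (int(k_range[0]), int(k_range[1]))
        n = trait_table.n_species
        if not 1 <= g_range[0] <= g_range[1] < n:
            raise ValueError(f"G range {g_range} invalid for N={n}")
        if not 2 <= k_range[0] <= k_range[1] <= n:
            raise ValueError(f"K range {k_range} invalid for N={n}")
        for taxon in np.unique(trait_table.taxon_labels().astype(str)):
            if taxon not in error_model.fallback_pools:
                raise ValueError(f"error model lacks taxon {taxon!r}")
        self.trait_table = trait_table
        self.error_model = error_model
        self.n_resamples = n_resamples
        self.assignment = assignment
        self.n_assignments = n_assignments
        self.g_range = g_range
        self.k_range = k_range
        self.scale = scale
        self.scale_refit = scale_refit
        self.linkage = linkage
        self.em_tol = em_tol
        self.em_restarts = em_restarts
        self.reg_covar = reg_covar
        self.em_max_iter = em_max_iter
        if scale == "robust" and scale_refit == "from_x":
            _, self._medians, self._iqrs = robust_scale(
                trait_table.values, trait_table.trait_names
            )
        else:
            self._medians = self._iqrs = None

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, id_column: str,
                       error_model: ErrorModel,
                       taxon_column: str | None = None, **config
                       ) -> "ConsensusClustering":
        """Build the model straight from a pandas DataFrame."""
        table = TraitTable.from_dataframe(df, id_column, taxon_column)
        return cls(table, error_model, **config)

    # -- pipeline pieces ---------------------------------------------------

    def _prepare(self, values: np.ndarray) -> np.ndarray:
        if self.scale == "none":
            return values
        if self.scale_refit == "from_x":
            return apply_robust_scale(values, self._medians, self._iqrs)
        scaled, _, _ = robust_scale(values, self.trait_table.trait_names)
        return scaled

    def _fit_member(self, seed: int, resample_index: int) -> EnsembleMember:
        """One ensemble member: resample -> scale -> select G -> assign."""
        draw = sample_resample(self.trait_table, self.error_model, seed,
                               resample_index)
        w = self._prepare(draw.values)
        member = select_G(
            w, range(self.g_range[0], self.g_range[1] + 1), seed,
            tol=self.em_tol, n_init=self.em_restarts,
            reg_covar=self.reg_covar, max_iter=self.em_max_iter,
            resample_index=resample_index,
        )
        member.assignments = assign_groups(
            member.fit, self.assignment, self.n_assignments, seed
        )
        member.fit = None  # responsibilities are large; drop after assignment
        return member

    def fit(self, seed: int = 0, progress: bool = False
            ) -> "ConsensusClusteringResults":
        """Run the full consensus pipeline.

        The base seed fully determines the result: resample s uses seed
        ``seed + s``, so parallel or re-ordered execution of the ensemble
        would accumulate the identical consensus matrix.
        """
        start = time.time()
        acc = ConsensusAccumulator(self.trait_table.n_species,
                                   self.trait_table.species_ids)
        members_meta = []
        for s in range(1, self.n_resamples + 1):
            t0 = time.time()
            try:
                member = self._fit_member(seed + s, s)
            except Exception as exc:
                raise RuntimeError(
                    f"pipeline stage 'ensemble' failed at resample {s}: {exc}"
                ) from exc
            acc.add_member(member)
            members_meta.append(member)
            if progress:
                logger.info(
                    "resample %d/%d: G*=%d, BIC_min=%.1f (%.1fs)",
                    s, self.n_resamples, member.selected_G,
                    min(member.bic_curve.values()), time.time() - t0,
                )
        consensus = acc.finalize()
        distance = consensus_to_distance(consensus)
        tree = hierarchy.ward_linkage(distance, self.linkage)
        partition = hierarchy.select_K(
            tree, distance, range(self.k_range[0], self.k_range[1] + 1),
            species_ids=self.trait_table.species_ids,
        )
        if progress:
            curve = partition.silhouette_curve
            ks = sorted(curve)
            past_peak = [k for k in ks if k > partition.selected_K]
            if past_peak and max(
                curve[k] for k in past_peak
            ) > 0.98 * curve[partition.selected_K]:
                logger.warning(
                    "silhouette curve plateaus beyond K*=%d; nearby cuts "
                    "score within 2%%", partition.selected_K,
                )
        return ConsensusClusteringResults(
            model=self, seed=seed, consensus=consensus, partition=partition,
            members=members_meta, wall_time=time.time() - start,
        )


@dataclass
class ConsensusClusteringResults:
    """Fitted consensus clustering: estimates, uncertainty and diagnostics."""

    model: ConsensusClustering
    seed: int
    consensus: ConsensusMatrix
    partition: hierarchy.ConsensusPartition
    members: list[EnsembleMember]
    wall_time: float

    # -- estimates ---------------------------------------------------------

    @property
    def labels(self) -> np.ndarray:
        """Final 1-based group labels at the selected K*."""
        return self.partition.labels

    @property
    def selected_K(self) -> int:
        return self.partition.selected_K

    @property
    def mean_silhouette(self) -> float:
        return self.partition.mean_silhouette

    @property
    def selected_G_per_resample(self) -> np.ndarray:
        return np.array([m.selected_G for m in self.members])

    @property
    def consensus_se_bound(self) -> float:
        """Worst-case Monte-Carlo SE of any consensus entry."""
        return max_consensus_se(self.consensus.n_samples_total)

    # -- diagnostics -------------------------------------------------------

    def species_stability(self) -> np.ndarray:
        return species_stability(self.consensus, self.labels)

    def group_summary(self) -> np.ndarray:
        return group_consensus_summary(self.consensus, self.labels)

    def within_group_consensus(self) -> tuple[float, float]:
        """Mean and sd of the per-group within-group consensus means."""
        diag = np.diag(self.group_summary())
        diag = diag[np.isfinite(diag)]
        return float(diag.mean()), float(diag.std())

    def bic_curves(self) -> pd.DataFrame:
        """Long-format (resample, G, BIC) table across the ensemble."""
        rows = [
            (m.resample_index, g, bic)
            for m in self.members for g, bic in sorted(m.bic_curve.items())
        ]
        return pd.DataFrame(rows, columns=["resample", "G", "bic"])

    def silhouette_curve(self) -> pd.DataFrame:
        n = self.partition.n_species
        ks = sorted(self.partition.silhouette_curve)
        totals = [self.partition.silhouette_curve[k] for k in ks]
        return pd.DataFrame(
            {"K": ks, "total": totals, "mean": np.asarray(totals) / n}
        )

    def group_map(self) -> dict[str, int]:
        """species id -> final group, for the diversity metrics."""
        return {
            str(sp): int(g)
            for sp, g in zip(self.consensus.species_ids, self.labels)
        }

    # -- output ------------------------------------------------------------

    def save_labels(self, path) -> None:
        io.write_labels(self.labels, self.consensus.species_ids, path)

    def save_consensus(self, path) -> None:
        io.save_consensus(self.consensus, path)

    def to_newick(self, path=None) -> str:
        newick = io.linkage_to_newick(self.partition.linkage,
                                      self.consensus.species_ids)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(newick + "\n")
        return newick

    def summary(self) -> str:
        """Human-readable summary table of the fitted clustering."""
        n, m = self.model.trait_table.values.shape
        sizes = self.partition.group_sizes()
        mean_within, sd_within = self.within_group_consensus()
        gs = self.selected_G_per_resample
        stab = self.species_stability()
        lines = [
            "Consensus Clustering Results",
            "=" * 60,
            f"Species (N)                 {n}",
            f"Traits (M)                  {m}",
            f"Resamples (S)               {self.model.n_resamples}",
            f"Assignment mode             {self.model.assignment}",
            f"Label vectors accumulated   {self.consensus.n_samples_total}",
            f"Consensus SE bound          {self.consensus_se_bound:.4f}",
            f"Scaling                     {self.model.scale}",
            f"Linkage                     {self.model.linkage}",
            "-" * 60,
            f"Selected G* per resample    min {gs.min()}  median "
            f"{int(np.median(gs))}  max {gs.max()}",
            f"Selected K*                 {self.selected_K}",
            f"Mean silhouette at K*       {self.mean_silhouette:.3f}",
            f"Within-group consensus      {mean_within:.3f} (sd {sd_within:.3f})",
            f"Mean species stability      {np.nanmean(stab):.3f}",
            f"Group sizes                 min {sizes.min()}  mean "
            f"{sizes.mean():.1f}  max {sizes.max()}",
            f"Wall time (s)               {self.wall_time:.1f}",
            "=" * 60,
        ]
        return "\n".join(lines)
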