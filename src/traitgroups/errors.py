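"""Empirical error models and trait-table resampling.

Imputed or predicted trait values carry unknown error. Rather than assume a
parametric error law, we pool the empirical prediction errors
(predicted - observed) per trait, nested within coarse taxa whose measurement
methodologies differ (e.g. angiosperms vs gymnosperms). A resample W of the
trait table X perturbs every cell independently by an error drawn uniformly
with replacement from the pool of its (taxon, trait) pair; traits with no
observed values in a taxon fall back to the union of that taxon's available
pools.

The sign convention stores predicted - observed. Sources differ on the sign
of reported errors, so ``flip_sign`` negates the pools at construction for
data recorded the other way round; with the symmetric pools typical of
prediction errors the choice barely matters, but it is exposed for fidelity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import DEFAULT_TAXON, TraitTable

__all__ = [
    "ErrorModel",
    "ResampleDraw",
    "build_error_model",
    "sample_resample",
    "robust_scale",
    "apply_robust_scale",
]


@dataclass(frozen=True)
class ErrorModel:
    """Taxon-nested pools of empirical prediction errors.

    ``pools`` maps (taxon, trait) to an array of errors; ``fallback_pools``
    maps each taxon to the union of its per-trait pools and serves traits
    with no errors of their own. Pools are immutable after construction and
    sampled uniformly with replacement.
    """

    pools: Mapping[tuple[str, str], np.ndarray]
    fallback_pools: Mapping[str, np.ndarray]

    def __post_init__(self):
        frozen = {}
        for key, pool in self.pools.items():
            arr = np.asarray(pool, dtype=float)
            if arr.size == 0:
                raise ValueError(f"empty error pool for {key}")
            arr.setflags(write=False)
            frozen[key] = arr
        object.__setattr__(self, "pools", frozen)
        fb = {}
        for taxon, pool in self.fallback_pools.items():
            arr = np.asarray(pool, dtype=float)
            if arr.size == 0:
                raise ValueError(f"empty fallback pool for taxon {taxon!r}")
            arr.setflags(write=False)
            fb[taxon] = arr
        object.__setattr__(self, "fallback_pools", fb)

    @property
    def taxa(self) -> list[str]:
        return sorted(self.fallback_pools)

    def pool_for(self, taxon: str, trait: str) -> np.ndarray:
        """Pool for a (taxon, trait) pair, union fallback when absent."""
        if taxon not in self.fallback_pools:
            raise KeyError(f"no error information for taxon {taxon!r}")
        return self.pools.get((taxon, trait), self.fallback_pools[taxon])

    def has_own_pool(self, taxon: str, trait: str) -> bool:
        return (taxon, trait) in self.pools

    @classmethod
    def from_pools(cls, pools: Mapping[tuple[str, str], Sequence[float]],
                   flip_sign: bool = False) -> "ErrorModel":
        """Build from explicit per-(taxon, trait) pools; fallbacks are the
        per-taxon unions."""
        sign = -1.0 if flip_sign else 1.0
        clean = {k: sign * np.asarray(v, dtype=float) for k, v in pools.items()}
        fallback: dict[str, np.ndarray] = {}
        for (taxon, _), arr in clean.items():
            fallback.setdefault(taxon, [])
        for taxon in fallback:
            parts = [arr for (t, _), arr in clean.items() if t == taxon]
            fallback[taxon] = np.concatenate(parts)
        return cls(clean, fallback)

    @classmethod
    def from_csv(cls, path, flip_sign: bool = False) -> "ErrorModel":
        """Read a long-format pool table with columns taxon, trait, error_value."""
        df = pd.read_csv(path)
        required = {"taxon", "trait", "error_value"}
        if not required.issubset(df.columns):
            raise ValueError(f"error-pool CSV needs columns {sorted(required)}")
        pools = {
            (str(t), str(j)): g["error_value"].to_numpy(dtype=float)
            for (t, j), g in df.groupby(["taxon", "trait"], sort=True)
        }
        return cls.from_pools(pools, flip_sign=flip_sign)

    def to_csv(self, path) -> None:
        rows = []
        for (taxon, trait), arr in sorted(self.pools.items()):
            for v in arr:
                rows.append((taxon, trait, v))
        pd.DataFrame(rows, columns=["taxon", "trait", "error_value"]).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class ResampleDraw:
    """One perturbed realization W = X + eps of a trait table."""

    values: np.ndarray
    resample_index: int
    seed_used: int


def build_error_model(observed: pd.DataFrame, predicted: pd.DataFrame,
                      taxon: Sequence[str], flip_sign: bool = False) -> ErrorModel:
    """Pool prediction errors per (taxon, trait) from paired value tables.

    ``observed`` is sparse (NaN where a species/trait was never measured);
    ``predicted`` must cover every observed cell. The pool for (taxon t,
    trait j) collects predicted - observed over species of taxon t with
    trait j observed. A taxon with no observed value for any trait carries
    no error information at all and is a hard error.
    """
    if list(observed.columns) != list(predicted.columns):
        raise ValueError("observed and predicted must share trait columns")
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must share shape")
    taxon = np.asarray(taxon, dtype=object)
    if len(taxon) != len(observed):
        raise ValueError("taxon length must match table height")
    obs = observed.to_numpy(dtype=float)
    pred = predicted.to_numpy(dtype=float)
    mask = np.isfinite(obs)
    if (np.isfinite(pred) < mask).any():
        raise ValueError("every observed cell needs a matching predicted cell")
    pools: dict[tuple[str, str], np.ndarray] = {}
    for t in np.unique(taxon.astype(str)):
        rows = taxon.astype(str) == t
        if not mask[rows].any():
            raise ValueError(
                f"taxon {t!r} has no observed trait values; no error "
                "information available"
            )
        for j, trait in enumerate(observed.columns):
            cells = rows & mask[:, j]
            if cells.any():
                pools[(t, str(trait))] = pred[cells, j] - obs[cells, j]
    return ErrorModel.from_pools(pools, flip_sign=flip_sign)


def sample_resample(table: TraitTable, model: ErrorModel, seed: int,
                    resample_index: int = 0) -> ResampleDraw:
    """Draw one resample W = X + eps of a trait table.

    Each cell's error is sampled uniformly with replacement, independently
    per cell, from the pool of its (taxon, trait) pair (errors across traits
    are assumed uncorrelated). The draw is fully determined by
    (table, model, seed).
    """
    rng = np.random.default_rng(seed)
    taxa = table.taxon_labels().astype(str)
    values = table.values.copy()
    for t in np.unique(taxa):
        rows = np.flatnonzero(taxa == t)
        for j, trait in enumerate(table.trait_names):
            pool = model.pool_for(t, trait)
            idx = rng.integers(0, pool.size, size=rows.size)
            values[rows, j] += pool[idx]
    return ResampleDraw(values, resample_index, seed)


def robust_scale(values: np.ndarray, trait_names: Sequence[str] | None = None
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center each column by its median and scale by its IQR.

    The IQR is the 75th minus the 25th percentile under numpy's linear
    interpolation convention (conventions differ, and IQR values with them).
    Returns (scaled, medians, iqrs) so the transform can be inverted exactly.
    A constant column (zero IQR) is a hard error naming the trait.
    """
    values = np.asarray(values, dtype=float)
    medians = np.median(values, axis=0)
    q75, q25 = np.percentile(values, [75, 25], axis=0)
    iqrs = q75 - q25
    if (iqrs <= 0).any():
        j = int(np.flatnonzero(iqrs <= 0)[0])
        name = trait_names[j] if trait_names is not None else f"column {j}"
        raise ValueError(f"zero interquartile range for trait {name!r}")
    return (values - medians) / iqrs, medians, iqrs


def apply_robust_scale(values: np.ndarray, medians: np.ndarray,
                       iqrs: np.ndarray) -> np.ndarray:
    """Apply previously fitted robust-scaling parameters."""
    return (np.asarray(values, dtype=float) - medians) / iqrs
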