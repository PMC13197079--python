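"""Gaussian mixture fitting, BIC component selection and group assignment.

Each resample of the trait table is modelled as a mixture of G multivariate
Gaussians with full covariance matrices, so that correlated traits and
group-specific correlation structure are captured rather than decorrelated
away. The number of components is chosen per resample by minimizing
BIC = -2 * log-likelihood + p * ln(N), with p the free-parameter count of a
full-covariance mixture. Species are then assigned to components either
deterministically (argmax of the posterior responsibilities) or by A
independent categorical draws from each species' responsibility row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

__all__ = [
    "GmmFit",
    "EnsembleMember",
    "count_gmm_parameters",
    "fit_gmm",
    "select_G",
    "assign_groups",
]

#: relative BIC difference below which two component counts tie
BIC_TIE_RTOL = 1e-6


def count_gmm_parameters(n_components: int, n_traits: int) -> int:
    """Free parameters of a full-covariance Gaussian mixture.

    (G - 1) mixture weights, G*M means, and G symmetric M x M covariances
    with M(M+1)/2 unique entries each.
    """
    G, M = int(n_components), int(n_traits)
    if G < 1 or M < 1:
        raise ValueError("component and trait counts must be positive")
    return (G - 1) + G * M + G * M * (M + 1) // 2


@dataclass
class GmmFit:
    """A converged mixture fit for one component count."""

    n_components: int
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    log_likelihood: float
    responsibilities: np.ndarray
    bic: float
    converged: bool
    n_iter: int

    @property
    def n_traits(self) -> int:
        return self.means.shape[1]


@dataclass
class EnsembleMember:
    """One resample's selected mixture and its group assignments.

    ``assignments`` holds one label vector in argmax mode or A vectors in
    sampling mode; labels run 1..G*.
    """

    resample_index: int
    selected_G: int
    bic_curve: dict[int, float]
    assignments: list[np.ndarray]
    fit: GmmFit | None = None


def fit_gmm(values: np.ndarray, n_components: int, seed: int | None = 0,
            *, tol: float = 1e-3, n_init: int = 3,
            reg_covar: float = 1e-6, max_iter: int = 200) -> GmmFit:
    """Fit one full-covariance Gaussian mixture by EM.

    Runs ``n_init`` k-means-initialized EM restarts and keeps the best.
    BIC is recomputed from the total log-likelihood and
    :func:`count_gmm_parameters` so the stored value satisfies the
    -2*ll + p*ln(N) identity exactly.
    """
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    if n <= n_components:
        raise ValueError(f"need more observations ({n}) than components "
                         f"({n_components})")
    gm = GaussianMixture(
        n_components=n_components,
        covariance_type="full",
        tol=tol,
        reg_covar=reg_covar,
        max_iter=max_iter,
        n_init=n_init,
        init_params="kmeans",
        random_state=seed,
    )
    try:
        gm.fit(values)
    except ValueError as exc:  # singular component despite regularization
        raise ValueError(
            f"EM failed for G={n_components}: {exc}; consider a larger "
            "covariance regularization (reg_covar) or fewer components"
        ) from exc
    log_likelihood = float(gm.score(values) * n)
    p = count_gmm_parameters(n_components, m)
    bic = -2.0 * log_likelihood + p * np.log(n)
    return GmmFit(
        n_components=n_components,
        weights=gm.weights_,
        means=gm.means_,
        covariances=gm.covariances_,
        log_likelihood=log_likelihood,
        responsibilities=gm.predict_proba(values),
        bic=bic,
        converged=bool(gm.converged_),
        n_iter=int(gm.n_iter_),
    )


def select_G(values: np.ndarray, g_range, seed: int | None = 0,
             *, tol: float = 1e-3, n_init: int = 3, reg_covar: float = 1e-6,
             max_iter: int = 200, resample_index: int = 0,
             keep_fit: bool = True) -> EnsembleMember:
    """Scan component counts and keep the BIC-minimizing fit.

    ``g_range`` is an iterable of candidate counts (e.g. ``range(10, 61)``).
    Ties within a relative BIC tolerance resolve toward the smaller count
    (parsimony). The full BIC curve is retained on the member.
    """
    candidates = sorted(set(int(g) for g in g_range))
    if not candidates:
        raise ValueError("empty component-count range")
    values = np.asarray(values, dtype=float)
    if candidates[-1] >= len(values):
        raise ValueError("largest candidate G must be below N")
    bic_curve: dict[int, float] = {}
    best_fit: GmmFit | None = None
    failures: list[str] = []
    for g in candidates:
        try:
            fit = fit_gmm(values, g, seed, tol=tol, n_init=n_init,
                          reg_covar=reg_covar, max_iter=max_iter)
        except ValueError as exc:
            failures.append(str(exc))
            continue
        bic_curve[g] = fit.bic
        if best_fit is None:
            best_fit = fit
        else:
            margin = BIC_TIE_RTOL * max(1.0, abs(best_fit.bic))
            if fit.bic < best_fit.bic - margin:
                best_fit = fit
    if best_fit is None:
        raise ValueError(
            "every mixture fit failed across the component range: "
            + "; ".join(failures[:3])
        )
    return EnsembleMember(
        resample_index=resample_index,
        selected_G=best_fit.n_components,
        bic_curve=bic_curve,
        assignments=[],
        fit=best_fit if keep_fit else None,
    )


def assign_groups(fit: GmmFit, mode: str = "argmax", n_assignments: int = 10,
                  seed: int | None = 0) -> list[np.ndarray]:
    """Turn responsibilities into 1-based group label vectors.

    ``argmax`` assigns each species to its most probable component (ties to
    the lowest component index) and returns one vector. ``sample`` returns
    ``n_assignments`` independent vectors with species i's label drawn from
    Categorical(tau_i).
    """
    tau = fit.responsibilities
    if mode == "argmax":
        return [np.argmax(tau, axis=1) + 1]
    if mode != "sample":
        raise ValueError(f"unknown assignment mode {mode!r}")
    if n_assignments < 1:
        raise ValueError("n_assignments must be >= 1 in sampling mode")
    rng = np.random.default_rng(seed)
    cum = np.cumsum(tau, axis=1)
    cum[:, -1] = 1.0  # guard against rounding in the last bin
    out = []
    for _ in range(n_assignments):
        u = rng.random(tau.shape[0])
        labels = (u[:, None] > cum).sum(axis=1) + 1
        out.append(labels)
    return out
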