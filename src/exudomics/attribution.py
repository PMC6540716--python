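"""Variance partitioning, Procrustes trait-exudate correlation, and the
land-use intensity index.

Variance partitioning decomposes the adjusted R-squared of a multivariate
response over 2-4 predictor sets by inclusion-exclusion: adjusted
(Ezekiel) R^2 is computed for every non-empty union of sets, the Venn
fractions solve the resulting linear system exactly, and the residual is
one minus the full-model fit.  Fractions can be negative under unbalanced
designs; that is a property of adjusted R^2, not an error.

The symmetric Procrustes statistic m^2 is the residual sum of squares after
optimally translating, scaling and rotating one configuration onto the
other; the reported correlation is sqrt(1 - m^2), and its significance is
assessed by permuting rows of one configuration (protest).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PartitionResult",
    "ProcrustesResult",
    "adjusted_r2",
    "variance_partition",
    "procrustes_fit",
    "protest",
    "lui_index",
]


def _as_array(X) -> np.ndarray:
    arr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else \
        np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr


def adjusted_r2(Y, X) -> float:
    """Ezekiel-adjusted R^2 of the redundancy fit of Y on X.

    ``R2adj = 1 - (1 - R2) (n - 1) / (n - p - 1)`` with R2 the constrained
    proportion of the RDA and p the rank of the centered predictor matrix.
    May be negative for uninformative predictors.
    """
    Xa = _as_array(X)
    Ya = _as_array(Y)
    n = Xa.shape[0]
    if Ya.shape[0] != n:
        raise ValueError("Y and X must be row-aligned")
    Xc = Xa - Xa.mean(axis=0)
    p = np.linalg.matrix_rank(Xc)
    if n <= p + 1:
        raise ValueError("adjusted R2 requires n > rank(X) + 1")
    # R2 = ||fitted||^2 / ||centered Y||^2, identical to the constrained
    # proportion of rda(Y, X) without the (unneeded) eigendecomposition
    Yc = Ya - Ya.mean(axis=0)
    total = (Yc**2).sum()
    if total == 0:
        return 0.0
    coef, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    r2 = float(((Xc @ coef) ** 2).sum() / total)
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - p - 1))


@dataclass(frozen=True)
class PartitionResult:
    """Inclusion-exclusion decomposition of explained variance.

    ``subset_adjR2`` maps every non-empty union of predictor-set names (a
    frozenset) to its adjusted R^2.  ``fractions`` maps each Venn atom (the
    part of variance attributable exactly to that combination of sets) to
    its fraction, plus the key 'residual'.  All fractions sum to one.
    """

    set_names: tuple[str, ...]
    subset_adjR2: dict
    fractions: dict

    def table(self) -> pd.Series:
        """Fractions in the canonical column order: singles, pairs, ...,
        full intersection, residual."""
        order = []
        names = self.set_names
        for size in range(1, len(names) + 1):
            for combo in combinations(names, size):
                order.append(frozenset(combo))
        labels = [" + ".join(sorted(k)) for k in order] + ["residual"]
        vals = [self.fractions[k] for k in order] + [
            self.fractions["residual"]
        ]
        return pd.Series(vals, index=labels, name="fraction")


def variance_partition(
    Y, predictor_sets: Mapping[str, object]
) -> PartitionResult:
    """Partition the variance of Y over named predictor sets (2-4 sets).

    Adjusted R^2 is computed for every non-empty union of sets; the Venn
    atoms are recovered by solving the exact inclusion-exclusion system, and
    the residual fraction is 1 minus the full-model adjusted R^2.
    """
    names = tuple(predictor_sets)
    k = len(names)
    if not 1 <= k <= 4:
        raise ValueError("variance_partition supports 1-4 predictor sets")
    mats = {name: _as_array(m) for name, m in predictor_sets.items()}
    n_rows = {m.shape[0] for m in mats.values()}
    if len(n_rows) != 1:
        raise ValueError("predictor sets must be row-aligned")

    subsets = []
    for size in range(1, k + 1):
        subsets.extend(frozenset(c) for c in combinations(names, size))
    subset_r2 = {}
    for sub in subsets:
        X = np.hstack([mats[name] for name in names if name in sub])
        subset_r2[sub] = adjusted_r2(Y, X)

    # R(U) = sum of atoms S with S intersecting U; solve for the atoms
    M = np.array(
        [[1.0 if s & u else 0.0 for s in subsets] for u in subsets]
    )
    rhs = np.array([subset_r2[u] for u in subsets])
    atoms = np.linalg.solve(M, rhs)
    fractions = {s: float(a) for s, a in zip(subsets, atoms)}
    fractions["residual"] = float(1.0 - subset_r2[frozenset(names)])
    return PartitionResult(
        set_names=names, subset_adjR2=subset_r2, fractions=fractions
    )


@dataclass(frozen=True)
class ProcrustesResult:
    """Symmetric Procrustes superimposition of two configurations."""

    rotation: np.ndarray
    scaling: float
    translation: np.ndarray
    m2: float
    correlation: float
    permutation_p: float | None = None
    n_permutations: int = 0


def _normalize_configuration(X: np.ndarray):
    """Center and scale to unit sum of squares."""
    mu = X.mean(axis=0)
    Xc = X - mu
    norm = np.sqrt((Xc**2).sum())
    if norm == 0:
        raise ValueError("configuration has zero spread")
    return Xc / norm, mu, norm


def _procrustes_statistic(Xn: np.ndarray, Yn: np.ndarray):
    """(m2, rotation, scaling) for unit-normalized configurations."""
    cross = Xn.T @ Yn
    U, s, Vt = np.linalg.svd(cross, full_matrices=False)
    trace = s.sum()
    m2 = 1.0 - trace**2
    rotation = Vt.T @ U.T
    return max(m2, 0.0), rotation, trace


def procrustes_fit(
    X_config, Y_config, symmetric: bool = True
) -> ProcrustesResult:
    """Optimal superimposition of Y onto X.

    Both configurations are centered; in the symmetric mode both are scaled
    to unit sum of squares, giving ``m2 = 1 - (sum of singular values of
    X'Y)^2`` and ``correlation = sqrt(1 - m2)``, invariant to translation,
    rotation, reflection and uniform scaling of either input.  Column counts
    may differ (the statistic uses the rectangular cross-product).
    """
    X = _as_array(X_config)
    Y = _as_array(Y_config)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("configurations must have equal row counts")
    if X.shape[0] < 3:
        raise ValueError("need at least three rows")
    Xn, mux, nx = _normalize_configuration(X)
    Yn, muy, ny = _normalize_configuration(Y)
    if not symmetric:
        # scale only Y onto X (asymmetric fit): statistic relative to X
        Xn = X - mux
        nx = 1.0
        Xn = Xn / np.sqrt((Xn**2).sum())
    m2, rotation, trace = _procrustes_statistic(Xn, Yn)
    return ProcrustesResult(
        rotation=rotation,
        scaling=float(trace * nx / ny) if ny else 0.0,
        translation=mux,
        m2=float(m2),
        correlation=float(np.sqrt(1.0 - m2)),
    )


def protest(
    X_config,
    Y_config,
    n_permutations: int = 999,
    seed: int = 0,
) -> ProcrustesResult:
    """Permutation test of the symmetric Procrustes correlation.

    Rows of Y are permuted ``n_permutations`` times;
    ``p = (1 + #{perm corr >= observed}) / (1 + n_permutations)``.
    """
    X = _as_array(X_config)
    Y = _as_array(Y_config)
    base = procrustes_fit(X, Y, symmetric=True)
    Xn, *_ = _normalize_configuration(X)
    Yn, *_ = _normalize_configuration(Y)
    rng = np.random.default_rng(seed)
    n = Xn.shape[0]
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        Yp = Yn[perm]
        Yp = Yp - Yp.mean(axis=0)
        norm = np.sqrt((Yp**2).sum())
        m2, _, _ = _procrustes_statistic(Xn, Yp / norm)
        if np.sqrt(1.0 - m2) >= base.correlation - 1e-12:
            count += 1
    p = (1.0 + count) / (1.0 + n_permutations)
    return ProcrustesResult(
        rotation=base.rotation,
        scaling=base.scaling,
        translation=base.translation,
        m2=base.m2,
        correlation=base.correlation,
        permutation_p=float(p),
        n_permutations=n_permutations,
    )


def lui_index(
    components: pd.DataFrame,
    reference_means: Mapping[str, float] | pd.DataFrame | None = None,
    year_range: tuple[int, int] = (2006, 2014),
) -> pd.DataFrame:
    """Land-use intensity index per plot-year and its multi-year mean.

    ``LUI = F_i/F_r + M_i/M_r + G_i/G_r`` where F (fertilization, kg N/ha/yr),
    M (mowing frequency per year) and G (grazing intensity) of plot i are
    standardized by reference means r.  By default the reference means are
    computed per year across all plots (per region-year when a 'region'
    column is present, mirroring within-site standardization); a mapping
    {'fertilization': f, 'mowing': m, 'grazing': g} fixes them globally.
    Returns one row per plot with the per-year index columns and the mean
    over ``year_range``.
    """
    comp = components.copy()
    needed = {"plot", "year", "fertilization", "mowing", "grazing"}
    if not needed <= set(comp.columns):
        raise ValueError(f"components must have columns {sorted(needed)}")
    parts = ("fertilization", "mowing", "grazing")
    if isinstance(reference_means, Mapping):
        for c in parts:
            ref = float(reference_means[c])
            if ref <= 0:
                raise ValueError(f"reference mean for {c} must be positive")
            comp[f"{c}_r"] = ref
    else:
        keys = ["year"] + (["region"] if "region" in comp.columns else [])
        refs = comp.groupby(keys)[list(parts)].transform("mean")
        for c in parts:
            if (refs[c] <= 0).any():
                raise ValueError(f"zero reference mean for {c}")
            comp[f"{c}_r"] = refs[c]
    comp["lui"] = sum(comp[c] / comp[f"{c}_r"] for c in parts)
    lo, hi = year_range
    in_range = comp[(comp["year"] >= lo) & (comp["year"] <= hi)]
    wide = comp.pivot_table(index="plot", columns="year", values="lui")
    wide.columns = [f"lui_{y}" for y in wide.columns]
    mean = in_range.groupby("plot")["lui"].mean()
    wide[f"lui_mean_{lo}_{hi}"] = mean
    return wide
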