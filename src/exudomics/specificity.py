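"""One-vs-rest exact binomial species-specificity screen and the
shared-compound accounting.

For each compound and each focal group (a species, a growth form, or a
pooled genus) the screen asks whether the compound occurs more frequently in
the focal group's samples than expected from the group's share of all
samples.  Conditioning on the compound's total occurrence count T, the null
is X ~ Binomial(T, p0) with p0 the focal sampling fraction, and the reported
p-value is the one-sided upper tail P(X >= k_focal).  A compound is called
specific at the 0.95 criterion when that tail probability is below 0.05;
compounds qualifying for several groups are attributed to the group with the
smallest p-value (ties broken by label order), so per-species counts are
disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import PresenceAbsenceMatrix

__all__ = [
    "SpecificityRecord",
    "SharingSummary",
    "ScreenResult",
    "compound_frequencies",
    "binomial_specificity",
    "screen_all",
    "shared_compounds",
]


@dataclass(frozen=True)
class SpecificityRecord:
    """Occurrence counts and exact-binomial tail for one compound x group."""

    feature_id: str
    focal_group: str
    k_focal: int
    n_focal: int
    k_other: int
    n_other: int
    p_value: float
    specific: bool


@dataclass(frozen=True)
class SharingSummary:
    """Tallies of the specificity screen over a compound collection."""

    n_considered: int
    specific_per_species: dict = field(default_factory=dict)
    specific_per_growth_form: dict = field(default_factory=dict)
    genus_specific: dict = field(default_factory=dict)
    shared_growth_forms: int = 0
    n_specific_total: int = 0


@dataclass(frozen=True)
class ScreenResult:
    """Full screen output: per-feature records, the p-value matrix
    (features x focal groups), and the sharing summary."""

    records: tuple[SpecificityRecord, ...]
    p_values: pd.DataFrame
    assignment: pd.Series
    summary: SharingSummary


def _as_values(pa) -> pd.DataFrame:
    return pa.values if isinstance(pa, PresenceAbsenceMatrix) else pa


def compound_frequencies(
    pa, grouping: Sequence
) -> tuple[pd.DataFrame, pd.Series]:
    """Per feature x group presence counts k and group sizes n."""
    values = _as_values(pa)
    groups = pd.Series(list(grouping), index=values.index, name="group")
    if groups.isna().any():
        raise ValueError("grouping must label every sample")
    sizes = groups.value_counts().sort_index()
    if (sizes == 0).any():
        raise ValueError("every group must contain at least one sample")
    k = values.groupby(groups).sum().T  # features x groups
    k = k[sizes.index]
    return k, sizes.rename("n")


def binomial_specificity(
    k_focal: int, n_focal: int, k_other: int, n_other: int
) -> float:
    """Exact one-sided binomial tail for over-representation in the focal
    group: P(X >= k_focal), X ~ Binomial(k_focal + k_other,
    n_focal / (n_focal + n_other))."""
    if not (0 <= k_focal <= n_focal and 0 <= k_other <= n_other):
        raise ValueError("need 0 <= k <= n on both sides")
    total = k_focal + k_other
    if total == 0:
        raise ValueError("compound was never observed; test undefined")
    p0 = n_focal / (n_focal + n_other)
    return float(stats.binom.sf(k_focal - 1, total, p0))


def _tail_matrix(k: np.ndarray, totals: np.ndarray, p0: np.ndarray):
    """Vectorized upper-tail p-values; entries with totals == 0 get 1.0."""
    with np.errstate(invalid="ignore"):
        p = stats.binom.sf(k - 1, np.maximum(totals, 1), p0)
    return np.where(totals == 0, 1.0, p)


def screen_all(
    pa,
    species_labels: Sequence,
    criterion: float = 0.95,
    genus_groups: Mapping[str, Sequence[str]] | None = None,
    growth_forms: Mapping[str, str] | None = None,
    min_occurrence: int = 2,
    fdr: bool = False,
) -> ScreenResult:
    """Screen every compound against every species (one-vs-rest).

    Only compounds occurring at least ``min_occurrence`` times across all
    samples are considered.  ``genus_groups`` maps a genus label to its
    member species; the pooled genus samples are screened against all
    remaining samples, independently of the per-species assignment.
    ``growth_forms`` (species -> growth form) enables the per-growth-form
    tallies and the shared-compound count.  ``fdr=True`` applies a
    Benjamini-Hochberg correction across compounds within each focal group
    before flagging (off by default: the plain per-test criterion is the
    default contract).
    """
    values = _as_values(pa)
    species_labels = pd.Series(list(species_labels), index=values.index)
    species = sorted(species_labels.unique().tolist())
    if len(species) < 2:
        raise ValueError("screen requires at least two species")
    alpha = 1.0 - criterion

    total_occ = values.sum(axis=0).to_numpy()
    considered = total_occ >= min_occurrence
    feats = values.columns

    k_df, n_ser = compound_frequencies(values, species_labels)
    k = k_df.to_numpy(dtype=float)  # features x species
    n = n_ser.to_numpy(dtype=float)
    N = n.sum()
    totals = total_occ[:, None].astype(float)
    p0 = (n / N)[None, :]
    pvals = _tail_matrix(k, np.broadcast_to(totals, k.shape), p0)
    p_df = pd.DataFrame(pvals, index=feats, columns=k_df.columns)

    flags = pvals < alpha
    if fdr:
        flags = np.column_stack(
            [
                _bh_flags(pvals[considered, j], alpha, considered)
                for j in range(pvals.shape[1])
            ]
        )
    flags &= considered[:, None]

    # exclusive attribution: smallest p among qualifying species, ties by
    # column (species label) order
    assignment = pd.Series("", index=feats, name="specific_for")
    any_flag = flags.any(axis=1)
    if any_flag.any():
        masked = np.where(flags, pvals, np.inf)
        best = masked[any_flag].argmin(axis=1)
        assignment.iloc[np.flatnonzero(any_flag)] = (
            k_df.columns.to_numpy()[best]
        )

    records = []
    for i in np.flatnonzero(any_flag):
        sp = assignment.iloc[i]
        j = k_df.columns.get_loc(sp)
        records.append(
            SpecificityRecord(
                feature_id=str(feats[i]),
                focal_group=sp,
                k_focal=int(k[i, j]),
                n_focal=int(n[j]),
                k_other=int(total_occ[i] - k[i, j]),
                n_other=int(N - n[j]),
                p_value=float(pvals[i, j]),
                specific=True,
            )
        )

    per_species = {
        sp: int((assignment == sp).sum()) for sp in k_df.columns
    }
    per_growth_form: dict[str, int] = {}
    shared = 0
    if growth_forms is not None:
        for sp, count in per_species.items():
            gf = growth_forms.get(sp, "")
            per_growth_form[gf] = per_growth_form.get(gf, 0) + count
        gf_of_sample = species_labels.map(growth_forms)
        shared = _shared_count(values, gf_of_sample, considered)

    genus_counts: dict[str, int] = {}
    if genus_groups:
        for genus, members in genus_groups.items():
            focal = species_labels.isin(list(members)).to_numpy()
            if not focal.any() or focal.all():
                raise ValueError(
                    f"genus group {genus!r} must be a proper sample subset"
                )
            kg = values.to_numpy()[focal].sum(axis=0).astype(float)
            ng, No = float(focal.sum()), float(len(focal))
            pg = _tail_matrix(
                kg, total_occ.astype(float), np.full_like(kg, ng / No)
            )
            genus_counts[genus] = int(
                ((pg < alpha) & considered).sum()
            )

    summary = SharingSummary(
        n_considered=int(considered.sum()),
        specific_per_species=per_species,
        specific_per_growth_form=per_growth_form,
        genus_specific=genus_counts,
        shared_growth_forms=shared,
        n_specific_total=int(any_flag.sum()),
    )
    return ScreenResult(
        records=tuple(records),
        p_values=p_df,
        assignment=assignment,
        summary=summary,
    )


def _bh_flags(p_sub: np.ndarray, alpha: float, considered: np.ndarray):
    out = np.zeros(len(considered), dtype=bool)
    m = len(p_sub)
    if m == 0:
        return out
    order = np.argsort(p_sub)
    ranked = p_sub[order]
    thresh = alpha * (np.arange(1, m + 1) / m)
    ok = ranked <= thresh
    passed = np.zeros(m, dtype=bool)
    if ok.any():
        passed[order[: np.max(np.flatnonzero(ok)) + 1]] = True
    out[np.flatnonzero(considered)] = passed
    return out


def _shared_count(values, gf_of_sample, considered) -> int:
    arr = values.to_numpy().astype(bool)
    gf = np.asarray(gf_of_sample)
    forms = [f for f in pd.unique(gf) if f]
    if len(forms) < 2:
        return 0
    in_all = np.ones(arr.shape[1], dtype=bool)
    for f in forms:
        in_all &= arr[gf == f].any(axis=0)
    return int((in_all & considered).sum())


def shared_compounds(
    pa, growth_form_labels: Sequence, min_occurrence: int = 2
) -> SharingSummary:
    """Count compounds shared between growth forms.

    Considers compounds with total occurrence >= ``min_occurrence``; a
    compound is shared when present in at least one sample of every growth
    form.
    """
    values = _as_values(pa)
    gf = pd.Series(list(growth_form_labels), index=values.index)
    forms = [f for f in gf.unique() if f]
    if len(forms) < 2:
        raise ValueError("both growth forms must be represented")
    considered = (values.sum(axis=0) >= min_occurrence).to_numpy()
    shared = _shared_count(values, gf, considered)
    return SharingSummary(
        n_considered=int(considered.sum()), shared_growth_forms=shared
    )
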