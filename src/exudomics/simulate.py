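"""Synthetic study generator for the root-exudate community pipeline.

Everything downstream of vendor feature extraction can be exercised on data
produced here: an unbalanced multi-species phytometer design, a feature table
with planted shared / species-specific / genus-specific / blank-contaminant /
singleton compounds, species-structured trait and neighborhood tables,
plot-level land-use components, and MS/MS spectra carrying diagnostic
fragments and neutral losses.  Every generator takes an integer seed and is
bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

__all__ = [
    "StudyDesign",
    "TruthSpec",
    "GroundTruth",
    "DEFAULT_SPECIES",
    "DEFAULT_COUNTS",
    "GENUS_GROUPS",
    "TRAIT_NAMES",
    "generate_design",
    "generate_feature_table",
    "generate_traits",
    "generate_neighborhood",
    "generate_lui_components",
    "generate_spectra",
    "write_study",
]

# Ten common German grassland species, five forbs and five grasses, with the
# unbalanced per-species phytometer counts of the field campaign (total 389).
DEFAULT_SPECIES: tuple[tuple[str, str], ...] = (
    ("Achillea millefolium", "forb"),
    ("Galium mollugo", "forb"),
    ("Galium verum", "forb"),
    ("Plantago lanceolata", "forb"),
    ("Ranunculus acris", "forb"),
    ("Alopecurus pratensis", "grass"),
    ("Arrhenatherum elatius", "grass"),
    ("Dactylis glomerata", "grass"),
    ("Lolium perenne", "grass"),
    ("Poa pratensis", "grass"),
)
DEFAULT_COUNTS: tuple[int, ...] = (38, 41, 37, 39, 28, 40, 40, 48, 37, 41)

#: Congeneric species pooled for the genus-level specificity screen.
GENUS_GROUPS: dict[str, tuple[str, ...]] = {
    "Galium": ("Galium mollugo", "Galium verum"),
}

#: The 18 above- and belowground functional traits measured per phytometer.
TRAIT_NAMES: tuple[str, ...] = (
    "SLA", "LDMC", "LAR", "RSR", "RDMC", "RMV", "RVol", "RCC", "RNC",
    "RCNR", "RPC", "RKC", "RMgC", "RCaC", "DM_leaves", "DM_roots",
    "DM_total", "DM_above",
)

REGIONS = ("Schorfheide-Chorin", "Hainich-Duen", "Swabian-Alb")


class DesignError(ValueError):
    """Raised for invalid study-design parameters."""


class ParameterError(ValueError):
    """Raised for out-of-range generator parameters."""


@dataclass(frozen=True)
class StudyDesign:
    """A phytometer sampling design plus its water-control (blank) samples.

    ``samples`` indexes every sample (exudates then blanks) and carries the
    metadata columns expected by the preprocessing stage: species,
    growth_form, plot, region, sample_type.
    """

    species: tuple[str, ...]
    growth_form: Mapping[str, str]
    plots: tuple[str, ...]
    plot_region: Mapping[str, str]
    samples: pd.DataFrame
    n_blanks: int

    @property
    def exudate_samples(self) -> pd.DataFrame:
        return self.samples[self.samples["sample_type"] == "exudate"]

    @property
    def n_samples(self) -> int:
        return int((self.samples["sample_type"] == "exudate").sum())

    def species_of(self, sample_ids: Sequence[str]) -> pd.Series:
        return self.samples.loc[list(sample_ids), "species"]


def generate_design(
    n_species: int = 10,
    n_plots: int = 46,
    per_species_counts: Sequence[int] | None = None,
    n_blanks: int = 30,
    species: Sequence[tuple[str, str]] | None = None,
    attrition: float = 0.0,
    seed: int = 0,
) -> StudyDesign:
    """Build a reproducible unbalanced phytometer design.

    Parameters
    ----------
    n_species, n_plots
        Number of phytometer species and of sampled grassland plots.
    per_species_counts
        Sampled plants per species; defaults to the unbalanced field counts
        (total 389) when ``n_species == 10``.
    n_blanks
        Water-control samples handled identically to exudates.
    attrition
        Probability that a planned sample is lost (plot access / mortality);
        applied independently per sample.
    """
    if n_species < 1 or n_plots < 1:
        raise DesignError("need at least one species and one plot")
    if species is None:
        if n_species <= len(DEFAULT_SPECIES):
            species = DEFAULT_SPECIES[:n_species]
        else:
            species = tuple(
                (f"Species_{i:02d}", "forb" if i % 2 == 0 else "grass")
                for i in range(n_species)
            )
    species = tuple(species)
    if per_species_counts is None:
        if n_species == 10:
            per_species_counts = DEFAULT_COUNTS
        else:
            per_species_counts = (40,) * n_species
    per_species_counts = tuple(int(c) for c in per_species_counts)
    if len(per_species_counts) != n_species:
        raise DesignError("per_species_counts length must equal n_species")
    if any(c < 1 for c in per_species_counts):
        raise DesignError("per-species sample counts must be positive")
    if not 0.0 <= attrition < 1.0:
        raise ParameterError("attrition must be in [0, 1)")

    rng = np.random.default_rng(seed)
    plots = tuple(f"P{i + 1:02d}" for i in range(n_plots))
    plot_region = {p: REGIONS[i % len(REGIONS)] for i, p in enumerate(plots)}
    growth_form = dict(species)

    rows = []
    for (name, _), count in zip(species, per_species_counts):
        # cycle through a shuffled plot order so plots are roughly balanced
        order = rng.permutation(n_plots)
        assigned = [plots[order[i % n_plots]] for i in range(count)]
        for j, plot in enumerate(assigned):
            if attrition and rng.random() < attrition:
                continue
            abbrev = "".join(w[0] for w in name.split())
            rows.append(
                {
                    "sample_id": f"{abbrev}_{plot}_{j + 1:03d}",
                    "species": name,
                    "growth_form": growth_form[name],
                    "plot": plot,
                    "region": plot_region[plot],
                    "sample_type": "exudate",
                }
            )
    for b in range(n_blanks):
        plot = plots[int(rng.integers(n_plots))]
        rows.append(
            {
                "sample_id": f"blank_{b + 1:03d}",
                "species": "",
                "growth_form": "",
                "plot": plot,
                "region": plot_region[plot],
                "sample_type": "blank",
            }
        )
    samples = pd.DataFrame(rows).set_index("sample_id")
    samples.index.name = None
    return StudyDesign(
        species=tuple(s for s, _ in species),
        growth_form=growth_form,
        plots=plots,
        plot_region=plot_region,
        samples=samples,
        n_blanks=n_blanks,
    )


@dataclass(frozen=True)
class TruthSpec:
    """Planted composition of the synthetic feature table.

    Default sizes mirror the printed shape of the study: a few hundred
    compounds common to both growth forms, species-specific compounds far
    more numerous in forbs than grasses, a block specific to the pooled
    congeneric pair, and a large background of unstructured features so the
    post-filter table lands in the several-thousand range.
    """

    n_shared: int = 270
    n_specific: Mapping[str, int] = field(
        default_factory=lambda: {
            "Achillea millefolium": 60,
            "Galium mollugo": 120,
            "Galium verum": 90,
            "Plantago lanceolata": 180,
            "Ranunculus acris": 84,
            "Alopecurus pratensis": 19,
            "Arrhenatherum elatius": 18,
            "Dactylis glomerata": 18,
            "Lolium perenne": 18,
            "Poa pratensis": 18,
        }
    )
    n_genus_specific: Mapping[str, int] = field(
        default_factory=lambda: {"Galium": 150}
    )
    n_background: int = 4369
    n_blank_contaminants: int = 100
    n_singletons: int = 150
    occupancy_shared: float = 0.8
    occupancy_focal: float = 0.8
    occupancy_background: float = 0.02
    background_occupancy_range: tuple[float, float] = (0.05, 0.5)
    blank_contaminant_rate: float = 0.8
    plot_effect_sd: float = 0.5
    log_intensity_mean: float = 11.5
    log_intensity_sd: float = 1.0

    def __post_init__(self) -> None:
        occs = [
            self.occupancy_shared,
            self.occupancy_focal,
            self.occupancy_background,
            self.blank_contaminant_rate,
            *self.background_occupancy_range,
        ]
        if any(not 0.0 <= o <= 1.0 for o in occs):
            raise ParameterError("occupancies must lie in [0, 1]")
        if self.plot_effect_sd < 0:
            raise ParameterError("plot_effect_sd must be nonnegative")


@dataclass(frozen=True)
class GroundTruth:
    """Per-feature planted labels and the plot-level log-odds shifts.

    ``features`` has one row per feature: feature_class in {shared,
    species_specific, genus_specific, blank_contaminant, singleton,
    background}, the focal species/genus (empty if none), and the occupancy
    parameters used.
    """

    features: pd.DataFrame
    plot_effects: pd.Series

    def of_class(self, feature_class: str) -> pd.Index:
        return self.features.index[
            self.features["feature_class"] == feature_class
        ]


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _apply_plot_effect(base: np.ndarray, shift: np.ndarray) -> np.ndarray:
    """Shift occupancy on the log-odds scale, keeping 0 and 1 fixed points."""
    base = np.asarray(base, dtype=float)
    shift = np.broadcast_to(shift, base.shape)
    out = base.copy()
    interior = (base > 0.0) & (base < 1.0)
    logit = np.log(base[interior] / (1.0 - base[interior]))
    out[interior] = _logistic(logit + shift[interior])
    return out


def generate_feature_table(
    design: StudyDesign,
    truth_spec: TruthSpec | None = None,
    seed: int = 0,
):
    """Simulate a samples x features intensity table with planted truth.

    Presence is Bernoulli per sample with a logistic plot shift; intensity is
    log-normal conditional on presence (downstream analysis binarizes, so
    only positivity matters).  Blank contaminants occupy at least the
    configured fraction of blanks; all other features are absent from blanks.

    Returns ``(FeatureTable, GroundTruth)``.
    """
    from .preprocess import FeatureTable  # local import to avoid a cycle

    spec = truth_spec if truth_spec is not None else TruthSpec()
    rng = np.random.default_rng(seed)
    samples = design.samples
    sample_ids = samples.index.to_numpy()
    is_blank = (samples["sample_type"] == "blank").to_numpy()
    exu_idx = np.flatnonzero(~is_blank)
    blank_idx = np.flatnonzero(is_blank)
    species = samples["species"].to_numpy()
    plot_of = samples["plot"].to_numpy()

    plot_effects = pd.Series(
        rng.normal(0.0, spec.plot_effect_sd, size=len(design.plots)),
        index=list(design.plots),
        name="plot_effect",
    )
    shift = plot_effects.reindex(plot_of).to_numpy()

    records: list[dict] = []
    prob_cols: list[np.ndarray] = []
    n_samples = len(sample_ids)

    def add(feature_class, focal, occ_focal, occ_bg, base_prob):
        i = len(records)
        mz = rng.uniform(90.0, 1000.0)
        rt = rng.uniform(0.01, 18.0)
        records.append(
            {
                "feature_id": f"M{mz:.4f}T{rt:.2f}_{i:05d}",
                "feature_class": feature_class,
                "focal": focal,
                "occupancy_focal": occ_focal,
                "occupancy_background": occ_bg,
            }
        )
        prob_cols.append(base_prob)

    for _ in range(spec.n_shared):
        base = np.where(is_blank, 0.0, spec.occupancy_shared)
        add("shared", "", spec.occupancy_shared, spec.occupancy_shared, base)
    for sp in design.species:
        for _ in range(int(spec.n_specific.get(sp, 0))):
            base = np.where(
                species == sp, spec.occupancy_focal, spec.occupancy_background
            )
            base = np.where(is_blank, 0.0, base)
            add("species_specific", sp, spec.occupancy_focal,
                spec.occupancy_background, base)
    for genus, members in spec.n_genus_specific.items():
        member_species = GENUS_GROUPS.get(genus, ())
        focal_mask = np.isin(species, member_species)
        for _ in range(int(members)):
            base = np.where(
                focal_mask, spec.occupancy_focal, spec.occupancy_background
            )
            base = np.where(is_blank, 0.0, base)
            add("genus_specific", genus, spec.occupancy_focal,
                spec.occupancy_background, base)
    lo, hi = spec.background_occupancy_range
    for _ in range(spec.n_background):
        occ = rng.uniform(lo, hi)
        base = np.where(is_blank, 0.0, occ)
        add("background", "", occ, occ, base)
    for _ in range(spec.n_blank_contaminants):
        base = np.where(is_blank, 0.0, 0.1)
        add("blank_contaminant", "", spec.blank_contaminant_rate, 0.1, base)
    for _ in range(spec.n_singletons):
        base = np.zeros(n_samples)
        add("singleton", "", 0.0, 0.0, base)

    prob = np.column_stack(prob_cols) if prob_cols else np.zeros((n_samples, 0))
    prob = _apply_plot_effect(prob, shift[:, None])
    present = rng.random(prob.shape) < prob

    # singletons: exactly one exudate occurrence each
    truth = pd.DataFrame(records).set_index("feature_id")
    singleton_cols = np.flatnonzero(
        (truth["feature_class"] == "singleton").to_numpy()
    )
    for j in singleton_cols:
        present[:, j] = False
        present[rng.choice(exu_idx), j] = True
    # blank contaminants: present in exactly ceil(rate * n_blanks) blanks,
    # guaranteeing the occurrence floor the blank filter relies on
    contaminant_cols = np.flatnonzero(
        (truth["feature_class"] == "blank_contaminant").to_numpy()
    )
    if len(blank_idx):
        n_hit = int(np.ceil(spec.blank_contaminant_rate * len(blank_idx)))
        for j in contaminant_cols:
            hit = rng.choice(blank_idx, size=n_hit, replace=False)
            present[blank_idx, j] = False
            present[hit, j] = True

    intens = np.where(
        present,
        rng.lognormal(spec.log_intensity_mean, spec.log_intensity_sd,
                      size=present.shape),
        0.0,
    )
    intensities = pd.DataFrame(intens, index=sample_ids,
                               columns=truth.index.copy())
    intensities.columns.name = None
    table = FeatureTable(intensities=intensities,
                         metadata=samples.copy())
    return table, GroundTruth(features=truth, plot_effects=plot_effects)


def generate_traits(
    design: StudyDesign,
    species_effect_size: float = 1.0,
    plot_sd: float = 0.3,
    noise_sd: float = 0.5,
    trait_names: Sequence[str] = TRAIT_NAMES,
    coverage: float = 302 / 389,
    seed: int = 0,
) -> pd.DataFrame:
    """Species-structured functional traits: species mean + plot shift + noise.

    ``species_effect_size`` scales the between-species spread and thereby the
    trait-exudate Procrustes correlation recoverable downstream;
    ``species_effect_size=0`` yields traits independent of species identity.
    ``coverage`` is the fraction of phytometers with trait records (field
    campaigns rarely measure every plant); uncovered samples are omitted.
    """
    if noise_sd < 0 or plot_sd < 0:
        raise ParameterError("standard deviations must be nonnegative")
    if not 0.0 < coverage <= 1.0:
        raise ParameterError("coverage must be in (0, 1]")
    rng = np.random.default_rng(seed)
    exu = design.exudate_samples
    if coverage < 1.0:
        n_keep = max(int(round(coverage * len(exu))), 1)
        keep = np.sort(
            rng.choice(len(exu), size=n_keep, replace=False)
        )
        exu = exu.iloc[keep]
    n_traits = len(trait_names)
    sp_means = {
        sp: rng.normal(0.0, species_effect_size, size=n_traits)
        for sp in design.species
    }
    plot_shift = {
        (p, t): rng.normal(0.0, plot_sd)
        for p in design.plots
        for t in range(n_traits)
    }
    values = np.empty((len(exu), n_traits))
    for i, (sid, row) in enumerate(exu.iterrows()):
        base = sp_means[row["species"]]
        shift = np.array(
            [plot_shift[(row["plot"], t)] for t in range(n_traits)]
        )
        values[i] = base + shift + rng.normal(0.0, noise_sd, size=n_traits)
    return pd.DataFrame(values, index=exu.index, columns=list(trait_names))


def generate_neighborhood(
    design: StudyDesign,
    n_neighbor_species: int = 30,
    mean_richness: float = 8.0,
    total_cover: float = 80.0,
    within_plot_noise: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample neighbor cover vectors (15 cm radius records), plot-structured.

    Each plot receives a fixed community profile (a Dirichlet draw over a
    random species subset); samples within the plot realize noisy copies of
    it, so ordination axes of the table cluster by plot.
    """
    if n_neighbor_species < 1:
        raise ParameterError("need at least one neighbor species")
    rng = np.random.default_rng(seed)
    neighbors = [f"NB_{i + 1:02d}" for i in range(n_neighbor_species)]
    exu = design.exudate_samples
    plot_profile: dict[str, np.ndarray] = {}
    for p in design.plots:
        richness = min(
            n_neighbor_species, 1 + rng.poisson(max(mean_richness - 1, 0.0))
        )
        members = rng.choice(n_neighbor_species, size=richness, replace=False)
        weights = rng.dirichlet(np.ones(richness))
        profile = np.zeros(n_neighbor_species)
        profile[members] = weights * total_cover
        plot_profile[p] = profile
    covers = np.empty((len(exu), n_neighbor_species))
    for i, (_, row) in enumerate(exu.iterrows()):
        noise = rng.lognormal(0.0, within_plot_noise, size=n_neighbor_species)
        covers[i] = plot_profile[row["plot"]] * noise
    return pd.DataFrame(covers, index=exu.index, columns=neighbors)


def generate_lui_components(
    plots: Sequence[str],
    years: Sequence[int] = tuple(range(2006, 2015)),
    seed: int = 0,
) -> pd.DataFrame:
    """Per plot-year fertilization (kg N/ha/yr), mowing (cuts/yr), grazing
    (livestock-unit grazing days/ha) components of the land-use index."""
    years = tuple(int(y) for y in years)
    if len(years) < 1:
        raise ParameterError("need at least one year")
    rng = np.random.default_rng(seed)
    rows = []
    # plot-level intensity regimes persist across years
    regime = {
        p: (
            rng.gamma(1.5, 30.0),   # typical fertilization level
            rng.uniform(0.0, 3.0),  # typical mowing frequency
            rng.gamma(1.2, 80.0),   # typical grazing pressure
        )
        for p in plots
    }
    for p in plots:
        f0, m0, g0 = regime[p]
        for y in years:
            rows.append(
                {
                    "plot": p,
                    "year": y,
                    "fertilization": max(f0 * rng.lognormal(0.0, 0.2), 0.0),
                    "mowing": float(rng.poisson(m0)),
                    "grazing": max(g0 * rng.lognormal(0.0, 0.3), 0.0),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# MS/MS spectra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedSpectrum:
    """Bookkeeping for one simulated spectrum: its planted class labels."""

    spectrum_id: str
    labels: frozenset[str]


def generate_spectra(
    rule_db,
    planted_classes: Sequence[Sequence[str]],
    noise_peaks: int = 0,
    noise_mode: str = "random",
    noise_above_threshold: bool = True,
    intensity_threshold: float = 1000.0,
    seed: int = 0,
):
    """Simulate negative-mode MS/MS spectra carrying diagnostic peaks.

    For every entry of ``planted_classes`` (a set of class/modifier labels)
    one spectrum is produced containing, for each label, the characteristic
    fragment or neutral-loss peak of one rule bearing that label.  Noise
    peaks are added either at random m/z away from every rule window
    (``noise_mode="random"``) or just inside the tolerance window of rules
    the spectrum was not planted with (``noise_mode="near_rules"``), with
    intensities above or below the cleaning threshold as configured.

    Returns ``(spectra, planted)`` where ``planted`` records the ground-truth
    label set per spectrum.
    """
    from .msclass import FragmentSpectrum  # avoid import cycle

    rules = list(rule_db)
    if not rules:
        raise ParameterError("rule database is empty")
    by_label: dict[str, list] = {}
    for r in rules:
        by_label.setdefault(r.label, []).append(r)
    for labels in planted_classes:
        for lab in labels:
            if lab not in by_label:
                raise ParameterError(f"planted class {lab!r} has no rule")
    if noise_mode not in ("random", "near_rules"):
        raise ParameterError("noise_mode must be 'random' or 'near_rules'")

    rng = np.random.default_rng(seed)
    max_frag = max(
        (r.target_mz for r in rules if r.kind == "fragment"), default=0.0
    )
    spectra = []
    planted = []
    for i, labels in enumerate(planted_classes):
        labels = tuple(labels)
        precursor = rng.uniform(max(300.0, max_frag + 50.0), 990.0)
        peaks: list[tuple[float, float]] = []
        planted_rules = []
        for lab in labels:
            rule = by_label[lab][int(rng.integers(len(by_label[lab])))]
            planted_rules.append(rule)
            mz = (
                rule.target_mz
                if rule.kind == "fragment"
                else precursor - rule.target_mz
            )
            peaks.append((mz, rng.uniform(2e4, 5e4)))
        for _ in range(noise_peaks):
            if noise_mode == "near_rules":
                others = [r for r in rules if r.label not in labels]
                r = others[int(rng.integers(len(others)))]
                center = (
                    r.target_mz
                    if r.kind == "fragment"
                    else precursor - r.target_mz
                )
                mz = center + rng.uniform(-r.tolerance, r.tolerance) * 0.5
            else:
                # keep random noise clear of every diagnostic window
                while True:
                    mz = rng.uniform(50.0, precursor - 1.0)
                    clear = all(
                        abs(mz - r.target_mz) > 5 * r.tolerance
                        and abs((precursor - mz) - r.target_mz)
                        > 5 * r.tolerance
                        for r in rules
                    )
                    if clear:
                        break
            if noise_above_threshold:
                inten = rng.uniform(2 * intensity_threshold, 5e4)
            else:
                inten = rng.uniform(1.0, 0.5 * intensity_threshold)
            peaks.append((mz, inten))
        peaks.sort()
        sid = f"SP{i + 1:04d}"
        spectra.append(
            FragmentSpectrum(
                spectrum_id=sid,
                precursor_mz=float(precursor),
                retention_time=float(rng.uniform(0.5, 18.0)),
                peaks=np.array(peaks, dtype=float).reshape(-1, 2),
            )
        )
        planted.append(PlantedSpectrum(sid, frozenset(labels)))
    return spectra, planted


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.10g"


def write_study(
    outdir: str | Path,
    table,
    truth: GroundTruth | None = None,
    traits: pd.DataFrame | None = None,
    neighborhood: pd.DataFrame | None = None,
    lui_components: pd.DataFrame | None = None,
    spectra=None,
    planted=None,
) -> dict[str, Path]:
    """Write every generated input as UTF-8 TSV (spectra as MGF).

    Returns a name -> path map of the files written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def tsv(name: str, df: pd.DataFrame, index_label: str) -> None:
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", float_format=_FLOAT_FMT,
                  index_label=index_label)
        paths[name] = p

    tsv("feature_table", table.intensities, "sample_id")
    tsv("sample_metadata", table.metadata, "sample_id")
    if truth is not None:
        tsv("ground_truth", truth.features, "feature_id")
        tsv("plot_effects", truth.plot_effects.to_frame(), "plot")
    if traits is not None:
        tsv("traits", traits, "sample_id")
    if neighborhood is not None:
        tsv("neighborhood", neighborhood, "sample_id")
    if lui_components is not None:
        p = outdir / "lui_components.tsv"
        lui_components.to_csv(p, sep="\t", float_format=_FLOAT_FMT,
                              index=False)
        paths["lui_components"] = p
    if spectra is not None:
        p = outdir / "spectra.mgf"
        write_mgf(spectra, p)
        paths["spectra"] = p
    if planted is not None:
        p = outdir / "planted_classes.tsv"
        pd.DataFrame(
            {
                "spectrum_id": [pl.spectrum_id for pl in planted],
                "labels": [";".join(sorted(pl.labels)) for pl in planted],
            }
        ).to_csv(p, sep="\t", index=False)
        paths["planted_classes"] = p
    return paths


def write_mgf(spectra, path: str | Path) -> None:
    """Write spectra as MGF (PEPMASS = precursor m/z, TITLE = spectrum id)."""
    entries = []
    for s in spectra:
        entries.append(
            {
                "m/z array": s.peaks[:, 0],
                "intensity array": s.peaks[:, 1],
                "params": {
                    "title": s.spectrum_id,
                    "pepmass": s.precursor_mz,
                    "rtinseconds": s.retention_time * 60.0,
                },
            }
        )
    with open(path, "w") as fh:
        _mgf.write(entries, fh)
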