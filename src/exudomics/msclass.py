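"""MS/MS fragment and neutral-loss compound-class annotation.

Negative-mode [M-H]- spectra are reduced to fragments above an absolute
intensity threshold, normalized to the base peak, and matched against a
rule table of characteristic fragments and neutral losses (hexose and
pentose losses, SO3, HPO3, hydroxycinnamoyl fragments, ...).  Matched rules
aggregate into putative class labels and modifiers (glycosylated, sulfated,
phosphorylated) that may co-occur, e.g. a sulfated, phosphorylated
glycoside.  Rule target masses are computed from monoisotopic atomic masses
at import time.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf
from pyteomics.mass import calculate_mass

__all__ = [
    "FragmentSpectrum",
    "ClassRule",
    "ClassAnnotation",
    "default_rules",
    "read_spectra",
    "clean_spectrum",
    "neutral_losses",
    "annotate_spectrum",
    "classify_batch",
]

_ELECTRON = 0.00054857990907


@dataclass(frozen=True)
class FragmentSpectrum:
    """One MS/MS spectrum: precursor m/z ([M-H]- assumed), retention time in
    minutes, and (m/z, intensity) peaks."""

    spectrum_id: str
    precursor_mz: float
    retention_time: float
    peaks: np.ndarray  # (n, 2)
    normalized: bool = False

    def __post_init__(self) -> None:
        peaks = np.asarray(self.peaks, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "peaks", peaks)
        if peaks.size and (peaks[:, 1] < 0).any():
            raise ValueError("intensities must be nonnegative")

    @property
    def mz(self) -> np.ndarray:
        return self.peaks[:, 0]

    @property
    def intensity(self) -> np.ndarray:
        return self.peaks[:, 1]


@dataclass(frozen=True)
class ClassRule:
    """A characteristic fragment m/z or neutral-loss mass with its label."""

    rule_id: str
    kind: str  # 'fragment' | 'neutral_loss'
    target_mz: float
    label: str
    tolerance: float = 0.005

    def __post_init__(self) -> None:
        if self.kind not in ("fragment", "neutral_loss"):
            raise ValueError("kind must be 'fragment' or 'neutral_loss'")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


def _loss(formula: str) -> float:
    return calculate_mass(formula=formula)


def _anion(formula: str) -> float:
    # deprotonated fragment ion m/z in negative mode
    return calculate_mass(formula=formula) - _loss("H") + _ELECTRON


def default_rules(tolerance: float = 0.005) -> tuple[ClassRule, ...]:
    """Chemistry-derived default rule table.

    Neutral losses diagnostic of conjugation (hexose, deoxyhexose, pentose,
    sulfate, phosphate, water, CO2) and fragment ions diagnostic of
    hydroxycinnamic acids, flavonoids and glycosides; all masses are
    monoisotopic, computed from atomic masses.  Users can supply their own
    table to mirror an in-house database.
    """
    t = tolerance
    rules = [
        ClassRule("NL_hexose", "neutral_loss", _loss("C6H10O5"),
                  "glycosylated", t),
        ClassRule("NL_deoxyhexose", "neutral_loss", _loss("C6H10O4"),
                  "glycosylated", t),
        ClassRule("NL_pentose", "neutral_loss", _loss("C5H8O4"),
                  "glycosylated", t),
        ClassRule("NL_hexuronic", "neutral_loss", _loss("C6H8O6"),
                  "glycosylated", t),
        ClassRule("NL_SO3", "neutral_loss", _loss("SO3"), "sulfated", t),
        ClassRule("NL_HPO3", "neutral_loss", _loss("HPO3"),
                  "phosphorylated", t),
        ClassRule("NL_H2O", "neutral_loss", _loss("H2O"), "hydroxylated", t),
        ClassRule("NL_CO2", "neutral_loss", _loss("CO2"),
                  "carboxylic acid", t),
        ClassRule("NL_coumaroyl", "neutral_loss", _loss("C9H6O2"),
                  "hydroxycinnamic acid", t),
        # deprotonated acid fragments of the hydroxycinnamates
        ClassRule("FR_coumarate", "fragment", _anion("C9H8O3"),
                  "hydroxycinnamic acid", t),
        ClassRule("FR_caffeate", "fragment", _anion("C9H8O4"),
                  "hydroxycinnamic acid", t),
        ClassRule("FR_ferulate", "fragment", _anion("C10H10O4"),
                  "hydroxycinnamic acid", t),
        # retro-Diels-Alder A-ring fragments typical of flavonoids
        ClassRule("FR_flavonoid_RDA", "fragment", _anion("C7H4O4"),
                  "flavonoid", t),
        ClassRule("FR_phloroglucinol", "fragment", _anion("C6H6O3"),
                  "flavonoid", t),
        ClassRule("FR_hexose_anion", "fragment", _anion("C6H12O6"),
                  "glycoside", t),
        ClassRule("FR_sulfate_anion", "fragment", _anion("H2SO4"),
                  "sulfated", t),
        ClassRule("FR_phosphate_anion", "fragment", _anion("H3PO4"),
                  "phosphorylated", t),
    ]
    return tuple(rules)


@dataclass(frozen=True)
class ClassAnnotation:
    """Rules matched in one spectrum and the resulting label set."""

    spectrum_id: str
    matched_rules: tuple[tuple[str, float, float], ...]  # id, observed, delta
    class_labels: tuple[str, ...]
    unclassified: bool


def read_spectra(path: str | Path) -> list[FragmentSpectrum]:
    """Read MS/MS spectra from an MGF or MSP file."""
    path = Path(path)
    if path.suffix.lower() == ".msp":
        return _read_msp(path)
    out = []
    with _mgf.MGF(str(path)) as reader:
        for i, entry in enumerate(reader):
            params = entry.get("params", {})
            if "pepmass" not in params:
                title = params.get("title", f"record {i + 1}")
                raise ValueError(f"spectrum {title!r} lacks a precursor m/z")
            pep = params["pepmass"]
            precursor = float(pep[0] if isinstance(pep, (tuple, list))
                              else pep)
            rt = float(params.get("rtinseconds", 0.0)) / 60.0
            peaks = np.column_stack(
                [entry["m/z array"], entry["intensity array"]]
            ) if len(entry["m/z array"]) else np.empty((0, 2))
            out.append(
                FragmentSpectrum(
                    spectrum_id=str(params.get("title", f"spectrum_{i + 1}")),
                    precursor_mz=precursor,
                    retention_time=rt,
                    peaks=peaks,
                )
            )
    return out


def _read_msp(path: Path) -> list[FragmentSpectrum]:
    from matchms.importing import load_from_msp

    out = []
    for i, sp in enumerate(load_from_msp(str(path))):
        meta = sp.metadata
        precursor = meta.get("precursor_mz") or meta.get("precursormz")
        if precursor is None:
            raise ValueError(
                f"spectrum {meta.get('compound_name', i + 1)!r} lacks a "
                "precursor m/z"
            )
        rt = float(meta.get("retention_time", 0.0) or 0.0)
        out.append(
            FragmentSpectrum(
                spectrum_id=str(
                    meta.get("compound_name", f"spectrum_{i + 1}")
                ),
                precursor_mz=float(precursor),
                retention_time=rt,
                peaks=np.column_stack([sp.peaks.mz, sp.peaks.intensities])
                if len(sp.peaks.mz) else np.empty((0, 2)),
            )
        )
    return out


def clean_spectrum(
    spectrum: FragmentSpectrum,
    abs_intensity_min: float = 1000.0,
    rel_intensity_min: float = 0.1,
) -> FragmentSpectrum:
    """Reduce to fragments above the absolute threshold and normalize to the
    base peak.

    Peaks with raw intensity <= ``abs_intensity_min`` are removed (strict
    boundary); survivors are divided by their maximum so the base peak is
    exactly 1.  Fragment-rule matching downstream only considers peaks with
    normalized intensity strictly above ``rel_intensity_min``; the gate is
    stored with the spectrum via the normalized flag and re-applied by
    :func:`annotate_spectrum`.
    """
    peaks = spectrum.peaks
    keep = peaks[:, 1] > abs_intensity_min
    kept = peaks[keep]
    if len(kept):
        kept = kept.copy()
        kept[:, 1] = kept[:, 1] / kept[:, 1].max()
    return replace(spectrum, peaks=kept, normalized=True)


def _eligible(spectrum: FragmentSpectrum,
              rel_intensity_min: float) -> np.ndarray:
    if not spectrum.normalized:
        spectrum = clean_spectrum(spectrum)
    if not len(spectrum.peaks):
        return np.empty((0, 2))
    return spectrum.peaks[spectrum.peaks[:, 1] > rel_intensity_min]


def neutral_losses(
    spectrum: FragmentSpectrum, rel_intensity_min: float = 0.1
) -> list[tuple[float, float]]:
    """(loss, fragment m/z) pairs, loss = precursor - fragment; nonpositive
    losses are discarded.  Operates on the cleaned, gated fragment set."""
    frags = _eligible(spectrum, rel_intensity_min)
    out = []
    for mz, _ in frags:
        loss = spectrum.precursor_mz - mz
        if loss > 0:
            out.append((float(loss), float(mz)))
    return out


def annotate_spectrum(
    spectrum: FragmentSpectrum,
    rules: Sequence[ClassRule],
    rel_intensity_min: float = 0.1,
) -> ClassAnnotation:
    """Match fragment and neutral-loss rules within their tolerances.

    Labels are the deduplicated, sorted union over matched rules; a spectrum
    matching nothing is flagged unclassified.  The result is independent of
    rule-table order.
    """
    rules = list(rules)
    if not rules:
        raise ValueError("rule table is empty")
    if not spectrum.normalized:
        spectrum = clean_spectrum(spectrum)
    frags = _eligible(spectrum, rel_intensity_min)
    losses = neutral_losses(spectrum, rel_intensity_min)
    matched = []
    labels = set()
    for rule in rules:
        if rule.kind == "fragment":
            for mz, _ in frags:
                delta = mz - rule.target_mz
                if abs(delta) <= rule.tolerance:
                    matched.append((rule.rule_id, float(mz), float(delta)))
                    labels.add(rule.label)
        else:
            for loss, frag_mz in losses:
                delta = loss - rule.target_mz
                if abs(delta) <= rule.tolerance:
                    matched.append((rule.rule_id, float(loss), float(delta)))
                    labels.add(rule.label)
    return ClassAnnotation(
        spectrum_id=spectrum.spectrum_id,
        matched_rules=tuple(sorted(matched)),
        class_labels=tuple(sorted(labels)),
        unclassified=not labels,
    )


def classify_batch(
    spectra: Iterable[FragmentSpectrum],
    rules: Sequence[ClassRule],
    species: Sequence[str] | None = None,
    rel_intensity_min: float = 0.1,
) -> pd.DataFrame:
    """Annotate a spectrum collection and tabulate label counts.

    Returns one row per spectrum with its combined label string (labels
    joined by '; ', 'Unclassified' when empty) and, if given, the species
    attribute -- the shape from which per-class, per-species count tables
    are built.
    """
    spectra = list(spectra)
    rows = []
    for i, sp in enumerate(spectra):
        ann = annotate_spectrum(sp, rules, rel_intensity_min)
        rows.append(
            {
                "spectrum_id": sp.spectrum_id,
                "labels": "; ".join(ann.class_labels) or "Unclassified",
                "n_matched_rules": len(ann.matched_rules),
                "unclassified": ann.unclassified,
                **({"species": species[i]} if species is not None else {}),
            }
        )
    return pd.DataFrame(rows)
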