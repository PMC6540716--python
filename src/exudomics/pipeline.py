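"""End-to-end orchestration of the exudate community analysis.

``run_pipeline`` wires the stages together: read (or simulate) the feature
table, apply the blank and singleton filters, binarize, then compute
chemical richness with ANOVA and Scheffé letters, the species-specificity
screen, RDA against species identity, hierarchical clustering, the
trait-exudate Procrustes test, variance partitioning (three-set and
single-variable layouts), the land-use index, and MS/MS class annotation.
Every artifact is written as TSV / Newick / YAML with deterministic
formatting so a rerun with the same seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import attribution, msclass, ordination, preprocess, richness
from . import simulate, specificity

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All tunables of one pipeline run.

    ``input_dir`` must contain feature_table.tsv / sample_metadata.tsv (and
    optionally traits.tsv, neighborhood.tsv, lui_components.tsv,
    spectra.mgf, ground_truth.tsv, planted_classes.tsv as written by the
    simulator); when it is None, a synthetic study is generated in-run from
    ``seed``.
    """

    input_dir: str | None = None
    output_dir: str = "exudomics_out"
    seed: int = 0
    blank_fraction: float = 0.5
    presence_threshold: float = 0.0
    specificity_criterion: float = 0.95
    min_occurrence: int = 2
    scheffe_alpha: float = 0.05
    cluster_metric: str = "euclidean"
    cluster_linkage: str = "complete"
    n_permutations: int = 999
    procrustes_axes: int | None = None
    dca_axes: int = 4
    rule_tolerance: float = 0.005
    rule_table: str | None = None

    def validate(self) -> None:
        if not 0.0 < self.blank_fraction <= 1.0:
            raise ValueError("blank_fraction must be in (0, 1]")
        if not 0.5 <= self.specificity_criterion < 1.0:
            raise ValueError("specificity_criterion must be in [0.5, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be positive")
        if self.presence_threshold < 0:
            raise ValueError("presence_threshold must be nonnegative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _tsv(path: Path, df: pd.DataFrame, index_label=None) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT,
              index_label=index_label)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute every stage and write the result bundle to
    ``config.output_dir``.  Returns a name -> path map of artifacts."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    def stage(name):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(name, exc) from exc
                log(f"stage {name}: ok")
                return False

        return _Ctx()

    # ---------------- inputs ----------------
    with stage("inputs"):
        inputs = _load_inputs(config, log)
    table = inputs["table"]
    design_meta = table.metadata

    # ---------------- filtering ----------------
    with stage("filter"):
        filtered = preprocess.filter_blank_features(
            table,
            blank_fraction=config.blank_fraction,
            presence_threshold=config.presence_threshold,
        )
        filtered = preprocess.filter_singletons(
            filtered, presence_threshold=config.presence_threshold
        )
        pa = preprocess.to_presence_absence(
            filtered, presence_threshold=config.presence_threshold
        )
        p = out / "presence_absence.tsv"
        _tsv(p, pa.values, "sample_id")
        artifacts["presence_absence"] = p
        log(
            f"filtered {table.n_features - filtered.n_features} features; "
            f"{pa.shape[1]} remain over {pa.shape[0]} exudate samples"
        )

    species = pa.metadata["species"]
    growth_form = pa.metadata["growth_form"]
    gf_map = (
        pa.metadata.drop_duplicates("species")
        .set_index("species")["growth_form"]
        .to_dict()
    )

    # ---------------- richness ----------------
    with stage("richness"):
        rich = richness.chemical_richness(pa)
        anova = richness.one_way_anova(rich, species)
        scheffe = richness.scheffe_posthoc(
            rich, species, alpha=config.scheffe_alpha
        )
        summary = richness.group_summary(rich, species)
        summary["letters"] = pd.Series(scheffe.letters)
        p = out / "richness_summary.tsv"
        _tsv(p, summary, "species")
        artifacts["richness_summary"] = p
        p = out / "richness_pairs.tsv"
        _tsv(p, scheffe.pairs)
        artifacts["richness_pairs"] = p
        log(
            f"richness ANOVA F={anova.F:.4g} "
            f"df=({anova.df1},{anova.df2}) p={anova.p:.4g}"
        )

    # ---------------- specificity ----------------
    with stage("specificity"):
        screen = specificity.screen_all(
            pa,
            species,
            criterion=config.specificity_criterion,
            genus_groups=_present_genus_groups(species),
            growth_forms=gf_map,
            min_occurrence=config.min_occurrence,
        )
        rec = pd.DataFrame([dataclasses.asdict(r) for r in screen.records])
        p = out / "specificity_records.tsv"
        if rec.empty:
            rec = pd.DataFrame(
                columns=["feature_id", "focal_group", "k_focal", "n_focal",
                         "k_other", "n_other", "p_value", "specific"]
            )
        _tsv(p, rec.set_index("feature_id"), "feature_id")
        artifacts["specificity_records"] = p
        p = out / "sharing_summary.yaml"
        with open(p, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(screen.summary), fh,
                           sort_keys=True)
        artifacts["sharing_summary"] = p
        log(
            f"specific compounds: {screen.summary.n_specific_total} of "
            f"{screen.summary.n_considered} considered"
        )

    # ---------------- ordination & clustering ----------------
    with stage("ordination"):
        species_X = ordination.one_hot(species)
        rda_res = ordination.rda(pa.values, species_X)
        eig = pd.DataFrame(
            {
                "eigenvalue": rda_res.eigenvalues,
                "proportion": rda_res.axis_proportions,
            },
            index=[f"RDA{i + 1}" for i in range(len(rda_res.eigenvalues))],
        )
        p = out / "rda_eigenvalues.tsv"
        _tsv(p, eig, "axis")
        artifacts["rda_eigenvalues"] = p
        p = out / "rda_site_scores.tsv"
        _tsv(p, rda_res.site_scores, "sample_id")
        artifacts["rda_site_scores"] = p

        exu_pca = ordination.pca(pa.values.astype(float))
        p = out / "pca_site_scores.tsv"
        _tsv(p, exu_pca.site_scores, "sample_id")
        artifacts["pca_site_scores"] = p

        dendro = ordination.hierarchical_cluster(
            pa, metric=config.cluster_metric, linkage=config.cluster_linkage
        )
        p = out / "dendrogram.nwk"
        p.write_text(dendro.to_newick() + "\n")
        artifacts["dendrogram"] = p
        log(
            "RDA constrained proportion "
            f"{rda_res.constrained_proportion:.4f}"
        )

    # ---------------- neighborhood metrics ----------------
    lnh_vars = None
    if inputs.get("neighborhood") is not None:
        with stage("neighborhood"):
            nb = inputs["neighborhood"].loc[
                inputs["neighborhood"].index.intersection(pa.values.index)
            ]
            nb = nb.reindex(pa.values.index).dropna()
            dca_res = ordination.dca(nb, n_axes=config.dca_axes)
            metrics = pd.DataFrame(
                {
                    "species_richness": (nb > 0).sum(axis=1),
                    "shannon": [
                        ordination.shannon_diversity(r)
                        for r in nb.to_numpy()
                    ],
                    "total_cover": nb.sum(axis=1),
                }
            )
            lnh_vars = metrics.join(
                dca_res.site_scores.reindex(metrics.index)
            )
            p = out / "neighborhood_metrics.tsv"
            _tsv(p, lnh_vars, "sample_id")
            artifacts["neighborhood_metrics"] = p

    # ---------------- Procrustes ----------------
    traits = inputs.get("traits")
    if traits is not None:
        with stage("procrustes"):
            common = pa.values.index.intersection(traits.index)
            exu_scores = ordination.pca(
                pa.values.loc[common].astype(float)
            ).site_scores
            trait_scores = ordination.pca(traits.loc[common]).site_scores
            if config.procrustes_axes is not None:
                exu_scores = exu_scores.iloc[:, : config.procrustes_axes]
                trait_scores = trait_scores.iloc[:, : config.procrustes_axes]
            pro = attribution.protest(
                exu_scores,
                trait_scores,
                n_permutations=config.n_permutations,
                seed=config.seed,
            )
            rep = pd.DataFrame(
                {
                    "value": [
                        pro.correlation,
                        pro.m2,
                        pro.permutation_p,
                        pro.n_permutations,
                        len(common),
                    ]
                },
                index=["correlation", "m2", "permutation_p",
                       "n_permutations", "n_samples"],
            )
            p = out / "procrustes.tsv"
            _tsv(p, rep, "quantity")
            artifacts["procrustes"] = p
            log(
                f"Procrustes correlation {pro.correlation:.4f} "
                f"(p={pro.permutation_p:.4g}, n={len(common)})"
            )

    # ---------------- LUI ----------------
    lui_per_sample = None
    if inputs.get("lui_components") is not None:
        with stage("lui"):
            lui = attribution.lui_index(inputs["lui_components"])
            p = out / "lui.tsv"
            _tsv(p, lui, "plot")
            artifacts["lui"] = p
            mean_col = [c for c in lui.columns if c.startswith("lui_mean")][0]
            lui_per_sample = (
                pa.metadata["plot"].map(lui[mean_col]).rename("LUI")
            )

    # ---------------- variance partitioning ----------------
    if traits is not None:
        with stage("varpart"):
            vp_rows = {}
            for gf in sorted(set(growth_form.dropna()) - {""}):
                mask = (growth_form == gf).to_numpy()
                idx = pa.values.index[mask]
                idx = idx.intersection(traits.index)
                Y = pa.values.loc[idx].astype(float)
                sets = {
                    "Species": ordination.one_hot(species.loc[idx]),
                    "Plot": ordination.one_hot(pa.metadata.loc[idx, "plot"]),
                    "Traits": traits.loc[idx],
                }
                part = attribution.variance_partition(Y, sets)
                vp_rows[gf] = part.table()
            vp = pd.DataFrame(vp_rows)
            p = out / "varpart_three_sets.tsv"
            _tsv(p, vp, "fraction")
            artifacts["varpart_three_sets"] = p

            sv_table = _single_variable_partitions(
                pa, traits, lnh_vars, lui_per_sample, growth_form, species
            )
            p = out / "varpart_single_variables.tsv"
            _tsv(p, sv_table)
            artifacts["varpart_single_variables"] = p

    # ---------------- MS/MS classification ----------------
    if inputs.get("spectra") is not None:
        with stage("classify"):
            rules = inputs["rules"]
            cleaned = [msclass.clean_spectrum(s) for s in inputs["spectra"]]
            counts = msclass.classify_batch(cleaned, rules)
            p = out / "class_annotations.tsv"
            _tsv(p, counts.set_index("spectrum_id"), "spectrum_id")
            artifacts["class_annotations"] = p

    # ---------------- recovery vs planted truth ----------------
    if inputs.get("truth") is not None:
        with stage("recovery"):
            rec = _recovery_metrics(screen, inputs["truth"], pa)
            if inputs.get("planted") is not None and \
                    inputs.get("spectra") is not None:
                ann = msclass.classify_batch(cleaned, rules)
                planted = inputs["planted"].set_index("spectrum_id")["labels"]
                got = ann.set_index("spectrum_id")["labels"].map(
                    lambda s: ";".join(sorted(s.split("; ")))
                    if s != "Unclassified" else ""
                )
                want = planted.map(
                    lambda s: ";".join(sorted(s.split(";"))) if s else ""
                )
                rec["class_recovery_rate"] = float(
                    (got.reindex(want.index) == want).mean()
                )
            p = out / "recovery_metrics.tsv"
            _tsv(
                p,
                pd.DataFrame({"value": pd.Series(rec)}),
                "metric",
            )
            artifacts["recovery_metrics"] = p

    # ---------------- manifest & log ----------------
    with stage("manifest"):
        cfg_record = dataclasses.asdict(config)
        # the output location is not a parameter of the analysis; keeping
        # it out makes reruns into different directories byte-comparable
        cfg_record.pop("output_dir")
        manifest = {
            "version": __version__,
            "config": cfg_record,
            "artifacts": {k: str(v.name) for k, v in artifacts.items()},
            "n_samples": int(pa.shape[0]),
            "n_features": int(pa.shape[1]),
        }
        p = out / "manifest.yaml"
        with open(p, "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
        artifacts["manifest"] = p
        p = out / "run.log"
        p.write_text("\n".join(log_lines) + "\n")
        artifacts["log"] = p
    return artifacts


def _load_inputs(config: PipelineConfig, log) -> dict:
    inputs: dict = {}
    if config.input_dir is None:
        log(f"simulating study (seed={config.seed})")
        design = simulate.generate_design(seed=config.seed)
        table, truth = simulate.generate_feature_table(
            design, seed=config.seed + 1
        )
        inputs["table"] = table
        inputs["truth"] = truth.features
        inputs["traits"] = simulate.generate_traits(
            design, seed=config.seed + 2
        )
        inputs["neighborhood"] = simulate.generate_neighborhood(
            design, seed=config.seed + 3
        )
        inputs["lui_components"] = simulate.generate_lui_components(
            design.plots, seed=config.seed + 4
        )
        rules = msclass.default_rules(config.rule_tolerance)
        planted_sets = _default_planted_classes(rules, n=60,
                                                seed=config.seed + 5)
        spectra, planted = simulate.generate_spectra(
            rules, planted_sets, seed=config.seed + 5
        )
        inputs["spectra"] = spectra
        inputs["planted"] = pd.DataFrame(
            {
                "spectrum_id": [p.spectrum_id for p in planted],
                "labels": [";".join(sorted(p.labels)) for p in planted],
            }
        )
        inputs["rules"] = rules
        return inputs

    d = Path(config.input_dir)
    inputs["table"] = preprocess.read_feature_table(
        d / "feature_table.tsv", d / "sample_metadata.tsv"
    )
    for name in ("traits", "neighborhood"):
        f = d / f"{name}.tsv"
        if f.exists():
            inputs[name] = pd.read_csv(f, sep="\t", index_col=0)
    f = d / "lui_components.tsv"
    if f.exists():
        inputs["lui_components"] = pd.read_csv(f, sep="\t")
    f = d / "ground_truth.tsv"
    if f.exists():
        inputs["truth"] = pd.read_csv(
            f, sep="\t", index_col=0, keep_default_na=False
        )
    for suffix in (".mgf", ".msp"):
        f = d / f"spectra{suffix}"
        if f.exists():
            inputs["spectra"] = msclass.read_spectra(f)
            break
    f = d / "planted_classes.tsv"
    if f.exists():
        inputs["planted"] = pd.read_csv(f, sep="\t", keep_default_na=False)
    if config.rule_table:
        rdf = pd.read_csv(config.rule_table, sep="\t")
        inputs["rules"] = tuple(
            msclass.ClassRule(
                rule_id=r.rule_id, kind=r.kind, target_mz=r.target_mz,
                label=r.label,
                tolerance=getattr(r, "tolerance", config.rule_tolerance),
            )
            for r in rdf.itertuples()
        )
    else:
        inputs["rules"] = msclass.default_rules(config.rule_tolerance)
    return inputs


def _default_planted_classes(rules, n: int, seed: int):
    rng = np.random.default_rng(seed)
    labels = sorted({r.label for r in rules})
    sets = []
    for _ in range(n):
        size = int(rng.integers(1, 4))
        sets.append(tuple(
            sorted(rng.choice(labels, size=size, replace=False))
        ))
    return sets


def _present_genus_groups(species: pd.Series):
    present = set(species.unique())
    groups = {
        g: members
        for g, members in simulate.GENUS_GROUPS.items()
        if 0 < len(present & set(members)) < len(present)
        and set(members) <= present
    }
    return groups or None


def _single_variable_partitions(
    pa, traits, lnh_vars, lui_per_sample, growth_form, species
) -> pd.DataFrame:
    """Three-set partition (Species, Plot, single variable) per growth form,
    one row per single variable -- the tabular layout of the study."""
    sv_frames = []
    single_vars: dict[str, pd.Series] = {
        c: traits[c] for c in traits.columns
    }
    if lnh_vars is not None:
        for c in lnh_vars.columns:
            single_vars[c] = lnh_vars[c]
    if lui_per_sample is not None:
        single_vars["LUI"] = lui_per_sample
    for gf in sorted(set(growth_form.dropna()) - {""}):
        mask = (growth_form == gf).to_numpy()
        idx_gf = pa.values.index[mask]
        for name, var in single_vars.items():
            idx = idx_gf.intersection(var.dropna().index)
            if len(idx) < 10:
                continue
            Y = pa.values.loc[idx].astype(float)
            sets = {
                "Species": ordination.one_hot(species.loc[idx]),
                "Plot": ordination.one_hot(pa.metadata.loc[idx, "plot"]),
                "SV": var.loc[idx].to_frame(),
            }
            part = attribution.variance_partition(Y, sets)
            row = part.table().mul(100.0)
            row.name = name
            frame = row.to_frame().T
            frame.insert(0, "growth_form", gf)
            sv_frames.append(frame)
    if not sv_frames:
        return pd.DataFrame()
    out = pd.concat(sv_frames)
    out.index.name = "single_variable"
    return out


def _recovery_metrics(screen, truth: pd.DataFrame, pa) -> dict:
    """Sensitivity / attribution accuracy of the screen vs planted truth."""
    planted = truth[truth["feature_class"] == "species_specific"]
    planted = planted[planted.index.isin(pa.values.columns)]
    if planted.empty:
        return {}
    assigned = screen.assignment.reindex(planted.index).fillna("")
    recovered = assigned != ""
    correct = assigned == planted["focal"]
    null_feats = truth[truth["feature_class"].isin(["shared", "background"])]
    null_feats = null_feats[null_feats.index.isin(pa.values.columns)]
    fp = (
        (screen.assignment.reindex(null_feats.index).fillna("") != "").mean()
        if len(null_feats)
        else 0.0
    )
    return {
        "specificity_sensitivity": float(recovered.mean()),
        "specificity_attribution_accuracy": float(
            correct[recovered].mean() if recovered.any() else 0.0
        ),
        "specificity_false_positive_rate": float(fp),
    }
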