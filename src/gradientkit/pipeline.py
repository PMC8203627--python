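"""End-to-end pipeline: data -> connectomes -> manifolds -> statistics -> decoding.

All stage outputs are plain TSV/JSON files in one directory per run, and
a run record (config snapshot, seeds, per-file SHA-256 digests, captured
warnings) is written atomically at the end, so seeded runs can be
verified digest-for-digest.

The default configuration mirrors the standard gradient-analysis
settings: 10% connection density, diffusion embedding with alpha = 0.5
and t = 0, three reported components, 5000 subject permutations, 100
sphere rotations for spatial nulls, FDR q = 0.05.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectome import (
    ConnectivityMatrix,
    RegionTimeSeries,
    correlation_connectome,
    group_average_connectome,
    threshold_by_density,
)
from .decoding import (
    csea_enrichment,
    donor_consistency_filter,
    fisher_enrichment,
    gene_map_association,
    spin_significance_filter,
)
from .embedding import build_aligned_set
from .metrics import (
    ModulePartition,
    centralities,
    louvain_partition,
    manifold_eccentricity,
    participation_coefficient,
    symmetrize_nonnegative,
    within_module_degree,
)
from .stats import (
    DesignMatrix,
    design_matrix,
    fdr_bh,
    group_hotelling,
    hotelling_glm,
    partial_correlation_permutation,
    stratify_map,
)
from .synthetic import (
    ParcelAtlas,
    SyntheticCohort,
    generate_atlas,
    generate_cell_type_specificity,
    generate_cohort,
    generate_expression_panel,
    generate_structural_maps,
)

__all__ = ["PipelineConfig", "RunRecord", "run_pipeline", "sensitivity_suite",
           "DEFAULT_PLANTED_EFFECT"]

log = logging.getLogger("gradientkit")

#: Planted coupling-modulation effect size giving a parcel-level
#: standardized effect (partial multivariate correlation between z(BMI)
#: and the aligned E1-E3 coordinates of affected parcels at n = 150) of
#: about 0.5 under the generator defaults; calibrated once on
#: independent draws.
DEFAULT_PLANTED_EFFECT = 0.08


@dataclass
class PipelineConfig:
    """Every knob of the pipeline, serialized verbatim into run records."""

    out_dir: str = "runs/run0"
    input_dir: str | None = None  # None -> synthesize a cohort
    seed: int = 0

    # synthetic cohort
    n_parcels: int = 100
    n_modules: int = 12
    n_subjects: int = 150
    n_timepoints: int = 200
    effect_size: float = DEFAULT_PLANTED_EFFECT
    affected_modules: tuple = ("M0", "M1")
    noise_sd: float = 1.0
    effect_size_struct: float = -0.1

    # embedding
    density: float = 0.10
    alpha: float = 0.5
    t: float = 0.0
    n_components_report: int = 3
    n_components_internal: int = 10

    # statistics
    covariate_columns: tuple = ("age", "sex", "bmi")
    term: str = "bmi"
    n_perm: int = 5000
    n_spins: int = 100
    fdr_q: float = 0.05
    module_source: str = "atlas_communities"  # or "louvain" / "hierarchy"
    group_comparison: bool = True

    # decoding panel
    n_donors: int = 4
    n_genes: int = 200
    n_signal_genes: int = 20
    signal_corr: float = 0.9

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("affected_modules", "covariate_columns"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["affected_modules"] = list(d["affected_modules"])
        d["covariate_columns"] = list(d["covariate_columns"])
        return d


@dataclass
class RunRecord:
    config: dict
    version: str
    seed: int
    digests: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    stages: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------- IO helpers

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_tsv(df: pd.DataFrame, path: Path, float_format: str = "%.10g"):
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def write_matrix(values: np.ndarray, path: Path):
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, values, delimiter="\t", fmt="%.10g")


def read_atlas(path) -> ParcelAtlas:
    df = pd.read_csv(path, sep="\t").sort_values("parcel_id")
    return ParcelAtlas(
        centroids=df[["x", "y", "z"]].to_numpy(float),
        module_labels=df["module"].to_numpy(str),
        hierarchy_labels=df["hierarchy"].to_numpy(str),
    )


def read_cohort(input_dir) -> tuple[ParcelAtlas, SyntheticCohort]:
    """Load atlas, covariates and per-subject time series from a directory.

    Expects atlas.tsv, covariates.tsv and ts/<subject_id>.tsv matrices
    (parcels x timepoints, tab-delimited); truth.json is read if present.
    """
    input_dir = Path(input_dir)
    atlas = read_atlas(input_dir / "atlas.tsv")
    cov = pd.read_csv(input_dir / "covariates.tsv", sep="\t")
    series = []
    for sid in cov["subject_id"]:
        series.append(np.loadtxt(input_dir / "ts" / f"{sid}.tsv", delimiter="\t"))
    truth = {}
    truth_path = input_dir / "truth.json"
    if truth_path.exists():
        truth = json.loads(truth_path.read_text())
    cohort = SyntheticCohort(time_series=np.stack(series), covariates=cov, truth=truth)
    if cohort.n_parcels != atlas.n_parcels:
        raise ValueError("time-series parcel count does not match atlas")
    return atlas, cohort


def write_cohort(atlas: ParcelAtlas, cohort: SyntheticCohort, out_dir,
                 structural: dict | None = None):
    out = Path(out_dir)
    write_tsv(atlas.to_frame(), out / "atlas.tsv")
    write_tsv(cohort.covariates, out / "covariates.tsv")
    for i, sid in enumerate(cohort.covariates["subject_id"]):
        write_matrix(cohort.time_series[i], out / "ts" / f"{sid}.tsv")
    (out / "truth.json").write_text(json.dumps(cohort.truth, indent=1))
    for name, vals in (structural or {}).items():
        write_matrix(vals, out / f"structural_{name}.tsv")


# ------------------------------------------------------------------ pipeline

def _statmap_frame(sm) -> pd.DataFrame:
    return sm.to_frame()


def run_pipeline(config: PipelineConfig) -> RunRecord:
    """Execute every stage in dependency order; returns the run record."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    record = RunRecord(config=config.to_dict(), version=__version__,
                       seed=config.seed)
    caught: list[str] = []

    def stage(name):
        log.info("stage %s", name)
        record.stages.append(name)

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        try:
            _run_stages(config, out, record, stage)
        except Exception as exc:
            stage_name = record.stages[-1] if record.stages else "setup"
            raise RuntimeError(f"pipeline failed at stage {stage_name!r}: {exc}") from exc
        caught = [str(w.message) for w in wlist]

    record.warnings = caught
    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "run_record.json":
            record.digests[str(f.relative_to(out))] = _sha256(f)
    tmp = out / "run_record.json.tmp"
    tmp.write_text(json.dumps(record.to_dict(), indent=1, default=str))
    tmp.replace(out / "run_record.json")
    return record


def _run_stages(config: PipelineConfig, out: Path, record: RunRecord, stage):
    rng_seed = int(config.seed)

    # -- data -----------------------------------------------------------
    stage("data")
    if config.input_dir in (None, "synthetic"):
        atlas = generate_atlas(config.n_parcels, config.n_modules, seed=rng_seed)
        cohort = generate_cohort(
            atlas,
            n_subjects=config.n_subjects,
            n_timepoints=config.n_timepoints,
            effect_size=config.effect_size,
            affected_modules=config.affected_modules,
            noise_sd=config.noise_sd,
            seed=rng_seed,
        )
        structural = generate_structural_maps(
            atlas, cohort, effect_size_struct=config.effect_size_struct,
            seed=rng_seed + 1,
        )
        write_cohort(atlas, cohort, out / "data", structural)
    else:
        atlas, cohort = read_cohort(config.input_dir)
        structural = {}
        for f in Path(config.input_dir).glob("structural_*.tsv"):
            structural[f.stem.removeprefix("structural_")] = np.loadtxt(
                f, delimiter="\t"
            )
    subject_ids = list(cohort.covariates["subject_id"])

    # -- connectomes ----------------------------------------------------
    stage("connectome")
    connectomes = [
        correlation_connectome(RegionTimeSeries(cohort.time_series[i], sid))
        for i, sid in enumerate(subject_ids)
    ]
    group = group_average_connectome(connectomes)
    write_matrix(group.values, out / "connectome_group.tsv")

    # -- manifolds ------------------------------------------------------
    stage("embedding")
    aligned = build_aligned_set(
        group, connectomes,
        density=config.density, alpha=config.alpha, t=config.t,
        n_components=config.n_components_report,
        n_components_internal=config.n_components_internal,
    )
    k = config.n_components_report
    cols = [f"E{i + 1}" for i in range(k)]
    tdf = pd.DataFrame(aligned.template.eigenvectors, columns=cols)
    tdf.insert(0, "parcel_id", np.arange(atlas.n_parcels))
    write_tsv(tdf, out / "template_embedding.tsv")
    (out / "template_embedding.json").write_text(json.dumps({
        "eigenvalues": aligned.template.eigenvalues.tolist(),
        "variance_explained": aligned.template.variance_explained.tolist(),
        "alpha": config.alpha, "t": config.t, "density": config.density,
    }, indent=1))
    sub_rows = []
    for sid in subject_ids:
        df = pd.DataFrame(aligned.subjects[sid], columns=cols)
        df.insert(0, "parcel_id", np.arange(atlas.n_parcels))
        df.insert(0, "subject_id", sid)
        sub_rows.append(df)
    write_tsv(pd.concat(sub_rows, ignore_index=True),
              out / "subject_embeddings.tsv")

    # -- network metrics ------------------------------------------------
    stage("metrics")
    center = aligned.template.center()
    ecc = np.stack([
        manifold_eccentricity(aligned.subjects[sid], center, sid).values
        for sid in subject_ids
    ])
    edf = pd.DataFrame(ecc, columns=[f"p{i}" for i in range(atlas.n_parcels)])
    edf.insert(0, "subject_id", subject_ids)
    write_tsv(edf, out / "eccentricity.tsv")

    group_thr = threshold_by_density(group, config.density)
    Wsym = symmetrize_nonnegative(group_thr.values)
    partitions = {
        "atlas_communities": ModulePartition(atlas.module_labels,
                                             "atlas_communities"),
        "louvain": louvain_partition(Wsym, seed=rng_seed),
        "hierarchy": ModulePartition(atlas.hierarchy_labels, "hierarchy"),
    }
    metric_rows = []
    for pname, part in partitions.items():
        metric_rows.append(pd.DataFrame({
            "parcel_id": np.arange(atlas.n_parcels),
            "partition": pname,
            "within_module_degree": within_module_degree(Wsym, part),
            "participation_coefficient": participation_coefficient(Wsym, part),
        }))
    cent = centralities(Wsym)
    write_tsv(pd.concat(metric_rows, ignore_index=True),
              out / "modular_metrics.tsv")
    write_tsv(pd.DataFrame({"parcel_id": np.arange(atlas.n_parcels), **cent}),
              out / "centralities.tsv")

    # -- association ----------------------------------------------------
    stage("association")
    Y = np.stack([aligned.subjects[sid] for sid in subject_ids])  # (n, P, k)
    X = design_matrix(cohort.covariates, columns=config.covariate_columns)
    main = hotelling_glm(Y, X, term=config.term, q=config.fdr_q)
    write_tsv(main.to_frame(), out / "statmap_main.tsv")
    mask = np.flatnonzero(main.significant)
    write_tsv(pd.DataFrame({"parcel_id": mask}), out / "mask_significant.tsv")

    for by, fname in (("module_label", "stratified_module.tsv"),
                      ("hierarchy_label", "stratified_hierarchy.tsv")):
        strat = stratify_map(main, atlas, by=by).reset_index()
        strat.columns = ["category", "mean_statistic"]
        write_tsv(strat, out / fname)

    # BMI vs manifold eccentricity within the significant mask
    covars_ns = design_matrix(cohort.covariates, columns=("age", "sex"))
    bmi = cohort.covariates["bmi"].to_numpy(float)
    ecc_rows = []
    for pi, parcel in enumerate(mask):
        r, p = partial_correlation_permutation(
            bmi, ecc[:, parcel], covars_ns,
            n_perm=config.n_perm, seed=rng_seed + 100 + pi)
        ecc_rows.append(dict(parcel_id=int(parcel), r=r, p=p))
    ecc_df = pd.DataFrame(ecc_rows)
    if len(ecc_df):
        ecc_df["q"], _ = fdr_bh(ecc_df["p"].to_numpy(), config.fdr_q)
    write_tsv(ecc_df, out / "eccentricity_bmi.tsv")

    # spatial correlation of mean eccentricity with modular measures
    mean_ecc = ecc.mean(axis=0)
    sel = mask if mask.size >= 10 else np.arange(atlas.n_parcels)
    mod_rows = []
    rng = np.random.default_rng(rng_seed + 500)
    for pname, part in partitions.items():
        for metric_name, vals in (
            ("within_module_degree", within_module_degree(Wsym, part)),
            ("participation_coefficient", participation_coefficient(Wsym, part)),
        ):
            r = float(np.corrcoef(mean_ecc[sel], vals[sel])[0, 1])
            null = np.empty(config.n_perm)
            for i in range(config.n_perm):
                null[i] = np.corrcoef(mean_ecc[sel],
                                      vals[rng.permutation(sel)])[0, 1]
            p = (1.0 + np.sum(np.abs(null) >= abs(r))) / (config.n_perm + 1.0)
            mod_rows.append(dict(partition=pname, metric=metric_name, r=r, p=p))
    mod_df = pd.DataFrame(mod_rows)
    mod_df["q"], _ = fdr_bh(mod_df["p"].to_numpy(), config.fdr_q)
    write_tsv(mod_df, out / "graph_metric_correlations.tsv")

    # confound-adjusted model: per-parcel structural indices as covariates
    if structural:
        padj = np.empty(atlas.n_parcels)
        stat_adj = np.empty(atlas.n_parcels)
        for parcel in range(atlas.n_parcels):
            data = pd.DataFrame({"intercept": np.ones(cohort.n_subjects)})
            for c in config.covariate_columns:
                data[c] = cohort.covariates[c].to_numpy(float)
            for name, vals in structural.items():
                data[f"struct_{name}"] = vals[:, parcel]
            Xp = DesignMatrix(data=data)
            sm = hotelling_glm(Y[:, parcel, :], Xp, term=config.term)
            stat_adj[parcel], padj[parcel] = sm.statistic[0], sm.p_value[0]
        qadj, rejadj = fdr_bh(padj, config.fdr_q)
        write_tsv(pd.DataFrame({
            "parcel_id": np.arange(atlas.n_parcels), "statistic": stat_adj,
            "p": padj, "q": qadj, "significant": rejadj.astype(int),
        }), out / "statmap_struct_adjusted.tsv")

    # weight model (height + weight replace BMI)
    if {"height", "weight"} <= set(cohort.covariates.columns):
        Xw = design_matrix(cohort.covariates,
                           columns=("age", "sex", "height", "weight"))
        wmap = hotelling_glm(Y, Xw, term="weight", q=config.fdr_q)
        write_tsv(wmap.to_frame(), out / "statmap_weight.tsv")

    # overweight vs healthy-weight group contrast (underweight excluded)
    if config.group_comparison:
        keep = bmi >= 18.5
        groups = (bmi[keep] >= 25).astype(int)
        k = config.n_components_report
        sizes = [(groups == g).sum() for g in (0, 1)]
        if min(sizes) >= k + 2:
            gmap = group_hotelling(Y[keep], groups,
                                   cohort.covariates.loc[keep], q=config.fdr_q)
            write_tsv(gmap.to_frame(), out / "statmap_group.tsv")
        else:
            warnings.warn(
                f"group comparison skipped: group sizes {sizes} too small "
                f"for k={k} responses",
                stacklevel=2,
            )

    # -- transcriptomic decoding ---------------------------------------
    stage("decoding")
    panel, signal_genes = generate_expression_panel(
        atlas, n_donors=config.n_donors, n_genes=config.n_genes,
        n_signal_genes=config.n_signal_genes, target_map=main.statistic,
        signal_corr=config.signal_corr, seed=rng_seed + 7,
    )
    assoc = gene_map_association(main.statistic, panel)
    _, rej = fdr_bh(assoc["p"].to_numpy(), config.fdr_q)
    parametric = [g for g, r in zip(assoc.index, rej) if r]
    spin_ok = spin_significance_filter(
        assoc, main.statistic, atlas, panel, genes=parametric,
        n_rotations=config.n_spins, seed=rng_seed + 8, q=config.fdr_q)
    consistent = donor_consistency_filter(panel, genes=spin_ok, q=config.fdr_q)
    adf = assoc.reset_index().rename(columns={"index": "gene"})
    adf["parametric_fdr"] = [g in set(parametric) for g in adf["gene"]]
    adf["spin_fdr"] = [g in set(spin_ok) for g in adf["gene"]]
    adf["donor_consistent"] = [g in set(consistent) for g in adf["gene"]]
    write_tsv(adf, out / "gene_associations.tsv")

    rng_sets = np.random.default_rng(rng_seed + 9)
    gene_sets = {"planted_signal": set(signal_genes)}
    for i in range(5):
        gene_sets[f"random_set_{i}"] = set(
            rng_sets.choice(panel.gene_ids, size=20, replace=False))
    enr = fisher_enrichment(consistent, gene_sets, set(panel.gene_ids))
    write_tsv(enr, out / "enrichment_gene_sets.tsv")

    cell_types = ["cortex_neuron", "striatum_d1", "cerebellum_stellate",
                  "astrocyte", "oligodendrocyte", "microglia"]
    spec = generate_cell_type_specificity(
        n_genes=config.n_genes, cell_types=cell_types,
        enriched_type="cortex_neuron", signal_genes=signal_genes,
        gene_ids=panel.gene_ids, seed=rng_seed + 10)
    csea = csea_enrichment(consistent, spec, set(panel.gene_ids))
    write_tsv(csea, out / "enrichment_cell_types.tsv")


# ------------------------------------------------------------- sensitivity

def sensitivity_suite(config: PipelineConfig,
                      densities=(0.05, 0.10, 0.15, 0.20),
                      scales=()) -> dict:
    """Re-run embedding + association across densities and atlas scales.

    Returns per-setting template E1 maps and main statistic maps plus
    their pairwise spatial correlation matrices; everything is also
    written under ``<out_dir>/sensitivity``.
    """
    out = Path(config.out_dir) / "sensitivity"
    out.mkdir(parents=True, exist_ok=True)
    e1_maps: dict[str, np.ndarray] = {}
    stat_maps: dict[str, np.ndarray] = {}

    def one_setting(tag: str, cfg: PipelineConfig):
        atlas = generate_atlas(cfg.n_parcels, cfg.n_modules, seed=cfg.seed)
        cohort = generate_cohort(
            atlas, n_subjects=cfg.n_subjects, n_timepoints=cfg.n_timepoints,
            effect_size=cfg.effect_size, affected_modules=cfg.affected_modules,
            noise_sd=cfg.noise_sd, seed=cfg.seed)
        connectomes = [
            correlation_connectome(RegionTimeSeries(cohort.time_series[i], sid))
            for i, sid in enumerate(cohort.covariates["subject_id"])
        ]
        group = group_average_connectome(connectomes)
        aligned = build_aligned_set(
            group, connectomes, density=cfg.density, alpha=cfg.alpha, t=cfg.t,
            n_components=cfg.n_components_report,
            n_components_internal=cfg.n_components_internal)
        Y = np.stack([aligned.subjects[s]
                      for s in cohort.covariates["subject_id"]])
        X = design_matrix(cohort.covariates, columns=cfg.covariate_columns)
        sm = hotelling_glm(Y, X, term=cfg.term, q=cfg.fdr_q)
        e1_maps[tag] = aligned.template.eigenvectors[:, 0]
        stat_maps[tag] = sm.statistic
        write_tsv(sm.to_frame(), out / f"statmap_{tag}.tsv")

    for d in densities:
        one_setting(f"density_{d:g}", dataclasses.replace(config, density=d))
    for n in scales:
        one_setting(f"scale_{n}", dataclasses.replace(config, n_parcels=n))

    def corr_table(maps: dict[str, np.ndarray]) -> pd.DataFrame:
        tags = list(maps)
        rows = []
        for a in tags:
            for b in tags:
                if maps[a].shape == maps[b].shape:
                    r = float(np.corrcoef(maps[a], maps[b])[0, 1])
                else:
                    r = np.nan  # different atlas scales are not comparable
                rows.append(dict(setting_a=a, setting_b=b, r=r))
        return pd.DataFrame(rows)

    e1_corr = corr_table(e1_maps)
    stat_corr = corr_table(stat_maps)
    write_tsv(e1_corr, out / "e1_map_correlations.tsv")
    write_tsv(stat_corr, out / "statmap_correlations.tsv")
    return {"e1_maps": e1_maps, "stat_maps": stat_maps,
            "e1_correlations": e1_corr, "stat_correlations": stat_corr}
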