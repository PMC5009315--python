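"""End-to-end orchestration: simulate, signature, meta, cluster, ddCt, synergy.

Each ``run_*`` stage reads/writes plain-text files (TSV / JSON / Newick)
under a configured output directory, so any stage can be re-run or fed
with user-supplied files in the same dialects. Every stage logs the
package version, a hash of the configuration and the seed; identical
config + seed reproduce identical output bytes (timestamps are confined
to the log).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .clustering import export_newick, export_ordered_matrix, hierarchical_cluster, separation_score
from .diffexp import differential_genes, write_de_table
from .expr_io import (
    apply_annotation_mask,
    read_annotation_mask,
    read_expression_matrix,
    read_gene_list,
    write_annotation_mask,
    write_expression_matrix,
    write_gene_list,
)
from .meta_signature import (
    ALL_CONCORDANT,
    build_meta_profile,
    decompose_signature,
    derive_reference_signature,
    maintenance_analysis,
    write_decomposition_report,
    write_summary_json,
)
from .qpcr import delta_delta_ct, expression_group_test, read_ct_table
from .synergy import (
    combination_index,
    isobologram,
    median_effect_fit,
    read_dose_response,
    write_ci_table,
)
from . import synthetic_data as synth
from .synthetic_data import (
    CtConfig,
    DoseResponseConfig,
    MultiStudyConfig,
    generate_ct_table,
    generate_dose_response,
    generate_multistudy,
)

logger = logging.getLogger("intestsig")

__all__ = [
    "PipelineConfig",
    "setup_logging",
    "run_simulate",
    "run_signature",
    "run_meta",
    "run_cluster",
    "run_ddct",
    "run_synergy",
]


@dataclass
class PipelineConfig:
    """All knobs of the pipeline in one (YAML-loadable) place."""

    outdir: str = "intestsig_out"
    seed: int = 0
    fc_threshold: float = 1.5
    p_threshold: float = 0.001
    meta_rule: str = ALL_CONCORDANT
    require_direction_match: bool = True
    collapse_rule: str = "max_mean"

    # input paths; run_simulate populates the defaults it writes
    tissue_matrix: str = "studies/tissue.tsv"
    tissue_groups: str = "studies/tissue.groups.tsv"
    mask_path: str = "mask.tsv"
    signature_path: str = "signature.tsv"
    early_matrices: list[str] = field(default_factory=list)
    early_group_maps: list[str] = field(default_factory=list)
    late_matrices: list[str] = field(default_factory=list)
    late_group_maps: list[str] = field(default_factory=list)

    tissue_reference: str = synth.TISSUE_REFERENCE
    tissue_test_groups: list[str] = field(default_factory=lambda: list(synth.TISSUE_GROUPS))
    disease_reference: str = synth.DISEASE_REFERENCE
    early_group: str = synth.EARLY_GROUP
    late_group: str = synth.LATE_GROUP

    # clustering stage
    cluster_matrix: str = ""
    cluster_groups: str = ""
    cluster_gene_list: str = ""
    cluster_metric: str = "correlation"
    cluster_linkage: str = "average"
    cluster_center_rows: bool = False
    cluster_k: int = 2

    # qPCR stage
    ct_path: str = "ct.tsv"
    ct_target: str = "NR5A2"
    ct_reference: str = "GAPDH"
    ct_control: str = "SQ"
    ct_test_group: str = "BO"

    # synergy stage
    dose_response_path: str = "dose_response.tsv"
    combinations_path: str = "combinations.tsv"

    # overrides forwarded to the synthetic generators
    simulate: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")
        if not (0 < self.p_threshold <= 1):
            raise ValueError("p_threshold must lie in (0, 1]")

    # -- plumbing --------------------------------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"{path}: unknown config keys: {unknown}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        # the hash covers the scientific configuration; the output location
        # is excluded so identical runs in different directories agree
        payload = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def resolve(self, relpath: str) -> Path:
        p = Path(relpath)
        return p if p.is_absolute() else Path(self.outdir) / p

    def require(self, relpath: str, what: str) -> Path:
        p = self.resolve(relpath)
        if not p.exists():
            raise ValueError(f"{what} not found: {p}")
        return p


def setup_logging(config: PipelineConfig, logfile: str | None = "intestsig.log") -> None:
    """Plain-text log with ISO-8601 timestamps under the output directory."""
    if logger.handlers:
        return
    logger.setLevel(logging.INFO)
    fmt = logging.Formatter(
        "%(asctime)s %(levelname)s %(message)s", datefmt="%Y-%m-%dT%H:%M:%S%z"
    )
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        Path(config.outdir).mkdir(parents=True, exist_ok=True)
        handlers.append(logging.FileHandler(Path(config.outdir) / logfile))
    for h in handlers:
        h.setFormatter(fmt)
        logger.addHandler(h)


def _stage_banner(stage: str, config: PipelineConfig) -> None:
    logger.info(
        "stage=%s version=%s config_hash=%s seed=%d",
        stage,
        __version__,
        config.config_hash(),
        config.seed,
    )


def _base_summary(config: PipelineConfig) -> dict:
    return {"version": __version__, "config_hash": config.config_hash(), "seed": config.seed}


# -- stages --------------------------------------------------------------------


def run_simulate(config: PipelineConfig) -> dict:
    """Generate every pipeline input (expression studies, Ct table,
    dose-response tables) under the output directory, with truth files."""
    _stage_banner("simulate", config)
    out = Path(config.outdir)
    (out / "studies").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(parents=True, exist_ok=True)

    sim = dict(config.simulate)
    ms_conf = MultiStudyConfig(**sim.get("multistudy", {}))
    result = generate_multistudy(ms_conf, seed=config.seed)

    def dump_study(study, stem: str) -> tuple[str, str]:
        m = f"studies/{stem}.tsv"
        g = f"studies/{stem}.groups.tsv"
        write_expression_matrix(study, out / m, out / g)
        return m, g

    dump_study(result.tissue_study, "tissue")
    config.early_matrices, config.early_group_maps = [], []
    for study in result.early_studies:
        m, g = dump_study(study, study.study_id)
        config.early_matrices.append(m)
        config.early_group_maps.append(g)
    config.late_matrices, config.late_group_maps = [], []
    for study in result.late_studies:
        m, g = dump_study(study, study.study_id)
        config.late_matrices.append(m)
        config.late_group_maps.append(g)
    write_annotation_mask(result.mask, out / config.mask_path)

    truth = result.truth
    write_gene_list(truth.signature, out / "truth" / "signature.tsv")
    write_gene_list(truth.early_profile, out / "truth" / "early_profile.tsv")
    write_gene_list(truth.late_profile, out / "truth" / "late_profile.tsv")
    truth_summary = {
        **_base_summary(config),
        "n_signature": len(truth.signature),
        "n_early_profile": len(truth.early_profile),
        "n_early_reference_like": len(truth.early_reference_like),
        "n_late_profile": len(truth.late_profile),
        "maintenance_fraction_planted": truth.maintenance_fraction,
        "maintenance_fraction_realized": truth.realized_maintenance_fraction,
    }
    write_summary_json(truth_summary, out / "truth" / "truth.json")

    ct_table, _ = generate_ct_table(CtConfig(**sim.get("ct", {})), seed=config.seed)
    ct_table.data.to_csv(out / config.ct_path, sep="\t", index=False, lineterminator="\n")

    dr = generate_dose_response(DoseResponseConfig(**sim.get("dose_response", {})), seed=config.seed)
    dr.single_agent.to_csv(
        out / config.dose_response_path, sep="\t", index=False, lineterminator="\n"
    )
    dr.combinations.to_csv(
        out / config.combinations_path, sep="\t", index=False, lineterminator="\n"
    )
    logger.info("simulate: wrote studies, truth, ct and dose-response tables to %s", out)
    return truth_summary


def _load_gene_level(config: PipelineConfig, matrix: str, groups: str, study_id: str):
    study = read_expression_matrix(
        config.require(matrix, "expression matrix"),
        config.require(groups, "group map"),
        study_id=study_id,
    )
    mask = read_annotation_mask(config.require(config.mask_path, "annotation mask"))
    return apply_annotation_mask(study, mask, collapse_rule=config.collapse_rule)


def run_signature(config: PipelineConfig) -> dict:
    """Derive the reference signature from the normal-tissue study."""
    _stage_banner("signature", config)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    study = _load_gene_level(config, config.tissue_matrix, config.tissue_groups, "tissue")
    per_comparison = []
    for group in config.tissue_test_groups:
        de = differential_genes(
            study,
            test_group=group,
            ref_group=config.tissue_reference,
            fc_threshold=config.fc_threshold,
            p_threshold=config.p_threshold,
        )
        write_de_table(de, out / f"de_{group}_vs_{config.tissue_reference}.tsv")
        per_comparison.append(de)
    if len(per_comparison) != 2:
        raise ValueError("the reference signature needs exactly two tissue comparisons")
    signature = derive_reference_signature(*per_comparison)
    write_gene_list(signature, out / config.signature_path)
    summary = {
        **_base_summary(config),
        "n_per_comparison": [len(s) for s in per_comparison],
        "n_signature": len(signature),
    }
    write_summary_json(summary, out / "signature_summary.json")
    logger.info("signature: %d concordant genes", len(signature))
    return summary


def run_meta(config: PipelineConfig) -> dict:
    """Meta-profiles, decomposition, maintenance and summary reports."""
    _stage_banner("meta", config)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    signature = read_gene_list(config.require(config.signature_path, "reference signature"))

    def profile(matrices, group_maps, test_group, label):
        if not matrices:
            raise ValueError(f"no {label} study inputs configured")
        sets, ids = [], []
        for i, (m, g) in enumerate(zip(matrices, group_maps), start=1):
            study_id = Path(m).stem
            study = _load_gene_level(config, m, g, study_id)
            de = differential_genes(
                study,
                test_group=test_group,
                ref_group=config.disease_reference,
                fc_threshold=config.fc_threshold,
                p_threshold=config.p_threshold,
            )
            write_de_table(de, out / f"de_{study_id}.tsv")
            sets.append(de)
            ids.append(study_id)
        meta = build_meta_profile(sets, rule=config.meta_rule, study_ids=ids)
        write_gene_list(meta.entries, out / f"meta_{label}.tsv")
        return meta

    early = profile(config.early_matrices, config.early_group_maps, config.early_group, "early")
    late = profile(config.late_matrices, config.late_group_maps, config.late_group, "late")

    decomp = decompose_signature(
        early, signature, require_direction_match=config.require_direction_match
    )
    maint = maintenance_analysis(
        decomp, late, require_direction_match=config.require_direction_match
    )
    write_decomposition_report(decomp, out / "decomposition.tsv", maintenance=maint)
    summary = {
        **_base_summary(config),
        "n_signature": len(signature),
        "n_early_profile": len(early),
        "n_late_profile": len(late),
        "decomposition": decomp.summary(),
        "maintenance": maint.summary(),
    }
    write_summary_json(summary, out / "meta_summary.json")
    logger.info(
        "meta: early=%d late=%d reference_like=%.1f%% maintained=%s",
        len(early),
        len(late),
        decomp.fraction_reference_like_1dp,
        maint.fractions_1dp,
    )
    return summary


def run_cluster(config: PipelineConfig) -> dict:
    """Cluster samples on a gene list; export Newick, ordered matrix, purity."""
    _stage_banner("cluster", config)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    matrix = config.cluster_matrix or config.early_matrices[0]
    groups = config.cluster_groups or config.early_group_maps[0]
    study = _load_gene_level(config, matrix, groups, Path(matrix).stem)
    gene_list = config.cluster_gene_list or config.signature_path
    subset = read_gene_list(config.require(gene_list, "gene list"))
    dend = hierarchical_cluster(
        study,
        gene_subset=subset,
        axis="samples",
        metric=config.cluster_metric,
        linkage=config.cluster_linkage,
        center_rows=config.cluster_center_rows,
    )
    export_newick(dend, out / "samples.nwk")
    export_ordered_matrix(study, out / "ordered_matrix.tsv", dend_cols=dend)
    score = separation_score(dend, study.groups, k=config.cluster_k)
    summary = {
        **_base_summary(config),
        "n_samples": dend.n_leaves,
        "k": score.k,
        "purity": score.purity,
    }
    write_summary_json(summary, out / "cluster_summary.json")
    logger.info("cluster: %d samples, purity(k=%d)=%.3f", dend.n_leaves, score.k, score.purity)
    return summary


def run_ddct(config: PipelineConfig) -> dict:
    """ddCt fold changes plus the group Mann-Whitney test."""
    _stage_banner("ddct", config)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    table = read_ct_table(config.require(config.ct_path, "Ct table"))
    result = delta_delta_ct(
        table, config.ct_target, config.ct_reference, control_group=config.ct_control
    )
    result.write_tsv(out / "ddct.tsv")
    p = expression_group_test(
        table, config.ct_target, config.ct_reference, config.ct_control, config.ct_test_group
    )
    summary = {
        **_base_summary(config),
        "target": config.ct_target,
        "reference": config.ct_reference,
        "group_fold_change": result.group_fold_change,
        "mann_whitney_p": p,
    }
    write_summary_json(summary, out / "ddct_summary.json")
    logger.info(
        "ddct: group FC %s, MW p=%.3g",
        {g: round(v, 3) for g, v in result.group_fold_change.items()},
        p,
    )
    return summary


def run_synergy(config: PipelineConfig) -> dict:
    """Median-effect fits, per-combination CI and isobologram coordinates."""
    _stage_banner("synergy", config)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    per_agent = read_dose_response(config.require(config.dose_response_path, "dose-response table"))
    if len(per_agent) != 2:
        raise ValueError(f"expected exactly 2 agents, got {sorted(per_agent)}")
    (name_a, pts_a), (name_b, pts_b) = per_agent.items()
    fit_a = median_effect_fit(pts_a)
    fit_b = median_effect_fit(pts_b)

    combos = pd.read_csv(config.require(config.combinations_path, "combination table"), sep="\t")
    missing = [c for c in ("d1", "d2", "fa") if c not in combos.columns]
    if missing:
        raise ValueError(f"combination table missing columns: {missing}")
    entries = [
        combination_index(fit_a, fit_b, float(r.d1), float(r.d2), float(r.fa))
        for r in combos.itertuples()
    ]
    write_ci_table(entries, out / "ci.tsv")
    iso = isobologram(fit_a, fit_b, fa_levels=(0.5, 0.75, 0.9), combination_points=entries)
    iso.to_csv(out / "isobologram.tsv", sep="\t", index=False, lineterminator="\n")
    summary = {
        **_base_summary(config),
        "agents": [name_a, name_b],
        "fit_a": {"m": fit_a.m, "Dm": fit_a.Dm, "r": fit_a.r},
        "fit_b": {"m": fit_b.m, "Dm": fit_b.Dm, "r": fit_b.r},
        "mean_ci": float(sum(e.CI for e in entries) / len(entries)) if entries else None,
        "n_combinations": len(entries),
    }
    write_summary_json(summary, out / "synergy_summary.json")
    logger.info("synergy: mean CI %.3f over %d points", summary["mean_ci"] or 0.0, len(entries))
    return summary
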