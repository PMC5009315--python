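"""Seeded generators for every input the analysis pipeline consumes.

Three generators, each a pure function of (config, seed) returning the
generated tables together with the planted ground truth:

* generate_multistudy — a normal-tissue study (oesophagus, duodenum,
  colon) plus several small early-stage ("BO") and late-stage ("OAC")
  disease studies on partially overlapping probe platforms, tied
  together by an annotation mask. Intensities are log-normal: value =
  2^(baseline + group effect + N(0, sigma)) with per-gene baselines
  drawn once and shared across studies. A directional signature is
  planted in the intestinal tissues; the early-stage profile overlaps it
  partially; each of its reference-like genes is retained at the late
  stage independently with probability maintenance_fraction (gene-wise
  Bernoulli maintenance).
* generate_ct_table — qPCR cycle thresholds with technical replicates,
  per-group dCt shifts and a housekeeping reference gene.
* generate_dose_response — median-effect single-agent curves plus
  combination points constructed under Loewe additivity with the
  required doses scaled by an interaction factor s (s = 1 additive,
  s < 1 synergy): the planted combination index equals s.

The defaults mirror the scale of the multi-study meta-analysis the
package targets: a 2861-gene reference signature, an early-stage profile
of 989 genes of which 769 are reference-like, 85% maintenance, three
studies per disease stage. The simulated data has clean group structure —
no batch effects, probe-level hybridization physics or array artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .expr_io import AnnotationMask, ExpressionStudy
from .meta_signature import DOWN, UP, DirectionalGeneSet
from .qpcr import CtTable
from .synergy import DoseResponsePoint, MedianEffectFit, dose_for_effect

__all__ = [
    "MultiStudyConfig",
    "MultiStudyTruth",
    "MultiStudyResult",
    "generate_multistudy",
    "CtConfig",
    "CtTruth",
    "generate_ct_table",
    "DoseResponseConfig",
    "DoseResponseTruth",
    "DoseResponseResult",
    "generate_dose_response",
    "full_scale_config",
]

# group labels used by the generated studies
TISSUE_REFERENCE = "OES"
TISSUE_GROUPS = ("DUO", "COL")
DISEASE_REFERENCE = "SQ"
EARLY_GROUP = "BO"
LATE_GROUP = "OAC"


# -- multi-study expression ----------------------------------------------------


@dataclass(frozen=True)
class MultiStudyConfig:
    """Shape and strength of the simulated multi-study compendium.

    Sizes default to the scale of the target meta-analysis; noise_sigma
    and effect_log2 are on the log2-intensity scale. platform_overlap is
    the probability that a *background* gene is present on a disease
    study's platform (planted genes are always present wherever their
    effect is planted, so the meta-profiles are well defined).
    """

    n_genes: int = 6000
    signature_size: int = 2861
    early_reference_like_size: int = 769
    early_non_reference_size: int = 220
    late_novel_size: int = 381
    maintenance_fraction: float = 0.85
    non_reference_maintenance: float = 45 / 220
    n_per_group_tissue: int = 9
    n_early_studies: int = 3
    n_late_studies: int = 3
    n_per_group_disease: int = 9
    effect_log2: float = 2.0
    noise_sigma: float = 0.25
    platform_overlap: float = 0.9
    multi_probe_fraction: float = 0.2
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 1.0

    def validate(self) -> None:
        if not (0.0 <= self.maintenance_fraction <= 1.0):
            raise ValueError("maintenance_fraction must lie in [0, 1]")
        if not (0.0 <= self.non_reference_maintenance <= 1.0):
            raise ValueError("non_reference_maintenance must lie in [0, 1]")
        if self.signature_size > self.n_genes:
            raise ValueError("signature larger than the gene universe")
        needed = (
            self.signature_size + self.early_non_reference_size + self.late_novel_size
        )
        if needed > self.n_genes:
            raise ValueError(
                f"gene universe ({self.n_genes}) too small for the planted sets ({needed})"
            )
        if self.early_reference_like_size > self.signature_size:
            raise ValueError("early_reference_like_size exceeds the signature size")
        if self.n_per_group_tissue < 2 or self.n_per_group_disease < 2:
            raise ValueError("each group needs >= 2 samples")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")


def full_scale_config(**overrides) -> MultiStudyConfig:
    """The default, full-scale study design (see MultiStudyConfig)."""
    return MultiStudyConfig(**overrides)


@dataclass
class MultiStudyTruth:
    """Everything planted: the answer key the pipeline should recover."""

    signature: DirectionalGeneSet
    early_profile: DirectionalGeneSet
    early_reference_like: set[str]
    early_non_reference: set[str]
    late_profile: DirectionalGeneSet
    maintained_reference_like: set[str]
    maintained_non_reference: set[str]
    maintenance_fraction: float
    platforms: dict[str, set[str]] = field(default_factory=dict)

    @property
    def realized_maintenance_fraction(self) -> float:
        """Share of reference-like early genes actually retained (Bernoulli draw)."""
        return len(self.maintained_reference_like) / len(self.early_reference_like)


@dataclass
class MultiStudyResult:
    tissue_study: ExpressionStudy
    early_studies: list[ExpressionStudy]
    late_studies: list[ExpressionStudy]
    mask: AnnotationMask
    truth: MultiStudyTruth


def _gene_names(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _study_matrix(
    rng: np.random.Generator,
    genes: Sequence[str],
    baselines: dict[str, float],
    group_sizes: dict[str, int],
    effects: dict[str, dict[str, float]],
    sigma: float,
    study_id: str,
    sample_prefix: str,
    multi_probe: set[str],
) -> ExpressionStudy:
    """Probe-level log-normal intensities for one study.

    effects maps group -> gene -> signed log2 shift. Genes in multi_probe
    get a second, dimmer probe (baseline - 0.8 log2) carrying the same
    effect with independent noise.
    """
    sample_ids: list[str] = []
    group_of: dict[str, str] = {}
    for group, size in group_sizes.items():
        for i in range(1, size + 1):
            sid = f"{sample_prefix}_{group}_{i}"
            sample_ids.append(sid)
            group_of[sid] = group

    probe_rows: list[str] = []
    log2 = []
    for gene in genes:
        probes = [f"{gene}_at"] + ([f"{gene}_x_at"] if gene in multi_probe else [])
        for k, probe in enumerate(probes):
            base = baselines[gene] - 0.8 * k
            row = np.empty(len(sample_ids))
            col = 0
            for group, size in group_sizes.items():
                shift = effects.get(group, {}).get(gene, 0.0)
                noise = rng.normal(0.0, sigma, size=size) if sigma > 0 else np.zeros(size)
                row[col : col + size] = base + shift + noise
                col += size
            probe_rows.append(probe)
            log2.append(row)
    values = np.power(2.0, np.array(log2))
    return ExpressionStudy(
        study_id=study_id,
        feature_ids=probe_rows,
        sample_ids=sample_ids,
        values=values,
        groups=group_of,
        platform_id=f"platform_{study_id}",
        is_gene_level=False,
    )


def generate_multistudy(
    config: MultiStudyConfig | None = None, seed: int = 0
) -> MultiStudyResult:
    """Simulate the full multi-study compendium with its answer key."""
    config = config or MultiStudyConfig()
    config.validate()
    rng = np.random.default_rng(seed)

    genes = _gene_names(config.n_genes)
    baselines = {
        g: float(b)
        for g, b in zip(
            genes,
            rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=len(genes)),
        )
    }

    order = list(rng.permutation(len(genes)))
    sig_idx = order[: config.signature_size]
    rest = order[config.signature_size :]
    nonref_idx = rest[: config.early_non_reference_size]
    novel_idx = rest[
        config.early_non_reference_size : config.early_non_reference_size
        + config.late_novel_size
    ]

    def directional(idx: Sequence[int]) -> DirectionalGeneSet:
        dirs = rng.random(len(idx)) < 0.5
        return DirectionalGeneSet(
            entries={genes[i]: (UP if u else DOWN) for i, u in zip(idx, dirs)}
        )

    signature = directional(sig_idx)
    # early-stage profile: a sample of the signature (directions inherited)
    # plus a disjoint non-reference component
    ref_like_idx = list(rng.choice(sig_idx, size=config.early_reference_like_size, replace=False))
    early_ref_like = {genes[i]: signature.entries[genes[i]] for i in ref_like_idx}
    early_non_ref = directional(nonref_idx).entries
    early_profile = DirectionalGeneSet(entries={**early_ref_like, **early_non_ref})

    # gene-wise Bernoulli maintenance at the late stage
    keep_ref = rng.random(len(ref_like_idx)) < config.maintenance_fraction
    maintained_ref = {
        genes[i] for i, k in zip(ref_like_idx, keep_ref) if k
    }
    keep_non = rng.random(len(nonref_idx)) < config.non_reference_maintenance
    maintained_non = {genes[i] for i, k in zip(nonref_idx, keep_non) if k}
    late_novel = directional(novel_idx).entries
    late_profile = DirectionalGeneSet(
        entries={
            **{g: early_profile.entries[g] for g in sorted(maintained_ref | maintained_non)},
            **late_novel,
        }
    )

    sigma = config.noise_sigma
    effect = config.effect_log2

    def signed(dset: dict[str, str]) -> dict[str, float]:
        return {g: (effect if d == UP else -effect) for g, d in dset.items()}

    # normal-tissue study: the signature is planted in both intestinal tissues
    tissue_study = _study_matrix(
        rng,
        genes,
        baselines,
        {TISSUE_REFERENCE: config.n_per_group_tissue}
        | {g: config.n_per_group_tissue for g in TISSUE_GROUPS},
        {g: signed(signature.entries) for g in TISSUE_GROUPS},
        sigma,
        study_id="tissue",
        sample_prefix="T",
        multi_probe=set(),
    )

    multi_probe = {
        g for g, r in zip(genes, rng.random(len(genes))) if r < config.multi_probe_fraction
    }
    platforms: dict[str, set[str]] = {"tissue": set(genes)}

    def disease_platform(planted: set[str], study_key: str) -> list[str]:
        cover = rng.random(len(genes)) < config.platform_overlap
        keep = [g for g, c in zip(genes, cover) if c or g in planted]
        platforms[study_key] = set(keep)
        return keep

    early_studies = []
    for k in range(1, config.n_early_studies + 1):
        study_id = f"early{k}"
        keep = disease_platform(early_profile.genes(), study_id)
        early_studies.append(
            _study_matrix(
                rng,
                keep,
                baselines,
                {
                    DISEASE_REFERENCE: config.n_per_group_disease,
                    EARLY_GROUP: config.n_per_group_disease,
                },
                {EARLY_GROUP: signed(early_profile.entries)},
                sigma,
                study_id=study_id,
                sample_prefix=f"E{k}",
                multi_probe=multi_probe,
            )
        )

    late_studies = []
    for k in range(1, config.n_late_studies + 1):
        study_id = f"late{k}"
        keep = disease_platform(late_profile.genes(), study_id)
        late_studies.append(
            _study_matrix(
                rng,
                keep,
                baselines,
                {
                    DISEASE_REFERENCE: config.n_per_group_disease,
                    LATE_GROUP: config.n_per_group_disease,
                },
                {LATE_GROUP: signed(late_profile.entries)},
                sigma,
                study_id=study_id,
                sample_prefix=f"L{k}",
                multi_probe=multi_probe,
            )
        )

    probe_to_gene = {f"{g}_at": g for g in genes}
    probe_to_gene.update({f"{g}_x_at": g for g in sorted(multi_probe)})
    mask = AnnotationMask(platform_id="common_mask", probe_to_gene=probe_to_gene)

    truth = MultiStudyTruth(
        signature=signature,
        early_profile=early_profile,
        early_reference_like=set(early_ref_like),
        early_non_reference=set(early_non_ref),
        late_profile=late_profile,
        maintained_reference_like=maintained_ref,
        maintained_non_reference=maintained_non,
        maintenance_fraction=config.maintenance_fraction,
        platforms=platforms,
    )
    return MultiStudyResult(
        tissue_study=tissue_study,
        early_studies=early_studies,
        late_studies=late_studies,
        mask=mask,
        truth=truth,
    )


# -- qPCR Ct tables ------------------------------------------------------------


@dataclass(frozen=True)
class CtConfig:
    """Design of a simulated qPCR experiment.

    shifts maps gene -> group -> dCt shift in cycles (negative = higher
    expression); the reference gene has no shift anywhere. replicate_sigma
    is the technical-replicate noise; sample_sigma is a per-sample loading
    offset applied to every gene of the sample (it cancels in dCt).
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"SQ": 17, "BO": 17}
    )
    control_group: str = "SQ"
    reference_gene: str = "GAPDH"
    reference_base_ct: float = 18.0
    target_base_ct: dict[str, float] = field(default_factory=lambda: {"NR5A2": 26.0})
    shifts: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"NR5A2": {"BO": -3.0}}
    )
    n_replicates: int = 3
    replicate_sigma: float = 0.3
    sample_sigma: float = 0.0
    non_detect_ceiling: float = 40.0

    def validate(self) -> None:
        if self.control_group not in self.group_sizes:
            raise ValueError(f"control group {self.control_group!r} not in group_sizes")
        for g, n in self.group_sizes.items():
            if n < 2:
                raise ValueError(f"group {g!r} needs n >= 2, got {n}")
        for gene in self.shifts:
            if gene not in self.target_base_ct:
                raise ValueError(f"shifted gene {gene!r} has no base Ct")
        if self.n_replicates < 1:
            raise ValueError("need >= 1 technical replicate")


@dataclass
class CtTruth:
    shifts: dict[str, dict[str, float]]
    expected_fold_change: dict[str, dict[str, float]]  # gene -> group -> 2^-shift


def generate_ct_table(config: CtConfig | None = None, seed: int = 0) -> tuple[CtTable, CtTruth]:
    """Simulate Ct records: base + group shift + technical noise."""
    config = config or CtConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    rows = []
    for group, size in config.group_sizes.items():
        for i in range(1, size + 1):
            sample = f"{group}_{i}"
            offset = rng.normal(0.0, config.sample_sigma) if config.sample_sigma > 0 else 0.0
            gene_plan = [(config.reference_gene, config.reference_base_ct, 0.0)] + [
                (g, base, config.shifts.get(g, {}).get(group, 0.0))
                for g, base in config.target_base_ct.items()
            ]
            for gene, base, shift in gene_plan:
                for rep in range(1, config.n_replicates + 1):
                    noise = (
                        rng.normal(0.0, config.replicate_sigma)
                        if config.replicate_sigma > 0
                        else 0.0
                    )
                    rows.append((sample, group, gene, rep, base + shift + offset + noise))
    table = CtTable(
        data=pd.DataFrame(rows, columns=["sample_id", "group", "gene", "replicate", "ct"]),
        non_detect_ceiling=config.non_detect_ceiling,
    )
    expected = {
        gene: {group: float(2.0 ** (-shift)) for group, shift in per_group.items()}
        for gene, per_group in config.shifts.items()
    }
    return table, CtTruth(shifts=dict(config.shifts), expected_fold_change=expected)


# -- dose-response / synergy ---------------------------------------------------


@dataclass(frozen=True)
class DoseResponseConfig:
    """Two median-effect agents plus combination points under scaled Loewe.

    interaction s rescales the dose requirement of the combination: a
    combination point (d1, d2) is assigned the effect fa solving
    d1/Dx1(fa) + d2/Dx2(fa) = s, so its true combination index is s
    (s = 1 plain Loewe additivity, s < 1 synergy, s > 1 antagonism).
    sigma is Gaussian noise on log10(fa/fu). Doses are in the agents'
    native concentration units (defaults sit in a nM siRNA-like range).
    """

    m_a: float = 1.3
    dm_a: float = 20.0
    m_b: float = 1.7
    dm_b: float = 30.0
    doses_a: tuple[float, ...] = (1.0, 2.5, 6.3, 16.0, 40.0, 100.0)
    doses_b: tuple[float, ...] = (1.0, 2.5, 6.3, 16.0, 40.0, 100.0)
    combo_pairs: tuple[tuple[float, float], ...] | None = None
    sigma: float = 0.0
    interaction: float = 1.0

    def validate(self) -> None:
        if self.m_a <= 0 or self.m_b <= 0 or self.dm_a <= 0 or self.dm_b <= 0:
            raise ValueError("median-effect parameters m and Dm must be positive")
        if self.interaction <= 0:
            raise ValueError("interaction factor must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        for d in list(self.doses_a) + list(self.doses_b):
            if d <= 0:
                raise ValueError("doses must be positive")


@dataclass
class DoseResponseTruth:
    fit_a: MedianEffectFit
    fit_b: MedianEffectFit
    interaction: float


@dataclass
class DoseResponseResult:
    single_agent: pd.DataFrame  # agent, dose, fa
    combinations: pd.DataFrame  # d1, d2, fa
    truth: DoseResponseTruth


def _loewe_effect(
    fit_a: MedianEffectFit, fit_b: MedianEffectFit, d1: float, d2: float, s: float
) -> float:
    """Effect at which the combination satisfies d1/Dx1 + d2/Dx2 = s."""

    def excess(fa: float) -> float:
        return d1 / dose_for_effect(fit_a, fa) + d2 / dose_for_effect(fit_b, fa) - s

    lo, hi = 1e-9, 1.0 - 1e-9
    return float(brentq(excess, lo, hi, xtol=1e-15, rtol=8.9e-16))


def generate_dose_response(
    config: DoseResponseConfig | None = None, seed: int = 0
) -> DoseResponseResult:
    """Simulate single-agent curves and Loewe-constructed combination points."""
    config = config or DoseResponseConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    fit_a = MedianEffectFit(m=config.m_a, Dm=config.dm_a, r=1.0)
    fit_b = MedianEffectFit(m=config.m_b, Dm=config.dm_b, r=1.0)

    def noisy_fa(logit10: float) -> float:
        if config.sigma > 0:
            logit10 = logit10 + rng.normal(0.0, config.sigma)
        fa = 10.0**logit10 / (1.0 + 10.0**logit10)
        return float(np.clip(fa, 1e-6, 1.0 - 1e-6))

    rows = []
    for agent, fit, doses in (("A", fit_a, config.doses_a), ("B", fit_b, config.doses_b)):
        for d in doses:
            logit10 = fit.m * (np.log10(d) - np.log10(fit.Dm))
            rows.append((agent, d, noisy_fa(logit10)))
    single = pd.DataFrame(rows, columns=["agent", "dose", "fa"])

    pairs = config.combo_pairs
    if pairs is None:
        pairs = tuple(zip(config.doses_a, config.doses_b))
    combo_rows = []
    for d1, d2 in pairs:
        fa = _loewe_effect(fit_a, fit_b, d1, d2, config.interaction)
        logit10 = float(np.log10(fa / (1.0 - fa)))
        combo_rows.append((d1, d2, noisy_fa(logit10)))
    combos = pd.DataFrame(combo_rows, columns=["d1", "d2", "fa"])
    return DoseResponseResult(
        single_agent=single,
        combinations=combos,
        truth=DoseResponseTruth(fit_a=fit_a, fit_b=fit_b, interaction=config.interaction),
    )


def single_agent_points(result: DoseResponseResult, agent: str) -> list[DoseResponsePoint]:
    block = result.single_agent[result.single_agent["agent"] == agent]
    if block.empty:
        raise ValueError(f"no single-agent points for agent {agent!r}")
    return [DoseResponsePoint(float(d), float(f)) for d, f in zip(block["dose"], block["fa"])]
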