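"""Cross-study signature inference for metaplasia-to-carcinoma progression.

The central objects are *directional gene sets*: per-gene up/down calls
produced by differential expression of a disease tissue against a normal
reference. The module builds

* a reference "intestine-enriched" signature as the direction-concordant
  intersection of two intestinal-vs-oesophageal comparisons,
* per-disease *meta-profiles* as the concordant intersection of several
  independent studies of the same condition,
* a decomposition of a disease meta-profile into its reference-like and
  non-reference components,
* maintenance statistics for those components in a later disease stage
  (2x2 Pearson chi-square), and
* specificity fractions of the signature in unrelated conditions.

"Similarly altered" is interpreted throughout as membership *with the same
direction of dysregulation*; a flag relaxes this to bare membership.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats

UP = "up"
DOWN = "down"
DIRECTIONS = (UP, DOWN)

__all__ = [
    "UP",
    "DOWN",
    "Provenance",
    "DirectionalGeneSet",
    "MetaProfile",
    "SignatureDecomposition",
    "MaintenanceResult",
    "SpecificityResult",
    "derive_reference_signature",
    "build_meta_profile",
    "decompose_signature",
    "maintenance_analysis",
    "specificity_fraction",
    "chi_square_2x2",
    "round_half_away",
]


def round_half_away(value: float, ndigits: int = 1) -> float:
    """Round with halves going away from zero (77.75 -> 77.8, -0.05 -> -0.1).

    Python's builtin ``round`` is banker's rounding; reported percentages
    use the conventional half-away rule instead.
    """
    value = float(value)
    if not np.isfinite(value):
        return value
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Provenance:
    """Where a direction call came from: one study's DE evidence.

    U (the rank statistic) is carried when the call came from a
    Mann-Whitney run and is NaN for aggregated or file-loaded sets.
    """

    study_id: str
    fold_change: float
    p: float
    U: float = float("nan")


@dataclass
class DirectionalGeneSet:
    """Per-gene direction calls with optional per-study provenance.

    entries maps gene symbol -> "up" | "down" (one direction per gene).
    provenance maps gene -> list of Provenance, at most one per study.
    """

    entries: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, list[Provenance]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, direction in self.entries.items():
            if direction not in DIRECTIONS:
                raise ValueError(
                    f"gene {gene!r} has invalid direction {direction!r}; "
                    f"expected one of {DIRECTIONS}"
                )
        for gene, records in self.provenance.items():
            ids = [r.study_id for r in records]
            if len(ids) != len(set(ids)):
                raise ValueError(f"duplicate provenance study ids for gene {gene!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, gene: str) -> bool:
        return gene in self.entries

    def __iter__(self):
        return iter(self.entries)

    def genes(self) -> set[str]:
        return set(self.entries)

    def direction_of(self, gene: str) -> str:
        return self.entries[gene]

    def up_genes(self) -> set[str]:
        return {g for g, d in self.entries.items() if d == UP}

    def down_genes(self) -> set[str]:
        return {g for g, d in self.entries.items() if d == DOWN}

    def concordant(self, gene: str, direction: str, match_direction: bool = True) -> bool:
        """Is *gene* present (and, if requested, with the given direction)?"""
        if gene not in self.entries:
            return False
        return (not match_direction) or self.entries[gene] == direction

    def subset(self, genes: Iterable[str]) -> "DirectionalGeneSet":
        keep = set(genes)
        return DirectionalGeneSet(
            entries={g: d for g, d in self.entries.items() if g in keep},
            provenance={g: list(v) for g, v in self.provenance.items() if g in keep},
        )


ALL_CONCORDANT = "all_concordant"
MAJORITY_CONCORDANT = "majority_concordant"


@dataclass
class MetaProfile:
    """Concordant cross-study intersection of per-study DE sets."""

    entries: DirectionalGeneSet
    member_studies: list[str]
    rule: str = ALL_CONCORDANT

    def __post_init__(self) -> None:
        if self.rule not in (ALL_CONCORDANT, MAJORITY_CONCORDANT):
            raise ValueError(f"unknown meta-profile rule {self.rule!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def genes(self) -> set[str]:
        return self.entries.genes()


@dataclass
class SignatureDecomposition:
    """Partition of a disease profile into reference-like vs non-reference parts."""

    reference_like: DirectionalGeneSet
    non_reference: DirectionalGeneSet
    n_disease: int
    n_reference: int

    def __post_init__(self) -> None:
        if len(self.reference_like) + len(self.non_reference) != self.n_disease:
            raise ValueError("reference_like and non_reference must partition the disease profile")

    @property
    def fraction_reference_like(self) -> float:
        """Percentage of the disease profile that is reference-like (exact)."""
        return 100.0 * len(self.reference_like) / self.n_disease

    @property
    def fraction_reference_like_1dp(self) -> float:
        """The reported percentage, one decimal, halves away from zero."""
        return round_half_away(self.fraction_reference_like, 1)

    def summary(self) -> dict:
        return {
            "n_disease": self.n_disease,
            "n_reference": self.n_reference,
            "n_reference_like": len(self.reference_like),
            "n_non_reference": len(self.non_reference),
            "fraction_reference_like_pct": self.fraction_reference_like_1dp,
        }


class SpecificityResult(NamedTuple):
    fraction: float
    chi2: float | None
    p: float | None


@dataclass
class MaintenanceResult:
    """2x2 stage-transition table: component (rows) x maintained/lost (cols).

    chi2/p are None when a zero row margin makes the statistic undefined.
    """

    table: np.ndarray  # rows: reference_like, non_reference; cols: maintained, lost
    maintained: dict[str, set[str]]  # component name -> maintained genes
    lost: dict[str, set[str]]
    chi2: float | None
    p: float | None

    ROW_NAMES = ("reference_like", "non_reference")

    @property
    def fractions(self) -> dict[str, float]:
        """Per-component maintained percentage (exact)."""
        out = {}
        for i, name in enumerate(self.ROW_NAMES):
            total = self.table[i].sum()
            out[name] = 100.0 * self.table[i, 0] / total if total else float("nan")
        return out

    @property
    def fractions_1dp(self) -> dict[str, float]:
        return {k: round_half_away(v, 1) for k, v in self.fractions.items()}

    def summary(self) -> dict:
        return {
            "table": self.table.tolist(),
            "maintained_pct": self.fractions_1dp,
            "chi2": self.chi2,
            "p": self.p,
        }


def derive_reference_signature(
    cmp_a: DirectionalGeneSet, cmp_b: DirectionalGeneSet
) -> DirectionalGeneSet:
    """Direction-concordant intersection of two tissue-vs-reference DE sets.

    A gene enters the reference signature iff it is called in both
    comparisons with the same direction; discordant genes are dropped.
    """
    entries: dict[str, str] = {}
    provenance: dict[str, list[Provenance]] = {}
    for gene in cmp_a.genes() & cmp_b.genes():
        if cmp_a.direction_of(gene) == cmp_b.direction_of(gene):
            entries[gene] = cmp_a.direction_of(gene)
            records = cmp_a.provenance.get(gene, []) + cmp_b.provenance.get(gene, [])
            if records:
                provenance[gene] = records
    return DirectionalGeneSet(entries=entries, provenance=provenance)


def build_meta_profile(
    per_study_sets: Sequence[DirectionalGeneSet],
    rule: str = ALL_CONCORDANT,
    study_ids: Sequence[str] | None = None,
) -> MetaProfile:
    """Concordant intersection of several studies' DE sets.

    all_concordant: a gene is kept iff every study calls it, all with one
    direction. majority_concordant: called with one common direction in
    more than half of the studies and never with the opposite direction.
    """
    if not per_study_sets:
        raise ValueError("at least one per-study gene set is required")
    if len(per_study_sets) < 2:
        raise ValueError("a meta-profile needs >= 2 study sets")
    if rule not in (ALL_CONCORDANT, MAJORITY_CONCORDANT):
        raise ValueError(f"unknown meta-profile rule {rule!r}")
    n = len(per_study_sets)
    if study_ids is None:
        study_ids = [f"study{i + 1}" for i in range(n)]

    all_genes: set[str] = set()
    for s in per_study_sets:
        all_genes |= s.genes()

    entries: dict[str, str] = {}
    provenance: dict[str, list[Provenance]] = {}
    for gene in sorted(all_genes):
        dirs = [s.entries.get(gene) for s in per_study_sets]
        n_up = sum(d == UP for d in dirs)
        n_down = sum(d == DOWN for d in dirs)
        direction: str | None = None
        if rule == ALL_CONCORDANT:
            if n_up == n:
                direction = UP
            elif n_down == n:
                direction = DOWN
        else:  # majority_concordant: strict majority, no dissent
            if n_up > n / 2 and n_down == 0:
                direction = UP
            elif n_down > n / 2 and n_up == 0:
                direction = DOWN
        if direction is None:
            continue
        entries[gene] = direction
        records = []
        for sid, s in zip(study_ids, per_study_sets):
            if gene in s.provenance:
                records.extend(s.provenance[gene])
            elif gene in s:
                records.append(Provenance(study_id=sid, fold_change=float("nan"), p=float("nan")))
        if records:
            provenance[gene] = records
    return MetaProfile(
        entries=DirectionalGeneSet(entries=entries, provenance=provenance),
        member_studies=list(study_ids),
        rule=rule,
    )


def decompose_signature(
    disease: MetaProfile | DirectionalGeneSet,
    reference: DirectionalGeneSet,
    require_direction_match: bool = True,
) -> SignatureDecomposition:
    """Split a disease profile into reference-like vs non-reference genes.

    reference_like genes are members of the reference signature (with the
    same direction when require_direction_match); the rest form the
    non-reference component. The two parts partition the disease profile.
    """
    dset = disease.entries if isinstance(disease, MetaProfile) else disease
    if len(dset) == 0:
        raise ValueError("disease profile is empty")
    like: dict[str, str] = {}
    other: dict[str, str] = {}
    for gene, direction in dset.entries.items():
        if reference.concordant(gene, direction, require_direction_match):
            like[gene] = direction
        else:
            other[gene] = direction
    return SignatureDecomposition(
        reference_like=DirectionalGeneSet(
            entries=like, provenance={g: v for g, v in dset.provenance.items() if g in like}
        ),
        non_reference=DirectionalGeneSet(
            entries=other, provenance={g: v for g, v in dset.provenance.items() if g in other}
        ),
        n_disease=len(dset),
        n_reference=len(reference),
    )


def chi_square_2x2(
    table: np.ndarray | Sequence[Sequence[float]], yates: bool = False
) -> tuple[float | None, float | None]:
    """Pearson chi-square on a 2x2 table, df=1, upper-tail p.

    Yates continuity correction is off by default (the counts this package
    reports are large). A zero row margin leaves the statistic undefined:
    (None, None). A zero column margin with both rows populated means the
    rows are indistinguishable (observed equals expected everywhere):
    chi2 = 0, p = 1.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("table counts must be nonnegative")
    if (t.sum(axis=1) == 0).any():
        return None, None
    if (t.sum(axis=0) == 0).any():
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(t, correction=yates)
    return float(chi2), float(p)


def maintenance_analysis(
    decomp: SignatureDecomposition,
    later_stage: MetaProfile | DirectionalGeneSet,
    require_direction_match: bool = True,
    yates: bool = False,
) -> MaintenanceResult:
    """How much of each decomposition component persists at a later stage.

    A gene is *maintained* when the later-stage profile contains it (with
    the same direction when require_direction_match). Association between
    component and maintenance is tested with a 2x2 Pearson chi-square.
    """
    later = later_stage.entries if isinstance(later_stage, MetaProfile) else later_stage
    if len(later) == 0:
        raise ValueError("later-stage profile is empty")
    maintained: dict[str, set[str]] = {}
    lost: dict[str, set[str]] = {}
    counts = np.zeros((2, 2), dtype=int)
    for i, (name, component) in enumerate(
        (("reference_like", decomp.reference_like), ("non_reference", decomp.non_reference))
    ):
        kept = {
            g
            for g, d in component.entries.items()
            if later.concordant(g, d, require_direction_match)
        }
        maintained[name] = kept
        lost[name] = component.genes() - kept
        counts[i, 0] = len(kept)
        counts[i, 1] = len(component) - len(kept)
    chi2, p = chi_square_2x2(counts, yates=yates)
    return MaintenanceResult(table=counts, maintained=maintained, lost=lost, chi2=chi2, p=p)


def specificity_fraction(
    signature: DirectionalGeneSet,
    other_profile: MetaProfile | DirectionalGeneSet,
    comparator_split: tuple[int, int] | None = None,
    require_direction_match: bool = True,
    yates: bool = False,
) -> SpecificityResult:
    """Share of another condition's profile that lies inside the signature.

    fraction = 100 * |profile ∩ signature (direction-concordant)| / |profile|.
    When a comparator (in_signature, out_of_signature) split is supplied —
    typically the split of the profile the signature was defined against —
    the two splits are compared by 2x2 chi-square.
    """
    profile = other_profile.entries if isinstance(other_profile, MetaProfile) else other_profile
    if len(profile) == 0:
        raise ValueError("other profile is empty")
    n_in = sum(
        1
        for g, d in profile.entries.items()
        if signature.concordant(g, d, require_direction_match)
    )
    fraction = 100.0 * n_in / len(profile)
    chi2 = p = None
    if comparator_split is not None:
        table = [[n_in, len(profile) - n_in], list(comparator_split)]
        chi2, p = chi_square_2x2(table, yates=yates)
    return SpecificityResult(fraction=fraction, chi2=chi2, p=p)


def write_decomposition_report(
    decomp: SignatureDecomposition,
    path,
    maintenance: MaintenanceResult | None = None,
) -> None:
    """TSV report: component, gene, direction, maintained flag (if known)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("component\tgene\tdirection\tmaintained\n")
        for name, component in (
            ("reference_like", decomp.reference_like),
            ("non_reference", decomp.non_reference),
        ):
            kept = maintenance.maintained[name] if maintenance is not None else None
            for gene in sorted(component.entries):
                flag = "" if kept is None else ("yes" if gene in kept else "no")
                fh.write(f"{name}\t{gene}\t{component.entries[gene]}\t{flag}\n")


def write_summary_json(summary: Mapping, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
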