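"""Per-study two-group differential expression.

The workhorse is the two-sided Mann-Whitney (rank-sum) test combined with
a linear-scale fold-change gate: a gene is called differentially expressed
when p < 0.001 and its group-mean ratio is >= 1.5 or <= 1/1.5. No multiple
testing correction is applied — calls are gated on the raw p-value
throughout, and downstream cross-study intersection is the replication
filter. A plain equal-variance Student t-test is provided for viability
readouts.

For small untied samples (both groups <= 8) the Mann-Whitney p-value is
exact by enumeration; otherwise the normal approximation with tie and
continuity corrections is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .expr_io import ExpressionStudy
from .meta_signature import DOWN, UP, DirectionalGeneSet, Provenance

__all__ = [
    "DEResult",
    "mann_whitney_test",
    "fold_change",
    "differential_genes",
    "student_t_test",
    "write_de_table",
]

EXACT_MAX_N = 8  # exact enumeration bound per group (untied samples only)


@dataclass(frozen=True)
class DEResult:
    """One gene's differential-expression evidence."""

    gene: str
    fold_change: float
    direction: str
    U: float
    p: float

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError("fold change must be positive")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")
        expected = UP if self.fold_change > 1 else (DOWN if self.fold_change < 1 else UP)
        if self.direction != expected:
            raise ValueError(
                f"direction {self.direction!r} inconsistent with fold change {self.fold_change}"
            )


def _check_groups(x: np.ndarray, y: np.ndarray) -> None:
    if x.ndim != 1 or y.ndim != 1:
        raise ValueError("expected 1-D sample vectors")
    if len(x) < 2 or len(y) < 2:
        raise ValueError(f"each group needs >= 2 samples (got {len(x)} and {len(y)})")


def mann_whitney_test(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney test; returns (U, p).

    U is the smaller of the two one-sided U statistics. p is exact when
    both groups have <= 8 samples and the pooled values are untied, else
    the tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_groups(x, y)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):  # fully degenerate: no separation at all
        return n1 * n2 / 2.0, 1.0
    tied = len(np.unique(pooled)) < n1 + n2
    if n1 <= EXACT_MAX_N and n2 <= EXACT_MAX_N and not tied:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    u1 = float(res.statistic)
    return min(u1, n1 * n2 - u1), min(float(res.pvalue), 1.0)


def _mann_whitney_matrix(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sided Mann-Whitney, normal approximation.

    Tie-corrected, continuity-corrected; rows with zero rank variance
    (all pooled values tied) get p = 1. Matches the scalar asymptotic path
    of :func:`mann_whitney_test` row by row.
    """
    n1, n2 = X.shape[1], Y.shape[1]
    n = n1 + n2
    pooled = np.concatenate([X, Y], axis=1)
    ranks = stats.rankdata(pooled, axis=1)
    u1 = ranks[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2.0

    # per-row tie correction: sum over tie groups of (t^3 - t)
    srt = np.sort(pooled, axis=1)
    new_run = np.ones_like(srt, dtype=bool)
    new_run[:, 1:] = srt[:, 1:] != srt[:, :-1]
    run_id = np.cumsum(new_run, axis=1) + np.arange(srt.shape[0])[:, None] * n
    counts = np.bincount(run_id.ravel())
    # sum (t^3 - t) per row via the run-length counts
    t3 = counts.astype(float) ** 3 - counts
    row_of_run = np.zeros(len(counts), dtype=int)
    # run ids for row r live in [r*n + 1, (r+1)*n]; map run id -> row
    ids = np.nonzero(counts)[0]
    row_of_run[ids] = (ids - 1) // n
    tie_sum = np.zeros(srt.shape[0])
    np.add.at(tie_sum, row_of_run[ids], t3[ids])

    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_sum / (n * (n - 1)))
    diff = u1 - mu
    cc = np.sign(diff) * 0.5  # continuity correction shrinks |z|
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (diff - cc) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(var <= 0, 1.0, np.minimum(p, 1.0))
    u = np.minimum(u1, n1 * n2 - u1)
    return u, p


def fold_change(x, y_reference) -> tuple[float, str]:
    """Linear-scale mean ratio and its direction label.

    fold_change = mean(x) / mean(y_reference); direction is "up" when the
    ratio exceeds 1, "down" below 1; a ratio of exactly 1 is labelled "up"
    (the label never matters there — a unit ratio cannot pass the gate).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y_reference, dtype=float)
    ref_mean = float(y.mean())
    if ref_mean <= 0:
        raise ValueError(f"reference group mean must be positive, got {ref_mean}")
    fc = float(x.mean()) / ref_mean
    return fc, (DOWN if fc < 1 else UP)


def differential_genes(
    study: ExpressionStudy,
    test_group: str,
    ref_group: str,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.001,
) -> DirectionalGeneSet:
    """Mann-Whitney + fold-change gated DE calls for one study.

    A gene is included iff p < p_threshold and its fold change is
    >= fc_threshold or <= 1/fc_threshold. Per-gene evidence (fold change,
    p) is attached as provenance under the study id.
    """
    if not study.is_gene_level:
        raise ValueError(f"study {study.study_id!r} must be gene-level (apply the mask first)")
    if fc_threshold < 1:
        raise ValueError("fc_threshold must be >= 1")
    for g in (test_group, ref_group):
        if g not in study.group_labels():
            raise ValueError(f"group {g!r} not present in study {study.study_id!r}")
    X = study.group_values(test_group)
    Y = study.group_values(ref_group)
    if X.shape[1] < 2 or Y.shape[1] < 2:
        raise ValueError("each group needs >= 2 samples")

    n1, n2 = X.shape[1], Y.shape[1]
    U, P = _mann_whitney_matrix(X, Y)
    if n1 <= EXACT_MAX_N and n2 <= EXACT_MAX_N:
        # exact p where the pooled row is untied (small-sample path)
        for i in range(X.shape[0]):
            pooled = np.concatenate([X[i], Y[i]])
            if len(np.unique(pooled)) == n1 + n2:
                U[i], P[i] = mann_whitney_test(X[i], Y[i])

    ref_means = Y.mean(axis=1)
    if (ref_means <= 0).any():
        bad = study.feature_ids[int(np.argmax(ref_means <= 0))]
        raise ValueError(f"reference group mean is non-positive for gene {bad!r}")
    fc = X.mean(axis=1) / ref_means

    entries: dict[str, str] = {}
    provenance: dict[str, list[Provenance]] = {}
    passed = (P < p_threshold) & ((fc >= fc_threshold) | (fc <= 1.0 / fc_threshold))
    # provenance is keyed per comparison so that two comparisons within one
    # study (e.g. two tissues against the same reference) stay distinct
    prov_id = f"{study.study_id}:{test_group}_vs_{ref_group}"
    for i in np.nonzero(passed)[0]:
        gene = study.feature_ids[int(i)]
        direction = DOWN if fc[i] < 1 else UP
        entries[gene] = direction
        provenance[gene] = [
            Provenance(study_id=prov_id, fold_change=float(fc[i]), p=float(P[i]), U=float(U[i]))
        ]
    return DirectionalGeneSet(entries=entries, provenance=provenance)


def student_t_test(x, y) -> float:
    """Two-sided unpaired equal-variance t-test p-value.

    Degenerate inputs (zero pooled variance) return p = 1 when the means
    agree and p = 0 when they differ — the limiting convention for
    perfectly reproducible readouts.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_groups(x, y)
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        return 1.0 if x.mean() == y.mean() else 0.0
    return float(stats.ttest_ind(x, y, equal_var=True).pvalue)


def write_de_table(gene_set: DirectionalGeneSet, path) -> None:
    """TSV with fixed columns: gene, fold_change, direction, U, p.

    Cells are blank for genes whose provenance carries no statistics
    (aggregated or file-loaded sets).
    """

    def _fmt(v: float) -> str:
        return "" if np.isnan(v) else format(v, "g")

    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene\tfold_change\tdirection\tU\tp\n")
        for gene in sorted(gene_set.entries):
            recs = gene_set.provenance.get(gene)
            fc, u, p = ("", "", "")
            if recs:
                fc, u, p = _fmt(recs[0].fold_change), _fmt(recs[0].U), _fmt(recs[0].p)
            fh.write(f"{gene}\t{fc}\t{gene_set.entries[gene]}\t{u}\t{p}\n")
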