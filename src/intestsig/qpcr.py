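"""ddCt relative quantification for real-time RT-PCR.

Cycle thresholds (Ct) are averaged over technical replicates per
(sample, gene); the target gene is normalized to a reference housekeeping
gene (dCt = Ct_target - Ct_reference), then to the mean dCt of a control
group (ddCt), giving fold change 2^(-ddCt). Ct values above the
non-detect ceiling (default 40 cycles) are clamped to the ceiling and the
sample flagged as a non-detect; a drop policy is available. Group
significance is tested by two-sided Mann-Whitney on the per-sample
relative quantities 2^(-dCt).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexp import mann_whitney_test

__all__ = [
    "CtTable",
    "DdctResult",
    "read_ct_table",
    "write_ct_table",
    "delta_delta_ct",
    "expression_group_test",
]

CT_COLUMNS = ["sample_id", "group", "gene", "replicate", "ct"]

CLAMP = "clamp"
DROP = "drop"

ARITHMETIC = "arithmetic"
GEOMETRIC = "geometric"


@dataclass
class CtTable:
    """Long-format qPCR records with a non-detect convention.

    data columns: sample_id, group, gene, replicate, ct. Replicate indices
    must be unique per (sample, gene); Ct must be positive (a reaction that
    never crossed threshold is encoded as any value above the ceiling).
    """

    data: pd.DataFrame
    non_detect_ceiling: float = 40.0

    def __post_init__(self) -> None:
        missing = [c for c in CT_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"Ct table missing columns: {missing}")
        self.data = self.data[CT_COLUMNS].copy()
        self.data["ct"] = self.data["ct"].astype(float)
        if (self.data["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        if self.non_detect_ceiling <= 0:
            raise ValueError("non_detect_ceiling must be positive")
        dup = self.data.duplicated(subset=["sample_id", "gene", "replicate"])
        if dup.any():
            row = self.data[dup].iloc[0]
            raise ValueError(
                f"duplicate replicate index {row['replicate']} for sample "
                f"{row['sample_id']!r}, gene {row['gene']!r}"
            )
        groups_per_sample = self.data.groupby("sample_id")["group"].nunique()
        if (groups_per_sample > 1).any():
            bad = groups_per_sample[groups_per_sample > 1].index[0]
            raise ValueError(f"sample {bad!r} appears under more than one group")

    def genes(self) -> set[str]:
        return set(self.data["gene"])

    def groups(self) -> set[str]:
        return set(self.data["group"])


def read_ct_table(path, non_detect_ceiling: float = 40.0) -> CtTable:
    data = pd.read_csv(path, sep="\t")
    return CtTable(data=data, non_detect_ceiling=non_detect_ceiling)


def write_ct_table(table: CtTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False, lineterminator="\n")


def _mean_ct(
    table: CtTable, gene: str, nondetect_policy: str
) -> tuple[pd.Series, pd.Series]:
    """Per-sample replicate-mean Ct for one gene, plus a non-detect flag.

    clamp: Ct above the ceiling is set to the ceiling (kept); drop:
    above-ceiling replicates are removed (a sample with no surviving
    replicate stays flagged and gets the ceiling as its mean).
    """
    sub = table.data[table.data["gene"] == gene].copy()
    flagged = sub["ct"] > table.non_detect_ceiling
    nd = sub.assign(nd=flagged).groupby("sample_id")["nd"].any()
    if nondetect_policy == CLAMP:
        sub.loc[flagged, "ct"] = table.non_detect_ceiling
    elif nondetect_policy == DROP:
        sub = sub[~flagged]
    else:
        raise ValueError(f"unknown non-detect policy {nondetect_policy!r}")
    means = sub.groupby("sample_id")["ct"].mean()
    # drop policy can empty a sample out entirely; pin it at the ceiling
    means = means.reindex(nd.index, fill_value=table.non_detect_ceiling)
    return means, nd


def _delta_ct(
    table: CtTable, target_gene: str, reference_gene: str, nondetect_policy: str
) -> tuple[pd.Series, pd.Series]:
    for gene in (target_gene, reference_gene):
        if gene not in table.genes():
            raise ValueError(f"gene {gene!r} not present in the Ct table")
    target, nd_target = _mean_ct(table, target_gene, nondetect_policy)
    reference, nd_ref = _mean_ct(table, reference_gene, nondetect_policy)
    missing_ref = sorted(set(target.index) - set(reference.index))
    if missing_ref:
        raise ValueError(
            f"reference gene {reference_gene!r} not measured for sample {missing_ref[0]!r}"
        )
    dct = target - reference.reindex(target.index)
    nd = nd_target | nd_ref.reindex(target.index, fill_value=False)
    return dct, nd


@dataclass
class DdctResult:
    """Per-sample ddCt fold changes plus group summaries."""

    per_sample: pd.DataFrame  # sample_id, group, delta_ct, ddct, fold_change, non_detect
    group_fold_change: dict[str, float]
    control_group: str
    aggregate: str = ARITHMETIC

    def write_tsv(self, path) -> None:
        self.per_sample.to_csv(path, sep="\t", index=False, lineterminator="\n")


def delta_delta_ct(
    table: CtTable,
    target_gene: str,
    reference_gene: str,
    control_group: str,
    aggregate: str = ARITHMETIC,
    nondetect_policy: str = CLAMP,
) -> DdctResult:
    """Relative expression of target vs reference, normalized to a control group.

    Per sample: dCt = mean-replicate Ct(target) - mean-replicate
    Ct(reference); ddCt = dCt - mean dCt over the control group;
    fold change = 2^(-ddCt). The group summary is the arithmetic mean of
    per-sample fold changes (geometric mean available, which equals
    2^(-mean ddCt)).
    """
    if aggregate not in (ARITHMETIC, GEOMETRIC):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    if control_group not in table.groups():
        raise ValueError(f"control group {control_group!r} not present in the Ct table")
    dct, nd = _delta_ct(table, target_gene, reference_gene, nondetect_policy)
    sample_group = (
        table.data.drop_duplicates("sample_id").set_index("sample_id")["group"]
    )
    groups = sample_group.reindex(dct.index)
    control_dct = dct[groups == control_group]
    if control_dct.empty:
        raise ValueError(
            f"control group {control_group!r} has no sample with both genes measured"
        )
    ddct = dct - control_dct.mean()
    fc = np.power(2.0, -ddct)
    per_sample = pd.DataFrame(
        {
            "sample_id": dct.index,
            "group": groups.values,
            "delta_ct": dct.values,
            "ddct": ddct.values,
            "fold_change": fc.values,
            "non_detect": nd.reindex(dct.index).values,
        }
    ).reset_index(drop=True)
    group_fc: dict[str, float] = {}
    for g, block in per_sample.groupby("group"):
        if aggregate == ARITHMETIC:
            group_fc[g] = float(block["fold_change"].mean())
        else:
            group_fc[g] = float(np.power(2.0, -block["ddct"].mean()))
    return DdctResult(
        per_sample=per_sample,
        group_fold_change=group_fc,
        control_group=control_group,
        aggregate=aggregate,
    )


def expression_group_test(
    table: CtTable,
    target_gene: str,
    reference_gene: str,
    group_a: str,
    group_b: str,
    nondetect_policy: str = CLAMP,
) -> float:
    """Two-sided Mann-Whitney p between groups on per-sample 2^(-dCt).

    The statistic is rank-based, so testing on 2^(-dCt) and on -dCt are
    equivalent; the relative-quantity scale is used for reporting
    consistency.
    """
    dct, _ = _delta_ct(table, target_gene, reference_gene, nondetect_policy)
    sample_group = (
        table.data.drop_duplicates("sample_id").set_index("sample_id")["group"]
    )
    groups = sample_group.reindex(dct.index)
    qty = np.power(2.0, -dct)
    a = qty[groups == group_a].to_numpy()
    b = qty[groups == group_b].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 samples with both genes measured")
    _, p = mann_whitney_test(a, b)
    return p
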