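"""I/O and harmonization of expression matrices, annotation masks, gene lists.

Matrices are tab-delimited, features (probes or gene symbols) in rows and
samples in columns, linear-scale nonnegative intensities. Intensities are
assumed background-corrected and normalized upstream (vendor-processed
chips); no normalization happens here. Cross-platform comparison goes
through an *annotation mask* — a probe-to-gene map restricting every
platform to a shared gene universe — after which multi-probe genes are
collapsed to a single row.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .meta_signature import DIRECTIONS, DirectionalGeneSet

__all__ = [
    "ExpressionStudy",
    "AnnotationMask",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_group_map",
    "write_group_map",
    "apply_annotation_mask",
    "read_annotation_mask",
    "write_annotation_mask",
    "read_gene_list",
    "write_gene_list",
]

MAX_MEAN = "max_mean"
MEDIAN = "median"


@dataclass
class ExpressionStudy:
    """One study's intensity matrix with sample-group labels.

    values is features x samples on the linear scale. is_gene_level marks
    a matrix whose features are (unique) gene symbols rather than probes.
    """

    study_id: str
    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    groups: dict[str, str]
    platform_id: str = ""
    is_gene_level: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise ValueError(f"duplicate sample ids: {dupes}")
        if self.is_gene_level and len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("gene-level study must not contain duplicate feature ids")
        missing = [s for s in self.sample_ids if s not in self.groups]
        if missing:
            raise ValueError(f"samples missing from group map: {missing}")
        if not np.isfinite(self.values).all():
            raise ValueError("intensity matrix contains non-finite values")
        if (self.values < 0).any():
            raise ValueError("intensities must be nonnegative (linear scale)")

    # -- convenience accessors -------------------------------------------------

    def group_labels(self) -> set[str]:
        return {self.groups[s] for s in self.sample_ids}

    def sample_indices(self, group: str) -> list[int]:
        return [i for i, s in enumerate(self.sample_ids) if self.groups[s] == group]

    def group_values(self, group: str) -> np.ndarray:
        idx = self.sample_indices(group)
        if not idx:
            raise ValueError(f"group {group!r} not present in study {self.study_id!r}")
        return self.values[:, idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)


@dataclass
class AnnotationMask:
    """Probe-to-gene map defining the shared gene universe of a platform set.

    Probes absent from the map are excluded by construction; each probe maps
    to at most one gene symbol. Any user-supplied mask is treated as
    authoritative.
    """

    platform_id: str
    probe_to_gene: dict[str, str]
    gene_universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        mapped = set(self.probe_to_gene.values())
        if not self.gene_universe:
            self.gene_universe = mapped
        elif not mapped <= self.gene_universe:
            extra = sorted(mapped - self.gene_universe)[:5]
            raise ValueError(f"probe_to_gene maps to symbols outside gene_universe, e.g. {extra}")


# -- expression matrix I/O -----------------------------------------------------


def read_group_map(path) -> dict[str, str]:
    """Two-column TSV sample_id<TAB>group; an optional header row is skipped."""
    groups: dict[str, str] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for i, row in enumerate(csv.reader(fh, delimiter="\t")):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 2:
                raise ValueError(f"{path}: line {i + 1}: expected 2 columns, got {len(row)}")
            sample, group = row[0].strip(), row[1].strip()
            if i == 0 and sample.lower() == "sample_id":
                continue
            if sample in groups:
                raise ValueError(f"{path}: duplicate sample id {sample!r} in group map")
            groups[sample] = group
    return groups


def write_group_map(groups: dict[str, str], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample_id\tgroup\n")
        for sample, group in groups.items():
            fh.write(f"{sample}\t{group}\n")


def read_expression_matrix(
    path,
    group_map,
    study_id: str | None = None,
    platform_id: str = "",
    is_gene_level: bool = False,
) -> ExpressionStudy:
    """Read a feature x sample TSV plus its sample-to-group map.

    First column holds feature ids, header row holds sample ids; feature
    and sample order are preserved as in the file. group_map may be a path
    or an already-parsed dict.
    """
    path = Path(path)
    with open(path, encoding="utf-8", newline="") as fh:
        rows = [row for row in csv.reader(fh, delimiter="\t") if row]
    if not rows:
        raise ValueError(f"{path}: empty expression matrix")
    header = rows[0]
    sample_ids = [s.strip() for s in header[1:]]
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ValueError(f"{path}: duplicate sample ids in header: {dupes}")
    feature_ids: list[str] = []
    values = np.empty((len(rows) - 1, len(sample_ids)), dtype=float)
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != len(sample_ids) + 1:
            raise ValueError(f"{path}: line {r}: expected {len(sample_ids) + 1} columns, got {len(row)}")
        feature_ids.append(row[0].strip())
        for c, cell in enumerate(row[1:]):
            try:
                values[r - 2, c] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell {cell!r} at feature {row[0]!r}, "
                    f"sample {sample_ids[c]!r}"
                ) from None
    groups = group_map if isinstance(group_map, dict) else read_group_map(group_map)
    missing = [s for s in sample_ids if s not in groups]
    if missing:
        raise ValueError(f"{path}: samples absent from group map: {missing}")
    return ExpressionStudy(
        study_id=study_id if study_id is not None else path.stem,
        feature_ids=feature_ids,
        sample_ids=sample_ids,
        values=values,
        groups={s: groups[s] for s in sample_ids},
        platform_id=platform_id,
        is_gene_level=is_gene_level,
    )


def write_expression_matrix(study: ExpressionStudy, path, group_map_path=None) -> None:
    """Write the matrix as TSV (and optionally its group map alongside)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("feature_id\t" + "\t".join(study.sample_ids) + "\n")
        for fid, row in zip(study.feature_ids, study.values):
            # shortest round-trip representation: read-back is bit-identical
            fh.write(fid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    if group_map_path is not None:
        write_group_map({s: study.groups[s] for s in study.sample_ids}, group_map_path)


# -- annotation masking --------------------------------------------------------


def apply_annotation_mask(
    study: ExpressionStudy, mask: AnnotationMask, collapse_rule: str = MAX_MEAN
) -> ExpressionStudy:
    """Collapse a probe-level study onto the mask's gene universe.

    Output features are the genes with at least one mapped probe in the
    study, ordered by first probe occurrence. Multi-probe genes collapse by
    *max_mean* (the probe row with the highest mean intensity across all
    samples; ties go to the earliest probe) or *median* (per-sample median
    across probe rows).
    """
    if study.is_gene_level:
        raise ValueError(f"study {study.study_id!r} is already gene-level")
    if collapse_rule not in (MAX_MEAN, MEDIAN):
        raise ValueError(f"unknown collapse rule {collapse_rule!r}")
    probes_per_gene: dict[str, list[int]] = {}
    for i, probe in enumerate(study.feature_ids):
        gene = mask.probe_to_gene.get(probe)
        if gene is not None:
            probes_per_gene.setdefault(gene, []).append(i)
    if not probes_per_gene:
        raise ValueError(
            f"no probe of study {study.study_id!r} is mapped by mask {mask.platform_id!r}"
        )
    genes = list(probes_per_gene)
    out = np.empty((len(genes), len(study.sample_ids)), dtype=float)
    for g, gene in enumerate(genes):
        rows = study.values[probes_per_gene[gene], :]
        if rows.shape[0] == 1:
            out[g] = rows[0]
        elif collapse_rule == MAX_MEAN:
            out[g] = rows[int(np.argmax(rows.mean(axis=1)))]
        else:
            out[g] = np.median(rows, axis=0)
    return ExpressionStudy(
        study_id=study.study_id,
        feature_ids=genes,
        sample_ids=list(study.sample_ids),
        values=out,
        groups=dict(study.groups),
        platform_id=mask.platform_id,
        is_gene_level=True,
    )


def read_annotation_mask(path, platform_id: str | None = None) -> AnnotationMask:
    """Two-column TSV probe<TAB>gene; an optional header row is skipped."""
    path = Path(path)
    probe_to_gene: dict[str, str] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for i, row in enumerate(csv.reader(fh, delimiter="\t")):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 2:
                raise ValueError(f"{path}: line {i + 1}: expected 2 columns, got {len(row)}")
            probe, gene = row[0].strip(), row[1].strip()
            if i == 0 and probe.lower() in ("probe", "probe_id"):
                continue
            if probe in probe_to_gene:
                raise ValueError(f"{path}: probe {probe!r} mapped more than once")
            probe_to_gene[probe] = gene
    return AnnotationMask(
        platform_id=platform_id if platform_id is not None else path.stem,
        probe_to_gene=probe_to_gene,
    )


def write_annotation_mask(mask: AnnotationMask, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("probe_id\tgene\n")
        for probe, gene in mask.probe_to_gene.items():
            fh.write(f"{probe}\t{gene}\n")


# -- gene lists ----------------------------------------------------------------


def read_gene_list(path) -> DirectionalGeneSet:
    """Two-column TSV gene<TAB>direction with direction in {up, down}."""
    entries: dict[str, str] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for i, row in enumerate(csv.reader(fh, delimiter="\t")):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 2:
                raise ValueError(f"{path}: line {i + 1}: expected 2 columns, got {len(row)}")
            gene, direction = row[0].strip(), row[1].strip()
            if i == 0 and gene.lower() == "gene":
                continue
            if direction not in DIRECTIONS:
                raise ValueError(
                    f"{path}: line {i + 1}: unknown direction {direction!r}; expected up/down"
                )
            if gene in entries:
                raise ValueError(f"{path}: gene {gene!r} listed more than once")
            entries[gene] = direction
    return DirectionalGeneSet(entries=entries)


def write_gene_list(gene_set: DirectionalGeneSet, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene\tdirection\n")
        for gene in sorted(gene_set.entries):
            fh.write(f"{gene}\t{gene_set.entries[gene]}\n")
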