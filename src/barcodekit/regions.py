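"""Partition a barcode locus into named segments and score SNP density.

Primer placement on a barcode locus trades amplicon length against
variability, so the locus is split into contiguous parts (classically a
5' end, a core, and a 3' end) and each part is scored for the SNPs it
carries relative to the reference row.  Because the parts have unequal
lengths, comparisons between them use per-sequence SNP densities
(count / region length); raw counts are reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .alignio import Alignment
from .barcodegap import TestResult


@dataclass(frozen=True)
class RegionPartition:
    """Contiguous, non-overlapping 1-based regions covering [1, locus_length]."""

    locus_length: int
    regions: tuple[tuple[str, int, int], ...]  # (label, start, end) inclusive

    def __post_init__(self):
        if not self.regions:
            raise ValueError("partition needs at least one region")
        labels = [r[0] for r in self.regions]
        if len(set(labels)) != len(labels):
            raise ValueError("region labels must be unique")
        expect = 1
        for label, start, end in self.regions:
            if start != expect or end < start:
                raise ValueError(
                    f"region {label!r} [{start},{end}] breaks contiguous coverage"
                )
            expect = end + 1
        if expect != self.locus_length + 1:
            raise ValueError("regions must cover [1, locus_length] exactly")

    @property
    def labels(self) -> list[str]:
        return [r[0] for r in self.regions]

    def length_of(self, label: str) -> int:
        for lab, start, end in self.regions:
            if lab == label:
                return end - start + 1
        raise KeyError(label)


def partition(
    locus_length: int, breakpoints: list[int], labels: list[str]
) -> RegionPartition:
    """Build regions [1,b1], [b1+1,b2], ..., [b_k+1, L] from cut positions."""
    if len(labels) != len(breakpoints) + 1:
        raise ValueError("need exactly one more label than breakpoints")
    prev = 0
    for b in breakpoints:
        if not (1 <= b < locus_length):
            raise ValueError(f"breakpoint {b} outside (1, {locus_length})")
        if b <= prev:
            raise ValueError("breakpoints must be strictly increasing")
        prev = b
    bounds = [0] + list(breakpoints) + [locus_length]
    regions = tuple(
        (lab, bounds[i] + 1, bounds[i + 1]) for i, lab in enumerate(labels)
    )
    return RegionPartition(locus_length, regions)


def default_partition(locus_length: int) -> RegionPartition:
    """Default a/b/c split: 1/6 of the locus, the 4/6 core, the final 1/6."""
    b1 = max(1, locus_length // 6)
    b2 = max(b1 + 1, locus_length - locus_length // 6)
    if b2 >= locus_length:
        raise ValueError(f"locus of length {locus_length} too short to split in three")
    return partition(locus_length, [b1, b2], ["a", "b", "c"])


@dataclass
class RegionCounts:
    """Per-sequence SNP counts vs. the reference, by region, plus totals.

    ``totals[label] = (polymorphic site count, region length, density)``
    where a polymorphic site differs from the reference in at least one
    non-reference row.
    """

    reference_id: str
    sequence_ids: list[str]  # non-reference rows
    labels: list[str]
    per_sequence: dict[tuple[str, str], int]
    totals: dict[str, tuple[int, int, float]]

    def density(self, seq_id: str, label: str) -> float:
        return self.per_sequence[(seq_id, label)] / self.totals[label][1]

    def to_tsv(self) -> str:
        lines = ["id\tregion\tsnp_count\tregion_length\tdensity"]
        for sid in self.sequence_ids:
            for lab in self.labels:
                c = self.per_sequence[(sid, lab)]
                L = self.totals[lab][1]
                lines.append(f"{sid}\t{lab}\t{c}\t{L}\t{c / L:.6f}")
        for lab in self.labels:
            poly, L, dens = self.totals[lab]
            lines.append(f"TOTAL_polymorphic\t{lab}\t{poly}\t{L}\t{dens:.6f}")
        return "\n".join(lines) + "\n"


def snp_counts_by_region(
    alignment: Alignment,
    part: RegionPartition,
    frame: str = "alignment",
) -> RegionCounts:
    """Count sites differing from the reference row, per sequence and region.

    ``frame="alignment"`` takes the partition on current columns;
    ``frame="reference"`` translates through ``column_map`` so the partition
    can be stated in original reference coordinates.  ``N`` cells are
    excluded.  Totals count columns polymorphic in >= 1 non-reference row.
    """
    if not alignment.trimmed:
        raise ValueError("snp_counts_by_region requires a trimmed alignment")
    if frame not in ("alignment", "reference"):
        raise ValueError(f"unknown frame {frame!r}")
    mat = alignment.matrix()
    comp = alignment.comparable_mask()
    ref_idx = alignment.ids.index(alignment.reference_id)
    width = alignment.width
    if frame == "alignment":
        if part.locus_length != width:
            raise ValueError(
                f"partition length {part.locus_length} != alignment width {width}"
            )
        col_region = np.empty(width, dtype=object)
        for lab, start, end in part.regions:
            col_region[start - 1 : end] = lab
    else:
        cmap = np.asarray(alignment.column_map)
        if part.locus_length < cmap[-1]:
            raise ValueError("partition does not cover the reference coordinates")
        col_region = np.empty(width, dtype=object)
        for lab, start, end in part.regions:
            col_region[(cmap >= start) & (cmap <= end)] = lab

    diff = (mat != mat[ref_idx]) & comp & comp[ref_idx]
    per_sequence: dict[tuple[str, str], int] = {}
    seq_ids = [i for i in alignment.ids if i != alignment.reference_id]
    totals: dict[str, tuple[int, int, float]] = {}
    nonref = np.array([i != ref_idx for i in range(len(alignment.ids))])
    poly_col = diff[nonref].any(axis=0)
    for lab in part.labels:
        in_region = col_region == lab
        length = int(in_region.sum())
        if length == 0:
            raise ValueError(f"region {lab!r} covers no alignment column")
        for sid in seq_ids:
            i = alignment.ids.index(sid)
            per_sequence[(sid, lab)] = int(diff[i, in_region].sum())
        poly = int(poly_col[in_region].sum())
        totals[lab] = (poly, length, poly / length)
    return RegionCounts(
        reference_id=alignment.reference_id,
        sequence_ids=seq_ids,
        labels=list(part.labels),
        per_sequence=per_sequence,
        totals=totals,
    )


@dataclass(frozen=True)
class RegionComparison:
    other: str
    mean_difference: float  # focal density minus other density
    test: TestResult


def compare_regions(
    counts: RegionCounts, focal: str
) -> dict[str, RegionComparison]:
    """Paired two-sided t-test of focal-region SNP density against each other
    region, pairing on sequences (each sequence yields one density per
    region, so its overall divergence is controlled)."""
    if focal not in counts.labels:
        raise KeyError(f"unknown region {focal!r}")
    if len(counts.sequence_ids) < 2:
        raise ValueError("need at least two sequences for a paired comparison")
    out: dict[str, RegionComparison] = {}
    focal_d = np.array([counts.density(s, focal) for s in counts.sequence_ids])
    for other in counts.labels:
        if other == focal:
            continue
        other_d = np.array([counts.density(s, other) for s in counts.sequence_ids])
        d = focal_d - other_d
        n = d.size
        mean = float(d.mean())
        sd = float(d.std(ddof=1))
        if sd == 0.0:
            if mean == 0.0:
                res = TestResult(0.0, float(n - 1), 1.0)
            else:
                res = TestResult(math.copysign(math.inf, mean), float(n - 1), 0.0)
        else:
            t = mean / (sd / math.sqrt(n))
            p = 2.0 * stats.t.sf(abs(t), n - 1)
            res = TestResult(float(t), float(n - 1), float(p))
        out[other] = RegionComparison(other=other, mean_difference=mean, test=res)
    return out


def comparisons_to_tsv(focal: str, comps: dict[str, RegionComparison]) -> str:
    lines = ["focal\tother\tmean_density_difference\tt_statistic\tdf\tp_value"]
    for other in sorted(comps):
        c = comps[other]
        lines.append(
            f"{focal}\t{other}\t{c.mean_difference:.6f}\t"
            f"{c.test.statistic:.6f}\t{c.test.degrees_of_freedom:.0f}\t"
            f"{c.test.p_value:.6g}"
        )
    return "\n".join(lines) + "\n"
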