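"""Genomic spacing summaries of psPRS SNP sets.

Physical proximity stands in for linkage disequilibrium here: SNP
pairs on the same chromosome within a distance threshold (default
30.8 kb) are "nearby" and likely correlated, so a pruning step that
removes nearby SNPs is plausibly removing redundant LD partners.
Distances are never computed across chromosomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .exceptions import ValidationError
from .io_formats import SnpAnnotation

#: Default proximity threshold in bp.
DEFAULT_PROXIMITY_BP = 30_800


@dataclass(frozen=True)
class SpacingSummary:
    per_chromosome: dict[str, float]  # mean adjacent-SNP gap in bp
    overall_mean: float  # pooled mean gap; NaN when no chromosome has >= 2 SNPs
    n_pairs_within: int  # same-chromosome pairs at distance <= threshold
    n_snps_within: int  # SNPs in at least one such pair
    n_snps: int
    threshold: int

    @property
    def proportion_within(self) -> float:
        return self.n_snps_within / self.n_snps if self.n_snps else float("nan")


@dataclass(frozen=True)
class SpacingComparison:
    mean_change: float  # pruned overall mean - full overall mean, bp
    proportion_within_full: float
    proportion_within_pruned: float

    @property
    def proportion_change(self) -> float:
        return self.proportion_within_pruned - self.proportion_within_full


def spacing_summary(
    annotations: Sequence[SnpAnnotation],
    snp_set: Iterable[str] | None = None,
    threshold: int = DEFAULT_PROXIMITY_BP,
) -> SpacingSummary:
    """Per-chromosome mean adjacent-SNP distance and proximity counts.

    ``snp_set`` restricts the summary to a subset (default: all
    annotated SNPs). Chromosomes with fewer than two SNPs contribute no
    gaps; the overall mean pools adjacent gaps across chromosomes. The
    proximity count is over all same-chromosome pairs at distance <=
    ``threshold`` (inclusive).
    """
    by_rsid = {a.rsid: a for a in annotations}
    if snp_set is None:
        chosen = list(by_rsid)
    else:
        chosen = list(dict.fromkeys(snp_set))
        missing = sorted(r for r in chosen if r not in by_rsid)
        if missing:
            raise ValidationError(f"rsids without coordinates: {missing}")
    by_chrom: dict[str, list[SnpAnnotation]] = {}
    for rsid in chosen:
        ann = by_rsid[rsid]
        by_chrom.setdefault(ann.chromosome, []).append(ann)

    per_chrom: dict[str, float] = {}
    all_gaps: list[int] = []
    n_pairs = 0
    snps_within: set[str] = set()
    for chrom, anns in by_chrom.items():
        anns.sort(key=lambda a: a.position)
        gaps = [b.position - a.position for a, b in zip(anns, anns[1:])]
        if gaps:
            per_chrom[chrom] = sum(gaps) / len(gaps)
            all_gaps.extend(gaps)
        for i, left in enumerate(anns):
            for right in anns[i + 1 :]:
                if right.position - left.position > threshold:
                    break  # sorted: later SNPs are farther still
                n_pairs += 1
                snps_within.add(left.rsid)
                snps_within.add(right.rsid)
    overall = sum(all_gaps) / len(all_gaps) if all_gaps else math.nan
    return SpacingSummary(
        per_chromosome=per_chrom,
        overall_mean=overall,
        n_pairs_within=n_pairs,
        n_snps_within=len(snps_within),
        n_snps=len(chosen),
        threshold=threshold,
    )


def compare_spacing(full: SpacingSummary, pruned: SpacingSummary) -> SpacingComparison:
    """Change in mean spacing and in the proportion of nearby SNPs."""
    if full.threshold != pruned.threshold:
        raise ValidationError(
            f"threshold mismatch: {full.threshold} vs {pruned.threshold}"
        )
    return SpacingComparison(
        mean_change=pruned.overall_mean - full.overall_mean,
        proportion_within_full=full.proportion_within,
        proportion_within_pruned=pruned.proportion_within,
    )
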