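"""Greedy r2-maximization pruning of psPRS SNP sets.

The sensitivity analysis asks, for each SNP, what the linear
prevalence-vs-psPRS r2 would be if that SNP were removed from the
score, then discards SNPs whose removal improves the fit. Iterating
until no removal improves r2 leaves the subset of SNPs whose
frequencies co-vary with prevalence across all populations — a proxy
for "universal" (ancestry-transferable) effects, with SNPs carrying
population-specific or spurious signal pruned away.

Because the simple linear r2 equals the squared Pearson correlation
between score and phenotype, leave-one-out r2 for every candidate is
computed vectorised from the full-score column sums, making each
iteration O(n_snps * n_populations).

Two removal granularities are provided:

* ``single`` (default) — steepest-ascent: remove the one SNP whose
  exclusion maximises r2, accept while the new r2 >= the current one.
  This cannot overshoot the maximum and yields a strictly traceable,
  monotone non-decreasing r2 path.
* ``batch`` — remove every SNP whose exclusion r2 exceeds the current
  r2, then refit. Faster but can overshoot; provided for sensitivity.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io_formats import FrequencyMatrix, PopulationPanel

logger = logging.getLogger(__name__)

PruneMode = Literal["single", "batch"]

EXHAUSTIVE_MAX_SNPS = 15

# spread below which a psPRS is considered constant (frequencies are O(1))
_CONSTANT_TOL = 1e-9


@dataclass(frozen=True)
class PruningTrace:
    """Ordered record of SNP removals and the r2 after each step."""

    steps: tuple[tuple[str, float], ...]
    initial_r2: float
    final_r2: float
    retained: frozenset[str]

    @property
    def removed(self) -> list[str]:
        return [rsid for rsid, _ in self.steps]

    def to_frame(self) -> pd.DataFrame:
        """Removal-ordered table (rsid, r2 after removal)."""
        return pd.DataFrame(self.steps, columns=["removed_rsid", "r2_after_removal"])


def _ordered_rsids(snp_set: Iterable[str]) -> list[str]:
    # ties break by input position; unordered sets fall back to sorted order
    if isinstance(snp_set, (set, frozenset)):
        return sorted(snp_set)
    return list(dict.fromkeys(snp_set))


def _aligned_matrix(
    freqs: FrequencyMatrix, panel: PopulationPanel, rsids: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Frequency submatrix (snp x shared population) and phenotype vector."""
    present = set(freqs.values.index)
    missing = sorted(r for r in rsids if r not in present)
    if missing:
        raise ValidationError(f"rsids absent from frequency matrix: {missing}")
    codes = [c for c in freqs.population_codes if c in panel.table.index]
    if len(codes) < 3:
        raise ValidationError(
            f"need >= 3 populations shared between frequencies and panel, got {len(codes)}"
        )
    F = freqs.values.loc[list(rsids), codes].to_numpy(dtype=float)
    if np.isnan(F).any():
        bad = [r for r, row in zip(rsids, F) if np.isnan(row).any()]
        raise ValidationError(f"rsids with missing population frequencies: {bad}")
    y = panel.table.loc[codes, "phenotype_value"].to_numpy(dtype=float)
    return F, y


def _r2_single(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation; NaN when x is constant."""
    if np.ptp(x) < _CONSTANT_TOL:
        return float("nan")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    sxy = float(xc @ yc)
    return sxy * sxy / (sxx * syy)


def _loo_r2(F: np.ndarray, y: np.ndarray, active: np.ndarray) -> np.ndarray:
    """r2 of the score excluding each active SNP in turn (vectorised)."""
    total = F[active].sum(axis=0)
    X = total[None, :] - F[active]  # one row per leave-one-out score
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sxx = (Xc * Xc).sum(axis=1)
    syy = float(yc @ yc)
    sxy = Xc @ yc
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = (sxy * sxy) / (sxx * syy)
    # scores are column sums computed by subtraction; treat numerically
    # constant reduced scores as undefined, not as spurious correlation
    r2[np.ptp(X, axis=1) < _CONSTANT_TOL] = np.nan
    return r2


def leave_one_out_r2(
    freqs: FrequencyMatrix, panel: PopulationPanel, snp_set: Iterable[str]
) -> dict[str, float]:
    """Linear-fit r2 of the psPRS built from ``snp_set`` minus each rsid.

    Entries where the reduced fit is undefined (constant reduced score)
    are NaN, with a logged cause.
    """
    rsids = _ordered_rsids(snp_set)
    if len(rsids) < 2:
        raise ValidationError("leave-one-out requires at least 2 SNPs")
    F, y = _aligned_matrix(freqs, panel, rsids)
    r2 = _loo_r2(F, y, np.ones(len(rsids), dtype=bool))
    for rsid, val in zip(rsids, r2):
        if np.isnan(val):
            logger.info("leave-one-out fit undefined without %s (constant score)", rsid)
    return dict(zip(rsids, (float(v) for v in r2)))


def prune_maximize_r2(
    freqs: FrequencyMatrix,
    panel: PopulationPanel,
    snp_set: Iterable[str],
    mode: PruneMode = "single",
) -> PruningTrace:
    """Iteratively discard SNPs whose removal raises the linear-fit r2.

    Deterministic given the input order: exact ties in candidate r2
    break toward the earliest input position (logged). At least one SNP
    is always retained.
    """
    rsids = _ordered_rsids(snp_set)
    if len(rsids) < 2:
        raise ValidationError("pruning requires at least 2 SNPs")
    if mode not in ("single", "batch"):
        raise ValueError(f"unknown mode {mode!r}")
    F, y = _aligned_matrix(freqs, panel, rsids)
    if np.ptp(y) == 0.0:
        raise ValidationError("constant phenotype across populations; r2 undefined")

    active = np.ones(len(rsids), dtype=bool)
    initial_r2 = _r2_single(F.sum(axis=0), y)
    if np.isnan(initial_r2):
        raise ValidationError("full-set psPRS is constant across populations")
    current_r2 = initial_r2
    steps: list[tuple[str, float]] = []

    while active.sum() > 1:
        loo = _loo_r2(F, y, active)
        idx_active = np.flatnonzero(active)
        if mode == "single":
            valid = ~np.isnan(loo)
            if not valid.any():
                break
            best_pos = int(np.nanargmax(loo))  # first occurrence wins ties
            best_r2 = float(loo[best_pos])
            if best_r2 < current_r2:
                break
            ties = np.flatnonzero(valid & (loo == best_r2))
            if len(ties) > 1:
                logger.info(
                    "r2 tie among %d candidates; removing earliest input position",
                    len(ties),
                )
            removed = idx_active[best_pos]
            active[removed] = False
            current_r2 = best_r2
            steps.append((rsids[removed], best_r2))
        else:  # batch
            improving = np.flatnonzero(~np.isnan(loo) & (loo > current_r2))
            if len(improving) == 0:
                break
            if len(improving) >= active.sum():
                # keep at least one SNP: retain the one whose removal helps least
                order = improving[np.argsort(loo[improving], kind="stable")]
                improving = order[1:]
                logger.info("batch removal truncated to keep a non-empty retained set")
            removed_global = idx_active[improving]
            active[removed_global] = False
            current_r2 = _r2_single(F[active].sum(axis=0), y)
            for g in removed_global:
                steps.append((rsids[g], float(current_r2)))

    retained = frozenset(r for r, a in zip(rsids, active) if a)
    return PruningTrace(
        steps=tuple(steps),
        initial_r2=float(initial_r2),
        final_r2=float(current_r2),
        retained=retained,
    )


def exhaustive_best_subset(
    freqs: FrequencyMatrix, panel: PopulationPanel, snp_set: Iterable[str]
) -> tuple[frozenset[str], float]:
    """Enumerate all non-empty subsets and return the r2-maximising one.

    Intended as a ground-truth check of the greedy procedure on small
    sets; refuses more than ``EXHAUSTIVE_MAX_SNPS`` SNPs. Ties break
    toward the larger subset, then lexicographically smallest sorted
    rsid tuple.
    """
    rsids = _ordered_rsids(snp_set)
    n = len(rsids)
    if n == 0:
        raise ValidationError("empty SNP set")
    if n > EXHAUSTIVE_MAX_SNPS:
        raise ValidationError(
            f"exhaustive search limited to {EXHAUSTIVE_MAX_SNPS} SNPs, got {n}"
        )
    F, y = _aligned_matrix(freqs, panel, rsids)
    best: tuple[frozenset[str], float] | None = None
    best_size = -1
    best_names: tuple[str, ...] = ()
    for size in range(1, n + 1):
        for combo in itertools.combinations(range(n), size):
            r2 = _r2_single(F[list(combo)].sum(axis=0), y)
            if np.isnan(r2):
                continue
            names = tuple(sorted(rsids[i] for i in combo))
            if (
                best is None
                or r2 > best[1]
                or (r2 == best[1] and (size > best_size or (size == best_size and names < best_names)))
            ):
                best = (frozenset(names), float(r2))
                best_size = size
                best_names = names
    if best is None:
        raise ValidationError("no subset yields a defined r2 (all scores constant)")
    return best
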