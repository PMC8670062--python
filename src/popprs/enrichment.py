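"""Follow-up statistics on pruned psPRS SNP sets.

Three questions about what the r2-maximization pruning selects:

* does it enrich for genome-wide-significant GWAS hits (Fisher exact
  test on a significant-vs-not by unfiltered-vs-filtered 2x2 table)?
* does it shift the allele-frequency distribution (Welch t-test on
  per-SNP mean frequencies of full vs pruned sets)?
* what fraction of the input SNPs were discovered in European-descent
  cohorts (the ancestry-bias context for transferability)?
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .exceptions import ValidationError
from .io_formats import FrequencyMatrix, SnpAnnotation

#: GWAS genome-wide significance threshold.
GENOME_WIDE_SIGNIFICANCE = 5e-8

# relative slack when comparing point probabilities, as in R's fisher.test
_REL_TOL = 1 + 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: rows significant/not, columns unfiltered/filtered set."""

    a: int  # significant, unfiltered
    b: int  # significant, filtered
    c: int  # not significant, unfiltered
    d: int  # not significant, filtered

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in counts):
            raise ValidationError(f"negative count in 2x2 table: {counts}")
        if sum(counts) == 0:
            raise ValidationError("all-zero 2x2 table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def significance_table(
    annotations: Sequence[SnpAnnotation],
    retained: Iterable[str],
    threshold: float = GENOME_WIDE_SIGNIFICANCE,
) -> ContingencyTable2x2:
    """Cross-tabulate discovery p <= threshold against unfiltered vs retained.

    The filtered column counts the retained (pruned) set; the unfiltered
    column counts the full annotated set, so with ``retained`` equal to
    the full set the two columns coincide.
    """
    retained = set(retained)
    annotated = {a.rsid for a in annotations}
    orphans = sorted(retained - annotated)
    if orphans:
        raise ValidationError(f"retained rsids without annotation: {orphans}")
    sig = {a.rsid for a in annotations if a.discovery_p <= threshold}
    return ContingencyTable2x2(
        a=len(sig),
        b=len(sig & retained),
        c=len(annotated - sig),
        d=len(retained - sig),
    )


def fisher_2x2(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value by point-probability enumeration.

    With margins fixed, every admissible table corresponds to one value
    of the top-left count ``k``, hypergeometrically distributed. The
    two-sided p is the sum of probabilities of all tables whose point
    probability does not exceed the observed one — the convention of
    mainstream statistical software. Computed in log space for
    stability at large counts.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    k = np.arange(lo, hi + 1)
    # log hypergeometric pmf: C(row1, k) C(n - row1, col1 - k) / C(n, col1)
    lg = gammaln
    logpmf = (
        lg(row1 + 1) - lg(k + 1) - lg(row1 - k + 1)
        + lg(n - row1 + 1) - lg(col1 - k + 1) - lg(n - row1 - col1 + k + 1)
        - (lg(n + 1) - lg(col1 + 1) - lg(n - col1 + 1))
    )
    log_obs = logpmf[a - lo]
    p = float(np.exp(logpmf[logpmf <= log_obs + math.log(_REL_TOL)]).sum())
    return min(p, 1.0)


class FreqMeanComparison(NamedTuple):
    mean_a: float
    mean_b: float
    p_value: float


def compare_freq_means(
    freqs: FrequencyMatrix, set_a: Iterable[str], set_b: Iterable[str]
) -> FreqMeanComparison:
    """Compare mean allele frequency between two SNP sets.

    The per-SNP mean frequency across all populations is the unit of
    analysis; the two collections of per-SNP means are compared with a
    two-sided Welch (unequal-variance) t-test. With a singleton set the
    means are still returned and the p-value is NaN (undefined).
    """
    means = {}
    for name, rsids in (("a", set_a), ("b", set_b)):
        rsids = list(dict.fromkeys(rsids))
        if not rsids:
            raise ValidationError(f"set_{name} is empty")
        sub = freqs.subset(rsids).values
        if sub.isna().any().any():
            bad = sorted(sub.index[sub.isna().any(axis=1)])
            raise ValidationError(f"set_{name} has incomplete SNPs: {bad}")
        means[name] = sub.mean(axis=1).to_numpy(dtype=float)
    mean_a = float(means["a"].mean())
    mean_b = float(means["b"].mean())
    if len(means["a"]) < 2 or len(means["b"]) < 2:
        return FreqMeanComparison(mean_a, mean_b, float("nan"))
    t = stats.ttest_ind(means["a"], means["b"], equal_var=False)
    return FreqMeanComparison(mean_a, mean_b, float(t.pvalue))


def percent_discovery_ancestry(annotations: Sequence[SnpAnnotation]) -> float:
    """Percentage of SNPs discovered in European-descent cohorts.

    Rounded to 2 decimals for reporting.
    """
    if not annotations:
        raise ValidationError("empty annotation list")
    n_eur = sum(a.discovery_ancestry_european for a in annotations)
    return round(100.0 * n_eur / len(annotations), 2)
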