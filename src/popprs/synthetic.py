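"""Synthetic frequency panels and phenotypes with known ground truth.

The generator emulates the statistical structure the psPRS analysis
assumes about its real inputs:

* a hierarchical allele-frequency panel — populations nested in
  super-populations (26 in 5 by default, mirroring the 1000 Genomes
  panel) with Balding–Nichols differentiation: for each SNP an
  ancestral frequency p is drawn uniformly on (0.05, 0.95), each
  super-population draws its frequency from a Beta distribution with
  mean p and variance Fst * p * (1 - p), and each population adds a
  small clamped perturbation to its super-population value;
* an additive phenotype — a designated "universal" SNP subset drives
  the trait through the summed frequency s = sum of universal-SNP
  frequencies, passed through a linear, second-order polynomial or
  exponential link, plus Gaussian noise. Non-universal (decoy) SNPs
  carry either no effect or a population-specific one (their effect
  sign flips between super-populations), the mechanism that makes a
  SNP reduce cross-population predictability and thus gives the
  pruning procedure something real to remove.

Every artifact is a pure function of :class:`SyntheticConfig`; all
randomness flows through one seeded generator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io_formats import FrequencyMatrix, PopulationPanel, SnpAnnotation

logger = logging.getLogger(__name__)

#: The 26 populations of the 1000 Genomes panel, grouped by
#: super-population; used verbatim when the configured counts match.
THOUSAND_GENOMES_PANEL: tuple[tuple[str, str], ...] = (
    ("ACB", "AFR"), ("ASW", "AFR"), ("ESN", "AFR"), ("GWD", "AFR"),
    ("LWK", "AFR"), ("MSL", "AFR"), ("YRI", "AFR"),
    ("CLM", "AMR"), ("MXL", "AMR"), ("PEL", "AMR"), ("PUR", "AMR"),
    ("CDX", "EAS"), ("CHB", "EAS"), ("CHS", "EAS"), ("JPT", "EAS"),
    ("KHV", "EAS"),
    ("CEU", "EUR"), ("FIN", "EUR"), ("GBR", "EUR"), ("IBS", "EUR"),
    ("TSI", "EUR"),
    ("BEB", "SAS"), ("GIH", "SAS"), ("ITU", "SAS"), ("PJL", "SAS"),
    ("STU", "SAS"),
)

_SUPER_LABELS = ("AFR", "AMR", "EAS", "EUR", "SAS")

LinkKind = Literal["linear", "poly2", "exponential"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic study.

    Defaults describe a modest polygenic trait on the 26-population
    panel: 100 SNPs, half universal, Fst = 0.1 (continental-scale
    differentiation), a linear prevalence link with slope 0.02 per unit
    summed frequency and baseline 0.1, and phenotype noise of 0.01.
    """

    seed: int = 0
    n_populations: int = 26
    n_super: int = 5
    n_snps: int = 100
    frac_universal: float = 0.5
    fst: float = 0.1
    beta: float = 0.02
    beta2: float = 0.0
    intercept: float = 0.1
    noise_sd: float = 0.01
    link: LinkKind = "linear"
    decoy_beta: float = 0.0
    within_sd: float = 0.01  # population-level perturbation around super-population freq
    phenotype_kind: Literal["prevalence", "quantitative"] = "prevalence"

    def __post_init__(self) -> None:
        if min(self.n_populations, self.n_super, self.n_snps) < 1:
            raise ValidationError("counts must be >= 1")
        if self.n_super > self.n_populations:
            raise ValidationError("more super-populations than populations")
        if not 0.0 < self.fst < 1.0:
            raise ValidationError("fst must lie in (0, 1)")
        if not 0.0 <= self.frac_universal <= 1.0:
            raise ValidationError("frac_universal must lie in [0, 1]")
        if self.link not in ("linear", "poly2", "exponential"):
            raise ValidationError(f"unknown link {self.link!r}")
        if self.noise_sd < 0 or self.within_sd < 0:
            raise ValidationError("noise/perturbation SDs must be >= 0")


def population_codes(config: SyntheticConfig) -> list[tuple[str, str]]:
    """(population, super-population) pairs for a config.

    The real 1000 Genomes codes are used when the configured counts
    match that panel; otherwise synthetic codes POP01..., with
    populations split over super-populations as evenly as possible.
    """
    if config.n_populations == 26 and config.n_super == 5:
        return list(THOUSAND_GENOMES_PANEL)
    supers = [
        _SUPER_LABELS[i] if config.n_super <= 5 else f"SUP{i + 1:02d}"
        for i in range(config.n_super)
    ]
    pairs = []
    for i in range(config.n_populations):
        s = supers[i * config.n_super // config.n_populations]
        pairs.append((f"POP{i + 1:02d}", s))
    return pairs


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def generate_frequencies(config: SyntheticConfig) -> FrequencyMatrix:
    """Draw a Balding–Nichols-style SNP x population frequency panel."""
    rng = _rng(config, 0)
    pairs = population_codes(config)
    supers = sorted({s for _, s in pairs})
    ancestral = rng.uniform(0.05, 0.95, size=config.n_snps)
    shape = (1.0 - config.fst) / config.fst
    # Beta(p * shape, (1 - p) * shape): mean p, variance fst * p * (1 - p)
    super_freq = {
        s: rng.beta(ancestral * shape, (1.0 - ancestral) * shape) for s in supers
    }
    cols = {}
    for code, s in pairs:
        jitter = rng.normal(0.0, config.within_sd, size=config.n_snps)
        cols[code] = np.clip(super_freq[s] + jitter, 0.0, 1.0)
    snp_ids = [f"rs{100000 + i}" for i in range(config.n_snps)]
    values = pd.DataFrame(cols, index=pd.Index(snp_ids, name="rsid"), dtype=float)
    return FrequencyMatrix(values)


def generate_phenotype(
    freqs: FrequencyMatrix, config: SyntheticConfig
) -> tuple[PopulationPanel, frozenset[str]]:
    """Generate a phenotype panel from a frequency matrix.

    Returns the panel and the ground-truth universal SNP set. The
    phenotype is built from s = sum of universal-SNP frequencies per
    population through the configured link, plus decoy contributions
    (sign-flipped per super-population when ``decoy_beta`` is nonzero)
    and additive Gaussian noise. Prevalence-kind phenotypes are clipped
    to [0, 1] with a logged count.
    """
    rng = _rng(config, 1)
    n_universal = int(round(config.frac_universal * config.n_snps))
    if n_universal < 1:
        raise ValidationError("frac_universal * n_snps must be >= 1")
    snp_ids = freqs.snp_ids
    universal_idx = np.sort(rng.choice(len(snp_ids), size=n_universal, replace=False))
    universal = frozenset(snp_ids[i] for i in universal_idx)

    pairs = population_codes(config)
    code_order = [c for c, _ in pairs if c in freqs.population_codes]
    if len(code_order) != len(freqs.population_codes):
        code_order = freqs.population_codes  # user-supplied matrix
        super_of = dict(pairs)
    else:
        super_of = dict(pairs)
    F = freqs.values[code_order].to_numpy(dtype=float)
    is_universal = np.zeros(len(snp_ids), dtype=bool)
    is_universal[universal_idx] = True
    s = F[is_universal].sum(axis=0)

    eta = config.intercept + config.beta * s
    if config.link == "poly2":
        eta = eta + config.beta2 * s**2
    if config.decoy_beta != 0.0 and (~is_universal).any():
        supers = sorted({super_of.get(c, "NA") for c in code_order})
        super_idx = np.array(
            [supers.index(super_of.get(c, "NA")) for c in code_order]
        )
        # each decoy's effect sign alternates across super-populations,
        # with the phase alternating across decoys: every decoy is
        # inconsistent between ancestries and the aggregate decoy
        # contribution carries no net alignment with the phenotype
        decoy_rows = np.flatnonzero(~is_universal)
        signs = np.fromfunction(
            lambda j, s: (-1.0) ** (j + s), (len(decoy_rows), len(supers))
        )
        per_pop_signs = signs[:, super_idx]  # decoy x population
        eta = eta + config.decoy_beta * (per_pop_signs * F[decoy_rows]).sum(axis=0)
    if config.link == "exponential":
        with np.errstate(over="raise"):
            try:
                y = np.exp(eta)
            except FloatingPointError:
                raise ValidationError(
                    "exponential link overflows for the configured parameters"
                ) from None
    else:
        y = eta
    if config.noise_sd > 0:
        y = y + rng.normal(0.0, config.noise_sd, size=len(y))

    if config.phenotype_kind == "prevalence":
        clipped = int(((y < 0) | (y > 1)).sum())
        if clipped:
            logger.info("clipped %d prevalence values into [0, 1]", clipped)
        y = np.clip(y, 0.0, 1.0)

    table = pd.DataFrame(
        {
            "super_population": [super_of.get(c, "AFR") for c in code_order],
            "phenotype_value": y,
            "phenotype_kind": config.phenotype_kind,
            "sex_stratum": "combined",
        },
        index=pd.Index(code_order, name="code"),
    )
    return PopulationPanel(table), universal


def generate_annotations(
    config: SyntheticConfig,
    freqs: FrequencyMatrix | None = None,
    n_chromosomes: int = 22,
    chromosome_length: int = 50_000_000,
    frac_significant: float = 0.5,
    frac_european: float = 0.8,
) -> list[SnpAnnotation]:
    """Synthetic GWAS annotations for the panel's SNPs.

    Positions are uniform over ``n_chromosomes`` chromosomes of equal
    length; discovery p-values are log-uniform below the inclusion
    threshold, with ``frac_significant`` of SNPs pushed below
    genome-wide significance (5e-8). Useful for exercising spacing and
    enrichment analyses offline.
    """
    rng = _rng(config, 2)
    snp_ids = freqs.snp_ids if freqs is not None else [
        f"rs{100000 + i}" for i in range(config.n_snps)
    ]
    anns = []
    for rsid in snp_ids:
        chrom = str(int(rng.integers(1, n_chromosomes + 1)))
        pos = int(rng.integers(1, chromosome_length))
        if rng.random() < frac_significant:
            logp = rng.uniform(8.0, 30.0)  # below 5e-8
        else:
            logp = rng.uniform(5.5, 7.0)  # suggestive but not genome-wide
        anns.append(
            SnpAnnotation(
                rsid=rsid,
                chromosome=chrom,
                position=pos,
                risk_allele=str(rng.choice(["A", "C", "G", "T"])),
                discovery_p=float(10.0 ** -logp),
                discovery_ancestry_european=bool(rng.random() < frac_european),
                trait_id="synthetic",
            )
        )
    return anns
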