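"""Readers, writers and domain containers for the psPRS pipeline.

The pipeline consumes three kinds of tables, all tab-separated with a
mandatory header row ("." or an empty cell means missing):

* association tables — one GWAS risk variant per row (rsID, chromosome,
  position, risk allele, discovery p-value, discovery ancestry);
* frequency matrices — risk-allele frequencies, SNPs in rows and
  population codes in columns;
* population panels — population code, super-population, phenotype value
  (a prevalence proportion or a mean quantitative value such as height
  in cm), phenotype kind and sex stratum.

When no frequency matrix is available, :func:`frequencies_from_vcf`
computes risk-allele frequencies directly from a multi-sample VCF and a
sample-to-population map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

logger = logging.getLogger(__name__)

SUPER_POPULATIONS = ("AFR", "AMR", "EAS", "EUR", "SAS")
_VALID_BASES = frozenset("ACGT")
_VALID_CHROMOSOMES = frozenset([str(i) for i in range(1, 23)] + ["X"])

#: GWAS-Catalog inclusion threshold: variants with discovery p at or above
#: this value are dropped on read.
DEFAULT_P_THRESHOLD = 1e-5


def _normalize_chromosome(raw: str) -> str:
    chrom = str(raw).strip()
    if chrom.lower().startswith("chr"):
        chrom = chrom[3:]
    chrom = chrom.upper() if chrom.upper() == "X" else chrom
    if chrom not in _VALID_CHROMOSOMES:
        raise FormatError(f"unrecognized chromosome label {raw!r}")
    return chrom


@dataclass(frozen=True)
class SnpAnnotation:
    """One GWAS risk variant.

    ``discovery_ancestry_european`` records whether the association was
    discovered in a European-descent cohort, the classification used by
    discovery-ancestry percentage summaries.
    """

    rsid: str
    chromosome: str
    position: int
    risk_allele: str
    discovery_p: float
    discovery_ancestry_european: bool
    trait_id: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(f"{self.rsid}: position must be >= 1")
        if self.risk_allele not in _VALID_BASES:
            raise ValidationError(
                f"{self.rsid}: risk allele must be one of A/C/G/T, got "
                f"{self.risk_allele!r}"
            )
        if not 0.0 < self.discovery_p <= 1.0:
            raise ValidationError(
                f"{self.rsid}: discovery p-value {self.discovery_p} outside (0, 1]"
            )


@dataclass(frozen=True)
class FrequencyMatrix:
    """SNP x population risk-allele frequencies in [0, 1], NaN = missing.

    A SNP with any missing population entry is "incomplete"; scoring
    excludes incomplete SNPs for all populations so that scores stay
    comparable across populations.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValidationError(f"duplicate rsid rows: {dups}")
        if self.values.columns.has_duplicates:
            raise ValidationError("duplicate population columns")
        arr = self.values.to_numpy(dtype=float)
        bad = (arr < 0.0) | (arr > 1.0)
        if np.any(bad & ~np.isnan(arr)):
            snp_idx, pop_idx = np.argwhere(bad & ~np.isnan(arr))[0]
            raise ValidationError(
                f"frequency outside [0, 1] at SNP {self.values.index[snp_idx]!r}, "
                f"population {self.values.columns[pop_idx]!r}: {arr[snp_idx, pop_idx]}"
            )

    @property
    def snp_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def population_codes(self) -> list[str]:
        return list(self.values.columns)

    def complete_snps(self) -> list[str]:
        """rsids with a frequency in every population."""
        mask = self.values.notna().all(axis=1)
        return list(self.values.index[mask])

    def incomplete_snps(self) -> list[str]:
        mask = self.values.isna().any(axis=1)
        return list(self.values.index[mask])

    def subset(self, rsids: Iterable[str]) -> "FrequencyMatrix":
        rsids = list(rsids)
        missing = [r for r in rsids if r not in self.values.index]
        if missing:
            raise ValidationError(f"rsids not in frequency matrix: {missing}")
        return FrequencyMatrix(self.values.loc[rsids].copy())


@dataclass(frozen=True)
class PopulationPanel:
    """Population codes with super-population labels and phenotype values.

    ``phenotype_kind`` is "prevalence" (a proportion in [0, 1]) or
    "quantitative" (e.g. mean height in cm).
    """

    table: pd.DataFrame  # index: code; columns: super_population,
    # phenotype_value, phenotype_kind, sex_stratum

    def __post_init__(self) -> None:
        required = {"super_population", "phenotype_value", "phenotype_kind", "sex_stratum"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"panel missing columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].tolist()
            raise ValidationError(f"duplicate population codes: {dups}")
        bad_super = set(self.table["super_population"]) - set(SUPER_POPULATIONS)
        if bad_super:
            raise ValidationError(f"unknown super-population labels: {sorted(bad_super)}")
        bad_kind = set(self.table["phenotype_kind"]) - {"prevalence", "quantitative"}
        if bad_kind:
            raise ValidationError(f"unknown phenotype kinds: {sorted(bad_kind)}")
        prev = self.table[self.table["phenotype_kind"] == "prevalence"]
        out = prev[(prev["phenotype_value"] < 0) | (prev["phenotype_value"] > 1)]
        if len(out):
            raise ValidationError(
                "prevalence outside [0, 1] for populations: "
                f"{out.index.tolist()} (values {out['phenotype_value'].tolist()})"
            )

    @property
    def codes(self) -> list[str]:
        return list(self.table.index)

    @property
    def phenotype_values(self) -> pd.Series:
        return self.table["phenotype_value"]

    def super_population_of(self, code: str) -> str:
        return str(self.table.loc[code, "super_population"])

    def subset(self, codes: Iterable[str]) -> "PopulationPanel":
        codes = list(codes)
        return PopulationPanel(self.table.loc[codes].copy())


_ASSOC_ALIASES = {
    "rsid": {"rsid", "rs_id", "snp", "snp_id", "variant"},
    "chromosome": {"chromosome", "chrom", "chr"},
    "position": {"position", "pos", "bp", "base_pair"},
    "risk_allele": {"risk_allele", "riskallele", "allele"},
    "p_value": {"p_value", "pvalue", "p", "discovery_p"},
    "discovery_ancestry": {"discovery_ancestry", "ancestry", "discovery_population"},
}


def _resolve_assoc_columns(columns: Sequence[str]) -> dict[str, str]:
    lowered = {c.lower().replace("-", "_").replace(" ", "_"): c for c in columns}
    resolved: dict[str, str] = {}
    for canonical, aliases in _ASSOC_ALIASES.items():
        hit = next((lowered[a] for a in aliases if a in lowered), None)
        if hit is None:
            raise FormatError(f"association table missing required column: {canonical}")
        resolved[canonical] = hit
    return resolved


def read_association_table(
    path: str | Path,
    trait_id: str,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> list[SnpAnnotation]:
    """Read a GWAS-Catalog-style association TSV.

    Rows with discovery p-value at or above ``p_threshold`` are dropped
    (logged); duplicate rsids collapse to the record with the smallest
    discovery p-value.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["", "."])
    cols = _resolve_assoc_columns(df.columns)
    annotations: list[SnpAnnotation] = []
    n_dropped = 0
    for i, row in df.iterrows():
        line_no = int(i) + 2  # header is line 1
        raw_p = row[cols["p_value"]]
        try:
            p = float(raw_p)
        except (TypeError, ValueError):
            raise FormatError(
                f"{path}, line {line_no}: unparsable p-value {raw_p!r}"
            ) from None
        if not p < p_threshold:
            n_dropped += 1
            continue
        ancestry = str(row[cols["discovery_ancestry"]]).strip().lower()
        annotations.append(
            SnpAnnotation(
                rsid=str(row[cols["rsid"]]).strip(),
                chromosome=_normalize_chromosome(row[cols["chromosome"]]),
                position=int(row[cols["position"]]),
                risk_allele=str(row[cols["risk_allele"]]).strip().upper(),
                discovery_p=p,
                discovery_ancestry_european=ancestry.startswith("eur"),
                trait_id=trait_id,
            )
        )
    if n_dropped:
        logger.info(
            "%s: dropped %d rows at p >= %g", path, n_dropped, p_threshold
        )
    best: dict[str, SnpAnnotation] = {}
    for ann in annotations:
        kept = best.get(ann.rsid)
        if kept is None or ann.discovery_p < kept.discovery_p:
            best[ann.rsid] = ann
    if len(best) != len(annotations):
        logger.info(
            "%s: collapsed %d duplicate rsids", path, len(annotations) - len(best)
        )
    # preserve first-appearance order
    seen: list[SnpAnnotation] = []
    emitted: set[str] = set()
    for ann in annotations:
        if ann.rsid not in emitted:
            seen.append(best[ann.rsid])
            emitted.add(ann.rsid)
    return seen


def read_frequency_matrix(path: str | Path) -> FrequencyMatrix:
    """Read a SNP x population frequency TSV (first column rsid)."""
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["", "."])
    if df.columns[0].lower() not in {"rsid", "rs_id", "snp", "snp_id"}:
        raise FormatError(
            f"first column of a frequency matrix must be the rsid, got {df.columns[0]!r}"
        )
    df = df.set_index(df.columns[0])
    df.index.name = "rsid"
    values = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        for rsid, cell in df[col].items():
            if pd.isna(cell):
                continue
            try:
                values.loc[rsid, col] = float(cell)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric cell at SNP {rsid!r}, population {col!r}: {cell!r}"
                ) from None
    fm = FrequencyMatrix(values)
    if fm.incomplete_snps():
        logger.info(
            "%s: %d SNPs with missing entries flagged incomplete",
            path,
            len(fm.incomplete_snps()),
        )
    return fm


def write_frequency_matrix(freqs: FrequencyMatrix, path: str | Path) -> None:
    out = freqs.values.copy()
    out.index.name = "rsid"
    out.to_csv(path, sep="\t", na_rep=".")


def read_population_panel(path: str | Path) -> PopulationPanel:
    """Read a population phenotype panel TSV.

    Scientific-notation prevalence strings (e.g. ``1.04e-3``) parse
    exactly via float conversion.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["", "."])
    required = ["code", "super_population", "phenotype_value", "phenotype_kind", "sex_stratum"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"population panel missing columns: {missing}")
    df = df.dropna(subset=["phenotype_value"])
    table = pd.DataFrame(
        {
            "super_population": df["super_population"].str.strip().to_numpy(),
            "phenotype_value": df["phenotype_value"].astype(float).to_numpy(),
            "phenotype_kind": df["phenotype_kind"].str.strip().to_numpy(),
            "sex_stratum": df["sex_stratum"].str.strip().to_numpy(),
        },
        index=pd.Index(df["code"].str.strip().to_numpy(), name="code"),
    )
    return PopulationPanel(table)


def write_population_panel(panel: PopulationPanel, path: str | Path) -> None:
    out = panel.table.copy()
    out.index.name = "code"
    out.to_csv(path, sep="\t")


def frequencies_from_vcf(
    vcf: str | Path,
    sample_map: Mapping[str, str],
    annotations: Sequence[SnpAnnotation],
) -> FrequencyMatrix:
    """Compute per-population risk-allele frequencies from a VCF.

    Only GT is consumed. The risk allele is oriented against REF/ALT:
    when it equals ALT the ALT-allele frequency is reported, when it
    equals REF the REF-allele frequency (1 - ALT frequency among called
    alleles). Multi-allelic records and records whose alleles match
    neither REF nor ALT are excluded (logged); SNPs absent from the VCF
    are returned as missing in every population.
    """
    import pysam

    populations = sorted(set(sample_map.values()))
    by_site: dict[tuple[str, int], list[SnpAnnotation]] = {}
    for ann in annotations:
        by_site.setdefault((ann.chromosome, ann.position), []).append(ann)

    values = pd.DataFrame(
        np.nan,
        index=pd.Index([a.rsid for a in annotations], name="rsid"),
        columns=populations,
        dtype=float,
    )

    with pysam.VariantFile(str(vcf)) as vf:
        vcf_samples = list(vf.header.samples)
        unknown = [s for s in sample_map if s not in vcf_samples]
        if unknown:
            raise ValidationError(f"samples absent from VCF: {unknown}")
        for rec in vf:
            key = (_normalize_chromosome(rec.chrom), rec.pos)
            hits = by_site.get(key)
            if not hits:
                continue
            alts = rec.alts or ()
            if len(alts) != 1:
                logger.info(
                    "excluding multi-allelic record at %s:%d", rec.chrom, rec.pos
                )
                continue
            ref, alt = rec.ref.upper(), alts[0].upper()
            for ann in hits:
                if ann.risk_allele == alt:
                    risk_is_alt = True
                elif ann.risk_allele == ref:
                    risk_is_alt = False
                else:
                    logger.info(
                        "excluding %s: risk allele %s matches neither REF %s nor ALT %s",
                        ann.rsid,
                        ann.risk_allele,
                        ref,
                        alt,
                    )
                    continue
                risk_counts: dict[str, int] = {p: 0 for p in populations}
                called: dict[str, int] = {p: 0 for p in populations}
                for sample, pop in sample_map.items():
                    gt = rec.samples[sample].get("GT")
                    if gt is None:
                        continue
                    for allele_idx in gt:
                        if allele_idx is None:
                            continue
                        called[pop] += 1
                        is_alt = allele_idx > 0
                        if is_alt == risk_is_alt:
                            risk_counts[pop] += 1
                for pop in populations:
                    if called[pop]:
                        values.loc[ann.rsid, pop] = risk_counts[pop] / called[pop]
    absent = [a.rsid for a in annotations if values.loc[a.rsid].isna().all()]
    if absent:
        logger.info("%d SNPs absent or unresolvable in VCF: %s", len(absent), absent)
    return FrequencyMatrix(values)
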