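"""Bundled curated data for the four studied traits.

The package ships the small published summary tables the analysis
consumes directly:

* per-population phenotype values (prevalence proportions, or mean
  height in cm) for lactase persistence, melanoma, multiple sclerosis
  and male/female height across the 1000 Genomes populations;
* the genome-wide-significance enrichment 2x2 tables for the
  unfiltered vs pruned SNP sets of each trait;
* discovery-ancestry counts (European vs non-European discovery
  cohorts) and the full/pruned SNP-set sizes.

The per-SNP allele-frequency panels underlying the psPRS values are
published as supplementary spreadsheets and are not redistributed
here; :func:`load_supplementary_frequencies` reads them from a local
directory if the user has downloaded them.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .enrichment import ContingencyTable2x2
from .exceptions import ValidationError
from .io_formats import PopulationPanel, FrequencyMatrix, read_frequency_matrix

TRAITS = (
    "lactase_persistence",
    "melanoma",
    "multiple_sclerosis",
    "height_male",
    "height_female",
)

#: Unfiltered/filtered SNP counts split by genome-wide significance
#: (discovery p <= 5e-8) for each trait, as (a, b, c, d) =
#: (significant unfiltered, significant filtered,
#:  not-significant unfiltered, not-significant filtered).
SIGNIFICANCE_TABLES: dict[str, ContingencyTable2x2] = {
    "melanoma": ContingencyTable2x2(27, 12, 10, 4),
    "multiple_sclerosis": ContingencyTable2x2(199, 71, 169, 60),
    "height_male": ContingencyTable2x2(3552, 478, 656, 69),
    "height_female": ContingencyTable2x2(3552, 188, 656, 0),
}

#: (European-discovered, non-European-discovered) SNP counts per trait.
DISCOVERY_ANCESTRY_COUNTS: dict[str, tuple[int, int]] = {
    "lactase_persistence": (2, 9),
    "height": (3422, 786),
    "multiple_sclerosis": (366, 2),
    "melanoma": (37, 0),
}

#: (SNPs scored in the panel, SNPs retained after r2-maximization).
PRUNING_SET_SIZES: dict[str, tuple[int, int]] = {
    "lactase_persistence": (11, 4),
    "melanoma": (37, 16),
    "multiple_sclerosis": (368, 131),
    "height_male": (4209, 547),
    "height_female": (4209, 188),
}


def load_population_phenotypes(trait: str) -> PopulationPanel:
    """Load the curated phenotype panel for one trait.

    Populations without a published value for that trait are absent
    from the returned panel.
    """
    if trait not in TRAITS:
        raise ValidationError(f"unknown trait {trait!r}; choose from {TRAITS}")
    with resources.files("popprs.data").joinpath("population_phenotypes.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"phenotype_value": float})
    df = df[df["trait"] == trait].drop(columns="trait").set_index("code")
    return PopulationPanel(df)


def load_supplementary_frequencies(trait: str, directory: str | Path) -> FrequencyMatrix:
    """Read a locally stored per-trait allele-frequency panel.

    Expects ``<directory>/<trait>_frequencies.tsv`` in the standard
    frequency-matrix layout (first column rsid, one column per
    population code).
    """
    path = Path(directory) / f"{trait}_frequencies.tsv"
    if not path.exists():
        raise FileNotFoundError(
            f"allele-frequency panel for {trait!r} not found at {path}; "
            "these per-SNP panels are published as supplementary spreadsheets "
            "and are not bundled with the package"
        )
    return read_frequency_matrix(path)
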