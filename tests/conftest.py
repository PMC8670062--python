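"""Shared fixtures: small frequency/panel builders and exact oracles."""

from __future__ import annotations

from fractions import Fraction
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from popprs import FrequencyMatrix, PopulationPanel

#: Directory where users may place the published per-trait
#: allele-frequency panels (not bundled with the repository).
EXTERNAL_DATA_DIR = Path(__file__).resolve().parents[1] / "data" / "external"


@pytest.fixture
def make_freqs():
    """Build a FrequencyMatrix from {rsid: [freq per population]}."""

    def _make(freqs: dict[str, list[float]], populations: list[str] | None = None):
        n_pop = len(next(iter(freqs.values())))
        pops = populations or [f"POP{i + 1:02d}" for i in range(n_pop)]
        values = pd.DataFrame.from_dict(freqs, orient="index", columns=pops, dtype=float)
        values.index.name = "rsid"
        return FrequencyMatrix(values)

    return _make


@pytest.fixture
def make_panel():
    """Build a PopulationPanel from phenotype values (+ optional supers)."""

    def _make(
        values: list[float],
        populations: list[str] | None = None,
        supers: list[str] | None = None,
        kind: str = "quantitative",
    ):
        pops = populations or [f"POP{i + 1:02d}" for i in range(len(values))]
        sup = supers or ["AFR"] * len(values)
        table = pd.DataFrame(
            {
                "super_population": sup,
                "phenotype_value": values,
                "phenotype_kind": kind,
                "sex_stratum": "combined",
            },
            index=pd.Index(pops, name="code"),
        )
        return PopulationPanel(table)

    return _make


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Exact-rational two-sided Fisher p by direct table enumeration.

    Enumerates every 2x2 table with the observed margins and sums the
    probabilities of those whose point probability does not exceed the
    observed one (with the same 1e-7 relative slack the implementation
    uses for ties). Integer arithmetic throughout.
    """
    n = a + b + c + d
    row1, col1 = a + b, a + c
    denom = comb(n, col1)
    num_obs = comb(row1, a) * comb(n - row1, col1 - a)
    tol = Fraction(10**7 + 1, 10**7)
    total = 0
    for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        num_k = comb(row1, k) * comb(n - row1, col1 - k)
        if Fraction(num_k) <= num_obs * tol:
            total += num_k
    return Fraction(total, denom)


@pytest.fixture
def fisher_oracle():
    return fisher_two_sided_exact
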