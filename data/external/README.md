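# External allele-frequency panels

The per-SNP, per-population risk-allele frequency panels for the four
curated traits are published as supplementary spreadsheets alongside the
original study and are not redistributed in this repository.

To run the full published-result reproductions (in `tests/test_acceptance.py`
and the optional section of `scripts/acceptance.py`), export each panel as a
tab-separated file in this directory:

    lactase_persistence_frequencies.tsv
    melanoma_frequencies.tsv
    multiple_sclerosis_frequencies.tsv
    height_frequencies.tsv

Layout: first column `rsid`, one column per 1000 Genomes population code
(GBR, FIN, ...), cells as frequencies in [0, 1], "." or empty for missing.
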