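"""Physical spacing of SNP sets before and after pruning.

Physical proximity (pairs within 30.8 kb on the same chromosome)
serves as a linkage-disequilibrium proxy: if pruning removes redundant
LD partners, the pruned set should contain proportionally fewer nearby
pairs and show a larger mean adjacent-SNP distance.
"""

from popprs import (
    SyntheticConfig,
    compare_spacing,
    generate_annotations,
    generate_frequencies,
    generate_phenotype,
    prune_maximize_r2,
    spacing_summary,
)

cfg = SyntheticConfig(seed=11, n_snps=50, frac_universal=0.5, beta=1.0,
                      decoy_beta=0.5, noise_sd=0.1, phenotype_kind="quantitative")
freqs = generate_frequencies(cfg)
panel, _ = generate_phenotype(freqs, cfg)
annotations = generate_annotations(cfg, freqs, n_chromosomes=10,
                                   chromosome_length=2_000_000)

full = spacing_summary(annotations)
trace = prune_maximize_r2(freqs, panel, freqs.snp_ids)
pruned = spacing_summary(annotations, snp_set=sorted(trace.retained))

print(f"threshold: {full.threshold:,} bp")
print(f"full set   ({full.n_snps} SNPs): mean adjacent gap = "
      f"{full.overall_mean:,.0f} bp, {full.n_snps_within} SNPs in nearby pairs")
print(f"pruned set ({pruned.n_snps} SNPs): mean adjacent gap = "
      f"{pruned.overall_mean:,.0f} bp, {pruned.n_snps_within} SNPs in nearby pairs")

cmp = compare_spacing(full, pruned)
print(f"\nmean-gap change: {cmp.mean_change:+,.0f} bp")
print(f"proportion of SNPs within {full.threshold/1000:.1f} kb of another: "
      f"{cmp.proportion_within_full:.2f} -> {cmp.proportion_within_pruned:.2f}")
print("\nA positive gap change and a falling nearby proportion indicate the "
      "pruned set is more evenly spread across the genome.")
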