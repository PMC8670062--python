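"""Greedy r2-maximization pruning on a panel with misleading decoy SNPs.

Half of the SNPs drive the phenotype identically in every population
("universal"); the rest carry effects whose sign flips between
super-populations, so they add noise to the cross-population score.
The pruning procedure iteratively removes SNPs whose exclusion raises
the linear-fit r2, and should preferentially discard the decoys.
"""

from popprs import (
    SyntheticConfig,
    generate_frequencies,
    generate_phenotype,
    prune_maximize_r2,
)

cfg = SyntheticConfig(
    seed=7, n_snps=30, frac_universal=0.5, beta=1.0, decoy_beta=0.5,
    noise_sd=0.1, phenotype_kind="quantitative",
)
freqs = generate_frequencies(cfg)
panel, universal = generate_phenotype(freqs, cfg)

trace = prune_maximize_r2(freqs, panel, freqs.snp_ids)

print(f"input SNPs: {cfg.n_snps} ({len(universal)} truly universal)")
print(f"full-model r2:   {trace.initial_r2:.4f}")
print(f"pruned-model r2: {trace.final_r2:.4f}  ({len(trace.retained)} SNPs retained)")
kept_universal = len(trace.retained & universal)
print(f"universal SNPs retained: {kept_universal}/{len(trace.retained)} "
      f"({100 * kept_universal / len(trace.retained):.0f}% of the retained set)")
print("\nfirst removals (rsid, r2 after removal):")
for rsid, r2 in trace.steps[:5]:
    tag = "decoy" if rsid not in universal else "universal"
    print(f"  {rsid}  {r2:.4f}  [{tag}]")
print(
    "\nA rising r2 along the removal order means each discarded SNP was "
    "hurting cross-population predictability; retained-set enrichment for "
    "universal SNPs is the intended behaviour."
)
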