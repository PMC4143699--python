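"""Disjoint 100-kb window scan of a large gene with clustered causal variants.

The `map4_like` scenario plants a 239-kb gene across four absolute 100-kb
windows; its 9 causal rare variants cluster in two windows while neutral
rare variants dilute the rest of the span.  Scanning windows separately
recovers the signal that the whole-gene burden dilutes away.
"""

import fbatrare as fb

ds = fb.simulate_dataset(fb.make_gaw_like_scenario("map4_like", seed=1))
big = next(r for r in ds.regions if r.name == "BIG_GENE")
traits = ds.traits.replicate(1)
cfg = fb.TestConfig()  # v1 weights, MAF < 0.01, model variance

gene = fb.gene_test(ds.genotypes, ds.pedigree, big, traits, cfg)
print(f"gene-level  {big.name}: {gene.n_variants_collapsed} rare variants, "
      f"Z={gene.z:+.2f}, p={gene.p_two_sided:.2e}")

windows = fb.scan_region_windows(ds.genotypes, ds.pedigree, big, traits, cfg)
for w in windows:
    print(f"window {w.unit_name}: {w.n_variants_collapsed:2d} rare variants, "
          f"Z={w.z:+.2f}, p={w.p_two_sided:.2e}, Bonferroni p={w.p_bonferroni:.2e}")

best = min((w for w in windows if w.status == "ok"), key=lambda w: w.p_two_sided)
print(f"\nbest window {best.unit_name}: Bonferroni-adjusted p = {best.p_bonferroni:.2e} "
      f"vs gene-level p = {gene.p_two_sided:.2e}")
# Even after multiplying by the number of tested windows, the causal-dense
# window outperforms the diluted whole-gene test by orders of magnitude.
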