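"""Transcriptional burst inference with the two-state (telegraph) model.

Simulates per-cell allelic counts from the Poisson-beta steady state with
X-linked genes carrying a 1.19-fold burst-frequency (k_on) increase and a
0.82-fold burst-size (k_syn/k_off) decrease — the somatic active-X
signature — fits every gene by maximum likelihood and compares X against
autosomes.  (Scaled down from the 1800-gene experiment for a quick run.)
"""

import xdosage as xd

counts, params, x_genes, auto_genes = xd.simulate_burst_dataset(
    n_autosomal=300, n_x=100, n_cells=600,
    kon_fold_x=1.19, size_fold_x=0.82, seed=5)

fits = xd.fit_burst_table(counts, allele="cast")
print(f"converged fits: {int(fits['converged'].sum())}/{len(fits)}")

cmp = xd.compare_burst(fits, x_genes, auto_genes, allele="cast")
print(f"burst frequency fold (X/A): {cmp.fold_frequency:.3f} "
      f"(generative 1.19, rank-sum p = {cmp.p_frequency:.1e})")
print(f"burst size fold (X/A):      {cmp.fold_size:.3f} "
      f"(generative 0.82, rank-sum p = {cmp.p_size:.1e})")

print("\nThe fold of median k_on across genes recovers the planted "
      "burst-frequency increase on the active X, and the fold of median "
      "k_syn/k_off the planted burst-size decrease.")
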