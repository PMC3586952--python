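"""Site-rate stratification of a simulated alignment: assign every column to
one of 16 discrete-gamma rate categories, strip the fastest categories, and
partition columns by residue variability within the focal clade."""

from scipy.stats import spearmanr

from phyloscan import alignops
from phyloscan.simgen import evolve_alignment, fungal_species_tree

tree, groups = fungal_species_tree()
focal = [s for s, g in groups.items() if g == "Microsporidia"]

aln, truth = evolve_alignment(tree, n_columns=3000, gamma_shape=0.8,
                              n_categories=16, seed=9)
site_lnl = alignops.compute_site_loglik(aln, tree, gamma_shape=0.8,
                                        n_categories=16)
assignment = alignops.assign_rate_categories(site_lnl)
rho = spearmanr(truth.categories, assignment.categories).statistic
print(f"columns: {aln.n_sites}; Spearman(planted, assigned category) = "
      f"{rho:.3f}")

print(f"{'k fastest removed':>18} {'columns kept':>13} "
      f"{'mean planted rate':>18}")
for k in (0, 2, 4, 6, 8):
    kept = alignops.remove_fastest_sites(aln, assignment, k)
    mask = assignment.categories <= 16 - k
    print(f"{k:>18} {kept.n_sites:>13} {truth.rates[mask].mean():>18.3f}")

parts = alignops.partition_by_clade_variability(aln, focal)
sizes = {b: p.n_sites for b, p in parts.items()}
print(f"\nfocal-clade variability partitions (1: <=2 residues ... 4: >=5): "
      f"{sizes}")

recoded = alignops.recode_alphabet(aln)
symbols = sorted(str(s) for s in set(recoded.data.ravel()) - {"-"})
print(f"four-letter recoding symbols: {symbols}")
print("\nRemoving the fastest categories lowers the mean true rate of the"
      "\nsurviving columns — the stratification the saturation analyses"
      " rely on.")
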