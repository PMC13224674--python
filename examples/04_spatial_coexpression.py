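"""Spatial ligand-receptor co-expression with confounder adjustment.

Simulates the 60-segment design (two tissues x three sorted compartments,
slides of 24/24/12), Q3-normalizes the segments, screens ligand-receptor
pairs for co-expression (Spearman rho > 0.7, BH q < 0.001), and re-tests
the top pair controlling for a composite immune score — the check that a
"co-expression" signal is not just shared immune content.
"""

import nichecompare as nc

config = nc.SimConfig(n_genes=400)
segments, truth = nc.simulate_segments(config, seed=7)
segments = nc.qc_filter_segments(segments)        # detection rate > 30%
print(f"segments passing QC: {segments.n_obs} (expected all 60)")

norm = nc.log_segments(nc.q3_normalize(segments))
pairs = [(p["ligand"], p["receptor"]) for p in truth.lr_pairs]
genes = sorted({g for pair in pairs for g in pair})
records = nc.spearman_matrix(norm, genes)
screen = nc.ligand_receptor_screen(records, pairs)
print("\nligand-receptor screen:")
print(screen.round(4).to_string(index=False))

ligand, receptor = pairs[0]
immune = nc.immune_score_segments(norm)
rho_partial, p_partial = nc.partial_spearman(
    norm[:, ligand].X.ravel(), norm[:, receptor].X.ravel(), immune
)
print(f"\n{ligand}-{receptor} partial Spearman given immune score: "
      f"rho = {rho_partial:.3f} (p = {p_partial:.2e})")

varpart = nc.variance_partition(norm)
print("\nvariance partition of the segment expression:")
print({k: round(v, 3) for k, v in varpart.items()})
print(
    "\nThe planted latent correlation (0.87 for the chemokine pair) passes"
    "\nthe screen; the partial correlation stays high because the pair's"
    "\ndirect association is real, not immune-content admixture.  Tissue and"
    "\ncompartment explain several times more variance than slide batch."
)
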