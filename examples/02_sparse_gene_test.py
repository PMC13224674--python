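"""Two-step differential test for a rarely expressed chemokine.

A gene expressed in <2% of cells is invisible to a bulk comparison diluted by
zeros.  The two-step test reports (i) whether the *fraction* of expressing
cells differs (two-proportion z-test) and (ii) whether *intensity among
expressors* differs (Welch's t on log values of the geometric-mean scale),
as two separate p-values.
"""

import nichecompare as nc

# triple the desk-scale cell numbers so the small control group carries
# enough expressors of a <2% gene for the intensity step to engage
cells, truth = nc.simulate_cells(nc.SimConfig(cells_per_patient=1500), seed=7)
kept, _ = nc.qc_filter_cells(cells)
norm = nc.lognormalize(kept)

table = nc.sparse_test_table(
    norm,
    genes=["CCL19", "NNMT"],
    comparisons=[("EcP", "Ctrl"), ("EcP", "EcO"), ("EcO", "Ctrl")],
)
cols = [
    "gene", "group_a", "group_b", "frac1", "frac2", "z", "p_frac",
    "intensity_ratio", "p_intensity", "q_frac", "q_intensity",
]
print(table[cols].round(4).to_string(index=False))
print(
    "\nfrac1/frac2 are the expressing-cell fractions; the planted CCL19"
    "\nenrichment in EcP (1.6% vs 0.25% in Ctrl, intensity 7.6x among"
    "\nexpressors) shows up as a small p_frac, while NNMT fractions are"
    "\ncomparable across groups.  q columns are BH-adjusted within each"
    "\nstep's family; the two p-values are never combined."
)
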