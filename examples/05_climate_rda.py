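"""Forward-selected climate RDA and four-model variance partitioning.

Builds the individual-level genotype response, extracts neutral PCs,
forward-selects bioclim predictors with the double stopping rule, then
compares the full model against climate-pure, structure-pure, and
geography-pure partial RDAs.
"""

from landrace_popgen import env_rda, io_filters
from landrace_popgen import synthetic_data as synth

cfg = synth.SimConfig(seed=9, n_pops=16, n_sites=1200, samples_per_pop=12)
panel, popmap, truth = synth.simulate_expansion(cfg)
bioclim, coeffs = synth.attach_bioclim(popmap, seed=9)
panel = io_filters.filter_sites(panel, drop_monomorphic=True)

# truth-neutral (unscored) sites stand in for the 4-fold degenerate list
scored = set(zip(truth.gerp["chrom"], truth.gerp["pos"]))
neutral = panel.sites[
    [(c, p) not in scored
     for c, p in zip(panel.sites["chrom"], panel.sites["pos"])]
][["chrom", "pos"]]

Y = env_rda.genotype_response(panel)
pcs = env_rda.neutral_pcs(panel, neutral)
bc = bioclim.set_index("population")
rows = [panel.pop_of_sample[s] for s in panel.sample_ids]
clim_all = bc.loc[rows, env_rda.BIOCLIM_VARS].reset_index(drop=True)
latlon = bc.loc[rows, ["latitude", "longitude"]].to_numpy(float)

sel = env_rda.forward_select(Y, clim_all, n_perm=99, seed=9)
print("forward-selected bioclim variables:")
print(sel.to_string(index=False, float_format=lambda v: f"{v:.4f}"))

clim = clim_all[sel["variable"]].to_numpy(float)
rep = env_rda.variance_partition(Y, clim, pcs, latlon, n_perm=199, seed=9)
print("\nfour-model comparison (adjusted R^2, permutation p):")
print(rep.models.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print(f"\nbest model: {rep.best_model}")
print("The selected variables carry the planted lat/lon climate gradients;")
print("each pure model conditions away the other two blocks, so its adj R^2")
print("is the variance that block alone explains.")
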