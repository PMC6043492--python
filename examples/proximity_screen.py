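"""Screen synthetic drugs against a planted disease module.

Builds a 500-node scale-free interactome, plants a clustered disease
module, generates 10 module-proximal and 10 degree-matched random drugs,
and screens them with the closest-distance z-score. Prints the ranked
table, the high-confidence calls (z < -4) and the ROC AUC for recovering
the proximal class.
"""

from netprox import build_degree_bins, filter_high_confidence, roc_auc, screen
from netprox.fixtures import make_screen_scenario

scenario = make_screen_scenario(
    seed=7, n_nodes=500, module_size=25, n_proximal=10, n_random=10, k_targets=3
)
g = scenario.interactome
module = scenario.disease_modules[0]
print(f"interactome: {g.number_of_nodes()} nodes, {g.number_of_edges()} edges")
print(f"disease module: {len(module)} genes (connected by construction)\n")

table = screen(
    g, scenario.drugs, [module], measure="closest", replicates=500, seed=1,
    min_bin_size=100,
)
print(table.df[["drug", "d", "z", "null_mean", "null_sd"]].to_string(index=False))

high_conf = filter_high_confidence(table, z_cutoff=-4.0)
print(f"\nhigh-confidence predictions (z < -4.0): {len(high_conf)}")

known = {
    (drug, module.name)
    for drug, label in scenario.drug_labels.items()
    if label == "proximal"
}
auc = roc_auc(table, known)
print(f"ROC AUC for recovering the planted-proximal drugs: {auc:.3f}")
print(
    "\nNegative z means the drug's targets sit closer to the disease module\n"
    "than random protein groups of the same size and degree; proximal drugs\n"
    "should dominate the top of the ranking, giving an AUC near 1."
)
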