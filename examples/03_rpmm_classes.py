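"""Recursively partitioned beta-mixture clustering into methylation classes.

Samples are split recursively by two-component beta-mixture EM; a split is
kept only when the two-component BIC beats the one-component BIC, so the
number of terminal classes is chosen by the data.
"""

from methclass import class_profiles, classify, fit_rpmm, simulate_class_matrix

beta, truth = simulate_class_matrix(
    n_samples=150, n_loci=500, n_classes=4, seed=0
)
model = fit_rpmm(beta)
print(f"terminal classes found: {model.n_classes} (4 planted)")
print(f"class sizes: {model.labels.value_counts().sort_index().to_dict()}")
print()
print(model.tree_summary())

profiles = class_profiles(model, beta)
print()
print("mean methylation of the first 5 loci per class:")
print(profiles.iloc[:, :5].round(3).to_string())

posterior = classify(model, beta)
agreement = (posterior.to_numpy().argmax(1) == model.W.to_numpy().argmax(1)).mean()
print()
print(
    f"posterior classification reproduces training assignments for "
    f"{agreement:.0%} of samples; each row of the membership matrix sums to 1."
)
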