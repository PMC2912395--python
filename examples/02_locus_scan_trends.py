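"""Array-wide locus-by-locus scans and the exposure sign trend.

Each CpG is regressed on an exposure under a quasi-binomial logit model;
q-values summarize array-wide significance, and the coefficient-sign
balance reveals weak but consistently signed exposure effects that
individual loci cannot show.
"""

from methclass import SimulationConfig, run_qc, scan, sign_trend, simulate_study

study = simulate_study(SimulationConfig(seed=1))
beta, _ = run_qc(study.beta, study.annotation, study.signals.detection_p)

for target in ("alcohol_gday", "folate_ugday"):
    result = scan(beta, study.covariates, target)
    trend = sign_trend(result)
    n_sig = int((result.table["q"] < 0.05).sum())
    print(f"{target}: pi0={result.pi0:.3f}, {n_sig} loci at Q<0.05")
    print(
        f"  coefficient signs: {trend.n_negative} negative / "
        f"{trend.n_positive} positive (sign-test p = {trend.sign_test_p:.2e})"
    )

print()
print(
    "Alcohol was planted to lower methylation and folate to raise it: only "
    "a minority of loci reach Q<0.05 individually, but the sign balance "
    "across the whole array is decisively shifted in the planted directions."
)
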