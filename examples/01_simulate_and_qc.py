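"""Generate a synthetic bead-array methylation study and run QC.

The generator emulates a 162-sample, 1505-locus tumor methylation study:
raw paired fluorescence signals, detection p-values, a per-sample covariate
table, and ground-truth class labels.  QC drops loci whose median detection
p exceeds 0.05, then everything on chromosome X.
"""

from methclass import SimulationConfig, run_qc, simulate_study

study = simulate_study(SimulationConfig(seed=1))
print(f"simulated {study.beta.n_samples} samples x {study.beta.n_loci} loci")
print(f"true classes: {sorted(int(c) for c in study.truth.labels.unique())}")

filtered, report = run_qc(
    study.beta, study.annotation, study.signals.detection_p
)
print()
print(report.summary())
print()
print(
    "The detection filter removes the planted failing loci and the X filter "
    "the X-linked block, leaving the autosomal analysis matrix."
)
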