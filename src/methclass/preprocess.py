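"""Beta-value assembly and quality control for bead-array methylation data.

A methylation measurement is summarized as
``beta = max(Cy5, 0) / (|Cy3| + |Cy5| + 100)`` where Cy5 is the methylated
and Cy3 the unmethylated fluorescence channel; the +100 offset regularizes
low-intensity cells.  Raw average beta values are analyzed without
normalization.  QC applies, in order:

1. sample filter — a sample passes iff strictly more than 75% of its loci
   have detection p < 1e-5;
2. locus filter — loci whose median detection p exceeds 0.05 are dropped;
3. chromosome-X filter — all X-linked loci are dropped.

A locus disqualified by both locus rules is attributed to the detection
rule, so the report's counts partition the input.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import BetaMatrix, QCReport

__all__ = ["compute_beta", "sample_qc", "locus_qc", "run_qc"]


def compute_beta(cy5, cy3):
    """Methylated-fraction estimate from paired channel intensities.

    Accepts scalars or arrays; negative intensities are admitted (the
    methylated channel is floored at zero, the unmethylated enters by
    absolute value).  Result is always in [0, 1).
    """
    cy5 = np.asarray(cy5, dtype=float)
    cy3 = np.asarray(cy3, dtype=float)
    if not (np.isfinite(cy5).all() and np.isfinite(cy3).all()):
        raise ValueError("intensities must be finite")
    out = np.maximum(cy5, 0.0) / (np.abs(cy3) + np.abs(cy5) + 100.0)
    return float(out) if out.ndim == 0 else out


def sample_qc(
    detection_p: pd.DataFrame,
    frac_threshold: float = 0.75,
    p_threshold: float = 1e-5,
) -> pd.Series:
    """Per-sample pass/fail: pass iff strictly more than ``frac_threshold``
    of loci are detected at p < ``p_threshold``.

    ``detection_p`` is samples x loci with values in [0, 1].
    """
    if detection_p.size == 0:
        raise ValueError("empty detection p-value grid")
    arr = detection_p.to_numpy(dtype=float)
    if np.nanmin(arr) < 0 or np.nanmax(arr) > 1:
        raise ValueError("detection p-values must lie in [0, 1]")
    frac = (arr < p_threshold).mean(axis=1)
    return pd.Series(frac > frac_threshold, index=detection_p.index, name="passed")


def locus_qc(
    beta: BetaMatrix,
    detection_p: pd.DataFrame | None,
    annotation: pd.DataFrame,
    median_p_threshold: float = 0.05,
) -> tuple[BetaMatrix, QCReport]:
    """Drop loci with median detection p above threshold, then X-linked loci.

    The median over samples uses the midpoint convention for even counts.
    Every locus in the matrix must be annotated (columns ``gene`` and
    ``chromosome``); an unannotated locus is an error naming the locus.
    """
    loci = beta.locus_ids
    missing = [l for l in loci if l not in annotation.index]
    if missing:
        raise ValueError(f"loci missing annotation: {missing[:5]}"
                         + ("..." if len(missing) > 5 else ""))
    ann = annotation.loc[loci]

    dropped_det: list[str] = []
    if detection_p is not None:
        det = detection_p.loc[:, loci]
        med = det.median(axis=0, skipna=True)
        dropped_det = [l for l in loci if med[l] > median_p_threshold]
    remaining = [l for l in loci if l not in set(dropped_det)]
    is_x = ann["chromosome"].astype(str).str.upper() == "X"
    dropped_x = [l for l in remaining if is_x[l]]
    final = [l for l in remaining if not is_x[l]]

    filtered = beta.select_loci(final)
    report = QCReport(
        loci_dropped_detection=dropped_det,
        loci_dropped_x=dropped_x,
        n_loci_input=len(loci),
        n_loci_final=len(final),
        n_genes_final=int(ann.loc[final, "gene"].nunique()) if final else 0,
    )
    return filtered, report


def run_qc(
    beta: BetaMatrix,
    annotation: pd.DataFrame,
    detection_p: pd.DataFrame | None = None,
    frac_threshold: float = 0.75,
    p_threshold: float = 1e-5,
    median_p_threshold: float = 0.05,
) -> tuple[BetaMatrix, QCReport]:
    """Full QC pass: sample filter (when detection p-values exist), then the
    locus filters.  Returns the analysis-ready autosomal matrix + report."""
    failed: list[str] = []
    frac: dict[str, float] = {}
    if detection_p is not None:
        passed = sample_qc(detection_p, frac_threshold, p_threshold)
        arr = (detection_p.to_numpy(dtype=float) < p_threshold).mean(axis=1)
        frac = dict(zip((str(i) for i in detection_p.index), arr.tolist()))
        failed = [str(s) for s in passed.index[~passed]]
        keep = [s for s in beta.sample_ids if s not in set(failed)]
        beta = beta.select_samples(keep)
        detection_p = detection_p.loc[keep]
    filtered, report = locus_qc(beta, detection_p, annotation, median_p_threshold)
    report.samples_failed = failed
    report.sample_pass_fraction = frac
    return filtered, report
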