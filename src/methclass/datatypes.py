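"""Core containers shared across the pipeline.

Orientation convention: in memory a methylation matrix is samples x loci
(one row per tumor, one column per CpG).  On disk the matrix is written
loci x samples, matching the orientation of GEO series-matrix tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["BetaMatrix", "QCReport"]


@dataclass
class BetaMatrix:
    """Samples x loci grid of average methylation (beta) values in [0, 1].

    Missing measurements are NaN; everything else must lie in the unit
    interval.  Row index = sample IDs, column index = locus IDs, both unique.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        arr = self.values.to_numpy(dtype=float)
        finite = arr[~np.isnan(arr)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ValueError("beta values must lie in [0, 1] (or be NaN)")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate sample IDs")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate locus IDs")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.index]

    @property
    def locus_ids(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_loci(self) -> int:
        return self.values.shape[1]

    def select_loci(self, loci) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[:, list(loci)])

    def select_samples(self, samples) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[list(samples), :])

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


@dataclass
class QCReport:
    """Outcome of sample- and locus-level quality control.

    Counts reconcile: ``n_loci_input == len(loci_dropped_detection)
    + len(loci_dropped_x) + n_loci_final`` — a locus failing both rules is
    attributed to the detection rule (applied first).
    """

    samples_failed: list[str] = field(default_factory=list)
    sample_pass_fraction: dict[str, float] = field(default_factory=dict)
    loci_dropped_detection: list[str] = field(default_factory=list)
    loci_dropped_x: list[str] = field(default_factory=list)
    n_loci_input: int = 0
    n_loci_final: int = 0
    n_genes_final: int = 0

    def __post_init__(self) -> None:
        expected = self.n_loci_input - len(self.loci_dropped_detection) - len(
            self.loci_dropped_x
        )
        if self.n_loci_input and self.n_loci_final != expected:
            raise ValueError(
                f"QC counts do not reconcile: {self.n_loci_final} final loci "
                f"but {expected} expected from drops"
            )

    def to_dict(self) -> dict:
        return {
            "samples_failed": list(self.samples_failed),
            "n_samples_failed": len(self.samples_failed),
            "n_loci_input": self.n_loci_input,
            "n_loci_dropped_detection": len(self.loci_dropped_detection),
            "n_loci_dropped_x": len(self.loci_dropped_x),
            "n_loci_final": self.n_loci_final,
            "n_genes_final": self.n_genes_final,
        }

    def summary(self) -> str:
        d = self.to_dict()
        lines = [
            f"samples failing detection QC : {d['n_samples_failed']}",
            f"loci on input                : {d['n_loci_input']}",
            f"loci dropped (detection p)   : {d['n_loci_dropped_detection']}",
            f"loci dropped (chromosome X)  : {d['n_loci_dropped_x']}",
            f"loci retained                : {d['n_loci_final']}",
            f"genes retained               : {d['n_genes_final']}",
        ]
        return "\n".join(lines)
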