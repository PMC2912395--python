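"""Synthetic GoldenGate-style methylation studies with known ground truth.

The generator emulates the design of a bead-array tumor-methylation study:
~162 samples measured at 1505 CpG loci (a handful failing detection QC, a
block on chromosome X), ~8 latent methylation classes whose per-locus beta
values follow class-specific Beta distributions, covariate-linked class
membership, and weak, consistently signed exposure effects acting on the
logit of locus means.  Every draw is controlled by a single integer seed.

Default study conditions
------------------------
* 162 samples, 1505 loci (84 on chromosome X, 8 failing detection QC),
  803 genes of which 30 are X-exclusive — so the stated QC filters leave
  1413 autosomal loci in 773 genes.
* 8 latent classes mixed at proportions 68/39/23/14/5/4/4/5 over 162.
* Beta concentration (a+b) of 20 at every locus; class separation acts as
  Normal(0, 1) offsets on the logit of locus means at 30% of loci.
* Exposure effects: alcohol (g/day) lowers methylation, dietary folate
  (ug/day) and tumor size (mm) raise it, each weakly at every locus with a
  consistently signed, Gamma-distributed per-locus magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from .datatypes import BetaMatrix
from .io import (
    write_annotation_tsv,
    write_beta_tsv,
    write_covariates_tsv,
    write_key_value,
)

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "SignalTable",
    "StudyTruth",
    "simulate_study",
    "simulate_signals",
    "simulate_exposure_scan",
    "write_study",
]

# Table-1-style marginal frequencies used for covariate synthesis.
_RACE = {"Caucasian": 0.727, "AfricanAmerican": 0.081, "Hispanic": 0.062,
         "Asian": 0.062, "Other": 0.068}
_PARITY = {"nulliparous": 0.188, "1-2": 0.481, "3-4": 0.281, "5+": 0.050}
_HISTOLOGY = {"ductal": 0.591, "lobular": 0.352, "adenocarcinoma": 0.057}
_STAGE = {"I": 0.590, "II": 0.292, "III": 0.093, "IV": 0.025}
_GRADE = {"well": 0.300, "moderate": 0.494, "poor": 0.200, "undifferentiated": 0.006}

_DEFAULT_MIXING = tuple(np.array([68, 39, 23, 14, 5, 4, 4, 5], dtype=float) / 162.0)

# Directions of the covariate-linked class-membership effects in the default
# 8-class design (per standardized covariate, on the class logit): larger
# tumors favor class 2; alcohol favors classes 3/8 over 2/4; folate favors
# class 6 over 1/3/4/7; the small late classes skew younger.
_DEFAULT_CLASS_COEF: dict[str, tuple[float, ...]] = {
    "tumor_size_mm": (-0.3, 0.5, 0.0, 0.0, -0.3, -0.3, -0.3, -0.3),
    "alcohol_gday": (0.0, -0.4, 0.4, -0.4, 0.3, 0.0, 0.0, 0.4),
    "folate_ugday": (-0.3, 0.0, -0.3, -0.3, 0.0, 0.6, -0.3, 0.0),
    "age": (0.3, -0.2, 0.3, 0.3, 0.3, 0.0, -0.2, -0.4),
}


@dataclass
class SimulationConfig:
    """Knobs of the generative model; defaults are the study conditions."""

    n_samples: int = 162
    n_loci: int = 1505
    n_classes: int = 8
    class_mixing: tuple[float, ...] = _DEFAULT_MIXING
    class_coef: dict[str, tuple[float, ...]] | str | None = "study-default"
    concentration: float = 20.0
    class_separation: float = 1.0
    frac_informative: float = 0.3
    n_x_loci: int = 84
    n_failing_loci: int = 8
    n_genes: int = 803
    n_x_exclusive_genes: int = 30
    exposure_effects: dict[str, float] = field(
        default_factory=lambda: {
            # logit-scale slope per SD of exposure, averaged over loci:
            # dietary exposures act as weak array-wide trends, tumor size
            # as a stronger signal with individually detectable loci
            "alcohol_gday": -0.05,
            "folate_ugday": 0.05,
            "tumor_size_mm": 0.12,
        }
    )
    missing_rate: float = 0.02
    with_signals: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1 or self.n_samples < 1 or self.n_loci < 1:
            raise ValueError("counts must be positive")
        mix = np.asarray(self.class_mixing, dtype=float)
        if len(mix) != self.n_classes:
            raise ValueError("class_mixing length must equal n_classes")
        if mix.min() < 0 or abs(mix.sum() - 1.0) > 1e-12:
            raise ValueError("class_mixing must be a probability vector summing to 1")
        if self.concentration <= 0:
            raise ValueError("concentration must be strictly positive")
        if self.n_x_loci < 0 or self.n_failing_loci < 0:
            raise ValueError("locus counts must be non-negative")
        if self.n_x_loci + self.n_failing_loci > self.n_loci:
            raise ValueError("n_x_loci + n_failing_loci exceeds n_loci")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.class_coef == "study-default":
            # covariate-linked membership is part of the default 8-class
            # design; other class counts get unlinked mixing unless the
            # caller supplies coefficients explicitly
            self.class_coef = (
                dict(_DEFAULT_CLASS_COEF) if self.n_classes == 8 else None
            )
        if isinstance(self.class_coef, dict):
            for cov, coefs in self.class_coef.items():
                if len(coefs) != self.n_classes:
                    raise ValueError(
                        f"class_coef[{cov!r}] must have length n_classes"
                    )

    def to_dict(self) -> dict:
        d = {
            "n_samples": self.n_samples,
            "n_loci": self.n_loci,
            "n_classes": self.n_classes,
            "class_mixing": [float(x) for x in self.class_mixing],
            "concentration": self.concentration,
            "class_separation": self.class_separation,
            "frac_informative": self.frac_informative,
            "n_x_loci": self.n_x_loci,
            "n_failing_loci": self.n_failing_loci,
            "n_genes": self.n_genes,
            "n_x_exclusive_genes": self.n_x_exclusive_genes,
            "exposure_effects": dict(self.exposure_effects),
            "missing_rate": self.missing_rate,
            "with_signals": self.with_signals,
            "seed": self.seed,
        }
        if self.class_coef is not None:
            d["class_coef"] = {k: [float(x) for x in v] for k, v in self.class_coef.items()}
        return d


@dataclass
class SignalTable:
    """Paired fluorescence intensities plus per-cell detection p-values."""

    cy5: pd.DataFrame  # samples x loci
    cy3: pd.DataFrame
    detection_p: pd.DataFrame

    def recompute_beta(self) -> BetaMatrix:
        from .preprocess import compute_beta

        vals = compute_beta(self.cy5.to_numpy(), self.cy3.to_numpy())
        return BetaMatrix(pd.DataFrame(vals, index=self.cy5.index, columns=self.cy5.columns))


@dataclass
class StudyTruth:
    labels: pd.Series                 # 1-based class label per sample
    class_means: pd.DataFrame         # classes x loci mean beta (no exposure shift)
    exposure_slopes: pd.DataFrame     # covariate x loci logit-scale slopes
    mixing: np.ndarray
    failing_loci: list[str]
    x_loci: list[str]


@dataclass
class SimulatedStudy:
    beta: BetaMatrix
    annotation: pd.DataFrame
    covariates: pd.DataFrame
    truth: StudyTruth
    signals: SignalTable | None
    config: SimulationConfig


def _draw_categorical(rng, levels: dict[str, float], n: int) -> np.ndarray:
    names = list(levels)
    p = np.array([levels[k] for k in names], dtype=float)
    return rng.choice(names, size=n, p=p / p.sum())


def _simulate_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    age = np.clip(rng.normal(59.2, 11.6, n), 30, 91).round(1)
    race = _draw_categorical(rng, _RACE, n)
    never = rng.random(n) < 0.27
    alcohol = np.where(never, 0.0, rng.lognormal(1.8, 1.1, n)).round(2)
    alcohol = np.clip(alcohol, 0, 85)
    folate = np.clip(rng.gamma(4.6, 100.0, n), 40, 1650).round(1)
    size = np.clip(rng.gamma(1.35, 12.9, n), 0.5, 135).round(1)
    bmi = np.clip(rng.normal(29.0, 6.7, n), 18.5, 56.1).round(1)
    er = rng.choice(["positive", "negative"], n, p=[0.876, 0.124])
    pr = rng.choice(["positive", "negative"], n, p=[0.734, 0.266])
    erbb2 = rng.choice(["negative", "positive"], n, p=[0.859, 0.141])
    triple_neg = np.where(
        (er == "negative") & (pr == "negative") & (erbb2 == "negative"), "yes", "no"
    )
    stage = _draw_categorical(rng, _STAGE, n)
    stage_binary = np.where(np.isin(stage, ["I", "II"]), "low", "high")
    grade = _draw_categorical(rng, _GRADE, n)
    histology = _draw_categorical(rng, _HISTOLOGY, n)
    parity = _draw_categorical(rng, _PARITY, n)
    node = rng.choice(["negative", "positive"], n, p=[0.692, 0.308])
    menopause = rng.choice(["post", "pre"], n, p=[0.722, 0.278])
    return pd.DataFrame(
        {
            "age": age,
            "race": race,
            "alcohol_gday": alcohol,
            "folate_ugday": folate,
            "bmi": bmi,
            "tumor_size_mm": size,
            "grade": grade,
            "stage": stage,
            "stage_binary": stage_binary,
            "er": er,
            "pr": pr,
            "erbb2": erbb2,
            "triple_negative": triple_neg,
            "histology": histology,
            "parity": parity,
            "lymph_node": node,
            "menopause": menopause,
        },
        index=[f"S{i + 1:04d}" for i in range(n)],
    )


def _make_annotation(cfg: SimulationConfig) -> pd.DataFrame:
    """Locus IDs, genes and chromosomes; X loci occupy the final block."""
    n_auto = cfg.n_loci - cfg.n_x_loci
    n_auto_genes = max(1, min(cfg.n_genes - cfg.n_x_exclusive_genes, n_auto))
    n_x_genes = max(0, min(cfg.n_x_exclusive_genes, cfg.n_x_loci))
    locus_ids = [f"CPG{i + 1:05d}" for i in range(cfg.n_loci)]
    genes, chroms = [], []
    for i in range(n_auto):
        genes.append(f"GENE{(i % n_auto_genes) + 1:04d}")
        chroms.append(str((i % 22) + 1))
    for i in range(cfg.n_x_loci):
        g = n_auto_genes + (i % n_x_genes) + 1 if n_x_genes else (i % n_auto_genes) + 1
        genes.append(f"GENE{g:04d}")
        chroms.append("X")
    return pd.DataFrame({"gene": genes, "chromosome": chroms}, index=locus_ids)


def _choose_failing(rng, cfg: SimulationConfig, annotation: pd.DataFrame) -> list[str]:
    """Pick detection-failing loci among autosomal loci whose gene has another
    autosomal locus, so the post-QC gene tally is unaffected."""
    auto = annotation[annotation["chromosome"] != "X"]
    counts = auto["gene"].value_counts()
    multi = auto[auto["gene"].map(counts) > 1]
    # at most one locus per gene, so no gene loses all its loci to QC
    one_per_gene = multi.groupby("gene", sort=True).head(1).index
    pool = one_per_gene if len(one_per_gene) >= cfg.n_failing_loci else auto.index
    return sorted(rng.choice(pool, size=cfg.n_failing_loci, replace=False))


def _standardize(col: pd.Series) -> np.ndarray:
    x = col.to_numpy(dtype=float)
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Draw a full synthetic study: covariates, class labels, beta matrix,
    annotation, optional raw signals, and the ground truth behind them."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    covariates = _simulate_covariates(rng, cfg.n_samples)
    annotation = _make_annotation(cfg)
    locus_ids = list(annotation.index)
    sample_ids = list(covariates.index)

    # latent class per sample
    mixing = np.asarray(cfg.class_mixing, dtype=float)
    if cfg.class_coef:
        eta = np.tile(np.log(np.clip(mixing, 1e-12, None)), (cfg.n_samples, 1))
        for cov, coefs in cfg.class_coef.items():
            z = _standardize(covariates[cov])
            eta += z[:, None] * np.asarray(coefs, dtype=float)[None, :]
        eta -= eta.max(axis=1, keepdims=True)
        probs = np.exp(eta)
        probs /= probs.sum(axis=1, keepdims=True)
        labels0 = np.array([rng.choice(cfg.n_classes, p=p) for p in probs])
    else:
        labels0 = rng.choice(cfg.n_classes, size=cfg.n_samples, p=mixing)

    # per-locus base means: bimodal, as methylation arrays show
    kind = rng.choice(3, size=cfg.n_loci, p=[0.55, 0.30, 0.15])
    base = np.where(
        kind == 0, rng.beta(2, 8, cfg.n_loci),
        np.where(kind == 1, rng.beta(8, 2, cfg.n_loci), rng.beta(2, 2, cfg.n_loci)),
    )
    base = np.clip(base, 0.02, 0.98)
    mu = logit(base)

    informative = rng.random(cfg.n_loci) < cfg.frac_informative
    delta = np.zeros((cfg.n_classes, cfg.n_loci))
    delta[:, informative] = rng.normal(
        0.0, cfg.class_separation, (cfg.n_classes, int(informative.sum()))
    )

    # weak consistently signed exposure slopes on the logit scale
    slopes = {}
    for cov, eff in cfg.exposure_effects.items():
        mag = rng.gamma(2.0, 0.5, cfg.n_loci)  # mean 1, all positive
        slopes[cov] = eff * mag
    slope_frame = pd.DataFrame(slopes, index=locus_ids).T

    eta = mu[None, :] + delta[labels0, :]
    for cov, s in slopes.items():
        z = _standardize(covariates[cov])
        eta = eta + z[:, None] * s[None, :]
    mean = np.clip(expit(eta), 1e-4, 1 - 1e-4)
    a = np.maximum(mean * cfg.concentration, 1e-3)
    b = np.maximum((1 - mean) * cfg.concentration, 1e-3)
    # keep draws invertible by the signal synthesis (beta < 1 strictly)
    beta_vals = np.clip(rng.beta(a, b), 0.0, 1.0 - 1e-6)
    beta = BetaMatrix(pd.DataFrame(beta_vals, index=sample_ids, columns=locus_ids))

    failing = _choose_failing(rng, cfg, annotation) if cfg.n_failing_loci else []
    signals = None
    if cfg.with_signals:
        signals = simulate_signals(beta, cfg, failing_loci=failing, rng=rng)

    if cfg.missing_rate > 0:
        mask = rng.random(covariates.shape) < cfg.missing_rate
        covariates = covariates.mask(mask)

    class_mean = expit(mu[None, :] + delta)
    truth = StudyTruth(
        labels=pd.Series(labels0 + 1, index=sample_ids, name="class"),
        class_means=pd.DataFrame(
            class_mean, index=[f"class{k + 1}" for k in range(cfg.n_classes)],
            columns=locus_ids,
        ),
        exposure_slopes=slope_frame,
        mixing=mixing,
        failing_loci=list(failing),
        x_loci=list(annotation.index[annotation["chromosome"] == "X"]),
    )
    return SimulatedStudy(beta, annotation, covariates, truth, signals, cfg)


def simulate_signals(
    beta: BetaMatrix,
    config: SimulationConfig,
    failing_loci: list[str] | None = None,
    rng: np.random.Generator | None = None,
    base_total: float = 2000.0,
) -> SignalTable:
    """Invert beta values into paired Cy5/Cy3 intensities plus detection p.

    For each cell a total intensity S >= 100*beta/(1-beta) is chosen so that
    Cy5 = beta*(S+100) and Cy3 = S-Cy5 reproduce beta exactly under
    beta = max(Cy5,0)/(|Cy3|+|Cy5|+100).  beta values at (or numerically at)
    1 are clamped to 1-1e-6 first, which caps the implied intensity; exact
    inversion is then only guaranteed for the clamped value.  Designated
    failing loci receive detection p-values above 0.05 in ~70% of samples so
    their median detection p fails the locus filter.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    vals = np.clip(beta.to_numpy(), 0.0, 1.0 - 1e-6)
    required = 100.0 * vals / (1.0 - vals)
    total = np.maximum(base_total, required)
    cy5 = vals * (total + 100.0)
    cy3 = total - cy5
    idx, cols = beta.values.index, beta.values.columns

    detection = rng.uniform(0.0, 1e-6, size=vals.shape)
    failing_loci = failing_loci or []
    if failing_loci:
        pos = [list(cols).index(l) for l in failing_loci]
        fail_mask = rng.random((vals.shape[0], len(pos))) < 0.7
        detection[:, pos] = np.where(
            fail_mask, rng.uniform(0.06, 0.5, fail_mask.shape), detection[:, pos]
        )
    return SignalTable(
        cy5=pd.DataFrame(cy5, index=idx, columns=cols),
        cy3=pd.DataFrame(cy3, index=idx, columns=cols),
        detection_p=pd.DataFrame(detection, index=idx, columns=cols),
    )


def simulate_exposure_scan(
    n_samples: int = 160,
    n_loci: int = 200,
    n_affected: int = 0,
    effect: float = 0.5,
    concentration: float = 20.0,
    seed: int = 0,
) -> tuple[BetaMatrix, pd.Series, np.ndarray]:
    """Minimal locus-scan testbed: one continuous exposure, the first
    ``n_affected`` loci carry a logit-scale slope of ``effect`` per SD of
    exposure, the rest are null.  Returns (beta, exposure, affected mask)."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, 1.0, n_samples)
    base = np.clip(rng.beta(2, 2, n_loci), 0.05, 0.95)
    eta = np.tile(logit(base), (n_samples, 1))
    affected = np.zeros(n_loci, dtype=bool)
    affected[:n_affected] = True
    eta[:, affected] += np.outer(x, np.full(n_affected, effect))
    mean = np.clip(expit(eta), 1e-4, 1 - 1e-4)
    vals = rng.beta(mean * concentration, (1 - mean) * concentration)
    ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    loci = [f"CPG{j + 1:05d}" for j in range(n_loci)]
    beta = BetaMatrix(pd.DataFrame(vals, index=ids, columns=loci))
    return beta, pd.Series(x, index=ids, name="exposure"), affected


def simulate_class_matrix(
    n_samples: int = 150,
    n_loci: int = 500,
    n_classes: int = 4,
    mean_levels: tuple[float, ...] = (0.15, 0.4, 0.6, 0.85),
    concentration: float = 20.0,
    mixing: tuple[float, ...] | None = None,
    seed: int = 0,
) -> tuple[BetaMatrix, pd.Series]:
    """Well-separated latent-class testbed for the mixture clustering.

    Each class's per-locus mean is drawn from ``mean_levels``; beta values
    are Beta(mean * c, (1 - mean) * c) draws at fixed concentration c.
    Returns (beta matrix, true 1-based labels).
    """
    rng = np.random.default_rng(seed)
    mix = (
        np.full(n_classes, 1.0 / n_classes)
        if mixing is None
        else np.asarray(mixing, dtype=float)
    )
    labels = rng.choice(n_classes, size=n_samples, p=mix / mix.sum())
    means = rng.choice(mean_levels, size=(n_classes, n_loci))
    m = means[labels, :]
    vals = rng.beta(m * concentration, (1 - m) * concentration)
    ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    loci = [f"CPG{j + 1:05d}" for j in range(n_loci)]
    beta = BetaMatrix(pd.DataFrame(vals, index=ids, columns=loci))
    return beta, pd.Series(labels + 1, index=ids, name="class")


def write_study(study: SimulatedStudy, out_dir) -> None:
    """Persist a study as plain text: beta TSV (loci x samples), covariate and
    annotation TSVs, truth sidecar JSON, config YAML, optional signal TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_beta_tsv(study.beta, out / "beta.tsv")
    write_covariates_tsv(study.covariates, out / "covariates.tsv")
    write_annotation_tsv(study.annotation, out / "annotation.tsv")
    write_key_value(
        {
            "labels": {k: int(v) for k, v in study.truth.labels.items()},
            "mixing": study.truth.mixing,
            "failing_loci": study.truth.failing_loci,
            "x_loci": study.truth.x_loci,
        },
        out / "truth.json",
    )
    (out / "config.yaml").write_text(yaml.safe_dump(study.config.to_dict()))
    if study.signals is not None:
        study.signals.detection_p.T.to_csv(out / "detection_p.tsv", sep="\t")
        study.signals.cy5.T.to_csv(out / "signal_cy5.tsv", sep="\t")
        study.signals.cy3.T.to_csv(out / "signal_cy3.tsv", sep="\t")
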