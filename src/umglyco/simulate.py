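"""Known-truth synthetic inputs for every pipeline stage.

The generators emulate the statistical structure each analysis assumes,
so the whole pipeline runs and can be validated offline:

* stain-composited PAS image pairs (Beer-Lambert forward model with the
  default stain vectors; the amylase image carries the PAS concentration
  reduced by a known glycogen fraction f),
* per-nucleus chromosome-3 FISH counts (true copy number 1 with the
  planted monosomy fraction, else 2; each signal independently lost with
  a truncation probability, reproducing chromosomal indices below 2),
* a two-group log2-expression cohort with planted per-gene effects and
  copy-number calls carrying an additive dosage shift,
* a clinical table with binary/numeric covariates and exponential
  survival times under a group hazard ratio with uniform censoring.

All generators are pure functions of (params, seed): the same seed gives
bit-identical output.

Image defaults deliberately sit in the faint-stain regime (peak PAS
optical density ~0.08, low noise): the green-minimum display rescale
applied before deconvolution is nonlinear in concentration, and the
differential glycogen estimate is accurate to a few percentage points
only when absorbances are small (see the methods documentation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import CopyNumberCalls
from .imaging import DEFAULT_STAIN_VECTORS, StainVectors, od_to_rgb
from .panel import load_panel

__all__ = [
    "ImageSimParams",
    "FISHSimParams",
    "SurvivalSimParams",
    "CohortSimParams",
    "gen_pas_image_pair",
    "gen_fish_counts",
    "gen_expression_cohort",
    "gen_clinical_table",
]


@dataclass(frozen=True)
class ImageSimParams:
    """Forward-model parameters for one differential PAS image pair."""

    width: int = 96
    height: int = 96
    glycogen_fraction: float = 0.5  # amylase-labile fraction f of the PAS signal
    pas_concentration: float = 0.08  # peak PAS optical density inside the mask
    pigment_concentration: float = 0.0  # melanin OD (crosstalk source when > 0)
    mask_shape: str = "disk"  # "disk" or "blob"
    noise_sd: float = 0.005  # Gaussian OD noise per channel
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 32 or self.height < 32:
            raise ValueError("image dimensions must be >= 32 pixels")
        if not 0.0 <= self.glycogen_fraction <= 1.0:
            raise ValueError("glycogen_fraction must be in [0, 1]")
        if self.pas_concentration < 0 or self.pigment_concentration < 0:
            raise ValueError("stain concentrations must be non-negative")
        if self.mask_shape not in ("disk", "blob"):
            raise ValueError(f"unknown mask shape {self.mask_shape!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _tumor_mask(p: ImageSimParams, rng: np.random.Generator) -> np.ndarray:
    yy, xx = np.mgrid[0 : p.height, 0 : p.width]
    cy, cx = (p.height - 1) / 2.0, (p.width - 1) / 2.0
    r = np.hypot(yy - cy, xx - cx)
    radius = 0.35 * min(p.height, p.width)
    if p.mask_shape == "disk":
        return r <= radius
    # blob: disk with a smooth random angular perturbation of the radius
    theta = np.arctan2(yy - cy, xx - cx)
    wobble = np.zeros_like(theta)
    for k in (2, 3, 5):
        wobble += rng.uniform(-0.15, 0.15) * np.sin(k * theta + rng.uniform(0, 2 * np.pi))
    return r <= radius * (1.0 + wobble)


def _composite(
    c_pas: float,
    c_pig: float,
    mask: np.ndarray,
    stains: StainVectors,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    h, w = mask.shape
    conc = np.zeros((h, w, 3))
    conc[mask, 0] = c_pas
    conc[mask, 2] = c_pig
    od = conc @ stains.matrix
    if noise_sd > 0:
        od = od + rng.normal(0.0, noise_sd, od.shape)
    return od_to_rgb(np.maximum(od, 0.0))


def gen_pas_image_pair(
    p: ImageSimParams, stains: StainVectors = DEFAULT_STAIN_VECTORS
):
    """Untreated/amylase RGB pair, tumor mask, and the true fraction f.

    Inside the mask the untreated image carries (pas_concentration,
    pigment_concentration); the amylase image is identical except the PAS
    concentration is scaled by (1 - f).  Gaussian OD noise is added
    before 8-bit quantization.
    """
    rng = np.random.default_rng(p.seed)
    mask = _tumor_mask(p, rng)
    untreated = _composite(
        p.pas_concentration, p.pigment_concentration, mask, stains, p.noise_sd, rng
    )
    amylase = _composite(
        p.pas_concentration * (1.0 - p.glycogen_fraction),
        p.pigment_concentration,
        mask,
        stains,
        p.noise_sd,
        rng,
    )
    return untreated, amylase, mask, p.glycogen_fraction


def gen_fish_counts(
    n_nuclei: int, monosomy_fraction: float, truncation_prob: float, seed: int
) -> np.ndarray:
    """Per-nucleus chromosome-3 signal counts.

    Each nucleus is monosomic (one true copy) with the given fraction,
    disomic (two) otherwise; every signal is independently lost with the
    truncation probability (section truncation / hybridization failure),
    so the expected disomic index is 2(1 - t).
    """
    if not 0.0 <= monosomy_fraction <= 1.0:
        raise ValueError("monosomy_fraction must be in [0, 1]")
    if not 0.0 <= truncation_prob <= 1.0:
        raise ValueError("truncation_prob must be in [0, 1]")
    if n_nuclei < 1:
        raise ValueError("need at least one nucleus")
    rng = np.random.default_rng(seed)
    copies = np.where(rng.random(n_nuclei) < monosomy_fraction, 1, 2)
    return rng.binomial(copies, 1.0 - truncation_prob)


@dataclass(frozen=True)
class FISHSimParams:
    n_nuclei: int = 300
    monosomy_fraction: float = 0.3
    truncation_prob: float = 0.3


@dataclass(frozen=True)
class SurvivalSimParams:
    baseline_hazard: float = 0.02  # events per month in the reference group
    hazard_ratio: float = 1.0
    follow_up_months: float = 108.0  # uniform censoring horizon (9 years)


@dataclass(frozen=True)
class CohortSimParams:
    """Cohort-level generator parameters (expression, FISH, clinical)."""

    n_samples: int = 80
    monosomy_prob: float = 0.5
    baseline: float = 8.0  # log2(FPKM-uq+1) baseline expression
    noise_sd: float = 0.5  # log2 residual spread
    delta: dict = field(default_factory=dict)  # per-gene planted log2 effect
    cn_aberration_rate: float = 0.05
    cn_dosage_shift: float = 0.8  # +/- log2 shift for gain/loss calls
    covariate_odds_ratio: float = 1.0
    fish: FISHSimParams = field(default_factory=FISHSimParams)
    survival: SurvivalSimParams = field(default_factory=SurvivalSimParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")
        for name in ("monosomy_prob", "cn_aberration_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _is_chr3(chrom: str) -> bool:
    return str(chrom).removeprefix("chr") == "3"


def gen_expression_cohort(p: CohortSimParams, panel: pd.DataFrame | None = None):
    """Two-group log2 expression cohort with planted effects.

    Returns (expression genes x samples, CopyNumberCalls, labels, truth
    deltas).  Sample group is drawn with monosomy_prob; monosomy-3
    samples lose both chromosome-3 arms (and their chromosome-3 gene
    loci).  Off chromosome 3, per-(gene, sample) aberrations are planted
    at cn_aberration_rate with an additive +/- dosage shift.  Values are
    baseline + delta * 1[monosomy3] + dosage + N(0, noise_sd), floored
    at 0.
    """
    if panel is None:
        panel = load_panel()
    rng = np.random.default_rng(p.seed)
    samples = [f"S{i:03d}" for i in range(p.n_samples)]
    is_m3 = rng.random(p.n_samples) < p.monosomy_prob
    # degenerate draws would leave a group empty; force one of each
    if is_m3.all():
        is_m3[0] = False
    if not is_m3.any():
        is_m3[0] = True
    labels = pd.Series(np.where(is_m3, "monosomy3", "disomy3"), index=samples)

    arm_calls = pd.DataFrame(
        {"arm3p_loss": is_m3, "arm3q_loss": is_m3}, index=samples, dtype=object
    )

    genes = list(panel["symbol"])
    chroms = dict(zip(panel["symbol"], panel["chrom"]))
    deltas = pd.Series({g: float(p.delta.get(g, 0.0)) for g in genes})

    offpanel = [g for g in genes if not _is_chr3(chroms[g])]
    shape = (len(offpanel), p.n_samples)
    aberrant = rng.random(shape) < p.cn_aberration_rate
    kind = np.where(aberrant, rng.integers(1, 3, shape), 0)
    gene_calls = pd.DataFrame(
        np.array(["neutral", "loss", "gain"], dtype=object)[kind],
        index=offpanel,
        columns=samples,
    )
    off_dosage = np.select(
        [kind == 1, kind == 2], [-p.cn_dosage_shift, p.cn_dosage_shift], 0.0
    )
    dosage = pd.DataFrame(0.0, index=genes, columns=samples)
    dosage.loc[offpanel] = off_dosage

    values = (
        p.baseline
        + np.outer(deltas.to_numpy(), is_m3.astype(float))
        + dosage.to_numpy()
        + rng.normal(0.0, p.noise_sd, (len(genes), p.n_samples))
    )
    expr = pd.DataFrame(np.maximum(values, 0.0), index=genes, columns=samples)
    cn = CopyNumberCalls(arm_calls=arm_calls, gene_calls=gene_calls)
    return expr, cn, labels, deltas


def gen_clinical_table(p: CohortSimParams) -> pd.DataFrame:
    """Clinical table with covariates and survival under a hazard ratio.

    Subjects are split evenly into "high" and "low" groups.  A binary
    covariate is associated with the group at the configured odds ratio
    (baseline probability 0.5); age is a nuisance numeric.  Survival is
    exponential with the baseline hazard in the high group and
    hazard_ratio times that in the low group, censored uniformly on
    (0, follow_up_months].
    """
    rng = np.random.default_rng(p.seed)
    n = p.n_samples
    n_high = n // 2
    group = np.array(["high"] * n_high + ["low"] * (n - n_high))

    odds0 = 1.0  # baseline probability 0.5
    p_cov = np.where(
        group == "high",
        0.5,
        (p.covariate_odds_ratio * odds0) / (1.0 + p.covariate_odds_ratio * odds0),
    )
    covariate = (rng.random(n) < p_cov).astype(int)
    gender = np.where(rng.random(n) < 0.5, "Female", "Male")
    age = np.round(rng.normal(65.0, 10.0, n)).clip(30, 95)

    hazard = np.where(
        group == "high",
        p.survival.baseline_hazard,
        p.survival.baseline_hazard * p.survival.hazard_ratio,
    )
    event_time = rng.exponential(1.0 / hazard)
    censor_time = rng.uniform(0.0, p.survival.follow_up_months, n)
    event = event_time <= censor_time
    time = np.minimum(event_time, censor_time)

    return pd.DataFrame(
        {
            "subject": [f"P{i:03d}" for i in range(n)],
            "group": group,
            "covariate": covariate,
            "gender": gender,
            "age": age,
            "time_months": time,
            "event": event.astype(int),
        }
    )
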