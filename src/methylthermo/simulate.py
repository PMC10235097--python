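"""Seeded generators of synthetic methylome data with known ground truth.

Three layers of the analysis can be exercised without any downloads:

* count level — :func:`simulate_methylome_pair` draws per-site true
  methylation levels from a bimodal beta mixture (methylomes are
  strongly bimodal: most cytosines are nearly un- or fully methylated),
  samples read coverage from a gamma-mixed Poisson (negative-binomial
  like) law, shifts a configurable fraction of treatment sites, and
  emits binomial read counts for a control/treatment pair plus the
  ground-truth table of shifted sites;
* divergence level — :func:`simulate_divergence_ensemble` draws χ
  values directly from a chosen generalized-gamma law;
* fluctuation level — :func:`simulate_feedback_ensemble` builds
  (|S|/c, ν) point clouds satisfying the feedback relation
  e^{−|S|/c} = η(1 − e^{−ν}) up to Gaussian noise.

What the generator does **not** emulate: sequence context of
neighbouring cytosines, spatial correlation along the chromosome, and
bisulfite conversion errors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fluctuation import FluctuationPoint
from .ggfamily import GGParams, gg_sample
from .io import SITE_COLUMNS, MethylomeSample


@dataclass
class SimulationConfig:
    """Study conditions for the count-level simulation.

    Defaults: 10⁴ sites on each of 5 chromosomes; coverage mean 30 with
    negative-binomial dispersion 5; baseline levels from the mixture
    0.7·Beta(1, 10) + 0.3·Beta(10, 1); no treatment effect.
    """

    n_sites: int = 10_000
    n_chromosomes: int = 5
    coverage_mean: float = 30.0
    coverage_dispersion: float = 5.0
    low_mode: tuple[float, float] = (1.0, 10.0)
    high_mode: tuple[float, float] = (10.0, 1.0)
    low_weight: float = 0.7
    # chromosome-level random effects: real chromosomes differ in mean
    # sequencing depth (mappability, copy number) and in methylation
    # composition (gene/transposon density); these give each chromosome
    # its own coverage factor (lognormal, sigma below) and its own
    # low-mode mixture weight (Gaussian jitter on the logit scale)
    chromosome_coverage_sd: float = 0.1
    chromosome_weight_sd: float = 0.3
    effect_fraction: float = 0.0
    effect_shift: float = 0.5
    divergence_law: GGParams | None = None
    seed: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.low_weight <= 1 and 0 <= self.effect_fraction <= 1):
            raise ValueError("weights and fractions must lie in [0, 1]")
        if self.coverage_mean <= 0 or self.coverage_dispersion <= 0:
            raise ValueError("coverage mean and dispersion must be positive")
        if self.n_sites < 1 or self.n_chromosomes < 1:
            raise ValueError("need at least one site and one chromosome")
        if self.chromosome_coverage_sd < 0 or self.chromosome_weight_sd < 0:
            raise ValueError("chromosome-effect sds must be non-negative")


def _draw_levels(
    rng: np.random.Generator, low_weight: np.ndarray, cfg: SimulationConfig
) -> np.ndarray:
    n = len(low_weight)
    low = rng.random(n) < low_weight
    levels = np.empty(n)
    levels[low] = rng.beta(*cfg.low_mode, size=int(low.sum()))
    levels[~low] = rng.beta(*cfg.high_mode, size=int((~low).sum()))
    return levels


def _draw_coverage(
    rng: np.random.Generator, mean: np.ndarray, cfg: SimulationConfig
) -> np.ndarray:
    # gamma-mixed Poisson: NB with mean m and dispersion r (var = m + m^2/r)
    lam = rng.gamma(cfg.coverage_dispersion, mean / cfg.coverage_dispersion)
    return rng.poisson(lam)


def simulate_methylome_pair(
    config: SimulationConfig,
) -> tuple[MethylomeSample, MethylomeSample, pd.DataFrame]:
    """Simulate a (control, treatment) methylome pair with ground truth.

    Shifted sites move away from their baseline level by
    ``effect_shift`` (towards the opposite methylation state), clipped
    to (0.001, 0.999).  The truth table lists every site with its true
    control/treatment levels and a ``shifted`` flag.  Byte-identical for
    a fixed config (including seed).
    """
    rng = np.random.default_rng(config.seed)
    n_total = config.n_sites * config.n_chromosomes
    chroms = np.repeat(
        [f"chr{i + 1}" for i in range(config.n_chromosomes)], config.n_sites
    )
    positions = np.tile(np.arange(1, config.n_sites + 1) * 10, config.n_chromosomes)

    # chromosome-level random effects, shared by control and treatment
    cov_factor = np.exp(
        rng.normal(0.0, config.chromosome_coverage_sd, config.n_chromosomes)
    )
    logit_w = math.log(config.low_weight / (1 - config.low_weight)) if (
        0 < config.low_weight < 1
    ) else None
    if logit_w is not None and config.chromosome_weight_sd > 0:
        w_chrom = 1.0 / (1.0 + np.exp(-(
            logit_w + rng.normal(0.0, config.chromosome_weight_sd, config.n_chromosomes)
        )))
    else:
        w_chrom = np.full(config.n_chromosomes, config.low_weight)
    site_weight = np.repeat(w_chrom, config.n_sites)
    site_cov_mean = np.repeat(config.coverage_mean * cov_factor, config.n_sites)

    p_control = _draw_levels(rng, site_weight, config)
    shifted = rng.random(n_total) < config.effect_fraction
    p_treat = p_control.copy()
    direction = np.where(p_control < 0.5, 1.0, -1.0)
    p_treat[shifted] = p_control[shifted] + direction[shifted] * config.effect_shift
    p_treat = np.clip(p_treat, 1e-3, 1 - 1e-3)
    p_control = np.clip(p_control, 1e-3, 1 - 1e-3)

    cov_c = _draw_coverage(rng, site_cov_mean, config)
    cov_t = _draw_coverage(rng, site_cov_mean, config)
    meth_c = rng.binomial(cov_c, p_control)
    meth_t = rng.binomial(cov_t, p_treat)

    def build(name: str, group: str, cov: np.ndarray, meth: np.ndarray) -> MethylomeSample:
        df = pd.DataFrame(
            {
                "chromosome": chroms,
                "position": positions,
                "strand": "+",
                "context": "CG",
                "n_meth": meth,
                "n_unmeth": cov - meth,
            },
            columns=SITE_COLUMNS,
        )
        return MethylomeSample(name, df, group_label=group)

    control = build("control", "control", cov_c, meth_c)
    treatment = build("treatment", "treatment", cov_t, meth_t)
    truth = pd.DataFrame(
        {
            "chromosome": chroms,
            "position": positions,
            "true_level_control": p_control,
            "true_level_treatment": p_treat,
            "shifted": shifted,
        }
    )
    return control, treatment, truth


def simulate_divergence_ensemble(params: GGParams, n: int, seed) -> np.ndarray:
    """Draw n divergence values from the target generalized-gamma law."""
    return gg_sample(params, n, seed)


def simulate_feedback_ensemble(
    eta: float,
    noise_sd: float,
    n: int,
    seed,
    nu_range: tuple[float, float] = (0.1, 3.0),
) -> list[FluctuationPoint]:
    """Point cloud obeying e^{−|S|/c} = η(1 − e^{−ν}) plus Gaussian noise.

    ν is uniform on ``nu_range``; points whose noisy factor would be
    non-positive (impossible for a Boltzmann factor) are resampled with
    a warning.  With ``noise_sd=0`` the relation is exact.
    """
    if eta <= 0:
        raise ValueError("eta must be positive")
    if n < 3:
        raise ValueError("need at least 3 points")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nu = rng.uniform(*nu_range, size=n)
    y = eta * (1.0 - np.exp(-nu))
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n)
        bad = y <= 0
        n_resampled = 0
        while bad.any():
            y[bad] = eta * (1.0 - np.exp(-nu[bad])) + rng.normal(
                0.0, noise_sd, size=int(bad.sum())
            )
            n_resampled += int(bad.sum())
            bad = y <= 0
        if n_resampled:
            warnings.warn(
                f"simulate_feedback_ensemble: resampled {n_resampled} "
                "non-positive factor draw(s)",
                stacklevel=2,
            )
    s_abs = -np.log(y)
    return [
        FluctuationPoint(
            sample_id="sim",
            chromosome=f"chr{i + 1}",
            s_abs=float(s_abs[i]),
            nu_mean=float(nu[i]),
            factor_S=float(y[i]),
            factor_nu=float(math.exp(-nu[i])),
            group_label="sim",
        )
        for i in range(n)
    ]
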