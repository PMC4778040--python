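"""Synthetic data with the statistical structure the paired analyses assume.

Two generators stand in for the study's (undeposited) raw data:

* :func:`generate_motility` draws paired dyed/undyed CASA summaries for
  ``n_males`` males.  Each male has a latent 7-trait kinematic profile
  drawn from a factor-structured multivariate normal (velocities strongly
  correlated), both treatments share that profile, and an additive
  ``dye_effect`` plus independent within-male measurement noise separates
  the two samples.  The kinematic ordering VSL ≤ VCL, VAP ≤ VCL holds by
  construction (VCL is taken as the maximum of the three velocities).

* :func:`generate_fertilisation` draws reciprocal-cross trial triplets.
  Per pair a fertilisation probability z_i is drawn around the observed
  mean rate, the focal male's undyed share of fertilised eggs is
  logistic(logit(baseline) + pair noise + observation noise), and dyeing
  subtracts ``dye_delta`` on the probability scale (a logit-scale option
  exists).  Cross C draws the overall fertilised count; crosses A and B
  draw the dyed male's labelled count among the fertilised eggs.

:func:`paired_binomial_dataset` is the stripped-down observation model of
the power simulation: per pair one binomial draw per treatment arm,
directly as grouped GLMM observations.
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np
from scipy import special

from .config import ConfigError, FertilisationGenConfig, MotilityGenConfig
from .glmm import GLMMData
from .records import TRAITS, FertilisationTrial, MotilitySample

_VEL_IDX = {t: i for i, t in enumerate(TRAITS)}


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def generate_motility(cfg: MotilityGenConfig, seed) -> List[MotilitySample]:
    """Draw 2·n_males paired CASA summaries (one dyed, one undyed per male)."""
    cfg.validate()
    rng = _rng(seed)
    p = len(TRAITS)
    means = np.asarray(cfg.trait_means, float)
    cov = np.asarray(cfg.trait_cov, float)
    dye = np.asarray(cfg.dye_effect, float)
    if dye.shape != (p,):
        raise ConfigError(f"dye_effect must have length {p}")
    # within-male measurement noise shares the trait covariance structure,
    # so paired differences keep the strong inter-trait correlations that
    # make the difference-PCA low-dimensional
    noise_cov = cfg.within_male_noise_frac ** 2 * cov

    latent = rng.multivariate_normal(means, cov, size=cfg.n_males,
                                     method="cholesky")
    samples: List[MotilitySample] = []
    for i in range(cfg.n_males):
        male_id = f"M{i + 1:02d}"
        # one shared logit motile fraction per male, jittered per sample
        logit_p = rng.normal(special.logit(cfg.pct_motile_mean), 0.5)
        for treatment in ("undyed", "dyed"):
            traits = latent[i] + rng.multivariate_normal(
                np.zeros(p), noise_cov, method="cholesky")
            if treatment == "dyed":
                traits = traits + dye
            vap, vsl = traits[_VEL_IDX["vap"]], traits[_VEL_IDX["vsl"]]
            vcl = max(traits[_VEL_IDX["vcl"]], vap, vsl)  # ordering by construction
            vap, vsl, vcl = (max(v, 0.0) for v in (vap, vsl, vcl))
            str_r = float(np.clip(traits[_VEL_IDX["str"]], 0.0, 1.0))
            lin_r = float(np.clip(traits[_VEL_IDX["lin"]], 0.0, 1.0))
            alh = max(float(traits[_VEL_IDX["alh"]]), 0.0)
            bcf = max(float(traits[_VEL_IDX["bcf"]]), 0.0)
            p_motile = special.expit(logit_p + rng.normal(0.0, 0.15))
            motile = max(
                int(round(rng.normal(cfg.cells_per_sample_mean,
                                     cfg.cells_per_sample_sd))), 10,
            )
            total = max(motile, int(round(motile / p_motile)))
            samples.append(
                MotilitySample(
                    male_id=male_id, treatment=treatment,
                    motile_count=motile, total_count=total,
                    vap=float(vap), vsl=float(vsl), vcl=float(vcl),
                    str_ratio=str_r, lin_ratio=lin_r, alh=alh, bcf=bcf,
                )
            )
    return samples


def _share_pair(cfg: FertilisationGenConfig, rng: np.random.Generator):
    """Focal undyed share and the two dyed shares (crosses A and B).

    The pair effect u is shared; each cross's share carries its own
    observation-level logit noise, so the dyed and (derived) undyed
    observations have independent extra-binomial variation.
    """
    lo, hi = cfg.share_clamp
    u = rng.normal(0.0, cfg.pair_sd) if cfg.pair_sd > 0 else 0.0
    base = special.logit(cfg.baseline_share) + u
    e_a = rng.normal(0.0, cfg.obs_sd) if cfg.obs_sd > 0 else 0.0
    e_b = rng.normal(0.0, cfg.obs_sd) if cfg.obs_sd > 0 else 0.0
    p_undyed = float(np.clip(special.expit(base), lo, hi))
    p_focal_a = float(special.expit(base + e_a))   # focal share realised in cross A
    p_focal_b = float(special.expit(base + e_b))   # focal share realised in cross B
    if cfg.effect_scale == "probability":
        focal_dyed = float(np.clip(p_focal_a - cfg.dye_delta, lo, hi))
        rival_dyed = float(np.clip((1.0 - p_focal_b) - cfg.dye_delta, lo, hi))
    else:  # logit-scale decrease
        focal_dyed = float(np.clip(
            special.expit(special.logit(p_focal_a) - cfg.dye_delta), lo, hi))
        rival_dyed = float(np.clip(
            special.expit(special.logit(1.0 - p_focal_b) - cfg.dye_delta), lo, hi))
    return p_undyed, focal_dyed, rival_dyed


def _fert_rate(cfg: FertilisationGenConfig, rng: np.random.Generator) -> float:
    """Per-pair overall fertilisation probability z_i.

    Beta distribution with mean ``fert_rate_mean`` and SD matched to the
    observed between-pair spread (s.e.m. 0.050 over 10 pairs → SD ≈ 0.158),
    truncated to ``fert_rate_range`` by redrawing.
    """
    mu = cfg.fert_rate_mean
    var = 0.158 ** 2
    nu = mu * (1 - mu) / var - 1.0
    a, b = max(mu * nu, 0.5), max((1 - mu) * nu, 0.5)
    lo, hi = cfg.fert_rate_range
    for _ in range(1000):
        z = float(rng.beta(a, b))
        if lo <= z <= hi:
            return z
    return float(np.clip(z, lo, hi))


def generate_fertilisation(cfg: FertilisationGenConfig, seed) -> List[FertilisationTrial]:
    """Draw 3·n_pairs reciprocal-cross fertilisation trials (A, B, C)."""
    cfg.validate()
    rng = _rng(seed)
    trials: List[FertilisationTrial] = []
    for i in range(cfg.n_pairs):
        pair_id = f"P{i + 1:02d}"
        z = _fert_rate(cfg, rng)
        p_undyed, focal_dyed, rival_dyed = _share_pair(cfg, rng)
        m = cfg.eggs_scored
        fert_a = int(rng.binomial(m, z))
        fert_b = int(rng.binomial(m, z))
        fert_c = int(rng.binomial(m, z))
        lab_a = int(rng.binomial(fert_a, focal_dyed)) if fert_a else 0
        lab_b = int(rng.binomial(fert_b, rival_dyed)) if fert_b else 0
        trials.append(FertilisationTrial(pair_id, "A_focal_dyed", m, fert_a, lab_a))
        trials.append(FertilisationTrial(pair_id, "B_rival_dyed", m, fert_b, lab_b))
        trials.append(FertilisationTrial(pair_id, "C_undyed", m, fert_c, None))
    return trials


def paired_binomial_dataset(
    n_pairs: int,
    eggs_scored: int,
    baseline_share: float,
    dye_delta: float,
    rng: np.random.Generator,
    pair_sd: float = 0.0,
    obs_sd: float = 0.0,
) -> GLMMData:
    """One simulated paired experiment as grouped GLMM observations.

    Per pair: an undyed observation k ~ Binomial(m, p_i) at x = 0 and a
    dyed observation at x = 1 with success probability p_i − dye_delta
    (probability-scale decrease), where p_i = logistic(logit(baseline) +
    pair noise) with optional observation-level logit noise per arm.
    """
    obs = []
    for i in range(n_pairs):
        u = rng.normal(0.0, pair_sd) if pair_sd > 0 else 0.0
        base_logit = special.logit(baseline_share) + u
        for x, delta in ((0.0, 0.0), (1.0, dye_delta)):
            e = rng.normal(0.0, obs_sd) if obs_sd > 0 else 0.0
            p = float(special.expit(base_logit + e)) - delta
            p = float(np.clip(p, 0.001, 0.999))
            k = int(rng.binomial(eggs_scored, p))
            obs.append((f"P{i + 1:02d}", x, k, eggs_scored))
    return GLMMData.from_observations(obs)
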