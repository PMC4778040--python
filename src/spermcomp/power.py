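"""Simulation-based power analysis of the paired dye-effect design.

For each probability-scale effect size δ on a grid, ``n_sims`` paired
binomial experiments are drawn (per pair: one undyed observation at the
baseline share and one dyed observation at baseline − δ, both over
``eggs_scored`` eggs), each is refitted with the random-intercept binomial
logit GLMM, and power is the proportion of two-sided Wald t tests
(residual df = 2·n_pairs − 3) significant at α.  The 0.8-power crossing
of the (isotonically smoothed) curve gives the minimum detectable effect
bracket.

Replicate seeds are derived deterministically from the master seed via
``numpy.random.SeedSequence(master, spawn_key=(delta_index, replicate))``,
so runs are reproducible and trivially parallelisable.  Replicates whose
fit fails to converge are excluded from the denominator and counted; a
grid row losing more than ``max_nonconverged_frac`` of its replicates is
flagged in the log.
"""

from __future__ import annotations

import logging
from typing import Optional, Tuple

import numpy as np
from sklearn.isotonic import IsotonicRegression

from .config import PowerConfig
from .glmm import GLMMError, fit_glmm, wald_test
from .records import PowerCurve
from .simulate import paired_binomial_dataset

log = logging.getLogger("spermcomp.power")


class NoCrossingError(ValueError):
    """The power curve does not cross the target power on the grid."""

    def __init__(self, message: str, direction: str):
        super().__init__(message)
        self.direction = direction  # 'above' (already powered) or 'below'


def replicate_rng(master_seed: int, delta_index: int,
                  replicate: int) -> np.random.Generator:
    """Deterministic per-replicate generator (documented mixing function)."""
    ss = np.random.SeedSequence(master_seed,
                                spawn_key=(delta_index, replicate))
    return np.random.default_rng(ss)


def simulate_one(delta: float, cfg: PowerConfig,
                 rng: np.random.Generator) -> Tuple[Optional[bool], bool]:
    """One replicate: draw, refit, test.  Returns (significant, converged).

    A non-converged fit returns (None, False) and is never counted as
    significant.
    """
    data = paired_binomial_dataset(
        cfg.n_pairs, cfg.eggs_scored, cfg.baseline_share, delta, rng,
        pair_sd=cfg.pair_sd, obs_sd=cfg.obs_sd,
    )
    try:
        fit = fit_glmm(data)
        test = wald_test(fit)
    except GLMMError as exc:
        log.debug("replicate failed: %s", exc)
        return None, False
    return bool(test.p_value < cfg.alpha), True


def power_at(delta: float, cfg: PowerConfig, master_seed: int,
             delta_index: int = 0) -> Tuple[float, float, int]:
    """Monte-Carlo power at one effect size: (power, mc_se, n_converged)."""
    n_sig = n_conv = 0
    for rep in range(cfg.n_sims):
        sig, conv = simulate_one(delta, cfg, replicate_rng(master_seed, delta_index, rep))
        if conv:
            n_conv += 1
            n_sig += int(sig)
    if n_conv == 0:
        raise GLMMError(f"no replicate converged at delta={delta}")
    if cfg.n_sims - n_conv > cfg.max_nonconverged_frac * cfg.n_sims:
        log.warning("delta=%.3g: %d/%d replicates non-converged",
                    delta, cfg.n_sims - n_conv, cfg.n_sims)
    p = n_sig / n_conv
    return p, float(np.sqrt(p * (1 - p) / n_conv)), n_conv


def power_curve(cfg: PowerConfig, master_seed: int = 0) -> PowerCurve:
    """Estimate power across the configured effect-size grid."""
    cfg.validate()
    deltas = np.asarray(list(cfg.delta_grid), float)
    power = np.empty_like(deltas)
    mc_se = np.empty_like(deltas)
    n_conv = np.empty(len(deltas), dtype=int)
    for i, d in enumerate(deltas):
        power[i], mc_se[i], n_conv[i] = power_at(float(d), cfg, master_seed, i)
        log.info("delta=%.3f power=%.3f (mc_se=%.3f, n=%d)",
                 d, power[i], mc_se[i], n_conv[i])
    return PowerCurve(deltas=deltas, power=power, mc_se=mc_se,
                      n_converged=n_conv, n_sims=cfg.n_sims)


def isotonic_power(curve: PowerCurve) -> np.ndarray:
    """Monotone (nondecreasing) smoothing of the raw power estimates."""
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    return iso.fit_transform(curve.deltas, curve.power)


def minimum_detectable_effect(curve: PowerCurve,
                              target_power: float = 0.8
                              ) -> Tuple[float, float]:
    """Grid bracket (delta_lo, delta_hi) where power crosses the target.

    The raw curve is isotonically smoothed first to absorb Monte-Carlo
    noise.  Raises :class:`NoCrossingError` when the whole curve lies on
    one side of the target.
    """
    smooth = isotonic_power(curve)
    if smooth[0] >= target_power:
        raise NoCrossingError(
            f"power is already >= {target_power} at the smallest effect "
            f"({curve.deltas[0]:.3g}); design is already powered", "above",
        )
    if smooth[-1] < target_power:
        raise NoCrossingError(
            f"power stays below {target_power} across the grid "
            f"(max {smooth[-1]:.3f})", "below",
        )
    idx = int(np.argmax(smooth >= target_power))
    return float(curve.deltas[idx - 1]), float(curve.deltas[idx])


def plot_power_curve(curve: PowerCurve, path,
                     target_power: float = 0.8) -> None:
    """Power vs. effect-size figure (proportion of significant tests)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(curve.deltas, curve.power, yerr=curve.mc_se, fmt="o-",
                capsize=3, color="black")
    ax.axhline(target_power, linestyle="--", color="grey")
    ax.set_xlabel("Difference in probability of success when dyed")
    ax.set_ylabel(f"Proportion of significant P values ({curve.n_sims} simulations)")
    ax.set_ylim(0, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
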