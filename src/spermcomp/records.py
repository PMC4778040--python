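"""Domain record types shared by every analysis stage.

The experiment behind these records is a paired dyed/undyed control for a
fluorescent sperm-labelling technique in a broadcast-spawning mussel:

* :class:`MotilitySample` — one computer-assisted sperm analysis (CASA)
  summary for one male under one treatment (mitochondrial dye applied or
  not): motile/total cell counts plus seven kinematic traits.
* :class:`FertilisationTrial` — egg counts from one cross of a reciprocal
  sperm-competition design in which two males compete for one female's
  eggs.  In cross A the focal male's sperm is dyed, in cross B the rival's,
  and in cross C neither (cross C measures the overall fertilisation rate).
* :class:`CompetitionPair` — the assembled paired dyed/undyed competitive
  success observations for one focal/rival/female triplet.

Result containers (:class:`TestResult`, :class:`PCAResult`,
:class:`GLMMFit`, :class:`DispersionReport`, :class:`PowerCurve`) hold the
outputs of the statistical stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

#: Canonical order of the seven CASA kinematic traits.
TRAITS = ("vap", "vsl", "vcl", "str", "lin", "alh", "bcf")

#: Canonical treatment labels.
TREATMENTS = ("dyed", "undyed")

#: Canonical cross labels of the reciprocal design.
CROSSES = ("A_focal_dyed", "B_rival_dyed", "C_undyed")


class ValidationError(ValueError):
    """An input record violates a domain invariant."""


@dataclass(frozen=True)
class MotilitySample:
    """One CASA summary for one male under one dye treatment.

    Velocities are in μm/s, ``alh`` in μm, ``bcf`` in Hz; ``str_ratio``
    (VSL/VCL) and ``lin_ratio`` (VAP/VCL) are dimensionless in [0, 1].
    """

    male_id: str
    treatment: str  # 'dyed' | 'undyed'
    motile_count: int
    total_count: int
    vap: float
    vsl: float
    vcl: float
    str_ratio: float
    lin_ratio: float
    alh: float
    bcf: float

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValidationError(
                f"treatment must be one of {TREATMENTS}, got {self.treatment!r}"
            )
        if self.total_count <= 0:
            raise ValidationError(f"total_count must be positive ({self.male_id})")
        if not 0 <= self.motile_count <= self.total_count:
            raise ValidationError(
                f"motile_count {self.motile_count} exceeds total_count "
                f"{self.total_count} for male {self.male_id!r}"
            )
        for name in ("vap", "vsl", "vcl", "alh", "bcf"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative ({self.male_id})")

    @property
    def percent_motile(self) -> float:
        return 100.0 * self.motile_count / self.total_count

    def kinematic_ordering_ok(self, rtol: float = 1e-9) -> bool:
        """VSL ≤ VCL and VAP ≤ VCL (the curvilinear path is the longest)."""
        lim = self.vcl * (1 + rtol)
        return self.vsl <= lim and self.vap <= lim

    def trait_vector(self) -> np.ndarray:
        return np.array(
            [self.vap, self.vsl, self.vcl, self.str_ratio, self.lin_ratio,
             self.alh, self.bcf]
        )


@dataclass(frozen=True)
class FertilisationTrial:
    """Egg counts from one cross (A, B or C) of one competing pair.

    ``labelled_count`` is the number of fertilised eggs carrying fluorescent
    sperm mitochondria; it is absent (None) for cross C, where no sperm are
    dyed.
    """

    pair_id: str
    cross: str  # one of CROSSES
    eggs_scored: int
    fertilised_count: int
    labelled_count: Optional[int] = None

    def __post_init__(self) -> None:
        if self.cross not in CROSSES:
            raise ValidationError(
                f"cross must be one of {CROSSES}, got {self.cross!r}"
            )
        if self.eggs_scored <= 0:
            raise ValidationError(f"eggs_scored must be positive ({self.pair_id})")
        if not 0 <= self.fertilised_count <= self.eggs_scored:
            raise ValidationError(
                f"fertilised_count {self.fertilised_count} out of range for "
                f"pair {self.pair_id!r} cross {self.cross}"
            )
        if self.cross == "C_undyed":
            if self.labelled_count is not None:
                raise ValidationError(
                    f"labelled_count must be absent for cross C (pair {self.pair_id!r})"
                )
        else:
            if self.labelled_count is None:
                raise ValidationError(
                    f"labelled_count required for cross {self.cross} "
                    f"(pair {self.pair_id!r})"
                )
            if not 0 <= self.labelled_count <= self.fertilised_count:
                raise ValidationError(
                    f"labelled_count {self.labelled_count} exceeds fertilised_count "
                    f"{self.fertilised_count} for pair {self.pair_id!r}"
                )


@dataclass(frozen=True)
class CompetitionPair:
    """Paired dyed/undyed competitive-success observations for one triplet.

    X is the focal male's success when dyed (from cross A), Y the rival's
    when dyed (from cross B) and Z the overall fertilisation rate (cross C).
    Under the null of no dye effect X = Z − Y, so the focal male's undyed
    success is estimated as (Z − Y)/Z and expressed as binomial counts over
    the fertilised eggs of cross C.
    """

    pair_id: str
    X: float
    Y: float
    Z: float
    k_dyed: int
    m_dyed: int
    k_undyed: int
    m_undyed: int
    dyed_share: float
    undyed_share: float
    flagged: bool = False  # implied undyed success was negative, truncated to 0

    def __post_init__(self) -> None:
        for name in ("X", "Y", "Z", "dyed_share", "undyed_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1] (pair {self.pair_id})")
        if not 0 <= self.k_dyed <= self.m_dyed:
            raise ValidationError(f"dyed counts invalid for pair {self.pair_id}")
        if not 0 <= self.k_undyed <= self.m_undyed:
            raise ValidationError(f"undyed counts invalid for pair {self.pair_id}")


@dataclass(frozen=True)
class TestResult:
    """A t-type (or z-type) test: statistic, reference df, two-sided p."""

    statistic: float
    df: float
    p_value: float
    estimate: float
    stderr: float
    kind: str = "t"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(f"p_value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class PCAResult:
    """Correlation-matrix PCA of paired trait differences.

    ``loadings`` are variable–component correlations (|loading| ≤ 1);
    eigenvalues sum to the number of traits; ``scores`` have column mean
    zero because the input is centred.
    """

    traits: Sequence[str]
    eigenvalues: np.ndarray          # (p,), nonincreasing
    loadings: np.ndarray             # (p traits, p components)
    scores: np.ndarray               # (n males, p components)
    retained: np.ndarray             # indices of components with λ > threshold
    cum_var_pct: np.ndarray          # (p,)
    male_ids: Sequence[str] = ()

    @property
    def n_retained(self) -> int:
        return int(len(self.retained))


@dataclass
class GLMMFit:
    """A fitted random-intercept binomial logit mixed model.

    ``sigma_u`` is the pair-level random-intercept SD on the logit scale;
    ``sigma_obs`` the observation-level random effect (OLRE) SD, present
    only in the OLRE variant. ``loglik`` is the Laplace-approximated
    marginal log-likelihood. ``conditional_modes`` are the per-group
    posterior modes of the random intercepts.
    """

    beta0: float
    beta1: float
    sigma_u: float
    loglik: float
    se_beta0: float
    se_beta1: float
    conditional_modes: np.ndarray
    n_obs: int
    n_groups: int
    sigma_obs: Optional[float] = None
    olre_modes: Optional[np.ndarray] = None
    n_fixed: int = 2
    boundary: bool = False
    converged: bool = True
    separation: bool = False
    loglik_trace: list = field(default_factory=list)

    @property
    def has_olre(self) -> bool:
        return self.sigma_obs is not None


@dataclass(frozen=True)
class DispersionReport:
    """Residual deviance / Pearson chi-square diagnostics of a binomial fit.

    A well-specified binomial model has dispersion ≈ 1; values well above 1
    indicate overdispersion.
    """

    residual_deviance: float
    pearson_chi2: float
    residual_df: int
    dispersion_deviance: float
    dispersion_pearson: float

    def __post_init__(self) -> None:
        if self.residual_df < 1:
            raise ValidationError("residual_df must be >= 1")


@dataclass(frozen=True)
class PowerCurve:
    """Monte-Carlo power estimates over a grid of probability-scale effects."""

    deltas: np.ndarray       # ordered effect sizes
    power: np.ndarray        # proportion of significant replicates
    mc_se: np.ndarray        # sqrt(p(1-p)/n) Monte-Carlo standard errors
    n_converged: np.ndarray  # replicates entering each denominator
    n_sims: int

    def __post_init__(self) -> None:
        d = np.asarray(self.deltas, float)
        if np.any(np.diff(d) <= 0):
            raise ValidationError("deltas must be strictly increasing")
        if np.any((np.asarray(self.power) < 0) | (np.asarray(self.power) > 1)):
            raise ValidationError("power outside [0, 1]")

    def to_records(self):
        return [
            {
                "delta": float(d), "power": float(p), "mc_se": float(s),
                "n_converged": int(c),
            }
            for d, p, s, c in zip(self.deltas, self.power, self.mc_se, self.n_converged)
        ]


def record_to_dict(obj):
    """Dataclass → plain dict with numpy types converted to builtins."""
    def convert(v):
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        if isinstance(v, dict):
            return {k: convert(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [convert(x) for x in v]
        return v

    return {k: convert(v) for k, v in asdict(obj).items()}
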