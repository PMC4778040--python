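"""Paired dyed/undyed sperm-motility pipeline.

The workflow mirrors a standard paired CASA comparison: a paired t-test on
percent motile; per-male, per-trait differences (undyed − dyed) with a
Shapiro–Wilk normality screen and a square-root transform for flagged
traits (applied to the raw values before differencing, since differences
can be negative); PCA of the 7 difference columns on the correlation
matrix with Kaiser retention (eigenvalue > 1); and one-sample t-tests on
the retained component scores.

Note a structural property of the last step: PCA scores of centred data
have column mean exactly zero, so a one-sample t-test of a score column
against zero is identically ~0 regardless of the data.  The pipeline
reproduces the procedure as published and flags this property in its
output rather than silently substituting a different test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .records import TRAITS, MotilitySample, PCAResult, TestResult

TRANSFORM_NONE = "none"
TRANSFORM_SQRT = "sqrt"


class InsufficientDataError(ValueError):
    pass


class DegenerateInputError(ValueError):
    pass


@dataclass
class PairedDifferenceSet:
    """Per-male undyed − dyed trait differences, one row per male."""

    male_ids: List[str]
    traits: Tuple[str, ...]
    diffs: np.ndarray                      # (n_males, 7)
    transformed_flags: Dict[str, str] = field(default_factory=dict)

    @property
    def n_males(self) -> int:
        return len(self.male_ids)


def _paired_samples(samples: Iterable[MotilitySample]):
    """Group into {male_id: {treatment: sample}}, sorted by male_id."""
    by_male: Dict[str, Dict[str, MotilitySample]] = {}
    for s in samples:
        by_male.setdefault(s.male_id, {})[s.treatment] = s
    incomplete = [m for m, d in by_male.items() if set(d) != {"dyed", "undyed"}]
    if incomplete:
        raise InsufficientDataError(
            "incomplete dyed/undyed pair for male(s): " + ", ".join(sorted(incomplete))
        )
    return {m: by_male[m] for m in sorted(by_male)}


def _one_sample_t(values: np.ndarray) -> TestResult:
    n = len(values)
    mean = float(np.mean(values))
    se = float(np.std(values, ddof=1) / math.sqrt(n))
    if se == 0.0:
        # degenerate: all values identical; t is 0/0 for mean 0 (no
        # evidence against the null) and unbounded otherwise
        t = 0.0 if mean == 0.0 else math.copysign(math.inf, mean)
        p = 1.0 if mean == 0.0 else 0.0
    else:
        t, p = (float(v) for v in stats.ttest_1samp(values, 0.0))
    return TestResult(statistic=float(t), df=float(n - 1), p_value=float(p),
                      estimate=mean, stderr=se)


def percent_motile_test(samples: Iterable[MotilitySample]) -> TestResult:
    """Paired t-test on percent motile sperm (undyed − dyed differences)."""
    pairs = _paired_samples(samples)
    if len(pairs) < 2:
        raise InsufficientDataError("paired t-test needs at least 2 males")
    diffs = np.array([
        p["undyed"].percent_motile - p["dyed"].percent_motile
        for p in pairs.values()
    ])
    return _one_sample_t(diffs)


def compute_differences(
    samples: Iterable[MotilitySample],
    transforms: Optional[Sequence[str]] = ("bcf",),
) -> PairedDifferenceSet:
    """Undyed − dyed difference per male and trait.

    ``transforms`` names the traits whose raw values are square-root
    transformed before differencing (default: BCF, the study's choice);
    pass None or () for no transform.
    """
    transforms = set(transforms or ())
    unknown = transforms - set(TRAITS)
    if unknown:
        raise ValueError(f"unknown trait(s) in transform policy: {sorted(unknown)}")
    pairs = _paired_samples(samples)
    male_ids = list(pairs)
    rows = []
    for m in male_ids:
        undyed = pairs[m]["undyed"].trait_vector()
        dyed = pairs[m]["dyed"].trait_vector()
        row = np.empty(len(TRAITS))
        for j, trait in enumerate(TRAITS):
            a, b = undyed[j], dyed[j]
            if trait in transforms:
                if a < 0 or b < 0:
                    raise ValueError(
                        f"square-root transform undefined for negative {trait} "
                        f"(male {m})"
                    )
                a, b = math.sqrt(a), math.sqrt(b)
            row[j] = a - b
        rows.append(row)
    flags = {t: (TRANSFORM_SQRT if t in transforms else TRANSFORM_NONE)
             for t in TRAITS}
    return PairedDifferenceSet(
        male_ids=male_ids, traits=TRAITS, diffs=np.array(rows),
        transformed_flags=flags,
    )


def normality_screen(diffs: PairedDifferenceSet, alpha: float = 0.05
                     ) -> Dict[str, dict]:
    """Shapiro–Wilk test of each trait's difference column.

    Traits with p ≤ alpha are flagged for transform-and-rescreen.
    """
    if diffs.n_males < 3:
        raise InsufficientDataError("Shapiro-Wilk needs n >= 3")
    out = {}
    for j, trait in enumerate(diffs.traits):
        col = diffs.diffs[:, j]
        if np.ptp(col) == 0:
            raise DegenerateInputError(
                f"constant difference column for trait {trait!r}: W undefined"
            )
        w, p = stats.shapiro(col)
        out[trait] = {"W": float(w), "p_value": float(p), "flagged": bool(p <= alpha)}
    return out


def pca_differences(diffs: PairedDifferenceSet,
                    eigenvalue_threshold: float = 1.0) -> PCAResult:
    """Correlation-matrix PCA of the difference columns.

    Loadings are variable–component correlations (eigenvector × √λ), each
    component oriented so its largest-magnitude loading is positive;
    scores are the standardized data projected on the eigenvectors, so
    their column means are exactly zero and their variances are the
    eigenvalues.
    """
    X = diffs.diffs
    n, p = X.shape
    if n < 3:
        raise InsufficientDataError("PCA needs at least 3 males")
    sd = X.std(axis=0, ddof=1)
    dead = [t for t, s in zip(diffs.traits, sd) if s == 0]
    if dead:
        raise DegenerateInputError(
            "zero-variance difference column(s): " + ", ".join(dead)
        )
    Z = (X - X.mean(axis=0)) / sd
    R = (Z.T @ Z) / (n - 1)
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    loadings = evecs * np.sqrt(evals)
    for j in range(p):
        if loadings[np.argmax(np.abs(loadings[:, j])), j] < 0:
            loadings[:, j] *= -1
            evecs[:, j] *= -1
    scores = Z @ evecs
    retained = np.flatnonzero(evals > eigenvalue_threshold)
    cum_var = 100.0 * np.cumsum(evals) / p
    return PCAResult(
        traits=diffs.traits, eigenvalues=evals, loadings=loadings,
        scores=scores, retained=retained, cum_var_pct=cum_var,
        male_ids=diffs.male_ids,
    )


def pc_score_tests(pca: PCAResult, alpha: float = 0.05) -> List[TestResult]:
    """One-sample t-test (H0: μ = 0) per retained component's scores.

    Centred PCA scores have mean exactly zero, so these statistics are
    ~0 up to floating-point round-off for any input; see module docstring.
    """
    if pca.n_retained < 1:
        raise InsufficientDataError("no retained components to test")
    return [_one_sample_t(pca.scores[:, j]) for j in pca.retained]


@dataclass
class MotilityResult:
    """Full paired-motility analysis output."""

    percent_motile: TestResult
    screen_initial: Dict[str, dict]
    transforms_applied: Tuple[str, ...]
    screen_final: Dict[str, dict]
    differences: PairedDifferenceSet
    pca: PCAResult
    pc_tests: List[TestResult]
    notes: Tuple[str, ...] = ()


def run_motility_analysis(samples: Iterable[MotilitySample],
                          alpha: float = 0.05,
                          eigenvalue_threshold: float = 1.0) -> MotilityResult:
    """Screen → transform flagged traits → re-screen → PCA → score tests."""
    samples = list(samples)
    pct = percent_motile_test(samples)
    raw = compute_differences(samples, transforms=None)
    screen0 = normality_screen(raw, alpha)
    flagged = tuple(t for t, r in screen0.items() if r["flagged"])
    diffs = compute_differences(samples, transforms=flagged)
    screen1 = normality_screen(diffs, alpha) if flagged else screen0
    pca = pca_differences(diffs, eigenvalue_threshold)
    tests = pc_score_tests(pca, alpha) if pca.n_retained else []
    notes = (
        "One-sample t-tests on PC scores are structurally ~0: centred PCA "
        "scores have mean exactly zero for any input.",
    )
    return MotilityResult(
        percent_motile=pct, screen_initial=screen0, transforms_applied=flagged,
        screen_final=screen1, differences=diffs, pca=pca, pc_tests=tests,
        notes=notes,
    )


def pca_table(pca: PCAResult) -> "object":
    """Loadings table with eigenvalue and cumulative-variance rows appended."""
    import pandas as pd

    cols = [f"PC{j + 1}" for j in range(len(pca.eigenvalues))]
    body = pd.DataFrame(pca.loadings, index=list(pca.traits), columns=cols)
    body.loc["eigenvalue"] = pca.eigenvalues
    body.loc["cum_var_pct"] = pca.cum_var_pct
    return body
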