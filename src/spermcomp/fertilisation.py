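"""Reciprocal-cross assembly and the dye-effect GLMM comparison.

The design: each pair of competing males (focal, rival) is crossed three
times with the same female's eggs.  Cross A dyes the focal male's sperm
and yields his dyed success X; cross B dyes the rival's sperm and yields
the rival's dyed success Y; cross C dyes nobody and yields the overall
fertilisation rate Z.  Under the null of no dye effect X = Z − Y, so the
focal male's undyed success is estimated as (Z − Y)/Z.

Success is modelled as the focal male's SHARE of fertilised eggs —
proportions with denominator Z.  Two conventions for measuring Y are
supported:

* ``share`` (default): Y is the rival's share of the fertilised eggs in
  cross B (labelled_B / fertilised_B), so the focal undyed share is
  1 − Y_share, which is always in [0, 1].
* ``rate``: Y is the rival's success per egg scored
  (labelled_B / eggs_scored_B) and the undyed share is (Z − Y)/Z, which
  can be negative when sampling noise puts Y above Z; such pairs are
  truncated to 0 and flagged, never dropped.

Either way the undyed share is converted back to binomial counts over the
fertilised eggs of cross C (round-half-even), and the paired dyed/undyed
observations feed a binomial logit GLMM with a fixed dye effect and a
random pair intercept, with Wald t inference, both dispersion flavours,
and the observation-level random effect (OLRE) variant alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, List, Optional

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .glmm import (
    GLMMData,
    GLMMError,
    GLMMFit,
    dispersion,
    fit_glmm,
    wald_test,
)
from .records import (
    CompetitionPair,
    DispersionReport,
    FertilisationTrial,
    TestResult,
)

log = logging.getLogger("spermcomp.fertilisation")


class DataInconsistencyError(ValueError):
    pass


def _round_half_even(x: float) -> int:
    return int(round(x))  # Python's round is banker's rounding


def assemble_pairs(trials: Iterable[FertilisationTrial],
                   share_convention: str = "share") -> List[CompetitionPair]:
    """Assemble A/B/C triplets into paired dyed/undyed observations.

    Pairs with zero fertilised eggs in cross C (Z = 0) are excluded with a
    logged reason; a pair whose implied undyed success is negative (rate
    convention only) is truncated to zero and flagged.
    """
    if share_convention not in ("share", "rate"):
        raise ValueError("share_convention must be 'share' or 'rate'")
    by_pair = {}
    for t in trials:
        by_pair.setdefault(t.pair_id, {})[t.cross] = t
    pairs: List[CompetitionPair] = []
    for pid in sorted(by_pair):
        crosses = by_pair[pid]
        missing = {"A_focal_dyed", "B_rival_dyed", "C_undyed"} - set(crosses)
        if missing:
            raise DataInconsistencyError(
                f"pair {pid!r} missing cross(es): {', '.join(sorted(missing))}"
            )
        a, b, c = (crosses["A_focal_dyed"], crosses["B_rival_dyed"],
                   crosses["C_undyed"])
        if a.fertilised_count == 0 and (a.labelled_count or 0) > 0:
            raise DataInconsistencyError(
                f"pair {pid!r}: labelled eggs without fertilised eggs in cross A"
            )
        Z = c.fertilised_count / c.eggs_scored
        if c.fertilised_count == 0 or a.fertilised_count == 0:
            log.warning("pair %s excluded: no fertilised eggs in cross %s",
                        pid, "C" if c.fertilised_count == 0 else "A")
            continue
        X = a.labelled_count / a.fertilised_count
        dyed_share = X
        flagged = False
        if share_convention == "share":
            y_share = b.labelled_count / b.fertilised_count if b.fertilised_count else 0.0
            Y = y_share
            undyed_share = 1.0 - y_share
        else:
            Y = b.labelled_count / b.eggs_scored
            undyed_share = (Z - Y) / Z
            if undyed_share < 0:
                flagged = True
                undyed_share = 0.0
            undyed_share = min(undyed_share, 1.0)
        m_undyed = c.fertilised_count
        k_undyed = min(_round_half_even(undyed_share * m_undyed), m_undyed)
        pairs.append(
            CompetitionPair(
                pair_id=pid, X=X, Y=Y, Z=Z,
                k_dyed=a.labelled_count, m_dyed=a.fertilised_count,
                k_undyed=k_undyed, m_undyed=m_undyed,
                dyed_share=dyed_share, undyed_share=undyed_share,
                flagged=flagged,
            )
        )
    return pairs


def pairs_to_glmm_data(pairs: Iterable[CompetitionPair]) -> GLMMData:
    """Two observations per pair: undyed (x = 0) and dyed (x = 1)."""
    obs = []
    for p in pairs:
        obs.append((p.pair_id, 0.0, p.k_undyed, p.m_undyed))
        obs.append((p.pair_id, 1.0, p.k_dyed, p.m_dyed))
    return GLMMData.from_observations(obs)


@dataclass
class DyeEffectResult:
    """Dye-effect comparison: base GLMM, OLRE variant, and descriptives."""

    fit: GLMMFit
    test: TestResult
    dispersion: DispersionReport
    olre_fit: Optional[GLMMFit]
    olre_test: Optional[TestResult]
    olre_dispersion: Optional[DispersionReport]
    pair_table: pd.DataFrame
    summary: dict = field(default_factory=dict)


def dye_effect_analysis(pairs: Iterable[CompetitionPair],
                        cfg: Optional[AnalysisConfig] = None,
                        olre: bool = True) -> DyeEffectResult:
    """Fit the dye-effect GLMM (and OLRE variant) on assembled pairs.

    Reports the Wald t on the dye coefficient, both dispersion flavours,
    a per-pair table of X, Y, Z and the dyed/undyed shares, and the
    descriptive summary of the dyed − undyed share difference (mean,
    s.e.m., range).
    """
    cfg = cfg or AnalysisConfig()
    pairs = list(pairs)
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs")
    data = pairs_to_glmm_data(pairs)
    fit = fit_glmm(data, olre=False)
    infl = None
    if cfg.se_inflation:
        infl = dispersion(fit, data).dispersion_pearson
    test = wald_test(fit, se_inflation=infl)
    disp = dispersion(fit, data)

    olre_fit = olre_test = olre_disp = None
    if olre:
        try:
            olre_fit = fit_glmm(data, olre=True)
            olre_test = wald_test(olre_fit, dist="z")
            olre_disp = dispersion(olre_fit, data)
        except GLMMError as exc:
            log.warning("OLRE variant failed: %s", exc)

    table = pd.DataFrame([
        {
            "pair_id": p.pair_id, "X": p.X, "Y": p.Y, "Z": p.Z,
            "dyed_share": p.dyed_share, "undyed_share": p.undyed_share,
            "flagged": p.flagged,
        }
        for p in pairs
    ])
    diff = table["dyed_share"] - table["undyed_share"]
    summary = {
        "mean_difference": float(diff.mean()),
        "sem_difference": float(diff.std(ddof=1) / np.sqrt(len(diff))),
        "range_difference": [float(diff.min()), float(diff.max())],
        "mean_fertilisation_rate": float(table["Z"].mean()),
        "sem_fertilisation_rate": float(table["Z"].std(ddof=1) / np.sqrt(len(table))),
        "range_fertilisation_rate": [float(table["Z"].min()), float(table["Z"].max())],
        "n_pairs": len(pairs),
        "n_flagged": int(table["flagged"].sum()),
    }
    return DyeEffectResult(
        fit=fit, test=test, dispersion=disp,
        olre_fit=olre_fit, olre_test=olre_test, olre_dispersion=olre_disp,
        pair_table=table, summary=summary,
    )
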