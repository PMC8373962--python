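"""Biogeochemical screening diagnostics for nitrate pollution.

Three screens, all operating on :class:`~nitratrace.datatypes.SampleRecord`
collections:

* **Nitrification δ¹⁸O window** — nitrate produced by nitrification takes
  one oxygen atom in three from dissolved O₂ and the other two from ambient
  water, so its δ¹⁸O is bounded by
  ``(1/3)·δ¹⁸O–O₂ + (2/3)·δ¹⁸O–H₂O`` evaluated at the ambient-water
  extremes.  Samples are classified as below / within / above the window.

* **Denitrification / mixing correlations** — denitrification preferentially
  removes light isotopes, leaving residual nitrate enriched along a Rayleigh
  trend: δ¹⁵N falls linearly in ln(NO₃⁻) with negative slope, and δ¹⁵N and
  δ¹⁸O rise together.  Pearson correlations of (δ¹⁵N, ln NO₃⁻),
  (δ¹⁸O, δ¹⁵N) and (conductivity, NO₃⁻) are screened against a
  configurable significance level and mapped to interpretations by an
  overridable rule table.

* **Exceedance flags** — per-sample comparison of NO₃⁻ against the WHO
  drinking-water guideline (50 mg/L) and TN against a configurable
  surface-water-standard threshold, both strict inequalities.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats

from .datatypes import SampleRecord

logger = logging.getLogger(__name__)

__all__ = [
    "NitrificationWindow",
    "NitrificationStatus",
    "Interpretation",
    "CorrelationDiagnostic",
    "ExceedanceFlags",
    "nitrification_o18_range",
    "classify_nitrification",
    "pearson_with_p",
    "denitrification_assessment",
    "exceedance_flags",
]

D18O_O2_DEFAULT = 23.5  # ‰, atmospheric dissolved O2


@dataclass(frozen=True)
class NitrificationWindow:
    """Theoretical δ¹⁸O–NO₃⁻ bounds for nitrification-produced nitrate."""

    lo: float
    hi: float
    d18O_O2: float = D18O_O2_DEFAULT
    d18O_H2O_range: tuple[float, float] = (0.0, 0.0)


class NitrificationStatus(str, Enum):
    WITHIN = "within"
    ABOVE = "above"
    BELOW = "below"
    NOT_EVALUABLE = "not_evaluable"


class Interpretation(str, Enum):
    DENITRIFICATION = "denitrification_signal"
    MIXING_OR_NONE = "mixing_or_none"
    NOT_SIGNIFICANT = "not_significant"


@dataclass(frozen=True)
class CorrelationDiagnostic:
    pair: str  # d15N_vs_lnNO3 | d18O_vs_d15N | cond_vs_no3
    r: float | None
    p: float | None
    n: int
    interpretation: Interpretation


@dataclass(frozen=True)
class ExceedanceFlags:
    sample_id: str
    who_no3_exceeded: bool | None  # None = not evaluable
    class_v_tn_exceeded: bool | None
    who_threshold: float
    class_v_threshold: float


def nitrification_o18_range(
    d18O_H2O_min: float,
    d18O_H2O_max: float,
    d18O_O2: float = D18O_O2_DEFAULT,
) -> NitrificationWindow:
    """One-third/two-thirds oxygen mass balance for nitrification:

    bound = (1/3)·δ¹⁸O–O₂ + (2/3)·δ¹⁸O–H₂O, at each ambient-water extreme.
    """
    if d18O_H2O_min > d18O_H2O_max:
        raise ValueError("d18O_H2O_min must not exceed d18O_H2O_max")
    lo = d18O_O2 / 3.0 + 2.0 * d18O_H2O_min / 3.0
    hi = d18O_O2 / 3.0 + 2.0 * d18O_H2O_max / 3.0
    return NitrificationWindow(
        lo=lo, hi=hi, d18O_O2=d18O_O2, d18O_H2O_range=(d18O_H2O_min, d18O_H2O_max)
    )


def classify_nitrification(
    samples: Sequence[SampleRecord], window: NitrificationWindow
) -> dict[str, NitrificationStatus]:
    """Compare each sample's δ¹⁸O–NO₃⁻ to the closed interval [lo, hi]."""
    out = {}
    for s in samples:
        v = s.tracer("d18O_NO3")
        if v is None:
            out[s.sample_id] = NitrificationStatus.NOT_EVALUABLE
        elif v < window.lo:
            out[s.sample_id] = NitrificationStatus.BELOW
        elif v > window.hi:
            out[s.sample_id] = NitrificationStatus.ABOVE
        else:
            out[s.sample_id] = NitrificationStatus.WITHIN
    return out


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float | None, float | None, int]:
    """Pearson r and the two-tailed p from the t distribution on n − 2 df.

    Pairs with a missing (None/NaN) member are dropped; ``n`` counts
    retained pairs.  Zero variance in either variable → (None, None, n).
    """
    pairs = [
        (a, b)
        for a, b in zip(x, y)
        if a is not None and b is not None and math.isfinite(a) and math.isfinite(b)
    ]
    n = len(pairs)
    if n < 3:
        return None, None, n
    xa = np.array([p[0] for p in pairs])
    ya = np.array([p[1] for p in pairs])
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        logger.info("zero variance; Pearson r not evaluable")
        return None, None, n
    res = stats.pearsonr(xa, ya)
    return float(res.statistic), float(res.pvalue), n


# The default rule table codifies the narrative logic of isotope
# biogeochemistry: a significant negative d15N-ln(NO3) relation (Rayleigh
# behavior) or a significant positive d15N-d18O coupling indicates
# denitrification; a significant negative d15N-d18O relation indicates
# mixing with no heavy-isotope enrichment.
DEFAULT_RULES = {
    ("d15N_vs_lnNO3", "negative"): Interpretation.DENITRIFICATION,
    ("d18O_vs_d15N", "positive"): Interpretation.DENITRIFICATION,
    ("d18O_vs_d15N", "negative"): Interpretation.MIXING_OR_NONE,
}


def _interpret(pair: str, r: float | None, p: float | None, alpha: float, rules) -> Interpretation:
    if r is None or p is None or p >= alpha:
        return Interpretation.NOT_SIGNIFICANT
    direction = "negative" if r < 0 else "positive"
    return rules.get((pair, direction), Interpretation.NOT_SIGNIFICANT)


def denitrification_assessment(
    samples: Sequence[SampleRecord],
    alpha: float = 0.01,
    rules: dict | None = None,
) -> list[CorrelationDiagnostic]:
    """Correlation screen of one region/group of samples.

    Computes (a) r(δ¹⁵N, ln NO₃⁻), (b) r(δ¹⁸O, δ¹⁵N), and
    (c) r(conductivity, NO₃⁻), each with a two-tailed p, and maps each to
    an interpretation via the rule table.  Samples with NO₃⁻ ≤ 0 are
    dropped pairwise from (a) with a logged notice (log undefined).
    """
    rules = DEFAULT_RULES if rules is None else rules
    out: list[CorrelationDiagnostic] = []

    d15 = [s.tracer("d15N_NO3") for s in samples]
    d18 = [s.tracer("d18O_NO3") for s in samples]
    no3 = [s.no3 for s in samples]
    cond = [s.cond for s in samples]

    ln_no3: list[float | None] = []
    n_nonpos = 0
    for c in no3:
        if c is None:
            ln_no3.append(None)
        elif c <= 0:
            ln_no3.append(None)
            n_nonpos += 1
        else:
            ln_no3.append(math.log(c))
    if n_nonpos:
        logger.info("dropped %d samples with NO3- <= 0 from ln(NO3-) pair", n_nonpos)

    for pair, (xv, yv) in {
        "d15N_vs_lnNO3": (d15, ln_no3),
        "d18O_vs_d15N": (d18, d15),
        "cond_vs_no3": (cond, no3),
    }.items():
        r, p, n = pearson_with_p(xv, yv)
        out.append(
            CorrelationDiagnostic(
                pair=pair, r=r, p=p, n=n,
                interpretation=_interpret(pair, r, p, alpha, rules),
            )
        )
    return out


def exceedance_flags(
    samples: Sequence[SampleRecord],
    who_no3_threshold: float = 50.0,
    class_v_tn_threshold: float = 2.0,
) -> list[ExceedanceFlags]:
    """Strict-inequality exceedance flags; missing concentrations are
    reported as not evaluable (None), never as False."""
    if who_no3_threshold <= 0 or class_v_tn_threshold <= 0:
        raise ValueError("thresholds must be positive")
    out = []
    for s in samples:
        out.append(
            ExceedanceFlags(
                sample_id=s.sample_id,
                who_no3_exceeded=None if s.no3 is None else s.no3 > who_no3_threshold,
                class_v_tn_exceeded=None if s.tn is None else s.tn > class_v_tn_threshold,
                who_threshold=who_no3_threshold,
                class_v_threshold=class_v_tn_threshold,
            )
        )
    return out
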