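"""Virology readout statistics: restriction ratios and normalised titres.

The two-colour restriction assay infects a mixed population in which only
some cells express the restriction factor (EYFP+).  The readout is the
ratio of the infection rate (EGFP+ fraction) in factor-positive cells to
that in factor-negative cells: a ratio below 0.3 indicates restriction,
above 0.7 its absence, and the band between is intermediate.  Ratios are
formed per independent experiment and then averaged (mean +/- sd), and
titres are expressed as a percentage of the wild-type titre measured in
the same experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

RESTRICTED_BELOW = 0.3
NOT_RESTRICTED_ABOVE = 0.7


@dataclass
class RestrictionMeasurement:
    """Replicate pairs of (% infected among factor-positive, % among
    factor-negative) cells for one virus/factor combination."""

    pct_positive: Sequence[float]
    pct_negative: Sequence[float]

    def __post_init__(self) -> None:
        self.pct_positive = np.asarray(self.pct_positive, float)
        self.pct_negative = np.asarray(self.pct_negative, float)
        if self.pct_positive.shape != self.pct_negative.shape:
            raise ValueError("replicate lists must have equal length")
        for v in (self.pct_positive, self.pct_negative):
            if np.any((v < 0) | (v > 100)):
                raise ValueError("percentages must lie in [0, 100]")


@dataclass
class RestrictionResult:
    ratio: float
    sd: float
    classification: str  # restricted / intermediate / not_restricted
    replicate_ratios: np.ndarray = field(repr=False)


def classify_ratio(ratio: float) -> str:
    """Apply the 0.3 / 0.7 rule; boundary values are intermediate (the rule
    is stated with strict inequalities)."""
    if ratio < RESTRICTED_BELOW:
        return "restricted"
    if ratio > NOT_RESTRICTED_ABOVE:
        return "not_restricted"
    return "intermediate"


def restriction_ratio(m: RestrictionMeasurement) -> RestrictionResult:
    """Per-replicate infection ratios, their mean +/- sd, and the class."""
    if np.any(m.pct_negative <= 0):
        raise ZeroDivisionError(
            "factor-negative infection is zero: ratio undefined"
        )
    ratios = m.pct_positive / m.pct_negative
    mean = float(np.mean(ratios))
    sd = float(np.std(ratios, ddof=1)) if ratios.size > 1 else 0.0
    return RestrictionResult(ratio=mean, sd=sd,
                             classification=classify_ratio(mean),
                             replicate_ratios=ratios)


def normalize_titres(titres: np.ndarray, wt_index: int = 0) -> np.ndarray:
    """Titres as % of the wild type within one experiment.

    ``titres`` is 1-D (one experiment) or 2-D (experiments x samples);
    normalisation is per experiment, so the wild-type column is exactly 100
    everywhere and the result is invariant to rescaling any experiment.
    """
    t = np.atleast_2d(np.asarray(titres, float))
    wt = t[:, wt_index]
    if np.any(wt <= 0):
        raise ZeroDivisionError("wild-type titre must be positive")
    pct = t * 100.0 / wt[:, None]
    return pct[0] if np.asarray(titres).ndim == 1 else pct


def titre_summary(titres: np.ndarray, wt_index: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """(mean, sd) of wild-type-normalised percentages across experiments."""
    pct = np.atleast_2d(normalize_titres(titres, wt_index))
    return pct.mean(axis=0), pct.std(axis=0, ddof=1) if pct.shape[0] > 1 else np.zeros(pct.shape[1])
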