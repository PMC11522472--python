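"""ELISPOT stimulation-index scoring and AIM phenotype gating.

The ELISPOT stimulation index (SI) is the ratio of the mean antigen-stimulated
spot count to the mean diluent spot count over triplicate wells; SI >= 3 scores
a positive response.  The AIM arm assigns a naive/memory surface phenotype to
each index-sorted cell post hoc from CD45RO / CD27 / CD95 intensities against
sample-specific gates, and summarises phenotypes as per-individual fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .repertoire_io import PHENOTYPES

SI_THRESHOLD = 3.0


@dataclass(frozen=True)
class ElispotMeasurement:
    donor_id: str
    cytokine: str  # "IFNg" | "IL10"
    spots_antigen: tuple[float, ...]
    spots_diluent: tuple[float, ...]

    def __post_init__(self):
        for trip in (self.spots_antigen, self.spots_diluent):
            if len(trip) == 0:
                raise ValueError("each condition needs at least one well")
            if any(v < 0 for v in trip):
                raise ValueError("spot counts must be non-negative")


@dataclass(frozen=True)
class ElispotResult:
    si: float
    positive: bool
    zero_background: bool = False
    threshold: float = SI_THRESHOLD


def stimulation_index(m: ElispotMeasurement) -> ElispotResult:
    """SI = mean(antigen wells) / mean(diluent wells); positive iff SI >= 3.

    A zero diluent mean leaves the ratio undefined; the result then uses a
    pseudocount denominator of 1 and carries ``zero_background=True`` so
    positivity at zero background is explicit rather than a silent infinity.
    """
    num = float(np.mean(m.spots_antigen))
    den = float(np.mean(m.spots_diluent))
    if den == 0.0:
        si = num / 1.0
        return ElispotResult(si=si, positive=si >= SI_THRESHOLD, zero_background=True)
    si = num / den
    return ElispotResult(si=si, positive=si >= SI_THRESHOLD)


def classify_elispot_response(ifng: ElispotResult, il10: ElispotResult) -> str:
    """Combine the two cytokine positivity flags into one response class."""
    if ifng.positive and il10.positive:
        return "dual"
    if ifng.positive:
        return "IFNg_only"
    if il10.positive:
        return "IL10_only"
    return "negative"


@dataclass(frozen=True)
class CellMarkers:
    """Index-sort fluorescence intensities for one cell."""

    CD45RO: float
    CD27: float
    CD95: float
    CD154: float = 0.0
    CD69: float = 0.0


@dataclass(frozen=True)
class GateThresholds:
    """Per-marker positivity cutoffs; gates are drawn per sample."""

    CD45RO: float
    CD27: float
    CD95: float


def gate_phenotype(c: CellMarkers, g: GateThresholds) -> str:
    """Assign TN / CM / EM / NTEM / Tscm from marker positivity.

    Positivity means intensity strictly above the cutoff.  The mapping is
    total: CD45RO+CD27+ -> CM; CD45RO+CD27- -> EM; CD45RO-CD27- -> NTEM;
    CD45RO-CD27+ splits on CD95 into Tscm (+) and TN (-).
    """
    ro = c.CD45RO > g.CD45RO
    cd27 = c.CD27 > g.CD27
    cd95 = c.CD95 > g.CD95
    if ro:
        return "CM" if cd27 else "EM"
    if not cd27:
        return "NTEM"
    return "Tscm" if cd95 else "TN"


def phenotype_distribution(labels: Sequence[str], donor_id: Optional[str] = None) -> dict[str, float]:
    """Per-individual phenotype fractions over the five classes, summing to 1."""
    if len(labels) == 0:
        raise ValueError(f"no labelled cells for donor {donor_id!r}")
    out = {p: 0.0 for p in PHENOTYPES}
    for lab in labels:
        if lab not in out:
            raise ValueError(f"unknown phenotype label {lab!r}")
        out[lab] += 1.0
    n = float(len(labels))
    return {p: v / n for p, v in out.items()}


def aim_frequency(n_cd154_cd69: int, n_cd4: int) -> float:
    """Antigen-responsive (CD154+CD69+) fraction of CD4+ events, per condition.

    No background subtraction: stimulated and diluent conditions are compared
    directly downstream.
    """
    if n_cd4 <= 0:
        raise ValueError("n_cd4 must be positive")
    return n_cd154_cd69 / n_cd4
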