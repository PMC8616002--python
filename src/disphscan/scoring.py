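"""The DispH score: a linear charge-hydrophobicity boundary.

Folded (compact) and intrinsically disordered proteins separate across a
line in the mean-hydrophobicity / net-charge plane. The DispH score is the
signed offset from that boundary,

    DispH = c1 * <H> - |NCPR| - c2

evaluated with both <H> and NCPR recomputed at the pH of interest.
Positive scores predict a folded state, negative scores a disordered one.
The default coefficients are the classic charge-hydrophobicity boundary
(c1 = 2.785, c2 = 1.151); both are configurable so a recalibrated boundary
can be dropped in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .physchem import (
    LipophilicityScale,
    ParameterError,
    PKaSet,
    ProteinRecord,
    residue_charges,
    residue_lipophilicities,
    sliding_window_mean,
)

FOLDED = "folded"
UNFOLDED = "unfolded"


@dataclass(frozen=True)
class BoundaryParams:
    """Coefficients of the linear boundary ``c1 * <H> - |NCPR| - c2``."""

    c1: float = 2.785
    c2: float = 1.151

    def __post_init__(self) -> None:
        if self.c1 <= 0:
            raise ParameterError(f"boundary slope c1 must be > 0, got {self.c1}")


def disph_score(
    mean_h: float, ncpr: float, boundary: BoundaryParams = BoundaryParams()
) -> float:
    """Signed distance-like score from the charge-hydrophobicity boundary.

    Depends on NCPR only through its magnitude: a strongly positive and a
    strongly negative chain are equally far from the folded region.
    """
    return boundary.c1 * mean_h - abs(ncpr) - boundary.c2


def classify_state(score: float) -> str:
    """Folded iff score > 0; a score of exactly 0 is called unfolded
    (tie broken conservatively toward disorder)."""
    return FOLDED if score > 0.0 else UNFOLDED


@dataclass(frozen=True)
class PhPoint:
    """The score and its ingredients at one pH."""

    ph: float
    mean_hydrophobicity: float
    ncpr: float
    score: float
    state: str

    def __post_init__(self) -> None:
        if self.state != classify_state(self.score):
            raise ValueError("state label inconsistent with score sign")


def evaluate_at_ph(
    record: ProteinRecord,
    ph: float,
    window: int,
    scale: LipophilicityScale,
    pkas: PKaSet,
    boundary: BoundaryParams = BoundaryParams(),
    include_termini: bool = False,
) -> PhPoint:
    """Compute <H>, NCPR and the DispH score of a sequence at one pH."""
    from .physchem import mean_hydrophobicity, net_charge_per_residue

    h = mean_hydrophobicity(record, ph, window, scale, pkas)
    q = net_charge_per_residue(record, ph, pkas, include_termini=include_termini)
    s = disph_score(h, q, boundary)
    return PhPoint(ph=ph, mean_hydrophobicity=h, ncpr=q, score=s,
                   state=classify_state(s))


def residue_disph_profile(
    record: ProteinRecord,
    ph: float,
    window: int,
    scale: LipophilicityScale,
    pkas: PKaSet,
    boundary: BoundaryParams = BoundaryParams(),
) -> np.ndarray:
    """Per-position DispH profile at a single pH.

    Each position's score uses that position's windowed local
    hydrophobicity and windowed local NCPR, with the same centered window
    and end-truncation policy for both, so the profile is a local version
    of the global score.
    """
    seq = record.sequence
    local_h = sliding_window_mean(
        residue_lipophilicities(seq, ph, scale, pkas), window
    )
    local_q = sliding_window_mean(residue_charges(seq, ph, pkas), window)
    return boundary.c1 * local_h - np.abs(local_q) - boundary.c2
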