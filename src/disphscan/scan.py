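"""pH-grid scanning, transition detection and dataset aggregation.

A sequence is scored at every pH of a user-defined grid. A transition is a
sign change of the DispH score along the grid, trusted only when the score
actually leaves a confidence band of half-width ``ci`` (default 0.02)
around zero: a transition is reported only if the profile's maximum score
exceeds +ci AND its minimum falls below -ci, and sign changes are counted
on a debounced series in which in-band points inherit the previous
definite sign. A disorder-to-order switch as pH increases is *conditional
folding*; the reverse is *conditional unfolding*. Crossing pHs are placed
by linear interpolation of the score's zero and classed as acid (< 6),
neutral ([6, 8]) or basic (> 8).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .physchem import (
    LipophilicityScale,
    ParameterError,
    PKaSet,
    ProteinRecord,
)
from .scoring import (
    BoundaryParams,
    PhPoint,
    classify_state,
    evaluate_at_ph,
)

logger = logging.getLogger("disphscan")

CONDITIONAL_FOLDING = "conditional folding"
CONDITIONAL_UNFOLDING = "conditional unfolding"

ACID = "acid"
NEUTRAL = "neutral"
BASIC = "basic"

VERDICT_FOLDED = "folded"
VERDICT_UNFOLDED = "unfolded"
VERDICT_TRANSITION = "transition"
VERDICT_MULTITRANSITION = "multitransition"

_GRID_EPS = 1e-9


@dataclass(frozen=True)
class PhGrid:
    """An ordered pH grid: ``floor((max - min)/step) + 1`` values from
    ``ph_min``. Single-pH mode is the degenerate grid ``ph_min == ph_max``."""

    ph_min: float
    ph_max: float
    step: float
    values: tuple[float, ...] = field(default=(), compare=False)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def is_single_ph(self) -> bool:
        return len(self.values) == 1


def build_ph_grid(ph_min: float, ph_max: float, step: float = 0.5) -> PhGrid:
    """Build the pH grid. The default full-range scan, 0-14 at step 0.5,
    has 29 values."""
    if not (0.0 <= ph_min <= 14.0 and 0.0 <= ph_max <= 14.0):
        raise ParameterError("pH bounds must lie within [0, 14]")
    if ph_min > ph_max:
        raise ParameterError(f"ph_min {ph_min} exceeds ph_max {ph_max}")
    if ph_min == ph_max:
        return PhGrid(ph_min, ph_max, step, (float(ph_min),))
    if step <= 0:
        raise ParameterError(f"step must be > 0, got {step}")
    count = int(math.floor((ph_max - ph_min) / step + _GRID_EPS)) + 1
    values = tuple(float(ph_min + i * step) for i in range(count))
    return PhGrid(ph_min, ph_max, step, values)


@dataclass(frozen=True)
class PhProfile:
    """Per-sequence series of (pH, <H>, NCPR, score, state) over the grid."""

    identifier: str
    points: tuple[PhPoint, ...]
    grid: PhGrid
    window: int
    boundary: BoundaryParams

    def scores(self) -> np.ndarray:
        return np.array([p.score for p in self.points])

    def phs(self) -> np.ndarray:
        return np.array([p.ph for p in self.points])


def scan_sequence(
    record: ProteinRecord,
    grid: PhGrid,
    window: int,
    scale: LipophilicityScale,
    pkas: PKaSet,
    boundary: BoundaryParams = BoundaryParams(),
    include_termini: bool = False,
) -> PhProfile:
    """Evaluate <H>, NCPR and the DispH score at every grid pH."""
    points = tuple(
        evaluate_at_ph(record, ph, window, scale, pkas, boundary,
                       include_termini=include_termini)
        for ph in grid.values
    )
    return PhProfile(
        identifier=record.identifier,
        points=points,
        grid=grid,
        window=window,
        boundary=boundary,
    )


@dataclass(frozen=True)
class Transition:
    """One detected sign change of the score along the pH axis."""

    ph: float
    direction: str  # CONDITIONAL_FOLDING | CONDITIONAL_UNFOLDING
    ph_class: str   # ACID | NEUTRAL | BASIC


@dataclass(frozen=True)
class TransitionReport:
    """The per-sequence verdict with its supporting extrema."""

    identifier: str
    verdict: str
    transitions: tuple[Transition, ...]
    max_score: float
    max_score_ph: float
    min_score: float
    min_score_ph: float
    ci: float

    def __post_init__(self) -> None:
        n = len(self.transitions)
        if self.verdict == VERDICT_TRANSITION and n != 1:
            raise ValueError("verdict 'transition' requires exactly 1 transition")
        if self.verdict == VERDICT_MULTITRANSITION and n < 2:
            raise ValueError("verdict 'multitransition' requires >= 2 transitions")
        if self.verdict in (VERDICT_FOLDED, VERDICT_UNFOLDED) and n:
            raise ValueError("no-transition verdicts carry no transitions")
        if self.max_score < self.min_score:
            raise ValueError("max score below min score")


def classify_transition_ph(ph: float) -> str:
    """Acid below pH 6, neutral on the closed interval [6, 8], basic above."""
    if not 0.0 <= ph <= 14.0:
        raise ParameterError(f"pH {ph} outside [0, 14]")
    if ph < 6.0:
        return ACID
    if ph <= 8.0:
        return NEUTRAL
    return BASIC


def _debounced_signs(scores: np.ndarray, ci: float) -> np.ndarray:
    """Map scores to {+1, -1}: > ci is +1, < -ci is -1, in-band points
    inherit the previous definite sign (leading in-band points inherit the
    first definite sign). Requires at least one definite point."""
    raw = np.where(scores > ci, 1, np.where(scores < -ci, -1, 0))
    definite = raw[raw != 0]
    if definite.size == 0:
        raise ValueError("no score outside the confidence band")
    out = np.empty_like(raw)
    prev = definite[0]
    for i, s in enumerate(raw):
        if s != 0:
            prev = s
        out[i] = prev
    return out


def _interpolate_crossing(
    phs: np.ndarray, scores: np.ndarray, start: int, stop: int, new_sign: int
) -> float:
    """Linearly interpolated zero of the score between grid points, searched
    between the last definite point of the old sign (``start``) and the
    first definite point of the new sign (``stop``)."""
    for k in range(start, stop):
        crosses = scores[k + 1] > 0 if new_sign > 0 else scores[k + 1] < 0
        if crosses:
            s0, s1 = scores[k], scores[k + 1]
            if s1 == s0:  # flat segment straddling zero; take the left point
                return float(phs[k])
            return float(phs[k] + (phs[k + 1] - phs[k]) * (0.0 - s0) / (s1 - s0))
    # fallback: the definite endpoints themselves bracket the zero
    s0, s1 = scores[start], scores[stop]
    return float(phs[start] + (phs[stop] - phs[start]) * (0.0 - s0) / (s1 - s0))


def detect_transitions(profile: PhProfile, ci: float = 0.02) -> TransitionReport:
    """Detect and classify pH-induced order/disorder transitions.

    Gate: a transition can exist only if the maximum score is above +ci and
    the minimum below -ci. Profiles failing the gate (including degenerate
    single-point profiles) are labeled folded or unfolded by the score's
    sign at the grid median; if every point sits inside the band a
    low-confidence warning is logged.
    """
    if ci < 0:
        raise ParameterError(f"confidence half-width must be >= 0, got {ci}")
    scores = profile.scores()
    phs = profile.phs()
    imax = int(np.argmax(scores))
    imin = int(np.argmin(scores))
    max_score, min_score = float(scores[imax]), float(scores[imin])

    def _no_transition() -> TransitionReport:
        median_score = float(scores[len(scores) // 2])
        if np.all(np.abs(scores) <= ci):
            logger.warning(
                "%s: all scores within the +/-%.3g confidence band; "
                "low-confidence %s call",
                profile.identifier, ci, classify_state(median_score),
            )
        return TransitionReport(
            identifier=profile.identifier,
            verdict=VERDICT_FOLDED if classify_state(median_score) == "folded"
            else VERDICT_UNFOLDED,
            transitions=(),
            max_score=max_score,
            max_score_ph=float(phs[imax]),
            min_score=min_score,
            min_score_ph=float(phs[imin]),
            ci=ci,
        )

    if len(scores) < 2 or not (max_score > ci and min_score < -ci):
        return _no_transition()

    signs = _debounced_signs(scores, ci)
    transitions: list[Transition] = []
    raw_definite = np.abs(scores) > ci
    last_definite = 0 if raw_definite[0] else int(np.argmax(raw_definite))
    for i in range(1, len(signs)):
        if signs[i] != signs[i - 1]:
            ph = _interpolate_crossing(phs, scores, last_definite, i, int(signs[i]))
            direction = (
                CONDITIONAL_FOLDING if signs[i] > 0 else CONDITIONAL_UNFOLDING
            )
            transitions.append(
                Transition(ph=ph, direction=direction,
                           ph_class=classify_transition_ph(ph))
            )
        if raw_definite[i]:
            last_definite = i

    if not transitions:
        return _no_transition()
    verdict = (
        VERDICT_TRANSITION if len(transitions) == 1 else VERDICT_MULTITRANSITION
    )
    return TransitionReport(
        identifier=profile.identifier,
        verdict=verdict,
        transitions=tuple(transitions),
        max_score=max_score,
        max_score_ph=float(phs[imax]),
        min_score=min_score,
        min_score_ph=float(phs[imin]),
        ci=ci,
    )


@dataclass(frozen=True)
class ScanSummary:
    """Dataset-level aggregation of transition reports."""

    total: int
    n_no_transition: int
    n_single_transition: int
    n_multitransition: int
    pct_no_transition: float
    pct_transition: float
    pct_single_of_transitioning: float
    pct_multi_of_transitioning: float
    pct_conditional_folding: float
    pct_conditional_unfolding: float
    pct_acid: float
    pct_neutral: float
    pct_basic: float


def summarize_scan(reports: list[TransitionReport]) -> ScanSummary:
    """Aggregate verdict counts and transition-nature percentages.

    The folding/unfolding split among transitioning proteins uses each
    protein's *first* transition; the acid/neutral/basic split counts
    every crossing. Splits over empty denominators are reported as 0.
    """
    if not reports:
        raise ParameterError("summarize_scan requires at least one report")
    total = len(reports)
    transitioning = [r for r in reports if r.transitions]
    n_single = sum(1 for r in transitioning if len(r.transitions) == 1)
    n_multi = len(transitioning) - n_single
    n_none = total - len(transitioning)

    n_trans = len(transitioning)
    n_fold = sum(
        1 for r in transitioning
        if r.transitions[0].direction == CONDITIONAL_FOLDING
    )
    crossings = [t for r in transitioning for t in r.transitions]
    n_cross = len(crossings)
    n_acid = sum(1 for t in crossings if t.ph_class == ACID)
    n_neutral = sum(1 for t in crossings if t.ph_class == NEUTRAL)
    n_basic = n_cross - n_acid - n_neutral

    def pct(num: int, den: int) -> float:
        return 100.0 * num / den if den else 0.0

    return ScanSummary(
        total=total,
        n_no_transition=n_none,
        n_single_transition=n_single,
        n_multitransition=n_multi,
        pct_no_transition=pct(n_none, total),
        pct_transition=pct(n_trans, total),
        pct_single_of_transitioning=pct(n_single, n_trans),
        pct_multi_of_transitioning=pct(n_multi, n_trans),
        pct_conditional_folding=pct(n_fold, n_trans),
        pct_conditional_unfolding=pct(n_trans - n_fold, n_trans),
        pct_acid=pct(n_acid, n_cross),
        pct_neutral=pct(n_neutral, n_cross),
        pct_basic=pct(n_basic, n_cross),
    )
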