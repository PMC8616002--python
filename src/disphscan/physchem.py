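"""pH-dependent per-residue physical chemistry.

This module is the biophysical substrate of the DispH score: Henderson-
Hasselbalch titration of ionizable side chains, a pH-dependent per-residue
lipophilicity (a protonation-weighted mix of neutral- and charged-species
values), and centered sliding-window averaging along the sequence.

Charge conventions
------------------
An *acid* (D, E, C, Y, C-terminus) is neutral when protonated and carries
-1 when deprotonated; its mean charge at a given pH is

    q_acid(pH) = -1 / (1 + 10^(pKa - pH))

A *base* (H, K, R, N-terminus) carries +1 when protonated:

    q_base(pH) = +1 / (1 + 10^(pH - pKa))

Both are the ensemble-average charge of the group, so every per-residue
charge lies in [-1, +1] and is non-increasing in pH.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

logger = logging.getLogger("disphscan")

#: The 20 standard one-letter amino-acid codes.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Tolerated ambiguity / non-standard codes: scored as zero charge and
#: scale-mean lipophilicity, with a logged warning per sequence.
AMBIGUOUS_AA = "XBZUO"

ACID_RESIDUES = frozenset("DECY")
BASE_RESIDUES = frozenset("HKR")
IONIZABLE_RESIDUES = ACID_RESIDUES | BASE_RESIDUES


class SequenceError(ValueError):
    """A sequence (or one of its characters) failed validation."""


class ParameterError(ValueError):
    """An analysis parameter (window, grid, pKa, scale ...) is invalid."""


def validate_sequence(sequence: str, identifier: str = "<sequence>") -> str:
    """Uppercase and validate an amino-acid sequence.

    Rejects empty sequences, whitespace/gap characters and any letter
    outside the standard alphabet plus the tolerated ambiguity codes.
    Returns the validated uppercase sequence.
    """
    seq = sequence.upper()
    if len(seq) == 0:
        raise SequenceError(f"{identifier}: empty sequence")
    allowed = set(STANDARD_AA) | set(AMBIGUOUS_AA)
    for pos, ch in enumerate(seq, start=1):
        if ch not in allowed:
            raise SequenceError(
                f"{identifier}: invalid character {ch!r} at position {pos}"
            )
    n_ambiguous = sum(seq.count(c) for c in AMBIGUOUS_AA)
    if n_ambiguous:
        logger.warning(
            "%s: %d ambiguous residue(s) scored as zero charge / mean lipophilicity",
            identifier,
            n_ambiguous,
        )
    return seq


@dataclass(frozen=True)
class ProteinRecord:
    """One FASTA entry: identifier, free-text description, validated sequence."""

    identifier: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.identifier:
            raise SequenceError("record identifier must be non-empty")
        object.__setattr__(
            self, "sequence", validate_sequence(self.sequence, self.identifier)
        )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PKaEntry:
    pka: float
    polarity: str  # "acid" | "base"

    def __post_init__(self) -> None:
        if not 0.0 < self.pka < 14.0:
            raise ParameterError(f"pKa {self.pka} outside (0, 14)")
        if self.polarity not in ("acid", "base"):
            raise ParameterError(f"polarity must be 'acid' or 'base', got {self.polarity!r}")


@dataclass(frozen=True)
class PKaSet:
    """Titration constants for the seven ionizable side chains plus termini.

    Lookups for non-ionizable residues return ``None`` ("no entry"), never
    raise. The default set is the EMBOSS pKa table.
    """

    side_chains: Mapping[str, PKaEntry]
    n_terminus: float = 8.6
    c_terminus: float = 3.6
    name: str = "custom"

    def __post_init__(self) -> None:
        required = set(IONIZABLE_RESIDUES)
        have = set(self.side_chains)
        if have != required:
            raise ParameterError(
                f"pKa set must cover exactly {sorted(required)}, got {sorted(have)}"
            )
        for aa, entry in self.side_chains.items():
            expected = "acid" if aa in ACID_RESIDUES else "base"
            if entry.polarity != expected:
                raise ParameterError(f"residue {aa} must be polarity {expected!r}")
        if not (0.0 < self.n_terminus < 14.0 and 0.0 < self.c_terminus < 14.0):
            raise ParameterError("terminal pKa values must lie in (0, 14)")

    def get(self, aa: str) -> PKaEntry | None:
        return self.side_chains.get(aa)

    @classmethod
    def emboss(cls) -> "PKaSet":
        """The EMBOSS default pKa set (as used by e.g. the EMBOSS iep tool)."""
        return cls(
            side_chains={
                "D": PKaEntry(3.9, "acid"),
                "E": PKaEntry(4.1, "acid"),
                "C": PKaEntry(8.5, "acid"),
                "Y": PKaEntry(10.1, "acid"),
                "H": PKaEntry(6.5, "base"),
                "K": PKaEntry(10.8, "base"),
                "R": PKaEntry(12.5, "base"),
            },
            n_terminus=8.6,
            c_terminus=3.6,
            name="EMBOSS",
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "PKaSet":
        """Load a pKa set from a CSV with columns ``residue,pka,polarity``.

        Rows named ``N-term`` / ``C-term`` (case-insensitive) override the
        terminal-group pKa values.
        """
        side: dict[str, PKaEntry] = {}
        n_term, c_term = 8.6, 3.6
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                residue = row["residue"].strip()
                pka = float(row["pka"])
                if residue.upper() in ("N-TERM", "NTERM", "N_TERM"):
                    n_term = pka
                elif residue.upper() in ("C-TERM", "CTERM", "C_TERM"):
                    c_term = pka
                else:
                    side[residue.upper()] = PKaEntry(pka, row["polarity"].strip().lower())
        return cls(side_chains=side, n_terminus=n_term, c_terminus=c_term,
                   name=str(path))


# Kyte-Doolittle hydropathy values, min-max normalized to [0, 1] below.
_KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}


@dataclass(frozen=True)
class LipophilicityScale:
    """Per-residue lipophilicity, normalized to [0, 1].

    Every standard residue has a neutral-species value; ionizable residues
    additionally carry a charged-species value, never larger than the
    neutral one (ionization never increases lipophilicity). The effective
    per-residue value at a given pH mixes the two by the Henderson-
    Hasselbalch protonation state (see :func:`residue_lipophilicity`).
    """

    neutral: Mapping[str, float]
    charged: Mapping[str, float]
    name: str = "custom"
    provenance: str = ""
    _mean_neutral: float = field(init=False, repr=False, default=0.0)

    def __post_init__(self) -> None:
        missing = set(STANDARD_AA) - set(self.neutral)
        if missing:
            raise ParameterError(f"scale lacks neutral values for {sorted(missing)}")
        for aa, v in self.neutral.items():
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"neutral value for {aa} outside [0, 1]: {v}")
        for aa, v in self.charged.items():
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"charged value for {aa} outside [0, 1]: {v}")
            if v > self.neutral[aa] + 1e-12:
                raise ParameterError(
                    f"charged-species value for {aa} exceeds the neutral value"
                )
        object.__setattr__(
            self,
            "_mean_neutral",
            float(np.mean([self.neutral[aa] for aa in STANDARD_AA])),
        )

    @property
    def mean_neutral(self) -> float:
        """Scale-wide mean neutral value, used for ambiguity codes."""
        return self._mean_neutral

    @classmethod
    def kyte_doolittle_normalized(cls) -> "LipophilicityScale":
        """Bundled stand-in scale: Kyte-Doolittle hydropathy min-max
        normalized to [0, 1] for the neutral species, with every charged
        species pinned to the scale minimum (0.0).

        This is a documented synthetic stand-in that preserves the
        protonation-weighted mixing structure of a pH-dependent
        implicit-solvation scale; supply a custom CSV to replace it.
        """
        lo = min(_KYTE_DOOLITTLE.values())
        hi = max(_KYTE_DOOLITTLE.values())
        neutral = {aa: (v - lo) / (hi - lo) for aa, v in _KYTE_DOOLITTLE.items()}
        charged = {aa: 0.0 for aa in IONIZABLE_RESIDUES}
        return cls(
            neutral=neutral,
            charged=charged,
            name="KD-normalized",
            provenance="Kyte-Doolittle hydropathy, min-max normalized; "
            "charged species at scale minimum (synthetic stand-in)",
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "LipophilicityScale":
        """Load a scale from a CSV with columns ``residue,h_neutral,h_charged``
        (``h_charged`` blank for non-ionizable residues)."""
        neutral: dict[str, float] = {}
        charged: dict[str, float] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                aa = row["residue"].strip().upper()
                neutral[aa] = float(row["h_neutral"])
                raw = (row.get("h_charged") or "").strip()
                if raw:
                    charged[aa] = float(raw)
        return cls(neutral=neutral, charged=charged, name=str(path))


def residue_charge(aa: str, ph: float, pkas: PKaSet) -> float:
    """Mean Henderson-Hasselbalch charge of one residue's side chain at ``ph``.

    Acids return -1/(1+10^(pKa-pH)); bases +1/(1+10^(pH-pKa));
    non-ionizable residues and tolerated ambiguity codes return 0.
    """
    if aa in AMBIGUOUS_AA:
        return 0.0
    if aa not in STANDARD_AA:
        raise SequenceError(f"invalid amino-acid code {aa!r}")
    entry = pkas.get(aa)
    if entry is None:
        return 0.0
    if entry.polarity == "acid":
        return -1.0 / (1.0 + 10.0 ** (entry.pka - ph))
    return 1.0 / (1.0 + 10.0 ** (ph - entry.pka))


def terminal_charges(ph: float, pkas: PKaSet) -> float:
    """Combined charge of the free N- and C-terminal groups at ``ph``."""
    n = 1.0 / (1.0 + 10.0 ** (ph - pkas.n_terminus))
    c = -1.0 / (1.0 + 10.0 ** (pkas.c_terminus - ph))
    return n + c


def residue_charges(sequence: str, ph: float, pkas: PKaSet) -> np.ndarray:
    """Per-position side-chain charges for a validated sequence."""
    return np.array([residue_charge(aa, ph, pkas) for aa in sequence])


def net_charge_per_residue(
    record: ProteinRecord | str,
    ph: float,
    pkas: PKaSet,
    include_termini: bool = False,
) -> float:
    """NCPR: the sum of all per-residue charges divided by sequence length.

    With ``include_termini`` the free terminal-group charges are added to
    the sum before length normalization (off by default; terminal
    contributions are negligible at typical lengths).
    """
    seq = record.sequence if isinstance(record, ProteinRecord) else record
    total = float(residue_charges(seq, ph, pkas).sum())
    if include_termini:
        total += terminal_charges(ph, pkas)
    return total / len(seq)


def residue_lipophilicity(
    aa: str, ph: float, scale: LipophilicityScale, pkas: PKaSet
) -> float:
    """pH-dependent lipophilicity of one residue.

    Ionizable residues return ``f * h_neutral + (1 - f) * h_charged`` where
    ``f`` is the Henderson-Hasselbalch fraction of the *neutral* species at
    this pH (``f = 1 - |charge|``); non-ionizable residues return the
    neutral value independent of pH; ambiguity codes return the scale-wide
    mean.
    """
    if aa in AMBIGUOUS_AA:
        return scale.mean_neutral
    if aa not in STANDARD_AA:
        raise SequenceError(f"invalid amino-acid code {aa!r}")
    h_neutral = scale.neutral[aa]
    if aa not in IONIZABLE_RESIDUES or aa not in scale.charged:
        return h_neutral
    f_neutral = 1.0 - abs(residue_charge(aa, ph, pkas))
    return f_neutral * h_neutral + (1.0 - f_neutral) * scale.charged[aa]


def residue_lipophilicities(
    sequence: str, ph: float, scale: LipophilicityScale, pkas: PKaSet
) -> np.ndarray:
    """Per-position pH-dependent lipophilicities."""
    return np.array(
        [residue_lipophilicity(aa, ph, scale, pkas) for aa in sequence]
    )


def _check_window(window: int) -> None:
    if window < 1:
        raise ParameterError(f"window must be >= 1, got {window}")
    if window % 2 == 0:
        raise ParameterError(
            f"window must be odd for a well-defined center, got {window}"
        )


def sliding_window_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Centered sliding mean, truncated at the ends.

    Each output position averages the input over a window of ``window``
    positions centered there, shrunk to whatever is available near the
    sequence ends. Sequences shorter than the window therefore collapse to
    the whole-sequence mean at every position.
    """
    _check_window(window)
    x = np.asarray(values, dtype=float)
    n = x.size
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(n)
    lo = np.maximum(0, idx - half)
    hi = np.minimum(n, idx + half + 1)
    return (csum[hi] - csum[lo]) / (hi - lo)


def windowed_hydrophobicity(
    record: ProteinRecord | str,
    ph: float,
    window: int,
    scale: LipophilicityScale,
    pkas: PKaSet,
) -> np.ndarray:
    """Per-position local lipophilicity: sliding-window mean of the
    pH-dependent per-residue values."""
    seq = record.sequence if isinstance(record, ProteinRecord) else record
    return sliding_window_mean(
        residue_lipophilicities(seq, ph, scale, pkas), window
    )


def mean_hydrophobicity(
    record: ProteinRecord | str,
    ph: float,
    window: int,
    scale: LipophilicityScale,
    pkas: PKaSet,
) -> float:
    """Mean hydrophobicity <H>: the average of the windowed local series."""
    return float(windowed_hydrophobicity(record, ph, window, scale, pkas).mean())
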