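"""Deterministic synthetic sequences with designed titration behavior.

The catalog covers each behavior class the scanner must recognize:

* ``polyG50`` — no titratable groups: the score is pH-flat (control).
* ``polyK50`` / ``polyE50`` — single-group titration controls.
* ``VK25`` — (VK)x25: hydrophobic valines diluted by lysines; below the Lys
  pKa the chain is charged and disordered, above it neutral and folded,
  so exactly one conditional-folding crossing near pKa(K) is designed in.
* ``VE25`` — (VE)x25: the mirror image via glutamate, one conditional-
  unfolding crossing near pKa(E).
* ``VH25`` — (VH)x25: histidine titrates near neutrality, placing the
  crossing inside the neutral class [6, 8].
* random 100-mers at uniform composition for property tests.

Truth tables for the mini-proteome are computed at generation time from
the configured scale / pKa set / boundary, so swapping the bundled scale
for another regenerates a consistent truth table.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from .physchem import (
    LipophilicityScale,
    PKaSet,
    ProteinRecord,
    STANDARD_AA,
    SequenceError,
)
from .scan import PhGrid, build_ph_grid, detect_transitions, scan_sequence
from .scoring import BoundaryParams

KINDS = ("homopolymer", "alternating", "block", "random")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one deterministic synthetic sequence."""

    kind: str  # one of KINDS
    residues: tuple[str, ...]
    length: int
    seed: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.length < 1:
            raise ValueError("fixture length must be >= 1")
        for aa in self.residues:
            if aa not in STANDARD_AA:
                raise SequenceError(f"invalid residue {aa!r} in fixture spec")


def make_fixture(spec: FixtureSpec) -> ProteinRecord:
    """Build the deterministic sequence a spec describes.

    ``alternating`` with residues (X, Y) and length n yields XYXY... of
    length 2n; ``block`` concatenates equal blocks of each residue;
    ``random`` draws uniformly from the listed residues with the spec seed.
    """
    if spec.kind == "homopolymer":
        (aa,) = spec.residues
        seq = aa * spec.length
    elif spec.kind == "alternating":
        x, y = spec.residues
        seq = (x + y) * spec.length
    elif spec.kind == "block":
        seq = "".join(aa * spec.length for aa in spec.residues)
    else:  # random
        rng = np.random.default_rng(spec.seed)
        pool = spec.residues or tuple(STANDARD_AA)
        seq = "".join(rng.choice(list(pool), size=spec.length))
    name = spec.name or f"{spec.kind}_{''.join(spec.residues)}_{spec.length}"
    return ProteinRecord(identifier=name, sequence=seq,
                         description=f"synthetic {spec.kind} fixture")


def catalog_specs() -> list[FixtureSpec]:
    """The labeled fixture catalog."""
    return [
        FixtureSpec("homopolymer", ("G",), 50, name="polyG50"),
        FixtureSpec("homopolymer", ("K",), 50, name="polyK50"),
        FixtureSpec("homopolymer", ("E",), 50, name="polyE50"),
        FixtureSpec("alternating", ("V", "K"), 25, name="VK25"),
        FixtureSpec("alternating", ("V", "E"), 25, name="VE25"),
        FixtureSpec("alternating", ("V", "H"), 25, name="VH25"),
    ]


def catalog() -> list[ProteinRecord]:
    return [make_fixture(s) for s in catalog_specs()]


def random_sequence(length: int, seed: int,
                    alphabet: str = STANDARD_AA) -> ProteinRecord:
    """A uniform-composition random sequence, reproducible from the seed."""
    spec = FixtureSpec("random", tuple(alphabet), length, seed=seed,
                       name=f"random{length}_s{seed}")
    return make_fixture(spec)


def make_mini_proteome(
    n: int,
    seed: int = 0,
    grid: PhGrid | None = None,
    window: int = 51,
    scale: LipophilicityScale | None = None,
    pkas: PKaSet | None = None,
    boundary: BoundaryParams = BoundaryParams(),
    ci: float = 0.02,
) -> tuple[str, list[dict]]:
    """Generate an ``n``-record synthetic proteome as multi-FASTA text plus
    a truth table.

    Records cycle through the designed catalog interleaved with seeded
    random 100-mers. The truth table (one dict per record: identifier,
    expected verdict, expected first-transition direction or ``""``) is
    computed at generation time with the supplied scale/pKa/boundary so it
    stays consistent with whatever configuration is in force.
    """
    if n < 1:
        raise ValueError("mini proteome needs n >= 1")
    grid = grid or build_ph_grid(0.0, 14.0, 0.5)
    scale = scale or LipophilicityScale.kyte_doolittle_normalized()
    pkas = pkas or PKaSet.emboss()

    base = catalog_specs()
    records: list[ProteinRecord] = []
    for i in range(n):
        slot = i % (len(base) + 1)
        if slot < len(base):
            spec = base[slot]
            rec = make_fixture(spec)
            rec = ProteinRecord(
                identifier=f"{spec.name}_{i:04d}",
                sequence=rec.sequence,
                description=rec.description,
            )
        else:
            rec = random_sequence(100, seed=seed * 100003 + i)
            rec = ProteinRecord(
                identifier=f"{rec.identifier}_{i:04d}",
                sequence=rec.sequence,
                description=rec.description,
            )
        records.append(rec)

    truth: list[dict] = []
    for rec in records:
        profile = scan_sequence(rec, grid, window, scale, pkas, boundary)
        report = detect_transitions(profile, ci=ci)
        truth.append(
            {
                "identifier": rec.identifier,
                "verdict": report.verdict,
                "first_direction": (
                    report.transitions[0].direction if report.transitions else ""
                ),
                "n_transitions": len(report.transitions),
            }
        )

    buf = io.StringIO()
    for rec in records:
        buf.write(f">{rec.identifier} {rec.description}\n")
        for i in range(0, len(rec.sequence), 60):
            buf.write(rec.sequence[i:i + 60] + "\n")
    return buf.getvalue(), truth


def truth_table_tsv(truth: list[dict]) -> str:
    """Serialize a truth table as TSV."""
    lines = ["identifier\tverdict\tfirst_direction\tn_transitions"]
    for row in truth:
        lines.append(
            f"{row['identifier']}\t{row['verdict']}\t"
            f"{row['first_direction']}\t{row['n_transitions']}"
        )
    return "\n".join(lines) + "\n"
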