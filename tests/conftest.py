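import pytest

from disphscan import (
    BoundaryParams,
    LipophilicityScale,
    PhGrid,
    PhProfile,
    PKaSet,
    build_ph_grid,
)
from disphscan.scoring import PhPoint, classify_state


@pytest.fixture(scope="session")
def pkas() -> PKaSet:
    return PKaSet.emboss()


@pytest.fixture(scope="session")
def scale() -> LipophilicityScale:
    return LipophilicityScale.kyte_doolittle_normalized()


@pytest.fixture(scope="session")
def boundary() -> BoundaryParams:
    return BoundaryParams()


@pytest.fixture(scope="session")
def full_grid() -> PhGrid:
    return build_ph_grid(0.0, 14.0, 0.5)


def profile_from_scores(scores, phs=None, identifier="synthetic"):
    """Build a PhProfile directly from a score series (test helper).

    Default pH values are evenly spaced over [0, 14] so any series length
    stays inside the physical pH range.
    """
    if phs is None:
        if len(scores) == 1:
            phs = [7.0]
        else:
            phs = [14.0 * i / (len(scores) - 1) for i in range(len(scores))]
    grid = PhGrid(phs[0], phs[-1], phs[1] - phs[0] if len(phs) > 1 else 1.0,
                  tuple(phs))
    points = tuple(
        PhPoint(ph=ph, mean_hydrophobicity=0.5, ncpr=0.0, score=float(s),
                state=classify_state(s))
        for ph, s in zip(phs, scores)
    )
    return PhProfile(identifier=identifier, points=points, grid=grid,
                     window=1, boundary=BoundaryParams())
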