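import numpy as np
import pytest

from kpibench import datasets, dematel
from kpibench.preprocessing import IndicatorPanel, IndicatorSeries, Orientation
from kpibench.synthetic import generate_economic_panel, generate_survey_panel


@pytest.fixture(scope="session")
def economic_matrix():
    return datasets.economic_impact_matrix()


@pytest.fixture(scope="session")
def social_matrix():
    return datasets.social_impact_matrix()


@pytest.fixture(scope="session")
def economic_indicators(economic_matrix):
    return dematel.analyse(economic_matrix)


@pytest.fixture(scope="session")
def social_indicators(social_matrix):
    return dematel.analyse(social_matrix)


@pytest.fixture(scope="session")
def economic_panel():
    return generate_economic_panel(seed=2024)


@pytest.fixture(scope="session")
def survey_panel():
    return generate_survey_panel(seed=2024)


@pytest.fixture
def mixed_panel():
    """Small hand-built panel with one series of each orientation."""
    return IndicatorPanel(
        periods=(2000, 2001, 2002, 2003),
        series=(
            IndicatorSeries("output", np.array([1.0, 2.0, 3.0, 4.0])),
            IndicatorSeries("jobless", np.array([10.0, 5.0, 20.0, 8.0]), Orientation.DESTIMULANT),
            IndicatorSeries("prices", np.array([102.5, 105.0, 100.0, 102.5]),
                            Orientation.NOMINANT, target=102.5),
        ),
    )


def random_impact_matrix(rng: np.random.Generator, n: int, scale_max: int = 3) -> dematel.ImpactMatrix:
    """Random admissible expert matrix: integers on 0..scale_max, zero diagonal."""
    cells = rng.integers(0, scale_max + 1, size=(n, n))
    np.fill_diagonal(cells, 0)
    if cells.sum() == 0:  # avoid the degenerate all-zero case
        cells[0, 1] = 1
    return dematel.ImpactMatrix(labels=tuple(f"v{i}" for i in range(n)), cells=cells,
                                scale_max=scale_max)
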