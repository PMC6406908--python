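import numpy as np
import pytest

from minerva import CountPanel, FieldSpec, JournalSpec


@pytest.fixture
def journals() -> list[JournalSpec]:
    return [
        JournalSpec("Nature", 40.137),
        JournalSpec("JAMA", 44.405),
        JournalSpec("Child's nervous system", 1.081),
    ]


@pytest.fixture
def small_panel(journals) -> CountPanel:
    fields = [FieldSpec("glioma"), FieldSpec("epigenetics")]
    counts = np.array(
        [
            [[2, 1, 0], [0, 3, 1], [5, 0, 2]],  # glioma
            [[0, 0, 1], [1, 0, 0], [0, 2, 0]],  # epigenetics
        ]
    )
    return CountPanel(fields=fields, journals=journals, years=range(2015, 2018), counts=counts)


def random_panel(rng: np.random.Generator, n_fields=4, n_journals=5, n_years=6) -> CountPanel:
    """Small random panel for oracle comparisons."""
    fields = [FieldSpec(f"f{i}") for i in range(n_fields)]
    journals = [
        JournalSpec(f"J{i}", float(rng.uniform(1.0, 45.0))) for i in range(n_journals)
    ]
    counts = rng.poisson(1.5, size=(n_fields, n_journals, n_years))
    return CountPanel(fields=fields, journals=journals, years=range(2010, 2010 + n_years), counts=counts)
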