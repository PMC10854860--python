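import pytest

import gypaetus as g


@pytest.fixture(scope="session")
def small_design() -> g.StudyDesign:
    return g.StudyDesign(tuple(range(2000, 2006)))  # 6 occasions


@pytest.fixture(scope="session")
def adult_design() -> g.StudyDesign:
    """Four occasions; any bird born 7+ years earlier is always adult."""
    return g.StudyDesign(tuple(range(2000, 2004)))


def make_dataset(design: g.StudyDesign, rows) -> g.EncounterDataset:
    """rows: iterable of (id, birth_year, detections)."""
    return g.EncounterDataset(
        design,
        tuple(g.EncounterHistory(i, b, tuple(d)) for i, b, d in rows),
    )


@pytest.fixture(scope="session")
def sim_dataset_small() -> g.EncounterDataset:
    cfg = g.SimulationConfig(
        design=g.StudyDesign(tuple(range(1987, 1997))),
        n_individuals=150,
        seed=123,
    )
    return g.simulate_dataset(cfg)
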