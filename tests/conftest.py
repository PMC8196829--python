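import numpy as np
import pandas as pd
import pytest

from pharmacotype.plate_io import (
    CONTROL,
    DosePanel,
    WellMeasurement,
    default_panels,
    write_plate,
)


@pytest.fixture
def panel():
    return DosePanel.default("gemcitabine")


@pytest.fixture
def panels():
    return default_panels()


def make_wells(pdo="PDO01", drug="gemcitabine", viability=100.0, ctrl_net=1000.0,
               background=100.0, replicates=2, panel=None):
    """Wells for one PDO x drug curve at constant viability, plus controls."""
    panel = panel or DosePanel.default(drug)
    wells = [
        WellMeasurement(pdo, CONTROL, None, r, background, background + ctrl_net)
        for r in range(1, replicates + 1)
    ]
    for c in panel.concentrations:
        for r in range(1, replicates + 1):
            net = ctrl_net * viability / 100.0
            wells.append(WellMeasurement(pdo, drug, c, r, background, background + net))
    return wells


@pytest.fixture
def plate_csv(tmp_path):
    """One PDO x one drug x 10 concentrations x 2 replicates + 2 controls."""
    path = tmp_path / "plate.csv"
    write_plate(make_wells(), path)
    return path


@pytest.fixture(scope="session")
def fixture_cohort():
    from pharmacotype.synthetic_cohort import paper_fixture

    return paper_fixture()


def random_auc_library(rng, n_pdos=28, drugs=("gemcitabine", "paclitaxel")):
    from pharmacotype.viability_auc import AUCLibrary

    matrix = pd.DataFrame(
        rng.uniform(50, 350, size=(n_pdos, len(drugs))),
        index=[f"PDO{i:02d}" for i in range(n_pdos)],
        columns=list(drugs),
    )
    return AUCLibrary(matrix)
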