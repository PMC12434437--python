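import logging

import pandas as pd
import pytest

from grazeniche.filtering import run_filter_cascade
from grazeniche.readtable import ReplicateReadTable
from grazeniche.simulate import SimulationConfig, generate_community, simulate_study

logging.getLogger("grazeniche").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def community():
    return generate_community(n_taxa=25, seed=0)


@pytest.fixture(scope="session")
def study():
    """One full synthetic field study at the default design."""
    return simulate_study(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def filtered(study):
    """(OTU table, diet profiles) from the default cascade on the study."""
    return run_filter_cascade(study.reads, study.community.reference_sequences())


def build_table(cells, wells, sequences) -> ReplicateReadTable:
    """Assemble a ReplicateReadTable from plain dicts.

    cells: {(sequence_id, well_id): count}; wells: {well_id: dict of metadata
    fields (sample_id, species, year, subarea, control_type, library_id)}.
    """
    counts = pd.DataFrame(
        [(s, w, c) for (s, w), c in cells.items()],
        columns=["sequence_id", "well_id", "read_count"],
    )
    defaults = {
        "sample_id": None,
        "species": None,
        "year": None,
        "subarea": None,
        "control_type": None,
        "library_id": "lib1",
    }
    rows = []
    for wid, meta in wells.items():
        row = {"well_id": wid, **defaults, **meta}
        rows.append(row)
    return ReplicateReadTable(counts, pd.DataFrame(rows), dict(sequences))
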