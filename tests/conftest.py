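import numpy as np
import pandas as pd
import pytest

from pitmatch import (
    Repertoire,
    SimConfig,
    UniqueJunction,
    build_repertoire,
    simulate_germline_reference,
    simulate_repertoire,
)


def make_repertoire(locus: str, entries: dict) -> Repertoire:
    """Build a Repertoire from {junction: (v_genes, j_genes, nts, cells_per_donor)}
    or {junction: None} shorthand."""
    rep = Repertoire(locus=locus)
    for j, spec in entries.items():
        e = UniqueJunction(j)
        if spec is None:
            e.cells_per_donor["d1"] = 1
        else:
            v, jj, nts, cpd = spec
            e.v_genes = set(v)
            e.j_genes = set(jj)
            e.nt_sequences = set(nts)
            e.cells_per_donor = dict(cpd)
        rep.entries[j] = e
    return rep


@pytest.fixture(scope="session")
def germline():
    return simulate_germline_reference(seed=7)


@pytest.fixture(scope="session")
def small_simulation(germline):
    cfg = SimConfig(seed=11, n_donors=4, clones_per_donor=25)
    return simulate_repertoire(cfg, germline)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def cell_table(tmp_path):
    """A tiny well-formed AIRR-style TSV on disk."""
    df = pd.DataFrame(
        {
            "cell_id": ["c1", "c1", "c2", "c2", "c3"],
            "donor_id": ["d1", "d1", "d1", "d1", "d2"],
            "locus": ["TRA", "TRB", "TRA", "TRB", "TRA"],
            "v_call": ["TRAV1-2*01", "TRBV9", "TRAV41", "TRBV12-4", "TRAV1-2"],
            "j_call": ["TRAJ8", "TRBJ2-1", "TRAJ49", "TRBJ1-1", "TRAJ8"],
            "junction_aa": [
                "CAVRMNTGFQKLVF",
                "CASSFGGGATDTQYF",
                "CAASNTGNQFYF",
                "CASSPQGGNTEAFF",
                "CAVRMNTGFQKLVF",
            ],
            "junction": ["", "", "", "", ""],
        }
    )
    path = tmp_path / "cells.tsv"
    df.to_csv(path, sep="\t", index=False)
    return path
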