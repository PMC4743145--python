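"""Shared fixtures: generated SD files and a fully analyzed default series."""

from __future__ import annotations

import pytest
from rdkit import Chem

from analogsar import chem_io, fixtures, mcs, pipeline
from analogsar import series as series_mod


@pytest.fixture(scope="session")
def default_spec():
    return fixtures.default_fixture_spec(seed=0)


@pytest.fixture(scope="session")
def default_sdf(tmp_path_factory, default_spec):
    path = tmp_path_factory.mktemp("fixtures") / "default.sdf"
    fixtures.generate_series_sdf(default_spec, path)
    return path


@pytest.fixture(scope="session")
def default_records(default_sdf):
    return chem_io.read_sd_file(default_sdf, chem_io.PotencyConfig(["pKi"]))


@pytest.fixture(scope="session")
def default_analysis(default_records):
    sl = series_mod.group_into_series(default_records)
    assert len(sl) == 1
    return pipeline.analyze_series(sl[0], default_records)


@pytest.fixture(scope="session")
def stereo_analysis(tmp_path_factory):
    path = tmp_path_factory.mktemp("fixtures") / "stereo.sdf"
    fixtures.generate_series_sdf(fixtures.stereo_demo_fixture_spec(seed=0), path)
    records = chem_io.read_sd_file(path, chem_io.PotencyConfig(["pKi"]))
    sl = series_mod.group_into_series(records)
    return pipeline.analyze_series(sl[0], records)


def records_from_smiles(smiles: list[str], potency: float = 6.0) -> list[chem_io.CompoundRecord]:
    """Build in-memory compound records straight from SMILES."""
    out = []
    for i, smi in enumerate(smiles):
        mol = Chem.MolFromSmiles(smi)
        assert mol is not None, smi
        out.append(chem_io.CompoundRecord(
            compound_id=f"C{i + 1}", mol=mol, potencies={"pKi": potency + 0.1 * i}))
    return out


def series_of(records) -> series_mod.AnalogSeries:
    """Wrap records into one analog series (scaffold left unset)."""
    return series_mod.AnalogSeries(
        series_id="S1", scaffold=None, members=[r.compound_id for r in records])


def analyze_smiles(smiles: list[str]) -> pipeline.SeriesAnalysis:
    records = records_from_smiles(smiles)
    return pipeline.analyze_series(series_of(records), records)
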