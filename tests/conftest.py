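import datetime as dt

import pytest

from whalekin.encounter_store import Encounter, EncounterStore, Individual
from whalekin.synthetic_data import scenario_wsa_default, simulate_scenario


def build_store(encounters, individuals=None):
    """Compact store builder.

    ``encounters``: iterable of (encounter_id, iso_date, sighting_no, member_ids)
    or (..., group_size_estimate).  ``individuals``: optional {id: kwargs}.
    """
    individuals = individuals or {}
    inds = {}
    encs = {}
    for spec in encounters:
        eid, date, sno, members = spec[:4]
        gs = spec[4] if len(spec) > 4 else len(members)
        for iid in members:
            if iid not in inds:
                inds[iid] = Individual(individual_id=iid, has_dorsal_photo=True,
                                       **individuals.get(iid, {}))
        encs[eid] = Encounter(
            encounter_id=eid,
            date=dt.date.fromisoformat(date),
            sighting_no=sno,
            location_name="Saldanha Bay",
            group_size_estimate=gs,
            member_ids=frozenset(members),
        )
    for iid, kwargs in individuals.items():
        if iid not in inds:
            inds[iid] = Individual(individual_id=iid, has_dorsal_photo=True, **kwargs)
    return EncounterStore(inds, encs)


@pytest.fixture(scope="session")
def default_scenario():
    """One full default-scale synthetic scenario shared across the session."""
    return simulate_scenario(scenario_wsa_default(1234))


@pytest.fixture()
def default_store(default_scenario, tmp_path):
    from whalekin.encounter_store import load_encounters

    path = tmp_path / "enc.csv"
    default_scenario.encounters.to_csv(path, index=False)
    return load_encounters(path)
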