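import pytest

from anthonet import VisitRecord, build_network


def vr(site="S01", elev=1200.0, jd=160, order="Diptera", family="Syrphidae",
       species="Syrphidae_sp001", plant="Plant_01", count=1):
    return VisitRecord(site_id=site, elevation=elev, julian_day=jd,
                       order=order, family=family, species=species,
                       plant_species=plant, count=count)


@pytest.fixture
def make_record():
    return vr


@pytest.fixture
def partitioned_network():
    """One site, two orders on disjoint plant sets, 5 species each."""
    records = []
    for i in range(5):
        for j in range(3):
            records.append(vr(species=f"fly{i}", plant=f"FlyPlant_{j}",
                              order="Diptera", family="Muscidae", count=4))
            records.append(vr(species=f"bee{i}", plant=f"BeePlant_{j}",
                              order="Hymenoptera", family="Apidae", count=4))
    return build_network(records, "S01")
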