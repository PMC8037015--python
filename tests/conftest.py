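import pytest

from hbttc.core import Concentration
from hbttc.pnec import ToxEndpointRecord

TROPHIC_GROUPS = ("algae", "invertebrate", "fish")


def rec(chem="X", trophic="fish", duration="acute", value=1.0, unit="mg/L", label=""):
    return ToxEndpointRecord(
        chemical_id=chem,
        trophic_group=trophic,
        duration_class=duration,
        value=Concentration(value, unit),
        endpoint_label=label,
    )


def records_from_cells(cells, chem="X"):
    """cells: {(trophic, duration): [values mg/L]} -> record list."""
    out = []
    for (trophic, duration), values in cells.items():
        for v in values:
            out.append(rec(chem, trophic, duration, v))
    return out


@pytest.fixture
def make_records():
    return records_from_cells


# Published per-class fifth-percentile candidate triples, ng/L
# (empirical, normal, logistic)
PUBLISHED_CANDIDATES_NG_L = {
    1: (5.496, 5.587, 5.929),
    2: (9.455, 37.53, 44.45),
    3: (1.254, 2.534, 2.982),
    4: (0.134, 0.1433, 0.1175),
    5: (4.012, 5.434, 5.750),
}

# Published class thresholds after the min rule, ng/L, and the winning method
PUBLISHED_ECOTTC_NG_L = {
    1: (5.496, "empirical"),
    2: (9.455, "empirical"),
    3: (1.254, "empirical"),
    4: (0.1175, "logistic"),
    5: (4.012, "empirical"),
}

# Published QS values, µg/L, per Cramer class: (bw=70 column, bw=60 column)
PUBLISHED_QS_UG_L = {1: (105.0, 90.0), 2: (31.5, 27.0), 3: (5.25, 4.5)}
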