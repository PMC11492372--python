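import pytest

import poresig as ps


@pytest.fixture(scope="session")
def naf_1mM():
    return ps.binary_solution("Na+", "F-", 1e-3)


@pytest.fixture(scope="session")
def pore23():
    return ps.NanoporeGeometry(r_np=2.3e-9)


@pytest.fixture(scope="session")
def baseline_naf(naf_1mM, pore23):
    return ps.baseline_state(naf_1mM, pore23)


@pytest.fixture(scope="session")
def validation_analytes():
    """The four small-molecule validation analytes from the shipped table."""
    out = {}
    for name in ("hydroquinone", "oxalic_acid", "ascorbic_acid", "citric_acid"):
        ion = ps.ion_from_table(name)
        out[name] = ps.Analyte(name=name, r_analyte=ion.radius, z_analyte=ion.valence)
    return out


@pytest.fixture(scope="session")
def ceria_small():
    """Nanoparticle-scale analyte (reduced state)."""
    return ps.Analyte(name="ceria_small", r_analyte=0.92e-9, z_analyte=28)


@pytest.fixture(scope="session")
def ceria_oxidized():
    """Nanoparticle-scale analyte (oxidised state)."""
    return ps.Analyte(name="ceria_oxidized", r_analyte=1.27e-9, z_analyte=112)
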