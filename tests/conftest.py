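import pytest

from bayesdta import tables_io


@pytest.fixture(scope="session")
def est_cad():
    table, _ = tables_io.load_fixture("est_cad")
    return table


@pytest.fixture(scope="session")
def mammography():
    table, _ = tables_io.load_fixture("mammography")
    return table


@pytest.fixture(scope="session")
def diabetes():
    table, _ = tables_io.load_fixture("diabetes")
    return table


@pytest.fixture(scope="session")
def lung_ct_mri():
    table, _ = tables_io.load_fixture("lung_ct_mri")
    return table


@pytest.fixture(scope="session")
def scintigraphy():
    table, _ = tables_io.load_fixture("scintigraphy")
    return table


@pytest.fixture(scope="session")
def mammography_verification():
    table, _ = tables_io.load_fixture("mammography_verification")
    return table


@pytest.fixture(scope="session")
def strongyloides():
    table, _ = tables_io.load_fixture("strongyloides")
    return table


@pytest.fixture(scope="session")
def stenosis():
    table, _ = tables_io.load_fixture("stenosis")
    return table
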