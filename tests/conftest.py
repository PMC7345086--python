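import pytest

from codonchron import (
    arrange,
    load_abundance,
    load_aars_classes,
    load_standard_code,
    overlay,
)


@pytest.fixture(scope="session")
def table():
    return load_standard_code()


@pytest.fixture(scope="session")
def classes():
    return load_aars_classes()


@pytest.fixture(scope="session")
def abundance():
    return load_abundance()


@pytest.fixture(scope="session")
def order(table):
    return arrange(table)


@pytest.fixture(scope="session")
def class_seq(order, classes):
    return overlay(order, classes)
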