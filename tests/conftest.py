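import io

import pytest

from metaprot.taxonomy import loads_taxonomy

# Toy taxonomy: root(1) > Bacteria(2) > {Proteobacteria(1224) >
# Gammaproteobacteria(1236) > E. coli(562); Firmicutes(1239) > B. subtilis(1423)}
TOY_NODES = (
    "1\t|\t1\t|\tno rank\t|\n"
    "2\t|\t1\t|\tsuperkingdom\t|\n"
    "1224\t|\t2\t|\tphylum\t|\n"
    "1236\t|\t1224\t|\tclass\t|\n"
    "562\t|\t1236\t|\tspecies\t|\n"
    "1239\t|\t2\t|\tphylum\t|\n"
    "1423\t|\t1239\t|\tspecies\t|\n"
)

TOY_NAMES = (
    "1\t|\troot\t|\t\t|\tscientific name\t|\n"
    "2\t|\tBacteria\t|\t\t|\tscientific name\t|\n"
    "1224\t|\tProteobacteria\t|\t\t|\tscientific name\t|\n"
    "1236\t|\tGammaproteobacteria\t|\t\t|\tscientific name\t|\n"
    "562\t|\tEscherichia coli\t|\t\t|\tscientific name\t|\n"
    "1239\t|\tFirmicutes\t|\t\t|\tscientific name\t|\n"
    "1423\t|\tBacillus subtilis\t|\t\t|\tscientific name\t|\n"
)

TOY_MERGED = "561\t|\t562\t|\n"


@pytest.fixture
def toy_tree():
    return loads_taxonomy(TOY_NODES, TOY_NAMES, TOY_MERGED)


@pytest.fixture
def stream():
    """Factory turning a string into a fresh text stream."""
    return io.StringIO
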