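import pytest

from boolfg import li_yeast_network

# Published knockout trajectories of the yeast cell-cycle network, as
# bitstrings in the gene order Cln3, MBF, SBF, Cln1,2, Cdh1, Swi5,
# Cdc20,14, Clb5,6, Sic1, Clb1,2, Mcm1/SFF.

SIC1_KO_TABLE = (
    "10001000000",
    "01101000000",
    "01111001000",
    "01110001001",
    "01110111011",
    "00010111011",
    "00000110011",
)

CLN_KO_TABLE = ("00001000100",)

CLB12_KO_TABLE = (
    "10001000100",
    "01101000100",
    "01111000100",
    "01110000000",
    "01110001000",
    "01110001001",
    "01110111001",
)

SBF_MBF_KO_TABLE = (
    "10001000100",
    "00001000100",
)

#: Li edge-perspective degree distribution of the yeast factor graph.
LI_RHO = {1: 0.025, 2: 0.05, 3: 0.3, 4: 0.2, 5: 0.125, 6: 0.3}


@pytest.fixture(scope="session")
def yeast():
    return li_yeast_network()
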