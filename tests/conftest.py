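import pytest

from dsrloops import get_fixture


@pytest.fixture(scope="session")
def mitosis_z1():
    return get_fixture("mitosis_z1")


@pytest.fixture(scope="session")
def mitosis_z2():
    return get_fixture("mitosis_z2")


MITOSIS_TEXT = """\
r1: Xcyt -> Xnuc
r2: Xnuc -> Xcyt
r3: Xnuc -> Xnucp
r4: Xnucp -> Xnuc
"""

# Golden renderings of the two mitosis injectivity polynomials (canonical
# term order; s = 2, so the wrong sign is '-').
MITOSIS_P1 = "g[1,1]*g[2,3] - g[1,1]*g[3,3] + g[1,1]*g[3,4] - g[2,2]*g[3,3] + g[2,2]*g[3,4]"
MITOSIS_P2 = "g[1,1]*g[2,3] + g[1,1]*g[3,4] + g[2,2]*g[3,4]"
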