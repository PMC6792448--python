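import pandas as pd
import pytest

from domevol import PresenceMatrix, parse_newick


@pytest.fixture
def four_tip_tree():
    """((A,B)X,(C,D)Y)R with auto ids N0=R, N1=X, N2=Y."""
    return parse_newick("((A,B)X,(C,D)Y)R;")


@pytest.fixture
def four_tip_matrix():
    """3 domains on 4 taxa: patterns {A,B,C}, {A}, {A,B,C,D}."""
    frame = pd.DataFrame(
        {
            "d_abc": [1, 1, 2, 0],
            "d_a": [1, 0, 0, 0],
            "d_all": [1, 1, 1, 3],
        },
        index=pd.Index(["A", "B", "C", "D"], name="taxon"),
    )
    return PresenceMatrix(frame)


PFAMSCAN_TWO_HITS = """\
# pfam_scan.pl output
seq1 10 80 8 82 PF00157.1 Pou Domain 1 70 70 120.5 1.2e-30 1 CL0123
seq1 90 150 88 152 PF00046.1 Homeobox Domain 1 57 57 95.0 3.4e-25 1 CL0123
"""


@pytest.fixture
def pfamscan_text():
    return PFAMSCAN_TWO_HITS
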