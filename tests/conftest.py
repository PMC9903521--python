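import numpy as np
import pytest

import panretain as pr


@pytest.fixture
def uniform_pi():
    return np.full(61, 1.0 / 61.0)


@pytest.fixture
def toy_hog_file(tmp_path):
    """Two HOGs over three species; the second has an empty wheat cell
    (the gene family is absent from the wheat reference)."""
    text = (
        "HOG\tOG\tGene Tree Parent Clade\tbarley\temmer\twheat\n"
        "N1.HOG0000001\tOG0000001\tN1\tHv1, Hv2\tTd1\tTa1, Ta2, Ta3\n"
        "N1.HOG0000002\tOG0000002\tN1\tHv3\tTd2\t\n"
    )
    path = tmp_path / "hogs.tsv"
    path.write_text(text)
    return path


@pytest.fixture
def partially_retained_pav(tmp_path):
    """One-gene barley panel: present in 13 of 20 lines."""
    lines = ["line_id,geneA"]
    lines += [f"L{i:02d},{1 if i < 13 else 0}" for i in range(20)]
    path = tmp_path / "pav.csv"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def small_labeled_tree():
    return pr.read_newick_labeled("((A:0.3,B:0.3):0.2,(C#1:0.4,D#1:0.4)#1:0.3);")
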