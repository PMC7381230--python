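import numpy as np
import pandas as pd
import pytest

from seroglycan.array import ReactivityMatrix
from seroglycan.enrichment import OTUTable


def make_matrix(values: np.ndarray, groups: list[str], glycans=None, library=None):
    """Assemble a ReactivityMatrix directly from a values array."""
    samples = [f"s{i + 1:02d}" for i in range(values.shape[0])]
    glycans = glycans or [f"g{j + 1:04d}" for j in range(values.shape[1])]
    frame = pd.DataFrame(values, index=samples, columns=glycans)
    return ReactivityMatrix(
        values=frame,
        isotype="IgG",
        sample_groups=pd.Series(groups, index=samples),
        library=library,
    )


@pytest.fixture
def small_otu_table() -> OTUTable:
    """Two Bacteroides OTUs, two background genera, one family-only OTU;
    one AAL-sorted and one IgG-sorted pair plus matched unsorted samples."""
    counts = pd.DataFrame(
        {
            "uns_1": [100, 50, 500, 300, 50],
            "aal_pos_1": [300, 150, 350, 150, 50],
            "uns_2": [120, 60, 480, 290, 50],
            "igg_pos_2": [350, 160, 300, 140, 50],
        },
        index=pd.Index(
            ["otu_b1", "otu_b2", "otu_f1", "otu_r1", "otu_lx"], name="otu_id"
        ),
    )
    taxonomy = {
        "otu_b1": "d:Bacteria;p:Bacteroidetes;f:Bacteroidaceae;g:Bacteroides;s:stercoris",
        "otu_b2": "d:Bacteria;p:Bacteroidetes;f:Bacteroidaceae;g:Bacteroides;s:vulgatus",
        "otu_f1": "d:Bacteria;p:Firmicutes;f:Ruminococcaceae;g:Faecalibacterium;s:prausnitzii",
        "otu_r1": "d:Bacteria;p:Firmicutes;f:Lachnospiraceae;g:Roseburia;s:intestinalis",
        "otu_lx": "d:Bacteria;p:Firmicutes;f:Lachnospiraceae",
    }
    samples = pd.DataFrame(
        {
            "sample_id": ["uns_1", "aal_pos_1", "uns_2", "igg_pos_2"],
            "fraction": ["unsorted", "AAL_pos", "unsorted", "IgG_pos"],
            "serum_group": ["none", "none", "none", "CD"],
            "matched_unsorted_id": ["", "uns_1", "", "uns_2"],
        }
    ).set_index("sample_id")
    return OTUTable(counts=counts, taxonomy=taxonomy, samples=samples)
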