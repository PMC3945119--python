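import numpy as np
import pandas as pd
import pytest

from plast import imaging, segmentation
from plast.synthdata import SyntheticFieldSpec, SyntheticStrainSet, generate_field, generate_feature_table


@pytest.fixture(scope="session")
def nuclear_field():
    """Default synthetic field (10 cells, nuclear GFP) with ground truth."""
    return generate_field(SyntheticFieldSpec(seed=2))


@pytest.fixture(scope="session")
def segmented(nuclear_field):
    """Preprocessed channels plus detected nuclei and cells for the field."""
    fieldi, truth = nuclear_field
    dna = imaging.subtract_background_fluorescence(fieldi.dna, 50)
    gfp = imaging.subtract_background_fluorescence(fieldi.gfp, 50)
    dic = imaging.subtract_background_dic(fieldi.dic, 25)
    nuclei = segmentation.detect_nuclei(dna)
    cells = segmentation.segment_cells(dic, nuclei)
    return {"gfp": gfp, "dna": dna, "dic": dic, "nuclei": nuclei, "cells": cells, "truth": truth}


@pytest.fixture(scope="session")
def three_class_table():
    """Feature table for 18 strains over three localization classes."""
    assign = {f"S{i:02d}": ("nuclear", "cytoplasmic", "punctate")[i % 3] for i in range(18)}
    ss = SyntheticStrainSet(pattern_assignments=assign)
    table = generate_feature_table(ss, seed=5)
    return table, assign


@pytest.fixture()
def reference_cells():
    """Unstructured reference pool (background distribution) for SVM profiles."""
    rng = np.random.default_rng(99)
    cols = [f"f_{j + 1:04d}" for j in range(50)]
    return pd.DataFrame(rng.standard_normal((40, 50)), columns=cols)
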