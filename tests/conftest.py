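import numpy as np
import pandas as pd
import pytest

from callomap import (
    CallosalMask,
    RoiSampleTable,
    build_roi_template,
    default_spec,
    generate_mask,
    generate_modality_images,
    parcellate_witelson,
)


def make_rect_mask(width=100, height=20, pad=0):
    """Solid rectangle mask, optionally padded with background."""
    px = np.zeros((height + 2 * pad, width + 2 * pad), dtype=bool)
    px[pad : pad + height, pad : pad + width] = True
    return CallosalMask(pixels=px)


def table_from_matrix(matrix, modality="X", units="raw"):
    """RoiSampleTable from an (n_samples, n_rois) value matrix."""
    n_samples, n_rois = matrix.shape
    rows = []
    for s in range(n_samples):
        for j in range(n_rois):
            rows.append(
                {
                    "modality": modality,
                    "sample": f"sample{s + 1}",
                    "roi_index": j + 1,
                    "region": "splenium",
                    "value": float(matrix[s, j]),
                    "n_pixels": 1,
                }
            )
    return RoiSampleTable(data=pd.DataFrame(rows), units_state=units)


@pytest.fixture(scope="session")
def rect_mask():
    return make_rect_mask()


@pytest.fixture(scope="session")
def phantom_mask():
    return generate_mask(default_spec())


@pytest.fixture(scope="session")
def phantom_label_map(phantom_mask):
    return parcellate_witelson(phantom_mask)


@pytest.fixture(scope="session")
def phantom_template(phantom_label_map):
    return build_roi_template(phantom_label_map)


@pytest.fixture(scope="session")
def phantom_dataset(phantom_mask, phantom_template):
    return generate_modality_images(
        phantom_mask, default_spec(seed=0), template=phantom_template
    )
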