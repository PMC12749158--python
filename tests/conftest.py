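import numpy as np
import pandas as pd
import pytest

from vasosyn.io import CONDITIONS, CountMatrix, SampleSheet


@pytest.fixture
def small_sheet() -> SampleSheet:
    """Two animals x four conditions, one cell type."""
    rows = []
    for a in ("a1", "a2"):
        for cond in CONDITIONS:
            rows.append(
                {
                    "sample_id": f"{a}_{cond}",
                    "animal_id": a,
                    "cell_type": "WT_VSMC",
                    "sex": "male",
                    "passage": 3,
                    "condition": cond,
                }
            )
    return SampleSheet(pd.DataFrame(rows))


@pytest.fixture
def small_counts(small_sheet) -> CountMatrix:
    rng = np.random.default_rng(42)
    samples = small_sheet.sample_ids
    counts = rng.integers(10, 1000, size=(20, len(samples)))
    return CountMatrix([f"g{i}" for i in range(20)], samples, counts)


@pytest.fixture
def ellipse_objects() -> pd.DataFrame:
    """Cell-object table of exact ellipses with known circularities."""
    from vasosyn.phenotypes import ellipse_perimeter

    rows = []
    for i, (r, area, n_nuc) in enumerate(
        [(9.0, 1000.0, 1), (2.0, 1500.0, 1), (1.0, 300.0, 1), (3.0, 5000.0, 1), (4.0, 900.0, 2)]
    ):
        b = np.sqrt(area / (np.pi * r))
        rows.append(
            {
                "object_id": i,
                "area_um2": area,
                "perimeter_um": ellipse_perimeter(r * b, b),
                "n_nuclei": n_nuc,
                "x_um": 10.0 * i,
                "y_um": 0.0,
            }
        )
    return pd.DataFrame(rows)
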