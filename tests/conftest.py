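import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from elevmicro.core_io import CommunityTable, DistanceMatrix, metadata_from_records

settings.register_profile("ci", max_examples=25, deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def small_table() -> CommunityTable:
    """3 samples x 4 taxa with known structure."""
    counts = pd.DataFrame(
        [[6, 2, 0, 1], [2, 2, 0, 5], [0, 0, 7, 3]],
        index=["s1", "s2", "s3"],
        columns=["t1", "t2", "t3", "t4"],
    )
    return CommunityTable(counts)


@pytest.fixture
def toy_metadata() -> pd.DataFrame:
    rows = []
    elevations = [501.0, 501.0, 3431.0, 3431.0]
    for i, elev in enumerate(elevations):
        rows.append(
            {
                "sample_id": f"s{i + 1}",
                "subject_id": f"u{i + 1}",
                "elevation_m": elev,
                "body_site": "forehead",
                "gender": "female" if i % 2 else "male",
                "age": 30.0 + i,
                "height": 170.0,
                "weight": 65.0,
            }
        )
    return metadata_from_records(rows)


def random_distance_matrix(n: int, seed: int, ids=None) -> DistanceMatrix:
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n, 3))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    ids = ids or [f"x{i}" for i in range(n)]
    return DistanceMatrix(ids, d, "euclidean")
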