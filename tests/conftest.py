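import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from dpannkit import CopyNumberMatrix  # noqa: E402


@pytest.fixture
def toy_matrix() -> CopyNumberMatrix:
    """4 genomes x 4 markers with mixed presence, duplication, and lineages."""
    counts = np.array(
        [
            [1, 2, 1, 0],
            [1, 1, 0, 0],
            [2, 1, 1, 0],
            [0, 1, 1, 1],
        ]
    )
    return CopyNumberMatrix(
        genome_ids=["g1", "g2", "g3", "g4"],
        marker_ids=["m1", "m2", "m3", "m4"],
        counts=counts,
        lineage={"g1": "A", "g2": "A", "g3": "B", "g4": "B"},
        prior_completeness={"g1": 90.0, "g2": 40.0, "g3": 75.0, "g4": 50.0},
    )
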