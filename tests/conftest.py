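import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tespatial import GenomeLayout

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=100,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def layout() -> GenomeLayout:
    return GenomeLayout({"chr1": 10_000, "chr2": 5_000})


def bitmap_coverage(layout: GenomeLayout, interval_set) -> dict[str, np.ndarray]:
    """Per-base boolean oracle, independent of the array-based implementation."""
    bitmaps = {c: np.zeros(layout[c], dtype=bool) for c in layout.chrom_names}
    for iv in interval_set:
        bitmaps[iv.chrom][iv.start:iv.end] = True
    return bitmaps
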