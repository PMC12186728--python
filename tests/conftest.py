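import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from punctakit import AnalysisConfig, NucleusROI

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture
def full_frame_roi():
    """A NucleusROI covering a whole small frame (no ring)."""

    def make(shape=(32, 32), nucleus_id=1):
        mask = np.ones(shape, dtype=bool)
        return NucleusROI(
            nucleus_id=nucleus_id,
            mask=mask,
            perinuclear_mask=np.zeros(shape, dtype=bool),
            centroid=((shape[0] - 1) / 2, (shape[1] - 1) / 2),
            area_um2=float(mask.sum()) * 0.01,
        )

    return make


def flood_fill_components(binary, connectivity=8):
    """Brute-force connected components by explicit flood fill.

    Independent oracle for the labeling used in segmentation: returns a
    list of frozensets of (row, col) pixel coordinates.
    """
    binary = np.asarray(binary, dtype=bool)
    if connectivity == 4:
        neigh = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        neigh = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    seen = np.zeros_like(binary)
    comps = []
    h, w = binary.shape
    for r in range(h):
        for c in range(w):
            if binary[r, c] and not seen[r, c]:
                stack = [(r, c)]
                seen[r, c] = True
                comp = set()
                while stack:
                    rr, cc = stack.pop()
                    comp.add((rr, cc))
                    for dr, dc in neigh:
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < h and 0 <= nc < w and binary[nr, nc] and not seen[nr, nc]:
                            seen[nr, nc] = True
                            stack.append((nr, nc))
                comps.append(frozenset(comp))
    return comps
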