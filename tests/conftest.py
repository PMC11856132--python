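import numpy as np
import pytest

from weeviltrack.mot_io import BoundingBox, Detection, FrameStream, GroundTruthObject


def box(left=0.0, top=0.0, w=10.0, h=10.0) -> BoundingBox:
    return BoundingBox(left, top, w, h)


def random_stream(rng: np.random.Generator, n_frames=5, max_objs=4,
                  kind="gt") -> FrameStream:
    """Random valid FrameStream whose last frame is non-empty."""
    stream = FrameStream(n_frames)
    next_id = 1
    for f in range(1, n_frames + 1):
        n = int(rng.integers(0, max_objs + 1)) if f < n_frames else int(rng.integers(1, max_objs + 1))
        for _ in range(n):
            b = BoundingBox(
                float(np.round(rng.uniform(0, 500), 2)),
                float(np.round(rng.uniform(0, 500), 2)),
                float(np.round(rng.uniform(5, 60), 2)),
                float(np.round(rng.uniform(5, 60), 2)),
            )
            if kind == "gt":
                stream.add(GroundTruthObject(f, next_id, b))
                next_id += 1
            else:
                stream.add(Detection(f, b, float(np.round(rng.uniform(0, 1), 6))))
    return stream


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
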