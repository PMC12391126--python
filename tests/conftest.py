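import numpy as np
import pytest

import leafcal as lc


def small_spec(**overrides) -> lc.SceneSpec:
    """Scaled-down scene: same physical layout and schedule, smaller raster
    so rendering stays cheap in tests."""
    kwargs = dict(img_width_px=360, img_height_px=370, seed=3)
    kwargs.update(overrides)
    return lc.SceneSpec(**kwargs)


@pytest.fixture(scope="session")
def tracked_scene():
    """A 30-frame non-occluded scene rendered once and tracked once."""
    spec = small_spec()
    frames, gt, _ = lc.render_scene(spec, n_frames=30)
    tracks = lc.track_sequence(frames)
    return spec, frames, gt, tracks


def id_consistency(tracks, frames, gt) -> float:
    """Fraction of track observations attached to the correct true leaf."""
    by_time = {f.time: (f, ids) for f, ids in zip(frames, gt.frame_ids)}
    good = total = 0
    for tr in tracks:
        for t, inst in tr.observations:
            frame, ids = by_time[t]
            total += 1
            if tr.leaf_id in ids:
                true_mask = frame.masks[ids.index(tr.leaf_id)]
                if np.array_equal(inst.raster > 0, true_mask > 127):
                    good += 1
    return good / total if total else 0.0


def make_mask(shape, slices, value=255):
    m = np.zeros(shape, dtype=np.uint8)
    m[slices] = value
    return m
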