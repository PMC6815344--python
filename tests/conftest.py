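import numpy as np
import pytest

import limbusflow as lf


def polyline_distance_um(points_um: np.ndarray, centerline_um: np.ndarray) -> np.ndarray:
    """Min Euclidean distance from each point to a polyline (um)."""
    out = np.full(points_um.shape[0], np.inf)
    for a, b in zip(centerline_um[:-1], centerline_um[1:]):
        ab = b - a
        L2 = float(ab @ ab)
        if L2 == 0:
            d = np.hypot(*(points_um - a).T)
        else:
            t = np.clip(((points_um - a) @ ab) / L2, 0.0, 1.0)
            proj = a + t[:, None] * ab
            d = np.hypot(*(points_um - proj).T)
        out = np.minimum(out, d)
    return out


def match_segment(segments, spec, centerline_um, min_points=30):
    """Segment whose midline lies closest to a ground-truth centerline.

    Standard detection-to-truth matching for recovery measurements: among
    segments with enough points, pick the one with the smallest median
    distance to the true centerline.
    """
    best, best_d = None, np.inf
    for seg in segments:
        if len(seg.points) < min_points:
            continue
        d = float(np.median(polyline_distance_um(
            seg.positions_px * spec.pitch_um, centerline_um)))
        if d < best_d:
            best, best_d = seg, d
    return best, best_d


@pytest.fixture
def px_spec():
    """256 px grid at 1 um pitch, no PSF/noise: scale-space math in px == um."""
    return lf.FrameSpec(fov_um=256, grid_px=256, background_au=0.0,
                        noise_sd_au=0.0, psf_sigma_um=0.0)


@pytest.fixture
def cle_spec():
    """CLE-like geometry scaled down to 256 px (pitch ~1.65 um) for speed."""
    return lf.FrameSpec(fov_um=423.0, grid_px=256, background_au=20.0,
                        noise_sd_au=0.0)


@pytest.fixture
def noisy_params():
    return lf.ScaleSpaceParams(response_threshold=4.0)
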