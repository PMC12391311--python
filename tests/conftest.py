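import numpy as np
import pytest

from facesym import SyntheticFaceSpec, generate_face_pair
from facesym.mask import FaceMask


@pytest.fixture(scope="session")
def template_pair():
    """Default synthetic neutral/expression pair with landmark templates."""
    spec = SyntheticFaceSpec(expression_index=7, asymmetry=0.5, seed=7)
    return generate_face_pair(spec)


@pytest.fixture(scope="session")
def template_landmarks(template_pair):
    """Bilaterally symmetric neutral landmark template (478 points)."""
    return template_pair[2]


def make_mask(raster, midline_x):
    return FaceMask(raster=np.asarray(raster, dtype=bool), midline_x=midline_x)


def brute_force_score(raster, mask_raster, midline_x, sigma2_max=5000.0):
    """Independent per-pixel implementation of the symmetry score.

    Explicit double loop over pixels: pair each masked left pixel with
    the masked pixel containing its mirrored center, then evaluate the
    mean-absolute-difference score and the variance weight directly.
    Returns (s_mean, variance, score, n_pairs).
    """
    h, w = raster.shape
    left_vals, right_vals = [], []
    for i in range(h):
        for j in range(w):
            cx = j + 0.5
            if cx >= midline_x or not mask_raster[i, j]:
                continue
            jm = int(np.floor(2.0 * midline_x - cx))
            if 0 <= jm < w and jm + 0.5 > midline_x and mask_raster[i, jm]:
                left_vals.append(float(raster[i, j]))
                right_vals.append(float(raster[i, jm]))
    n = len(left_vals)
    if n == 0:
        return None
    diffs = [l - r for l, r in zip(left_vals, right_vals)]
    s_mean = 1.0 - sum(abs(d) for d in diffs) / n / 255.0
    mu = sum(diffs) / n
    var = sum((d - mu) ** 2 for d in diffs) / n
    score = s_mean * (1.0 - min(var / sigma2_max, 1.0))
    return s_mean, var, score, n
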