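"""Independent brute-force / closed-form oracles shared by the test suite.

These deliberately avoid the package's own implementations: distances by
exhaustive pairwise enumeration, AUC by the positive-negative pair
statistic, ICC by a hand-rolled ANOVA decomposition.
"""

import numpy as np
from scipy.ndimage import (binary_erosion, gaussian_filter,
                           generate_binary_structure, label)
from scipy.spatial.distance import cdist

from aortaquant.volume_io import ImageVolume


def random_blob(rng, size=40):
    """Random connected 2D blob via thresholded smoothed noise."""
    field = gaussian_filter(rng.normal(size=(size, size)), 4.0)
    mask = field > np.percentile(field, 70)
    lab, n = label(mask)
    if n == 0:
        mask = np.zeros((size, size), bool)
        mask[size // 2, size // 2] = True
        return mask
    counts = np.bincount(lab.ravel())[1:]
    return lab == (np.argmax(counts) + 1)


def brute_force_max_diameter(mask, pixel_mm=1.0):
    """O(n^2) max distance over boundary pixel centers (largest component)."""
    st = generate_binary_structure(2, 1)
    lab, n = label(mask, structure=st)
    if n == 0:
        return 0.0
    counts = np.bincount(lab.ravel())[1:]
    comp = lab == (np.argmax(counts) + 1)
    er = binary_erosion(comp, structure=st, border_value=0)
    pts = np.argwhere(comp & ~er).astype(float)
    best = 0.0
    for i in range(len(pts)):
        d = np.linalg.norm(pts[i + 1:] - pts[i], axis=1)
        if len(d):
            best = max(best, float(d.max()))
    return best * pixel_mm


def random_mask_pair(rng, n=10):
    """Two random small ball masks on a shared grid."""
    vols = []
    for _ in range(2):
        m = np.zeros((n, n, n), dtype=np.uint8)
        c = rng.integers(2, n - 2, size=3)
        r = rng.integers(1, 4)
        x, y, z = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
        m[(x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2 <= r ** 2] = 1
        vols.append(ImageVolume(m, (1, 1, 1)))
    return vols[0], vols[1]


def brute_force_distances(a, b):
    """Pooled bidirectional nearest-surface distances by full enumeration."""
    st = generate_binary_structure(3, 1)
    fa, fb = a.data.astype(bool), b.data.astype(bool)
    sa = np.argwhere(fa & ~binary_erosion(fa, st, border_value=0)) * a.spacing
    sb = np.argwhere(fb & ~binary_erosion(fb, st, border_value=0)) * b.spacing
    m = cdist(sa, sb)
    return np.concatenate([m.min(axis=1), m.min(axis=0)])


def auc_pair_oracle(scores, labels):
    """Exhaustive mean over positive-negative pairs with half-credit ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos, neg = scores[labels], scores[~labels]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def anova_icc21_oracle(x, y):
    """ICC(2,1) from an independent two-way ANOVA sum-of-squares split."""
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.mean()
    ss_rows = k * ((data.mean(1) - grand) ** 2).sum()
    ss_cols = n * ((data.mean(0) - grand) ** 2).sum()
    ss_err = ((data - grand) ** 2).sum() - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
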