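"""Independent brute-force reference implementations used only by tests."""

import numpy as np
from scipy import ndimage

_STRUCTS = {6: 1, 18: 2, 26: 3}


def tfce_bruteforce(stat, mask, E=0.5, H=2.0, n_steps=100, dh=None,
                    connectivity=26):
    """Explicit threshold loop + connected-component labeling TFCE."""
    s = np.where(mask, stat, 0.0)
    vmax = s.max()
    out = np.zeros_like(s, dtype=float)
    if vmax <= 0:
        return out
    if dh is None:
        dh = vmax / n_steps
        k_max = n_steps
    else:
        k_max = int(np.floor(vmax / dh + 1e-12))
    struct = ndimage.generate_binary_structure(3, _STRUCTS[connectivity])
    for k in range(1, k_max + 1):
        h = dh * k
        sup = s >= h
        labels, _ = ndimage.label(sup, structure=struct)
        sizes = np.bincount(labels.ravel())
        out += np.where(sup, sizes[labels] ** E * h**H * dh, 0.0)
    return out


def glm_t_bruteforce(X, Y):
    """Per-voxel OLS t statistic for the last column, one voxel at a time."""
    n, p = X.shape
    df = n - p
    xtx_inv = np.linalg.inv(X.T @ X)
    ts = np.empty(Y.shape[1])
    for v in range(Y.shape[1]):
        beta = xtx_inv @ X.T @ Y[:, v]
        resid = Y[:, v] - X @ beta
        sigma2 = resid @ resid / df
        ts[v] = beta[-1] / np.sqrt(sigma2 * xtx_inv[-1, -1])
    return ts, df
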