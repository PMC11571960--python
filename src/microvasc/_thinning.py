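"""3D curve thinning (medial-axis skeletonization) with guaranteed
homotopy preservation.

Border-sequential thinning in the style of Lee/Bertrand: iterate over the
six border directions, collect deletable candidates (simple points that are
not curve endpoints), then delete them sequentially, re-testing simplicity
after every deletion. A point is *simple* (deletable without changing
topology) iff its foreground 26-neighborhood forms exactly one 26-connected
component and the background within its 18-neighborhood forms exactly one
6-connected component adjacent to the point (Bertrand & Malandain's
characterization). Sequential rechecking makes the result correct for
even-width objects, which parallel deletion schemes can erase entirely —
the scikit-image 0.26 3D skeletonize does exactly that (an 8 µm ball or a
4-voxel-wide rod comes back empty), which is why this routine exists.

The result is a one-voxel-wide 26-connected curve skeleton: loops in the
mask remain loops, components remain components.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# 26-neighborhood offsets as flat index deltas within a 3x3x3 block are
# computed on the fly; blocks are addressed as idx = (dz+1)*9 + (dy+1)*3 + (dx+1).

_FACE_OFFSETS = np.array([
    (-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)
], dtype=np.int64)


@njit(cache=True)
def _is_simple_and_not_endpoint(img, z, y, x):
    """Deletability test for the voxel at (z, y, x) of a padded image."""
    # gather the 3x3x3 neighborhood (center at block index 13)
    nb = np.zeros(27, dtype=np.uint8)
    k = 0
    n_fg = 0
    for dz in range(-1, 2):
        for dy in range(-1, 2):
            for dx in range(-1, 2):
                v = img[z + dz, y + dy, x + dx]
                nb[k] = v
                if v and k != 13:
                    n_fg += 1
                k += 1
    if n_fg <= 1:
        return False  # endpoint or isolated: preserve

    # --- exactly one 26-connected foreground component in N26 \ {center} ---
    label = np.zeros(27, dtype=np.uint8)
    stack = np.zeros(27, dtype=np.int64)
    n_comp = 0
    for start in range(27):
        if start == 13 or nb[start] == 0 or label[start]:
            continue
        n_comp += 1
        if n_comp > 1:
            return False
        top = 0
        stack[top] = start
        top += 1
        label[start] = 1
        while top > 0:
            top -= 1
            cur = stack[top]
            cz = cur // 9 - 1
            cy = (cur % 9) // 3 - 1
            cx = cur % 3 - 1
            for dz in range(-1, 2):
                nz = cz + dz
                if nz < -1 or nz > 1:
                    continue
                for dy in range(-1, 2):
                    ny = cy + dy
                    if ny < -1 or ny > 1:
                        continue
                    for dx in range(-1, 2):
                        nx = cx + dx
                        if nx < -1 or nx > 1:
                            continue
                        nk = (nz + 1) * 9 + (ny + 1) * 3 + (nx + 1)
                        if nk == 13 or label[nk] or nb[nk] == 0:
                            continue
                        label[nk] = 1
                        stack[top] = nk
                        top += 1
    if n_comp != 1:
        return False

    # --- exactly one 6-connected background component in N18 touching the
    #     center through a face ---
    # N18: block cells with |dz|+|dy|+|dx| <= 2, excluding the center.
    blabel = np.zeros(27, dtype=np.uint8)
    n_bg_comp = 0
    for f in range(6):
        fz = _FACE_OFFSETS[f, 0]
        fy = _FACE_OFFSETS[f, 1]
        fx = _FACE_OFFSETS[f, 2]
        fk = (fz + 1) * 9 + (fy + 1) * 3 + (fx + 1)
        if nb[fk] != 0 or blabel[fk]:
            continue
        n_bg_comp += 1
        if n_bg_comp > 1:
            return False
        top = 0
        stack[top] = fk
        top += 1
        blabel[fk] = 1
        while top > 0:
            top -= 1
            cur = stack[top]
            cz = cur // 9 - 1
            cy = (cur % 9) // 3 - 1
            cx = cur % 3 - 1
            for f2 in range(6):
                nz = cz + _FACE_OFFSETS[f2, 0]
                ny = cy + _FACE_OFFSETS[f2, 1]
                nx = cx + _FACE_OFFSETS[f2, 2]
                if nz < -1 or nz > 1 or ny < -1 or ny > 1 or nx < -1 or nx > 1:
                    continue
                if abs(nz) + abs(ny) + abs(nx) > 2:
                    continue  # outside N18
                nk = (nz + 1) * 9 + (ny + 1) * 3 + (nx + 1)
                if nk == 13 or blabel[nk] or nb[nk] != 0:
                    continue
                blabel[nk] = 1
                stack[top] = nk
                top += 1
    if n_bg_comp != 1:
        return False
    return True


@njit(cache=True)
def _thin_pass(img, coords, dz, dy, dx, cand):
    """Collect deletable border candidates for one direction, then delete
    them sequentially with re-testing. Returns the number deleted."""
    n_cand = 0
    for i in range(coords.shape[0]):
        z = coords[i, 0]
        y = coords[i, 1]
        x = coords[i, 2]
        if img[z, y, x] == 0:
            continue
        if img[z + dz, y + dy, x + dx] != 0:
            continue  # not a border point in this direction
        if _is_simple_and_not_endpoint(img, z, y, x):
            cand[n_cand, 0] = z
            cand[n_cand, 1] = y
            cand[n_cand, 2] = x
            n_cand += 1
    n_del = 0
    for i in range(n_cand):
        z = cand[i, 0]
        y = cand[i, 1]
        x = cand[i, 2]
        if _is_simple_and_not_endpoint(img, z, y, x):
            img[z, y, x] = 0
            n_del += 1
    return n_del


def skeletonize_3d(mask: np.ndarray) -> np.ndarray:
    """Thin a 3D boolean mask to a one-voxel-wide curve skeleton."""
    if mask.ndim != 3:
        raise ValueError("expected a 3D mask")
    if not mask.any():
        return np.zeros(mask.shape, dtype=bool)
    img = np.pad(mask.astype(np.uint8), 1)
    coords = np.argwhere(img)
    cand = np.empty((coords.shape[0], 3), dtype=np.int64)
    while True:
        deleted = 0
        for f in range(6):
            dz, dy, dx = _FACE_OFFSETS[f]
            deleted += _thin_pass(img, coords, int(dz), int(dy), int(dx), cand)
        if deleted == 0:
            break
        keep = img[coords[:, 0], coords[:, 1], coords[:, 2]] != 0
        coords = coords[keep]
        cand = cand[: coords.shape[0]]
    return img[1:-1, 1:-1, 1:-1].astype(bool)
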