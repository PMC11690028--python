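"""Exhaustive per-voxel section-mask predicate, used by acceptance.py as an
independent reference for the vectorized implementation."""

import numpy as np


def brute_force_section_mask(labels, affine, muscle, landmarks, offset_mm,
                             inferior_offset_mm=30.0):
    p1, p2, p3 = (np.asarray(p, float) for p in landmarks.y_plane_points)
    n = np.cross(p2 - p1, p3 - p1)
    n = n / np.linalg.norm(n)
    if np.dot(n, np.asarray(landmarks.medial_reference) - p1) < 0:
        n = -n
    ax, ay, az = float(n[0]), float(n[1]), float(n[2])
    px, py, pz = float(p1[0]), float(p1[1]), float(p1[2])
    cut_z = float(landmarks.labrum_inferior[2]) - inferior_offset_mm
    A = np.asarray(affine, float)
    ni, nj, nk = labels.shape
    out = np.zeros(labels.shape, dtype=bool)
    for i in range(ni):
        for j in range(nj):
            for k in range(nk):
                if labels[i, j, k] != muscle:
                    continue
                x = A[0, 0] * i + A[0, 1] * j + A[0, 2] * k + A[0, 3]
                y = A[1, 0] * i + A[1, 1] * j + A[1, 2] * k + A[1, 3]
                z = A[2, 0] * i + A[2, 1] * j + A[2, 2] * k + A[2, 3]
                if ax * (x - px) + ay * (y - py) + az * (z - pz) > offset_mm:
                    continue
                if z < cut_z:
                    continue
                out[i, j, k] = True
    return out
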