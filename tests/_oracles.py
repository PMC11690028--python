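"""Independent reference computations used to cross-check the package.

Everything here is deliberately written from first principles (explicit
loops, plane equations solved as linear systems, closed-form test statistics)
and shares no code path with the implementation under test.
"""

import numpy as np
import scipy.stats


def plane_signed_distance_from_points(p1, p2, p3, toward, query):
    """Signed distance of ``query`` to the plane through p1,p2,p3.

    The plane coefficients (a,b,c,d) with a x + b y + c z = d are obtained by
    solving the 3x3 linear system through the points; the sign is fixed so
    that ``toward`` is on the positive side.
    """
    pts = np.array([p1, p2, p3], dtype=float)
    # solve for (a,b,c) with d=1; shift coordinates if the plane passes
    # through the origin (making the system singular for d=1)
    shift = np.array([17.0, -11.0, 5.0])
    shifted = pts + shift
    abc = np.linalg.solve(shifted, np.ones(3))
    norm = np.linalg.norm(abc)
    dist = (np.dot(abc, np.asarray(query, dtype=float) + shift) - 1.0) / norm
    side = (np.dot(abc, np.asarray(toward, dtype=float) + shift) - 1.0) / norm
    return dist if side > 0 else -dist


def brute_force_section_mask(labels, affine, muscle, landmarks, offset_mm,
                             inferior_offset_mm=30.0):
    """Per-voxel loop applying the three section predicates.

    A voxel is kept iff (a) its label equals ``muscle``; (b) its world-mapped
    center lies at signed distance <= offset from the Y-view plane, positive
    side medial; (c) its center lies on or above the plane
    ``inferior_offset_mm`` below the labrum-inferior landmark.
    """
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
                d_plane = ax * (x - px) + ay * (y - py) + az * (z - pz)
                if d_plane > offset_mm:
                    continue
                if -(z - cut_z) > 0:  # below the inferior cut-off
                    continue
                out[i, j, k] = True
    return out


def paired_t_closed_form(a, b):
    """t and two-sided p of the paired t-test, from the defining formula."""
    d = np.asarray(a, float) - np.asarray(b, float)
    n = d.size
    t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
    p = 2.0 * scipy.stats.t.sf(abs(t), n - 1)
    return t, p


def pearson_closed_form(x, y):
    """Pearson r and two-sided p via the t transform with n-2 df."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    yc = y - y.mean()
    r = (xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    n = x.size
    t = r * np.sqrt((n - 2) / (1 - r ** 2))
    p = 2.0 * scipy.stats.t.sf(abs(t), n - 2)
    return r, p


def ols_closed_form(x, y):
    """OLS coefficients, standard errors and two-sided p-values via the
    normal equations (design ``x`` must already include an intercept)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n, p = x.shape
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    s2 = resid @ resid / (n - p)
    se = np.sqrt(np.diag(xtx_inv) * s2)
    tvals = beta / se
    pvals = 2.0 * scipy.stats.t.sf(np.abs(tvals), n - p)
    return beta, se, pvals


def icc21_closed_form(matrix):
    """ICC(2,1) from the two-way ANOVA mean squares, spelled out."""
    x = np.asarray(matrix, float)
    n, k = x.shape
    grand = x.mean()
    msr = k * ((x.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((x.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sse = ((x - x.mean(axis=1, keepdims=True)
            - x.mean(axis=0, keepdims=True) + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def ellipsoid_halfspace_volume_mc(ellipsoid, normal, plane_offset,
                                  n_points=2_000_000, seed=0):
    """Monte-Carlo volume of an ellipsoid intersected with n.x <= offset."""
    rng = np.random.default_rng(seed)
    c = np.asarray(ellipsoid.center, float)
    r = np.eye(3) if ellipsoid.rotation is None \
        else np.asarray(ellipsoid.rotation, float).reshape(3, 3)
    axes = np.asarray(ellipsoid.semi_axes, float)
    half = np.abs(r * axes).sum(axis=1)  # bounding box half-widths
    lo, hi = c - half, c + half
    pts = rng.uniform(lo, hi, size=(n_points, 3))
    local = (pts - c) @ r / axes
    inside = (local ** 2).sum(axis=1) <= 1.0
    nrm = np.asarray(normal, float)
    nrm = nrm / np.linalg.norm(nrm)
    kept = inside & (pts @ nrm <= plane_offset)
    box_vol = np.prod(hi - lo)
    return kept.mean() * box_vol
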