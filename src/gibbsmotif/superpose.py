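"""Optimal rigid-body superposition RMSD of paired Cα coordinate sets.

Two independent routes compute the same quantity,

    RMSD(C, D) = min over rotations R, translations t of
                 sqrt( (1/k) Σ_i || R C_i + t − D_i ||² ),

with point i of one set paired positionally with point i of the other:

* :func:`superpose_rmsd` — the fast path, Theobald's quaternion
  characteristic-polynomial (QCP) method: the minimal RMSD is obtained from
  the largest eigenvalue of the 4×4 quaternion key matrix, found by
  Newton–Raphson on its characteristic polynomial without ever forming a
  rotation matrix.
* :func:`kabsch_rmsd` — the brute-force oracle: centroid removal, SVD of the
  3×3 covariance, determinant sign correction to exclude reflections, then
  explicit rotation and residual.

The QCP iteration falls back to the SVD route when it fails to converge
(degenerate sets: k = 1, collinear points), so the public function is total
over all legal inputs.

:func:`average_pairwise_rmsd` is the alignment score used throughout the
search: the mean superposition RMSD over all structure pairs, pairing
aligned residues column-wise.
"""

from __future__ import annotations

import numpy as np

__all__ = ["superpose_rmsd", "kabsch_rmsd", "average_pairwise_rmsd"]

_NEWTON_MAX_STEPS = 50
_NEWTON_TOL = 1e-11


def _as_points(a) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate set must have shape (k, 3)")
    if a.shape[0] < 1:
        raise ValueError("coordinate set must contain at least one point")
    if not np.all(np.isfinite(a)):
        raise ValueError("coordinates must be finite")
    return a


def _check_pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a, b = _as_points(a), _as_points(b)
    if a.shape[0] != b.shape[0]:
        raise ValueError(f"size mismatch: {a.shape[0]} vs {b.shape[0]} points")
    return a, b


def kabsch_rmsd(a, b) -> float:
    """Minimal RMSD by the Kabsch SVD method (independent oracle).

    Centroids are removed, the optimal proper rotation is ``V diag(1,1,d) Uᵀ``
    with ``d = sign(det(VUᵀ))`` from the SVD of the covariance ``H = AᵀB``,
    and the residual of the explicitly rotated points gives the RMSD.
    Reflections are excluded, so mirror-image sets score strictly above zero.
    """
    a, b = _check_pair(a, b)
    k = a.shape[0]
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    h = ac.T @ bc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    diff = ac @ rot.T - bc
    return float(np.sqrt(max((diff**2).sum() / k, 0.0)))


def _qcp_rmsd(a: np.ndarray, b: np.ndarray) -> float | None:
    """QCP RMSD, or None when the Newton iteration does not converge."""
    k = a.shape[0]
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    g = float((ac**2).sum() + (bc**2).sum())
    if g <= 0.0:  # both sets collapse to a single point
        return 0.0
    m = ac.T @ bc

    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]

    # Coefficients of the quartic characteristic polynomial
    # P(x) = x^4 + c2 x^2 + c1 x + c0 (c3 = 0 by construction).
    sxx2, syy2, szz2 = sxx**2, syy**2, szz**2
    sxy2, syz2, sxz2 = sxy**2, syz**2, sxz**2
    syx2, szy2, szx2 = syx**2, szy**2, szx**2

    syzszymsyyszz2 = 2.0 * (syz * szy - syy * szz)
    sxx2syy2szz2syz2szy2 = syy2 + szz2 - sxx2 + syz2 + szy2

    c2 = -2.0 * (sxx2 + syy2 + szz2 + sxy2 + syx2 + sxz2 + szx2 + syz2 + szy2)
    c1 = 8.0 * (
        sxx * syz * szy
        + syy * szx * sxz
        + szz * sxy * syx
        - sxx * syy * szz
        - syz * szx * sxy
        - szy * syx * sxz
    )

    sxzpszx = sxz + szx
    syzpszy = syz + szy
    sxypsyx = sxy + syx
    syzmszy = syz - szy
    sxzmszx = sxz - szx
    sxymsyx = sxy - syx
    sxxpsyy = sxx + syy
    sxxmsyy = sxx - syy

    c0 = (
        (sxy2 + sxz2 - syx2 - szx2) ** 2
        + (sxx2syy2szz2syz2szy2 + syzszymsyyszz2)
        * (sxx2syy2szz2syz2szy2 - syzszymsyyszz2)
        + (-sxzpszx * syzmszy + sxymsyx * (sxxmsyy - szz))
        * (-sxzmszx * syzpszy + sxymsyx * (sxxmsyy + szz))
        + (-sxzpszx * syzpszy - sxypsyx * (sxxpsyy - szz))
        * (-sxzmszx * syzmszy - sxypsyx * (sxxpsyy + szz))
        + (+sxypsyx * syzpszy + sxzpszx * (sxxmsyy + szz))
        * (-sxymsyx * syzmszy + sxzpszx * (sxxpsyy + szz))
        + (+sxypsyx * syzmszy + sxzmszx * (sxxmsyy - szz))
        * (-sxymsyx * syzpszy + sxzmszx * (sxxpsyy - szz))
    )

    # Newton-Raphson from the upper bound g/2 >= lambda_max. In exact
    # arithmetic the iterate descends monotonically onto the largest root;
    # an increasing step or a negative root (lambda_max >= 0 always, since
    # the key matrix is traceless) means rounding noise took over — give up
    # and let the caller fall back to the SVD route.
    lam = g / 2.0
    for _ in range(_NEWTON_MAX_STEPS):
        lam2 = lam * lam
        p = lam2 * lam2 + c2 * lam2 + c1 * lam + c0
        dp = 4.0 * lam2 * lam + 2.0 * c2 * lam + c1
        if dp == 0.0:
            return None
        step = p / dp
        if step < -1e-6 * max(abs(lam), 1.0):
            return None
        lam -= step
        if abs(step) < _NEWTON_TOL * max(abs(lam), 1.0):
            break
    else:
        return None
    if lam < -1e-8 * max(g, 1.0):
        return None

    val = (g - 2.0 * lam) / k
    # Near lambda = g/2 the residual is a difference of large numbers and the
    # polynomial root carries too little relative precision for the RMSD;
    # defer to the SVD route, which forms the residual from rotated points.
    if val < 1e-6:
        return None
    return float(np.sqrt(val))


def superpose_rmsd(a, b) -> float:
    """Minimal RMSD in Å between positionally paired coordinate sets.

    Uses the QCP quaternion method and falls back to :func:`kabsch_rmsd`
    on the rare degenerate inputs where the Newton iteration fails.
    Symmetric in its arguments; invariant under proper rigid transforms of
    either argument.
    """
    a, b = _check_pair(a, b)
    k = a.shape[0]
    if k == 1:
        return 0.0  # a single point always superposes exactly
    if k == 2:
        # Two segments superpose with centroids coincident and directions
        # aligned; each point is off by half the length difference. The
        # closed form avoids the doubly degenerate (+/-lambda) key-matrix
        # spectrum where the polynomial iteration is semi-convergent.
        da = float(np.linalg.norm(a[1] - a[0]))
        db = float(np.linalg.norm(b[1] - b[0]))
        return abs(da - db) / 2.0
    r = _qcp_rmsd(a, b)
    if r is None:
        return kabsch_rmsd(a, b)
    return r


def average_pairwise_rmsd(rows_coords: list[np.ndarray]) -> float:
    """Mean superposition RMSD over all pairs of aligned substructures.

    Parameters
    ----------
    rows_coords : list of (w, 3) arrays
        One coordinate block per structure; residue h of one block pairs
        with residue h of every other (column-wise correspondence).
    """
    n = len(rows_coords)
    if n < 2:
        raise ValueError("need at least 2 substructures")
    width = rows_coords[0].shape[0] if hasattr(rows_coords[0], "shape") else len(rows_coords[0])
    blocks = [_as_points(r) for r in rows_coords]
    if any(b.shape[0] != width for b in blocks):
        raise ValueError("ragged alignment: all rows must have equal width")
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            total += superpose_rmsd(blocks[i], blocks[j])
    return total / (n * (n - 1) / 2)
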