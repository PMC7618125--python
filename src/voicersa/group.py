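"""Group-level inference: one-sample t maps, probability-matched z maps,
threshold-free cluster enhancement (TFCE) and sign-flip permutation FWE
correction with the maximum-statistic null.

The one-sample t test compares per-subject Fisher-z searchlight values with
zero, using only the subjects observed at each voxel (degrees of freedom
adjusted per voxel for missing coverage).  TFCE integrates
``extent(h)^E * h^H * dh`` over supra-threshold 6-connected components
(E = 0.5, H = 2, dh = z_max/100 by default); the negative tail is enhanced
on the negated map.  Family-wise error is controlled by the permutation
distribution of the maximum TFCE score over the mask per tail, built by
randomly sign-flipping subject maps; corrected z = Phi^-1(1 - p/2) per tail
with the observed sign restored (so |z| > 1.96 means FWE p < .05 in that
tail), thresholded at +/-1.96.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import ndimage, stats
from scipy.special import ndtri, ndtri_exp

from .mask import VoxelMask
from .searchlight import SearchlightMap

__all__ = [
    "GroupStatResult",
    "group_tmap",
    "t_to_z",
    "tfce_enhance",
    "permutation_correct",
    "threshold_map",
    "Z_THRESHOLD",
]

#: Two-sided alpha = 0.05 normal critical value used for map thresholding.
Z_THRESHOLD = float(np.round(ndtri(0.975), 2))

_MAX_T = np.finfo(np.float64).max / 1e10


def _stack(subject_maps) -> np.ndarray:
    if isinstance(subject_maps, np.ndarray):
        return np.asarray(subject_maps, dtype=float)
    return np.stack([m.values if isinstance(m, SearchlightMap) else np.asarray(m, float)
                     for m in subject_maps])


def group_tmap(subject_maps):
    """Voxel-wise one-sample t vs 0 over subjects, with per-voxel dof.

    Only subjects with finite values at a voxel contribute; dof = n_obs - 1.
    Voxels observed in fewer than 3 subjects are NaN.  Zero-variance voxels
    map to the largest finite representable t (sign of the mean) with a
    warning.
    """
    x = _stack(subject_maps)
    finite = np.isfinite(x)
    n = finite.sum(axis=0).astype(float)
    x0 = np.where(finite, x, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = x0.sum(axis=0) / n
        ss = (np.where(finite, (x0 - mean) ** 2, 0.0)).sum(axis=0)
        var = ss / (n - 1)
        t = mean / np.sqrt(var / n)
    zero_var = (var == 0) & (n >= 3)
    if zero_var.any():
        warnings.warn("zero variance across subjects at some voxels; "
                      "t set to the largest finite value", RuntimeWarning,
                      stacklevel=2)
        t = np.where(zero_var, np.sign(mean) * _MAX_T, t)
    t = np.where(n >= 3, t, np.nan)
    dof = np.where(n >= 3, n - 1, np.nan)
    return t, dof


def t_to_z(t, dof):
    """Probability-matching t -> z, sign-preserving, tail-stable.

    z = Phi^-1(F_t(t; dof)) computed through log survival functions so that
    very large |t| stays finite and accurate.
    """
    t = np.asarray(t, dtype=float)
    dof = np.asarray(dof, dtype=float)
    if np.nanmin(np.where(np.isfinite(dof), dof, np.inf)) < 1:
        raise ValueError("dof must be >= 1")
    at = np.abs(t)
    with np.errstate(invalid="ignore"):
        logp = stats.t.logsf(at, dof)
    z = -ndtri_exp(logp)
    out = np.sign(t) * z
    out = np.where(np.isfinite(t) & np.isfinite(dof), out, np.nan)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# TFCE
# ---------------------------------------------------------------------------

_STRUCT6 = ndimage.generate_binary_structure(3, 1)


def mask_adjacency(mask_data: np.ndarray):
    """CSR 6-connectivity neighbor lists over in-mask voxels (C-order)."""
    mask_data = np.asarray(mask_data, dtype=bool)
    n = int(mask_data.sum())
    idx = -np.ones(mask_data.shape, dtype=np.int64)
    idx[mask_data] = np.arange(n)
    src_all, dst_all = [], []
    for axis in range(3):
        for sign in (1, -1):
            shifted = np.roll(idx, sign, axis=axis)
            # voxels at the rolled-over border are not neighbors
            sl = [slice(None)] * 3
            sl[axis] = 0 if sign == 1 else -1
            shifted[tuple(sl)] = -1
            a = idx[mask_data]
            b = shifted[mask_data]
            valid = b >= 0
            src_all.append(a[valid])
            dst_all.append(b[valid])
    src = np.concatenate(src_all)
    dst = np.concatenate(dst_all)
    order = np.argsort(src, kind="stable")
    indices = dst[order]
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(np.bincount(src, minlength=n), out=indptr[1:])
    return indptr, indices


@njit(cache=True)
def _tfce_values(vals, indptr, indices, e_exp, h_exp, dh, n_steps):  # pragma: no cover
    n = vals.shape[0]
    out = np.zeros(n)
    vmax = 0.0
    for i in range(n):
        if vals[i] > vmax:
            vmax = vals[i]
    if vmax <= 0.0:
        return out
    step = dh if dh > 0.0 else vmax / n_steps
    n_h = int(np.ceil(vmax / step + 1e-12))
    order = np.argsort(-vals)
    parent = np.empty(n, dtype=np.int64)
    size = np.empty(n, dtype=np.int64)
    active = np.zeros(n, dtype=np.uint8)
    ptr = 0
    for s in range(n_h, 0, -1):
        h = s * step
        if h > vmax:
            continue
        while ptr < n and vals[order[ptr]] >= h:
            v = order[ptr]
            parent[v] = v
            size[v] = 1
            active[v] = 1
            for e in range(indptr[v], indptr[v + 1]):
                u = indices[e]
                if active[u] == 1:
                    # find roots
                    ra = v
                    while parent[ra] != ra:
                        ra = parent[ra]
                    rb = u
                    while parent[rb] != rb:
                        rb = parent[rb]
                    if ra != rb:
                        if size[ra] < size[rb]:
                            ra, rb = rb, ra
                        parent[rb] = ra
                        size[ra] += size[rb]
            ptr += 1
        hterm = h ** h_exp * step
        for i in range(ptr):
            v = order[i]
            r = v
            while parent[r] != r:
                r = parent[r]
            # path compression
            w = v
            while parent[w] != r:
                nxt = parent[w]
                parent[w] = r
                w = nxt
            out[v] += size[r] ** e_exp * hterm
    return out


def tfce_enhance(zmap, mask, E: float = 0.5, H: float = 2.0,
                 dh: float | None = None, n_steps: int = 100,
                 _adjacency=None) -> np.ndarray:
    """Positive-tail TFCE of a statistic map over a mask.

    ``zmap`` may be a 3-D volume or a vector over mask voxels; the return
    matches the input form.  Only positive values are enhanced; enhance the
    negated map for the negative tail.  ``dh`` defaults to max/``n_steps``
    per map.
    """
    if dh is not None and dh <= 0:
        raise ValueError("dh must be positive")
    mask_data = mask.data if isinstance(mask, VoxelMask) else np.asarray(mask, bool)
    z = np.asarray(zmap, dtype=float)
    as_volume = z.ndim == 3
    vals = z[mask_data] if as_volume else z.copy()
    if vals.shape[0] != int(mask_data.sum()):
        raise ValueError("map does not match mask voxel count")
    vals = np.where(np.isfinite(vals), vals, 0.0)
    indptr, indices = _adjacency if _adjacency is not None else mask_adjacency(mask_data)
    out = _tfce_values(vals, indptr, indices, float(E), float(H),
                       float(dh) if dh is not None else 0.0, int(n_steps))
    if as_volume:
        vol = np.zeros(mask_data.shape)
        vol[mask_data] = out
        return vol
    return out


# ---------------------------------------------------------------------------
# Sign-flip permutation correction
# ---------------------------------------------------------------------------

@dataclass
class GroupStatResult:
    """Group statistics over a mask: t, dof, z and TFCE-corrected z."""

    t: np.ndarray
    dof: np.ndarray
    z: np.ndarray
    corrected_z: np.ndarray
    mask: VoxelMask
    n_perm: int
    seed: int
    exhaustive: bool = False
    threshold: float = Z_THRESHOLD
    pos_mask: np.ndarray = field(default=None, repr=False)
    neg_mask: np.ndarray = field(default=None, repr=False)

    def volume(self, which: str = "corrected_z") -> np.ndarray:
        return self.mask.volume_from_values(getattr(self, which))


def _zmaps_for_perms(x0, n, ss, dofs, signs):
    """Vectorized sign-flipped t -> z maps, (n_perm, n_vox)."""
    means = (signs @ x0) / n
    with np.errstate(invalid="ignore", divide="ignore"):
        var = (ss - n * means ** 2) / (n - 1)
        var = np.where(var <= 0, np.nan, var)
        t = means / np.sqrt(var / n)
    z = np.full_like(t, np.nan)
    good = np.isfinite(t)
    at = np.abs(t[good])
    d = np.broadcast_to(dofs, t.shape)[good]
    z[good] = np.sign(t[good]) * (-ndtri_exp(stats.t.logsf(at, d)))
    return z


def permutation_correct(subject_maps, mask: VoxelMask, n_perm: int = 10000,
                        seed: int = 0, E: float = 0.5, H: float = 2.0,
                        n_steps: int = 100) -> GroupStatResult:
    """TFCE + max-statistic sign-flip permutation FWE correction.

    Builds the null by randomly negating each subject's map (probability
    1/2 per subject and permutation), recomputing the group t -> z -> TFCE
    map, and recording the maximum TFCE over the mask per tail.  Per-voxel
    FWE p = (1 + #{null max >= observed}) / (n_perm + 1); corrected
    z = Phi^-1(1 - p/2) per tail with the observed sign restored.  When the
    subject count allows fewer than ``n_perm`` distinct sign patterns the
    full set is enumerated instead (with a warning).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    x = _stack(subject_maps)
    n_sub, n_vox = x.shape
    if n_vox != mask.n_voxels:
        raise ValueError("subject maps do not match mask voxel count")

    t, dof = group_tmap(x)
    z = t_to_z(t, np.where(np.isfinite(dof), dof, 1.0))
    z = np.where(np.isfinite(t), z, np.nan)

    adjacency = mask_adjacency(mask.data)
    obs_pos = tfce_enhance(z, mask.data, E, H, n_steps=n_steps, _adjacency=adjacency)
    obs_neg = tfce_enhance(-z, mask.data, E, H, n_steps=n_steps, _adjacency=adjacency)

    exhaustive = 2 ** n_sub < n_perm
    if exhaustive:
        warnings.warn(
            f"only 2^{n_sub} distinct sign flips available; enumerating "
            "exhaustively instead of sampling", RuntimeWarning, stacklevel=2)
        grid = np.indices((2,) * n_sub).reshape(n_sub, -1).T
        signs = (1 - 2 * grid).astype(float)
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))
    n_eff = signs.shape[0]

    finite = np.isfinite(x)
    x0 = np.where(finite, x, 0.0)
    n = finite.sum(axis=0).astype(float)
    n = np.where(n >= 3, n, np.nan)
    ss = (x0 ** 2).sum(axis=0)
    dofs = n - 1

    null_max_pos = np.empty(n_eff)
    null_max_neg = np.empty(n_eff)
    block = 256
    for start in range(0, n_eff, block):
        zb = _zmaps_for_perms(x0, n, ss, dofs, signs[start:start + block])
        zb = np.where(np.isfinite(zb), zb, 0.0)
        for i in range(zb.shape[0]):
            p = _tfce_values(zb[i], *adjacency, E, H, 0.0, n_steps)
            m = _tfce_values(-zb[i], *adjacency, E, H, 0.0, n_steps)
            null_max_pos[start + i] = p.max()
            null_max_neg[start + i] = m.max()

    if exhaustive:
        # identity flip is part of the enumerated set; exact p = count / total
        p_pos = _exceedance(null_max_pos, obs_pos, plus_one=False)
        p_neg = _exceedance(null_max_neg, obs_neg, plus_one=False)
    else:
        p_pos = _exceedance(null_max_pos, obs_pos, plus_one=True)
        p_neg = _exceedance(null_max_neg, obs_neg, plus_one=True)

    # per-tail score on the two-sided normal scale, Phi^-1(1 - p/2), so that
    # thresholding at 1.96 corresponds to FWE p < .05 in that tail; p = 1
    # maps to 0, keeping nonsignificant voxels out of the opposite tail
    floor = 1.0 / (n_eff + (0 if exhaustive else 1))
    s_pos = ndtri(1.0 - np.clip(p_pos, floor, 1.0) / 2.0)
    s_neg = ndtri(1.0 - np.clip(p_neg, floor, 1.0) / 2.0)
    corrected = np.where(z >= 0, s_pos, -s_neg)
    corrected = np.where(np.isfinite(z), corrected, np.nan)

    result = GroupStatResult(t, dof, z, corrected, mask, n_eff, seed, exhaustive)
    pos, neg, _ = threshold_map(result)
    result.pos_mask, result.neg_mask = pos, neg
    return result


def _exceedance(null_max, observed, plus_one: bool):
    srt = np.sort(null_max)
    total = len(srt)
    count = total - np.searchsorted(srt, observed, side="left")
    if plus_one:
        return (1.0 + count) / (total + 1.0)
    return count / total


def threshold_map(result: GroupStatResult | None = None, level: float = Z_THRESHOLD,
                  corrected_z=None, uncorrected_z=None, mask: VoxelMask = None):
    """Threshold a corrected z map at +/-``level`` and tabulate peaks.

    Returns (positive 3-D mask, negative 3-D mask, peak table).  Peak voxels
    within each supra-threshold connected region are identified from the
    uncorrected group map.
    """
    if result is not None:
        corrected_z = result.corrected_z
        uncorrected_z = result.z
        mask = result.mask
    corr_vol = mask.volume_from_values(np.asarray(corrected_z, dtype=float))
    unc_vol = mask.volume_from_values(np.asarray(uncorrected_z, dtype=float))
    with np.errstate(invalid="ignore"):
        pos = np.nan_to_num(corr_vol, nan=0.0) > level
        neg = np.nan_to_num(corr_vol, nan=0.0) < -level

    rows = []
    for tail, region in (("positive", pos), ("negative", neg)):
        lab, n_reg = ndimage.label(region, structure=_STRUCT6)
        for r in range(1, n_reg + 1):
            in_r = lab == r
            vals = np.where(in_r, unc_vol, np.nan)
            flat = np.nanargmax(np.abs(vals))
            ijk = np.unravel_index(flat, vals.shape)
            mm = (mask.affine @ np.array([*ijk, 1.0]))[:3]
            rows.append(dict(tail=tail, n_voxels=int(in_r.sum()),
                             x=int(ijk[0]), y=int(ijk[1]), z=int(ijk[2]),
                             x_mm=mm[0], y_mm=mm[1], z_mm=mm[2],
                             corrected_z=float(corr_vol[ijk]),
                             uncorrected_z=float(unc_vol[ijk])))
    peaks = pd.DataFrame(rows, columns=["tail", "n_voxels", "x", "y", "z",
                                        "x_mm", "y_mm", "z_mm", "corrected_z",
                                        "uncorrected_z"])
    return pos, neg, peaks
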