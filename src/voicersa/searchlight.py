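"""Searchlight RSA: nearest-k voxel neighborhoods, partial Spearman
correlation with a nuisance control, and per-center map construction.

Each searchlight is the 100 (by default) nearest in-mask voxels around a
center, by Euclidean distance in voxel units with deterministic
tie-breaking (lexicographic flat voxel index).  Per center, the observed
neural dissimilarity vector over the neighborhood is rank-correlated with a
hypothesis model RDM while controlling for the acoustic RDM (first-order
partial correlation on average-ranked data), and the coefficient is
Fisher-z transformed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .mask import PatternDataset, VoxelMask
from .rdm import RDM, compute_ondm

__all__ = [
    "NeighborhoodTable",
    "SearchlightMap",
    "build_neighborhoods",
    "partial_spearman",
    "fisher_z",
    "searchlight_rsa",
    "mean_dissimilarity_map",
]

_FISHER_CAP = 1.0 - 1e-15


@dataclass
class NeighborhoodTable:
    """Per-center neighborhoods as indices into the mask-voxel ordering."""

    indices: np.ndarray  # (n_centers, k_actual)
    k_requested: int
    truncated: bool = False

    @property
    def n_centers(self) -> int:
        return self.indices.shape[0]

    @property
    def k_actual(self) -> int:
        return self.indices.shape[1]


def build_neighborhoods(mask: VoxelMask, k: int = 100,
                        chunk: int = 512) -> NeighborhoodTable:
    """Nearest-k in-mask voxels around every in-mask center.

    Distances are Euclidean in voxel units; ties are broken by the smaller
    flat (C-order) voxel index, so the result is deterministic and equals an
    exhaustive sort.  The center is always a member of its own neighborhood
    (distance 0).  If the mask holds fewer than ``k`` voxels, all are used
    and the table is flagged as truncated.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    coords = mask.coords().astype(np.int64)
    n = coords.shape[0]
    if n == 0:
        raise ValueError("mask contains no voxels")
    truncated = n < k
    if truncated:
        warnings.warn(
            f"mask holds {n} voxels, fewer than the requested {k}; "
            "using all of them",
            RuntimeWarning,
            stacklevel=2,
        )
    k_eff = min(k, n)
    out = np.empty((n, k_eff), dtype=np.int64)
    tie_break = np.arange(n, dtype=np.int64)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        diff = coords[start:stop, None, :] - coords[None, :, :]
        d2 = (diff * diff).sum(axis=2)
        # squared distances are exact integers: key sorts by (d2, index)
        key = d2 * n + tie_break[None, :]
        out[start:stop] = np.argsort(key, axis=1)[:, :k_eff]
    return NeighborhoodTable(out, k, truncated)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return np.nan
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def partial_spearman(x, y, z) -> float:
    """First-order partial Spearman correlation of x and y controlling z.

    Average ranks handle ties; the closed-form first-order formula
    ``(r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))`` is evaluated on
    the ranks.  Non-finite triples are removed pairwise first.  A constant
    control reduces to the plain Spearman correlation; a control perfectly
    collinear with x or y yields NaN with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y) & np.isfinite(z)
    if ok.sum() < 4:
        raise ValueError("need at least 4 complete (x, y, z) triples")
    x, y, z = x[ok], y[ok], z[ok]
    rx, ry = rankdata(x), rankdata(y)
    r_xy = _pearson(rx, ry)
    if np.ptp(z) == 0:
        return r_xy
    rz = rankdata(z)
    r_xz = _pearson(rx, rz)
    r_yz = _pearson(ry, rz)
    den2 = (1.0 - r_xz ** 2) * (1.0 - r_yz ** 2)
    if not np.isfinite(den2) or den2 <= 1e-24:
        warnings.warn("control variable collinear with x or y; partial "
                      "correlation undefined", RuntimeWarning, stacklevel=2)
        return np.nan
    return float(np.clip((r_xy - r_xz * r_yz) / np.sqrt(den2), -1.0, 1.0))


def fisher_z(r) -> np.ndarray:
    """Fisher z = atanh(r); |r| = 1 is clamped to +/- atanh(1 - 1e-15)."""
    r = np.asarray(r, dtype=float)
    clipped = np.clip(r, -_FISHER_CAP, _FISHER_CAP)
    if np.any(np.abs(r[np.isfinite(r)]) >= 1.0):
        warnings.warn("|r| = 1 clamped before Fisher transform",
                      RuntimeWarning, stacklevel=2)
    out = np.arctanh(clipped)
    out = np.where(np.isfinite(r), out, np.nan)
    return out if out.ndim else float(out)


@dataclass
class SearchlightMap:
    """Per-center scalar map over a mask (NaN where skipped)."""

    values: np.ndarray  # (n_centers,) aligned with mask.coords()
    mask: VoxelMask

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.mask.n_voxels,):
            raise ValueError("values must have one entry per mask voxel")
        self.values = v

    def volume(self) -> np.ndarray:
        return self.mask.volume_from_values(self.values)

    def to_nifti(self, path) -> None:
        import nibabel as nib

        nib.save(nib.Nifti1Image(self.volume(), self.mask.affine), str(path))

    @classmethod
    def from_nifti(cls, path, mask: VoxelMask) -> "SearchlightMap":
        import nibabel as nib

        vol = np.asarray(nib.load(str(path)).dataobj, dtype=float)
        return cls(vol[mask.data], mask)


def _batched_ondm_vectors(pats: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """ONDM vectors (1 - r, upper triangle) for a batch of neighborhoods.

    ``pats`` is (n_items, n_voxels), ``idx`` (n_centers, k); returns
    (n_centers, n_pairs).  Constant rows yield NaN cells.
    """
    sub = np.swapaxes(pats[:, idx], 0, 1)  # (C, n_items, k)
    subc = sub - sub.mean(axis=2, keepdims=True)
    norms = np.linalg.norm(subc, axis=2)
    safe = np.where(norms == 0, 1.0, norms)
    u = subc / safe[:, :, None]
    corr = np.clip(u @ np.swapaxes(u, 1, 2), -1.0, 1.0)
    bad = norms == 0
    if bad.any():
        corr[np.broadcast_to(bad[:, :, None], corr.shape)] = np.nan
        corr[np.broadcast_to(bad[:, None, :], corr.shape)] = np.nan
    i, j = np.triu_indices(pats.shape[0], k=1)
    return 1.0 - corr[:, i, j]


def _check_alignment(labels, *rdms):
    for r in rdms:
        if r.labels != labels:
            raise ValueError("RDM item labels are not aligned with the patterns")


def searchlight_rsa(dataset: PatternDataset, nbhd: NeighborhoodTable,
                    model: RDM, acoustic: RDM, min_cells: int = 4) -> SearchlightMap:
    """Fisher-z partial Spearman map: ONDM vs model, controlling acoustic.

    Per center: the ONDM over the neighborhood voxels is vectorized and
    partially rank-correlated with the model over the cells where the model
    is coded (non-NaN), controlling the acoustic RDM; the result is
    Fisher-z transformed.  Centers with fewer than ``min_cells`` usable
    cells, or with undefined correlations, are NaN.
    """
    mask = dataset.mask
    if mask is None:
        raise ValueError("dataset must carry a mask")
    _check_alignment(dataset.labels, model, acoustic)

    model_vec = model.vector()
    acoustic_vec = acoustic.vector()
    base = np.isfinite(model_vec) & np.isfinite(acoustic_vec)
    out = np.full(mask.n_voxels, np.nan)
    if base.sum() < min_cells:
        warnings.warn("model RDM has fewer usable cells than min_cells; "
                      "map is all NaN", RuntimeWarning, stacklevel=2)
        return SearchlightMap(out, mask)

    # precompute control/model ranks on the base cell set (fast path)
    y_r = rankdata(model_vec[base])
    z_r = rankdata(acoustic_vec[base])
    yc = y_r - y_r.mean()
    zc = z_r - z_r.mean()
    ny, nz = np.linalg.norm(yc), np.linalg.norm(zc)
    r_yz = float(np.clip(yc @ zc / (ny * nz), -1, 1)) if ny and nz else np.nan

    pats = dataset.patterns
    if not np.isfinite(pats).all() or ny == 0 or nz == 0:
        # general path: pairwise voxel exclusion / degenerate rank vectors
        for c in range(nbhd.n_centers):
            vec = compute_ondm(pats[:, nbhd.indices[c]], dataset.labels).vector()
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    rho = partial_spearman(vec[base], model_vec[base],
                                           acoustic_vec[base])
            except ValueError:
                rho = np.nan
            out[c] = np.arctanh(np.clip(rho, -_FISHER_CAP, _FISHER_CAP)) \
                if np.isfinite(rho) else np.nan
        return SearchlightMap(out, mask)

    den_yz = 1.0 - r_yz ** 2 if np.isfinite(r_yz) else np.nan
    chunk = 256
    for start in range(0, nbhd.n_centers, chunk):
        idx = nbhd.indices[start:start + chunk]
        xv = _batched_ondm_vectors(pats, idx)[:, base]
        rho = np.full(xv.shape[0], np.nan)
        good = np.isfinite(xv).all(axis=1)
        if good.any():
            xr = rankdata(xv[good], axis=1)
            xc = xr - xr.mean(axis=1, keepdims=True)
            nx = np.linalg.norm(xc, axis=1)
            nx_safe = np.where(nx == 0, 1.0, nx)
            with np.errstate(invalid="ignore", divide="ignore"):
                r_xy = np.clip(xc @ yc / (nx_safe * ny), -1, 1)
                r_xz = np.clip(xc @ zc / (nx_safe * nz), -1, 1)
                den2 = (1.0 - r_xz ** 2) * den_yz
                val = np.clip((r_xy - r_xz * r_yz) / np.sqrt(den2), -1, 1)
            val = np.where((nx > 0) & (den2 > 1e-24), val, np.nan)
            rho[good] = val
        if (~good).any():
            # constant patterns in some neighborhoods: per-center fallback
            for c in np.flatnonzero(~good):
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", RuntimeWarning)
                        rho[c] = partial_spearman(xv[c], model_vec[base],
                                                  acoustic_vec[base])
                except ValueError:
                    rho[c] = np.nan
        out[start:start + chunk] = np.where(
            np.isfinite(rho),
            np.arctanh(np.clip(rho, -_FISHER_CAP, _FISHER_CAP)),
            np.nan,
        )
    return SearchlightMap(out, mask)


def mean_dissimilarity_map(dataset: PatternDataset, nbhd: NeighborhoodTable,
                           pair_class=None) -> SearchlightMap:
    """Per-center mean of ONDM cells in a pair class (e.g. within-Familiar).

    ``pair_class`` is an unordered identity pair like ("Familiar",
    "Familiar"); None selects all cells (grand-mean dissimilarity map).
    """
    mask = dataset.mask
    if mask is None:
        raise ValueError("dataset must carry a mask")
    n = dataset.n_items
    i, j = np.triu_indices(n, k=1)
    classes = [tuple(sorted((dataset.labels[a][0], dataset.labels[b][0])))
               for a, b in zip(i, j)]
    if pair_class is None:
        sel = np.ones(len(classes), dtype=bool)
    else:
        want = tuple(sorted(pair_class))
        sel = np.array([c == want for c in classes])
    if not sel.any():
        raise ValueError(f"pair class {pair_class!r} selects no cells")

    pats = dataset.patterns
    out = np.full(mask.n_voxels, np.nan)
    if np.isfinite(pats).all():
        chunk = 256
        for start in range(0, nbhd.n_centers, chunk):
            vec = _batched_ondm_vectors(pats, nbhd.indices[start:start + chunk])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                out[start:start + chunk] = np.nanmean(vec[:, sel], axis=1)
    else:
        for c in range(nbhd.n_centers):
            vec = compute_ondm(pats[:, nbhd.indices[c]], dataset.labels).vector()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                out[c] = np.nanmean(vec[sel])
    return SearchlightMap(out, mask)
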