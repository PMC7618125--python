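"""Representational dissimilarity matrices (RDMs).

Observed neural dissimilarity matrices (ONDMs) are computed as 1 minus the
Pearson correlation between item response patterns, with no mean-centering of
the patterns across items (only Pearson's own per-vector centering).
Hypothesis model RDMs assign predicted dissimilarity codes to item-pair
classes (e.g. Familiar-Lab = 1, Familiar-Familiar = 0) and exclude all other
pairs as NaN.

A single canonical vectorization — row-major upper triangle with items sorted
by (identity in the order Familiar, Lab, New; then clip index) — is used
throughout the package so observed, model and acoustic vectors always align.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FAMILIAR",
    "LAB",
    "NEW",
    "IDENTITY_ORDER",
    "RDM",
    "make_item_labels",
    "compute_ondm",
    "vectorize",
    "identity_model",
    "familiarity_model",
    "model_rdm",
    "pair_class_counts",
    "IDENTITY_MODEL_VARIANTS",
    "FAMILIARITY_MODEL_VARIANTS",
]

FAMILIAR = "Familiar"
LAB = "Lab"
NEW = "New"

#: Canonical identity ordering used for item sorting everywhere.
IDENTITY_ORDER = (FAMILIAR, LAB, NEW)


def make_item_labels(n_clips: int = 8, identities=IDENTITY_ORDER):
    """Item labels in canonical order: identity-major, clip-minor.

    The default (3 identities x 8 clips) yields the 24-item design.
    """
    return [(ident, clip) for ident in identities for clip in range(n_clips)]


def _check_labels(labels):
    labels = [(str(i), int(c)) for i, c in labels]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate item labels")
    return labels


@dataclass
class RDM:
    """Symmetric item-pair dissimilarity structure.

    ``values`` is a square symmetric matrix; the diagonal is excluded (stored
    as NaN).  Model RDMs may carry NaN in off-diagonal cells for excluded
    pair classes; observed RDMs are expected to be finite and in [0, 2].
    """

    values: np.ndarray
    labels: list = field(default_factory=list)

    def __post_init__(self):
        v = np.array(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("RDM values must be a square matrix")
        if not np.allclose(np.nan_to_num(v), np.nan_to_num(v.T), atol=1e-12):
            raise ValueError("RDM values must be symmetric")
        np.fill_diagonal(v, np.nan)
        self.values = v
        self.labels = _check_labels(self.labels)
        if len(self.labels) != v.shape[0]:
            raise ValueError("label count does not match matrix size")

    @property
    def n_items(self) -> int:
        return self.values.shape[0]

    # -- canonical vector form ------------------------------------------------
    def vector(self) -> np.ndarray:
        """Row-major upper triangle, length n(n-1)/2."""
        i, j = np.triu_indices(self.n_items, k=1)
        return self.values[i, j]

    @classmethod
    def from_vector(cls, vec, labels) -> "RDM":
        labels = _check_labels(labels)
        n = len(labels)
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (n * (n - 1) // 2,):
            raise ValueError("vector length does not match n(n-1)/2")
        m = np.full((n, n), np.nan)
        i, j = np.triu_indices(n, k=1)
        m[i, j] = vec
        m[j, i] = vec
        return cls(m, labels)

    def pair_classes(self) -> list:
        """Unordered identity pair per upper-triangle cell, aligned with vector()."""
        i, j = np.triu_indices(self.n_items, k=1)
        return [
            tuple(sorted((self.labels[a][0], self.labels[b][0])))
            for a, b in zip(i, j)
        ]

    # -- I/O ------------------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        names = [f"{i}_{c}" for i, c in self.labels]
        return pd.DataFrame(self.values, index=names, columns=names)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "RDM":
        df = pd.read_csv(path, index_col=0)
        labels = []
        for name in df.index:
            ident, clip = str(name).rsplit("_", 1)
            labels.append((ident, int(clip)))
        return cls(df.to_numpy(dtype=float), labels)

    def to_json(self, path) -> None:
        payload = {
            "labels": [[i, c] for i, c in self.labels],
            "vector": [None if not np.isfinite(x) else float(x) for x in self.vector()],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "RDM":
        with open(path) as fh:
            payload = json.load(fh)
        vec = np.array(
            [np.nan if x is None else x for x in payload["vector"]], dtype=float
        )
        labels = [(i, int(c)) for i, c in payload["labels"]]
        return cls.from_vector(vec, labels)


def vectorize(rdm: RDM) -> np.ndarray:
    """Canonical vector of the n(n-1)/2 unique off-diagonal cells."""
    return rdm.vector()


# ---------------------------------------------------------------------------
# Observed neural dissimilarity
# ---------------------------------------------------------------------------

def compute_ondm(patterns: np.ndarray, labels) -> RDM:
    """Observed neural dissimilarity matrix: 1 - Pearson r between patterns.

    Parameters
    ----------
    patterns
        (n_items, n_voxels) response patterns (e.g. T statistics).  Voxels
        that are non-finite in either member of a pair are dropped pairwise
        before the correlation.  No mean-centering across items is applied.
    labels
        Item labels aligned with pattern rows.

    Constant patterns (zero variance on the shared voxels) yield an undefined
    correlation; the affected cells are reported as NaN with a warning.
    """
    patterns = np.asarray(patterns, dtype=float)
    if patterns.ndim != 2:
        raise ValueError("patterns must be 2-D (items x voxels)")
    n = patterns.shape[0]
    labels = _check_labels(labels)
    if len(labels) != n:
        raise ValueError("label count does not match pattern rows")

    finite = np.isfinite(patterns)
    if finite.all():
        d = 1.0 - _rowwise_pearson(patterns)
    else:
        d = np.full((n, n), np.nan)
        np.fill_diagonal(d, 0.0)
        for a in range(n):
            for b in range(a + 1, n):
                shared = finite[a] & finite[b]
                if shared.sum() < 2:
                    continue
                x, y = patterns[a, shared], patterns[b, shared]
                sx, sy = x.std(), y.std()
                if sx == 0 or sy == 0:
                    continue
                r = float(np.corrcoef(x, y)[0, 1])
                d[a, b] = d[b, a] = 1.0 - r
    off = ~np.eye(n, dtype=bool)
    if not np.isfinite(d[off]).all():
        warnings.warn(
            "undefined correlation for one or more item pairs "
            "(constant pattern or too few shared voxels); cells set to NaN",
            RuntimeWarning,
            stacklevel=2,
        )
    return RDM(d, labels)


def _rowwise_pearson(x: np.ndarray) -> np.ndarray:
    """Pearson correlation between rows; NaN rows where sd == 0."""
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(xc, axis=1)
    bad = norms == 0
    safe = np.where(bad, 1.0, norms)
    u = xc / safe[:, None]
    c = u @ u.T
    c = np.clip(c, -1.0, 1.0)
    c[bad, :] = np.nan
    c[:, bad] = np.nan
    np.fill_diagonal(c, 1.0)
    return c


# ---------------------------------------------------------------------------
# Hypothesis model RDMs
# ---------------------------------------------------------------------------

#: Between > within identity-contrast codings: between-speaker pairs dissimilar
#: (1), within-speaker pairs similar (0); all other pair classes NaN.
IDENTITY_MODEL_VARIANTS = {
    "all_voices": {
        (FAMILIAR, LAB): 1.0,
        (FAMILIAR, NEW): 1.0,
        (LAB, NEW): 1.0,
        (FAMILIAR, FAMILIAR): 0.0,
        (LAB, LAB): 0.0,
        (NEW, NEW): 0.0,
    },
    "familiar_lab_vs_familiar": {(FAMILIAR, LAB): 1.0, (FAMILIAR, FAMILIAR): 0.0},
    "familiar_lab_vs_lab": {(FAMILIAR, LAB): 1.0, (LAB, LAB): 0.0},
    "familiar_new_vs_familiar": {(FAMILIAR, NEW): 1.0, (FAMILIAR, FAMILIAR): 0.0},
    "familiar_new_vs_new": {(FAMILIAR, NEW): 1.0, (NEW, NEW): 0.0},
    "lab_new_vs_lab": {(LAB, NEW): 1.0, (LAB, LAB): 0.0},
    "lab_new_vs_new": {(LAB, NEW): 1.0, (NEW, NEW): 0.0},
}

#: Familiarity-graded within-speaker codings: within-speaker dissimilarity
#: increases with decreasing familiarity; between-speaker pairs NaN.
FAMILIARITY_MODEL_VARIANTS = {
    "all_voices": {
        (FAMILIAR, FAMILIAR): 1.0,
        (LAB, LAB): 2.0,
        (NEW, NEW): 3.0,
    },
    "familiar_vs_lab": {(FAMILIAR, FAMILIAR): 0.0, (LAB, LAB): 1.0},
    "familiar_vs_new": {(FAMILIAR, FAMILIAR): 0.0, (NEW, NEW): 1.0},
    "lab_vs_new": {(LAB, LAB): 0.0, (NEW, NEW): 1.0},
}


def model_rdm(labels, coding: dict) -> RDM:
    """Build a model RDM from a pair-class -> code mapping.

    Every identity referenced by ``coding`` must occur at least twice among
    ``labels`` for within-speaker classes (so the class has at least one
    pair); unreferenced pair classes are NaN.
    """
    labels = _check_labels(labels)
    present = {}
    for ident, _ in labels:
        present[ident] = present.get(ident, 0) + 1
    for a, b in coding:
        if a not in present or b not in present:
            raise ValueError(
                f"model references identity pair ({a}, {b}) but labels only "
                f"contain identities {sorted(present)}"
            )
        if a == b and present[a] < 2:
            raise ValueError(
                f"within-speaker class ({a}, {b}) needs at least 2 items of "
                f"identity {a!r}"
            )
    coding = {tuple(sorted(k)): float(v) for k, v in coding.items()}
    n = len(labels)
    m = np.full((n, n), np.nan)
    for a in range(n):
        for b in range(a + 1, n):
            key = tuple(sorted((labels[a][0], labels[b][0])))
            if key in coding:
                m[a, b] = m[b, a] = coding[key]
    return RDM(m, labels)


def identity_model(labels, variant: str) -> RDM:
    """Between-speaker > within-speaker contrast model (7 codings)."""
    try:
        coding = IDENTITY_MODEL_VARIANTS[variant]
    except KeyError:
        raise ValueError(
            f"unknown identity model variant {variant!r}; "
            f"choose from {sorted(IDENTITY_MODEL_VARIANTS)}"
        ) from None
    return model_rdm(labels, coding)


def familiarity_model(labels, variant: str) -> RDM:
    """Within-speaker familiarity-graded model (4 codings)."""
    try:
        coding = FAMILIARITY_MODEL_VARIANTS[variant]
    except KeyError:
        raise ValueError(
            f"unknown familiarity model variant {variant!r}; "
            f"choose from {sorted(FAMILIARITY_MODEL_VARIANTS)}"
        ) from None
    return model_rdm(labels, coding)


def pair_class_counts(labels) -> dict:
    """Number of unique pairs per unordered identity pair class."""
    labels = _check_labels(labels)
    counts: dict = {}
    n = len(labels)
    for a in range(n):
        for b in range(a + 1, n):
            key = tuple(sorted((labels[a][0], labels[b][0])))
            counts[key] = counts.get(key, 0) + 1
    return counts
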