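"""Event-related GLM: canonical HRF, design matrices, item T-pattern maps.

Events are modelled as instantaneous impulses convolved with the canonical
double-gamma haemodynamic response function and sampled at scan times.  Item
T patterns are estimated by ordinary least squares on concatenated runs (one
regressor set and intercept per run) with the item-versus-null-baseline
contrast averaged across runs as a fixed-effects contrast.

No prewhitening or drift regressors are fitted: the synthetic noise model is
white by construction.  ``extra_regressors`` on :func:`build_design_matrix`
is the hook for cosine drift or motion columns when reusing the module on
real data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.stats import gamma

__all__ = [
    "canonical_hrf",
    "build_design_matrix",
    "fit_item_tmaps",
    "DesignMatrix",
    "TPatternMap",
    "NULL_REGRESSOR",
    "RESPONSE_CORRECT",
    "RESPONSE_INCORRECT",
    "INTERCEPT",
]

NULL_REGRESSOR = "null"
RESPONSE_CORRECT = "response_correct"
RESPONSE_INCORRECT = "response_incorrect"
INTERCEPT = "intercept"

# Canonical double-gamma parameters: peak delay 6 s, undershoot delay 16 s,
# dispersions 1 s, peak:undershoot ratio 6, kernel length 32 s.
_PEAK_DELAY = 6.0
_UNDERSHOOT_DELAY = 16.0
_PEAK_DISP = 1.0
_UNDERSHOOT_DISP = 1.0
_RATIO = 6.0
_LENGTH_S = 32.0


def canonical_hrf(dt_s: float, length_s: float = _LENGTH_S) -> np.ndarray:
    """Canonical double-gamma HRF sampled every ``dt_s`` s, unit peak."""
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    t = np.arange(0.0, length_s, dt_s)
    h = gamma.pdf(t, _PEAK_DELAY / _PEAK_DISP, scale=_PEAK_DISP)
    h = h - gamma.pdf(t, _UNDERSHOOT_DELAY / _UNDERSHOOT_DISP, scale=_UNDERSHOOT_DISP) / _RATIO
    return h / h.max()


@dataclass
class DesignMatrix:
    """Time x regressor matrix with column names.

    ``item_columns`` maps item label -> column index; the null, response and
    intercept columns are named by the module constants.
    """

    matrix: np.ndarray
    names: list
    item_columns: dict

    @property
    def n_scans(self) -> int:
        return self.matrix.shape[0]

    def column(self, name) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]


def _regressor(onsets, n_scans, tr_s, hrf_fine, oversample):
    """Unit impulses at ``onsets`` convolved with the HRF, sampled at scans."""
    n_fine = n_scans * oversample
    fine = np.zeros(n_fine)
    dt = tr_s / oversample
    for t in onsets:
        idx = int(round(t / dt))
        if not (0 <= idx < n_fine):
            raise ValueError(f"event at t={t:.3f}s falls outside the scan window")
        fine[idx] += 1.0
    conv = np.convolve(fine, hrf_fine)[:n_fine]
    return conv[::oversample]


def build_design_matrix(sequence, n_scans: int, tr_s: float, oversample: int = 16,
                        extra_regressors: dict | None = None) -> DesignMatrix:
    """Design matrix for one run from a trial sequence.

    Includes one regressor per unique experimental item, a single null-event
    regressor, correct/incorrect response regressors (timeout trials placed
    at response-screen time plus the run's mean response time, in the
    incorrect regressor) and an intercept.  Regressors with no events are
    omitted.
    """
    if n_scans < 1 or tr_s <= 0:
        raise ValueError("n_scans must be >= 1 and tr_s positive")
    hrf_fine = canonical_hrf(tr_s / oversample)
    frame = sequence.frame if hasattr(sequence, "frame") else sequence

    cols, names, item_columns = [], [], {}

    exp = frame[frame["kind"] == "experimental"]
    for (ident, clip), grp in exp.groupby(["identity", "clip"], sort=True):
        key = (str(ident), int(clip))
        item_columns[key] = len(cols)
        names.append(f"item_{ident}_{clip}")
        cols.append(_regressor(grp["onset_s"].to_numpy(), n_scans, tr_s,
                               hrf_fine, oversample))

    nulls = frame[frame["kind"] == "null"]
    if len(nulls):
        names.append(NULL_REGRESSOR)
        cols.append(_regressor(nulls["onset_s"].to_numpy(), n_scans, tr_s,
                               hrf_fine, oversample))

    if "response_event_s" in frame.columns and len(exp):
        resp = exp["response_event_s"].to_numpy(dtype=float)
        correct = exp["correct"].to_numpy(dtype=bool) if "correct" in exp else \
            np.ones(len(exp), dtype=bool)
        timeout = exp["timeout"].to_numpy(dtype=bool) if "timeout" in exp else \
            np.zeros(len(exp), dtype=bool)
        ok = np.isfinite(resp)
        for flag, name in (
            (correct & ~timeout & ok, RESPONSE_CORRECT),
            ((~correct | timeout) & ok, RESPONSE_INCORRECT),
        ):
            if flag.any():
                names.append(name)
                cols.append(_regressor(resp[flag], n_scans, tr_s, hrf_fine,
                                       oversample))

    for name, col in (extra_regressors or {}).items():
        col = np.asarray(col, dtype=float)
        if col.shape != (n_scans,):
            raise ValueError(f"extra regressor {name!r} has wrong length")
        names.append(name)
        cols.append(col)

    names.append(INTERCEPT)
    cols.append(np.ones(n_scans))
    return DesignMatrix(np.column_stack(cols), names, item_columns)


@dataclass
class TPatternMap:
    """Items x voxels T statistics (item vs null baseline, run-averaged).

    ``contrast`` holds the raw run-averaged contrast estimates; ``t`` is
    contrast / standard error.  With exactly zero noise the standard error
    vanishes and T is undefined, so exact-recovery checks belong on
    ``contrast``.
    """

    t: np.ndarray
    labels: list
    dof: int
    contrast: np.ndarray | None = None

    @property
    def n_items(self) -> int:
        return self.t.shape[0]

    def dataset(self, mask=None):
        from .mask import PatternDataset

        return PatternDataset(self.t, self.labels, mask)


def _collinear_columns(x, names, tol=1e-8):
    """Names of columns implicated in rank deficiency (pivoted QR)."""
    _, r, piv = linalg.qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    bad = piv[diag < tol * diag.max()]
    return [names[i] for i in sorted(bad)]


def fit_item_tmaps(runs, designs) -> TPatternMap:
    """OLS fit of concatenated runs; item-vs-null-baseline T map.

    Parameters
    ----------
    runs
        List of (n_scans, n_voxels) BOLD matrices.
    designs
        Matching list of :class:`DesignMatrix`.  Regressors are kept separate
        per run (block-diagonal stacking, per-run intercepts).  The contrast
        for each item weights that item's regressor 1/n_runs and the null
        regressor -1/n_runs in every run where both exist, implementing the
        item-versus-null-baseline estimate averaged across runs.
    """
    if len(runs) != len(designs) or not runs:
        raise ValueError("runs and designs must be non-empty and aligned")
    n_vox = runs[0].shape[1]
    items = sorted(designs[0].item_columns)
    for d in designs:
        if sorted(d.item_columns) != items:
            raise ValueError("all runs must model the same items")

    blocks, names = [], []
    offsets = []
    for r, (y, d) in enumerate(zip(runs, designs)):
        if y.shape != (d.n_scans, n_vox):
            raise ValueError("BOLD run shape does not match its design")
        offsets.append(sum(b.shape[1] for b in blocks))
        blocks.append(d.matrix)
        names.extend(f"run{r}_{n}" for n in d.names)
    x = linalg.block_diag(*blocks)
    y = np.vstack(runs)

    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        bad = _collinear_columns(x, names)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")

    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ (x.T @ y)
    resid = y - x @ beta
    dof = x.shape[0] - rank
    sigma2 = (resid ** 2).sum(axis=0) / dof

    n_runs = len(runs)
    tmap = np.empty((len(items), n_vox))
    cmap = np.empty((len(items), n_vox))
    for k, item in enumerate(items):
        c = np.zeros(x.shape[1])
        for r, d in enumerate(designs):
            c[offsets[r] + d.item_columns[item]] = 1.0 / n_runs
            if NULL_REGRESSOR in d.names:
                c[offsets[r] + d.names.index(NULL_REGRESSOR)] = -1.0 / n_runs
        con = c @ beta
        se = np.sqrt(sigma2 * (c @ xtx_inv @ c))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = con / se
        if (se == 0).any():
            warnings.warn("zero residual variance at some voxels; T undefined there",
                          RuntimeWarning, stacklevel=2)
        tmap[k] = t
        cmap[k] = con
    return TPatternMap(tmap, list(items), dof, cmap)
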