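"""Synthetic study generator: trial sequences, planted-geometry voxel
patterns, event-related BOLD runs, audio clips and forced-choice behavior.

Every generator takes explicit parameters and an integer seed and is fully
deterministic.  Defaults mirror the study conditions: 3 voice identities
(Familiar, Lab, New) x 8 clips x 3 repetitions plus 24 null trials per run,
4 runs, TR 1 s, 2-3 s stimuli with jittered onsets.

The planted representational geometry specifies target 1-Pearson
dissimilarities between item patterns; patterns are drawn from a zero-mean
Gaussian process whose cross-pattern correlation matrix equals 1 minus the
target dissimilarities (eigenvalue-clipped to the nearest positive
semidefinite matrix when needed), so the whole analysis pipeline can be
verified by parameter recovery.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import glm
from .mask import PatternDataset, VoxelMask
from .rdm import IDENTITY_ORDER, RDM, make_item_labels
from .acoustics import acoustic_rdm, LtasVector

__all__ = [
    "StudyDesign",
    "TrialSequence",
    "make_trial_sequence",
    "PlantedGeometry",
    "plant_patterns",
    "simulate_bold_run",
    "run_length_scans",
    "ClipRecipe",
    "simulate_audio_clips",
    "write_wav",
    "simulate_behavior",
    "MaskSpec",
    "GroupSimulation",
    "simulate_group",
]


def _identity_names(n: int):
    if n <= len(IDENTITY_ORDER):
        return list(IDENTITY_ORDER[:n])
    return list(IDENTITY_ORDER) + [f"Voice{i + 1}" for i in range(len(IDENTITY_ORDER), n)]


@dataclass
class StudyDesign:
    """Trial-structure parameters of one scanning run."""

    n_identities: int = 3
    n_clips_per_identity: int = 8
    n_reps_per_clip: int = 3
    n_null: int = 24
    tr_s: float = 1.0
    stim_dur_range_s: tuple = (2.0, 3.0)
    onset_jitter_mean_s: float = 0.375
    onset_jitter_sd_s: float = 0.125
    pre_response_fixation_s: float = 0.5
    response_window_s: float = 2.0
    fixation_range_s: tuple = (0.25, 1.0)
    null_mean_dur_s: float = 5.0
    n_runs: int = 4

    def __post_init__(self):
        for name in ("n_identities", "n_clips_per_identity", "n_reps_per_clip",
                     "n_runs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_null < 0:
            raise ValueError("n_null must be >= 0")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        for name in ("stim_dur_range_s", "fixation_range_s"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must have lower <= upper")

    @property
    def identities(self):
        return _identity_names(self.n_identities)

    @property
    def n_items(self) -> int:
        return self.n_identities * self.n_clips_per_identity

    @property
    def n_experimental(self) -> int:
        return self.n_items * self.n_reps_per_clip

    @property
    def n_trials(self) -> int:
        return self.n_experimental + self.n_null

    def item_labels(self):
        return make_item_labels(self.n_clips_per_identity, self.identities)


@dataclass
class TrialSequence:
    """Ordered trial records for one run (DataFrame-backed).

    Columns: ``kind`` (experimental|null), ``identity``, ``clip``,
    ``onset_s``, ``duration_s``, ``response_prompt_s``, ``response_event_s``,
    ``response_identity``, ``correct``, ``timeout``, ``run``.
    """

    frame: pd.DataFrame

    def __post_init__(self):
        onsets = self.frame["onset_s"].to_numpy()
        if not (np.diff(onsets) > 0).all():
            raise ValueError("trial onsets must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return len(self.frame)

    @property
    def n_experimental(self) -> int:
        return int((self.frame["kind"] == "experimental").sum())

    @property
    def n_null(self) -> int:
        return int((self.frame["kind"] == "null").sum())

    def items(self):
        exp = self.frame[self.frame["kind"] == "experimental"]
        return sorted({(str(i), int(c)) for i, c in zip(exp["identity"], exp["clip"])})

    @property
    def end_s(self) -> float:
        return float(self.frame["end_s"].iloc[-1])

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrialSequence":
        return cls(pd.read_csv(path))


def _pseudorandom_order(design: StudyDesign, rng) -> list:
    """Permutation of experimental items + nulls with no identical
    experimental item on adjacent trials."""
    trials = [("experimental", ident, clip)
              for ident, clip in design.item_labels()
              for _ in range(design.n_reps_per_clip)]
    trials += [("null", None, None)] * design.n_null

    def ok(seq):
        for a, b in zip(seq, seq[1:]):
            if a[0] == b[0] == "experimental" and a[1:] == b[1:]:
                return False
        return True

    order = list(trials)
    for _ in range(1000):
        rng.shuffle(order)
        if ok(order):
            return order
    # deterministic repair: swap offending trials forward
    for i in range(1, len(order)):
        if order[i] == order[i - 1] and order[i][0] == "experimental":
            for j in range(i + 1, len(order)):
                if order[j] != order[i - 1] and (j == len(order) - 1
                                                 or order[j] != order[i + 1]):
                    order[i], order[j] = order[j], order[i]
                    break
    if not ok(order):
        raise RuntimeError("could not build a constrained pseudorandom order")
    return order


def _truncnorm_nonneg(rng, mean, sd):
    while True:
        x = rng.normal(mean, sd)
        if x >= 0:
            return x


def make_trial_sequence(design: StudyDesign, run_index: int = 0, seed: int = 0,
                        p_correct: float = 0.9, p_timeout: float = 0.02) -> TrialSequence:
    """Pseudorandomized trial sequence with jittered timing for one run.

    Each experimental item appears exactly ``n_reps_per_clip`` times and no
    item directly repeats.  Simulated responses (for the GLM response
    regressors and the behavior module) are correct with ``p_correct``; a
    timeout occurs with ``p_timeout``, in which case the response event is
    placed at response-screen onset plus the run's mean response time.
    """
    design.__post_init__()  # re-validate in case fields were mutated
    rng = np.random.default_rng([int(seed), int(run_index)])
    order = _pseudorandom_order(design, rng)

    identities = design.identities
    rows = []
    t = 0.0
    for kind, ident, clip in order:
        if kind == "null":
            dur = rng.uniform(0.8 * design.null_mean_dur_s, 1.2 * design.null_mean_dur_s)
            rows.append(dict(kind="null", identity=None, clip=-1, onset_s=t,
                             duration_s=dur, response_prompt_s=np.nan,
                             response_event_s=np.nan, response_identity=None,
                             correct=False, timeout=False, end_s=t + dur))
            t += dur
            continue
        jitter = _truncnorm_nonneg(rng, design.onset_jitter_mean_s,
                                   design.onset_jitter_sd_s)
        onset = t + jitter
        dur = rng.uniform(*design.stim_dur_range_s)
        prompt = onset + dur + design.pre_response_fixation_s
        timeout = rng.random() < p_timeout
        if timeout:
            rt = np.nan
            resp_ident, correct = None, False
        else:
            rt = rng.uniform(0.3, design.response_window_s)
            correct = rng.random() < p_correct
            if correct or len(identities) == 1:
                resp_ident = ident
            else:
                others = [i for i in identities if i != ident]
                resp_ident = others[rng.integers(len(others))]
        resp_event = prompt + rt if np.isfinite(rt) else np.nan
        end = prompt + design.response_window_s + rng.uniform(*design.fixation_range_s)
        rows.append(dict(kind="experimental", identity=ident, clip=int(clip),
                         onset_s=onset, duration_s=dur, response_prompt_s=prompt,
                         response_event_s=resp_event, response_identity=resp_ident,
                         correct=bool(correct), timeout=bool(timeout), end_s=end))
        t = end

    frame = pd.DataFrame(rows)
    frame["run"] = int(run_index)
    # timeout response events: response-screen time + mean RT over responses
    exp = frame["kind"] == "experimental"
    responded = exp & frame["response_event_s"].notna()
    if responded.any():
        mean_rt = float((frame.loc[responded, "response_event_s"]
                         - frame.loc[responded, "response_prompt_s"]).mean())
    else:
        mean_rt = design.response_window_s / 2
    missing = exp & frame["response_event_s"].isna()
    frame.loc[missing, "response_event_s"] = (
        frame.loc[missing, "response_prompt_s"] + mean_rt
    )
    return TrialSequence(frame)


# ---------------------------------------------------------------------------
# Planted representational geometry
# ---------------------------------------------------------------------------

@dataclass
class PlantedGeometry:
    """Target 1-Pearson dissimilarities between item patterns.

    ``within`` maps identity -> within-speaker target; ``between`` is either
    a scalar applied to every identity pair or a mapping with sorted
    identity-pair tuples as keys.  All targets must lie in [0, 2].
    """

    within: dict = field(default_factory=lambda: {i: 0.5 for i in IDENTITY_ORDER})
    between: object = 1.0
    n_signal_voxels: int = 5000
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.n_signal_voxels < 1:
            raise ValueError("n_signal_voxels must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for v in list(self.within.values()) + (
            [self.between] if np.isscalar(self.between)
            else list(self.between.values())
        ):
            if not 0.0 <= float(v) <= 2.0:
                raise ValueError("dissimilarity targets must lie in [0, 2]")

    @classmethod
    def null(cls, identities=IDENTITY_ORDER, n_signal_voxels=5000, noise_sd=0.0):
        """Pure-noise geometry: every pairwise target 1 (independent patterns)."""
        return cls({i: 1.0 for i in identities}, 1.0, n_signal_voxels, noise_sd)

    def target(self, ident_a: str, ident_b: str) -> float:
        if ident_a == ident_b:
            return float(self.within[ident_a])
        if np.isscalar(self.between):
            return float(self.between)
        return float(self.between[tuple(sorted((ident_a, ident_b)))])

    def target_matrix(self, labels) -> np.ndarray:
        n = len(labels)
        d = np.zeros((n, n))
        for a in range(n):
            for b in range(a + 1, n):
                d[a, b] = d[b, a] = self.target(labels[a][0], labels[b][0])
        return d


def _nearest_correlation(c: np.ndarray, clip: float = 1e-8,
                         tol: float = 0.1) -> np.ndarray:
    """PSD repair by eigenvalue clipping, rescaled to unit diagonal."""
    w, v = np.linalg.eigh(c)
    if w.min() >= clip:
        return c
    w = np.clip(w, clip, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    if np.abs(fixed - c).max() > tol:
        raise ValueError(
            "target geometry implies a correlation matrix with no positive "
            f"semidefinite repair within tolerance {tol}"
        )
    return fixed


def plant_patterns(geometry: PlantedGeometry, items, seed: int = 0,
                   n_voxels: int | None = None) -> np.ndarray:
    """Sample item patterns whose pairwise 1-r matches the planted targets.

    Patterns are ``A @ G`` with ``A A^T`` equal to the (repaired) target
    correlation matrix and ``G`` i.i.d. standard normal, plus optional
    i.i.d. measurement noise of scale ``geometry.noise_sd``.  The expected
    empirical error shrinks with the number of voxels.
    """
    items = list(items)
    n_vox = int(n_voxels if n_voxels is not None else geometry.n_signal_voxels)
    if n_vox < 1:
        raise ValueError("number of voxels must be >= 1")
    rng = np.random.default_rng(seed) if np.isscalar(seed) else seed
    c = _nearest_correlation(1.0 - geometry.target_matrix(items)
                             + np.diag(np.zeros(len(items))))
    np.fill_diagonal(c, 1.0)
    w, v = np.linalg.eigh(c)
    a = v * np.sqrt(np.clip(w, 0.0, None))
    x = a @ rng.standard_normal((len(items), n_vox))
    if geometry.noise_sd > 0:
        x = x + geometry.noise_sd * rng.standard_normal(x.shape)
    return x


# ---------------------------------------------------------------------------
# BOLD forward model
# ---------------------------------------------------------------------------

def run_length_scans(sequence: TrialSequence, design: StudyDesign,
                     hrf_tail_s: float = 30.0) -> int:
    """Smallest whole number of TRs covering the last event plus HRF tail."""
    frame = sequence.frame
    last = float(np.nanmax(frame[["onset_s", "response_event_s", "end_s"]]
                           .to_numpy(dtype=float)))
    return int(np.ceil((last + hrf_tail_s) / design.tr_s))


def simulate_bold_run(patterns: np.ndarray, sequence: TrialSequence,
                      design: StudyDesign, noise_sd: float = 1.0,
                      seed: int = 0, item_labels=None):
    """Forward-model one BOLD run: design matrix x item patterns + noise.

    ``patterns`` rows must cover all items in the sequence (aligned with
    ``item_labels``, default the design's canonical item list).  Returns
    ``(bold, design_matrix)`` where bold is (n_scans, n_voxels).
    """
    patterns = np.asarray(patterns, dtype=float)
    labels = list(item_labels) if item_labels is not None else design.item_labels()
    if patterns.shape[0] != len(labels):
        raise ValueError("pattern rows do not match item labels")
    missing = set(sequence.items()) - set(labels)
    if missing:
        raise ValueError(f"sequence contains items without patterns: {sorted(missing)}")

    n_scans = run_length_scans(sequence, design)
    dm = glm.build_design_matrix(sequence, n_scans, design.tr_s)
    amp = np.zeros((dm.matrix.shape[1], patterns.shape[1]))
    row = {lab: k for k, lab in enumerate(labels)}
    for item, col in dm.item_columns.items():
        amp[col] = patterns[row[item]]
    bold = dm.matrix @ amp
    if noise_sd > 0:
        rng = np.random.default_rng(seed) if np.isscalar(seed) else seed
        bold = bold + noise_sd * rng.standard_normal(bold.shape)
    return bold, dm


# ---------------------------------------------------------------------------
# Audio clips
# ---------------------------------------------------------------------------

@dataclass
class ClipRecipe:
    """Spectral recipe for one synthetic clip: sinusoid components + noise."""

    freqs: tuple
    amps: tuple
    duration_s: float = 2.5
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if len(self.freqs) != len(self.amps):
            raise ValueError("freqs and amps must have equal length")


def simulate_audio_clips(recipes, seed: int = 0, sample_rate: int = 44100):
    """Deterministic synthetic clips from spectral recipes.

    Component phases are derived from the recipe content, so clips built
    from identical recipes are sample-identical (hence LTAS cosine
    dissimilarity exactly 0) regardless of their position in the set.
    Returns a list of float waveforms in [-1, 1].
    """
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    clips = []
    for recipe in recipes:
        key = zlib.crc32(repr((tuple(recipe.freqs), tuple(recipe.amps),
                               round(recipe.duration_s, 9),
                               round(recipe.noise_sd, 9))).encode())
        rng = np.random.default_rng([int(seed), key])
        t = np.arange(int(round(recipe.duration_s * sample_rate))) / sample_rate
        wave = np.zeros_like(t)
        for f, a in zip(recipe.freqs, recipe.amps):
            wave += a * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        if recipe.noise_sd > 0:
            wave += recipe.noise_sd * rng.standard_normal(t.shape)
        peak = np.abs(wave).max()
        if peak > 1.0:
            wave = wave / peak
        clips.append(wave)
    return clips


def write_wav(path, wave: np.ndarray, sample_rate: int = 44100) -> None:
    """Write a float waveform as 16-bit PCM WAV."""
    from scipy.io import wavfile

    pcm = np.clip(np.asarray(wave, dtype=float), -1.0, 1.0)
    wavfile.write(str(path), int(sample_rate), (pcm * 32767).astype(np.int16))


# ---------------------------------------------------------------------------
# Behavior
# ---------------------------------------------------------------------------

def simulate_behavior(confusion_probs, n_trials_per_category: int, seed: int = 0,
                      categories=None) -> pd.DataFrame:
    """Trial-level 3-AFC responses from a stimulus x response probability table.

    Rows of ``confusion_probs`` must sum to at most 1; any remaining mass is
    the per-category timeout probability.  Returns a DataFrame with columns
    ``stimulus_category``, ``response_category`` (None on timeout) and
    ``timeout``.
    """
    probs = np.asarray(confusion_probs, dtype=float)
    if probs.ndim != 2 or probs.shape[0] != probs.shape[1]:
        raise ValueError("confusion_probs must be square (stimulus x response)")
    if (probs < 0).any():
        raise ValueError("probabilities must be nonnegative")
    rowsum = probs.sum(axis=1)
    if (rowsum > 1 + 1e-9).any():
        raise ValueError("each row must sum to at most 1 (remainder = timeouts)")
    if n_trials_per_category < 1:
        raise ValueError("n_trials_per_category must be >= 1")
    k = probs.shape[0]
    categories = list(categories) if categories is not None else _identity_names(k)
    if len(categories) != k:
        raise ValueError("category labels do not match table size")

    rng = np.random.default_rng(seed)
    rows = []
    for s in range(k):
        full = np.append(probs[s], max(0.0, 1.0 - rowsum[s]))
        full = full / full.sum()
        draws = rng.choice(k + 1, size=n_trials_per_category, p=full)
        for d in draws:
            timeout = d == k
            rows.append(dict(stimulus_category=categories[s],
                             response_category=None if timeout else categories[d],
                             timeout=bool(timeout)))
    frame = pd.DataFrame(rows)
    return frame.sample(frac=1.0, random_state=int(rng.integers(2 ** 31))) \
                .reset_index(drop=True)


# ---------------------------------------------------------------------------
# Multi-subject group simulation
# ---------------------------------------------------------------------------

@dataclass
class MaskSpec:
    """Cuboid signal and null regions inside a 3-D grid.

    Boxes are ((x0, x1), (y0, y1), (z0, z1)) half-open voxel ranges.  The
    planted geometry applies inside the signal box; the null box holds
    independent (pure-noise) item patterns.
    """

    shape: tuple = (36, 10, 5)
    signal_box: tuple = ((0, 10), (0, 10), (0, 5))
    null_box: tuple | None = ((26, 36), (0, 10), (0, 5))

    def _fill(self, box):
        grid = np.zeros(self.shape, dtype=bool)
        if box is not None:
            (x0, x1), (y0, y1), (z0, z1) = box
            grid[x0:x1, y0:y1, z0:z1] = True
        return grid

    def build(self):
        signal = self._fill(self.signal_box)
        null = self._fill(self.null_box)
        if not signal.any():
            raise ValueError("signal region is empty")
        if self.null_box is not None and not null.any():
            raise ValueError("null region is empty")
        if (signal & null).any():
            raise ValueError("signal and null regions overlap")
        return VoxelMask(signal | null), signal, null


@dataclass
class GroupSimulation:
    """Per-subject pattern datasets over a shared mask, plus acoustic RDMs."""

    design: StudyDesign
    geometry: PlantedGeometry
    mask: VoxelMask
    signal: np.ndarray
    null: np.ndarray
    subjects: list
    acoustic: list
    seed: int

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def signal_indices(self) -> np.ndarray:
        """Indices of signal voxels within the mask-voxel ordering."""
        return np.flatnonzero(self.signal[self.mask.data])

    def null_indices(self) -> np.ndarray:
        return np.flatnonzero(self.null[self.mask.data])


def _random_acoustic_rdm(labels, rng, n_bins: int = 64) -> RDM:
    """Nuisance acoustic RDM from random nonnegative spectra (1 - cosine)."""
    ltas = [LtasVector(rng.gamma(2.0, size=n_bins), sample_rate=44100,
                       n_fft=2 * (n_bins - 1), hop=n_bins - 1, window="hann")
            for _ in labels]
    return acoustic_rdm(ltas, labels)


def simulate_group(design: StudyDesign, geometry: PlantedGeometry,
                   n_subjects: int, mask_spec: MaskSpec | None = None,
                   seed: int = 0, via_bold: bool = False,
                   bold_noise_sd: float = 1.0) -> GroupSimulation:
    """Simulate a multi-subject dataset with planted geometry.

    Each subject receives independently sampled patterns: signal-region
    voxels follow the planted geometry; null-region voxels are independent
    noise per item.  With ``via_bold=True`` the subject patterns are pushed
    through the BOLD forward model and re-estimated with the GLM (slower;
    used for forward/inverse consistency checks), otherwise the planted
    patterns stand in directly for T patterns.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    mask_spec = mask_spec or MaskSpec()
    mask, signal, null = mask_spec.build()
    labels = design.item_labels()
    n_sig = int(signal.sum())
    n_null = int(null.sum())

    sig_in_mask = np.flatnonzero(signal[mask.data])
    null_in_mask = np.flatnonzero(null[mask.data])

    subjects, acoustic = [], []
    root = np.random.SeedSequence(seed)
    for sub_ss in root.spawn(n_subjects):
        rng = np.random.default_rng(sub_ss)
        pats = np.empty((len(labels), mask.n_voxels))
        pats[:, sig_in_mask] = plant_patterns(geometry, labels, seed=rng,
                                              n_voxels=n_sig)
        if n_null:
            noise = rng.standard_normal((len(labels), n_null))
            if geometry.noise_sd > 0:
                noise = noise + geometry.noise_sd * rng.standard_normal(noise.shape)
            pats[:, null_in_mask] = noise
        if via_bold:
            runs, designs = [], []
            for r in range(design.n_runs):
                seq = make_trial_sequence(design, run_index=r,
                                          seed=int(rng.integers(2 ** 31)))
                bold, dm = simulate_bold_run(pats, seq, design,
                                             noise_sd=bold_noise_sd, seed=rng,
                                             item_labels=labels)
                runs.append(bold)
                designs.append(dm)
            tmap = glm.fit_item_tmaps(runs, designs)
            pats = tmap.t
        subjects.append(PatternDataset(pats, labels, mask))
        acoustic.append(_random_acoustic_rdm(labels, rng))
    return GroupSimulation(design, geometry, mask, signal, null, subjects,
                           acoustic, seed)
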