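# voicersa

Searchlight representational similarity analysis (RSA) of voice-identity
fMRI, with a synthetic-data generator that plants known representational
geometry so the whole analysis chain can be validated by parameter
recovery.

## What this package is for

When a listener hears different utterances of the same speaker, how
similar are the evoked brain response patterns — and how does personal
familiarity with a voice reshape that similarity?  The standard way to ask
this question is RSA: for each of 24 stimulus items (3 voice identities
labelled *Familiar*, *Lab* and *New*, 8 spontaneous speech clips each),
estimate a multivoxel response pattern, compute the observed neural
dissimilarity matrix (ONDM)

&nbsp;&nbsp;&nbsp;&nbsp;d(i, j) = 1 − r(**b**ᵢ, **b**ⱼ)

over the ((24 × 24) − 24)/2 = 276 item pairs (Pearson r between
T-statistic patterns, no mean-centering across items), and rank-correlate
it with hypothesis model RDMs inside a moving 100-voxel searchlight —
partialling out a nuisance RDM of low-level acoustic similarity
(1 − cosine between long-term average spectra).  Per-subject
Fisher-z maps are tested at group level with voxel-wise one-sample
t-tests (degrees of freedom adjusted per voxel for missing coverage),
converted to z, corrected with threshold-free cluster enhancement (TFCE,
E = 0.5, H = 2) and a sign-flip max-statistic permutation null, and
thresholded at z = ±1.96 (FWE p < .05 per tail).  Behavioral
identification is summarised with the unbiased hit rate
Hu = (hits/trials) × (hits/responses), arcsine-transformed for model
fitting.

The raw study data (human fMRI and speech audio) are not distributable,
so the package ships a first-class synthetic module: it plants a target
1 − r geometry in item patterns (per-identity within-speaker and
between-speaker dissimilarity targets), simulates event-related BOLD runs
(TR 1 s, 2–3 s stimuli, jittered onsets, null trials, canonical
double-gamma HRF), audio clips with controllable spectral similarity, and
3-alternative forced-choice responses with controllable confusion
probabilities.  Every result the package claims can therefore be checked
by recovering what was planted.

## Worked example

Plant a familiarity-graded geometry — the Familiar voice's clips more
dissimilar to each other (0.8) than the Lab or New voices' clips (0.4) —
in a 500-voxel region for 20 simulated subjects, then run the searchlight
with the graded familiarity model (within-speaker codes 1/2/3, between
pairs excluded) and TFCE permutation inference:

```python
import numpy as np
import voicersa as v

design = v.StudyDesign()                      # 3 voices x 8 clips x 3 reps
geometry = v.PlantedGeometry(
    within={"Familiar": 0.8, "Lab": 0.4, "New": 0.4},
    between=1.0, n_signal_voxels=500, noise_sd=0.5)
mask_spec = v.MaskSpec(shape=(36, 10, 5),
                       signal_box=((0, 10), (0, 10), (0, 5)),
                       null_box=((26, 36), (0, 10), (0, 5)))
sim = v.simulate_group(design, geometry, n_subjects=20,
                       mask_spec=mask_spec, seed=42)

nbhd = v.build_neighborhoods(sim.mask, k=100)
labels = design.item_labels()
model = v.familiarity_model(labels, "all_voices")   # codes 1/2/3
maps = [v.searchlight_rsa(ds, nbhd, model, ac).values
        for ds, ac in zip(sim.subjects, sim.acoustic)]
result = v.permutation_correct(np.stack(maps), sim.mask,
                               n_perm=1000, seed=7)

signal = sim.signal_indices()
print("signal voxels with corrected z < -1.96:",
      f"{(result.corrected_z[signal] < -1.96).mean():.0%}")
for ident in ("Familiar", "Lab", "New"):
    m = v.mean_dissimilarity_map(sim.subjects[0], nbhd, (ident, ident))
    print(f"within-{ident} mean dissimilarity (signal):",
          f"{np.nanmean(m.values[signal]):.3f}")
```

Output:

```
signal voxels with corrected z < -1.96: 100%
within-Familiar mean dissimilarity (signal): 0.860
within-Lab mean dissimilarity (signal): 0.513
within-New mean dissimilarity (signal): 0.505
```

The group map is significantly *negative* under the graded model —
observed within-speaker dissimilarity runs opposite to the 1/2/3 coding
because the most familiar voice was planted with the *highest*
within-speaker dissimilarity — and the per-condition mean-dissimilarity
maps recover the planted ordering (the measured values sit above the
planted 0.8/0.4 targets by the known attenuation factor of the pattern
noise).  No voxel in the separate null region survives correction.

There is also a config-driven CLI over the same library
(`voicersa run -c config.yaml -o out/`, with `simulate`, `glm`, `rsa`,
`group`, `behavior` and `report` subcommands and a `--dry-run` validator);
outputs are NIfTI maps, CSV tables and a JSON manifest of checksums for
reproducibility.

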