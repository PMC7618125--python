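"""Config-driven orchestration of the end-to-end analysis.

Stages: ``simulate`` (synthetic multi-subject dataset) -> ``glm`` (T-pattern
fitting when BOLD-level simulation is configured) -> ``rsa`` (per-subject
searchlight maps per model variant) -> ``group`` (TFCE-corrected group
inference) -> ``behavior`` (confusion tables and Hu export) -> ``report``
(summary + manifest).  Outputs land in a derivatives-like folder layout;
every stochastic stage derives its seed from the single config seed, and a
run manifest records config and artifact checksums so deterministic stages
can be verified to reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as beh
from . import group as grp
from . import rdm as rdm_mod
from . import searchlight as sl
from .mask import PatternDataset, VoxelMask
from .simulate import MaskSpec, PlantedGeometry, StudyDesign, simulate_behavior, \
    simulate_group

log = logging.getLogger("voicersa")

STAGES = ("simulate", "glm", "rsa", "group", "behavior", "report")

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "STAGES",
           "parse_model_spec", "all_model_specs"]


def all_model_specs():
    """All 11 model variants as 'family:variant' strings."""
    return ([f"identity:{v}" for v in rdm_mod.IDENTITY_MODEL_VARIANTS]
            + [f"familiarity:{v}" for v in rdm_mod.FAMILIARITY_MODEL_VARIANTS])


def parse_model_spec(spec: str):
    """'identity:all_voices' -> (family, variant, coding dict)."""
    try:
        family, variant = spec.split(":")
    except ValueError:
        raise ValueError(f"model spec {spec!r} must look like 'family:variant'")
    table = {"identity": rdm_mod.IDENTITY_MODEL_VARIANTS,
             "familiarity": rdm_mod.FAMILIARITY_MODEL_VARIANTS}
    if family not in table:
        raise ValueError(f"unknown model family {family!r}")
    if variant not in table[family]:
        raise ValueError(f"unknown {family} model variant {variant!r}")
    return family, variant, table[family][variant]


def _from_mapping(cls, data, where):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown keys in {where}: {sorted(unknown)}")
    kwargs = dict(data)
    for key in ("stim_dur_range_s", "fixation_range_s", "shape", "signal_box",
                "null_box"):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = _to_tuple(kwargs[key])
    return cls(**kwargs)


def _to_tuple(x):
    if isinstance(x, (list, tuple)):
        return tuple(_to_tuple(v) for v in x)
    return x


@dataclass
class SimulationConfig:
    n_subjects: int = 6
    via_bold: bool = False
    bold_noise_sd: float = 1.0


@dataclass
class GeometryConfig:
    within: dict = field(default_factory=lambda: {"Familiar": 0.8, "Lab": 0.4,
                                                  "New": 0.4})
    between: float = 1.0
    noise_sd: float = 0.0


@dataclass
class SearchlightConfig:
    k: int = 100


@dataclass
class GroupConfig:
    n_perm: int = 1000
    tfce_e: float = 0.5
    tfce_h: float = 2.0
    threshold: float = grp.Z_THRESHOLD


@dataclass
class BehaviorConfig:
    n_trials_per_category: int = 96
    confusion: list = field(default_factory=lambda: [
        [0.95, 0.02, 0.02],
        [0.05, 0.85, 0.08],
        [0.05, 0.09, 0.84],
    ])


@dataclass
class PipelineConfig:
    """Schema-validated configuration for the whole pipeline."""

    seed: int = 0
    design: StudyDesign = field(default_factory=StudyDesign)
    mask: MaskSpec = field(default_factory=MaskSpec)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    models: list = field(default_factory=all_model_specs)
    searchlight: SearchlightConfig = field(default_factory=SearchlightConfig)
    group: GroupConfig = field(default_factory=GroupConfig)
    behavior: BehaviorConfig = field(default_factory=BehaviorConfig)

    @classmethod
    def from_mapping(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        sections = {
            "design": StudyDesign, "mask": MaskSpec, "geometry": GeometryConfig,
            "simulation": SimulationConfig, "searchlight": SearchlightConfig,
            "group": GroupConfig, "behavior": BehaviorConfig,
        }
        kwargs = {}
        for key, value in data.items():
            if key in sections:
                kwargs[key] = _from_mapping(sections[key], value or {}, key)
            else:
                kwargs[key] = value
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    def validate(self) -> None:
        identities = set(self.design.identities)
        for spec in self.models:
            _, _, coding = parse_model_spec(spec)
            referenced = {i for pair in coding for i in pair}
            missing = referenced - identities
            if missing:
                raise ValueError(
                    f"model {spec!r} references identities {sorted(missing)} "
                    f"not present in the design ({sorted(identities)})"
                )
        missing_geo = set(self.design.identities) - set(self.geometry.within)
        if missing_geo:
            raise ValueError(
                f"geometry.within lacks targets for identities {sorted(missing_geo)}"
            )
        k = len(self.behavior.confusion)
        if k != self.design.n_identities:
            raise ValueError("behavior.confusion size must match n_identities")

    def planted_geometry(self, n_signal_voxels: int) -> PlantedGeometry:
        return PlantedGeometry(dict(self.geometry.within), self.geometry.between,
                               n_signal_voxels, self.geometry.noise_sd)

    def to_mapping(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_mapping(), sort_keys=True, default=str).encode()
        ).hexdigest()


@dataclass
class RunManifest:
    """Reproducibility metadata: config hash and per-artifact checksums."""

    config_hash: str
    version: str
    checksums: dict = field(default_factory=dict)
    timestamps: dict = field(default_factory=dict)

    def record(self, path: Path, root: Path) -> None:
        rel = str(path.relative_to(root))
        self.checksums[rel] = hashlib.sha256(path.read_bytes()).hexdigest()
        self.timestamps[rel] = time.time()

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def _sub(i: int) -> str:
    return f"sub-{i + 1:02d}"


def _model_tag(spec: str) -> str:
    return spec.replace(":", "_")


def run_pipeline(config: PipelineConfig, outdir, stages=STAGES,
                 dry_run: bool = False) -> RunManifest:
    """Execute the requested stages in order; returns the run manifest.

    Stages are idempotent given unchanged inputs.  A stage whose upstream
    artifacts are missing raises an error naming the stage to run first.
    """
    from . import __version__

    config.validate()
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]
    outdir = Path(outdir)
    manifest = RunManifest(config.digest(), __version__)
    if dry_run:
        log.info("dry run: config valid; would run stages %s", stages)
        return manifest
    outdir.mkdir(parents=True, exist_ok=True)

    for stage in stages:
        t0 = time.time()
        _STAGE_FUNCS[stage](config, outdir, manifest)
        log.info("stage %s finished in %.1fs", stage, time.time() - t0)

    manifest.save(outdir / "manifest.json")
    return manifest


def _require(path: Path, produced_by: str):
    if not path.exists():
        raise FileNotFoundError(
            f"missing upstream artifact {path}; run the {produced_by!r} stage first"
        )
    return path


def _stage_simulate(config, outdir, manifest):
    sim_dir = outdir / "simulated"
    sim_dir.mkdir(exist_ok=True)
    mask_spec = config.mask
    _, signal, _ = mask_spec.build()
    geometry = config.planted_geometry(int(signal.sum()))
    sim = simulate_group(config.design, geometry,
                         config.simulation.n_subjects, mask_spec,
                         seed=config.seed, via_bold=config.simulation.via_bold,
                         bold_noise_sd=config.simulation.bold_noise_sd)
    sim.mask.to_nifti(sim_dir / "mask.nii")
    np.savetxt(sim_dir / "signal_voxels.txt", sim.signal_indices(), fmt="%d")
    for i, (ds, ac) in enumerate(zip(sim.subjects, sim.acoustic)):
        ds.to_nifti(sim_dir / f"{_sub(i)}_patterns.nii",
                    sim_dir / f"{_sub(i)}_labels.csv")
        ac.to_csv(sim_dir / f"{_sub(i)}_acoustic.csv")
    for path in sorted(sim_dir.iterdir()):
        manifest.record(path, outdir)
    log.info("simulated %d subjects over %d mask voxels (%d signal)",
             sim.n_subjects, sim.mask.n_voxels, int(sim.signal.sum()))


def _stage_glm(config, outdir, manifest):
    sim_dir = outdir / "simulated"
    _require(sim_dir / "mask.nii", "simulate")
    # pattern-level simulation writes T-pattern stand-ins directly; with
    # via_bold the GLM fit already ran inside the simulate stage
    n = config.simulation.n_subjects
    for i in range(n):
        _require(sim_dir / f"{_sub(i)}_patterns.nii", "simulate")
    log.info("glm: %d subject pattern sets present; nothing further to fit", n)


def _stage_rsa(config, outdir, manifest):
    sim_dir = outdir / "simulated"
    mask = VoxelMask.from_nifti(_require(sim_dir / "mask.nii", "simulate"))
    nbhd = sl.build_neighborhoods(mask, k=config.searchlight.k)
    labels = config.design.item_labels()
    rsa_dir = outdir / "rsa"
    rsa_dir.mkdir(exist_ok=True)
    for spec in config.models:
        family, variant, _ = parse_model_spec(spec)
        model = (rdm_mod.identity_model(labels, variant) if family == "identity"
                 else rdm_mod.familiarity_model(labels, variant))
        mdir = rsa_dir / _model_tag(spec)
        mdir.mkdir(exist_ok=True)
        model.to_csv(mdir / "model_rdm.csv")
        manifest.record(mdir / "model_rdm.csv", outdir)
        for i in range(config.simulation.n_subjects):
            ds = PatternDataset.from_nifti(
                _require(sim_dir / f"{_sub(i)}_patterns.nii", "simulate"),
                sim_dir / f"{_sub(i)}_labels.csv", mask)
            acoustic = rdm_mod.RDM.from_csv(sim_dir / f"{_sub(i)}_acoustic.csv")
            smap = sl.searchlight_rsa(ds, nbhd, model, acoustic)
            path = mdir / f"{_sub(i)}_zmap.nii"
            smap.to_nifti(path)
            manifest.record(path, outdir)
        log.info("rsa: model %s done (%d subjects)", spec,
                 config.simulation.n_subjects)


def _stage_group(config, outdir, manifest):
    sim_dir = outdir / "simulated"
    mask = VoxelMask.from_nifti(_require(sim_dir / "mask.nii", "simulate"))
    group_dir = outdir / "group"
    group_dir.mkdir(exist_ok=True)
    rng = np.random.SeedSequence([config.seed, 7])
    for spec, child in zip(config.models, rng.spawn(len(config.models))):
        mdir = outdir / "rsa" / _model_tag(spec)
        maps = []
        for i in range(config.simulation.n_subjects):
            path = _require(mdir / f"{_sub(i)}_zmap.nii", "rsa")
            maps.append(sl.SearchlightMap.from_nifti(path, mask).values)
        result = grp.permutation_correct(
            np.stack(maps), mask, n_perm=config.group.n_perm,
            seed=int(child.generate_state(1)[0] % (2 ** 31)),
            E=config.group.tfce_e, H=config.group.tfce_h)
        pos, neg, peaks = grp.threshold_map(result, level=config.group.threshold)
        tag = _model_tag(spec)
        import nibabel as nib

        nib.save(nib.Nifti1Image(result.volume("corrected_z"), mask.affine),
                 group_dir / f"{tag}_corrected_z.nii")
        nib.save(nib.Nifti1Image(pos.astype(np.uint8), mask.affine),
                 group_dir / f"{tag}_pos_mask.nii")
        nib.save(nib.Nifti1Image(neg.astype(np.uint8), mask.affine),
                 group_dir / f"{tag}_neg_mask.nii")
        peaks.to_csv(group_dir / f"{tag}_peaks.csv", index=False)
        for name in (f"{tag}_corrected_z.nii", f"{tag}_pos_mask.nii",
                     f"{tag}_neg_mask.nii", f"{tag}_peaks.csv"):
            manifest.record(group_dir / name, outdir)
        log.info("group: model %s -> %d positive / %d negative voxels",
                 spec, int(pos.sum()), int(neg.sum()))


def _stage_behavior(config, outdir, manifest):
    beh_dir = outdir / "behavior"
    beh_dir.mkdir(exist_ok=True)
    frames = []
    root = np.random.SeedSequence([config.seed, 11])
    for i, child in enumerate(root.spawn(config.simulation.n_subjects)):
        frame = simulate_behavior(config.behavior.confusion,
                                  config.behavior.n_trials_per_category,
                                  seed=int(child.generate_state(1)[0] % (2 ** 31)),
                                  categories=config.design.identities)
        frame.insert(0, "subject", _sub(i))
        frames.append(frame)
    trials = pd.concat(frames, ignore_index=True)
    trials.to_csv(beh_dir / "trials.csv", index=False)
    hu = beh.hu_table(trials, categories=config.design.identities)
    hu.to_csv(beh_dir / "hu.csv", index=False)
    for name in ("trials.csv", "hu.csv"):
        manifest.record(beh_dir / name, outdir)
    log.info("behavior: %d trials, mean Hu per condition:\n%s", len(trials),
             hu.groupby("condition")["hu"].mean())


def _stage_report(config, outdir, manifest):
    summary = {"config_hash": config.digest(), "models": {}}
    group_dir = outdir / "group"
    for spec in config.models:
        tag = _model_tag(spec)
        peaks_path = group_dir / f"{tag}_peaks.csv"
        _require(peaks_path, "group")
        peaks = pd.read_csv(peaks_path)
        summary["models"][spec] = {
            "n_pos_voxels": int(peaks.loc[peaks["tail"] == "positive",
                                          "n_voxels"].sum()) if len(peaks) else 0,
            "n_neg_voxels": int(peaks.loc[peaks["tail"] == "negative",
                                          "n_voxels"].sum()) if len(peaks) else 0,
            "n_regions": int(len(peaks)),
        }
    hu_path = outdir / "behavior" / "hu.csv"
    if hu_path.exists():
        hu = pd.read_csv(hu_path)
        summary["behavior_mean_hu"] = hu.groupby("condition")["hu"].mean().to_dict()
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    manifest.record(outdir / "summary.json", outdir)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "glm": _stage_glm,
    "rsa": _stage_rsa,
    "group": _stage_group,
    "behavior": _stage_behavior,
    "report": _stage_report,
}
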