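"""End-to-end pipeline: simulate -> morphometry/densitometry -> features
-> group statistics -> classification.

Every constant the workflow fixes (cartilage HU window 0-300, hole-grade
cutoff 20 mm^2, k = 5 folds, the alpha weights 0.5/0.5/0.5/0.3 for wall
and 5 for curvature) lives in :class:`RunConfig`; a run writes its
resolved config next to its outputs and is deterministic for a fixed
seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classification as cls
from . import densitometry as dens
from . import group_stats as gs
from . import morphometry as mm
from . import synthetic_knee as sk
from . import wtc_features as wtc

log = logging.getLogger(__name__)

#: compartment key -> feature-name stem
CART_FEATURE_STEM = {
    "fem_cart": "FemCart",
    "tib_cart_lat": "TibCartLat",
    "tib_cart_med": "TibCartMed",
    "pat_cart": "PatCart",
}
BONE_FEATURE_STEM = {"femur": "Femur", "tibia": "Tibia", "patella": "Patella"}


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run."""

    seed: int = 42
    n_D: int = 24
    n_T: int = 15
    n_C: int = 8
    spacing_mm: float = 0.5
    refinement: int = 1
    noise_sd_hu: float = 10.0
    hu_lo: float = 0.0
    hu_hi: float = 300.0
    grade_cutoff_mm2: float = 20.0
    calibration_pairs: tuple = dens.DEFAULT_CALIBRATION_PAIRS
    alphas: dict = field(default_factory=lambda: dict(wtc.DEFAULT_ALPHAS))
    alpha_grid: tuple = wtc.DEFAULT_ALPHA_GRID
    select_alphas: bool = False
    cv_k: int = 5
    algorithms: tuple = cls.ALGORITHMS
    hyperparams: dict = field(default_factory=dict)
    unstable_threshold: float = 5.0
    apply_unstable_rule: bool = False
    archetype_files: dict = field(default_factory=dict)  # group -> json path
    out_dir: str = "results/run"

    def to_json(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        raw["alphas"] = {f"{c}|{k}": v for (c, k), v in self.alphas.items()}
        Path(path).write_text(json.dumps(raw, indent=2, default=list))

    @classmethod
    def from_json(cls_, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        raw["alphas"] = {
            tuple(k.split("|")): float(v) for k, v in raw["alphas"].items()
        }
        raw["calibration_pairs"] = tuple(
            tuple(p) for p in raw["calibration_pairs"]
        )
        raw["alpha_grid"] = tuple(raw["alpha_grid"])
        raw["algorithms"] = tuple(raw["algorithms"])
        return cls_(**raw)

    def archetypes(self) -> dict[str, sk.GroupArchetype]:
        arch = sk.default_archetypes()
        for group, path in self.archetype_files.items():
            arch[group] = sk.GroupArchetype.from_json(path)
        return arch


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage and offending subject."""

    def __init__(self, stage: str, subject_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on subject {subject_id!r}: {cause}")
        self.stage = stage
        self.subject_id = subject_id


# ---------------------------------------------------------------------------
# per-subject feature extraction
# ---------------------------------------------------------------------------

def bone_features(
    volume: dens.LabeledVolume, cal: dens.BmdCalibration
) -> dict[str, float]:
    """The 8 bone features: BMD mean/SD per bone, patella volume and surface.

    Bone densities are reported on the BMD scale (g/cm^3); STD is the
    intra-subject per-voxel SD of the same quantity.
    """
    out: dict[str, float] = {}
    for bone, stem in BONE_FEATURE_STEM.items():
        mean_hu, sd_hu, vol = dens.mask_density_stats(
            volume, volume.masks[bone], bone
        )
        out[f"{stem}DENS"] = dens.apply_bmd(cal, mean_hu)
        out[f"{stem}STD"] = cal.slope * sd_hu
        if bone == "patella":
            out["PatellaVOL"] = vol
            area, _ = dens.mask_surface_area(volume.masks[bone], volume.spacing)
            out["PatellaSURF"] = area
    return out


def cartilage_features(
    volume: dens.LabeledVolume,
    compartments: dict[str, sk.ShellCompartment],
    hu_lo: float = 0.0,
    hu_hi: float = 300.0,
) -> dict[str, float]:
    """The 16 cartilage features: HU mean/SD and volume from the thresholded
    voxel mask, surface from the articulating mesh."""
    from .mesh_core import surface_area

    out: dict[str, float] = {}
    for cart, stem in CART_FEATURE_STEM.items():
        mask = dens.threshold_mask(volume, hu_lo, hu_hi, volume.masks[cart])
        mean_hu, sd_hu, vol = dens.mask_density_stats(volume, mask, cart)
        out[f"{stem}DENS"] = mean_hu
        out[f"{stem}STD"] = sd_hu
        out[f"{stem}VOL"] = vol
        out[f"{stem}SURF"] = surface_area(compartments[cart].outer_patch)
    return out


def subject_analyses(
    compartments: dict[str, sk.ShellCompartment]
) -> dict[tuple[str, str], wtc.NormalizedField]:
    """The 8 per-element analyses (4 compartments x wall/curvature),
    area-normalized."""
    out = {}
    for cart, comp in compartments.items():
        wall = mm.wall_thickness(comp.closed_shell)
        curv = mm.gaussian_curvature(comp.closed_shell)
        out[(cart, "wall")] = wtc.normalize_by_area(wall, cart)
        out[(cart, "curvature")] = wtc.normalize_by_area(curv, cart)
    return out


def hole_features(
    compartments: dict[str, sk.ShellCompartment], cutoff: float = 20.0
) -> dict[str, float]:
    """Per-compartment hole count, total fitted area and 0/1/2 grade.

    Kept out of every classification selection; reported for bookkeeping.
    """
    out: dict[str, float] = {}
    for cart, stem in CART_FEATURE_STEM.items():
        records = mm.detect_holes(compartments[cart].outer_patch, cart)
        grade, total, n = mm.grade_compartment(records, cutoff)
        out[f"{stem}HoleCount"] = n
        out[f"{stem}HoleArea"] = total
        out[f"{stem}HoleGrade"] = grade
    return out


def extract_subject_features(
    subject: sk.SyntheticSubject,
    cal: dens.BmdCalibration,
    alphas: dict,
    hu_lo: float = 0.0,
    hu_hi: float = 300.0,
    grade_cutoff: float = 20.0,
    analyses: dict | None = None,
    include_wtc: bool = True,
) -> dict[str, float]:
    """One feature row: 8 bone + 16 cartilage + 48 WT-C + hole bookkeeping.

    ``include_wtc=False`` skips the per-element mesh analyses and yields
    the 24 bone/cartilage densitometric features only.
    """
    row: dict[str, float] = {"subject_id": subject.subject_id,
                             "group": subject.group_label}
    row.update(bone_features(subject.volume, cal))
    row.update(cartilage_features(subject.volume, subject.compartments,
                                  hu_lo, hu_hi))
    if include_wtc:
        if analyses is None:
            analyses = subject_analyses(subject.compartments)
        row.update(wtc.assemble_wtc_block(analyses, alphas))
    row.update(hole_features(subject.compartments, grade_cutoff))
    return row


# ---------------------------------------------------------------------------
# field-file import (per-element text dialect)
# ---------------------------------------------------------------------------

def import_field_files(directory: str | Path) -> dict[str, mm.ElementField]:
    """Read every per-element field file in a directory.

    Each ``*.txt`` file must hold 10 whitespace-separated numbers per
    line (three element corners + value).  The analysis kind is inferred
    from the file name (``wall``/``curv``); everything else defaults to
    wall.  Returns ``{file stem: ElementField}``, usable by the feature
    statistics without any mesh.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(directory)
    out = {}
    for path in sorted(directory.glob("*.txt")):
        kind = "curvature" if "curv" in path.stem.lower() else "wall"
        out[path.stem] = mm.read_field_file(path, kind)
    return out


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_pipeline(
    config: RunConfig,
    stages: tuple[str, ...] = ("simulate", "features", "stats", "classify"),
    resume: bool = False,
) -> dict:
    """Run the pipeline, writing all outputs under ``config.out_dir``.

    Stages: ``simulate`` (cohort + manifest), ``features`` (morphometry,
    densitometry and the WT-C block into one feature table), ``stats``
    (per-feature group comparison), ``classify`` (5 selections x the
    configured algorithms).  With ``resume=True`` a stage whose output
    file already exists is loaded instead of recomputed.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _setup_run_logging(out_dir / "run.log")
    config.to_json(out_dir / "config.resolved.json")
    cal = dens.calibrate_bmd(config.calibration_pairs)
    results: dict = {"out_dir": out_dir}
    t_start = time.time()
    log.info("pipeline start: seed=%d cohort=(%d,%d,%d)",
             config.seed, config.n_D, config.n_T, config.n_C)

    subjects = None
    manifest_path = out_dir / "manifest.csv"
    if "simulate" in stages or "features" in stages:
        subjects, manifest = sk.generate_cohort(
            config.n_D, config.n_T, config.n_C, config.seed,
            archetypes=config.archetypes(),
            spacing=config.spacing_mm,
            refinement=config.refinement,
            noise_sd_hu=config.noise_sd_hu,
            calibration=cal,
        )
        manifest.to_csv(manifest_path, index=False)
        results["manifest"] = manifest
        log.info("simulate: %d subjects (%.1fs)", len(subjects),
                 time.time() - t_start)

    features_path = out_dir / "features.csv"
    if "features" in stages:
        if resume and features_path.exists():
            features = pd.read_csv(features_path)
        else:
            alphas = dict(config.alphas)
            rows, all_analyses, labels = [], [], []
            for s in subjects:
                try:
                    analyses = subject_analyses(s.compartments)
                except Exception as err:  # noqa: BLE001 - stage boundary
                    raise StageError("features", s.subject_id, err) from err
                all_analyses.append(analyses)
                labels.append(s.group_label)
            if config.select_alphas and len(set(labels)) >= 2:
                for key in alphas:
                    fields = [a[key] for a in all_analyses]
                    alphas[key] = wtc.select_alpha(
                        fields, labels, config.alpha_grid
                    )
                log.info("selected alphas: %s", alphas)
                wtc.save_alphas(alphas, out_dir / "alphas.json")
            for s, analyses in zip(subjects, all_analyses):
                try:
                    rows.append(extract_subject_features(
                        s, cal, alphas, config.hu_lo, config.hu_hi,
                        config.grade_cutoff_mm2, analyses=analyses,
                    ))
                except Exception as err:  # noqa: BLE001
                    raise StageError("features", s.subject_id, err) from err
            features = pd.DataFrame(rows)
            features.to_csv(features_path, index=False)
        results["features"] = features
        log.info("features: %d rows x %d cols (%.1fs)", *features.shape,
                 time.time() - t_start)
    elif (resume or "stats" in stages or "classify" in stages) \
            and features_path.exists():
        results["features"] = features = pd.read_csv(features_path)
    else:
        features = results.get("features")

    if "stats" in stages:
        if features is None:
            raise StageError("stats", "-", RuntimeError("no feature table"))
        stats_in = features.drop(
            columns=[c for c in features.columns if c == "subject_id"]
        )
        stats = gs.compare_table(stats_in, group_col="group")
        stats.to_csv(out_dir / "stats.csv", index=False)
        results["stats"] = stats
        log.info("stats: %d features compared", len(stats))

    if "classify" in stages:
        if features is None:
            raise StageError("classify", "-", RuntimeError("no feature table"))
        unstable: list[str] = []
        if config.apply_unstable_rule:
            wtc_cols = [c for c in wtc.wtc_column_names()
                        if not c.endswith("STDWeight")
                        or c.endswith(("BelowSTDWeight", "AboveSTDWeight"))]
            unstable = wtc.unstable_features(
                features[wtc_cols], config.unstable_threshold
            )
            log.info("unstable WT-C features excluded: %s", unstable)
        cls_dir = out_dir / "classification"
        cls_dir.mkdir(exist_ok=True)
        reports = []
        labels = features["group"].to_numpy()
        for sel in cls.SELECTIONS:
            sub = cls.build_selection(features, sel, unstable)
            for alg in config.algorithms:
                rep = cls.crossval_classify(
                    sub, labels, alg, k=config.cv_k, seed=config.seed,
                    selection_name=sel,
                    hyperparams=config.hyperparams.get(alg),
                )
                reports.append(rep)
                stem = f"{sel.replace('-', '')}_{alg}"
                (cls_dir / f"{stem}.json").write_text(
                    json.dumps(rep.to_dict(), indent=2)
                )
                pd.DataFrame(rep.confusion, index=rep.classes,
                             columns=rep.classes).to_csv(
                    cls_dir / f"{stem}_confusion.csv"
                )
                if rep.importance:
                    pd.DataFrame(rep.importance,
                                 columns=["feature", "importance_pct"]
                                 ).to_csv(cls_dir / f"{stem}_importance.csv",
                                          index=False)
        results["reports"] = reports
        log.info("classify: %d reports", len(reports))

    log.info("pipeline done in %.1fs", time.time() - t_start)
    return results


def _setup_run_logging(logfile: Path) -> None:
    root = logging.getLogger("kneemorph")
    root.setLevel(logging.INFO)
    have = {getattr(h, "baseFilename", None) for h in root.handlers}
    if str(logfile) not in have:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
        root.addHandler(fh)
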