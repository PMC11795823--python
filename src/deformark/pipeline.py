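"""End-to-end pipeline orchestration, configuration and provenance.

Stages run in the order: synth (optional) -> select-reference ->
register -> screen -> refine -> combine -> morphology. Every stage
reads only files written by earlier stages and writes its artifacts
under the run directory, so stages can also be run individually from
the CLI. A manifest (config echo + artifact checksums) makes runs
diffable; wall-clock timings go to a sidecar file so the manifest
itself is bit-reproducible under a fixed config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as dio
from .locale_screening import (
    CohortFeatures,
    cohort_features_from_fields,
    screen_all_seeds,
    stratified_split,
    AUCMap,
)
from .morphology_inference import summarize_morphology
from .reference_selection import LandmarkSet, choice_to_dict, select_reference
from .registration import DemonsParams, Image2D, demons_register, rigid_align
from .roi_combination import LinearModel, crosscheck_fraction_negative, search_combinations
from .roi_refinement import RegionScorer, Region, refine_all, regions_to_mask
from . import synthetic_cohort as synth

logger = logging.getLogger("deformark")

_KNOWN_SYNTH_KEYS = {"n_loci", "n_control", "n_disease", "null", "single_locus"}


@dataclass
class RunConfig:
    """Parameters of one full pipeline run.

    Defaults mirror the method's settings: 9 x 9 locale, eight folds,
    80/20 train/test split, AUC threshold 0.62.
    """

    schema_version: int = 1
    experiment: str = "default"
    images_dir: str | None = None
    landmarks_path: str | None = None
    labels_path: str | None = None
    synth: dict | None = None
    k: int = 9
    n_folds: int = 8
    split_ratio: float = 0.8
    auc_threshold: float = 0.62
    max_regions: int = 10
    demons_smooth_sigma: float = 1.5
    demons_levels: tuple[int, ...] = (4, 2, 1)
    demons_max_iter: int = 100
    demons_tol: float = 1e-4
    synth_seed: int = 1234
    split_seed: int = 1234
    fold_seed: int = 1235

    def __post_init__(self) -> None:
        if self.k % 2 != 1 or self.k < 3:
            raise ValueError("locale size k must be odd and >= 3")
        if not (0.5 < self.auc_threshold < 1.0):
            raise ValueError("AUC threshold must lie in (0.5, 1)")
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")
        for name in ("synth_seed", "split_seed", "fold_seed"):
            if not isinstance(getattr(self, name), int):
                raise ValueError(f"{name} must be an integer")
        if self.synth is not None:
            unknown = set(self.synth) - _KNOWN_SYNTH_KEYS
            if unknown:
                raise ValueError(f"unknown synth keys: {sorted(unknown)}")
        self.demons_levels = tuple(int(v) for v in self.demons_levels)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(dio.load_json(path))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["demons_levels"] = list(self.demons_levels)
        return d

    def demons_params(self) -> DemonsParams:
        return DemonsParams(
            smooth_sigma=self.demons_smooth_sigma,
            levels=self.demons_levels,
            max_iter=self.demons_max_iter,
            tol=self.demons_tol,
        )


# --------------------------------------------------------------------------
# Individual stages
# --------------------------------------------------------------------------


def stage_synth(config: RunConfig, out: Path) -> dict:
    opts = dict(config.synth or {})
    phantom = synth.default_phantom()
    if opts.get("single_locus"):
        cohort = synth.single_locus_cohort(seed=config.synth_seed)
        cohort = dataclasses.replace(
            cohort,
            n_control=opts.get("n_control", cohort.n_control),
            n_disease=opts.get("n_disease", cohort.n_disease),
        )
    else:
        cohort = synth.default_cohort(
            n_loci=opts.get("n_loci", 2),
            n_control=opts.get("n_control", 30),
            n_disease=opts.get("n_disease", 30),
            seed=config.synth_seed,
            null=bool(opts.get("null", False)),
        )
    cohort_dir = out / "cohort"
    synth.render_cohort(phantom, cohort, out_dir=cohort_dir)
    return {"cohort_dir": str(cohort_dir), "n_subjects": cohort.n_control + cohort.n_disease}


def stage_select_reference(landmarks_path: Path, labels_path: Path, out_file: Path) -> str:
    landmarks = dio.load_landmarks(landmarks_path)
    labels = dio.load_labels(labels_path)
    control_sets = [
        LandmarkSet(sid, pts) for sid, pts in landmarks.items() if labels.get(sid) == "control"
    ]
    choice = select_reference(control_sets)
    dio.save_json(choice_to_dict(choice), out_file)
    return choice.subject_id


def stage_register(
    images_dir: Path,
    landmarks_path: Path,
    labels_path: Path,
    reference_id: str,
    out_dir: Path,
    params: DemonsParams,
    reference_images_dir: Path | None = None,
    reference_landmarks_path: Path | None = None,
) -> None:
    """Register every labeled subject to the reference.

    The reference image/landmarks normally come from the same cohort;
    the two override paths let an external cohort (e.g. a crosscheck
    set) be registered against another run's reference.
    """
    landmarks = dio.load_landmarks(landmarks_path)
    labels = dio.load_labels(labels_path)
    ref_img = _find_image(reference_images_dir or images_dir, reference_id)
    ref_landmark_map = (
        dio.load_landmarks(reference_landmarks_path) if reference_landmarks_path else landmarks
    )
    ref_lm = LandmarkSet(reference_id, ref_landmark_map[reference_id])
    transforms = {}
    for sid in sorted(labels):
        try:
            img = _find_image(images_dir, sid)
            aligned, transform = rigid_align(img, LandmarkSet(sid, landmarks[sid]), ref_lm)
            field_out = demons_register(ref_img, aligned, params)
            dio.save_field(field_out, out_dir / f"{sid}.nii.gz")
            transforms[sid] = {
                "rotation_deg": transform.rotation_deg,
                "translation": list(transform.translation),
                "center": list(transform.center),
                "degenerate": transform.degenerate,
            }
        except Exception as exc:
            raise RuntimeError(f"registration failed for subject {sid}: {exc}") from exc
    dio.save_json(transforms, out_dir / "rigid_transforms.json")


def _find_image(images_dir: Path, sid: str) -> Image2D:
    for suffix in (".nii.gz", ".nii", ".png"):
        p = images_dir / f"{sid}{suffix}"
        if p.exists():
            return dio.load_image(p)
    raise FileNotFoundError(f"no image for subject {sid} under {images_dir}")


def load_cohort_features(
    fields_dir: Path,
    labels_path: Path,
    split_ratio: float,
    split_seed: int,
    split_file: Path | None = None,
) -> CohortFeatures:
    """Assemble magnitude stack + labels; split from file or derived."""
    labels_map = dio.load_labels(labels_path)
    subject_ids = sorted(labels_map)
    fields = {sid: dio.load_field(fields_dir / f"{sid}.nii.gz") for sid in subject_ids}
    y = dio.label_codes(labels_map, subject_ids)
    if split_file is not None and split_file.exists():
        assignment = dio.load_json(split_file)
        split = np.array([assignment[sid] == "train" for sid in subject_ids])
    else:
        split = stratified_split(y, ratio=split_ratio, seed=split_seed)
    return cohort_features_from_fields(fields, y, subject_ids, split)


def stage_screen(config: RunConfig, fields_dir: Path, labels_path: Path, out: Path) -> AUCMap:
    cohort = load_cohort_features(
        fields_dir, labels_path, config.split_ratio, config.split_seed
    )
    dio.save_json(
        {
            sid: ("train" if tr else "test")
            for sid, tr in zip(cohort.subject_ids, cohort.split)
        },
        out / "split.json",
    )
    auc_map = screen_all_seeds(cohort, k=config.k, n_folds=config.n_folds, seed=config.fold_seed)
    _save_auc_map(auc_map, out)
    _render_auc_heatmap(auc_map, out / "auc_map.png")
    return auc_map


def _save_auc_map(auc_map: AUCMap, out: Path) -> None:
    import nibabel as nib

    data = np.stack(
        [np.nan_to_num(auc_map.auc, nan=0.0), auc_map.valid_mask.astype(float)], axis=-1
    ).astype(np.float32)[:, :, np.newaxis, :]
    out.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(data, np.eye(4)), str(out / "auc_map.nii.gz"))
    dio.save_json({"k": auc_map.k}, out / "auc_map_meta.json")


def load_auc_map(out: Path) -> AUCMap:
    import nibabel as nib

    data = np.squeeze(np.asarray(nib.load(str(out / "auc_map.nii.gz")).dataobj, dtype=float))
    meta = dio.load_json(out / "auc_map_meta.json")
    valid = data[..., 1] > 0.5
    auc = np.where(valid, data[..., 0], np.nan)
    return AUCMap(auc=auc, valid_mask=valid, k=int(meta["k"]))


def stage_refine(
    config: RunConfig, auc_map: AUCMap, cohort: CohortFeatures, out: Path
) -> list[Region]:
    scorer = RegionScorer(cohort, n_folds=config.n_folds, seed=config.fold_seed)
    regions = refine_all(
        auc_map, scorer, threshold=config.auc_threshold, max_regions=config.max_regions
    )
    payload = [
        {
            "pixels": [list(p) for p in rg.sorted_pixels],
            "train_auc": rg.train_auc,
            "history": [[step, auc] for step, auc in rg.history],
        }
        for rg in regions
    ]
    dio.save_json(payload, out / "regions.json")
    if regions:
        mask = regions_to_mask(regions, cohort.shape)
        import nibabel as nib

        nib.save(
            nib.Nifti1Image(mask[:, :, np.newaxis].astype(np.int16), np.eye(4)),
            str(out / "regions.nii.gz"),
        )
    return regions


def load_regions(path: Path) -> list[Region]:
    payload = dio.load_json(path)
    return [
        Region(
            pixels=frozenset(tuple(p) for p in item["pixels"]),
            train_auc=item["train_auc"],
            history=[(s, a) for s, a in item["history"]],
        )
        for item in payload
    ]


def stage_combine(config: RunConfig, regions: list[Region], cohort: CohortFeatures, out: Path):
    scorer = RegionScorer(cohort, n_folds=config.n_folds, seed=config.fold_seed)
    result = search_combinations(regions, scorer)
    dio.save_json(result.to_dict(), out / "combination_result.json")
    _render_roc(result, out / "roc.png")
    return result


def stage_morphology(
    regions: list[Region],
    winner_indices: tuple[int, ...],
    fields_dir: Path,
    labels_path: Path,
    out: Path,
    reference_image: Image2D | None = None,
):
    labels_map = dio.load_labels(labels_path)
    subject_ids = sorted(labels_map)
    fields = {sid: dio.load_field(fields_dir / f"{sid}.nii.gz") for sid in subject_ids}
    y = dio.label_codes(labels_map, subject_ids)
    winning = [regions[i] for i in winner_indices]
    summary = summarize_morphology(winning, fields, subject_ids, y)
    dio.save_json(summary.to_dict(), out / "morphology.json")
    _render_morphology(summary, reference_image, out / "morphology.png")
    return summary


# --------------------------------------------------------------------------
# Full run + crosscheck
# --------------------------------------------------------------------------


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute every stage and write the provenance manifest.

    Returns the manifest dict. Re-running with an identical config
    reproduces every numeric artifact (and hence the manifest)
    bit-identically.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []
    timings: dict[str, float] = {}

    def _timed(name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        logger.info("stage %s started", name)
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"stage {name} failed: {exc}") from exc
        timings[name] = time.perf_counter() - t0
        stages.append(name)
        logger.info("stage %s finished in %.1fs", name, timings[name])
        return result

    if config.synth is not None:
        info = _timed("synth", stage_synth, config, out)
        cohort_dir = Path(info["cohort_dir"])
        images_dir = cohort_dir / "images"
        landmarks_path = cohort_dir / "landmarks.csv"
        labels_path = cohort_dir / "labels.csv"
    else:
        if not (config.images_dir and config.landmarks_path and config.labels_path):
            raise ValueError("without a synth block, images/landmarks/labels paths are required")
        images_dir = Path(config.images_dir)
        landmarks_path = Path(config.landmarks_path)
        labels_path = Path(config.labels_path)
        for p in (images_dir, landmarks_path, labels_path):
            if not p.exists():
                raise FileNotFoundError(f"input not found: {p}")
        stages.append("synth-skipped")

    reference_id = _timed(
        "select_reference",
        stage_select_reference,
        landmarks_path,
        labels_path,
        out / "reference_choice.json",
    )
    fields_dir = out / "fields"
    _timed(
        "register",
        stage_register,
        images_dir,
        landmarks_path,
        labels_path,
        reference_id,
        fields_dir,
        config.demons_params(),
    )
    auc_map = _timed("screen", stage_screen, config, fields_dir, labels_path, out)
    cohort = load_cohort_features(
        fields_dir, labels_path, config.split_ratio, config.split_seed,
        split_file=out / "split.json",
    )
    regions = _timed("refine", stage_refine, config, auc_map, cohort, out)
    if regions:
        result = _timed("combine", stage_combine, config, regions, cohort, out)
        ref_img = _find_image(images_dir, reference_id)
        _timed(
            "morphology",
            stage_morphology,
            regions,
            result.region_indices,
            fields_dir,
            labels_path,
            out,
            ref_img,
        )
    else:
        logger.warning("no supra-threshold regions; combine/morphology skipped")
        stages.extend(["combine-skipped", "morphology-skipped"])

    manifest = {
        "config": config.to_dict(),
        "stages": stages,
        "checksums": _checksums(out),
    }
    dio.save_json(manifest, out / "manifest.json")
    dio.save_json(timings, out / "timings.json")
    return manifest


def _checksums(out: Path) -> dict[str, str]:
    """SHA-256 of every numeric artifact (renders excluded)."""
    sums = {}
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.suffix in {".gz", ".nii", ".json", ".csv"}:
            if p.name in {"manifest.json", "timings.json"}:
                continue
            sums[str(p.relative_to(out))] = hashlib.sha256(p.read_bytes()).hexdigest()
    return sums


def crosscheck(run_dir: str | Path, other_labels_path: str | Path, other_fields_dir: str | Path) -> dict:
    """Score an external registered cohort with the frozen winning model.

    Reports the fraction of subjects classified negative (score below
    the stored operating threshold) — the external analogue of
    specificity when the cohort is known to lack the condition.
    """
    run_dir = Path(run_dir)
    payload = dio.load_json(run_dir / "combination_result.json")
    model = LinearModel.from_dict(payload["model"])
    threshold = payload["operating_threshold"]
    labels_map = dio.load_labels(other_labels_path)
    subject_ids = sorted(labels_map)
    if not subject_ids:
        raise ValueError("external cohort is empty")
    missing = [
        sid for sid in subject_ids if not (Path(other_fields_dir) / f"{sid}.nii.gz").exists()
    ]
    if missing:
        raise FileNotFoundError(f"unregistered subjects: {missing}")
    from .registration import field_magnitude

    stack = np.stack(
        [
            field_magnitude(dio.load_field(Path(other_fields_dir) / f"{sid}.nii.gz"))
            for sid in subject_ids
        ]
    )
    frac = crosscheck_fraction_negative(model, threshold, stack)
    return {"n_subjects": len(subject_ids), "fraction_negative": frac}


# --------------------------------------------------------------------------
# Renders (presentation only; excluded from manifests)
# --------------------------------------------------------------------------


def _render_auc_heatmap(auc_map: AUCMap, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    shown = np.where(auc_map.valid_mask & (np.nan_to_num(auc_map.auc) >= 0.5), auc_map.auc, np.nan)
    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(shown, cmap="hot", vmin=0.5, vmax=1.0)
    fig.colorbar(im, ax=ax, label="cross-validated AUC")
    ax.set_title("searchlight AUC map (>= 0.5 shown)")
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _render_roc(result, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fpr = [v[0] for v in result.roc]
    tpr = [v[1] for v in result.roc]
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(fpr, tpr, marker="o", label=f"test AUC = {result.test_auc:.2f}")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.plot(
        1 - result.specificity,
        result.sensitivity,
        "r*",
        ms=14,
        label=f"operating point ({result.sensitivity:.0%} sens, {result.specificity:.0%} spec)",
    )
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _render_morphology(summary, reference: Image2D | None, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    if reference is not None:
        ax.imshow(reference.pixels, cmap="gray")
    colors = {"control": "tab:blue", "disease": "tab:orange"}
    scale = 6.0
    for rm in summary.regions:
        r, c = rm.exemplar
        for name, cm in rm.per_class.items():
            dr, dc = cm.mean_vector
            ax.plot([c, c + scale * dc], [r, r + scale * dr], "-", color=colors[name], lw=2)
            if cm.direction_defined:
                pr, pc = cm.principal_direction
                ax.plot(
                    [c, c + scale * pc], [r, r + scale * pr], "--", color=colors[name], lw=1.2
                )
    ax.set_title("class mean (solid) and principal (dashed) displacement")
    fig.savefig(path, dpi=100)
    plt.close(fig)
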