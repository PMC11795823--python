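"""Shared fixtures.

Fast unit tests use a small 64 x 64 phantom and mini-cohorts. The three
full-scale study runs (single-locus, two-locus, null) are expensive
(minutes each: 60 subjects, full searchlight sweep), so they are
session-scoped and shared between the module tests and the acceptance
suite.
"""

from __future__ import annotations

import numpy as np
import pytest

import deformark as dm
from deformark.pipeline import RunConfig, run_pipeline


def small_phantom() -> dm.PhantomSpec:
    """64 x 64 textured phantom for fast tests."""
    return dm.PhantomSpec(
        image_height=64,
        image_width=64,
        blob_centers=((32.0, 32.0), (20.0, 22.0), (22.0, 44.0), (44.0, 22.0), (44.0, 44.0)),
        blob_amplitudes=(1.0, 0.7, 0.8, 0.7, 0.6),
        blob_sigmas=(8.0, 4.0, 3.5, 4.0, 4.5),
        landmark_positions=(
            (32.0, 32.0), (20.0, 22.0), (22.0, 44.0), (44.0, 22.0),
            (44.0, 44.0), (15.0, 32.0), (49.0, 32.0),
        ),
        texture_amplitude=0.15,
    )


def small_cohort(seed: int = 11, **overrides) -> dm.CohortSpec:
    """8 + 8 subjects, one strong effect on a blob flank of the small phantom."""
    effect = dm.EffectSpec(
        locus_center=(22.0, 40.0),
        locus_sigma=3.0,
        control_direction=(0.0, -1.0),
        disease_direction=(0.0, 1.0),
        control_amplitude=0.0,
        disease_amplitude=3.0,
    )
    defaults = dict(
        n_control=8,
        n_disease=8,
        effects=(effect,),
        background_field_sigma=6.0,
        background_field_amplitude=0.5,
        intensity_noise_sd=0.01,
        seed=seed,
    )
    defaults.update(overrides)
    return dm.CohortSpec(**defaults)


@pytest.fixture(scope="session")
def small_bundle():
    return dm.render_cohort(small_phantom(), small_cohort())


def small_run_config(**overrides) -> RunConfig:
    cfg = dict(
        synth=None,  # callers set paths or synth
        k=5,
        n_folds=4,
        split_ratio=0.75,
        auc_threshold=0.62,
        max_regions=6,
        synth_seed=11,
        split_seed=11,
        fold_seed=12,
    )
    cfg.update(overrides)
    return RunConfig(**cfg)


@pytest.fixture(scope="session")
def small_cohort_dir(tmp_path_factory):
    """Small cohort written to disk in the standard layout."""
    out = tmp_path_factory.mktemp("small_cohort")
    dm.render_cohort(small_phantom(), small_cohort(), out_dir=out)
    return out


# --------------------------------------------------------------------------
# Full-scale study runs (shared by module tests and the acceptance suite)
# --------------------------------------------------------------------------


@pytest.fixture(scope="session")
def single_locus_run(tmp_path_factory):
    """Full pipeline on the single-locus study cohort (disease 3 px vs
    control 0, background 1 px, noise SD 0.02, seeds 1234/1235)."""
    out = tmp_path_factory.mktemp("run_single")
    cfg = RunConfig(synth={"single_locus": True}, experiment="single-locus")
    manifest = run_pipeline(cfg, out)
    return {"out": out, "config": cfg, "manifest": manifest,
            "cohort_spec": dm.single_locus_cohort()}


@pytest.fixture(scope="session")
def two_locus_run(tmp_path_factory):
    """Full pipeline on the default two-locus study cohort."""
    out = tmp_path_factory.mktemp("run_two")
    cfg = RunConfig(synth={"n_loci": 2}, experiment="two-locus")
    manifest = run_pipeline(cfg, out)
    return {"out": out, "config": cfg, "manifest": manifest,
            "cohort_spec": dm.default_cohort(n_loci=2)}


@pytest.fixture(scope="session")
def null_run(tmp_path_factory):
    """Full pipeline on the null cohort (class effects identical)."""
    out = tmp_path_factory.mktemp("run_null")
    cfg = RunConfig(synth={"n_loci": 2, "null": True}, experiment="null")
    manifest = run_pipeline(cfg, out)
    return {"out": out, "config": cfg, "manifest": manifest,
            "cohort_spec": dm.default_cohort(n_loci=2, null=True)}


# --------------------------------------------------------------------------
# Helpers shared by tests
# --------------------------------------------------------------------------


def angle_between(v, u) -> float:
    v = np.asarray(v, dtype=float)
    u = np.asarray(u, dtype=float)
    c = np.dot(v, u) / (np.linalg.norm(v) * np.linalg.norm(u))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
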