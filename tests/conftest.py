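"""Shared fixtures: configs, small synthetic frames, rendered scenarios.

Scenario renders and pipeline runs are session-scoped because several test
modules interrogate the same sequences.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from hypothesis import settings

from depthfall.frames import DepthFrame, Stage, SystemConfig
from depthfall.preprocess import clamp_floor, fill_nulls
from depthfall.simulate import make_scenario, reference_frame
from depthfall.track import run_sequence

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cfg() -> SystemConfig:
    return SystemConfig()


def make_rf(spec, cfg: SystemConfig) -> DepthFrame:
    """Person-free reference frame of a scene, preprocessed to RF stage."""
    rf = fill_nulls(clamp_floor(reference_frame(spec), cfg), cfg)
    return dataclasses.replace(rf, stage=Stage.RF)


def flat_rf(cfg: SystemConfig) -> DepthFrame:
    """A bare-floor reference (the no-reference-frame operating mode)."""
    grid = np.full(cfg.frame_shape, cfg.max_height, dtype=np.uint16)
    return DepthFrame(grid=grid, stage=Stage.RF)


def uniform_cf(value: int, cfg: SystemConfig) -> DepthFrame:
    return DepthFrame(grid=np.full(cfg.frame_shape, value, dtype=np.uint16),
                      stage=Stage.CF)


@pytest.fixture(scope="session")
def simple_fall(cfg):
    spec, frames, truth = make_scenario("simple_fall", seed=1)
    return spec, frames, truth


@pytest.fixture(scope="session")
def simple_fall_run(cfg, simple_fall):
    spec, frames, truth = simple_fall
    return run_sequence(frames, make_rf(spec, cfg), cfg)


@pytest.fixture(scope="session")
def complex_fall(cfg):
    spec, frames, truth = make_scenario("complex_fall", seed=1)
    return spec, frames, truth


@pytest.fixture(scope="session")
def complex_fall_run(cfg, complex_fall):
    spec, frames, truth = complex_fall
    return run_sequence(frames, make_rf(spec, cfg), cfg)


@pytest.fixture(scope="session")
def complex_fall_run_no_rf(cfg, complex_fall):
    spec, frames, truth = complex_fall
    return run_sequence(frames, flat_rf(cfg), cfg)


@pytest.fixture(scope="session")
def fusion_walk(cfg):
    spec, frames, truth = make_scenario("fusion_walk", seed=1)
    return spec, frames, truth


@pytest.fixture(scope="session")
def standing_person_scene(cfg):
    """A single upright subject centered in an otherwise empty room."""
    from depthfall.simulate import Actor, SceneSpec, render_frame
    spec = SceneSpec(actors=[Actor(trajectory=[(0.0, 0.0, 0.0)])])
    frame, gt = render_frame(spec, 0.0, cfg)
    cf = fill_nulls(clamp_floor(frame, cfg), cfg)
    return spec, frame, cf, gt
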