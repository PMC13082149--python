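"""Shared fixtures: a ground-truthed suite of rendered channel stacks.

The suite spans both channel designs (adult D1 and larval L4), trap
positions, centerline curvature, focus planes and embryo loads, plus
truncated (partial) and empty (none) channels, so pipeline tests exercise
the classifier and the morphometric chain against generator truth.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from wormdart.chip import d1_geometry, l4_geometry, minimal_plan
from wormdart.synthetic import (
    EmbryoSpec,
    GeometryError,
    SyntheticWormSpec,
    render_channel_stack,
    render_empty_channel,
)

settings.register_profile(
    "suite", derandomize=True, max_examples=40,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("suite")

SUITE_SEED = 20240117


def _sample_spec(rng: np.random.Generator, design: str) -> SyntheticWormSpec:
    if design == "D1":
        body = float(rng.uniform(950, 1350))
        radius = float(rng.uniform(26, 31))
        offset = float(rng.uniform(120, 220))
        amplitude = float(rng.uniform(3, 8))
    else:  # L4 design, smaller larvae trapped deeper in the taper
        body = float(rng.uniform(450, 650))
        radius = float(rng.uniform(9, 11.5))
        offset = float(rng.uniform(1500, 1750))
        amplitude = float(rng.uniform(1, 2.5))
    n_embryos = int(rng.integers(0, 7)) if design == "D1" else 0
    embryos = tuple(
        EmbryoSpec(
            arc_pos_um=float(rng.uniform(0.35, 0.65) * body),
            lateral_offset_um=float(rng.uniform(-6, 6)),
            stage="early" if rng.random() < 0.69 else "late",
        )
        for _ in range(n_embryos)
    )
    return SyntheticWormSpec(
        body_length=body,
        max_radius=radius,
        amplitude=amplitude,
        wavelength=float(rng.uniform(450, 750)),
        phase=float(rng.uniform(0, 2 * np.pi)),
        axial_offset=offset,
        embryos=embryos,
        best_focus_z=int(rng.integers(5, 13)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def build_fixture_suite(
    n_full_d1: int = 23, n_full_l4: int = 15, n_partial: int = 7,
    n_none: int = 5, seed: int = SUITE_SEED,
) -> list[dict]:
    rng = np.random.default_rng(seed)
    plan = minimal_plan()
    geos = {"D1": d1_geometry(), "L4": l4_geometry()}
    suite: list[dict] = []

    def render_full(design):
        for _ in range(50):  # resample if a draw does not fit the channel
            spec = _sample_spec(rng, design)
            try:
                stack, truth = render_channel_stack(spec, geos[design], plan)
            except GeometryError:
                continue
            if truth.classification == "full":
                return {"kind": "full", "design": design, "spec": spec,
                        "stack": stack, "truth": truth, "geometry": geos[design]}
        raise RuntimeError("could not sample a feasible worm")

    for _ in range(n_full_d1):
        suite.append(render_full("D1"))
    for _ in range(n_full_l4):
        suite.append(render_full("L4"))
    for _ in range(n_partial):
        for _attempt in range(50):
            spec = _sample_spec(rng, "D1")
            cut = (max(0.0, spec.axial_offset - 60.0),
                   spec.axial_offset + 0.6 * spec.body_length)
            try:
                stack, truth = render_channel_stack(
                    spec, geos["D1"], plan, crop_axial_range=cut)
            except GeometryError:
                continue
            suite.append({"kind": "partial", "design": "D1", "spec": spec,
                          "stack": stack, "truth": truth, "geometry": geos["D1"]})
            break
    for i in range(n_none):
        stack = render_empty_channel(geos["D1"], plan, seed=int(rng.integers(0, 2**31 - 1)))
        suite.append({"kind": "none", "design": "D1", "spec": None,
                      "stack": stack, "truth": None, "geometry": geos["D1"]})
    return suite


@pytest.fixture(scope="session")
def fixture_suite() -> list[dict]:
    """50 rendered channel fixtures (38 full, 7 partial, 5 none)."""
    return build_fixture_suite()


@pytest.fixture(scope="session")
def one_full_fixture(fixture_suite) -> dict:
    return next(f for f in fixture_suite if f["kind"] == "full" and f["truth"].n_total > 0)
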