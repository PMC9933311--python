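"""Parameter-recovery benchmark fixtures.

The published per-condition values (``conditions.REFERENCE_CONDITIONS``)
cannot be re-measured from the original micrographs, which are not
distributed; instead, the synthetic generator is calibrated so that its
ground truth equals a published condition, and the full measurement
pipeline is then required to recover that value.  This module builds those
calibrated fixtures and measures them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .conditions import REFERENCE_CONDITIONS
from .fluorometry import intensity_at
from .pipeline import SPECIES_PROFILES, run_section
from .synthetic import SectionSpec, calibrate_to_target, generate_section

__all__ = ["FixtureResult", "recovery_fixture_spec", "measure_fixture", "FIXTURE_LAYOUTS"]

# frame size / cell count per species: >= 1000 tracheids or >= 200 vessels,
# the smallest frames that hold the published mean lumen sizes at that count
FIXTURE_LAYOUTS = {
    "spruce": {"n_cells": 1200, "image_size": (1280, 1280)},
    "beechwood": {"n_cells": 200, "image_size": (1024, 1024)},
}
# wall gain used when a condition has no published reference-exposure grey
DEFAULT_WALL_GREY_2000MS = 25.0


@dataclass
class FixtureResult:
    """Ground-truth and pipeline-measured means of one calibrated section."""

    species: str
    treatment: str
    n_particles: int
    measured_area_um2: float
    measured_circularity: float
    measured_perimeter_um: float
    measured_wall_grey_2000ms: float
    true_area_um2: float
    true_circularity: float
    true_perimeter_um: float
    true_wall_grey_2000ms: float


def recovery_fixture_spec(
    species: str,
    treatment: str,
    seed: int,
    n_cells: int | None = None,
    image_size: tuple[int, int] | None = None,
) -> SectionSpec:
    """Calibrate a section spec to a published condition's mean values."""
    cond = REFERENCE_CONDITIONS[(species, treatment)]
    layout = FIXTURE_LAYOUTS[species]
    return calibrate_to_target(
        species,
        target_mean_area_um2=cond.area_um2,
        target_mean_circularity=cond.circularity,
        target_wall_grey_at_2000ms=cond.wall_grey_2000ms or DEFAULT_WALL_GREY_2000MS,
        n_cells=n_cells or layout["n_cells"],
        seed=seed,
        image_size=image_size or layout["image_size"],
    )


def measure_fixture(species: str, treatment: str, seed: int, **kwargs) -> FixtureResult:
    """Generate the calibrated section and push it through the full pipeline."""
    spec = recovery_fixture_spec(species, treatment, seed, **kwargs)
    stack, truth = generate_section(spec)
    result = run_section(stack, SPECIES_PROFILES[species])
    if any(s != "ok" for s in result.status.values()):
        raise RuntimeError(f"pipeline failed on the {species}/{treatment} fixture: {result.status}")
    coi = truth.cells_of_interest()
    particles = result.particles
    return FixtureResult(
        species=species,
        treatment=treatment,
        n_particles=len(particles),
        measured_area_um2=float(np.mean([p.area_um2 for p in particles])),
        measured_circularity=float(np.mean([p.circularity for p in particles])),
        measured_perimeter_um=float(np.mean([p.perimeter_um for p in particles])),
        measured_wall_grey_2000ms=intensity_at(result.curve, 2000.0),
        true_area_um2=float(coi.true_area_um2.mean()),
        true_circularity=float(coi.true_circularity.mean()),
        true_perimeter_um=float(coi.true_perimeter_um.mean()),
        true_wall_grey_2000ms=truth.true_wall_grey_at(2000.0),
    )
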