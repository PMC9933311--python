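"""Published per-condition benchmark values for steam-exploded wood.

Mean +/- SD of lumen perimeter (um), area (um^2) and circularity, and the
mean cell-wall grey value at the 2000 ms reference exposure where reported,
for untreated and steam-exploded (170/190/210 degC, 15 min) spruce and
beechwood transverse sections.  The recovery fixtures calibrate the
synthetic generator's ground truth to these values and then require the
full pipeline to measure them back.

The 210 degC spruce condition came from a single analysable section (the
pretreatment shatters the samples) and is flagged accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ReferenceCondition", "REFERENCE_CONDITIONS"]


@dataclass(frozen=True)
class ReferenceCondition:
    species: str                  # 'spruce' | 'beechwood'
    treatment: str                # 'untreated' | '170C' | '190C' | '210C'
    perimeter_um: float
    perimeter_sd: float
    area_um2: float
    area_sd: float
    circularity: float
    circularity_sd: float
    wall_grey_2000ms: float | None = None
    wall_grey_sd: float | None = None
    n_sections: int = 5


REFERENCE_CONDITIONS: dict[tuple[str, str], ReferenceCondition] = {
    ("spruce", "untreated"): ReferenceCondition("spruce", "untreated", 76, 28, 414, 260, 0.79, 0.11),
    ("spruce", "170C"): ReferenceCondition("spruce", "170C", 72, 26, 347, 224, 0.76, 0.11),
    ("spruce", "190C"): ReferenceCondition("spruce", "190C", 68, 29, 270, 190, 0.66, 0.13),
    ("spruce", "210C"): ReferenceCondition("spruce", "210C", 73, 34, 280, 201, 0.62, 0.16, n_sections=1),
    ("beechwood", "untreated"): ReferenceCondition(
        "beechwood", "untreated", 146, 53, 1309, 796, 0.71, 0.13, wall_grey_2000ms=23.44, wall_grey_sd=2.74
    ),
    ("beechwood", "170C"): ReferenceCondition("beechwood", "170C", 145, 50, 1396, 889, 0.74, 0.11),
    ("beechwood", "190C"): ReferenceCondition(
        "beechwood", "190C", 143, 46, 1292, 750, 0.73, 0.11, wall_grey_2000ms=15.49, wall_grey_sd=1.13
    ),
    ("beechwood", "210C"): ReferenceCondition(
        "beechwood", "210C", 134, 48, 776, 546, 0.50, 0.13, wall_grey_2000ms=7.34, wall_grey_sd=0.94
    ),
}
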