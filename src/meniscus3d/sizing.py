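"""The three allograft-sizing/selection rules.

* 3D-MRI sizing: the mirrored contralateral meniscus is the template;
  the allograft with the closest MeSD is selected.
* 2D-MRI sizing: the contralateral 2D width/length is the target; the
  allograft minimizing the error sum of squares
  (width_sized - width_allograft)^2 + (length_sized - length_allograft)^2
  is selected.
* 2D-RX sizing: target width/length derived from the ipsilateral tibia
  plateau by the Pollard rules (width = plateau width; length = 0.8 x
  plateau length medial, 0.7 x lateral), then the same error sum of
  squares.

2D scores are in mm^2, the 3D score in mm (MeSD); they are never
compared across methods. 2D targets are scored against the bank's 3D
(OBB) width/length by default, switchable to the bank's 2D measurement.
Ties are broken deterministically by the smaller candidate id.
"""
from __future__ import annotations

import dataclasses
import enum

from .bank import AllograftBank, BankEntry, RadiographMeasure
from .mesh_model import Laterality, MeniscusMesh, Side, mirror_to_right
from .obb import MeniscusDimensions, measure_dimensions_2d
from .surface_distance import SurfaceDistanceEngine
from .synthetic import POLLARD_LENGTH_FACTOR, VirtualPatient

__all__ = [
    "SizingMethod",
    "SizingTemplate",
    "SelectionResult",
    "pollard_derive",
    "select_by_dims",
    "select_by_mesd",
    "build_template",
]


class SizingMethod(str, enum.Enum):
    BEST = "best"  # gold standard: the original meniscus itself as template
    MRI3D = "mri3d"
    MRI2D = "mri2d"
    RX2D = "rx2d"


@dataclasses.dataclass
class SizingTemplate:
    """What a sizing method matches against the bank."""

    method: SizingMethod
    template_mesh: MeniscusMesh | None = None  # mri3d/best only
    target_dims: MeniscusDimensions | None = None  # mri2d/rx2d only

    def __post_init__(self):
        needs_mesh = self.method in (SizingMethod.MRI3D, SizingMethod.BEST)
        if needs_mesh and self.template_mesh is None:
            raise ValueError(f"{self.method.value} template requires a mesh")
        if not needs_mesh and self.target_dims is None:
            raise ValueError(f"{self.method.value} template requires target dims")


@dataclasses.dataclass
class SelectionResult:
    """Ranked allograft selection; score in mm^2 (2D) or mm MeSD (3D)."""

    method: SizingMethod
    selected_id: str
    score: float
    ranking: list[tuple[str, float]]  # ascending score, id tie-break


def pollard_derive(radiograph: RadiographMeasure, side: Side | str) -> MeniscusDimensions:
    """Meniscal width/length from tibia plateau measurements (Pollard).

    Width equals the plateau width for both sides; length is 80%
    (medial) or 70% (lateral) of the plateau length.
    """
    side = Side(side)
    return MeniscusDimensions(
        width=radiograph.tibia_plateau_width,
        length=POLLARD_LENGTH_FACTOR[side] * radiograph.tibia_plateau_length,
        height=None,
    )


def _rank(scores: list[tuple[str, float]]) -> list[tuple[str, float]]:
    return sorted(scores, key=lambda kv: (kv[1], kv[0]))


def _candidates(bank: AllograftBank, side: Side | str,
                exclude_patient: str | None) -> list[BankEntry]:
    pool = bank.pool(side, exclude_patient)
    if not pool:
        raise ValueError("allograft pool is empty after exclusion")
    return pool


def select_by_dims(
    target: MeniscusDimensions,
    bank: AllograftBank,
    side: Side | str,
    exclude_patient: str | None = None,
    method: SizingMethod = SizingMethod.MRI2D,
    use_bank_dims2d: bool = False,
) -> SelectionResult:
    """Smallest width/length error sum of squares over the pool (mm^2)."""
    pool = _candidates(bank, side, exclude_patient)
    scores = []
    for e in pool:
        dims = e.dims2d if use_bank_dims2d else e.dims3d
        score = (target.width - dims.width) ** 2 + (target.length - dims.length) ** 2
        scores.append((e.entry_id, float(score)))
    ranking = _rank(scores)
    return SelectionResult(method, ranking[0][0], ranking[0][1], ranking)


def select_by_mesd(
    template_mesh: MeniscusMesh,
    bank: AllograftBank,
    side: Side | str,
    exclude_patient: str | None = None,
    engine: SurfaceDistanceEngine | None = None,
    method: SizingMethod = SizingMethod.MRI3D,
    mesd_lookup=None,
) -> SelectionResult:
    """Closest-MeSD selection over the pool (score in mm).

    ``mesd_lookup(template_mesh, entry) -> mesd`` may be supplied to
    reuse precomputed pairwise distances; otherwise distances come from
    ``engine`` (a fresh one if omitted).
    """
    pool = _candidates(bank, side, exclude_patient)
    if mesd_lookup is None:
        eng = engine or SurfaceDistanceEngine()
        mesd_lookup = lambda tmpl, entry: eng.distance(tmpl, entry.mesh).mesd
    scores = [(e.entry_id, float(mesd_lookup(template_mesh, e))) for e in pool]
    ranking = _rank(scores)
    return SelectionResult(method, ranking[0][0], ranking[0][1], ranking)


def build_template(
    method: SizingMethod | str,
    patient: VirtualPatient,
    side: Side | str,
    target_laterality: Laterality | str,
) -> SizingTemplate:
    """Template for sizing the (target_laterality, side) meniscus.

    mri3d: the mirrored contralateral meniscus surface; mri2d: the 2D
    width/length of the mirrored contralateral meniscus; rx2d: the
    Pollard-derived width/length from the ipsilateral radiograph.
    """
    method = SizingMethod(method)
    side = Side(side)
    target_laterality = Laterality(target_laterality)
    contralateral = (
        Laterality.LEFT if target_laterality is Laterality.RIGHT else Laterality.RIGHT
    )
    if method in (SizingMethod.MRI3D, SizingMethod.MRI2D):
        key = (contralateral, side)
        if key not in patient.menisci:
            raise ValueError(f"patient {patient.patient_id} lacks contralateral {side.value}")
        mirrored = mirror_to_right(patient.menisci[key])
        if method is SizingMethod.MRI3D:
            return SizingTemplate(method, template_mesh=mirrored)
        return SizingTemplate(method, target_dims=measure_dimensions_2d(mirrored))
    if method is SizingMethod.RX2D:
        key = (target_laterality, side)
        if key not in patient.radiographs:
            raise ValueError(f"patient {patient.patient_id} lacks radiograph for {key}")
        return SizingTemplate(
            method, target_dims=pollard_derive(patient.radiographs[key], side)
        )
    if method is SizingMethod.BEST:
        key = (target_laterality, side)
        return SizingTemplate(method, template_mesh=mirror_to_right(patient.menisci[key]))
    raise ValueError(f"unknown sizing method {method}")
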