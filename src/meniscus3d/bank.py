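"""Allograft bank containers.

The bank is the in-silico tissue bank: every meniscus mirrored to a
right-side surface model, with its 3D (OBB) and 2D (axial-footprint)
dimensions precomputed, plus patient provenance so that a leave-one-out
validation can exclude the tested patient's own menisci.
"""
from __future__ import annotations

import dataclasses

from .mesh_model import Laterality, MeniscusMesh, Side
from .obb import MeniscusDimensions

__all__ = ["RadiographMeasure", "BankEntry", "AllograftBank"]


@dataclasses.dataclass(frozen=True)
class RadiographMeasure:
    """Tibia plateau width/length (mm) read off calibrated radiographs."""

    tibia_plateau_width: float
    tibia_plateau_length: float

    def __post_init__(self):
        if not (self.tibia_plateau_width > 0 and self.tibia_plateau_length > 0):
            raise ValueError("tibia plateau measurements must be positive")


@dataclasses.dataclass
class BankEntry:
    """One bank meniscus: right-mirrored mesh + precomputed dimensions.

    ``source_laterality`` records which knee the meniscus came from
    before mirroring (the mesh itself is always right). ``dims3d`` is
    recomputable from the mesh via the OBB measurement; ``dims2d`` is
    the 2D-MRI-style width/length (possibly noise-perturbed).
    """

    entry_id: str
    patient_id: str
    side: Side
    source_laterality: Laterality
    mesh: MeniscusMesh
    dims3d: MeniscusDimensions
    dims2d: MeniscusDimensions
    is_validation: bool = False


class AllograftBank:
    """Collection of bank entries with per-patient and per-side indexing."""

    def __init__(self, entries: list[BankEntry],
                 radiographs: dict[tuple[str, Laterality, Side], RadiographMeasure] | None = None):
        seen = set()
        for e in entries:
            key = (e.patient_id, e.side, e.source_laterality)
            if key in seen:
                raise ValueError(f"duplicate bank entry {key}")
            seen.add(key)
        self.entries = list(entries)
        self.radiographs = dict(radiographs or {})
        self._by_id = {e.entry_id: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, entry_id: str) -> BankEntry:
        return self._by_id[entry_id]

    def per_side(self, side: Side | str) -> list[BankEntry]:
        side = Side(side)
        return [e for e in self.entries if e.side is side]

    def pool(self, side: Side | str, exclude_patient: str | None = None) -> list[BankEntry]:
        """Side entries minus every meniscus of the excluded patient."""
        return [
            e for e in self.per_side(side)
            if exclude_patient is None or e.patient_id != exclude_patient
        ]

    def validation_ids(self, side: Side | str | None = None) -> list[str]:
        entries = self.entries if side is None else self.per_side(side)
        return [e.entry_id for e in entries if e.is_validation]

    def contralateral(self, entry: BankEntry) -> BankEntry | None:
        """The same patient's same-side meniscus from the other knee."""
        other = (
            Laterality.LEFT
            if entry.source_laterality is Laterality.RIGHT
            else Laterality.RIGHT
        )
        for e in self.entries:
            if (
                e.patient_id == entry.patient_id
                and e.side is entry.side
                and e.source_laterality is other
            ):
                return e
        return None

    def radiograph(self, patient_id: str, laterality: Laterality | str,
                   side: Side | str) -> RadiographMeasure:
        key = (patient_id, Laterality(laterality), Side(side))
        if key not in self.radiographs:
            raise KeyError(f"no radiograph for {key}")
        return self.radiographs[key]
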