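"""Dataset records and cohorts.

One :class:`DatasetRecord` bundles the map, (optional) model and soak
metadata of a single crystal; a :class:`DatasetCohort` is the unit over
which background density is statistically characterized, so all member
maps must share one grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .density import DensityMap
from .errors import InsufficientDataError, ValidationError
from .structure import MulticonformerModel


@dataclass
class DatasetRecord:
    dataset_id: str
    map: DensityMap
    model: MulticonformerModel | None = None
    temperature_K: float = 100.0
    soak_compound: str = "DMSO"
    resolution: float | None = None

    def __post_init__(self) -> None:
        if self.temperature_K <= 0:
            raise ValidationError(f"temperature must be positive, got {self.temperature_K}")
        if self.resolution is not None and self.resolution <= 0:
            raise ValidationError(f"resolution must be positive, got {self.resolution}")


@dataclass
class DatasetCohort:
    """Grid-compatible collection of dataset records.

    ``ground_truth`` and ``reference_maps`` are populated by the synthetic
    generators (planted occupancies, event centroids, noise-free component
    maps) so recovery tests can compare against construction.
    """

    records: list[DatasetRecord]
    ground_truth: dict = field(default_factory=dict)
    reference_maps: dict[str, DensityMap] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.dataset_id for r in self.records]

    def get(self, dataset_id: str) -> DatasetRecord:
        for r in self.records:
            if r.dataset_id == dataset_id:
                return r
        raise KeyError(dataset_id)

    def validate_for_statistics(self) -> None:
        if len(self.records) < 2:
            raise InsufficientDataError(
                f"statistical characterization needs >= 2 datasets, got {len(self.records)}"
            )
        ref = self.records[0].map
        for r in self.records[1:]:
            ref.require_compatible(r.map)

    def partition_by_resolution(self, edges: list[float]) -> list["DatasetCohort"]:
        """Optional cohort partitioning into resolution bins (edges in A,
        increasing); records with unknown resolution go to the last bin."""
        bounds = [0.0, *sorted(edges), float("inf")]
        parts: list[DatasetCohort] = []
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            recs = [
                r
                for r in self.records
                if r.resolution is not None and lo < r.resolution <= hi
            ]
            if hi == float("inf"):
                recs += [r for r in self.records if r.resolution is None]
            if recs:
                parts.append(
                    DatasetCohort(records=recs, ground_truth=self.ground_truth,
                                  reference_maps=self.reference_maps)
                )
        return parts
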