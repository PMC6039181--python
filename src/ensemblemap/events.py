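"""Cohort-level background characterization and binding-event detection.

The background of a soak cohort is summarized per voxel as a mean map and a
(population) standard-deviation map over the included datasets.  A dataset's
Z-map standardizes its deviation from that background; contiguous
supra-threshold Z clusters are candidate binding events.  For an event, the
background-subtracted event map

    E_bdc = (rho_dataset - bdc * mean) / (1 - bdc)

reconstructs the bound-state density when bdc equals the ground-state
fraction, i.e. event-map occupancy = 1 - bdc.  The subtraction fraction is
chosen by scanning bdc and minimizing the absolute correlation between the
event map and the mean map inside the event region, subject to the event
map remaining faithful to the mean map (correlation >= 0.95) outside it.

The two-pass protocol re-characterizes the background after excluding the
datasets that produced events in the first pass, which removes bound-state
contamination from the mean map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .datasets import DatasetCohort, DatasetRecord
from .density import DensityMap
from .errors import (
    DegenerateCohortError,
    InsufficientDataError,
    NoEventError,
    ValidationError,
)

DEFAULT_SD_FLOOR = 0.05  # sigma-scaled units; avoids division blow-ups
DEFAULT_Z_THRESHOLD = 2.5
DEFAULT_MIN_CLUSTER_VOXELS = 27  # ~ a 1.5 A-radius blob at 0.5 A spacing
_OUTSIDE_CORR_MIN = 0.95


@dataclass
class BackgroundModel:
    """Per-voxel mean/sd of the background density across a cohort."""

    mean_map: DensityMap
    sd_map: DensityMap
    n_datasets: int
    excluded_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_datasets < 2:
            raise InsufficientDataError("background characterization needs >= 2 datasets")
        if np.any(self.sd_map.values < 0):
            raise ValidationError("sd_map must be non-negative")


@dataclass
class Event:
    """A detected bound-state signal."""

    dataset_id: str
    centroid: np.ndarray
    peak_z: float
    cluster_voxels: int
    bdc: float | None = None

    @property
    def event_occupancy(self) -> float | None:
        """Event-map occupancy, exactly 1 - BDC."""
        return None if self.bdc is None else 1.0 - self.bdc


@dataclass
class EventParams:
    """Defaults for the two-pass analysis."""

    z_threshold: float = DEFAULT_Z_THRESHOLD
    min_cluster_voxels: int = DEFAULT_MIN_CLUSTER_VOXELS
    sd_floor: float = DEFAULT_SD_FLOOR
    bdc_step: float = 0.01
    event_region_radius: float = 4.0  # A around the event centroid


def characterize_background(
    cohort: DatasetCohort, excluded_ids: tuple[str, ...] = ()
) -> BackgroundModel:
    """Uniform-weight per-voxel mean and population (1/n) sd across the
    cohort, optionally excluding event datasets."""
    included = [r for r in cohort.records if r.dataset_id not in set(excluded_ids)]
    sub = DatasetCohort(records=included)
    sub.validate_for_statistics()
    stack = np.stack([r.map.values for r in included])
    ref = included[0].map
    return BackgroundModel(
        mean_map=ref.with_values(stack.mean(axis=0)),
        sd_map=ref.with_values(stack.std(axis=0)),
        n_datasets=len(included),
        excluded_ids=tuple(excluded_ids),
    )


def z_map(
    record: DatasetRecord, background: BackgroundModel, sd_floor: float = DEFAULT_SD_FLOOR
) -> DensityMap:
    """Voxelwise standardized deviation: Z = (rho - mu) / max(sigma, floor)."""
    record.map.require_compatible(background.mean_map)
    denom = np.maximum(background.sd_map.values, sd_floor)
    return record.map.with_values((record.map.values - background.mean_map.values) / denom)


def compute_event_map(
    record: DatasetRecord, background: BackgroundModel, bdc: float
) -> DensityMap:
    """Background-subtracted event map (rho - bdc*mu) / (1 - bdc)."""
    if not 0.0 <= bdc < 1.0:
        raise ValidationError(f"bdc must be in [0, 1), got {bdc}")
    record.map.require_compatible(background.mean_map)
    values = (record.map.values - bdc * background.mean_map.values) / (1.0 - bdc)
    return record.map.with_values(values)


def _corr_profile(rho: np.ndarray, mu: np.ndarray, bdcs: np.ndarray) -> np.ndarray:
    """corr(rho - b*mu, mu) for every scan value b, from sufficient statistics.

    The 1/(1-b) event-map scaling does not change the correlation magnitude,
    so the scan works directly on rho - b*mu.  Values are centred about the
    solvent baseline (the region median) rather than the region mean:
    density blobs are nonnegative, so mean-centring would make disjoint
    features (a ligand vs. the solvent it displaces) spuriously
    anticorrelated and bias the scan, whereas about the flat solvent level
    non-overlapping features are orthogonal.
    """
    n = rho.size
    mr, mm = np.median(rho), np.median(mu)
    var_m = ((mu - mm) ** 2).sum() / n
    var_r = ((rho - mr) ** 2).sum() / n
    cov_rm = ((rho - mr) * (mu - mm)).sum() / n
    num = cov_rm - bdcs * var_m
    var_e = var_r - 2.0 * bdcs * cov_rm + bdcs**2 * var_m
    denom = np.sqrt(np.maximum(var_m * var_e, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, num / denom, 0.0)
    return corr


def estimate_bdc(
    record: DatasetRecord,
    background: BackgroundModel,
    event_region: np.ndarray,
    grid_step: float = 0.01,
    sd_floor: float = DEFAULT_SD_FLOOR,
    signal_threshold: float = DEFAULT_Z_THRESHOLD,
) -> float:
    """Scan bdc over {0, step, ..., 1-step} and pick the admissible optimum.

    Admissible: the event map stays correlated (>= 0.95) with the mean map
    outside the region.  Optimum: minimal |corr(event, mean)| inside the
    region -- at the true ground-state fraction the mean-map component
    vanishes from the event map, so the minimum sits at bdc = 1 - f for
    mixtures whose displaced/bound features are uncorrelated with the
    background inside the region.
    """
    if not 0.0 < grid_step <= 0.05:
        raise ValidationError("grid_step must be in (0, 0.05]")
    region = np.asarray(event_region, dtype=bool)
    if region.shape != record.map.shape:
        raise ValidationError("event_region mask must match the map shape")
    if not region.any():
        raise ValidationError("event_region must be nonempty")
    record.map.require_compatible(background.mean_map)
    zvals = z_map(record, background, sd_floor).values[region]
    if np.abs(zvals).max() < signal_threshold:
        raise NoEventError("dataset indistinguishable from background inside region")
    rho, mu = record.map.values, background.mean_map.values
    bdcs = np.arange(0.0, 1.0 - grid_step / 2, grid_step)
    corr_in = _corr_profile(rho[region], mu[region], bdcs)
    corr_out = _corr_profile(rho[~region], mu[~region], bdcs)
    # The event map amplifies voxel noise by 1/(1-bdc), which attenuates the
    # observed outside correlation even for a perfectly faithful subtraction.
    # Disattenuate by the reliability implied by the cohort sd map (the
    # per-voxel noise level); with a noise-free cohort this is a no-op.
    noise_sd = float(np.median(background.sd_map.values[~region]))
    mu_out = mu[~region]
    var_mu_out = float(((mu_out - np.median(mu_out)) ** 2).mean())
    signal_var = (1.0 - bdcs) ** 2 * var_mu_out
    with np.errstate(divide="ignore", invalid="ignore"):
        reliability = signal_var / (signal_var + noise_sd**2)
        corr_out_adj = np.minimum(np.abs(corr_out / np.sqrt(reliability)), 1.0) * np.sign(corr_out)
    admissible = corr_out_adj >= _OUTSIDE_CORR_MIN
    if not admissible.any():
        raise NoEventError("no subtraction keeps the event map faithful outside the region")
    scores = np.where(admissible, np.abs(corr_in), np.inf)
    return float(bdcs[int(np.argmin(scores))])


def detect_events(
    z: DensityMap,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    min_cluster_voxels: int = DEFAULT_MIN_CLUSTER_VOXELS,
    dataset_id: str = "",
) -> list[Event]:
    """6-connected clusters of voxels with Z >= threshold.

    Each surviving cluster is reported with its Z-weighted centroid and
    peak Z; events are sorted by peak Z descending, ties broken by cluster
    size then lexicographic centroid.
    """
    if z_threshold <= 0:
        raise ValidationError("z_threshold must be positive")
    mask = z.values >= z_threshold
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    labels, n_labels = ndimage.label(mask, structure=structure)
    events: list[Event] = []
    for lab in range(1, n_labels + 1):
        idx = np.argwhere(labels == lab)
        if len(idx) < min_cluster_voxels:
            continue
        weights = z.values[tuple(idx.T)]
        centroid_idx = (idx * weights[:, None]).sum(axis=0) / weights.sum()
        events.append(
            Event(
                dataset_id=dataset_id,
                centroid=z.index_to_position(centroid_idx),
                peak_z=float(weights.max()),
                cluster_voxels=int(len(idx)),
            )
        )
    events.sort(key=lambda e: (-e.peak_z, -e.cluster_voxels, tuple(e.centroid)))
    return events


def run_two_pass_analysis(
    cohort: DatasetCohort, params: EventParams | None = None
) -> tuple[BackgroundModel, dict[str, list[Event]]]:
    """Characterize, detect, exclude event datasets, re-characterize,
    re-detect, and estimate each event's subtraction fraction.

    Returns the pass-2 background (with excluded ids recorded) and the
    pass-2 events per dataset (only datasets with events appear).
    """
    params = params or EventParams()
    cohort.validate_for_statistics()

    bg1 = characterize_background(cohort)
    flagged = [
        r.dataset_id
        for r in cohort.records
        if detect_events(z_map(r, bg1, params.sd_floor), params.z_threshold,
                         params.min_cluster_voxels, r.dataset_id)
    ]
    if len(flagged) >= len(cohort.records) - 1:
        raise DegenerateCohortError("nearly all datasets flagged as events in pass 1")

    bg2 = characterize_background(cohort, excluded_ids=tuple(flagged))
    results: dict[str, list[Event]] = {}
    for record in cohort.records:
        found = detect_events(z_map(record, bg2, params.sd_floor), params.z_threshold,
                              params.min_cluster_voxels, record.dataset_id)
        kept: list[Event] = []
        for ev in found:
            region = record.map.voxel_centers_mask_within(ev.centroid,
                                                          params.event_region_radius)
            try:
                ev.bdc = estimate_bdc(record, bg2, region, params.bdc_step,
                                      params.sd_floor, params.z_threshold)
            except NoEventError:
                continue
            kept.append(ev)
        if kept:
            results[record.dataset_id] = kept
    return bg2, results
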