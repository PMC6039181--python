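"""Temperature-dependent conformational-occupancy analysis.

Two-state occupancy is fit against a density map by closed-form 1-D least
squares under the constraint occ_A + occ_B = 1, restricted to the informative
footprint (atom spheres of radius 2 sigma_atom).  A variant fits one
conformer against the map with the remaining occupancy interpreted as a
disordered (zero excess density) state.  Minor-state heterogeneity across a
temperature series is summarized by summing map values at the centers of
atoms unique to the minor state and min-max normalizing across temperatures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .datasets import DatasetCohort
from .density import DensityMap, interpolate, sigma_scale
from .errors import DegenerateFitError, UndefinedScoreError, ValidationError
from .simulate import SimulationConfig, atom_sigma, render_density
from .structure import Atom, MulticonformerModel

logger = logging.getLogger(__name__)


@dataclass
class TwoStateFit:
    occ_state_a: float
    occ_state_b: float
    residual: float
    mode: str  # "two-conformer" | "conformer-vs-disorder"
    clamped: bool = False


@dataclass
class TemperatureProfile:
    residue_id: str
    temperatures: np.ndarray
    scores_raw: np.ndarray
    scores_normalized: np.ndarray
    degenerate: bool = False


def _unit_render(atoms: list[Atom], target: DensityMap, config: SimulationConfig) -> DensityMap:
    model = MulticonformerModel(atoms=list(atoms))
    return render_density(model, config, origin=target.origin, shape=target.shape,
                          unit_occupancy=True)


def _footprint(atoms: list[Atom], target: DensityMap, n_sigmas: float = 2.0) -> np.ndarray:
    """Union of atom spheres of radius n_sigmas * sigma_atom, as a voxel mask."""
    mask = np.zeros(target.shape, dtype=bool)
    for a in atoms:
        mask |= target.voxel_centers_mask_within(a.position, n_sigmas * atom_sigma(a.b_factor))
    return mask


def fit_two_state_occupancy(
    density: DensityMap,
    conf_a: list[Atom],
    conf_b: list[Atom],
    config: SimulationConfig,
) -> TwoStateFit:
    """Occupancy of conformer A under the constraint occ_A + occ_B = 1.

    Minimizes RMS between the map and occ*render(A) + (1-occ)*render(B)
    over the union footprint; the 1-D least squares has the closed form
    occ = <m - B, A - B> / |A - B|^2, clamped to [0, 1].
    """
    if not conf_a or not conf_b:
        raise ValidationError("conformer atom sets must be nonempty")
    map_a = _unit_render(conf_a, density, config)
    map_b = _unit_render(conf_b, density, config)
    mask = _footprint(conf_a, density, 2.0) | _footprint(conf_b, density, 2.0)
    diff = (map_a.values - map_b.values)[mask]
    denom = float((diff**2).sum())
    if denom < 1e-12:
        raise DegenerateFitError("identical conformers: occupancy unidentifiable")
    m = density.values[mask]
    b = map_b.values[mask]
    occ = float(((m - b) * diff).sum() / denom)
    clamped = not 0.0 <= occ <= 1.0
    if clamped:
        logger.info("two-state occupancy %.3f clamped to [0, 1]", occ)
        occ = float(np.clip(occ, 0.0, 1.0))
    resid = float(np.sqrt(np.mean((m - (occ * map_a.values[mask] + (1 - occ) * b)) ** 2)))
    return TwoStateFit(occ, 1.0 - occ, resid, "two-conformer", clamped)


def fit_occupancy_vs_disorder(
    density: DensityMap, conf: list[Atom], config: SimulationConfig
) -> TwoStateFit:
    """Occupancy of a single conformer, remainder modeled as disordered
    (no excess density): occ = <m, A> / |A|^2 over the conformer footprint."""
    if not conf:
        raise ValidationError("conformer atom set must be nonempty")
    map_a = _unit_render(conf, density, config)
    mask = _footprint(conf, density, 2.0)
    a = map_a.values[mask]
    denom = float((a**2).sum())
    if denom < 1e-12:
        raise DegenerateFitError("conformer renders no density inside its footprint")
    m = density.values[mask]
    occ = float((m * a).sum() / denom)
    clamped = not 0.0 <= occ <= 1.0
    if clamped:
        logger.info("occupancy-vs-disorder fit %.3f clamped to [0, 1]", occ)
        occ = float(np.clip(occ, 0.0, 1.0))
    resid = float(np.sqrt(np.mean((m - occ * a) ** 2)))
    return TwoStateFit(occ, 1.0 - occ, resid, "conformer-vs-disorder", clamped)


def unique_minor_atoms(
    major: list[Atom], minor: list[Atom], cutoff: float = 1.0
) -> list[Atom]:
    """Atoms of the minor state at least ``cutoff`` A from every major atom
    (boundary included: exactly cutoff counts as unique)."""
    if cutoff <= 0:
        raise ValidationError("cutoff must be positive")
    if not minor:
        return []
    if not major:
        return list(minor)
    dmin = cdist(
        np.stack([a.position for a in minor]), np.stack([a.position for a in major])
    ).min(axis=1)
    return [a for a, d in zip(minor, dmin) if d >= cutoff]


def minor_state_density_score(density: DensityMap, unique_atoms: list[Atom]) -> float:
    """Sum of interpolated map values at the unique-atom centers.

    Undefined (an error), not zero, for an empty atom set -- a silent zero
    would masquerade as low heterogeneity.
    """
    if not unique_atoms:
        raise UndefinedScoreError("no atoms unique to the minor state")
    centers = np.stack([a.position for a in unique_atoms])
    return float(np.sum(interpolate(density, centers)))


def normalize_profile(scores_raw) -> tuple[np.ndarray, bool]:
    """Min-max normalization to [0, 1] across temperatures.

    Returns (normalized, degenerate); a zero range maps to all zeros with
    the degeneracy flag set.
    """
    scores = np.asarray(scores_raw, dtype=float)
    if scores.size < 2:
        raise ValidationError("normalization needs at least 2 temperatures")
    lo, hi = float(scores.min()), float(scores.max())
    if hi == lo:
        return np.zeros_like(scores), True
    return (scores - lo) / (hi - lo), False


def residue_temperature_profiles(
    series: DatasetCohort,
    residue_conformer_pairs: dict[str, tuple[list[Atom], list[Atom]]],
    config: SimulationConfig | None = None,
    cutoff: float = 1.0,
) -> dict[str, TemperatureProfile]:
    """Per-residue minor-state density profiles across a temperature series.

    For each residue (given its major/minor conformer atoms): find the
    minor-state atoms unique w.r.t. the major state, sum sigma-scaled map
    density at their centers for each temperature, and min-max normalize.
    Maps are sigma-scaled before scoring, matching the sigma-contour
    convention of the statistic.
    """
    records = sorted(series.records, key=lambda r: r.temperature_K)
    temps = np.array([r.temperature_K for r in records])
    scaled = [sigma_scale(r.map) for r in records]
    out: dict[str, TemperatureProfile] = {}
    for rid, (major, minor) in residue_conformer_pairs.items():
        uniq = unique_minor_atoms(major, minor, cutoff)
        raw = np.array([minor_state_density_score(m, uniq) for m in scaled])
        norm, degenerate = normalize_profile(raw)
        out[rid] = TemperatureProfile(rid, temps, raw, norm, degenerate)
    return out


def occupancy_bimodality(
    occupancies, edge_width: float = 0.1
) -> tuple[float, str]:
    """Fraction of occupancies within ``edge_width`` of 0 or 1, and a verdict.

    A panel dominated (>= 80%) by near-edge occupancies indicates the
    residues are better described by single-state models than by partial
    occupancies ("single-state-panel"); otherwise "mixed".
    """
    occ = np.asarray(occupancies, dtype=float)
    if occ.size == 0:
        raise ValidationError("occupancy list must not be empty")
    if np.any((occ < 0) | (occ > 1)):
        raise ValidationError("occupancies must lie in [0, 1]")
    frac = float(np.mean((occ <= edge_width) | (occ >= 1.0 - edge_width)))
    return frac, ("single-state-panel" if frac >= 0.8 else "mixed")
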