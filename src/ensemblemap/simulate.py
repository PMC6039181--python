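"""Synthetic-data generators with known ground truth.

Everything the pipeline consumes can be generated here: two-state
multiconformer models, Gaussian-forward-model density maps, soak cohorts
with rare low-occupancy binders, temperature series, per-resolution-bin
quality tables, and dose-response / kinetics assay tables.

Density forward model
---------------------
Each atom contributes an isotropic Gaussian

    rho(r) = sum_atoms  occ * exp(-|r - r_atom|^2 / (2 sigma_atom^2)),

with sigma_atom^2 = B / (8 pi^2).  This is a real-space stand-in for 2Fo-Fc
synthesis that preserves the two properties the pipeline relies on:
strict linearity in occupancy (superposition) and locality.  Defaults mimic
the study conditions: ~6% of soaked crystals carry a binder at 10-30%
occupancy, temperature ladders span 100-278 K with open-state occupancies
drifting from ~0.33 to ~0.65, tethering uses nine 3-fold dilutions from
50 uM, and kinetics uses twelve 2-fold pNPP dilutions from 20 mM with
three replicates throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datasets import DatasetCohort, DatasetRecord
from .density import DensityMap
from .errors import OutOfBoundsError, ValidationError
from .structure import Atom, MulticonformerModel

EIGHT_PI_SQ = 8.0 * math.pi**2


@dataclass
class SimulationConfig:
    """Knobs of the forward model.

    grid_spacing: voxel size in A (0.5 A default -- much finer than the
    ~1.7-2.6 A resolutions being emulated, so discretization never
    dominates).  noise_sd: i.i.d. Gaussian map noise in sigma-scaled units.
    """

    seed: int = 0
    grid_spacing: float = 0.5
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.grid_spacing <= 0:
            raise ValidationError("grid_spacing must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def atom_sigma(b_factor: float) -> float:
    """Gaussian width (A) from a B-factor: sigma^2 = B / (8 pi^2)."""
    return math.sqrt(b_factor / EIGHT_PI_SQ)


# ---------------------------------------------------------------------------
# structural generators


def _coil_positions(n_residues: int, radius: float = 5.0, rise: float = 1.2,
                    turn_deg: float = 100.0) -> np.ndarray:
    """CA positions along a compact helical coil centred near the origin."""
    i = np.arange(n_residues)
    ang = np.deg2rad(turn_deg) * i
    z = rise * (i - (n_residues - 1) / 2.0)
    return np.stack([radius * np.cos(ang), radius * np.sin(ang), z], axis=1)


def make_two_state_model(
    n_residues: int,
    displacement: float,
    occ_state_a: float,
    seed: int,
    b_factor: float = 20.0,
) -> MulticonformerModel:
    """Backbone-only model whose residues each have A/B altlocs separated
    by ``displacement`` A (rigid per-residue shift in a random direction).

    With occ_state_a == 1 a single-conformer model (empty altloc) is built.
    """
    if n_residues < 1:
        raise ValidationError("n_residues must be >= 1")
    if not 0.0 <= occ_state_a <= 1.0:
        raise ValidationError("occ_state_a must be in [0, 1]")
    if displacement < 0:
        raise ValidationError("displacement must be non-negative")
    rng = np.random.default_rng(seed)
    ca = _coil_positions(n_residues)
    # N and C flank CA along the chain direction
    atoms: list[Atom] = []
    two_state = occ_state_a < 1.0
    for i in range(n_residues):
        rid = f"A{i + 1}"
        tangent = ca[min(i + 1, n_residues - 1)] - ca[max(i - 1, 0)]
        tangent = tangent / (np.linalg.norm(tangent) + 1e-12)
        local = {
            "N": ca[i] - 1.2 * tangent,
            "CA": ca[i],
            "C": ca[i] + 1.2 * tangent,
        }
        if two_state:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            shift = displacement * direction
            for name, pos in local.items():
                atoms.append(Atom(rid, name, "N" if name == "N" else "C", pos,
                                  altloc="A", occupancy=occ_state_a,
                                  b_factor=b_factor))
            for name, pos in local.items():
                atoms.append(Atom(rid, name, "N" if name == "N" else "C", pos + shift,
                                  altloc="B", occupancy=1.0 - occ_state_a,
                                  b_factor=b_factor))
        else:
            for name, pos in local.items():
                atoms.append(Atom(rid, name, "N" if name == "N" else "C", pos,
                                  altloc="", occupancy=1.0, b_factor=b_factor))
    return MulticonformerModel(atoms=atoms)


# ---------------------------------------------------------------------------
# density rendering


def auto_box(atoms: list[Atom], spacing: float, margin_sigmas: float = 4.0
             ) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Rectangular box covering all atoms with a Gaussian-tail margin."""
    coords = np.stack([a.position for a in atoms])
    sig = max(atom_sigma(a.b_factor) for a in atoms)
    lo = coords.min(axis=0) - margin_sigmas * sig - spacing
    hi = coords.max(axis=0) + margin_sigmas * sig + spacing
    lo = np.floor(lo / spacing) * spacing
    shape = tuple(int(np.ceil((hi[d] - lo[d]) / spacing)) + 1 for d in range(3))
    return lo, shape  # type: ignore[return-value]


def render_density(
    model: MulticonformerModel,
    config: SimulationConfig,
    origin: np.ndarray | None = None,
    shape: tuple[int, int, int] | None = None,
    unit_occupancy: bool = False,
) -> DensityMap:
    """Evaluate the Gaussian forward model on a grid.

    The output is linear in occupancy: rendering an occupancy-scaled union
    of models equals the same linear combination of their renders.  With
    ``unit_occupancy`` atom occupancies are ignored (treated as 1).
    """
    if not model.atoms:
        raise ValidationError("cannot render an empty model")
    sp = config.grid_spacing
    if origin is None or shape is None:
        origin, shape = auto_box(model.atoms, sp)
    origin = np.asarray(origin, dtype=float)
    spacing = np.full(3, sp)
    values = np.zeros(shape)
    axes = [origin[d] + np.arange(shape[d]) * sp for d in range(3)]
    upper = origin + (np.array(shape) - 1) * sp
    for a in model.atoms:
        if np.any(a.position < origin) or np.any(a.position > upper):
            raise OutOfBoundsError(
                f"atom {a.residue_id}/{a.atom_name} at {a.position} outside the box"
            )
        sig = atom_sigma(a.b_factor)
        occ = 1.0 if unit_occupancy else a.occupancy
        if occ == 0.0:
            continue
        cut = 4.5 * sig
        sub = []
        for d in range(3):
            i0 = max(0, int(math.ceil((a.position[d] - cut - origin[d]) / sp)))
            i1 = min(shape[d] - 1, int(math.floor((a.position[d] + cut - origin[d]) / sp)))
            if i1 < i0:
                break
            sub.append((i0, i1, np.exp(-((axes[d][i0:i1 + 1] - a.position[d]) ** 2)
                                       / (2.0 * sig * sig))))
        else:
            (x0, x1, gx), (y0, y1, gy), (z0, z1, gz) = sub
            values[x0:x1 + 1, y0:y1 + 1, z0:z1 + 1] += (
                occ * gx[:, None, None] * gy[None, :, None] * gz[None, None, :]
            )
    return DensityMap(values=values, origin=origin, spacing=spacing)


# ---------------------------------------------------------------------------
# soak cohorts


def _pocket_geometry(protein: MulticonformerModel, b_factor: float = 20.0
                     ) -> tuple[list[Atom], list[Atom], np.ndarray]:
    """Ligand and displaceable-water atoms in a solvent pocket.

    The pocket sits off the protein surface with enough clearance that
    protein density barely reaches it; the waters are what the bound state
    displaces, and they are kept >= ~2.2 A from every ligand atom so the
    two features are essentially uncorrelated on the grid.
    """
    coords = protein.coordinates()
    center = np.array([coords[:, 0].max() + 6.5,
                       float(coords[:, 1].mean()),
                       float(coords[:, 2].mean())])
    arm = 1.3
    ligand_offsets = np.array([
        [arm, 0.0, 0.0], [-arm, 0.0, 0.0], [0.0, arm, 0.0], [0.0, -arm, 0.0],
    ])
    water_offsets = np.array([[0.0, 0.0, 2.3], [0.0, 0.0, -2.3], [2.3, 0.0, 2.3]])
    ligand = [
        Atom("L900", f"C{i + 1}", "C", center + off, occupancy=1.0,
             b_factor=b_factor, res_name="LIG")
        for i, off in enumerate(ligand_offsets)
    ]
    waters = [
        Atom(f"W{90 + i}", "O", "O", center + off, occupancy=1.0,
             b_factor=b_factor, res_name="HOH")
        for i, off in enumerate(water_offsets)
    ]
    return ligand, waters, center


def simulate_soak_cohort(
    n_datasets: int,
    fraction_with_binder: float,
    bound_occ_range: tuple[float, float],
    config: SimulationConfig,
    n_residues: int = 12,
) -> DatasetCohort:
    """Cohort of maps sharing one ground state, a few carrying a rare
    low-occupancy binding event.

    Binder maps are (1-f)*ground + f*bound + noise, with the bound state
    formed by removing the pocket waters and adding the ligand, and f drawn
    uniformly from ``bound_occ_range``.  All maps share a single affine
    scaling chosen so the noise-free ground map is exactly sigma-scaled;
    a common affine transform commutes with the mixtures, so the algebraic
    event-map identities hold exactly on noise-free cohorts.

    Ground truth (planted occupancies, ligand centroid, binder ids) is
    stored on the cohort for recovery tests.
    """
    if n_datasets < 2:
        raise ValidationError("a cohort needs at least 2 datasets")
    if not 0.0 <= fraction_with_binder <= 1.0:
        raise ValidationError("fraction_with_binder must be in [0, 1]")
    lo, hi = bound_occ_range
    if not 0.0 < lo <= hi < 1.0:
        raise ValidationError("bound_occ_range must satisfy 0 < lo <= hi < 1")
    rng = config.rng()
    protein = make_two_state_model(n_residues, 0.0, 1.0, seed=config.seed)
    ligand, waters, pocket_center = _pocket_geometry(protein)
    ground_model = MulticonformerModel(atoms=protein.atoms + waters)
    bound_model = MulticonformerModel(atoms=protein.atoms + ligand)
    all_atoms = protein.atoms + waters + ligand
    origin, shape = auto_box(all_atoms, config.grid_spacing)
    g_raw = render_density(ground_model, config, origin, shape)
    b_raw = render_density(bound_model, config, origin, shape)
    mu, sd = float(g_raw.values.mean()), float(g_raw.values.std())
    ground = g_raw.with_values((g_raw.values - mu) / sd)
    bound = g_raw.with_values((b_raw.values - mu) / sd)

    n_binders = int(round(n_datasets * fraction_with_binder))
    binder_idx = set(rng.choice(n_datasets, size=n_binders, replace=False).tolist())
    ligand_centroid = np.stack([a.position for a in ligand]).mean(axis=0)

    records: list[DatasetRecord] = []
    truth: dict = {"binders": {}, "ligand_centroid": ligand_centroid,
                   "pocket_center": pocket_center}
    for i in range(n_datasets):
        ds_id = f"ds_{i:03d}"
        values = ground.values.copy()
        if i in binder_idx:
            f = float(rng.uniform(lo, hi))
            values += f * (bound.values - ground.values)
            truth["binders"][ds_id] = {"occupancy": f, "centroid": ligand_centroid}
        if config.noise_sd > 0:
            values = values + rng.normal(0.0, config.noise_sd, size=values.shape)
        records.append(
            DatasetRecord(
                dataset_id=ds_id,
                map=ground.with_values(values),
                model=None,
                temperature_K=100.0,
                soak_compound="DMSO" if i % 37 == 0 else f"frag{i:04d}",
                resolution=float(np.round(rng.uniform(1.7, 2.6), 2)),
            )
        )
    return DatasetCohort(
        records=records,
        ground_truth=truth,
        reference_maps={"ground": ground, "bound": bound,
                        "binding_difference": ground.with_values(bound.values - ground.values)},
    )


# ---------------------------------------------------------------------------
# temperature series

#: open-state occupancies mirroring the 100/180/240/278 K apo ladder
DEFAULT_TEMPERATURE_LADDER = {100.0: 0.33, 180.0: 0.45, 240.0: 0.55, 278.0: 0.65}


def simulate_temperature_series(
    occ_by_temperature: dict[float, float],
    config: SimulationConfig,
    displacement: float = 3.0,
    n_residues: int = 6,
) -> DatasetCohort:
    """One record per temperature, rendered at the given state-A occupancy.

    Maps stay on the raw forward-model scale (the occupancy fit's render
    convention); optional noise is ``config.noise_sd`` times the sd of the
    state-A render, i.e. expressed in sigma-like units.
    """
    if not occ_by_temperature:
        raise ValidationError("occ_by_temperature must not be empty")
    for occ in occ_by_temperature.values():
        if not 0.0 <= occ <= 1.0:
            raise ValidationError(f"occupancy {occ} outside [0, 1]")
    rng = config.rng()
    model = make_two_state_model(n_residues, displacement, 0.5, seed=config.seed)
    conf_a = [a.copy(occupancy=1.0) for a in model.atoms_with_altloc("A")]
    conf_b = [a.copy(occupancy=1.0) for a in model.atoms_with_altloc("B")]
    origin, shape = auto_box(model.atoms, config.grid_spacing)
    map_a = render_density(MulticonformerModel(atoms=conf_a), config, origin, shape)
    map_b = render_density(MulticonformerModel(atoms=conf_b), config, origin, shape)
    scale = float(map_a.values.std())
    records = []
    truth: dict = {"occupancy_by_T": dict(sorted(occ_by_temperature.items())),
                   "conf_a": conf_a, "conf_b": conf_b, "model": model}
    for temp in sorted(occ_by_temperature):
        occ = occ_by_temperature[temp]
        values = occ * map_a.values + (1.0 - occ) * map_b.values
        if config.noise_sd > 0:
            values = values + rng.normal(0.0, config.noise_sd * scale, size=values.shape)
        records.append(
            DatasetRecord(dataset_id=f"T{int(round(temp))}",
                          map=map_a.with_values(values), model=model,
                          temperature_K=float(temp), soak_compound="DMSO")
        )
    return DatasetCohort(records=records, ground_truth=truth,
                         reference_maps={"state_a": map_a, "state_b": map_b})


# ---------------------------------------------------------------------------
# assay tables


def serial_dilutions(start: float, factor: float, n: int) -> np.ndarray:
    """Descending serial-dilution series, e.g. nine 3-fold from 50 uM."""
    return start / factor ** np.arange(n)


@dataclass
class DoseResponseTable:
    """Concentration-response observations with replicate structure."""

    concentrations: np.ndarray  # uM, strictly positive (0 allowed for controls)
    responses: np.ndarray  # (n_doses, n_replicates)
    n_replicates: int
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if np.any(self.concentrations < 0):
            raise ValidationError("concentrations must be non-negative")
        if len(set(self.concentrations.tolist())) != len(self.concentrations):
            raise ValidationError("concentrations must be distinct")
        if self.responses.shape != (len(self.concentrations), self.n_replicates):
            raise ValidationError("responses must have shape (n_doses, n_replicates)")

    def means(self) -> np.ndarray:
        return self.responses.mean(axis=1)


@dataclass
class KineticsTable:
    """Substrate-rate observations (pNPP-style initial rates)."""

    substrate_concentrations: np.ndarray  # mM
    rates: np.ndarray  # mAU/min, (n_s, n_replicates)
    enzyme_concentration: float = 200.0  # nM
    inhibitor_concentration: float = 0.0  # uM
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.substrate_concentrations = np.asarray(self.substrate_concentrations, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if np.any(self.substrate_concentrations <= 0):
            raise ValidationError("substrate concentrations must be positive")
        if not np.all(np.isfinite(self.rates)):
            raise ValidationError("rates must be finite")

    def means(self) -> np.ndarray:
        return self.rates.mean(axis=1)


def simulate_tethering_curve(
    ec50: float,
    concentrations: np.ndarray | list[float],
    noise_sd: float,
    n_replicates: int,
    seed: int,
) -> DoseResponseTable:
    """Fractional tethering c/(EC50 + c) with Gaussian noise, clipped to [0, 1]."""
    if ec50 <= 0:
        raise ValidationError("ec50 must be positive")
    conc = np.asarray(concentrations, dtype=float)
    if conc.size == 0:
        raise ValidationError("concentration list must not be empty")
    rng = np.random.default_rng(seed)
    clean = conc / (ec50 + conc)
    resp = clean[:, None] + rng.normal(0.0, noise_sd, size=(conc.size, n_replicates))
    resp = np.clip(resp, 0.0, 1.0)
    return DoseResponseTable(conc, resp, n_replicates,
                             truth={"ec50": ec50, "noise_sd": noise_sd})


def simulate_inhibition_curve(
    ki: float,
    max_inhibition: float,
    v0: float,
    concentrations: np.ndarray | list[float],
    noise_sd: float,
    n_replicates: int,
    seed: int,
) -> DoseResponseTable:
    """Rates under partial noncompetitive inhibition:
    v(c) = v0 * (1 - Imax * c / (Ki + c)) + noise."""
    if ki <= 0:
        raise ValidationError("ki must be positive")
    if not 0.0 <= max_inhibition <= 1.0:
        raise ValidationError("max_inhibition must be in [0, 1]")
    conc = np.asarray(concentrations, dtype=float)
    if conc.size == 0:
        raise ValidationError("concentration list must not be empty")
    rng = np.random.default_rng(seed)
    clean = v0 * (1.0 - max_inhibition * conc / (ki + conc))
    resp = clean[:, None] + rng.normal(0.0, noise_sd, size=(conc.size, n_replicates))
    return DoseResponseTable(conc, resp, n_replicates,
                             truth={"ki": ki, "max_inhibition": max_inhibition, "v0": v0})


def simulate_michaelis_menten(
    vmax: float,
    km: float,
    substrate: np.ndarray | list[float],
    noise_sd: float,
    n_replicates: int,
    seed: int,
    enzyme_concentration: float = 200.0,
) -> KineticsTable:
    """Michaelis-Menten rates v = Vmax*S/(Km+S) + noise."""
    if vmax <= 0 or km <= 0:
        raise ValidationError("vmax and km must be positive")
    sub = np.asarray(substrate, dtype=float)
    if sub.size == 0:
        raise ValidationError("substrate list must not be empty")
    rng = np.random.default_rng(seed)
    clean = vmax * sub / (km + sub)
    rates = clean[:, None] + rng.normal(0.0, noise_sd, size=(sub.size, n_replicates))
    return KineticsTable(sub, rates, enzyme_concentration=enzyme_concentration,
                         truth={"vmax": vmax, "km": km})


# ---------------------------------------------------------------------------
# per-resolution-bin quality tables


@dataclass
class StatProfile:
    """Logistic decay of one merging statistic with resolution.

    value(d) = low + (high - low) / (1 + exp(-(d - d_cross) / width)); with
    d in A, the statistic decays monotonically toward higher resolution
    (smaller d) and crosses halfway at d_cross.
    """

    high: float
    low: float
    d_cross: float
    width: float = 0.03

    def __call__(self, d: np.ndarray | float) -> np.ndarray | float:
        d = np.asarray(d, dtype=float)
        return self.low + (self.high - self.low) / (1.0 + np.exp(-(d - self.d_cross) / self.width))


@dataclass
class BinProfile:
    """Decay parameters for the three cutoff criteria statistics."""

    i_over_sigma: StatProfile = field(default_factory=lambda: StatProfile(25.0, 0.2, 1.9))
    cc_half: StatProfile = field(default_factory=lambda: StatProfile(0.998, 0.05, 1.8))
    completeness: StatProfile = field(default_factory=lambda: StatProfile(99.5, 99.0, 2.0))
    d_max: float = 3.0
    d_min: float = 1.3


@dataclass
class ResolutionBinTable:
    """Per-bin merging statistics, finest bin last (edges decreasing in A)."""

    resolution_bin_edge: np.ndarray
    i_over_sigma: np.ndarray
    cc_half: np.ndarray
    completeness: np.ndarray

    def __post_init__(self) -> None:
        self.resolution_bin_edge = np.asarray(self.resolution_bin_edge, dtype=float)
        self.i_over_sigma = np.asarray(self.i_over_sigma, dtype=float)
        self.cc_half = np.asarray(self.cc_half, dtype=float)
        self.completeness = np.asarray(self.completeness, dtype=float)
        if np.any(np.diff(self.resolution_bin_edge) >= 0):
            raise ValidationError("bin edges must be strictly decreasing in A")
        if np.any((self.cc_half < -1) | (self.cc_half > 1)):
            raise ValidationError("CC1/2 must lie in [-1, 1]")
        if np.any((self.completeness < 0) | (self.completeness > 100)):
            raise ValidationError("completeness must lie in [0, 100]")

    def __len__(self) -> int:
        return len(self.resolution_bin_edge)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "resolution_bin_edge": self.resolution_bin_edge,
            "i_over_sigma": self.i_over_sigma,
            "cc_half": self.cc_half,
            "completeness": self.completeness,
        })


def simulate_bin_table(profile: BinProfile, bins: int) -> ResolutionBinTable:
    """Evaluate the decay profiles on ``bins`` edges from d_max down to d_min."""
    if bins < 1:
        raise ValidationError("bins must be >= 1")
    edges = np.linspace(profile.d_max, profile.d_min, bins)
    return ResolutionBinTable(
        resolution_bin_edge=edges,
        i_over_sigma=np.asarray(profile.i_over_sigma(edges)),
        cc_half=np.clip(np.asarray(profile.cc_half(edges)), -1.0, 1.0),
        completeness=np.clip(np.asarray(profile.completeness(edges)), 0.0, 100.0),
    )


def simulate_soak_results_table(
    n_soaks: int = 120,
    fail_fraction: float = 0.10,
    seed: int = 0,
):
    """Synthetic stand-in for a soak-results summary table.

    Columns mirror a fragment-soaking campaign export (dataset id,
    temperature, resolution with missing entries for failed soaks, fragment
    name, SMILES, library, modeled occupancy, PDB id).  Purely synthetic;
    used to exercise the parsing/summary code path.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    n_fail = int(round(n_soaks * fail_fraction))
    failed = set(rng.choice(n_soaks, size=n_fail, replace=False).tolist())
    for i in range(n_soaks):
        is_dmso = i % 40 == 0
        bound = (not is_dmso) and (i not in failed) and rng.uniform() < 0.06
        rows.append({
            "dataset_id": f"soak_{i:04d}",
            "temperature_K": 100.0,
            "resolution": None if i in failed else float(np.round(rng.gamma(40, 0.052) + 0.1, 2)),
            "fragment": "DMSO" if is_dmso else f"frag{i:04d}",
            "smiles": "" if is_dmso else "c1ccccc1",
            "library": "none" if is_dmso else "synthetic-set",
            "occupancy": float(np.round(rng.uniform(0.1, 0.3), 2)) if bound else None,
            "pdb_id": f"9X{i:02d}"[:4] if bound else None,
        })
    return pd.DataFrame(rows)
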