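"""Ground + bound ensemble construction.

Merges a ground-state and a bound-state model of the same crystal into one
multiconformer ensemble using per-residue all-atom RMSD rules (merge very
similar conformers; restrain somewhat similar ones to identical
coordinates; leave distinct ones free), assigns state occupancies from the
event-map occupancy, and measures the global backbone RMSD between states.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .errors import AlignmentError, RepresentationError, ValidationError
from .structure import Atom, MulticonformerModel, write_multiconformer_model

#: assigned bound occupancy = OCC_FACTOR * event-map occupancy (1 - BDC)
OCC_FACTOR = 2.2
#: total bound occupancy at or above this triggers the inspection flag
INSPECTION_THRESHOLD = 0.5
#: cap keeping ground + bound totals physical when the factor overshoots
BOUND_TOTAL_CAP = 0.95

_GROUND_ALTLOCS = "AB"
_BOUND_ALTLOCS = "CD"


@dataclass
class MergeConfig:
    """RMSD thresholds (A): below ``prune_rms`` conformers are merged into
    one; between ``prune_rms`` and ``restrain_rms`` they stay separate but
    their coordinates are restrained to be identical; above, free."""

    prune_rms: float = 0.2
    restrain_rms: float = 0.4

    def __post_init__(self) -> None:
        if not 0.0 < self.prune_rms < self.restrain_rms:
            raise ValidationError("need 0 < prune_rms < restrain_rms")


class MergeStatus(Enum):
    MERGED = "merged"
    RESTRAINED = "restrained"
    FREE = "free"
    GROUND_ONLY = "ground-only"
    BOUND_ONLY = "bound-only"


AtomKey = tuple[str, str, str]  # (residue_id, atom_name, altloc)


@dataclass
class EnsembleModel:
    model: MulticonformerModel
    restraint_pairs: list[tuple[AtomKey, AtomKey]] = field(default_factory=list)
    residue_status: dict[str, MergeStatus] = field(default_factory=dict)
    bound_occupancy_total: float | None = None
    inspection_flag: bool = False


def _conformers(model: MulticonformerModel, residue_id: str) -> dict[str, list[Atom]]:
    out: dict[str, list[Atom]] = {}
    for a in model.atoms:
        if a.residue_id == residue_id:
            out.setdefault(a.altloc, []).append(a)
    return out


def _residue_rmsd(a_atoms: list[Atom], b_atoms: list[Atom]) -> float:
    """All-atom (non-hydrogen) RMSD between two conformers of one residue,
    matched by atom name, in the shared crystal frame (no superposition)."""
    a_map = {x.atom_name: x for x in a_atoms if x.element != "H"}
    b_map = {x.atom_name: x for x in b_atoms if x.element != "H"}
    if set(a_map) != set(b_map):
        raise AlignmentError(
            f"atom names differ between states for residue {a_atoms[0].residue_id}"
        )
    d2 = [float(np.sum((a_map[n].position - b_map[n].position) ** 2)) for n in a_map]
    return float(np.sqrt(np.mean(d2)))


def merge_conformations(
    ground: MulticonformerModel,
    bound: MulticonformerModel,
    config: MergeConfig | None = None,
) -> EnsembleModel:
    """Build the ensemble model from ground and bound single-crystal models.

    Per residue present in both states with a single conformer each:
    RMSD < prune_rms      -> one shared conformer (ground coordinates);
    RMSD < restrain_rms   -> two conformers plus per-atom restraint pairs;
    otherwise             -> two free conformers.
    Residues where either state already has alternate conformations, and
    residues present in only one state (e.g. the ligand), are carried as-is
    for that state.  Thresholds are half-open: [0, prune), [prune, restrain).
    """
    config = config or MergeConfig()
    ground_res = ground.residues()
    bound_res = bound.residues()
    atoms: list[Atom] = []
    restraints: list[tuple[AtomKey, AtomKey]] = []
    status: dict[str, MergeStatus] = {}
    used_ground_alts: set[str] = set()
    used_bound_alts: set[str] = set()

    all_rids = list(ground_res) + [r for r in bound_res if r not in ground_res]
    for rid in all_rids:
        g_conf = _conformers(ground, rid) if rid in ground_res else {}
        b_conf = _conformers(bound, rid) if rid in bound_res else {}

        def add_state(confs: dict[str, list[Atom]], alphabet: str, used: set[str]) -> None:
            if len(confs) > len(alphabet):
                raise RepresentationError(
                    f"residue {rid} needs more than {len(alphabet)} conformers per state"
                )
            for alt, (_, conf_atoms) in zip(alphabet, sorted(confs.items())):
                used.add(alt)
                atoms.extend(a.copy(altloc=alt) for a in conf_atoms)

        if not b_conf:
            status[rid] = MergeStatus.GROUND_ONLY
            add_state(g_conf, _GROUND_ALTLOCS, used_ground_alts)
            continue
        if not g_conf:
            status[rid] = MergeStatus.BOUND_ONLY
            add_state(b_conf, _BOUND_ALTLOCS, used_bound_alts)
            continue
        if len(g_conf) > 1 or len(b_conf) > 1:
            status[rid] = MergeStatus.FREE
            add_state(g_conf, _GROUND_ALTLOCS, used_ground_alts)
            add_state(b_conf, _BOUND_ALTLOCS, used_bound_alts)
            continue

        (g_atoms,) = g_conf.values()
        (b_atoms,) = b_conf.values()
        rmsd = _residue_rmsd(g_atoms, b_atoms)
        if rmsd < config.prune_rms:
            status[rid] = MergeStatus.MERGED
            atoms.extend(a.copy(altloc="", occupancy=1.0) for a in g_atoms)
        else:
            status[rid] = (
                MergeStatus.RESTRAINED if rmsd < config.restrain_rms else MergeStatus.FREE
            )
            used_ground_alts.add("A")
            used_bound_alts.add("C")
            atoms.extend(a.copy(altloc="A") for a in g_atoms)
            atoms.extend(a.copy(altloc="C") for a in b_atoms)
            if status[rid] is MergeStatus.RESTRAINED:
                b_names = {a.atom_name for a in b_atoms if a.element != "H"}
                restraints.extend(
                    ((rid, a.atom_name, "A"), (rid, a.atom_name, "C"))
                    for a in g_atoms
                    if a.atom_name in b_names
                )

    model = MulticonformerModel(
        atoms=atoms,
        state_altlocs={
            "ground": tuple(sorted(used_ground_alts)),
            "bound": tuple(sorted(used_bound_alts)),
        },
    )
    return EnsembleModel(model=model, restraint_pairs=restraints, residue_status=status)


def assign_occupancies(ensemble: EnsembleModel, event_occupancy: float) -> EnsembleModel:
    """Set state occupancies from the event-map occupancy (1 - BDC).

    bound total = min(2.2 * event_occupancy, 0.95); ground total is the
    complement; within each state, each residue's occupancy is divided
    evenly among that state's alternate conformers.  Ensembles whose bound
    total reaches 50% are flagged for manual inspection.
    """
    if event_occupancy < 0:
        raise ValidationError("event_occupancy must be non-negative")
    if event_occupancy >= 1:
        raise ValidationError("event_occupancy must be < 1")
    bound_total = min(OCC_FACTOR * event_occupancy, BOUND_TOTAL_CAP)
    ground_total = 1.0 - bound_total
    ensemble.bound_occupancy_total = bound_total
    ensemble.inspection_flag = bound_total >= INSPECTION_THRESHOLD

    ground_alts = set(ensemble.model.state_altlocs.get("ground", ()))
    bound_alts = set(ensemble.model.state_altlocs.get("bound", ()))
    by_residue: dict[str, list[Atom]] = ensemble.model.residues()
    for rid, res_atoms in by_residue.items():
        g_alts_here = sorted({a.altloc for a in res_atoms if a.altloc in ground_alts})
        b_alts_here = sorted({a.altloc for a in res_atoms if a.altloc in bound_alts})
        for a in res_atoms:
            if a.altloc == "":
                a.occupancy = 1.0
            elif a.altloc in ground_alts:
                total = ground_total if b_alts_here else 1.0
                a.occupancy = total / len(g_alts_here)
            elif a.altloc in bound_alts:
                total = bound_total if g_alts_here else bound_total
                a.occupancy = total / len(b_alts_here)
    return ensemble


def backbone_rmsd(state_a: MulticonformerModel, state_b: MulticonformerModel) -> float:
    """Global backbone RMSD over matched N, CA, C atoms of shared residues,
    in the common crystal frame (no superposition)."""
    from .structure import match_atoms

    pa, pb, _ = match_atoms(state_a, state_b, names={"N", "CA", "C"})
    return float(np.sqrt(np.mean(np.sum((pa - pb) ** 2, axis=1))))


def emit_ensemble(ensemble: EnsembleModel, path) -> None:
    """Write the ensemble in the altloc dialect with the state side table.

    Residues carry one conformer (fully merged) or up to four altlocs
    (ground A/B + bound C/D); per-residue occupancies must already be
    assigned and sum to 1.
    """
    if ensemble.bound_occupancy_total is None:
        raise ValidationError("occupancies must be assigned before emitting")
    for rid, res_atoms in ensemble.model.residues().items():
        n_conf = len({a.altloc for a in res_atoms if a.altloc})
        if n_conf > 4:
            raise RepresentationError(f"residue {rid} has {n_conf} > 4 conformers")
    write_multiconformer_model(ensemble.model, path)
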