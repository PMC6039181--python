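"""Multiconformer structural models and PDB-dialect I/O.

A :class:`MulticonformerModel` is an ordered collection of :class:`Atom`
records in which alternate conformations of a residue carry distinct
altloc labels and partial occupancies.  Ground/bound state membership of
altlocs is carried in a side table (``state_altlocs``) and serialized as
``REMARK 399 STATE`` lines, never in the atom records themselves.

All coordinates are orthogonal Cartesian angstroms; maps and models share
one frame (no crystallographic symmetry handling).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from .errors import AlignmentError, ParseError, ValidationError

_RESIDUE_ID_RE = re.compile(r"^([A-Za-z0-9]+?)(-?\d+)$")
_STATE_REMARK_PREFIX = "REMARK 399 STATE"

OCC_TOL = 1e-6


@dataclass(eq=False)
class Atom:
    """One atom record.

    ``residue_id`` is a chain letter plus residue number ("A12").
    ``altloc`` is a single character, or "" for a sole conformer.
    Occupancy is a fraction of unit cells; B-factor is in A^2 and sets the
    Gaussian width used by the forward density model (sigma^2 = B/(8 pi^2)).
    """

    residue_id: str
    atom_name: str
    element: str
    position: np.ndarray
    altloc: str = ""
    occupancy: float = 1.0
    b_factor: float = 20.0
    res_name: str = "ALA"

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValidationError(f"position must be a 3-vector, got {self.position.shape}")
        if not 0.0 <= self.occupancy <= 1.0 + OCC_TOL:
            raise ValidationError(
                f"occupancy {self.occupancy} outside [0, 1] for atom "
                f"{self.residue_id}/{self.atom_name}/{self.altloc!r}"
            )
        if self.b_factor < 0:
            raise ValidationError(f"negative B-factor {self.b_factor}")
        if len(self.altloc) > 1:
            raise ValidationError(f"altloc must be one character, got {self.altloc!r}")

    def key(self) -> tuple[str, str, str]:
        """Identity of the atom within a model: (residue, name, altloc)."""
        return (self.residue_id, self.atom_name, self.altloc)

    def copy(self, **changes) -> "Atom":
        if "position" not in changes:
            changes["position"] = self.position.copy()
        return replace(self, **changes)


def split_residue_id(residue_id: str) -> tuple[str, int]:
    """Split "A12" into ("A", 12)."""
    m = _RESIDUE_ID_RE.match(residue_id)
    if m is None:
        raise ValidationError(f"cannot parse residue id {residue_id!r}")
    return m.group(1), int(m.group(2))


@dataclass
class MulticonformerModel:
    """An ordered atom list plus the ground/bound state side table.

    ``state_altlocs`` maps a state label ("ground", "bound") to the tuple of
    altloc characters belonging to that state.  Atoms with altloc "" are
    shared between states.
    """

    atoms: list[Atom] = field(default_factory=list)
    state_altlocs: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.atoms)

    def residues(self) -> dict[str, list[Atom]]:
        """Atoms grouped by residue id, preserving record order."""
        out: dict[str, list[Atom]] = {}
        for a in self.atoms:
            out.setdefault(a.residue_id, []).append(a)
        return out

    def conformer_groups(self) -> dict[tuple[str, str], list[Atom]]:
        """Mapping (state, altloc) -> atoms, derived from the side table."""
        groups: dict[tuple[str, str], list[Atom]] = {}
        for state, alts in self.state_altlocs.items():
            for alt in alts:
                groups[(state, alt)] = [a for a in self.atoms if a.altloc == alt]
        return groups

    def atoms_with_altloc(self, altloc: str) -> list[Atom]:
        return [a for a in self.atoms if a.altloc == altloc]

    def state_atoms(self, state: str) -> list[Atom]:
        """Atoms belonging to a state: its altlocs plus shared ("") atoms."""
        alts = set(self.state_altlocs.get(state, ()))
        return [a for a in self.atoms if a.altloc == "" or a.altloc in alts]

    def coordinates(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.stack([a.position for a in self.atoms])

    def validate(self) -> None:
        """Check the per-residue occupancy invariant.

        For each (residue, atom name), the occupancies of alternate
        conformers must sum to at most 1 (+ tolerance).
        """
        sums: dict[tuple[str, str], float] = {}
        for a in self.atoms:
            if a.altloc:
                k = (a.residue_id, a.atom_name)
                sums[k] = sums.get(k, 0.0) + a.occupancy
        for (rid, name), s in sums.items():
            if s > 1.0 + 1e-6 + OCC_TOL:
                raise ValidationError(
                    f"altloc occupancies of {rid}/{name} sum to {s:.4f} > 1"
                )

    def copy(self) -> "MulticonformerModel":
        return MulticonformerModel(
            atoms=[a.copy() for a in self.atoms],
            state_altlocs=dict(self.state_altlocs),
        )


def models_equal(a: MulticonformerModel, b: MulticonformerModel, atol: float = 5e-3) -> bool:
    """Field-wise equality up to the file-format precision (used by tests
    and the CLI validator; coordinates to 1e-3 A, occupancies/B to 1e-2)."""
    if len(a.atoms) != len(b.atoms) or a.state_altlocs != b.state_altlocs:
        return False
    for x, y in zip(a.atoms, b.atoms):
        if (x.residue_id, x.atom_name, x.element, x.altloc) != (
            y.residue_id,
            y.atom_name,
            y.element,
            y.altloc,
        ):
            return False
        if not np.allclose(x.position, y.position, atol=atol):
            return False
        if abs(x.occupancy - y.occupancy) > 1e-2 + 1e-9:
            return False
        if abs(x.b_factor - y.b_factor) > 1e-2 + 1e-9:
            return False
    return True


def _prescan_pdb_lines(lines: list[str]) -> None:
    """Fail early, naming the line, on malformed fixed-width atom records."""
    for i, line in enumerate(lines, start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line.rstrip("\n")) < 54:
            raise ParseError(f"line {i}: atom record shorter than coordinate fields")
        try:
            float(line[30:38])
            float(line[38:46])
            float(line[46:54])
            occ = float(line[54:60]) if line[54:60].strip() else 1.0
            if line[60:66].strip():
                float(line[60:66])
        except ValueError as exc:
            raise ParseError(f"line {i}: malformed atom record ({exc})") from exc
        if not 0.0 <= occ <= 1.0 + OCC_TOL:
            raise ValidationError(f"line {i}: occupancy {occ} outside [0, 1]")


def _parse_state_remarks(lines: list[str]) -> dict[str, tuple[str, ...]]:
    states: dict[str, list[str]] = {}
    for line in lines:
        if line.startswith(_STATE_REMARK_PREFIX):
            parts = line.split()
            # REMARK 399 STATE <altloc> <label>
            if len(parts) >= 5:
                alt, label = parts[3], parts[4]
                states.setdefault(label, []).append(alt)
    return {k: tuple(v) for k, v in states.items()}


def read_multiconformer_model(path) -> MulticonformerModel:
    """Read a model from the classic PDB altloc dialect.

    Altlocs, occupancies, B-factors, coordinates and record order are
    preserved; ``REMARK 399 STATE`` lines populate the state side table.
    """
    with open(path) as fh:
        lines = fh.readlines()
    _prescan_pdb_lines(lines)
    state_altlocs = _parse_state_remarks(lines)
    try:
        st = gemmi.read_pdb_string("".join(lines))
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi detail
        raise ParseError(f"failed to parse {path}: {exc}") from exc
    atoms: list[Atom] = []
    if len(st) > 0:
        for chain in st[0]:
            for res in chain:
                for at in res:
                    alt = at.altloc if at.altloc not in ("", "\x00", " ") else ""
                    atoms.append(
                        Atom(
                            residue_id=f"{chain.name}{res.seqid.num}",
                            atom_name=at.name,
                            element=at.element.name,
                            position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                            altloc=alt,
                            occupancy=round(float(at.occ), 4),
                            b_factor=float(at.b_iso),
                            res_name=res.name,
                        )
                    )
    return MulticonformerModel(atoms=atoms, state_altlocs=state_altlocs)


def write_multiconformer_model(model: MulticonformerModel, path) -> None:
    """Write the altloc dialect; refuses models violating occupancy sums.

    Occupancies are emitted to 2 decimal places, matching deposition
    practice, so write-then-read equality holds at that precision.
    """
    model.validate()
    # group atoms by chain and residue, preserving first-seen order
    # (gemmi's add_* methods copy their argument, so build bottom-up)
    chains: dict[str, dict[int, list[Atom]]] = {}
    res_names: dict[tuple[str, int], str] = {}
    for a in model.atoms:
        chain_name, seqnum = split_residue_id(a.residue_id)
        chains.setdefault(chain_name, {}).setdefault(seqnum, []).append(a)
        res_names.setdefault((chain_name, seqnum), a.res_name)
    st = gemmi.Structure()
    st.name = "ensemblemap"
    gmodel = gemmi.Model("1")
    for chain_name, residues in chains.items():
        chain = gemmi.Chain(chain_name)
        for seqnum, res_atoms in residues.items():
            res = gemmi.Residue()
            res.name = res_names[(chain_name, seqnum)]
            res.seqid = gemmi.SeqId(seqnum, " ")
            for a in res_atoms:
                at = gemmi.Atom()
                at.name = a.atom_name
                at.element = gemmi.Element(a.element)
                at.altloc = a.altloc if a.altloc else "\x00"
                at.occ = round(a.occupancy, 2)
                at.b_iso = a.b_factor
                at.pos = gemmi.Position(*a.position)
                res.add_atom(at)
            chain.add_residue(res)
        gmodel.add_chain(chain)
    st.add_model(gmodel)
    remarks = [
        f"{_STATE_REMARK_PREFIX} {alt} {state}"
        for state, alts in model.state_altlocs.items()
        for alt in alts
    ]
    st.raw_remarks = remarks
    with open(path, "w") as fh:
        fh.write(st.make_pdb_string())


def match_atoms(
    a: MulticonformerModel,
    b: MulticonformerModel,
    names: set[str] | None = None,
    altloc_a: str | None = None,
    altloc_b: str | None = None,
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, str]]]:
    """Pair atoms of two models by (residue_id, atom_name).

    Used by backbone RMSD and merge logic; raises AlignmentError when no
    atoms can be matched.
    """

    def index(m: MulticonformerModel, altloc: str | None) -> dict[tuple[str, str], Atom]:
        out = {}
        for at in m.atoms:
            if names is not None and at.atom_name not in names:
                continue
            if altloc is not None and at.altloc != altloc:
                continue
            k = (at.residue_id, at.atom_name)
            out.setdefault(k, at)
        return out

    ia, ib = index(a, altloc_a), index(b, altloc_b)
    keys = [k for k in ia if k in ib]
    if not keys:
        raise AlignmentError("no atoms could be matched between the two models")
    pa = np.stack([ia[k].position for k in keys])
    pb = np.stack([ib[k].position for k in keys])
    return pa, pb, keys
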