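"""Dataset-level quality control and binding-site clustering.

Covers the iterative high-resolution cutoff heuristic (start at 1.4 A,
step outward until the highest-resolution bin passes I/sigma >= 1.0,
CC1/2 >= 0.50 and completeness >= 90%), cohort resolution summaries,
ligand contact-residue determination, and single-linkage clustering of
fragment contact sets into non-overlapping binding sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import NoAcceptableCutoffError, ValidationError
from .simulate import ResolutionBinTable
from .structure import Atom, MulticonformerModel


@dataclass
class QcCriteria:
    min_i_over_sigma: float = 1.0
    min_cc_half: float = 0.50
    min_completeness: float = 90.0  # percent
    initial_cutoff: float = 1.4  # A
    increment: float = 0.05  # A

    def __post_init__(self) -> None:
        if min(self.min_i_over_sigma, self.min_completeness,
               self.initial_cutoff, self.increment) <= 0:
            raise ValidationError("criteria thresholds must be positive")


@dataclass
class BindingSite:
    site_id: int
    member_fragments: list[str]
    contact_residues: frozenset[str]


def choose_resolution_cutoff(table: ResolutionBinTable, criteria: QcCriteria | None = None
                             ) -> float:
    """Smallest cutoff >= initial_cutoff (stepping by ``increment``) whose
    highest-resolution bin jointly satisfies all three criteria.

    At cutoff c the highest-resolution bin is the table row with the
    smallest edge >= c.  Raises when no cutoff inside the table's range
    works.
    """
    criteria = criteria or QcCriteria()
    edges = table.resolution_bin_edge
    if edges.min() > criteria.initial_cutoff + 1e-9:
        raise ValidationError(
            f"table (finest bin {edges.min():.2f} A) does not span the "
            f"initial cutoff {criteria.initial_cutoff:.2f} A"
        )
    cutoff = criteria.initial_cutoff
    while cutoff <= edges.max() + 1e-9:
        candidates = np.nonzero(edges >= cutoff - 1e-9)[0]
        row = candidates[np.argmin(edges[candidates])]
        if (
            table.i_over_sigma[row] >= criteria.min_i_over_sigma
            and table.cc_half[row] >= criteria.min_cc_half
            and table.completeness[row] >= criteria.min_completeness
        ):
            return round(cutoff, 10)
        cutoff += criteria.increment
    raise NoAcceptableCutoffError("no cutoff within the table satisfies the criteria")


def cohort_resolution_summary(
    resolutions, thresholds: tuple[float, ...] = (2.0, 2.5)
) -> tuple[float, dict[float, float]]:
    """Arithmetic mean resolution and, per threshold t, the fraction of
    datasets better (numerically smaller) than t."""
    res = np.asarray([r for r in resolutions if r is not None and np.isfinite(r)], dtype=float)
    if res.size == 0:
        raise ValidationError("resolution list must not be empty")
    if np.any(res <= 0):
        raise ValidationError("resolutions must be positive")
    return float(res.mean()), {t: float(np.mean(res < t)) for t in thresholds}


def parse_soak_results(source) -> pd.DataFrame:
    """Load a soak-results table (CSV path or DataFrame).

    Expected columns: dataset_id, temperature_K, resolution (empty for
    failed soaks), fragment, smiles, library, occupancy, pdb_id.
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    missing = {"dataset_id", "resolution"} - set(df.columns)
    if missing:
        raise ValidationError(f"soak table lacks columns: {sorted(missing)}")
    return df


def soak_campaign_summary(df: pd.DataFrame) -> dict:
    """Headline numbers of a soaking campaign: totals, processed datasets
    (those with a resolution), bound entries (those with a modeled
    occupancy), and the resolution summary over processed datasets."""
    processed = df[df["resolution"].notna()]
    mean_res, better = cohort_resolution_summary(processed["resolution"].tolist())
    bound = df[df["occupancy"].notna()] if "occupancy" in df.columns else df.iloc[0:0]
    return {
        "n_total": int(len(df)),
        "n_processed": int(len(processed)),
        "n_bound": int(len(bound)),
        "mean_resolution": mean_res,
        "fraction_better_than": better,
    }


def fragment_contact_residues(
    model: MulticonformerModel,
    ligand_atoms: list[Atom],
    contact_cutoff: float = 4.0,
) -> frozenset[str]:
    """Residues with any heavy atom within ``contact_cutoff`` A (inclusive)
    of any ligand atom."""
    if not ligand_atoms:
        raise ValidationError("ligand_atoms must be nonempty")
    heavy = [a for a in model.atoms if a.element != "H"]
    if not heavy:
        return frozenset()
    d = cdist(
        np.stack([a.position for a in heavy]),
        np.stack([a.position for a in ligand_atoms]),
    ).min(axis=1)
    return frozenset(a.residue_id for a, dist in zip(heavy, d) if dist <= contact_cutoff)


def cluster_sites(contact_sets: dict[str, frozenset[str]]) -> list[BindingSite]:
    """Single-linkage clustering of fragments into non-overlapping sites.

    Fragments sharing at least one contact residue belong to the same site
    (closed transitively); a site's contact set is the union over members.
    Sites are numbered from 1 by descending member count, ties broken by
    the smallest residue id in the site.
    """
    frags = sorted(contact_sets)
    for f in frags:
        if not contact_sets[f]:
            raise ValidationError(f"fragment {f} has an empty contact set")
    parent = {f: f for f in frags}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    residue_owner: dict[str, str] = {}
    for f in frags:
        for res in contact_sets[f]:
            if res in residue_owner:
                ra, rb = find(residue_owner[res]), find(f)
                if ra != rb:
                    parent[rb] = ra
            else:
                residue_owner[res] = f

    groups: dict[str, list[str]] = {}
    for f in frags:
        groups.setdefault(find(f), []).append(f)
    sites = [
        (sorted(members), frozenset().union(*(contact_sets[m] for m in members)))
        for members in groups.values()
    ]
    sites.sort(key=lambda s: (-len(s[0]), min(s[1])))
    return [
        BindingSite(site_id=i + 1, member_fragments=members, contact_residues=residues)
        for i, (members, residues) in enumerate(sites)
    ]
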