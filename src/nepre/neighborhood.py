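"""Residue-residue contact enumeration under fixed or radius-sum cutoffs.

Two residues are neighbors when the distance between their geometric centers
is at or below the applicable cutoff: either one universal fixed radius
(default 6 A) or the sum of the two residue-type radii (the shipped defaults
come from a non-redundant structure survey).  Contacts are *ordered*: the
pair (m, n) is recorded in m's local frame and (n, m) in n's, because each
residue's own neighborhood contributes separately to the total energy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.spatial.distance import cdist

from .errors import DegenerateFrameError, IncompleteBackboneError
from .geometry import SphericalPoint, build_local_frame, local_spherical_arrays
from .structure_io import AA_INDEX, STANDARD_AA3, ProteinChain

logger = logging.getLogger(__name__)

#: Per-type amino-acid radii (A) shipped as the radius-sum cutoff defaults;
#: mean residue radii extracted from a non-redundant structure set.
DEFAULT_RADII: dict[str, float] = {
    "ALA": 3.20, "ARG": 5.60, "ASN": 4.04, "ASP": 4.04, "CYS": 3.65,
    "GLN": 4.64, "GLU": 4.63, "GLY": 1.72, "HIS": 4.73, "ILE": 3.94,
    "LEU": 4.24, "LYS": 5.02, "MET": 4.47, "PHE": 4.99, "PRO": 3.61,
    "SER": 3.39, "THR": 3.56, "TRP": 5.38, "TYR": 5.36, "VAL": 3.55,
}

#: Default universal fixed cutoff (A); the operating point used for scoring.
DEFAULT_FIXED_CUTOFF = 6.0


@dataclass(frozen=True)
class CutoffScheme:
    """Neighborhood definition: ``fixed`` (one radius) or ``radius_sum``.

    In ``radius_sum`` mode the cutoff for a type pair (i, j) is
    ``radii[i] + radii[j]``; ``radii`` defaults to :data:`DEFAULT_RADII`.
    """

    mode: str = "fixed"
    r_fixed: float = DEFAULT_FIXED_CUTOFF
    radii: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "radius_sum"):
            raise ValueError(f"unknown cutoff mode {self.mode!r}")
        if not self.r_fixed > 0:
            raise ValueError("r_fixed must be positive")
        radii = dict(DEFAULT_RADII) if self.radii is None else dict(self.radii)
        if set(radii) != set(STANDARD_AA3):
            missing = set(STANDARD_AA3) - set(radii)
            extra = set(radii) - set(STANDARD_AA3)
            raise ValueError(f"radii table must cover exactly 20 types (missing={missing}, extra={extra})")
        if any(not v > 0 for v in radii.values()):
            raise ValueError("all radii must be positive")
        object.__setattr__(self, "radii", radii)

    def pair_cutoff(self, type_i: str, type_j: str) -> float:
        """Cutoff (A) for the ordered pair (i, j); symmetric in its arguments."""
        if type_i not in AA_INDEX or type_j not in AA_INDEX:
            bad = type_i if type_i not in AA_INDEX else type_j
            raise KeyError(f"unknown residue type {bad!r}")
        if self.mode == "fixed":
            return self.r_fixed
        return self.radii[type_i] + self.radii[type_j]

    def cutoff_matrix(self, types: list[str]) -> np.ndarray:
        """(n, n) cutoff matrix for a list of residue types."""
        if self.mode == "fixed":
            return np.full((len(types), len(types)), self.r_fixed)
        r = np.array([self.radii[t] for t in types])
        return r[:, None] + r[None, :]

    @property
    def max_cutoff(self) -> float:
        if self.mode == "fixed":
            return self.r_fixed
        return 2.0 * max(self.radii.values())


def pair_cutoff(scheme: CutoffScheme, type_i: str, type_j: str) -> float:
    """Module-level convenience wrapper around :meth:`CutoffScheme.pair_cutoff`."""
    return scheme.pair_cutoff(type_i, type_j)


@dataclass(frozen=True)
class ContactRecord:
    """One ordered observation: neighbor j seen from center i's local frame."""

    center_type: str
    neighbor_type: str
    sph: SphericalPoint
    center_seq: tuple[int, str]
    neighbor_seq: tuple[int, str]


def chain_frames(chain: ProteinChain) -> list:
    """Local frame per residue, ``None`` where construction fails (logged)."""
    frames = []
    n_failed = 0
    for res in chain.residues:
        try:
            frames.append(build_local_frame(res))
        except (IncompleteBackboneError, DegenerateFrameError):
            frames.append(None)
            n_failed += 1
    if n_failed:
        logger.warning(
            "chain %s: %d/%d residues skipped as centers (no valid frame)",
            chain.chain_id, n_failed, len(chain.residues),
        )
    return frames


def enumerate_contacts(
    chain: ProteinChain,
    scheme: CutoffScheme | None = None,
    include_adjacent: bool = True,
) -> list[ContactRecord]:
    """All ordered contacts of a chain with local spherical coordinates.

    A residue without a valid frame still counts as a *neighbor* of others;
    it is only skipped as a *center*.  With ``include_adjacent=False``,
    residues adjacent in the chain (consecutive positions in sequence order)
    are not paired.  The boundary is inclusive: distance == cutoff counts.
    """
    scheme = scheme or CutoffScheme()
    n = len(chain.residues)
    if n < 2:
        return []
    types = [r.res_type for r in chain.residues]
    centers = chain.centers()
    dist = cdist(centers, centers)
    within = dist <= scheme.cutoff_matrix(types)
    np.fill_diagonal(within, False)
    if not include_adjacent:
        idx = np.arange(n)
        adjacent = np.abs(idx[:, None] - idx[None, :]) == 1
        within &= ~adjacent

    frames = chain_frames(chain)
    records: list[ContactRecord] = []
    for m in range(n):
        if frames[m] is None:
            continue
        nbrs = np.nonzero(within[m])[0]
        if nbrs.size == 0:
            continue
        r, theta, phi = local_spherical_arrays(frames[m], centers[nbrs])
        for k, nb in enumerate(nbrs):
            records.append(
                ContactRecord(
                    center_type=types[m],
                    neighbor_type=types[nb],
                    sph=SphericalPoint(float(r[k]), float(theta[k]), float(phi[k])),
                    center_seq=chain.residues[m].seq_id,
                    neighbor_seq=chain.residues[nb].seq_id,
                )
            )
    return records
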