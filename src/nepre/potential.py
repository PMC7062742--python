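"""The orientation-dependent neighborhood-preference potential.

The statistic behind the potential is the observed distribution of each
ordered residue-type pair (i, j) over angular bins of the contact sphere:
N_ij(theta, phi) counts how often a type-j neighbor falls in a given
(theta, phi) bin of a type-i residue's local frame, with the radial
coordinate integrated from 0 to the cutoff.  The energy follows from the
quasi-Boltzmann inversion of observed over expected probability,

    E(i, j, theta, phi) = -kT log[ (p_ij / (p_i p_j)) *
                                   (p_ij(theta, phi) / w(theta, phi)) ],

where p_i is the type abundance, p_ij the pair probability among contacts,
p_ij(theta, phi) the per-pair angular distribution, and w the fraction of
the sphere's solid angle in the bin (the expected probability for a neighbor
placed uniformly on the sphere).  kT = 1 throughout; ranking only requires
relative energies.  The total energy of a structure is the sum of the
pairwise energies over every residue's neighborhood.

The default angular weight is the *exact* bin-integrated solid-angle
fraction (cos(theta_lo) - cos(theta_hi)) / 2 / n_phi, which removes the
polar singularity of the midpoint weight sin(theta) dtheta dphi; the
midpoint weight is available as ``angular_weight="point"`` for comparison.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import h5py
import numpy as np

from .errors import (
    EmptyModelError,
    IncompatibleModelError,
    ScoreUndefinedError,
    ZeroCountError,
)
from .geometry import SphericalPoint
from .neighborhood import CutoffScheme, enumerate_contacts
from .structure_io import AA_INDEX, STANDARD_AA3, ProteinChain

logger = logging.getLogger(__name__)

#: Thermal energy unit: energies are reported in units of kT with kT = 1.
KT = 1.0

MODEL_FORMAT = "nepre-model"
MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class AngularGrid:
    """Regular (theta, phi) grid tiling [0, pi] x [0, 2*pi)."""

    n_theta: int = 20
    n_phi: int = 20

    def __post_init__(self) -> None:
        if self.n_theta < 2 or self.n_phi < 2:
            raise ValueError("grid needs at least 2 bins per angle")

    @property
    def d_theta(self) -> float:
        return np.pi / self.n_theta

    @property
    def d_phi(self) -> float:
        return 2.0 * np.pi / self.n_phi

    @property
    def n_bins(self) -> int:
        return self.n_theta * self.n_phi

    def bin_of(self, sph: SphericalPoint) -> tuple[int, int]:
        """Bin indices of a spherical point; theta = pi clamps to the last row."""
        t = min(int(sph.theta / self.d_theta), self.n_theta - 1)
        p = min(int(sph.phi / self.d_phi), self.n_phi - 1)
        return t, p

    def bin_arrays(self, theta: np.ndarray, phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        t = np.minimum((np.asarray(theta) / self.d_theta).astype(int), self.n_theta - 1)
        p = np.minimum((np.asarray(phi) / self.d_phi).astype(int), self.n_phi - 1)
        return t, p

    def solid_angle_fraction(self, theta_bin: int, phi_bin: int) -> float:
        """Exact fraction of the sphere's solid angle inside one bin."""
        if not (0 <= theta_bin < self.n_theta and 0 <= phi_bin < self.n_phi):
            raise IndexError(f"bin ({theta_bin}, {phi_bin}) outside {self.n_theta}x{self.n_phi} grid")
        lo = theta_bin * self.d_theta
        hi = lo + self.d_theta
        return (np.cos(lo) - np.cos(hi)) / 2.0 / self.n_phi

    def solid_angle_fractions(self) -> np.ndarray:
        """(n_theta, n_phi) array of exact solid-angle fractions; sums to 1."""
        edges = np.linspace(0.0, np.pi, self.n_theta + 1)
        per_row = (np.cos(edges[:-1]) - np.cos(edges[1:])) / 2.0 / self.n_phi
        return np.repeat(per_row[:, None], self.n_phi, axis=1)

    def point_weights(self) -> np.ndarray:
        """Midpoint weights sin(theta_mid) * dtheta * dphi / (4*pi).

        The literal point-estimate of the uniform expectation; kept for
        comparison with the exact integral.  Does not sum exactly to 1.
        """
        mids = (np.arange(self.n_theta) + 0.5) * self.d_theta
        w = np.sin(mids) * self.d_theta * self.d_phi / (4.0 * np.pi)
        return np.repeat(w[:, None], self.n_phi, axis=1)


def bin_of(grid: AngularGrid, sph: SphericalPoint) -> tuple[int, int]:
    """Module-level wrapper around :meth:`AngularGrid.bin_of`."""
    return grid.bin_of(sph)


def solid_angle_fraction(grid: AngularGrid, theta_bin: int, phi_bin: int) -> float:
    """Module-level wrapper around :meth:`AngularGrid.solid_angle_fraction`."""
    return grid.solid_angle_fraction(theta_bin, phi_bin)


@dataclass
class CountModel:
    """Raw sufficient statistics of a corpus.

    ``n_i``: residue occurrences per type, shape (20,).
    ``n_ij``: contact totals per ordered type pair, shape (20, 20).
    ``h_ij``: per-pair angular histograms, shape (20, 20, n_theta, n_phi).
    """

    grid: AngularGrid
    scheme: CutoffScheme
    n_i: np.ndarray
    n_ij: np.ndarray
    h_ij: np.ndarray
    n_residues_total: int
    n_contacts_total: int
    include_adjacent: bool = True
    provenance: dict = field(default_factory=dict)

    def validate(self) -> None:
        """Assert count-conservation invariants."""
        if not np.array_equal(self.h_ij.sum(axis=(2, 3)), self.n_ij):
            raise AssertionError("histogram totals disagree with per-pair contact counts")
        if int(self.n_ij.sum()) != self.n_contacts_total:
            raise AssertionError("per-pair totals disagree with the global contact count")
        if int(self.n_i.sum()) != self.n_residues_total:
            raise AssertionError("per-type totals disagree with the global residue count")


class TypeStatistics(NamedTuple):
    """Type-level corpus statistics: abundances, pair probabilities, o/e ratios."""

    p_i: np.ndarray      # (20,)  type abundance, sums to 1
    p_ij: np.ndarray     # (20, 20) ordered-pair probability, sums to 1
    oe_ij: np.ndarray    # (20, 20) observed/expected = p_ij / (p_i p_j); NaN where undefined
    types: tuple[str, ...] = STANDARD_AA3


@dataclass
class EnergyModel:
    """Trained potential: per ordered pair, an (n_theta, n_phi) energy grid (kT)."""

    grid: AngularGrid
    scheme: CutoffScheme
    e_ij: np.ndarray  # (20, 20, n_theta, n_phi)
    include_adjacent: bool = True
    pseudocount: float = 0.0
    missing_pair_energy: float = 0.0
    provenance: dict = field(default_factory=dict)

    def pair_table(self, type_i: str, type_j: str) -> np.ndarray:
        return self.e_ij[AA_INDEX[type_i], AA_INDEX[type_j]]


def accumulate(
    corpus: Iterable[ProteinChain],
    scheme: CutoffScheme | None = None,
    grid: AngularGrid | None = None,
    include_adjacent: bool = True,
) -> CountModel:
    """Accumulate neighborhood statistics over a corpus of chains.

    Pure summation, deterministic in corpus order.  Raises
    :class:`EmptyModelError` on an empty corpus.
    """
    scheme = scheme or CutoffScheme()
    grid = grid or AngularGrid()
    n_i = np.zeros(20, dtype=np.int64)
    n_ij = np.zeros((20, 20), dtype=np.int64)
    h_ij = np.zeros((20, 20, grid.n_theta, grid.n_phi), dtype=np.int64)
    n_chains = 0
    for chain in corpus:
        n_chains += 1
        for res in chain.residues:
            n_i[AA_INDEX[res.res_type]] += 1
        for rec in enumerate_contacts(chain, scheme, include_adjacent):
            i = AA_INDEX[rec.center_type]
            j = AA_INDEX[rec.neighbor_type]
            t, p = grid.bin_of(rec.sph)
            n_ij[i, j] += 1
            h_ij[i, j, t, p] += 1
    if n_chains == 0 or n_i.sum() == 0:
        raise EmptyModelError("cannot accumulate statistics from an empty corpus")
    model = CountModel(
        grid=grid,
        scheme=scheme,
        n_i=n_i,
        n_ij=n_ij,
        h_ij=h_ij,
        n_residues_total=int(n_i.sum()),
        n_contacts_total=int(n_ij.sum()),
        include_adjacent=include_adjacent,
        provenance={"n_chains": n_chains},
    )
    model.validate()
    return model


def type_statistics(model: CountModel) -> TypeStatistics:
    """Type abundances p_i, pair probabilities p_ij, and o/e ratios.

    o/e = p_ij / (p_i * p_j) quantifies type-level neighbor preference;
    entries involving absent types are NaN.
    """
    if model.n_residues_total == 0 or model.n_contacts_total == 0:
        raise EmptyModelError("type statistics need nonzero residue and contact totals")
    p_i = model.n_i / model.n_residues_total
    p_ij = model.n_ij / model.n_contacts_total
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = p_i[:, None] * p_i[None, :]
        oe = np.where(expected > 0, p_ij / np.where(expected > 0, expected, 1.0), np.nan)
    return TypeStatistics(p_i=p_i, p_ij=p_ij, oe_ij=oe)


def derive_energy(
    model: CountModel,
    pseudocount: float | None = None,
    missing_pair_energy: float = 0.0,
    angular_weight: str = "exact",
) -> EnergyModel:
    """Quasi-Boltzmann inversion of a :class:`CountModel`.

    For each ordered pair with observed contacts,

        e[t, p] = -log[ oe_ij * ((h[t, p] + a) / (n_ij + a * B)) / w[t, p] ]

    with a the per-bin additive pseudocount (default: one contact spread over
    the B = n_theta * n_phi bins, i.e. a = 1/B) and w the angular weight.
    Pairs never observed in contact get the constant ``missing_pair_energy``
    (default 0: uninformative).  With ``pseudocount=0``, any empty bin of an
    observed pair raises :class:`ZeroCountError` rather than emitting
    infinities.
    """
    if model.n_residues_total == 0 or model.n_contacts_total == 0:
        raise EmptyModelError("cannot derive energies from a model with zero totals")
    grid = model.grid
    B = grid.n_bins
    alpha = 1.0 / B if pseudocount is None else float(pseudocount)
    if alpha < 0:
        raise ValueError("pseudocount must be >= 0")
    if angular_weight == "exact":
        w = grid.solid_angle_fractions()
    elif angular_weight == "point":
        w = grid.point_weights()
    else:
        raise ValueError(f"unknown angular_weight {angular_weight!r}")

    stats = type_statistics(model)
    observed = model.n_ij > 0
    if alpha == 0.0 and np.any((model.h_ij == 0) & observed[:, :, None, None]):
        raise ZeroCountError(
            "empty angular bins with pseudocount=0 would give infinite energies; "
            "set pseudocount > 0 or rely on missing_pair_energy for absent pairs"
        )
    e = np.full((20, 20, grid.n_theta, grid.n_phi), float(missing_pair_energy))
    ii, jj = np.nonzero(observed)
    for i, j in zip(ii, jj):
        p_bin = (model.h_ij[i, j] + alpha) / (model.n_ij[i, j] + alpha * B)
        e[i, j] = -KT * (np.log(stats.oe_ij[i, j]) + np.log(p_bin) - np.log(w))
    if not np.all(np.isfinite(e)):
        raise ZeroCountError("energy derivation produced non-finite values")
    return EnergyModel(
        grid=grid,
        scheme=model.scheme,
        e_ij=e,
        include_adjacent=model.include_adjacent,
        pseudocount=alpha,
        missing_pair_energy=float(missing_pair_energy),
        provenance={**model.provenance,
                    "n_residues_total": model.n_residues_total,
                    "n_contacts_total": model.n_contacts_total},
    )


def score_structure(
    chain: ProteinChain,
    model: EnergyModel,
    per_residue: bool = False,
):
    """Total neighborhood-preference energy of a chain under a trained model.

    Sums the pairwise energy over every ordered contact enumerated with the
    model's own cutoff scheme and grid.  With ``per_residue=True`` returns
    ``(total, breakdown)`` where ``breakdown`` maps each center residue's
    seq_id to its summed contribution (the breakdown sums exactly to the
    total).

    Raises :class:`ScoreUndefinedError` if no residue of the chain can act
    as a scoring center (empty chain or no valid frames) -- distinct from a
    legitimate score of 0 for a chain without contacts.
    """
    from .neighborhood import chain_frames  # local import to avoid cycle noise

    if len(chain.residues) == 0:
        raise ScoreUndefinedError("cannot score an empty chain")
    frames = chain_frames(chain)
    if all(f is None for f in frames):
        raise ScoreUndefinedError(
            f"chain {chain.chain_id!r}: no residue has a valid local frame"
        )
    total = 0.0
    breakdown: dict[tuple[int, str], float] = {r.seq_id: 0.0 for r in chain.residues}
    for rec in enumerate_contacts(chain, model.scheme, model.include_adjacent):
        i = AA_INDEX[rec.center_type]
        j = AA_INDEX[rec.neighbor_type]
        t, p = model.grid.bin_of(rec.sph)
        e = float(model.e_ij[i, j, t, p])
        total += e
        breakdown[rec.center_seq] += e
    if per_residue:
        return total, breakdown
    return total


def estimate_radii(corpus: Iterable[ProteinChain]) -> dict[str, float]:
    """Per-type residue radius estimated from a corpus.

    Convention: for each residue, the mean distance from its geometric center
    to its heavy atoms; the type radius is the mean of this over all residues
    of the type.  Types absent from the corpus are omitted with a warning.
    """
    sums = {t: 0.0 for t in STANDARD_AA3}
    counts = {t: 0 for t in STANDARD_AA3}
    n_chains = 0
    for chain in corpus:
        n_chains += 1
        for res in chain.residues:
            d = np.linalg.norm(res.coords() - res.center, axis=1).mean()
            sums[res.res_type] += float(d)
            counts[res.res_type] += 1
    if n_chains == 0:
        raise EmptyModelError("cannot estimate radii from an empty corpus")
    out = {}
    for t in STANDARD_AA3:
        if counts[t]:
            out[t] = sums[t] / counts[t]
        else:
            logger.warning("type %s absent from corpus; omitted from radii map", t)
    return out


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def _scheme_to_attrs(f: h5py.File, scheme: CutoffScheme) -> None:
    f.attrs["scheme_mode"] = scheme.mode
    f.attrs["r_fixed"] = scheme.r_fixed
    f.create_dataset("radii", data=np.array([scheme.radii[t] for t in STANDARD_AA3]))


def _scheme_from_file(f: h5py.File) -> CutoffScheme:
    radii = {t: float(v) for t, v in zip(STANDARD_AA3, f["radii"][()])}
    return CutoffScheme(mode=str(f.attrs["scheme_mode"]), r_fixed=float(f.attrs["r_fixed"]), radii=radii)


def save_model(model: CountModel | EnergyModel, path: str | Path) -> None:
    """Persist a count or energy model as a self-describing HDF5 container."""
    kind = "counts" if isinstance(model, CountModel) else "energy"
    with h5py.File(path, "w") as f:
        f.attrs["format"] = MODEL_FORMAT
        f.attrs["version"] = MODEL_FORMAT_VERSION
        f.attrs["kind"] = kind
        f.attrs["n_theta"] = model.grid.n_theta
        f.attrs["n_phi"] = model.grid.n_phi
        f.attrs["include_adjacent"] = model.include_adjacent
        f.attrs["types"] = ",".join(STANDARD_AA3)
        f.attrs["provenance"] = json.dumps(model.provenance)
        _scheme_to_attrs(f, model.scheme)
        if kind == "counts":
            f.create_dataset("n_i", data=model.n_i)
            f.create_dataset("n_ij", data=model.n_ij)
            f.create_dataset("h_ij", data=model.h_ij, compression="gzip")
            f.attrs["n_residues_total"] = model.n_residues_total
            f.attrs["n_contacts_total"] = model.n_contacts_total
        else:
            f.create_dataset("e_ij", data=model.e_ij, compression="gzip")
            f.attrs["pseudocount"] = model.pseudocount
            f.attrs["missing_pair_energy"] = model.missing_pair_energy


def load_model(path: str | Path, expected_grid: AngularGrid | None = None):
    """Load a model written by :func:`save_model`.

    If ``expected_grid`` is given and the file's grid differs, raise
    :class:`IncompatibleModelError`.
    """
    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != MODEL_FORMAT:
            raise IncompatibleModelError(f"{path}: not a nepre model file")
        if int(f.attrs.get("version", -1)) != MODEL_FORMAT_VERSION:
            raise IncompatibleModelError(
                f"{path}: format version {f.attrs.get('version')} != {MODEL_FORMAT_VERSION}"
            )
        grid = AngularGrid(int(f.attrs["n_theta"]), int(f.attrs["n_phi"]))
        if expected_grid is not None and grid != expected_grid:
            raise IncompatibleModelError(
                f"{path}: model grid {grid.n_theta}x{grid.n_phi} incompatible with "
                f"expected {expected_grid.n_theta}x{expected_grid.n_phi}"
            )
        scheme = _scheme_from_file(f)
        include_adjacent = bool(f.attrs["include_adjacent"])
        provenance = json.loads(f.attrs["provenance"])
        kind = f.attrs["kind"]
        if kind == "counts":
            model = CountModel(
                grid=grid,
                scheme=scheme,
                n_i=f["n_i"][()],
                n_ij=f["n_ij"][()],
                h_ij=f["h_ij"][()],
                n_residues_total=int(f.attrs["n_residues_total"]),
                n_contacts_total=int(f.attrs["n_contacts_total"]),
                include_adjacent=include_adjacent,
                provenance=provenance,
            )
            model.validate()
            return model
        return EnergyModel(
            grid=grid,
            scheme=scheme,
            e_ij=f["e_ij"][()],
            include_adjacent=include_adjacent,
            pseudocount=float(f.attrs["pseudocount"]),
            missing_pair_energy=float(f.attrs["missing_pair_energy"]),
            provenance=provenance,
        )


def export_energy_text(model: EnergyModel, path: str | Path) -> None:
    """Plain-text export: one matrix per ordered pair (rows = theta bins)."""
    with open(path, "w") as fh:
        fh.write(f"# {MODEL_FORMAT} v{MODEL_FORMAT_VERSION} grid={model.grid.n_theta}x{model.grid.n_phi} "
                 f"mode={model.scheme.mode} r_fixed={model.scheme.r_fixed}\n")
        for i, ti in enumerate(STANDARD_AA3):
            for j, tj in enumerate(STANDARD_AA3):
                fh.write(f"> {ti} {tj}\n")
                for row in model.e_ij[i, j]:
                    fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


def corpus_hash(chains: Iterable[ProteinChain]) -> str:
    """Stable fingerprint of a corpus (types + rounded coordinates)."""
    h = hashlib.sha256()
    for chain in chains:
        for res in chain.residues:
            h.update(res.res_type.encode())
            h.update(np.round(res.coords(), 3).tobytes())
    return h.hexdigest()[:16]
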