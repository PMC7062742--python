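"""Deterministic synthetic structures and corpora for training and testing.

Every generator is seedable and uses only integer-seeded NumPy generators,
so fixtures are reproducible across platforms.  Residues are built from
idealized per-type templates: the four backbone heavy atoms at standard-ish
bond geometry plus a type-specific number of pseudo side-chain atoms on a
straight extension, enough to give each type a distinct geometric center and
radius.  No rotamer realism is claimed; the templates exist to exercise
centers, frames, radii and contact statistics.

Geometries
----------
``ideal_helix``
    CA trace on canonical alpha-helix parameters (rise 1.5 A, 100 deg/res,
    radius 2.3 A), templates rotated to follow the turn.
``random_coil``
    A 3.8 A-step random walk of CA positions with random residue orientations.
``planted_contact``
    Isolated, well-separated residue pairs in which the neighbor's center
    falls inside a requested (theta, phi) bin of the center residue's local
    frame -- the construction used to plant an orientation preference (for a
    random bin per pair, leave ``planted_bin`` unset).
``uniform_pairs``
    Isolated pairs with the neighbor direction uniform on the sphere and both
    residue orientations uniformly random: the null model in which the
    trained energies converge to zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import FixtureSpecError
from .geometry import build_local_frame, random_rotation
from .potential import AngularGrid
from .structure_io import AA_INDEX, Atom, ProteinChain, Residue, write_pdb

logger = logging.getLogger(__name__)

# Backbone template (local coordinates, CA at origin, all in the z=0 plane).
_BACKBONE = (
    ("N", "N", (1.458, 0.0, 0.0)),
    ("CA", "C", (0.0, 0.0, 0.0)),
    ("C", "C", (-0.55, 1.35, 0.0)),
    ("O", "O", (-0.55, 2.58, 0.0)),
)

# Pseudo side-chain: k atoms on a straight 1.53 A-step extension from CA.
_SIDE_NAMES = ("CB", "CG", "CD", "CE", "CZ", "CH2", "CZ2")
_SIDE_COUNT = {
    "ALA": 1, "ARG": 7, "ASN": 4, "ASP": 4, "CYS": 2, "GLN": 5, "GLU": 5,
    "GLY": 0, "HIS": 6, "ILE": 4, "LEU": 4, "LYS": 5, "MET": 4, "PHE": 7,
    "PRO": 3, "SER": 2, "THR": 3, "TRP": 7, "TYR": 7, "VAL": 3,
}
_SIDE_START = np.array([-0.72, -1.20, 0.85])
_SIDE_STEP = 1.53 * np.array([-0.35, -0.75, 0.56]) / np.linalg.norm([-0.35, -0.75, 0.56])

# Pair-geometry layout: lattice spacing keeping distinct pairs out of any
# cutoff's reach (max radius-sum cutoff is 2 x 5.60 = 11.2 A).
_SITE_SPACING = 25.0

# Alpha-helix backbone parameters.
_HELIX_RADIUS = 2.3
_HELIX_RISE = 1.5
_HELIX_TWIST = np.deg2rad(100.0)


def residue_template(res_type: str) -> np.ndarray:
    """(k, 3) template coordinates for a residue type (CA at the origin)."""
    coords = [np.array(p) for _, _, p in _BACKBONE]
    for k in range(_SIDE_COUNT[res_type]):
        coords.append(_SIDE_START + k * _SIDE_STEP)
    return np.array(coords)


def _template_atoms(res_type: str) -> list[tuple[str, str]]:
    names = [(n, el) for n, el, _ in _BACKBONE]
    names += [(n, "C") for n in _SIDE_NAMES[: _SIDE_COUNT[res_type]]]
    return names


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic chain; identical specs give identical chains."""

    seed: int
    n_residues: int
    composition: Mapping[str, float] | None = None  # None = all-ALA
    geometry: str = "ideal_helix"
    planted_bin: tuple[int, int] | None = None
    noise_sigma: float = 0.0
    n_theta: int = 20
    n_phi: int = 20
    pair_distance: tuple[float, float] = (3.8, 5.5)
    bin_margin: float = 0.1  # fraction of the bin width kept clear of the edges

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise FixtureSpecError("n_residues must be >= 1")
        if self.geometry not in ("ideal_helix", "random_coil", "planted_contact", "uniform_pairs"):
            raise FixtureSpecError(f"unknown geometry {self.geometry!r}")
        if self.planted_bin is not None:
            if self.geometry != "planted_contact":
                raise FixtureSpecError("planted_bin requires the planted_contact geometry")
            t, p = self.planted_bin
            if not (0 <= t < self.n_theta and 0 <= p < self.n_phi):
                raise FixtureSpecError(f"planted_bin {self.planted_bin} outside {self.n_theta}x{self.n_phi} grid")
        comp = self.composition
        if comp is not None:
            if any(w < 0 for w in comp.values()) or not any(w > 0 for w in comp.values()):
                raise FixtureSpecError("composition weights must be >= 0 with at least one positive")
            unknown = set(comp) - set(AA_INDEX)
            if unknown:
                raise FixtureSpecError(f"unknown residue types in composition: {unknown}")
        if self.noise_sigma < 0:
            raise FixtureSpecError("noise_sigma must be >= 0")
        if not 0 < self.pair_distance[0] <= self.pair_distance[1]:
            raise FixtureSpecError("pair_distance must be an increasing positive range")

    @property
    def grid(self) -> AngularGrid:
        return AngularGrid(self.n_theta, self.n_phi)


def _sample_types(spec: FixtureSpec, rng: np.random.Generator) -> list[str]:
    comp = spec.composition or {"ALA": 1.0}
    names = sorted(comp)
    weights = np.array([comp[n] for n in names], dtype=float)
    weights /= weights.sum()
    return [names[i] for i in rng.choice(len(names), size=spec.n_residues, p=weights)]


def _place(res_type: str, seq_num: int, rotation: np.ndarray,
           target_center: np.ndarray | None = None,
           ca_position: np.ndarray | None = None) -> Residue:
    tpl = residue_template(res_type)
    if target_center is not None:
        coords = (tpl - tpl.mean(axis=0)) @ rotation.T + target_center
    else:
        coords = tpl @ rotation.T + ca_position
    atoms = [
        Atom(name=n, element=el, position=xyz)
        for (n, el), xyz in zip(_template_atoms(res_type), coords)
    ]
    return Residue(res_type=res_type, seq_id=(seq_num, " "), atoms=atoms)


def _rot_z(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _helix_residues(types: list[str]) -> list[Residue]:
    residues = []
    for i, t in enumerate(types):
        angle = i * _HELIX_TWIST
        ca = np.array([_HELIX_RADIUS * np.cos(angle), _HELIX_RADIUS * np.sin(angle), i * _HELIX_RISE])
        residues.append(_place(t, i + 1, _rot_z(angle), ca_position=ca))
    return residues


def _coil_residues(types: list[str], rng: np.random.Generator) -> list[Residue]:
    residues = []
    ca = np.zeros(3)
    for i, t in enumerate(types):
        residues.append(_place(t, i + 1, random_rotation(rng), ca_position=ca.copy()))
        step = rng.normal(size=3)
        ca = ca + 3.8 * step / np.linalg.norm(step)
    return residues


def _lattice_side(n_sites: int) -> int:
    side = max(1, int(np.ceil(n_sites ** (1.0 / 3.0))))
    while side ** 3 < n_sites:
        side += 1
    return side


def _lattice_site(index: int, side: int) -> np.ndarray:
    # index -> (ix, iy, iz) in a cube of fixed side, row-major
    iz, rem = divmod(index, side * side)
    iy, ix = divmod(rem, side)
    return _SITE_SPACING * np.array([ix, iy, iz], dtype=float)


def _pair_residues(spec: FixtureSpec, types: list[str], rng: np.random.Generator) -> list[Residue]:
    grid = spec.grid
    residues: list[Residue] = []
    n_pairs = spec.n_residues // 2
    side = _lattice_side(n_pairs + spec.n_residues % 2)
    for k in range(n_pairs):
        site = _lattice_site(k, side)
        center_res = _place(types[2 * k], 2 * k + 1, random_rotation(rng), target_center=site)
        frame = build_local_frame(center_res)
        if spec.geometry == "planted_contact":
            if spec.planted_bin is not None:
                t_bin, p_bin = spec.planted_bin
            else:
                t_bin = int(rng.integers(grid.n_theta))
                p_bin = int(rng.integers(grid.n_phi))
            u, v = rng.uniform(spec.bin_margin, 1.0 - spec.bin_margin, size=2)
            theta = (t_bin + u) * grid.d_theta
            phi = (p_bin + v) * grid.d_phi
            direction = (
                np.sin(theta) * np.cos(phi) * frame.x_axis
                + np.sin(theta) * np.sin(phi) * frame.y_axis
                + np.cos(theta) * frame.z_axis
            )
        else:  # uniform_pairs
            vec = rng.normal(size=3)
            direction = vec / np.linalg.norm(vec)
        r = rng.uniform(*spec.pair_distance)
        neighbor_center = frame.origin + r * direction
        residues.append(center_res)
        residues.append(
            _place(types[2 * k + 1], 2 * k + 2, random_rotation(rng), target_center=neighbor_center)
        )
    if spec.n_residues % 2:  # leftover residue, isolated on its own site
        residues.append(
            _place(types[-1], spec.n_residues, random_rotation(rng),
                   target_center=_lattice_site(n_pairs, side))
        )
    return residues


def make_chain(spec: FixtureSpec) -> ProteinChain:
    """Generate one synthetic chain; deterministic for a fixed spec."""
    rng = np.random.default_rng(spec.seed)
    types = _sample_types(spec, rng)
    if spec.geometry == "ideal_helix":
        residues = _helix_residues(types)
    elif spec.geometry == "random_coil":
        residues = _coil_residues(types, rng)
    else:
        residues = _pair_residues(spec, types, rng)
    if spec.noise_sigma > 0:
        residues = [_jitter_residue(r, spec.noise_sigma, rng) for r in residues]
    return ProteinChain(
        chain_id="A",
        residues=residues,
        source=f"fixture:{spec.geometry}:seed={spec.seed}",
    )


def _jitter_residue(res: Residue, sigma: float, rng: np.random.Generator) -> Residue:
    atoms = [
        Atom(name=a.name, element=a.element, position=a.position + rng.normal(0.0, sigma, 3),
             occupancy=a.occupancy, altloc=a.altloc)
        for a in res.atoms
    ]
    return Residue(res_type=res.res_type, seq_id=res.seq_id, atoms=atoms)


def transform_chain(chain: ProteinChain, rotation: np.ndarray, translation: np.ndarray) -> ProteinChain:
    """Apply one rigid motion (proper rotation + translation) to every atom."""
    residues = [
        Residue(
            res_type=r.res_type,
            seq_id=r.seq_id,
            atoms=[
                Atom(name=a.name, element=a.element,
                     position=rotation @ a.position + translation,
                     occupancy=a.occupancy, altloc=a.altloc)
                for a in r.atoms
            ],
        )
        for r in chain.residues
    ]
    return ProteinChain(chain_id=chain.chain_id, residues=residues,
                        source=chain.source + "+rigid")


def perturb_chain(chain: ProteinChain, sigma: float, rng: np.random.Generator) -> ProteinChain:
    """Isotropic Gaussian jitter of every atom position (decoy generator)."""
    return ProteinChain(
        chain_id=chain.chain_id,
        residues=[_jitter_residue(r, sigma, rng) for r in chain.residues],
        source=chain.source + f"+jitter({sigma})",
    )


def make_corpus(spec: FixtureSpec, n_chains: int, out_dir: str | Path | None = None) -> list[ProteinChain]:
    """n_chains chains with per-chain seeds ``spec.seed + chain_index``.

    If ``out_dir`` is given, each chain is also written as
    ``chain_{index:04d}.pdb`` (exercising the PDB round-trip).
    """
    if n_chains < 1:
        raise FixtureSpecError("n_chains must be >= 1")
    chains = [make_chain(replace(spec, seed=spec.seed + i)) for i in range(n_chains)]
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for i, chain in enumerate(chains):
            write_pdb(chain, out_dir / f"chain_{i:04d}.pdb")
    return chains


@dataclass
class DecoySetLayout:
    """On-disk decoy set: one native plus sigma-graded perturbed decoys."""

    native_path: Path
    decoy_paths: list[Path]
    sigmas: dict[str, float]  # decoy stem -> jitter sigma (A)


def make_decoy_set(
    native_spec: FixtureSpec,
    n_decoys: int,
    sigma_schedule: list[float],
    out_dir: str | Path,
) -> DecoySetLayout:
    """Write a native and ``n_decoys`` jittered decoys per sigma level.

    Decoy seeds derive from ``(native seed, level index, decoy index)``; RMSD
    to the native is monotone in sigma in expectation.
    """
    if n_decoys < 1:
        raise FixtureSpecError("n_decoys must be >= 1")
    if any(not s > 0 for s in sigma_schedule):
        raise FixtureSpecError("all sigmas must be > 0")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    native = make_chain(native_spec)
    native_path = out_dir / "native.pdb"
    write_pdb(native, native_path)
    decoy_paths: list[Path] = []
    sigmas: dict[str, float] = {}
    for li, sigma in enumerate(sigma_schedule):
        for d in range(n_decoys):
            rng = np.random.default_rng((native_spec.seed, li, d))
            decoy = perturb_chain(native, sigma, rng)
            stem = f"decoy_s{li}_{d:03d}"
            path = out_dir / f"{stem}.pdb"
            write_pdb(decoy, path)
            decoy_paths.append(path)
            sigmas[stem] = sigma
    return DecoySetLayout(native_path=native_path, decoy_paths=decoy_paths, sigmas=sigmas)
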