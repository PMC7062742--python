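"""Scikit-learn-style estimator facade over the neighborhood potential.

`NeighborhoodPotential` follows the fit/score convention: ``fit`` takes an
iterable of :class:`~nepre.structure_io.ProteinChain` (the training corpus)
and derives the energy tables; ``score_samples`` returns the total energy of
each structure (lower = more native-like).  Parameters follow the sklearn
``get_params``/``set_params`` contract, so the estimator composes with
sklearn model-selection utilities that treat X as an opaque sequence.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .neighborhood import CutoffScheme
from .potential import (
    AngularGrid,
    EnergyModel,
    accumulate,
    derive_energy,
    score_structure,
    type_statistics,
)
from .structure_io import ProteinChain


class NeighborhoodPotential(BaseEstimator):
    """Orientation-dependent residue neighborhood-preference potential.

    Parameters
    ----------
    cutoff_mode : {"fixed", "radius_sum"}
        Neighborhood definition: one universal cutoff, or the sum of the two
        residue-type radii.
    r_fixed : float
        Universal cutoff in Angstrom (used in "fixed" mode).  Default 6.0,
        the operating point that best recognizes native structures.
    radii : dict or None
        Per-type radii for "radius_sum" mode; None = shipped defaults.
    n_theta, n_phi : int
        Angular grid resolution; 20 x 20 by default.
    pseudocount : float or None
        Per-bin additive pseudocount; None = one contact spread over the
        bins (1 / (n_theta * n_phi)).
    missing_pair_energy : float
        Constant energy assigned to pairs never observed in contact.
    include_adjacent : bool
        Whether sequence-adjacent residues count as neighbors (default True).
    angular_weight : {"exact", "point"}
        Uniform-expectation weight per bin: exact solid-angle integral, or
        the midpoint estimate sin(theta) * dtheta * dphi.

    Attributes
    ----------
    counts_ : CountModel
        Accumulated sufficient statistics.
    energy_model_ : EnergyModel
        The trained potential (400 angular energy tables).
    n_chains_, n_residues_, n_contacts_ : int
        Corpus summary numbers.

    Examples
    --------
    >>> pot = NeighborhoodPotential().fit(training_chains)   # doctest: +SKIP
    >>> energies = pot.score_samples(decoy_chains)           # doctest: +SKIP
    """

    def __init__(
        self,
        cutoff_mode: str = "fixed",
        r_fixed: float = 6.0,
        radii: dict | None = None,
        n_theta: int = 20,
        n_phi: int = 20,
        pseudocount: float | None = None,
        missing_pair_energy: float = 0.0,
        include_adjacent: bool = True,
        angular_weight: str = "exact",
    ):
        self.cutoff_mode = cutoff_mode
        self.r_fixed = r_fixed
        self.radii = radii
        self.n_theta = n_theta
        self.n_phi = n_phi
        self.pseudocount = pseudocount
        self.missing_pair_energy = missing_pair_energy
        self.include_adjacent = include_adjacent
        self.angular_weight = angular_weight

    # -- helpers -----------------------------------------------------------
    def _scheme(self) -> CutoffScheme:
        return CutoffScheme(mode=self.cutoff_mode, r_fixed=self.r_fixed, radii=self.radii)

    def _grid(self) -> AngularGrid:
        return AngularGrid(self.n_theta, self.n_phi)

    def _check_fitted(self) -> None:
        if not hasattr(self, "energy_model_"):
            raise AttributeError("this NeighborhoodPotential instance is not fitted yet")

    # -- sklearn surface ---------------------------------------------------
    def fit(self, X: Iterable[ProteinChain], y=None) -> "NeighborhoodPotential":
        """Accumulate corpus statistics and derive the energy tables."""
        chains = list(X)
        self.counts_ = accumulate(
            chains, scheme=self._scheme(), grid=self._grid(),
            include_adjacent=self.include_adjacent,
        )
        self.energy_model_ = derive_energy(
            self.counts_,
            pseudocount=self.pseudocount,
            missing_pair_energy=self.missing_pair_energy,
            angular_weight=self.angular_weight,
        )
        self.n_chains_ = len(chains)
        self.n_residues_ = self.counts_.n_residues_total
        self.n_contacts_ = self.counts_.n_contacts_total
        return self

    def score_samples(self, X: Sequence[ProteinChain]) -> np.ndarray:
        """Total energy (kT) of each structure; lower is better."""
        self._check_fitted()
        return np.array([score_structure(c, self.energy_model_) for c in X], dtype=float)

    def score_structure(self, chain: ProteinChain, per_residue: bool = False):
        """Energy of one structure; optionally with the per-center breakdown."""
        self._check_fitted()
        return score_structure(chain, self.energy_model_, per_residue=per_residue)

    def type_statistics(self):
        """Type abundances, pair probabilities and o/e ratios of the corpus."""
        self._check_fitted()
        return type_statistics(self.counts_)

    @classmethod
    def from_energy_model(cls, model: EnergyModel) -> "NeighborhoodPotential":
        """Wrap a persisted :class:`EnergyModel` as a fitted estimator."""
        est = cls(
            cutoff_mode=model.scheme.mode,
            r_fixed=model.scheme.r_fixed,
            radii=dict(model.scheme.radii),
            n_theta=model.grid.n_theta,
            n_phi=model.grid.n_phi,
            pseudocount=model.pseudocount,
            missing_pair_energy=model.missing_pair_energy,
            include_adjacent=model.include_adjacent,
        )
        est.energy_model_ = model
        return est
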