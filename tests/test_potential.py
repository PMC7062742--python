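"""Binning, solid angles, count accumulation, energy derivation, scoring,
radius estimation, and model persistence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from nepre import (
    AngularGrid,
    Atom,
    CountModel,
    CutoffScheme,
    FixtureSpec,
    NeighborhoodPotential,
    ProteinChain,
    Residue,
    SphericalPoint,
    accumulate,
    bin_of,
    derive_energy,
    estimate_radii,
    load_model,
    make_chain,
    make_corpus,
    save_model,
    score_structure,
    solid_angle_fraction,
    transform_chain,
    type_statistics,
)
from nepre.errors import (
    EmptyModelError,
    IncompatibleModelError,
    ScoreUndefinedError,
    ZeroCountError,
)
from nepre.geometry import random_rotation
from nepre.structure_io import AA_INDEX

from brute_reference import bf_bin, bf_train, bf_score


class TestBinning:
    def test_first_bin_and_pole_clamp(self):
        g = AngularGrid()
        assert bin_of(g, SphericalPoint(1.0, 0.0, 0.0)) == (0, 0)
        assert bin_of(g, SphericalPoint(1.0, np.pi, 0.0)) == (19, 0)

    @given(st.integers(0, 10_000))
    @settings(max_examples=300)
    def test_matches_edge_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = AngularGrid(rng.choice([15, 20, 25, 30]), rng.choice([15, 20, 25, 30]))
        theta = rng.uniform(0, np.pi)
        phi = rng.uniform(0, 2 * np.pi)
        assert bin_of(g, SphericalPoint(1.0, theta, phi)) == \
            bf_bin(theta, phi, g.n_theta, g.n_phi)

    def test_every_angle_maps_to_exactly_one_bin(self, rng):
        g = AngularGrid()
        theta = rng.uniform(0, np.pi, 5000)
        phi = rng.uniform(0, 2 * np.pi, 5000)
        t, p = g.bin_arrays(theta, phi)
        assert np.all((t >= 0) & (t < 20) & (p >= 0) & (p < 20))


class TestSolidAngle:
    @pytest.mark.parametrize("n", [15, 20, 25, 30])
    def test_partition_of_unity(self, n):
        g = AngularGrid(n, n)
        assert abs(g.solid_angle_fractions().sum() - 1.0) < 1e-12

    def test_polar_bin_against_numerical_quadrature(self):
        g = AngularGrid()
        # fraction = int_bin sin(t) dt dphi / (4 pi)
        integral, _ = quad(np.sin, 0.0, np.pi / 20)
        expected = integral * (2 * np.pi / 20) / (4 * np.pi)
        assert abs(solid_angle_fraction(g, 0, 0) - expected) < 1e-12
        assert solid_angle_fraction(g, 0, 0) == pytest.approx(3.078e-4, rel=1e-3)

    def test_equatorial_exceeds_polar(self):
        g = AngularGrid()
        assert solid_angle_fraction(g, 9, 0) > solid_angle_fraction(g, 0, 0)

    def test_invalid_indices(self):
        with pytest.raises(IndexError):
            solid_angle_fraction(AngularGrid(), 20, 0)


class TestAccumulate:
    def test_one_contact_pair_counts_both_directions(self):
        chain = make_chain(FixtureSpec(seed=4, n_residues=2, geometry="uniform_pairs"))
        model = accumulate([chain])
        assert model.n_contacts_total == 2
        assert model.n_residues_total == 2
        i = AA_INDEX["ALA"]
        assert model.n_ij[i, i] == 2
        assert (model.h_ij[i, i] > 0).sum() <= 2  # each direction in exactly one bin

    def test_no_contacts_still_counts_residues(self):
        chain = make_chain(FixtureSpec(seed=4, n_residues=3, geometry="uniform_pairs",
                                       pair_distance=(12.0, 13.0)))
        # pair distance beyond every cutoff: residues counted, histograms empty
        model = accumulate([chain], CutoffScheme())
        assert model.n_residues_total == 3
        assert model.n_contacts_total == 0
        assert model.h_ij.sum() == 0

    def test_empty_corpus_raises(self):
        with pytest.raises(EmptyModelError):
            accumulate([])

    def test_matches_composed_brute_oracles(self, coil_chain):
        """CountModel equals an independent recount via the brute-force
        contact loop plus edge-scan binning."""
        model = accumulate([coil_chain])
        model.validate()
        from brute_reference import bf_contacts
        n_ij = np.zeros((20, 20), dtype=int)
        h = np.zeros((20, 20, 20, 20), dtype=int)
        for (ti, tj, _si, _sj, sph) in bf_contacts(coil_chain):
            tb, pb = bf_bin(sph[1], sph[2], 20, 20)
            n_ij[AA_INDEX[ti], AA_INDEX[tj]] += 1
            h[AA_INDEX[ti], AA_INDEX[tj], tb, pb] += 1
        assert np.array_equal(model.n_ij, n_ij)
        assert np.array_equal(model.h_ij, h)


class TestTypeStatistics:
    def test_single_type_corpus(self):
        chains = make_corpus(FixtureSpec(seed=1, n_residues=4, geometry="uniform_pairs"), 2)
        stats = type_statistics(accumulate(chains))
        i = AA_INDEX["ALA"]
        assert stats.p_i[i] == 1.0
        assert stats.p_i.sum() == pytest.approx(1.0)
        assert stats.p_ij[i, i] == 1.0

    def test_hand_counted_pair_probabilities(self):
        grid = AngularGrid(2, 2)
        n_ij = np.zeros((20, 20), dtype=int)
        a, g = AA_INDEX["ALA"], AA_INDEX["GLY"]
        n_ij[a, a] = 2
        n_ij[a, g] = 1
        n_ij[g, a] = 1
        h = np.zeros((20, 20, 2, 2), dtype=int)
        h[:, :, 0, 0] = n_ij
        model = CountModel(grid=grid, scheme=CutoffScheme(), n_i=np.bincount([a, a, g], minlength=20),
                           n_ij=n_ij, h_ij=h, n_residues_total=3, n_contacts_total=4)
        stats = type_statistics(model)
        assert stats.p_ij[a, a] == 0.5
        assert stats.p_ij[a, g] == 0.25
        assert stats.p_ij[g, a] == 0.25

    def test_type_independent_pairing_gives_unit_oe(self):
        """Uniform pairs with iid 2-type composition: o/e -> 1 at large n."""
        chains = make_corpus(
            FixtureSpec(seed=77, n_residues=200, geometry="uniform_pairs",
                        composition={"ALA": 1, "GLY": 1}),
            n_chains=50,
        )
        model = accumulate(chains)
        stats = type_statistics(model)
        n = model.n_contacts_total
        assert n == 10_000
        for ti in ("ALA", "GLY"):
            for tj in ("ALA", "GLY"):
                i, j = AA_INDEX[ti], AA_INDEX[tj]
                q = stats.p_i[i] * stats.p_i[j]
                se = np.sqrt((1 - q) / (n * q))  # binomial, delta method on the ratio
                assert abs(stats.oe_ij[i, j] - 1.0) < 4 * se


def uniform_count_model(grid, n_contacts=4000):
    """Counts exactly proportional to the bin solid angles, one type only."""
    i = AA_INDEX["ALA"]
    n_i = np.zeros(20)
    n_i[i] = 10
    n_ij = np.zeros((20, 20))
    n_ij[i, i] = n_contacts
    h = np.zeros((20, 20, grid.n_theta, grid.n_phi))
    h[i, i] = n_contacts * grid.solid_angle_fractions()
    return CountModel(grid=grid, scheme=CutoffScheme(), n_i=n_i, n_ij=n_ij, h_ij=h,
                      n_residues_total=10, n_contacts_total=n_contacts)


class TestDeriveEnergy:
    def test_observed_equals_expected_gives_zero_energy(self):
        model = uniform_count_model(AngularGrid())
        energy = derive_energy(model, pseudocount=0.0)
        i = AA_INDEX["ALA"]
        np.testing.assert_allclose(energy.e_ij[i, i], 0.0, atol=1e-9)

    def test_doubling_counts_leaves_energy_unchanged(self):
        chains = make_corpus(
            FixtureSpec(seed=5, n_residues=40, geometry="uniform_pairs",
                        n_theta=2, n_phi=2), 10)
        model = accumulate(chains, grid=AngularGrid(2, 2))
        assert np.all(model.h_ij[AA_INDEX["ALA"], AA_INDEX["ALA"]] > 0)
        e1 = derive_energy(model, pseudocount=0.0)
        doubled = CountModel(
            grid=model.grid, scheme=model.scheme, n_i=2 * model.n_i,
            n_ij=2 * model.n_ij, h_ij=2 * model.h_ij,
            n_residues_total=2 * model.n_residues_total,
            n_contacts_total=2 * model.n_contacts_total)
        e2 = derive_energy(doubled, pseudocount=0.0)
        np.testing.assert_allclose(e1.e_ij, e2.e_ij, atol=1e-12)

    def test_corpus_duplication_leaves_energy_unchanged(self):
        chains = make_corpus(FixtureSpec(seed=6, n_residues=40, geometry="uniform_pairs"), 5)
        m1 = accumulate(chains, grid=AngularGrid(2, 2))
        m3 = accumulate(chains * 3, grid=AngularGrid(2, 2))
        np.testing.assert_allclose(
            derive_energy(m1, pseudocount=0.0).e_ij,
            derive_energy(m3, pseudocount=0.0).e_ij, atol=1e-12)

    def test_hand_built_two_type_model_matches_direct_formula(self):
        """Counts {10, 30} in two designated bins, alpha = 1: bin-by-bin
        agreement with an independently transcribed single formula."""
        grid = AngularGrid(4, 4)
        a, g = AA_INDEX["ALA"], AA_INDEX["GLY"]
        n_i = np.zeros(20)
        n_i[a], n_i[g] = 6, 4
        n_ij = np.zeros((20, 20))
        n_ij[a, g] = 40
        h = np.zeros((20, 20, 4, 4))
        h[a, g, 1, 2] = 10
        h[a, g, 3, 0] = 30
        model = CountModel(grid=grid, scheme=CutoffScheme(), n_i=n_i, n_ij=n_ij,
                           h_ij=h, n_residues_total=10, n_contacts_total=40)
        energy = derive_energy(model, pseudocount=1.0)
        B = 16
        p_ij, p_a, p_g = 40 / 40, 6 / 10, 4 / 10
        for tb in range(4):
            lo, hi = tb * np.pi / 4, (tb + 1) * np.pi / 4
            w = (np.cos(lo) - np.cos(hi)) / 2 / 4
            for pb in range(4):
                expected = -np.log(
                    (p_ij / (p_a * p_g)) * ((h[a, g, tb, pb] + 1.0) / (40 + B)) / w)
                assert energy.e_ij[a, g, tb, pb] == pytest.approx(expected, abs=1e-12)

    def test_unobserved_pairs_get_constant_penalty(self):
        model = uniform_count_model(AngularGrid(2, 2))
        energy = derive_energy(model, missing_pair_energy=2.5)
        trp = AA_INDEX["TRP"]
        assert np.all(energy.e_ij[trp, trp] == 2.5)

    def test_zero_pseudocount_with_empty_bin_refuses(self):
        chain = make_chain(FixtureSpec(seed=4, n_residues=2, geometry="uniform_pairs"))
        model = accumulate([chain])  # 2 contacts cannot fill 400 bins
        with pytest.raises(ZeroCountError):
            derive_energy(model, pseudocount=0.0)


class TestScoreStructure:
    def test_no_contacts_scores_zero(self):
        chain = make_chain(FixtureSpec(seed=4, n_residues=3, geometry="uniform_pairs",
                                       pair_distance=(12.0, 13.0)))
        model = derive_energy(uniform_count_model(AngularGrid()))
        assert score_structure(chain, model) == 0.0

    def test_rigid_motion_leaves_score_unchanged(self, small_corpus, rng):
        pot = NeighborhoodPotential().fit(small_corpus)
        chain = small_corpus[0]
        ref = pot.score_structure(chain)
        moved = transform_chain(chain, random_rotation(rng), rng.uniform(-30, 30, 3))
        assert abs(pot.score_structure(moved) - ref) < 1e-9

    def test_matches_brute_force_resummation(self, small_corpus, coil_chain):
        pot = NeighborhoodPotential().fit(small_corpus)
        energies = bf_train(small_corpus)
        assert abs(pot.score_structure(coil_chain) - bf_score(coil_chain, energies)) < 1e-9

    def test_per_residue_decomposition_sums_to_total(self, small_corpus):
        pot = NeighborhoodPotential().fit(small_corpus)
        total, breakdown = pot.score_structure(small_corpus[1], per_residue=True)
        assert sum(breakdown.values()) == pytest.approx(total, abs=1e-9)

    def test_unscoreable_chain_raises(self):
        # residues with no N atom: no frames, score undefined
        res = [Residue("ALA", (i, " "), [Atom("CA", "C", np.array([3.0 * i, 0, 0])),
                                         Atom("CB", "C", np.array([3.0 * i, 1.5, 0]))])
               for i in range(1, 4)]
        chain = ProteinChain("A", res)
        model = derive_energy(uniform_count_model(AngularGrid()))
        with pytest.raises(ScoreUndefinedError):
            score_structure(chain, model)


class TestEstimateRadii:
    def test_single_atom_residue_has_zero_radius(self):
        res = Residue("GLY", (1, " "), [Atom("CA", "C", np.array([1.0, 1.0, 1.0]))])
        radii = estimate_radii([ProteinChain("A", [res])])
        assert radii["GLY"] == 0.0

    def test_two_atoms_two_angstrom_apart(self):
        res = Residue("GLY", (1, " "), [Atom("N", "N", np.array([0.0, 0, 0])),
                                        Atom("CA", "C", np.array([2.0, 0, 0]))])
        radii = estimate_radii([ProteinChain("A", [res])])
        assert radii["GLY"] == pytest.approx(1.0)

    def test_absent_types_omitted(self, small_corpus):
        radii = estimate_radii(small_corpus)
        assert "TRP" not in radii  # corpus composition has no TRP
        assert set(radii) <= {"ALA", "GLY", "LEU", "VAL"}


class TestPersistence:
    def test_count_model_round_trip_is_exact(self, small_corpus, tmp_path):
        model = accumulate(small_corpus)
        p = tmp_path / "counts.h5"
        save_model(model, p)
        back = load_model(p)
        assert isinstance(back, CountModel)
        assert np.array_equal(back.h_ij, model.h_ij)
        assert np.array_equal(back.n_i, model.n_i)
        assert back.n_contacts_total == model.n_contacts_total
        assert back.scheme == model.scheme

    def test_energy_model_round_trip(self, small_corpus, tmp_path):
        pot = NeighborhoodPotential().fit(small_corpus)
        p = tmp_path / "energy.h5"
        save_model(pot.energy_model_, p)
        back = load_model(p)
        assert np.max(np.abs(back.e_ij - pot.energy_model_.e_ij)) < 1e-12
        assert back.grid == pot.energy_model_.grid
        assert back.pseudocount == pot.energy_model_.pseudocount

    def test_grid_mismatch_on_load_is_rejected(self, small_corpus, tmp_path):
        pot = NeighborhoodPotential(n_theta=15, n_phi=15).fit(small_corpus)
        p = tmp_path / "m15.h5"
        save_model(pot.energy_model_, p)
        with pytest.raises(IncompatibleModelError):
            load_model(p, expected_grid=AngularGrid(20, 20))

    def test_non_model_file_rejected(self, tmp_path):
        import h5py
        p = tmp_path / "other.h5"
        with h5py.File(p, "w") as f:
            f.attrs["whatever"] = 1
        with pytest.raises(IncompatibleModelError):
            load_model(p)
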