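"""Energy terms and geometry kernels: examples, oracles, invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

import foldscape as fs
from foldscape import energies as en
from foldscape.errors import ConfigurationError


def random_rigid(rng):
    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    shift = rng.normal(scale=10, size=3)
    return lambda x: rot.apply(x) + shift


# ----------------------------------------------------------------------
# sequence + confidence terms
# ----------------------------------------------------------------------


class TestHydrophobic:
    @pytest.mark.parametrize("seq, expected", [
        ("VLST", 0.5), ("WWWW", 1.0), ("GGGG", 0.0), ("VILFMW", 1.0),
    ])
    def test_strict_fraction(self, seq, expected):
        assert en.hydrophobic_energy(seq) == pytest.approx(expected)

    def test_mild_set_is_opt_in(self):
        assert en.hydrophobic_energy("YCAG") == 0.0
        assert en.hydrophobic_energy("YCAG", include_mild=True) == 1.0

    def test_sasa_weights_reduce_buried_contributions(self):
        # buried W (weight 0) costs nothing, exposed W full price
        assert en.hydrophobic_energy("WS", sasa_weights=[0.0, 1.0]) == 0.0
        assert en.hydrophobic_energy("WS", sasa_weights=[1.0, 1.0]) == 0.5

    def test_unit_weights_reduce_to_plain_fraction(self):
        assert en.hydrophobic_energy("VLST", [1.0] * 4) == en.hydrophobic_energy("VLST")

    def test_empty_group_rejected(self):
        with pytest.raises(ConfigurationError):
            en.hydrophobic_energy("")


class TestChemicalPotential:
    @pytest.mark.parametrize("mu, n, nt, p, expected", [
        (1.0, 10, 10, 2.0, 0.0),
        (0.5, 8, 10, 2.0, 2.0),
        (2.0, 12, 10, 1.0, 4.0),
    ])
    def test_substitution(self, mu, n, nt, p, expected):
        assert en.chemical_potential_energy(mu, n, nt, p) == pytest.approx(expected)


class TestConfidenceTerms:
    @pytest.mark.parametrize("ptm", [0.8, 1.0, 0.0])
    def test_ptm_negation(self, ptm):
        assert en.ptm_energy(ptm) == pytest.approx(-ptm)

    @pytest.mark.parametrize("values, expected", [
        ([0.9, 0.7], -0.8), ([1.0, 1.0, 1.0], -1.0), ([0.42], -0.42),
    ])
    def test_plddt_negative_mean(self, values, expected):
        assert en.plddt_energy(values) == pytest.approx(expected)

    def test_pae_bounds(self):
        full = np.full((4, 4), 30.0)
        assert en.pae_energy(full, [0, 1], [2, 3], pae_max=30.0) == pytest.approx(1.0)
        assert en.pae_energy(np.zeros((4, 4)), [0, 1], [2, 3]) == pytest.approx(0.0)

    def test_pae_single_residue_pair(self):
        pae = np.zeros((2, 2))
        pae[0, 1] = pae[1, 0] = 15.0
        assert en.pae_energy(pae, [0], [1], pae_max=30.0) == pytest.approx(0.5)

    def test_pae_averages_both_directed_blocks(self):
        pae = np.zeros((2, 2))
        pae[0, 1], pae[1, 0] = 10.0, 20.0  # asymmetric, as real PAE is
        assert en.pae_energy(pae, [0], [1], pae_max=30.0) == pytest.approx(0.5)

    def test_pae_single_group_mode_uses_offdiagonal_pairs(self):
        pae = np.array([[0.0, 6.0, 12.0],
                        [6.0, 0.0, 18.0],
                        [12.0, 18.0, 0.0]])
        expected = (6 + 12 + 6 + 18 + 12 + 18) / 6 / 30.0
        assert en.pae_energy(pae, [0, 1, 2], pae_max=30.0) == pytest.approx(expected)


# ----------------------------------------------------------------------
# SASA kernel
# ----------------------------------------------------------------------


class TestShrakeRupley:
    def test_isolated_atom_closed_form(self):
        area = en.shrake_rupley_sasa(np.zeros((1, 3)), ["S"], 1.4, 1000)[0]
        exact = 4 * math.pi * (1.8 + 1.4) ** 2
        assert area == pytest.approx(exact, rel=0.01)

    def test_distant_atoms_keep_full_spheres(self):
        coords = np.array([[0.0, 0, 0], [50.0, 0, 0]])
        areas = en.shrake_rupley_sasa(coords, ["C", "C"], 1.4, 500)
        exact = 4 * math.pi * (1.7 + 1.4) ** 2
        assert areas == pytest.approx([exact, exact], rel=0.01)

    def test_caged_atom_is_buried(self):
        # 26-neighbour cube cage around a central carbon
        offsets = [np.array([i, j, k], dtype=float)
                   for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
                   if (i, j, k) != (0, 0, 0)]
        coords = np.vstack([[0.0, 0, 0]] + [2.0 * o / np.linalg.norm(o) for o in offsets])
        areas = en.shrake_rupley_sasa(coords, ["C"] * 27, 1.4, 1000)
        free = 4 * math.pi * (1.7 + 1.4) ** 2
        assert areas[0] < 0.01 * free

    def test_monotone_under_added_neighbour(self):
        rng = np.random.default_rng(5)
        coords = rng.normal(scale=2.5, size=(8, 3))
        elements = ["C"] * 8
        # fixed lattice orientation: burial can only grow with neighbours
        base = en.shrake_rupley_sasa(coords, elements, 1.4, 500,
                                     canonicalize=False)
        grown = en.shrake_rupley_sasa(
            np.vstack([coords, rng.normal(scale=2.5, size=(1, 3))]),
            elements + ["N"], 1.4, 500, canonicalize=False)
        assert np.all(grown[:8] <= base + 1e-9)

    def test_matches_independent_implementation(self):
        """Dual route: same radii/point count as biotite's Shrake–Rupley."""
        import biotite.structure as struc

        rng = np.random.default_rng(1)
        n = 12
        coords = rng.normal(scale=3.0, size=(n, 3))
        elements = rng.choice(["C", "N", "O", "S"], size=n)
        mine = en.shrake_rupley_sasa(coords, elements, 1.4, 500,
                                     canonicalize=False)
        arr = struc.AtomArray(n)
        arr.coord = coords.astype(np.float32)
        arr.chain_id[:] = "A"
        arr.res_id[:] = np.arange(1, n + 1)
        arr.res_name[:] = "ALA"
        arr.atom_name[:] = [f"X{i}" for i in range(n)]
        arr.element[:] = elements
        ref = struc.sasa(arr, probe_radius=1.4, point_number=500, vdw_radii="Single")
        np.testing.assert_allclose(mine, ref, atol=1e-3)

    def test_unknown_element_named_in_error(self):
        with pytest.raises(ConfigurationError, match="Zz"):
            en.shrake_rupley_sasa(np.zeros((1, 3)), ["Zz"])


# ----------------------------------------------------------------------
# superposition
# ----------------------------------------------------------------------


def _brute_force_min_rmsd(mobile, reference, n_grid=48):
    """Independent oracle: dense Euler-angle grid over proper rotations,
    optimal translation by centroid matching."""
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)
    angles = np.linspace(0, 2 * np.pi, n_grid, endpoint=False)
    betas = np.linspace(0, np.pi, n_grid // 2)
    grid = np.stack(np.meshgrid(angles, betas, angles, indexing="ij"),
                    axis=-1).reshape(-1, 3)
    mats = Rotation.from_euler("zyz", grid).as_matrix()
    diffs = mats @ mob.T - ref.T  # (M, 3, n_atoms)
    rmsds = np.sqrt((diffs ** 2).sum(axis=(1, 2)) / len(mob))
    return float(rmsds.min())


class TestSuperposition:
    def test_identity(self):
        coords = np.random.default_rng(0).normal(size=(5, 3))
        _, _, rmsd = en.optimal_superposition(coords, coords)
        assert rmsd <= 1e-8

    def test_rigid_transform_recovers_zero(self, rng):
        coords = rng.normal(size=(10, 3))
        moved = random_rigid(rng)(coords)
        matrix, translation, rmsd = en.optimal_superposition(coords, moved)
        assert rmsd <= 1e-8
        np.testing.assert_allclose(coords @ matrix.T + translation, moved, atol=1e-7)

    def test_matches_brute_force_grid_oracle(self):
        mobile = np.array([[0.0, 0, 0], [3.8, 0, 0], [3.8, 3.8, 0]])
        reference = mobile.copy()
        reference[2] += [0.0, 0.7, 0.4]  # one displaced atom
        _, _, rmsd = en.optimal_superposition(mobile, reference)
        brute = _brute_force_min_rmsd(mobile, reference)
        assert rmsd <= brute + 1e-9          # never worse than the grid
        assert brute - rmsd < 0.05           # and the grid confirms it

    def test_optimal_vs_random_rotations(self, rng):
        mobile = rng.normal(size=(10, 3))
        reference = rng.normal(size=(10, 3))
        _, _, rmsd = en.optimal_superposition(mobile, reference)
        mob = mobile - mobile.mean(axis=0)
        ref = reference - reference.mean(axis=0)
        identity = math.sqrt(((mob - ref) ** 2).sum() / 10)
        assert rmsd <= identity + 1e-12
        for _ in range(100):
            rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
            trial = math.sqrt(((rot.apply(mob) - ref) ** 2).sum() / 10)
            assert rmsd <= trial + 1e-9

    def test_count_mismatch_rejected(self):
        with pytest.raises(ConfigurationError, match="mismatch"):
            en.optimal_superposition(np.zeros((4, 3)), np.zeros((5, 3)))


# ----------------------------------------------------------------------
# structural terms
# ----------------------------------------------------------------------


class TestSeparationAndGlobular:
    def test_separation_345(self):
        c1 = np.array([[0.0, 0, 0]])
        c2 = np.array([[3.0, 4, 0]])
        assert en.separation_energy(c1, c2) == pytest.approx(5.0)

    def test_identical_groups_zero(self):
        c = np.random.default_rng(0).normal(size=(6, 3))
        assert en.separation_energy(c, c) == pytest.approx(0.0)

    def test_globular_sphere_shell_zero(self, rng):
        # antipodal pairs: centroid exactly at the origin, radii all 5
        dirs = rng.normal(size=(15, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        shell = 5.0 * np.vstack([dirs, -dirs])
        assert en.globular_energy(shell) == pytest.approx(0.0, abs=1e-9)

    def test_globular_two_atoms_zero(self):
        assert en.globular_energy(np.array([[0.0, 0, 0], [2.0, 0, 0]])) == pytest.approx(0.0)

    def test_globular_collinear_hand_value(self):
        coords = np.array([[-3.0, 0, 0], [-1.0, 0, 0], [1.0, 0, 0], [3.0, 0, 0]])
        assert en.globular_energy(coords) == pytest.approx(1.0)


class TestTemplateMatch:
    def test_exact_match_zero_both_modes(self, rng):
        coords = rng.normal(size=(8, 3))
        for mode in ("rmsd", "distogram"):
            assert en.template_match_energy(coords, coords, mode) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_transform_zero_both_modes(self, rng):
        coords = rng.normal(size=(8, 3))
        moved = random_rigid(rng)(coords)
        for mode in ("rmsd", "distogram"):
            assert en.template_match_energy(moved, coords, mode) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_translation_degenerate_zero(self, rng):
        coords = rng.normal(size=(6, 3))
        shifted = coords + np.array([1.0, 0.0, 0.0])
        for mode in ("rmsd", "distogram"):
            assert en.template_match_energy(shifted, coords, mode) == pytest.approx(0.0, abs=1e-12)


def ideal_helix(n, radius=2.3, rise=1.5, turn=100.0):
    t = np.deg2rad(turn) * np.arange(n)
    return np.stack([radius * np.cos(t), radius * np.sin(t), rise * np.arange(n)], axis=1)


def ideal_strand(n, rise=3.3, wobble=0.5):
    x = rise * np.arange(n)
    y = wobble * (-1.0) ** np.arange(n)
    return np.stack([x, y, np.zeros(n)], axis=1)


def random_walk(n, step=10.0, seed=0):
    rng = np.random.default_rng(seed)
    steps = rng.normal(size=(n, 3))
    steps = step * steps / np.linalg.norm(steps, axis=1, keepdims=True)
    return np.cumsum(steps, axis=0)


class TestSecondaryStructure:
    def test_ideal_helix_interior(self):
        labels = en.assign_secondary_structure(ideal_helix(12))
        assert all(lab == "helix" for lab in labels[2:-2])

    def test_ideal_strand_interior(self):
        labels = en.assign_secondary_structure(ideal_strand(12))
        assert all(lab == "sheet" for lab in labels[2:-2])

    def test_random_walk_is_coil(self):
        labels = en.assign_secondary_structure(random_walk(10))
        assert labels == ["coil"] * 10

    def test_missing_ca_labelled_coil_with_warning(self):
        coords = ideal_helix(12)
        coords[5] = np.nan
        with pytest.warns(UserWarning, match="without"):
            labels = en.assign_secondary_structure(coords)
        assert labels[5] == "coil"

    @pytest.mark.parametrize("labels, target, expected", [
        (["helix"] * 4, "helix", 0.0),
        (["coil"] * 4, "helix", 1.0),
        (["helix", "helix", "helix", "coil"], "helix", 0.25),
    ])
    def test_mismatch_fraction(self, labels, target, expected):
        assert en.secondary_structure_energy(labels, target) == pytest.approx(expected)


UNIT_SQUARE = [np.array([[0.0, 0, 0]]), np.array([[1.0, 0, 0]]),
               np.array([[1.0, 1, 0]]), np.array([[0.0, 1, 0]])]


class TestRingSymmetry:
    @pytest.mark.parametrize("n", range(3, 9))
    def test_regular_polygon_zero(self, n):
        """Neighbors mode sees only the N equal edges, so every regular
        polygon scores zero; all-pairs additionally sees diagonals, so
        only the triangle (no diagonals) is zero there."""
        groups = [
            np.array([[math.cos(2 * math.pi * k / n), math.sin(2 * math.pi * k / n), 0.0]])
            for k in range(n)
        ]
        assert en.ring_symmetry_energy(groups, "neighbors") == pytest.approx(0.0, abs=1e-12)
        if n == 3:
            assert en.ring_symmetry_energy(groups, "all_pairs") == pytest.approx(0.0, abs=1e-12)

    def test_unit_square_neighbors_zero(self):
        assert en.ring_symmetry_energy(UNIT_SQUARE, "neighbors") == pytest.approx(0.0, abs=1e-12)

    def test_unit_square_all_pairs_value(self):
        # independent arithmetic: d = {1,1,1,1,sqrt2,sqrt2}, population std
        d = [1.0] * 4 + [math.sqrt(2.0)] * 2
        m = sum(d) / 6
        expected = math.sqrt(sum((x - m) ** 2 for x in d) / 6)
        assert en.ring_symmetry_energy(UNIT_SQUARE, "all_pairs") == pytest.approx(expected)
        assert expected == pytest.approx(0.195262145875635)

    def test_fewer_than_three_groups_rejected(self):
        with pytest.raises(ConfigurationError):
            en.ring_symmetry_energy(UNIT_SQUARE[:2])


class TestEmbeddingSimilarity:
    def test_identical_orthogonal_antiparallel(self):
        v = np.array([[1.0, 0.0], [0.0, 2.0]])
        assert en.embeddings_similarity_energy(v, v) == pytest.approx(0.0)
        orth = np.array([[0.0, 3.0], [1.0, 0.0]])
        assert en.embeddings_similarity_energy(v, orth) == pytest.approx(1.0)
        assert en.embeddings_similarity_energy(v, -v) == pytest.approx(2.0)

    def test_zero_norm_vector_rejected(self):
        with pytest.raises(ConfigurationError, match="zero-norm"):
            en.embeddings_similarity_energy(np.zeros((1, 3)), np.ones((1, 3)))


# ----------------------------------------------------------------------
# invariances (property)
# ----------------------------------------------------------------------


@settings(deadline=None, max_examples=25)
@given(seed=st.integers(0, 10_000))
def test_rigid_motion_invariance(seed):
    """Separation, globular, ring symmetry, template (both modes) and
    SASA are unchanged by a global rotation + translation."""
    rng = np.random.default_rng(seed)
    transform = random_rigid(rng)
    g1 = rng.normal(scale=4, size=(5, 3))
    g2 = rng.normal(scale=4, size=(6, 3)) + 8.0
    g3 = rng.normal(scale=4, size=(4, 3)) - 8.0
    atoms = np.vstack([g1, g2, g3])
    elements = ["C"] * len(atoms)

    assert en.separation_energy(transform(g1), transform(g2)) == pytest.approx(
        en.separation_energy(g1, g2), abs=1e-8)
    assert en.globular_energy(transform(g1)) == pytest.approx(
        en.globular_energy(g1), abs=1e-8)
    for mode in ("all_pairs", "neighbors"):
        assert en.ring_symmetry_energy(
            [transform(g) for g in (g1, g2, g3)], mode) == pytest.approx(
            en.ring_symmetry_energy([g1, g2, g3], mode), abs=1e-8)
    for mode in ("rmsd", "distogram"):
        assert en.template_match_energy(transform(g1), g1, mode) == pytest.approx(0.0, abs=1e-8)
    np.testing.assert_allclose(
        en.shrake_rupley_sasa(transform(atoms), elements, 1.4, 200),
        en.shrake_rupley_sasa(atoms, elements, 1.4, 200),
        atol=1e-8)  # exact thanks to the canonical-frame convention


# ----------------------------------------------------------------------
# term classes wired into a State
# ----------------------------------------------------------------------


class TestTermClasses:
    def _system(self, seq="ACDWFG"):
        chain = fs.Chain("A", seq)
        group = fs.ResidueGroup("A", [1, 2, 3])
        state = fs.State("s", [chain], [
            fs.EnergyTermBinding(fs.PLDDTEnergy(), 1.0, [group], oracle_id="fold"),
            fs.EnergyTermBinding(fs.PTMEnergy(), 1.0, [], oracle_id="fold"),
            fs.EnergyTermBinding(fs.PAEEnergy(), 1.0, [group], oracle_id="fold"),
            fs.EnergyTermBinding(fs.SurfaceAreaEnergy(n_points=200), 1.0, [],
                                 oracle_id="fold"),
        ])
        return fs.System([chain], [state]), state

    def test_terms_match_functional_forms(self, toy_fold):
        system, state = self._system()
        fold = toy_fold(state.sequences)
        bd = fs.system_energy(system, {"fold": fold})
        assert bd.raw_per_term[("s", "PLDDTEnergy")] == pytest.approx(
            en.plddt_energy(fold.plddt[[1, 2, 3]]))
        assert bd.raw_per_term[("s", "PTMEnergy")] == pytest.approx(-fold.ptm)
        assert bd.raw_per_term[("s", "PAEEnergy")] == pytest.approx(
            en.pae_energy(fold.pae, [1, 2, 3]))
        assert 0.0 <= bd.raw_per_term[("s", "SurfaceAreaEnergy")] <= 1.5

    def test_template_match_on_own_fold_is_zero(self, toy_fold):
        chain = fs.Chain("A", "ACDWFG")
        fold = toy_fold([chain.sequence])
        template = fs.TemplateStructure.from_fold_output(fold, [1, 2, 3])
        group = fs.ResidueGroup("A", [1, 2, 3])
        state = fs.State("s", [chain], [
            fs.EnergyTermBinding(fs.TemplateMatchEnergy(template), 1.0, [group],
                                 oracle_id="fold"),
        ])
        system = fs.System([chain], [state])
        bd = fs.system_energy(system, {"fold": fold})
        assert bd.total == pytest.approx(0.0, abs=1e-10)

    def test_embedding_term_zero_on_reference(self, toy_embed):
        chain = fs.Chain("A", "ACDWFG")
        ref = toy_embed([chain.sequence])
        group = fs.ResidueGroup("A", [0, 1, 2, 3, 4, 5])
        state = fs.State("s", [chain], [
            fs.EnergyTermBinding(fs.EmbeddingsSimilarityEnergy(ref), 1.0, [group],
                                 oracle_id="embed"),
        ])
        system = fs.System([chain], [state])
        bd = fs.system_energy(system, {"embed": ref})
        assert bd.total == pytest.approx(0.0, abs=1e-12)

    def test_chemical_potential_counts_whole_system(self):
        a, b = fs.Chain("A", "ACDEF"), fs.Chain("B", "KLM")
        state = fs.State("s", [a], [
            fs.EnergyTermBinding(fs.ChemicalPotentialEnergy(mu=0.5, n_target=10, p=2), 1.0, []),
        ])
        system = fs.System([a, b], [state])
        bd = fs.system_energy(system, {})
        assert bd.total == pytest.approx(0.5 * (10 - 8) ** 2)
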