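"""Ensemble I/O, disulfide detection, RMSD to mean, pseudocyclicity."""

import numpy as np
import pytest

from ginsentides import data, structure, synth
from ginsentides.connectivity import DisulfideTopology
from ginsentides.structure import (
    detect_ss_bonds,
    ensemble_rmsd,
    pseudocyclicity,
    read_ensemble,
    write_ensemble,
)
from ginsentides.synth import GeneratorConfig, gen_ensemble


@pytest.fixture
def tp1_ensemble(tp1):
    cfg = GeneratorConfig(seed=3, n_models=20, coord_noise_sd=0.3)
    return gen_ensemble(tp1, data.TP1_TOPOLOGY_BONDS, cfg)


class TestIO:
    def test_write_read_round_trip(self, tp1_ensemble, tmp_path):
        ens, _ = tp1_ensemble
        path = tmp_path / "ens.pdb"
        write_ensemble(ens, str(path))
        back = read_ensemble(str(path))
        assert back.n_models == ens.n_models
        assert back.n_atoms == ens.n_atoms
        assert np.allclose(back.stack.coord, ens.stack.coord, atol=5e-3)

    def test_single_model_file(self, tp1, tmp_path):
        cfg = GeneratorConfig(seed=5, n_models=1)
        ens, _ = gen_ensemble(tp1, data.TP1_TOPOLOGY_BONDS, cfg)
        path = tmp_path / "single.pdb"
        write_ensemble(ens, str(path))
        assert read_ensemble(str(path)).n_models == 1

    def test_truncated_file_errors(self, tp1_ensemble, tmp_path):
        ens, _ = tp1_ensemble
        path = tmp_path / "ens.pdb"
        write_ensemble(ens, str(path))
        text = path.read_text().splitlines()
        # cut inside the second model so atom sets disagree
        cut = [i for i, l in enumerate(text) if l.startswith("MODEL")][1] + 5
        (tmp_path / "trunc.pdb").write_text("\n".join(text[:cut] + ["ENDMDL"]))
        with pytest.raises(ValueError):
            read_ensemble(str(tmp_path / "trunc.pdb"))


class TestDisulfideDetection:
    def test_known_bonds_recovered(self, tp1_ensemble):
        ens, truth = tp1_ensemble
        report = detect_ss_bonds(ens, cutoff=2.5)
        assert report.consensus == truth.bonds
        assert not report.flagged

    def test_tight_cutoff_finds_nothing(self, tp1_ensemble):
        ens, _ = tp1_ensemble
        assert detect_ss_bonds(ens, cutoff=0.1).consensus == frozenset()

    def test_seeded_geometries_match_ground_truth(self, tp1, rng):
        from ginsentides.connectivity import enumerate_matchings

        matchings = enumerate_matchings(8)
        for seed in range(50):
            bonds = matchings[int(rng.integers(len(matchings)))]
            cfg = GeneratorConfig(seed=seed, n_models=5, coord_noise_sd=0.15)
            ens, truth = gen_ensemble(tp1, bonds, cfg)
            assert detect_ss_bonds(ens).consensus == truth.bonds

    def test_missing_sg_atoms_reported(self, tp1_ensemble):
        ens, _ = tp1_ensemble
        stripped = type(ens)(ens.stack[:, ens.stack.atom_name != "SG"])
        with pytest.raises(ValueError, match="SG"):
            detect_ss_bonds(stripped)


class TestEnsembleRmsd:
    def test_identical_models_have_zero_rmsd(self, tp1):
        cfg = GeneratorConfig(seed=9, n_models=4, coord_noise_sd=0.0)
        ens, _ = gen_ensemble(tp1, data.TP1_TOPOLOGY_BONDS, cfg)
        result = ensemble_rmsd(ens, "backbone")
        assert result.mean == pytest.approx(0.0, abs=1e-6)
        assert result.sd == pytest.approx(0.0, abs=1e-6)

    def test_rigid_motion_is_removed_by_superposition(self, tp1):
        cfg = GeneratorConfig(seed=9, n_models=2, coord_noise_sd=0.0)
        ens, _ = gen_ensemble(tp1, data.TP1_TOPOLOGY_BONDS, cfg)
        theta = 0.7
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0.0],
                [np.sin(theta), np.cos(theta), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        coords = ens.stack.coord.copy()
        coords[1] = coords[1] @ rot.T + np.array([5.0, -3.0, 12.0])
        ens.stack.coord = coords
        result = ensemble_rmsd(ens, "heavy")
        assert result.mean == pytest.approx(0.0, abs=1e-4)

    def test_noise_matches_analytic_expectation(self, tp1_ensemble):
        ens, truth = tp1_ensemble
        result = ensemble_rmsd(ens, "backbone", residue_range=(1, 31))
        assert result.mean == pytest.approx(truth.expected_rmsd, rel=0.15)

    def test_superposition_never_increases_pairwise_rmsd(self, tp1_ensemble):
        from ginsentides.structure import _kabsch_fit

        ens, _ = tp1_ensemble
        coords = ens.stack.coord.astype(float)
        for m in range(1, ens.n_models):
            before = np.sqrt(((coords[m] - coords[0]) ** 2).sum(axis=1).mean())
            fitted = _kabsch_fit(coords[m], coords[0])
            after = np.sqrt(((fitted - coords[0]) ** 2).sum(axis=1).mean())
            assert after <= before + 1e-9

    def test_residue_range_changes_atom_count(self, tp1_ensemble):
        ens, _ = tp1_ensemble
        full = ensemble_rmsd(ens, "backbone")
        part = ensemble_rmsd(ens, "backbone", residue_range=(1, 10))
        assert part.n_atoms == 40 and full.n_atoms == 124

    def test_single_model_rejected(self, tp1):
        cfg = GeneratorConfig(seed=5, n_models=1)
        ens, _ = gen_ensemble(tp1, data.TP1_TOPOLOGY_BONDS, cfg)
        with pytest.raises(ValueError, match="at least 2"):
            ensemble_rmsd(ens)


class TestPseudocyclicity:
    def test_tp1_topology_is_pseudocyclic_with_expected_anchors(self):
        topo = DisulfideTopology(8, data.TP1_TOPOLOGY_BONDS)
        report = pseudocyclicity(topo)
        assert report.pseudocyclic
        assert report.n_terminal_anchor == (1, 4)
        assert report.c_terminal_anchor == (5, 8)

    def test_sequential_pairing_is_also_pseudocyclic_by_definition(self):
        topo = DisulfideTopology(8, {(1, 2), (3, 4), (5, 6), (7, 8)})
        report = pseudocyclicity(topo)
        assert report.pseudocyclic
        assert report.n_terminal_anchor == (1, 2) and report.c_terminal_anchor == (7, 8)

    def test_free_terminal_cysteine_breaks_pseudocyclicity(self):
        topo = DisulfideTopology(6, {(2, 3), (4, 5)})
        report = pseudocyclicity(topo)
        assert not report.pseudocyclic

    def test_cross_module_consistency_on_fixture(self, tp1_ensemble):
        """Coordinate-detected bonds equal the chemically mapped topology."""
        ens, _ = tp1_ensemble
        consensus = detect_ss_bonds(ens).consensus
        assert consensus == data.TP1_TOPOLOGY_BONDS
        assert pseudocyclicity(DisulfideTopology(8, consensus)).pseudocyclic
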