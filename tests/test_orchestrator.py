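"""Refinement engine: filters, ranking, capacity, determinism, contracts."""

import numpy as np
import pytest

from pocketforge.backends import ToyBackends
from pocketforge.core_model import kabsch_fit
from pocketforge.errors import ConfigError, RankingError
from pocketforge.orchestrator import (
    LDMConfig,
    LDMModel,
    combined_rank,
    derive_seed,
    pocket_distance_filter,
    polar_conservation_filter,
    run_ldm,
    top_k,
    _pocket_of,
)
from pocketforge.synthetic import (
    designed_contact_wells,
    make_toy_complex,
    perturb_complex,
)


@pytest.fixture(scope="module")
def small_cfg():
    return LDMConfig(n_replicas=2, n_rounds=3, n_directories_per_round=4,
                     master_seed=11)


@pytest.fixture(scope="module")
def wells(toy_complex, toy_pocket):
    return designed_contact_wells(toy_complex, toy_pocket)


def _model(dock, fold, replica=0, rnd=0):
    return LDMModel(complex=None, dock_score=dock, fold_score=fold,
                    replica=replica, round=rnd)


class TestFilters:
    def test_identity_passes_distance_filter_at_any_cutoff(self, toy_complex,
                                                           toy_pocket):
        kept, rmsds = pocket_distance_filter(
            [toy_complex.copy()], toy_complex, cutoff=0.0,
            pocket_residues=toy_pocket.residues,
        )
        assert kept and rmsds[0] == pytest.approx(0.0, abs=1e-7)

    def test_rmsd_above_cutoff_removed(self, toy_complex, toy_pocket):
        # verified against the independent Kabsch oracle
        from tests.test_core_model import _brute_kabsch

        cand = perturb_complex(toy_complex, toy_pocket.residues, 2.5, seed=9)
        kept, rmsds = pocket_distance_filter(
            [cand], toy_complex, cutoff=rmsds_oracle(toy_complex, cand,
                                                     toy_pocket) - 0.05,
            pocket_residues=toy_pocket.residues,
        )
        oracle = rmsds_oracle(toy_complex, cand, toy_pocket)
        assert rmsds[0] == pytest.approx(oracle, abs=1e-8)
        assert not kept

    def test_infinite_cutoff_keeps_all(self, toy_complex, toy_pocket):
        cands = [perturb_complex(toy_complex, toy_pocket.residues, 3.0, seed=s)
                 for s in range(3)]
        kept, _ = pocket_distance_filter(
            cands, toy_complex, cutoff=np.inf,
            pocket_residues=toy_pocket.residues,
        )
        assert len(kept) == 3

    def test_empty_input_is_empty_output(self, toy_complex, toy_pocket):
        kept, rmsds = pocket_distance_filter(
            [], toy_complex, 1.0, toy_pocket.residues)
        assert kept == [] and rmsds == []

    def test_identical_candidate_fully_conserved(self, toy_complex,
                                                 toy_pocket):
        kept, fracs = polar_conservation_filter(
            [toy_complex.copy()], toy_complex, fraction=1.0,
            pocket_residues=toy_pocket.residues,
        )
        assert kept and fracs[0] == 1.0

    def test_partial_conservation_thresholds(self, toy_complex, toy_pocket):
        from pocketforge.core_model import atom_res_keys

        # displace the polar group of exactly one of the polar residues
        polar_keys = [r for r, p in zip(toy_pocket.residues,
                                        toy_pocket.polar_mask) if p]
        n = len(polar_keys)
        cand = toy_complex.copy()
        keys = atom_res_keys(cand.receptor)
        mask = (keys == polar_keys[0]) & (cand.receptor.atom_name != "CA") \
            & (cand.receptor.atom_name != "CB")
        cand.receptor.coord[mask] += [5.0, 0, 0]
        conserved = (n - 1) / n
        kept, fracs = polar_conservation_filter(
            [cand], toy_complex, fraction=conserved - 0.01,
            pocket_residues=toy_pocket.residues,
        )
        assert kept and fracs[0] == pytest.approx(conserved)
        kept, _ = polar_conservation_filter(
            [cand], toy_complex, fraction=conserved + 0.01,
            pocket_residues=toy_pocket.residues,
        )
        assert not kept

    def test_apolar_reference_passes_all_with_warning(self, toy_complex):
        # residues 3-5 of the toy bundle have apolar side chains only
        with pytest.warns(UserWarning):
            kept, fracs = polar_conservation_filter(
                [toy_complex.copy()], toy_complex, fraction=0.8,
                pocket_residues=tuple(toy_complex.residue_keys[2:5]),
            )
        assert kept and fracs == [1.0]


def rmsds_oracle(ref_cpx, cand_cpx, pocket):
    from tests.test_core_model import _brute_kabsch

    ref = _pocket_of(ref_cpx, pocket.residues).ca_coords
    mov = _pocket_of(cand_cpx, pocket.residues).ca_coords
    return _brute_kabsch(ref, mov)[1]


class TestCombinedRank:
    def test_minmax_arithmetic(self):
        models = [_model(-40, 80), _model(-30, 100)]
        ranked = combined_rank(models)
        assert ranked[0].combined_score == pytest.approx(1.0)
        assert ranked[1].combined_score == pytest.approx(0.0)
        assert ranked[0].dock_score == -40

    def test_single_model_gets_half(self):
        ranked = combined_rank([_model(-10, 5)])
        assert ranked[0].combined_score == pytest.approx(0.5)

    def test_identical_models_tie_break_deterministic(self):
        a = _model(-10, 5, replica=1, rnd=0)
        b = _model(-10, 5, replica=0, rnd=1)
        ranked = combined_rank([a, b])
        assert (ranked[0].replica, ranked[0].round) == (0, 1)

    def test_missing_score_raises(self):
        with pytest.raises(RankingError):
            combined_rank([LDMModel(complex=None, dock_score=None,
                                    fold_score=1.0, replica=0, round=0)])

    def test_zero_range_score_contributes_half(self):
        models = [_model(-10, 7), _model(-20, 7)]
        ranked = combined_rank(models)
        assert ranked[0].combined_score == pytest.approx(1.0 * 0.5 + 0.5 * 0.5)


class TestTopK:
    def test_renaming_convention(self):
        models = combined_rank([_model(-float(i), float(i))
                                for i in range(30)])
        top = top_k(models, k=25)
        assert [m.name for m in top][:3] == ["LDM 000", "LDM 001", "LDM 002"]
        assert len(top) == 25

    def test_k_larger_than_available_warns(self):
        models = combined_rank([_model(-1.0, 1.0), _model(-2.0, 2.0)])
        with pytest.warns(UserWarning):
            top = top_k(models, k=25)
        assert len(top) == 2

    def test_k_one_is_single_best(self):
        models = combined_rank([_model(-5, 10), _model(-9, 2)])
        assert len(top_k(models, k=1)) == 1


class TestRunLdm:
    def test_capacity_two_by_three_gives_six(self, toy, small_cfg, wells):
        cpx, topology, bw_map = toy
        models = run_ldm(small_cfg, cpx, topology, bw_map,
                         ToyBackends(contact_wells=wells))
        assert len(models) == 6
        assert len({(m.replica, m.round) for m in models}) == 6

    def test_determinism_same_seed_same_output(self, toy, small_cfg, wells):
        cpx, topology, bw_map = toy
        a = run_ldm(small_cfg, cpx, topology, bw_map,
                    ToyBackends(contact_wells=wells))
        b = run_ldm(small_cfg, cpx, topology, bw_map,
                    ToyBackends(contact_wells=wells))
        for ma, mb in zip(a, b):
            assert ma.dock_score == mb.dock_score
            assert ma.combined_score == mb.combined_score
            assert np.array_equal(ma.complex.receptor.coord,
                                  mb.complex.receptor.coord)
            assert np.array_equal(ma.complex.ligand.coord,
                                  mb.complex.ligand.coord)

    def test_extraction_takes_best_dock_score(self, toy, small_cfg, wells):
        cpx, topology, bw_map = toy
        provenance = []
        run_ldm(small_cfg, cpx, topology, bw_map,
                ToyBackends(contact_wells=wells), provenance=provenance)
        by_round = {}
        for rec in provenance:
            if "dock_score" in rec and "event" not in rec:
                by_round.setdefault((rec["replica"], rec["round"]),
                                    []).append(rec["dock_score"])
        extracted = {(r["replica"], r["round"]): r["dock_score"]
                     for r in provenance if r.get("event") == "extracted"}
        assert extracted
        for key, score in extracted.items():
            assert score == pytest.approx(min(by_round[key]), abs=1e-9)

    def test_impossible_filter_yields_no_models_but_continues(self, toy,
                                                              wells):
        cpx, topology, bw_map = toy
        cfg = LDMConfig(n_replicas=1, n_rounds=2, n_directories_per_round=2,
                        pocket_rmsd_cutoff=1e-9, master_seed=1)
        provenance = []
        models = run_ldm(cfg, cpx, topology, bw_map,
                         ToyBackends(contact_wells=wells),
                         provenance=provenance)
        assert models == []
        assert any(r.get("event") == "round_empty" for r in provenance)

    def test_static_region_never_moves(self, toy, small_cfg, wells):
        from pocketforge.core_model import (
            atom_res_keys, partition_regions, trim_loops,
        )

        cpx, topology, bw_map = toy
        models = run_ldm(small_cfg, cpx, topology, bw_map,
                         ToyBackends(contact_wells=wells))
        prepared = trim_loops(cpx, topology)
        part = partition_regions(prepared, topology, bw_map)
        keys_ref = atom_res_keys(prepared.receptor)
        for m in models:
            keys = atom_res_keys(m.complex.receptor)
            for key in part.cytoplasmic_residues:
                assert np.allclose(
                    m.complex.receptor.coord[keys == key],
                    prepared.receptor.coord[keys_ref == key],
                    atol=1e-9,
                )

    def test_planted_optimum_recovery_single_seed(self, toy, toy_pocket,
                                                  wells):
        cpx, topology, bw_map = toy
        planted = _pocket_of(cpx, toy_pocket.residues)
        start = perturb_complex(cpx, toy_pocket.residues, 1.5, seed=77)
        r0 = kabsch_fit(planted.ca_coords,
                        _pocket_of(start, toy_pocket.residues).ca_coords)[1]
        cfg = LDMConfig(n_replicas=1, n_rounds=8,
                        n_directories_per_round=10, master_seed=5)
        models = run_ldm(cfg, start, topology, bw_map,
                         ToyBackends(contact_wells=wells))
        r1 = kabsch_fit(
            planted.ca_coords,
            _pocket_of(models[0].complex, toy_pocket.residues).ca_coords,
        )[1]
        assert r1 < r0


class TestConfigAndSeeds:
    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            LDMConfig(n_replicas=0)
        with pytest.raises(ConfigError):
            LDMConfig(polar_conservation_fraction=0.0)
        with pytest.raises(ConfigError):
            LDMConfig.from_json('{"bogus_key": 1}')

    def test_json_roundtrip(self):
        cfg = LDMConfig(n_replicas=3, n_rounds=4, master_seed=9)
        assert LDMConfig.from_json(cfg.to_json()) == cfg

    def test_seed_derivation_distinct_and_stable(self):
        seen = {derive_seed(1, r, d, k)
                for r in range(4) for d in range(4) for k in range(4)}
        assert len(seen) == 64
        assert derive_seed(1, 2, 3, 4) == derive_seed(1, 2, 3, 4)
        assert all(0 <= s < 2 ** 63 for s in seen)
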