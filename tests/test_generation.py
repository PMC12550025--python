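"""Sampling schemes, generation metrics against brute-force oracles,
task-specific validity and ligand filtering."""

import itertools

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem, DataStructs

from catgen.generation import (GenerationReport, SamplingScheme,
                               evaluate_generation, generate, latent_box,
                               ligand_filter, sample_latent, task_validity,
                               tanimoto_similarity)


def brute_tanimoto(a, b):
    fa = AllChem.GetMorganFingerprintAsBitVect(Chem.MolFromSmiles(a), 2, 2048)
    fb = AllChem.GetMorganFingerprintAsBitVect(Chem.MolFromSmiles(b), 2, 2048)
    return DataStructs.TanimotoSimilarity(fa, fb)


class TestSampling:
    def test_zero_noise_reproduces_anchor_latent(self, trained_results):
        anchor = trained_results.split.train[0]
        scheme = SamplingScheme("around_sample_sample_condition",
                                noise_scale=0.0, seed=3)
        z, c = sample_latent(scheme, trained_results, anchor=anchor)
        mean, cond = trained_results.encode_records([anchor])
        assert np.allclose(z, mean[0])
        assert np.array_equal(c, cond[0])

    def test_sample_condition_never_foreign(self, trained_results):
        anchor = trained_results.split.train[1]
        _, cond = trained_results.encode_records([anchor])
        rng = np.random.default_rng(0)
        scheme = SamplingScheme("around_sample_sample_condition",
                                noise_scale=0.7)
        for _ in range(20):
            _, c = sample_latent(scheme, trained_results, anchor=anchor,
                                 rng=rng)
            assert np.array_equal(c, cond[0])

    def test_random_scheme_respects_integer_box(self, trained_results):
        means, _ = trained_results.training_latents()
        box = latent_box(means)
        rng = np.random.default_rng(1)
        scheme = SamplingScheme("random_latent_random_condition")
        for _ in range(500):
            z, _ = sample_latent(scheme, trained_results, rng=rng)
            assert np.all(z >= box[0]) and np.all(z <= box[1])

    def test_around_sample_requires_anchor(self, trained_results):
        with pytest.raises(ValueError):
            sample_latent(SamplingScheme("around_sample_random_condition"),
                          trained_results)

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            SamplingScheme("grid")


class TestGenerate:
    def test_n_zero(self, trained_results):
        out = generate(0, SamplingScheme(seed=0), trained_results)
        assert out.smiles == [] and out.reports == []

    def test_fixed_seed_is_deterministic(self, trained_results):
        a = generate(25, SamplingScheme(seed=5), trained_results)
        b = generate(25, SamplingScheme(seed=5), trained_results)
        assert a.smiles == b.smiles

    def test_post_processing_improves_validity(self, trained_results):
        on = generate(60, SamplingScheme(seed=2), trained_results,
                      post_processing=True)
        off = generate(60, SamplingScheme(seed=2), trained_results,
                       post_processing=False)
        assert len(on.valid_smiles) >= len(off.valid_smiles)


class TestMetrics:
    TRAIN = ["CCO", "CCN", "c1ccccc1", "CC(=O)O"]

    def test_self_match(self):
        rep = evaluate_generation(self.TRAIN, self.TRAIN)
        assert rep.valid == 1.0 and rep.unique == 1.0
        assert rep.novel == 0.0 and rep.snn == 1.0

    def test_duplicate_pairs_halve_uniqueness(self):
        rep = evaluate_generation(["CCO", "CCO", "CCN", "CCN"], self.TRAIN)
        assert rep.valid == 1.0 and rep.unique == 0.5

    def test_intdiv_matches_pairwise_oracle(self):
        gen = ["CCO", "c1ccccc1C", "CC(=O)NC"]
        rep = evaluate_generation(gen, self.TRAIN)
        dists = [1 - brute_tanimoto(a, b)
                 for a, b in itertools.combinations(gen, 2)]
        assert rep.intdiv == pytest.approx(np.mean(dists), abs=1e-12)

    def test_snn_matches_bruteforce_oracle(self):
        gen = ["CCOC", "c1ccncc1", "CCCl", None]
        rep = evaluate_generation(gen, self.TRAIN)
        valid = [s for s in gen if s]
        expected = np.mean([max(brute_tanimoto(g, t) for t in self.TRAIN)
                            for g in valid])
        assert rep.snn == pytest.approx(expected, abs=1e-12)

    def test_all_metrics_against_oracle_on_mixed_set(self):
        gen = ["CCO", "CCO", None, "CCOC", "c1ccccc1", "CCN", "xxx"]
        rep = evaluate_generation(gen, self.TRAIN)
        n = len(gen)
        valid = [Chem.CanonSmiles(s) for s in gen
                 if s and Chem.MolFromSmiles(s)]
        distinct = sorted(set(valid))
        train = {Chem.CanonSmiles(t) for t in self.TRAIN}
        novel = [s for s in distinct if s not in train]
        assert rep.valid == len(valid) / n
        assert rep.unique == len(distinct) / n
        assert rep.novel == len(novel) / n

    def test_chain_inequality_on_random_reports(self, trained_results):
        train = [r.catalyst for r in trained_results.split.train]
        for seed in range(5):
            out = generate(30, SamplingScheme(seed=seed), trained_results)
            rep = evaluate_generation(out, train)   # __post_init__ asserts
            assert rep.novel <= rep.unique <= rep.valid <= 1.0

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            evaluate_generation(["CCO"], [])


class TestTaskValidity:
    @pytest.mark.parametrize("smi,rule,expected", [
        ("c1ccccc1", "single_fragment", True),
        ("CC.O", "single_fragment", False),
        ("c1ccccc1P(C)C.[Pd].P(C)(C)C", "three_fragment_metal", True),
        ("c1ccccc1", "three_fragment_metal", False),
        ("CC.[Pd].CC.CC", "three_fragment_metal", False),   # 4 fragments
        ("CC(=O)O[Pd]OC(C)=O", "pd_acetate", True),
        ("CC(=O)[O-].CC(=O)[O-].[Pd+2]", "pd_acetate", True),
        ("c1ccccc1P(C)C", "pd_acetate", False),
    ])
    def test_builtin_rules(self, smi, rule, expected):
        assert task_validity(smi, rule) is expected

    def test_fragment_metal_census_oracle(self, fixture_dataset):
        from catgen.generation import METALS
        for rec in fixture_dataset.records[:40]:
            smi = rec.catalyst
            frags = smi.split(".")
            lone_metals = sum(f.strip("[]") in METALS for f in frags)
            expected = len(frags) == 3 and lone_metals == 1
            assert task_validity(smi, "three_fragment_metal") is expected

    def test_unknown_rule(self):
        with pytest.raises(KeyError):
            task_validity("CCO", "nope")

    def test_user_registered_rule(self):
        from catgen.generation import register_task_rule
        register_task_rule("has_ring", lambda m: m.GetRingInfo().NumRings() > 0)
        assert task_validity("c1ccccc1", "has_ring")
        assert not task_validity("CCO", "has_ring")


class TestLigandFilter:
    def test_triphenylphosphine_passes(self):
        ok, v = ligand_filter("c1ccccc1P(c1ccccc1)c1ccccc1")
        assert ok and v == []

    def test_benzene_fails_no_n_or_p(self):
        ok, v = ligand_filter("c1ccccc1")
        assert not ok and v == ["missing_n_or_p"]

    def test_phosphirane_lists_both_violations(self):
        ok, v = ligand_filter("C1CP1")   # P-H and P in 3-ring
        assert not ok
        assert set(v) == {"p_h_bond", "p_in_three_membered_ring"}

    def test_amine_without_p_passes(self):
        ok, v = ligand_filter("CCN")
        assert ok

    def test_overbonded_phosphorus_flagged(self):
        ok, v = ligand_filter("CP(C)(C)(C)C")   # P with 5 bonds
        assert not ok and "phosphine_not_three_bonds" in v
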