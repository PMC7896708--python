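"""Fingerprints, Tanimoto similarity and the diet-max index."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from resistsurv import chemsim
from resistsurv.chemsim import (
    FingerprintConfig,
    SmilesError,
    diet_similarity_index,
    fingerprint,
    fingerprint_smiles,
    parse_smiles,
    similarity_by_moa_summary,
    tanimoto,
)


class TestParseSmiles:
    def test_minimal_molecule_parses(self):
        assert parse_smiles("C") is not None

    @pytest.mark.parametrize("bad", ["", "   ", "notasmiles((", "C(("])
    def test_invalid_smiles_raise(self, bad):
        with pytest.raises(SmilesError):
            parse_smiles(bad)

    def test_benzene_has_six_heavy_atoms(self):
        assert parse_smiles("c1ccccc1").GetNumHeavyAtoms() == 6


class TestFingerprint:
    def test_deterministic_for_identical_smiles(self):
        a = fingerprint_smiles("CC(=O)Oc1ccccc1C(=O)O")
        b = fingerprint_smiles("CC(=O)Oc1ccccc1C(=O)O")
        assert np.array_equal(a, b)

    def test_different_molecules_differ(self):
        assert not np.array_equal(fingerprint_smiles("C"), fingerprint_smiles("CCCCCCCC"))

    def test_bonded_molecule_sets_bits(self):
        assert fingerprint_smiles("CCO").sum() >= 1

    def test_length_configurable(self):
        fp = fingerprint_smiles("CCO", FingerprintConfig(n_bits=256))
        assert len(fp) == 256

    def test_too_short_length_rejected(self):
        with pytest.raises(ValueError):
            FingerprintConfig(n_bits=32)


def _bits(on, length=8):
    v = np.zeros(length, dtype=bool)
    v[list(on)] = True
    return v


class TestTanimoto:
    def test_self_similarity_is_one(self):
        fp = fingerprint_smiles("c1ccccc1O")
        assert tanimoto(fp, fp) == 1.0

    def test_disjoint_sets_are_zero(self):
        assert tanimoto(_bits({0, 1}), _bits({2, 3})) == 0.0

    def test_explicit_set_arithmetic(self):
        # |{1,2} & {1,3}| = 1, |{1,2} | {1,3}| = 3
        assert tanimoto(_bits({1, 2}), _bits({1, 3})) == pytest.approx(1 / 3)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            tanimoto(_bits({1}), _bits({1}, length=16))

    def test_all_zero_pair_is_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert tanimoto(_bits(set()), _bits(set())) == 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_symmetry_on_random_pairs(self, seed):
        r = np.random.default_rng(seed)
        a, b = r.random(64) < 0.3, r.random(64) < 0.3
        assert tanimoto(a, b) == tanimoto(b, a)

    def test_agrees_with_rdkit_on_real_molecules(self):
        # independent oracle: RDKit's own bit-vector Tanimoto
        from rdkit import Chem, DataStructs

        cfg = FingerprintConfig()
        smiles = ["CCO", "c1ccccc1", "CC(=O)Oc1ccccc1C(=O)O", "CN1C=NC2=C1C(=O)N(C(=O)N2C)C"]
        for s1 in smiles:
            for s2 in smiles:
                bv1 = Chem.RDKFingerprint(parse_smiles(s1), minPath=1, maxPath=cfg.max_path,
                                          fpSize=cfg.n_bits, nBitsPerHash=2)
                bv2 = Chem.RDKFingerprint(parse_smiles(s2), minPath=1, maxPath=cfg.max_path,
                                          fpSize=cfg.n_bits, nBitsPerHash=2)
                expected = DataStructs.TanimotoSimilarity(bv1, bv2)
                got = tanimoto(fingerprint_smiles(s1, cfg), fingerprint_smiles(s2, cfg))
                assert got == pytest.approx(expected, abs=1e-12)


def _brute_force_max(ins_fp, diet_fps):
    best, best_id = -1.0, None
    for pid in sorted(diet_fps):
        inter = np.count_nonzero(ins_fp & diet_fps[pid])
        union = np.count_nonzero(ins_fp | diet_fps[pid])
        s = inter / union if union else 0.0
        if s > best:
            best, best_id = s, pid
    return best, best_id


class TestDietSimilarityIndex:
    def test_identical_compound_in_diet_scores_one(self):
        # a pyrethrin-like case: insecticide structurally identical to a diet compound
        fps = {
            "ins": fingerprint_smiles("CC(C)=CC1C(C(=O)OC)C1(C)C"),
            "p_same": fingerprint_smiles("CC(C)=CC1C(C(=O)OC)C1(C)C"),
            "p_other": fingerprint_smiles("CCO"),
        }
        idx = diet_similarity_index("ins", ["p_other", "p_same"], fps)
        assert idx.score == 1.0
        assert idx.closest_phytochemical_id == "p_same"

    def test_singleton_diet_equals_pairwise(self):
        fps = {"ins": fingerprint_smiles("c1ccccc1"), "p": fingerprint_smiles("c1ccccc1O")}
        idx = diet_similarity_index("ins", ["p"], fps)
        assert idx.score == pytest.approx(tanimoto(fps["ins"], fps["p"]))

    def test_matches_brute_force_over_random_sets(self, rng):
        for _ in range(20):
            fps = {f"p{i}": rng.random(128) < 0.2 for i in range(5)}
            fps["ins"] = rng.random(128) < 0.2
            expected, expected_id = _brute_force_max(fps["ins"], {k: v for k, v in fps.items() if k != "ins"})
            idx = diet_similarity_index("ins", [f"p{i}" for i in range(5)], fps)
            assert idx.score == pytest.approx(expected)
            assert idx.closest_phytochemical_id == expected_id

    def test_monotone_under_diet_growth(self, rng):
        fps = {f"p{i}": rng.random(128) < 0.2 for i in range(8)}
        fps["ins"] = rng.random(128) < 0.2
        prev = -1.0
        for k in range(1, 9):
            idx = diet_similarity_index("ins", [f"p{i}" for i in range(k)], fps)
            assert idx.score >= prev
            prev = idx.score

    def test_empty_diet_errors(self):
        with pytest.raises(ValueError):
            diet_similarity_index("ins", [], {"ins": _bits({1})})

    def test_tie_broken_lexicographically(self):
        fp = _bits({1, 2, 3}, 64)
        fps = {"ins": fp, "pb": fp.copy(), "pa": fp.copy()}
        idx = diet_similarity_index("ins", ["pb", "pa"], fps)
        assert idx.closest_phytochemical_id == "pa"


class TestBuildSimilarityTable:
    def test_unparseable_smiles_land_in_exclusion_ledger(self):
        compounds = pd.DataFrame(
            {
                "id": ["i1", "p1", "p2"],
                "smiles": ["c1ccccc1", "CCO", "not_a_smiles(("],
                "kind": ["insecticide", "phytochemical", "phytochemical"],
            }
        )
        diet = pd.DataFrame({"pest_id": ["sp1", "sp1"], "phytochemical_id": ["p1", "p2"]})
        table, excl = chemsim.build_similarity_table(compounds, diet)
        assert list(excl["id"]) == ["p2"]
        assert len(table) == 1
        assert table.loc[0, "closest_phytochemical_id"] == "p1"

    def test_pest_without_usable_diet_is_excluded(self):
        compounds = pd.DataFrame(
            {"id": ["i1", "p1"], "smiles": ["CCO", "(("], "kind": ["insecticide", "phytochemical"]}
        )
        diet = pd.DataFrame({"pest_id": ["sp1"], "phytochemical_id": ["p1"]})
        table, excl = chemsim.build_similarity_table(compounds, diet)
        assert table.empty
        assert set(excl["id"]) == {"p1", "sp1"}


class TestMoaSummary:
    def test_constant_scores_have_zero_iqr(self):
        sim = pd.DataFrame(
            {"pest_id": ["a"] * 3, "insecticide_id": ["i1", "i2", "i3"],
             "score": [0.4] * 3, "closest_phytochemical_id": ["p"] * 3}
        )
        out = similarity_by_moa_summary(sim, {"i1": "m1", "i2": "m1", "i3": "m2"})
        row = out[out["moa_class"] == "m1"].iloc[0]
        assert row["q3"] - row["q1"] == 0.0

    def test_quartiles_match_order_statistics(self):
        scores = [0.0, 0.25, 0.5, 0.75, 1.0]
        sim = pd.DataFrame(
            {"pest_id": ["a"] * 5, "insecticide_id": [f"i{k}" for k in range(5)],
             "score": scores, "closest_phytochemical_id": ["p"] * 5}
        )
        out = similarity_by_moa_summary(sim, {f"i{k}": "m" for k in range(5)})
        row = out[out["moa_class"] == "m"].iloc[0]
        assert (row["min"], row["q1"], row["median"], row["q3"], row["max"]) == (0.0, 0.25, 0.5, 0.75, 1.0)
        glob = out[out["moa_class"] == "__all__"].iloc[0]
        assert glob["min"] == 0.0 and glob["max"] == 1.0

    def test_missing_moa_class_errors(self):
        sim = pd.DataFrame(
            {"pest_id": ["a"], "insecticide_id": ["i1"], "score": [0.1],
             "closest_phytochemical_id": ["p"]}
        )
        with pytest.raises(KeyError):
            similarity_by_moa_summary(sim, {})
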