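"""Chemistry I/O, tokenization, splits and the synthetic generator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mffgnn import (build_dataset, fit_vocabulary, generate_synthetic,
                    make_splits, pad_or_cut, parse_smiles, read_dataset,
                    tokenize_smiles, write_dataset)
from mffgnn.data import SmilesParseError


class TestParseSmiles:
    @pytest.mark.parametrize("smiles,n_atoms,n_directed_edges", [
        ("CCO", 3, 4),
        ("C", 1, 0),
        ("c1ccccc1", 6, 12),
    ])
    def test_atom_and_edge_counts(self, smiles, n_atoms, n_directed_edges):
        g = parse_smiles(smiles)
        assert g.n_atoms == n_atoms
        assert len(g.edge_src) == n_directed_edges

    def test_benzene_all_atoms_aromatic(self):
        g = parse_smiles("c1ccccc1")
        # aromatic flag sits after element (13) + charge (5) one-hot blocks
        assert np.all(g.atom_features[:, 18] == 1.0)
        # all bonds aromatic
        assert np.all(g.bond_features[:, 3] == 1.0)

    def test_directed_edges_mirror_each_other(self):
        g = parse_smiles("CC(=O)Oc1ccccc1C(=O)O")
        pairs = {(int(s), int(d)) for s, d in zip(g.edge_src, g.edge_dst)}
        assert pairs == {(d, s) for s, d in pairs}
        assert not any(s == d for s, d in pairs)

    def test_one_hot_blocks_sum_to_one(self):
        g = parse_smiles("C[NH+](C)C")
        f = g.atom_features
        blocks = [(0, 13), (13, 18), (19, 26), (26, 30), (30, 37)]
        for a, b in blocks:
            assert np.allclose(f[:, a:b].sum(axis=1), 1.0)

    @pytest.mark.parametrize("bad", ["", "not_a_smiles", "C(("])
    def test_rejects_unparsable(self, bad):
        with pytest.raises(SmilesParseError):
            parse_smiles(bad)


class TestTokenizer:
    @pytest.mark.parametrize("smiles,expected", [
        ("CCO", ["C", "C", "O"]),
        ("CC(Cl)Br", ["C", "C", "(", "Cl", ")", "Br"]),
        ("C[NH+](C)C", ["C", "[NH+]", "(", "C", ")", "C"]),
        ("c1ccccc1", ["c", "1", "c", "c", "c", "c", "c", "1"]),
    ])
    def test_examples(self, smiles, expected):
        assert tokenize_smiles(smiles) == expected

    def test_unbalanced_brackets_rejected(self):
        with pytest.raises(ValueError):
            tokenize_smiles("C[NH2")

    def test_vocabulary_first_appearance_order(self):
        vocab = fit_vocabulary([["C", "C", "O"]])
        assert vocab == {"<pad>": 0, "C": 1, "O": 2}

    def test_vocabulary_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            fit_vocabulary([])

    def test_vocabulary_is_order_sensitive(self):
        a = fit_vocabulary([["C", "O"], ["N"]])
        b = fit_vocabulary([["O", "C"], ["N"]])
        assert a != b


class TestPadOrCut:
    def test_pads_with_zeros(self):
        seq = pad_or_cut(np.arange(1, 11), 150)
        assert seq.valid_length == 10
        assert np.all(seq.token_ids[10:] == 0)

    def test_cuts_tail(self):
        seq = pad_or_cut(np.arange(1, 201), 150)
        assert seq.valid_length == 150
        assert np.array_equal(seq.token_ids, np.arange(1, 151))

    @given(st.integers(1, 40), st.integers(0, 60))
    @settings(max_examples=30, deadline=None)
    def test_idempotent(self, L_s, n_tokens):
        ids = np.arange(1, n_tokens + 1)
        once = pad_or_cut(ids, L_s)
        twice = pad_or_cut(once.token_ids, L_s)
        assert np.array_equal(once.token_ids, twice.token_ids)
        # re-padding a padded sequence keeps at most the same content
        assert twice.valid_length >= once.valid_length


class TestReadDataset:
    def _write(self, tmp_path, drugs, edges):
        dp = tmp_path / "drugs.csv"
        ep = tmp_path / "edges.csv"
        dp.write_text("drug_id,smiles\n" +
                      "\n".join(f"{i},{s}" for i, s in drugs) + "\n")
        ep.write_text("drug_id_a,drug_id_b\n" +
                      "\n".join(f"{a},{b}" for a, b in edges) + "\n")
        return dp, ep

    def test_basic_read(self, tmp_path):
        dp, ep = self._write(tmp_path,
                             [("d1", "CCO"), ("d2", "CCN"), ("d3", "CCC")],
                             [("d1", "d2"), ("d2", "d3")])
        ds = read_dataset(dp, ep, L_s=20)
        assert ds.n_drugs == 3
        assert len(ds.positive_pairs) == 2
        ds.validate()

    def test_self_edge_rejected(self, tmp_path):
        dp, ep = self._write(tmp_path, [("d1", "CCO"), ("d2", "CCN")],
                             [("d1", "d1")])
        with pytest.raises(ValueError, match="self-interaction"):
            read_dataset(dp, ep)

    def test_duplicate_ids_rejected(self, tmp_path):
        dp, ep = self._write(tmp_path, [("d1", "CCO"), ("d1", "CCN")],
                             [("d1", "d1")])
        with pytest.raises(ValueError, match="duplicate drug ids"):
            read_dataset(dp, ep)

    def test_missing_column_rejected(self, tmp_path):
        dp = tmp_path / "drugs.csv"
        dp.write_text("id,smiles\nd1,CCO\n")
        ep = tmp_path / "edges.csv"
        ep.write_text("drug_id_a,drug_id_b\n")
        with pytest.raises(ValueError, match="missing column"):
            read_dataset(dp, ep)

    def test_unparsable_drug_and_incident_edge_dropped(self, tmp_path):
        dp, ep = self._write(
            tmp_path,
            [("d1", "CCO"), ("d2", "xyzzy"), ("d3", "CCC")],
            [("d1", "d3"), ("d1", "d2")])
        ds = read_dataset(dp, ep, L_s=20)
        assert ds.n_drugs == 2
        assert len(ds.positive_pairs) == 1

    def test_write_read_round_trip(self, tmp_path):
        ds = generate_synthetic(8, 2, 0.8, 0.1, seed=2, L_s=20)
        write_dataset(ds, tmp_path)
        ds2 = read_dataset(tmp_path / "drugs.csv", tmp_path / "edges.csv",
                           L_s=20)
        assert {d.smiles for d in ds.drugs} == {d.smiles for d in ds2.drugs}
        ids = lambda d, p: {(d.drugs[i].drug_id, d.drugs[j].drug_id)
                            for i, j in p}
        assert ids(ds, ds.positive_pairs) == ids(ds2, ds2.positive_pairs)


class TestMakeSplits:
    def test_partition_sizes_64_16_20(self):
        from mffgnn.data import SMILES_LIBRARY
        records = [(f"d{i}", s) for i, s in enumerate(SMILES_LIBRARY[:25])]
        # exactly 100 positive pairs over 25 drugs (300 possible)
        pairs = [(f"d{i}", f"d{j}") for i in range(25)
                 for j in range(i + 1, 25)][:100]
        ds = build_dataset(records, pairs, L_s=20)
        assert len(ds.positive_pairs) == 100
        sp = make_splits(ds, seed=0)
        assert (len(sp.train_pos), len(sp.val_pos), len(sp.test_pos)) \
            == (64, 16, 20)
        assert (len(sp.train_neg), len(sp.val_neg), len(sp.test_neg)) \
            == (64, 16, 20)

    def test_partitions_disjoint_and_cover(self, tiny_dataset, tiny_splits):
        parts = [set(tiny_splits.train_pos), set(tiny_splits.val_pos),
                 set(tiny_splits.test_pos)]
        assert parts[0] | parts[1] | parts[2] == tiny_dataset.positive_pairs
        assert not (parts[0] & parts[1] or parts[0] & parts[2]
                    or parts[1] & parts[2])

    def test_deterministic_under_seed(self, tiny_dataset):
        a = make_splits(tiny_dataset, seed=9)
        b = make_splits(tiny_dataset, seed=9)
        assert a == b

    def test_negatives_never_positive_exhaustive(self):
        """Brute-force check on a 6-drug graph over many seeds: sampled
        negatives never collide with positives, within or across parts."""
        records = [(f"d{i}", s) for i, s in enumerate(
            ["CCO", "CCN", "CCC", "CCF", "COC", "CNC"])]
        pairs = [("d0", "d1"), ("d1", "d2"), ("d2", "d3"), ("d3", "d4"),
                 ("d4", "d5"), ("d0", "d5")]
        ds = build_dataset(records, pairs, L_s=20)
        for seed in range(50):
            sp = make_splits(ds, seed=seed)
            negs = sp.train_neg + sp.val_neg + sp.test_neg
            assert len(set(negs)) == len(negs)
            assert not set(negs) & ds.positive_pairs

    def test_too_dense_graph_errors(self):
        records = [(f"d{i}", s) for i, s in enumerate(
            ["CCO", "CCN", "CCC", "CCF", "COC"])]
        pairs = [(f"d{i}", f"d{j}") for i in range(5) for j in range(i + 1, 5)]
        ds = build_dataset(records, pairs, L_s=20)
        with pytest.raises(ValueError, match="too dense"):
            make_splits(ds, seed=0)


class TestGenerateSynthetic:
    def test_deterministic(self):
        a = generate_synthetic(20, 2, 0.6, 0.05, seed=7, L_s=20)
        b = generate_synthetic(20, 2, 0.6, 0.05, seed=7, L_s=20)
        assert a.positive_pairs == b.positive_pairs
        assert [d.smiles for d in a.drugs] == [d.smiles for d in b.drugs]

    def test_degenerate_probabilities(self):
        ds = generate_synthetic(10, 2, 1.0 - 1e-12, 0.0, seed=1, L_s=20)
        community = [i * 2 // 10 for i in range(10)]
        for i, j in ds.positive_pairs:
            assert community[i] == community[j]
        n_within = sum(1 for i in range(10) for j in range(i + 1, 10)
                       if community[i] == community[j])
        assert len(ds.positive_pairs) == n_within

    def test_adjacency_symmetric_zero_diagonal(self):
        for seed in range(5):
            ds = generate_synthetic(15, 3, 0.7, 0.1, seed=seed, L_s=20)
            ds.validate()

    def test_expected_edge_count(self):
        """Mean edge count over many seeds approximates
        p_in * 2 * C(10,2) + p_out * 100 = 59 for (20, 2, 0.6, 0.05)."""
        counts = [len(generate_synthetic(20, 2, 0.6, 0.05, seed=s,
                                         L_s=20).positive_pairs)
                  for s in range(200)]
        # sd of a single draw is ~6.3, so the mean of 200 has se ~0.45
        assert abs(np.mean(counts) - 59.0) < 1.5

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            generate_synthetic(1, 2, 0.6, 0.05, seed=0)
        with pytest.raises(ValueError):
            generate_synthetic(10, 2, 0.3, 0.5, seed=0)
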