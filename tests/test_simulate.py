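"""Benchmark simulator: database evolution, read errors, confusion tallies."""

import numpy as np
import pytest

from bayeslca.formats import UNCLASSIFIED, RankAssignment, ResultRow
from bayeslca.simulate import (
    SimConfig,
    f_score,
    mutate_read,
    precision_recall,
    simulate_queries,
    simulate_reference,
    tally_confusion,
    write_benchmark,
)

from .conftest import random_dna


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


class TestSimulateReference:
    def test_sibling_species_divergence(self):
        cfg = SimConfig(n_phyla=1, genera_per_family=1, species_per_genus=2,
                        seq_length=1000,
                        divergence={"species": 0.03}, seed=2)
        refs, tree, _ = simulate_reference(cfg)
        assert len(refs) == 2
        d = hamming(refs[0].seq, refs[1].seq)
        # ~30 differing positions expected; allow generous binomial slack
        assert 10 <= d <= 55

    def test_deterministic_for_fixed_seed(self):
        cfg = SimConfig(seed=9, n_queries=5, seq_length=200)
        a = simulate_reference(cfg)
        b = simulate_reference(cfg)
        assert [r.seq for r in a[0]] == [r.seq for r in b[0]]
        qa, ta = simulate_queries(a[0], cfg)
        qb, tb = simulate_queries(b[0], cfg)
        assert [q.seq for q in qa] == [q.seq for q in qb] and ta == tb

    def test_between_genus_exceeds_within_genus_distance(self):
        cfg = SimConfig(n_phyla=1, genera_per_family=2, species_per_genus=2,
                        seq_length=1000,
                        divergence={"genus": 0.10, "species": 0.02}, seed=4)
        refs, tree, _ = simulate_reference(cfg)
        by_genus = {}
        for r in refs:
            genus = tree.ancestor_at(r.taxid, "genus")
            by_genus.setdefault(genus, []).append(r.seq)
        (g1a, g1b), (g2a, g2b) = by_genus.values()
        within = max(hamming(g1a, g1b), hamming(g2a, g2b))
        between = min(hamming(a, b) for a in (g1a, g1b) for b in (g2a, g2b))
        assert between > within

    def test_truth_map_covers_all_references(self):
        cfg = SimConfig(seed=1, seq_length=150)
        refs, tree, ref_to_leaf = simulate_reference(cfg)
        assert set(ref_to_leaf) == {r.id for r in refs}
        for r in refs:
            assert tree.rank(r.taxid) == "species"

    def test_zero_divergence_warns(self):
        cfg = SimConfig(n_phyla=1, species_per_genus=3, seq_length=100,
                        divergence={"species": 0.0})
        with pytest.warns(UserWarning, match="indistinguishable"):
            simulate_reference(cfg)


class TestMutateRead:
    def test_zero_rate_is_identity(self):
        rng = np.random.default_rng(0)
        seq = random_dna(rng, 200)
        assert mutate_read(seq, 0.0, rng) == seq

    def test_substitutions_change_the_base(self):
        rng = np.random.default_rng(1)
        seq = random_dna(rng, 100)
        for _ in range(20):
            mutated = mutate_read(seq, 0.1, rng)
            assert len(mutated) == len(seq)
            for a, b in zip(seq, mutated):
                if a != b:
                    assert b in "ACGT"

    def test_mean_mutation_count_tracks_rate(self):
        rng = np.random.default_rng(2)
        seq = random_dna(rng, 100)
        n = 3000
        total = sum(hamming(seq, mutate_read(seq, 0.01, rng)) for _ in range(n))
        mean = total / n
        # Poisson mean 1.0, back-mutations negligible; 3 SE band for n=3000
        assert abs(mean - 1.0) < 3.0 / np.sqrt(n) + 0.02

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            mutate_read("ACGT", 1.5, np.random.default_rng(0))


def _result(qid, **rank_names):
    ranks = ("phylum", "class", "order", "family", "genus", "species")
    assignments = []
    for rank in ranks:
        name = rank_names.get(rank, UNCLASSIFIED)
        conf = None if name == UNCLASSIFIED else 1.0
        assignments.append(RankAssignment(rank, name, conf))
    return ResultRow(qid, tuple(assignments))


class TestConfusion:
    @pytest.fixture
    def small_truth(self):
        cfg = SimConfig(n_phyla=1, genera_per_family=2, species_per_genus=2,
                        seq_length=100, n_queries=4, seed=6)
        refs, tree, _ = simulate_reference(cfg)
        queries, truth = simulate_queries(refs, cfg)
        return tree, truth

    def _perfect(self, tree, truth):
        rows = []
        for qid, leaf in truth.items():
            names = {rt.rank: rt.name for rt in tree.lineage_of(leaf)}
            names.pop("superkingdom", None)
            rows.append(_result(qid, **names))
        return rows

    def test_all_correct_has_no_errors(self, small_truth):
        tree, truth = small_truth
        tally = tally_confusion(self._perfect(tree, truth), truth, tree)
        for rank in ("phylum", "genus", "species"):
            tp, fn, fp, tn = tally[rank]
            assert fn == fp == 0
            assert tp == len(truth)
            assert f_score(tally, rank) == 1.0

    def test_all_unclassified_is_pure_false_negative(self, small_truth):
        tree, truth = small_truth
        rows = [_result(qid) for qid in truth]
        tally = tally_confusion(rows, truth, tree)
        for rank in ("phylum", "genus", "species"):
            tp, fn, fp, tn = tally[rank]
            assert tp == 0 and fp == 0 and fn == len(truth)
            assert f_score(tally, rank) == 0.0

    def test_single_genus_error_matches_hand_count(self, small_truth):
        tree, truth = small_truth
        rows = self._perfect(tree, truth)
        # corrupt the genus (and species) of the first query
        first = rows[0]
        names = {a.rank: a.name for a in first.assignments}
        names["genus"] = "Genus_wrong"
        names["species"] = "Species_wrong"
        rows[0] = _result(first.query_id, **names)
        tally = tally_confusion(rows, truth, tree)
        tp, fn, fp, tn = tally["genus"]
        assert (tp, fn, fp) == (3, 1, 1)
        assert tally["phylum"][:2] == (4, 0)

    def test_id_mismatch_rejected(self, small_truth):
        tree, truth = small_truth
        rows = self._perfect(tree, truth)[:-1]
        with pytest.raises(ValueError, match="query ids"):
            tally_confusion(rows, truth, tree)


class TestFScore:
    @pytest.mark.parametrize(
        "tp,fn,fp,expected",
        [
            (50, 50, 50, 0.5),
            (0, 10, 10, 0.0),
            (90, 30, 10, 2 * 0.9 * 0.75 / (0.9 + 0.75)),
        ],
    )
    def test_worked_examples(self, tp, fn, fp, expected):
        from bayeslca.simulate import ConfusionTally

        tally = ConfusionTally(counts={"species": (tp, fn, fp, 0)})
        assert f_score(tally, "species") == pytest.approx(expected)

    def test_bounds_and_perfection(self):
        from bayeslca.simulate import ConfusionTally

        rng = np.random.default_rng(3)
        for _ in range(50):
            tp, fn, fp = (int(x) for x in rng.integers(0, 100, size=3))
            tally = ConfusionTally(counts={"species": (tp, fn, fp, 0)})
            f = f_score(tally, "species")
            assert 0.0 <= f <= 1.0
            if f == 1.0:
                assert fn == fp == 0 and tp > 0


class TestWriteBenchmark:
    def test_emitted_files_are_consistent(self, tmp_path):
        cfg = SimConfig(n_phyla=1, genera_per_family=2, species_per_genus=2,
                        seq_length=120, n_queries=3, seed=8)
        paths = write_benchmark(cfg, tmp_path)
        from bayeslca.formats import read_fasta, read_taxid_map
        from bayeslca.taxonomy import load_lineage_tsv

        refs = read_fasta(paths["references"])
        mapping = read_taxid_map(paths["taxid_map"])
        tree = load_lineage_tsv(paths["lineage"])
        queries = read_fasta(paths["queries"])
        assert {r.id for r in refs} == set(mapping)
        assert all(mapping[r.id] in tree for r in refs)
        assert len(queries) == 3
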