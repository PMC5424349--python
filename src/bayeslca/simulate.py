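"""Synthetic marker-gene benchmark: reference database, noisy reads, scoring.

The generator emulates the structure a classifier benchmark needs: a
multi-rank taxonomy (phylum ... species under a bacterial root) whose
reference sequences diverge progressively with rank — an ancestral sequence
is evolved down the tree, and at each rank split every child receives
substitutions at half the configured per-rank divergence, so two siblings
created at a split differ by roughly the configured fraction — and query
reads drawn from known leaf species carrying sequencing errors: each read
receives a Poisson-distributed number of substitutions with mean
``rate × length`` (default rate 1%, the upper range reported for Illumina
MiSeq), at uniformly chosen positions, each substituted base replaced by a
uniformly chosen different base (substitution-only; an indel option exists
but defaults to off).

Evaluation follows the standard per-rank confusion tally: for each rank and
each taxon label, a prediction is a true positive if truth and prediction
agree on that label, a false negative if the truth carries the label but
the prediction does not (including "unclassified"), a false positive if the
prediction carries the label but the truth does not; counts are summed over
labels and turned into precision / recall / F-score.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .formats import (
    UNCLASSIFIED,
    QueryRecord,
    ReferenceRecord,
    ResultRow,
    write_fasta,
)
from .taxonomy import CANONICAL_RANKS, TaxonomyTree

__all__ = [
    "SimConfig",
    "ConfusionTally",
    "simulate_reference",
    "simulate_queries",
    "mutate_read",
    "tally_confusion",
    "f_score",
    "precision_recall",
    "write_benchmark",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Rank order used by the simulated taxonomy (root is a superkingdom node).
SIM_RANKS = ("phylum", "class", "order", "family", "genus", "species")

_DEFAULT_DIVERGENCE = {
    "phylum": 0.20,
    "class": 0.10,
    "order": 0.08,
    "family": 0.06,
    "genus": 0.15,
    "species": 0.05,
}


@dataclass(frozen=True)
class SimConfig:
    """Shape and noise parameters of the synthetic benchmark.

    ``divergence[rank]`` is the approximate pairwise substitution fraction
    between siblings created at that rank's split (each child is mutated at
    half that rate relative to the parent sequence).  ``mutation_rate`` is
    the expected per-base substitution rate of simulated reads.
    """

    n_phyla: int = 2
    classes_per_phylum: int = 1
    orders_per_class: int = 1
    families_per_order: int = 1
    genera_per_family: int = 5
    species_per_genus: int = 5
    seq_length: int = 1000
    divergence: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_DIVERGENCE)
    )
    mutation_rate: float = 0.01
    indel_rate: float = 0.0
    n_queries: int = 200
    subregion: tuple[int, int] | None = None  # (start, length), 0-based window
    seed: int = 0

    def __post_init__(self):
        counts = (
            self.n_phyla, self.classes_per_phylum, self.orders_per_class,
            self.families_per_order, self.genera_per_family,
            self.species_per_genus, self.seq_length, self.n_queries,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all counts and lengths must be >= 1")
        rates = [self.mutation_rate, self.indel_rate, *self.divergence.values()]
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("rates must lie in [0, 1]")

    @property
    def children_per_rank(self) -> dict[str, int]:
        return {
            "phylum": self.n_phyla,
            "class": self.classes_per_phylum,
            "order": self.orders_per_class,
            "family": self.families_per_order,
            "genus": self.genera_per_family,
            "species": self.species_per_genus,
        }


@dataclass
class ConfusionTally:
    """Per-rank TP/FN/FP/TN counts summed over taxon labels."""

    counts: dict[str, tuple[int, int, int, int]]  # rank -> (tp, fn, fp, tn)

    def __getitem__(self, rank: str) -> tuple[int, int, int, int]:
        return self.counts[rank]


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------

def _mutate_positions(seq: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Substitute k distinct positions, each to a different base."""
    out = seq.copy()
    if k == 0:
        return out
    pos = rng.choice(seq.size, size=k, replace=False)
    old = out[pos]
    # draw among the 3 alternatives by offsetting the base index
    base_idx = np.searchsorted(_BASES, old)
    shift = rng.integers(1, 4, size=k)
    out[pos] = _BASES[(base_idx + shift) % 4]
    return out


def mutate_read(seq: str, rate: float, rng: np.random.Generator) -> str:
    """One simulated read: Poisson(rate × length) substitutions, positions
    uniform without replacement, each to a uniformly chosen different base."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("mutation rate must lie in [0, 1]")
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    k = min(int(rng.poisson(rate * arr.size)), arr.size)
    return _mutate_positions(arr, k, rng).tobytes().decode("ascii")


def _diverge(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Child sequence at a rank split: Binomial(L, rate) substitutions."""
    k = int(rng.binomial(seq.size, rate))
    return _mutate_positions(seq, k, rng)


def simulate_reference(
    cfg: SimConfig,
) -> tuple[list[ReferenceRecord], TaxonomyTree, dict[str, str]]:
    """Generate the reference database.

    Returns ``(references, tree, ref_to_leaf)`` where each leaf species owns
    exactly one reference sequence and ``ref_to_leaf`` maps reference ids to
    their species taxids.  Deterministic for a fixed ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    for rank, n in cfg.children_per_rank.items():
        if n > 1 and cfg.divergence.get(rank, 0.0) == 0.0:
            import warnings

            warnings.warn(
                f"divergence 0 at rank {rank!r} with {n} children: "
                "siblings are indistinguishable by construction",
                stacklevel=2,
            )
    root_seq = _BASES[rng.integers(0, 4, size=cfg.seq_length)]
    nodes: dict[str, tuple[str, str, str | None]] = {
        "root": ("Bacteria", "superkingdom", None)
    }
    references: list[ReferenceRecord] = []
    ref_to_leaf: dict[str, str] = {}

    def descend(parent_id: str, parent_seq: np.ndarray, level: int) -> None:
        rank = SIM_RANKS[level]
        n_children = cfg.children_per_rank[rank]
        half_rate = cfg.divergence.get(rank, 0.0) / 2.0
        for i in range(1, n_children + 1):
            taxid = f"{parent_id}.{rank[0]}{i}" if parent_id != "root" else f"{rank[0]}{i}"
            name = f"{rank.capitalize()}_{taxid}"
            nodes[taxid] = (name, rank, parent_id)
            child_seq = _diverge(parent_seq, half_rate, rng)
            if level == len(SIM_RANKS) - 1:
                ref_id = f"ref_{taxid}"
                references.append(
                    ReferenceRecord(
                        id=ref_id,
                        seq=child_seq.tobytes().decode("ascii"),
                        taxid=taxid,
                    )
                )
                ref_to_leaf[ref_id] = taxid
            else:
                descend(taxid, child_seq, level + 1)

    descend("root", root_seq, 0)
    return references, TaxonomyTree(nodes), ref_to_leaf


def simulate_queries(
    references: Sequence[ReferenceRecord],
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[QueryRecord], dict[str, str]]:
    """Draw reads from random leaves and add sequencing errors.

    Returns ``(queries, truth)`` with ``truth`` mapping query id to the true
    species taxid.  If ``cfg.subregion`` is set, the window is cut from the
    source sequence before mutation (emulating a variable-region extract).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    queries: list[QueryRecord] = []
    truth: dict[str, str] = {}
    for i in range(cfg.n_queries):
        ref = references[int(rng.integers(0, len(references)))]
        seq = ref.seq
        if cfg.subregion is not None:
            start, length = cfg.subregion
            seq = seq[start:start + length]
            if not seq:
                raise ValueError("subregion window outside the reference sequence")
        qid = f"q{i:05d}"
        queries.append(QueryRecord(id=qid, seq=mutate_read(seq, cfg.mutation_rate, rng)))
        truth[qid] = ref.taxid
    return queries, truth


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def _truth_names(
    truth: Mapping[str, str], tree: TaxonomyTree
) -> dict[str, dict[str, str]]:
    out = {}
    for qid, leaf in truth.items():
        out[qid] = {rt.rank: rt.name for rt in tree.lineage_of(leaf)}
    return out


def tally_confusion(
    results: Sequence[ResultRow],
    truth: Mapping[str, str],
    tree: TaxonomyTree,
    ranks: Sequence[str] | None = None,
) -> ConfusionTally:
    """Per-rank confusion counts of predictions against the truth map.

    ``truth`` maps query ids to true leaf taxids; predictions are taken from
    the per-rank names in each result row.  Counts are summed over taxon
    labels (the union of true and predicted labels at each rank).
    """
    pred = {r.query_id: r.as_dict() for r in results}
    missing = set(truth) ^ set(pred)
    if missing:
        raise ValueError(
            f"results and truth disagree on query ids: {sorted(missing)[:10]!r}"
        )
    truth_names = _truth_names(truth, tree)
    if ranks is None:
        ranks = [
            r for r in CANONICAL_RANKS
            if any(r in names for names in truth_names.values())
        ]
    counts: dict[str, tuple[int, int, int, int]] = {}
    n = len(truth)
    for rank in ranks:
        labels = {names.get(rank) for names in truth_names.values()}
        labels |= {
            p.get(rank) for p in pred.values() if p.get(rank, UNCLASSIFIED) != UNCLASSIFIED
        }
        labels.discard(None)
        tp = fn = fp = tn = 0
        for label in sorted(labels):
            for qid in truth:
                truly = truth_names[qid].get(rank) == label
                predicted = pred[qid].get(rank) == label
                if truly and predicted:
                    tp += 1
                elif truly:
                    fn += 1
                elif predicted:
                    fp += 1
                else:
                    tn += 1
        counts[rank] = (tp, fn, fp, tn)
    return ConfusionTally(counts=counts)


def precision_recall(tally: ConfusionTally, rank: str) -> tuple[float, float]:
    tp, fn, fp, _ = tally[rank]
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    return precision, recall


def f_score(tally: ConfusionTally, rank: str) -> float:
    """Harmonic mean of precision and recall at ``rank``; 0 when TP = 0."""
    precision, recall = precision_recall(tally, rank)
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


# ---------------------------------------------------------------------------
# Fixture emission
# ---------------------------------------------------------------------------

def write_benchmark(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Emit a complete benchmark as files consumable by the classifier CLI:
    reference FASTA, seqid->taxid map, lineage TSV, query FASTA, truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    references, tree, _ = simulate_reference(cfg)
    queries, truth = simulate_queries(references, cfg)
    paths = {
        "references": outdir / "references.fasta",
        "taxid_map": outdir / "taxid_map.tsv",
        "lineage": outdir / "lineage.tsv",
        "queries": outdir / "queries.fasta",
        "truth": outdir / "truth.tsv",
    }
    write_fasta(references, paths["references"])
    with open(paths["taxid_map"], "w") as fh:
        for ref in references:
            fh.write(f"{ref.id}\t{ref.taxid}\n")
    with open(paths["lineage"], "w") as fh:
        for ref in references:
            lineage = tree.lineage_of(ref.taxid)
            body = ";".join(f"{rt.rank}:{rt.name}" for rt in lineage if rt.rank != "superkingdom")
            fh.write(f"{ref.taxid}\t{body}\n")
    write_fasta(queries, paths["queries"])
    with open(paths["truth"], "w") as fh:
        for qid, leaf in truth.items():
            fh.write(f"{qid}\t{leaf}\n")
    return paths
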