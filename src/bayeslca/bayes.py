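"""Bayesian posteriors over candidate taxa and bootstrap confidence scores.

Given the multiple alignment of a query Q with its retained database hits,
each hit's annotated taxon T_i is a candidate leaf hypothesis with
likelihood

    Pr(Q | T_i) = score(Q, T_i) / score(T_i, T_i),

the query-vs-hit alignment score normalised by the hit's self-alignment
score — the maximum score any sequence could achieve against that hit — so
the likelihood lies in [0, 1], reaching 1 for a perfect match and 0 for no
match (ratios driven negative by mismatch/gap-heavy alignments are clamped
to 0).  Bayes' rule with a prior Pr(T_i) (uniform by default, in which case
it cancels) gives the posterior over leaves:

    Pr(T_i | Q) = Pr(Q | T_i) Pr(T_i) / sum_j Pr(Q | T_j) Pr(T_j),

and the posterior of any internal taxonomy node is the sum over its
descendant leaves (the addition rule).

Reliability is assessed by bootstrap resampling of alignment columns:
columns are drawn uniformly with replacement (as many draws as the query
has bases), leaf posteriors are recomputed on the resampled columns, and
the top-posterior leaf is tallied as the winner; a leaf's confidence is its
winning fraction over the replicates, and internal-node confidence is the
sum over descendant leaves.  Exact ties are split fractionally (1/k to each
of k tied leaves), which keeps per-rank confidences summing to 1 and the
procedure fully deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .alignment import (
    AlignedBlock,
    ScoringScheme,
    column_pair_scores,
    column_self_scores,
    pairwise_score,
    self_score,
)
from .taxonomy import CANONICAL_RANKS, TaxonomyTree

__all__ = [
    "LeafHypothesis",
    "BootstrapConfig",
    "likelihood",
    "posterior_leaves",
    "posterior_ranks",
    "bootstrap_confidence",
    "dedupe_hypotheses",
]


@dataclass(frozen=True)
class LeafHypothesis:
    """A candidate leaf taxon backed by one retained hit."""

    taxid: str
    subject_id: str
    likelihood: float

    def __post_init__(self):
        if not 0.0 <= self.likelihood <= 1.0:
            raise ValueError(f"likelihood {self.likelihood!r} outside [0, 1]")


@dataclass(frozen=True)
class BootstrapConfig:
    replicates: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("bootstrap replicates must be >= 1")


def likelihood(
    block: AlignedBlock,
    subject_id: str,
    scheme: ScoringScheme | None = None,
    columns=None,
) -> float:
    """Normalised alignment score Pr(Q | T_i) in [0, 1].

    The pairwise query-vs-hit score over the selected columns divided by the
    hit's self score there, clamped into [0, 1]; a hit with no aligned
    residues (self score 0) has likelihood 0.
    """
    denom = self_score(block, subject_id, scheme, columns)
    if denom <= 0:
        return 0.0
    ratio = pairwise_score(block, subject_id, scheme, columns) / denom
    return min(max(ratio, 0.0), 1.0)


def dedupe_hypotheses(hypotheses: Sequence[LeafHypothesis]) -> list[LeafHypothesis]:
    """Keep one hypothesis per leaf taxid — the highest-likelihood one
    (first on ties) — so database redundancy cannot double-count a taxon."""
    best: dict[str, LeafHypothesis] = {}
    for h in hypotheses:
        prev = best.get(h.taxid)
        if prev is None or h.likelihood > prev.likelihood:
            best[h.taxid] = h
    return list(best.values())


def posterior_leaves(
    likelihoods: Mapping[str, float],
    prior: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Posterior Pr(T_i | Q) over leaf taxa from their likelihoods.

    With the default uniform prior this is plain likelihood normalisation.
    If every likelihood-prior product is zero the query carries no evidence
    for any candidate; all posteriors are defined as 0 (the query will be
    reported unclassified rather than raising).
    """
    if not likelihoods:
        raise ValueError("posterior_leaves requires at least one leaf hypothesis")
    if prior is not None:
        for t, p in prior.items():
            if p < 0:
                raise ValueError(f"negative prior {p!r} for taxid {t!r}")
    weights = {
        t: lik * (1.0 if prior is None else prior.get(t, 0.0))
        for t, lik in likelihoods.items()
    }
    marginal = sum(weights.values())
    if marginal <= 0.0:
        return {t: 0.0 for t in likelihoods}
    return {t: w / marginal for t, w in weights.items()}


def posterior_ranks(
    tree: TaxonomyTree,
    leaf_posteriors: Mapping[str, float],
    ranks: Sequence[str] = CANONICAL_RANKS,
) -> dict[str, dict[str, float]]:
    """Posterior at every requested rank by summation over descendant leaves."""
    return {rank: tree.sum_to_rank(leaf_posteriors, rank) for rank in ranks}


def bootstrap_confidence(
    block: AlignedBlock,
    hypotheses: Sequence[LeafHypothesis],
    tree: TaxonomyTree,
    scheme: ScoringScheme | None = None,
    cfg: BootstrapConfig | None = None,
    prior: Mapping[str, float] | None = None,
    rng: np.random.Generator | None = None,
    ranks: Sequence[str] = CANONICAL_RANKS,
) -> tuple[dict[str, float], dict[str, dict[str, float]]]:
    """Bootstrap confidence scores for the leaf taxa and every rank.

    Each replicate draws alignment columns uniformly with replacement —
    as many as the query has bases — recomputes all leaf posteriors on the
    resampled columns, and tallies the top-posterior leaf; exact ties are
    split 1/k.  Returns ``(leaf_confidence, {rank: {taxid: confidence}})``.
    Deterministic for a fixed seed (``cfg.seed``) or caller-provided ``rng``.
    """
    scheme = scheme or ScoringScheme()
    cfg = cfg or BootstrapConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if not hypotheses:
        raise ValueError("bootstrap_confidence requires at least one hypothesis")

    pair = np.vstack(
        [column_pair_scores(block, h.subject_id, scheme) for h in hypotheses]
    )
    selfs = np.vstack(
        [column_self_scores(block, h.subject_id, scheme) for h in hypotheses]
    )
    prior_vec = None
    if prior is not None:
        prior_vec = np.array([prior.get(h.taxid, 0.0) for h in hypotheses])

    n_cols = block.column_count
    draw = block.query_length
    tallies = np.zeros(len(hypotheses))
    for _ in range(cfg.replicates):
        idx = rng.integers(0, n_cols, size=draw)
        ps = pair[:, idx].sum(axis=1)
        ss = selfs[:, idx].sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            lik = np.clip(np.where(ss > 0, ps / np.where(ss > 0, ss, 1.0), 0.0), 0.0, 1.0)
        weight = lik if prior_vec is None else lik * prior_vec
        top = weight.max()
        winners = np.flatnonzero(weight == top)
        tallies[winners] += 1.0 / winners.size
    leaf_conf = {
        h.taxid: float(t / cfg.replicates) for h, t in zip(hypotheses, tallies)
    }
    rank_conf = {rank: tree.sum_to_rank(leaf_conf, rank) for rank in ranks}
    return leaf_conf, rank_conf
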