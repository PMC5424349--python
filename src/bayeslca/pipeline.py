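"""End-to-end classification: search -> filter -> align -> posterior ->
bootstrap -> threshold -> report.

Each query is processed independently: candidate hits are taken from a
precomputed tabular hit file when one is supplied, otherwise every
reference is scored directly (practical for fixture- and benchmark-sized
databases); hits are filtered, the retained hit subsequences are multiply
aligned with the query, leaf posteriors and bootstrap confidences are
computed, and each canonical rank is assigned the top-confidence taxon at
that rank provided its confidence reaches the threshold (default 0.8, with
0.5 the common alternative for short reads) — otherwise the rank is
reported unclassified.  Ranks are decided independently, so a query can be
unclassified at species yet confidently assigned at genus: confidences grow
toward the root by summation.

Per-query randomness is derived from ``(seed, query index)``, so a query's
bootstrap result does not depend on which other queries are in the batch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .alignment import (
    AlignedBlock,
    FilterConfig,
    ScoringScheme,
    build_msa,
    extract_padded_subject,
    filter_hits,
    search_hits,
)
from .bayes import (
    BootstrapConfig,
    LeafHypothesis,
    bootstrap_confidence,
    dedupe_hypotheses,
    likelihood,
    posterior_leaves,
    posterior_ranks,
)
from .formats import (
    UNCLASSIFIED,
    HitRow,
    QueryRecord,
    RankAssignment,
    ReferenceRecord,
    ResultRow,
    group_hits_by_query,
    load_lineage_tsv,
    load_taxonomy,
    parse_hit_table,
    read_fasta,
    read_reference_fasta,
    write_results,
)
from .taxonomy import CANONICAL_RANKS, TaxonomyTree

__all__ = ["RunConfig", "classify_query", "run_batch", "REPORTED_RANKS"]

logger = logging.getLogger("bayeslca")

#: Ranks reported per query, root-most first (subspecies is reported only
#: when the reference annotation actually descends that far).
REPORTED_RANKS: tuple[str, ...] = CANONICAL_RANKS[:7]


@dataclass
class RunConfig:
    """Everything a batch run needs; file paths plus all tunables."""

    queries: str | Path
    reference: str | Path
    taxonomy: str | Path
    taxonomy_format: str = "tsv"  # "tsv" or "ncbi"
    taxid_map: str | Path | None = None  # required unless lineage TSV doubles as map
    names: str | Path | None = None  # names.dmp when taxonomy_format == "ncbi"
    hits: str | Path | None = None  # optional precomputed hit table
    out: str | Path = "results.tsv"
    filter: FilterConfig = field(default_factory=FilterConfig)
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    confidence_threshold: float = 0.8
    aligner: str = "internal"
    aligner_binary: str | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.confidence_threshold <= 1.0:
            raise ValueError("confidence threshold must lie in [0, 1]")


def _unclassified_row(query_id: str, ranks: Sequence[str] = REPORTED_RANKS) -> ResultRow:
    return ResultRow(
        query_id=query_id,
        assignments=tuple(RankAssignment(r, UNCLASSIFIED, None) for r in ranks),
    )


def classify_query(
    query: QueryRecord,
    references: Mapping[str, ReferenceRecord],
    tree: TaxonomyTree,
    hits: Sequence[HitRow] | None = None,
    filter_cfg: FilterConfig | None = None,
    scheme: ScoringScheme | None = None,
    bootstrap_cfg: BootstrapConfig | None = None,
    confidence_threshold: float = 0.8,
    aligner: str = "internal",
    aligner_binary: str | None = None,
    rng: np.random.Generator | None = None,
    ranks: Sequence[str] = REPORTED_RANKS,
) -> ResultRow:
    """Classify one query; returns its per-rank assignments.

    ``hits`` is an optional precomputed candidate list for this query; when
    absent, every reference is scored.  A query whose hits are all filtered
    out, or whose retained hits all have likelihood 0, is reported
    unclassified at every rank.
    """
    filter_cfg = filter_cfg or FilterConfig()
    scheme = scheme or ScoringScheme()
    bootstrap_cfg = bootstrap_cfg or BootstrapConfig()

    if hits is None:
        hits = search_hits(query, references.values(), scheme)
    kept = filter_hits(hits, filter_cfg)
    if not kept:
        logger.warning("query %s: no hits survive the filters; unclassified", query.id)
        return _unclassified_row(query.id, ranks)

    subjects = {}
    for h in kept:
        ref = references.get(h.subject_id)
        if ref is None:
            raise KeyError(f"hit subject {h.subject_id!r} missing from the reference set")
        subjects[h.subject_id] = extract_padded_subject(ref, h, filter_cfg.pad)

    block = build_msa(query, subjects, scheme, backend=aligner, binary=aligner_binary)
    hyps = [
        LeafHypothesis(
            taxid=references[sid].taxid,
            subject_id=sid,
            likelihood=likelihood(block, sid, scheme),
        )
        for sid in subjects
    ]
    hyps = dedupe_hypotheses(hyps)
    leaf_post = posterior_leaves({h.taxid: h.likelihood for h in hyps})
    if all(p == 0.0 for p in leaf_post.values()):
        logger.warning("query %s: all candidate likelihoods are 0; unclassified", query.id)
        return _unclassified_row(query.id, ranks)

    rank_post = posterior_ranks(tree, leaf_post, ranks)
    _, rank_conf = bootstrap_confidence(
        block, hyps, tree, scheme, bootstrap_cfg, rng=rng, ranks=ranks
    )

    assignments = []
    for rank in ranks:
        cands = rank_conf.get(rank, {})
        if not cands:
            assignments.append(RankAssignment(rank, UNCLASSIFIED, None))
            continue
        post = rank_post.get(rank, {})
        # top confidence wins; posterior then taxid break ties deterministically
        taxid = max(cands, key=lambda t: (cands[t], post.get(t, 0.0), t))
        conf = cands[taxid]
        if conf >= confidence_threshold:
            assignments.append(RankAssignment(rank, tree.name(taxid), conf))
        else:
            assignments.append(RankAssignment(rank, UNCLASSIFIED, None))
    return ResultRow(query_id=query.id, assignments=tuple(assignments))


def classify_batch(
    queries: Sequence[QueryRecord],
    references: Mapping[str, ReferenceRecord],
    tree: TaxonomyTree,
    hits_by_query: Mapping[str, Sequence[HitRow]] | None = None,
    filter_cfg: FilterConfig | None = None,
    scheme: ScoringScheme | None = None,
    bootstrap_cfg: BootstrapConfig | None = None,
    confidence_threshold: float = 0.8,
    aligner: str = "internal",
    aligner_binary: str | None = None,
    seed: int = 0,
    ranks: Sequence[str] = REPORTED_RANKS,
) -> list[ResultRow]:
    """Classify queries independently, preserving input order.

    Each query gets its own generator seeded from ``(seed, index)``, so
    results are invariant to batch composition and ordering.
    """
    rows = []
    for i, query in enumerate(queries):
        rng = np.random.default_rng([seed, i])
        q_hits = None if hits_by_query is None else hits_by_query.get(query.id, [])
        try:
            row = classify_query(
                query, references, tree,
                hits=q_hits,
                filter_cfg=filter_cfg,
                scheme=scheme,
                bootstrap_cfg=bootstrap_cfg,
                confidence_threshold=confidence_threshold,
                aligner=aligner,
                aligner_binary=aligner_binary,
                rng=rng,
                ranks=ranks,
            )
        except Exception:
            logger.exception("query %s: classification failed; unclassified", query.id)
            row = _unclassified_row(query.id, ranks)
        rows.append(row)
    return rows


def run_batch(cfg: RunConfig) -> list[ResultRow]:
    """Load all inputs, classify every query, and write the result table."""
    queries = read_fasta(cfg.queries)
    if cfg.taxonomy_format == "ncbi":
        if cfg.names is None:
            raise ValueError("NCBI taxonomy format needs both nodes.dmp and names.dmp")
        tree = load_taxonomy(cfg.taxonomy, cfg.names)
    elif cfg.taxonomy_format == "tsv":
        tree = load_lineage_tsv(cfg.taxonomy)
    else:
        raise ValueError(f"unknown taxonomy format {cfg.taxonomy_format!r}")
    if cfg.taxid_map is None:
        raise ValueError("a seqid->taxid mapping is required")
    references = {
        r.id: r for r in read_reference_fasta(cfg.reference, cfg.taxid_map)
    }
    for ref in references.values():
        if ref.taxid not in tree:
            raise ValueError(
                f"reference {ref.id!r} is annotated with taxid {ref.taxid!r}, "
                "which is absent from the taxonomy"
            )
    hits_by_query = None
    if cfg.hits is not None:
        hits_by_query = group_hits_by_query(parse_hit_table(cfg.hits))

    logger.info(
        "classifying %d queries against %d references (threshold %.2f, seed %d)",
        len(queries), len(references), cfg.confidence_threshold, cfg.seed,
    )
    rows = classify_batch(
        queries, references, tree,
        hits_by_query=hits_by_query,
        filter_cfg=cfg.filter,
        scheme=cfg.scoring,
        bootstrap_cfg=cfg.bootstrap,
        confidence_threshold=cfg.confidence_threshold,
        aligner=cfg.aligner,
        aligner_binary=cfg.aligner_binary,
        seed=cfg.seed,
    )
    write_results(rows, cfg.out)
    for rank in REPORTED_RANKS:
        n_cls = sum(1 for r in rows for a in r.assignments if a.rank == rank and a.name != UNCLASSIFIED)
        logger.info("%s: %d/%d classified", rank, n_cls, len(rows))
    return rows
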