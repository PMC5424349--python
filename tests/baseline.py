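"""A deliberately naive equal-weight LCA classifier used as a comparison
baseline in tests.

Every retained hit counts the same: the query is assigned, at each rank,
the taxon of the lowest common ancestor of all retained hits — no
posterior weighting, no bootstrap.  Ranks below the LCA are unclassified.
"""

from __future__ import annotations

from bayeslca.alignment import FilterConfig, filter_hits, search_hits
from bayeslca.formats import UNCLASSIFIED, RankAssignment, ResultRow
from bayeslca.pipeline import REPORTED_RANKS


def lca_classify_batch(queries, references, tree, filter_cfg: FilterConfig):
    refmap = {r.id: r for r in references} if not isinstance(references, dict) else references
    rows = []
    for query in queries:
        hits = search_hits(query, refmap.values())
        kept = filter_hits(hits, filter_cfg)
        if not kept:
            rows.append(ResultRow(query.id, tuple(
                RankAssignment(r, UNCLASSIFIED, None) for r in REPORTED_RANKS)))
            continue
        lca = tree.lca([refmap[h.subject_id].taxid for h in kept])
        names = {rt.rank: rt.name for rt in tree.lineage_of(lca)}
        rows.append(ResultRow(query.id, tuple(
            RankAssignment(r, names[r], 1.0) if r in names
            else RankAssignment(r, UNCLASSIFIED, None)
            for r in REPORTED_RANKS)))
    return rows
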