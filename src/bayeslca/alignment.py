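"""Candidate-hit selection, subsequence extraction and alignment scoring.

The classifier measures query-to-hit similarity with *global* pairwise
alignment scores read off a query-anchored multiple alignment of the query
and all retained hits.  This module implements:

* ``filter_hits`` — the identity / coverage / topPercent retention filters
  (defaults 95%, 95%, 10%; topPercent keeps hits whose bit score is within
  the given percentage of the best hit, the MEGAN-style criterion),
* ``extract_padded_subject`` — the hit subsequence actually aligned: the
  matched subject region plus 10 nt of flanking context on each side, to
  avoid spurious terminal overhangs in the multiple alignment,
* ``nw_align`` — Needleman–Wunsch global alignment with linear gap costs
  under the BLASTN-default DNA scheme (match +1, mismatch −2, gap −2.5),
* ``build_msa`` — a query-anchored star multiple alignment (each subject is
  globally aligned to the query, then all pairwise alignments are merged on
  query coordinates); an adapter for an external aligner binary (MAFFT /
  MUSCLE style) is available behind ``backend="external"``,
* ``pairwise_score`` / ``self_score`` — column-wise alignment scores over an
  arbitrary column multiset, the primitive both the likelihood and the
  bootstrap resampling are built on.

Column scoring rules: a column contributes ``match`` if both rows carry the
same non-``N`` residue, ``mismatch`` if both carry residues that differ (or
either is ``N``), ``gap`` if exactly one row has a gap, and 0 if both rows
have gaps (neither sequence is present there, so the column carries no
evidence).  With these rules the pairwise score of any subject against the
query over *all* columns of the star alignment equals its optimal global
alignment score, because the filler columns introduced when merging are
double-gap columns for every other subject.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .formats import FormatError, HitRow, QueryRecord, ReferenceRecord

__all__ = [
    "ScoringScheme",
    "FilterConfig",
    "AlignedBlock",
    "filter_hits",
    "extract_padded_subject",
    "reverse_complement",
    "nw_align",
    "build_msa",
    "pairwise_score",
    "self_score",
    "column_pair_scores",
    "column_self_scores",
    "search_hits",
    "AlignerNotFoundError",
]

_GAP = ord("-")
_N = ord("N")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ScoringScheme:
    """DNA alignment scoring; defaults are the BLASTN defaults.

    The gap penalty is linear (per gap character), matching the single
    stated gap cost; no separate gap-open term is used.
    """

    match: float = 1.0
    mismatch: float = -2.0
    gap: float = -2.5

    def __post_init__(self):
        if not self.match > 0:
            raise ValueError("match score must be positive")
        if self.mismatch > 0 or self.gap > 0:
            raise ValueError("mismatch and gap scores must be non-positive")


@dataclass(frozen=True)
class FilterConfig:
    """Hit-retention thresholds.

    min_identity / min_coverage are percentages of the query; ``top_percent``
    retains hits whose bit score is at least ``best * (1 - top_percent/100)``.
    ``pad`` is the number of flanking nucleotides included on each side of
    the matched subject region before multiple alignment.
    """

    min_identity: float = 95.0
    min_coverage: float = 95.0
    top_percent: float = 10.0
    pad: int = 10

    def __post_init__(self):
        if not (0 <= self.min_identity <= 100 and 0 <= self.min_coverage <= 100):
            raise ValueError("identity/coverage thresholds must lie in [0, 100]")
        if self.top_percent < 0 or self.pad < 0:
            raise ValueError("top_percent and pad must be non-negative")


@dataclass(frozen=True)
class AlignedBlock:
    """A query-anchored multiple alignment: one gapped query row plus one
    gapped row per retained hit, all of equal length.  Removing the gaps
    from the query row reproduces the query sequence exactly."""

    query_id: str
    query_row: str
    hit_rows: Mapping[str, str]

    def __post_init__(self):
        n = len(self.query_row)
        for sid, row in self.hit_rows.items():
            if len(row) != n:
                raise ValueError(
                    f"row {sid!r} has {len(row)} columns, query row has {n}"
                )

    @property
    def column_count(self) -> int:
        return len(self.query_row)

    @property
    def query_length(self) -> int:
        """Ungapped query length."""
        return len(self.query_row) - self.query_row.count("-")


# ---------------------------------------------------------------------------
# Hit filtering and subsequence extraction
# ---------------------------------------------------------------------------

def filter_hits(hits: Sequence[HitRow], cfg: FilterConfig | None = None) -> list[HitRow]:
    """Apply identity, coverage and topPercent filters; one hit per subject.

    All rows must share one query id.  The topPercent cutoff is taken
    relative to the best bit score among the input rows (e.g. best 1000 and
    topPercent 10% retain only hits scoring at least 900).  If several rows
    survive for the same subject, the highest-bitscore one (first on ties)
    is kept, so one reference sequence never contributes twice.
    """
    cfg = cfg or FilterConfig()
    if not hits:
        return []
    qids = {h.query_id for h in hits}
    if len(qids) > 1:
        raise ValueError(f"filter_hits expects a single query; got {sorted(qids)!r}")
    best = max(h.bitscore for h in hits)
    floor = best * (1.0 - cfg.top_percent / 100.0)
    kept = [
        h
        for h in hits
        if h.pct_identity >= cfg.min_identity
        and h.coverage >= cfg.min_coverage
        and h.bitscore >= floor
    ]
    per_subject: dict[str, HitRow] = {}
    for h in kept:
        prev = per_subject.get(h.subject_id)
        if prev is None or h.bitscore > prev.bitscore:
            per_subject[h.subject_id] = h
    # preserve input order of the retained representatives
    chosen = set(map(id, per_subject.values()))
    return [h for h in kept if id(h) in chosen]


def extract_padded_subject(ref: ReferenceRecord, hit: HitRow, pad: int = 10) -> str:
    """The subject subsequence to align: matched region ± ``pad`` nt, clamped
    to the reference ends, reverse-complemented for minus-strand hits
    (``sstart > send``) so that it lies on the query strand."""
    lo, hi = sorted((hit.sstart, hit.send))
    n = len(ref.seq)
    if lo < 1 or hi > n:
        raise FormatError(
            f"hit {hit.query_id!r}/{hit.subject_id!r}: subject coordinates "
            f"{hit.sstart}..{hit.send} outside reference of length {n}"
        )
    # single 1-based-inclusive -> Python-slice conversion point
    start = max(lo - pad, 1) - 1
    stop = min(hi + pad, n)
    sub = ref.seq[start:stop]
    if hit.sstart > hit.send:
        sub = reverse_complement(sub)
    return sub


# ---------------------------------------------------------------------------
# Needleman–Wunsch global alignment (linear gap costs)
# ---------------------------------------------------------------------------

def _substitution_matrix(a: np.ndarray, b: np.ndarray, scheme: ScoringScheme) -> np.ndarray:
    eq = (a[:, None] == b[None, :]) & (a[:, None] != _N) & (b[None, :] != _N)
    return np.where(eq, scheme.match, scheme.mismatch)


def nw_align(
    a: str, b: str, scheme: ScoringScheme | None = None
) -> tuple[float, str, str]:
    """Optimal global alignment of two sequences under linear gap costs.

    Returns ``(score, gapped_a, gapped_b)``.  ``N`` is scored as a mismatch
    against everything, including another ``N`` (conservative: ambiguity
    never inflates similarity).  Traceback ties prefer diagonal moves, then
    gaps in ``b``, then gaps in ``a``, which makes the reported alignment
    deterministic.
    """
    scheme = scheme or ScoringScheme()
    if not a or not b:
        raise ValueError("nw_align requires two non-empty sequences")
    A = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    B = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    n, m = len(A), len(B)
    sub = _substitution_matrix(A, B, scheme)
    g = scheme.gap
    j_gap = g * np.arange(m + 1)
    D = np.empty((n + 1, m + 1))
    D[0] = j_gap
    base = np.empty(m + 1)
    for i in range(1, n + 1):
        # candidate best at column j ignoring horizontal moves
        base[0] = D[i - 1, 0] + g
        np.maximum(D[i - 1, :-1] + sub[i - 1], D[i - 1, 1:] + g, out=base[1:])
        # fold in horizontal (gap-in-a) chains with a prefix max:
        # D[i,j] = max_{k<=j} base[k] + g*(j-k)
        D[i] = np.maximum.accumulate(base - j_gap) + j_gap
    score = float(D[n, m])
    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    tol = 1e-9
    while i > 0 or j > 0:
        here = D[i, j]
        if i > 0 and j > 0 and abs(D[i - 1, j - 1] + sub[i - 1, j - 1] - here) <= tol:
            i -= 1
            j -= 1
            out_a.append(a[i])
            out_b.append(b[j])
        elif i > 0 and abs(D[i - 1, j] + g - here) <= tol:
            i -= 1
            out_a.append(a[i])
            out_b.append("-")
        else:
            j -= 1
            out_a.append("-")
            out_b.append(b[j])
    return score, "".join(reversed(out_a)), "".join(reversed(out_b))


# ---------------------------------------------------------------------------
# Query-anchored star MSA
# ---------------------------------------------------------------------------

def _pairwise_profile(gapped_q: str, gapped_s: str, qlen: int) -> tuple[list[str], list[str]]:
    """Split one pairwise alignment into, per query position i (0..qlen):
    the subject characters inserted *before* query char i, and the subject
    character aligned *to* query char i (slot qlen holds trailing insertions
    only)."""
    inserts = [""] * (qlen + 1)
    aligned = [""] * qlen
    qi = 0
    for qc, sc in zip(gapped_q, gapped_s):
        if qc == "-":
            inserts[qi] += sc
        else:
            aligned[qi] = sc
            qi += 1
    return inserts, aligned


def build_msa(
    query: QueryRecord,
    subjects: Mapping[str, str],
    scheme: ScoringScheme | None = None,
    backend: str = "internal",
    binary: str | None = None,
) -> AlignedBlock:
    """Multiple alignment of the query with its retained hit subsequences.

    ``backend="internal"`` (default) builds a query-anchored star alignment:
    each subject is globally aligned to the query with :func:`nw_align`, and
    the pairwise alignments are merged on query coordinates.  In the merged
    block a subject's score against the query over all columns is exactly
    its optimal pairwise global score (merging only adds columns where both
    members of any other pair are gapped, which score 0).

    ``backend="external"`` shells out to an external multiple aligner
    (MAFFT or MUSCLE command-line conventions, chosen from the binary name).
    """
    scheme = scheme or ScoringScheme()
    if not subjects:
        raise ValueError("build_msa requires at least one subject sequence")
    if backend == "external":
        return _external_msa(query, subjects, binary or "mafft")
    if backend != "internal":
        raise ValueError(f"unknown MSA backend {backend!r}")

    qlen = len(query.seq)
    profiles = {
        sid: _pairwise_profile(*nw_align(query.seq, sseq, scheme)[1:], qlen=qlen)
        for sid, sseq in subjects.items()
    }
    max_ins = [0] * (qlen + 1)
    for inserts, _ in profiles.values():
        for i, ins in enumerate(inserts):
            max_ins[i] = max(max_ins[i], len(ins))

    q_parts = []
    for i in range(qlen):
        q_parts.append("-" * max_ins[i] + query.seq[i])
    q_parts.append("-" * max_ins[qlen])
    query_row = "".join(q_parts)

    hit_rows = {}
    for sid, (inserts, aligned) in profiles.items():
        parts = []
        for i in range(qlen):
            parts.append(inserts[i].ljust(max_ins[i], "-") + aligned[i])
        parts.append(inserts[qlen].ljust(max_ins[qlen], "-"))
        hit_rows[sid] = "".join(parts)
    return AlignedBlock(query_id=query.id, query_row=query_row, hit_rows=hit_rows)


class AlignerNotFoundError(RuntimeError):
    """The external aligner binary is not on PATH."""


def _external_msa(query: QueryRecord, subjects: Mapping[str, str], binary: str) -> AlignedBlock:
    if shutil.which(binary) is None:
        raise AlignerNotFoundError(
            f"external aligner {binary!r} not found on PATH; "
            "use backend='internal' (CLI: --aligner internal)"
        )
    with tempfile.TemporaryDirectory() as tmp:
        infile = Path(tmp) / "in.fasta"
        outfile = Path(tmp) / "out.fasta"
        with open(infile, "w") as fh:
            fh.write(f">{query.id}\n{query.seq}\n")
            for sid, seq in subjects.items():
                fh.write(f">{sid}\n{seq}\n")
        name = Path(binary).name.lower()
        if "muscle" in name:
            cmd = [binary, "-align", str(infile), "-output", str(outfile)]
            res = subprocess.run(cmd, capture_output=True, text=True)
            if res.returncode != 0:  # muscle v3 flag style
                cmd = [binary, "-in", str(infile), "-out", str(outfile)]
                res = subprocess.run(cmd, capture_output=True, text=True)
        else:  # mafft conventions
            cmd = [binary, "--auto", "--quiet", str(infile)]
            res = subprocess.run(cmd, capture_output=True, text=True)
            if res.returncode == 0:
                outfile.write_text(res.stdout)
        if res.returncode != 0:
            raise RuntimeError(
                f"external aligner failed ({' '.join(cmd)}): {res.stderr.strip()}"
            )
        rows: dict[str, str] = {}
        for name_, seq in _read_aligned_fasta(outfile):
            rows[name_] = seq.upper()
    try:
        query_row = rows.pop(query.id)
    except KeyError:
        raise RuntimeError(f"aligner output lacks the query row {query.id!r}") from None
    if query_row.replace("-", "") != query.seq:
        raise RuntimeError(
            f"aligner output query row does not reproduce the query {query.id!r}"
        )
    return AlignedBlock(query_id=query.id, query_row=query_row, hit_rows=rows)


def _read_aligned_fasta(path: Path):
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    yield name, "".join(chunks)
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
    if name is not None:
        yield name, "".join(chunks)


# ---------------------------------------------------------------------------
# Column scoring
# ---------------------------------------------------------------------------

def _rows_as_bytes(block: AlignedBlock, subject_id: str) -> tuple[np.ndarray, np.ndarray]:
    try:
        row = block.hit_rows[subject_id]
    except KeyError:
        raise KeyError(
            f"subject {subject_id!r} not in alignment block "
            f"(has {sorted(block.hit_rows)!r})"
        ) from None
    q = np.frombuffer(block.query_row.encode("ascii"), dtype=np.uint8)
    s = np.frombuffer(row.encode("ascii"), dtype=np.uint8)
    return q, s


def column_pair_scores(
    block: AlignedBlock, subject_id: str, scheme: ScoringScheme | None = None
) -> np.ndarray:
    """Per-column query-vs-subject scores (length = column_count)."""
    scheme = scheme or ScoringScheme()
    q, s = _rows_as_bytes(block, subject_id)
    q_res = q != _GAP
    s_res = s != _GAP
    both = q_res & s_res
    eq = both & (q == s) & (q != _N) & (s != _N)
    scores = np.zeros(len(q))
    scores[eq] = scheme.match
    scores[both & ~eq] = scheme.mismatch
    scores[q_res ^ s_res] = scheme.gap
    return scores


def column_self_scores(
    block: AlignedBlock, subject_id: str, scheme: ScoringScheme | None = None
) -> np.ndarray:
    """Per-column subject self-alignment scores: ``match`` wherever the
    subject row carries a residue (a sequence aligned to itself has neither
    mismatches nor gaps)."""
    scheme = scheme or ScoringScheme()
    _, s = _rows_as_bytes(block, subject_id)
    return np.where(s != _GAP, scheme.match, 0.0)


def _select(per_column: np.ndarray, columns) -> float:
    if columns is None:
        return float(per_column.sum())
    idx = np.asarray(columns, dtype=np.intp)
    if idx.size and (idx.min() < 0 or idx.max() >= per_column.size):
        raise IndexError("column index out of range")
    return float(per_column[idx].sum())


def pairwise_score(
    block: AlignedBlock,
    subject_id: str,
    scheme: ScoringScheme | None = None,
    columns=None,
) -> float:
    """Query-vs-subject alignment score over the selected columns
    (a multiset — repeats allowed, as used by bootstrap resampling);
    default is all columns."""
    return _select(column_pair_scores(block, subject_id, scheme), columns)


def self_score(
    block: AlignedBlock,
    subject_id: str,
    scheme: ScoringScheme | None = None,
    columns=None,
) -> float:
    """Subject self-alignment score over the selected columns: the maximum
    score any sequence can reach against this subject there."""
    return _select(column_self_scores(block, subject_id, scheme), columns)


# ---------------------------------------------------------------------------
# Internal exhaustive candidate search (small databases)
# ---------------------------------------------------------------------------

def search_hits(
    query: QueryRecord,
    references: Iterable[ReferenceRecord],
    scheme: ScoringScheme | None = None,
) -> list[HitRow]:
    """Score the query against every reference and synthesize hit rows.

    A stand-in for an external similarity search on small (fixture or
    simulated) databases: every reference is globally aligned to the query
    with edlib, and a pseudo hit row is emitted carrying percent identity
    over alignment columns and, as the bit score, the alignment score under
    ``scheme`` (clamped at 0).  Plus-strand, full-span hits only.
    """
    import edlib

    scheme = scheme or ScoringScheme()
    rows = []
    for ref in references:
        res = edlib.align(query.seq, ref.seq, mode="NW", task="path")
        matches = mism = ins = dels = 0
        num = ""
        for ch in res["cigar"]:
            if ch.isdigit():
                num += ch
                continue
            k = int(num)
            num = ""
            if ch == "=":
                matches += k
            elif ch == "X":
                mism += k
            elif ch == "I":
                ins += k
            elif ch == "D":
                dels += k
        aln_len = matches + mism + ins + dels
        gapchars = ins + dels
        score = matches * scheme.match + mism * scheme.mismatch + gapchars * scheme.gap
        gap_opens = res["cigar"].count("I") + res["cigar"].count("D")
        rows.append(
            HitRow(
                query_id=query.id,
                subject_id=ref.id,
                pct_identity=100.0 * matches / aln_len,
                align_len=aln_len,
                mismatch=mism,
                gapopen=gap_opens,
                qstart=1,
                qend=len(query.seq),
                sstart=1,
                send=len(ref.seq),
                evalue=0.0,
                bitscore=max(score, 0.0),
                qlen=len(query.seq),
            )
        )
    return rows
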