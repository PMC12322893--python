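"""Cross-version gene-annotation reconciliation.

Two gene annotations (e.g. two GENCODE releases) rarely agree exactly: gene
names get revised, identifier versions are bumped, and coordinates shift.
This module builds a one-to-one correspondence from annotation A to
annotation B using three similarity metrics per coordinate-overlapping gene
pair — gene-name equality, version-insensitive gene-ID equality, and the
Jaccard index of the two intervals — with a high Jaccard index (> 0.99 by
default) as the primary criterion and unique gene-name equality as the
fallback for genes the Jaccard criterion leaves unmatched.

The resolution is a function on A genes: each A gene is matched at most
once.  B-side uniqueness is *not* enforced; entries whose B gene is shared
by several A genes carry a warning flag instead.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .io_formats import GeneRecord, GenomicInterval, strip_version

__all__ = [
    "MatchConfig",
    "GenePair",
    "GroupCensus",
    "CorrespondenceEntry",
    "CorrespondenceTable",
    "jaccard_index",
    "overlap_pairs",
    "classify_groups",
    "resolve_one_to_one",
    "match_annotations",
]


@dataclass(frozen=True)
class MatchConfig:
    """Knobs of the reconciliation.

    jaccard_threshold
        Pairs with Jaccard index strictly above this are eligible for the
        primary (coordinate-based) match.  Default 0.99.
    version_insensitive_id
        Strip version suffixes before comparing gene IDs (required for the
        ID metric to be informative across annotation releases).
    """

    jaccard_threshold: float = 0.99
    version_insensitive_id: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.jaccard_threshold <= 1.0):
            raise ValueError("jaccard_threshold must be in (0, 1]")


@dataclass
class GenePair:
    """One coordinate-overlapping (A gene, B gene) candidate with its metrics."""

    gene_a: GeneRecord
    gene_b: GeneRecord
    name_match: bool
    id_match: bool
    jaccard: float
    group: Optional[int] = None


def jaccard_index(a: GenomicInterval, b: GenomicInterval) -> float:
    """Overlap length over union length of two intervals (half-open arithmetic).

    Returns 0.0 for disjoint intervals or different chromosomes; symmetric.
    """
    if a.chrom != b.chrom:
        return 0.0
    inter = min(a.end, b.end) - max(a.start, b.start)
    if inter <= 0:
        return 0.0
    union = len(a) + len(b) - inter
    return inter / union


@dataclass
class OverlapResult:
    pairs: list[GenePair]
    non_intersecting_a: list[GeneRecord]


def overlap_pairs(
    genes_a: Sequence[GeneRecord],
    genes_b: Sequence[GeneRecord],
    cfg: MatchConfig = MatchConfig(),
) -> OverlapResult:
    """All (A, B) pairs sharing >= 1 bp on the same chromosome, with metrics.

    Strand is ignored throughout.  A genes overlapping no B gene are
    returned separately in ``non_intersecting_a``.
    """
    if not genes_a or not genes_b:
        raise ValueError("both annotations must be non-empty")
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for idx, g in enumerate(genes_b):
        trees[g.interval.chrom].addi(g.interval.start, g.interval.end, idx)

    pairs: list[GenePair] = []
    orphans: list[GeneRecord] = []
    for ga in genes_a:
        hits = trees.get(ga.interval.chrom)
        found = sorted(h.data for h in hits.overlap(ga.interval.start, ga.interval.end)) if hits else []
        if not found:
            orphans.append(ga)
            continue
        for idx in found:
            gb = genes_b[idx]
            if cfg.version_insensitive_id:
                id_match = ga.unversioned_id == gb.unversioned_id
            else:
                id_match = ga.gene_id == gb.gene_id
            pairs.append(
                GenePair(
                    gene_a=ga,
                    gene_b=gb,
                    name_match=ga.gene_name == gb.gene_name,
                    id_match=id_match,
                    jaccard=jaccard_index(ga.interval, gb.interval),
                )
            )
    return OverlapResult(pairs=pairs, non_intersecting_a=orphans)


def _triple(pair: GenePair, cfg: MatchConfig) -> tuple[bool, bool, bool]:
    return (pair.name_match, pair.id_match, pair.jaccard > cfg.jaccard_threshold)


def group_index(triple: tuple[bool, bool, bool]) -> int:
    """Canonical small-integer label of a (name, id, jaccard) metric triple."""
    name, id_, jac = triple
    return 4 * int(name) + 2 * int(id_) + int(jac)


def group_label(triple: tuple[bool, bool, bool]) -> str:
    parts = [p for p, ok in zip(("name", "id", "jaccard"), triple) if ok]
    return "+".join(parts) if parts else "overlap-only"


@dataclass
class GroupCensus:
    """Count of pairs per occupied similarity-metric triple."""

    counts: dict[tuple[bool, bool, bool], int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def eligible_triples(self) -> set[tuple[bool, bool, bool]]:
        """Triples whose pairs qualify for the primary (Jaccard) match."""
        return {t for t in self.counts if t[2]}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "group": group_index(t),
                "label": group_label(t),
                "name_match": t[0],
                "id_match": t[1],
                "jaccard_pass": t[2],
                "unambiguous_eligible": t[2],
                "n_pairs": n,
            }
            for t, n in sorted(self.counts.items(), key=lambda kv: group_index(kv[0]))
        ]
        return pd.DataFrame(rows)


def classify_groups(
    pairs: Sequence[GenePair], cfg: MatchConfig = MatchConfig()
) -> GroupCensus:
    """Label each pair with the canonical index of its metric triple.

    Mutates ``pair.group`` in place and returns the census.  Census counts
    always sum to ``len(pairs)``.
    """
    counts: Counter = Counter()
    for p in pairs:
        t = _triple(p, cfg)
        p.group = group_index(t)
        counts[t] += 1
    return GroupCensus(counts=dict(counts))


@dataclass
class CorrespondenceEntry:
    gene_a_id: str
    gene_a_name: str
    gene_b_id: str
    gene_b_name: str
    jaccard: float
    method: str  # "jaccard" | "name_fallback"
    ambiguous: bool = False
    b_shared: bool = False


@dataclass
class CorrespondenceTable:
    """One-to-one (per A gene) mapping plus full accounting of the leftovers."""

    entries: list[CorrespondenceEntry]
    unmatched_a: list[str]
    ambiguous_a: list[tuple[str, int]] = field(default_factory=list)

    def as_dict(self) -> dict[str, str]:
        return {e.gene_a_id: e.gene_b_id for e in self.entries}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_a_id": e.gene_a_id,
                    "gene_a_name": e.gene_a_name,
                    "gene_b_id": e.gene_b_id,
                    "gene_b_name": e.gene_b_name,
                    "jaccard": e.jaccard,
                    "method": e.method,
                    "ambiguous": e.ambiguous,
                    "b_shared": e.b_shared,
                }
                for e in self.entries
            ]
        )


def resolve_one_to_one(
    pairs: Sequence[GenePair], cfg: MatchConfig = MatchConfig()
) -> CorrespondenceTable:
    """Resolve candidate pairs into a per-A-gene correspondence.

    Stage 1 (primary): every A gene with exactly one pair whose Jaccard
    index exceeds the threshold takes that pair (``method="jaccard"``).
    A genes with two or more passing pairs are recorded in ``ambiguous_a``
    and tie-broken deterministically: larger Jaccard first, then the
    lexicographically smallest B gene ID.

    Stage 2 (fallback): A genes left over from stage 1 that have exactly
    one name-matching pair take it (``method="name_fallback"``).  Everything
    else lands in ``unmatched_a``.
    """
    by_a: dict[str, list[GenePair]] = defaultdict(list)
    a_order: list[str] = []
    a_names: dict[str, str] = {}
    for p in pairs:
        aid = p.gene_a.gene_id
        if aid not in by_a:
            a_order.append(aid)
        by_a[aid].append(p)
        a_names[aid] = p.gene_a.gene_name

    entries: list[CorrespondenceEntry] = []
    ambiguous: list[tuple[str, int]] = []
    unmatched: list[str] = []

    for aid in a_order:
        cand = by_a[aid]
        passing = [p for p in cand if p.jaccard > cfg.jaccard_threshold]
        chosen: Optional[GenePair] = None
        method = "jaccard"
        if len(passing) == 1:
            chosen = passing[0]
        elif len(passing) >= 2:
            ambiguous.append((aid, len(passing)))
            chosen = min(passing, key=lambda p: (-p.jaccard, p.gene_b.gene_id))
        else:
            name_hits = [p for p in cand if p.name_match]
            if len(name_hits) == 1:
                chosen = name_hits[0]
                method = "name_fallback"
        if chosen is None:
            unmatched.append(aid)
            continue
        entries.append(
            CorrespondenceEntry(
                gene_a_id=aid,
                gene_a_name=a_names[aid],
                gene_b_id=chosen.gene_b.gene_id,
                gene_b_name=chosen.gene_b.gene_name,
                jaccard=chosen.jaccard,
                method=method,
                ambiguous=len(passing) >= 2,
            )
        )

    # flag B genes claimed by more than one A gene
    b_use = Counter(e.gene_b_id for e in entries)
    shared = {b for b, n in b_use.items() if n > 1}
    for e in entries:
        e.b_shared = e.gene_b_id in shared
    if shared:
        warnings.warn(
            f"{len(shared)} B gene(s) matched by multiple A genes", stacklevel=2
        )

    # invariant: the mapping is a function on A genes
    assert len({e.gene_a_id for e in entries}) == len(entries)
    return CorrespondenceTable(entries=entries, unmatched_a=unmatched, ambiguous_a=ambiguous)


def match_annotations(
    genes_a: Sequence[GeneRecord],
    genes_b: Sequence[GeneRecord],
    cfg: MatchConfig = MatchConfig(),
) -> tuple[CorrespondenceTable, GroupCensus, OverlapResult]:
    """End-to-end reconciliation: overlap, classify, resolve.

    A genes with no coordinate overlap at all are appended to
    ``unmatched_a`` of the returned table.
    """
    ov = overlap_pairs(genes_a, genes_b, cfg)
    census = classify_groups(ov.pairs, cfg)
    table = resolve_one_to_one(ov.pairs, cfg)
    table.unmatched_a.extend(g.gene_id for g in ov.non_intersecting_a)
    return table, census, ov
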