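"""Taxonomic assignment of short reads from tabular alignment hits.

Each read's hits are filtered at a minimum percent identity (default
97%, the similarity threshold conventional for species-level rRNA/short
read binning), restricted to the best-scoring set (optionally within a
score margin), and resolved to a single taxon: a lone surviving taxid is
assigned directly ("nearest neighbor"), while multiple distinct taxids
are promoted to their lowest common ancestor.  The LCA promotion makes
ambiguous assignments conservative: a read hitting two sibling species
equally well is counted at their genus.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from itertools import groupby
from typing import Iterable, Iterator, Optional, Sequence

from .taxonomy import TaxonomyTree

logger = logging.getLogger(__name__)

#: Relative tolerance for score equality; alignment scores come from
#: text parsing, so exact float comparison is too strict.
SCORE_REL_TOL = 1e-9


@dataclass(frozen=True)
class AlignmentHit:
    """One read-vs-subject alignment (BLAST-tabular-like).

    Subject coordinates are 0-based half-open on the subject sequence.
    """

    read_id: str
    subject_id: str
    subject_taxid: int
    percent_identity: float
    score: float
    subject_start: int = 0
    subject_end: int = 1
    strand: str = "+"

    def __post_init__(self):
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(
                f"percent_identity {self.percent_identity} outside [0, 100]"
            )
        if self.subject_start >= self.subject_end:
            raise ValueError(
                f"subject interval [{self.subject_start}, {self.subject_end}) "
                "is empty or reversed"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class ReadAssignment:
    """Outcome for one read: a taxid, or unassigned when no hit survived."""

    read_id: str
    taxid: Optional[int]
    n_hits_considered: int

    def __post_init__(self):
        if (self.taxid is None) != (self.n_hits_considered == 0):
            raise ValueError(
                "taxid must be None exactly when no hits were considered"
            )

    @property
    def assigned(self) -> bool:
        return self.taxid is not None


def filter_hits_by_identity(
    hits: Sequence[AlignmentHit], min_identity: float = 97.0
) -> list[AlignmentHit]:
    """Keep hits with ``percent_identity >= min_identity``, order preserved."""
    return [h for h in hits if h.percent_identity >= min_identity]


def assign_read(
    hits: Sequence[AlignmentHit],
    tree: TaxonomyTree,
    min_identity: float = 97.0,
    score_margin: float = 0.0,
) -> ReadAssignment:
    """Resolve one read's hits to a single taxon.

    Hits below ``min_identity`` are discarded, then only hits whose score
    is within ``score_margin`` of the best surviving score are kept
    (margin 0 keeps ties with the best).  Hits whose taxid is absent
    from the tree are dropped with a logged warning rather than raising:
    reference databases routinely contain stale taxids.
    """
    if hits:
        read_ids = {h.read_id for h in hits}
        if len(read_ids) > 1:
            raise ValueError(f"hits span multiple reads: {sorted(read_ids)}")
        read_id = hits[0].read_id
    else:
        read_id = ""

    survivors = filter_hits_by_identity(hits, min_identity)
    known = [h for h in survivors if h.subject_taxid in tree]
    n_dropped = len(survivors) - len(known)
    if n_dropped:
        logger.warning(
            "read %s: dropped %d hits with taxids absent from the taxonomy",
            read_id,
            n_dropped,
        )
    if not known:
        return ReadAssignment(read_id=read_id, taxid=None, n_hits_considered=0)

    best = max(h.score for h in known)
    cutoff = best - score_margin - SCORE_REL_TOL * abs(best)
    top = [h for h in known if h.score >= cutoff]
    taxids = {h.subject_taxid for h in top}
    if len(taxids) == 1:
        taxid = taxids.pop()
    else:
        taxid = tree.lca(taxids)
    return ReadAssignment(
        read_id=read_id, taxid=taxid, n_hits_considered=len(top)
    )


def iter_read_groups(
    hits: Iterable[AlignmentHit],
) -> Iterator[tuple[str, list[AlignmentHit]]]:
    """Group a read-sorted hit stream by read id.

    The stream must present each read's hits contiguously; a read id
    reappearing after another read is an error (the caller should sort).
    """
    seen: set[str] = set()
    for read_id, group in groupby(hits, key=lambda h: h.read_id):
        if read_id in seen:
            raise ValueError(
                f"hit stream is not grouped by read: {read_id!r} reappears"
            )
        seen.add(read_id)
        yield read_id, list(group)


def profile_sample(
    hits: Iterable[AlignmentHit],
    tree: TaxonomyTree,
    min_identity: float = 97.0,
    score_margin: float = 0.0,
) -> tuple[Counter, int]:
    """Per-taxon raw read counts for one sample.

    Every read contributes exactly one count to exactly one bucket (a
    taxid or the unassigned tally), so assigned + unassigned equals the
    number of distinct reads in the stream.

    Returns
    -------
    (counts, unassigned):
        ``counts`` maps taxid to raw read count; ``unassigned`` is the
        number of reads with no surviving hit.
    """
    counts: Counter = Counter()
    unassigned = 0
    for read_id, read_hits in iter_read_groups(hits):
        assignment = assign_read(
            read_hits, tree, min_identity=min_identity, score_margin=score_margin
        )
        if assignment.assigned:
            counts[assignment.taxid] += 1
        else:
            unassigned += 1
    return counts, unassigned
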