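"""Pairwise-alignment primitives shared by the tag and indel classifiers.

Two alignment engines are used behind one surface:

* :class:`Bio.Align.PairwiseAligner` for affine-gap Smith-Waterman (tag
  detection) and global read-vs-reference alignment (indel calling);
* ``edlib`` for cheap edit-distance screening, and as a fast path that
  settles equal-length read/reference pairs whose optimal edit path
  contains no indels without running the affine DP.

Coordinates are 0-based, half-open, on the forward strand throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import edlib
import numpy as np
from Bio import Align

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement (upper/lower case preserved, N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignmentScoring:
    """Affine-gap scoring plus the acceptance thresholds for tag hits.

    Defaults: match +2, mismatch -4, gap open -6, gap extend -1. A local
    tag hit is reported only when its identity (matches over aligned
    columns, gaps included) reaches ``min_identity`` and the aligned tag
    span covers at least ``min_tag_coverage`` of the tag. The coverage
    default (0.80) keeps tags detectable when a junction deletion has
    removed up to a tenth of the tag: local alignment clips rather than
    bridges such gaps, and may also shed a few isolated matching bases
    beyond the gap, so the surviving aligned span can fall to ~83% of
    the tag. Long spurious matches at 80% identity are still effectively
    impossible by chance in reads of this size.
    """

    match: int = 2
    mismatch: int = -4
    gap_open: int = -6
    gap_extend: int = -1
    min_identity: float = 0.80
    min_tag_coverage: float = 0.80

    def __post_init__(self) -> None:
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")
        for name in ("min_identity", "min_tag_coverage"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


def _aligner(scoring: AlignmentScoring, mode: str) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = mode
    al.match_score = scoring.match
    al.mismatch_score = scoring.mismatch
    al.open_gap_score = scoring.gap_open
    al.extend_gap_score = scoring.gap_extend
    return al


def local_aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    return _aligner(scoring, "local")


def reference_aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    """Global affine aligner for read-vs-reference alignment.

    End gaps carry the ordinary affine cost. Making read end gaps free
    was tried and rejected: a kilobase deletion close to one amplicon
    end then scores better as "mismatch the short flank and leave the
    reference tail unaligned for free" than as a real interior deletion,
    silently erasing the large-deletion class. Under ordinary end-gap
    costs that shortcut can never win, and genuinely truncated reads
    still align fine - their missing ends become end gaps, which produce
    no indel events.
    """
    return _aligner(scoring, "global")


@dataclass
class GapEvent:
    """A contiguous gap run on the reference: either bases present in the
    reference but absent from the read (deletion) or extra read bases at a
    reference position (insertion, zero reference width)."""

    ref_pos: int
    size: int
    kind: str  # "insertion" | "deletion"
    seq: str = ""  # inserted bases, for insertions


@dataclass
class RefAlignment:
    """A read-vs-reference alignment reduced to aligned blocks
    plus gap events, with enough structure to answer per-site queries."""

    ref_len: int
    read_len: int
    blocks: list  # list of (ref_start, ref_end, read_start, read_end)
    events: list  # list[GapEvent], reference order
    matches: int
    mismatches: int

    @property
    def ref_start(self) -> int:
        return self.blocks[0][0] if self.blocks else 0

    @property
    def ref_end(self) -> int:
        return self.blocks[-1][1] if self.blocks else 0

    def identity(self) -> float:
        """Base-level identity over aligned columns (gaps excluded), so a
        read carrying a genuine kilobase-scale deletion still passes the
        alignment-quality gate."""
        aligned = self.matches + self.mismatches
        return self.matches / aligned if aligned else 0.0

    def read_base_at(self, read: str, ref_pos: int) -> Optional[str]:
        """Read base aligned to ``ref_pos``; None if deleted or uncovered."""
        for t0, t1, q0, q1 in self.blocks:
            if t0 <= ref_pos < t1:
                return read[q0 + (ref_pos - t0)]
        return None


def _count_block_matches(read: str, ref: str, blocks) -> tuple[int, int]:
    matches = 0
    total = 0
    for t0, t1, q0, q1 in blocks:
        a = np.frombuffer(ref[t0:t1].encode(), dtype=np.uint8)
        b = np.frombuffer(read[q0:q1].encode(), dtype=np.uint8)
        matches += int((a == b).sum())
        total += t1 - t0
    return matches, total - matches


def _blocks_to_events(read: str, blocks) -> list[GapEvent]:
    events: list[GapEvent] = []
    for (pt0, pt1, pq0, pq1), (t0, t1, q0, q1) in zip(blocks, blocks[1:]):
        dgap = t0 - pt1
        igap = q0 - pq1
        if dgap > 0:
            events.append(GapEvent(pt1, dgap, "deletion"))
        if igap > 0:
            events.append(GapEvent(t0, igap, "insertion", read[pq1:q0]))
    return events


def align_semiglobal(read: str, ref: str, scoring: AlignmentScoring) -> RefAlignment:
    """Affine alignment of a read to a reference.

    Equal-length pairs whose optimal edit-distance path is indel-free are
    resolved directly from that path; everything else runs the affine DP.
    Gap runs are reported as raw events (left-shift normalization is the
    indel caller's job).
    """
    if len(read) == len(ref):
        res = edlib.align(read, ref, mode="NW", task="path")
        cig = res["cigar"] or ""
        if "I" not in cig and "D" not in cig:
            a = np.frombuffer(ref.encode(), dtype=np.uint8)
            b = np.frombuffer(read.encode(), dtype=np.uint8)
            m = int((a == b).sum())
            blocks = [(0, len(ref), 0, len(read))]
            return RefAlignment(len(ref), len(read), blocks, [], m, len(ref) - m)
    aln = reference_aligner(scoring).align(ref, read)[0]
    t_blocks, q_blocks = aln.aligned
    blocks = [
        (int(t0), int(t1), int(q0), int(q1))
        for (t0, t1), (q0, q1) in zip(t_blocks, q_blocks)
    ]
    matches, mismatches = _count_block_matches(read, ref, blocks)
    events = _blocks_to_events(read, blocks)
    return RefAlignment(len(ref), len(read), blocks, events, matches, mismatches)


@dataclass
class LocalHit:
    """One local alignment of a query (the tag) within a longer target
    (the read), in read coordinates."""

    read_start: int
    read_end: int
    identity: float
    coverage: float
    strand: str  # "+" | "-"
    score: float


def _best_local_hit(target: str, query: str, strand: str,
                    aligner: Align.PairwiseAligner) -> Optional[LocalHit]:
    alns = aligner.align(target, query)
    if alns.score <= 0:
        return None
    a = alns[0]
    t_blocks, q_blocks = a.aligned
    if len(t_blocks) == 0:
        return None
    blocks = [
        (int(t0), int(t1), int(q0), int(q1))
        for (t0, t1), (q0, q1) in zip(t_blocks, q_blocks)
    ]
    matches, mismatches = _count_block_matches(query, target, [
        (t0, t1, q0, q1) for (t0, t1, q0, q1) in blocks
    ])
    # aligned columns = matched/mismatched columns + internal gap columns
    columns = sum(t1 - t0 for t0, t1, _, _ in blocks)
    for (pt0, pt1, pq0, pq1), (t0, t1, q0, q1) in zip(blocks, blocks[1:]):
        columns += (t0 - pt1) + (q0 - pq1)
    identity = matches / columns if columns else 0.0
    q_span = blocks[-1][3] - blocks[0][2]
    coverage = q_span / len(query)
    return LocalHit(blocks[0][0], blocks[-1][1], identity, coverage,
                    strand, float(alns.score))


def find_local_hits(read_seq: str, query: str, scoring: AlignmentScoring,
                    max_hits: int = 8) -> list[LocalHit]:
    """All mutually non-overlapping local hits of ``query`` in ``read_seq``
    on either strand, by iterative best-hit masking.

    Each round takes the best-scoring Smith-Waterman hit over both strands
    of the query, keeps it if it clears the identity and coverage
    thresholds, masks the matched read interval and repeats. Tandem copies
    separated by at least one unmasked base are therefore counted
    separately. Hits are returned sorted by read coordinate.
    """
    al = local_aligner(scoring)
    rc_query = revcomp(query)
    masked = read_seq
    hits: list[LocalHit] = []
    while len(hits) < max_hits:
        best: Optional[LocalHit] = None
        for strand, q in (("+", query), ("-", rc_query)):
            hit = _best_local_hit(masked, q, strand, al)
            if hit is None:
                continue
            if best is None or (hit.score, -hit.read_start) > (best.score, -best.read_start):
                best = hit
        if best is None:
            break
        if best.identity < scoring.min_identity or best.coverage < scoring.min_tag_coverage:
            break
        hits.append(best)
        masked = masked[: best.read_start] + "N" * (best.read_end - best.read_start) \
            + masked[best.read_end:]
    hits.sort(key=lambda h: h.read_start)
    return hits
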