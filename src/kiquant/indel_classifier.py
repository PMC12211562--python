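"""Reference alignment, indel calling and repair-outcome classification.

Single-tag reads are aligned to the precise knock-in reference and
subclassified by the coordinates of their indels: no indels across the
tag plus both full homology arms (plus a margin) means a precise,
seamless knock-in; indels confined 5' of the tag midpoint give a 5'
junction indel, 3' of it a 3' junction indel, and indels on both sides an
explicit both-sided label. Tag-less reads are aligned to the unmodified
reference and called as target-site indels when any event overlaps a
window around the cut/insertion site. Substitutions never change a label
(residual CCS errors are tolerated); the configured SNP/PAM-edit site is
read out separately and, by default, annotates rather than gates the
precise class.

Indel events are left-shift normalized through homopolymer/repeat
context, so their coordinates are independent of aligner tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .align import AlignmentScoring, GapEvent, RefAlignment, align_semiglobal
from .preprocess import ProcessedRead
from .target_model import ReferenceSet, SnpSite, TargetSpec
from . import tag_classifier

UNMODIFIED = "unmodified"
INDEL_NO_TAG = "indel_no_tag"
PRECISE_TAG = "precise_tag"
TAG_5P_INDEL = "tag_5p_indel"
TAG_3P_INDEL = "tag_3p_indel"
TAG_BOTH_INDEL = "tag_both_indel"
MULTIPLE_TAGS = "multiple_tags"
UNCLASSIFIED = "unclassified"

CLASS_LABELS = (UNMODIFIED, INDEL_NO_TAG, PRECISE_TAG, TAG_5P_INDEL,
                TAG_3P_INDEL, TAG_BOTH_INDEL, MULTIPLE_TAGS, UNCLASSIFIED)

MIN_ALIGN_IDENTITY = 0.70
DEFAULT_JUNCTION_MARGIN = 10
DEFAULT_CUT_HALFWIDTH = 60


@dataclass(frozen=True)
class IndelEvent:
    ref_pos: int
    size: int
    kind: str  # "insertion" | "deletion"

    def overlaps(self, window: tuple) -> bool:
        """Half-open window overlap; insertions are points at ref_pos."""
        lo, hi = window
        if self.kind == "insertion":
            return lo <= self.ref_pos < hi
        return self.ref_pos < hi and self.ref_pos + self.size > lo


@dataclass
class ReadClass:
    read_id: str
    umi: str
    label: str
    events: list = field(default_factory=list)  # list[IndelEvent]
    snp_allele: Optional[str] = None
    n_tag_hits: int = 0


def align_to_reference(read_seq: str, reference: str,
                       scoring: Optional[AlignmentScoring] = None) -> RefAlignment:
    """Global affine alignment of the read to the reference. Gap
    placement among equal-score paths is settled downstream by left-shift
    normalization of the events."""
    scoring = scoring or AlignmentScoring()
    return align_semiglobal(read_seq, reference, scoring)


def _left_shift(event: GapEvent, reference: str) -> IndelEvent:
    """Shift a gap run to its lowest equivalent reference coordinate."""
    pos, size = event.ref_pos, event.size
    if event.kind == "deletion":
        while pos > 0 and reference[pos - 1] == reference[pos + size - 1]:
            pos -= 1
        return IndelEvent(pos, size, "deletion")
    seq = event.seq
    while pos > 0 and seq and seq[-1] == reference[pos - 1]:
        seq = reference[pos - 1] + seq[:-1]
        pos -= 1
    return IndelEvent(pos, size, "insertion")


def call_indels(alignment: RefAlignment, reference: str,
                window: Optional[tuple] = None, min_size: int = 1) -> list:
    """Left-shift-normalized indel events, restricted to those of at
    least ``min_size`` overlapping the scoring window (None = whole
    reference)."""
    events = [_left_shift(e, reference) for e in alignment.events]
    events = [e for e in events if e.size >= min_size]
    if window is not None:
        events = [e for e in events if e.overlaps(window)]
    events.sort(key=lambda e: (e.ref_pos, e.kind, e.size))
    return events


def parse_snp(alignment: RefAlignment, read_seq: str, snp_pos: int,
              snp: SnpSite) -> str:
    """Read base aligned to the SNP/PAM-edit site, mapped to
    'ref' | 'template' | 'other' | 'uncovered' (deletion over the site)."""
    base = alignment.read_base_at(read_seq, snp_pos)
    if base is None:
        return "uncovered"
    if base == snp.ref_base:
        return "ref"
    if base == snp.template_base:
        return "template"
    return "other"


def _snp_call(alignment: RefAlignment, read_seq: str, spec: TargetSpec,
              refs: ReferenceSet, on_precise: bool) -> Optional[str]:
    if spec.snp_site is None:
        return None
    pos = (refs.lift_to_precise(spec.snp_site.position) if on_precise
           else spec.snp_site.position)
    return parse_snp(alignment, read_seq, pos, spec.snp_site)


def classify_single_tag_read(read: ProcessedRead, refs: ReferenceSet,
                             spec: TargetSpec,
                             scoring: Optional[AlignmentScoring] = None,
                             junction_margin: int = DEFAULT_JUNCTION_MARGIN,
                             require_template_snp: bool = False) -> ReadClass:
    """Subclassify a single-tag read against the precise reference.

    The scoring window spans both full homology arms, the tag, and a
    margin on each side. No indel in the window means a seamless precise
    knock-in; otherwise the 5'/3' assignment splits at the tag midpoint.
    With ``require_template_snp`` the precise label additionally demands
    the template allele at the configured SNP site.
    """
    scoring = scoring or AlignmentScoring()
    aln = align_to_reference(read.seq, refs.precise_ref, scoring)
    if aln.identity() < MIN_ALIGN_IDENTITY:
        return ReadClass(read.read_id, read.umi, UNCLASSIFIED, n_tag_hits=1)
    lo = refs.junction_5p - len(spec.left_arm) - junction_margin
    hi = refs.junction_3p + len(spec.right_arm) + junction_margin
    events = call_indels(aln, refs.precise_ref, (lo, hi))
    snp_allele = _snp_call(aln, read.seq, spec, refs, on_precise=True)
    if not events:
        label = PRECISE_TAG
        if require_template_snp and spec.snp_site is not None \
                and snp_allele != "template":
            label = TAG_5P_INDEL if spec.snp_site.position < refs.junction_5p \
                else TAG_3P_INDEL
        return ReadClass(read.read_id, read.umi, label, [], snp_allele, 1)
    midpoint = (refs.junction_5p + refs.junction_3p) / 2
    side_5p = any(e.ref_pos < midpoint for e in events)
    side_3p = any(e.ref_pos >= midpoint for e in events)
    if side_5p and side_3p:
        label = TAG_BOTH_INDEL
    elif side_5p:
        label = TAG_5P_INDEL
    else:
        label = TAG_3P_INDEL
    return ReadClass(read.read_id, read.umi, label, events, snp_allele, 1)


def classify_no_tag_read(read: ProcessedRead, refs: ReferenceSet,
                         spec: TargetSpec,
                         scoring: Optional[AlignmentScoring] = None,
                         cut_halfwidth: int = DEFAULT_CUT_HALFWIDTH) -> ReadClass:
    """Classify a tag-less read against the unmodified reference: any
    indel overlapping the cut window (insertion point +/- ``cut_halfwidth``,
    covering both homology arms) makes it a target-site indel, else the
    read is unmodified. Deletions up to 1 kb are reportable - overlap with
    the window suffices."""
    scoring = scoring or AlignmentScoring()
    aln = align_to_reference(read.seq, refs.unmodified_ref, scoring)
    if aln.identity() < MIN_ALIGN_IDENTITY:
        return ReadClass(read.read_id, read.umi, UNCLASSIFIED)
    ip = spec.insertion_point
    window = (ip - cut_halfwidth, ip + cut_halfwidth)
    events = call_indels(aln, refs.unmodified_ref, window)
    snp_allele = _snp_call(aln, read.seq, spec, refs, on_precise=False)
    label = INDEL_NO_TAG if events else UNMODIFIED
    return ReadClass(read.read_id, read.umi, label, events, snp_allele)


def classify_multi_tag_read(read: ProcessedRead, refs: ReferenceSet,
                            spec: TargetSpec, n_hits: int,
                            scoring: Optional[AlignmentScoring] = None,
                            junction_margin: int = DEFAULT_JUNCTION_MARGIN) -> ReadClass:
    """A multi-tag read keeps the multiple_tags label; it is aligned to
    the precise reference so its indel events can be reported and (for
    this class, per the method) filtered against control samples."""
    scoring = scoring or AlignmentScoring()
    aln = align_to_reference(read.seq, refs.precise_ref, scoring)
    if aln.identity() < MIN_ALIGN_IDENTITY:
        return ReadClass(read.read_id, read.umi, UNCLASSIFIED, n_tag_hits=n_hits)
    lo = refs.junction_5p - len(spec.left_arm) - junction_margin
    hi = refs.junction_3p + len(spec.right_arm) + junction_margin
    events = call_indels(aln, refs.precise_ref, (lo, hi))
    snp_allele = _snp_call(aln, read.seq, spec, refs, on_precise=True)
    return ReadClass(read.read_id, read.umi, MULTIPLE_TAGS, events,
                     snp_allele, n_hits)


def classify_read(read: ProcessedRead, refs: ReferenceSet, spec: TargetSpec,
                  scoring: Optional[AlignmentScoring] = None,
                  junction_margin: int = DEFAULT_JUNCTION_MARGIN,
                  cut_halfwidth: int = DEFAULT_CUT_HALFWIDTH,
                  require_template_snp: bool = False) -> ReadClass:
    """Full per-read decision: tag detection first, then the appropriate
    reference alignment and indel-based subclassification."""
    scoring = scoring or AlignmentScoring()
    tag = tag_classifier.classify_by_tag(read, spec, scoring)
    if tag.label == tag_classifier.NO_TAG:
        return classify_no_tag_read(read, refs, spec, scoring, cut_halfwidth)
    if tag.label == tag_classifier.SINGLE_TAG:
        return classify_single_tag_read(read, refs, spec, scoring,
                                        junction_margin, require_template_snp)
    return classify_multi_tag_read(read, refs, spec, tag.n_hits, scoring,
                                   junction_margin)


def classify_reads(reads: Iterable, refs: ReferenceSet, spec: TargetSpec,
                   scoring: Optional[AlignmentScoring] = None,
                   **kwargs) -> list:
    return [classify_read(r, refs, spec, scoring, **kwargs) for r in reads]


class MissingControlError(ValueError):
    pass


def filter_natural_indels(events_by_read: dict, control_events: Iterable,
                          pos_tol: int = 10, size_tol: int = 2) -> dict:
    """Remove events matching a control ('natural') indel of the same
    kind within ``pos_tol`` bp and ``size_tol`` bp. Returns a new
    read_id -> events mapping."""
    control = list(control_events)

    def is_natural(e: IndelEvent) -> bool:
        return any(c.kind == e.kind
                   and abs(c.ref_pos - e.ref_pos) <= pos_tol
                   and abs(c.size - e.size) <= size_tol
                   for c in control)

    return {read_id: [e for e in events if not is_natural(e)]
            for read_id, events in events_by_read.items()}


def apply_control_filter(classes: list, control_classes: list,
                         pos_tol: int = 10, size_tol: int = 2,
                         all_classes: bool = False) -> list:
    """Apply the natural-indel filter to multi-tag reads (optionally all
    classes) using events called in a control sample run through the same
    pipeline."""
    control_events = [e for rc in control_classes for e in rc.events]
    targets = CLASS_LABELS if all_classes else (MULTIPLE_TAGS,)
    events_by_read = {rc.read_id: rc.events for rc in classes
                      if rc.label in targets}
    filtered = filter_natural_indels(events_by_read, control_events,
                                     pos_tol, size_tol)
    out = []
    for rc in classes:
        if rc.read_id in filtered:
            out.append(ReadClass(rc.read_id, rc.umi, rc.label,
                                 filtered[rc.read_id], rc.snp_allele,
                                 rc.n_tag_hits))
        else:
            out.append(rc)
    return out
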