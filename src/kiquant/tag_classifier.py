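"""Tag detection: classify representative reads as without tag, with a
single tag, or with multiple tags.

Each read is treated as the reference and the insert tag is locally
aligned to it (Smith-Waterman, affine gaps) on both strands; all mutually
non-overlapping hits above the identity and coverage thresholds are found
by iterative best-hit masking. An inverted tag copy still counts as a tag
for total-knock-in purposes, but can never satisfy the junction check
downstream, so it is never called precise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .align import AlignmentScoring, LocalHit, find_local_hits
from .preprocess import ProcessedRead
from .target_model import TargetSpec

NO_TAG = "no_tag"
SINGLE_TAG = "single_tag"
MULTIPLE_TAGS = "multiple_tags"

# TagHit is the field-facing name for a local tag alignment on a read.
TagHit = LocalHit


def align_local(query: str, target: str,
                scoring: Optional[AlignmentScoring] = None) -> list:
    """All non-overlapping local hits of ``query`` (the tag) in ``target``
    (the read), both strands, sorted by read coordinate."""
    scoring = scoring or AlignmentScoring()
    return find_local_hits(target, query, scoring)


@dataclass
class TagClassification:
    read: ProcessedRead
    label: str  # no_tag | single_tag | multiple_tags
    hits: list  # list[TagHit]

    @property
    def n_hits(self) -> int:
        return len(self.hits)


def classify_by_tag(read: ProcessedRead, spec: TargetSpec,
                    scoring: Optional[AlignmentScoring] = None) -> TagClassification:
    """Label a representative read by its tag-copy count (0 / 1 / >=2)."""
    scoring = scoring or AlignmentScoring()
    hits = find_local_hits(read.seq, spec.tag_seq, scoring)
    if len(hits) == 0:
        label = NO_TAG
    elif len(hits) == 1:
        label = SINGLE_TAG
    else:
        label = MULTIPLE_TAGS
    return TagClassification(read, label, hits)


def write_tag_tsv(classifications: list, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tumi\tlabel\tn_hits\thits\tidentities\n")
        for c in classifications:
            intervals = ";".join(f"{h.read_start}-{h.read_end}({h.strand})"
                                 for h in c.hits)
            idents = ";".join(f"{h.identity:.4f}" for h in c.hits)
            fh.write(f"{c.read.read_id}\t{c.read.umi}\t{c.label}\t"
                     f"{c.n_hits}\t{intervals}\t{idents}\n")
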