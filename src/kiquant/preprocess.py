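"""Read preprocessing: orientation, filtering, demultiplexing, trimming,
UMI extraction and UMI-group collapse to representative reads.

The stages mirror the preprocessing workflow of a UMI-tagged linear
amplification library: lanes are concatenated, reads are oriented onto
the forward-primer strand, abnormal reads (length outside 1,000-5,000 bp
or a head that deviates from the expected barcode+adapter prefix) are
dropped with a reason code, reads are demultiplexed by their sample
barcode pair, adapters/barcodes/UMI are trimmed off, reads are grouped by
UMI, and each group is collapsed to its most frequent exact sequence - the
representative read that stands in for one original template molecule.

Every drop is counted; input reads equal kept reads plus the sum of the
drop ledger at every stage.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional

import edlib
from Bio import SeqIO

from .align import revcomp
from .target_model import TargetSpec

MIN_READ_LEN = 1000
MAX_READ_LEN = 5000
UNDETERMINED = "undetermined"


@dataclass
class ProcessedRead:
    read_id: str
    sample_id: str
    umi: str
    seq: str  # adapter/primer/UMI-trimmed amplicon portion
    orientation_flipped: bool


@dataclass
class UmiGroup:
    umi: str
    members: list  # list[ProcessedRead]
    representative: ProcessedRead

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class DropLedger:
    """Per-stage drop counts; conservation (input = kept + dropped) is
    checkable at any point."""

    input_reads: int = 0
    kept: int = 0
    dropped: Counter = field(default_factory=Counter)

    def drop(self, stage: str, reason: str) -> None:
        self.dropped[f"{stage}:{reason}"] += 1

    def total_dropped(self) -> int:
        return sum(self.dropped.values())

    def check_conservation(self) -> bool:
        return self.input_reads == self.kept + self.total_dropped()


def _edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def _infix_distance(pattern: str, text: str) -> int:
    """Best edit distance of pattern against any substring of text."""
    if not text:
        return len(pattern)
    return edlib.align(pattern, text, mode="HW", task="distance")["editDistance"]


def orient_read(raw_seq: str, spec: TargetSpec) -> Optional[tuple]:
    """Orient a read onto the forward-primer strand.

    The forward universal adapter is sought (by edit distance) within the
    head of the read and of its reverse complement; the better match
    decides the orientation, ties staying unflipped. Returns
    ``(oriented_seq, flipped)`` or None when neither orientation comes
    within twice ``prefix_max_edits``.
    """
    if not raw_seq:
        return None
    head_len = (max((len(f) for _, f, _ in spec.barcode_pairs), default=0)
                + len(spec.fwd_universal) + 8)
    rc = revcomp(raw_seq)
    d_fwd = _infix_distance(spec.fwd_universal, raw_seq[:head_len])
    d_rev = _infix_distance(spec.fwd_universal, rc[:head_len])
    if min(d_fwd, d_rev) > 2 * spec.prefix_max_edits:
        return None
    if d_rev < d_fwd:
        return rc, True
    return raw_seq, False


def filter_abnormal(oriented_seq: str, spec: TargetSpec) -> Optional[str]:
    """Return a drop reason ('length' | 'prefix') or None to keep.

    Reads are dropped when their length falls outside [1,000, 5,000] bp
    (bounds retained), or when the first ``prefix_check_len`` bases differ
    from the closest expected barcode+adapter prefix by more than
    ``prefix_max_edits`` edits (default 6 of 30).
    """
    n = len(oriented_seq)
    if n < MIN_READ_LEN or n > MAX_READ_LEN:
        return "length"
    head = oriented_seq[: spec.prefix_check_len]
    if spec.barcode_pairs:
        prefixes = [(fwd + spec.fwd_universal)[: spec.prefix_check_len]
                    for _, fwd, _ in spec.barcode_pairs]
    else:
        prefixes = [spec.fwd_universal[: spec.prefix_check_len]]
    if min(_edit_distance(head, p) for p in prefixes) > spec.prefix_max_edits:
        return "prefix"
    return None


def match_barcodes(oriented_seq: str, spec: TargetSpec,
                   max_edits_per_barcode: int = 1) -> str:
    """Assign a read to the unique barcode pair with minimal combined
    edit distance, requiring at most ``max_edits_per_barcode`` edits for
    each barcode; ambiguous or unmatched reads go to ``undetermined``."""
    best_sample = UNDETERMINED
    best_d = None
    ambiguous = False
    for sample, fwd, rev in spec.barcode_pairs:
        head = oriented_seq[: len(fwd) + 4]
        tail = oriented_seq[-(len(rev) + 4):]
        d_f = _infix_distance(fwd, head)
        d_r = _infix_distance(revcomp(rev), tail)
        if d_f > max_edits_per_barcode or d_r > max_edits_per_barcode:
            continue
        d = d_f + d_r
        if best_d is None or d < best_d:
            best_d, best_sample, ambiguous = d, sample, False
        elif d == best_d:
            ambiguous = True
    if best_d is None or ambiguous:
        return UNDETERMINED
    return best_sample


def demultiplex(reads: Iterable[tuple], spec: TargetSpec) -> dict:
    """Map sample_id -> list of (read_id, seq, flipped); unassignable
    reads are binned under ``undetermined``."""
    out: dict = defaultdict(list)
    for item in reads:
        sample = match_barcodes(item[1], spec)
        out[sample].append(item)
    return dict(out)


def trim_and_extract_umi(read_id: str, oriented_seq: str, spec: TargetSpec,
                         sample_id: str, flipped: bool = False,
                         max_adapter_error: float = 0.20):
    """Trim barcodes/adapters, extract the UMI, and return a
    :class:`ProcessedRead`, or a drop-reason string.

    The forward adapter is located by best semi-global alignment within
    the first 100 bases; the ``umi_length`` bases immediately after it
    are the UMI. The reverse adapter (reverse-complemented) is located
    near the read end and everything from it onward is removed. An
    adapter that cannot be placed within 20% edits drops the read
    ('adapter'); a UMI running off the read end drops it ('truncated').
    """
    max_fwd = int(max_adapter_error * len(spec.fwd_universal))
    head = oriented_seq[:100]
    res = edlib.align(spec.fwd_universal, head, mode="HW", task="locations")
    if res["editDistance"] < 0 or res["editDistance"] > max_fwd:
        return "adapter"
    adapter_end = res["locations"][0][1] + 1  # edlib ends are inclusive
    umi_end = adapter_end + spec.umi_length
    if umi_end >= len(oriented_seq):
        return "truncated"
    umi = oriented_seq[adapter_end:umi_end]

    rev_rc = revcomp(spec.rev_universal)
    max_rev = int(max_adapter_error * len(spec.rev_universal))
    tail_start = max(umi_end, len(oriented_seq) - 100)
    tail = oriented_seq[tail_start:]
    res = edlib.align(rev_rc, tail, mode="HW", task="locations")
    if res["editDistance"] < 0 or res["editDistance"] > max_rev:
        return "adapter"
    rev_start = tail_start + res["locations"][0][0]
    seq = oriented_seq[umi_end:rev_start]
    if not seq:
        return "truncated"
    return ProcessedRead(read_id, sample_id, umi, seq, flipped)


def _hamming1(a: str, b: str) -> bool:
    if len(a) != len(b):
        return False
    return sum(x != y for x, y in zip(a, b)) <= 1


def group_by_umi(reads: list, merge_distance: int = 0) -> list:
    """Group reads by exact UMI; with ``merge_distance=1`` apply the
    directional rule: a group whose UMI lies within Hamming distance 1 of
    a group at least twice its size is absorbed into it (the largest such
    neighbour, ties to the lexicographically smallest UMI). Merge
    decisions use the initial exact-group sizes, smallest groups first,
    with union-find chaining. Groups are returned sorted by UMI."""
    exact: dict = defaultdict(list)
    for r in reads:
        exact[r.umi].append(r)
    umis = sorted(exact)
    parent = {u: u for u in umis}

    def find(u: str) -> str:
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    if merge_distance >= 1:
        size0 = {u: len(exact[u]) for u in umis}
        for u in sorted(umis, key=lambda x: (size0[x], x)):
            candidates = [v for v in umis
                          if v != u and size0[v] >= 2 * size0[u]
                          and _hamming1(u, v)]
            if candidates:
                target = max(candidates, key=lambda v: (size0[v], [-ord(c) for c in v]))
                parent[find(u)] = find(target)

    merged: dict = defaultdict(list)
    for u in umis:
        merged[find(u)].extend(exact[u])
    groups = []
    for u in sorted(merged):
        members = merged[u]
        groups.append(UmiGroup(u, members, select_representative(members)))
    return groups


def select_representative(members: list):
    """The modal exact sequence of a UMI group; ties broken by longest
    sequence, then lexicographically smallest. Among reads carrying the
    winning sequence the smallest read_id is returned, so the choice is
    independent of input order."""
    if not members:
        raise ValueError("empty UMI group")
    counts = Counter(r.seq for r in members)
    best_seq = min(counts, key=lambda s: (-counts[s], -len(s), s))
    return min((r for r in members if r.seq == best_seq),
               key=lambda r: r.read_id)


@dataclass
class PreprocessResult:
    groups_by_sample: dict  # sample_id -> list[UmiGroup]
    ledger: DropLedger
    group_size_stats: dict  # sample_id -> Counter of group sizes

    def representatives(self, sample_id: str) -> list:
        return [g.representative for g in self.groups_by_sample.get(sample_id, [])]


def preprocess_run(fastq_paths, spec: TargetSpec, merge_distance: int = 0,
                   min_group_size: int = 1) -> PreprocessResult:
    """Run the full preprocessing stage over one or more FASTQ lanes
    (plain concatenation), returning UMI groups per sample plus the drop
    ledger and group-size statistics."""
    if isinstance(fastq_paths, (str, bytes)):
        fastq_paths = [fastq_paths]
    ledger = DropLedger()
    oriented = []
    for path in fastq_paths:
        for rec in SeqIO.parse(path, "fastq"):
            ledger.input_reads += 1
            res = orient_read(str(rec.seq).upper(), spec)
            if res is None:
                ledger.drop("orient", "unorientable")
                continue
            seq, flipped = res
            reason = filter_abnormal(seq, spec)
            if reason is not None:
                ledger.drop("filter", reason)
                continue
            oriented.append((rec.id, seq, flipped))

    by_sample = demultiplex(oriented, spec)
    processed: dict = defaultdict(list)
    for sample, items in sorted(by_sample.items()):
        if sample == UNDETERMINED:
            for _ in items:
                ledger.drop("demux", "undetermined")
            continue
        for read_id, seq, flipped in items:
            out = trim_and_extract_umi(read_id, seq, spec, sample, flipped)
            if isinstance(out, str):
                ledger.drop("trim", out)
                continue
            processed[sample].append(out)

    groups_by_sample: dict = {}
    size_stats: dict = {}
    for sample in sorted(processed):
        groups = group_by_umi(processed[sample], merge_distance)
        if min_group_size > 1:
            kept_groups = []
            for g in groups:
                if g.size >= min_group_size:
                    kept_groups.append(g)
                else:
                    for _ in g.members:
                        ledger.drop("collapse", "small_group")
            groups = kept_groups
        groups_by_sample[sample] = groups
        size_stats[sample] = Counter(g.size for g in groups)
        ledger.kept += sum(g.size for g in groups)
    return PreprocessResult(groups_by_sample, ledger, size_stats)


def write_processed_fastq(reads: list, path: str) -> None:
    """Intermediate FASTQ dialect: the UMI is appended to the read name
    as ``@id_UMI:NNNNNNNN``."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}_UMI:{r.umi}\n{r.seq}\n+\n{'~' * len(r.seq)}\n")
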