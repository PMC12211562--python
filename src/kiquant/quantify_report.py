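"""Class tallies, headline editing rates, indel spectra, founder rates
and report writing; hosts the end-to-end run orchestration.

The three headline rates over all counted representative reads (one per
original template molecule):

* indel rate       - reads without any tag but with indels at the target
                     site, over all counted reads;
* total KI rate    - reads containing any tag insertion (precise, with
                     junction indels on either or both sides, or multiple
                     copies), over all counted reads;
* precise KI rate  - reads whose single tag has seamless junctions, over
                     all counted reads.

By this denominator convention the three rates plus the unmodified and
unclassified fractions sum to one.
"""

from __future__ import annotations

import json
import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from . import indel_classifier as ic
from .align import AlignmentScoring
from .indel_classifier import IndelEvent
from .preprocess import DropLedger, preprocess_run
from .target_model import TargetSpec, build_references


class EmptySampleError(ValueError):
    pass


TAG_LABELS = (ic.PRECISE_TAG, ic.TAG_5P_INDEL, ic.TAG_3P_INDEL,
              ic.TAG_BOTH_INDEL, ic.MULTIPLE_TAGS)


@dataclass
class ClassCounts:
    counts: Counter = field(default_factory=Counter)

    @classmethod
    def from_classes(cls, classes: Iterable) -> "ClassCounts":
        c = Counter(rc.label for rc in classes)
        unknown = set(c) - set(ic.CLASS_LABELS)
        if unknown:
            raise ValueError(f"unknown class labels: {sorted(unknown)}")
        return cls(c)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __getitem__(self, label: str) -> int:
        return self.counts.get(label, 0)


@dataclass
class RateReport:
    sample_id: str
    indel_rate: float
    total_ki_rate: float
    precise_ki_rate: float
    total: int


def compute_rates(counts: ClassCounts, sample_id: str = "sample") -> RateReport:
    """Headline rates from class counts; all denominators are the total
    counted representative reads."""
    total = counts.total
    if total == 0:
        raise EmptySampleError("no counted reads in sample")
    indel = counts[ic.INDEL_NO_TAG] / total
    total_ki = sum(counts[lab] for lab in TAG_LABELS) / total
    precise = counts[ic.PRECISE_TAG] / total
    return RateReport(sample_id, indel, total_ki, precise, total)


def indel_spectrum(events: Iterable):
    """Histogram of indel events by size and kind, plus summary fractions:
    fraction of insertions, fraction of indels under 10 bp, and the count
    of deletions of at least 100 bp."""
    events = list(events)
    hist = Counter((e.kind, e.size) for e in events)
    rows = [{"kind": kind, "size": size, "count": n}
            for (kind, size), n in sorted(hist.items())]
    df = pd.DataFrame(rows, columns=["kind", "size", "count"])
    n = len(events)
    summary = {
        "n_events": n,
        "fraction_insertions": (sum(e.kind == "insertion" for e in events) / n
                                if n else 0.0),
        "fraction_lt10bp": (sum(e.size < 10 for e in events) / n if n else 0.0),
        "n_deletions_ge100bp": sum(e.kind == "deletion" and e.size >= 100
                                   for e in events),
    }
    return df, summary


def founder_rate(total_p0: int, precise_founders: int) -> int:
    """Percentage of screened P0 founders transmitting the precise allele,
    rounded to the nearest integer (halves away from zero)."""
    if total_p0 <= 0:
        raise ValueError("total_p0 must be positive")
    if not 0 <= precise_founders <= total_p0:
        raise ValueError("precise_founders must be within [0, total_p0]")
    import math
    return int(math.floor(100.0 * precise_founders / total_p0 + 0.5))


SUMMARY_SCHEMA = {
    "config": dict,
    "samples": dict,
    "drop_ledger": dict,
    "parameters": dict,
}


def validate_summary(obj: dict) -> None:
    """Minimal structural validation of a run summary document."""
    for key, typ in SUMMARY_SCHEMA.items():
        if key not in obj:
            raise ValueError(f"summary missing key: {key}")
        if not isinstance(obj[key], typ):
            raise ValueError(f"summary key {key} has wrong type")
    for sample, entry in obj["samples"].items():
        for key in ("counts", "rates", "spectrum_summary"):
            if key not in entry:
                raise ValueError(f"sample {sample} missing {key}")


@dataclass
class RunResult:
    classes_by_sample: dict  # sample_id -> list[ReadClass]
    counts_by_sample: dict   # sample_id -> ClassCounts
    rates_by_sample: dict    # sample_id -> RateReport
    spectra_by_sample: dict  # sample_id -> (DataFrame, summary dict)
    ledger: DropLedger
    out_dir: Optional[str] = None


def write_report(result: RunResult, out_dir: str, spec: TargetSpec,
                 parameters: Optional[dict] = None) -> None:
    """Write rates.tsv, classes.tsv, indel_spectrum.tsv, drop_ledger.tsv
    and run_summary.json with deterministic ordering."""
    os.makedirs(out_dir, exist_ok=True)
    samples = sorted(result.rates_by_sample)

    with open(os.path.join(out_dir, "rates.tsv"), "w") as fh:
        fh.write("sample\ttotal_reads\tindel_rate\ttotal_ki_rate\tprecise_ki_rate\n")
        for s in samples:
            r = result.rates_by_sample[s]
            fh.write(f"{s}\t{r.total}\t{r.indel_rate:.6f}\t"
                     f"{r.total_ki_rate:.6f}\t{r.precise_ki_rate:.6f}\n")

    with open(os.path.join(out_dir, "classes.tsv"), "w") as fh:
        fh.write("sample\tread_id\tumi\tlabel\tevents\tsnp_allele\n")
        for s in samples:
            for rc in sorted(result.classes_by_sample[s], key=lambda x: x.read_id):
                ev = ";".join(f"{e.kind}:{e.ref_pos}:{e.size}" for e in rc.events)
                fh.write(f"{s}\t{rc.read_id}\t{rc.umi}\t{rc.label}\t{ev}\t"
                         f"{rc.snp_allele or ''}\n")

    with open(os.path.join(out_dir, "indel_spectrum.tsv"), "w") as fh:
        fh.write("sample\tkind\tsize\tcount\n")
        for s in samples:
            df, _ = result.spectra_by_sample[s]
            for _, row in df.iterrows():
                fh.write(f"{s}\t{row['kind']}\t{row['size']}\t{row['count']}\n")

    with open(os.path.join(out_dir, "drop_ledger.tsv"), "w") as fh:
        fh.write("stage_reason\tcount\n")
        fh.write(f"input\t{result.ledger.input_reads}\n")
        fh.write(f"kept\t{result.ledger.kept}\n")
        for key in sorted(result.ledger.dropped):
            fh.write(f"{key}\t{result.ledger.dropped[key]}\n")

    summary = {
        "config": {
            "gene": spec.gene_name,
            "amplicon_length": len(spec.amplicon_seq),
            "tag_length": len(spec.tag_seq),
            "insertion_point": spec.insertion_point,
            "umi_length": spec.umi_length,
            "n_barcode_pairs": len(spec.barcode_pairs),
            "prefix_check_len": spec.prefix_check_len,
            "prefix_max_edits": spec.prefix_max_edits,
        },
        "parameters": parameters or {},
        "samples": {
            s: {
                "counts": dict(sorted(result.counts_by_sample[s].counts.items())),
                "rates": {
                    "indel_rate": result.rates_by_sample[s].indel_rate,
                    "total_ki_rate": result.rates_by_sample[s].total_ki_rate,
                    "precise_ki_rate": result.rates_by_sample[s].precise_ki_rate,
                    "total": result.rates_by_sample[s].total,
                },
                "spectrum_summary": result.spectra_by_sample[s][1],
            }
            for s in samples
        },
        "drop_ledger": {
            "input": result.ledger.input_reads,
            "kept": result.ledger.kept,
            **{k: result.ledger.dropped[k] for k in sorted(result.ledger.dropped)},
        },
    }
    validate_summary(summary)
    with open(os.path.join(out_dir, "run_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_all(spec: TargetSpec, fastq_paths, out_dir: Optional[str] = None,
            control_fastq=None, merge_distance: int = 0,
            min_group_size: int = 1,
            scoring: Optional[AlignmentScoring] = None,
            junction_margin: int = ic.DEFAULT_JUNCTION_MARGIN,
            cut_halfwidth: int = ic.DEFAULT_CUT_HALFWIDTH,
            require_template_snp: bool = False,
            filter_all_classes: bool = False) -> RunResult:
    """End-to-end pipeline: preprocess, classify, (optionally) filter
    natural indels against a control sample, tally, and report."""
    scoring = scoring or AlignmentScoring()
    refs = build_references(spec)
    pre = preprocess_run(fastq_paths, spec, merge_distance, min_group_size)

    control_classes: list = []
    if control_fastq is not None:
        cpre = preprocess_run(control_fastq, spec, merge_distance, min_group_size)
        for s in sorted(cpre.groups_by_sample):
            control_classes.extend(
                ic.classify_reads(cpre.representatives(s), refs, spec, scoring,
                                  junction_margin=junction_margin,
                                  cut_halfwidth=cut_halfwidth,
                                  require_template_snp=require_template_snp))

    classes_by_sample: dict = {}
    for s in sorted(pre.groups_by_sample):
        classes = ic.classify_reads(pre.representatives(s), refs, spec, scoring,
                                    junction_margin=junction_margin,
                                    cut_halfwidth=cut_halfwidth,
                                    require_template_snp=require_template_snp)
        if control_classes:
            classes = ic.apply_control_filter(classes, control_classes,
                                              all_classes=filter_all_classes)
        classes_by_sample[s] = classes

    counts_by_sample = {s: ClassCounts.from_classes(c)
                        for s, c in classes_by_sample.items()}
    rates_by_sample = {s: compute_rates(counts, s)
                       for s, counts in counts_by_sample.items()
                       if counts.total > 0}
    spectra_by_sample = {
        s: indel_spectrum(e for rc in classes if rc.label == ic.INDEL_NO_TAG
                          for e in rc.events)
        for s, classes in classes_by_sample.items()
    }
    result = RunResult(classes_by_sample, counts_by_sample, rates_by_sample,
                       spectra_by_sample, pre.ledger, out_dir)
    if out_dir is not None:
        write_report(result, out_dir, spec, parameters={
            "merge_distance": merge_distance,
            "min_group_size": min_group_size,
            "junction_margin": junction_margin,
            "cut_halfwidth": cut_halfwidth,
            "require_template_snp": require_template_snp,
            "scoring": {
                "match": scoring.match, "mismatch": scoring.mismatch,
                "gap_open": scoring.gap_open, "gap_extend": scoring.gap_extend,
                "min_identity": scoring.min_identity,
                "min_tag_coverage": scoring.min_tag_coverage,
            },
        })
    return result
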