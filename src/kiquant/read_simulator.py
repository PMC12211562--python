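"""HiFi-like amplicon read simulator with per-molecule ground truth.

Emulates the linear-amplification/PCR library architecture used for
long-read knock-in quantification: each template molecule receives a
random 8-bp UMI during linear amplification, is flanked by universal
adapters and sample barcodes, PCR-duplicated a variable number of times
("jackpot" amplification), sequenced in either orientation, and read out
with a low residual circular-consensus error rate.

Repair outcomes are drawn from an :class:`OutcomeMixture` over the seven
classes the classifier must resolve; the emitted truth table carries one
row per template molecule so every downstream stage can be scored against
ground truth.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .align import revcomp
from .target_model import TargetSpec, build_references

LABELS = (
    "unmodified",
    "indel_no_tag",
    "precise_tag",
    "tag_5p_indel",
    "tag_3p_indel",
    "multiple_tags",
    "large_deletion",
)

#: The pipeline label each simulated outcome should receive: large
#: deletions carry no tag and are called as indels at the target site.
EXPECTED_PIPELINE_LABEL = {
    "unmodified": "unmodified",
    "indel_no_tag": "indel_no_tag",
    "precise_tag": "precise_tag",
    "tag_5p_indel": "tag_5p_indel",
    "tag_3p_indel": "tag_3p_indel",
    "multiple_tags": "multiple_tags",
    "large_deletion": "indel_no_tag",
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimulationUsageError(ValueError):
    pass


@dataclass(frozen=True)
class OutcomeMixture:
    """Probabilities over the seven repair-outcome labels."""

    probabilities: dict

    def __post_init__(self) -> None:
        unknown = set(self.probabilities) - set(LABELS)
        if unknown:
            raise SimulationUsageError(f"unknown outcome labels: {sorted(unknown)}")
        probs = [self.probabilities.get(lab, 0.0) for lab in LABELS]
        if any(p < 0 or p > 1 for p in probs):
            raise SimulationUsageError("probabilities must be in [0, 1]")
        total = sum(probs)
        if abs(total - 1.0) > 1e-9:
            raise SimulationUsageError(f"probabilities must sum to 1 (got {total})")
        if total <= 0 or all(p == 0 for p in probs):
            raise SimulationUsageError("mixture has no support")

    def as_vector(self) -> np.ndarray:
        return np.array([self.probabilities.get(lab, 0.0) for lab in LABELS])


@dataclass(frozen=True)
class ErrorModel:
    """Per-base sequencing error rates applied independently to every
    read copy, with a constant FASTQ quality symbol (CCS qualities are
    not modeled)."""

    sub_rate: float = 0.0049
    ins_rate: float = 0.00005
    del_rate: float = 0.00005
    quality_char: str = "~"

    def __post_init__(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 0.05:
                raise SimulationUsageError(f"{name} must be in [0, 0.05], got {v}")

    @classmethod
    def hifi(cls, total_rate: float = 0.005) -> "ErrorModel":
        """HiFi-like residual error: 98% substitutions, 1% insertions,
        1% deletions of the total per-base rate."""
        return cls(sub_rate=0.98 * total_rate,
                   ins_rate=0.01 * total_rate,
                   del_rate=0.01 * total_rate)

    @classmethod
    def perfect(cls) -> "ErrorModel":
        return cls(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class JackpotModel:
    """PCR duplication-count model: zero-truncated geometric with the
    given mean, optionally with one designated "mega-jackpot" molecule
    receiving a fixed large copy number."""

    mean: float = 2.0
    mega_molecule: Optional[int] = None
    mega_count: int = 100

    def __post_init__(self) -> None:
        if self.mean < 1.0:
            raise SimulationUsageError("duplication mean must be >= 1")


@dataclass
class SimTruth:
    molecule_id: str
    true_label: str
    umi: str
    sample_id: str
    duplication_count: int
    indel_details: list  # list of (position, size, kind) on the aligned reference

    @property
    def expected_class(self) -> str:
        return EXPECTED_PIPELINE_LABEL[self.true_label]


@dataclass
class SimulatedRun:
    fastq_path: str
    truth_path: str
    truths: list  # list[SimTruth]
    n_reads: int


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _indel_size(rng: np.random.Generator, kind: str,
                del_mean: float, ins_mean: float, cap: int = 99) -> int:
    mean = del_mean if kind == "deletion" else ins_mean
    return int(min(rng.geometric(1.0 / mean), cap))


def make_amplicon(spec: TargetSpec, label: str, rng: np.random.Generator,
                  deletion_mean: float = 6.0, insertion_mean: float = 4.0,
                  deletion_fraction: float = 0.65,
                  apply_template_snp: bool = True):
    """One molecule's amplicon sequence plus its true indel events.

    Indel positions in the returned details are coordinates on the
    reference the pipeline will align that molecule to (unmodified for
    tag-less outcomes, precise for tagged ones). Small indels follow a
    Cas9-like spectrum: geometric sizes (deletions mean 6 bp, insertions
    mean 4 bp), placed at the cut/insertion site; junction indels are
    1-10 bp within +/-10 bp of the respective junction; large deletions
    span 100-1,000 bp across the insertion point while always preserving
    both primer-binding ends (molecules losing a primer site would not
    amplify and are invisible to the assay by construction).
    """
    if label not in LABELS:
        raise SimulationUsageError(f"unknown outcome label: {label}")
    refs = build_references(spec)
    amp = spec.amplicon_seq
    ip = spec.insertion_point
    precise = refs.precise_ref
    if apply_template_snp and spec.snp_site is not None:
        p = refs.lift_to_precise(spec.snp_site.position)
        precise = precise[:p] + spec.snp_site.template_base + precise[p + 1:]

    if label == "unmodified":
        return amp, []
    if label == "precise_tag":
        return precise, []
    if label == "multiple_tags":
        k = int(rng.integers(2, 4))
        seq = amp[:ip] + spec.tag_seq * k + amp[ip:]
        # relative to the precise reference, the extra copies are one
        # insertion of (k-1) tag lengths at the 3' junction
        return seq, [(refs.junction_3p, (k - 1) * len(spec.tag_seq), "insertion")]
    if label == "large_deletion":
        size = int(rng.integers(100, 1001))
        lo = max(50, ip - size + 1)
        hi = min(ip, len(amp) - 50 - size)
        if hi < lo:
            size = len(amp) - 100
            lo, hi = 50, min(ip, len(amp) - 50 - size)
        start = int(rng.integers(lo, hi + 1))
        return amp[:start] + amp[start + size:], [(start, size, "deletion")]
    if label == "indel_no_tag":
        kind = "deletion" if rng.random() < deletion_fraction else "insertion"
        size = _indel_size(rng, kind, deletion_mean, insertion_mean)
        if kind == "deletion":
            start = int(rng.integers(max(1, ip - size), ip + 1))
            start = min(start, len(amp) - size - 1)
            return amp[:start] + amp[start + size:], [(start, size, "deletion")]
        pos = ip + int(rng.integers(-5, 6))
        return amp[:pos] + _random_seq(rng, size) + amp[pos:], \
            [(pos, size, "insertion")]
    # junction indels on the precise product
    junction = refs.junction_5p if label == "tag_5p_indel" else refs.junction_3p
    kind = "deletion" if rng.random() < 0.5 else "insertion"
    size = int(rng.integers(1, 11))
    offset = int(rng.integers(-10, 11))
    pos = junction + offset
    if kind == "deletion":
        pos = min(max(1, pos), len(precise) - size - 1)
        return precise[:pos] + precise[pos + size:], [(pos, size, "deletion")]
    pos = min(max(1, pos), len(precise) - 1)
    return precise[:pos] + _random_seq(rng, size) + precise[pos:], \
        [(pos, size, "insertion")]


def assemble_library_read(amplicon: str, spec: TargetSpec, umi: str,
                          fwd_barcode: str, rev_barcode: str,
                          orientation: str = "forward") -> str:
    """Assemble the full library molecule:

    ``fwd_barcode + fwd_universal + UMI + amplicon + rc(rev_universal) +
    rc(rev_barcode)``, reverse-complemented in full for reverse-strand
    sequencing.
    """
    if len(umi) != spec.umi_length:
        raise SimulationUsageError(
            f"UMI length {len(umi)} != spec.umi_length {spec.umi_length}")
    read = (fwd_barcode + spec.fwd_universal + umi + amplicon
            + revcomp(spec.rev_universal) + revcomp(rev_barcode))
    if orientation == "reverse":
        return revcomp(read)
    if orientation != "forward":
        raise SimulationUsageError(f"unknown orientation: {orientation}")
    return read


def apply_errors(seq: str, model: ErrorModel, rng: np.random.Generator) -> str:
    """Independent per-base substitution/insertion/deletion noise.

    Substituted bases are always changed to a different base, so
    ``sub_rate`` is the realized mismatch rate.
    """
    if model.sub_rate == model.ins_rate == model.del_rate == 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n = arr.size
    u = rng.random(n)
    del_mask = u < model.del_rate
    sub_mask = (u >= model.del_rate) & (u < model.del_rate + model.sub_rate)
    ins_mask = rng.random(n) < model.ins_rate
    if sub_mask.any():
        idx = np.searchsorted(_BASES, arr[sub_mask])
        shift = rng.integers(1, 4, size=idx.size)
        arr[sub_mask] = _BASES[(idx + shift) % 4]
    if not del_mask.any() and not ins_mask.any():
        return arr.tobytes().decode()
    # stable-merge survivors with inserted bases: insertions sort just
    # before the base they precede
    keep_idx = np.nonzero(~del_mask)[0]
    ins_idx = np.nonzero(ins_mask)[0]
    ins_bases = rng.choice(_BASES, size=ins_idx.size)
    keys = np.concatenate([keep_idx * 2 + 1, ins_idx * 2])
    vals = np.concatenate([arr[keep_idx], ins_bases])
    order = np.argsort(keys, kind="stable")
    return vals[order].tobytes().decode()


def simulate_run(spec: TargetSpec, mixture: OutcomeMixture, n_molecules: int,
                 out_dir: str, seed: int,
                 error_model: Optional[ErrorModel] = None,
                 jackpot: Optional[JackpotModel] = None,
                 sample_ids: Optional[list] = None,
                 unique_umis: bool = False,
                 fastq_name: str = "reads.fastq",
                 truth_name: str = "truth.tsv") -> SimulatedRun:
    """Simulate a sequencing run and write FASTQ plus a truth table.

    One FASTQ record is emitted per molecule per duplication copy, each
    independently error-mutated and sequenced in a random orientation.
    The truth TSV has one row per molecule. Identical seeds give
    byte-identical outputs.
    """
    if n_molecules < 1:
        raise SimulationUsageError("n_molecules must be >= 1")
    if not spec.barcode_pairs:
        raise SimulationUsageError("spec has no barcode pairs")
    error_model = error_model or ErrorModel()
    jackpot = jackpot or JackpotModel()
    rng = np.random.default_rng(seed)
    os.makedirs(out_dir, exist_ok=True)

    pairs = {s: (f, r) for s, f, r in spec.barcode_pairs}
    if sample_ids is None:
        sample_ids = [spec.barcode_pairs[0][0]]
    for s in sample_ids:
        if s not in pairs:
            raise SimulationUsageError(f"sample {s!r} has no barcode pair")

    labels = rng.choice(len(LABELS), size=n_molecules, p=mixture.as_vector())
    samples = rng.integers(0, len(sample_ids), size=n_molecules)
    if jackpot.mean <= 1.0:
        dups = np.ones(n_molecules, dtype=int)
    else:
        dups = rng.geometric(1.0 / jackpot.mean, size=n_molecules)
    if jackpot.mega_molecule is not None:
        dups[jackpot.mega_molecule] = jackpot.mega_count

    seen_umis: set = set()
    truths: list[SimTruth] = []
    n_reads = 0
    fastq_path = os.path.join(out_dir, fastq_name)
    truth_path = os.path.join(out_dir, truth_name)
    with open(fastq_path, "w") as fq:
        for i in range(n_molecules):
            label = LABELS[int(labels[i])]
            umi = _random_seq(rng, spec.umi_length)
            if unique_umis:
                while umi in seen_umis:
                    umi = _random_seq(rng, spec.umi_length)
                seen_umis.add(umi)
            sample = sample_ids[int(samples[i])]
            fwd_bc, rev_bc = pairs[sample]
            amplicon, details = make_amplicon(spec, label, rng)
            mol_id = f"mol{i:06d}"
            truths.append(SimTruth(mol_id, label, umi, sample,
                                   int(dups[i]), details))
            for c in range(int(dups[i])):
                orientation = "reverse" if rng.random() < 0.5 else "forward"
                read = assemble_library_read(amplicon, spec, umi, fwd_bc,
                                             rev_bc, orientation)
                read = apply_errors(read, error_model, rng)
                fq.write(f"@{mol_id}_c{c}\n{read}\n+\n"
                         f"{error_model.quality_char * len(read)}\n")
                n_reads += 1
    with open(truth_path, "w") as fh:
        fh.write("molecule_id\tlabel\tumi\tsample\tdup_count\tindels\n")
        for t in truths:
            ind = ";".join(f"{k}:{p}:{s}" for p, s, k in t.indel_details)
            fh.write(f"{t.molecule_id}\t{t.true_label}\t{t.umi}\t"
                     f"{t.sample_id}\t{t.duplication_count}\t{ind}\n")
    return SimulatedRun(fastq_path, truth_path, truths, n_reads)


def read_truth_table(path: str) -> list:
    """Parse a truth TSV back into :class:`SimTruth` rows."""
    truths = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            mol, label, umi, sample, dup, ind = line.rstrip("\n").split("\t")
            details = []
            if ind:
                for item in ind.split(";"):
                    kind, pos, size = item.split(":")
                    details.append((int(pos), int(size), kind))
            truths.append(SimTruth(mol, label, umi, sample, int(dup), details))
    return truths
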