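"""Target locus model: the edited amplicon and its expected references.

A knock-in experiment is described by a :class:`TargetSpec`: the
unmodified target amplicon (on the forward-primer strand), the two
homology arms flanking the insertion point, the exogenous tag insert, the
universal adapter/primer sequences and sample barcodes used in library
construction, the UMI length, and optionally a single-nucleotide site
(e.g. a silent PAM edit carried by the donor) whose allele is read out
per molecule.

:func:`build_references` derives the two expected references every read
is compared against: the unmodified amplicon and the precise knock-in
product (amplicon with the tag spliced in at the insertion point), with
the 5' and 3' junction coordinates recorded.

All coordinates are 0-based, half-open, on the forward strand.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_DNA = set("ACGT")


class TargetConfigError(ValueError):
    """The target configuration is missing fields or unreadable."""


class TargetConsistencyError(ValueError):
    """The target configuration violates a structural invariant."""


@dataclass(frozen=True)
class SnpSite:
    """A single-nucleotide readout site in unmodified-amplicon coordinates
    (typically a silent PAM edit carried by the HDR template)."""

    position: int
    ref_base: str
    template_base: str


@dataclass(frozen=True)
class TargetSpec:
    gene_name: str
    amplicon_seq: str
    left_arm: str
    right_arm: str
    tag_seq: str
    insertion_point: int
    fwd_universal: str
    rev_universal: str
    umi_length: int = 8
    barcode_pairs: tuple = ()  # tuple of (sample_id, fwd_barcode, rev_barcode)
    snp_site: Optional[SnpSite] = None
    prefix_check_len: int = 30
    prefix_max_edits: int = 6

    def validate(self) -> "TargetSpec":
        amp = self.amplicon_seq
        for name in ("amplicon_seq", "left_arm", "right_arm",
                     "fwd_universal", "rev_universal"):
            seq = getattr(self, name)
            if not seq:
                raise TargetConfigError(f"{name} is empty")
            if not set(seq) <= _DNA:
                raise TargetConfigError(f"{name} contains non-ACGT characters")
        if self.tag_seq and not set(self.tag_seq) <= _DNA:
            raise TargetConfigError("tag_seq contains non-ACGT characters")
        if len(amp) < 1000:
            raise TargetConsistencyError(
                f"amplicon must be >= 1000 bp (got {len(amp)})")
        if not 0 < self.insertion_point < len(amp):
            raise TargetConsistencyError("insertion_point outside amplicon")
        ip = self.insertion_point
        if amp[ip - len(self.left_arm): ip] != self.left_arm:
            raise TargetConsistencyError(
                "left_arm does not match amplicon immediately 5' of insertion_point")
        if amp[ip: ip + len(self.right_arm)] != self.right_arm:
            raise TargetConsistencyError(
                "right_arm does not match amplicon immediately 3' of insertion_point")
        if self.tag_seq and self.tag_seq in amp:
            raise TargetConsistencyError("tag_seq occurs in the unmodified amplicon")
        if self.umi_length <= 0:
            raise TargetConfigError("umi_length must be positive")
        seen = set()
        for sample, fwd, rev in self.barcode_pairs:
            if (fwd, rev) in seen:
                raise TargetConfigError(
                    f"duplicate barcode pair ({fwd}, {rev}) for sample {sample}")
            seen.add((fwd, rev))
            for bc in (fwd, rev):
                if not bc or not set(bc) <= _DNA:
                    raise TargetConfigError(f"invalid barcode for sample {sample}")
        if self.snp_site is not None:
            s = self.snp_site
            if not 0 <= s.position < len(amp):
                raise TargetConsistencyError("snp_site position outside amplicon")
            if amp[s.position] != s.ref_base:
                raise TargetConsistencyError(
                    "snp_site ref_base does not match the amplicon")
            if s.template_base == s.ref_base:
                raise TargetConsistencyError("snp_site template equals ref base")
        return self


@dataclass(frozen=True)
class ReferenceSet:
    """Expected references with the tag junction coordinates on the
    precise reference. ``tag_span`` is half-open: precise_ref with
    ``tag_span`` excised is the unmodified amplicon."""

    unmodified_ref: str
    precise_ref: str
    junction_5p: int
    junction_3p: int

    @property
    def tag_span(self) -> tuple:
        return (self.junction_5p, self.junction_3p)

    def lift_to_precise(self, unmodified_pos: int) -> int:
        """Lift an unmodified-amplicon coordinate onto the precise reference."""
        if unmodified_pos < self.junction_5p:
            return unmodified_pos
        return unmodified_pos + (self.junction_3p - self.junction_5p)


def build_references(spec: TargetSpec) -> ReferenceSet:
    """Construct unmodified and precise-knock-in references.

    The precise reference is the amplicon with the tag inserted at the
    insertion point; its 5' junction coordinate equals the insertion
    point, and the 3' junction sits one tag length downstream.
    """
    ip = spec.insertion_point
    precise = spec.amplicon_seq[:ip] + spec.tag_seq + spec.amplicon_seq[ip:]
    return ReferenceSet(
        unmodified_ref=spec.amplicon_seq,
        precise_ref=precise,
        junction_5p=ip,
        junction_3p=ip + len(spec.tag_seq),
    )


def _load_sequence(value, config_dir: str, key: str) -> str:
    """A sequence field is either an inline string or a FASTA reference
    ``{fasta: path, record: name}`` resolved relative to the config."""
    if isinstance(value, str):
        return value.upper()
    if isinstance(value, dict) and "fasta" in value:
        path = value["fasta"]
        if not os.path.isabs(path):
            path = os.path.join(config_dir, path)
        if not os.path.exists(path):
            raise TargetConfigError(f"{key}: FASTA file not found: {path}")
        want = value.get("record")
        for rec in SeqIO.parse(path, "fasta"):
            if want is None or rec.id == want:
                return str(rec.seq).upper()
        raise TargetConfigError(f"{key}: record {want!r} not found in {path}")
    raise TargetConfigError(f"{key}: expected a sequence or {{fasta, record}}")


def load_target_spec(config_path: str) -> TargetSpec:
    """Load and validate a target specification from a YAML document.

    Required keys: ``gene``, ``amplicon``, ``left_arm``, ``right_arm``,
    ``tag``, ``insertion_point``, ``fwd_universal``, ``rev_universal``.
    Optional: ``umi_length``, ``barcodes`` (list of ``{sample, fwd, rev}``),
    ``snp_site`` (``{position, ref, template}``), ``prefix_check_len``,
    ``prefix_max_edits``. Sequences may be inline or FASTA references.
    """
    if not os.path.exists(config_path):
        raise TargetConfigError(f"config file not found: {config_path}")
    with open(config_path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise TargetConfigError("config must be a mapping")
    cfg_dir = os.path.dirname(os.path.abspath(config_path))
    required = ["gene", "amplicon", "left_arm", "right_arm", "tag",
                "insertion_point", "fwd_universal", "rev_universal"]
    missing = [k for k in required if k not in doc]
    if missing:
        raise TargetConfigError(f"missing config fields: {', '.join(missing)}")
    barcodes = []
    for entry in doc.get("barcodes", []) or []:
        try:
            barcodes.append((str(entry["sample"]), entry["fwd"].upper(),
                             entry["rev"].upper()))
        except (KeyError, TypeError, AttributeError) as exc:
            raise TargetConfigError(f"malformed barcode entry: {entry!r}") from exc
    snp = None
    if doc.get("snp_site") is not None:
        s = doc["snp_site"]
        try:
            snp = SnpSite(int(s["position"]), s["ref"].upper(), s["template"].upper())
        except (KeyError, TypeError, AttributeError) as exc:
            raise TargetConfigError(f"malformed snp_site: {s!r}") from exc
    spec = TargetSpec(
        gene_name=str(doc["gene"]),
        amplicon_seq=_load_sequence(doc["amplicon"], cfg_dir, "amplicon"),
        left_arm=_load_sequence(doc["left_arm"], cfg_dir, "left_arm"),
        right_arm=_load_sequence(doc["right_arm"], cfg_dir, "right_arm"),
        tag_seq=_load_sequence(doc["tag"], cfg_dir, "tag") if doc["tag"] else "",
        insertion_point=int(doc["insertion_point"]),
        fwd_universal=_load_sequence(doc["fwd_universal"], cfg_dir, "fwd_universal"),
        rev_universal=_load_sequence(doc["rev_universal"], cfg_dir, "rev_universal"),
        umi_length=int(doc.get("umi_length", 8)),
        barcode_pairs=tuple(barcodes),
        snp_site=snp,
        prefix_check_len=int(doc.get("prefix_check_len", 30)),
        prefix_max_edits=int(doc.get("prefix_max_edits", 6)),
    )
    return spec.validate()


def write_references_fasta(refs: ReferenceSet, path: str) -> None:
    records = [
        SeqRecord(Seq(refs.unmodified_ref), id="unmodified", description=""),
        SeqRecord(Seq(refs.precise_ref), id="precise", description=""),
    ]
    SeqIO.write(records, path, "fasta")


def default_target_spec() -> TargetSpec:
    """The packaged default fixture: a 2,000 bp amplicon, 50 bp homology
    arms, a 90 bp Avitag-Myc insert at position 1,000, three barcoded
    samples and a PAM-edit readout site in the left arm."""
    from importlib.resources import files

    path = files("kiquant").joinpath("data/default_target.yaml")
    return load_target_spec(str(path))
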