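import numpy as np
import pytest

from kiquant.target_model import (SnpSite, TargetSpec, build_references,
                                  default_target_spec)

BASES = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


def make_spec(rng: np.random.Generator, amplicon_len: int = 1200,
              tag_len: int = 60, arm_len: int = 50,
              insertion_point: int = None, with_snp: bool = False,
              n_samples: int = 1) -> TargetSpec:
    """A self-consistent random target spec for property tests."""
    amp = random_dna(rng, amplicon_len)
    ip = insertion_point if insertion_point is not None else amplicon_len // 2
    if tag_len and tag_len < 15:
        raise ValueError("tag_len must be 0 or >= 15 to stay absent from a "
                         "random amplicon")
    tag = random_dna(rng, tag_len)
    while tag and tag in amp:
        tag = random_dna(rng, tag_len)
    barcodes = []
    for i in range(n_samples):
        barcodes.append((f"s{i}", random_dna(rng, 8), random_dna(rng, 8)))
    snp = None
    if with_snp:
        pos = ip - 6
        ref_base = amp[pos]
        snp = SnpSite(pos, ref_base, "ACGT"[("ACGT".index(ref_base) + 1) % 4])
    return TargetSpec(
        gene_name="randspec",
        amplicon_seq=amp,
        left_arm=amp[ip - arm_len: ip],
        right_arm=amp[ip: ip + arm_len],
        tag_seq=tag,
        insertion_point=ip,
        fwd_universal=random_dna(rng, 30),
        rev_universal=random_dna(rng, 30),
        barcode_pairs=tuple(barcodes),
        snp_site=snp,
    ).validate()


@pytest.fixture(scope="session")
def spec():
    return default_target_spec()


@pytest.fixture(scope="session")
def refs(spec):
    return build_references(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
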