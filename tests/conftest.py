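import numpy as np
import pytest

from pingovir.io import ContigRecord

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(BASES, size=n).tobytes().decode()


def mutate(rng: np.random.Generator, seq: str, sub: float, indel: float = 0.0) -> str:
    """Copy of ``seq`` with per-base substitutions (and optional indels)."""
    out = []
    for ch in seq:
        r = rng.random()
        if r < sub:
            choices = [b for b in "ACGT" if b != ch]
            out.append(choices[rng.integers(3)])
        elif r < sub + indel / 2:
            continue
        elif r < sub + indel:
            out.append(ch)
            out.append("ACGT"[rng.integers(4)])
        else:
            out.append(ch)
    return "".join(out)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_community():
    """A small but complete synthetic community shared across tests."""
    from pingovir.synthetic import CommunityDesign, generate_community

    design = CommunityDesign(
        n_phage=12,
        n_hosts=4,
        phage_len_range=(3_000, 9_000),
        host_len_range=(30_000, 50_000),
        arrays_per_host=(1, 3),
        mutation_rate=0.0,
        n_false_negatives=1,
    )
    return generate_community(design, seed=11)


def contig(id_: str, seq: str) -> ContigRecord:
    return ContigRecord(id_, seq)
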