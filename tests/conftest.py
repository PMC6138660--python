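import textwrap

import numpy as np
import pytest

from recynh.library import LibraryEntry, Role, build_reference
from recynh.matrix import CountMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_fasta(tmp_path):
    path = tmp_path / "lib.fasta"
    path.write_text(
        textwrap.dedent(
            """\
            >orf1 first test ORF
            ATGGCTGCTACTGGTCCTAAAGAAGACGTT
            >orf2
            atgtctcaagttgctgctgctgctgaataa
            """
        )
    )
    return path


def _random_entries(n, length, role, seed):
    gen = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    return [
        LibraryEntry(
            id=f"{role.value}{i}",
            display_name=f"{role.value}{i}",
            sequence="".join(gen.choice(bases, size=length)),
            role=role,
        )
        for i in range(n)
    ]


@pytest.fixture
def bait_entries():
    return _random_entries(4, 240, Role.BAIT, seed=11)


@pytest.fixture
def prey_entries():
    return _random_entries(5, 240, Role.PREY, seed=22)


@pytest.fixture
def bait_refs(bait_entries):
    return build_reference(bait_entries)


@pytest.fixture
def prey_refs(prey_entries):
    return build_reference(prey_entries)


@pytest.fixture
def count_2x2():
    return CountMatrix(
        baits=["x1", "x2"],
        preys=["y1", "y2"],
        values=np.array([[2, 2], [0, 4]]),
        condition="RS",
    )
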