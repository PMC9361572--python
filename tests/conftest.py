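import random

import pytest

from ksdater import read_newick
from ksdater.ng86 import GENETIC_CODE, NUCLEOTIDES, STOP_CODONS

SENSE_CODONS = sorted(GENETIC_CODE)


def random_codon_pair_seqs(rng: random.Random, n_codons: int, n_mut: int):
    """A random sense-codon sequence and a point-mutated copy.

    Mutations avoid creating stop codons so both sequences stay valid
    in-frame coding sequences.
    """
    a = [rng.choice(SENSE_CODONS) for _ in range(n_codons)]
    b = list(a)
    applied = 0
    while applied < n_mut:
        ci = rng.randrange(n_codons)
        pos = rng.randrange(3)
        base = rng.choice([x for x in NUCLEOTIDES if x != b[ci][pos]])
        mutant = b[ci][:pos] + base + b[ci][pos + 1 :]
        if mutant in STOP_CODONS:
            continue
        b[ci] = mutant
        applied += 1
    return "".join(a), "".join(b)


@pytest.fixture
def species_tree_7():
    """A rooted binary 7-species tree used by reconciliation tests."""
    return read_newick("(((A,B),(C,D)),(E,(F,G)));")


@pytest.fixture
def write_fasta(tmp_path):
    def _write(records, name="seqs.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in records:
                fh.write(f">{rid}\n{seq}\n")
        return path

    return _write


@pytest.fixture
def write_tsv(tmp_path):
    def _write(rows, name="table.tsv"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for row in rows:
                fh.write("\t".join(str(x) for x in row) + "\n")
        return path

    return _write
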