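from __future__ import annotations

import numpy as np
import pytest

from kcvkit.msa import ScoringScheme
from kcvkit.seq_io import Alphabet, SequenceRecord


@pytest.fixture
def dna(tmp_path):
    """Factory for DNA records."""

    def make(rid: str, seq: str) -> SequenceRecord:
        return SequenceRecord(id=rid, residues=seq, alphabet=Alphabet.DNA)

    return make


@pytest.fixture
def protein():
    def make(rid: str, seq: str) -> SequenceRecord:
        return SequenceRecord(id=rid, residues=seq, alphabet=Alphabet.PROTEIN)

    return make


@pytest.fixture
def simple_dna_scheme():
    return ScoringScheme.dna_default(match=1, mismatch=-1, gap_open=2, gap_extend=2)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_force_global_score(sa: str, sb: str, scheme: ScoringScheme) -> float:
    """Exhaustive enumeration of all global alignments (oracle).

    Gap convention matches the production aligner: the first gapped
    position of a run costs gap_open, later ones gap_extend.
    """
    best = -float("inf")

    def rec(i: int, j: int, prev: str | None, acc: float) -> None:
        nonlocal best
        if i == len(sa) and j == len(sb):
            best = max(best, acc)
            return
        if i < len(sa) and j < len(sb):
            rec(i + 1, j + 1, "D", acc + scheme.score(sa[i], sb[j]))
        if i < len(sa):
            rec(i + 1, j, "U", acc - (scheme.gap_extend if prev == "U" else scheme.gap_open))
        if j < len(sb):
            rec(i, j + 1, "L", acc - (scheme.gap_extend if prev == "L" else scheme.gap_open))

    rec(0, 0, None, 0.0)
    return best
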