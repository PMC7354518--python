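"""Global pairwise alignment, progressive multiple alignment, conservation.

The aligner is a Gotoh affine-gap dynamic program maximizing score, with
the convention that a gap of length L costs ``gap_open + (L-1)*gap_extend``
and a deterministic traceback tie-break of diagonal > up > left. The same
engine aligns sequences and profiles (columns scored sum-of-pairs over
residue counts), so progressive merges obey "once a gap, always a gap".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from kcvkit.seq_io import Alphabet, SequenceRecord

__all__ = [
    "ScoringScheme",
    "PairwiseAlignment",
    "MultipleAlignment",
    "global_align",
    "progressive_msa",
    "column_conservation",
    "read_aligned_fasta",
    "write_aligned_fasta",
]

GAP = "-"


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution scores plus affine gap penalties (both nonnegative)."""

    matrix: dict[tuple[str, str], float]
    gap_open: float
    gap_extend: float
    alphabet: Alphabet

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend >= 0):
            raise ValueError("require gap_open >= gap_extend >= 0")

    def score(self, a: str, b: str) -> float:
        return self.matrix.get((a, b), self.matrix.get((b, a), 0.0))

    @staticmethod
    def protein_default(gap_open: float = 10.0, gap_extend: float = 0.5) -> "ScoringScheme":
        blosum = substitution_matrices.load("BLOSUM62")
        mat = {
            (a, b): float(blosum[a, b])
            for a in blosum.alphabet
            for b in blosum.alphabet
        }
        return ScoringScheme(mat, gap_open, gap_extend, Alphabet.PROTEIN)

    @staticmethod
    def dna_default(
        match: float = 2.0, mismatch: float = -3.0, gap_open: float = 5.0, gap_extend: float = 2.0
    ) -> "ScoringScheme":
        letters = "ACGT"
        mat = {(a, b): (match if a == b else mismatch) for a in letters for b in letters}
        return ScoringScheme(mat, gap_open, gap_extend, Alphabet.DNA)

    @staticmethod
    def default_for(alphabet: Alphabet) -> "ScoringScheme":
        return (
            ScoringScheme.protein_default()
            if alphabet is Alphabet.PROTEIN
            else ScoringScheme.dna_default()
        )


@dataclass(frozen=True)
class PairwiseAlignment:
    row_a: str
    row_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.row_a) != len(self.row_b):
            raise ValueError("aligned rows must have equal length")
        if any(a == GAP and b == GAP for a, b in zip(self.row_a, self.row_b)):
            raise ValueError("gap-gap column in pairwise alignment")

    def __len__(self) -> int:
        return len(self.row_a)


@dataclass
class MultipleAlignment:
    """Ordered rows of equal-length gapped sequences."""

    rows: list[tuple[str, str]]  # (id, gapped string)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment must have at least one row")
        n = len(self.rows[0][1])
        for rid, row in self.rows:
            if len(row) != n:
                raise ValueError(f"row {rid!r} has length {len(row)} != {n}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def column(self, i: int) -> str:
        return "".join(row[i] for _, row in self.rows)

    def row(self, rid: str) -> str:
        for r, s in self.rows:
            if r == rid:
                return s
        raise KeyError(rid)

    def degapped(self, rid: str) -> str:
        return self.row(rid).replace(GAP, "")


# ---------------------------------------------------------------------------
# Gotoh engine
# ---------------------------------------------------------------------------

_NEG = -1e30


def _gotoh(sim: np.ndarray, gap_open: float, gap_extend: float) -> tuple[float, list[str]]:
    """Affine-gap global alignment over a precomputed similarity matrix.

    Returns the optimal score and the traceback as a list of ops:
    'D' consumes one item of both axes, 'U' consumes a row item against a
    gap, 'L' a column item against a gap. Tie-break: D > U > L.
    """
    n, m = sim.shape
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)  # gap in columns axis (op 'U')
    Y = np.full((n + 1, m + 1), _NEG)  # gap in rows axis (op 'L')
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(gap_open + (i - 1) * gap_extend)
    for j in range(1, m + 1):
        Y[0, j] = -(gap_open + (j - 1) * gap_extend)

    # backpointers: which state each cell came from (0=M, 1=X, 2=Y)
    bM = np.zeros((n + 1, m + 1), dtype=np.int8)
    bX = np.zeros((n + 1, m + 1), dtype=np.int8)
    bY = np.zeros((n + 1, m + 1), dtype=np.int8)
    for i in range(2, n + 1):
        bX[i, 0] = 1
    for j in range(2, m + 1):
        bY[0, j] = 2

    for i in range(1, n + 1):
        si = sim[i - 1]
        for j in range(1, m + 1):
            # M: diagonal move; source ranked M > X > Y on ties
            cands = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            k = max(range(3), key=lambda q: (cands[q], -q))
            M[i, j] = cands[k] + si[j - 1]
            bM[i, j] = k
            # X: consume row item i against gap
            cands = (M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend, Y[i - 1, j] - gap_open)
            k = max(range(3), key=lambda q: (cands[q], -q))
            X[i, j] = cands[k]
            bX[i, j] = k
            # Y: consume column item j against gap
            cands = (M[i, j - 1] - gap_open, X[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend)
            k = max(range(3), key=lambda q: (cands[q], -q))
            Y[i, j] = cands[k]
            bY[i, j] = k

    finals = (M[n, m], X[n, m], Y[n, m])
    state = max(range(3), key=lambda q: (finals[q], -q))
    score = finals[state]

    ops: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            ops.append("D")
            prev = bM[i, j]
            i, j = i - 1, j - 1
        elif state == 1:
            ops.append("U")
            prev = bX[i, j]
            i -= 1
        else:
            ops.append("L")
            prev = bY[i, j]
            j -= 1
        state = prev
    ops.reverse()
    return float(score), ops


def global_align(a: SequenceRecord, b: SequenceRecord, scheme: ScoringScheme | None = None) -> PairwiseAlignment:
    """Optimal global alignment of two records under an affine-gap scheme."""
    if a.alphabet is not b.alphabet:
        raise ValueError("cannot align records with different alphabets")
    if scheme is None:
        scheme = ScoringScheme.default_for(a.alphabet)
    sa, sb = a.residues, b.residues
    if not sa and not sb:
        raise ValueError("both sequences empty")
    sim = np.array([[scheme.score(x, y) for y in sb] for x in sa], dtype=float).reshape(
        len(sa), len(sb)
    )
    score, ops = _gotoh(sim, scheme.gap_open, scheme.gap_extend)
    ra, rb = [], []
    i = j = 0
    for op in ops:
        if op == "D":
            ra.append(sa[i]); rb.append(sb[j]); i += 1; j += 1
        elif op == "U":
            ra.append(sa[i]); rb.append(GAP); i += 1
        else:
            ra.append(GAP); rb.append(sb[j]); j += 1
    return PairwiseAlignment("".join(ra), "".join(rb), score)


# ---------------------------------------------------------------------------
# Progressive MSA
# ---------------------------------------------------------------------------


def _kmer_set(seq: str, k: int = 3) -> frozenset[str]:
    if len(seq) < k:
        return frozenset([seq])
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def _jaccard_distance(a: frozenset[str], b: frozenset[str]) -> float:
    union = len(a | b)
    return 1.0 - (len(a & b) / union if union else 1.0)


def _profile_counts(rows: list[str], letters: str) -> np.ndarray:
    """Column x symbol count matrix; the last symbol slot is the gap."""
    index = {c: i for i, c in enumerate(letters)}
    out = np.zeros((len(rows[0]), len(letters)), dtype=float)
    for row in rows:
        for pos, c in enumerate(row):
            out[pos, index[c]] += 1
    return out


def _merge_profiles(
    rows_a: list[str], rows_b: list[str], scheme: ScoringScheme, letters: str, smat: np.ndarray
) -> tuple[list[str], list[str]]:
    """Align two gapped profiles; returns the two row blocks re-gapped."""
    ca = _profile_counts(rows_a, letters)
    cb = _profile_counts(rows_b, letters)
    # mean sum-of-pairs score between non-gap residues of the two columns
    na = ca[:, :-1].sum(axis=1)
    nb = cb[:, :-1].sum(axis=1)
    denom = np.outer(na, nb)
    denom[denom == 0] = 1.0
    sim = (ca[:, :-1] @ smat @ cb[:, :-1].T) / denom
    _, ops = _gotoh(sim, scheme.gap_open, scheme.gap_extend)
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    i = j = 0
    gap_a = GAP
    for op in ops:
        if op == "D":
            for r, row in enumerate(rows_a):
                out_a[r] += row[i]
            for r, row in enumerate(rows_b):
                out_b[r] += row[j]
            i += 1; j += 1
        elif op == "U":
            for r, row in enumerate(rows_a):
                out_a[r] += row[i]
            for r in range(len(rows_b)):
                out_b[r] += gap_a
            i += 1
        else:
            for r in range(len(rows_a)):
                out_a[r] += gap_a
            for r, row in enumerate(rows_b):
                out_b[r] += row[j]
            j += 1
    return out_a, out_b


def progressive_msa(
    seqs: Sequence[SequenceRecord], scheme: ScoringScheme | None = None
) -> MultipleAlignment:
    """Progressive multiple alignment with a single-linkage 3-mer guide.

    Guide order comes from single-linkage clustering on 3-mer Jaccard
    distances; merges are profile-profile alignments under the scheme;
    output rows keep the input order.
    """
    if len(seqs) < 2:
        raise ValueError("progressive_msa needs at least 2 sequences")
    alphabet = seqs[0].alphabet
    if any(s.alphabet is not alphabet for s in seqs):
        raise ValueError("mixed alphabets")
    if scheme is None:
        scheme = ScoringScheme.default_for(alphabet)

    letters = "ACDEFGHIKLMNPQRSTVWYX*" if alphabet is Alphabet.PROTEIN else "ACGTN"
    letters = letters + GAP
    smat = np.array(
        [[scheme.score(x, y) for y in letters[:-1]] for x in letters[:-1]], dtype=float
    )

    kmers = [_kmer_set(s.residues) for s in seqs]
    n = len(seqs)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = _jaccard_distance(kmers[i], kmers[j])

    # clusters: member index list + current gapped rows (same order)
    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [seqs[i].residues]) for i in range(n)
    }
    while len(clusters) > 1:
        best: tuple[float, int, int] | None = None
        keys = sorted(clusters)
        for ai, a in enumerate(keys):
            for b in keys[ai + 1 :]:
                d = min(dist[x, y] for x in clusters[a][0] for y in clusters[b][0])
                if best is None or d < best[0]:
                    best = (d, a, b)
        assert best is not None
        _, a, b = best
        mem_a, rows_a = clusters.pop(a)
        mem_b, rows_b = clusters.pop(b)
        out_a, out_b = _merge_profiles(rows_a, rows_b, scheme, letters, smat)
        clusters[a] = (mem_a + mem_b, out_a + out_b)

    members, rows = next(iter(clusters.values()))
    order = {m: rows[k] for k, m in enumerate(members)}
    return MultipleAlignment([(seqs[i].id, order[i]) for i in range(n)])


def column_conservation(msa: MultipleAlignment) -> tuple[list[float], int]:
    """Per-column fraction of rows carrying the modal symbol (gaps count).

    Returns the fraction vector and the number of fully conserved columns.
    """
    fractions = []
    full = 0
    for i in range(msa.n_columns):
        col = msa.column(i)
        best = max(set(col), key=col.count)
        frac = col.count(best) / len(col)
        fractions.append(frac)
        if frac == 1.0:
            full += 1
    return fractions, full


def read_aligned_fasta(path: str | Path) -> MultipleAlignment:
    """Read a gapped FASTA file as a MultipleAlignment."""
    rows: list[tuple[str, str]] = []
    rid: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if rid is not None:
                    rows.append((rid, "".join(chunks).upper()))
                rid = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
        if rid is not None:
            rows.append((rid, "".join(chunks).upper()))
    return MultipleAlignment(rows)


def write_aligned_fasta(msa: MultipleAlignment, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, row in msa.rows:
            fh.write(f">{rid}\n")
            for i in range(0, len(row), width):
                fh.write(row[i : i + width] + "\n")
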