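"""Unique-sequence collapse, divergence counting, and domain profiling.

The counting analysis at the heart of the pipeline: exact-identity
collapse of coding sequences and proteins, variable-site counts over an
alignment, alignment-based pairwise difference counts (gap-vs-residue
columns count as differences; percent divergence uses alignment length as
the denominator), protein length histograms, K+ selectivity-filter motif
classification, and domain-interval transfer for per-domain conservation.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from kcvkit import msa as _msa
from kcvkit.msa import MultipleAlignment, ScoringScheme, column_conservation, global_align
from kcvkit.seq_io import Alphabet, SequenceRecord, translate

__all__ = [
    "UniqueGroup",
    "DomainAnnotation",
    "MotifMatch",
    "DiversityReport",
    "DOMAIN_ORDER",
    "DEFAULT_REFERENCE_DOMAINS",
    "FILTER_MOTIF_PATTERN",
    "collapse_unique",
    "variable_sites",
    "pairwise_differences",
    "length_histogram",
    "classify_filter_motif",
    "annotate_domains",
    "per_domain_conservation",
    "build_report",
]

DOMAIN_ORDER = ("slide_helix", "TMD1", "turret", "pore_helix", "filter", "TMD2", "c_tail")

#: Selectivity-filter octapeptide: T-T-x-G-[Y/F]-G-[D/N]-x.
FILTER_MOTIF_PATTERN = re.compile(r"TT.G[YF]G[DN].")


@dataclass(frozen=True)
class UniqueGroup:
    """One identity class from a collapse, with its multiplicity."""

    representative: SequenceRecord
    member_ids: tuple[str, ...]

    @property
    def count(self) -> int:
        return len(self.member_ids)


@dataclass(frozen=True)
class MotifMatch:
    """A located selectivity-filter octapeptide."""

    motif: str
    start: int  # 1-based

    def __post_init__(self) -> None:
        if len(self.motif) != 8:
            raise ValueError("filter motif must be 8 residues")


@dataclass(frozen=True)
class DomainAnnotation:
    """Half-open 1-based residue intervals [start, end) per domain.

    Domains may be absent (empty interval); intervals are ordered and
    non-overlapping; the filter interval is always 8 residues long.
    """

    intervals: Mapping[str, tuple[int, int]]

    def __post_init__(self) -> None:
        unknown = set(self.intervals) - set(DOMAIN_ORDER)
        if unknown:
            raise ValueError(f"unknown domains {sorted(unknown)}")
        prev_end = 0
        for name in DOMAIN_ORDER:
            if name not in self.intervals:
                continue
            start, end = self.intervals[name]
            if start > end:
                raise ValueError(f"{name}: start > end")
            if start < prev_end + 1 and start != end:
                raise ValueError(f"{name}: overlaps a preceding domain")
            if start != end:
                prev_end = end - 1
        if "filter" in self.intervals:
            s, e = self.intervals["filter"]
            if e - s != 8:
                raise ValueError("filter interval must span exactly 8 residues")

    def length(self, name: str) -> int:
        if name not in self.intervals:
            return 0
        s, e = self.intervals[name]
        return e - s

    def domain_of(self, pos: int) -> str | None:
        """Domain containing 1-based residue position ``pos``, if any."""
        for name in DOMAIN_ORDER:
            if name in self.intervals:
                s, e = self.intervals[name]
                if s <= pos < e:
                    return name
        return None


#: Domain layout of the 82-residue reference channel subunit (1-based,
#: half-open): no slide helix, outer helix, turret, pore helix, 8-residue
#: filter, inner helix, short cytosolic tail.
DEFAULT_REFERENCE_DOMAINS = DomainAnnotation(
    {
        "TMD1": (1, 23),
        "turret": (23, 40),
        "pore_helix": (40, 48),
        "filter": (48, 56),
        "TMD2": (56, 79),
        "c_tail": (79, 83),
    }
)


def collapse_unique(seqs: Sequence[SequenceRecord]) -> list[UniqueGroup]:
    """Group records by exact (case-insensitive) sequence identity.

    Groups are ordered by descending multiplicity, then first appearance.
    """
    if not seqs:
        raise ValueError("collapse_unique: empty input")
    alphabet = seqs[0].alphabet
    if any(s.alphabet is not alphabet for s in seqs):
        raise ValueError("collapse_unique: mixed alphabets")
    groups: dict[str, list[str]] = {}
    reps: dict[str, SequenceRecord] = {}
    first_seen: dict[str, int] = {}
    for idx, rec in enumerate(seqs):
        key = rec.residues  # records are canonical upper case
        groups.setdefault(key, []).append(rec.id)
        reps.setdefault(key, rec)
        first_seen.setdefault(key, idx)
    order = sorted(groups, key=lambda k: (-len(groups[k]), first_seen[k]))
    return [UniqueGroup(reps[k], tuple(groups[k])) for k in order]


def variable_sites(msa: MultipleAlignment) -> tuple[int, int]:
    """(variable column count, total columns); gaps count as a symbol."""
    variable = 0
    for i in range(msa.n_columns):
        if len(set(msa.column(i))) >= 2:
            variable += 1
    return variable, msa.n_columns


def pairwise_differences(
    a: SequenceRecord, b: SequenceRecord, scheme: ScoringScheme | None = None
) -> tuple[int, int, float]:
    """(diff count, alignment length, percent) from a global alignment.

    A column differs when its two symbols differ; a residue aligned to a
    gap is one difference. Percent uses alignment length as denominator.
    """
    aln = global_align(a, b, scheme)
    diffs = sum(x != y for x, y in zip(aln.row_a, aln.row_b))
    return diffs, len(aln), 100.0 * diffs / len(aln)


def length_histogram(proteins: Iterable[SequenceRecord]) -> dict[int, int]:
    """Map of protein length to count."""
    return dict(sorted(Counter(len(p) for p in proteins).items()))


def classify_filter_motif(protein: SequenceRecord) -> MotifMatch | None:
    """Leftmost selectivity-filter octapeptide, or None when absent."""
    m = FILTER_MOTIF_PATTERN.search(protein.residues)
    if m is None:
        return None
    return MotifMatch(motif=m.group(0), start=m.start() + 1)


def annotate_domains(
    protein: SequenceRecord,
    reference: SequenceRecord,
    reference_domains: DomainAnnotation = DEFAULT_REFERENCE_DOMAINS,
    scheme: ScoringScheme | None = None,
) -> DomainAnnotation:
    """Transfer reference domain intervals to a query through an alignment.

    Each query residue takes the domain of its aligned reference residue;
    insertions relative to the reference inherit the preceding domain,
    except that insertions falling between TMD1 and the pore helix are
    assigned to the turret. The filter interval is then re-anchored on the
    query's own motif match.
    """
    q_motif = classify_filter_motif(protein)
    r_motif = classify_filter_motif(reference)
    if q_motif is None or r_motif is None:
        raise ValueError("both query and reference must carry a filter motif")

    aln = global_align(protein, reference, scheme)
    labels: list[str | None] = []
    qpos = rpos = 0
    tmd1_end = reference_domains.intervals.get("TMD1", (0, 0))[1]
    pore_start = reference_domains.intervals.get("pore_helix", (0, 0))[0]
    for qc, rc in zip(aln.row_a, aln.row_b):
        if rc != _msa.GAP:
            rpos += 1
        if qc == _msa.GAP:
            continue
        qpos += 1
        if rc != _msa.GAP:
            labels.append(reference_domains.domain_of(rpos))
        else:
            # insertion: rpos is the last consumed reference residue
            if tmd1_end and pore_start and tmd1_end - 1 <= rpos < pore_start:
                labels.append("turret")
            elif rpos >= 1:
                labels.append(reference_domains.domain_of(rpos) or "c_tail")
            else:
                labels.append(DOMAIN_ORDER[1])  # N-terminal insertion -> TMD1 side

    # re-anchor the filter on the query's own motif
    fstart = q_motif.start
    for k in range(len(labels)):
        pos = k + 1
        if fstart <= pos < fstart + 8:
            labels[k] = "filter"
        elif labels[k] == "filter":
            labels[k] = "pore_helix" if pos < fstart else "TMD2"

    intervals: dict[str, tuple[int, int]] = {}
    for k, lab in enumerate(labels):
        if lab is None:
            continue
        pos = k + 1
        if lab in intervals:
            s, e = intervals[lab]
            intervals[lab] = (s, max(e, pos + 1))
        else:
            intervals[lab] = (pos, pos + 1)
    return DomainAnnotation(intervals)


def per_domain_conservation(
    msa: MultipleAlignment,
    reference_id: str,
    reference_domains: DomainAnnotation = DEFAULT_REFERENCE_DOMAINS,
) -> dict[str, float]:
    """Mean column conservation per domain of the reference row.

    A column belongs to a domain when the reference row carries a residue
    of that domain there; domains with no columns are absent from the
    result.
    """
    fractions, _ = column_conservation(msa)
    ref_row = msa.row(reference_id)
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    rpos = 0
    for col, ch in enumerate(ref_row):
        if ch == _msa.GAP:
            continue
        rpos += 1
        dom = reference_domains.domain_of(rpos)
        if dom is None:
            continue
        sums[dom] = sums.get(dom, 0.0) + fractions[col]
        counts[dom] = counts.get(dom, 0) + 1
    return {d: sums[d] / counts[d] for d in DOMAIN_ORDER if d in sums}


def pick_conservation_reference(
    proteins: Sequence[SequenceRecord],
    reference_domains: DomainAnnotation = DEFAULT_REFERENCE_DOMAINS,
) -> SequenceRecord:
    """Choose a protein the default domain layout applies to directly.

    Prefers a protein whose filter motif sits exactly at the layout's
    filter anchor and whose length matches the layout span; falls back to
    any motif-anchored protein.
    """
    fstart = reference_domains.intervals["filter"][0]
    span = max(e for _, e in reference_domains.intervals.values()) - 1
    anchored = [
        p
        for p in proteins
        if (m := classify_filter_motif(p)) is not None and m.start == fstart
    ]
    for p in anchored:
        if len(p) == span:
            return p
    if anchored:
        return anchored[0]
    raise ValueError("no protein matches the reference domain anchor")


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------


@dataclass
class DiversityReport:
    """Aggregated counts for a coding-sequence family."""

    n_input: int
    n_unique_dna: int
    n_unique_protein: int
    variable_site_count: int
    alignment_length: int
    protein_length_histogram: dict[int, int]
    filter_motif_counts: dict[str, int]
    differences_vs_reference: dict[str, tuple[int, int, float]]
    reference_id: str | None

    def __post_init__(self) -> None:
        if not (self.n_unique_protein <= self.n_unique_dna <= self.n_input):
            raise ValueError("expected n_unique_protein <= n_unique_dna <= n_input")
        if sum(self.protein_length_histogram.values()) != self.n_unique_protein:
            raise ValueError("length histogram must sum to n_unique_protein")

    def to_json(self) -> str:
        payload = {
            "n_input": self.n_input,
            "n_unique_dna": self.n_unique_dna,
            "n_unique_protein": self.n_unique_protein,
            "variable_site_count": self.variable_site_count,
            "alignment_length": self.alignment_length,
            "protein_length_histogram": {str(k): v for k, v in self.protein_length_histogram.items()},
            "filter_motif_counts": self.filter_motif_counts,
            "reference_id": self.reference_id,
            "differences_vs_reference": {
                k: {"diff_count": d, "alignment_length": l, "percent": p}
                for k, (d, l, p) in self.differences_vs_reference.items()
            },
        }
        return json.dumps(payload, indent=2)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# section\tkey\tvalue\n")
            fh.write(f"counts\tn_input\t{self.n_input}\n")
            fh.write(f"counts\tn_unique_dna\t{self.n_unique_dna}\n")
            fh.write(f"counts\tn_unique_protein\t{self.n_unique_protein}\n")
            fh.write(f"counts\tvariable_sites\t{self.variable_site_count}\n")
            fh.write(f"counts\talignment_length\t{self.alignment_length}\n")
            for length, cnt in self.protein_length_histogram.items():
                fh.write(f"length_histogram\t{length}\t{cnt}\n")
            for motif, cnt in self.filter_motif_counts.items():
                fh.write(f"filter_motif\t{motif}\t{cnt}\n")
            for rid, (d, l, p) in self.differences_vs_reference.items():
                fh.write(f"diff_vs_ref\t{rid}\t{d}/{l} ({p:.1f}%)\n")


def build_report(
    cds_records: Sequence[SequenceRecord],
    reference_id: str | None = None,
    scheme: ScoringScheme | None = None,
) -> DiversityReport:
    """Run the full counting analysis on a family of coding sequences.

    Collapses CDSs, translates representatives (terminal stop stripped),
    collapses proteins, counts variable sites gap-free over the modal
    protein-length class, classifies filter motifs, and tabulates
    differences of each unique protein against the reference protein.
    """
    dna_groups = collapse_unique(cds_records)
    proteins = [translate(g.representative, strip_terminal_stop=True) for g in dna_groups]
    prot_groups = collapse_unique(proteins)
    unique_prots = [g.representative for g in prot_groups]

    hist = length_histogram(unique_prots)
    modal_len = max(hist, key=lambda k: (hist[k], -k)) if hist else 0

    # variable sites over the modal-length class, gap-free (all CDSs of
    # the class have equal nucleotide length, alignment is positional)
    modal_cds = [
        r for r in cds_records if len(translate(r, strip_terminal_stop=True)) == modal_len
    ]
    if modal_cds:
        cds_len_counts = Counter(len(r) for r in modal_cds)
        modal_cds_len = cds_len_counts.most_common(1)[0][0]
        modal_cds = [r for r in modal_cds if len(r) == modal_cds_len]
    if len(modal_cds) >= 2:
        aln = MultipleAlignment([(r.id, r.residues) for r in modal_cds])
        var_count, aln_len = variable_sites(aln)
    else:
        var_count, aln_len = 0, len(modal_cds[0]) if modal_cds else 0

    motif_counts: dict[str, int] = {}
    for p in unique_prots:
        m = classify_filter_motif(p)
        key = m.motif if m else "none"
        motif_counts[key] = motif_counts.get(key, 0) + 1

    diffs: dict[str, tuple[int, int, float]] = {}
    ref_id = reference_id
    if ref_id is not None:
        ref_cds = next((r for r in cds_records if r.id == ref_id), None)
        if ref_cds is None:
            raise ValueError(f"reference id {ref_id!r} not in input")
        ref_prot = translate(ref_cds, strip_terminal_stop=True)
        for p in unique_prots:
            diffs[p.id] = pairwise_differences(p, ref_prot, scheme)

    return DiversityReport(
        n_input=len(cds_records),
        n_unique_dna=len(dna_groups),
        n_unique_protein=len(prot_groups),
        variable_site_count=var_count,
        alignment_length=aln_len,
        protein_length_histogram=hist,
        filter_motif_counts=dict(sorted(motif_counts.items())),
        differences_vs_reference=diffs,
        reference_id=ref_id,
    )
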