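"""Seeded generator of kcv-like gene families with known ground truth.

Builds a 249-nt ancestral coding sequence (82 codons plus stop) whose
selectivity-filter segment translates to TTVGYGDL, evolves lineages with
domain-specific substitution probabilities (filter most constrained,
transmembrane helices most variable), plants duplicate isolate clusters,
in-frame turret insertions and C-terminal extensions, and wraps every
isolate in flanking DNA carrying binding sites drawn from the expansion
sets of the standard amplification primer pair. Ground truth for every
downstream count is carried alongside the records.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from kcvkit.diversity import DEFAULT_REFERENCE_DOMAINS, DomainAnnotation
from kcvkit.insilico_pcr import Primer, bundled_primers
from kcvkit.seq_io import (
    CODON_TABLE,
    STOP_CODONS,
    Alphabet,
    SequenceRecord,
    expand_degenerate,
    reverse_complement,
    translate,
)

__all__ = [
    "FamilyConfig",
    "GroundTruth",
    "generate_family",
    "mutate_cds",
    "default_domain_probabilities",
    "ancestral_cds",
    "cds_records",
    "SURVEY_LIKE",
]

FILTER_PEPTIDE = "TTVGYGDL"

_CODONS_BY_AA: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TABLE.items()):
    _CODONS_BY_AA.setdefault(_aa, []).append(_codon)


def default_domain_probabilities() -> dict[str, float]:
    """Per-site substitution probabilities: filter << pore/turret < TMDs."""
    return {
        "TMD1": 0.06,
        "turret": 0.03,
        "pore_helix": 0.03,
        "filter": 0.005,
        "TMD2": 0.06,
        "c_tail": 0.02,
    }


@dataclass(frozen=True)
class FamilyConfig:
    """Knobs for one synthetic family; fully deterministic under seed."""

    n_isolates: int = 103
    n_lineages: int = 26
    domain_probabilities: Mapping[str, float] = field(default_factory=default_domain_probabilities)
    duplicate_clusters: tuple[int, ...] = (20, 9)
    turret_insertion_lineages: tuple[int, ...] = (0,)   # lineage indices, 24-nt in-frame
    c_extension_lineages: Mapping[int, int] = field(
        default_factory=lambda: {1: 6, 2: 9}            # lineage -> extra coding nt
    )
    preserve_filter_motif: bool = True
    flank_length: int = 60
    topology: str = "star"                               # "star" | "tree"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lineages < 1 or self.n_isolates < self.n_lineages:
            raise ValueError("need 1 <= n_lineages <= n_isolates")
        for p in self.domain_probabilities.values():
            if not 0 <= p <= 1:
                raise ValueError("substitution probabilities must be in [0,1]")
        if sum(self.duplicate_clusters) > self.n_isolates:
            raise ValueError("duplicate cluster sizes exceed n_isolates")
        if len(self.duplicate_clusters) > self.n_lineages:
            raise ValueError("more duplicate clusters than lineages")
        for extra in self.c_extension_lineages.values():
            if extra % 3 != 0:
                raise ValueError("C-terminal extensions must be in-frame (multiple of 3)")
        for idx in self.turret_insertion_lineages:
            if not 0 <= idx < self.n_lineages:
                raise ValueError("turret insertion lineage index out of range")
        if self.topology not in ("star", "tree"):
            raise ValueError("topology must be 'star' or 'tree'")

    @classmethod
    def for_size(cls, n_isolates: int, seed: int = 0, **overrides) -> "FamilyConfig":
        """A feasible config scaled down from the survey-like defaults."""
        n_lineages = max(1, min(n_isolates, max(3, n_isolates // 4)))
        clusters = tuple(
            c for c in (n_isolates // 5, n_isolates // 10) if c >= 2
        )[: max(0, n_lineages - 1)]
        c_ext = {1: 6, 2: 9} if n_lineages >= 3 else {}
        params = dict(
            n_isolates=n_isolates,
            n_lineages=n_lineages,
            duplicate_clusters=clusters,
            turret_insertion_lineages=(0,),
            c_extension_lineages=c_ext,
            seed=seed,
        )
        params.update(overrides)
        return cls(**params)


@dataclass(frozen=True)
class GroundTruth:
    """What the generator knows that the pipeline must recover."""

    ancestral_cds: str
    lineage_cds: tuple[str, ...]
    isolate_lineage: tuple[int, ...]
    n_unique_dna: int
    n_unique_protein: int
    protein_length_histogram: dict[int, int]
    filter_motif_counts: dict[str, int]
    nt_differences: np.ndarray          # lineage x lineage; NaN when lengths differ
    aa_differences: np.ndarray
    primer_compatible: tuple[bool, ...]  # per isolate
    lineage_newick: str | None

    def to_json(self) -> str:
        return json.dumps(
            {
                "ancestral_cds": self.ancestral_cds,
                "lineage_cds": list(self.lineage_cds),
                "isolate_lineage": list(self.isolate_lineage),
                "n_unique_dna": self.n_unique_dna,
                "n_unique_protein": self.n_unique_protein,
                "protein_length_histogram": {
                    str(k): v for k, v in self.protein_length_histogram.items()
                },
                "filter_motif_counts": self.filter_motif_counts,
                "nt_differences": [
                    [None if np.isnan(x) else int(x) for x in row] for row in self.nt_differences
                ],
                "aa_differences": [
                    [None if np.isnan(x) else int(x) for x in row] for row in self.aa_differences
                ],
                "primer_compatible": list(self.primer_compatible),
                "lineage_newick": self.lineage_newick,
            },
            indent=2,
        )


def _codon_domain_map(domains: DomainAnnotation, n_codons: int) -> list[str | None]:
    """Domain label per coding codon (stop codon excluded)."""
    return [domains.domain_of(i + 1) for i in range(n_codons)]


def ancestral_cds(rng: np.random.Generator, domains: DomainAnnotation = DEFAULT_REFERENCE_DOMAINS) -> str:
    """A random 249-nt CDS: ATG start, filter octapeptide, TAA stop."""
    n_codons = 82
    codons = []
    sense_codons = sorted(set(CODON_TABLE) - STOP_CODONS)
    for i in range(n_codons):
        codons.append(sense_codons[rng.integers(len(sense_codons))])
    codons[0] = "ATG"
    fstart, _ = domains.intervals["filter"]
    for k, aa in enumerate(FILTER_PEPTIDE):
        options = _CODONS_BY_AA[aa]
        codons[fstart - 1 + k] = options[rng.integers(len(options))]
    return "".join(codons) + "TAA"


def mutate_cds(
    cds: str,
    domain_map: Sequence[str | None],
    probabilities: Mapping[str, float],
    rng: np.random.Generator,
    preserve_filter_motif: bool = True,
) -> str:
    """Per-site substitutions with domain-specific probabilities.

    The terminal stop codon is never touched; substitutions creating an
    internal stop are reverted; with the preserve flag, filter-codon
    changes are restricted to synonymous ones (non-synonymous draws are
    reverted).
    """
    if len(cds) % 3 != 0:
        raise ValueError("CDS must be in frame")
    n_codons = len(cds) // 3 - 1  # exclude stop
    if len(domain_map) < n_codons:
        raise ValueError("domain map must cover all coding codons")
    bases = "ACGT"
    seq = list(cds)
    for ci in range(n_codons):
        dom = domain_map[ci]
        p = probabilities.get(dom, 0.0) if dom else 0.0
        if p == 0.0:
            continue
        old_codon = "".join(seq[3 * ci : 3 * ci + 3])
        new_codon = list(old_codon)
        for k in range(3):
            if rng.random() < p:
                choices = [b for b in bases if b != new_codon[k]]
                new_codon[k] = choices[rng.integers(3)]
        candidate = "".join(new_codon)
        if candidate == old_codon:
            continue
        if candidate in STOP_CODONS:
            continue  # revert: no internal stops
        if preserve_filter_motif and dom == "filter" and CODON_TABLE[candidate] != CODON_TABLE[old_codon]:
            continue  # revert: keep the filter peptide intact
        seq[3 * ci : 3 * ci + 3] = new_codon
    return "".join(seq)


def _insert_turret(cds: str, rng: np.random.Generator, domains: DomainAnnotation, n_aa: int = 8) -> str:
    """In-frame insertion of ``n_aa`` random sense codons mid-turret."""
    t_start, t_end = domains.intervals["turret"]
    mid_codon = (t_start + t_end) // 2  # 1-based codon index to insert before
    sense_codons = sorted(set(CODON_TABLE) - STOP_CODONS)
    insert = "".join(sense_codons[rng.integers(len(sense_codons))] for _ in range(n_aa))
    cut = 3 * (mid_codon - 1)
    return cds[:cut] + insert + cds[cut:]


def _extend_c_terminus(cds: str, rng: np.random.Generator, extra_nt: int) -> str:
    """Replace the stop with extra sense codons and a fresh stop."""
    sense_codons = sorted(set(CODON_TABLE) - STOP_CODONS)
    extra = "".join(sense_codons[rng.integers(len(sense_codons))] for _ in range(extra_nt // 3))
    return cds[:-3] + extra + "TAA"


def _random_bifurcating_newick(labels: list[str], rng: np.random.Generator) -> str:
    """Random topology with exponential branch lengths (guide for tree mode)."""
    nodes = [f"{lab}:{rng.exponential(0.05):.4f}" for lab in labels]
    while len(nodes) > 1:
        i = int(rng.integers(len(nodes)))
        a = nodes.pop(i)
        j = int(rng.integers(len(nodes)))
        b = nodes.pop(j)
        nodes.append(f"({a},{b}):{rng.exponential(0.05):.4f}")
    return nodes[0].rsplit(":", 1)[0] + ";"


def _planted_flanks(rng: np.random.Generator, flank_length: int, fwd: Primer, rev: Primer) -> tuple[str, str]:
    """Upstream/downstream flanks carrying concrete primer binding sites."""
    bases = "ACGT"

    def random_dna(n: int) -> str:
        return "".join(bases[rng.integers(4)] for _ in range(n))

    fwd_expansions = list(expand_degenerate(fwd.iupac_seq))
    rev_expansions = list(expand_degenerate(rev.iupac_seq))
    fwd_site = fwd_expansions[rng.integers(len(fwd_expansions))]
    rev_site = reverse_complement(rev_expansions[rng.integers(len(rev_expansions))])
    pad = max(flank_length - len(fwd_site), 4)
    upstream = random_dna(pad // 2) + fwd_site + random_dna(pad - pad // 2)
    pad = max(flank_length - len(rev_site), 4)
    downstream = random_dna(pad // 2) + rev_site + random_dna(pad - pad // 2)
    return upstream, downstream


def generate_family(config: FamilyConfig) -> tuple[list[SequenceRecord], GroundTruth]:
    """Generate isolates (CDS plus flanks) and the matching ground truth.

    Returned records are full templates (upstream flank + CDS + downstream
    flank); the CDS of isolate ``i`` is ``records[i].description``-free but
    recoverable from the ground-truth lineage assignment.
    """
    rng = np.random.default_rng(config.seed)
    domains = DEFAULT_REFERENCE_DOMAINS
    anc = ancestral_cds(rng, domains)
    domain_map = _codon_domain_map(domains, 82)

    lineage_cds: list[str] = []
    for li in range(config.n_lineages):
        cds = mutate_cds(
            anc, domain_map, config.domain_probabilities, rng, config.preserve_filter_motif
        )
        if li in config.turret_insertion_lineages:
            cds = _insert_turret(cds, rng, domains)
        if li in config.c_extension_lineages:
            cds = _extend_c_terminus(cds, rng, config.c_extension_lineages[li])
        lineage_cds.append(cds)

    newick = None
    if config.topology == "tree":
        newick = _random_bifurcating_newick([f"L{i}" for i in range(config.n_lineages)], rng)

    # isolate -> lineage: duplicate clusters first, then round-robin
    assignment: list[int] = []
    for ci, size in enumerate(config.duplicate_clusters):
        assignment.extend([ci] * size)
    li = len(config.duplicate_clusters)
    while len(assignment) < config.n_isolates:
        assignment.append(li % config.n_lineages)
        li += 1

    primers = {p.name: p for p in bundled_primers()}
    fwd, rev = primers["Kcv9_Frw"], primers["Kcv6_Rvs"]

    records: list[SequenceRecord] = []
    compatible: list[bool] = []
    for iso, lin in enumerate(assignment):
        up, down = _planted_flanks(rng, config.flank_length, fwd, rev)
        records.append(
            SequenceRecord(
                id=f"iso{iso:03d}",
                residues=up + lineage_cds[lin] + down,
                alphabet=Alphabet.DNA,
                description=f"lineage=L{lin}",
            )
        )
        compatible.append(True)

    # ground truth bookkeeping
    unique_dna = sorted(set(lineage_cds[lin] for lin in assignment))
    proteins = {
        cds: translate(
            SequenceRecord(id="x", residues=cds, alphabet=Alphabet.DNA), strip_terminal_stop=True
        ).residues
        for cds in unique_dna
    }
    unique_prot = sorted(set(proteins.values()))
    hist: dict[int, int] = {}
    for p in unique_prot:
        hist[len(p)] = hist.get(len(p), 0) + 1

    from kcvkit.diversity import classify_filter_motif  # local import avoids cycle

    motif_counts: dict[str, int] = {}
    for p in unique_prot:
        m = classify_filter_motif(SequenceRecord(id="x", residues=p, alphabet=Alphabet.PROTEIN))
        key = m.motif if m else "none"
        motif_counts[key] = motif_counts.get(key, 0) + 1

    n = config.n_lineages
    nt_diff = np.full((n, n), np.nan)
    aa_diff = np.full((n, n), np.nan)
    lineage_prot = [
        translate(
            SequenceRecord(id="x", residues=c, alphabet=Alphabet.DNA), strip_terminal_stop=True
        ).residues
        for c in lineage_cds
    ]
    for i in range(n):
        nt_diff[i, i] = aa_diff[i, i] = 0
        for j in range(i + 1, n):
            if len(lineage_cds[i]) == len(lineage_cds[j]):
                d = sum(a != b for a, b in zip(lineage_cds[i], lineage_cds[j]))
                nt_diff[i, j] = nt_diff[j, i] = d
            if len(lineage_prot[i]) == len(lineage_prot[j]):
                d = sum(a != b for a, b in zip(lineage_prot[i], lineage_prot[j]))
                aa_diff[i, j] = aa_diff[j, i] = d

    truth = GroundTruth(
        ancestral_cds=anc,
        lineage_cds=tuple(lineage_cds),
        isolate_lineage=tuple(assignment),
        n_unique_dna=len(unique_dna),
        n_unique_protein=len(set(proteins[c] for c in unique_dna)),
        protein_length_histogram=dict(sorted(hist.items())),
        filter_motif_counts=dict(sorted(motif_counts.items())),
        nt_differences=nt_diff,
        aa_differences=aa_diff,
        primer_compatible=tuple(compatible),
        lineage_newick=newick,
    )
    return records, truth


def cds_records(records: list[SequenceRecord], truth: GroundTruth) -> list[SequenceRecord]:
    """CDS-only records for the isolates (flank-free), same ids and order."""
    return [
        SequenceRecord(
            id=rec.id,
            residues=truth.lineage_cds[truth.isolate_lineage[i]],
            alphabet=Alphabet.DNA,
            description=rec.description,
        )
        for i, rec in enumerate(records)
    ]


#: Family mirroring the real survey's headline structure: 103 isolates,
#: duplicate clusters of 20 and 9, one turret-insertion lineage, two
#: C-terminally extended lineages.
SURVEY_LIKE = FamilyConfig()
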