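"""Degenerate-primer matching, amplicon prediction, and primer-panel scoring.

Coordinates are 1-based inclusive on the plus strand throughout. Reverse
primers are written 5'->3' on the minus strand (standard convention) and
matched on the plus strand via their reverse complement. Annotated primer
positions are carried as metadata only and never used in matching.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

from kcvkit.seq_io import IUPAC_SETS, SequenceRecord, reverse_complement

__all__ = [
    "Primer",
    "AmpliconHit",
    "PanelReport",
    "iupac_match",
    "find_sites",
    "simulate_pcr",
    "evaluate_panel",
    "gc_content",
    "wallace_tm",
    "load_primer_panel",
    "bundled_primers",
    "DEFAULT_MIN_LEN",
    "DEFAULT_MAX_LEN",
]

DEFAULT_MIN_LEN = 200
DEFAULT_MAX_LEN = 2000

_GC = frozenset("GC")


@dataclass(frozen=True)
class Primer:
    """A named degenerate oligo, 5'->3' in its own orientation."""

    name: str
    iupac_seq: str
    orientation: Literal["forward", "reverse"]
    annotated_position: int | None = None

    def __post_init__(self) -> None:
        seq = self.iupac_seq.upper().replace("U", "T")
        object.__setattr__(self, "iupac_seq", seq)
        bad = set(seq) - set(IUPAC_SETS)
        if bad:
            raise ValueError(f"primer {self.name!r}: invalid IUPAC character(s) {sorted(bad)}")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"primer {self.name!r}: bad orientation {self.orientation!r}")

    def __len__(self) -> int:
        return len(self.iupac_seq)


@dataclass(frozen=True)
class AmpliconHit:
    """A predicted PCR product on a single template."""

    template_id: str
    fwd_start: int          # 1-based, + strand
    rev_last: int           # 1-based last base covered by the reverse site
    product_length: int
    fwd_mismatches: int
    rev_mismatches: int

    def __post_init__(self) -> None:
        if self.fwd_start > self.rev_last:
            raise ValueError("fwd_start must not exceed rev_last")
        if self.product_length != self.rev_last - self.fwd_start + 1:
            raise ValueError("product_length inconsistent with site coordinates")


@dataclass
class PanelReport:
    """Which templates each primer pair amplifies."""

    template_ids: list[str]
    amplified: dict[tuple[str, str], set[str]]

    def covers_all(self, fwd_name: str, rev_name: str) -> bool:
        return self.amplified[(fwd_name, rev_name)] == set(self.template_ids)

    @property
    def covering_pairs(self) -> list[tuple[str, str]]:
        return [pair for pair in self.amplified if self.covers_all(*pair)]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["fwd", "rev", *self.template_ids, "covers_all"])
            for (fwd, rev), hits in self.amplified.items():
                row = [fwd, rev]
                row += ["1" if tid in hits else "0" for tid in self.template_ids]
                row.append(str(int(self.covers_all(fwd, rev))))
                writer.writerow(row)


def iupac_match(primer_window: str, template_window: str, max_mismatches: int) -> int | None:
    """Count mismatches of a degenerate window against a concrete one.

    A position matches iff the template base is in the ambiguity set of the
    primer base. Returns the mismatch count if it is <= ``max_mismatches``,
    else ``None``.
    """
    if len(primer_window) != len(template_window):
        raise ValueError("primer and template windows must have equal length")
    mism = 0
    for p, t in zip(primer_window.upper(), template_window.upper()):
        if t not in "ACGT":
            raise ValueError(f"ambiguous template base {t!r}")
        if t not in IUPAC_SETS[p]:
            mism += 1
            if mism > max_mismatches:
                return None
    return mism


def find_sites(primer: Primer, template: SequenceRecord, max_mismatches: int = 0) -> list[int]:
    """1-based start positions of primer binding sites on the + strand.

    Forward primers are scanned as written; reverse primers as the reverse
    complement of their sequence. Positions are returned ascending.
    """
    probe = primer.iupac_seq
    if primer.orientation == "reverse":
        probe = reverse_complement(probe)
    tpl = template.residues
    k = len(probe)
    sites = []
    for start in range(len(tpl) - k + 1):
        if iupac_match(probe, tpl[start : start + k], max_mismatches) is not None:
            sites.append(start + 1)
    return sites


def simulate_pcr(
    fwd: Primer,
    rev: Primer,
    template: SequenceRecord,
    max_mismatches: int = 0,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> list[AmpliconHit]:
    """Predict amplicons for a primer pair on one template.

    One hit per (forward site, reverse site) pair with the forward site
    upstream and the product length within bounds; sorted by forward start
    then product length.
    """
    if fwd.orientation != "forward":
        raise ValueError(f"{fwd.name!r} is not a forward primer")
    if rev.orientation != "reverse":
        raise ValueError(f"{rev.name!r} is not a reverse primer")
    if min_len > max_len:
        raise ValueError("min_len must not exceed max_len")

    probe_f = fwd.iupac_seq
    probe_r = reverse_complement(rev.iupac_seq)
    tpl = template.residues

    def mism_at(probe: str, start1: int) -> int:
        m = iupac_match(probe, tpl[start1 - 1 : start1 - 1 + len(probe)], max_mismatches)
        assert m is not None
        return m

    hits = []
    for fstart in find_sites(fwd, template, max_mismatches):
        for rstart in find_sites(rev, template, max_mismatches):
            rev_last = rstart + len(rev) - 1
            if fstart > rstart:
                continue
            length = rev_last - fstart + 1
            if min_len <= length <= max_len:
                hits.append(
                    AmpliconHit(
                        template_id=template.id,
                        fwd_start=fstart,
                        rev_last=rev_last,
                        product_length=length,
                        fwd_mismatches=mism_at(probe_f, fstart),
                        rev_mismatches=mism_at(probe_r, rstart),
                    )
                )
    hits.sort(key=lambda h: (h.fwd_start, h.product_length))
    return hits


def evaluate_panel(
    fwd_primers: Sequence[Primer],
    rev_primers: Sequence[Primer],
    templates: Sequence[SequenceRecord],
    max_mismatches: int = 0,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> PanelReport:
    """Score every forward/reverse pair against a template panel."""
    if not fwd_primers or not rev_primers:
        raise ValueError("primer panels must be non-empty")
    if not templates:
        raise ValueError("template panel must be non-empty")
    amplified: dict[tuple[str, str], set[str]] = {}
    for fwd in fwd_primers:
        for rev in rev_primers:
            hits = set()
            for tpl in templates:
                if simulate_pcr(fwd, rev, tpl, max_mismatches, min_len, max_len):
                    hits.add(tpl.id)
            amplified[(fwd.name, rev.name)] = hits
    return PanelReport(template_ids=[t.id for t in templates], amplified=amplified)


def gc_content(primer: Primer, mode: Literal["unambiguous_only", "expected"] = "unambiguous_only") -> int:
    """GC percentage of a primer, rounded to the nearest integer.

    ``unambiguous_only`` counts only literal G/C positions over the full
    length; ``expected`` sums per-position P(G or C) under a uniform draw
    from each ambiguity set.
    """
    seq = primer.iupac_seq
    if mode == "unambiguous_only":
        frac = sum(c in _GC for c in seq) / len(seq)
    elif mode == "expected":
        frac = sum(len(IUPAC_SETS[c] & _GC) / len(IUPAC_SETS[c]) for c in seq) / len(seq)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return round(100 * frac)


def wallace_tm(primer: Primer, mode: Literal["min", "max", "expected"] = "expected") -> float:
    """Wallace-rule melting temperature: 2*(A+T) + 4*(G+C).

    ``min``/``max`` take the realization of the degenerate sequence with
    the fewest/most G+C; ``expected`` uses expected base counts under
    uniform draws within each ambiguity set.
    """
    tm = 0.0
    for c in primer.iupac_seq:
        bases = IUPAC_SETS[c]
        p_gc = len(bases & _GC) / len(bases)
        if mode == "min":
            tm += 2 if p_gc < 1 else 4
        elif mode == "max":
            tm += 4 if p_gc > 0 else 2
        elif mode == "expected":
            tm += 4 * p_gc + 2 * (1 - p_gc)
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return tm


def load_primer_panel(path: str | Path) -> list[Primer]:
    """Read primers from TSV with columns name, sequence, orientation, position."""
    primers = []
    names = set()
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            name = row["name"].strip()
            if name in names:
                raise ValueError(f"duplicate primer name {name!r}")
            names.add(name)
            pos = row.get("position", "").strip()
            primers.append(
                Primer(
                    name=name,
                    iupac_seq=row["sequence"].strip(),
                    orientation=row["orientation"].strip(),  # type: ignore[arg-type]
                    annotated_position=int(pos) if pos else None,
                )
            )
    if not primers:
        raise ValueError(f"{path}: no primers found")
    return primers


def bundled_primers() -> list[Primer]:
    """The packaged degenerate primer panel used to amplify kcv genes."""
    with resources.as_file(resources.files("kcvkit").joinpath("data/kcv_primers.tsv")) as p:
        return load_primer_panel(p)
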