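import pytest

from kcvkit.diversity import (
    DEFAULT_REFERENCE_DOMAINS,
    DomainAnnotation,
    annotate_domains,
    build_report,
    classify_filter_motif,
    collapse_unique,
    length_histogram,
    pairwise_differences,
    per_domain_conservation,
    pick_conservation_reference,
    variable_sites,
)
from kcvkit.msa import MultipleAlignment, progressive_msa
from kcvkit.seq_io import Alphabet, SequenceRecord, translate


class TestCollapseUnique:
    def test_basic_grouping(self, dna):
        groups = collapse_unique([dna("x", "AAA"), dna("y", "AAA"), dna("z", "AAC")])
        assert [g.count for g in groups] == [2, 1]
        assert groups[0].member_ids == ("x", "y")

    def test_all_distinct(self, dna):
        groups = collapse_unique([dna(f"s{i}", "AAA" + "ACGT"[i]) for i in range(4)])
        assert len(groups) == 4
        assert all(g.count == 1 for g in groups)

    def test_counts_sum_to_input(self, dna, rng):
        seqs = [dna(f"s{i}", "".join(rng.choice(list("ACGT"), 6))) for i in range(30)]
        groups = collapse_unique(seqs)
        assert sum(g.count for g in groups) == 30

    def test_case_insensitive(self, tmp_path, dna):
        # records canonicalize to upper case, so collapse is case-blind
        a = SequenceRecord(id="a", residues="acgt", alphabet=Alphabet.DNA)
        b = SequenceRecord(id="b", residues="ACGT", alphabet=Alphabet.DNA)
        assert len(collapse_unique([a, b])) == 1

    def test_idempotent(self, dna, rng):
        seqs = [dna(f"s{i}", "".join(rng.choice(list("ACG"), 4))) for i in range(25)]
        groups = collapse_unique(seqs)
        again = collapse_unique([g.representative for g in groups])
        assert [g.representative.residues for g in again] == [
            g.representative.residues for g in groups
        ]
        assert all(g.count == 1 for g in again)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            collapse_unique([])

    def test_protein_unique_not_more_than_dna(self, rng, dna):
        from kcvkit.synthetic_data import FamilyConfig, generate_family, cds_records

        records, truth = generate_family(FamilyConfig.for_size(30, seed=3, n_lineages=10))
        cds = cds_records(records, truth)
        dna_groups = collapse_unique(cds)
        prots = [translate(g.representative, strip_terminal_stop=True) for g in dna_groups]
        prot_groups = collapse_unique(prots)
        assert len(prot_groups) <= len(dna_groups) <= len(cds)


class TestVariableSites:
    def test_identical_rows(self):
        aln = MultipleAlignment([("a", "ACGT"), ("b", "ACGT")])
        assert variable_sites(aln) == (0, 4)

    def test_three_differences(self):
        aln = MultipleAlignment([("a", "ACGTACGT"), ("b", "TCGAACGA")])
        assert variable_sites(aln) == (3, 8)

    def test_gap_counts_as_symbol(self):
        aln = MultipleAlignment([("a", "AC-T"), ("b", "ACGT")])
        assert variable_sites(aln)[0] == 1

    def test_partition(self, rng):
        rows = [("r%d" % i, "".join(rng.choice(list("ACGT"), 50))) for i in range(5)]
        aln = MultipleAlignment(rows)
        var, total = variable_sites(aln)
        invariant = sum(
            1 for i in range(aln.n_columns) if len(set(aln.column(i))) == 1
        )
        assert var + invariant == total == 50


class TestPairwiseDifferences:
    def test_identical(self, protein):
        d, length, pct = pairwise_differences(protein("a", "MVKL"), protein("b", "MVKL"))
        assert (d, pct) == (0, 0.0)
        assert length == 4

    def test_symmetric_and_zero_on_self(self, protein, rng):
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(5):
            pa = "".join(rng.choice(aas, 20))
            pb = "".join(rng.choice(aas, 18))
            d1 = pairwise_differences(protein("a", pa), protein("b", pb))[0]
            d2 = pairwise_differences(protein("a", pb), protein("b", pa))[0]
            assert d1 == d2
            assert pairwise_differences(protein("a", pa), protein("b", pa))[0] == 0

    def test_gap_columns_count_as_differences(self, protein):
        d, length, pct = pairwise_differences(
            protein("a", "MVVVVVVKL"), protein("b", "MVVVVKL")
        )
        assert d == 2
        assert length == 9

    def test_percent_uses_alignment_length(self, protein):
        d, length, pct = pairwise_differences(protein("a", "MKKKKKKKKV"), protein("b", "MV"))
        assert pct == pytest.approx(100.0 * d / length)


class TestLengthHistogram:
    def test_basic(self, protein):
        h = length_histogram(
            [protein("a", "A" * 82), protein("b", "C" * 82), protein("c", "D" * 89)]
        )
        assert h == {82: 2, 89: 1}

    def test_empty(self):
        assert length_histogram([]) == {}


class TestFilterMotif:
    @pytest.mark.parametrize("motif", ["TTVGYGDL", "TTTGYGDL", "TTTGFGDV"])
    def test_known_classes_found(self, protein, motif):
        p = protein("a", "MAK" + motif + "LRS")
        m = classify_filter_motif(p)
        assert m is not None
        assert m.motif == motif
        assert m.start == 4

    def test_no_motif_is_explicit(self, protein):
        assert classify_filter_motif(protein("a", "A" * 40)) is None

    def test_leftmost_match(self, protein):
        p = protein("a", "TTVGYGDL" + "A" * 5 + "TTTGYGDL")
        assert classify_filter_motif(p).start == 1


class TestDomainAnnotation:
    def test_filter_length_enforced(self):
        with pytest.raises(ValueError, match="filter"):
            DomainAnnotation({"filter": (10, 15)})

    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            DomainAnnotation({"TMD1": (1, 10), "turret": (5, 12)})

    def test_default_reference_covers_82(self):
        total = sum(
            DEFAULT_REFERENCE_DOMAINS.length(d) for d in DEFAULT_REFERENCE_DOMAINS.intervals
        )
        assert total == 82

    def _reference(self, protein):
        # residues chosen so each domain is distinguishable; filter planted
        seq = (
            "M" + "A" * 21          # TMD1  1..22
            + "N" * 17               # turret 23..39
            + "Q" * 8                # pore helix 40..47
            + "TTVGYGDL"            # filter 48..55
            + "L" * 23               # TMD2 56..78
            + "KRSE"                # c_tail 79..82
        )
        return protein("ref", seq)

    def test_reference_self_annotation(self, protein):
        ref = self._reference(protein)
        ann = annotate_domains(ref, ref)
        assert dict(ann.intervals) == dict(DEFAULT_REFERENCE_DOMAINS.intervals)

    def test_turret_insertion_grows_turret_only(self, protein):
        ref = self._reference(protein)
        q = protein("q", ref.residues[:30] + "WDEWDEWD" + ref.residues[30:])
        ann = annotate_domains(q, ref)
        assert ann.length("turret") == DEFAULT_REFERENCE_DOMAINS.length("turret") + 8
        for dom in ("TMD1", "pore_helix", "filter", "TMD2", "c_tail"):
            assert ann.length(dom) == DEFAULT_REFERENCE_DOMAINS.length(dom)

    def test_c_terminal_extension_grows_tail(self, protein):
        ref = self._reference(protein)
        q = protein("q", ref.residues + "GGG")
        ann = annotate_domains(q, ref)
        assert ann.length("c_tail") == DEFAULT_REFERENCE_DOMAINS.length("c_tail") + 3
        assert ann.length("TMD2") == DEFAULT_REFERENCE_DOMAINS.length("TMD2")

    def test_missing_motif_errors(self, protein):
        ref = self._reference(protein)
        with pytest.raises(ValueError, match="motif"):
            annotate_domains(protein("q", "A" * 50), ref)


class TestPerDomainConservation:
    def test_identical_rows_all_one(self, protein):
        ref = TestDomainAnnotation()._reference(protein)
        seqs = [protein(f"s{i}", ref.residues) for i in range(3)]
        seqs[0] = protein("ref", ref.residues)
        aln = progressive_msa(seqs)
        cons = per_domain_conservation(aln, "ref")
        assert all(v == 1.0 for v in cons.values())

    def test_tmd_mutations_rank_below_filter(self, protein, rng):
        ref = TestDomainAnnotation()._reference(protein)
        aas = list("ACDEFGHIKMNPQRSTVWY")
        seqs = [protein("ref", ref.residues)]
        for i in range(5):
            s = list(ref.residues)
            for k in list(range(1, 22)) + list(range(56, 78)):  # TMD residues only
                if rng.random() < 0.4:
                    s[k] = str(rng.choice(aas))
            seqs.append(protein(f"s{i}", "".join(s)))
        # equal lengths: the positional alignment is exact by construction
        aln = MultipleAlignment([(p.id, p.residues) for p in seqs])
        cons = per_domain_conservation(aln, "ref")
        assert cons["filter"] == 1.0
        assert cons["TMD1"] < 1.0 and cons["TMD2"] < 1.0
        worst_two = sorted(cons, key=cons.get)[:2]
        assert set(worst_two) == {"TMD1", "TMD2"}


class TestBuildReport:
    def test_synthetic_family_matches_ground_truth(self):
        from kcvkit.synthetic_data import SURVEY_LIKE, cds_records, generate_family

        records, truth = generate_family(SURVEY_LIKE)
        rep = build_report(cds_records(records, truth))
        assert rep.n_input == 103
        assert rep.n_unique_dna == truth.n_unique_dna
        assert rep.n_unique_protein == truth.n_unique_protein
        assert rep.protein_length_histogram == truth.protein_length_histogram
        assert rep.filter_motif_counts == truth.filter_motif_counts

    def test_reference_differences(self, tmp_path):
        from kcvkit.synthetic_data import FamilyConfig, cds_records, generate_family

        records, truth = generate_family(FamilyConfig.for_size(20, seed=9, n_lineages=6))
        cds = cds_records(records, truth)
        rep = build_report(cds, reference_id=cds[0].id)
        ref_prot = translate(cds[0], strip_terminal_stop=True).residues
        for pid, (d, _, _) in rep.differences_vs_reference.items():
            if pid == cds[0].id:
                assert d == 0

    def test_pick_conservation_reference(self, protein):
        ref = TestDomainAnnotation()._reference(protein)
        shifted = protein("shifted", "AA" + ref.residues)
        assert pick_conservation_reference([shifted, ref]).id == "ref"
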