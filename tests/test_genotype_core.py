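import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hybridpanel._errors import EmptyPanelError, GenotypeParseError, ValidationError
from hybridpanel.genotype_core import (
    HET,
    HOM1,
    HOM2,
    MISSING,
    ConcordanceReport,
    GenotypeMatrix,
    Individual,
    Locus,
    ReplicateSet,
    aggregate_concordance,
    concordance,
    consensus_genotype,
    filter_samples_and_loci,
    genotyping_success_rate,
    read_genotypes,
    read_panel,
    write_genotypes,
    write_panel,
)

from conftest import make_loci, make_matrix


class TestModel:
    def test_locus_invariants(self):
        with pytest.raises(ValidationError):
            Locus(id="x", chromosome="1", position=1, allele1="A", allele2="A")
        with pytest.raises(ValidationError):
            Locus(id="x", chromosome="1", position=0, allele1="A", allele2="G")

    def test_shape_mismatch(self):
        with pytest.raises(ValidationError):
            make_matrix(np.zeros((2, 3)), loci=make_loci(2))

    def test_invalid_call_code(self):
        with pytest.raises(ValidationError, match="ind1"):
            make_matrix([[5]])

    def test_duplicate_locus_ids(self):
        loci = make_loci(2)
        with pytest.raises(ValidationError, match="duplicate"):
            GenotypeMatrix(loci=[loci[0], loci[0]],
                           individuals=[Individual("a")], calls=np.zeros((1, 2)))

    def test_allele1_frequency(self):
        m = make_matrix([[HOM1, HET], [HOM2, MISSING]])
        np.testing.assert_allclose(m.allele1_frequency(), [0.5, 0.5])


# ---------------------------------------------------------------------------
# I/O


def _random_matrix(rng, n=5, L=4):
    bases = ["A", "C", "G", "T"]
    loci = []
    for j in range(L):
        a1, a2 = rng.choice(4, size=2, replace=False)
        loci.append(Locus(id=f"snp{j}", chromosome=str(rng.integers(1, 4)),
                          position=int(rng.integers(1, 10**6)),
                          allele1=bases[a1], allele2=bases[a2]))
    calls = rng.integers(-1, 3, size=(n, L)).astype(np.int8)
    inds = [Individual(id=f"s{i}", group=rng.choice(["wolf", "dog", "hybrid"]),
                       sample_type=rng.choice(["tissue", "scat", "hair"]))
            for i in range(n)]
    return GenotypeMatrix(loci=loci, individuals=inds, calls=calls)


class TestIO:
    def test_tabular_example(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text(
            "id\tgroup\tsample_type\tL1\tL2\n"
            "a\twolf\ttissue\tAA\tAG\n"
            "b\tdog\ttissue\tGG\t--\n"
        )
        panel = [Locus("L1", "1", 1, "A", "G"), Locus("L2", "1", 2, "A", "G")]
        m = read_genotypes(path, "tabular", panel=panel)
        assert m.calls.tolist() == [[HOM1, HET], [HOM2, MISSING]]

    def test_ped_map_equivalent_to_tabular(self, tmp_path):
        rng = np.random.default_rng(0)
        m = _random_matrix(rng)
        write_genotypes(m, tmp_path / "x.tsv", "tabular")
        write_genotypes(m, tmp_path / "x.ped", "ped-map")
        a = read_genotypes(tmp_path / "x.tsv", "tabular", panel=m.loci)
        b = read_genotypes(tmp_path / "x.ped", "ped-map", panel=m.loci)
        assert a == b == m

    @pytest.mark.parametrize("fmt,name", [("tabular", "g.tsv"), ("ped-map", "g.ped"),
                                          ("vcf", "g.vcf")])
    def test_round_trip(self, tmp_path, fmt, name):
        rng = np.random.default_rng(7)
        for trial in range(3):
            m = _random_matrix(rng)
            path = tmp_path / f"{trial}_{name}"
            write_genotypes(m, path, fmt)
            assert read_genotypes(path, fmt, panel=m.loci) == m

    def test_vcf_missing_token(self, tmp_path):
        m = make_matrix([[MISSING]])
        write_genotypes(m, tmp_path / "m.vcf", "vcf")
        assert "./." in (tmp_path / "m.vcf").read_text()

    def test_ped_missing_token(self, tmp_path):
        m = make_matrix([[MISSING]])
        write_genotypes(m, tmp_path / "m.ped", "ped-map")
        assert (tmp_path / "m.ped").read_text().split()[-2:] == ["0", "0"]

    def test_empty_individuals(self, tmp_path):
        m = GenotypeMatrix(loci=make_loci(2), individuals=[],
                           calls=np.empty((0, 2), dtype=np.int8))
        write_genotypes(m, tmp_path / "e.tsv", "tabular")
        assert read_genotypes(tmp_path / "e.tsv", panel=m.loci) == m

    def test_vcf_multiallelic_rejected(self, tmp_path):
        path = tmp_path / "bad.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "1\t100\trs1\tA\tG,T\t.\tPASS\t.\tGT\t0/1\n"
        )
        with pytest.raises(ValidationError, match="rs1"):
            read_genotypes(path, "vcf")

    def test_allele_outside_pair(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text("id\tgroup\tsample_type\tL1\na\twolf\ttissue\tAT\n")
        with pytest.raises(ValidationError, match="L1"):
            read_genotypes(path, "tabular", panel=[Locus("L1", "1", 1, "A", "G")])

    def test_malformed_tabular_names_line(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text("id\tgroup\tsample_type\tL1\na\twolf\ttissue\tAAA\n")
        with pytest.raises(GenotypeParseError, match="line 2"):
            read_genotypes(path, "tabular")

    def test_panel_round_trip(self, tmp_path):
        loci = make_loci(5)
        write_panel(loci, tmp_path / "panel.tsv")
        assert read_panel(tmp_path / "panel.tsv") == loci


# ---------------------------------------------------------------------------
# consensus


class TestConsensus:
    def test_majority(self):
        reps = ReplicateSet("a", [[HET], [HET], [HOM1]])
        assert consensus_genotype(reps).tolist() == [HET]

    def test_single_observation_is_missing(self):
        assert consensus_genotype(ReplicateSet("a", [[HOM1]])).tolist() == [MISSING]

    def test_tie_is_missing(self):
        reps = ReplicateSet("a", [[HOM1], [HOM1], [HET], [HET]])
        assert consensus_genotype(reps).tolist() == [MISSING]

    def test_twice_suffices(self):
        reps = ReplicateSet("a", [[HOM2], [HOM2], [MISSING]])
        assert consensus_genotype(reps).tolist() == [HOM2]

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            ReplicateSet("a", [[HOM1, HET], [HOM1]])

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.lists(st.sampled_from([-1, 0, 1, 2]), min_size=4, max_size=4),
                    min_size=1, max_size=5),
           st.randoms(use_true_random=False))
    def test_permutation_invariance(self, reps, rnd):
        base = consensus_genotype(ReplicateSet("a", [np.array(r) for r in reps]))
        shuffled = list(reps)
        rnd.shuffle(shuffled)
        perm = consensus_genotype(ReplicateSet("a", [np.array(r) for r in shuffled]))
        assert base.tolist() == perm.tolist()


class TestSuccessRate:
    def test_example_93(self):
        calls = np.full(93, HOM1, dtype=np.int8)
        calls[:3] = MISSING
        assert genotyping_success_rate(calls) == pytest.approx(90 / 93)

    def test_degenerate(self):
        assert genotyping_success_rate(np.full(5, MISSING, dtype=np.int8)) == 0.0
        assert genotyping_success_rate(np.full(5, HET, dtype=np.int8)) == 1.0

    def test_empty_vector(self):
        with pytest.raises(ValidationError):
            genotyping_success_rate(np.array([]))


class TestFilter:
    def _matrix(self):
        # 4 samples x 10 loci; sample 3 has 60% success; locus 9 has 25% success
        calls = np.zeros((4, 10), dtype=np.int8)
        calls[2, :4] = MISSING
        calls[:3, 9] = MISSING
        return make_matrix(calls)

    def test_sample_below_threshold_removed(self):
        calls = np.zeros((2, 20), dtype=np.int8)
        calls[0, :5] = MISSING  # 0.75 success
        m = make_matrix(calls)
        out, rep = filter_samples_and_loci(m, sample_min=0.8, locus_min=0.0)
        assert [i.id for i in out.individuals] == ["ind2"]
        assert rep.removed_samples == {"ind1": 0.75}

    def test_locus_below_threshold_removed(self):
        calls = np.zeros((10, 2), dtype=np.int8)
        calls[:4, 1] = MISSING  # 0.6 success
        out, rep = filter_samples_and_loci(make_matrix(calls), sample_min=0.0, locus_min=0.7)
        assert out.n_loci == 1
        assert list(rep.removed_loci) == ["L002"]

    def test_keep_list_override(self):
        calls = np.zeros((2, 20), dtype=np.int8)
        calls[0, :5] = MISSING
        out, rep = filter_samples_and_loci(make_matrix(calls), sample_min=0.8,
                                           locus_min=0.0, keep_samples=["ind1"])
        assert out.n_individuals == 2
        assert rep.kept_by_override == {"ind1": 0.75}

    def test_empty_panel_error(self):
        calls = np.full((3, 2), MISSING, dtype=np.int8)
        with pytest.raises(EmptyPanelError):
            filter_samples_and_loci(make_matrix(calls), locus_min=0.5)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        calls = rng.choice([HOM1, HET, HOM2, MISSING], p=[0.3, 0.2, 0.2, 0.3],
                           size=(6, 8)).astype(np.int8)
        if not (calls != MISSING).any(axis=0).any():
            return
        try:
            once, _ = filter_samples_and_loci(make_matrix(calls), 0.6, 0.6)
        except EmptyPanelError:
            return
        twice, rep = filter_samples_and_loci(once, 0.6, 0.6)
        assert twice == once
        assert not rep.removed_loci and not rep.removed_samples


# ---------------------------------------------------------------------------
# concordance


class TestConcordance:
    def test_false_allele_from_het_test(self):
        rep = concordance(np.array([HOM1]), np.array([HET]))
        assert rep.false_allele_count == 1
        assert rep.hom_reference_count == 1

    def test_opposite_hom_counts_two(self):
        rep = concordance(np.array([HOM1]), np.array([HOM2]))
        assert rep.false_allele_count == 2

    def test_missing_allele(self):
        rep = concordance(np.array([HET]), np.array([HOM1]))
        assert rep.missing_allele_count == 1
        assert rep.het_reference_count == 1

    def test_het_agreement_no_increment(self):
        rep = concordance(np.array([HET]), np.array([HET]))
        assert rep.missing_allele_count == 0
        assert rep.false_allele_count == 0
        assert rep.het_reference_count == 1

    def test_missing_test_counts_per_sample(self):
        rep = concordance(np.array([HOM1, HET]), np.array([MISSING, HET]))
        assert rep.per_sample_missing == [0.5]
        assert rep.hom_reference_count == 0  # missing test call not compared

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            concordance(np.array([0, 1]), np.array([0]))

    def test_rate_rounding_two_decimals(self):
        total = ConcordanceReport(false_allele_count=1, hom_reference_count=2664,
                                  missing_allele_count=3, het_reference_count=104)
        assert f"{total.false_allele_rate:.2f}" == "0.04"
        assert f"{total.missing_allele_rate:.2f}" == "2.88"

    def test_zero_false_alleles(self):
        total = ConcordanceReport(hom_reference_count=100)
        assert f"{total.false_allele_rate:.2f}" == "0.00"

    def test_zero_denominator_undefined(self):
        assert ConcordanceReport().false_allele_rate is None
        assert ConcordanceReport().missing_allele_rate is None

    def test_aggregate(self):
        incs = [concordance(np.array([HOM1]), np.array([HET])),
                concordance(np.array([HET]), np.array([HOM2]))]
        total = aggregate_concordance(incs)
        assert total.false_allele_count == 1
        assert total.missing_allele_count == 1
        assert len(total.per_sample_missing) == 2
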