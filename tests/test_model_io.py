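"""Domain types, format readers and multi-caller consensus."""

import textwrap

import pytest
from hypothesis import given, strategies as st

from ba_prioritize.io import (
    AnnotationError,
    PedError,
    VcfError,
    consensus_intersect,
    read_annotation_table,
    read_gmt,
    read_ped,
    read_vcf,
    write_annotation_table,
    write_gmt,
)
from ba_prioritize.model import (
    AnnotatedVariant,
    CallSet,
    Sex,
    VariantKey,
    Zygosity,
    normalize_chrom,
    trim_key,
)


class TestVariantKey:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(chrom="chr1", pos=0, ref="A", alt="T"),
            dict(chrom="chr1", pos=5, ref="", alt="T"),
            dict(chrom="chr1", pos=5, ref="A", alt="A"),
            dict(chrom="1", pos=5, ref="A", alt="T"),
        ],
    )
    def test_invariants_rejected(self, kwargs):
        with pytest.raises(ValueError):
            VariantKey(**kwargs)

    def test_normalize_chrom(self):
        assert normalize_chrom("X") == "chrX"
        assert normalize_chrom("chr9") == "chr9"
        assert normalize_chrom("MT") == "chrM"

    @pytest.mark.parametrize(
        "raw,expected",
        [
            # identical padded context trims away, position advances
            (("1", 100, "CA", "CT"), ("chr1", 101, "A", "T")),
            (("1", 100, "ACG", "ATG"), ("chr1", 101, "C", "T")),
            # plain SNV unchanged
            (("chrX", 7, "G", "C"), ("chrX", 7, "G", "C")),
            # indel keeps one anchor base
            (("1", 100, "ATT", "A"), ("chr1", 100, "ATT", "A")),
        ],
    )
    def test_trim_key(self, raw, expected):
        k = trim_key(*raw)
        assert (k.chrom, k.pos, k.ref, k.alt) == expected


def write_vcf_text(tmp_path, body, samples=("P", "M", "F")):
    text = textwrap.dedent(
        """\
        ##fileformat=VCFv4.2
        ##contig=<ID=chr1,length=100000000>
        ##contig=<ID=chrX,length=160000000>
        ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
        #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
        """.format(samples="\t".join(samples))
    ) + body
    path = tmp_path / "test.vcf"
    path.write_text(text)
    return path


class TestReadVcf:
    def test_male_x_hemizygous_coding(self, tmp_path):
        """Male non-PAR chrX genotypes collapse to hemizygous calls whether
        coded haploid ('1') or diploid ('1/1'); the carrier mother stays HET."""
        path = write_vcf_text(
            tmp_path,
            "chrX\t123888703\t.\tG\tC\t.\tPASS\t.\tGT\t1\t0/1\t./.\n",
        )
        [(key, calls)] = read_vcf(path, sample_sexes={"P": Sex.MALE, "M": Sex.FEMALE})
        assert key == VariantKey("chrX", 123888703, "G", "C")
        assert calls == {
            "P": Zygosity.HEMI_ALT,
            "M": Zygosity.HET,
            "F": Zygosity.MISSING,
        }

    def test_male_x_diploid_coded(self, tmp_path):
        path = write_vcf_text(
            tmp_path, "chrX\t123888703\t.\tG\tC\t.\tPASS\t.\tGT\t1/1\t0/0\t0/0\n"
        )
        [(_, calls)] = read_vcf(path, sample_sexes={"P": Sex.MALE})
        assert calls["P"] is Zygosity.HEMI_ALT
        # females (and sex-unknown samples) keep diploid zygosity on chrX
        assert calls["M"] is Zygosity.HOM_REF

    def test_hom_ref_and_missing(self, tmp_path):
        path = write_vcf_text(
            tmp_path, "chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t./.\n"
        )
        [(_, calls)] = read_vcf(path)
        assert calls["P"] is Zygosity.HOM_REF
        assert calls["F"] is Zygosity.MISSING

    def test_multiallelic_decomposition_preserves_dosage(self, tmp_path):
        """chr1:100 A>T,C with GT 1/2 yields two keys, each HET; total
        alt dosage across decomposed keys equals the original genotype's."""
        path = write_vcf_text(
            tmp_path, "chr1\t100\t.\tA\tT,C\t.\tPASS\t.\tGT\t1/2\t1/1\t0/2\n"
        )
        calls = read_vcf(path)
        assert [k for k, _ in calls] == [
            VariantKey("chr1", 100, "A", "T"),
            VariantKey("chr1", 100, "A", "C"),
        ]
        by_alt = {k.alt: c for k, c in calls}
        assert by_alt["T"]["P"] is Zygosity.HET
        assert by_alt["C"]["P"] is Zygosity.HET
        assert by_alt["T"]["M"] is Zygosity.HOM_ALT
        assert by_alt["C"]["M"] is Zygosity.HOM_REF
        dosage = {Zygosity.HOM_REF: 0, Zygosity.HET: 1, Zygosity.HOM_ALT: 2}
        for sample, total in {"P": 2, "M": 2, "F": 1}.items():
            assert sum(dosage[c[sample]] for _, c in calls) == total

    def test_absent_sample_is_named_error(self, tmp_path):
        path = write_vcf_text(tmp_path, "chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0\n")
        with pytest.raises(VcfError, match="NOPE"):
            read_vcf(path, sample_names=["NOPE"])

    def test_haploid_autosome_rejected(self, tmp_path):
        path = write_vcf_text(tmp_path, "chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t1\t0/0\t0/0\n")
        with pytest.raises(VcfError, match="haploid"):
            read_vcf(path)


PED_OK = """\
FAM2 BA002_4 F2 M2 1 2
FAM2 F2 0 0 1 1
FAM2 M2 0 0 2 1
"""


class TestReadPed:
    def test_trio(self, tmp_path):
        p = tmp_path / "a.ped"
        p.write_text(PED_OK)
        ped = read_ped(p)
        [proband] = ped.probands()
        assert proband.iid == "BA002_4"
        assert proband.sex is Sex.MALE
        assert proband.father_id == "F2" and proband.mother_id == "M2"

    def test_absent_father_coded_zero(self, tmp_path):
        p = tmp_path / "a.ped"
        p.write_text("FAM1 KID 0 MUM 2 2\nFAM1 MUM 0 0 2 1\n")
        ped = read_ped(p)
        [proband] = ped.probands()
        assert proband.father_id is None

    def test_affected_sib_sharing_parents(self, tmp_path):
        p = tmp_path / "a.ped"
        p.write_text(
            PED_OK + "FAM2 BA002_3 F2 M2 2 2\n"
        )
        ped = read_ped(p)
        probands = {x.iid for x in ped.probands()}
        assert probands == {"BA002_4", "BA002_3"}
        assert [s.iid for s in ped.affected_sibs("BA002_4")] == ["BA002_3"]

    def test_bad_sex_code(self, tmp_path):
        p = tmp_path / "a.ped"
        p.write_text("FAM1 KID 0 0 9 2\n")
        with pytest.raises(PedError, match="sex"):
            read_ped(p)

    def test_cyclic_parentage(self, tmp_path):
        p = tmp_path / "a.ped"
        p.write_text("F A B 0 1 2\nF B A 0 1 1\n")
        with pytest.raises(PedError, match="cyclic"):
            read_ped(p)

    def test_unknown_parent_id(self, tmp_path):
        p = tmp_path / "a.ped"
        p.write_text("F KID DAD 0 1 2\n")
        with pytest.raises(PedError, match="DAD"):
            read_ped(p)


_sym = st.text(alphabet="ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789", min_size=1, max_size=8)
_maf = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)
_keys = (
    st.tuples(
        st.sampled_from(["chr1", "chr2", "chrX"]),
        st.integers(min_value=1, max_value=10**8),
        st.sampled_from(list("ACGT")),
        st.sampled_from(list("ACGT")),
    )
    .filter(lambda t: t[2] != t[3])
    .map(lambda t: VariantKey(*t))
)
_annotated = st.builds(
    AnnotatedVariant,
    key=_keys,
    gene=_sym,
    transcript_change=_sym,
    consequence=st.sampled_from(["missense", "stopgain", "splice", "synonymous", "other"]),
    maf=st.dictionaries(st.sampled_from(["KHV", "GnomAD_EAS", "1KG"]), _maf, max_size=3),
    cadd_phred=st.one_of(st.none(), st.floats(min_value=0, max_value=99, allow_nan=False)),
)


def _distinct_keys(anns):
    return len({a.key for a in anns}) == len(anns)


class TestAnnotationTable:
    @given(anns=st.lists(_annotated, min_size=0, max_size=8).filter(_distinct_keys))
    def test_round_trip_exact(self, tmp_path_factory, anns):
        path = tmp_path_factory.mktemp("ann") / "a.tsv"
        write_annotation_table(anns, path)
        back = read_annotation_table(path)
        assert back == {a.key: a for a in anns}

    def test_known_row(self, tmp_path, table2_annotations):
        """Published HACE1 annotation: three MAFs and CADD parse exactly."""
        a = next(v for v in table2_annotations.values() if v.gene == "HACE1")
        assert a.maf == {"KHV": 0.01, "GnomAD_EAS": 0.001731, "1KG": 0.001996}
        assert a.cadd_phred == 26.2

    def test_zero_maf_row(self, table2_annotations):
        a = next(v for v in table2_annotations.values() if v.gene == "UBQLN2")
        assert set(a.maf.values()) == {0.0}
        assert a.cadd_phred == 23.7

    def test_blank_maf_means_unobserved(self, tmp_path):
        path = tmp_path / "a.tsv"
        path.write_text(
            "chrom\tpos\tref\talt\tgene\ttranscript_change\tconsequence\t"
            "maf_khv\tmaf_gnomad_eas\tmaf_1kg\tcadd_phred\n"
            "chr1\t5\tA\tT\tG1\tc.1A>T\tmissense\t\t0.001\t\t22\n"
        )
        [a] = read_annotation_table(path).values()
        assert a.maf == {"GnomAD_EAS": 0.001}

    def test_duplicate_key_rejected(self, tmp_path):
        path = tmp_path / "a.tsv"
        row = "chr1\t5\tA\tT\tG1\tc.1A>T\tmissense\t0\t0\t0\t22\n"
        path.write_text(
            "chrom\tpos\tref\talt\tgene\ttranscript_change\tconsequence\t"
            "maf_khv\tmaf_gnomad_eas\tmaf_1kg\tcadd_phred\n" + row + row
        )
        with pytest.raises(AnnotationError, match="duplicate"):
            read_annotation_table(path)

    def test_non_numeric_maf_rejected(self, tmp_path):
        path = tmp_path / "a.tsv"
        path.write_text(
            "chrom\tpos\tref\talt\tgene\ttranscript_change\tconsequence\t"
            "maf_khv\tmaf_gnomad_eas\tmaf_1kg\tcadd_phred\n"
            "chr1\t5\tA\tT\tG1\tc.1A>T\tmissense\tlow\t0\t0\t22\n"
        )
        with pytest.raises(AnnotationError, match="non-numeric"):
            read_annotation_table(path)


class TestGmt:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "x.gmt"
        write_gmt({"S1": ("desc", ["a", "B"]), "S2": ("d2", ["C"])}, path)
        sets = read_gmt(path)
        assert sets["S1"] == ("desc", frozenset({"A", "B"}))
        assert sets["S2"][1] == frozenset({"C"})

    def test_short_line_rejected(self, tmp_path):
        path = tmp_path / "x.gmt"
        path.write_text("ONLY_NAME\tdesc\n")
        with pytest.raises(AnnotationError):
            read_gmt(path)


def _key(i):
    return VariantKey("chr1", i + 1, "A", "T")


class TestConsensus:
    def test_identical_sets_identity(self):
        s = frozenset(map(_key, range(5)))
        sets = [CallSet(c, s) for c in "abc"]
        assert consensus_intersect(sets) == s

    def test_min_callers_boundary(self):
        shared = {_key(0)}
        two_of_three = {_key(1)}
        sets = [
            CallSet("a", frozenset(shared | two_of_three)),
            CallSet("b", frozenset(shared | two_of_three)),
            CallSet("c", frozenset(shared)),
        ]
        assert _key(1) not in consensus_intersect(sets, 3)
        assert _key(1) in consensus_intersect(sets, 2)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            consensus_intersect([])

    def test_out_of_range_min_callers(self):
        sets = [CallSet("a", frozenset({_key(0)}))]
        with pytest.raises(ValueError):
            consensus_intersect(sets, 2)

    @given(
        st.lists(
            st.frozensets(st.integers(min_value=0, max_value=20), max_size=15),
            min_size=1,
            max_size=5,
        ),
        st.data(),
    )
    def test_matches_brute_force_membership_count(self, keysets, data):
        sets = [CallSet(str(i), frozenset(map(_key, ks))) for i, ks in enumerate(keysets)]
        m = data.draw(st.integers(min_value=1, max_value=len(sets)))
        result = consensus_intersect(sets, m)
        union = set().union(*(s.keys for s in sets))
        expected = {
            k for k in union if sum(k in s.keys for s in sets) >= m
        }
        assert result == expected
        # consensus is contained in every input at full stringency and is
        # monotone nonincreasing in min_callers
        assert consensus_intersect(sets, len(sets)) <= frozenset.intersection(
            *(s.keys for s in sets)
        ) | set()
        for lo in range(1, len(sets)):
            assert consensus_intersect(sets, lo + 1) <= consensus_intersect(sets, lo)
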