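"""Data model canonicalization and file-format round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from hairsnag.io import (
    GenotypeTableError,
    read_cluster_input,
    read_genotype_table,
    write_cluster_input,
    write_genepop,
    write_genotype_table,
    validate_dataset,
)
from hairsnag.model import (
    Dataset,
    Locus,
    LocusGenotype,
    MultilocusGenotype,
    SampleRecord,
    Source,
)
from hairsnag.simulate import generate_study_like_dataset


class TestLocusGenotype:
    def test_canonical_sorted_order(self):
        g = LocusGenotype(102, 100)
        assert (g.allele_a, g.allele_b) == (100, 102)

    def test_single_allele_becomes_provisional_homozygote(self):
        g = LocusGenotype(100, None)
        assert (g.allele_a, g.allele_b) == (100, 100)
        assert g.low_confidence
        assert not g.is_heterozygote

    def test_missing(self):
        g = LocusGenotype()
        assert g.is_missing
        with pytest.raises(ValueError):
            g.alleles

    @given(
        a=hst.one_of(hst.none(), hst.integers(80, 400)),
        b=hst.one_of(hst.none(), hst.integers(80, 400)),
    )
    @settings(max_examples=200, deadline=None)
    def test_canonicalization_idempotent(self, a, b):
        g = LocusGenotype(a, b)
        g2 = LocusGenotype(g.allele_a, g.allele_b, g.low_confidence)
        assert g2.same_call(g)
        assert g2.low_confidence == g.low_confidence

    @pytest.mark.parametrize(
        "g1,g2,expected",
        [
            ((100, 102), (100, 102), 2),
            ((100, 102), (100, 100), 1),
            ((100, 102), (104, 106), 0),
            ((100, 100), (100, 102), 1),
        ],
    )
    def test_shared_count(self, g1, g2, expected):
        assert LocusGenotype(*g1).shared_count(LocusGenotype(*g2)) == expected


def _toy_dataset():
    loci = [Locus("A", 2), Locus("B", 4)]
    def mlg(pairs):
        return MultilocusGenotype(
            {n: LocusGenotype(*p) if p else LocusGenotype() for n, p in zip("AB", pairs)}
        )
    s1 = SampleRecord(
        "H1", "Artvin", Source.TREE, 2010, 41.1, 41.8,
        replicates=[mlg([(102, 100), (200, 204)]), mlg([(100, 102), (200, 204)])],
        sry_positive=[True, True],
    )
    s2 = SampleRecord(
        "H2", "Bayburt", Source.POLE, 2012, 40.2, 40.3,
        replicates=[mlg([(104, 104), None]), mlg([(104, 104), (208, 208)])],
        sry_positive=[False, False],
    )
    return Dataset(samples=[s1, s2], loci=loci)


class TestGenotypeTable:
    def test_round_trip_lossless(self, tmp_path):
        ds = _toy_dataset()
        path = tmp_path / "t.csv"
        write_genotype_table(ds, path)
        back = read_genotype_table(path, loci=ds.loci)
        assert len(back.samples) == 2
        for orig, rt in zip(ds.samples, back.samples):
            assert rt.sample_id == orig.sample_id
            assert rt.province == orig.province
            assert rt.source == orig.source
            assert rt.year == orig.year
            assert rt.sry_positive == orig.sry_positive
            for m1, m2 in zip(orig.replicates, rt.replicates):
                assert m1.same_calls(m2)

    def test_alleles_stored_sorted(self, tmp_path):
        ds = _toy_dataset()
        g = ds.samples[0].replicates[0]["A"]
        assert (g.allele_a, g.allele_b) == (100, 102)

    def test_single_allele_flag_survives_round_trip(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "sample_id,replicate,province,source,year,lat,lon,sry,A_1,A_2\n"
            "H1,1,Artvin,tree,2010,41.0,41.0,0,100,\n"
            "H1,2,Artvin,tree,2010,41.0,41.0,0,100,102\n"
        )
        ds = read_genotype_table(path)
        g = ds.samples[0].replicates[0]["A"]
        assert g.low_confidence and g.alleles == (100, 100)
        out = tmp_path / "o.csv"
        write_genotype_table(ds, out)
        g2 = read_genotype_table(out).samples[0].replicates[0]["A"]
        assert g2.same_call(g)
        assert g2.low_confidence  # dropout-suspect status survives the round trip

    def test_duplicate_sample_replicate_errors(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "sample_id,replicate,province,source,year,lat,lon,sry,A_1,A_2\n"
            "H1,1,Artvin,tree,2010,41.0,41.0,0,100,102\n"
            "H1,1,Artvin,tree,2010,41.0,41.0,0,100,102\n"
        )
        with pytest.raises(GenotypeTableError, match="duplicated"):
            read_genotype_table(path)

    def test_unknown_locus_column_errors(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "sample_id,replicate,province,source,year,lat,lon,sry,A_1,A_2\n"
            "H1,1,Artvin,tree,2010,41.0,41.0,0,100,102\n"
        )
        with pytest.raises(GenotypeTableError, match="unknown locus column"):
            read_genotype_table(path, loci=[Locus("B", 2)])

    def test_non_integer_allele_reports_line(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "sample_id,replicate,province,source,year,lat,lon,sry,A_1,A_2\n"
            "H1,1,Artvin,tree,2010,41.0,41.0,0,100,102\n"
            "H2,1,Artvin,tree,2010,41.0,41.0,0,oops,102\n"
        )
        with pytest.raises(GenotypeTableError, match="line 3"):
            read_genotype_table(path)


def _parse_genepop(text):
    """Independent minimal Genepop reader used as the parse-back oracle."""
    lines = [l.rstrip() for l in text.splitlines() if l.strip()]
    title, rest = lines[0], lines[1:]
    loci = []
    i = 0
    while i < len(rest) and rest[i].lower() != "pop":
        loci.append(rest[i])
        i += 1
    pops = []
    current = None
    for line in rest[i:]:
        if line.lower() == "pop":
            current = []
            pops.append(current)
            continue
        name, genos = line.split(",", 1)
        fields = genos.split()
        calls = []
        for f in fields:
            a, b = int(f[:3]), int(f[3:])
            calls.append(None if a == 0 else (a, b))
        current.append((name.strip(), calls))
    return title, loci, pops


class TestGenepop:
    def _consensus_dataset(self):
        ds = _toy_dataset()
        for s in ds.samples:
            s.consensus = s.replicates[1]
        return ds

    def test_field_format_and_pop_blocks(self, tmp_path):
        ds = self._consensus_dataset()
        path = tmp_path / "gp.txt"
        write_genepop(ds, path, group_by="province")
        text = path.read_text()
        _, loci, pops = _parse_genepop(text)
        assert loci == ["A", "B"]
        assert len(pops) == 2  # one Pop block per province
        # H1 consensus A=(100,102) -> codes 001 002
        flat = {name: calls for pop in pops for name, calls in pop}
        assert flat["H1"][0] == (1, 2)

    def test_parse_back_recovers_allele_counts(self, tmp_path):
        ds = self._consensus_dataset()
        path = tmp_path / "gp.txt"
        write_genepop(ds, path)
        _, loci, pops = _parse_genepop(path.read_text())
        counts = {}
        for pop in pops:
            for _, calls in pop:
                for locus, call in zip(loci, calls):
                    if call:
                        for c in call:
                            counts[(locus, c)] = counts.get((locus, c), 0) + 1
        # locus A: H1 has (100,102)->(1,2), H2 has (104,104)->(3,3)
        assert counts[("A", 1)] == 1 and counts[("A", 2)] == 1 and counts[("A", 3)] == 2


class TestClusterInput:
    def test_two_rows_per_individual_and_missing(self, tmp_path):
        from tests.conftest import make_mlg

        mlg = make_mlg([(100, 102), None])
        path = tmp_path / "c.txt"
        write_cluster_input([("I1", mlg)], path)
        lines = path.read_text().splitlines()
        assert len(lines) == 2
        assert lines[0].split("\t") == ["I1", "100", "-9"]
        assert lines[1].split("\t") == ["I1", "102", "-9"]

    def test_parse_back_recovers_genotype(self, tmp_path):
        from tests.conftest import make_mlg

        mlg = make_mlg([(100, 102), None, (88, 88)])
        path = tmp_path / "c.txt"
        write_cluster_input([("I1", mlg)], path)
        (label, back), = read_cluster_input(path)
        assert label == "I1"
        assert back.same_calls(make_mlg([(100, 102), None, (88, 88)], loci=back.loci))


class TestValidate:
    def test_clean_dataset_empty_report(self, study):
        dataset, _, _ = study
        report = validate_dataset(dataset)
        assert report["too_few_replicates"] == []
        assert report["coordinate_outliers"] == []

    def test_off_grid_allele_flagged(self):
        ds = _toy_dataset()
        ds.samples[0].replicates[0].calls["A"] = LocusGenotype(100, 101)
        report = validate_dataset(ds)
        assert {"locus": "A", "allele": 101} in report["off_grid_alleles"]

    def test_single_replicate_hair_flagged(self):
        ds = _toy_dataset()
        ds.samples[1].replicates = ds.samples[1].replicates[:1]
        report = validate_dataset(ds)
        assert "H2" in report["too_few_replicates"]


def test_study_like_round_trip(tmp_path, study):
    """Full-size read -> write -> read round trip preserves every call."""
    dataset, _, _ = study
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    write_genotype_table(dataset, p1)
    back = read_genotype_table(p1, loci=dataset.loci)
    write_genotype_table(back, p2)
    assert p1.read_text() == p2.read_text()
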