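"""Haploid calling, site/individual filters, VCF/NEXUS/FASTA round-trips."""

import numpy as np
import pandas as pd
import pytest

from wolbscan import (
    ConfigError,
    HaplotypeMatrix,
    ParseError,
    WolbscanError,
    call_haploid,
    export_nexus,
    filter_complete_individuals,
    filter_sites,
    read_haplotype_fasta,
    read_vcf,
    write_haplotype_fasta,
    write_vcf,
)


def depth_frame(rows):
    return pd.DataFrame(rows, columns=["site", "individual_id",
                                       "ref_depth", "alt_depth"])


class TestCallHaploid:
    def test_majority_allele_called(self):
        df = depth_frame([("s1", "a", 3, 0), ("s1", "b", 0, 2)])
        mat = call_haploid(df)
        assert mat.alleles[mat.individuals.index("a"), 0] == 0
        assert mat.alleles[mat.individuals.index("b"), 0] == 1

    def test_no_coverage_is_missing(self):
        df = depth_frame([("s1", "a", 0, 0)])
        assert call_haploid(df).alleles[0, 0] == -1

    def test_tie_policy(self):
        df = depth_frame([("s1", "a", 2, 2)])
        assert call_haploid(df).alleles[0, 0] == -1
        assert call_haploid(df, tie="ref").alleles[0, 0] == 0
        assert call_haploid(df, tie="alt").alleles[0, 0] == 1

    def test_tie_individual_dropped_downstream(self):
        # conservative tie rule propagates: the tied individual is
        # incomplete and removed by the complete-case filter
        df = depth_frame([("s1", "a", 2, 2), ("s2", "a", 3, 0),
                          ("s1", "b", 4, 0), ("s2", "b", 0, 4)])
        mat = filter_complete_individuals(call_haploid(df))
        assert mat.individuals == ["b"]

    def test_negative_depths_rejected(self):
        with pytest.raises(ConfigError):
            call_haploid(depth_frame([("s1", "a", -1, 0)]))


class TestFilters:
    def make(self, alleles, individuals=None, sites=None):
        alleles = np.asarray(alleles, dtype=np.int8)
        individuals = individuals or [f"i{k}"
                                      for k in range(alleles.shape[0])]
        sites = sites or [f"s{k}" for k in range(alleles.shape[1])]
        return HaplotypeMatrix(individuals, sites, alleles)

    def test_site_over_missingness_dropped(self):
        mat = self.make([[0, -1], [1, -1], [0, 0], [1, 0]])
        out = filter_sites(mat, 0.25)   # second site missing in 2/4 = 0.5
        assert out.sites == ["s0"]

    def test_max_missing_one_keeps_all(self):
        mat = self.make([[0, -1], [1, -1]])
        assert filter_sites(mat, 1.0).sites == ["s0", "s1"]

    def test_complete_matrix_unchanged(self):
        mat = self.make([[0, 1], [1, 0]])
        assert filter_sites(mat, 0.25).sites == mat.sites
        assert filter_complete_individuals(mat).individuals == \
            mat.individuals

    def test_denominator_restricted_to_infected(self):
        # the site is missing only in the uninfected row; over infected
        # rows missingness is 0 and the site is kept
        mat = self.make([[0, 0], [1, 0], [-1, -1]],
                        individuals=["a", "b", "u"])
        out = filter_sites(mat, 0.25, individuals=["a", "b"])
        assert out.sites == ["s0", "s1"]
        # counting the uninfected row (1/3 missing) would drop both sites
        assert filter_sites(mat, 0.25).sites == []

    def test_any_missing_individual_dropped(self):
        mat = self.make([[0] * 114 + [-1], [1] * 115])
        out = filter_complete_individuals(mat)
        assert out.individuals == ["i1"]

    def test_planted_incomplete_fraction_recovered(self, rng):
        n, m = 200, 40
        alleles = rng.integers(0, 2, size=(n, m)).astype(np.int8)
        bad = rng.choice(n, size=20, replace=False)
        for i in bad:
            alleles[i, rng.integers(m)] = -1
        out = filter_complete_individuals(self.make(alleles))
        assert out.n_individuals == n - 20

    def test_pipeline_idempotent(self, rng):
        alleles = rng.choice([0, 1, -1], size=(30, 20),
                             p=[0.45, 0.45, 0.1]).astype(np.int8)
        mat = self.make(alleles)
        once = filter_complete_individuals(filter_sites(mat, 0.25))
        twice = filter_complete_individuals(filter_sites(once, 0.25))
        assert once.individuals == twice.individuals
        assert once.sites == twice.sites
        assert (once.alleles == twice.alleles).all()


class TestVcfRoundTrip:
    def test_round_trip_identity(self, tmp_path, rng):
        for k in range(3):
            n, m = int(rng.integers(1, 8)), int(rng.integers(1, 12))
            alleles = rng.choice([0, 1, -1], size=(n, m),
                                 p=[0.4, 0.4, 0.2]).astype(np.int8)
            mat = HaplotypeMatrix([f"ind{j}" for j in range(n)],
                                  [f"site{j}" for j in range(m)], alleles)
            p = tmp_path / f"m{k}.vcf"
            write_vcf(mat, p)
            back = read_vcf(p)
            assert back.individuals == mat.individuals
            assert back.sites == mat.sites
            assert (back.alleles == mat.alleles).all()

    def test_missing_written_as_dot(self, tmp_path):
        mat = HaplotypeMatrix(["a"], ["s1"], np.array([[-1]], dtype=np.int8))
        p = tmp_path / "x.vcf"
        write_vcf(mat, p)
        data_line = [ln for ln in p.read_text().splitlines()
                     if not ln.startswith("#")][0]
        assert data_line.endswith("\t.")

    def test_diploid_vcf_rejected(self, tmp_path):
        p = tmp_path / "dip.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=c1,length=1000>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\n"
            "c1\t1\ts1\tA\tC\t.\tPASS\t.\tGT\t0/1\n")
        with pytest.raises(ParseError, match="ploidy"):
            read_vcf(p)

    def test_multiallelic_vcf_rejected(self, tmp_path):
        p = tmp_path / "multi.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=c1,length=1000>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\n"
            "c1\t1\ts1\tA\tC,G\t.\tPASS\t.\tGT\t1\n")
        with pytest.raises(ParseError, match="biallelic"):
            read_vcf(p)


class TestNexusAndFasta:
    def test_nexus_dimensions_and_parse_back(self, tmp_path):
        alleles = np.array([[0, 1, 0], [1, 1, 0], [0, 0, 1]],
                           dtype=np.int8)
        mat = HaplotypeMatrix(["h1", "h2", "h3"], ["s1", "s2", "s3"],
                              alleles)
        p = tmp_path / "h.nex"
        export_nexus(mat, p)
        text = p.read_text()
        assert "NTAX=3" in text and "NCHAR=3" in text
        from Bio.Nexus import Nexus
        nx = Nexus.Nexus(str(p))
        seqs = {t: str(nx.matrix[t]) for t in nx.taxlabels}
        assert seqs == {"h1": "010", "h2": "110", "h3": "001"}

    def test_empty_export_is_an_error(self, tmp_path):
        mat = HaplotypeMatrix([], ["s1"],
                              np.empty((0, 1), dtype=np.int8))
        with pytest.raises(WolbscanError):
            export_nexus(mat, tmp_path / "e.nex")

    def test_fasta_round_trip(self, tmp_path, rng):
        alleles = rng.integers(0, 2, size=(5, 30)).astype(np.int8)
        mat = HaplotypeMatrix([f"i{j}" for j in range(5)],
                              [f"s{j}" for j in range(30)], alleles)
        p = tmp_path / "h.fasta"
        write_haplotype_fasta(mat, p)
        strings = read_haplotype_fasta(p)
        assert strings == mat.haplotype_strings()


class TestRecovery:
    def test_planted_haplotypes_recovered_exactly(self):
        """With per-site depth >= 3 and no sequencing error, called
        haplotypes equal planted haplotypes for all complete-case
        individuals."""
        from wolbscan import SimulationConfig, simulate_read_data, \
            simulate_truth
        for seed in range(3):
            cfg = SimulationConfig(
                n_localities=5, individuals_per_locality=10,
                depth_per_site_dist=("uniform_int", {"low": 3, "high": 8}),
                depth_scaled_by_reads=False, seed=seed)
            truth = simulate_truth(cfg)
            _, depths = simulate_read_data(cfg, truth)
            mat = filter_complete_individuals(
                filter_sites(call_haploid(depths), 0.25))
            planted = dict(zip(truth.individuals.individual_id,
                               truth.individuals.haplotype))
            called = mat.haplotype_strings()
            infected = truth.individuals.infected.sum()
            assert len(called) == infected  # full depth: nobody dropped
            assert all(called[iid] == planted[iid] for iid in called)
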