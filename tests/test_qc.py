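"""QC filters, empirical inbreeding, gene partitioning, pedigree kinship."""

import numpy as np
import pandas as pd
import pytest

from abt import (GeneRegion, GenotypeMatrix, SimConfig, empirical_self_kinship,
                 filter_samples, filter_snps, partition_by_gene,
                 pedigree_kinship, run_qc, simulate_genotypes,
                 simulate_pedigree)
from abt.qc import MISSING

from _oracles import gene_drop_kinship


def make_matrix(dosage, positions=None, chrom="1"):
    dosage = np.asarray(dosage, dtype=np.int8)
    m = dosage.shape[1]
    pos = positions if positions is not None else 1000 * np.arange(1, m + 1)
    meta = pd.DataFrame({"id": [f"snp{j}" for j in range(m)],
                         "chrom": chrom, "pos": pos, "a1": "A", "a2": "G"})
    ids = np.array([f"s{i}" for i in range(dosage.shape[0])], dtype=object)
    return GenotypeMatrix(dosage, meta, ids)


class TestSelfKinship:
    def test_outbred_hardy_weinberg_sample(self, rng):
        p = rng.uniform(0.1, 0.5, 4000)
        dos = rng.binomial(2, p, size=(300, 4000)).astype(np.int8)
        phi = empirical_self_kinship(make_matrix(dos))
        assert abs(phi.mean() - 0.5) < 0.01
        assert np.all(np.abs(phi - 0.5) < 0.05)

    def test_fully_homozygous_sample_reaches_one(self, rng):
        # many outbred samples at freq ~0.5 plus one all-homozygous sample
        dos = rng.binomial(2, 0.5, size=(200, 2000)).astype(np.int8)
        dos[0] = 2 * rng.binomial(1, 0.5, 2000).astype(np.int8)
        phi = empirical_self_kinship(make_matrix(dos))
        assert phi[0] > 0.95

    def test_parent_child_mating_offspring(self):
        """The child of a parent-child mating has inbreeding coefficient
        phi_parent,child = 1/4; the genomic estimator should recover it."""
        rows = [("U%04d" % u, f"U{u:04d}_1", None, None, "male")
                for u in range(300)]
        rows += [("FAM", "A", None, None, "male"),
                 ("FAM", "C0", None, None, "female"),
                 ("FAM", "B", "A", "C0", "female"),
                 ("FAM", "D", "A", "B", "male")]
        ped = pd.DataFrame(rows, columns=["family", "iid", "father", "mother",
                                          "sex"])
        cfg = SimConfig(n_families=1, n_unrelated=1, n_genes=250,
                        snps_per_gene=400, ld_block_rho=0.0,
                        maf_range=(0.1, 0.5), seed=77)
        G = simulate_genotypes(ped, cfg)
        h = 2 * empirical_self_kinship(G) - 1
        assert abs(h[-1] - 0.25) < 0.03       # inbred child
        assert abs(np.mean(h[:300])) < 0.02   # outbred background

    def test_all_missing_sample_errors(self):
        dos = np.array([[0, 1, 2], [MISSING, MISSING, MISSING]])
        with pytest.raises(ValueError, match="s1"):
            empirical_self_kinship(make_matrix(dos))


class TestSampleFilter:
    def test_low_completeness_removed_boundary_kept(self, rng):
        dos = rng.binomial(2, 0.4, size=(3, 1000)).astype(np.int8)
        dos[0, :30] = MISSING   # 97.0% complete
        dos[1, :40] = MISSING   # 96.0% complete -> kept (boundary)
        dos[2, :41] = MISSING   # 95.9% complete -> removed
        G2, rep = filter_samples(make_matrix(dos))
        assert list(G2.sample_ids) == ["s0", "s1"]
        assert rep.samples_removed["reason"].tolist() == ["low_completeness"]

    def test_clean_outbred_data_untouched(self, rng):
        # enough SNPs that self-kinship noise (sd ~ 1/sqrt(m)) stays far
        # below the 0.525 exclusion threshold
        dos = rng.binomial(2, 0.3, size=(50, 20_000)).astype(np.int8)
        G2, rep = filter_samples(make_matrix(dos))
        assert G2.n_samples == 50
        assert rep.samples_removed.empty

    def test_inbred_sample_flagged(self, rng):
        dos = rng.binomial(2, 0.5, size=(100, 2000)).astype(np.int8)
        dos[3] = 2 * rng.binomial(1, 0.5, 2000).astype(np.int8)
        G2, rep = filter_samples(make_matrix(dos))
        assert "s3" not in G2.sample_ids
        assert rep.samples_removed["reason"].tolist() == ["high_self_kinship"]

    def test_removing_everything_errors(self):
        dos = np.full((2, 10), MISSING, dtype=np.int8)
        dos[:, 0] = [0, 1]
        with pytest.raises(ValueError, match="every sample"):
            filter_samples(make_matrix(dos))


class TestSnpFilter:
    def test_rare_snp_removed(self, rng):
        dos = rng.binomial(2, [0.3, 0.005, 0.5], size=(1000, 3)).astype(np.int8)
        G2, rep = filter_snps(make_matrix(dos))
        assert "snp1" in rep.snps_removed["snp_id"].tolist()
        assert G2.n_snps == 2

    def test_full_call_common_snp_retained(self, rng):
        dos = rng.binomial(2, 0.5, size=(200, 1)).astype(np.int8)
        G2, rep = filter_snps(make_matrix(dos))
        assert G2.n_snps == 1 and rep.snps_removed.empty

    def test_toy_matrix_counts(self, rng):
        """10 SNPs: 2 with low call rate, 1 rare -> 7 survive."""
        n = 500
        dos = rng.binomial(2, 0.3, size=(n, 10)).astype(np.int8)
        dos[: int(0.05 * n), 0] = MISSING
        dos[: int(0.05 * n), 1] = MISSING
        dos[:, 2] = rng.binomial(2, 0.004, n).astype(np.int8)
        G2, rep = filter_snps(make_matrix(dos))
        assert G2.n_snps == 7
        assert len(rep.snps_removed) == 3

    def test_recoding_makes_counted_allele_minor(self, rng):
        dos = rng.binomial(2, 0.9, size=(500, 1)).astype(np.int8)
        G2, _ = filter_snps(make_matrix(dos))
        assert G2.allele_freq()[0] <= 0.5
        assert G2.snp_meta["a1"].iloc[0] == "G"   # alleles swapped

    def test_qc_is_idempotent(self, rng):
        dos = rng.binomial(2, rng.uniform(0.05, 0.5, 20_000),
                           size=(300, 20_000)).astype(np.int8)
        miss = rng.random(dos.shape) < 0.02
        dos[miss] = MISSING
        G1, rep1 = run_qc(make_matrix(dos))
        G2, rep2 = run_qc(G1)
        assert rep2.samples_removed.empty and rep2.snps_removed.empty
        assert np.array_equal(G1.dosage, G2.dosage)


class TestPartition:
    def test_interval_membership(self, rng):
        dos = rng.binomial(2, 0.4, size=(60, 5)).astype(np.int8)
        G = make_matrix(dos, positions=[10, 20, 30, 40, 50])
        parts = partition_by_gene(G, [GeneRegion("g1", "1", 9, 35)])
        assert len(parts) == 1
        assert parts[0].m == 3
        assert parts[0].snp_ids == ["snp0", "snp1", "snp2"]

    def test_gene_without_snps_omitted(self, rng):
        dos = rng.binomial(2, 0.4, size=(20, 2)).astype(np.int8)
        G = make_matrix(dos, positions=[100, 200])
        parts = partition_by_gene(G, [GeneRegion("far", "1", 10_000, 20_000),
                                      GeneRegion("hit", "1", 0, 500)])
        assert [p.region.gene_id for p in parts] == ["hit"]

    def test_duplicate_column_dropped_first_kept(self, rng):
        dos = rng.binomial(2, 0.4, size=(40, 3)).astype(np.int8)
        dos[:, 2] = dos[:, 0]
        G = make_matrix(dos)
        parts = partition_by_gene(G, [GeneRegion("g", "1", 0, 10_000)])
        assert parts[0].m == 2
        assert parts[0].dropped_duplicate == ["snp2"]

    def test_monomorphic_column_dropped(self, rng):
        dos = rng.binomial(2, 0.4, size=(40, 2)).astype(np.int8)
        dos[:, 1] = 1
        G = make_matrix(dos)
        parts = partition_by_gene(G, [GeneRegion("g", "1", 0, 10_000)])
        assert parts[0].m == 1
        assert parts[0].dropped_monomorphic == ["snp1"]

    def test_overlapping_genes_share_snps(self, rng):
        dos = rng.binomial(2, 0.4, size=(30, 4)).astype(np.int8)
        G = make_matrix(dos, positions=[10, 20, 30, 40])
        parts = partition_by_gene(G, [GeneRegion("a", "1", 0, 25),
                                      GeneRegion("b", "1", 15, 45)])
        ids = {p.region.gene_id: p.snp_ids for p in parts}
        assert ids["a"] == ["snp0", "snp1"]
        assert ids["b"] == ["snp1", "snp2", "snp3"]

    def test_column_conservation(self, small_study):
        parts = partition_by_gene(small_study.genotypes,
                                  small_study.gene_regions)
        gene_col = small_study.genotypes.snp_meta["gene"]
        for p in parts:
            expected = set(small_study.genotypes.snp_meta.loc[
                gene_col == p.region.gene_id, "id"])
            got = set(p.snp_ids) | set(p.dropped_monomorphic) \
                | set(p.dropped_duplicate)
            assert got == expected
            assert len(p.snp_ids) == len(set(p.snp_ids))

    def test_invalid_region_errors(self):
        with pytest.raises(ValueError, match="start"):
            GeneRegion("bad", "1", 100, 100)

    def test_mean_imputation(self):
        dos = np.array([[0, 2], [1, MISSING], [2, 0], [1, 2]], dtype=np.int8)
        G = make_matrix(dos)
        parts = partition_by_gene(G, [GeneRegion("g", "1", 0, 10_000)])
        X = parts[0].genotypes
        assert X[1, 1] == pytest.approx((2 + 0 + 2) / 3)


class TestPedigreeKinship:
    def test_unrelated_founders(self):
        ped = pd.DataFrame({"family": list("abc"), "iid": list("xyz"),
                            "father": [None] * 3, "mother": [None] * 3,
                            "sex": ["male"] * 3})
        kin = pedigree_kinship(ped)
        assert np.allclose(kin.phi, 0.5 * np.eye(3))

    def test_parent_offspring_and_sibs(self):
        ped = pd.DataFrame({
            "family": ["f"] * 4,
            "iid": ["dad", "mom", "kid1", "kid2"],
            "father": [None, None, "dad", "dad"],
            "mother": [None, None, "mom", "mom"],
            "sex": ["male", "female", "male", "female"]})
        kin = pedigree_kinship(ped)
        i = {v: k for k, v in enumerate(kin.ids)}
        assert kin.phi[i["dad"], i["kid1"]] == pytest.approx(0.25)
        assert kin.phi[i["kid1"], i["kid2"]] == pytest.approx(0.25)
        assert kin.phi[i["dad"], i["mom"]] == 0.0

    def test_three_generation_pedigree_vs_gene_dropping(self):
        """8-member, 3-generation pedigree against a Monte Carlo gene-
        dropping oracle (1e5 drops, elementwise tolerance 0.01)."""
        ped = pd.DataFrame({
            "family": ["f"] * 8,
            "iid": ["gp1", "gm1", "gp2", "gm2", "dad", "mom", "c1", "c2"],
            "father": [None, None, None, None, "gp1", "gp2", "dad", "dad"],
            "mother": [None, None, None, None, "gm1", "gm2", "mom", "mom"],
            "sex": ["male", "female", "male", "female", "male", "female",
                    "male", "female"]})
        kin = pedigree_kinship(ped)
        phi_mc = gene_drop_kinship(ped, n_reps=100_000, seed=8)
        assert np.abs(kin.phi - phi_mc).max() < 0.01

    def test_inbred_loop(self):
        ped = pd.DataFrame({
            "family": ["f"] * 4,
            "iid": ["A", "C0", "B", "D"],
            "father": [None, None, "A", "A"],
            "mother": [None, None, "C0", "B"],
            "sex": ["male", "female", "female", "male"]})
        kin = pedigree_kinship(ped)
        i = {v: k for k, v in enumerate(kin.ids)}
        assert kin.phi[i["D"], i["D"]] == pytest.approx(0.5 + 0.5 * 0.25)

    def test_cycle_detected(self):
        ped = pd.DataFrame({
            "family": ["f"] * 2, "iid": ["a", "b"],
            "father": ["b", "a"], "mother": ["b", "a"],
            "sex": ["male", "female"]})
        with pytest.raises(ValueError, match="cycle"):
            pedigree_kinship(ped)

    def test_psd_and_diagonal_range(self):
        cfg = SimConfig(n_families=25, n_unrelated=10, n_genes=1, seed=15)
        kin = pedigree_kinship(simulate_pedigree(cfg))
        ev = np.linalg.eigvalsh(kin.phi)
        assert ev.min() > -1e-10
        assert np.all((kin.phi.diagonal() >= 0.5)
                      & (kin.phi.diagonal() <= 1.0))
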