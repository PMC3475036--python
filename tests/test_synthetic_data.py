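"""Tests of the cross simulator: pedigree, transmission, phenotype model."""

import numpy as np
import pytest

import imprintqtl as iq
from imprintqtl.synthetic_data import haldane_recombination, sample_gamete


class TestPedigree:
    def test_default_sizes(self, default_pedigree):
        frame = default_pedigree.to_frame()
        counts = frame["generation"].value_counts()
        assert counts["F2"] == 94
        assert counts["F3"] == 345
        assert frame.loc[frame["generation"] == "F3", "analyzable"].sum() == 331

    def test_structure_invariants(self, default_pedigree):
        ped = default_pedigree
        order = {ind_id: k for k, ind_id in enumerate(ped.ids)}
        gen_rank = {"F0": 0, "F1": 1, "F2": 2, "F3": 3}
        for ind in ped.individuals:
            if ind.generation == "F0":
                assert ind.founder_line in ("A", "B")
                continue
            sire, dam = ped[ind.sire_id], ped[ind.dam_id]
            assert order[sire.id] < order[ind.id] and order[dam.id] < order[ind.id]
            assert sire.sex == "M" and dam.sex == "F"
            assert gen_rank[ind.generation] == gen_rank[sire.generation] + 1

    def test_f3_families_are_non_sibling_pairs(self, default_pedigree):
        ped = default_pedigree
        for sire_id, dam_id, gen in ped.matings():
            if gen == "F3":
                sire, dam = ped[sire_id], ped[dam_id]
                assert (sire.sire_id, sire.dam_id) != (dam.sire_id, dam.dam_id)

    def test_zero_descendants(self):
        ped = iq.simulate_pedigree(iq.CrossConfig(n_f2=0, n_f3=0, n_f3_analyzable=0), seed=0)
        gens = {i.generation for i in ped.individuals}
        assert gens == {"F0", "F1"}

    def test_same_seed_reproducible(self):
        a = iq.simulate_pedigree(seed=7).to_frame()
        b = iq.simulate_pedigree(seed=7).to_frame()
        assert a.equals(b)

    def test_reciprocal_directions_present(self, default_pedigree):
        f2_dirs = {i.grandmaternal_line for i in default_pedigree.generation("F2")}
        assert f2_dirs == {"A", "B"}


class TestGenotypes:
    def test_founders_and_f1_forced(self, small_dataset):
        geno = small_dataset["genotypes"]
        ped = small_dataset["pedigree"]
        codes = geno.codes()
        for ind in ped.generation("F0"):
            expect = "AA" if ind.founder_line == "A" else "BB"
            assert (codes.loc[ind.id] == expect).all()
        for ind in ped.generation("F1"):
            sire_line = ped[ind.sire_id].founder_line
            expect = "AB" if sire_line == "A" else "BA"
            assert (codes.loc[ind.id] == expect).all()

    def test_mendelian_consistency(self, small_dataset):
        geno = small_dataset["genotypes"]
        ped = small_dataset["pedigree"]
        for ind in ped.individuals[:200]:
            if ind.sire_id is None:
                continue
            r, rs, rd = geno.row(ind.id), geno.row(ind.sire_id), geno.row(ind.dam_id)
            assert np.all(
                (geno.paternal[r] == geno.paternal[rs]) | (geno.paternal[r] == geno.maternal[rs])
            )
            assert np.all(
                (geno.maternal[r] == geno.paternal[rd]) | (geno.maternal[r] == geno.maternal[rd])
            )

    def test_haldane_recombinant_fraction(self):
        """Fraction of gametes recombinant across a 10 cM interval matches
        the closed-form Haldane fraction (1 - e^-0.2)/2 ~ 0.0906."""
        rng = np.random.default_rng(5)
        rf = haldane_recombination(np.array([10.0]))
        pat = np.array([0, 0], dtype=np.int8)
        mat = np.array([1, 1], dtype=np.int8)
        n = 10_000
        rec = 0
        for _ in range(n):
            g = sample_gamete(pat, mat, rf, rng)
            rec += g[0] != g[1]
        expected = (1 - np.exp(-0.2)) / 2
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(rec / n - expected) < 4 * se

    def test_class_frequencies_near_quarter(self, small_dataset):
        """F3 ordered-class frequencies hover around 0.25 at every marker."""
        geno = small_dataset["genotypes"]
        ped = small_dataset["pedigree"]
        f3 = [i.id for i in ped.generation("F3")]
        codes = geno.codes().loc[f3]
        for mk in geno.marker_ids:
            freqs = codes[mk].value_counts(normalize=True)
            assert set(freqs.index) <= {"AA", "AB", "BA", "BB"}
            assert freqs.min() > 0.10 and freqs.max() < 0.45

    def test_same_seed_reproducible(self, default_pedigree, small_map):
        a = iq.simulate_genotypes(default_pedigree, small_map, seed=3)
        b = iq.simulate_genotypes(default_pedigree, small_map, seed=3)
        assert np.array_equal(a.paternal, b.paternal)
        assert np.array_equal(a.maternal, b.maternal)

    def test_unorder_collapses_reciprocal_heterozygotes(self, small_dataset):
        geno = small_dataset["genotypes"]
        uno = iq.unorder(geno)
        het = (geno.paternal != geno.maternal) & (geno.paternal >= 0)
        assert np.all(uno.dosage[het] == 1)
        assert np.all(uno.dosage[(geno.paternal == 0) & (geno.maternal == 0)] == 0)
        assert np.all(uno.dosage[(geno.paternal == 1) & (geno.maternal == 1)] == 2)


class TestPhenotypes:
    def test_degenerate_noiseless_grand_mean(self, small_dataset):
        spec = iq.TraitSpec("flat", grand_mean=3.25, family_sd=0.0, residual_sd=0.0)
        pheno = iq.simulate_phenotypes(
            small_dataset["pedigree"], small_dataset["genotypes"], small_dataset["map"], [spec], seed=0
        )
        assert np.all(pheno["flat"] == 3.25)

    def test_pure_imprinting_heterozygote_gap(self, small_dataset):
        """With i = 2 and no other effect, AB minus BA means is exactly 4."""
        spec = iq.TraitSpec(
            "imp", qtls=[iq.QTLEffect(1, 20.0, i=2.0)], family_sd=0.0, residual_sd=0.0
        )
        geno = small_dataset["genotypes"]
        pheno = iq.simulate_phenotypes(
            small_dataset["pedigree"], geno, small_dataset["map"], [spec], seed=0
        )
        codes = geno.codes()["m01_05"].loc[pheno["id"]]
        gap = pheno.loc[codes.values == "AB", "imp"].mean() - pheno.loc[
            codes.values == "BA", "imp"
        ].mean()
        assert gap == pytest.approx(4.0)

    def test_variance_matches_analytic_sum(self):
        """Sample phenotypic variance in a large F3 matches the analytic
        variance-component sum given the realized genotype frequencies."""
        cfg = iq.CrossConfig(n_f2=94, n_f3=5000, n_f3_analyzable=5000)
        ped = iq.simulate_pedigree(cfg, seed=9)
        gmap = iq.default_map(n_markers=5, n_chromosomes=1)
        geno = iq.simulate_genotypes(ped, gmap, seed=10)
        spec = iq.TraitSpec(
            "t",
            qtls=[iq.QTLEffect(1, 10.0, a=1.0, d=0.5, i=0.8)],
            family_sd=0.5,
            residual_sd=1.0,
        )
        pheno = iq.simulate_phenotypes(ped, geno, gmap, [spec], seed=11, generations=("F3",))
        idx = iq.EffectIndexMatrix.from_ordered(geno)
        rows = np.array([geno.row(i) for i in pheno["id"]])
        col = geno.col("m01_03")
        g = 1.0 * idx.x_a[rows, col] + 0.5 * idx.x_d[rows, col] + 0.8 * idx.x_i[rows, col]
        analytic = g.var() + 0.5**2 + 1.0**2
        assert pheno["t"].var() == pytest.approx(analytic, rel=0.05)

    def test_chromosome_absent_raises(self, small_dataset):
        spec = iq.TraitSpec("bad", qtls=[iq.QTLEffect(7, 10.0, a=1.0)])
        with pytest.raises(KeyError):
            iq.simulate_phenotypes(
                small_dataset["pedigree"],
                small_dataset["genotypes"],
                small_dataset["map"],
                [spec],
                seed=0,
            )

    def test_no_imprinting_no_reciprocal_gap(self, small_dataset):
        """With i = 0 and no maternal effect the expected AB-BA difference
        is zero; check it is small relative to its standard error."""
        geno = small_dataset["genotypes"]
        gaps = []
        for seed in range(10):
            spec = iq.TraitSpec(
                "t", qtls=[iq.QTLEffect(1, 20.0, a=1.0, d=0.5)], family_sd=0.0, residual_sd=1.0
            )
            pheno = iq.simulate_phenotypes(
                small_dataset["pedigree"], geno, small_dataset["map"], [spec], seed=20 + seed
            )
            codes = geno.codes()["m01_05"].loc[pheno["id"]].values
            gaps.append(
                pheno.loc[codes == "AB", "t"].mean() - pheno.loc[codes == "BA", "t"].mean()
            )
        assert abs(np.mean(gaps)) < 3 * np.std(gaps) / np.sqrt(len(gaps))


def test_default_map_shape():
    gmap = iq.default_map()
    assert gmap.n_markers == 164
    assert gmap.chromosomes() == list(range(1, 20))
    for chrom in gmap.chromosomes():
        sub = gmap.chromosome_slice(chrom)
        assert (np.diff(sub["position_cM"]) > 0).all()
        assert np.allclose(sub["position_Mb"], 2 * sub["position_cM"])
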