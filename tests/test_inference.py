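"""Permutation thresholds, QTL calling, support intervals, Mc naming."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import imprintqtl as iq
from imprintqtl.inference import (
    QTLRecord,
    ThresholdSet,
    call_qtl,
    name_qtl,
    permutation_thresholds,
    support_interval,
)
from imprintqtl.scan import STATISTICS, ScanResult, genome_scan


def _profile_scan(lods, trait="t", statistic="iLOD", chromosome=1):
    """Build a minimal one-trait ScanResult from a LOD profile."""
    n = len(lods)
    tab = pd.DataFrame(
        {
            "trait": trait,
            "marker_id": [f"mk{j}" for j in range(n)],
            "chromosome": chromosome,
            "position_cM": np.arange(n) * 5.0,
            "position_Mb": np.arange(n) * 10.0,
            "n_used": 100,
            "a": 0.0,
            "d": 0.0,
            "i": 0.0,
            "se_a": 0.1,
            "se_d": 0.1,
            "se_i": 0.1,
            "mLOD": 0.0,
            "aLOD": 0.0,
            "dLOD": 0.0,
            "iLOD": 0.0,
            "sigma2_family": 0.0,
            "sigma2_residual": 1.0,
            "status": "ok",
        }
    )
    tab[statistic] = lods
    return ScanResult(table=tab)


@pytest.fixture(scope="module")
def null_inputs(small_dataset):
    spec = iq.TraitSpec("null", family_sd=0.5, residual_sd=1.0)
    pheno = iq.simulate_phenotypes(
        small_dataset["pedigree"],
        small_dataset["genotypes"],
        small_dataset["map"],
        [spec],
        seed=77,
    )
    return pheno, small_dataset["indices"], small_dataset["map"]


class TestPermutationThresholds:
    def test_too_few_permutations_rejected(self, null_inputs):
        pheno, idx, gmap = null_inputs
        with pytest.raises(ValueError, match="permutations"):
            permutation_thresholds(pheno, idx, gmap, n_perm=10, alpha=0.05, seed=0)

    def test_alpha_one_gives_minimum_of_null_maxima(self, null_inputs):
        pheno, idx, gmap = null_inputs
        thr = permutation_thresholds(pheno, idx, gmap, n_perm=25, alpha=1.0, seed=1)
        thr95 = permutation_thresholds(pheno, idx, gmap, n_perm=25, alpha=0.04, seed=1)
        for s in STATISTICS:
            assert thr.genomewide["null"][s] <= thr95.genomewide["null"][s]

    def test_bit_exact_reproducible(self, null_inputs):
        pheno, idx, gmap = null_inputs
        a = permutation_thresholds(pheno, idx, gmap, n_perm=30, alpha=0.1, seed=5)
        b = permutation_thresholds(pheno, idx, gmap, n_perm=30, alpha=0.1, seed=5)
        assert a.genomewide == b.genomewide

    def test_more_markers_raise_thresholds(self, small_dataset):
        """Genome-wide maxima grow with map size (multiplicity)."""
        spec = iq.TraitSpec("null", family_sd=0.5, residual_sd=1.0)
        big = small_dataset["map"]
        small = iq.default_map(n_markers=2, n_chromosomes=1)
        pheno = iq.simulate_phenotypes(
            small_dataset["pedigree"], small_dataset["genotypes"], big, [spec], seed=78
        )
        idx = small_dataset["indices"]
        diffs = []
        for seed in range(8):
            t_small = permutation_thresholds(pheno, idx, small, n_perm=25, alpha=0.1, seed=seed)
            t_big = permutation_thresholds(pheno, idx, big, n_perm=25, alpha=0.1, seed=seed)
            diffs.append(
                t_big.genomewide["null"]["mLOD"] - t_small.genomewide["null"]["mLOD"]
            )
        assert np.median(diffs) >= 0.0


class TestSupportInterval:
    def test_unimodal_profile_brackets_peak(self):
        scan = _profile_scan([0.1, 1.0, 3.0, 5.0, 3.5, 1.2, 0.3])
        lo, hi = support_interval(scan, "t", "mk3", statistic="iLOD", drop=2.5)
        assert lo <= 15.0 <= hi
        assert (lo, hi) == (10.0, 20.0)
        # a tighter drop keeps only markers within 1 LOD of the peak
        assert support_interval(scan, "t", "mk3", statistic="iLOD", drop=1.0) == (15.0, 15.0)

    def test_zero_drop_degenerates_to_ties(self):
        scan = _profile_scan([1.0, 5.0, 5.0, 1.0])
        lo, hi = support_interval(scan, "t", "mk1", statistic="iLOD", drop=0.0)
        assert (lo, hi) == (5.0, 10.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 10, allow_nan=False), min_size=3, max_size=12), st.integers(0, 11))
    def test_wider_drop_nests(self, lods, peak_idx):
        """drop=2 interval contains the drop=1 interval on any profile."""
        peak_idx = min(peak_idx, len(lods) - 1)
        scan = _profile_scan(lods)
        peak = f"mk{peak_idx}"
        lo1, hi1 = support_interval(scan, "t", peak, statistic="iLOD", drop=1.0)
        lo2, hi2 = support_interval(scan, "t", peak, statistic="iLOD", drop=2.0)
        assert lo2 <= lo1 and hi2 >= hi1


class TestNaming:
    def test_chromosome_ordering(self):
        recs = [
            QTLRecord("", 12, "x", 43.9, 91.4, (40, 50)),
            QTLRecord("", 12, "y", 9.7, 27.3, (5, 15)),
            QTLRecord("", 19, "z", 23.5, 28.9, (20, 25)),
        ]
        named = {r.peak_marker: r.name for r in name_qtl(recs)}
        assert named == {"y": "Mc12.1", "x": "Mc12.2", "z": "Mc19.1"}

    def test_empty(self):
        assert name_qtl([]) == []


def _thresholds(trait="t", level=3.0):
    return ThresholdSet(genomewide={trait: {s: level for s in STATISTICS}}, alpha=0.05, n_perm=100)


class TestCallQtl:
    def test_nothing_significant_empty(self):
        scan = _profile_scan([0.5, 1.0, 0.8])
        assert call_qtl(scan, _thresholds()) == []

    def test_single_peak_called_and_named(self):
        scan = _profile_scan([0.5, 4.0, 3.6, 0.2])
        recs = call_qtl(scan, _thresholds())
        assert len(recs) == 1
        rec = recs[0]
        assert rec.name == "Mc1.1"
        assert rec.peak_marker == "mk1"
        assert rec.primary_trait == "t"
        assert rec.support_interval_cM[0] <= rec.peak_cM <= rec.support_interval_cM[1]

    def test_merge_window_splits_distant_peaks(self):
        lods = [4.0, 0.0, 0.0, 0.0, 0.0, 0.0, 4.5]  # peaks 30 cM apart
        recs = call_qtl(_profile_scan(lods), _thresholds(), merge_window_cM=20.0)
        assert [r.name for r in recs] == ["Mc1.1", "Mc1.2"]
        merged = call_qtl(_profile_scan(lods), _thresholds(), merge_window_cM=40.0)
        assert len(merged) == 1

    def test_raising_threshold_never_adds_qtl(self):
        rng = np.random.default_rng(0)
        lods = list(rng.uniform(0, 5, 15))
        lo = call_qtl(_profile_scan(lods), _thresholds(level=2.0))
        hi = call_qtl(_profile_scan(lods), _thresholds(level=3.5))
        assert len(hi) <= len(lo)
        lo_peaks = {r.peak_marker for r in lo}
        assert {r.peak_marker for r in hi} <= lo_peaks | set()

    def test_pointwise_pleiotropy_flags(self):
        """A second trait crossing only the pointwise bar is attached as
        pleiotropic, and every attached flag respects the 1.3 floor."""
        t1 = _profile_scan([0.2, 4.0, 0.1], trait="t1").table
        t2 = _profile_scan([0.0, 1.6, 0.0], trait="t2").table
        scan = ScanResult(table=pd.concat([t1, t2], ignore_index=True))
        thr = ThresholdSet(
            genomewide={t: {s: 3.0 for s in STATISTICS} for t in ("t1", "t2")},
            alpha=0.05,
            n_perm=100,
        )
        recs = call_qtl(scan, thr)
        assert len(recs) == 1
        traits = {e.trait: e for e in recs[0].trait_effects}
        assert recs[0].primary_trait == "t1"
        assert traits["t1"].flags["iLOD"] == "genomewide"
        assert traits["t2"].flags["iLOD"] == "pointwise"
        for eff in recs[0].trait_effects:
            for s, lvl in eff.flags.items():
                if lvl is not None:
                    assert eff.lods[s] >= thr.pointwise_lod


def test_end_to_end_call_on_simulated_qtl(small_dataset):
    """The imprinted QTL simulated on chromosome 1 is recovered by the full
    permute-and-call path near its true position (20 cM)."""
    res = genome_scan(small_dataset["adjusted"], small_dataset["indices"], small_dataset["map"])
    thr = permutation_thresholds(
        small_dataset["adjusted"],
        small_dataset["indices"],
        small_dataset["map"],
        n_perm=50,
        alpha=0.1,
        seed=3,
    )
    recs = call_qtl(res, thr)
    assert any(r.chromosome == 1 and abs(r.peak_cM - 20.0) <= 5.0 for r in recs)
    rec = next(r for r in recs if r.chromosome == 1)
    eff = rec.trait_effects[0]
    assert eff.flags["iLOD"] is not None
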