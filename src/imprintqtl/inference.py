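"""Genome-wide significance, QTL calling and naming.

Genome-wide thresholds are empirical quantiles of the per-trait maximum LOD
under permutation: each permutation shuffles the (phenotype, family) rows as
a unit against the genotype rows — preserving the family variance structure
of the trait while destroying any genotype-phenotype association — and the
full scan is re-run.  A locus is called when any of the four statistics
(mLOD, aLOD, dLOD, iLOD) exceeds its trait- and statistic-specific
genome-wide threshold; pleiotropic effects on further traits are attached
with the fixed pointwise LOD >= 1.3 (p <= 0.05) rule.  Called loci are
named ``Mc<chromosome>.<k>`` with ``k`` increasing along the chromosome.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .adi_model import EffectIndexMatrix
from .scan import STATISTICS, ScanResult, genome_scan
from .synthetic_data import GeneticMap

POINTWISE_LOD = 1.3


@dataclass
class ThresholdSet:
    """Per-trait, per-statistic genome-wide LOD thresholds."""

    genomewide: dict[str, dict[str, float]]  # trait -> statistic -> threshold
    pointwise_lod: float = POINTWISE_LOD
    alpha: float = 0.05
    n_perm: int = 0
    seed: int | None = None

    def threshold(self, trait: str, statistic: str) -> float:
        return self.genomewide[trait][statistic]

    def to_json(self, path) -> None:
        payload = {
            "genomewide": self.genomewide,
            "pointwise_lod": self.pointwise_lod,
            "alpha": self.alpha,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "ThresholdSet":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(**payload)


@dataclass
class TraitEffect:
    """One trait's effects and significance flags at a called locus."""

    trait: str
    a: float
    d: float
    i: float
    lods: dict[str, float]
    flags: dict[str, str | None]  # statistic -> "genomewide" | "pointwise" | None

    def significant_statistics(self) -> list[str]:
        return [s for s, lvl in self.flags.items() if lvl is not None]


@dataclass
class QTLRecord:
    """A called locus with its Mc name and per-trait effect summary."""

    name: str
    chromosome: int
    peak_marker: str
    peak_cM: float
    peak_Mb: float
    support_interval_cM: tuple[float, float]
    trait_effects: list[TraitEffect] = field(default_factory=list)
    primary_trait: str = ""


def permutation_thresholds(
    phenotypes: pd.DataFrame,
    indices: EffectIndexMatrix,
    genetic_map: GeneticMap,
    traits: list[str] | None = None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    min_per_class: int = 5,
    pointwise_lod: float = POINTWISE_LOD,
) -> ThresholdSet:
    """Empirical genome-wide thresholds from a permutation null.

    The threshold for each (trait, statistic) is the ``ceil((1-alpha) *
    n_perm)``-th order statistic of that statistic's genome-wide maximum
    over permutations.  Reproducible bit-exact given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    if n_perm < int(np.ceil(1.0 / alpha)):
        raise ValueError(
            f"n_perm={n_perm} cannot resolve the {1 - alpha:.3f} quantile; "
            f"need at least {int(np.ceil(1.0 / alpha))} permutations"
        )
    rng = np.random.default_rng(seed)
    base = genome_scan(
        phenotypes, indices, genetic_map, traits=traits, min_per_class=min_per_class,
        compute_reml=False,
    )
    traits = base.traits()
    maxima = {t: {s: [] for s in STATISTICS} for t in traits}
    pheno_cols = ["id", *traits, "family_id"]
    for _ in range(n_perm):
        perm = rng.permutation(len(phenotypes))
        shuffled = phenotypes[pheno_cols].iloc[perm].reset_index(drop=True)
        # genotype rows keep their original order: re-attach the original ids
        shuffled["id"] = phenotypes["id"].to_numpy()
        res = genome_scan(
            shuffled, indices, genetic_map, traits=traits,
            min_per_class=min_per_class, compute_reml=False,
        )
        ok = res.table[res.table["status"] == "ok"]
        for t in traits:
            sub = ok[ok["trait"] == t]
            for s in STATISTICS:
                maxima[t][s].append(float(sub[s].max()) if len(sub) else 0.0)
    k = max(1, int(np.ceil((1.0 - alpha) * n_perm)))
    genomewide = {
        t: {s: float(np.sort(maxima[t][s])[k - 1]) for s in STATISTICS} for t in traits
    }
    return ThresholdSet(
        genomewide=genomewide,
        pointwise_lod=pointwise_lod,
        alpha=alpha,
        n_perm=n_perm,
        seed=seed,
    )


def support_interval(
    scan: ScanResult,
    trait: str,
    peak_marker: str,
    statistic: str = "mLOD",
    drop: float = 1.0,
) -> tuple[float, float]:
    """LOD-drop support interval around a peak.

    The interval is the widest contiguous marker span containing the peak
    whose ``statistic`` stays within ``drop`` LOD of the peak value; with a
    single qualifying marker it degenerates to a zero-width interval at the
    peak.
    """
    prof = scan.profile(trait)
    peak_rows = prof.index[prof["marker_id"] == peak_marker]
    if len(peak_rows) == 0:
        raise KeyError(f"peak marker {peak_marker!r} not in scan for trait {trait!r}")
    p = int(peak_rows[0])
    chrom = prof.loc[p, "chromosome"]
    on_chr = prof[prof["chromosome"] == chrom].reset_index()
    pj = int(on_chr.index[on_chr["marker_id"] == peak_marker][0])
    peak_lod = float(on_chr.loc[pj, statistic])
    lo = hi = pj
    while lo > 0 and float(on_chr.loc[lo - 1, statistic]) >= peak_lod - drop:
        lo -= 1
    while hi < len(on_chr) - 1 and float(on_chr.loc[hi + 1, statistic]) >= peak_lod - drop:
        hi += 1
    return float(on_chr.loc[lo, "position_cM"]), float(on_chr.loc[hi, "position_cM"])


def _merge_markers(marked: pd.DataFrame, merge_window_cM: float) -> list[pd.DataFrame]:
    """Chain-merge significant markers per chromosome into locus groups."""
    groups = []
    for _, sub in marked.groupby("chromosome"):
        sub = sub.sort_values("position_cM", kind="stable")
        positions = sub["position_cM"].unique()
        start = positions[0]
        current = [start]
        for pos in positions[1:]:
            if pos - current[-1] <= merge_window_cM:
                current.append(pos)
            else:
                groups.append(sub[sub["position_cM"].isin(current)])
                current = [pos]
        groups.append(sub[sub["position_cM"].isin(current)])
    return groups


def name_qtl(records: list[QTLRecord]) -> list[QTLRecord]:
    """Assign Mc names: per chromosome, ``.1, .2, ...`` in cM order."""
    by_chrom: dict[int, list[QTLRecord]] = {}
    for rec in records:
        by_chrom.setdefault(rec.chromosome, []).append(rec)
    for chrom, recs in by_chrom.items():
        for k, rec in enumerate(sorted(recs, key=lambda r: r.peak_cM), start=1):
            rec.name = f"Mc{chrom}.{k}"
    return records


def call_qtl(
    scan: ScanResult,
    thresholds: ThresholdSet,
    merge_window_cM: float = 20.0,
    ci_drop: float = 1.0,
) -> list[QTLRecord]:
    """Call, merge, annotate and name QTL from a scan.

    A (trait, marker) pair is genome-wide significant when any statistic
    reaches its trait-specific threshold.  Significant markers on the same
    chromosome within ``merge_window_cM`` collapse into one locus whose peak
    is the marker carrying the largest significant statistic (ties break to
    the smaller cM).  Other traits are attached at the peak when any of
    their LODs reaches the pointwise threshold.
    """
    tab = scan.table[scan.table["status"] == "ok"].copy()
    if tab.empty:
        return []
    sig_any = np.zeros(len(tab), dtype=bool)
    best_sig = np.full(len(tab), -np.inf)
    for s in STATISTICS:
        thr = tab["trait"].map({t: d[s] for t, d in thresholds.genomewide.items()})
        hit = tab[s].to_numpy() >= thr.to_numpy(float)
        sig_any |= hit
        best_sig = np.where(hit, np.maximum(best_sig, tab[s].to_numpy()), best_sig)
    tab["_sig"] = sig_any
    tab["_best"] = best_sig
    marked = tab[tab["_sig"]]
    if marked.empty:
        return []

    records = []
    for grp in _merge_markers(marked, merge_window_cM):
        # peak: largest significant statistic, ties to smaller cM
        grp = grp.sort_values(["_best", "position_cM"], ascending=[False, True])
        peak = grp.iloc[0]
        peak_marker = peak["marker_id"]
        primary_trait = peak["trait"]
        peak_stat = max(STATISTICS, key=lambda s: _sig_value(peak, s, thresholds))
        at_peak = tab[tab["marker_id"] == peak_marker]
        effects = []
        gw_traits = set(grp["trait"])
        for _, row in at_peak.iterrows():
            flags: dict[str, str | None] = {}
            for s in STATISTICS:
                thr = thresholds.genomewide[row["trait"]][s]
                if row[s] >= thr and row["trait"] in gw_traits and bool(row["_sig"]):
                    flags[s] = "genomewide"
                elif row[s] >= thresholds.pointwise_lod:
                    flags[s] = "pointwise"
                else:
                    flags[s] = None
            if any(v is not None for v in flags.values()):
                effects.append(
                    TraitEffect(
                        trait=row["trait"],
                        a=float(row["a"]),
                        d=float(row["d"]),
                        i=float(row["i"]),
                        lods={s: float(row[s]) for s in STATISTICS},
                        flags=flags,
                    )
                )
        # primary trait first
        effects.sort(key=lambda e: (e.trait != primary_trait, -max(e.lods.values())))
        ci = support_interval(scan, primary_trait, peak_marker, statistic=peak_stat, drop=ci_drop)
        records.append(
            QTLRecord(
                name="",
                chromosome=int(peak["chromosome"]),
                peak_marker=str(peak_marker),
                peak_cM=float(peak["position_cM"]),
                peak_Mb=float(peak.get("position_Mb", np.nan)),
                support_interval_cM=ci,
                trait_effects=effects,
                primary_trait=str(primary_trait),
            )
        )
    return name_qtl(sorted(records, key=lambda r: (r.chromosome, r.peak_cM)))


def _sig_value(row: pd.Series, statistic: str, thresholds: ThresholdSet) -> float:
    thr = thresholds.genomewide[row["trait"]][statistic]
    v = float(row[statistic])
    return v if v >= thr else -np.inf
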