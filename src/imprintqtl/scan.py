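"""Per-marker mixed-model fitting and whole-genome LOD scans.

At every marker the model ``y = r + a x_a + d x_d + i x_i + u_family + eps``
is fitted to the covariate-adjusted trait.  Four LOD scores are reported:

* ``mLOD`` — joint test of all three genotypic effects,
* ``aLOD``/``dLOD``/``iLOD`` — single-effect tests dropping one index column.

Likelihood-ratio contrasts use maximum-likelihood fits (REML likelihoods are
not comparable across different fixed-effect structures); the variance
components and effect standard errors reported per locus come from the REML
fit of the full model.  Individuals missing the ordered genotype at a marker
are dropped for that marker only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .adi_model import EffectIndexMatrix, GenotypicEffects
from .lmm import fit_lmm, lod_contrast
from .synthetic_data import GeneticMap

logger = logging.getLogger(__name__)

STATISTICS = ("mLOD", "aLOD", "dLOD", "iLOD")

SCAN_COLUMNS = [
    "trait",
    "marker_id",
    "chromosome",
    "position_cM",
    "position_Mb",
    "n_used",
    "a",
    "d",
    "i",
    "se_a",
    "se_d",
    "se_i",
    "mLOD",
    "aLOD",
    "dLOD",
    "iLOD",
    "sigma2_family",
    "sigma2_residual",
    "status",
]


@dataclass
class LocusFit:
    """Effect estimates and LOD scores of one trait at one marker."""

    marker_id: str
    trait: str
    n_used: int
    estimates: GenotypicEffects
    mLOD: float
    aLOD: float
    dLOD: float
    iLOD: float
    family_variance: float
    residual_variance: float
    status: str = "ok"  # ok | skipped | failed

    def lod(self, statistic: str) -> float:
        return getattr(self, statistic)


@dataclass
class ScanResult:
    """Map-ordered locus fits for each scanned trait plus run metadata."""

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def traits(self) -> list[str]:
        return list(dict.fromkeys(self.table["trait"]))

    def profile(self, trait: str) -> pd.DataFrame:
        return self.table[self.table["trait"] == trait].reset_index(drop=True)

    def at(self, trait: str, marker_id: str) -> pd.Series:
        sub = self.table[(self.table["trait"] == trait) & (self.table["marker_id"] == marker_id)]
        if sub.empty:
            raise KeyError(f"no scan row for trait {trait!r} at {marker_id!r}")
        return sub.iloc[0]


def _zero_fit(marker_id: str, trait: str, n: int, status: str = "ok") -> LocusFit:
    return LocusFit(
        marker_id=marker_id,
        trait=trait,
        n_used=n,
        estimates=GenotypicEffects(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
        mLOD=0.0,
        aLOD=0.0,
        dLOD=0.0,
        iLOD=0.0,
        family_variance=0.0,
        residual_variance=0.0,
        status=status,
    )


def fit_locus(
    y: np.ndarray,
    x_a: np.ndarray,
    x_d: np.ndarray,
    x_i: np.ndarray,
    family_ids: np.ndarray,
    marker_id: str = "",
    trait: str = "",
    min_per_class: int = 1,
    compute_reml: bool = True,
) -> LocusFit:
    """Fit the a/d/i mixed model at one marker.

    Rows with a missing phenotype or missing index scores are dropped.  If
    any ordered class has fewer than ``min_per_class`` individuals the
    marker is skipped for this trait.  With a single family the family
    variance is not identifiable and is constrained to zero, making every
    LOD identical to its ordinary-least-squares counterpart.
    """
    y = np.asarray(y, float)
    ok = np.isfinite(y) & np.isfinite(x_a) & np.isfinite(x_d) & np.isfinite(x_i)
    y, xa, xd, xi = y[ok], x_a[ok], x_d[ok], x_i[ok]
    fam = np.asarray(family_ids)[ok]
    n = len(y)
    counts = {
        "AA": int(np.sum(xa == 1)),
        "AB": int(np.sum(xi == 1)),
        "BA": int(np.sum(xi == -1)),
        "BB": int(np.sum(xa == -1)),
    }
    if n == 0 or min(counts.values()) < min_per_class:
        return _zero_fit(marker_id, trait, n, status="skipped")
    if np.ptp(y) == 0.0:
        return _zero_fit(marker_id, trait, n)

    X_full = np.column_stack([np.ones(n), xa, xd, xi])
    try:
        full_ml = fit_lmm(X_full, y, fam, method="ml")
        lods = {}
        drops = {"mLOD": [1, 2, 3], "aLOD": [1], "dLOD": [2], "iLOD": [3]}
        for stat, cols in drops.items():
            keep = [c for c in range(4) if c not in cols]
            red = fit_lmm(X_full[:, keep], y, fam, method="ml")
            lods[stat] = lod_contrast(full_ml.loglik, red.loglik)
        if compute_reml:
            reml = fit_lmm(X_full, y, fam, method="reml")
        else:
            reml = full_ml
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate design
        logger.warning("locus fit failed at %s/%s: %s", trait, marker_id, exc)
        return _zero_fit(marker_id, trait, n, status="failed")

    se = reml.se_beta
    est = GenotypicEffects(
        r=float(reml.beta[0]),
        a=float(reml.beta[1]),
        d=float(reml.beta[2]),
        i=float(reml.beta[3]),
        se_a=float(se[1]),
        se_d=float(se[2]),
        se_i=float(se[3]),
    )
    return LocusFit(
        marker_id=marker_id,
        trait=trait,
        n_used=n,
        estimates=est,
        mLOD=lods["mLOD"],
        aLOD=lods["aLOD"],
        dLOD=lods["dLOD"],
        iLOD=lods["iLOD"],
        family_variance=reml.sigma2_f,
        residual_variance=reml.sigma2_e,
    )


def genome_scan(
    phenotypes: pd.DataFrame,
    indices: EffectIndexMatrix,
    genetic_map: GeneticMap,
    traits: list[str] | None = None,
    min_per_class: int = 5,
    compute_reml: bool = True,
    metadata: dict | None = None,
) -> ScanResult:
    """Scan every marker of the map for every trait.

    ``phenotypes`` must carry ``id`` and ``family_id`` columns plus one
    column per trait (already covariate-adjusted).  Rows are matched to the
    index matrix by ``id``; per-locus failures are recorded in the
    ``status`` column and never abort the scan.
    """
    if traits is None:
        reserved = {"id", "sex", "grandmaternal_line", "family_id", "analyzable"}
        traits = [
            c
            for c in phenotypes.columns
            if c not in reserved and pd.api.types.is_numeric_dtype(phenotypes[c])
        ]
    id_to_row = {i: k for k, i in enumerate(indices.ids)}
    try:
        rows = np.array([id_to_row[i] for i in phenotypes["id"]])
    except KeyError as exc:
        raise KeyError(f"phenotyped individual {exc} absent from genotype matrix") from None
    fam = phenotypes["family_id"].to_numpy()
    xa, xd, xi = indices.x_a[rows], indices.x_d[rows], indices.x_i[rows]

    records = []
    mtab = genetic_map.table
    n_skipped = 0
    for trait in traits:
        y = phenotypes[trait].to_numpy(float)
        for j, mrow in mtab.iterrows():
            mk = mrow["marker_id"]
            col = indices._marker_index[mk]
            fit = fit_locus(
                y,
                xa[:, col],
                xd[:, col],
                xi[:, col],
                fam,
                marker_id=mk,
                trait=trait,
                min_per_class=min_per_class,
                compute_reml=compute_reml,
            )
            if fit.status != "ok":
                n_skipped += 1
            e = fit.estimates
            records.append(
                (
                    trait,
                    mk,
                    int(mrow["chromosome"]),
                    float(mrow["position_cM"]),
                    float(mrow["position_Mb"]),
                    fit.n_used,
                    e.a,
                    e.d,
                    e.i,
                    e.se_a,
                    e.se_d,
                    e.se_i,
                    fit.mLOD,
                    fit.aLOD,
                    fit.dLOD,
                    fit.iLOD,
                    fit.family_variance,
                    fit.residual_variance,
                    fit.status,
                )
            )
    if n_skipped:
        logger.info("genome scan skipped %d (trait, marker) fits", n_skipped)
    table = pd.DataFrame.from_records(records, columns=SCAN_COLUMNS)
    meta = {
        "traits": traits,
        "min_per_class": min_per_class,
        "lod_likelihood": "ml",
        "variance_components": "reml" if compute_reml else "ml",
        "n_skipped": n_skipped,
    }
    if metadata:
        meta.update(metadata)
    return ScanResult(table=table, metadata=meta)
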