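"""Orthogonal additive/dominance/imprinting (a/d/i) genotypic model.

Parent-of-origin analysis distinguishes the four *ordered* genotypes at a
biallelic locus, written ``AA, AB, BA, BB`` with the paternally inherited
allele first.  Each ordered class is assigned three index scores

====== ===== ===== =====
class  x_a   x_d   x_i
====== ===== ===== =====
AA      +1    0     0
AB       0    1    +1
BA       0    1    -1
BB      -1    0     0
====== ===== ===== =====

so that a linear model ``y = r + a*x_a + d*x_d + i*x_i`` reproduces the four
class means with

* ``r`` — the reference point (midpoint of the homozygotes),
* ``a`` — the additive value, half the homozygote difference,
* ``d`` — the dominance value, heterozygote mean minus homozygote midpoint,
* ``i`` — the imprinting value, half the difference between the reciprocal
  heterozygotes (AB vs BA); non-zero ``i`` is the phenotypic signature of a
  parent-of-origin effect.

In a sample with balanced ordered-class counts the three index columns are
mutually orthogonal (after centring), which is what lets the percent variance
explained by the three effect types be computed separately and summed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Ordered genotype codes in canonical order (paternal allele first).
ORDERED_CLASSES = ("AA", "AB", "BA", "BB")

#: Index scores (x_a, x_d, x_i) per ordered class.
ADI_SCORES: dict[str, tuple[int, int, int]] = {
    "AA": (1, 0, 0),
    "AB": (0, 1, 1),
    "BA": (0, 1, -1),
    "BB": (-1, 0, 0),
}

#: Integer genotype coding used in matrices: allele 0 = A, 1 = B, -1 missing.
_CLASS_FROM_PAIR = {(0, 0): "AA", (0, 1): "AB", (1, 0): "BA", (1, 1): "BB"}


def encode_adi(ordered_class: str | None) -> tuple[float, float, float]:
    """Return the (x_a, x_d, x_i) index scores for one ordered genotype.

    Parameters
    ----------
    ordered_class
        One of ``"AA", "AB", "BA", "BB"``, or ``None``/``"NA"`` for a
        missing genotype.

    Returns
    -------
    tuple of float
        The three index scores; ``(nan, nan, nan)`` when missing.
    """
    if ordered_class is None or ordered_class == "NA":
        return (np.nan, np.nan, np.nan)
    try:
        return tuple(float(v) for v in ADI_SCORES[ordered_class])
    except KeyError:
        raise ValueError(
            f"unknown ordered genotype class {ordered_class!r}; "
            f"expected one of {ORDERED_CLASSES}"
        ) from None


@dataclass
class GenotypicEffects:
    """Genotypic values of a locus in trait units.

    ``se_a/se_d/se_i`` are standard errors when the effects come from a model
    fit; they stay ``None`` for exact algebraic decompositions.
    """

    r: float
    a: float
    d: float
    i: float
    se_a: float | None = None
    se_d: float | None = None
    se_i: float | None = None

    def class_means(self) -> dict[str, float]:
        """Reconstruct the four ordered-class means implied by (r, a, d, i)."""
        return {
            "AA": self.r + self.a,
            "AB": self.r + self.d + self.i,
            "BA": self.r + self.d - self.i,
            "BB": self.r - self.a,
        }


def genotypic_values_from_means(
    m_aa: float, m_ab: float, m_ba: float, m_bb: float
) -> GenotypicEffects:
    """Solve the four ordered-class means for (r, a, d, i).

    The map is a bijection: ``r = (AA+BB)/2``, ``a = (AA-BB)/2``,
    ``d = (AB+BA)/2 - (AA+BB)/2`` and ``i = (AB-BA)/2``, so
    :meth:`GenotypicEffects.class_means` is its exact inverse.
    """
    r = (m_aa + m_bb) / 2.0
    a = (m_aa - m_bb) / 2.0
    d = (m_ab + m_ba) / 2.0 - (m_aa + m_bb) / 2.0
    i = (m_ab - m_ba) / 2.0
    return GenotypicEffects(r=r, a=a, d=d, i=i)


@dataclass
class EffectIndexMatrix:
    """Per-individual, per-marker a/d/i index scores.

    Arrays are ``n_individuals x n_markers`` floats with NaN where the
    ordered genotype is missing.
    """

    ids: list[str]
    marker_ids: list[str]
    x_a: np.ndarray
    x_d: np.ndarray
    x_i: np.ndarray

    def __post_init__(self) -> None:
        n, m = len(self.ids), len(self.marker_ids)
        for arr in (self.x_a, self.x_d, self.x_i):
            if arr.shape != (n, m):
                raise ValueError("index arrays must be n_individuals x n_markers")
        self._marker_index = {mk: j for j, mk in enumerate(self.marker_ids)}

    @classmethod
    def from_ordered(cls, genotypes) -> "EffectIndexMatrix":
        """Encode an :class:`~imprintqtl.synthetic_data.OrderedGenotypeMatrix`."""
        pat = genotypes.paternal
        mat = genotypes.maternal
        missing = (pat < 0) | (mat < 0)
        # x_a: +1 for AA, -1 for BB; x_d: 1 for either heterozygote;
        # x_i: +1 for AB (paternal A), -1 for BA.
        x_a = np.where(pat == mat, 1.0 - 2.0 * pat, 0.0)
        x_d = np.where(pat != mat, 1.0, 0.0)
        x_i = np.where(pat != mat, 1.0 - 2.0 * pat, 0.0)
        for arr in (x_a, x_d, x_i):
            arr[missing] = np.nan
        return cls(
            ids=list(genotypes.ids),
            marker_ids=list(genotypes.marker_ids),
            x_a=x_a,
            x_d=x_d,
            x_i=x_i,
        )

    def at_marker(self, marker_id: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return the three index columns for one marker."""
        j = self._marker_index[marker_id]
        return self.x_a[:, j], self.x_d[:, j], self.x_i[:, j]


def adjust_phenotypes(
    pheno: pd.DataFrame,
    trait_columns: list[str] | None = None,
    covariates: tuple[str, ...] = ("sex", "grandmaternal_line"),
) -> pd.DataFrame:
    """Remove fixed covariate effects (sex, direction of cross) from traits.

    Each trait column is replaced by the residuals of an ordinary
    least-squares fit on indicator variables for the covariates, re-centred
    at the original grand mean so effect estimates keep their trait units.
    A covariate with a single observed level carries no information and is
    skipped with a warning.

    Parameters
    ----------
    pheno
        Phenotype table with one row per individual; must contain the
        covariate columns.
    trait_columns
        Trait columns to adjust.  Defaults to every numeric column that is
        not a covariate or one of the bookkeeping columns
        (``id``, ``family_id``, ``analyzable``).

    Returns
    -------
    pandas.DataFrame
        Copy of ``pheno`` with adjusted trait columns.
    """
    out = pheno.copy()
    reserved = {"id", "family_id", "analyzable", *covariates}
    if trait_columns is None:
        trait_columns = [
            c
            for c in pheno.columns
            if c not in reserved and pd.api.types.is_numeric_dtype(pheno[c])
        ]
    usable = []
    for cov in covariates:
        if cov not in pheno.columns:
            raise KeyError(f"covariate column {cov!r} missing from phenotype table")
        if pheno[cov].nunique(dropna=True) < 2:
            warnings.warn(
                f"covariate {cov!r} has a single level; skipped in adjustment",
                stacklevel=2,
            )
            logger.warning("covariate %r has a single level; skipped", cov)
            continue
        usable.append(cov)
    if not usable:
        return out
    X = pd.get_dummies(pheno[usable].astype(str), drop_first=True).to_numpy(float)
    X = np.column_stack([np.ones(len(pheno)), X])
    for trait in trait_columns:
        y = pheno[trait].to_numpy(float)
        ok = np.isfinite(y)
        beta, *_ = np.linalg.lstsq(X[ok], y[ok], rcond=None)
        resid = y.copy()
        resid[ok] = y[ok] - X[ok] @ beta + y[ok].mean()
        out[trait] = resid
    return out


def r2_effect(value: float, effect_type: str, vp: float) -> float:
    """Percent phenotypic variance explained by a single genotypic effect.

    With balanced ordered-class frequencies (1/4 each) the index-score
    variances are Var(x_a) = Var(x_i) = 1/2 and Var(x_d) = 1/4, hence

    * additive:   (a^2 / 2) / Vp * 100
    * dominance:  (d^2 / 4) / Vp * 100
    * imprinting: (i^2 / 2) / Vp * 100

    Parameters
    ----------
    value
        Effect estimate in trait units.
    effect_type
        One of ``"a"``, ``"d"``, ``"i"``.
    vp
        Phenotypic variance of the (adjusted) trait; must be positive.
    """
    if vp <= 0:
        raise ValueError(f"phenotypic variance must be positive, got {vp}")
    coeff = {"a": 0.5, "d": 0.25, "i": 0.5}
    try:
        c = coeff[effect_type]
    except KeyError:
        raise ValueError(f"effect_type must be one of 'a', 'd', 'i', got {effect_type!r}") from None
    return c * value**2 / vp * 100.0


def total_r2(components: list[float] | tuple[float, ...]) -> float:
    """Sum percent-variance components of an orthogonal decomposition.

    Orthogonality of the a/d/i index columns is what justifies plain
    addition of the per-effect percentages.
    """
    comps = [float(c) for c in components]
    if any(c < 0 for c in comps):
        raise ValueError("variance components must be non-negative")
    return float(sum(comps))
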