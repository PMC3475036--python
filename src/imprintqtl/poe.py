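"""Parent-of-origin effect patterns and the imprinting vs maternal-effect test.

A significant imprinting contrast (AB vs BA heterozygotes differing) can
arise from two very different mechanisms:

* **genomic imprinting** — parent-of-origin-dependent expression of the
  locus in the offspring itself, and
* **maternal genetic effects** — the dam's genotype shaping the offspring
  environment, which produces the same reciprocal-heterozygote signature
  because a heterozygous offspring's maternal allele is correlated with its
  mother's genotype.

The two are separated by asking whether the apparent imprinting effect
differs between offspring reared by homozygous versus heterozygous mothers:
under true imprinting it does not; under a maternal effect the contrast is
carried entirely by the hom-mother offspring (whose maternal allele is
fixed by the dam) and vanishes among het-mother offspring.

Pattern taxonomy at loci with a significant imprinting effect:

* ``paternal_expression`` — phenotype tracks the paternal allele
  (``i = a``, ``d = 0``),
* ``maternal_expression`` — tracks the maternal allele (``i = -a``,
  ``d = 0``),
* ``bipolar`` — the heterozygotes differ but the homozygotes do not
  (``i`` without ``a``),
* ``other`` — anything else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .adi_model import GenotypicEffects
from .lmm import fit_lmm

PATTERNS = ("paternal_expression", "maternal_expression", "bipolar", "other")


@dataclass
class PatternCall:
    pattern: str
    evidence: dict = field(default_factory=dict)


@dataclass
class MaternalTestResult:
    """Outcome of the imprinting-vs-maternal-genetic-effect contrast."""

    interaction_estimate: float
    p_value: float
    verdict: str  # imprinting | maternal_effect | inconclusive
    n_by_mother_class: dict[str, int] = field(default_factory=dict)


def classify_pattern(
    effects: GenotypicEffects,
    a_significant: bool,
    d_significant: bool,
    i_significant: bool,
    ratio_tol: float = 2.0,
) -> PatternCall:
    """Classify the expression pattern at a parent-of-origin locus.

    Only meaningful where the imprinting effect is significant (error
    otherwise).  Parental expression requires a matching additive effect —
    pure paternal expression forces ``i = a`` and ``d = 0``, maternal
    expression ``i = -a`` — and is accepted when ``|i/a|`` lies within
    ``[1/ratio_tol, ratio_tol]``.  A significant ``i`` without a significant
    ``a`` is the bipolar pattern.
    """
    if not i_significant:
        raise ValueError("pattern classification requires a significant imprinting effect")
    ratio = effects.i / effects.a if effects.a != 0 else np.inf
    evidence = {
        "a_significant": a_significant,
        "d_significant": d_significant,
        "i_significant": i_significant,
        "i_over_a_ratio": float(ratio) if np.isfinite(ratio) else None,
    }
    if not a_significant:
        return PatternCall("bipolar", evidence)
    if (
        not d_significant
        and effects.a != 0
        and 1.0 / ratio_tol <= abs(ratio) <= ratio_tol
    ):
        if np.sign(effects.i) == np.sign(effects.a):
            return PatternCall("paternal_expression", evidence)
        return PatternCall("maternal_expression", evidence)
    return PatternCall("other", evidence)


def maternal_vs_imprinting(
    y: np.ndarray,
    x_a: np.ndarray,
    x_d: np.ndarray,
    x_i: np.ndarray,
    dam_b_count: np.ndarray,
    family_ids: np.ndarray,
    alpha: float = 0.05,
    min_n: int = 5,
) -> MaternalTestResult:
    """Test whether a parent-of-origin effect reflects the dam's genotype.

    Fits the locus mixed model augmented with a mother-class indicator
    (heterozygous vs homozygous dam at the locus) and its interaction with
    the imprinting score ``x_i``; the p-value is the 1-df likelihood-ratio
    test of the interaction.  A significant interaction means the apparent
    imprinting contrast depends on the mother's genotype and is attributed
    to a maternal genetic effect; otherwise the verdict is imprinting.  The
    test is inconclusive when either mother class contributes fewer than
    ``min_n`` informative (heterozygous) offspring.

    Parameters
    ----------
    dam_b_count
        The dam's unordered B-allele dosage at the locus (0, 1 or 2) per
        offspring; negative or NaN marks a missing maternal genotype.
    """
    y = np.asarray(y, float)
    dam = np.asarray(dam_b_count, float)
    ok = (
        np.isfinite(y)
        & np.isfinite(x_a)
        & np.isfinite(x_d)
        & np.isfinite(x_i)
        & np.isfinite(dam)
        & (dam >= 0)
    )
    y, xa, xd, xi, dam = y[ok], x_a[ok], x_d[ok], x_i[ok], dam[ok]
    fam = np.asarray(family_ids)[ok]
    het_off = xd == 1
    if not het_off.any():
        raise ValueError("no heterozygous offspring: the parent-of-origin contrast is undefined")
    mother_het = (dam == 1).astype(float)
    n_info = {
        "het_mother": int(np.sum(het_off & (mother_het == 1))),
        "hom_mother": int(np.sum(het_off & (mother_het == 0))),
    }
    if min(n_info.values()) < min_n:
        return MaternalTestResult(
            interaction_estimate=float("nan"),
            p_value=float("nan"),
            verdict="inconclusive",
            n_by_mother_class=n_info,
        )
    n = len(y)
    X_full = np.column_stack([np.ones(n), xa, xd, xi, mother_het, xi * mother_het])
    X_red = X_full[:, :-1]
    full = fit_lmm(X_full, y, fam, method="ml")
    red = fit_lmm(X_red, y, fam, method="ml")
    lr = max(2.0 * (full.loglik - red.loglik), 0.0)
    p = float(stats.chi2.sf(lr, df=1))
    verdict = "maternal_effect" if p < alpha else "imprinting"
    return MaternalTestResult(
        interaction_estimate=float(full.beta[-1]),
        p_value=p,
        verdict=verdict,
        n_by_mother_class=n_info,
    )
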