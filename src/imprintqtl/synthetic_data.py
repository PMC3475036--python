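"""Simulation of a two-line reciprocal F0→F3 mouse cross.

The generator emulates the study design the analysis modules assume: two
inbred founder lines (allele ``A`` and allele ``B``), reciprocal F0 matings,
an F1 generation, 94 F2 animals from reciprocal F1 pairs, and 345 F3 animals
from random non-sibling F2 matings of which 331 are flagged analyzable
(emulating genotyping drop-out).  Genotypes are *ordered* — stored as
(paternal allele, maternal allele) — which is the substrate of every
parent-of-origin analysis downstream.

Transmission uses the Haldane map function with no crossover interference:
the recombination fraction between adjacent markers ``d`` cM apart is
``r = (1 - exp(-2d/100)) / 2``, independent across intervals.

Phenotypes follow the generative counterpart of the orthogonal a/d/i model:

``y = grand_mean + sex_effect*[male] + cross_direction_effect*[grandmaternal
line B] + sum_q (a_q x_a + d_q x_d + i_q x_i) + u_family + m * (# B alleles
in the dam's genotype at the maternal-effect locus) + eps``

with ``u_family ~ N(0, family_sd^2)`` shared by full sibs and independent
``eps ~ N(0, residual_sd^2)``.  The maternal term is the one confounder the
discrimination test must separate from true imprinting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .adi_model import EffectIndexMatrix

N_AUTOSOMES = 19

# --------------------------------------------------------------------------
# genetic map
# --------------------------------------------------------------------------


@dataclass
class GeneticMap:
    """Ordered marker map over the autosomes.

    ``table`` has columns ``marker_id, chromosome, position_cM, position_Mb``
    sorted by chromosome then cM; positions are strictly increasing within a
    chromosome and marker ids are unique.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        req = ["marker_id", "chromosome", "position_cM", "position_Mb"]
        missing = [c for c in req if c not in self.table.columns]
        if missing:
            raise ValueError(f"map table lacks columns {missing}")
        t = self.table.reset_index(drop=True)
        if t["marker_id"].duplicated().any():
            raise ValueError("duplicate marker ids in map")
        for _, grp in t.groupby("chromosome"):
            if not (np.diff(grp["position_cM"]) > 0).all() or not (
                np.diff(grp["position_Mb"]) > 0
            ).all():
                raise ValueError("marker positions must strictly increase within a chromosome")
        self.table = t

    @property
    def marker_ids(self) -> list[str]:
        return list(self.table["marker_id"])

    @property
    def n_markers(self) -> int:
        return len(self.table)

    def chromosomes(self) -> list[int]:
        return sorted(self.table["chromosome"].unique())

    def chromosome_slice(self, chromosome: int) -> pd.DataFrame:
        sub = self.table[self.table["chromosome"] == chromosome]
        if sub.empty:
            raise KeyError(f"chromosome {chromosome} absent from map")
        return sub

    def nearest_marker(self, chromosome: int, position_cM: float) -> str:
        """Marker on ``chromosome`` closest in cM to ``position_cM``."""
        sub = self.chromosome_slice(chromosome)
        j = (sub["position_cM"] - position_cM).abs().idxmin()
        return str(sub.loc[j, "marker_id"])


def default_map(
    n_markers: int = 164,
    n_chromosomes: int = N_AUTOSOMES,
    spacing_cM: float = 5.0,
    mb_per_cM: float = 2.0,
) -> GeneticMap:
    """Default autosomal map: 164 markers, ~5 cM spacing, nominal Mb = 2 cM.

    Markers are spread over the autosomes as evenly as integer counts allow
    (larger chromosomes first), mirroring the density of an informative-SNP
    panel in a two-line cross without copying any real marker list.
    """
    base, extra = divmod(n_markers, n_chromosomes)
    rows = []
    for chrom in range(1, n_chromosomes + 1):
        k = base + (1 if chrom <= extra else 0)
        for j in range(k):
            cm = j * spacing_cM
            rows.append(
                {
                    "marker_id": f"m{chrom:02d}_{j + 1:02d}",
                    "chromosome": chrom,
                    "position_cM": cm,
                    "position_Mb": cm * mb_per_cM,
                }
            )
    return GeneticMap(pd.DataFrame(rows))


# --------------------------------------------------------------------------
# pedigree
# --------------------------------------------------------------------------


@dataclass
class Individual:
    id: str
    sire_id: str | None
    dam_id: str | None
    sex: str  # "M" or "F"
    generation: str  # F0..F3
    founder_line: str | None  # "A"/"B" for F0 only
    grandmaternal_line: str  # matrilineal cross-direction label
    analyzable: bool = True


class Pedigree:
    """Topologically ordered pedigree (parents always precede offspring)."""

    def __init__(self, individuals: list[Individual]):
        self.individuals = list(individuals)
        self._by_id = {ind.id: ind for ind in self.individuals}
        if len(self._by_id) != len(self.individuals):
            raise ValueError("duplicate individual ids in pedigree")
        seen: set[str] = set()
        for ind in self.individuals:
            if ind.generation == "F0":
                if ind.sire_id is not None or ind.dam_id is not None:
                    raise ValueError(f"founder {ind.id} must have no parents")
                if ind.founder_line not in ("A", "B"):
                    raise ValueError(f"founder {ind.id} needs a founder line")
            else:
                if ind.sire_id is None or ind.dam_id is None:
                    raise ValueError(f"non-founder {ind.id} must have both parents")
                if ind.sire_id not in seen or ind.dam_id not in seen:
                    raise ValueError(f"pedigree not topologically ordered at {ind.id}")
                if self._by_id[ind.sire_id].sex != "M" or self._by_id[ind.dam_id].sex != "F":
                    raise ValueError(f"sire/dam sexes inconsistent for {ind.id}")
            seen.add(ind.id)

    def __len__(self) -> int:
        return len(self.individuals)

    def __getitem__(self, ind_id: str) -> Individual:
        return self._by_id[ind_id]

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    def generation(self, gen: str) -> list[Individual]:
        return [ind for ind in self.individuals if ind.generation == gen]

    def family_id(self, ind_id: str) -> str | None:
        """Identifier of the sire-dam pair that produced an individual."""
        ind = self._by_id[ind_id]
        if ind.sire_id is None:
            return None
        return f"{ind.sire_id}x{ind.dam_id}"

    def matings(self) -> list[tuple[str, str, str]]:
        """Distinct (sire, dam, offspring-generation) triples."""
        seen = {}
        for ind in self.individuals:
            if ind.sire_id is not None:
                seen[(ind.sire_id, ind.dam_id)] = ind.generation
        return [(s, d, g) for (s, d), g in seen.items()]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [i.id for i in self.individuals],
                "sire": [i.sire_id or "" for i in self.individuals],
                "dam": [i.dam_id or "" for i in self.individuals],
                "sex": [i.sex for i in self.individuals],
                "generation": [i.generation for i in self.individuals],
                "founder_line": [i.founder_line or "" for i in self.individuals],
                "grandmaternal_line": [i.grandmaternal_line for i in self.individuals],
                "analyzable": [i.analyzable for i in self.individuals],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Pedigree":
        inds = [
            Individual(
                id=str(r["id"]),
                sire_id=str(r["sire"]) or None if str(r["sire"]) != "" else None,
                dam_id=str(r["dam"]) or None if str(r["dam"]) != "" else None,
                sex=str(r["sex"]),
                generation=str(r["generation"]),
                founder_line=str(r["founder_line"]) or None,
                grandmaternal_line=str(r["grandmaternal_line"]),
                analyzable=bool(r["analyzable"]),
            )
            for _, r in frame.iterrows()
        ]
        return cls(inds)


@dataclass
class CrossConfig:
    """Sizes and mating structure of the simulated cross.

    Defaults reproduce the study design: two reciprocal F0 pairs, two
    reciprocal F1 pairs, 94 F2, 345 F3 of which 331 analyzable.
    """

    n_f2: int = 94
    n_f3: int = 345
    n_f3_analyzable: int = 331
    n_f1_pairs: int = 2
    f1_per_mating: int = 2  # one male + one female per reciprocal F0 mating

    def __post_init__(self) -> None:
        if min(self.n_f2, self.n_f3, self.n_f1_pairs) < 0:
            raise ValueError("cross sizes must be non-negative")
        if not 0 <= self.n_f3_analyzable <= self.n_f3:
            raise ValueError("n_f3_analyzable must lie in [0, n_f3]")


def simulate_pedigree(config: CrossConfig | None = None, seed: int = 0) -> Pedigree:
    """Simulate the F0→F3 pedigree of a reciprocal two-line cross.

    Two reciprocal F0 matings (line-A sire x line-B dam, and the reverse)
    each produce one male and one female F1; reciprocal F1 couples produce
    the F2; F3 families come from random non-sibling F2 pairings (falling
    back to any distinct opposite-sex pair when no non-sibling pair exists).
    The matrilineal ``grandmaternal_line`` label records the direction of
    cross each animal descends from.

    Deterministic given ``config`` and ``seed``.
    """
    config = config or CrossConfig()
    rng = np.random.default_rng(seed)
    inds: list[Individual] = []

    # founders: two pairs, one for each direction of cross
    f0 = {
        "A_m1": Individual("A_m1", None, None, "M", "F0", "A", "A"),
        "B_f1": Individual("B_f1", None, None, "F", "F0", "B", "B"),
        "B_m1": Individual("B_m1", None, None, "M", "F0", "B", "B"),
        "A_f1": Individual("A_f1", None, None, "F", "F0", "A", "A"),
    }
    inds.extend(f0.values())

    # F1: each reciprocal F0 mating yields one male and one female
    f1_matings = [("A_m1", "B_f1"), ("B_m1", "A_f1")]
    f1_males, f1_females = [], []
    for k, (sire, dam) in enumerate(f1_matings, start=1):
        gml = f0[dam].founder_line
        for j in range(config.f1_per_mating):
            sex = "M" if j % 2 == 0 else "F"
            ind = Individual(f"F1_{k}_{j + 1}", sire, dam, sex, "F1", None, gml)
            inds.append(ind)
            (f1_males if sex == "M" else f1_females).append(ind)

    if config.n_f2 > 0 and (not f1_males or not f1_females):
        raise ValueError("cannot produce F2: an F1 sex class is empty")

    # F2 from reciprocal F1 couples (male of one direction x female of the other)
    f2: list[Individual] = []
    if config.n_f2 > 0:
        pairs = []
        for k in range(config.n_f1_pairs):
            sire = f1_males[k % len(f1_males)]
            # prefer a female from the other cross direction
            others = [f for f in f1_females if f.grandmaternal_line != sire.grandmaternal_line]
            dam = (others or f1_females)[k % len(others or f1_females)]
            pairs.append((sire, dam))
        for j in range(config.n_f2):
            sire, dam = pairs[j % len(pairs)]
            sex = "M" if rng.random() < 0.5 else "F"
            ind = Individual(f"F2_{j + 1:03d}", sire.id, dam.id, sex, "F2", None, dam.grandmaternal_line)
            inds.append(ind)
            f2.append(ind)

    # F3 from random non-sibling F2 pairings
    if config.n_f3 > 0:
        males = [i for i in f2 if i.sex == "M"]
        females = [i for i in f2 if i.sex == "F"]
        if not males or not females:
            raise ValueError("cannot produce F3: an F2 sex class is empty")
        rng.shuffle(males)
        rng.shuffle(females)
        couples: list[tuple[Individual, Individual]] = []
        taken: set[str] = set()
        for m in males:
            non_sib = [
                f
                for f in females
                if f.id not in taken and (f.sire_id, f.dam_id) != (m.sire_id, m.dam_id)
            ]
            pool = non_sib or [f for f in females if f.id not in taken]
            if not pool:
                break
            f = pool[int(rng.integers(len(pool)))]
            taken.add(f.id)
            couples.append((m, f))
        analyzable = np.ones(config.n_f3, dtype=bool)
        if config.n_f3_analyzable < config.n_f3:
            drop = rng.choice(config.n_f3, size=config.n_f3 - config.n_f3_analyzable, replace=False)
            analyzable[drop] = False
        for j in range(config.n_f3):
            sire, dam = couples[j % len(couples)]
            sex = "M" if rng.random() < 0.5 else "F"
            inds.append(
                Individual(
                    f"F3_{j + 1:03d}",
                    sire.id,
                    dam.id,
                    sex,
                    "F3",
                    None,
                    dam.grandmaternal_line,
                    analyzable=bool(analyzable[j]),
                )
            )
    return Pedigree(inds)


# --------------------------------------------------------------------------
# genotypes
# --------------------------------------------------------------------------

_ORDERED_CODE = np.array(["AA", "AB", "BA", "BB"])


@dataclass
class OrderedGenotypeMatrix:
    """Per-individual, per-marker ordered genotypes.

    ``paternal`` and ``maternal`` are int8 arrays (0 = allele A, 1 = allele
    B, -1 = missing) of shape ``n_individuals x n_markers``.
    """

    ids: list[str]
    marker_ids: list[str]
    paternal: np.ndarray
    maternal: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(self.ids), len(self.marker_ids))
        if self.paternal.shape != shape or self.maternal.shape != shape:
            raise ValueError("genotype arrays must be n_individuals x n_markers")
        self._row = {i: k for k, i in enumerate(self.ids)}
        self._col = {m: k for k, m in enumerate(self.marker_ids)}

    def row(self, ind_id: str) -> int:
        return self._row[ind_id]

    def col(self, marker_id: str) -> int:
        return self._col[marker_id]

    def ordered_class(self, ind_id: str, marker_id: str) -> str | None:
        """Ordered class string at one cell, or None if missing."""
        r, c = self._row[ind_id], self._col[marker_id]
        p, m = int(self.paternal[r, c]), int(self.maternal[r, c])
        if p < 0 or m < 0:
            return None
        return str(_ORDERED_CODE[2 * p + m])

    def codes(self) -> pd.DataFrame:
        """Genotypes as an id-indexed frame of AA/AB/BA/BB/NA strings."""
        p, m = self.paternal, self.maternal
        flat = np.where((p >= 0) & (m >= 0), _ORDERED_CODE[2 * np.maximum(p, 0) + np.maximum(m, 0)], "NA")
        return pd.DataFrame(flat, index=self.ids, columns=self.marker_ids)

    def b_allele_count(self) -> np.ndarray:
        """Unordered B-allele dosage (0/1/2; -1 where missing)."""
        missing = (self.paternal < 0) | (self.maternal < 0)
        dose = (self.paternal + self.maternal).astype(np.int8)
        dose[missing] = -1
        return dose

    def effect_indices(self) -> EffectIndexMatrix:
        return EffectIndexMatrix.from_ordered(self)


@dataclass
class UnorderedGenotypeMatrix:
    """Unordered genotypes: 0 = hom A, 1 = het, 2 = hom B, -1 missing."""

    ids: list[str]
    marker_ids: list[str]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        if self.dosage.shape != (len(self.ids), len(self.marker_ids)):
            raise ValueError("dosage array must be n_individuals x n_markers")
        self._row = {i: k for k, i in enumerate(self.ids)}

    def row(self, ind_id: str) -> int:
        return self._row[ind_id]

    def codes(self) -> pd.DataFrame:
        sym = np.array(["A", "H", "B"])
        flat = np.where(self.dosage >= 0, sym[np.maximum(self.dosage, 0)], "NA")
        return pd.DataFrame(flat, index=self.ids, columns=self.marker_ids)


def unorder(genotypes: OrderedGenotypeMatrix) -> UnorderedGenotypeMatrix:
    """Collapse ordered genotypes to unordered dosages (AB and BA both het)."""
    return UnorderedGenotypeMatrix(
        ids=list(genotypes.ids),
        marker_ids=list(genotypes.marker_ids),
        dosage=genotypes.b_allele_count(),
    )


def haldane_recombination(d_cM: np.ndarray | float) -> np.ndarray | float:
    """Haldane map function: recombination fraction for a distance in cM."""
    return (1.0 - np.exp(-2.0 * np.asarray(d_cM) / 100.0)) / 2.0


def sample_gamete(
    paternal_hap: np.ndarray,
    maternal_hap: np.ndarray,
    rec_fractions: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one recombinant gamete from a parent's two haplotypes.

    ``rec_fractions[j]`` is the recombination probability between markers
    ``j`` and ``j+1`` (no interference).  The starting haplotype is chosen
    uniformly.
    """
    n = len(paternal_hap)
    state = np.empty(n, dtype=np.int8)
    start = int(rng.integers(2))
    if n > 1:
        switches = rng.random(n - 1) < rec_fractions
        state[0] = start
        state[1:] = (start + np.cumsum(switches)) % 2
    else:
        state[0] = start
    return np.where(state == 0, paternal_hap, maternal_hap).astype(np.int8)


def simulate_genotypes(
    pedigree: Pedigree, genetic_map: GeneticMap, seed: int = 0
) -> OrderedGenotypeMatrix:
    """Drop ordered genotypes through the pedigree by gametic transmission.

    Founders are homozygous for their line allele everywhere.  Every other
    individual receives one recombinant gamete from each parent (Haldane
    recombination fractions from the cM map, independent intervals), the
    sire's gamete becoming the paternal haplotype and the dam's the
    maternal.  Deterministic given inputs and ``seed``.
    """
    rng = np.random.default_rng(seed)
    ids = pedigree.ids
    markers = genetic_map.marker_ids
    n, m = len(ids), len(markers)
    pat = np.full((n, m), -1, dtype=np.int8)
    mat = np.full((n, m), -1, dtype=np.int8)
    row = {i: k for k, i in enumerate(ids)}

    # per-chromosome marker index blocks and recombination fractions
    blocks = []
    tab = genetic_map.table
    for chrom in genetic_map.chromosomes():
        idx = np.flatnonzero(tab["chromosome"].to_numpy() == chrom)
        d = np.diff(tab["position_cM"].to_numpy()[idx])
        blocks.append((idx, haldane_recombination(d)))

    allele = {"A": 0, "B": 1}
    for ind in pedigree.individuals:
        r = row[ind.id]
        if ind.generation == "F0":
            pat[r, :] = allele[ind.founder_line]
            mat[r, :] = allele[ind.founder_line]
            continue
        for parent_id, target in ((ind.sire_id, pat), (ind.dam_id, mat)):
            pr = row[parent_id]
            if (pat[pr] < 0).any() or (mat[pr] < 0).any():
                raise ValueError(f"parent {parent_id} of {ind.id} lacks genotypes")
            for idx, rf in blocks:
                target[r, idx] = sample_gamete(pat[pr, idx], mat[pr, idx], rf, rng)
    return OrderedGenotypeMatrix(ids=list(ids), marker_ids=list(markers), paternal=pat, maternal=mat)


# --------------------------------------------------------------------------
# phenotypes
# --------------------------------------------------------------------------


@dataclass
class QTLEffect:
    """One simulated locus: position plus a/d/i effects in trait units."""

    chromosome: int
    position_cM: float
    a: float = 0.0
    d: float = 0.0
    i: float = 0.0


@dataclass
class MaternalEffectSpec:
    """Additive effect of the dam's B-allele count at a locus."""

    chromosome: int
    position_cM: float
    m_per_maternal_B_allele: float


@dataclass
class TraitSpec:
    """Generative architecture of one quantitative trait."""

    trait_name: str
    grand_mean: float = 0.0
    qtls: list[QTLEffect] = field(default_factory=list)
    family_sd: float = 1.0
    residual_sd: float = 1.0
    sex_effect: float = 0.0
    cross_direction_effect: float = 0.0
    maternal_effect: MaternalEffectSpec | None = None

    def __post_init__(self) -> None:
        if self.family_sd < 0 or self.residual_sd < 0:
            raise ValueError("family_sd and residual_sd must be non-negative")


def simulate_phenotypes(
    pedigree: Pedigree,
    genotypes: OrderedGenotypeMatrix,
    genetic_map: GeneticMap,
    traitspecs: list[TraitSpec],
    seed: int = 0,
    generations: tuple[str, ...] = ("F2", "F3"),
) -> pd.DataFrame:
    """Generate the phenotype table for the analyzable animals.

    Returns one row per analyzable individual of the phenotyped generations
    with columns ``id, sex, grandmaternal_line, family_id`` followed by one
    column per trait.  Family deviations are drawn once per sire-dam pair
    and per trait; all randomness flows from ``seed``.
    """
    rng = np.random.default_rng(seed)
    subjects = [
        ind
        for ind in pedigree.individuals
        if ind.generation in generations and ind.analyzable
    ]
    if not subjects:
        raise ValueError("no analyzable individuals in the requested generations")
    rows = {
        "id": [s.id for s in subjects],
        "sex": [s.sex for s in subjects],
        "grandmaternal_line": [s.grandmaternal_line for s in subjects],
        "family_id": [pedigree.family_id(s.id) for s in subjects],
    }
    out = pd.DataFrame(rows)
    male = np.array([s.sex == "M" for s in subjects], dtype=float)
    dirB = np.array([s.grandmaternal_line == "B" for s in subjects], dtype=float)
    fam_codes, fam_index = pd.factorize(out["family_id"])
    indices = genotypes.effect_indices()
    sub_rows = np.array([genotypes.row(s.id) for s in subjects])

    for spec in traitspecs:
        y = np.full(len(subjects), spec.grand_mean, dtype=float)
        y += spec.sex_effect * male + spec.cross_direction_effect * dirB
        for q in spec.qtls:
            marker = genetic_map.nearest_marker(q.chromosome, q.position_cM)
            xa, xd, xi = indices.at_marker(marker)
            contrib = q.a * xa[sub_rows] + q.d * xd[sub_rows] + q.i * xi[sub_rows]
            y += np.nan_to_num(contrib)
        if spec.maternal_effect is not None:
            me = spec.maternal_effect
            marker = genetic_map.nearest_marker(me.chromosome, me.position_cM)
            col = genotypes.col(marker)
            dose = genotypes.b_allele_count()[:, col]
            dam_rows = np.array([genotypes.row(pedigree[s.id].dam_id) for s in subjects])
            dam_dose = dose[dam_rows].astype(float)
            dam_dose[dam_dose < 0] = np.nan
            y += me.m_per_maternal_B_allele * np.nan_to_num(dam_dose)
        u = rng.normal(0.0, spec.family_sd, size=len(fam_index))
        y += u[fam_codes]
        y += rng.normal(0.0, spec.residual_sd, size=len(subjects))
        out[spec.trait_name] = y
    return out


def default_trait_specs() -> list[TraitSpec]:
    """Seven-trait architecture echoing the study's genetic landscape.

    Additive loci dominate body-size traits, a dominance locus affects
    muscle mass, and two purely imprinted (bipolar) loci on chromosomes 12
    and 19 drive body weight, glycogen content and glycolytic potential.
    Effects are in residual-SD units (residual_sd = 1, family_sd = 0.5) and
    sized so single imprinted loci explain roughly 4-5% of variance.
    """
    chr1 = QTLEffect(1, 15.0, a=0.60, d=0.15)
    chr2 = QTLEffect(2, 25.0, a=0.55, d=0.25)
    chr12_i = QTLEffect(12, 10.0, i=0.40)
    chr15_d = QTLEffect(15, 20.0, d=0.60)
    chr19_i = QTLEffect(19, 23.0, i=0.42)
    return [
        TraitSpec("body_weight", 30.0, [chr1, chr12_i, chr19_i], 0.5, 1.0, 2.0, 0.3),
        TraitSpec("muscle_mass", 8.0, [chr2, chr15_d], 0.5, 1.0, 0.8, 0.2),
        TraitSpec("fat_mass", 5.0, [QTLEffect(1, 15.0, a=0.9)], 0.5, 1.0, 0.5, 0.1),
        TraitSpec("lean_mass", 20.0, [chr1, chr2], 0.5, 1.0, 1.5, 0.2),
        TraitSpec("glycolytic_potential", 100.0, [chr19_i], 0.5, 1.0, 0.0, 0.5),
        TraitSpec("glycogen_content", 50.0, [QTLEffect(19, 23.0, i=0.40)], 0.5, 1.0, 0.0, 0.3),
        TraitSpec("m_quadriceps", 2.0, [chr2, chr15_d], 0.5, 1.0, 0.3, 0.1),
    ]
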