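"""File formats, published-table fixtures and report generation.

Two fixtures ship with the package: the identified-loci table (per-locus,
per-trait effect LOD scores with boldface significance encoded as explicit
0/1 flags, since the per-trait permutation thresholds behind the boldface
were never published) and the variance-decomposition table (percent
phenotypic variance explained per trait by additive, dominance and
imprinting effects).  Trait labels are kept verbatim so round-trips are
exact.

All tabular interchange formats are plain text: TSV for maps, pedigrees,
scans and QTL tables; CSV for genotypes and phenotypes; JSON for threshold
sets; YAML for simulation configs.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .adi_model import genotypic_values_from_means, total_r2
from .inference import QTLRecord, TraitEffect, _merge_markers, name_qtl
from .scan import SCAN_COLUMNS, STATISTICS, ScanResult
from .synthetic_data import (
    CrossConfig,
    GeneticMap,
    MaternalEffectSpec,
    OrderedGenotypeMatrix,
    Pedigree,
    QTLEffect,
    TraitSpec,
    UnorderedGenotypeMatrix,
)

logger = logging.getLogger(__name__)

# --------------------------------------------------------------------------
# fixtures: published per-locus effect table (boldface -> sig_* flags)
# --------------------------------------------------------------------------

TABLE1_TSV = """\
qtl	trait	pos_Mb	pos_cM	ci_cM	mLOD	aLOD	dLOD	iLOD	sig_mLOD	sig_aLOD	sig_dLOD	sig_iLOD
Mc1.1	Body weight	34.6	13.3	13.33 - 44.4	4.91	4.89	0.88	0.45	1	1	0	0
Mc1.1	Lean mass	34.6	13.3	13.33 - 44.4	3.6	3.53	1.03	0.24	1	1	0	0
Mc1.1	Glycolytic potential	34.6	13.3	13.33	0.92	0.56	1.68	0.09	0	0	1	0
Mc1.1	Fat mass	34.6	13.3	13.33 - 40.2	2.28	3.21	0.81	0.13	1	1	0	0
Mc1.1	M. quadriceps	34.6	13.3	13.33	1.56	2.02	0.31	0.39	1	1	0	0
Mc1.1	M. longissimus	34.6	13.3	13.33 - 26.7	1.13	1.87	0.16	0.09	0	1	0	0
Mc1.1	Muscle mass	34.6	13.3	13.33	1.44	2.17	0.21	0.02	1	1	0	0
Mc2.1	M. longissimus	82.0	49.1	49.1 - 54.1	3.08	3.55	1.23	1.23	1	1	0	0
Mc2.1	Lean mass	82.0	49.1	49.1 - 54.1	2.86	3.53	1.47	0.96	1	1	1	0
Mc2.1	M. quadriceps	82.0	49.1	49.1 - 54.1	4.02	4.59	1.06	1.15	1	1	0	0
Mc2.1	Body weight	82.0	49.1	49.1 - 54.1	1.86	2.72	1.24	0.45	1	1	0	0
Mc2.1	Muscle mass	82.0	49.1	49.1 - 54.1	4.35	4.94	1.46	1.26	1	1	1	0
Mc6.1	M. longissimus	12.1	5.3	1.8 - 11.2	3.30	3.39	0.51	1.36	1	1	0	1
Mc8.1	M. longissimus	79.4	36.3	33.1 - 36.3	2.74	3.69	1.14	0.20	1	1	0	0
Mc8.1	Muscle mass	79.4	36.3	33.1 - 36.3	2.94	3.97	1.12	0.09	1	1	0	0
Mc12.1	Body weight	27.3	9.7	9.7 - 28.7	2.24	0.21	0.34	3.30	1	0	0	1
Mc12.2	Fat mass	91.4	43.9	51.4 - 61.2	2.17	3.30	0.11	0.01	1	1	0	0
Mc15.1	Muscle mass	10.3	58.7	58.7	2.57	0.19	3.32	0.13	1	0	1	0
Mc15.1	M. quadriceps	10.3	58.7	50.4 - 58.7	3.29	0.41	4.08	0.01	1	0	1	0
Mc17.1	Body weight	77.6	48.1	58.1 - 60.9	2.87	3.63	0.07	0.88	1	1	0	0
Mc19.1	Glycolytic potential	28.9	23.5	23.5	3.91	0.49	1.30	3.33	1	0	0	1
Mc19.1	Body weight	28.9	23.5	23.53 - 29.8	1.77	1.23	0.09	1.93	1	0	0	1
Mc19.1	Glycogen content	28.9	23.5	23.53	2.60	0.43	0.50	2.94	1	0	0	1
Mc19.1	Lean mass	28.9	23.5	23.53	2.21	1.5	0.01	2.20	1	0	0	1
Mc19.1	M. longissimus	28.9	23.5	23.53 - 29.8	1.91	0.39	0.06	2.78	1	0	0	1
Mc19.1	Muscle mass	28.9	23.5	23.53 - 29.8	2.07	0.40	0.05	2.82	1	0	0	1
Mc19.1	M. quadriceps	28.9	23.5	23.53 - 38.8	1.69	0.39	0.54	1.87	1	0	0	1
"""

# fixtures: published percent-variance decomposition per trait
TABLE2_TSV = """\
trait	loci	a_effects	d_effects	i_effects	R2_a	R2_d	R2_i	total_R2
Body weight	8	7	0	1	26.35	0	2.71	29.06
Muscle mass	7	6	1	0	19.08	4.03	0	23.11
Fat mass	5	4	0	0	39.36	0	0	39.36
Lean mass	7	7	0	0	15.28	0	0	15.28
Glycolytic potential	1	0	0	1	0	0	4.66	4.66
M. quadriceps	5	4	1	0	6.15	1.25	0	7.40
M. longissimus	5	5	0	0	14.60	0	0	14.60
Glycogen content	1	0	0	1	0	0	4.05	4.05
"""

_SIG_COLS = {"mLOD": "sig_mLOD", "aLOD": "sig_aLOD", "dLOD": "sig_dLOD", "iLOD": "sig_iLOD"}


def load_qtl_table_fixture() -> pd.DataFrame:
    """The published per-locus effect table with boldface as 0/1 flags."""
    df = pd.read_csv(io.StringIO(TABLE1_TSV), sep="\t")
    for c in _SIG_COLS.values():
        df[c] = df[c].astype(bool)
    return df


def load_r2_table_fixture() -> pd.DataFrame:
    """The published percent-variance decomposition per trait."""
    return pd.read_csv(io.StringIO(TABLE2_TSV), sep="\t")


def summarize_effect_counts(fixture: pd.DataFrame) -> dict[str, int]:
    """Count significant single-effect entries of each type across the table."""
    return {
        "a": int(fixture["sig_aLOD"].sum()),
        "d": int(fixture["sig_dLOD"].sum()),
        "i": int(fixture["sig_iLOD"].sum()),
    }


def summarize_qtl(fixture: pd.DataFrame) -> dict[str, int]:
    """Locus-level summary of the effect table.

    ``n_imprinting_top_qtl`` counts loci whose first-listed (primary) trait
    has the imprinting LOD as the largest of the three single-effect LODs.
    """
    n_qtl = fixture["qtl"].nunique()
    per_locus = fixture.groupby("qtl", sort=False)
    n_single = int((per_locus["trait"].nunique() == 1).sum())
    n_imp_top = 0
    for _, grp in per_locus:
        first = grp.iloc[0]
        if first["iLOD"] > first["aLOD"] and first["iLOD"] > first["dLOD"]:
            n_imp_top += 1
    return {
        "n_qtl": int(n_qtl),
        "n_single_trait_qtl": n_single,
        "n_imprinting_top_qtl": n_imp_top,
    }


def trait_totals(fixture: pd.DataFrame) -> pd.Series:
    """Per-trait total percent variance via orthogonal summation."""
    return pd.Series(
        {
            row["trait"]: total_r2([row["R2_a"], row["R2_d"], row["R2_i"]])
            for _, row in fixture.iterrows()
        }
    )


def qtl_records_from_fixture(
    fixture: pd.DataFrame, merge_window_cM: float = 20.0
) -> list[QTLRecord]:
    """Replay the fixture's flagged rows through the locus grouping logic.

    Flags are taken as printed; rows are merged per chromosome within the
    merge window and renamed through the Mc scheme, so the number and names
    of loci are recomputed rather than read off the fixture.
    """
    df = fixture.copy()
    df["chromosome"] = df["qtl"].str.extract(r"Mc(\d+)\.")[0].astype(int)
    df["position_cM"] = df["pos_cM"].astype(float)
    df["position_Mb"] = df["pos_Mb"].astype(float)
    df["marker_id"] = df["chromosome"].astype(str) + "@" + df["pos_cM"].astype(str)
    sig_any = np.zeros(len(df), dtype=bool)
    for col in _SIG_COLS.values():
        sig_any |= df[col].to_numpy(bool)
    marked = df[sig_any]
    records = []
    for grp in _merge_markers(marked, merge_window_cM):
        first = grp.iloc[0]
        effects = []
        for _, row in grp.iterrows():
            flags = {
                s: ("genomewide" if row[c] else ("pointwise" if row[s] >= 1.3 else None))
                for s, c in _SIG_COLS.items()
            }
            effects.append(
                TraitEffect(
                    trait=row["trait"],
                    a=np.nan,
                    d=np.nan,
                    i=np.nan,
                    lods={s: float(row[s]) for s in STATISTICS},
                    flags=flags,
                )
            )
        records.append(
            QTLRecord(
                name="",
                chromosome=int(first["chromosome"]),
                peak_marker=str(first["marker_id"]),
                peak_cM=float(first["position_cM"]),
                peak_Mb=float(first["position_Mb"]),
                support_interval_cM=(float(first["position_cM"]), float(first["position_cM"])),
                trait_effects=effects,
                primary_trait=str(first["trait"]),
            )
        )
    return name_qtl(sorted(records, key=lambda r: (r.chromosome, r.peak_cM)))


# --------------------------------------------------------------------------
# per-class genotype means (figure-style export)
# --------------------------------------------------------------------------


def genotype_means_export(
    y: np.ndarray, ordered_classes: np.ndarray | list[str]
) -> pd.DataFrame:
    """Mean, SE and count per ordered genotype class at one marker.

    The export feeds bar plots of the four ordered-class means — the shape
    that makes imprinting patterns (e.g. bipolar expression) visible.  An
    empty class is reported with ``n = 0`` and NaN mean.
    """
    y = np.asarray(y, float)
    cls = np.asarray(ordered_classes, dtype=object)
    rows = []
    for c in ("AA", "AB", "BA", "BB"):
        vals = y[(cls == c) & np.isfinite(y)]
        n = len(vals)
        rows.append(
            {
                "class": c,
                "mean": float(vals.mean()) if n else np.nan,
                "se": float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
                "n": n,
            }
        )
    return pd.DataFrame(rows)


def effects_from_class_means(means: pd.DataFrame):
    """Genotypic values (r, a, d, i) from a :func:`genotype_means_export` table."""
    m = means.set_index("class")["mean"]
    return genotypic_values_from_means(m["AA"], m["AB"], m["BA"], m["BB"])


# --------------------------------------------------------------------------
# readers / writers
# --------------------------------------------------------------------------


def write_map_tsv(genetic_map: GeneticMap, path) -> None:
    genetic_map.table.to_csv(path, sep="\t", index=False)


def read_map_tsv(path) -> GeneticMap:
    return GeneticMap(pd.read_csv(path, sep="\t"))


def write_pedigree_tsv(pedigree: Pedigree, path) -> None:
    pedigree.to_frame().to_csv(path, sep="\t", index=False)


def read_pedigree_tsv(path) -> Pedigree:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    frame["analyzable"] = frame["analyzable"].isin(("True", "true", "1"))
    return Pedigree.from_frame(frame)


def write_ordered_genotypes_csv(genotypes: OrderedGenotypeMatrix, path) -> None:
    codes = genotypes.codes()
    codes.index.name = "id"
    codes.to_csv(path)


def read_ordered_genotypes_csv(path) -> OrderedGenotypeMatrix:
    df = pd.read_csv(path, index_col="id", dtype=str)
    code_to_pair = {"AA": (0, 0), "AB": (0, 1), "BA": (1, 0), "BB": (1, 1), "NA": (-1, -1)}
    pat = np.array([[code_to_pair[v][0] for v in row] for row in df.to_numpy()], dtype=np.int8)
    mat = np.array([[code_to_pair[v][1] for v in row] for row in df.to_numpy()], dtype=np.int8)
    return OrderedGenotypeMatrix(
        ids=[str(i) for i in df.index], marker_ids=list(df.columns), paternal=pat, maternal=mat
    )


def write_unordered_genotypes_csv(genotypes: UnorderedGenotypeMatrix, path) -> None:
    codes = genotypes.codes()
    codes.index.name = "id"
    codes.to_csv(path)


def read_unordered_genotypes_csv(path) -> UnorderedGenotypeMatrix:
    df = pd.read_csv(path, index_col="id", dtype=str)
    code = {"A": 0, "H": 1, "B": 2, "NA": -1}
    dose = np.array([[code[v] for v in row] for row in df.to_numpy()], dtype=np.int8)
    return UnorderedGenotypeMatrix(
        ids=[str(i) for i in df.index], marker_ids=list(df.columns), dosage=dose
    )


def write_phenotypes_csv(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, index=False)


def read_phenotypes_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_scan_tsv(result: ScanResult, path) -> None:
    result.table.to_csv(path, sep="\t", index=False)


def read_scan_tsv(path) -> ScanResult:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in SCAN_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"scan table lacks columns {missing}")
    return ScanResult(table=table)


def qtl_records_to_frame(records: list[QTLRecord]) -> pd.DataFrame:
    """Flatten called loci into a report table (one row per locus x trait)."""
    rows = []
    for rec in records:
        for k, eff in enumerate(rec.trait_effects):
            sig = ";".join(
                f"{s}:{lvl}" for s, lvl in eff.flags.items() if lvl is not None
            )
            rows.append(
                {
                    "qtl": rec.name if k == 0 else "",
                    "trait": eff.trait,
                    "pos_Mb": round(rec.peak_Mb, 2) if np.isfinite(rec.peak_Mb) else "",
                    "pos_cM": round(rec.peak_cM, 2),
                    "ci_cM": f"{rec.support_interval_cM[0]:.2f} - {rec.support_interval_cM[1]:.2f}",
                    **{s: round(eff.lods[s], 2) for s in STATISTICS},
                    "significance": sig,
                }
            )
    return pd.DataFrame(rows)


def write_qtl_table_tsv(records: list[QTLRecord], path) -> None:
    qtl_records_to_frame(records).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# simulation config (YAML)
# --------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    cross: CrossConfig
    traits: list[TraitSpec]
    seed: int = 0
    map_n_markers: int = 164
    map_spacing_cM: float = 5.0


def parse_simulation_config(text_or_dict) -> SimulationConfig:
    """Parse a YAML simulation config into typed specs.

    Expected shape::

        seed: 1
        cross: {n_f2: 94, n_f3: 345, n_f3_analyzable: 331}
        map: {n_markers: 164, spacing_cM: 5.0}
        traits:
          - name: body_weight
            grand_mean: 30.0
            family_sd: 0.5
            residual_sd: 1.0
            sex_effect: 2.0
            cross_direction_effect: 0.3
            qtls:
              - {chromosome: 12, position_cM: 10.0, i: 0.4}
            maternal_effect: {chromosome: 12, position_cM: 10.0, m: 0.5}
    """
    raw = yaml.safe_load(text_or_dict) if isinstance(text_or_dict, str) else text_or_dict
    cross = CrossConfig(**raw.get("cross", {}))
    traits = []
    for t in raw.get("traits", []):
        qtls = [QTLEffect(**q) for q in t.get("qtls", [])]
        me = t.get("maternal_effect")
        maternal = (
            MaternalEffectSpec(
                chromosome=me["chromosome"],
                position_cM=me["position_cM"],
                m_per_maternal_B_allele=me["m"],
            )
            if me
            else None
        )
        traits.append(
            TraitSpec(
                trait_name=t["name"],
                grand_mean=float(t.get("grand_mean", 0.0)),
                qtls=qtls,
                family_sd=float(t.get("family_sd", 1.0)),
                residual_sd=float(t.get("residual_sd", 1.0)),
                sex_effect=float(t.get("sex_effect", 0.0)),
                cross_direction_effect=float(t.get("cross_direction_effect", 0.0)),
                maternal_effect=maternal,
            )
        )
    map_cfg = raw.get("map", {})
    return SimulationConfig(
        cross=cross,
        traits=traits,
        seed=int(raw.get("seed", 0)),
        map_n_markers=int(map_cfg.get("n_markers", 164)),
        map_spacing_cM=float(map_cfg.get("spacing_cM", 5.0)),
    )
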