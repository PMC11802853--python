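"""Clonal overlap between phenotypes, recirculation calls, and
known-TCR specificity screening.

Overlap counts cells, not clones: a clone with cells in subsets i and j
contributes (its cells in i + its cells in j) to entry (i, j). A clone
spanning three or more subsets contributes to each pair independently.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

COMPARTMENTS = ("blood", "tumour")


def clonal_overlap(
    cells: pd.DataFrame,
    subset_order: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Raw clonal-overlap matrix for one sample.

    `cells` columns: cell_id, clone_id, subset. Entry (i, j), i != j, sums
    over clones with >=1 cell in both i and j the count of the clone's
    cells in i plus its cells in j. Symmetric, zero diagonal.
    """
    if subset_order is None:
        subset_order = sorted(set(cells["subset"].astype(str)))
    labels = list(subset_order)
    mat = pd.DataFrame(0.0, index=labels, columns=labels)
    counts = cells.groupby(["clone_id", "subset"]).size()
    for _, by_subset in counts.groupby(level="clone_id"):
        present = by_subset.droplevel("clone_id")
        subs = [s for s in present.index.astype(str) if s in mat.index]
        for a_i in range(len(subs)):
            for b_i in range(a_i + 1, len(subs)):
                a, b = subs[a_i], subs[b_i]
                val = float(present[subs[a_i]] + present[subs[b_i]])
                mat.at[a, b] += val
                mat.at[b, a] += val
    return mat


def normalize_overlap(
    matrices: Mapping[str, pd.DataFrame],
) -> tuple[dict[str, pd.DataFrame], list[str]]:
    """Scale each sample's matrix to a total of 1; drop all-zero samples.

    Normalisation is per sample over all subset pairs jointly (entries of
    the symmetric matrix sum to 1, so each unordered pair carries half its
    weight in each triangle). Returns (normalised matrices, excluded
    sample ids).
    """
    out: dict[str, pd.DataFrame] = {}
    excluded: list[str] = []
    for sample_id, mat in matrices.items():
        total = float(mat.values.sum())
        if total <= 0:
            excluded.append(sample_id)
            continue
        out[sample_id] = mat / total
    return out, excluded


def classify_compartments(cells: pd.DataFrame) -> pd.Series:
    """Label each clone recirculating / tumour_only / blood_only.

    `cells` columns: clone_id, compartment (values blood|tumour). A clone
    with cells in both compartments is recirculating.
    """
    bad = set(cells["compartment"].astype(str)) - set(COMPARTMENTS)
    if bad:
        raise ValueError(f"unknown compartment values: {sorted(bad)}")
    def _label(comps: pd.Series) -> str:
        s = set(comps)
        if len(s) == 2:
            return "recirculating"
        return "tumour_only" if "tumour" in s else "blood_only"
    return cells.groupby("clone_id")["compartment"].agg(_label).rename("compartment_class")


def migration_linkage(
    cells: pd.DataFrame,
    calls: Optional[pd.Series] = None,
    blood_phenotypes: Optional[Sequence[str]] = None,
    tumour_phenotypes: Optional[Sequence[str]] = None,
    average_patients: bool = True,
) -> pd.DataFrame:
    """Blood-phenotype x tumour-phenotype weights over recirculating clones.

    `cells` columns: clone_id, compartment, subset, and patient when
    `average_patients`. weight(p_blood, p_tumour) counts recirculating
    clones with >=1 blood cell of p_blood and >=1 tumour cell of
    p_tumour. With `average_patients`, each patient's matrix is
    normalised to sum to 1 (patients with no recirculating clones are
    skipped) and the matrices are averaged.
    """
    if calls is None:
        calls = classify_compartments(cells)
    recirc = set(calls[calls == "recirculating"].index)
    if blood_phenotypes is None:
        blood_phenotypes = sorted(
            set(cells.loc[cells["compartment"] == "blood", "subset"].astype(str)))
    if tumour_phenotypes is None:
        tumour_phenotypes = sorted(
            set(cells.loc[cells["compartment"] == "tumour", "subset"].astype(str)))

    def _one(group: pd.DataFrame) -> pd.DataFrame:
        mat = pd.DataFrame(0.0, index=list(blood_phenotypes),
                           columns=list(tumour_phenotypes))
        for clone_id, cl in group.groupby("clone_id"):
            if clone_id not in recirc:
                continue
            b_ph = set(cl.loc[cl["compartment"] == "blood", "subset"].astype(str))
            t_ph = set(cl.loc[cl["compartment"] == "tumour", "subset"].astype(str))
            for pb in b_ph & set(mat.index):
                for pt in t_ph & set(mat.columns):
                    mat.at[pb, pt] += 1.0
        return mat

    if not average_patients or "patient" not in cells.columns:
        return _one(cells)
    mats = []
    for _, group in cells.groupby("patient"):
        mat = _one(group)
        total = mat.values.sum()
        if total > 0:
            mats.append(mat / total)
    if not mats:
        return pd.DataFrame(0.0, index=list(blood_phenotypes),
                            columns=list(tumour_phenotypes))
    return sum(mats) / len(mats)


def screen_known_tcrs(
    cells: pd.DataFrame,
    reference: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annotate TCRs against a known-specificity reference.

    `cells` columns: cell_id, cdr3_aa, optionally v_gene, clone_id,
    compartment_class. `reference` columns: cdr3_aa, antigen_category,
    optionally v_gene (when set on a reference row, the TRBV gene must
    also match; allele suffixes are ignored).

    Matching is exact on the CDR3 amino-acid string. Returns
    (per-cell annotation frame, per-compartment-class clone match table).
    """
    from .clones import strip_allele

    for col in ("cdr3_aa", "antigen_category"):
        if col not in reference.columns:
            raise ValueError(f"reference missing required column {col!r}")

    ref_any: dict[str, str] = {}
    ref_with_v: dict[tuple[str, str], str] = {}
    for _, row in reference.iterrows():
        cdr3 = str(row["cdr3_aa"])
        v = row.get("v_gene") if "v_gene" in reference.columns else None
        if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
            ref_any.setdefault(cdr3, str(row["antigen_category"]))
        else:
            ref_with_v.setdefault((cdr3, strip_allele(str(v))), str(row["antigen_category"]))

    categories = []
    for _, row in cells.iterrows():
        cdr3 = str(row["cdr3_aa"])
        category = ref_any.get(cdr3)
        if category is None and "v_gene" in cells.columns:
            category = ref_with_v.get((cdr3, strip_allele(str(row.get("v_gene", "")))))
        categories.append(category)
    annotated = cells.copy()
    annotated["antigen_category"] = categories
    annotated["matched"] = annotated["antigen_category"].notna()

    if "clone_id" in annotated.columns:
        group_col = ("compartment_class" if "compartment_class" in annotated.columns
                     else None)
        per_clone = annotated.groupby("clone_id").agg(
            matched=("matched", "any"),
            **({"compartment_class": (group_col, "first")} if group_col else {}),
        )
        if group_col:
            enrich = per_clone.groupby("compartment_class")["matched"].agg(
                ["mean", "size"]).rename(columns={"mean": "fraction_matched",
                                                  "size": "n_clones"}).reset_index()
        else:
            enrich = pd.DataFrame(
                {"compartment_class": ["all"],
                 "fraction_matched": [per_clone["matched"].mean() if len(per_clone) else 0.0],
                 "n_clones": [len(per_clone)]})
    else:
        enrich = pd.DataFrame(columns=["compartment_class", "fraction_matched", "n_clones"])
    return annotated, enrich
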