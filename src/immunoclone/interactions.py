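"""Cell-count-independent receptor-ligand interaction scoring.

The strength of a ligand-receptor interaction from sender subset A to
receiver subset B is the product of the fraction of A cells with a
nonzero ligand count and the fraction of B cells with a nonzero receptor
count, per patient. Subsets with fewer than `min_cells` cells in a
patient emit no entries. Because only expressing *fractions* enter, the
scores are independent of subset cell numbers and per-cell depth.
"""

from __future__ import annotations

import logging
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_MIN_CELLS = 3

TENSOR_COLUMNS = ["patient", "sender", "receiver", "ligand", "receptor", "strength"]


def load_default_pairs() -> pd.DataFrame:
    """Bundled curated immune ligand-receptor pair table."""
    with resources.files("immunoclone.data").joinpath("lr_pairs.csv").open() as fh:
        return pd.read_csv(fh)


def expressing_fraction(
    matrix: pd.DataFrame,
    cells: Sequence[str],
    gene: str,
) -> Optional[float]:
    """Fraction of the given cells with a nonzero count for `gene`.

    `matrix` is cells x genes. Returns None (and logs) when the gene is
    absent from the matrix.
    """
    if gene not in matrix.columns:
        logger.warning("gene %s absent from matrix; fraction reported as missing", gene)
        return None
    cells = list(cells)
    if not cells:
        raise ValueError("expressing_fraction requires a non-empty cell set")
    values = matrix.loc[cells, gene].to_numpy()
    return float((values > 0).mean())


def interaction_strengths(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    pairs: pd.DataFrame,
    min_cells: int = DEFAULT_MIN_CELLS,
    include_self: bool = True,
) -> pd.DataFrame:
    """Per-patient sender x receiver x ligand-receptor strength table.

    `matrix`: cells x genes counts (any monotone scaling; only count > 0
    matters). `meta`: indexed by cell_id (or with a cell_id column) with
    columns patient and subset. `pairs`: columns ligand, receptor and
    optionally tag. Pairs whose ligand or receptor is absent from the
    matrix are skipped with a log message.
    """
    if "cell_id" in meta.columns:
        meta = meta.set_index("cell_id")
    meta = meta.loc[meta.index.intersection(matrix.index)]
    for col in ("ligand", "receptor"):
        if col not in pairs.columns:
            raise ValueError(f"pairs table missing column {col!r}")
    usable = []
    for _, row in pairs.iterrows():
        if row["ligand"] in matrix.columns and row["receptor"] in matrix.columns:
            usable.append((row["ligand"], row["receptor"]))
        else:
            logger.warning("skipping pair %s-%s: gene absent from matrix",
                           row["ligand"], row["receptor"])
    genes = sorted({g for pair in usable for g in pair})

    rows = []
    for patient, pat_meta in meta.groupby("patient"):
        sizes = pat_meta.groupby("subset").size()
        eligible = sorted(sizes.index[sizes >= min_cells].astype(str))
        if not eligible:
            continue
        # expressing fraction per (subset, gene), computed once
        frac = {}
        for subset in eligible:
            cells = pat_meta.index[pat_meta["subset"] == subset]
            sub = (matrix.loc[cells, genes].to_numpy() > 0).mean(axis=0)
            frac[subset] = dict(zip(genes, sub))
        for sender in eligible:
            for receiver in eligible:
                if not include_self and sender == receiver:
                    continue
                for ligand, receptor in usable:
                    rows.append(
                        {
                            "patient": patient,
                            "sender": sender,
                            "receiver": receiver,
                            "ligand": ligand,
                            "receptor": receptor,
                            "strength": frac[sender][ligand] * frac[receiver][receptor],
                        }
                    )
    return pd.DataFrame(rows, columns=TENSOR_COLUMNS)


def link_counts(tensor: pd.DataFrame) -> pd.DataFrame:
    """Per patient and subset: counts of nonzero outgoing/incoming entries."""
    nz = tensor[tensor["strength"] > 0]
    subsets = sorted(set(tensor["sender"]) | set(tensor["receiver"]))
    rows = []
    for patient in sorted(set(tensor["patient"])):
        pat = nz[nz["patient"] == patient]
        out_counts = pat.groupby("sender").size()
        in_counts = pat.groupby("receiver").size()
        for subset in subsets:
            rows.append(
                {
                    "patient": patient,
                    "subset": subset,
                    "outgoing": int(out_counts.get(subset, 0)),
                    "incoming": int(in_counts.get(subset, 0)),
                }
            )
    return pd.DataFrame(rows, columns=["patient", "subset", "outgoing", "incoming"])


def rank_receptor_interactions(
    tensor: pd.DataFrame,
    receiver: str,
    receptors: Sequence[str],
    top_k: int = 20,
) -> pd.DataFrame:
    """Top interactions onto a receiver subset through the given receptors.

    Strengths are averaged across patients per (sender, ligand, receptor)
    and sorted descending, ties broken lexicographically.
    """
    known = sorted(set(tensor["receptor"]))
    unknown = sorted(set(receptors) - set(known))
    if unknown:
        raise ValueError(
            f"unknown receptors {unknown}; known receptors: {known}"
        )
    sub = tensor[(tensor["receiver"] == receiver) & tensor["receptor"].isin(receptors)]
    ranked = (
        sub.groupby(["sender", "ligand", "receptor"], as_index=False)["strength"]
        .mean()
        .rename(columns={"strength": "mean_strength"})
    )
    ranked = ranked[ranked["mean_strength"] > 0]
    ranked = ranked.sort_values(
        by=["mean_strength", "sender", "ligand", "receptor"],
        ascending=[False, True, True, True],
    ).reset_index(drop=True)
    return ranked.head(top_k)


def compare_edge_groups(
    tensor: pd.DataFrame,
    groups: Mapping[str, str],
) -> pd.DataFrame:
    """Group comparison of per-pair strength vectors for every edge.

    For each (sender, receiver) edge, the vector of ligand-receptor
    strengths per patient is compared between patient groups by
    multivariate analysis of variance. Returns one row per edge with the
    statistic, p-value and direction (+1 when the first group, sorted
    lexicographically, has the larger mean total strength).
    """
    from .stats import manova_compare

    group_ser = pd.Series(dict(groups))
    counts = group_ser.value_counts()
    if (counts < 2).any() or len(counts) < 2:
        raise ValueError("each group needs >= 2 patients and >= 2 groups required")
    group_names = sorted(counts.index.astype(str))

    rows = []
    for (sender, receiver), edge in tensor.groupby(["sender", "receiver"]):
        wide = edge.pivot_table(
            index="patient", columns=["ligand", "receptor"], values="strength",
            fill_value=0.0,
        )
        wide = wide.loc[wide.index.intersection(group_ser.index)]
        labels = group_ser.loc[wide.index]
        if labels.value_counts().reindex(group_names).fillna(0).min() < 2:
            continue
        comparison = manova_compare(wide, labels)
        mean_by_group = wide.sum(axis=1).groupby(labels).mean()
        diff = float(mean_by_group.get(group_names[0], 0.0)
                     - mean_by_group.get(group_names[1], 0.0))
        rows.append(
            {
                "sender": sender,
                "receiver": receiver,
                "statistic": comparison.statistic,
                "p_value": comparison.p_value,
                "direction": int(np.sign(diff)),
            }
        )
    return pd.DataFrame(
        rows, columns=["sender", "receiver", "statistic", "p_value", "direction"]
    )
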