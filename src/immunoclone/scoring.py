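"""Signature scoring, threshold learning, rule gating, gene-correlation
modules and SVM label transfer.

`module_score` follows the binned-control recipe: each signature gene is
compared against control genes drawn from the same average-expression
bin, so the expected score of a random gene set is zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.svm import LinearSVC


# ---------------------------------------------------------------------------
# signature scoring

@dataclass
class ScoreTable:
    scores: pd.Series  # index cell_id
    gene_set: str
    n_bins: int
    n_ctrl: int
    seed: Optional[int]


def log_normalize(matrix: pd.DataFrame, target_sum: float = 1e4) -> pd.DataFrame:
    """log1p of depth-normalised counts (counts-per-`target_sum`)."""
    depth = matrix.sum(axis=1).replace(0, np.nan)
    return np.log1p(matrix.div(depth, axis=0).fillna(0.0) * target_sum)


def module_score(
    matrix: pd.DataFrame,
    gene_set: Sequence[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: Optional[int] = None,
    set_name: str = "module",
) -> ScoreTable:
    """Per-cell signature score with expression-bin-matched controls.

    `matrix` is cells x genes of (log-normalised) expression. Genes are
    ranked by dataset-mean expression and cut into `n_bins`
    equal-frequency bins; for each signature gene, `n_ctrl` control genes
    are drawn (without replacement when the bin allows, never signature
    genes) from its bin. The score is mean(signature expression) minus
    mean(control expression) per cell.
    """
    genes = list(matrix.columns)
    if len(genes) < n_bins:
        raise ValueError(f"matrix has {len(genes)} genes; need >= n_bins={n_bins}")
    present = [g for g in gene_set if g in matrix.columns]
    missing = [g for g in gene_set if g not in matrix.columns]
    if not present:
        raise ValueError(
            f"no gene of set {set_name!r} found in matrix; missing: {missing}"
        )

    rng = np.random.default_rng(seed)
    mean_expr = matrix.mean(axis=0)
    # equal-frequency bins of the dataset-mean rank (ties broken stably)
    rank = mean_expr.rank(method="first")
    bins = pd.qcut(rank, q=n_bins, labels=False)

    set_index = set(present)
    control_pool: list[str] = []
    for gene in present:
        bin_id = bins[gene]
        eligible = sorted(
            g for g in matrix.columns[bins == bin_id] if g not in set_index
        )
        if not eligible:
            continue
        if len(eligible) <= n_ctrl:
            control_pool.extend(eligible)
        else:
            control_pool.extend(rng.choice(eligible, size=n_ctrl, replace=False))
    if not control_pool:
        raise ValueError("no eligible control genes outside the signature set")

    set_mean = matrix[present].mean(axis=1)
    ctrl_mean = matrix[control_pool].mean(axis=1)
    scores = (set_mean - ctrl_mean).rename("score")
    return ScoreTable(scores, set_name, n_bins, n_ctrl, seed)


# ---------------------------------------------------------------------------
# threshold learning and pAPC classification

def fit_score_threshold(
    scores_positive: Sequence[float],
    scores_negative: Sequence[float],
) -> float:
    """Decision threshold between two score distributions.

    A univariate logistic model (positive=1) is fitted and the score at
    predicted probability 0.5 returned. Perfectly separable inputs have
    no finite MLE, so the midpoint of the separating gap is returned
    instead. Identical distributions trigger a warning and the pooled
    median.
    """
    pos = np.asarray(list(scores_positive), dtype=float)
    neg = np.asarray(list(scores_negative), dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both score groups must be non-empty")
    if len(pos) == len(neg) and np.array_equal(np.sort(pos), np.sort(neg)):
        warnings.warn("identical score distributions; threshold set to pooled median",
                      RuntimeWarning, stacklevel=2)
        return float(np.median(np.concatenate([pos, neg])))
    if pos.min() > neg.max():
        return float((pos.min() + neg.max()) / 2.0)
    if neg.min() > pos.max():
        return float((neg.min() + pos.max()) / 2.0)

    import statsmodels.api as sm

    y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    x = sm.add_constant(np.concatenate([pos, neg]))
    fit = sm.GLM(y, x, family=sm.families.Binomial()).fit()
    intercept, slope = fit.params
    if slope == 0:
        warnings.warn("flat logistic fit; threshold set to pooled median",
                      RuntimeWarning, stacklevel=2)
        return float(np.median(np.concatenate([pos, neg])))
    return float(-intercept / slope)


def classify_papc(
    score_table: ScoreTable,
    threshold: float,
    meta: pd.DataFrame,
    cell_type_col: str = "subset",
    patient_col: str = "patient",
) -> tuple[pd.Series, pd.DataFrame]:
    """Flag professional APCs and summarise the pAPC pool per patient.

    A cell is a pAPC iff its score exceeds the threshold. The
    composition table gives, per patient, the fraction of its pAPCs
    contributed by each cell type (fractions sum to 1 over cell types
    with at least one pAPC).
    """
    if "cell_id" in meta.columns:
        meta = meta.set_index("cell_id")
    flags = (score_table.scores > threshold).rename("is_papc")
    joined = flags.to_frame().join(meta[[cell_type_col, patient_col]], how="inner")
    papcs = joined[joined["is_papc"]]
    if papcs.empty:
        composition = pd.DataFrame(columns=[patient_col, cell_type_col, "fraction"])
    else:
        counts = papcs.groupby([patient_col, cell_type_col]).size()
        totals = counts.groupby(level=patient_col).transform("sum")
        composition = (counts / totals).rename("fraction").reset_index()
    return flags, composition


# ---------------------------------------------------------------------------
# declarative rule gating

_COMPARATORS = {
    ">": np.greater,
    ">=": np.greater_equal,
    "<": np.less,
    "<=": np.less_equal,
    "==": np.equal,
}


@dataclass(frozen=True)
class GatePredicate:
    feature: str
    comparator: str  # one of > >= < <= ==
    threshold: float

    def evaluate(self, features: pd.DataFrame) -> pd.Series:
        if self.feature not in features.columns:
            raise KeyError(
                f"gate rule references unknown feature {self.feature!r}; "
                f"available: {sorted(features.columns)}"
            )
        if self.comparator not in _COMPARATORS:
            raise ValueError(f"unknown comparator {self.comparator!r}")
        return _COMPARATORS[self.comparator](features[self.feature], self.threshold)


@dataclass(frozen=True)
class GateRule:
    label: str
    priority: int  # smaller = applied first
    predicates: tuple[GatePredicate, ...]
    mode: str = "all"  # all | any

    def matches(self, features: pd.DataFrame) -> pd.Series:
        results = [p.evaluate(features) for p in self.predicates]
        stacked = pd.concat(results, axis=1)
        return stacked.all(axis=1) if self.mode == "all" else stacked.any(axis=1)


def load_gate_rules(path) -> list[GateRule]:
    """Read gate rules from YAML.

    Each entry: ``label``, ``priority``, optional ``mode`` (all/any) and
    ``predicates``: list of {feature, comparator, threshold}.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    rules = []
    for entry in raw["rules"]:
        predicates = tuple(
            GatePredicate(p["feature"], p["comparator"], float(p["threshold"]))
            for p in entry["predicates"]
        )
        rules.append(
            GateRule(entry["label"], int(entry["priority"]), predicates,
                     entry.get("mode", "all"))
        )
    return rules


def gate_cells(
    features: pd.DataFrame,
    rules: Sequence[GateRule],
    fallback: str = "unassigned",
) -> pd.Series:
    """Assign each row the label of its first matching rule by priority.

    Priorities must be unique; the result is independent of the order in
    which rules are supplied. Rows matching no rule get `fallback`.
    """
    priorities = [r.priority for r in rules]
    if len(set(priorities)) != len(priorities):
        raise ValueError("gate rule priorities must be unique")
    labels = pd.Series(fallback, index=features.index, dtype=object, name="label")
    unassigned = pd.Series(True, index=features.index)
    for rule in sorted(rules, key=lambda r: r.priority):
        hit = rule.matches(features) & unassigned
        labels[hit] = rule.label
        unassigned &= ~hit
    return labels


def aggregate_features(
    cell_features: pd.DataFrame,
    clusters: pd.Series,
    recipe: Mapping[str, object],
) -> pd.DataFrame:
    """Build cluster-level gating features from per-cell values.

    `recipe` maps output feature name to either ``("mean", col)`` or
    ``("fraction_gt", col, x)`` (fraction of the cluster's cells with
    col > x).
    """
    out = {}
    grouped = cell_features.groupby(clusters)
    for name, how in recipe.items():
        if how[0] == "mean":
            out[name] = grouped[how[1]].mean()
        elif how[0] == "fraction_gt":
            col, cutoff = how[1], float(how[2])
            out[name] = grouped[col].agg(lambda v: float((v > cutoff).mean()))
        else:
            raise ValueError(f"unknown aggregation {how[0]!r}")
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# gene-correlation modules

def downsample_counts(
    counts: pd.DataFrame,
    umi_target: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Downsample each cell (row) to `umi_target` UMIs without replacement.

    Cells already at or below the target are kept unchanged.
    """
    values = counts.to_numpy().astype(np.int64)
    out = values.copy()
    totals = values.sum(axis=1)
    for i in np.where(totals > umi_target)[0]:
        out[i] = rng.multivariate_hypergeometric(values[i], umi_target)
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def gene_modules(
    matrices: Mapping[str, pd.DataFrame],
    n_modules: int,
    umi_target: int = 2000,
    min_gene_umis: int = 5,
    seed: Optional[int] = None,
) -> tuple[pd.Series, np.ndarray, pd.DataFrame]:
    """Gene -> module assignment from sample-averaged gene correlations.

    Per sample: cells are downsampled to `umi_target` UMIs, genes with
    fewer than `min_gene_umis` UMIs are excluded, expression is
    log(1+UMI) transformed, and a gene-gene Pearson correlation matrix
    computed. Correlations are Fisher z-transformed, averaged across
    samples and transformed back, then complete-linkage hierarchical
    clustering of (1 - correlation) distances is cut into `n_modules`.

    Returns (assignments, linkage matrix, averaged correlation matrix).
    """
    rng = np.random.default_rng(seed)
    z_mats = []
    gene_sets = []
    per_sample = {}
    for sample_id in sorted(matrices):
        counts = matrices[sample_id]
        down = downsample_counts(counts, umi_target, rng)
        keep = down.columns[down.sum(axis=0) >= min_gene_umis]
        if len(keep) < 2:
            continue
        log_expr = np.log1p(down[keep])
        corr = log_expr.corr()  # pairwise Pearson
        per_sample[sample_id] = corr
        gene_sets.append(set(keep))
    if not gene_sets:
        raise ValueError("no sample yields >= 2 genes passing the UMI filter")
    common = sorted(set.intersection(*gene_sets))
    if len(common) < 2:
        raise ValueError("fewer than 2 genes pass the UMI filter in all samples")
    for sample_id, corr in per_sample.items():
        sub = corr.loc[common, common].to_numpy()
        sub = np.clip(np.nan_to_num(sub), -1 + 1e-12, 1 - 1e-12)
        z_mats.append(np.arctanh(sub))
    avg_corr = np.tanh(np.mean(z_mats, axis=0))
    np.fill_diagonal(avg_corr, 1.0)
    avg = pd.DataFrame(avg_corr, index=common, columns=common)

    dist = 1.0 - avg_corr
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    link = hierarchy.linkage(squareform(dist, checks=False), method="complete")
    flat = hierarchy.fcluster(link, t=n_modules, criterion="maxclust")
    assignments = pd.Series(flat, index=common, name="module")
    return assignments, link, avg


# ---------------------------------------------------------------------------
# SVM label transfer

def svm_label_transfer(
    reference: pd.DataFrame,
    ref_labels: Sequence,
    query: pd.DataFrame,
    cells_per_class: int = 50,
    reps: int = 25,
    seed: Optional[int] = None,
    C: float = 1.0,
) -> pd.DataFrame:
    """Reference-based cell labelling by repeated class-balanced SVMs.

    Over `reps` rounds a linear one-vs-rest SVM is trained on a
    class-balanced subsample (`cells_per_class` cells per class, drawn
    without replacement when the class allows, with replacement for rarer
    classes so rare cell types are never dropped) and applied to the
    query. The final label is the majority vote across rounds; the
    probability is the winning label's vote fraction.
    """
    ref = np.asarray(reference, dtype=float)
    qry = np.asarray(query, dtype=float)
    if ref.shape[1] != qry.shape[1]:
        raise ValueError(
            f"embedding dimensionality mismatch: reference {ref.shape[1]} "
            f"vs query {qry.shape[1]}"
        )
    labels = np.asarray(ref_labels)
    classes = np.unique(labels)
    rng = np.random.default_rng(seed)

    votes = pd.DataFrame(
        0, index=getattr(query, "index", pd.RangeIndex(len(qry))), columns=classes
    )
    for _ in range(reps):
        train_idx = []
        for cls in classes:
            members = np.where(labels == cls)[0]
            replace = len(members) < cells_per_class
            train_idx.append(rng.choice(members, size=cells_per_class, replace=replace))
        train_idx = np.concatenate(train_idx)
        clf = LinearSVC(C=C, random_state=int(rng.integers(2**31 - 1)))
        clf.fit(ref[train_idx], labels[train_idx])
        pred = clf.predict(qry)
        for cls in classes:
            votes.loc[:, cls] += (pred == cls).astype(int)

    fractions = votes / reps
    # deterministic winner: max vote fraction, ties to lexicographically first
    winner = fractions.columns[np.argmax(fractions.to_numpy(), axis=1)]
    out = pd.DataFrame(
        {
            "label": winner,
            "probability": fractions.to_numpy().max(axis=1),
        },
        index=votes.index,
    )
    for cls in classes:
        out[f"vote_{cls}"] = fractions[cls]
    return out
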