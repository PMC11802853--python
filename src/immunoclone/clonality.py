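"""Depth-normalised clonal-expansion metrics.

Both metrics subsample cells to a fixed depth many times and recount
clone sizes *inside each subsample*, which is what removes the
dependence on sequencing depth: a sample with twice the cells but the
same clone-frequency distribution yields the same expected value.

- intra-subset clonality: % of sampled cells (depth 5 within one subset)
  whose clone has >= 2 sampled members.
- inter-subset clonality: cells sampled at depth 50 across all subsets
  of one lineage; per subset, % of its sampled cells in clones with
  >= 3 sampled members counted across the whole subsample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

DEFAULT_INTRA_DEPTH = 5
DEFAULT_INTER_DEPTH = 50
DEFAULT_REPS = 1000
INTRA_MIN_CLONE = 2
INTER_MIN_CLONE = 3


@dataclass
class ClonalityResult:
    sample_id: str
    subset: str
    metric: str  # "intra" | "inter"
    value: Optional[float]  # percentage in [0, 100]; None when insufficient
    depth: int
    reps: int
    n_available: int
    status: str  # "ok" | "insufficient_cells"
    replicates: Optional[np.ndarray] = None  # per-replicate %, when requested

    @property
    def monte_carlo_se(self) -> Optional[float]:
        if self.replicates is None or len(self.replicates) < 2:
            return None
        return float(np.std(self.replicates, ddof=1) / np.sqrt(len(self.replicates)))

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "subset": self.subset,
            "metric": self.metric,
            "value": self.value,
            "depth": self.depth,
            "reps": self.reps,
            "n_available": self.n_available,
            "status": self.status,
        }


def _as_codes(clone_ids: Sequence) -> np.ndarray:
    codes, _ = pd.factorize(np.asarray(clone_ids))
    return codes


def intra_subset_clonality(
    clone_ids: Sequence,
    depth: int = DEFAULT_INTRA_DEPTH,
    reps: int = DEFAULT_REPS,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    sample_id: str = "",
    subset: str = "",
    keep_replicates: bool = False,
) -> ClonalityResult:
    """Mean % of `depth` subsampled cells in clones with >=2 sampled members.

    `clone_ids` are the clone labels of every cell of one subset in one
    sample. Sampling is without replacement; clone sizes are recounted
    within each subsample. Subsets with fewer than `depth` cells return
    status ``insufficient_cells`` rather than sampling with replacement.
    """
    if depth < 2:
        raise ValueError(f"depth must be >= 2, got {depth}")
    codes = _as_codes(clone_ids)
    n = len(codes)
    if n < depth:
        return ClonalityResult(sample_id, subset, "intra", None, depth, reps, n,
                               "insufficient_cells")
    if rng is None:
        rng = np.random.default_rng(seed)
    n_clones = codes.max() + 1
    values = np.empty(reps)
    for i in range(reps):
        picked = codes[rng.choice(n, size=depth, replace=False)]
        counts = np.bincount(picked, minlength=n_clones)
        values[i] = 100.0 * np.mean(counts[picked] >= INTRA_MIN_CLONE)
    return ClonalityResult(sample_id, subset, "intra", float(values.mean()),
                           depth, reps, n, "ok",
                           replicates=values if keep_replicates else None)


def inter_subset_clonality(
    clone_ids: Sequence,
    subsets: Sequence,
    depth: int = DEFAULT_INTER_DEPTH,
    reps: int = DEFAULT_REPS,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    sample_id: str = "",
    keep_replicates: bool = False,
) -> list[ClonalityResult]:
    """Per-subset % of cells in clones with >=3 sampled members lineage-wide.

    `clone_ids` and `subsets` are parallel over all cells of one lineage
    (B, CD4 or CD8) in one sample. Each replicate draws `depth` cells
    across all subsets without replacement; clone sizes are counted over
    the whole draw, then each subset is scored on its own sampled cells.
    Replicates where a subset receives zero cells contribute no
    observation for that subset.
    """
    if depth < 2:
        raise ValueError(f"depth must be >= 2, got {depth}")
    codes = _as_codes(clone_ids)
    subset_arr = np.asarray(subsets)
    if len(codes) != len(subset_arr):
        raise ValueError("clone_ids and subsets must be parallel")
    n = len(codes)
    subset_names = sorted(set(subset_arr.tolist()))
    if n < depth:
        return [
            ClonalityResult(sample_id, s, "inter", None, depth, reps,
                            int((subset_arr == s).sum()), "insufficient_cells")
            for s in subset_names
        ]
    if rng is None:
        rng = np.random.default_rng(seed)
    n_clones = codes.max() + 1
    subset_codes, uniques = pd.factorize(subset_arr)
    k = len(uniques)
    rep_values: list[list[float]] = [[] for _ in range(k)]
    for _ in range(reps):
        idx = rng.choice(n, size=depth, replace=False)
        picked = codes[idx]
        counts = np.bincount(picked, minlength=n_clones)
        in_big = counts[picked] >= INTER_MIN_CLONE
        picked_subsets = subset_codes[idx]
        for s in range(k):
            mask = picked_subsets == s
            if not mask.any():
                continue
            rep_values[s].append(100.0 * in_big[mask].mean())
    results = []
    for s, name in enumerate(uniques):
        vals = np.asarray(rep_values[s])
        value = float(vals.mean()) if len(vals) else None
        status = "ok" if len(vals) else "insufficient_cells"
        results.append(
            ClonalityResult(sample_id, str(name), "inter", value, depth, reps,
                            int((subset_codes == s).sum()), status,
                            replicates=vals if keep_replicates else None)
        )
    order = {name: i for i, name in enumerate(subset_names)}
    results.sort(key=lambda r: order[r.subset])
    return results


def results_to_frame(results: Sequence[ClonalityResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])


def repertoire_feature_matrix(
    samples: Mapping[str, Mapping],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample feature vectors: clonality + V-gene usage + isotype usage.

    `samples` maps sample_id to a dict with optional keys:

    - ``clonality``: scalar or {name: value} of clonality percentages
    - ``v_usage``: {gene: count} of heavy/beta V-gene usage
    - ``isotype``: {isotype: count}

    Usage blocks are normalised to sum to 1 within each sample. Features
    missing in a sample are 0-filled; the returned mask marks imputed
    entries (True = missing in the input).
    """
    rows = {}
    for sample_id, blocks in samples.items():
        row: dict[str, float] = {}
        clon = blocks.get("clonality", {})
        if isinstance(clon, (int, float)):
            clon = {"clonality": float(clon)}
        for name, value in clon.items():
            row[f"clonality:{name}"] = float(value)
        for block, prefix in (("v_usage", "v_usage:"), ("isotype", "isotype:")):
            counts = blocks.get(block, {})
            total = float(sum(counts.values()))
            if total > 0:
                for key, cnt in counts.items():
                    row[prefix + str(key)] = cnt / total
        rows[sample_id] = row
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index(axis=1)
    mask = df.isna()
    df = df.fillna(0.0)
    df.index.name = "sample_id"
    mask.index.name = "sample_id"
    return df, mask
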