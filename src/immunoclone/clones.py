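"""Clone calling for B and T cells.

B-cell clones are connected components of the union of two pairwise
relations on heavy-chain CDR3 DNA: (a) a point-mutation network linking
sequences at Hamming distance exactly 1, and (b) identity of CDR3 DNA
together with matching V and J gene families. T-cell clones require
identical beta-chain CDR3 DNA, V and J genes, with the alpha-chain CDR3
used as a discriminator when present in both cells.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import networkx as nx
import pandas as pd

_VALID_NT = re.compile(r"^[ACGTN]*$")


class UnionFind:
    """Disjoint-set forest with path compression and union by size."""

    def __init__(self, n: int):
        self.parent = list(range(n))
        self.size = [1] * n

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]


def gene_family(call: str) -> str:
    """IMGT-style family: allele stripped, text before the first hyphen.

    ``IGHV3-23*01`` -> ``IGHV3``; ``TRBV20-1`` -> ``TRBV20``.
    """
    if not call:
        return ""
    return call.split("*", 1)[0].split("-", 1)[0]


def strip_allele(call: str) -> str:
    return call.split("*", 1)[0] if call else ""


def _validate_sequences(sequences: Iterable[str]) -> None:
    for seq in sequences:
        if not _VALID_NT.match(seq):
            raise ValueError(f"non-ACGTN characters in sequence {seq!r}")


def hamming1_pairs(sequences: Sequence[str]) -> set[tuple[str, str]]:
    """All unordered pairs of equal-length sequences at Hamming distance 1.

    Buckets sequences by (position, sequence-with-position-masked); two
    sequences share a bucket for position i iff they agree everywhere
    except possibly at i. O(total length) rather than all-pairs.
    """
    unique = sorted(set(sequences))
    pairs: set[tuple[str, str]] = set()
    by_length: dict[int, list[str]] = defaultdict(list)
    for seq in unique:
        by_length[len(seq)].append(seq)
    for length, seqs in by_length.items():
        for pos in range(length):
            buckets: dict[str, list[str]] = defaultdict(list)
            for seq in seqs:
                buckets[seq[:pos] + seq[pos + 1:]].append(seq)
            for group in buckets.values():
                if len(group) < 2:
                    continue
                for i in range(len(group)):
                    for j in range(i + 1, len(group)):
                        a, b = group[i], group[j]
                        if a[pos] != b[pos]:  # distance exactly 1, not 0
                            pairs.add((a, b) if a < b else (b, a))
    return pairs


def build_mutation_network(sequences: Iterable[str]) -> nx.Graph:
    """Point-mutation network over unique nucleotide sequences.

    Nodes are unique sequences; an undirected edge joins two sequences of
    equal length at Hamming distance exactly 1.
    """
    seqs = list(sequences)
    _validate_sequences(seqs)
    graph = nx.Graph()
    graph.add_nodes_from(set(seqs))
    graph.add_edges_from(hamming1_pairs(seqs))
    return graph


@dataclass
class CloneTable:
    """Partition of cells into clones.

    ``assignments`` maps cell_id -> clone_id; ``clones`` summarises each
    clone (size, receptor class, optionally the subsets/compartments it
    spans and its patient when metadata is attached).
    """

    assignments: pd.Series  # index cell_id, values clone_id
    receptor_class: str
    clones: pd.DataFrame  # index clone_id, column "size" (+ annotation columns)

    def __len__(self) -> int:
        return len(self.clones)

    def clone_of(self, cell_id: str) -> str:
        return self.assignments[cell_id]

    def size_of(self, clone_id: str) -> int:
        return int(self.clones.at[clone_id, "size"])

    def to_frame(self) -> pd.DataFrame:
        df = self.assignments.rename("clone_id").rename_axis("cell_id").reset_index()
        df["clone_size"] = df["clone_id"].map(self.clones["size"]).astype(int)
        return df

    def attach_meta(self, meta: pd.DataFrame) -> "CloneTable":
        """Annotate clones with subsets/compartments spanned and patient.

        `meta` is indexed by cell_id (or has a cell_id column) with any of
        the columns subset, compartment, patient.
        """
        if "cell_id" in meta.columns:
            meta = meta.set_index("cell_id")
        joined = self.assignments.rename("clone_id").to_frame().join(meta, how="left")
        extra = {}
        for col, out in (("subset", "subsets"), ("compartment", "compartments")):
            if col in joined.columns:
                extra[out] = joined.groupby("clone_id")[col].agg(
                    lambda s: ",".join(sorted(set(s.dropna().astype(str))))
                )
        if "patient" in joined.columns:
            patients = joined.groupby("clone_id")["patient"].agg(
                lambda s: sorted(set(s.dropna().astype(str)))
            )
            if patients.map(len).max() > 1:
                raise ValueError("a clone spans more than one patient")
            extra["patient"] = patients.map(lambda p: p[0] if p else "")
        clones = self.clones.copy()
        for name, series in extra.items():
            clones[name] = series
        return CloneTable(self.assignments, self.receptor_class, clones)


def _components_to_table(
    cell_ids: Sequence[str],
    uf: UnionFind,
    receptor_class: str,
    prefix: str,
) -> CloneTable:
    groups: dict[int, list[str]] = defaultdict(list)
    for i, cell in enumerate(cell_ids):
        groups[uf.find(i)].append(cell)
    # deterministic ordering: size descending, then smallest cell_id
    ordered = sorted(groups.values(), key=lambda g: (-len(g), min(g)))
    assignments = {}
    sizes = {}
    for rank, members in enumerate(ordered, start=1):
        clone_id = f"{prefix}{rank}"
        sizes[clone_id] = len(members)
        for cell in members:
            assignments[cell] = clone_id
    ser = pd.Series(assignments, name="clone_id").rename_axis("cell_id")
    clones = pd.DataFrame({"size": pd.Series(sizes)}).rename_axis("clone_id")
    return CloneTable(ser, receptor_class, clones)


def call_bcr_clones(cells: pd.DataFrame, clone_prefix: str = "B") -> CloneTable:
    """Call B-cell clones from one heavy chain per cell, single patient.

    `cells` columns: cell_id, junction (CDR3 DNA), v_call, j_call, and
    optionally patient (must then be single-valued).
    """
    _require_single_patient(cells)
    cells = cells.reset_index(drop=True)
    _validate_sequences(cells["junction"].astype(str))
    cell_ids = cells["cell_id"].tolist()
    uf = UnionFind(len(cell_ids))

    seqs = cells["junction"].astype(str).tolist()
    index_of_seq: dict[str, list[int]] = defaultdict(list)
    for i, s in enumerate(seqs):
        index_of_seq[s].append(i)

    # criterion (a): point-mutation network on CDR3 DNA
    for a, b in hamming1_pairs(seqs):
        ia, ib = index_of_seq[a][0], index_of_seq[b][0]
        uf.union(ia, ib)

    # criterion (b): identical CDR3 DNA + same V family + same J family;
    # identical sequences also need criterion (b) or an (a)-path, so group
    # identical-CDR3 cells by family key only.
    by_key: dict[tuple[str, str, str], list[int]] = defaultdict(list)
    for i, row in cells.iterrows():
        key = (seqs[i], gene_family(str(row["v_call"])), gene_family(str(row["j_call"])))
        by_key[key].append(i)
    for members in by_key.values():
        for other in members[1:]:
            uf.union(members[0], other)

    # identical sequences at distance 0 are a single node in the mutation
    # network: all carriers of one sequence belong together under (a)
    for members in index_of_seq.values():
        for other in members[1:]:
            uf.union(members[0], other)

    return _components_to_table(cell_ids, uf, "BCR", clone_prefix)


def call_tcr_clones(cells: pd.DataFrame, clone_prefix: str = "T") -> CloneTable:
    """Call T-cell clones from beta (± alpha) chains, single patient.

    `cells` columns: cell_id, trb_junction, trb_v, trb_j, and optionally
    tra_junction (empty/NaN when the alpha chain was not captured).
    Two cells share a clone iff their TRB CDR3 DNA, TRBV and TRBJ match
    and, when both carry an alpha chain, their TRA CDR3 also matches.
    Cells lacking an alpha chain are compatible with any alpha.
    """
    _require_single_patient(cells)
    cells = cells.reset_index(drop=True)
    _validate_sequences(cells["trb_junction"].astype(str))
    cell_ids = cells["cell_id"].tolist()
    uf = UnionFind(len(cell_ids))

    groups: dict[tuple[str, str, str], list[int]] = defaultdict(list)
    for i, row in cells.iterrows():
        key = (
            str(row["trb_junction"]),
            strip_allele(str(row["trb_v"])),
            strip_allele(str(row["trb_j"])),
        )
        groups[key].append(i)

    has_tra = "tra_junction" in cells.columns
    for members in groups.values():
        by_alpha: dict[str, list[int]] = defaultdict(list)
        no_alpha: list[int] = []
        for i in members:
            tra = cells.at[i, "tra_junction"] if has_tra else None
            if tra is None or (isinstance(tra, float) and pd.isna(tra)) or tra == "":
                no_alpha.append(i)
            else:
                by_alpha[str(tra)].append(i)
        for alpha_members in by_alpha.values():
            for other in alpha_members[1:]:
                uf.union(alpha_members[0], other)
        # alpha-less cells are compatible with every cell of the TRB group
        if no_alpha:
            anchor = no_alpha[0]
            for other in no_alpha[1:]:
                uf.union(anchor, other)
            for alpha_members in by_alpha.values():
                uf.union(anchor, alpha_members[0])

    return _components_to_table(cell_ids, uf, "TCR", clone_prefix)


def _require_single_patient(cells: pd.DataFrame) -> None:
    if "patient" in cells.columns:
        patients = set(cells["patient"].dropna().astype(str))
        if len(patients) > 1:
            raise ValueError(
                f"clone calling is per patient; got {sorted(patients)} — "
                "call once per patient"
            )


def clone_size_spectrum(
    table: CloneTable,
    meta: Optional[pd.DataFrame] = None,
    sample_col: str = "sample_id",
) -> dict[str, Counter]:
    """Clone-size histogram, per sample when metadata is given.

    Sizes are recounted within each sample so that every histogram's
    total equals the number of cells of that sample. Without metadata a
    single histogram keyed ``"all"`` is returned.
    """
    df = table.assignments.rename("clone_id").rename_axis("cell_id").reset_index()
    if meta is None:
        df[sample_col] = "all"
    else:
        if "cell_id" in meta.columns:
            meta = meta.set_index("cell_id")
        df[sample_col] = df["cell_id"].map(meta[sample_col])
    out: dict[str, Counter] = {}
    for sample, grp in df.groupby(sample_col):
        sizes = grp.groupby("clone_id").size()
        hist: Counter = Counter()
        for size in sizes:
            hist[int(size)] += 1
        out[str(sample)] = hist
    return out
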