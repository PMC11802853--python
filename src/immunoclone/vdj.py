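"""Per-droplet VDJ contig parsing, chain selection, SHM and isotype usage.

A droplet (cell barcode) may carry several assembled contigs per locus;
the chain actually expressed is taken to be the one with the most UMI
support. Cells with contigs from both BCR and TCR loci are flagged
ambiguous rather than assigned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from typing import Iterable, Mapping, Optional

import pandas as pd

logger = logging.getLogger(__name__)

BCR_LOCI = frozenset({"IGH", "IGK", "IGL"})
TCR_LOCI = frozenset({"TRA", "TRB"})
KNOWN_LOCI = BCR_LOCI | TCR_LOCI

#: loci competing for the "heavy or beta" slot
HEAVY_SLOT = frozenset({"IGH", "TRB"})
#: loci competing for the "light or alpha" slot (IGK and IGL share one slot)
LIGHT_SLOT = frozenset({"IGK", "IGL", "TRA"})

AIRR_COLUMNS = [
    "cell_id", "locus", "v_call", "j_call", "c_call",
    "junction", "junction_aa", "duplicate_count", "v_identity",
]

TENX_COLUMNS = [
    "barcode", "chain", "v_gene", "j_gene", "c_gene",
    "cdr3_nt", "cdr3", "umis", "reads",
]


class FormatError(ValueError):
    """Raised when an input table lacks required columns."""


@dataclass(frozen=True)
class ContigRecord:
    """One annotated VDJ contig observed in one droplet."""

    cell_id: str
    locus: str
    v_call: str
    j_call: str
    c_call: str
    junction: str
    junction_aa: str
    umi_count: int
    read_count: int
    v_identity: Optional[float] = None  # percent, 0-100
    v_sequence_length: Optional[int] = None
    contig_id: str = ""

    def __post_init__(self) -> None:
        if self.umi_count < 0:
            raise ValueError(f"umi_count must be >= 0, got {self.umi_count}")
        if self.v_identity is not None and not (0.0 <= self.v_identity <= 100.0):
            raise ValueError(f"v_identity must be in [0, 100], got {self.v_identity}")


@dataclass
class ChainAssignment:
    """Selected chain pair for one droplet."""

    cell_id: str
    heavy_or_beta: Optional[ContigRecord] = None
    light_or_alpha: Optional[ContigRecord] = None
    receptor_class: str = "ambiguous"  # BCR | TCR | ambiguous
    extra: dict = field(default_factory=dict)

    @property
    def complete_pair(self) -> bool:
        return self.heavy_or_beta is not None and self.light_or_alpha is not None


class ParsedContigs(list):
    """List of ContigRecord with a count of skipped (unparseable) rows."""

    n_skipped: int = 0


def _to_int(value) -> int:
    if pd.isna(value):
        raise ValueError("missing")
    return int(value)


def parse_contigs(path, dialect: str = "airr") -> ParsedContigs:
    """Read a contig annotation table into ContigRecords.

    Parameters
    ----------
    path
        TSV (``airr`` dialect) or CSV (``10x_contig_csv`` dialect).
    dialect
        ``"airr"``: AIRR Rearrangement columns, ``duplicate_count`` is the
        UMI count and ``v_identity`` is a percentage.
        ``"10x_contig_csv"``: filtered_contig_annotations.csv columns.

    Rows that fail coercion (e.g. non-numeric UMI counts) are skipped and
    counted on the returned list's ``n_skipped`` attribute.
    """
    if dialect == "airr":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = AIRR_COLUMNS
    elif dialect == "10x_contig_csv":
        df = pd.read_csv(path, dtype=str)
        required = TENX_COLUMNS
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(
            f"{dialect} input missing required columns: {', '.join(missing)}"
        )

    records = ParsedContigs()
    skipped = 0
    for _, row in df.iterrows():
        try:
            if dialect == "airr":
                rec = ContigRecord(
                    cell_id=str(row["cell_id"]),
                    locus=str(row["locus"]),
                    v_call=_str_or_empty(row["v_call"]),
                    j_call=_str_or_empty(row["j_call"]),
                    c_call=_str_or_empty(row["c_call"]),
                    junction=_str_or_empty(row["junction"]),
                    junction_aa=_str_or_empty(row["junction_aa"]),
                    umi_count=_to_int(row["duplicate_count"]),
                    read_count=_to_int(row.get("consensus_count", 0))
                    if "consensus_count" in df.columns else 0,
                    v_identity=float(row["v_identity"])
                    if not pd.isna(row["v_identity"]) else None,
                    v_sequence_length=_to_int(row["v_sequence_length"])
                    if "v_sequence_length" in df.columns
                    and not pd.isna(row.get("v_sequence_length")) else None,
                    contig_id=_str_or_empty(row.get("sequence_id", "")),
                )
            else:
                rec = ContigRecord(
                    cell_id=str(row["barcode"]),
                    locus=str(row["chain"]),
                    v_call=_str_or_empty(row["v_gene"]),
                    j_call=_str_or_empty(row["j_gene"]),
                    c_call=_str_or_empty(row["c_gene"]),
                    junction=_str_or_empty(row["cdr3_nt"]),
                    junction_aa=_str_or_empty(row["cdr3"]),
                    umi_count=_to_int(row["umis"]),
                    read_count=_to_int(row["reads"]),
                    contig_id=_str_or_empty(row.get("contig_id", "")),
                )
        except (ValueError, TypeError):
            skipped += 1
            continue
        records.append(rec)

    records.n_skipped = skipped
    if skipped:
        logger.warning("parse_contigs: skipped %d unparseable rows", skipped)
    return records


def _str_or_empty(value) -> str:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ""
    if pd.isna(value):
        return ""
    return str(value)


def _contig_sort_key(rec: ContigRecord):
    # max UMIs, ties by read count, then lexicographically smallest contig id
    return (-rec.umi_count, -rec.read_count, rec.contig_id)


def select_chains(records: Iterable[ContigRecord]) -> dict[str, ChainAssignment]:
    """Pick the most probable chain per slot for every droplet.

    Per chain slot (heavy/beta vs light/alpha) the contig with maximal
    UMI count is kept; ties break by read count then contig id, so the
    result does not depend on input order. Droplets carrying both BCR
    and TCR loci are flagged ``receptor_class="ambiguous"`` with empty
    slots.
    """
    by_cell: dict[str, list[ContigRecord]] = {}
    for rec in records:
        if rec.locus not in KNOWN_LOCI:
            continue
        by_cell.setdefault(rec.cell_id, []).append(rec)

    out: dict[str, ChainAssignment] = {}
    for cell_id in sorted(by_cell):
        recs = by_cell[cell_id]
        loci = {r.locus for r in recs}
        has_bcr = bool(loci & BCR_LOCI)
        has_tcr = bool(loci & TCR_LOCI)
        if has_bcr and has_tcr:
            out[cell_id] = ChainAssignment(cell_id, receptor_class="ambiguous")
            continue
        receptor_class = "BCR" if has_bcr else "TCR"
        heavy = sorted(
            (r for r in recs if r.locus in HEAVY_SLOT), key=_contig_sort_key
        )
        light = sorted(
            (r for r in recs if r.locus in LIGHT_SLOT), key=_contig_sort_key
        )
        out[cell_id] = ChainAssignment(
            cell_id=cell_id,
            heavy_or_beta=heavy[0] if heavy else None,
            light_or_alpha=light[0] if light else None,
            receptor_class=receptor_class,
        )
    return out


def shm_count(v_identity: float, v_sequence_length: int) -> int:
    """Point mutations implied by a V-segment identity percentage.

    ``round((1 - v_identity/100) * v_sequence_length)``, clamped at 0.
    """
    if not 0.0 <= v_identity <= 100.0:
        raise ValueError(f"v_identity must be in [0, 100], got {v_identity}")
    if v_sequence_length <= 0:
        raise ValueError(f"v_sequence_length must be > 0, got {v_sequence_length}")
    return max(0, int(round((1.0 - v_identity / 100.0) * v_sequence_length)))


def isotype_usage(
    assignments: Mapping[str, ChainAssignment],
    meta: pd.DataFrame,
    by: str = "subset",
    sample_col: str = "sample_id",
) -> tuple[pd.DataFrame, int]:
    """Per-sample, per-group isotype proportions for BCR cells.

    `meta` must be indexed by cell_id (or carry a ``cell_id`` column) with
    `sample_col` and `by` columns. Cells without a heavy-chain ``c_call``
    are excluded; the count of excluded cells is returned alongside.
    Proportions within each (sample, group) sum to 1 over observed isotypes.
    """
    if "cell_id" in meta.columns:
        meta = meta.set_index("cell_id")
    rows = []
    n_missing = 0
    for cell_id, asg in assignments.items():
        if asg.receptor_class != "BCR" or asg.heavy_or_beta is None:
            continue
        if cell_id not in meta.index:
            continue
        isotype = asg.heavy_or_beta.c_call
        if not isotype:
            n_missing += 1
            continue
        rows.append(
            {
                "sample_id": meta.at[cell_id, sample_col],
                by: meta.at[cell_id, by],
                "isotype": isotype,
            }
        )
    if not rows:
        empty = pd.DataFrame(columns=["sample_id", by, "isotype", "proportion"])
        return empty, n_missing
    df = pd.DataFrame(rows)
    counts = df.groupby(["sample_id", by, "isotype"], sort=True).size()
    totals = counts.groupby(level=["sample_id", by]).transform("sum")
    table = (counts / totals).rename("proportion").reset_index()
    return table, n_missing


def assignments_to_frame(assignments: Mapping[str, ChainAssignment]) -> pd.DataFrame:
    """Flatten chain assignments to a TSV-ready table (one row per cell)."""
    rows = []
    for cell_id in sorted(assignments):
        asg = assignments[cell_id]
        row = {"cell_id": cell_id, "receptor_class": asg.receptor_class,
               "complete_pair": asg.complete_pair}
        for slot, rec in (("heavy", asg.heavy_or_beta), ("light", asg.light_or_alpha)):
            prefix = f"{slot}_"
            if rec is None:
                for f in fields(ContigRecord):
                    if f.name != "cell_id":
                        row[prefix + f.name] = None
            else:
                for f in fields(ContigRecord):
                    if f.name != "cell_id":
                        row[prefix + f.name] = getattr(rec, f.name)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_assignments(df: pd.DataFrame) -> dict[str, ChainAssignment]:
    """Inverse of :func:`assignments_to_frame`."""
    out: dict[str, ChainAssignment] = {}
    rec_fields = [f.name for f in fields(ContigRecord) if f.name != "cell_id"]
    for _, row in df.iterrows():
        cell_id = row["cell_id"]
        asg = ChainAssignment(cell_id=cell_id, receptor_class=row["receptor_class"])
        for slot_attr, prefix in (("heavy_or_beta", "heavy_"), ("light_or_alpha", "light_")):
            if pd.isna(row.get(prefix + "locus")):
                continue
            kwargs = {}
            for name in rec_fields:
                val = row[prefix + name]
                if pd.isna(val):
                    val = None
                kwargs[name] = val
            for int_field in ("umi_count", "read_count"):
                kwargs[int_field] = int(kwargs[int_field] or 0)
            if kwargs.get("v_sequence_length") is not None:
                kwargs["v_sequence_length"] = int(kwargs["v_sequence_length"])
            for str_field in ("locus", "v_call", "j_call", "c_call", "junction",
                              "junction_aa", "contig_id"):
                kwargs[str_field] = "" if kwargs[str_field] is None else str(kwargs[str_field])
            setattr(asg, slot_attr, ContigRecord(cell_id=cell_id, **kwargs))
        out[cell_id] = asg
    return out
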