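"""Seeded synthetic inputs: contig tables, metadata, count matrices,
receptor-ligand references and known-TCR tables.

The generator realises clones by copying a founder CDR3 DNA sequence
into every member cell (with optional point substitutions for B cells),
so every downstream module can be exercised against known ground truth.
Subset lineage is inferred from the subset name prefix: ``B*`` -> B,
``CD4*`` -> CD4, ``CD8*`` -> CD8.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.io import mmwrite
from scipy.sparse import csr_matrix

NT = np.array(list("ACGT"))

# standard genetic code, codon order TTT, TTC, ... with bases in TCAG order
_BASES = "TCAG"
_AA = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG")
_CODONS = {
    a + b + c: _AA[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}

IGHV_GENES = [f"IGHV{f}-{n}*01" for f in (1, 3, 4) for n in (2, 23, 34)]
IGHJ_GENES = [f"IGHJ{n}*01" for n in range(1, 7)]
IGKV_GENES = [f"IGKV{f}-{n}*01" for f in (1, 3) for n in (5, 39)]
IGKJ_GENES = [f"IGKJ{n}*01" for n in range(1, 5)]
IGLV_GENES = [f"IGLV{f}-{n}*01" for f in (1, 2) for n in (40, 44)]
IGLJ_GENES = [f"IGLJ{n}*01" for n in (1, 2, 3)]
TRBV_GENES = [f"TRBV{n}-1*01" for n in (2, 5, 7, 19, 20, 28)]
TRBJ_GENES = [f"TRBJ{m}-{n}*01" for m in (1, 2) for n in (1, 2, 3)]
TRAV_GENES = [f"TRAV{n}-1*01" for n in (1, 8, 12, 21)]
TRAJ_GENES = [f"TRAJ{n}*01" for n in (23, 33, 42)]

ISOTYPES_DEFAULT = {"IGHM": 0.4, "IGHD": 0.1, "IGHG1": 0.25, "IGHA1": 0.25}

V_SEGMENT_LENGTH = 300  # aligned V nucleotides assumed for identity arithmetic

LINEAGES = ("B", "CD4", "CD8")


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


def translate(dna: str) -> str:
    return "".join(_CODONS.get(dna[i:i + 3], "X") for i in range(0, len(dna) - 2, 3))


def lineage_of(subset: str) -> str:
    for lin in ("CD4", "CD8", "B"):
        if subset.startswith(lin):
            return lin
    raise ConfigurationError(
        f"cannot infer lineage of subset {subset!r}: names must start with "
        "B, CD4 or CD8"
    )


@dataclass
class SimConfig:
    """Parameters of the synthetic repertoire + expression generator."""

    n_patients: int = 2
    cells_per_sample: int = 500
    subsets: dict[str, float] = field(default_factory=lambda: {
        "B_naive": 0.2, "B_memory": 0.15, "CD4_naive": 0.15,
        "CD4_Treg": 0.1, "CD8_naive": 0.2, "CD8_EM": 0.2,
    })
    clone_size_law: tuple = ("power_law", 2.5)  # or ("geometric", p)
    shared_clone_prob: float = 0.2
    cross_subset_prob: float = 0.1
    shm_rate: float = 2.0  # expected point mutations per BCR
    isotype_probs: dict[str, float] = field(
        default_factory=lambda: dict(ISOTYPES_DEFAULT))
    expr_fractions: dict[str, dict[str, float]] = field(default_factory=dict)
    depth_mean: float = 2000.0
    decoy_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        errors = []
        if self.n_patients < 1:
            errors.append("n_patients must be >= 1")
        if self.cells_per_sample < 1:
            errors.append("cells_per_sample must be >= 1")
        for name, vec in (("subsets", self.subsets),
                          ("isotype_probs", self.isotype_probs)):
            if any(not 0.0 <= v <= 1.0 for v in vec.values()):
                errors.append(f"{name} probabilities must be in [0, 1]")
            if abs(sum(vec.values()) - 1.0) > 1e-9:
                errors.append(f"{name} frequencies must sum to 1 (got {sum(vec.values())})")
        for prob_name in ("shared_clone_prob", "cross_subset_prob", "decoy_prob"):
            v = getattr(self, prob_name)
            if not 0.0 <= v <= 1.0:
                errors.append(f"{prob_name} must be in [0, 1], got {v}")
        if self.shm_rate < 0:
            errors.append("shm_rate must be >= 0")
        law, param = self.clone_size_law
        if law == "power_law":
            if param <= 1.0:
                errors.append("power_law alpha must be > 1")
        elif law == "geometric":
            if not 0.0 < param <= 1.0:
                errors.append("geometric p must be in (0, 1]")
        else:
            errors.append(f"unknown clone_size_law {law!r}")
        for subset, fracs in self.expr_fractions.items():
            if any(not 0.0 <= v <= 1.0 for v in fracs.values()):
                errors.append(f"expr_fractions[{subset!r}] must be in [0, 1]")
        for subset in self.subsets:
            lineage_of(subset)  # raises on malformed names
        if errors:
            raise ConfigurationError("; ".join(errors))

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        data = dict(data)
        if "clone_size_law" in data and isinstance(data["clone_size_law"], (list, tuple)):
            data["clone_size_law"] = tuple(data["clone_size_law"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def sample_clone_sizes(
    law: tuple, n_cells: int, rng: np.random.Generator, size_cap: int = 10_000,
) -> list[int]:
    """Draw clone sizes from the configured law until `n_cells` are covered.

    The last clone is truncated so sizes sum exactly to `n_cells`.
    """
    name, param = law
    sizes: list[int] = []
    remaining = n_cells
    while remaining > 0:
        if name == "power_law":
            size = int(min(rng.zipf(param), size_cap))
        else:
            size = int(rng.geometric(param))
        size = min(size, remaining)
        sizes.append(size)
        remaining -= size
    return sizes


def _random_cdr3(rng: np.random.Generator, n_codons_low=12, n_codons_high=19) -> str:
    length = 3 * int(rng.integers(n_codons_low, n_codons_high))
    return "".join(rng.choice(NT, size=length))


def _mutate(seq: str, n_mut: int, rng: np.random.Generator) -> str:
    if n_mut <= 0:
        return seq
    chars = list(seq)
    positions = rng.choice(len(chars), size=min(n_mut, len(chars)), replace=False)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = alternatives[int(rng.integers(3))]
    return "".join(chars)


def simulate_repertoire(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate an AIRR-style contig table plus per-cell metadata.

    Every cell gets one heavy+light (B) or beta+alpha (T) chain pair;
    with probability `decoy_prob` a second, lower-UMI contig of the same
    locus is added to exercise chain selection. Metadata carries the
    ground-truth clone id (``true_clone_id``) for recovery tests.
    """
    root = np.random.SeedSequence(config.seed)
    rng_structure, rng_seq, rng_counts = (
        np.random.default_rng(s) for s in root.spawn(3)
    )

    lineage_freq: dict[str, float] = {}
    lineage_subsets: dict[str, list[str]] = {}
    for subset, freq in config.subsets.items():
        lin = lineage_of(subset)
        lineage_freq[lin] = lineage_freq.get(lin, 0.0) + freq
        lineage_subsets.setdefault(lin, []).append(subset)

    isotypes = sorted(config.isotype_probs)
    isotype_p = np.array([config.isotype_probs[i] for i in isotypes])

    contig_rows: list[dict] = []
    meta_rows: list[dict] = []
    seen_junctions: set[str] = set()
    cell_counter = 0
    clone_counter = 0

    for p_idx in range(config.n_patients):
        patient = f"P{p_idx + 1}"
        group = "ME" if p_idx % 2 == 0 else "AE"
        total_cells = 2 * config.cells_per_sample
        for lin in sorted(lineage_subsets):
            lin_cells = int(round(total_cells * lineage_freq[lin]))
            if lin_cells == 0:
                continue
            sizes = sample_clone_sizes(config.clone_size_law, lin_cells,
                                       rng_structure)
            subs = lineage_subsets[lin]
            freqs = np.array([config.subsets[s] for s in subs])
            freqs = freqs / freqs.sum()
            for size in sizes:
                clone_counter += 1
                clone_id = f"TRUE_{patient}_{lin}_{clone_counter}"
                shared = rng_structure.random() < config.shared_clone_prob
                home_compartment = ("blood" if rng_structure.random() < 0.5
                                    else "tumour")
                clone_subsets = [subs[int(rng_structure.choice(len(subs), p=freqs))]]
                if len(subs) > 1 and rng_structure.random() < config.cross_subset_prob:
                    others = [s for s in subs if s != clone_subsets[0]]
                    clone_subsets.append(others[int(rng_structure.integers(len(others)))])

                # founder receptor; junctions unique across clones so the
                # ground-truth partition is recoverable
                while True:
                    heavy_junction = _random_cdr3(rng_seq)
                    if heavy_junction not in seen_junctions:
                        seen_junctions.add(heavy_junction)
                        break
                light_junction = _random_cdr3(rng_seq)
                if lin == "B":
                    heavy_locus, v_pool, j_pool = "IGH", IGHV_GENES, IGHJ_GENES
                    light_locus, lv_pool, lj_pool = (
                        ("IGK", IGKV_GENES, IGKJ_GENES)
                        if rng_seq.random() < 0.6
                        else ("IGL", IGLV_GENES, IGLJ_GENES))
                else:
                    heavy_locus, v_pool, j_pool = "TRB", TRBV_GENES, TRBJ_GENES
                    light_locus, lv_pool, lj_pool = "TRA", TRAV_GENES, TRAJ_GENES
                heavy_v = v_pool[int(rng_seq.integers(len(v_pool)))]
                heavy_j = j_pool[int(rng_seq.integers(len(j_pool)))]
                light_v = lv_pool[int(rng_seq.integers(len(lv_pool)))]
                light_j = lj_pool[int(rng_seq.integers(len(lj_pool)))]

                for _ in range(size):
                    cell_counter += 1
                    cell_id = f"{patient}_cell_{cell_counter:06d}"
                    if shared:
                        compartment = ("blood" if rng_structure.random() < 0.5
                                       else "tumour")
                    else:
                        compartment = home_compartment
                    subset = clone_subsets[
                        int(rng_structure.integers(len(clone_subsets)))]
                    sample_id = f"{patient}_{compartment}"

                    if lin == "B":
                        n_mut = int(rng_seq.poisson(config.shm_rate))
                        junction = _mutate(heavy_junction, n_mut, rng_seq)
                        v_identity = max(
                            0.0, 100.0 * (1.0 - n_mut / V_SEGMENT_LENGTH))
                        c_call = isotypes[int(rng_seq.choice(len(isotypes),
                                                             p=isotype_p))]
                        light_c = "IGKC" if light_locus == "IGK" else "IGLC1"
                    else:
                        junction = heavy_junction
                        v_identity = 100.0
                        c_call = "TRBC1"
                        light_c = "TRAC"

                    meta_rows.append({
                        "cell_id": cell_id, "patient": patient,
                        "sample_id": sample_id, "compartment": compartment,
                        "subset": subset, "lineage": lin, "group": group,
                        "receptor_class": "BCR" if lin == "B" else "TCR",
                        "true_clone_id": clone_id,
                    })

                    n_contig = 0
                    for locus, v, j, c, jx, ident in (
                        (heavy_locus, heavy_v, heavy_j, c_call, junction,
                         v_identity),
                        (light_locus, light_v, light_j, light_c,
                         light_junction, 100.0),
                    ):
                        n_contig += 1
                        umi = 2 + int(rng_counts.poisson(4))
                        contig_rows.append({
                            "cell_id": cell_id,
                            "sequence_id": f"{cell_id}_contig_{n_contig}",
                            "locus": locus, "v_call": v, "j_call": j,
                            "c_call": c, "junction": jx,
                            "junction_aa": translate(jx),
                            "duplicate_count": umi,
                            "consensus_count": umi * int(10 + rng_counts.poisson(5)),
                            "v_identity": round(ident, 4),
                            "v_sequence_length": V_SEGMENT_LENGTH,
                        })
                        if rng_counts.random() < config.decoy_prob:
                            n_contig += 1
                            decoy_junction = _random_cdr3(rng_seq)
                            decoy_umi = int(rng_counts.integers(1, umi))
                            contig_rows.append({
                                "cell_id": cell_id,
                                "sequence_id": f"{cell_id}_contig_{n_contig}",
                                "locus": locus,
                                "v_call": v_pool[int(rng_seq.integers(len(v_pool)))]
                                if locus == heavy_locus else
                                lv_pool[int(rng_seq.integers(len(lv_pool)))],
                                "j_call": j, "c_call": c,
                                "junction": decoy_junction,
                                "junction_aa": translate(decoy_junction),
                                "duplicate_count": decoy_umi,
                                "consensus_count": decoy_umi * 10,
                                "v_identity": round(ident, 4),
                                "v_sequence_length": V_SEGMENT_LENGTH,
                            })

    contigs = pd.DataFrame(contig_rows)
    meta = pd.DataFrame(meta_rows)
    return contigs, meta


def simulate_expression(config: SimConfig, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-cell gene counts: Bernoulli expression x (1 + negative binomial).

    A cell of subset s has a nonzero count of gene g with probability
    ``expr_fractions[s][g]`` exactly (genes unlisted for a subset are 0);
    nonzero magnitudes follow 1 + NB with mean tied to ``depth_mean``.
    """
    genes = sorted({g for fracs in config.expr_fractions.values() for g in fracs})
    if not genes:
        raise ConfigurationError("expr_fractions defines no genes")
    unknown = set(meta["subset"].astype(str)) - set(config.subsets)
    if unknown:
        raise ConfigurationError(f"unknown subsets in metadata: {sorted(unknown)}")

    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])
    n_cells = len(meta)
    prob = np.zeros((n_cells, len(genes)))
    subset_arr = meta["subset"].astype(str).to_numpy()
    for subset, fracs in config.expr_fractions.items():
        mask = subset_arr == subset
        if not mask.any():
            continue
        row = np.array([fracs.get(g, 0.0) for g in genes])
        prob[mask] = row

    expressed = rng.random((n_cells, len(genes))) < prob
    mu = max(config.depth_mean / len(genes) - 1.0, 0.1)
    r = 2.0
    p_nb = r / (r + mu)
    magnitude = 1 + rng.negative_binomial(r, p_nb, size=(n_cells, len(genes)))
    counts = expressed * magnitude
    return pd.DataFrame(counts, index=meta["cell_id"].to_numpy(), columns=genes)


def simulate_tcr_reference(
    contigs: pd.DataFrame,
    fraction: float = 0.1,
    seed: int = 0,
    antigen_category: str = "viral",
) -> pd.DataFrame:
    """Known-TCR reference covering a random fraction of generated TRBs."""
    rng = np.random.default_rng(seed)
    trb = contigs[contigs["locus"] == "TRB"]
    cdr3s = sorted(set(trb["junction_aa"]))
    n_pick = int(round(fraction * len(cdr3s)))
    picked = rng.choice(cdr3s, size=n_pick, replace=False) if n_pick else []
    return pd.DataFrame({
        "cdr3_aa": list(picked),
        "v_gene": ["" for _ in picked],
        "antigen_category": [antigen_category] * len(picked),
    })


# ---------------------------------------------------------------------------
# writers

def write_airr(contigs: pd.DataFrame, path) -> None:
    contigs.to_csv(path, sep="\t", index=False)


def write_meta(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def write_mtx(counts: pd.DataFrame, out_dir) -> None:
    """Write genes x cells MTX triplet with barcodes.tsv / features.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sparse = csr_matrix(counts.to_numpy().T)
    mmwrite(str(out / "matrix.mtx"), sparse)
    pd.Series(counts.index).to_csv(out / "barcodes.tsv", index=False, header=False)
    pd.Series(counts.columns).to_csv(out / "features.tsv", index=False, header=False)


def read_mtx(in_dir) -> pd.DataFrame:
    from scipy.io import mmread

    path = Path(in_dir)
    mat = mmread(str(path / "matrix.mtx")).toarray().T
    barcodes = pd.read_csv(path / "barcodes.tsv", header=None)[0].tolist()
    features = pd.read_csv(path / "features.tsv", header=None)[0].tolist()
    return pd.DataFrame(mat, index=barcodes, columns=features)
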