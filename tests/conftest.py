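import numpy as np
import pandas as pd
import pytest

from immunoclone import synthetic

# expression fractions with complete ligand-receptor pairs so the
# interaction tensor is non-trivial on the fixture
EXPR_FRACTIONS = {
    "B_naive": {"CD19": 0.9, "CXCL13": 0.3, "CD86": 0.4, "CD28": 0.0,
                "CCR4": 0.1, "CCL22": 0.1, "PDCD1": 0.0, "CD274": 0.2},
    "B_memory": {"CD19": 0.9, "CD27": 0.8, "CD86": 0.6, "CD28": 0.0,
                 "CCL22": 0.2, "CCR4": 0.1, "PDCD1": 0.1, "CD274": 0.2},
    "CD4_naive": {"CD3E": 0.9, "CD28": 0.7, "CCR4": 0.2, "CXCL13": 0.0,
                  "CD86": 0.0, "CCL22": 0.0, "PDCD1": 0.1, "CD274": 0.0},
    "CD4_Treg": {"CD3E": 0.9, "CD28": 0.8, "CCR4": 0.7, "CCL22": 0.1,
                 "CD86": 0.1, "CXCL13": 0.0, "PDCD1": 0.3, "CD274": 0.1},
    "CD8_naive": {"CD3E": 0.9, "CD28": 0.6, "CCR4": 0.1, "CD86": 0.0,
                  "CCL22": 0.0, "CXCL13": 0.0, "PDCD1": 0.1, "CD274": 0.0},
    "CD8_EM": {"CD3E": 0.9, "CD28": 0.4, "GZMB": 0.6, "PDCD1": 0.4,
               "CD86": 0.0, "CCL22": 0.1, "CCR4": 0.1, "CD274": 0.1},
}


@pytest.fixture(scope="session")
def sim_config():
    return synthetic.SimConfig(
        n_patients=2,
        cells_per_sample=250,
        shared_clone_prob=0.3,
        cross_subset_prob=0.15,
        shm_rate=1.0,
        expr_fractions=EXPR_FRACTIONS,
        seed=11,
    )


@pytest.fixture(scope="session")
def repertoire(sim_config):
    return synthetic.simulate_repertoire(sim_config)


@pytest.fixture(scope="session")
def expression(sim_config, repertoire):
    _, meta = repertoire
    return synthetic.simulate_expression(sim_config, meta)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_bcr_instance(rng, n_cells, n_clusters=None):
    """Random heavy-chain table for clone-calling oracle tests.

    Sequences are drawn around a few founders so the Hamming-1 and
    identical-CDR3 relations both fire.
    """
    if n_clusters is None:
        n_clusters = max(2, n_cells // 8)
    founders = []
    for _ in range(n_clusters):
        length = 3 * int(rng.integers(4, 8))
        founders.append("".join(rng.choice(list("ACGT"), size=length)))
    v_genes = [f"IGHV{f}-{n}*01" for f in (1, 3) for n in (7, 23)]
    j_genes = [f"IGHJ{n}*01" for n in (1, 4)]
    rows = []
    for i in range(n_cells):
        founder = founders[int(rng.integers(n_clusters))]
        seq = list(founder)
        for _ in range(int(rng.integers(0, 3))):
            pos = int(rng.integers(len(seq)))
            seq[pos] = rng.choice([b for b in "ACGT" if b != seq[pos]])
        rows.append({
            "cell_id": f"cell{i:04d}",
            "junction": "".join(seq),
            "v_call": v_genes[int(rng.integers(len(v_genes)))],
            "j_call": j_genes[int(rng.integers(len(j_genes)))],
        })
    return pd.DataFrame(rows)


def brute_force_bcr_partition(cells: pd.DataFrame) -> dict:
    """Independent transitive closure of the pairwise clone relation."""
    from immunoclone.clones import gene_family

    n = len(cells)
    seqs = cells["junction"].tolist()
    vfam = [gene_family(v) for v in cells["v_call"]]
    jfam = [gene_family(j) for j in cells["j_call"]]

    def related(i, j):
        a, b = seqs[i], seqs[j]
        if a == b:
            if vfam[i] == vfam[j] and jfam[i] == jfam[j]:
                return True
            return True  # identical sequence = same mutation-network node
        if len(a) == len(b):
            return sum(x != y for x, y in zip(a, b)) == 1
        return False

    labels = list(range(n))
    changed = True
    while changed:
        changed = False
        for i in range(n):
            for j in range(i + 1, n):
                if related(i, j) and labels[i] != labels[j]:
                    old, new = max(labels[i], labels[j]), min(labels[i], labels[j])
                    labels = [new if x == old else x for x in labels]
                    changed = True
    return dict(zip(cells["cell_id"], labels))


def partitions_equal(part_a: dict, part_b: dict) -> bool:
    keys = sorted(part_a)
    if keys != sorted(part_b):
        return False
    groups_a = {}
    groups_b = {}
    for k in keys:
        groups_a.setdefault(part_a[k], set()).add(k)
        groups_b.setdefault(part_b[k], set()).add(k)
    return set(map(frozenset, groups_a.values())) == set(map(frozenset, groups_b.values()))
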