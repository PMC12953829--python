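"""Independent oracles and random-object builders shared across tests.

Everything here is deliberately naive (brute force, enumeration, direct
numerical optimisation) and independent of the implementation paths it is
used to check.
"""

from __future__ import annotations

import itertools

import dendropy
import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def lcs_length(a: str, b: str) -> int:
    """Classic O(nm) longest-common-subsequence DP."""
    n, m = len(a), len(b)
    prev = [0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        ai = a[i - 1]
        for j in range(1, m + 1):
            if ai == b[j - 1]:
                cur[j] = prev[j - 1] + 1
            else:
                cur[j] = max(prev[j], cur[j - 1])
        prev = cur
    return prev[m]


def enumerate_motif_8mers() -> set[str]:
    """All 8-mers accepted by the cap-helix pattern, by direct product."""
    positions = ["N", "VI", "W", "C", "AS", "AG", "G", "K"]
    return {"".join(t) for t in itertools.product(*positions)}


def pileup_mean_depth(reads, gene_start, gene_end, contig_len):
    """Per-base pileup oracle for one gene on one contig.

    ``reads`` are (ref_start_0based, cigar) tuples; cigar is a list of
    (op, length) with op in "MIS" ("M" consumes both, "I"/"S" query only).
    gene coords 1-based inclusive.
    """
    depth = np.zeros(contig_len, dtype=int)
    for start, cigar in reads:
        pos = start
        for op, length in cigar:
            if op == "M":
                depth[pos : pos + length] += 1
                pos += length
            # I and S consume no reference
    total = depth[gene_start - 1 : gene_end].sum()
    return total / (gene_end - gene_start + 1)


def rmsd_rotation_search(P, Q, n_starts=16, seed=0):
    """RMSD oracle: direct numerical minimisation over proper rotations.

    For fixed rotation the optimal translation aligns centroids, so the
    search is over rotation vectors only, multi-start to dodge local minima.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)

    def objective(rotvec):
        R = Rotation.from_rotvec(rotvec).as_matrix()
        d = Pc @ R.T - Qc
        return float(np.mean(np.sum(d * d, axis=1)))

    rng = np.random.default_rng(seed)
    starts = [np.zeros(3)]
    for _ in range(n_starts - 1):
        v = rng.normal(size=3)
        v = v / np.linalg.norm(v) * rng.uniform(0, np.pi)
        starts.append(v)
    best = np.inf
    for s in starts:
        res = minimize(objective, s, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-15, "maxiter": 5000})
        best = min(best, res.fun)
    return float(np.sqrt(max(best, 0.0)))


def random_tree(rng: np.random.Generator, n_leaves: int):
    """Random binary tree with branch lengths, plus its true clades.

    Built by repeatedly joining two random subtrees; every join records the
    union of leaf labels, so the returned ``clades`` list is an
    implementation-independent catalogue of the tree's monophyletic groups.
    Returns ``(dendropy.Tree, leaf_labels, clades)``.
    """
    labels = [f"T{i}" for i in range(n_leaves)]
    subtrees = [(lab, frozenset([lab])) for lab in labels]
    clades = []
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        (nj, sj) = subtrees.pop(j)
        (ni, si) = subtrees.pop(i)
        bi = rng.uniform(0.1, 2.0)
        bj = rng.uniform(0.1, 2.0)
        merged = f"({ni}:{bi:.6f},{nj}:{bj:.6f})"
        leafset = si | sj
        if len(leafset) < n_leaves:  # skip the trivial full-set "clade"
            clades.append(leafset)
        subtrees.append((merged, leafset))
    newick = subtrees[0][0] + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    return tree, labels, clades


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Substitute n_subs distinct positions (no indels)."""
    out = list(seq)
    for pos in rng.choice(len(seq), size=n_subs, replace=False):
        choices = [a for a in AA20 if a != out[pos]]
        out[pos] = choices[int(rng.integers(len(choices)))]
    return "".join(out)
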