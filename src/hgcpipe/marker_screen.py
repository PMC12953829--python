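"""Candidate validation cascade for hgcA marker genes.

The cascade takes translated gene candidates (optionally carrying a
profile-search e-value) and produces a nonredundant set of validated HgcA
sequences: e-value gating, cap-helix motif verification, a minimum-length
filter, and redundancy collapse with one representative per cluster.
A tandem-hgcB neighbourhood check and simple taxonomy assignment are
provided alongside.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import Align

logger = logging.getLogger(__name__)

#: 20 standard residues plus ambiguity X.
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: Cap-helix motif N(V/I)WC(A/S)(A/G)GK.  X is absent from every character
#: class, so ambiguous residues never satisfy a constrained position.
CAP_HELIX_MOTIF = re.compile(r"N[VI]WC[AS][AG]GK")

#: Allowed residues per motif position (used by generators and enumeration).
CAP_HELIX_POSITIONS = ("N", "VI", "W", "C", "AS", "AG", "G", "K")

#: Ferredoxin-like cysteine cluster C-x2-C-x2-C-x3-C of the HgcB partner.
HGCB_CYS_MOTIF = re.compile(r"C.{2}C.{2}C.{3}C")

DEFAULT_EVALUE = 1e-25
DEFAULT_MIN_AA = 100
HGCB_MAX_DISTANCE_BP = 500
HGCB_MAX_AA = 100


@dataclass
class CandidateGene:
    """A translated gene with coordinates on its contig.

    Coordinates are 1-based inclusive.  ``evalue`` is the profile-search
    e-value when a hit table was supplied; ``None`` means the candidate
    entered through motif-anchored discovery.
    """

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    aa_sequence: str
    evalue: Optional[float] = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"{self.gene_id}: end < start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.aa_sequence:
            raise ValueError(f"{self.gene_id}: empty amino-acid sequence")
        bad = set(self.aa_sequence) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"{self.gene_id}: invalid residues {sorted(bad)} "
                "(sequences must be uppercase over the 20-letter alphabet plus X)"
            )
        if self.evalue is not None and self.evalue < 0:
            raise ValueError(f"{self.gene_id}: negative e-value")

    @property
    def length_aa(self) -> int:
        return len(self.aa_sequence)


@dataclass
class ValidatedHgcA:
    """A candidate that survived the full cascade."""

    gene_id: str
    aa_sequence: str
    motif_start: int  # 1-based residue index of the cap-helix motif
    cluster_id: str
    is_representative: bool
    taxonomy_label: str = "unassigned"
    taxonomy_source: str = "unassigned"  # {bin_map, best_hit, unassigned}


def gate_by_evalue(
    candidates: Sequence[CandidateGene], threshold: float = DEFAULT_EVALUE
) -> list[CandidateGene]:
    """Retain candidates whose e-value is at or below ``threshold``.

    Candidates without an e-value pass through unchanged: they come from
    motif-anchored discovery and are judged by the later stages only.
    """
    if threshold <= 0:
        raise ValueError("e-value threshold must be positive")
    for c in candidates:
        if c.evalue is not None and c.evalue < 0:
            raise ValueError(f"{c.gene_id}: negative e-value")
    return [c for c in candidates if c.evalue is None or c.evalue <= threshold]


def verify_motif(aa_sequence: str) -> Optional[int]:
    """Return the 1-based start of the first cap-helix motif match, or None."""
    if not aa_sequence:
        return None
    m = CAP_HELIX_MOTIF.search(aa_sequence)
    return m.start() + 1 if m else None


def filter_length(
    candidates: Sequence[CandidateGene], min_aa: int = DEFAULT_MIN_AA
) -> list[CandidateGene]:
    """Retain candidates of length >= ``min_aa`` (shorter ones discarded)."""
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    return [c for c in candidates if c.length_aa >= min_aa]


def dedup_identical(
    candidates: Sequence[CandidateGene],
) -> list[tuple[str, list[CandidateGene], CandidateGene]]:
    """Collapse redundant sequences into clusters.

    Two sequences share a cluster iff they are identical or one is an exact
    substring of the other.  The representative is the longest member, ties
    broken by lexicographically smallest gene_id.  Returns a list of
    ``(cluster_id, members, representative)`` ordered by representative
    gene_id; the result is independent of input order.
    """
    if not candidates:
        raise ValueError("dedup_identical requires a non-empty candidate set")
    ordered = sorted(candidates, key=lambda c: (-c.length_aa, c.gene_id))
    reps: list[CandidateGene] = []
    members: dict[str, list[CandidateGene]] = {}
    for cand in ordered:
        for rep in reps:
            if cand.aa_sequence in rep.aa_sequence:
                members[rep.gene_id].append(cand)
                break
        else:
            reps.append(cand)
            members[cand.gene_id] = [cand]
    reps.sort(key=lambda c: c.gene_id)
    out = []
    for i, rep in enumerate(reps):
        cluster_id = f"cluster_{i + 1:04d}"
        out.append((cluster_id, members[rep.gene_id], rep))
    return out


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1
_aligner.mismatch_score = 0
_aligner.open_gap_score = 0
_aligner.extend_gap_score = 0


def global_identity(a: str, b: str) -> float:
    """Pairwise identity: aligned matches / length of the shorter sequence.

    Matches are counted under a global alignment that maximises the number
    of identical aligned residues (match 1, mismatch/gap 0), so the score
    equals the maximum achievable match count.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    matches = _aligner.score(a, b)
    return matches / min(len(a), len(b))


def select_representatives(
    sequences: Mapping[str, str] | Sequence[tuple[str, str]],
    identity: float = 0.5,
) -> list[str]:
    """Greedy representative selection at a pairwise-identity threshold.

    Sequences are visited in decreasing length order (ties by id); each
    sequence joins the first existing representative with identity >=
    ``identity`` (matches over shorter-sequence length), otherwise it founds
    a new cluster.  Returns representative ids in founding order.
    """
    if not 0 < identity <= 1:
        raise ValueError("identity threshold must be in (0, 1]")
    items = list(sequences.items()) if isinstance(sequences, Mapping) else list(sequences)
    if not items:
        return []
    items.sort(key=lambda kv: (-len(kv[1]), kv[0]))
    reps: list[tuple[str, str]] = []
    for sid, seq in items:
        for rid, rseq in reps:
            if global_identity(seq, rseq) >= identity:
                break
        else:
            reps.append((sid, seq))
    return [rid for rid, _ in reps]


def check_hgcB(
    hgcA: CandidateGene,
    neighbors: Iterable[CandidateGene],
    max_distance: int = HGCB_MAX_DISTANCE_BP,
) -> Optional[str]:
    """Find a tandem hgcB partner directly downstream of an hgcA gene.

    A partner must lie on the same contig and strand, start within
    ``max_distance`` bp downstream of hgcA's stop, be shorter than 100 aa,
    and contain at least two non-overlapping C-x2-C-x2-C-x3-C motifs.
    Returns the gene_id of the closest such neighbour, or None.
    """
    hits: list[tuple[int, str]] = []
    for n in neighbors:
        if n.contig_id != hgcA.contig_id or n.strand != hgcA.strand:
            continue
        if n.gene_id == hgcA.gene_id:
            continue
        if hgcA.strand == "+":
            gap = n.start - hgcA.end
        else:
            gap = hgcA.start - n.end
        if not (0 < gap <= max_distance):
            continue
        if n.length_aa >= HGCB_MAX_AA:
            continue
        if len(HGCB_CYS_MOTIF.findall(n.aa_sequence)) < 2:
            continue
        hits.append((gap, n.gene_id))
    if not hits:
        return None
    hits.sort()
    return hits[0][1]


def assign_taxonomy(
    gene_id: str,
    bin_map: Optional[pd.DataFrame] = None,
    best_hit: Optional[pd.DataFrame] = None,
) -> tuple[str, str]:
    """Resolve a taxonomy label for a gene.

    A genome-bin mapping (columns: gene_id, taxonomy, optionally bin_id)
    takes precedence; otherwise the top-ranked row of a best-hit table
    (columns: gene_id, taxonomy, rank) is used; otherwise "unassigned".
    Conflicting duplicate bin-map rows for a gene are rejected.
    """
    if bin_map is not None and len(bin_map):
        rows = bin_map[bin_map["gene_id"] == gene_id]
        if len(rows):
            labels = rows["taxonomy"].unique()
            if len(labels) > 1:
                raise ValueError(
                    f"{gene_id}: conflicting bin-map taxonomy {sorted(labels)}"
                )
            return str(labels[0]), "bin_map"
    if best_hit is not None and len(best_hit):
        rows = best_hit[best_hit["gene_id"] == gene_id]
        if len(rows):
            rows = rows.sort_values(["rank", "taxonomy"], kind="stable")
            return str(rows.iloc[0]["taxonomy"]), "best_hit"
    return "unassigned", "unassigned"


def screen(
    candidates: Sequence[CandidateGene],
    *,
    evalue_threshold: float = DEFAULT_EVALUE,
    min_aa: int = DEFAULT_MIN_AA,
    bin_map: Optional[pd.DataFrame] = None,
    best_hits: Optional[pd.DataFrame] = None,
) -> list[ValidatedHgcA]:
    """Run the full validation cascade.

    Order: e-value gate -> cap-helix motif verification -> minimum-length
    filter -> redundancy collapse, then taxonomy attachment.  Per-stage
    removal counts are logged.  Output is deterministically ordered by
    (cluster_id, gene_id) and independent of input order.
    """
    cands = sorted(candidates, key=lambda c: c.gene_id)
    n0 = len(cands)
    gated = gate_by_evalue(cands, evalue_threshold)
    motif_pass = [c for c in gated if verify_motif(c.aa_sequence) is not None]
    long_enough = filter_length(motif_pass, min_aa)
    logger.info(
        "screen: %d candidates; %d removed by e-value gate; %d lacking motif; "
        "%d shorter than %d aa; %d entering dedup",
        n0, n0 - len(gated), len(gated) - len(motif_pass),
        len(motif_pass) - len(long_enough), min_aa, len(long_enough),
    )
    if not long_enough:
        return []
    clusters = dedup_identical(long_enough)
    out: list[ValidatedHgcA] = []
    for cluster_id, members, rep in clusters:
        for cand in sorted(members, key=lambda c: c.gene_id):
            label, source = assign_taxonomy(cand.gene_id, bin_map, best_hits)
            motif_start = verify_motif(cand.aa_sequence)
            assert motif_start is not None
            out.append(
                ValidatedHgcA(
                    gene_id=cand.gene_id,
                    aa_sequence=cand.aa_sequence,
                    motif_start=motif_start,
                    cluster_id=cluster_id,
                    is_representative=cand.gene_id == rep.gene_id,
                    taxonomy_label=label,
                    taxonomy_source=source,
                )
            )
    out.sort(key=lambda v: (v.cluster_id, v.gene_id))
    logger.info("screen: %d validated sequences in %d clusters", len(out), len(clusters))
    return out


def representatives(validated: Iterable[ValidatedHgcA]) -> list[ValidatedHgcA]:
    """The one-per-cluster representative subset of a screen result."""
    return [v for v in validated if v.is_representative]


def parse_hits_table(path: str, dialect: str = "tsv") -> pd.DataFrame:
    """Read a hit table mapping gene_id to e-value.

    ``dialect`` is either "tsv" (two columns: gene_id, evalue, with header)
    or "tblout" (HMMER3 per-target table: whitespace-separated, '#' comments,
    target name in column 1 and full-sequence e-value in column 5).
    """
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t")
        if not {"gene_id", "evalue"}.issubset(df.columns):
            raise ValueError("hit table needs columns: gene_id, evalue")
        return df[["gene_id", "evalue"]].astype({"evalue": float})
    if dialect == "tblout":
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                parts = line.split()
                rows.append((parts[0], float(parts[4])))
        return pd.DataFrame(rows, columns=["gene_id", "evalue"])
    raise ValueError(f"unknown hit-table dialect: {dialect}")
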