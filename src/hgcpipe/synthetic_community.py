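"""Seeded generator of stratified water-column metagenome fixtures.

Builds a synthetic community of taxa with known genome structure: every
genome emits ten universal single-copy marker genes, and carrier genomes
additionally emit a tandem hgcA/hgcB pair whose cap-helix motif variant is
planted at a known position.  Per-sample gene coverage is drawn from each
taxon's community fraction (which varies with depth zone and FL/PA
lifestyle) times the target genome-equivalent count, with multiplicative
lognormal noise.  The planted truth (carrier fractions, true depths, taxon
fractions, decoy labels) is emitted alongside so downstream recovery can be
scored exactly.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .ecology import ZONES, classify_zone
from .marker_screen import CAP_HELIX_MOTIF, CAP_HELIX_POSITIONS, HGCB_CYS_MOTIF

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: All 8 cap-helix motif variants accepted by the degenerate pattern.
MOTIF_VARIANTS = tuple(
    f"N{v}WC{a}{g}GK" for v in "VI" for a in "AS" for g in "AG"
)

#: One fixed codon per residue, for reverse translation onto contigs.
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}

N_MARKERS = 10
MARKER_AA = 300  # 900 bp
HGCB_AA = 90
HGCB_GAP_BP = 20
INTERGENIC_BP = 20


@dataclass
class TaxonSpec:
    """A community member with known genome structure and ecology."""

    taxon_id: str
    phylum_label: str
    genome_size: int
    carries_hgcAB: bool
    zone_affinity: Mapping[str, float]
    motif_variant: str = "NVWCAAGK"
    lifestyle_bias: float = 0.0  # >0 prefers PA, <0 prefers FL (log2 units)

    def __post_init__(self) -> None:
        if self.genome_size <= 0:
            raise ValueError(f"{self.taxon_id}: genome_size must be positive")
        weights = [self.zone_affinity.get(z, 0.0) for z in ZONES]
        if any(w < 0 for w in weights):
            raise ValueError(f"{self.taxon_id}: negative zone affinity")
        if not any(w > 0 for w in weights):
            raise ValueError(f"{self.taxon_id}: all zone affinities are zero")
        if self.carries_hgcAB and not CAP_HELIX_MOTIF.fullmatch(self.motif_variant):
            raise ValueError(
                f"{self.taxon_id}: motif_variant {self.motif_variant!r} does not "
                "match the degenerate cap-helix pattern"
            )


@dataclass
class SampleDesign:
    """One metagenomic sample: a depth, a size fraction, a sequencing effort."""

    sample_id: str
    depth: float
    lifestyle: str  # "FL" or "PA"
    target_genome_equivalents: float
    noise_cv: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.depth <= 300:
            raise ValueError(f"{self.sample_id}: depth outside [0, 300] m")
        if self.lifestyle not in ("FL", "PA"):
            raise ValueError(f"{self.sample_id}: lifestyle must be FL or PA")
        if self.target_genome_equivalents <= 0:
            raise ValueError(f"{self.sample_id}: genome equivalents must be positive")
        if self.noise_cv < 0:
            raise ValueError(f"{self.sample_id}: noise_cv must be >= 0")


@dataclass
class TruthTable:
    """Planted truth for recovery scoring.

    samples: sample_id, carrier_fraction_pct (pre-noise).
    gene_depth: gene_id, sample_id, true_depth (pre-noise).
    taxa: taxon_id, sample_id, fraction (relative abundance, sums to 1).
    roles: gene_id, taxon_id, role, is_hgcA.
    """

    samples: pd.DataFrame
    gene_depth: pd.DataFrame
    taxa: pd.DataFrame
    roles: pd.DataFrame


@dataclass
class CommunityFixture:
    """In-memory fixture bundle; ``write`` serialises it to plain text."""

    contigs: dict[str, str]
    proteins: dict[str, str]
    genes: pd.DataFrame  # gene_id, contig_id, start, end, strand
    depth: pd.DataFrame  # gene_id, length_bp, one column per sample_id
    metadata: pd.DataFrame  # sample_id, depth_m, fraction
    markers: pd.DataFrame  # gene_id, family
    truth: TruthTable
    config: dict

    @property
    def sample_ids(self) -> list[str]:
        return list(self.metadata["sample_id"])

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_fasta(outdir / "contigs.fna", self.contigs)
        _write_fasta(outdir / "proteins.faa", self.proteins)
        kw = dict(sep="\t", index=False, float_format="%.10g", lineterminator="\n")
        self.genes.to_csv(outdir / "genes.tsv", **kw)
        self.depth.to_csv(outdir / "depth.tsv", **kw)
        self.metadata.to_csv(outdir / "metadata.tsv", **kw)
        self.markers.to_csv(outdir / "markers.tsv", **kw)
        self.truth.samples.to_csv(outdir / "truth_samples.tsv", **kw)
        self.truth.gene_depth.to_csv(outdir / "truth_genes.tsv", **kw)
        self.truth.taxa.to_csv(outdir / "truth_taxa.tsv", **kw)
        self.truth.roles.to_csv(outdir / "truth_roles.tsv", **kw)
        with open(outdir / "run_config.json", "w") as fh:
            json.dump(self.config, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _write_fasta(path: Path, records: Mapping[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in records:
            seq = records[name]
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _random_protein(rng: np.random.Generator, length: int) -> str:
    """Random protein with no accidental cap-helix motif."""
    while True:
        seq = "".join(rng.choice(list(AA20), size=length))
        if not CAP_HELIX_MOTIF.search(seq):
            return seq


def _hgcA_protein(rng: np.random.Generator, motif_variant: str, length: int) -> str:
    """Protein of the given length carrying exactly one planted motif."""
    while True:
        backbone = _random_protein(rng, length)
        pos = int(rng.integers(20, length - 20 - len(motif_variant)))
        seq = backbone[:pos] + motif_variant + backbone[pos + len(motif_variant):]
        matches = list(CAP_HELIX_MOTIF.finditer(seq))
        if len(matches) == 1 and matches[0].start() == pos:
            return seq


def _hgcB_protein(rng: np.random.Generator) -> str:
    """90-aa ferredoxin-like protein with two planted C-x2-C-x2-C-x3-C motifs."""
    motif_len = 11
    while True:
        seq = list(_random_protein(rng, HGCB_AA))
        for anchor in (9, 39):
            block = _random_protein(rng, motif_len)
            block = "C" + block[1:3] + "C" + block[4:6] + "C" + block[7:10] + "C"
            seq[anchor : anchor + motif_len] = block
        seq = "".join(seq)
        if len(HGCB_CYS_MOTIF.findall(seq)) >= 2 and not CAP_HELIX_MOTIF.search(seq):
            return seq


def _violated_motif(rng: np.random.Generator) -> str:
    """An 8-mer violating the cap-helix pattern at >= 1 constrained position."""
    base = list(MOTIF_VARIANTS[int(rng.integers(len(MOTIF_VARIANTS)))])
    pos = int(rng.integers(8))
    allowed = set(CAP_HELIX_POSITIONS[pos])
    choices = [a for a in AA20 if a not in allowed]
    base[pos] = choices[int(rng.integers(len(choices)))]
    return "".join(base)


def _reverse_translate(aa: str) -> str:
    return "".join(_CODON[r] for r in aa) + "TAA"


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Mean-1 multiplicative lognormal noise with the stated CV."""
    if cv == 0:
        return np.ones(n)
    sigma2 = math.log(1.0 + cv * cv)
    sigma = math.sqrt(sigma2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=sigma, size=n)


def taxon_fractions(
    taxa: Sequence[TaxonSpec], design: SampleDesign
) -> dict[str, float]:
    """Pre-noise relative abundance of each taxon in one sample.

    Weight = zone affinity at the sample's depth zone, times a lifestyle
    factor 2**(+bias) in PA samples and 2**(-bias) in FL samples; fractions
    are the normalised weights.
    """
    zone = classify_zone(design.depth)
    weights = {}
    for t in taxa:
        b = 2.0 ** t.lifestyle_bias if design.lifestyle == "PA" else 2.0 ** -t.lifestyle_bias
        weights[t.taxon_id] = t.zone_affinity.get(zone, 0.0) * b
    total = sum(weights.values())
    if total <= 0:
        raise ValueError(f"{design.sample_id}: no taxon has affinity for zone {zone}")
    return {tid: w / total for tid, w in weights.items()}


def build_community(
    taxa: Sequence[TaxonSpec],
    designs: Sequence[SampleDesign],
    seed: int,
) -> CommunityFixture:
    """Generate a full fixture bundle with planted truth.

    Deterministic for a fixed (taxa, designs, seed): identical calls produce
    byte-identical files from :meth:`CommunityFixture.write`.
    """
    if not taxa:
        raise ValueError("empty taxa list")
    if not any(t.carries_hgcAB for t in taxa):
        raise ValueError("need at least one hgcAB carrier taxon")
    if not any(not t.carries_hgcAB for t in taxa):
        raise ValueError("need at least one non-carrier taxon")
    tids = [t.taxon_id for t in taxa]
    if len(set(tids)) != len(tids):
        raise ValueError("duplicate taxon_id")
    sids = [d.sample_id for d in designs]
    if len(set(sids)) != len(sids):
        raise ValueError("duplicate sample_id")
    if not designs:
        raise ValueError("empty sample design list")

    rng = np.random.default_rng(seed)

    contigs: dict[str, str] = {}
    proteins: dict[str, str] = {}
    gene_rows = []  # gene_id, contig_id, start, end, strand
    role_rows = []  # gene_id, taxon_id, role, is_hgcA
    marker_rows = []
    seen_hgcA: set[str] = set()

    for t in taxa:
        contig_id = f"{t.taxon_id}_contig"
        genes: list[tuple[str, str, str]] = []  # gene_id, role, aa
        for k in range(N_MARKERS):
            genes.append((f"{t.taxon_id}_marker{k:02d}", f"marker_{k:02d}",
                          _random_protein(rng, MARKER_AA)))
        if t.carries_hgcAB:
            length = int(rng.integers(150, 351))
            aa = _hgcA_protein(rng, t.motif_variant, length)
            while aa in seen_hgcA:  # enforce nonredundancy of planted carriers
                aa = _hgcA_protein(rng, t.motif_variant, length)
            seen_hgcA.add(aa)
            genes.append((f"{t.taxon_id}_hgcA", "hgcA", aa))
            genes.append((f"{t.taxon_id}_hgcB", "hgcB", _hgcB_protein(rng)))
        _lay_out_contig(rng, contig_id, genes, contigs, proteins, gene_rows)
        for gid, role, _aa in genes:
            is_marker = role.startswith("marker")
            role_name = "marker" if is_marker else role
            role_rows.append((gid, t.taxon_id, role_name, role == "hgcA"))
            if is_marker:
                marker_rows.append((gid, role))

    # --- coverage ---------------------------------------------------------
    genes_df = pd.DataFrame(
        gene_rows, columns=["gene_id", "contig_id", "start", "end", "strand"]
    )
    roles_df = pd.DataFrame(role_rows, columns=["gene_id", "taxon_id", "role", "is_hgcA"])
    genes_by_taxon = roles_df.groupby("taxon_id")["gene_id"].apply(list).to_dict()
    lengths = dict(zip(genes_df["gene_id"], genes_df["end"] - genes_df["start"] + 1))

    depth_df = pd.DataFrame({"gene_id": genes_df["gene_id"]})
    depth_df["length_bp"] = depth_df["gene_id"].map(lengths)

    truth_sample_rows = []
    truth_gene_rows = []
    truth_taxon_rows = []
    meta_rows = []
    for d in designs:
        fractions = taxon_fractions(taxa, d)
        carrier_pct = 100.0 * sum(
            fractions[t.taxon_id] for t in taxa if t.carries_hgcAB
        )
        truth_sample_rows.append((d.sample_id, carrier_pct))
        col = np.zeros(len(depth_df))
        gene_index = {g: i for i, g in enumerate(depth_df["gene_id"])}
        for t in taxa:
            true_depth = fractions[t.taxon_id] * d.target_genome_equivalents
            gids = genes_by_taxon[t.taxon_id]
            noise = _lognormal_factors(rng, d.noise_cv, len(gids))
            for gid, eps in zip(gids, noise):
                col[gene_index[gid]] = true_depth * eps
                truth_gene_rows.append((gid, d.sample_id, true_depth))
            truth_taxon_rows.append((t.taxon_id, d.sample_id, fractions[t.taxon_id]))
        depth_df[d.sample_id] = col
        meta_rows.append((d.sample_id, d.depth, "3um" if d.lifestyle == "PA" else "0.22um"))

    truth = TruthTable(
        samples=pd.DataFrame(truth_sample_rows, columns=["sample_id", "carrier_fraction_pct"]),
        gene_depth=pd.DataFrame(truth_gene_rows, columns=["gene_id", "sample_id", "true_depth"]),
        taxa=pd.DataFrame(truth_taxon_rows, columns=["taxon_id", "sample_id", "fraction"]),
        roles=roles_df,
    )
    config = {
        "seed": seed,
        "n_taxa": len(taxa),
        "n_carriers": sum(t.carries_hgcAB for t in taxa),
        "taxa": [
            {
                "taxon_id": t.taxon_id,
                "phylum_label": t.phylum_label,
                "genome_size": t.genome_size,
                "carries_hgcAB": t.carries_hgcAB,
                "motif_variant": t.motif_variant,
                "zone_affinity": {z: t.zone_affinity.get(z, 0.0) for z in ZONES},
                "lifestyle_bias": t.lifestyle_bias,
            }
            for t in taxa
        ],
        "designs": [
            {
                "sample_id": d.sample_id,
                "depth": d.depth,
                "lifestyle": d.lifestyle,
                "target_genome_equivalents": d.target_genome_equivalents,
                "noise_cv": d.noise_cv,
            }
            for d in designs
        ],
        "decoys": {"n_paralogs": 0, "n_fragments": 0},
    }
    return CommunityFixture(
        contigs=contigs,
        proteins=proteins,
        genes=genes_df,
        depth=depth_df,
        metadata=pd.DataFrame(meta_rows, columns=["sample_id", "depth_m", "fraction"]),
        markers=pd.DataFrame(marker_rows, columns=["gene_id", "family"]),
        truth=truth,
        config=config,
    )


def _lay_out_contig(rng, contig_id, genes, contigs, proteins, gene_rows) -> None:
    """Place genes consecutively on one contig (all forward strand).

    The hgcB gene starts exactly HGCB_GAP_BP after the hgcA stop; other
    genes are separated by INTERGENIC_BP of random sequence.
    """
    parts: list[str] = []
    cursor = 0
    prev_role = None
    for gid, role, aa in genes:
        gap = HGCB_GAP_BP if role == "hgcB" and prev_role == "hgcA" else INTERGENIC_BP
        spacer = "".join(rng.choice(list("ACGT"), size=gap))
        parts.append(spacer)
        cursor += gap
        nt = _reverse_translate(aa)
        start = cursor + 1  # 1-based inclusive
        end = cursor + len(nt)
        parts.append(nt)
        cursor = end
        gene_rows.append((gid, contig_id, start, end, "+"))
        proteins[gid] = aa
        prev_role = role
    contigs[contig_id] = "".join(parts)


def plant_decoys(
    fixture: CommunityFixture,
    n_paralogs: int,
    n_fragments: int,
    seed: int,
) -> CommunityFixture:
    """Return a copy of the fixture with decoy genes planted.

    Paralog decoys are full-length proteins whose motif-like window violates
    at least one constrained position (and which contain no genuine motif);
    fragment decoys are true motifs embedded in sub-100-aa proteins.  All
    decoys are marked non-hgcA in the truth table and receive low coverage.
    """
    if n_paralogs < 0 or n_fragments < 0:
        raise ValueError("decoy counts must be >= 0")
    fx = copy.deepcopy(fixture)
    rng = np.random.default_rng(seed)

    decoys: list[tuple[str, str, str]] = []
    for i in range(n_paralogs):
        length = int(rng.integers(150, 301))
        backbone = _random_protein(rng, length)
        pos = int(rng.integers(10, length - 18))
        bad = _violated_motif(rng)
        seq = backbone[:pos] + bad + backbone[pos + 8:]
        while CAP_HELIX_MOTIF.search(seq):
            backbone = _random_protein(rng, length)
            seq = backbone[:pos] + bad + backbone[pos + 8:]
        decoys.append((f"decoyP{i:03d}", "paralog_decoy", seq))
    for i in range(n_fragments):
        length = int(rng.integers(60, 100))
        variant = MOTIF_VARIANTS[int(rng.integers(len(MOTIF_VARIANTS)))]
        decoys.append((f"decoyF{i:03d}", "fragment_decoy",
                       _hgcA_protein(rng, variant, length)))

    gene_rows: list[tuple] = []
    role_rows = []
    for gid, role, aa in decoys:
        contig_id = f"{gid}_contig"
        _lay_out_contig(rng, contig_id, [(gid, role, aa)], fx.contigs, fx.proteins, gene_rows)
        role_rows.append((gid, gid, role, False))

    if decoys:
        new_genes = pd.DataFrame(
            gene_rows, columns=["gene_id", "contig_id", "start", "end", "strand"]
        )
        fx.genes = pd.concat([fx.genes, new_genes], ignore_index=True)
        new_depth = pd.DataFrame({"gene_id": new_genes["gene_id"]})
        new_depth["length_bp"] = new_genes["end"] - new_genes["start"] + 1
        truth_gene_rows = []
        for d in fx.config["designs"]:
            ge = d["target_genome_equivalents"]
            true_depth = 0.01 * ge
            noise = _lognormal_factors(rng, d["noise_cv"], len(decoys))
            new_depth[d["sample_id"]] = true_depth * noise
            for gid, _role, _aa in decoys:
                truth_gene_rows.append((gid, d["sample_id"], true_depth))
        fx.depth = pd.concat([fx.depth, new_depth], ignore_index=True)
        fx.truth.gene_depth = pd.concat(
            [fx.truth.gene_depth,
             pd.DataFrame(truth_gene_rows, columns=["gene_id", "sample_id", "true_depth"])],
            ignore_index=True,
        )
        fx.truth.roles = pd.concat(
            [fx.truth.roles,
             pd.DataFrame(role_rows, columns=["gene_id", "taxon_id", "role", "is_hgcA"])],
            ignore_index=True,
        )
    fx.config = dict(fx.config)
    fx.config["decoys"] = {
        "n_paralogs": fx.config["decoys"]["n_paralogs"] + n_paralogs,
        "n_fragments": fx.config["decoys"]["n_fragments"] + n_fragments,
        "decoy_seed": seed,
    }
    return fx


def profile_taxa(
    zone_carrier_fraction: Mapping[str, float],
    n_carriers: int,
    n_noncarriers: int,
    rng: Optional[np.random.Generator] = None,
    lifestyle_bias: float = 0.0,
) -> list[TaxonSpec]:
    """Construct a taxon set realising target carrier fractions per zone.

    ``zone_carrier_fraction`` maps each zone to the community fraction (0-1)
    that hgcAB carriers should jointly occupy there; carriers split that
    fraction evenly, non-carriers split the complement evenly.  Motif
    variants cycle through all eight accepted degeneracies.
    """
    for z, f in zone_carrier_fraction.items():
        if z not in ZONES:
            raise ValueError(f"unknown zone {z!r}")
        if not 0 <= f <= 1:
            raise ValueError(f"carrier fraction for {z} outside [0, 1]")
    if n_carriers < 1 or n_noncarriers < 1:
        raise ValueError("need at least one carrier and one non-carrier")
    taxa = []
    for i in range(n_carriers):
        aff = {z: zone_carrier_fraction.get(z, 0.0) / n_carriers for z in ZONES}
        taxa.append(
            TaxonSpec(
                taxon_id=f"carrier{i:03d}",
                phylum_label=f"phylum_{i % 6}",
                genome_size=4_000_000,
                carries_hgcAB=True,
                motif_variant=MOTIF_VARIANTS[i % len(MOTIF_VARIANTS)],
                zone_affinity=aff,
                lifestyle_bias=lifestyle_bias,
            )
        )
    for i in range(n_noncarriers):
        aff = {z: (1.0 - zone_carrier_fraction.get(z, 0.0)) / n_noncarriers for z in ZONES}
        taxa.append(
            TaxonSpec(
                taxon_id=f"noncarrier{i:03d}",
                phylum_label=f"phylum_nc{i % 6}",
                genome_size=3_000_000,
                carries_hgcAB=False,
                zone_affinity=aff,
            )
        )
    return taxa


def default_designs(
    depths: Sequence[float] = (0, 30, 50, 90, 120, 140, 170),
    lifestyles: Sequence[str] = ("FL", "PA"),
    genome_equivalents: float = 50.0,
    noise_cv: float = 0.1,
) -> list[SampleDesign]:
    """The 7-depth x 2-lifestyle water-column sampling design."""
    return [
        SampleDesign(
            sample_id=f"{lf}_{int(d):03d}m",
            depth=float(d),
            lifestyle=lf,
            target_genome_equivalents=genome_equivalents,
            noise_cv=noise_cv,
        )
        for d in depths
        for lf in lifestyles
    ]
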