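"""Length-normalised coverage, genome equivalents, relative abundance.

Coverage is the mean per-base depth of a gene (aligned bases overlapping the
gene interval divided by gene length), taken either from primary SAM
alignments or from a precomputed per-gene depth table.  The genome
equivalent of a sample is estimated as the median summed depth of universal
single-copy marker-gene families, and the relative abundance of a gene is
its coverage divided by the genome equivalent, times 100 — the percentage of
genomes in the sample that carry the gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

MIN_MARKERS = 3


@dataclass
class CoverageRecord:
    gene_id: str
    sample_id: str
    gene_length: int
    mean_depth: float

    def __post_init__(self) -> None:
        if self.gene_length <= 0:
            raise ValueError(f"{self.gene_id}: gene_length must be positive")
        if self.mean_depth < 0:
            raise ValueError(f"{self.gene_id}: negative mean_depth")


@dataclass
class GenomeEquivalent:
    sample_id: str
    value: float

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError(f"{self.sample_id}: genome equivalent must be positive")


@dataclass
class AbundanceRecord:
    gene_id: str
    sample_id: str
    rel_abundance: float  # percent of genomes carrying the gene
    taxonomy_label: str = "unassigned"


def coverage_from_sam(
    sam_path: str | Path,
    gene_table: pd.DataFrame,
    sample_id: str,
) -> list[CoverageRecord]:
    """Length-normalised gene coverage from primary SAM alignments.

    ``gene_table`` columns: gene_id, contig_id, start, end (1-based
    inclusive).  mean_depth = total aligned bases overlapping the gene
    interval / gene length.  Secondary, supplementary and unmapped records
    are skipped; genes whose interval exceeds their contig are dropped with
    a warning.
    """
    with pysam.AlignmentFile(str(sam_path), "r") as sam:
        contig_len = dict(zip(sam.references, sam.lengths))
        genes: dict[str, list[tuple[str, int, int]]] = {}
        kept: list[tuple[str, int]] = []
        for row in gene_table.itertuples(index=False):
            clen = contig_len.get(row.contig_id)
            if clen is None or row.start < 1 or row.end > clen:
                logger.warning(
                    "gene %s interval [%d, %d] outside contig %s; skipped",
                    row.gene_id, row.start, row.end, row.contig_id,
                )
                continue
            genes.setdefault(row.contig_id, []).append(
                (row.gene_id, row.start - 1, row.end)  # 0-based half-open
            )
            kept.append((row.gene_id, row.end - row.start + 1))
        aligned: dict[str, int] = {gid: 0 for gid, _ in kept}
        for read in sam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            intervals = genes.get(read.reference_name)
            if not intervals:
                continue
            for block_start, block_end in read.get_blocks():
                for gid, gstart, gend in intervals:
                    ov = min(block_end, gend) - max(block_start, gstart)
                    if ov > 0:
                        aligned[gid] += ov
    return [
        CoverageRecord(gene_id=gid, sample_id=sample_id,
                       gene_length=length, mean_depth=aligned[gid] / length)
        for gid, length in kept
    ]


def coverage_from_depth_table(
    depth: pd.DataFrame | str | Path,
    samples: Optional[Sequence[str]] = None,
) -> list[CoverageRecord]:
    """Coverage records from a per-gene depth table.

    The table has columns gene_id, length_bp, then one mean-depth column per
    sample (the jgi-style summary dialect; any '-var' variance columns are
    ignored).  Values are validated and passed through.
    """
    if not isinstance(depth, pd.DataFrame):
        depth = pd.read_csv(depth, sep="\t")
    required = {"gene_id", "length_bp"}
    if not required.issubset(depth.columns):
        raise ValueError("depth table needs columns: gene_id, length_bp, <samples...>")
    sample_cols = [
        c for c in depth.columns
        if c not in required and not c.endswith("-var")
    ]
    if samples is not None:
        missing = set(samples) - set(sample_cols)
        if missing:
            raise ValueError(f"samples missing from depth table: {sorted(missing)}")
        sample_cols = list(samples)
    records = []
    for row in depth.itertuples(index=False):
        for s in sample_cols:
            records.append(
                CoverageRecord(
                    gene_id=row.gene_id,
                    sample_id=s,
                    gene_length=int(row.length_bp),
                    mean_depth=float(getattr(row, s)),
                )
            )
    return records


def estimate_genome_equivalents(
    marker_coverages: Sequence[CoverageRecord],
    families: Optional[Mapping[str, str]] = None,
) -> GenomeEquivalent:
    """Median single-copy-marker depth of one sample.

    Every genome carries one copy of each universal marker family, so the
    summed depth of a family across the community estimates the number of
    genome copies in the sample; the median across families is robust to
    mismapped-depth outliers.  ``families`` maps gene_id -> marker family;
    without it each record is its own family (one marker gene per genome).
    Fewer than three families is an error — supply explicit genome
    equivalents instead.
    """
    if not marker_coverages:
        raise ValueError("no marker coverage records")
    sample_ids = {r.sample_id for r in marker_coverages}
    if len(sample_ids) != 1:
        raise ValueError(f"marker records span multiple samples: {sorted(sample_ids)}")
    sample_id = sample_ids.pop()
    if families:
        sums: dict[str, float] = {}
        for r in marker_coverages:
            fam = families.get(r.gene_id, r.gene_id)
            sums[fam] = sums.get(fam, 0.0) + r.mean_depth
        values = np.array(sorted(sums.values()))
    else:
        values = np.array(sorted(r.mean_depth for r in marker_coverages))
    if len(values) < MIN_MARKERS:
        raise ValueError(
            f"{sample_id}: only {len(values)} marker families with coverage "
            f"(need >= {MIN_MARKERS}); supply genome equivalents explicitly"
        )
    return GenomeEquivalent(sample_id=sample_id, value=float(np.median(values)))


def relative_abundance(cov: CoverageRecord, ge: GenomeEquivalent) -> AbundanceRecord:
    """Gene coverage / genome equivalent x 100 (% of genomes carrying it)."""
    if cov.sample_id != ge.sample_id:
        raise ValueError(
            f"sample mismatch: coverage {cov.sample_id} vs genome equivalent {ge.sample_id}"
        )
    return AbundanceRecord(
        gene_id=cov.gene_id,
        sample_id=cov.sample_id,
        rel_abundance=cov.mean_depth / ge.value * 100.0,
    )


def abundance_table(
    coverages: Iterable[CoverageRecord],
    genome_equivalents: Mapping[str, GenomeEquivalent],
    taxonomy: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Long-format abundance table (gene_id, sample_id, rel_abundance_pct).

    ``genome_equivalents`` maps sample_id to its estimate; taxonomy labels
    are attached when provided.
    """
    rows = []
    for cov in coverages:
        ge = genome_equivalents.get(cov.sample_id)
        if ge is None:
            raise ValueError(f"no genome equivalent for sample {cov.sample_id}")
        rec = relative_abundance(cov, ge)
        label = taxonomy.get(cov.gene_id, "unassigned") if taxonomy else "unassigned"
        rows.append((rec.gene_id, rec.sample_id, rec.rel_abundance, label))
    return pd.DataFrame(
        rows, columns=["gene_id", "sample_id", "rel_abundance_pct", "taxonomy_label"]
    )


_GROUP_KEYS = {
    "taxon": ["sample_id", "taxonomy_label"],
    "sample": ["sample_id"],
    "zone": ["zone"],
    "lifestyle": ["lifestyle"],
}


def aggregate(
    records: pd.DataFrame,
    by: str,
    metadata: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Sum relative abundance within groups.

    ``by`` is one of taxon, sample, zone, lifestyle; zone and lifestyle
    require a sample metadata table (sample_id, depth_m, fraction).  Group
    sums are additive: the per-sample grand total equals the sum of its
    per-taxon parts.
    """
    if by not in _GROUP_KEYS:
        raise ValueError(f"unknown grouping {by!r}; expected one of {sorted(_GROUP_KEYS)}")
    df = records
    if len(df) == 0:
        return pd.DataFrame(columns=_GROUP_KEYS[by] + ["rel_abundance_pct"])
    if by in ("zone", "lifestyle"):
        if metadata is None:
            raise ValueError(f"grouping by {by} requires sample metadata")
        from .ecology import annotate_samples

        meta = annotate_samples(metadata)
        df = df.merge(meta[["sample_id", "zone", "lifestyle"]], on="sample_id")
    out = df.groupby(_GROUP_KEYS[by], as_index=False)["rel_abundance_pct"].sum()
    return out.sort_values(_GROUP_KEYS[by], kind="stable").reset_index(drop=True)


def read_marker_list(path: str | Path) -> dict[str, str]:
    """Read a marker list: one gene_id per line, optional tab-separated family."""
    families: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "gene_id":  # tolerate a header row
                continue
            families[parts[0]] = parts[1] if len(parts) > 1 else parts[0]
    return families
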