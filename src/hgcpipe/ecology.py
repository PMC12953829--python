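"""Depth-zone classification, lifestyle labelling and habitat preference.

Samples from a stratified water column are grouped into surface, intermediate
and deep redox zones by depth, and into free-living (FL) vs particle-
associated (PA) fractions by the retaining filter pore size.  Habitat
preference contrasts the PA and FL abundance of a gene or taxon at one depth
as a log2 ratio with a stated zero-handling policy.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Optional

import pandas as pd

ZONES = ("surface", "intermediate", "deep")

SURFACE_MAX_M = 50.0
INTERMEDIATE_MAX_M = 100.0
MAX_DEPTH_M = 300.0


@dataclass
class SampleContext:
    sample_id: str
    depth: float
    lifestyle: str  # "FL" or "PA"
    zone: str

    @classmethod
    def from_metadata(cls, sample_id: str, depth_m: float, fraction: str) -> "SampleContext":
        return cls(
            sample_id=sample_id,
            depth=float(depth_m),
            lifestyle=label_lifestyle(fraction),
            zone=classify_zone(depth_m),
        )


@dataclass
class PreferenceScore:
    key: str
    depth: float
    log2_pa_fl: float
    pa_pct: float
    fl_pct: float
    status: str = "ok"  # "ok" or "absent" (both fractions zero)


def classify_zone(depth: float) -> str:
    """Classify a sampling depth (m) into a redox zone.

    surface: depth <= 50; intermediate: 50 < depth <= 100; deep: depth > 100.
    The zones partition the sampled water column with no gaps; anoxia sets in
    below 100 m, so the unsampled gaps (50-60, 100-105 m) are closed by
    extending surface down to 50 m and deep up from 100 m.
    """
    d = float(depth)
    if d < 0:
        raise ValueError(f"negative depth: {depth}")
    if d > MAX_DEPTH_M:
        raise ValueError(f"depth {depth} m outside supported range [0, {MAX_DEPTH_M}]")
    if d <= SURFACE_MAX_M:
        return "surface"
    if d <= INTERMEDIATE_MAX_M:
        return "intermediate"
    return "deep"


_PORE_RE = re.compile(r"^([0-9.]+)\s*(?:um|µm|μm)?$")


def label_lifestyle(fraction: str) -> str:
    """Map a retaining filter pore size to a lifestyle fraction.

    3 um retentate -> "PA" (particle-associated); 0.22 um retentate -> "FL"
    (free-living).  Any other pore size is undefined and rejected.
    """
    if fraction in ("FL", "PA"):
        return fraction
    m = _PORE_RE.match(str(fraction).strip().lower())
    if m:
        pore = float(m.group(1))
        if pore == 3.0:
            return "PA"
        if pore == 0.22:
            return "FL"
    raise ValueError(f"unknown filter fraction: {fraction!r}")


def habitat_preference(
    pa_pct: float, fl_pct: float, epsilon: Optional[float] = None
) -> tuple[float, str]:
    """log2 PA/FL abundance contrast with pseudocount handling.

    Returns ``(score, status)`` where score = log2((pa + eps)/(fl + eps)).
    The pseudocount eps is applied only when one side is zero; by default it
    is half the smallest nonzero abundance of the pair, and callers with
    sample-level context may pass a smaller ``epsilon`` (half the smallest
    nonzero abundance across the two sample profiles).  Both sides zero
    yields score 0.0 flagged "absent".  The policy is symmetric, so
    score(pa, fl) == -score(fl, pa).
    """
    if pa_pct < 0 or fl_pct < 0:
        raise ValueError("abundances must be non-negative")
    if pa_pct == 0 and fl_pct == 0:
        return 0.0, "absent"
    if pa_pct > 0 and fl_pct > 0:
        eps = 0.0
    else:
        eps = epsilon if epsilon is not None else min(v for v in (pa_pct, fl_pct) if v > 0) / 2
    # difference of logs keeps the score exactly antisymmetric under swap
    return math.log2(pa_pct + eps) - math.log2(fl_pct + eps), "ok"


def preference_table(
    abundance: pd.DataFrame,
    metadata: pd.DataFrame,
    key: str = "gene_id",
) -> pd.DataFrame:
    """PA-vs-FL preference scores for every key at every paired depth.

    ``abundance`` is long-format (gene_id, sample_id, rel_abundance_pct,
    optionally taxonomy_label); ``metadata`` has sample_id, depth_m,
    fraction.  Depths with both an FL and a PA sample are contrasted; the
    per-pair pseudocount is half the smallest nonzero abundance seen in
    either sample's profile.
    """
    meta = annotate_samples(metadata)
    merged = abundance.merge(meta[["sample_id", "depth_m", "lifestyle"]], on="sample_id")
    rows = []
    for depth, grp in merged.groupby("depth_m"):
        lifestyles = set(grp["lifestyle"])
        if not {"FL", "PA"}.issubset(lifestyles):
            continue
        pa = grp[grp["lifestyle"] == "PA"].set_index(key)["rel_abundance_pct"]
        fl = grp[grp["lifestyle"] == "FL"].set_index(key)["rel_abundance_pct"]
        nonzero = grp.loc[grp["rel_abundance_pct"] > 0, "rel_abundance_pct"]
        eps = float(nonzero.min()) / 2 if len(nonzero) else None
        for k in sorted(set(pa.index) | set(fl.index)):
            p = float(pa.get(k, 0.0))
            f = float(fl.get(k, 0.0))
            score, status = habitat_preference(p, f, epsilon=eps)
            rows.append((k, depth, score, p, f, status))
    return pd.DataFrame(
        rows, columns=[key, "depth_m", "log2_pa_fl", "pa_pct", "fl_pct", "status"]
    )


def dominant_methylators(
    abundance: pd.DataFrame, top_k: int, key: str = "gene_id"
) -> pd.DataFrame:
    """Per-sample top-k keys by relative abundance.

    Stable descending sort on rel_abundance_pct, ties broken by key.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    out = []
    for sample_id, grp in abundance.groupby("sample_id"):
        ranked = grp.sort_values(
            [key], kind="stable"
        ).sort_values("rel_abundance_pct", ascending=False, kind="stable")
        top = ranked.head(top_k).copy()
        top["rank"] = range(1, len(top) + 1)
        out.append(top)
    if not out:
        return abundance.iloc[0:0].assign(rank=pd.Series(dtype=int))
    return pd.concat(out, ignore_index=True)


def annotate_samples(metadata: pd.DataFrame) -> pd.DataFrame:
    """Add zone and lifestyle columns to a sample metadata table."""
    meta = metadata.copy()
    meta["zone"] = meta["depth_m"].map(classify_zone)
    meta["lifestyle"] = meta["fraction"].map(label_lifestyle)
    return meta


def depth_profile(abundance: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-sample summed abundance with depth, zone and lifestyle attached."""
    totals = (
        abundance.groupby("sample_id", as_index=False)["rel_abundance_pct"].sum()
        .rename(columns={"rel_abundance_pct": "total_pct"})
    )
    meta = annotate_samples(metadata)
    out = meta[["sample_id", "depth_m", "zone", "lifestyle"]].merge(
        totals, on="sample_id", how="left"
    )
    out["total_pct"] = out["total_pct"].fillna(0.0)
    return out.sort_values(["depth_m", "lifestyle"], kind="stable").reset_index(drop=True)


def taxon_profile(abundance: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-sample per-taxon summed abundance (stacked-bar style table)."""
    if "taxonomy_label" not in abundance.columns:
        raise ValueError("abundance table lacks a taxonomy_label column")
    sums = (
        abundance.groupby(["sample_id", "taxonomy_label"], as_index=False)[
            "rel_abundance_pct"
        ].sum()
    )
    meta = annotate_samples(metadata)
    out = sums.merge(meta[["sample_id", "depth_m", "zone", "lifestyle"]], on="sample_id")
    return out.sort_values(
        ["depth_m", "lifestyle", "taxonomy_label"], kind="stable"
    ).reset_index(drop=True)
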