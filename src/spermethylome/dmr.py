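"""Merge significant CpG sites into differentially methylated regions (DMRs).

Each significant probe is modelled as a 1-bp interval [pos, pos+1); adjacent
intervals on the same chromosome merge when the gap between them (next start
minus previous end) is at most the merge distance — BEDtools ``merge -d``
semantics, the tool the merge mirrors. Most significant CpGs in sparse array
data remain isolated singletons; multi-site DMRs are ranked by how many
significant sites they contain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "merge_sites",
    "classify_singletons",
    "SingletonSummary",
    "rank_dmrs",
    "dmr_group_means",
    "sites_from_results",
    "write_dmr_bed",
]

_DMR_COLUMNS = ["chrom", "start", "end", "n_sites", "site_ids"]


def _chrom_key(chrom: str):
    c = chrom.removeprefix("chr")
    return (0, int(c)) if c.isdigit() else (1, c)


def sites_from_results(table: pd.DataFrame, annotation_frame: pd.DataFrame) -> pd.DataFrame:
    """Significant-probe (chrom, pos, probe_id) sites from a results table."""
    sig = table.index[table["significant"]]
    ann = annotation_frame.set_index("probe_id").loc[sig]
    return pd.DataFrame(
        {"chrom": ann["chrom"], "pos": ann["pos"], "probe_id": sig}
    ).reset_index(drop=True)


def merge_sites(sites, merge_distance_bp: int = 1000) -> pd.DataFrame:
    """Merge CpG sites within ``merge_distance_bp`` of each other into DMRs.

    Parameters
    ----------
    sites
        DataFrame with columns chrom / pos (optionally probe_id), or an
        iterable of (chrom, pos[, probe_id]) tuples. Sites must be
        deduplicated; positions are 0-based.
    merge_distance_bp
        Maximum gap between the 1-bp site intervals for them to merge
        (gap = next_pos - prev_pos - 1 <= d).

    Returns a DataFrame of DMRs (chrom, start, end, n_sites, site_ids)
    sorted in genomic order; every input site appears in exactly one DMR.
    """
    if not isinstance(sites, pd.DataFrame):
        rows = list(sites)
        if rows and len(rows[0]) > 2:
            sites = pd.DataFrame(rows, columns=["chrom", "pos", "probe_id"])
        else:
            sites = pd.DataFrame(rows, columns=["chrom", "pos"])
    if sites.empty:
        return pd.DataFrame(columns=_DMR_COLUMNS)
    sites = sites.copy()
    sites["pos"] = sites["pos"].astype(np.int64)
    if (sites["pos"] < 0).any():
        raise ValueError("negative site positions")
    if sites.duplicated(subset=["chrom", "pos"]).any():
        raise ValueError("duplicate (chrom, pos) sites; deduplicate first")
    if "probe_id" not in sites.columns:
        sites["probe_id"] = [f"{c}:{p}" for c, p in zip(sites["chrom"], sites["pos"])]

    out = []
    for chrom in sorted(sites["chrom"].unique(), key=_chrom_key):
        sub = sites[sites["chrom"] == chrom].sort_values("pos")
        pos = sub["pos"].to_numpy()
        ids = sub["probe_id"].to_numpy()
        # gap between consecutive 1-bp intervals: pos[i] - (pos[i-1] + 1)
        breaks = np.flatnonzero(np.diff(pos) - 1 > merge_distance_bp) + 1
        for seg_pos, seg_ids in zip(np.split(pos, breaks), np.split(ids, breaks)):
            out.append(
                {
                    "chrom": chrom,
                    "start": int(seg_pos[0]),
                    "end": int(seg_pos[-1]) + 1,
                    "n_sites": len(seg_pos),
                    "site_ids": list(seg_ids),
                }
            )
    return pd.DataFrame(out, columns=_DMR_COLUMNS)


@dataclass
class SingletonSummary:
    n_single: int
    n_regions: int  # multi-site merged regions
    total_sites: int
    pct_single: float


def classify_singletons(dmrs: pd.DataFrame) -> SingletonSummary:
    """Split merged output into isolated sites vs multi-site regions.

    ``pct_single`` is 100 * singletons / total input sites.
    """
    if dmrs.empty:
        return SingletonSummary(0, 0, 0, float("nan"))
    single = int((dmrs["n_sites"] == 1).sum())
    multi = int((dmrs["n_sites"] > 1).sum())
    total = int(dmrs["n_sites"].sum())
    return SingletonSummary(single, multi, total, 100.0 * single / total)


def rank_dmrs(dmrs: pd.DataFrame) -> pd.DataFrame:
    """Sort DMRs by descending site count; ties in genomic order. Adds rank."""
    if dmrs.empty:
        out = dmrs.copy()
        out["rank"] = pd.Series(dtype=int)
        return out
    keys = dmrs.assign(_ck=[_chrom_key(c) for c in dmrs["chrom"]])
    out = keys.sort_values(
        by=["n_sites", "_ck", "start"], ascending=[False, True, True], kind="mergesort"
    ).drop(columns="_ck")
    out = out.reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def dmr_group_means(dmrs: pd.DataFrame, group_means: pd.DataFrame) -> pd.DataFrame:
    """Unweighted per-group mean beta across each DMR's member probes.

    ``group_means`` is a per-probe table (e.g. the mean_CC/mean_HD/mean_TC
    columns of the differential results), indexed by probe_id.
    """
    cols = [c for c in group_means.columns if c.startswith("mean_")]
    rows = []
    for _, r in dmrs.iterrows():
        member = group_means.loc[[p for p in r["site_ids"] if p in group_means.index], cols]
        rows.append(member.mean(axis=0))
    extra = pd.DataFrame(rows, index=dmrs.index) if rows else pd.DataFrame(columns=cols)
    return pd.concat([dmrs, extra], axis=1)


def write_dmr_bed(dmrs: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for i, r in dmrs.iterrows():
            name = f"DMR_{i+1:05d}"
            fh.write(f"{r['chrom']}\t{r['start']}\t{r['end']}\t{name}\t{r['n_sites']}\n")
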