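"""UMI consolidation and RNA/DNA ratio quantification.

Reads carrying the same UMI within one (barcode, replicate, molecule) key are
PCR copies of a single molecule, so abundance is the number of distinct UMIs
(exact-match collapsing, no edit-distance merging). Expression per sequence
is then summarized as the aggregate RNA/DNA ratio: normalized RNA UMIs summed
over all barcodes and replicates, divided by the same sum for DNA.

Normalization uses per-replicate, per-molecule-class size factors: the total
UMI count of a class in a replicate divided by the geometric mean of those
totals across replicates. This is a plain library-size correction; pass
``normalize=False`` to work on raw sums instead.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InputError

COUNT_KEY = ["oligo_id", "allele", "barcode", "replicate", "molecule"]


def consolidate_umis(
    reads: pd.DataFrame,
    barcode_map: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Collapse reads to distinct-UMI counts per (oligo, allele, barcode, replicate, molecule).

    If ``barcode_map`` is given (columns barcode, oligo_id[, allele]), reads
    whose barcode is absent from the map are dropped and counted in the
    report; the oligo/allele assignment then comes from the map rather than
    from the reads.
    """
    lengths = reads["umi"].str.len()
    if len(reads) and lengths.nunique() > 1:
        raise InputError("UMI length mismatch in read table")

    report = {"input_reads": int(len(reads)), "unmapped_barcode_reads": 0}
    if barcode_map is not None:
        known = reads["barcode"].isin(set(barcode_map["barcode"]))
        report["unmapped_barcode_reads"] = int((~known).sum())
        reads = reads[known]
        key_cols = ["barcode", "replicate", "molecule"]
        counts = (
            reads.groupby(key_cols, sort=False)["umi"].nunique().reset_index(name="umi_count")
        )
        meta = barcode_map.drop_duplicates("barcode")
        if "allele" not in meta.columns:
            split = meta["oligo_id"].str.split("|", n=1, expand=True)
            meta = meta.assign(oligo_id=split[0], allele=split[1])
        counts = counts.merge(meta[["barcode", "oligo_id", "allele"]], on="barcode")
    else:
        counts = (
            reads.groupby(COUNT_KEY, sort=False)["umi"].nunique().reset_index(name="umi_count")
        )
    counts = counts[COUNT_KEY + ["umi_count"]].sort_values(COUNT_KEY, ignore_index=True)
    report["consolidated_umis"] = int(counts["umi_count"].sum())
    return counts, report


def size_factors(counts: pd.DataFrame) -> pd.DataFrame:
    """Per (molecule, replicate) size factor: total / geometric mean across replicates."""
    totals = counts.groupby(["molecule", "replicate"])["umi_count"].sum().astype(float)
    logs = np.log(totals)
    geo = logs.groupby(level="molecule").transform("mean")
    return np.exp(logs - geo).rename("size_factor").reset_index()


def _normalized(counts: pd.DataFrame, normalize: bool) -> pd.DataFrame:
    df = counts.copy()
    if normalize:
        sf = size_factors(counts)
        df = df.merge(sf, on=["molecule", "replicate"], how="left")
        df["norm_count"] = df["umi_count"] / df["size_factor"]
    else:
        df["norm_count"] = df["umi_count"].astype(float)
    return df


def aggregate_ratios(counts: pd.DataFrame, normalize: bool = True) -> pd.DataFrame:
    """RNA/DNA ratio per (oligo_id, allele), aggregated over barcodes and replicates.

    Returns columns: oligo_id, allele, aggregate_ratio, n_barcodes, plus
    rna_sum/dna_sum. Sequences with zero DNA get a NaN ratio and are excluded
    downstream. ``n_barcodes`` counts barcodes with any DNA evidence.
    """
    df = _normalized(counts, normalize)
    g = df.groupby(["oligo_id", "allele", "molecule"], sort=False)["norm_count"].sum()
    wide = g.unstack("molecule").rename(columns={"RNA": "rna_sum", "DNA": "dna_sum"})
    for col in ("rna_sum", "dna_sum"):
        if col not in wide:
            wide[col] = 0.0
    wide = wide.fillna(0.0)
    wide["aggregate_ratio"] = np.where(
        wide["dna_sum"] > 0, wide["rna_sum"] / wide["dna_sum"], np.nan
    )
    nbc = (
        df[df["molecule"] == "DNA"]
        .groupby(["oligo_id", "allele"])["barcode"].nunique()
        .rename("n_barcodes")
    )
    out = wide.join(nbc).reset_index()
    out["n_barcodes"] = out["n_barcodes"].fillna(0).astype(int)
    return out


def aggregate_ratio(counts: pd.DataFrame, oligo_id: str, allele: str,
                    normalize: bool = True) -> float:
    """Aggregate RNA/DNA ratio for one sequence (KeyError if absent)."""
    table = aggregate_ratios(counts, normalize=normalize).set_index(["oligo_id", "allele"])
    if (oligo_id, allele) not in table.index:
        raise KeyError(f"unknown sequence ({oligo_id}, {allele})")
    return float(table.loc[(oligo_id, allele), "aggregate_ratio"])


def replicate_ratios(counts: pd.DataFrame, normalize: bool = True) -> pd.DataFrame:
    """RNA/DNA ratio per (oligo_id, allele, replicate) — wide, one column per replicate."""
    df = _normalized(counts, normalize)
    g = df.groupby(["oligo_id", "allele", "replicate", "molecule"])["norm_count"].sum()
    wide = g.unstack("molecule").fillna(0.0)
    ratio = np.where(wide.get("DNA", 0) > 0, wide.get("RNA", 0.0) / wide["DNA"], np.nan)
    out = pd.Series(ratio, index=wide.index, name="ratio").unstack("replicate")
    return out


def replicate_correlation(rep_ratios: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson r between replicate ratio vectors.

    Constant replicate vectors yield NaN for their pairs (correlation
    undefined); the diagonal is 1.
    """
    if rep_ratios.shape[1] < 2:
        raise InputError("need at least 2 replicates for correlation")
    corr = rep_ratios.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


def downsample_ratio(
    counts: pd.DataFrame,
    oligo_id: str,
    allele: str,
    k: int,
    seed: int | np.random.Generator = 0,
    normalize: bool = True,
) -> float:
    """Aggregate ratio of a uniform without-replacement sample of k barcodes."""
    sub = counts[(counts["oligo_id"] == oligo_id) & (counts["allele"] == allele)]
    barcodes = sub["barcode"].unique()
    if k > len(barcodes):
        raise InputError(f"k={k} exceeds available barcodes ({len(barcodes)})")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chosen = set(rng.choice(np.sort(barcodes), size=k, replace=False))
    df = _normalized(counts, normalize)
    df = df[(df["oligo_id"] == oligo_id) & (df["allele"] == allele)
            & df["barcode"].isin(chosen)]
    sums = df.groupby("molecule")["norm_count"].sum()
    dna = float(sums.get("DNA", 0.0))
    return float(sums.get("RNA", 0.0)) / dna if dna > 0 else float("nan")


def downsample_curve(
    counts: pd.DataFrame,
    oligo_id: str,
    allele: str,
    grid: list[int],
    seed: int = 0,
) -> pd.DataFrame:
    """Ratio-vs-k curve over a grid of barcode subsample sizes."""
    rng = np.random.default_rng(seed)
    rows = [
        {"k": k, "ratio": downsample_ratio(counts, oligo_id, allele, k, seed=rng)}
        for k in grid
    ]
    return pd.DataFrame(rows)
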