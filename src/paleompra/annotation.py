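"""Target-gene linking, enrichment tests, and genomic-context comparisons.

Loci (the 200-bp windows around each variant) are linked to candidate target
genes through four evidence sources — eQTLs within +/-1 kb of the variant,
promoter-capture Hi-C fragments within +/-10 kb, putative enhancers within
+/-10 kb, and strand-aware promoter windows (5 kb upstream to 1 kb downstream
of a TSS) — with a closest-TSS fallback, regardless of distance, for loci
with no other evidence. All window endpoints are inclusive; variant
coordinates are 1-based, interval tracks BED-style 0-based half-open.

Enrichment of gene sets (anatomical terms, phenotype ontology terms) is
tested against the genes linked to *active* loci as the background, which
controls for composition biases of the active set. Phenotype direction tests
ask whether the phenotypes of a gene's loss-of-function disorder are
divergent between human groups and whether the patient direction matches the
modern-vs-archaic direction, against a 0.5 chance level.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats as sps

from .errors import InputError
from .stats import bh_fdr, binomial_tail, fisher_2x2, hypergeom_tail

EQTL_WINDOW = 1_000
HIC_WINDOW = 10_000
ENHANCER_WINDOW = 10_000
PROMOTER_UP = 5_000
PROMOTER_DOWN = 1_000
RATIO_CUTOFFS = (1.0, 1.5, 2.0, 2.5, 3.0, 3.5)
SEX_CHROMS = {"chrX", "chrY", "X", "Y"}


def _trees(intervals: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in intervals.groupby("chrom"):
        bad = grp["end"] <= grp["start"]
        if bad.any():
            raise InputError(f"malformed interval on {chrom} (end <= start)")
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e), i) for i, (s, e) in enumerate(zip(grp["start"], grp["end"]))
        )
    return trees


def link_targets(
    loci: pd.DataFrame,
    tss: pd.DataFrame,
    eqtls: pd.DataFrame,
    hic: pd.DataFrame,
    enhancers: pd.DataFrame,
) -> pd.DataFrame:
    """GeneLink table: one row per (locus, gene, evidence[, tier]).

    ``loci`` needs columns locus_id, chrom, pos (1-based variant position),
    start, end (0-based half-open window). Evidence values: eqtl, hic,
    enhancer, promoter, closest_tss. Hi-C links are tiered stringent when
    cell-matched, enhancer links when elite; other evidence is stringent.
    """
    links = []

    for _, row in loci.iterrows():
        pos = int(row["pos"])  # 1-based
        chrom = row["chrom"]

        near = eqtls[(eqtls["chrom"] == chrom)
                     & ((eqtls["pos"] - pos).abs() <= EQTL_WINDOW)]
        for g in near["gene"].unique():
            links.append((row["locus_id"], g, "eqtl", "stringent"))

        for df, ev, window, tier_col in (
            (hic, "hic", HIC_WINDOW, "cell_matched"),
            (enhancers, "enhancer", ENHANCER_WINDOW, "elite"),
        ):
            sub = df[df["chrom"] == chrom]
            # inclusive +/-window around the variant position itself
            point = pos - 1  # 0-based
            lo, hi = point - window, point + window
            hit = sub[(sub["start"] <= hi) & (sub["end"] - 1 >= lo)]
            for _, h in hit.iterrows():
                tier = "stringent" if bool(h[tier_col]) else "lenient"
                links.append((row["locus_id"], h["gene"], ev, tier))

        # strand-aware promoter window: upstream is 5' of the gene
        sub = tss[tss["chrom"] == chrom]
        t = sub["start"].to_numpy()  # 0-based TSS position
        plus = sub["strand"].to_numpy() == "+"
        win_lo = np.where(plus, t - PROMOTER_UP, t - PROMOTER_DOWN)
        win_hi = np.where(plus, t + PROMOTER_DOWN, t + PROMOTER_UP)
        inside = (pos - 1 >= win_lo) & (pos - 1 <= win_hi)
        for g in sub.loc[inside, "gene"].unique():
            links.append((row["locus_id"], g, "promoter", "stringent"))

    out = pd.DataFrame(links, columns=["locus_id", "gene", "evidence", "tier"])
    out = out.drop_duplicates(ignore_index=True)

    # closest-TSS fallback for loci with no evidence at all, ties to the
    # lower coordinate for determinism
    covered = set(out["locus_id"])
    fallback = []
    for _, row in loci.iterrows():
        if row["locus_id"] in covered:
            continue
        chrom = row["chrom"]
        center = (int(row["start"]) + int(row["end"])) / 2.0
        sub = tss[tss["chrom"] == chrom]
        if len(sub) == 0:
            sub = tss
        d = (sub["start"] - center).abs()
        # lowest-coordinate preference among exact ties, for determinism
        ties = sub[d == d.min()].sort_values("start")
        best = ties.iloc[0]
        fallback.append((row["locus_id"], best["gene"], "closest_tss", "stringent"))
    if fallback:
        out = pd.concat(
            [out, pd.DataFrame(fallback, columns=out.columns)], ignore_index=True
        )
    return out


def term_enrichment(
    target_genes: set[str],
    background_genes: set[str],
    term_table: pd.DataFrame,
    min_genes: int = 3,
) -> pd.DataFrame:
    """Hypergeometric term over-representation against the active background.

    The universe is the background gene set (genes linked to active loci);
    target genes outside it are ignored. Terms with fewer than ``min_genes``
    genes in the universe are excluded before BH.
    """
    universe = set(background_genes)
    if not universe:
        raise InputError("background gene set is empty")
    target = set(target_genes) & universe
    rows = []
    for term, grp in term_table.groupby("term"):
        members = set(grp["gene"]) & universe
        if len(members) < min_genes:
            continue
        k = len(members & target)
        M, n, N = len(universe), len(members), len(target)
        fold = (k / N) / (n / M) if N and n else np.nan
        rows.append({
            "term": term, "term_genes": n, "hits": k, "fold": fold,
            "p": hypergeom_tail(k, M, n, N) if k else 1.0,
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = bh_fdr(out["p"])
        out = out.sort_values("p", ignore_index=True)
    return out


def direction_tests(
    n_phenotypes: int,
    n_divergent: int,
    n_match: int,
    population_total: int,
    population_divergent: int,
    match_prob: float = 0.5,
) -> dict:
    """Divergence/direction statistics for one gene's phenotype list.

    ``n_phenotypes`` phenotypes are annotated for the gene, ``n_divergent``
    of them divergent between the human groups, ``n_match`` of those matching
    the predicted direction. The population totals give the overall annotated
    phenotypes and how many are divergent; under the null, a fraction
    ``match_prob`` of divergent phenotypes match by chance.
    """
    if not (0 <= n_match <= n_divergent <= n_phenotypes):
        raise InputError("need match <= divergent <= total phenotype counts")
    if population_divergent > population_total:
        raise InputError("population_divergent exceeds population_total")
    expected_successes = int(round(population_divergent * match_prob))
    expected = n_phenotypes * expected_successes / population_total
    return {
        "n_phenotypes": n_phenotypes,
        "n_divergent": n_divergent,
        "n_match": n_match,
        "binomial_p": binomial_tail(n_match, n_divergent, match_prob),
        "expected_match": expected,
        "fold": n_match / expected if expected > 0 else np.nan,
        "hypergeom_p": hypergeom_tail(
            n_match, population_total, expected_successes, n_phenotypes
        ),
    }


def context_enrichment(
    loci: pd.DataFrame,
    features: dict[str, pd.DataFrame],
    ratio_cutoffs=RATIO_CUTOFFS,
    exclude_sex_chroms: bool = True,
) -> pd.DataFrame:
    """Fisher enrichment of genomic features in active vs. inactive loci.

    ``loci`` needs locus_id, chrom, start, end, active (bool), ratio. For
    each feature track and RNA/DNA cutoff, the 2x2 is (active with ratio >=
    cutoff vs inactive) x (overlaps feature vs not); BH is applied across
    all feature x cutoff tests of the run. Sex-chromosome loci are removed.
    """
    df = loci.copy()
    if exclude_sex_chroms:
        df = df[~df["chrom"].isin(SEX_CHROMS)]
    rows = []
    for name, track in features.items():
        trees = _trees(track)
        overlaps = np.array([
            bool(trees.get(c)) and bool(trees[c].overlap(int(s), int(e)))
            for c, s, e in zip(df["chrom"], df["start"], df["end"])
        ])
        inactive = ~df["active"].to_numpy(dtype=bool)
        for cutoff in ratio_cutoffs:
            act = df["active"].to_numpy(dtype=bool) & (df["ratio"] >= cutoff).to_numpy()
            if act.sum() == 0 or inactive.sum() == 0:
                continue
            a, b = int((act & overlaps).sum()), int((act & ~overlaps).sum())
            c, d = int((inactive & overlaps).sum()), int((inactive & ~overlaps).sum())
            if b == 0 or c == 0:
                odds = np.inf if a and d else np.nan
                _, p = fisher_2x2([[a, b], [c, d]])
            else:
                odds, p = fisher_2x2([[a, b], [c, d]])
            rows.append({"feature": name, "cutoff": cutoff, "n_active": int(act.sum()),
                         "odds_ratio": odds, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = bh_fdr(out["p"])
    return out


def cpg_density(seq: str) -> float:
    """CpG dinucleotides per base of the window."""
    if not seq:
        raise InputError("empty sequence")
    return seq.upper().count("CG") / len(seq)


def methylation_direction_test(
    methylation: pd.DataFrame,
    direction: pd.Series,
    strata: pd.Series | None = None,
) -> pd.DataFrame:
    """Mean modern-minus-archaic methylation of up- vs down-regulating loci.

    ``methylation`` has columns locus_id, modern, archaic (fractions);
    ``direction`` maps locus_id -> {"up", "down"}. Per-locus deltas pair the
    two genomes; the up and down groups are then contrasted with a t-test.
    Optional ``strata`` maps locus_id -> stratum label; tests run per
    stratum plus "all". Degenerate groups report NaN p (no signal).
    """
    df = methylation.dropna(subset=["modern", "archaic"]).copy()
    df["delta"] = df["modern"] - df["archaic"]
    df["direction"] = direction.reindex(df["locus_id"]).to_numpy()
    df = df.dropna(subset=["direction"])
    strata_map = (strata.reindex(df["locus_id"]).to_numpy()
                  if strata is not None else np.array(["all"] * len(df)))
    df["stratum"] = strata_map
    groups = [("all", df)] + [
        (s, df[df["stratum"] == s]) for s in pd.unique(df["stratum"]) if s != "all"
    ]
    rows = []
    for name, sub in groups:
        up = sub.loc[sub["direction"] == "up", "delta"]
        down = sub.loc[sub["direction"] == "down", "delta"]
        if len(up) >= 2 and len(down) >= 2 and (up.std() > 0 or down.std() > 0):
            t, p = sps.ttest_ind(up, down, equal_var=False)
        else:
            t, p = np.nan, np.nan
        rows.append({
            "stratum": name, "n_up": len(up), "n_down": len(down),
            "mean_delta_up": float(up.mean()) if len(up) else np.nan,
            "mean_delta_down": float(down.mean()) if len(down) else np.nan,
            "t": float(t) if t == t else np.nan, "p": float(p) if p == p else np.nan,
        })
    return pd.DataFrame(rows)


def group_mean_compare(groups: dict[str, tuple[np.ndarray, np.ndarray]]) -> pd.DataFrame:
    """Welch t-tests of active vs inactive values across named comparisons.

    ``groups`` maps comparison name -> (active_values, inactive_values).
    BH is applied across all comparisons in the call.
    """
    rows = []
    for name, (a, b) in groups.items():
        a, b = np.asarray(a, float), np.asarray(b, float)
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if len(a) < 2 or len(b) < 2:
            raise InputError(f"comparison {name!r}: need >= 2 values per group")
        t, p = sps.ttest_ind(a, b, equal_var=False)
        rows.append({"comparison": name, "mean_active": float(a.mean()),
                     "mean_inactive": float(b.mean()), "t": float(t), "p": float(p)})
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p"])
    return out


def nearest_distance(
    loci: pd.DataFrame, features: pd.DataFrame, feature_point: str = "start"
) -> pd.Series:
    """Distance from each locus center to the nearest feature point on its chromosome."""
    out = {}
    for chrom, grp in loci.groupby("chrom"):
        pts = np.sort(features.loc[features["chrom"] == chrom, feature_point].to_numpy())
        centers = ((grp["start"] + grp["end"]) / 2.0).to_numpy()
        if len(pts) == 0:
            for lid in grp["locus_id"]:
                out[lid] = np.nan
            continue
        idx = np.searchsorted(pts, centers)
        left = np.abs(centers - pts[np.clip(idx - 1, 0, len(pts) - 1)])
        right = np.abs(pts[np.clip(idx, 0, len(pts) - 1)] - centers)
        d = np.minimum(left, right)
        for lid, dist in zip(grp["locus_id"], d):
            out[lid] = float(dist)
    return pd.Series(out, name="distance")
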