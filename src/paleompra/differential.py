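"""Allele-differential activity among active pairs, and cross-set statistics.

The allele comparison replaces a nested count-GLM with a fully specified
linear model on barcode-level log activities. For every (allele, barcode,
replicate) cell of one pair, the activity is

    a = log2((RNA_norm + 0.5) / (DNA_norm + 0.5)),

with size-factor-normalized counts and a 0.5 pseudocount to keep zeros
finite. The full model ``a ~ replicate + allele`` is tested against the
reduced model ``a ~ replicate`` with an F-test on the allele term; the allele
coefficient is the log2 fold-change of the modern over the archaic allele.
Benjamini-Hochberg is applied afterwards over the active pairs of one cell
type, mirroring how the assay corrects only the active set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateNullError, InputError
from .quantify import size_factors as _size_factors
from .stats import bh_fdr, binomial_tail, binomial_two_sided

PSEUDOCOUNT = 0.5


def barcode_activities(
    pair_counts: pd.DataFrame,
    sf: pd.DataFrame | None = None,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Long table of per-(allele, barcode, replicate) log2 activities for one pair."""
    df = pair_counts.copy()
    if sf is not None:
        df = df.merge(sf, on=["molecule", "replicate"], how="left")
        df["norm"] = df["umi_count"] / df["size_factor"]
    else:
        df["norm"] = df["umi_count"].astype(float)
    wide = (
        df.pivot_table(index=["allele", "barcode", "replicate"],
                       columns="molecule", values="norm", aggfunc="sum", fill_value=0.0)
        .reset_index()
    )
    for col in ("RNA", "DNA"):
        if col not in wide:
            wide[col] = 0.0
    wide["activity"] = np.log2((wide["RNA"] + pseudocount) / (wide["DNA"] + pseudocount))
    return wide


def differential_test(
    pair_counts: pd.DataFrame,
    sf: pd.DataFrame | None = None,
    pseudocount: float = PSEUDOCOUNT,
) -> dict:
    """LFC and F-test p-value for one pair's modern-vs-archaic activity.

    Returns ``{"lfc", "p", "direction", "rep_lfc", "n_obs"}`` where rep_lfc
    maps each replicate to its own modern-minus-archaic mean activity.
    Ties (lfc exactly 0) are deterministically assigned direction "up".
    """
    acts = barcode_activities(pair_counts, sf=sf, pseudocount=pseudocount)
    reps = sorted(acts["replicate"].unique())
    if len(reps) < 2:
        raise InputError(f"need >= 2 replicates, got {len(reps)}")
    alleles = set(acts["allele"])
    if not {"modern", "archaic"}.issubset(alleles):
        raise InputError(f"pair must have modern and archaic alleles, got {alleles}")

    y = acts["activity"].to_numpy()
    n = len(y)
    allele_ind = (acts["allele"] == "modern").to_numpy(dtype=float)
    rep_dummies = np.column_stack([
        (acts["replicate"] == r).to_numpy(dtype=float) for r in reps[1:]
    ])
    intercept = np.ones((n, 1))
    x_reduced = np.hstack([intercept, rep_dummies])
    x_full = np.hstack([x_reduced, allele_ind[:, None]])

    beta_f, *_ = np.linalg.lstsq(x_full, y, rcond=None)
    rss_f = float(np.sum((y - x_full @ beta_f) ** 2))
    beta_r, *_ = np.linalg.lstsq(x_reduced, y, rcond=None)
    rss_r = float(np.sum((y - x_reduced @ beta_r) ** 2))

    df_full = n - x_full.shape[1]
    if df_full <= 0 or rss_f <= 0:
        raise DegenerateNullError("zero residual variance; differential fit is degenerate")
    fstat = (rss_r - rss_f) / (rss_f / df_full)
    p = float(sps.f.sf(fstat, 1, df_full))
    lfc = float(beta_f[-1])

    rep_lfc = {}
    for r in reps:
        sub = acts[acts["replicate"] == r]
        m = sub.loc[sub["allele"] == "modern", "activity"].mean()
        a = sub.loc[sub["allele"] == "archaic", "activity"].mean()
        rep_lfc[int(r)] = float(m - a)

    return {
        "lfc": lfc,
        "p": p,
        "direction": "up" if lfc >= 0 else "down",
        "rep_lfc": rep_lfc,
        "n_obs": n,
    }


def differential_analysis(
    counts: pd.DataFrame,
    active_pairs: list[str],
    normalize: bool = True,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Run the allele test over every active pair and BH-correct within the set.

    Returns one row per active pair: pair_id, lfc, p, fdr, direction, and one
    ``lfc_rep{r}`` column per replicate.
    """
    if not active_pairs:
        return pd.DataFrame(columns=["pair_id", "lfc", "p", "fdr", "direction"])
    sf = _size_factors(counts) if normalize else None
    grouped = dict(tuple(counts[counts["oligo_id"].isin(active_pairs)].groupby("oligo_id")))
    rows = []
    for pair_id in active_pairs:
        if pair_id not in grouped:
            continue
        res = differential_test(grouped[pair_id], sf=sf, pseudocount=pseudocount)
        row = {"pair_id": pair_id, "lfc": res["lfc"], "p": res["p"],
               "direction": res["direction"]}
        for r, v in res["rep_lfc"].items():
            row[f"lfc_rep{r}"] = v
        rows.append(row)
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p"])
    return out


def direction_agreement(diff_tables: dict[str, pd.DataFrame], fdr: float = 0.05) -> dict:
    """Cross-cell-type concordance of differential direction.

    ``diff_tables`` maps cell type -> differential_analysis output. For pairs
    significantly differential in exactly two cell types the chance level of
    direction agreement is 0.5 (one-sided binomial); for pairs differential
    in all three the chance of full concordance is 2/2^3 = 0.25, and the
    two-sided p at chance 0.5 is reported alongside.
    """
    if len(diff_tables) < 2:
        raise InputError("need >= 2 cell types")
    sig = {
        ct: df[df["fdr"] <= fdr].set_index("pair_id")["lfc"]
        for ct, df in diff_tables.items()
    }
    all_pairs = pd.concat([s.rename(ct) for ct, s in sig.items()], axis=1)
    n_sig = all_pairs.notna().sum(axis=1)

    two = all_pairs[n_sig == 2]
    k2 = int((two.apply(lambda r: len(set(np.sign(r.dropna()))) == 1, axis=1)).sum())
    n2 = len(two)

    three = all_pairs[n_sig == len(diff_tables)]
    k3 = int((three.apply(lambda r: len(set(np.sign(r))) == 1, axis=1)).sum())
    n3 = len(three)

    return {
        "two_cell": {
            "n": n2, "k": k2,
            "p": binomial_tail(k2, n2, 0.5) if n2 else None,
        },
        "three_cell": {
            "n": n3, "k": k3,
            "p_concordant": binomial_tail(k3, n3, 0.25) if n3 else None,
            "p_two_sided_half": binomial_two_sided(k3, n3, 0.5) if n3 else None,
        },
    }


def replicate_sign_agreement(diff: pd.DataFrame) -> dict:
    """Fraction of pairs whose per-replicate LFCs all share a sign, vs. 2/2^R chance."""
    rep_cols = [c for c in diff.columns if c.startswith("lfc_rep")]
    if len(rep_cols) < 2:
        raise InputError("need per-replicate LFC columns")
    signs = np.sign(diff[rep_cols].to_numpy())
    concordant = np.all(signs == signs[:, [0]], axis=1) & (signs[:, 0] != 0)
    n, k = len(diff), int(concordant.sum())
    chance = 2.0 / (2 ** len(rep_cols))
    return {
        "n": n,
        "k": k,
        "fraction": k / n if n else float("nan"),
        "chance": chance,
        "p": binomial_tail(k, n, chance) if n else None,
    }


@dataclass(frozen=True)
class OverlapStat:
    sizes: tuple[int, ...]
    universe: int
    observed: int
    expected: float
    fold: float
    p: float | None


def multiset_overlap(
    sizes: list[int],
    universe: int,
    observed: int,
    seed: int = 0,
    n_mc: int = 20_000,
) -> OverlapStat:
    """Fold enrichment and p-value of a multi-set intersection.

    Expected intersection of independent uniform random sets is
    ``N * prod(|S_i| / N)``. The p-value P(intersection >= observed) is exact
    (convolved hypergeometrics) for up to three sets, and Monte-Carlo beyond.
    """
    sizes = [int(s) for s in sizes]
    if any(s > universe for s in sizes):
        raise InputError("a set is larger than the universe")
    if any(s < 0 for s in sizes) or universe <= 0:
        raise InputError("sizes must be >= 0 and universe > 0")
    expected = universe * float(np.prod([s / universe for s in sizes]))
    fold = observed / expected if expected > 0 else float("nan")

    if len(sizes) == 1:
        p = 1.0 if observed <= sizes[0] else 0.0
    elif len(sizes) == 2:
        p = float(sps.hypergeom.sf(observed - 1, universe, sizes[0], sizes[1]))
    elif len(sizes) == 3:
        s1, s2, s3 = sizes
        t = np.arange(0, min(s1, s2) + 1)
        pmf_ab = sps.hypergeom.pmf(t, universe, s1, s2)
        tail = sps.hypergeom.sf(observed - 1, universe, t, s3)
        p = float(np.sum(pmf_ab * tail))
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_mc):
            inter = None
            for s in sizes:
                draw = set(rng.choice(universe, size=s, replace=False))
                inter = draw if inter is None else inter & draw
                if not inter:
                    break
            if inter is not None and len(inter) >= observed:
                hits += 1
        p = (hits + 1) / (n_mc + 1)
    return OverlapStat(tuple(sizes), universe, observed, expected, fold, p)
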