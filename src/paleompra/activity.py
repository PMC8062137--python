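"""Activity calling against the scrambled-sequence empirical null.

A sequence pair is called *active* only if it passes two independent tests:

1. **MAD-score test.** The transcription rate alpha of each allele (here the
   size-factor-normalized RNA/DNA ratio) is converted to a robust z-score
   against the scrambled controls, ``(alpha - median(scr)) / (1.4826 *
   MAD(scr))``, with an upper-tail normal p-value; Benjamini-Hochberg is
   applied over all tested sequences (positive controls included, scrambled
   excluded). At least one allele must reach FDR <= 0.05, and both alleles
   need >= 10 barcodes.

2. **Empirical ratio test.** Scrambled controls further than 2 sample SDs
   from the scrambled mean ratio are pruned once (they likely drive some
   expression by chance); the pair's FDR is then the fraction of remaining
   scrambled controls whose ratio is at least as high as the pair's. The pair
   must reach FDR <= 0.05. By default the test is evaluated on the pair's
   best (highest-ratio) allele; per-allele evaluation is available via
   ``empirical_on="allele"``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateNullError, InputError
from .quantify import aggregate_ratios
from .stats import bh_fdr

MAD_CONSISTENCY = 1.4826
MIN_SCRAMBLED = 20


def estimate_alpha(counts: pd.DataFrame, normalize: bool = True) -> pd.DataFrame:
    """Per-sequence transcription rate alpha (columns of aggregate_ratios plus ``alpha``).

    Alpha equals the aggregate normalized RNA/DNA ratio; sequences without
    DNA evidence get NaN and are excluded from testing.
    """
    table = aggregate_ratios(counts, normalize=normalize)
    table["alpha"] = table["aggregate_ratio"]
    return table


def mad_score_test(alpha: pd.Series, scrambled_alpha: pd.Series) -> pd.DataFrame:
    """Robust z-score and upper-tail normal p for each alpha against the scrambled null."""
    scr = np.asarray(scrambled_alpha.dropna(), dtype=float)
    if len(scr) < MIN_SCRAMBLED:
        raise InputError(f"need >= {MIN_SCRAMBLED} scrambled alphas, got {len(scr)}")
    med = np.median(scr)
    mad = np.median(np.abs(scr - med))
    if mad == 0:
        raise DegenerateNullError(
            "scrambled alpha MAD is zero; the null is degenerate — inspect the "
            "controls or jitter the input"
        )
    z = (alpha - med) / (MAD_CONSISTENCY * mad)
    p = pd.Series(sps.norm.sf(z), index=alpha.index)
    return pd.DataFrame({"mad_z": z, "mad_p": p})


def prune_scrambled(scrambled_ratios: pd.Series, n_sd: float = 2.0) -> pd.Series:
    """Single-pass removal of scrambled ratios > n_sd sample SDs from their mean."""
    scr = scrambled_ratios.dropna()
    mean, sd = scr.mean(), scr.std(ddof=1)
    kept = scr[(scr - mean).abs() <= n_sd * sd]
    if len(kept) == 0:
        raise DegenerateNullError("all scrambled controls were pruned")
    return kept


def empirical_ratio_fdr(
    ratios: pd.Series, scrambled_ratios: pd.Series, n_sd: float = 2.0
) -> pd.Series:
    """Fraction of (pruned) scrambled controls with a ratio >= each sequence's ratio."""
    scr = scrambled_ratios.dropna()
    if len(scr) < MIN_SCRAMBLED:
        raise InputError(f"need >= {MIN_SCRAMBLED} scrambled ratios, got {len(scr)}")
    kept = np.sort(prune_scrambled(scr, n_sd=n_sd).to_numpy())
    n = len(kept)
    # count of kept >= r via searchsorted on the sorted null
    counts = n - np.searchsorted(kept, ratios.to_numpy(), side="left")
    return pd.Series(counts / n, index=ratios.index, name="fdr_empirical")


def activity_table(
    counts: pd.DataFrame,
    scrambled_class: str = "scrambled",
    normalize: bool = True,
    prune_sd: float = 2.0,
) -> pd.DataFrame:
    """Per-sequence activity statistics: alpha, MAD z/p, alpha FDR, empirical FDR.

    The BH family for the MAD p-values is every tested sequence except the
    scrambled controls themselves.
    """
    table = estimate_alpha(counts, normalize=normalize)
    table = table[table["dna_sum"] > 0].reset_index(drop=True)
    is_scr = table["allele"] == scrambled_class
    scr_alpha = table.loc[is_scr, "alpha"]

    mad = mad_score_test(table["alpha"], scr_alpha)
    table = pd.concat([table, mad], axis=1)
    table["fdr_alpha"] = np.nan
    table.loc[~is_scr, "fdr_alpha"] = bh_fdr(table.loc[~is_scr, "mad_p"])
    table["fdr_empirical"] = empirical_ratio_fdr(
        table["aggregate_ratio"], table.loc[is_scr, "aggregate_ratio"], n_sd=prune_sd
    )
    return table


def call_active_pairs(
    activity: pd.DataFrame,
    fdr: float = 0.05,
    min_barcodes: int = 10,
    empirical_on: str = "pair",
) -> pd.DataFrame:
    """Active-pair calls from the per-sequence activity table.

    A pair is active iff (a) at least one allele reaches the MAD-score FDR
    threshold, (b) both alleles have >= ``min_barcodes`` barcodes, and (c)
    the empirical ratio FDR — of the best allele when ``empirical_on="pair"``,
    of the same passing allele when ``"allele"`` — is at or below threshold.

    Returns one row per test pair: pair-level flags plus per-allele summary.
    """
    if empirical_on not in ("pair", "allele"):
        raise InputError(f"empirical_on must be 'pair' or 'allele', got {empirical_on!r}")
    test = activity[activity["allele"].isin(["modern", "archaic"])]
    rows = []
    for oligo_id, grp in test.groupby("oligo_id", sort=False):
        g = grp.set_index("allele")
        if not {"modern", "archaic"}.issubset(g.index):
            continue
        alpha_pass = g["fdr_alpha"] <= fdr
        barcodes_ok = bool((g["n_barcodes"] >= min_barcodes).all())
        if empirical_on == "pair":
            best = g["aggregate_ratio"].idxmax()
            empirical_pass = bool(g.loc[best, "fdr_empirical"] <= fdr)
        else:
            empirical_pass = bool((alpha_pass & (g["fdr_empirical"] <= fdr)).any())
        active = bool(alpha_pass.any()) and barcodes_ok and empirical_pass
        rows.append({
            "oligo_id": oligo_id,
            "active_pair": active,
            "alpha_pass_any": bool(alpha_pass.any()),
            "barcodes_ok": barcodes_ok,
            "empirical_pass": empirical_pass,
            "n_barcodes_modern": int(g.loc["modern", "n_barcodes"]),
            "n_barcodes_archaic": int(g.loc["archaic", "n_barcodes"]),
            "ratio_modern": float(g.loc["modern", "aggregate_ratio"]),
            "ratio_archaic": float(g.loc["archaic", "aggregate_ratio"]),
        })
    return pd.DataFrame(rows)
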