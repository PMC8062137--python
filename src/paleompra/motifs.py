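"""PWM scanning with exact tail p-values, and differential TF-binding scores.

The scanner mirrors the FIMO procedure: position probability matrices are
pseudocount-regularized, converted to log2-odds against an order-0
strand-symmetric background, and slid over both strands of each sequence. The
p-value of a window score is the exact probability, under the background,
that a random motif-length word scores at least as high; it is computed by
dynamic programming over the integer-discretized score distribution (the
discretization bin is chosen so the DP stays under a bounded state count, and
the observed score is discretized identically, so DP and exhaustive
enumeration agree exactly). Hits are reported at p <= 1e-4; q-values are
Benjamini-Hochberg over every position x strand scanned for that motif in
the batch.

Allele comparison: hits of the same motif at the same strand and offset are
matched across the modern and archaic sequences. A pair is retained when at
least one allele reaches q <= 0.05. When only one allele has a reported
score, the other is conservatively filled with the lowest score reported for
that motif anywhere in the batch — the unreported score cannot exceed it, so
the score difference is underestimated, never overestimated. When several
motifs map to one TF, the motif with the largest absolute score difference
represents that TF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError
from .stats import bh_fdr, binomial_tail, fisher_2x2

BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
COMPLEMENT = str.maketrans("ACGT", "TGCA")

P_REPORT = 1e-4        # reporting threshold on the exact p-value
PWM_PSEUDOCOUNT = 0.01
SCORE_BIN = 1e-3       # target discretization bin (score units)
MAX_DP_STATES = 100_000


@dataclass(frozen=True)
class PWM:
    """A position probability matrix over A,C,G,T with its TF attribution."""

    motif_id: str
    tf_name: str
    matrix: np.ndarray  # shape (L, 4), rows sum to 1
    source: str = "direct"  # direct | inferred

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 4:
            raise InputError(f"{self.motif_id}: matrix must be (L>=4, 4)")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-6):
            raise InputError(f"{self.motif_id}: matrix rows must sum to 1")
        object.__setattr__(self, "matrix", m)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=1))


def log_odds(pwm: PWM, background: np.ndarray,
             pseudocount: float = PWM_PSEUDOCOUNT) -> np.ndarray:
    """Pseudocount-regularized log2-odds matrix (L, 4)."""
    m = (pwm.matrix + pseudocount) / (1.0 + 4.0 * pseudocount)
    return np.log2(m / np.asarray(background, dtype=float))


def background_model(sequences) -> np.ndarray:
    """Order-0 strand-symmetric base frequencies of a sequence set.

    Non-ACGT characters are skipped. A=T and C=G by construction.
    """
    counts = np.zeros(4)
    for seq in sequences:
        for ch in seq.upper():
            idx = BASE_INDEX.get(ch)
            if idx is not None:
                counts[idx] += 1
    if counts.sum() == 0:
        raise InputError("no ACGT bases in background sequences")
    # pool with the reverse complement: A<->T, C<->G
    sym = counts + counts[::-1]
    return sym / sym.sum()


def score_distribution(
    lo: np.ndarray,
    background: np.ndarray,
    bin_size: float = SCORE_BIN,
    max_states: int = MAX_DP_STATES,
) -> tuple[np.ndarray, float, int, np.ndarray]:
    """Exact null distribution of the discretized window score.

    Returns ``(q, delta, offset, tail)`` where ``q`` is the integer score
    matrix (L, 4) at bin width ``delta``, and ``tail[i]`` is the probability
    that a background-random word has integer score >= offset + i.
    """
    span = float((lo.max(axis=1) - lo.min(axis=1)).sum())
    delta = max(bin_size, span / max_states) if span > 0 else bin_size
    q = np.round(lo / delta).astype(np.int64)
    dist = np.array([1.0])
    offset = 0
    for i in range(q.shape[0]):
        row = q[i]
        lo_i, hi_i = int(row.min()), int(row.max())
        new = np.zeros(len(dist) + (hi_i - lo_i))
        for b in range(4):
            shift = int(row[b]) - lo_i
            new[shift:shift + len(dist)] += background[b] * dist
        dist = new
        offset += lo_i
    tail = np.cumsum(dist[::-1])[::-1]
    return q, delta, offset, tail


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode(), dtype=np.uint8).copy().view(np.uint8)


_LUT = np.full(256, -1, dtype=np.int64)
for _b, _i in BASE_INDEX.items():
    _LUT[ord(_b)] = _i


def _window_scores(seq: str, q: np.ndarray) -> np.ndarray:
    """Integer window scores at every start offset of one strand."""
    L = q.shape[0]
    s = _LUT[_encode(seq)]
    if (s < 0).any():
        raise InputError("sequence contains non-ACGT characters")
    n = len(s) - L + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(s, L)
    return q[np.arange(L), windows].sum(axis=1)


def scan_sequence(
    seq: str,
    pwm: PWM,
    background: np.ndarray,
    pseudocount: float = PWM_PSEUDOCOUNT,
    bin_size: float = SCORE_BIN,
) -> pd.DataFrame:
    """Score every position on both strands; returns start, strand, score, p.

    Starts are 0-based on the forward strand; reverse-strand hits are mapped
    back to forward coordinates. An empty frame is returned when the motif is
    longer than the sequence.
    """
    lo = log_odds(pwm, background, pseudocount)
    q, delta, offset, tail = score_distribution(lo, background, bin_size)
    L = q.shape[0]
    frames = []
    for strand, s in (("+", seq), ("-", seq.upper().translate(COMPLEMENT)[::-1])):
        ints = _window_scores(s, q)
        if len(ints) == 0:
            continue
        idx = np.clip(ints - offset, 0, len(tail) - 1)
        p = tail[idx]
        p[ints - offset < 0] = 1.0
        starts = np.arange(len(ints))
        if strand == "-":
            starts = len(seq) - L - starts
        frames.append(pd.DataFrame({
            "start": starts,
            "strand": strand,
            "score": ints * delta,
            "p": p,
        }))
    if not frames:
        return pd.DataFrame(columns=["start", "strand", "score", "p"])
    return pd.concat(frames, ignore_index=True)


def scan_batch(
    sequences: dict[str, str],
    pwm: PWM,
    background: np.ndarray,
    p_report: float = P_REPORT,
    pseudocount: float = PWM_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Scan a batch of sequences with one motif; q = BH over all scanned positions.

    Only positions with p <= ``p_report`` are returned (columns: seq_id,
    motif_id, start, strand, score, p, q), but the BH family is every
    position x strand scanned in the batch.
    """
    frames = []
    for seq_id, seq in sequences.items():
        df = scan_sequence(seq, pwm, background, pseudocount)
        df.insert(0, "seq_id", seq_id)
        frames.append(df)
    allpos = pd.concat(frames, ignore_index=True)
    if len(allpos) == 0:
        return pd.DataFrame(columns=["seq_id", "motif_id", "start", "strand",
                                     "score", "p", "q"])
    allpos["q"] = bh_fdr(allpos["p"])
    hits = allpos[allpos["p"] <= p_report].copy()
    hits.insert(1, "motif_id", pwm.motif_id)
    return hits.reset_index(drop=True)


def trim_to_variant(modern_seq: str, archaic_seq: str, variant_offsets,
                    flank: int = 30) -> tuple[str, str, int]:
    """Trim a single-variant pair to +/-``flank`` bases around the variant.

    Multi-variant pairs are returned untrimmed (offset shift 0). Windows are
    clipped at the oligo ends. Returns (modern, archaic, start_of_window).
    """
    offsets = list(variant_offsets)
    if len(offsets) != 1:
        return modern_seq, archaic_seq, 0
    off = offsets[0]
    start = max(0, off - flank)
    end = min(len(modern_seq), off + flank + 1)
    return modern_seq[start:end], archaic_seq[start:end], start


def diff_binding(
    hits: pd.DataFrame,
    motif_meta: pd.DataFrame,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-pair, per-TF differential binding scores from allele-matched hits.

    ``hits`` must carry (pair_id, allele, motif_id, strand, start, score, q)
    with allele in {modern, archaic}; ``motif_meta`` maps motif_id -> tf.
    Returns one row per (pair_id, tf): score_modern, score_archaic,
    score_diff, motif_id, filled in {none, modern, archaic}.
    """
    if len(hits) == 0:
        return pd.DataFrame(columns=["pair_id", "tf", "motif_id", "score_modern",
                                     "score_archaic", "score_diff", "filled"])
    floor = hits.groupby("motif_id")["score"].min()  # batch-lowest reported score
    key = ["pair_id", "motif_id", "strand", "start"]
    best = (hits.sort_values("score", ascending=False)
                .drop_duplicates(["allele"] + key))
    m = best[best["allele"] == "modern"].set_index(key)
    a = best[best["allele"] == "archaic"].set_index(key)
    joined = m[["score", "q"]].join(a[["score", "q"]], how="outer",
                                    lsuffix="_modern", rsuffix="_archaic")
    qmin = joined[["q_modern", "q_archaic"]].min(axis=1)
    joined = joined[qmin <= q_threshold].reset_index()

    motif_floor = joined["motif_id"].map(floor)
    filled = np.where(joined["score_modern"].isna(), "modern",
                      np.where(joined["score_archaic"].isna(), "archaic", "none"))
    joined["filled"] = filled
    joined["score_modern"] = joined["score_modern"].fillna(motif_floor)
    joined["score_archaic"] = joined["score_archaic"].fillna(motif_floor)
    joined["score_diff"] = joined["score_modern"] - joined["score_archaic"]

    joined = joined.merge(motif_meta[["motif_id", "tf"]], on="motif_id", how="left")
    # best site per (pair, motif), then the motif with the largest |diff| per TF
    joined["absdiff"] = joined["score_diff"].abs()
    per_motif = (joined.sort_values("absdiff", ascending=False)
                       .drop_duplicates(["pair_id", "motif_id"]))
    per_tf = (per_motif.sort_values("absdiff", ascending=False)
                       .drop_duplicates(["pair_id", "tf"]))
    out = per_tf[["pair_id", "tf", "motif_id", "score_modern", "score_archaic",
                  "score_diff", "filled"]].reset_index(drop=True)
    return out


def tf_analyses(
    diffbind: pd.DataFrame,
    diff_results: pd.DataFrame,
    active_pairs: list[str],
    tf_expression: pd.DataFrame | None = None,
    min_sites: int = 10,
    fpkm_min: float = 1.0,
    fdr: float = 0.05,
) -> dict:
    """Per-TF enrichment, binding-vs-expression correlation, and directionality.

    - Fisher enrichment: (differentially active vs other active pairs) x
      (TF site present vs absent), BH across TFs with >= ``min_sites`` sites.
    - Correlation: Pearson r between score_diff and LFC over pairs with a
      site for the TF (same site cutoff).
    - Directionality: one global binomial test of sign(score_diff) ==
      sign(lfc) among differentially active pairs, chance 0.5.

    TFs with expression below ``fpkm_min`` are excluded when a
    (tf, fpkm) table is supplied.
    """
    db = diffbind[diffbind["score_diff"] != 0].copy()
    if tf_expression is not None:
        expressed = set(tf_expression.loc[tf_expression["fpkm"] >= fpkm_min, "tf"])
        db = db[db["tf"].isin(expressed)]

    sites_per_tf = db.groupby("tf").size()
    kept_tfs = sites_per_tf[sites_per_tf >= min_sites].index
    db = db[db["tf"].isin(kept_tfs)]

    diff_set = set(diff_results.loc[diff_results["fdr"] <= fdr, "pair_id"])
    active_set = set(active_pairs)
    other_active = active_set - diff_set
    lfc = diff_results.set_index("pair_id")["lfc"]

    enr_rows, cor_rows = [], []
    for tf, grp in db.groupby("tf"):
        with_site = set(grp["pair_id"])
        table = [
            [len(diff_set & with_site), len(diff_set - with_site)],
            [len(other_active & with_site), len(other_active - with_site)],
        ]
        odds, p = fisher_2x2(table)
        enr_rows.append({"tf": tf, "n_sites": len(grp), "odds_ratio": odds, "p": p})

        joined = grp.merge(lfc.rename("lfc"), left_on="pair_id", right_index=True)
        if len(joined) >= min_sites and joined["score_diff"].nunique() > 1 \
                and joined["lfc"].nunique() > 1:
            r, rp = sps.pearsonr(joined["score_diff"], joined["lfc"])
            cor_rows.append({"tf": tf, "n": len(joined), "r": float(r), "p": float(rp)})

    enrichment = pd.DataFrame(enr_rows)
    if len(enrichment):
        enrichment["fdr"] = bh_fdr(enrichment["p"])
    correlation = pd.DataFrame(cor_rows)
    if len(correlation):
        correlation["fdr"] = bh_fdr(correlation["p"])

    dsub = db[db["pair_id"].isin(diff_set)].merge(
        lfc.rename("lfc"), left_on="pair_id", right_index=True)
    dsub = dsub[dsub["lfc"] != 0]
    n = len(dsub)
    k = int((np.sign(dsub["score_diff"]) == np.sign(dsub["lfc"])).sum())
    directionality = {
        "n": n, "k": k,
        "p": binomial_tail(k, n, 0.5) if n else None,
    }
    return {"enrichment": enrichment, "correlation": correlation,
            "directionality": directionality}


def random_pwms(
    n_motifs: int,
    tf_names: list[str],
    seed: int = 0,
    min_len: int = 6,
    max_len: int = 12,
    concentration: float = 0.5,
    frac_inferred: float = 0.2,
) -> list[PWM]:
    """Synthetic sharp PWMs with TF attributions (several motifs may share a TF)."""
    rng = np.random.default_rng(seed)
    pwms = []
    for i in range(n_motifs):
        L = int(rng.integers(min_len, max_len + 1))
        mat = rng.dirichlet(np.full(4, concentration), size=L)
        pwms.append(PWM(
            motif_id=f"M{i:04d}",
            tf_name=str(rng.choice(tf_names)),
            matrix=mat,
            source="inferred" if rng.random() < frac_inferred else "direct",
        ))
    return pwms
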