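"""Synthetic lentiMPRA experiment generator with stored ground truth.

This module fabricates every input the analysis pipeline consumes — a small
reference genome with annotation tracks, a candidate-variant table, the oligo
library, barcode-to-oligo association reads, and RNA/DNA UMI count tables —
so that every downstream stage can be exercised against a known truth without
any external download.

The count model mirrors the structure of the assay. Each test sequence (one
allele of one locus) is tagged by many 15-base barcodes; each barcode b has a
latent copy number mu_b (lognormal). DNA counts measure integrated copies,

    DNA_{b,r} ~ NB(mean = mu_b * s_r, dispersion = phi_D),

and RNA counts measure transcription from those copies,

    RNA_{b,r} ~ NB(mean = alpha_o * 2^{e} * mu_b * s'_r, dispersion = phi_R),

with replicate-level library-size factors s_r, s'_r and the allele effect
split symmetrically (e = +effect/2 for the modern allele, -effect/2 for the
archaic one) so that the pair-level transcription rate alpha is effect-free.
The NB parameterization is mean/dispersion with variance mu + phi*mu^2; a
dispersion of 0 degenerates to Poisson.

The activity truth is spike-and-slab: a fraction ``frac_active`` of pairs get
an elevated alpha, a fraction ``frac_diff`` of those get a nonzero log2
allele effect drawn from N(0, effect_sd^2), and everything else (including
the scrambled controls, which always use ``alpha_null``) is null. All draws
descend from ``SimConfig.seed``, so identical configurations reproduce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import OligoPair, build_oligo_pairs, make_scrambled_controls, select_fixed_variants
from .errors import ConfigError, InputError

BASES = np.array(list("ACGT"))

_HISTONE_MARKS = ("H3K27ac", "H3K4me1", "H3K4me3")

# fixed per-operation stream tags so each generator is independently
# deterministic under the top-level seed
_STREAMS = {
    "reference": 11,
    "variants": 13,
    "library": 17,
    "truth": 19,
    "counts": 23,
    "assoc": 29,
    "umi": 31,
    "phenotypes": 37,
    "methylation": 41,
}


@dataclass(frozen=True)
class AssocNoise:
    """Rates of the association-read artefacts the filters must remove."""

    promiscuous: float = 0.0   # barcode with records hitting two oligos
    low_support: float = 0.0   # barcode seen fewer than 3 times
    low_quality: float = 0.0   # barcode reads with a base below Q30
    discordant: float = 0.0    # read pairs that disagree / are improper


@dataclass
class SimConfig:
    """All knobs of the synthetic experiment; defaults emulate the study design.

    The real experiment assayed ~14,042 allele pairs with 100 scrambled and
    299 positive controls, three replicates of RNA and DNA, and a median of
    96 barcodes per sequence; defaults here keep those ratios at a desk-scale
    number of pairs.
    """

    seed: int = 0
    # library composition
    n_pairs: int = 2000
    n_scrambled: int = 100
    n_positive: int = 299
    # reference genome and annotation tracks
    chrom_length: int = 300_000
    n_genes: int = 300
    n_tss: int | None = None          # defaults to n_genes
    n_repeats: int = 300
    n_eqtls: int = 600
    n_hic: int = 250
    n_enhancers: int = 250
    n_histone_peaks: int = 200
    n_variants: int = 4000
    # per-filter failure rates for the candidate-variant table
    frac_archaic_mismatch: float = 0.25
    frac_ape_polymorphic: float = 0.10
    frac_human_polymorphic: float = 0.20
    frac_repeat_fail: float = 0.10
    # barcodes and counts
    barcodes_per_oligo: int = 96      # target median of the truncated NB
    barcode_dispersion: float = 0.2
    n_replicates: int = 3
    umi_length: int = 16
    barcode_length: int = 15
    dna_mean: float = 50.0            # expected DNA UMIs per barcode
    mu_sigma: float = 0.5             # lognormal sd of per-barcode copy number
    rep_sigma: float = 0.15           # lognormal sd of replicate size factors
    dispersion_dna: float = 0.3
    dispersion_rna: float = 0.5
    # activity ground truth
    alpha_null: float = 1.0
    alpha_active: float = 3.0
    alpha_sigma: float = 0.15         # lognormal jitter on true alpha
    frac_active: float = 0.13
    frac_diff: float = 0.23
    effect_sd: float = 0.26           # ~ median fold-change 1.2x among non-null
    # association sequencing
    assoc_mean_support: float = 8.0
    assoc_noise: AssocNoise = field(default_factory=AssocNoise)
    # phenotype / annotation truth
    n_terms: int = 60
    n_phenotypes: int = 300
    frac_divergent: float = 0.62
    plant_term_size: int = 12
    n_tfs: int = 30
    meth_delta_up: float = -0.02
    meth_delta_down: float = 0.01
    meth_noise_sd: float = 0.05

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        positive = (
            "n_pairs", "n_scrambled", "n_positive", "chrom_length", "n_genes",
            "n_repeats", "n_eqtls", "n_hic", "n_enhancers", "n_histone_peaks",
            "n_variants", "barcodes_per_oligo", "n_replicates", "umi_length",
            "barcode_length", "dna_mean", "assoc_mean_support", "n_terms",
            "n_phenotypes", "n_tfs", "plant_term_size",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        nonneg = (
            "barcode_dispersion", "dispersion_dna", "dispersion_rna",
            "mu_sigma", "rep_sigma", "alpha_sigma", "effect_sd",
            "meth_noise_sd",
        )
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        fractions = (
            "frac_archaic_mismatch", "frac_ape_polymorphic",
            "frac_human_polymorphic", "frac_repeat_fail", "frac_active",
            "frac_diff", "frac_divergent",
        )
        for name in fractions:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in ("promiscuous", "low_support", "low_quality", "discordant"):
            v = getattr(self.assoc_noise, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"assoc_noise.{name} must be in [0, 1], got {v}")
        if sum(dataclasses.astuple(self.assoc_noise)) > 1.0:
            raise ConfigError("assoc_noise rates must sum to <= 1")
        if self.alpha_null <= 0 or self.alpha_active <= 0:
            raise ConfigError("alpha_null and alpha_active must be > 0")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([_STREAMS[stream], self.seed])


@dataclass
class ReferenceBundle:
    """Reference sequences plus the annotation tracks the linker consumes."""

    sequences: dict[str, str]
    tss: pd.DataFrame          # chrom, start, end, gene, strand (BED, 0-based)
    repeats: pd.DataFrame      # chrom, start, end
    eqtls: pd.DataFrame        # chrom, pos (1-based), gene
    hic: pd.DataFrame          # chrom, start, end, gene, cell_matched
    enhancers: pd.DataFrame    # chrom, start, end, gene, elite
    histone_peaks: dict[str, pd.DataFrame]
    phylop: pd.DataFrame       # chrom, start, end, score (1 kb tiles)

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline is asked to recover."""

    alpha: pd.Series          # true pair-level transcription rate, by oligo_id
    effect: pd.Series         # true log2(modern/archaic), 0 for null pairs
    active: pd.Series         # bool, by oligo_id (test pairs only)
    barcode_map: pd.DataFrame  # barcode, oligo_id, allele, seq_id, mu


def _random_intervals(rng, chroms, sizes, n, min_len, max_len):
    chrom = rng.choice(chroms, size=n)
    length = rng.integers(min_len, max_len + 1, size=n)
    start = np.empty(n, dtype=int)
    for c in set(chrom):
        m = chrom == c
        start[m] = rng.integers(0, sizes[c] - max_len, size=m.sum())
    df = pd.DataFrame({"chrom": chrom, "start": start, "end": start + length})
    return df.sort_values(["chrom", "start"], ignore_index=True)


def simulate_reference(config: SimConfig) -> ReferenceBundle:
    """Generate reference sequences and an internally consistent annotation bundle."""
    rng = config.rng("reference")
    L = config.chrom_length
    sizes = {"chr1": L, "chr2": L, "chrX": max(L // 2, 1000)}
    chroms = np.array(["chr1", "chr2", "chrX"])
    sequences = {
        c: "".join(BASES[rng.integers(0, 4, size=n)]) for c, n in sizes.items()
    }

    n_tss = config.n_tss if config.n_tss is not None else config.n_genes
    genes = [f"G{i:04d}" for i in range(n_tss)]
    tss_chrom = rng.choice(chroms, size=n_tss)
    tss_pos = np.array([rng.integers(0, sizes[c]) for c in tss_chrom])
    tss = pd.DataFrame({
        "chrom": tss_chrom,
        "start": tss_pos,
        "end": tss_pos + 1,
        "gene": genes,
        "strand": rng.choice(["+", "-"], size=n_tss),
    }).sort_values(["chrom", "start"], ignore_index=True)

    repeats = _random_intervals(rng, chroms, sizes, config.n_repeats, 50, 500)

    eq_chrom = rng.choice(chroms, size=config.n_eqtls)
    eq_pos = np.array([rng.integers(1, sizes[c] + 1) for c in eq_chrom])
    eqtls = pd.DataFrame({
        "chrom": eq_chrom,
        "pos": eq_pos,
        "gene": rng.choice(genes, size=config.n_eqtls),
    })

    hic = _random_intervals(rng, chroms, sizes, config.n_hic, 2000, 8000)
    hic["gene"] = rng.choice(genes, size=len(hic))
    hic["cell_matched"] = rng.random(len(hic)) < 0.4

    enhancers = _random_intervals(rng, chroms, sizes, config.n_enhancers, 500, 2000)
    enhancers["gene"] = rng.choice(genes, size=len(enhancers))
    enhancers["elite"] = rng.random(len(enhancers)) < 0.3

    histone_peaks = {
        mark: _random_intervals(rng, chroms, sizes, config.n_histone_peaks, 500, 3000)
        for mark in _HISTONE_MARKS
    }

    tiles = []
    for c, n in sizes.items():
        starts = np.arange(0, n, 1000)
        tiles.append(pd.DataFrame({
            "chrom": c,
            "start": starts,
            "end": np.minimum(starts + 1000, n),
            "score": rng.normal(-0.05, 0.2, size=len(starts)),
        }))
    phylop = pd.concat(tiles, ignore_index=True)

    return ReferenceBundle(
        sequences=sequences, tss=tss, repeats=repeats, eqtls=eqtls,
        hic=hic, enhancers=enhancers, histone_peaks=histone_peaks,
        phylop=phylop,
    )


def simulate_variants(reference: ReferenceBundle, config: SimConfig) -> pd.DataFrame:
    """Candidate single-nucleotide changes with per-genome filter flags.

    The reference carries the ancestral allele; the derived allele is a random
    different base. Configured fractions of records fail each selection filter
    (archaic mismatch, ape polymorphism, human polymorphism, repeat content)
    so the selection stage has real work to do.
    """
    rng = config.rng("variants")
    sizes = reference.chrom_sizes
    chroms = list(sizes)
    rows = []
    per_chrom = np.maximum(
        rng.multinomial(config.n_variants, [sizes[c] / sum(sizes.values()) for c in chroms]), 1
    )
    for c, n in zip(chroms, per_chrom):
        # keep full oligo windows inside the chromosome
        pos = rng.choice(np.arange(101, sizes[c] - 100), size=n, replace=False)
        rows.append(pd.DataFrame({"chrom": c, "pos": np.sort(pos)}))
    variants = pd.concat(rows, ignore_index=True)
    n = len(variants)
    variants["variant_id"] = [f"v{i:06d}" for i in range(n)]

    anc = np.array([reference.sequences[c][p - 1] for c, p in
                    zip(variants["chrom"], variants["pos"])])
    shift = rng.integers(1, 4, size=n)
    base_idx = np.searchsorted(BASES, anc)
    der = BASES[(base_idx + shift) % 4]
    variants["ancestral"] = anc
    variants["derived"] = der

    mismatch = rng.random(n) < config.frac_archaic_mismatch
    for flag in ("altai_match", "vindija_match", "denisovan_match", "chagyrskaya_match"):
        variants[flag] = True
    which = rng.integers(0, 4, size=n)
    flags = ["altai_match", "vindija_match", "denisovan_match", "chagyrskaya_match"]
    for i, flag in enumerate(flags):
        variants.loc[mismatch & (which == i), flag] = False
    variants["ape_polymorphic"] = rng.random(n) < config.frac_ape_polymorphic
    variants["human_polymorphic"] = rng.random(n) < config.frac_human_polymorphic

    fail_rep = rng.random(n) < config.frac_repeat_fail
    rf = np.where(fail_rep,
                  rng.uniform(0.2500001, 1.0, size=n),
                  rng.uniform(0.0, 0.25, size=n))
    variants["repeat_fraction"] = rf
    return variants


def simulate_library(
    reference: ReferenceBundle, config: SimConfig
) -> tuple[list[OligoPair], pd.DataFrame]:
    """Variant selection + oligo construction + controls, returning the library.

    Returns the list of :class:`OligoPair` (test pairs first, then scrambled,
    then positive controls) and the candidate-variant table used.
    """
    variants = simulate_variants(reference, config)
    selected, _ = select_fixed_variants(variants)
    pairs, _ = build_oligo_pairs(reference.sequences, selected)
    if len(pairs) < config.n_pairs:
        raise ConfigError(
            f"n_variants={config.n_variants} yielded only {len(pairs)} pairs; "
            f"raise n_variants or lower n_pairs={config.n_pairs}"
        )
    pairs = pairs[: config.n_pairs]

    rng = config.rng("library")
    scrambled = make_scrambled_controls(pairs, n=config.n_scrambled, seed=rng)

    positives = []
    chroms = list(reference.sequences)
    for i in range(config.n_positive):
        c = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, len(reference.sequences[c]) - 200))
        positives.append(OligoPair(
            oligo_id=f"pos{i:04d}", chrom=c, window_start=start,
            modern_seq=reference.sequences[c][start:start + 200],
            archaic_seq=None, oligo_class="positive",
        ))
    return pairs + scrambled + positives, variants


def _calibrated_nb_mean(target_median: int, dispersion: float) -> float:
    """Mean of a >=1-truncated NB whose median equals the target.

    Solved by bisection on the analytic truncated CDF; no sampling involved.
    """
    def trunc_median(mean):
        if dispersion <= 0:
            dist = sps.poisson(mean)
        else:
            r = 1.0 / dispersion
            dist = sps.nbinom(r, r / (r + mean))
        p0 = dist.cdf(0)
        # smallest k >= 1 with truncated CDF >= 0.5
        q = p0 + 0.5 * (1 - p0)
        return int(dist.ppf(q))

    lo, hi = float(target_median), 4.0 * target_median
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if trunc_median(mid) >= target_median:
            hi = mid
        else:
            lo = mid
    return hi


def _nb_draw(rng, mean, dispersion):
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean))


def _random_kmers(rng, n: int, k: int) -> np.ndarray:
    """n distinct random k-mers over ACGT."""
    seen: set[int] = set()
    out = np.empty(n, dtype=object)
    filled = 0
    while filled < n:
        draw = rng.integers(0, 4 ** k, size=(n - filled) * 2)
        for v in draw:
            if filled == n:
                break
            v = int(v)
            if v in seen:
                continue
            seen.add(v)
            chars = []
            for _ in range(k):
                chars.append("ACGT"[v & 3])
                v >>= 2
            out[filled] = "".join(chars)
            filled += 1
    return out


def assign_truth(library: list[OligoPair], config: SimConfig) -> GroundTruth:
    """Draw the latent activity state, allele effects, and barcode assignments."""
    rng = config.rng("truth")
    test = [o for o in library if o.oligo_class == "test"]
    ids = pd.Index([o.oligo_id for o in library], name="oligo_id")
    test_ids = pd.Index([o.oligo_id for o in test], name="oligo_id")

    active = pd.Series(rng.random(len(test)) < config.frac_active, index=test_ids)
    jitter = rng.lognormal(0.0, config.alpha_sigma, size=len(ids))
    alpha = pd.Series(config.alpha_null * jitter, index=ids)
    alpha.loc[test_ids[active]] *= config.alpha_active
    pos_ids = [o.oligo_id for o in library if o.oligo_class == "positive"]
    alpha.loc[pos_ids] *= config.alpha_active
    # scrambled controls stay at alpha_null (times jitter)

    effect = pd.Series(0.0, index=test_ids)
    diff = active & (rng.random(len(test)) < config.frac_diff)
    effect.loc[test_ids[diff]] = rng.normal(0.0, config.effect_sd, size=int(diff.sum()))

    nb_mean = _calibrated_nb_mean(config.barcodes_per_oligo, config.barcode_dispersion)
    seq_ids, oligo_col, allele_col = [], [], []
    for o in library:
        alleles = ("modern", "archaic") if o.oligo_class == "test" else (o.oligo_class,)
        for a in alleles:
            seq_ids.append(f"{o.oligo_id}|{a}")
            oligo_col.append(o.oligo_id)
            allele_col.append(a)
    n_bc = np.maximum(_nb_draw(rng, np.full(len(seq_ids), nb_mean),
                               config.barcode_dispersion), 1)
    total = int(n_bc.sum())
    barcodes = _random_kmers(rng, total, config.barcode_length)
    barcode_map = pd.DataFrame({
        "barcode": barcodes,
        "oligo_id": np.repeat(oligo_col, n_bc),
        "allele": np.repeat(allele_col, n_bc),
        "seq_id": np.repeat(seq_ids, n_bc),
        "mu": rng.lognormal(np.log(config.dna_mean) - 0.5 * config.mu_sigma ** 2,
                            config.mu_sigma, size=total),
    })
    return GroundTruth(alpha=alpha, effect=effect, active=active, barcode_map=barcode_map)


def simulate_counts(
    library: list[OligoPair], truth: GroundTruth, config: SimConfig
) -> pd.DataFrame:
    """RNA and DNA UMI count tables for every replicate (long format).

    Zero counts are omitted, as in a real sparse count table. Columns:
    oligo_id, allele, barcode, replicate, molecule, umi_count.
    """
    if not library:
        raise InputError("library is empty")
    rng = config.rng("counts")
    bm = truth.barcode_map
    R = config.n_replicates
    s_dna = rng.lognormal(0.0, config.rep_sigma, size=R)
    s_rna = rng.lognormal(0.0, config.rep_sigma, size=R)

    pair_alpha = truth.alpha.reindex(bm["oligo_id"]).to_numpy()
    eff = truth.effect.reindex(bm["oligo_id"]).fillna(0.0).to_numpy()
    sign = np.where(bm["allele"].to_numpy() == "modern", 0.5,
                    np.where(bm["allele"].to_numpy() == "archaic", -0.5, 0.0))
    allele_rate = pair_alpha * np.power(2.0, sign * eff)
    mu = bm["mu"].to_numpy()

    frames = []
    for r in range(R):
        dna = _nb_draw(rng, mu * s_dna[r], config.dispersion_dna)
        rna = _nb_draw(rng, allele_rate * mu * s_rna[r], config.dispersion_rna)
        for molecule, counts in (("DNA", dna), ("RNA", rna)):
            nz = counts > 0
            frames.append(pd.DataFrame({
                "oligo_id": bm["oligo_id"].to_numpy()[nz],
                "allele": bm["allele"].to_numpy()[nz],
                "barcode": bm["barcode"].to_numpy()[nz],
                "replicate": r + 1,
                "molecule": molecule,
                "umi_count": counts[nz],
            }))
    out = pd.concat(frames, ignore_index=True)
    return out


def simulate_association_reads(truth: GroundTruth, config: SimConfig) -> pd.DataFrame:
    """Alignment-like association records linking barcodes to oligo sequences.

    Each barcode yields >=3 concordant, high-quality read pairs by default;
    the configured noise rates convert disjoint barcode subsets into
    promiscuous, low-support, low-quality, or discordant cases.
    """
    rng = config.rng("assoc")
    bm = truth.barcode_map
    n = len(bm)
    noise = config.assoc_noise
    u = rng.random(n)
    edges = np.cumsum([noise.promiscuous, noise.low_support,
                       noise.low_quality, noise.discordant])
    cls = np.select(
        [u < edges[0], u < edges[1], u < edges[2], u < edges[3]],
        ["promiscuous", "low_support", "low_quality", "discordant"],
        default="clean",
    )
    support = 3 + rng.poisson(max(config.assoc_mean_support - 3, 0), size=n)
    support[cls == "low_support"] = rng.integers(1, 3, size=(cls == "low_support").sum())

    seq_ids = bm["seq_id"].to_numpy()
    barcodes = bm["barcode"].to_numpy()
    good_q = "I" * config.barcode_length                     # Q40 everywhere
    bad_q = "I" * (config.barcode_length - 1) + "5"          # one base at Q20

    hit = np.repeat(seq_ids, support)
    bc = np.repeat(barcodes, support)
    k = len(hit)
    rec = pd.DataFrame({
        "read_id": [f"r{i:08d}" for i in range(k)],
        "oligo_hit_r1": hit,
        "oligo_hit_r3": hit,
        "mapq_r1": 42,
        "mapq_r3": 42,
        "proper_pair": True,
        "barcode_seq": bc,
        "barcode_quals": good_q,
    })
    rec_cls = np.repeat(cls, support)

    # discordant barcodes: r3 hits a different oligo (filtered by rule 1)
    disc = rec_cls == "discordant"
    if disc.any():
        uniq = np.unique(seq_ids)
        rec.loc[disc, "oligo_hit_r3"] = rng.choice(uniq, size=int(disc.sum()))
        rec.loc[disc, "proper_pair"] = False
    lowq = rec_cls == "low_quality"
    rec.loc[lowq, "barcode_quals"] = bad_q

    # promiscuous barcodes: extra concordant records against a second oligo
    prom_idx = np.flatnonzero(cls == "promiscuous")
    if len(prom_idx):
        uniq = np.unique(seq_ids)
        extra_n = np.maximum(support[prom_idx] // 2, 3)
        other = rng.choice(uniq, size=len(prom_idx))
        same = other == seq_ids[prom_idx]
        other[same] = uniq[(np.searchsorted(uniq, other[same]) + 1) % len(uniq)]
        hit2 = np.repeat(other, extra_n)
        bc2 = np.repeat(barcodes[prom_idx], extra_n)
        extra = pd.DataFrame({
            "read_id": [f"x{i:08d}" for i in range(len(hit2))],
            "oligo_hit_r1": hit2,
            "oligo_hit_r3": hit2,
            "mapq_r1": 42,
            "mapq_r3": 42,
            "proper_pair": True,
            "barcode_seq": bc2,
            "barcode_quals": good_q,
        })
        rec = pd.concat([rec, extra], ignore_index=True)
    return rec


def simulate_umi_reads(counts: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Explode a count table into barcode-level reads with UMIs (plus PCR duplicates).

    For each (sequence, barcode, replicate, molecule) key with umi_count = c,
    emits c distinct UMIs, each repeated 1 + Poisson(0.5) times. Distinct-UMI
    counting therefore recovers the input table exactly.
    """
    rng = config.rng("umi")
    c = counts["umi_count"].to_numpy()
    total_umis = int(c.sum())
    row_idx = np.repeat(np.arange(len(counts)), c)
    # UMIs distinct within a row: per-row random offset plus the within-row index
    space = 4 ** config.umi_length
    offset = rng.integers(0, space, size=len(counts))
    within = np.concatenate([np.arange(k) for k in c]) if total_umis else np.array([], dtype=int)
    umi_int = (offset[row_idx] + within) % space
    dup = 1 + rng.poisson(0.5, size=total_umis)

    k = config.umi_length
    lut = np.array(list("ACGT"))
    digits = np.empty((total_umis, k), dtype="<U1")
    v = umi_int.copy()
    for j in range(k):
        digits[:, j] = lut[v & 3]
        v >>= 2
    umis = np.array(["".join(row) for row in digits], dtype=object)

    reads = counts.iloc[np.repeat(row_idx, dup)][
        ["oligo_id", "allele", "barcode", "replicate", "molecule"]
    ].reset_index(drop=True)
    reads["umi"] = np.repeat(umis, dup)
    return reads


def simulate_phenotypes(
    genes: list[str],
    config: SimConfig,
    planted_genes: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Gene-term, gene-phenotype, and TF-expression tables with stored truth.

    If ``planted_genes`` is given, a term named ``TERM_PLANTED`` containing a
    sample of those genes is injected so enrichment recovery can be tested.
    """
    rng = config.rng("phenotypes")
    genes = list(genes)
    rows = []
    for t in range(config.n_terms):
        size = 3 + rng.poisson(5)
        members = rng.choice(genes, size=min(size, len(genes)), replace=False)
        rows.extend({"term": f"TERM_{t:04d}", "gene": g} for g in members)
    if planted_genes:
        members = list(pd.unique(pd.Series(planted_genes)))[: config.plant_term_size]
        rows.extend({"term": "TERM_PLANTED", "gene": g} for g in members)
    term_table = pd.DataFrame(rows)

    n_ph = config.n_phenotypes
    ph_genes = rng.choice(genes, size=n_ph)
    divergent = rng.random(n_ph) < config.frac_divergent
    match = np.where(divergent, rng.random(n_ph) < 0.5, False)
    phenotype_table = pd.DataFrame({
        "phenotype": [f"PH{i:04d}" for i in range(n_ph)],
        "gene": ph_genes,
        "divergent": divergent,
        "direction_match": match,
    })

    tf_expression = pd.DataFrame({
        "tf": [f"TF{i:02d}" for i in range(config.n_tfs)],
        "fpkm": rng.lognormal(1.0, 1.2, size=config.n_tfs),
    })
    return term_table, phenotype_table, tf_expression


def simulate_methylation(
    locus_ids: list[str],
    direction: pd.Series,
    config: SimConfig,
) -> pd.DataFrame:
    """Per-locus modern/archaic methylation with a planted direction effect.

    ``direction`` maps locus -> {"up", "down"} for differentially active loci
    (missing loci get no systematic shift). Upregulating loci lose methylation
    in the modern genome; downregulating loci gain it.
    """
    rng = config.rng("methylation")
    n = len(locus_ids)
    base = rng.beta(2.0, 2.0, size=n)
    delta = np.zeros(n)
    d = direction.reindex(locus_ids)
    delta[(d == "up").to_numpy()] = config.meth_delta_up
    delta[(d == "down").to_numpy()] = config.meth_delta_down
    noise = rng.normal(0.0, config.meth_noise_sd, size=n)
    modern = np.clip(base + delta + noise, 0.0, 1.0)
    return pd.DataFrame({
        "locus_id": locus_ids,
        "modern": modern,
        "archaic": np.clip(base, 0.0, 1.0),
    })
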