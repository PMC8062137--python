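"""Variant selection and oligo library construction.

The library compares, for each candidate locus, a "modern" sequence carrying
the derived allele(s) against an "archaic" sequence carrying the ancestral
allele(s). Candidates are single-nucleotide changes that are fixed (or nearly
fixed) on the modern human lineage: the ancestral state must be confirmed in
all four archaic genomes (three Neanderthals and one Denisovan), must not be
polymorphic among great apes or modern humans, and the surrounding 200 bp
window must not be more than 25% repeat-masked.

Each retained variant yields a 200-base oligo pair: 99 bases upstream and 100
bases downstream of the focal position. When several selected variants fall
inside one window, the modern sequence carries all derived alleles and the
archaic sequence all ancestral alleles. Scrambled controls are base
permutations of sampled test sequences (GC-matched empirical nulls).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataIntegrityError, InputError, SchemaError

ADAPTER_5 = "AGGACCGGATCAACT"
ADAPTER_3 = "CATTGCGTGAACCGA"
OLIGO_LEN = 200
FLANK_UP = 99    # bases upstream of the focal variant
FLANK_DOWN = 100  # bases downstream

ARCHAIC_MATCH_COLUMNS = (
    "altai_match",
    "vindija_match",
    "denisovan_match",
    "chagyrskaya_match",
)

VARIANT_COLUMNS = (
    "chrom",
    "pos",
    "ancestral",
    "derived",
    *ARCHAIC_MATCH_COLUMNS,
    "ape_polymorphic",
    "human_polymorphic",
    "repeat_fraction",
)


@dataclass(frozen=True)
class OligoPair:
    """A modern/archaic pair of 200-base test sequences for one locus.

    ``variant_offsets`` are 0-based offsets of the substituted positions
    within the oligo; the focal variant sits at offset 99 (the 100th base).
    Scrambled and positive controls carry a single sequence in ``modern_seq``
    with ``archaic_seq`` set to None.
    """

    oligo_id: str
    chrom: str
    window_start: int  # 0-based, half-open window [window_start, window_start+200)
    modern_seq: str
    archaic_seq: str | None
    oligo_class: str = "test"  # test | scrambled | positive
    variant_ids: tuple[str, ...] = ()
    variant_offsets: tuple[int, ...] = ()
    focal_pos: int = 0  # 1-based reference coordinate of the focal variant

    @property
    def n_variants(self) -> int:
        return len(self.variant_offsets)

    def __post_init__(self):
        if len(self.modern_seq) != OLIGO_LEN and self.oligo_class == "test":
            raise InputError(f"{self.oligo_id}: oligo length {len(self.modern_seq)} != {OLIGO_LEN}")
        if self.oligo_class == "test":
            if self.archaic_seq is None or len(self.archaic_seq) != OLIGO_LEN:
                raise InputError(f"{self.oligo_id}: test pair needs two {OLIGO_LEN}-base sequences")
            ndiff = sum(a != b for a, b in zip(self.modern_seq, self.archaic_seq))
            if ndiff != self.n_variants:
                raise DataIntegrityError(
                    f"{self.oligo_id}: sequences differ at {ndiff} positions, "
                    f"expected {self.n_variants}"
                )


def _require_columns(df: pd.DataFrame, columns: Iterable[str]) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"variant table is missing required column(s): {', '.join(missing)}")


def select_fixed_variants(
    variants: pd.DataFrame,
    max_repeat_fraction: float = 0.25,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter candidate variants down to fixed, derived, non-repetitive ones.

    Filters are applied conjunctively, in this order, and the attrition table
    attributes each removal to the first filter that rejected it:

    1. all four archaic genomes match the ancestral allele;
    2. not polymorphic among the 114 great-ape genomes;
    3. not polymorphic among modern humans (dbSNP / 1000 Genomes);
    4. repeat coverage of the surrounding 200 bp window <= 25% (inclusive).

    Returns ``(retained, attrition)`` where attrition is a DataFrame with one
    row per filter (``filter``, ``removed``, ``remaining``).
    """
    if len(variants) == 0:
        raise InputError("variant table is empty")
    _require_columns(variants, VARIANT_COLUMNS)

    steps = [
        ("archaic_match", variants[list(ARCHAIC_MATCH_COLUMNS)].all(axis=1)),
        ("ape_polymorphism", ~variants["ape_polymorphic"].astype(bool)),
        ("human_polymorphism", ~variants["human_polymorphic"].astype(bool)),
        ("repeats", variants["repeat_fraction"] <= max_repeat_fraction),
    ]
    keep = pd.Series(True, index=variants.index)
    rows = []
    for name, passed in steps:
        removed = int((keep & ~passed).sum())
        keep &= passed
        rows.append({"filter": name, "removed": removed, "remaining": int(keep.sum())})
    attrition = pd.DataFrame(rows)
    return variants[keep].copy(), attrition


def build_oligo_pair(
    reference: Mapping[str, str],
    focal: Mapping,
    others: pd.DataFrame | None = None,
    oligo_id: str | None = None,
    reference_allele: str = "ancestral",
) -> OligoPair:
    """Construct one 200-base modern/archaic pair centred on a focal variant.

    ``focal`` is a mapping with chrom/pos/ancestral/derived (pos 1-based).
    ``others`` optionally holds additional selected variants; those falling in
    the window are substituted consistently (derived-only in the modern
    sequence, ancestral-only in the archaic one).

    ``reference_allele`` declares which allele the reference sequence carries
    at variant positions ("ancestral" or "derived").

    Raises InputError if the window leaves the chromosome and
    DataIntegrityError if the reference base matches neither declared allele.
    """
    chrom = focal["chrom"]
    pos = int(focal["pos"])
    seq = reference[chrom]
    start = pos - 1 - FLANK_UP  # 0-based window start
    end = pos + FLANK_DOWN      # 0-based half-open end
    if start < 0 or end > len(seq):
        raise InputError(
            f"window [{start}, {end}) for variant at {chrom}:{pos} outside chromosome bounds"
        )
    window = list(seq[start:end])

    in_window = [dict(focal)]
    if others is not None and len(others):
        sub = others[
            (others["chrom"] == chrom)
            & (others["pos"] >= start + 1)
            & (others["pos"] <= end)
            & (others["pos"] != pos)
        ]
        in_window.extend(sub.to_dict("records"))

    modern = list(window)
    archaic = list(window)
    offsets, ids = [], []
    for v in sorted(in_window, key=lambda r: int(r["pos"])):
        off = int(v["pos"]) - 1 - start
        ref_base = window[off]
        anc, der = str(v["ancestral"]).upper(), str(v["derived"]).upper()
        expected = anc if reference_allele == "ancestral" else der
        if ref_base.upper() != expected:
            raise DataIntegrityError(
                f"reference base {ref_base} at {chrom}:{v['pos']} does not match "
                f"declared {reference_allele} allele {expected}"
            )
        modern[off] = der
        archaic[off] = anc
        offsets.append(off)
        ids.append(v.get("variant_id", f"{chrom}:{v['pos']}"))

    return OligoPair(
        oligo_id=oligo_id or f"{chrom}:{pos}",
        chrom=chrom,
        window_start=start,
        modern_seq="".join(modern),
        archaic_seq="".join(archaic),
        oligo_class="test",
        variant_ids=tuple(ids),
        variant_offsets=tuple(offsets),
        focal_pos=pos,
    )


def build_oligo_pairs(
    reference: Mapping[str, str],
    variants: pd.DataFrame,
    reference_allele: str = "ancestral",
) -> tuple[list[OligoPair], pd.DataFrame]:
    """Build one pair per selected variant; out-of-bounds windows are skipped.

    Returns the pair list and a skip report (variant_id, reason).
    """
    pairs: list[OligoPair] = []
    skipped = []
    for idx, row in variants.iterrows():
        vid = row.get("variant_id", f"{row['chrom']}:{row['pos']}")
        try:
            pairs.append(
                build_oligo_pair(
                    reference,
                    row,
                    others=variants,
                    oligo_id=str(vid),
                    reference_allele=reference_allele,
                )
            )
        except InputError as exc:
            skipped.append({"variant_id": vid, "reason": str(exc)})
    return pairs, pd.DataFrame(skipped, columns=["variant_id", "reason"])


def add_adapters(seq: str) -> str:
    """Flank a 200-base fragment with the cloning adapters (230 bases total)."""
    if len(seq) != OLIGO_LEN:
        raise InputError(f"expected a {OLIGO_LEN}-base sequence, got {len(seq)}")
    return ADAPTER_5 + seq + ADAPTER_3


def strip_adapters(seq: str) -> str:
    """Inverse of :func:`add_adapters`."""
    if len(seq) != OLIGO_LEN + len(ADAPTER_5) + len(ADAPTER_3):
        raise InputError(f"expected a 230-base adapted fragment, got {len(seq)}")
    if not (seq.startswith(ADAPTER_5) and seq.endswith(ADAPTER_3)):
        raise InputError("sequence does not carry the expected adapters")
    return seq[len(ADAPTER_5):-len(ADAPTER_3)]


def make_scrambled_controls(
    library: Sequence[OligoPair],
    n: int = 100,
    seed: int | np.random.Generator = 0,
) -> list[OligoPair]:
    """Scrambled negative controls: uniform base permutations of sampled oligos.

    Each control preserves the base composition (hence GC content) of its
    source test sequence. Deterministic under the seed.
    """
    if n > len(library):
        raise InputError(f"requested {n} scrambled controls from a library of {len(library)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chosen = rng.choice(len(library), size=n, replace=False)
    controls = []
    for i, src_idx in enumerate(chosen):
        src = library[int(src_idx)]
        bases = np.array(list(src.modern_seq))
        rng.shuffle(bases)
        controls.append(
            OligoPair(
                oligo_id=f"scr{i:04d}",
                chrom=src.chrom,
                window_start=src.window_start,
                modern_seq="".join(bases),
                archaic_seq=None,
                oligo_class="scrambled",
                variant_ids=(src.oligo_id,),
            )
        )
    return controls
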