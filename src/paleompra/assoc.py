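"""Barcode-to-oligo association from alignment-like read records.

A read pair supports a (barcode, oligo) link only if both reads hit the same
oligo, at least one read has mapping quality >= 6, the pair is proper, and
every base of the 15-base barcode read is at quality >= 30. Surviving records
are grouped by barcode; a barcode linked to more than one distinct oligo is
removed outright (no majority rescue), and a barcode whose link is seen fewer
than three times is dropped. Promiscuity is assessed after the read-level
quality filters, i.e. on the linked set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InputError, SchemaError

RECORD_COLUMNS = (
    "read_id", "oligo_hit_r1", "oligo_hit_r3", "mapq_r1", "mapq_r3",
    "proper_pair", "barcode_seq", "barcode_quals",
)

PHRED_OFFSET = 33


def _min_qual(quals: pd.Series) -> np.ndarray:
    """Minimum Phred score of an ASCII-33 encoded quality string."""
    return np.array([min(ord(ch) for ch in q) - PHRED_OFFSET for q in quals])


def associate_barcodes(
    records: pd.DataFrame,
    min_mapq: int = 6,
    min_barcode_q: int = 30,
    min_support: int = 3,
) -> tuple[pd.DataFrame, dict]:
    """Build the barcode -> oligo map, returning (map, per-rule filter report).

    The map has columns (barcode, oligo_id, support) with one row per barcode.
    Report keys count removals by: discordant_pair, low_mapq, improper_pair,
    low_barcode_quality (read level), then promiscuous_barcode and
    low_support_barcode (barcode level).
    """
    if len(records) == 0:
        raise InputError("no association records supplied")
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise SchemaError(f"association records missing column(s): {', '.join(missing)}")
    bc_len = records["barcode_seq"].str.len()
    if bc_len.nunique() > 1:
        raise InputError("conflicting barcode lengths in association records")

    report: dict[str, int] = {}
    concordant = (
        records["oligo_hit_r1"].notna()
        & (records["oligo_hit_r1"] == records["oligo_hit_r3"])
    )
    report["discordant_pair"] = int((~concordant).sum())
    kept = records[concordant]

    mapq_ok = np.maximum(kept["mapq_r1"], kept["mapq_r3"]) >= min_mapq
    report["low_mapq"] = int((~mapq_ok).sum())
    kept = kept[mapq_ok]

    proper = kept["proper_pair"].astype(bool)
    report["improper_pair"] = int((~proper).sum())
    kept = kept[proper]

    q_ok = _min_qual(kept["barcode_quals"]) >= min_barcode_q
    report["low_barcode_quality"] = int((~q_ok).sum())
    kept = kept[q_ok]

    links = kept.groupby(["barcode_seq", "oligo_hit_r1"], sort=False).size().reset_index()
    links.columns = ["barcode", "oligo_id", "support"]
    n_oligos = links.groupby("barcode")["oligo_id"].transform("nunique")
    promiscuous = n_oligos > 1
    report["promiscuous_barcode"] = int(links.loc[promiscuous, "barcode"].nunique())
    links = links[~promiscuous]

    low = links["support"] < min_support
    report["low_support_barcode"] = int(low.sum())
    links = links[~low]

    bc_map = links.sort_values("barcode", ignore_index=True)
    return bc_map, report


def merge_association_runs(
    records_a: pd.DataFrame,
    records_b: pd.DataFrame,
    **kwargs,
) -> tuple[pd.DataFrame, dict]:
    """Pool two association sequencing runs, then filter on the union.

    Support and promiscuity are assessed on the pooled record set, so a
    barcode seen twice in one run and once in the other reaches support 3.
    """
    for df in (records_a, records_b):
        if len(df) and df["barcode_seq"].str.len().nunique() > 1:
            raise InputError("conflicting barcode lengths within a run")
    if len(records_a) and len(records_b):
        la = records_a["barcode_seq"].str.len().iloc[0]
        lb = records_b["barcode_seq"].str.len().iloc[0]
        if la != lb:
            raise InputError(f"conflicting barcode lengths between runs ({la} vs {lb})")
    pooled = pd.concat([records_a, records_b], ignore_index=True)
    return associate_barcodes(pooled, **kwargs)
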