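"""End-to-end orchestration of the synthetic MPRA analysis.

``run_pipeline`` wires the stages in dependency order — simulate, design,
associate, count, activity, diff, motifs, link, enrich, context — writes
every result as TSV/JSON under the output directory, and records a manifest
with the seed, parameters, per-stage record counts, and content digests of
all artifacts, so that reruns with an identical configuration are verifiably
identical. Stage toggles allow omitting downstream stages; no stage mutates
another stage's outputs.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .activity import activity_table, call_active_pairs
from .annotation import (
    context_enrichment,
    group_mean_compare,
    link_targets,
    methylation_direction_test,
    term_enrichment,
)
from .assoc import associate_barcodes
from .differential import differential_analysis, replicate_sign_agreement
from .errors import ConfigError
from .motifs import background_model, diff_binding, random_pwms, scan_batch, tf_analyses, trim_to_variant
from .quantify import consolidate_umis, replicate_correlation, replicate_ratios
from .simulate import (
    AssocNoise,
    SimConfig,
    assign_truth,
    simulate_association_reads,
    simulate_counts,
    simulate_library,
    simulate_methylation,
    simulate_phenotypes,
    simulate_reference,
    simulate_umi_reads,
)

ALL_STAGES = ("simulate", "associate", "count", "activity", "diff",
              "motifs", "link", "enrich", "context")


@dataclass
class PipelineConfig:
    """Run configuration: seed, scale, thresholds, and stage toggles."""

    outdir: str = "paleompra_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    sim: SimConfig = field(default_factory=SimConfig)
    # thresholds (defaults are the assay's published cutoffs)
    fdr: float = 0.05
    min_barcodes: int = 10
    prune_sd: float = 2.0
    min_sites: int = 10
    fpkm_min: float = 1.0
    min_genes_term: int = 3
    n_motifs: int = 15
    motif_flank: int = 30

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stage(s): {sorted(unknown)}")
        for name in ("fdr", "fpkm_min"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0 < self.fdr <= 1:
            raise ConfigError("fdr must be in (0, 1]")

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        sim_data = data.pop("sim", {})
        noise = sim_data.pop("assoc_noise", None)
        if noise is not None:
            sim_data["assoc_noise"] = AssocNoise(**noise)
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(sim=SimConfig(**sim_data), **data)


def demo_config(seed: int = 0, n_pairs: int = 200) -> PipelineConfig:
    """A desk-scale configuration that runs the full pipeline in seconds."""
    sim = SimConfig(
        seed=seed,
        n_pairs=n_pairs,
        n_variants=max(4 * n_pairs, 400),
        n_scrambled=min(100, max(30, n_pairs // 2)),
        n_positive=30,
        barcodes_per_oligo=20,
        dna_mean=15.0,
        chrom_length=150_000,
        assoc_noise=AssocNoise(promiscuous=0.02, low_support=0.02,
                               low_quality=0.02, discordant=0.02),
    )
    return PipelineConfig(seed=seed, sim=sim)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages and write all outputs under ``config.outdir``.

    Returns a dict of in-memory results keyed by stage product name.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages = set(config.stages)
    results: dict = {}
    stage_counts: dict[str, dict] = {}
    artifacts: list[Path] = []

    def save_tsv(df: pd.DataFrame, name: str) -> None:
        path = out / name
        pio.write_tsv(df, path)
        artifacts.append(path)

    # --- simulate (reference, library, truth, counts) -----------------------
    sim = config.sim
    reference = simulate_reference(sim)
    library, variants = simulate_library(reference, sim)
    truth = assign_truth(library, sim)
    counts = simulate_counts(library, truth, sim)

    pio.write_fasta(reference.sequences, out / "reference.fa")
    pio.write_oligo_fasta(library, out / "oligos.fa")
    artifacts += [out / "reference.fa", out / "oligos.fa"]
    save_tsv(variants, "variants.tsv")
    save_tsv(truth.barcode_map, "barcode_truth.tsv")
    save_tsv(counts, "counts.tsv")
    stage_counts["simulate"] = {
        "variants": len(variants),
        "library_sequences": sum(2 if o.oligo_class == "test" else 1 for o in library),
        "pairs": sum(o.oligo_class == "test" for o in library),
        "barcodes": len(truth.barcode_map),
        "count_rows": len(counts),
    }
    results.update(reference=reference, library=library, truth=truth,
                   counts=counts, variants=variants)

    # --- associate -----------------------------------------------------------
    if "associate" in stages:
        assoc_records = simulate_association_reads(truth, sim)
        bc_map, assoc_report = associate_barcodes(assoc_records)
        save_tsv(bc_map, "barcode_map.tsv")
        stage_counts["associate"] = {
            "records": len(assoc_records),
            "barcodes_kept": len(bc_map),
            **assoc_report,
        }
        results["barcode_map"] = bc_map

    # --- count (UMI consolidation round trip) --------------------------------
    if "count" in stages:
        reads = simulate_umi_reads(counts, sim)
        consolidated, count_report = consolidate_umis(reads)
        save_tsv(consolidated, "counts_consolidated.tsv")
        stage_counts["count"] = count_report
        results["counts_consolidated"] = consolidated

    # --- activity ------------------------------------------------------------
    active_pairs: list[str] = []
    if "activity" in stages:
        act = activity_table(counts, prune_sd=config.prune_sd)
        pairs = call_active_pairs(act, fdr=config.fdr,
                                  min_barcodes=config.min_barcodes)
        active_pairs = pairs.loc[pairs["active_pair"], "oligo_id"].tolist()
        rep = replicate_ratios(counts)
        corr = replicate_correlation(rep)
        save_tsv(act, "activity.tsv")
        save_tsv(pairs, "active_pairs.tsv")
        stage_counts["activity"] = {
            "sequences_tested": len(act),
            "active_pairs": len(active_pairs),
        }
        results.update(activity=act, active_calls=pairs,
                       replicate_correlation=corr)

    # --- differential --------------------------------------------------------
    diff = pd.DataFrame(columns=["pair_id", "lfc", "p", "fdr", "direction"])
    if "diff" in stages and active_pairs:
        diff = differential_analysis(counts, active_pairs)
        save_tsv(diff, "differential.tsv")
        stage_counts["diff"] = {
            "tested": len(diff),
            "differential": int((diff["fdr"] <= config.fdr).sum()),
        }
        if len(diff) >= 2:
            results["replicate_sign_agreement"] = replicate_sign_agreement(diff)
        results["differential"] = diff
    diff_pairs = diff.loc[diff["fdr"] <= config.fdr, "pair_id"].tolist() \
        if len(diff) else []

    # --- motifs --------------------------------------------------------------
    if "motifs" in stages and active_pairs:
        term_genes, phenotype_table, tf_expression = simulate_phenotypes(
            list(reference.tss["gene"]), sim)
        pwms = random_pwms(config.n_motifs,
                           tf_names=list(tf_expression["tf"]),
                           seed=sim.seed)
        pwms = [p for p in pwms if p.source == "direct"]
        meta = pd.DataFrame({"motif_id": [p.motif_id for p in pwms],
                             "tf": [p.tf_name for p in pwms]})
        by_id = {o.oligo_id: o for o in library}
        seqs: dict[str, str] = {}
        pair_of_seq: dict[str, tuple[str, str]] = {}
        for pid in active_pairs:
            o = by_id[pid]
            mod, arc, _ = trim_to_variant(o.modern_seq, o.archaic_seq,
                                          o.variant_offsets, config.motif_flank)
            seqs[f"{pid}|modern"], seqs[f"{pid}|archaic"] = mod, arc
            pair_of_seq[f"{pid}|modern"] = (pid, "modern")
            pair_of_seq[f"{pid}|archaic"] = (pid, "archaic")
        bg = background_model(seqs.values())
        pio.write_meme(pwms, out / "motifs.meme", background=bg)
        artifacts.append(out / "motifs.meme")
        hit_frames = [scan_batch(seqs, p, bg) for p in pwms]
        hits = pd.concat(hit_frames, ignore_index=True)
        if len(hits):
            hits["pair_id"] = hits["seq_id"].map(lambda s: pair_of_seq[s][0])
            hits["allele"] = hits["seq_id"].map(lambda s: pair_of_seq[s][1])
        db = diff_binding(hits, meta) if len(hits) else pd.DataFrame()
        save_tsv(hits, "motif_hits.tsv")
        stage_counts["motifs"] = {"hits": len(hits), "diff_binding": len(db)}
        results.update(motif_hits=hits, diff_binding=db, pwms=pwms,
                       tf_expression=tf_expression)
        if len(db) and len(diff):
            results["tf_analyses"] = tf_analyses(
                db, diff, active_pairs, tf_expression,
                min_sites=config.min_sites, fpkm_min=config.fpkm_min)

    # --- link + enrich -------------------------------------------------------
    if "link" in stages and active_pairs:
        by_id = {o.oligo_id: o for o in library}
        loci = pd.DataFrame([
            {"locus_id": pid, "chrom": by_id[pid].chrom,
             "pos": by_id[pid].focal_pos,
             "start": by_id[pid].window_start,
             "end": by_id[pid].window_start + 200}
            for pid in active_pairs
        ])
        links = link_targets(loci, reference.tss, reference.eqtls,
                             reference.hic, reference.enhancers)
        save_tsv(links, "gene_links.tsv")
        stage_counts["link"] = {"loci": len(loci), "links": len(links)}
        results["gene_links"] = links

        if "enrich" in stages and diff_pairs:
            background_genes = set(links["gene"])
            target_genes = set(links.loc[links["locus_id"].isin(diff_pairs), "gene"])
            term_genes, phenotype_table, _tf = simulate_phenotypes(
                list(reference.tss["gene"]), sim,
                planted_genes=sorted(target_genes))
            enr = term_enrichment(target_genes, background_genes, term_genes,
                                  min_genes=config.min_genes_term)
            save_tsv(enr, "term_enrichment.tsv")
            stage_counts["enrich"] = {"terms_tested": len(enr)}
            results["term_enrichment"] = enr
            results["phenotype_table"] = phenotype_table

    # --- context -------------------------------------------------------------
    if "context" in stages and "activity" in stages:
        by_id = {o.oligo_id: o for o in library}
        pairs_df = results["active_calls"]
        loci = pd.DataFrame([
            {"locus_id": o.oligo_id, "chrom": o.chrom,
             "start": o.window_start, "end": o.window_start + 200}
            for o in library if o.oligo_class == "test"
        ])
        flags = pairs_df.set_index("oligo_id")
        loci["active"] = loci["locus_id"].map(flags["active_pair"]).fillna(False)
        loci["ratio"] = loci["locus_id"].map(
            flags[["ratio_modern", "ratio_archaic"]].max(axis=1))
        ctx = context_enrichment(loci, reference.histone_peaks)
        save_tsv(ctx, "context_enrichment.tsv")
        stage_counts["context"] = {"tests": len(ctx)}
        results["context_enrichment"] = ctx

        direction = diff.set_index("pair_id")["direction"] if len(diff) \
            else pd.Series(dtype=object)
        meth = simulate_methylation(loci["locus_id"].tolist(), direction, sim)
        results["methylation_test"] = methylation_direction_test(meth, direction)

        # conservation comparison on the tiled phyloP track
        tile = reference.phylop.set_index(["chrom"])
        scores = []
        for _, row in loci.iterrows():
            sub = reference.phylop[
                (reference.phylop["chrom"] == row["chrom"])
                & (reference.phylop["start"] < row["end"])
                & (reference.phylop["end"] > row["start"])
            ]
            scores.append(sub["score"].mean())
        loci["phylop"] = scores
        act_v = loci.loc[loci["active"], "phylop"].to_numpy()
        inact_v = loci.loc[~loci["active"], "phylop"].to_numpy()
        if len(act_v) >= 2 and len(inact_v) >= 2:
            results["conservation_compare"] = group_mean_compare(
                {"phylop": (act_v, inact_v)})

    manifest = pio.write_manifest(
        out / "manifest.json",
        seed=config.seed,
        params={
            **{k: v for k, v in dataclasses.asdict(config).items() if k != "sim"},
            "sim": dataclasses.asdict(config.sim),
        },
        artifacts=artifacts,
        stage_counts=stage_counts,
    )
    results["manifest"] = manifest
    summary = {
        "seed": config.seed,
        "stage_counts": stage_counts,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return results
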