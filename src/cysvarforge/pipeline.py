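"""End-to-end synthetic pipeline orchestration.

``run_all`` drives the full chain on generated fixtures: simulate a
genome/proteome and variant calls, write them as standard files, read
them back through the regular readers (the round-trip is part of the
test surface), predict missense consequences, forge the combinatorial
variant peptide database, run the two-stage search on planted spectra,
map accepted peptides to cysteine sites, aggregate benchmark quant
tables, and emit a summary report. Every output is plain text
(FASTA/GTF/VCF/MGF/TSV/JSON) and carries the tool version, seed and a
config hash in a run manifest, so reruns from one seed are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import pyfaidx

import cysvarforge
from cysvarforge import dbforge, mapping, missense, quant, search, simulate
from cysvarforge.dbforge import ForgeConfig
from cysvarforge.simulate import SimConfig

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs up to that stage remain."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclasses.dataclass
class RunConfig:
    sim: SimConfig = dataclasses.field(default_factory=SimConfig)
    forge: ForgeConfig = dataclasses.field(default_factory=ForgeConfig)
    fdr: float = 0.01
    proximity_window: int = 10
    ligandable_threshold: float = 2.0
    sd_max: float | None = 1.0
    min_replicates: int = 2
    n_noise_spectra: int = 40
    n_reference_spectra: int = 60

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_manifest(config: RunConfig, outdir: Path) -> None:
    manifest = {
        "tool": "cysvarforge",
        "version": cysvarforge.__version__,
        "seed": config.sim.seed,
        "config_hash": config.config_hash(),
        "config": dataclasses.asdict(config),
    }
    (outdir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
    )


def run_all(config: RunConfig | None = None, outdir: str | Path = "cysvarforge_run"):
    """Run the full synthetic pipeline; returns the summary dict."""
    config = config or RunConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_manifest(config, outdir)
    state: dict = {}
    for name, fn in [
        ("simulate", _stage_simulate),
        ("predict", _stage_predict),
        ("forge", _stage_forge),
        ("identify", _stage_identify),
        ("map", _stage_map),
        ("quant", _stage_quant),
        ("summarize", _stage_summarize),
    ]:
        t0 = time.perf_counter()
        try:
            fn(config, outdir, state)
        except Exception as exc:  # halt with stage context, keep partial outputs
            raise StageError(name, exc) from exc
        log.info("stage %-9s done in %.2fs", name, time.perf_counter() - t0)
    return state["summary"]


def _stage_simulate(config: RunConfig, outdir: Path, state: dict) -> None:
    toy = simulate.make_toy_genome_and_models(config.sim)
    simulate.write_genome_fasta(toy.genome, outdir / "genome.fa")
    simulate.write_gtf(toy.models, outdir / "models.gtf")
    simulate.write_proteome_fasta(toy.proteome, outdir / "proteome.fa")
    calls, truth, common_keys = simulate.make_variants(config.sim, toy)
    simulate.write_vcf(calls, toy.genome, outdir / "variants.vcf")
    truth.to_csv(outdir / "variant_truth.tsv", sep="\t", index=False)
    common_calls = [c for c in calls if c.genomic_key in common_keys]
    simulate.write_vcf(common_calls, toy.genome, outdir / "common_snps.vcf",
                       sample_name="common")
    state.update(toy=toy, truth=truth)


def _stage_predict(config: RunConfig, outdir: Path, state: dict) -> None:
    genome = pyfaidx.Fasta(str(outdir / "genome.fa"))
    models = missense.read_gene_models(outdir / "models.gtf")
    calls = missense.read_vcf(outdir / "variants.vcf", source="RNA")
    common_keys = missense.read_common_snp_keys(outdir / "common_snps.vcf")
    variants = missense.predict_all(calls, models, genome)
    variants = missense.merge_sources(variants)
    variants = missense.annotate_common(variants, common_keys)
    missense.write_missense_table(variants, outdir / "missense.tsv")
    signature = missense.net_signature(variants)
    signature.to_frame().to_csv(outdir / "aa_signature.tsv", sep="\t", index=False)
    state.update(variants=variants, models=models)


def _stage_forge(config: RunConfig, outdir: Path, state: dict) -> None:
    toy = state["toy"]
    by_protein: dict[str, list] = {}
    for v in state["variants"]:
        by_protein.setdefault(v.protein_accession, []).append(v)
    metadata = {
        m.protein_accession: (m.gene_id, m.transcript_id) for m in state["models"]
    }
    entries = dbforge.forge_database(
        toy.proteome, by_protein, config.forge, metadata
    )
    unique, sidecar = dbforge.dedup_and_write(
        entries,
        outdir / "variant_peptides.fasta",
        mode="search",
        sidecar_path=outdir / "variant_peptides_provenance.tsv",
        with_decoys=True,
    )
    dbforge.dedup_and_write(
        entries, outdir / "variant_peptides_detailed.fasta", mode="detailed"
    )
    state.update(entries=unique, sidecar=sidecar, variants_by_protein=by_protein)


def _reference_peptides(config: RunConfig, proteome: dict[str, str]):
    from cysvarforge.proteolysis import digest, monoisotopic_mass

    fc = config.forge
    records = []
    for acc in sorted(proteome):
        for pep in digest(proteome[acc], max_missed=fc.missed_cleavages,
                          proline_rule=fc.proline_rule):
            if (
                fc.min_len <= len(pep.sequence) <= fc.max_len
                and fc.min_mass <= monoisotopic_mass(pep.sequence) <= fc.max_mass
            ):
                records.append((acc, pep.sequence))
    return records


def _stage_identify(config: RunConfig, outdir: Path, state: dict) -> None:
    toy = state["toy"]
    ref_records = _reference_peptides(config, toy.proteome)
    ref_db = search.SearchDatabase.from_records(
        ref_records + dbforge.generate_decoys(ref_records)
    )
    var_records = [
        (e.protein_accession, e.peptide_sequence) for e in state["entries"]
    ]
    var_db = search.SearchDatabase.from_records(
        var_records + dbforge.generate_decoys(var_records)
    )
    rng = config.sim.rng(300)
    ref_pool = sorted({seq for _, seq in ref_records})
    n_ref = min(config.n_reference_spectra, len(ref_pool))
    planted_ref = [ref_pool[i] for i in
                   sorted(rng.choice(len(ref_pool), n_ref, replace=False))]
    var_pool = sorted({seq for _, seq in var_records})
    planted_var = var_pool[: min(len(var_pool), 40)]
    spectra_dicts, truth = simulate.make_spectra(
        config.sim,
        planted_ref + planted_var,
        noise_count=config.n_noise_spectra,
    )
    simulate.write_mgf(spectra_dicts, outdir / "spectra.mgf")
    truth.to_csv(outdir / "spectra_truth.tsv", sep="\t", index=False)
    spectra = search.read_mgf(outdir / "spectra.mgf")
    result = search.run_two_stage(spectra, ref_db, var_db, fdr=config.fdr)
    search.psms_to_frame(result.stage1_psms, result.stage1_q).to_csv(
        outdir / "stage1_psms.tsv", sep="\t", index=False
    )
    search.psms_to_frame(result.stage2_psms, result.stage2_q).to_csv(
        outdir / "stage2_psms.tsv", sep="\t", index=False
    )
    (outdir / "excluded_scan_list.txt").write_text(
        "".join(s + "\n" for s in result.excluded_scans)
    )
    state.update(two_stage=result)


def _stage_map(config: RunConfig, outdir: Path, state: dict) -> None:
    result = state["two_stage"]
    accepted = result.accepted(stage=2, q_threshold=config.fdr)
    # variant peptides are absent from the reference proteome by
    # construction; residue numbering comes from the forge sidecar instead
    # of substring lookup (SNV-only, so variant numbering == reference)
    sidecar = state["sidecar"]
    by_seq = sidecar.groupby("peptide_sequence").first()
    rows = []
    for p in accepted:
        if p.peptide in by_seq.index:
            meta = by_seq.loc[p.peptide]
            rows.append((p.peptide, meta["protein_accession"],
                         int(meta["start_index"])))
    sites_rows = []
    for peptide, accession, start in rows:
        variants = state["variants_by_protein"].get(accession, [])
        for site in mapping.classify_cysteines(
            peptide, accession, start, variants, config.proximity_window
        ):
            sites_rows.append(
                {
                    "unique_id": site.unique_id,
                    "site_key": site.site_key,
                    "protein_accession": site.protein_accession,
                    "residue_index": site.residue_index,
                    "site_class": site.site_class,
                    "labeling_state": site.labeling_state,
                    "proximal_variants": ";".join(
                        f"{v.ref_aa}{v.residue_index}{v.alt_aa}@{d}"
                        for v, d in site.proximal_variants
                    ),
                    "n_proximal": len(site.proximal_variants),
                }
            )
    sites = (
        pd.DataFrame(
            sites_rows,
            columns=["unique_id", "site_key", "protein_accession",
                     "residue_index", "site_class", "labeling_state",
                     "proximal_variants", "n_proximal"],
        )
        .drop_duplicates(subset="unique_id")
        .sort_values("unique_id")
        .reset_index(drop=True)
    )
    sites.to_csv(outdir / "cys_sites.tsv", sep="\t", index=False)
    state.update(sites=sites)


def _stage_quant(config: RunConfig, outdir: Path, state: dict) -> None:
    folds = {}
    for i, design in enumerate(config.sim.designs):
        tables = simulate.make_quant_tables(config.sim, design, design_salt=i)
        folds[f"{design[0]:g}:{design[1]:g}"] = quant.recover_design_ratio(tables)
    pd.DataFrame(
        [{"design": k, "median_recovered_fold": v} for k, v in folds.items()]
    ).to_csv(outdir / "ratio_benchmark.tsv", sep="\t", index=False)
    # site-level quant + ligandability for the first design
    tables = simulate.make_quant_tables(config.sim, config.sim.designs[0])
    sites = quant.quantify(
        tables,
        min_replicates=config.min_replicates,
        sd_max=config.sd_max,
        ligandable_threshold=config.ligandable_threshold,
    )
    sites.to_csv(outdir / "site_quant.tsv", sep="\t", index=False)
    sites[sites["is_ligandable"]].to_csv(
        outdir / "ligandable_sites.tsv", sep="\t", index=False
    )
    state.update(benchmark_folds=folds, site_quant=sites)


def _stage_summarize(config: RunConfig, outdir: Path, state: dict) -> None:
    variants = state["variants"]
    sites = state["sites"]
    summary = {
        "n_missense_variants": len(variants),
        "n_common": sum(v.is_common for v in variants),
        "n_rare": sum(not v.is_common for v in variants),
        "n_acquired_cys_variants": sum(v.alt_aa == "C" for v in variants),
        "n_lost_cys_variants": sum(v.ref_aa == "C" for v in variants),
        "site_class_counts": (
            sites["site_class"].value_counts().sort_index().to_dict()
        ),
        "n_proximal_sites": int(
            ((sites["site_class"] == "reference") & (sites["n_proximal"] > 0)).sum()
        ),
        "n_ligandable_sites": int(state["site_quant"]["is_ligandable"].sum()),
        "benchmark_folds": state["benchmark_folds"],
    }
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    state["summary"] = summary
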