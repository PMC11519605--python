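"""Seeded synthetic fixtures for every pipeline input.

Generates internally consistent toy genomes + gene models + proteomes,
SNV sets with a configurable C→T transition bias (the CpG-instability
signature that favors gain-of-cysteine codons), MS/MS peak lists with
planted identities, and heavy/light quant tables at designed mixing
ratios with multiplicative lognormal intensity noise. Every generator is
deterministic under a fixed seed and each artifact ships with a truth
sidecar so tests can verify recovery against planted ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from cysvarforge.missense import GeneModel, VariantCall, reverse_complement
from cysvarforge.proteolysis import fragment_ions, precursor_mz

CODONS: dict[str, list[str]] = {}
for _c in (
    a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
):
    _aa = str(Seq(_c).translate())
    CODONS.setdefault(_aa, []).append(_c)

#: the six pairwise mixing designs of the heavy/light validation benchmark
MIXING_DESIGNS: tuple[tuple[float, float], ...] = (
    (1, 1), (10, 10), (1, 4), (4, 1), (1, 10), (10, 1),
)


@dataclass
class SimConfig:
    seed: int = 1
    # genome / proteome
    n_proteins: int = 20
    protein_length_range: tuple[int, int] = (60, 120)
    n_chromosomes: int = 3
    minus_strand_fraction: float = 0.4
    two_exon_fraction: float = 0.5
    intron_length_range: tuple[int, int] = (20, 60)
    spacer_length_range: tuple[int, int] = (30, 80)
    # variants
    n_variants: int = 40
    ct_bias_weight: float = 10.0
    non_pass_fraction: float = 0.1
    common_fraction: float = 0.5
    # quant tables
    designs: tuple[tuple[float, float], ...] = MIXING_DESIGNS
    n_peptides: int = 500
    n_replicates: int = 3
    intensity_cv: float = 0.10
    base_intensity: float = 1e6
    n_unpaired_heavy: int = 10
    n_unpaired_light: int = 10
    n_metox: int = 10
    # spectra
    fragment_jitter_ppm: float = 5.0
    precursor_jitter_ppm: float = 2.0
    noise_peak_fraction: float = 0.2
    mz_range: tuple[float, float] = (200.0, 1500.0)

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng(self.seed + salt)


# ---------------------------------------------------------------------------
# toy genome / gene models / proteome


@dataclass
class ToyGenome:
    genome: dict[str, str]
    models: list[GeneModel]
    proteome: dict[str, str]  # protein accession -> sequence
    transcripts: dict[str, str]  # transcript id -> CDS nucleotide sequence


_AA_WEIGHTS = {aa: 1.0 for aa in "ACDEFGHIKLMNPQRSTVWY"}
_AA_WEIGHTS.update({"K": 2.5, "R": 2.5, "C": 1.5, "L": 2.0, "S": 1.5})


def _random_protein(rng: np.random.Generator, length: int) -> str:
    aas = list(_AA_WEIGHTS)
    w = np.array([_AA_WEIGHTS[a] for a in aas])
    body = rng.choice(aas, size=length - 1, p=w / w.sum())
    return "M" + "".join(body)


def _back_translate(rng: np.random.Generator, protein: str) -> str:
    return "".join(rng.choice(CODONS[aa]) for aa in protein)


def _random_bases(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def make_toy_genome_and_models(config: SimConfig) -> ToyGenome:
    """A consistent genome/GTF/proteome triple.

    Translating the spliced CDS of every model over the genome reproduces
    the proteome record exactly; roughly ``minus_strand_fraction`` of the
    genes lie on the minus strand and ``two_exon_fraction`` are split by an
    intron.
    """
    rng = config.rng(0)
    chromosomes = {f"chr{i + 1}": [] for i in range(config.n_chromosomes)}
    models = []
    proteome = {}
    transcripts = {}
    lo, hi = config.protein_length_range
    for g in range(config.n_proteins):
        protein = _random_protein(rng, int(rng.integers(lo, hi + 1)))
        cds = _back_translate(rng, protein)
        tx = f"TX{g + 1:04d}"
        acc = f"P{g + 1:04d}"
        gene = f"GENE{g + 1:04d}"
        strand = "-" if rng.random() < config.minus_strand_fraction else "+"
        chrom = f"chr{g % config.n_chromosomes + 1}"
        parts = [cds]
        if rng.random() < config.two_exon_fraction and len(cds) > 12:
            cut = int(rng.integers(3, len(cds) - 3))
            parts = [cds[:cut], cds[cut:]]
        # genomic (left-to-right) exon texts
        if strand == "+":
            exon_texts = parts
        else:
            exon_texts = [reverse_complement(p) for p in reversed(parts)]
        pieces = chromosomes[chrom]
        offset = sum(len(p) for p in pieces)
        spacer = _random_bases(rng, int(rng.integers(*config.spacer_length_range)))
        pieces.append(spacer)
        offset += len(spacer)
        intervals = []
        for i, text in enumerate(exon_texts):
            if i > 0:
                intron = _random_bases(
                    rng, int(rng.integers(*config.intron_length_range))
                )
                pieces.append(intron)
                offset += len(intron)
            start = offset + 1
            pieces.append(text)
            offset += len(text)
            intervals.append((start, offset))
        models.append(
            GeneModel(
                transcript_id=tx,
                protein_accession=acc,
                gene_id=gene,
                chromosome=chrom,
                strand=strand,
                cds_intervals=tuple(intervals),
            )
        )
        proteome[acc] = protein
        transcripts[tx] = cds
    genome = {chrom: "".join(pieces) for chrom, pieces in chromosomes.items()}
    return ToyGenome(genome=genome, models=models, proteome=proteome,
                     transcripts=transcripts)


def write_genome_fasta(genome: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def write_proteome_fasta(proteome: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for acc in sorted(proteome):
            fh.write(f">{acc}\n{proteome[acc]}\n")


def write_gtf(models: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            # frame of each CDS piece in transcript order
            order = m.cds_intervals if m.strand == "+" else m.cds_intervals[::-1]
            consumed = 0
            frames = {}
            for s, e in order:
                frames[(s, e)] = (3 - consumed % 3) % 3
                consumed += e - s + 1
            for s, e in m.cds_intervals:
                attrs = (
                    f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
                    f'protein_id "{m.protein_accession}";'
                )
                fh.write(
                    f"{m.chromosome}\tcysvarforge\tCDS\t{s}\t{e}\t.\t"
                    f"{m.strand}\t{frames[(s, e)]}\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# variants


_TRANSITION = {"C": "T", "G": "A"}


def make_variants(
    config: SimConfig, toy: ToyGenome
) -> tuple[list[VariantCall], pd.DataFrame, set[tuple[str, int, str, str]]]:
    """SNVs over coding positions with a C→T transition bias.

    Plus-strand C→T and G→A changes (the same transition on opposite
    strands) carry ``ct_bias_weight`` relative to every other substitution.
    Returns the calls, a truth table of expected consequences computed in
    transcript space (independent of the genomic-coordinate prediction
    path), and the genomic keys designated common.
    """
    rng = config.rng(1)
    # all coding positions: (model index, cds offset) -> genomic position
    coding = []
    for mi, m in enumerate(toy.models):
        plus_positions = [
            pos for s, e in m.cds_intervals for pos in range(s, e + 1)
        ]
        ordered = plus_positions if m.strand == "+" else plus_positions[::-1]
        for offset, gpos in enumerate(ordered):
            coding.append((mi, offset, gpos))
    take = min(config.n_variants, len(coding))
    chosen = rng.choice(len(coding), size=take, replace=False)
    calls, truth_rows = [], []
    common_keys: set[tuple[str, int, str, str]] = set()
    seen_positions = set()
    for idx in sorted(chosen):
        mi, offset, gpos = coding[idx]
        m = toy.models[mi]
        if (m.chromosome, gpos) in seen_positions:
            continue
        seen_positions.add((m.chromosome, gpos))
        ref = toy.genome[m.chromosome][gpos - 1]
        alts = [b for b in "ACGT" if b != ref]
        weights = np.array(
            [config.ct_bias_weight if _TRANSITION.get(ref) == b else 1.0
             for b in alts]
        )
        alt = str(rng.choice(alts, p=weights / weights.sum()))
        status = "PASS" if rng.random() >= config.non_pass_fraction else "lowqual"
        call = VariantCall(
            chromosome=m.chromosome,
            position=gpos,
            ref_base=ref,
            alt_base=alt,
            filter_status=status,
            source="RNA",
        )
        calls.append(call)
        if rng.random() < config.common_fraction:
            common_keys.add(call.genomic_key)
        # expected consequence from transcript-space bookkeeping
        cds = toy.transcripts[m.transcript_id]
        alt_cds_base = alt if m.strand == "+" else reverse_complement(alt)
        ci, within = divmod(offset, 3)
        codon = cds[3 * ci : 3 * ci + 3]
        alt_codon = codon[:within] + alt_cds_base + codon[within + 1 :]
        ref_aa = str(Seq(codon).translate())
        alt_aa = str(Seq(alt_codon).translate())
        kind = (
            "nonsense" if alt_aa == "*"
            else "synonymous" if alt_aa == ref_aa
            else "missense"
        )
        truth_rows.append(
            {
                "chromosome": m.chromosome,
                "position": gpos,
                "ref_base": ref,
                "alt_base": alt,
                "transcript_id": m.transcript_id,
                "protein_accession": m.protein_accession,
                "expected_kind": kind,
                "residue_index": ci + 1,
                "ref_aa": ref_aa,
                "alt_aa": alt_aa,
                "filter_status": status,
                "is_common": call.genomic_key in common_keys,
            }
        )
    truth = pd.DataFrame(truth_rows)
    return calls, truth, common_keys


def write_vcf(
    calls: list[VariantCall],
    genome: dict[str, str],
    path: str | Path,
    sample_name: str = "toy",
) -> None:
    """Minimal VCFv4.2 with contig headers (pysam-readable)."""
    ordered = sorted(calls, key=lambda c: (c.chromosome, c.position, c.alt_base))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=cysvarforge-simulate ({sample_name})\n")
        for chrom in sorted(genome):
            fh.write(f"##contig=<ID={chrom},length={len(genome[chrom])}>\n")
        fh.write('##FILTER=<ID=lowqual,Description="Low quality call">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in ordered:
            fh.write(
                f"{c.chromosome}\t{c.position}\t.\t{c.ref_base}\t{c.alt_base}"
                f"\t.\t{c.filter_status}\t.\n"
            )


# ---------------------------------------------------------------------------
# quant tables


def make_quant_tables(
    config: SimConfig,
    design: tuple[float, float],
    design_salt: int = 0,
) -> list[pd.DataFrame]:
    """Replicate quant tables at one designed H:L mixing ratio.

    Each of ``n_peptides`` sites gets one row per replicate with heavy and
    light intensities drawn around base * design with multiplicative
    lognormal noise at the configured CV. Extra planted rows (separate
    site ids) exercise the unpaired-channel caps and the Met-ox exclusion.
    """
    h_mix, l_mix = design
    rng = config.rng(100 + design_salt)
    sigma = float(np.sqrt(np.log1p(config.intensity_cv**2)))
    tables = []
    for rep in range(1, config.n_replicates + 1):
        rows = []
        base = config.base_intensity * rng.lognormal(0.0, 0.25, config.n_peptides)
        noise_h = rng.lognormal(-sigma**2 / 2, sigma, config.n_peptides)
        noise_l = rng.lognormal(-sigma**2 / 2, sigma, config.n_peptides)
        for i in range(config.n_peptides):
            rows.append(
                {
                    "modified_peptide": f"PEP{i + 1:05d}",
                    "site_id": f"SITE{i + 1:05d}",
                    "replicate_id": rep,
                    "heavy_intensity": base[i] * h_mix * noise_h[i],
                    "light_intensity": base[i] * l_mix * noise_l[i],
                    "has_met_oxidation": False,
                }
            )
        for i in range(config.n_unpaired_heavy):
            rows.append(
                {
                    "modified_peptide": f"UPH{i + 1:04d}",
                    "site_id": f"UPH{i + 1:04d}",
                    "replicate_id": rep,
                    "heavy_intensity": config.base_intensity
                    * rng.lognormal(0, sigma),
                    "light_intensity": np.nan,
                    "has_met_oxidation": False,
                }
            )
        for i in range(config.n_unpaired_light):
            rows.append(
                {
                    "modified_peptide": f"UPL{i + 1:04d}",
                    "site_id": f"UPL{i + 1:04d}",
                    "replicate_id": rep,
                    "heavy_intensity": np.nan,
                    "light_intensity": config.base_intensity
                    * rng.lognormal(0, sigma),
                    "has_met_oxidation": False,
                }
            )
        for i in range(config.n_metox):
            rows.append(
                {
                    "modified_peptide": f"MOX{i + 1:04d}",
                    "site_id": f"MOX{i + 1:04d}",
                    "replicate_id": rep,
                    "heavy_intensity": config.base_intensity,
                    "light_intensity": config.base_intensity,
                    "has_met_oxidation": True,
                }
            )
        tables.append(pd.DataFrame(rows))
    return tables


# ---------------------------------------------------------------------------
# spectra


def make_spectra(
    config: SimConfig,
    true_peptides: list[str],
    noise_count: int = 0,
    charge: int = 2,
    scan_start: int = 1,
    zero_pad_every: int = 7,
) -> tuple[list[dict], pd.DataFrame]:
    """MGF-ready spectra with planted identities.

    True spectra carry the peptide's b/y ladder with uniform ppm jitter
    plus ``noise_peak_fraction`` decoy peaks; noise spectra reuse a random
    true peptide's precursor (so database candidates exist) but carry only
    random peaks. Every ``zero_pad_every``-th scan id is zero-padded to
    exercise leading-zero normalization. Returns (spectra_dicts, truth)
    where truth maps normalized scan number to the planted peptide (empty
    string for noise).
    """
    rng = config.rng(200)
    lo_mz, hi_mz = config.mz_range
    spectra = []
    truth_rows = []
    entries = [(p, False) for p in true_peptides] + [
        (str(rng.choice(true_peptides)), True) for _ in range(noise_count)
    ]
    for i, (peptide, is_noise) in enumerate(entries):
        scan = scan_start + i
        scan_id = f"{scan:07d}" if zero_pad_every and scan % zero_pad_every == 0 else str(scan)
        ions = fragment_ions(peptide)
        ladder = np.array(ions["b"] + ions["y"])
        if is_noise:
            peaks = rng.uniform(lo_mz, hi_mz, size=len(ladder))
        else:
            jitter = rng.uniform(
                -config.fragment_jitter_ppm, config.fragment_jitter_ppm, len(ladder)
            )
            peaks = ladder * (1 + jitter * 1e-6)
            n_noise = int(
                round(
                    len(ladder)
                    * config.noise_peak_fraction
                    / (1 - config.noise_peak_fraction)
                )
            )
            peaks = np.concatenate([peaks, rng.uniform(lo_mz, hi_mz, n_noise)])
        pj = rng.uniform(-config.precursor_jitter_ppm, config.precursor_jitter_ppm)
        mz = precursor_mz(peptide, charge) * (1 + pj * 1e-6)
        spectra.append(
            {
                "m/z array": np.sort(peaks),
                "intensity array": np.ones(len(peaks)),
                "params": {
                    "title": f"scan={scan_id}",
                    "pepmass": (mz, None),
                    "charge": charge,
                    "scans": scan_id,
                },
            }
        )
        truth_rows.append(
            {
                "scan": str(scan),
                "peptide": "" if is_noise else peptide,
                "is_noise": is_noise,
            }
        )
    return spectra, pd.DataFrame(truth_rows)


def write_mgf(spectra: list[dict], path: str | Path) -> None:
    from pyteomics import mgf

    mgf.write(spectra, output=str(path), file_mode="w")
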