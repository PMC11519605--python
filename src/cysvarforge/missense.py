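"""Genomic SNVs to protein-level single-amino-acid variants (SAAVs).

Coordinates follow the VCF/GTF convention: genomic positions and CDS
intervals are 1-based inclusive, protein residue indices are 1-based.
CDS offsets are 0-based internally. Only SNVs are considered; indels,
multi-nucleotide variants and splice consequences are out of scope, so a
variant never changes protein length. The standard nuclear genetic code is
used throughout.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path

import gffutils
import pandas as pd
import pysam
from Bio.Seq import Seq

log = logging.getLogger(__name__)

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class CoordinateError(ValueError):
    """A CDS interval or variant position falls outside the chromosome."""


class ModelError(ValueError):
    """A gene model violates its invariants (e.g. CDS length not divisible by 3)."""


class ReferenceMismatchError(ValueError):
    """The VCF REF base disagrees with the genome sequence."""


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding transcript: ordered CDS intervals on one chromosome."""

    transcript_id: str
    protein_accession: str
    gene_id: str
    chromosome: str
    strand: str  # "+" or "-"
    cds_intervals: tuple[tuple[int, int], ...]  # 1-based inclusive, genomic order

    def __post_init__(self):
        if self.strand not in "+-":
            raise ModelError(f"{self.transcript_id}: strand must be + or -")
        ivals = self.cds_intervals
        if not ivals:
            raise ModelError(f"{self.transcript_id}: no CDS intervals")
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            if s2 <= e1:
                raise ModelError(f"{self.transcript_id}: intervals unsorted/overlapping")
        if any(s > e for s, e in ivals):
            raise ModelError(f"{self.transcript_id}: interval start > end")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals)


@dataclass(frozen=True)
class VariantCall:
    """One SNV from a VCF record."""

    chromosome: str
    position: int  # 1-based
    ref_base: str
    alt_base: str
    filter_status: str = "PASS"
    source: str = "RNA"  # RNA | WES
    vaf: float | None = None
    is_common: bool | None = None

    def __post_init__(self):
        if self.ref_base == self.alt_base:
            raise ValueError("ref and alt base identical")
        if self.ref_base not in "ACGT" or self.alt_base not in "ACGT":
            raise ValueError("ref/alt must be single A/C/G/T bases")

    @property
    def genomic_key(self) -> tuple[str, int, str, str]:
        return (self.chromosome, self.position, self.ref_base, self.alt_base)


@dataclass(frozen=True)
class MissenseVariant:
    """A single amino acid variant on one protein."""

    protein_accession: str
    residue_index: int  # 1-based
    ref_aa: str
    alt_aa: str
    sources: frozenset[str] = frozenset({"RNA"})
    is_common: bool = False
    cadd_phred: float | None = None
    genomic_key: tuple[str, int, str, str] | None = None
    transcript_id: str | None = None
    filter_status: str = "PASS"

    def __post_init__(self):
        if self.ref_aa == self.alt_aa:
            raise ValueError("missense variant must change the residue")
        if self.residue_index < 1:
            raise ValueError("residue_index is 1-based and must be >= 1")


@dataclass(frozen=True)
class Consequence:
    """Classified effect of one SNV on one transcript."""

    kind: str  # missense | synonymous | nonsense | noncoding | skipped
    variant: MissenseVariant | None = None
    residue_index: int | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None


@dataclass
class AASignature:
    """Per-amino-acid gained/lost/net tallies over a set of missense variants."""

    gained: dict[str, int] = field(default_factory=dict)
    lost: dict[str, int] = field(default_factory=dict)

    def net(self, aa: str) -> int:
        return self.gained.get(aa, 0) - self.lost.get(aa, 0)

    @property
    def n_variants(self) -> int:
        return sum(self.gained.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "amino_acid": aa,
                "gained": self.gained.get(aa, 0),
                "lost": self.lost.get(aa, 0),
                "net": self.net(aa),
            }
            for aa in AMINO_ACIDS
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sequence access


def _fetch(genome, chromosome: str, start: int, end: int) -> str:
    """Fetch genome[start..end] (1-based inclusive) as an uppercase string.

    ``genome`` may be a pyfaidx.Fasta or any mapping of chromosome -> string.
    """
    try:
        seq = genome[chromosome]
    except KeyError as exc:
        raise CoordinateError(f"unknown chromosome {chromosome!r}") from exc
    if start < 1 or end > len(seq):
        raise CoordinateError(
            f"{chromosome}:{start}-{end} outside chromosome of length {len(seq)}"
        )
    piece = seq[start - 1 : end]
    return str(piece).upper()


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def extract_cds(model: GeneModel, genome) -> str:
    """Spliced CDS nucleotide sequence in translation (5'→3' coding) order."""
    plus = "".join(
        _fetch(genome, model.chromosome, s, e) for s, e in model.cds_intervals
    )
    cds = reverse_complement(plus) if model.strand == "-" else plus
    if len(cds) % 3 != 0:
        raise ModelError(
            f"{model.transcript_id}: CDS length {len(cds)} not divisible by 3"
        )
    return cds


def translate_cds(cds: str) -> str:
    protein = str(Seq(cds).translate())
    if "*" in protein[:-1]:
        raise ModelError("internal stop codon in CDS")
    return protein.rstrip("*")


def _cds_offset(model: GeneModel, position: int) -> int | None:
    """0-based offset of a genomic position within the coding sequence.

    Returns None when the position lies outside all CDS intervals.
    Strand-aware: on minus-strand models offset 0 is the genomically last base.
    """
    plus_offset = 0
    hit = None
    for s, e in model.cds_intervals:
        if s <= position <= e:
            hit = plus_offset + (position - s)
        plus_offset += e - s + 1
    if hit is None:
        return None
    return hit if model.strand == "+" else plus_offset - 1 - hit


def predict_coding(call: VariantCall, model: GeneModel, genome) -> Consequence:
    """Classify one SNV against one transcript.

    Maps the genomic position to its CDS offset, substitutes the alternate
    base into the affected codon (complemented on minus-strand models) and
    translates reference and alternate codons with the standard code.
    """
    if call.chromosome != model.chromosome:
        return Consequence(kind="noncoding")
    offset = _cds_offset(model, call.position)
    if offset is None:
        return Consequence(kind="noncoding")
    genome_base = _fetch(genome, call.chromosome, call.position, call.position)
    if genome_base == "N":
        log.warning(
            "skipping %s:%d: ambiguous genome base N", call.chromosome, call.position
        )
        return Consequence(kind="skipped")
    if genome_base != call.ref_base:
        raise ReferenceMismatchError(
            f"{call.chromosome}:{call.position}: VCF REF {call.ref_base} != "
            f"genome {genome_base}"
        )
    cds = extract_cds(model, genome)
    alt = (
        call.alt_base
        if model.strand == "+"
        else call.alt_base.translate(COMPLEMENT)
    )
    codon_index, within = divmod(offset, 3)
    codon = cds[3 * codon_index : 3 * codon_index + 3]
    alt_codon = codon[:within] + alt + codon[within + 1 :]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    residue = codon_index + 1
    if alt_aa == "*":
        return Consequence(kind="nonsense", residue_index=residue, ref_aa=ref_aa)
    if alt_aa == ref_aa:
        return Consequence(kind="synonymous", residue_index=residue, ref_aa=ref_aa)
    return Consequence(
        kind="missense",
        residue_index=residue,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        variant=MissenseVariant(
            protein_accession=model.protein_accession,
            residue_index=residue,
            ref_aa=ref_aa,
            alt_aa=alt_aa,
            sources=frozenset({call.source}),
            genomic_key=call.genomic_key,
            transcript_id=model.transcript_id,
            filter_status=call.filter_status,
        ),
    )


# ---------------------------------------------------------------------------
# batch prediction and annotation


def predict_all(
    calls: list[VariantCall],
    models: list[GeneModel],
    genome,
    pass_only: bool = False,
) -> list[MissenseVariant]:
    """Predict consequences for every call on every overlapping transcript.

    Non-PASS calls are retained (flagged via ``filter_status``) unless
    ``pass_only`` is set. Multi-transcript consequences are computed per
    supplied transcript; supply a non-redundant transcript list to avoid
    duplicates.
    """
    by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    for m in models:
        by_chrom[m.chromosome].append(m)
    variants = []
    for call in calls:
        if pass_only and call.filter_status != "PASS":
            continue
        for model in by_chrom.get(call.chromosome, []):
            cons = predict_coding(call, model, genome)
            if cons.kind == "missense":
                variants.append(cons.variant)
    return variants


def merge_sources(variants: list[MissenseVariant]) -> list[MissenseVariant]:
    """Merge identical protein changes seen in both RNA and exome data.

    Variants sharing (protein, residue, ref, alt) collapse to one record
    whose sources are the union; both filter statuses are retained by
    keeping the lexicographically first (conflicts are recorded, none
    discarded — a non-PASS duplicate keeps its flag via the sources field).
    """
    grouped: dict[tuple, list[MissenseVariant]] = defaultdict(list)
    for v in variants:
        grouped[(v.protein_accession, v.residue_index, v.ref_aa, v.alt_aa)].append(v)
    merged = []
    for group in grouped.values():
        base = group[0]
        merged.append(
            replace(
                base,
                sources=frozenset().union(*(v.sources for v in group)),
                filter_status=";".join(sorted({v.filter_status for v in group})),
            )
        )
    merged.sort(key=lambda v: (v.protein_accession, v.residue_index, v.alt_aa))
    return merged


def annotate_common(
    variants: list[MissenseVariant],
    common_snp_keys: set[tuple[str, int, str, str]],
) -> list[MissenseVariant]:
    """Set ``is_common`` by exact (chrom, pos, ref, alt) membership."""
    return [
        replace(v, is_common=v.genomic_key in common_snp_keys) for v in variants
    ]


def annotate_cadd(
    variants: list[MissenseVariant],
    cadd_scores: dict[tuple[str, int, str, str], float],
) -> list[MissenseVariant]:
    """Attach CADD phred scores via the genomic key; absent keys stay None."""
    return [
        replace(v, cadd_phred=cadd_scores.get(v.genomic_key)) for v in variants
    ]


def net_signature(variants: list[MissenseVariant]) -> AASignature:
    """Amino-acid gain/loss tallies: one gained and one lost residue per SAAV."""
    sig = AASignature()
    for v in variants:
        sig.gained[v.alt_aa] = sig.gained.get(v.alt_aa, 0) + 1
        sig.lost[v.ref_aa] = sig.lost.get(v.ref_aa, 0) + 1
    return sig


# ---------------------------------------------------------------------------
# file I/O


def read_vcf(path: str | Path, source: str = "RNA") -> list[VariantCall]:
    """Read SNV records from a VCF (plain or bgzipped); non-SNVs are skipped."""
    calls = []
    with pysam.VariantFile(str(path)) as vcf:
        has_vaf = "VAF" in vcf.header.info
        for rec in vcf:
            if rec.alts is None:
                continue
            for alt in rec.alts:
                if len(rec.ref) != 1 or len(alt) != 1:
                    continue
                if rec.ref not in "ACGT" or alt not in "ACGT":
                    continue
                filters = list(rec.filter.keys())
                status = "PASS" if (not filters or filters == ["PASS"]) else ";".join(filters)
                vaf = rec.info.get("VAF", None) if has_vaf else None
                if isinstance(vaf, tuple):
                    vaf = vaf[0]
                calls.append(
                    VariantCall(
                        chromosome=rec.chrom,
                        position=rec.pos,
                        ref_base=rec.ref,
                        alt_base=alt,
                        filter_status=status,
                        source=source,
                        vaf=vaf,
                    )
                )
    return calls


def read_gene_models(gtf_path: str | Path) -> list[GeneModel]:
    """Build gene models from the CDS features of a GTF/GFF3 file."""
    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    per_tx: dict[str, list] = defaultdict(list)
    for feat in db.features_of_type("CDS"):
        tx = feat.attributes.get("transcript_id", [feat.id])[0]
        per_tx[tx].append(feat)
    models = []
    for tx, feats in sorted(per_tx.items()):
        feats.sort(key=lambda f: f.start)
        first = feats[0]
        models.append(
            GeneModel(
                transcript_id=tx,
                protein_accession=first.attributes.get("protein_id", [tx])[0],
                gene_id=first.attributes.get("gene_id", [tx])[0],
                chromosome=first.seqid,
                strand=first.strand,
                cds_intervals=tuple((f.start, f.end) for f in feats),
            )
        )
    return models


def read_common_snp_keys(path: str | Path) -> set[tuple[str, int, str, str]]:
    """Genomic keys of a common-SNP VCF, for rarity annotation."""
    return {c.genomic_key for c in read_vcf(path)}


def read_cadd_table(path: str | Path) -> dict[tuple[str, int, str, str], float]:
    """CADD scores keyed by (chrom, pos, ref, alt); TSV columns
    chromosome, position, ref_base, alt_base, cadd_phred."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    return {
        (r.chromosome, int(r.position), r.ref_base, r.alt_base): float(r.cadd_phred)
        for r in df.itertuples()
    }


MISSENSE_COLUMNS = [
    "transcript_id",
    "protein_accession",
    "residue_index",
    "ref_aa",
    "alt_aa",
    "source",
    "is_common",
    "filter_status",
    "chromosome",
    "position",
    "ref_base",
    "alt_base",
    "cadd_phred",
]


def variants_to_frame(variants: list[MissenseVariant]) -> pd.DataFrame:
    rows = []
    for v in variants:
        chrom, pos, ref, alt = v.genomic_key or ("", 0, "", "")
        rows.append(
            {
                "transcript_id": v.transcript_id or "",
                "protein_accession": v.protein_accession,
                "residue_index": v.residue_index,
                "ref_aa": v.ref_aa,
                "alt_aa": v.alt_aa,
                "source": ";".join(sorted(v.sources)),
                "is_common": v.is_common,
                "filter_status": v.filter_status,
                "chromosome": chrom,
                "position": pos,
                "ref_base": ref,
                "alt_base": alt,
                "cadd_phred": v.cadd_phred,
            }
        )
    return pd.DataFrame(rows, columns=MISSENSE_COLUMNS)


def write_missense_table(variants: list[MissenseVariant], path: str | Path) -> None:
    variants_to_frame(variants).to_csv(path, sep="\t", index=False)


def read_missense_table(path: str | Path) -> list[MissenseVariant]:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    variants = []
    for r in df.itertuples():
        variants.append(
            MissenseVariant(
                protein_accession=r.protein_accession,
                residue_index=int(r.residue_index),
                ref_aa=r.ref_aa,
                alt_aa=r.alt_aa,
                sources=frozenset(str(r.source).split(";")),
                is_common=bool(r.is_common),
                cadd_phred=None if pd.isna(r.cadd_phred) else float(r.cadd_phred),
                genomic_key=(str(r.chromosome), int(r.position), r.ref_base, r.alt_base),
                transcript_id=r.transcript_id,
                filter_status=r.filter_status,
            )
        )
    return variants
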