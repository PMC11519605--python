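"""Combinatorial variant peptide database construction.

Missense variants on one protein are clustered into 30-residue windows
(single-linkage on sorted positions); every nonempty combination of
variants within a window is applied to the reference sequence — two
alternate alleles at the same residue are mutually exclusive and never
co-applied. Proteins carrying more variants than the combinability cap
fall back to Single-Each sequences (one variant per sequence), the
conventional treatment for hyperpolymorphic genes such as HLA and MUC.

The database is peptide-level: each variant sequence is digested in
silico and only tryptic peptides (<=2 missed cleavages) that cover a
variant position and pass length 7-50 / mass 500-5000 Da filters are
kept. Peptides identical to a reference tryptic peptide of the same
protein are excluded, duplicates collapse to a single record whose full
provenance is retained in a sidecar map, and reversed decoys are
appended for target-decoy FDR.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby, product
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from cysvarforge.missense import MissenseVariant
from cysvarforge.proteolysis import digest, monoisotopic_mass

DECOY_PREFIX = "rev_"


@dataclass
class ForgeConfig:
    """Database-construction thresholds."""

    window_size: int = 30  # residues; combination window
    max_combinable_variants: int = 25  # per protein; above -> Single-Each
    missed_cleavages: int = 2
    min_len: int = 7
    max_len: int = 50
    min_mass: float = 500.0  # Da
    max_mass: float = 5000.0  # Da
    proline_rule: bool = True

    def __post_init__(self):
        if not (0 < self.min_len < self.max_len and 0 < self.min_mass < self.max_mass):
            raise ValueError("length/mass ranges must be positive with min < max")


@dataclass
class WindowCluster:
    """Variants of one protein whose sorted positions chain within the window."""

    protein_accession: str
    variants: tuple[MissenseVariant, ...]  # sorted by residue_index

    @property
    def n(self) -> int:
        return len(self.variants)

    def same_site_groups(self) -> list[tuple[MissenseVariant, ...]]:
        """Variants grouped by residue index; members of a group are
        mutually exclusive alternate alleles of one site."""
        return [
            tuple(g)
            for _, g in groupby(self.variants, key=lambda v: v.residue_index)
        ]


@dataclass(frozen=True)
class VariantPeptideEntry:
    """One database peptide carrying at least one applied variant."""

    peptide_sequence: str
    protein_accession: str
    applied_variants: tuple[MissenseVariant, ...]
    start_index: int  # 1-based in the variant protein
    is_decoy: bool = False
    gene_id: str = ""
    transcript_id: str = ""

    @property
    def variant_string(self) -> str:
        return ";".join(
            f"{v.ref_aa}{v.residue_index}{v.alt_aa}" for v in self.applied_variants
        )

    @property
    def sources(self) -> str:
        return ";".join(sorted(set().union(*(v.sources for v in self.applied_variants))))


def group_windows(
    variants: list[MissenseVariant], window_size: int = 30
) -> list[WindowCluster]:
    """Single-linkage clustering of one protein's variants.

    Consecutive sorted variants at most ``window_size`` residues apart join
    one cluster; distinct alleles at the same residue always share a cluster.
    """
    if not variants:
        return []
    accessions = {v.protein_accession for v in variants}
    if len(accessions) != 1:
        raise ValueError(f"variants span multiple proteins: {sorted(accessions)}")
    ordered = sorted(variants, key=lambda v: (v.residue_index, v.alt_aa))
    clusters: list[list[MissenseVariant]] = [[ordered[0]]]
    for v in ordered[1:]:
        if v.residue_index - clusters[-1][-1].residue_index <= window_size:
            clusters[-1].append(v)
        else:
            clusters.append([v])
    accession = ordered[0].protein_accession
    return [
        WindowCluster(protein_accession=accession, variants=tuple(c))
        for c in clusters
    ]


def count_combinations(cluster: WindowCluster) -> int:
    """Number of nonempty valid subsets, computed arithmetically.

    With g_i alleles at each of k distinct sites the count is
    prod(g_i + 1) - 1; for n distinct-site variants this is 2^n - 1. The
    arithmetic form lets callers test the combinability cap without ever
    materializing the (potentially billion-scale) enumeration.
    """
    total = 1
    for group in cluster.same_site_groups():
        total *= len(group) + 1
    return total - 1


def enumerate_combinations(cluster: WindowCluster):
    """Yield every nonempty subset with at most one allele per site."""
    choices = [(None, *group) for group in cluster.same_site_groups()]
    for combo in product(*choices):
        subset = tuple(v for v in combo if v is not None)
        if subset:
            yield subset


def apply_variants(reference: str, subset: tuple[MissenseVariant, ...]) -> str:
    """Substitute each variant's alternate residue into the reference sequence."""
    seq = list(reference)
    for v in subset:
        if v.residue_index > len(reference):
            raise ValueError(
                f"{v.protein_accession}: residue {v.residue_index} beyond "
                f"sequence of length {len(reference)}"
            )
        if reference[v.residue_index - 1] != v.ref_aa:
            raise ValueError(
                f"{v.protein_accession} position {v.residue_index}: variant "
                f"expects {v.ref_aa}, sequence has "
                f"{reference[v.residue_index - 1]}"
            )
        seq[v.residue_index - 1] = v.alt_aa
    return "".join(seq)


def single_each_fallback(
    reference: str, variants: list[MissenseVariant]
) -> list[tuple[str, tuple[MissenseVariant, ...]]]:
    """One variant sequence per variant, for hyperpolymorphic proteins."""
    return [(apply_variants(reference, (v,)), (v,)) for v in variants]


def reference_peptide_set(reference: str, config: ForgeConfig) -> set[str]:
    """All reference tryptic peptide sequences under the forge settings."""
    return {
        p.sequence
        for p in digest(
            reference,
            max_missed=config.missed_cleavages,
            proline_rule=config.proline_rule,
        )
    }


def extract_variant_peptides(
    variant_sequence: str,
    subset: tuple[MissenseVariant, ...],
    config: ForgeConfig,
    reference_peptides: set[str],
    accession: str,
    gene_id: str = "",
    transcript_id: str = "",
) -> list[VariantPeptideEntry]:
    """Tryptic peptides of the variant sequence that cover a variant position.

    Applies the length and mass windows, then drops any peptide identical to
    a reference tryptic peptide of the same protein (those carry no variant
    evidence). ``applied_variants`` on each entry is the subset restricted to
    the peptide's span.
    """
    positions = {v.residue_index: v for v in subset}
    entries = []
    for pep in digest(
        variant_sequence,
        max_missed=config.missed_cleavages,
        proline_rule=config.proline_rule,
    ):
        covered = tuple(
            positions[i] for i in sorted(positions) if pep.start <= i <= pep.end
        )
        if not covered:
            continue
        if not config.min_len <= len(pep.sequence) <= config.max_len:
            continue
        if not config.min_mass <= monoisotopic_mass(pep.sequence) <= config.max_mass:
            continue
        if pep.sequence in reference_peptides:
            continue
        entries.append(
            VariantPeptideEntry(
                peptide_sequence=pep.sequence,
                protein_accession=accession,
                applied_variants=covered,
                start_index=pep.start,
                gene_id=gene_id,
                transcript_id=transcript_id,
            )
        )
    return entries


def forge_protein(
    accession: str,
    reference: str,
    variants: list[MissenseVariant],
    config: ForgeConfig | None = None,
    gene_id: str = "",
    transcript_id: str = "",
) -> list[VariantPeptideEntry]:
    """All variant peptide entries for one protein.

    Combinatorial path when the protein has at most
    ``max_combinable_variants`` variants; Single-Each fallback above the cap.
    """
    config = config or ForgeConfig()
    if not variants:
        return []
    ref_peps = reference_peptide_set(reference, config)
    entries: list[VariantPeptideEntry] = []
    if len(variants) <= config.max_combinable_variants:
        for cluster in group_windows(variants, config.window_size):
            for subset in enumerate_combinations(cluster):
                entries.extend(
                    extract_variant_peptides(
                        apply_variants(reference, subset),
                        subset,
                        config,
                        ref_peps,
                        accession,
                        gene_id,
                        transcript_id,
                    )
                )
    else:
        for seq, subset in single_each_fallback(reference, variants):
            entries.extend(
                extract_variant_peptides(
                    seq, subset, config, ref_peps, accession, gene_id, transcript_id
                )
            )
    return entries


def forge_database(
    proteome: dict[str, str],
    variants_by_protein: dict[str, list[MissenseVariant]],
    config: ForgeConfig | None = None,
    metadata: dict[str, tuple[str, str]] | None = None,
) -> list[VariantPeptideEntry]:
    """Forge entries for every protein; returns the raw (pre-dedup) list.

    ``metadata`` optionally maps accession -> (gene_id, transcript_id) for
    detailed headers.
    """
    config = config or ForgeConfig()
    entries = []
    for accession in sorted(variants_by_protein):
        if accession not in proteome:
            raise KeyError(f"variants reference unknown protein {accession!r}")
        gene_id, transcript_id = (metadata or {}).get(accession, ("", ""))
        entries.extend(
            forge_protein(
                accession,
                proteome[accession],
                variants_by_protein[accession],
                config,
                gene_id,
                transcript_id,
            )
        )
    return entries


def dedup_entries(
    entries: list[VariantPeptideEntry],
) -> tuple[list[VariantPeptideEntry], pd.DataFrame]:
    """Exact-sequence dedup with deterministic ordering.

    Entries are sorted by (accession, start, sequence); the first-seen entry
    provides the FASTA record, and the returned sidecar frame maps each
    peptide sequence to every (protein, variants, source) provenance tuple.
    """
    ordered = sorted(
        entries,
        key=lambda e: (e.protein_accession, e.start_index, e.peptide_sequence,
                       e.variant_string),
    )
    kept: dict[str, VariantPeptideEntry] = {}
    sidecar_rows = []
    seen_prov = set()
    for e in ordered:
        if e.peptide_sequence not in kept:
            kept[e.peptide_sequence] = e
        prov = (e.peptide_sequence, e.protein_accession, e.variant_string, e.sources)
        if prov not in seen_prov:
            seen_prov.add(prov)
            sidecar_rows.append(
                {
                    "peptide_sequence": e.peptide_sequence,
                    "protein_accession": e.protein_accession,
                    "variants": e.variant_string,
                    "sources": e.sources,
                    "start_index": e.start_index,
                }
            )
    unique = [kept[e.peptide_sequence] for e in ordered if kept[e.peptide_sequence] is e]
    sidecar = pd.DataFrame(
        sidecar_rows,
        columns=["peptide_sequence", "protein_accession", "variants", "sources",
                 "start_index"],
    )
    return unique, sidecar


def entry_header(entry: VariantPeptideEntry, mode: str, sample: str = "") -> str:
    """FASTA header: ``search`` mode is accession-only (engine-friendly),
    ``detailed`` mode carries full provenance."""
    if mode == "search":
        return entry.protein_accession
    parts = [
        entry.protein_accession,
        entry.gene_id or "-",
        entry.transcript_id or "-",
        entry.variant_string,
        sample or "-",
        entry.sources,
    ]
    return "|".join(parts)


def generate_decoys(
    records: list[tuple[str, str]],
) -> list[tuple[str, str]]:
    """Reversed-sequence decoys, one per target, with a ``rev_`` accession
    prefix (decoy of a decoy restores the original)."""
    decoys = []
    for header, seq in records:
        if header.startswith(DECOY_PREFIX):
            decoys.append((header[len(DECOY_PREFIX):], seq[::-1]))
        else:
            decoys.append((DECOY_PREFIX + header, seq[::-1]))
    return decoys


def dedup_and_write(
    entries: list[VariantPeptideEntry],
    fasta_path: str | Path,
    mode: str = "search",
    sidecar_path: str | Path | None = None,
    sample: str = "",
    with_decoys: bool = False,
) -> tuple[list[VariantPeptideEntry], pd.DataFrame]:
    """Write the deduplicated peptide FASTA (and provenance sidecar TSV)."""
    if mode not in ("search", "detailed"):
        raise ValueError("mode must be 'search' or 'detailed'")
    unique, sidecar = dedup_entries(entries)
    records = [
        SeqRecord(Seq(e.peptide_sequence), id=entry_header(e, mode, sample),
                  description="")
        for e in unique
    ]
    if with_decoys:
        pairs = [(e.protein_accession, e.peptide_sequence) for e in unique]
        records.extend(
            SeqRecord(Seq(seq), id=header, description="")
            for header, seq in generate_decoys(pairs)
        )
    SeqIO.write(records, str(fasta_path), "fasta")
    if sidecar_path is not None:
        sidecar.to_csv(sidecar_path, sep="\t", index=False)
    return unique, sidecar
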