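"""Map identified peptides to proteins and classify cysteine sites.

Peptides are located by exact substring match (I and L are distinct —
no tolerant alignment), mirroring residue-number assignment by aligning
the peptide to its parent sequence. A peptide matching more than one
protein is multi-mapped and contributes no unambiguous site; multi-maps
are reported separately. Because only SNVs are in scope, variant-protein
residue numbering equals reference numbering.

Site classes: *acquired* (variant introduces a cysteine), *lost*
(variant removes one), and *reference* cysteines, annotated as
variant-proximal when a missense variant lies within the linear window
(default 10 residues, inclusive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from cysvarforge.missense import MissenseVariant

log = logging.getLogger(__name__)

PROXIMITY_WINDOW = 10


class UnmappedPeptideError(ValueError):
    """An identified peptide has no exact match in the protein database."""


@dataclass
class CysSite:
    protein_accession: str
    residue_index: int  # 1-based
    site_class: str  # reference | acquired | lost
    proximal_variants: list[tuple[MissenseVariant, int]] = field(default_factory=list)
    labeling_state: str = "light"  # light | heavy | both

    @property
    def unique_id(self) -> str:
        """UniProt-style unique identifier: accession_position_labelingstate."""
        return f"{self.protein_accession}_{self.residue_index}_{self.labeling_state}"

    @property
    def site_key(self) -> str:
        """accession_position key (CysDB convention, labeling-agnostic)."""
        return f"{self.protein_accession}_{self.residue_index}"


def locate_peptide(
    peptide: str, proteome: dict[str, str]
) -> list[tuple[str, int]]:
    """All exact (accession, 1-based start) matches of a peptide.

    More than one match flags the peptide multi-mapped; zero matches is a
    data inconsistency and raises ``UnmappedPeptideError``.
    """
    if not peptide:
        raise ValueError("empty peptide")
    matches = []
    for accession in sorted(proteome):
        seq = proteome[accession]
        start = seq.find(peptide)
        while start != -1:
            matches.append((accession, start + 1))
            start = seq.find(peptide, start + 1)
    if not matches:
        raise UnmappedPeptideError(f"peptide {peptide!r} not found in database")
    return matches


def is_multi_mapped(matches: list[tuple[str, int]]) -> bool:
    return len({acc for acc, _ in matches}) > 1


def classify_cysteines(
    peptide: str,
    accession: str,
    start: int,
    variants: list[MissenseVariant],
    proximity_window: int = PROXIMITY_WINDOW,
) -> list[CysSite]:
    """Cysteine sites covered by one located peptide.

    A variant position with alt C inside the peptide is an acquired site;
    a variant with ref C is a lost site; every other cysteine in the
    peptide is a reference site, annotated with all variants within
    ``proximity_window`` residues (inclusive) and their linear distances.
    """
    end = start + len(peptide) - 1
    by_pos = {v.residue_index: v for v in variants}
    sites = []
    for i, residue in enumerate(peptide):
        index = start + i
        v = by_pos.get(index)
        if v is not None and v.alt_aa == "C":
            if residue != "C":
                raise ValueError(
                    f"acquired-cysteine site {accession}:{index} but peptide "
                    f"residue is {residue}"
                )
            sites.append(
                CysSite(accession, index, "acquired", proximal_variants=[(v, 0)])
            )
            continue
        if residue == "C":
            proximal = [
                (w, abs(w.residue_index - index))
                for w in sorted(variants, key=lambda w: w.residue_index)
                if abs(w.residue_index - index) <= proximity_window
                and w.residue_index != index
            ]
            sites.append(CysSite(accession, index, "reference", proximal))
    for v in variants:
        if v.ref_aa == "C" and start <= v.residue_index <= end:
            sites.append(
                CysSite(accession, v.residue_index, "lost", [(v, 0)])
            )
    return sites


def assign_labeling_state(channels: list[str]) -> str:
    """Union of observed channels across rows/replicates: heavy, light or both."""
    seen = set(channels)
    bad = seen - {"heavy", "light", "both"}
    if bad:
        raise ValueError(f"unknown labeling channels: {sorted(bad)}")
    if "both" in seen or {"heavy", "light"} <= seen:
        return "both"
    return seen.pop()


def match_external_keys(
    table: pd.DataFrame,
    external: pd.DataFrame,
    key: str | list[str],
) -> pd.DataFrame:
    """Left join onto an external annotation table by exact key.

    Duplicate external keys keep the first occurrence (logged); unmatched
    rows retain nulls, so ``annotation isna()`` marks novel entries.
    """
    keys = [key] if isinstance(key, str) else list(key)
    n_dup = external.duplicated(subset=keys).sum()
    if n_dup:
        log.warning("%d duplicate keys in external table; keeping first", n_dup)
        external = external.drop_duplicates(subset=keys, keep="first")
    return table.merge(external, on=keys, how="left")


def sites_table(
    peptide_hits: list[tuple[str, str]],
    proteome: dict[str, str],
    variants_by_protein: dict[str, list[MissenseVariant]],
    proximity_window: int = PROXIMITY_WINDOW,
    cys_only: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Site table for a set of identified peptides.

    ``peptide_hits`` is a list of (peptide, labeling_channel). Returns
    (sites, multimapped) frames; multi-mapped peptides contribute rows only
    to the second frame. ``cys_only`` drops non-cysteine peptides, the
    enrichment-mode behaviour; bulk (high-pH) mode retains them but they
    produce no cysteine sites either way.
    """
    site_channels: dict[tuple[str, int, str], list[str]] = {}
    site_objs: dict[tuple[str, int, str], CysSite] = {}
    multi_rows = []
    for peptide, channel in peptide_hits:
        if cys_only and "C" not in peptide:
            continue
        matches = locate_peptide(peptide, proteome)
        if is_multi_mapped(matches):
            multi_rows.append(
                {
                    "peptide": peptide,
                    "n_matches": len(matches),
                    "accessions": ";".join(sorted({a for a, _ in matches})),
                }
            )
            continue
        for accession, start in matches:
            variants = variants_by_protein.get(accession, [])
            for site in classify_cysteines(
                peptide, accession, start, variants, proximity_window
            ):
                k = (site.protein_accession, site.residue_index, site.site_class)
                site_objs.setdefault(k, site)
                site_channels.setdefault(k, []).append(channel)
    rows = []
    for k in sorted(site_objs):
        site = site_objs[k]
        site.labeling_state = assign_labeling_state(site_channels[k])
        rows.append(
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
    columns = [
        "unique_id", "site_key", "protein_accession", "residue_index",
        "site_class", "labeling_state", "proximal_variants", "n_proximal",
    ]
    sites = pd.DataFrame(rows, columns=columns)
    multi = pd.DataFrame(multi_rows, columns=["peptide", "n_matches", "accessions"])
    return sites, multi
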