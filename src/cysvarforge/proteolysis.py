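"""In-silico proteolysis, peptide masses and fragment ions.

Trypsin cleaves C-terminal to K/R; by default the bond is left intact when
the next residue is proline (the common convention — a strict mode cleaves
regardless). Digestion is fully tryptic and reports, for every peptide, its
1-based start position in the parent and the number of internal missed
cleavage sites, which downstream database forging needs to anchor variant
positions.

Masses are monoisotopic: residue masses from the standard table
(pyteomics), water 18.010565 Da, proton 1.007276 Da.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from pyteomics import mass as _pmass

WATER = 18.010565
PROTON = 1.007276

#: monoisotopic residue masses for the 20 standard amino acids
RESIDUE_MASS: dict[str, float] = {
    aa: _pmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"
}

# variable cysteine modifications used throughout the chemoproteomic workflow
CARBAMIDOMETHYL = 57.02146
BIOTIN_AZIDE_LIGHT = 463.2366
BIOTIN_AZIDE_HEAVY = 469.2742
MET_OXIDATION = 15.9949


@dataclass(frozen=True)
class Peptide:
    """One proteolytic peptide.

    ``start`` is the 1-based position of the peptide's first residue in the
    parent sequence; ``missed_cleavages`` counts internal uncut K/R sites;
    ``modifications`` is a list of ``(position_in_peptide_1based, shift_da)``.
    """

    sequence: str
    start: int
    missed_cleavages: int
    modifications: tuple[tuple[int, float], ...] = field(default_factory=tuple)

    @property
    def end(self) -> int:
        """1-based inclusive end position in the parent."""
        return self.start + len(self.sequence) - 1


def cleavage_sites(sequence: str, proline_rule: bool = True) -> list[int]:
    """0-based indices *after* which trypsin cuts (i.e. cut between i and i+1)."""
    sites = []
    for i, aa in enumerate(sequence[:-1]):
        if aa in "KR" and not (proline_rule and sequence[i + 1] == "P"):
            sites.append(i)
    return sites


def digest(
    sequence: str,
    max_missed: int = 2,
    proline_rule: bool = True,
    min_len: int = 1,
    max_len: int | None = None,
) -> list[Peptide]:
    """Fully tryptic digest with up to ``max_missed`` missed cleavages.

    Peptides are emitted in order of start position, then length. Raises
    ``ValueError`` on an empty sequence or non-standard residues.
    """
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    bad = set(sequence) - set(RESIDUE_MASS)
    if bad:
        raise ValueError(f"non-standard residues in sequence: {sorted(bad)}")
    # boundaries: 0, each cut point + 1, len(sequence)
    cuts = [i + 1 for i in cleavage_sites(sequence, proline_rule)]
    bounds = [0, *cuts, len(sequence)]
    peptides = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + max_missed, len(bounds))):
            seq = sequence[bounds[i] : bounds[j]]
            if len(seq) < min_len or (max_len is not None and len(seq) > max_len):
                continue
            peptides.append(
                Peptide(sequence=seq, start=bounds[i] + 1, missed_cleavages=j - i - 1)
            )
    return peptides


def monoisotopic_mass(
    sequence: str, modifications: tuple[tuple[int, float], ...] | None = None
) -> float:
    """Neutral monoisotopic peptide mass: residues + water + modification shifts."""
    try:
        m = sum(RESIDUE_MASS[aa] for aa in sequence) + WATER
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r}") from exc
    if modifications:
        m += sum(shift for _, shift in modifications)
    return m


def fragment_ions(
    sequence: str,
    modifications: tuple[tuple[int, float], ...] | None = None,
) -> dict[str, list[float]]:
    """Singly-charged b- and y-ion m/z series.

    Modification shifts are applied positionally, so a modified cysteine
    shifts every fragment that contains it. Returns ``{"b": [...], "y": [...]}``
    with ions b_1..b_{n-1} and y_1..y_{n-1}.
    """
    n = len(sequence)
    shifts = [0.0] * n
    for pos, shift in modifications or ():
        if not 1 <= pos <= n:
            raise ValueError(f"modification position {pos} outside peptide")
        shifts[pos - 1] += shift
    residue = [RESIDUE_MASS[aa] + s for aa, s in zip(sequence, shifts)]
    b, y = [], []
    running = 0.0
    for i in range(n - 1):
        running += residue[i]
        b.append(running + PROTON)
    running = WATER
    for i in range(n - 1, 0, -1):
        running += residue[i]
        y.append(running + PROTON)
    return {"b": b, "y": y}


def precursor_mz(
    sequence: str,
    charge: int,
    modifications: tuple[tuple[int, float], ...] | None = None,
) -> float:
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (monoisotopic_mass(sequence, modifications) + charge * PROTON) / charge
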