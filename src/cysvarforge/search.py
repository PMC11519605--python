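"""Two-stage class-specific FDR peptide identification.

Stage 1 searches spectra against the reference database; spectra whose
target match passes the FDR threshold are written to an excluded-scan
list (leading zeros stripped, one integer per line) and removed. Stage 2
searches the remainder against the variant peptide database, with
q-values computed only within stage-2 matches — class-specific FDR that
prevents variant peptides from stealing well-explained wild-type
spectra.

The scorer is a deliberately simple matched b/y-fragment counter with a
mean-ppm-error tie-break: enough to exercise the two-stage logic and FDR
machinery end to end at desk scale. Rescoring (PeptideProphet /
Percolator style) is not implemented; the raw score feeds the
target-decoy estimate directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from cysvarforge.dbforge import DECOY_PREFIX
from cysvarforge.proteolysis import PROTON, fragment_ions, monoisotopic_mass

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Spectrum:
    scan_id: str  # as read; may carry leading zeros
    precursor_mz: float
    charge: int
    mz: tuple[float, ...]

    @property
    def neutral_mass(self) -> float:
        return self.precursor_mz * self.charge - self.charge * PROTON


@dataclass(frozen=True)
class PSM:
    scan_id: str
    peptide: str
    charge: int
    score: float
    is_decoy: bool
    stage: int
    protein_accessions: tuple[str, ...] = ()
    n_matched: int = 0
    mean_ppm_error: float = float("nan")
    modifications: tuple[tuple[int, float], ...] = ()


@dataclass
class SearchDatabase:
    """Indexed peptide database: (accession, sequence, decoy flag) records
    with precomputed neutral masses and fragment ladders."""

    peptides: list[tuple[str, str, bool]]  # (accession, sequence, is_decoy)
    _masses: np.ndarray = field(init=False, repr=False)
    _order: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        masses = np.array(
            [monoisotopic_mass(seq) for _, seq, _ in self.peptides], dtype=float
        )
        self._order = np.argsort(masses, kind="stable")
        self._masses = masses[self._order]

    def __len__(self) -> int:
        return len(self.peptides)

    @property
    def n_targets(self) -> int:
        return sum(not d for _, _, d in self.peptides)

    def candidates(self, neutral_mass: float, tol_ppm: float):
        lo = neutral_mass * (1 - tol_ppm * 1e-6)
        hi = neutral_mass * (1 + tol_ppm * 1e-6)
        i = int(np.searchsorted(self._masses, lo, side="left"))
        j = int(np.searchsorted(self._masses, hi, side="right"))
        for k in self._order[i:j]:
            yield self.peptides[k]

    @classmethod
    def from_records(cls, records: list[tuple[str, str]]) -> "SearchDatabase":
        return cls(
            peptides=[
                (header, seq, header.startswith(DECOY_PREFIX))
                for header, seq in records
            ]
        )

    @classmethod
    def from_fasta(cls, path: str | Path) -> "SearchDatabase":
        from Bio import SeqIO

        return cls.from_records(
            [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
        )


def read_mgf(path: str | Path) -> list[Spectrum]:
    spectra = []
    with _mgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            scan = str(params.get("scans", params.get("title", "")))
            charge = int(params["charge"][0])
            spectra.append(
                Spectrum(
                    scan_id=scan,
                    precursor_mz=float(params["pepmass"][0]),
                    charge=charge,
                    mz=tuple(float(x) for x in entry["m/z array"]),
                )
            )
    return spectra


def _match_fragments(
    peaks: np.ndarray, theoretical: list[float], tol_ppm: float
) -> tuple[int, float]:
    """Count theoretical ions with a peak within tol_ppm; return the count
    and the mean absolute ppm error of the matched ions."""
    n = 0
    errs = []
    for mz in theoretical:
        tol = mz * tol_ppm * 1e-6
        i = np.searchsorted(peaks, mz)
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(peaks):
                d = abs(peaks[j] - mz)
                if d <= tol and (best is None or d < best):
                    best = d
        if best is not None:
            n += 1
            errs.append(best / mz * 1e6)
    return n, (float(np.mean(errs)) if errs else float("nan"))


def score_candidate(
    spectrum: Spectrum, sequence: str, tol_ppm: float
) -> tuple[float, int, float]:
    """Matched-fragment score with continuous ppm tie-break.

    The score is ``n_matched - 0.5 * mean_ppm_error / tol_ppm``: a one-ion
    difference always dominates, while among equal counts the candidate
    with smaller mean error ranks first.
    """
    ions = fragment_ions(sequence)
    peaks = np.asarray(spectrum.mz)
    n, err = _match_fragments(peaks, ions["b"] + ions["y"], tol_ppm)
    score = float(n) - (0.5 * err / tol_ppm if n else 0.5)
    return score, n, err


def toy_search(
    spectra: list[Spectrum],
    database: SearchDatabase,
    precursor_tol_ppm: float = 20.0,
    fragment_tol_ppm: float = 20.0,
    stage: int = 1,
) -> list[PSM]:
    """Best target and best decoy match per spectrum."""
    psms = []
    for spectrum in spectra:
        if not spectrum.mz:
            continue
        best: dict[bool, tuple[float, int, float, str, str]] = {}
        for accession, seq, is_decoy in database.candidates(
            spectrum.neutral_mass, precursor_tol_ppm
        ):
            score, n, err = score_candidate(spectrum, seq, fragment_tol_ppm)
            cur = best.get(is_decoy)
            if cur is None or score > cur[0]:
                best[is_decoy] = (score, n, err, seq, accession)
        for is_decoy, (score, n, err, seq, accession) in sorted(best.items()):
            psms.append(
                PSM(
                    scan_id=spectrum.scan_id,
                    peptide=seq,
                    charge=spectrum.charge,
                    score=score,
                    is_decoy=is_decoy,
                    stage=stage,
                    protein_accessions=(accession,),
                    n_matched=n,
                    mean_ppm_error=err,
                )
            )
    return psms


def tda_qvalues(psms: list[PSM], conservative: bool = False) -> list[float]:
    """Target-decoy q-values, aligned with the input PSM list.

    At each score threshold s, FDR(s) = #decoys>=s / max(1, #targets>=s)
    (``conservative`` uses (#decoys+1) in the numerator); q-values are the
    monotonized running minimum, clipped to [0, 1]. With no decoys present
    all q-values are 0 and a warning is logged.
    """
    if not psms:
        return []
    if not any(p.is_decoy for p in psms):
        log.warning("no decoy PSMs: all q-values set to 0")
        return [0.0] * len(psms)
    scores = np.array([p.score for p in psms])
    decoy = np.array([p.is_decoy for p in psms])
    order = np.argsort(-scores, kind="stable")
    d_cum = np.cumsum(decoy[order])
    t_cum = np.cumsum(~decoy[order])
    num = d_cum + (1 if conservative else 0)
    fdr = num / np.maximum(t_cum, 1)
    # ties share the worst (largest-index) raw FDR of their score group
    sorted_scores = scores[order]
    for i in range(len(fdr) - 2, -1, -1):
        if sorted_scores[i] == sorted_scores[i + 1]:
            fdr[i] = fdr[i + 1]
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(len(psms))
    q[order] = q_sorted
    return q.tolist()


def normalize_scan(scan_id: str) -> str:
    """Strip leading zeros: '00012' -> '12' (integer scan identity)."""
    return str(int(scan_id))


def excluded_scan_list(
    psms: list[PSM],
    qvalues: list[float],
    q_threshold: float = 0.01,
    path: str | Path | None = None,
) -> list[str]:
    """Scan numbers of target PSMs passing the FDR threshold.

    Leading zeros are stripped, duplicates collapsed, and the list is
    sorted numerically; when ``path`` is given it is written one integer
    per line (the excluded_scan_list file consumed by stage 2).
    """
    scans = {
        int(normalize_scan(p.scan_id))
        for p, q in zip(psms, qvalues)
        if not p.is_decoy and q <= q_threshold
    }
    lines = [str(s) for s in sorted(scans)]
    if path is not None:
        Path(path).write_text("".join(line + "\n" for line in lines))
    return lines


def peptide_level(psms: list[PSM]) -> tuple[list[PSM], list[float]]:
    """Best PSM per peptide sequence, with q-values recomputed over that set."""
    best: dict[str, PSM] = {}
    for p in psms:
        cur = best.get(p.peptide)
        if cur is None or p.score > cur.score:
            best[p.peptide] = p
    reps = sorted(best.values(), key=lambda p: (-p.score, p.peptide))
    return reps, tda_qvalues(reps)


def protein_level(psms: list[PSM]) -> tuple[list[PSM], list[float]]:
    """Best peptide PSM per accession (razor: first accession
    alphabetically on multi-mapped peptides), q-values recomputed."""
    peptides, _ = peptide_level(psms)
    best: dict[str, PSM] = {}
    for p in peptides:
        accession = sorted(p.protein_accessions)[0]
        cur = best.get(accession)
        if cur is None or p.score > cur.score:
            best[accession] = p
    reps = sorted(best.values(), key=lambda p: (-p.score, p.peptide))
    return reps, tda_qvalues(reps)


@dataclass
class TwoStageResult:
    stage1_psms: list[PSM]
    stage1_q: list[float]
    excluded_scans: list[str]
    stage2_psms: list[PSM]
    stage2_q: list[float]

    def accepted(self, stage: int, q_threshold: float = 0.01) -> list[PSM]:
        psms, qs = (
            (self.stage1_psms, self.stage1_q)
            if stage == 1
            else (self.stage2_psms, self.stage2_q)
        )
        return [p for p, q in zip(psms, qs) if not p.is_decoy and q <= q_threshold]


def run_two_stage(
    spectra: list[Spectrum],
    reference_db: SearchDatabase,
    variant_db: SearchDatabase,
    fdr: float = 0.01,
    precursor_tol_ppm: float = 20.0,
    fragment_tol_ppm: float = 20.0,
    conservative: bool = False,
) -> TwoStageResult:
    """Stage-1 reference search, exclusion of confident scans, stage-2
    variant search of the remainder with its own (class-specific) FDR."""
    ref_targets = {a for a, _, d in reference_db.peptides if not d}
    var_targets = {a for a, _, d in variant_db.peptides if not d}
    overlap = ref_targets & var_targets
    if overlap:
        log.warning(
            "%d accessions shared between reference and variant databases",
            len(overlap),
        )
    stage1 = toy_search(
        spectra, reference_db, precursor_tol_ppm, fragment_tol_ppm, stage=1
    )
    q1 = tda_qvalues(stage1, conservative)
    excluded = excluded_scan_list(stage1, q1, fdr)
    excluded_set = set(excluded)
    remaining = [
        s for s in spectra if normalize_scan(s.scan_id) not in excluded_set
    ]
    stage2 = toy_search(
        remaining, variant_db, precursor_tol_ppm, fragment_tol_ppm, stage=2
    )
    q2 = tda_qvalues(stage2, conservative)
    return TwoStageResult(
        stage1_psms=stage1,
        stage1_q=q1,
        excluded_scans=excluded,
        stage2_psms=stage2,
        stage2_q=q2,
    )


def psms_to_frame(psms: list[PSM], qvalues: list[float] | None = None) -> pd.DataFrame:
    rows = []
    for i, p in enumerate(psms):
        rows.append(
            {
                "scan_id": p.scan_id,
                "peptide": p.peptide,
                "charge": p.charge,
                "score": p.score,
                "is_decoy": p.is_decoy,
                "stage": p.stage,
                "proteins": ";".join(p.protein_accessions),
                "n_matched": p.n_matched,
                "mean_ppm_error": p.mean_ppm_error,
                "q_value": qvalues[i] if qvalues is not None else float("nan"),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "scan_id", "peptide", "charge", "score", "is_decoy", "stage",
            "proteins", "n_matched", "mean_ppm_error", "q_value",
        ],
    )
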