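"""Variant stratification statistics.

Distribution comparisons (Mann-Whitney U, two-sample Kolmogorov-
Smirnov) for CADD-score stratification, linear-sequence and spatial
(alpha-carbon) functional-site proximity, and the pooled two-sample
test of proportions. p-values are reported raw, to machine precision;
a Benjamini-Hochberg utility is provided but not applied by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _ss
from statsmodels.distributions.empirical_distribution import ECDF

log = logging.getLogger(__name__)

SPATIAL_RADIUS = 10.0  # Angstrom
LINEAR_WINDOW = 10  # residues

EXACT_MWU_MAX_N = 8


@dataclass
class ComparisonResult:
    test: str
    statistic: float
    pvalue: float
    ecdf_x: ECDF
    ecdf_y: ECDF


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return len(np.unique(pooled)) < len(pooled)


def compare_distributions(
    x, y, test: str = "mannwhitney"
) -> ComparisonResult:
    """Two-sided MWU or KS comparison with ECDFs.

    MWU uses exact enumeration for small tie-free samples
    (n1 + n2 <= 8) and the tie-corrected normal approximation otherwise;
    KS is the two-sample D with asymptotic p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    if test == "mannwhitney":
        small = x.size + y.size <= EXACT_MWU_MAX_N and not _has_ties(x, y)
        res = _ss.mannwhitneyu(
            x, y, alternative="two-sided", method="exact" if small else "asymptotic"
        )
    elif test == "ks":
        res = _ss.ks_2samp(x, y, alternative="two-sided", method="asymp")
    else:
        raise ValueError(f"unknown test {test!r}")
    return ComparisonResult(
        test=test,
        statistic=float(res.statistic),
        pvalue=float(min(res.pvalue, 1.0)),
        ecdf_x=ECDF(x),
        ecdf_y=ECDF(y),
    )


def ecdf_table(result: ComparisonResult) -> pd.DataFrame:
    """Step-function coordinates of both ECDFs, ready to write/plot."""
    rows = []
    for label, ecdf in (("x", result.ecdf_x), ("y", result.ecdf_y)):
        for xv, p in zip(ecdf.x[1:], ecdf.y[1:]):  # drop the -inf anchor
            rows.append({"sample": label, "value": float(xv), "ecdf": float(p)})
    return pd.DataFrame(rows, columns=["sample", "value", "ecdf"])


def linear_proximity(
    variants: pd.DataFrame,
    sites: pd.DataFrame,
    window: int = LINEAR_WINDOW,
) -> pd.DataFrame:
    """Flag variants 'in or near' annotated sites in linear sequence.

    Both frames need columns protein_accession and residue_index; a
    variant is flagged iff its minimum |index difference| to any site on
    the same protein is <= window (inclusive boundary). The minimum
    distance is recorded (NaN when the protein has no annotated site).
    """
    out = variants.copy()
    by_protein = {
        acc: np.sort(grp["residue_index"].to_numpy())
        for acc, grp in sites.groupby("protein_accession")
    }
    distances = []
    for r in out.itertuples():
        positions = by_protein.get(r.protein_accession)
        if positions is None or positions.size == 0:
            distances.append(float("nan"))
        else:
            distances.append(float(np.min(np.abs(positions - r.residue_index))))
    out["site_distance"] = distances
    out["near_site"] = pd.Series(distances).le(window).to_numpy()
    return out


def load_ca_coordinates(pdb_path: str | Path) -> dict[tuple[str, int], np.ndarray]:
    """Alpha-carbon coordinates per (chain, residue number) from ATOM records."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("model", str(pdb_path))
    coords: dict[tuple[str, int], np.ndarray] = {}
    for model in structure:
        for chain in model:
            for residue in chain:
                hetflag, resseq, _ = residue.id
                if hetflag.strip():
                    continue
                if "CA" in residue:
                    coords[(chain.id, resseq)] = residue["CA"].coord.astype(float)
                else:
                    log.warning(
                        "residue %s:%d lacks a CA atom; skipped", chain.id, resseq
                    )
        break  # first model only
    return coords


def spatial_proximity(
    coordinates: dict[tuple[str, int], np.ndarray],
    focal: tuple[str, int],
    radius: float = SPATIAL_RADIUS,
) -> list[tuple[str, int, float]]:
    """Residues whose CA lies within ``radius`` Å of the focal CA.

    Includes the focal residue itself (distance 0); raises ``KeyError``
    when the focal residue has no CA coordinate.
    """
    if focal not in coordinates:
        raise KeyError(f"focal residue {focal} has no CA coordinate")
    center = coordinates[focal]
    neighbors = []
    for key in sorted(coordinates):
        d = float(np.linalg.norm(coordinates[key] - center))
        if d <= radius:
            neighbors.append((key[0], key[1], d))
    return neighbors


def proportions_test(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled two-sample z-test of proportions, two-sided.

    z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)) with the pooled p. A
    degenerate pooled proportion of exactly 0 or 1 yields (0, 1) by
    convention (logged).
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        log.warning("degenerate pooled proportion %.0f: returning z=0, p=1", pooled)
        return 0.0, 1.0
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (k1 / n1 - k2 / n2) / se
    p = 2 * _ss.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH-adjusted q-values (utility; not applied by default)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.clip(q_sorted, 0, 1)
    return q
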