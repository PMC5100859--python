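"""Correspondence analysis of the genomes x codons RSCU matrix.

CA is the chi-square-distance ordination classically used to summarize
codon-usage variation among genomes: the first axis typically separates
G/C-ending from A/T-ending codons when compositional (GC3) pressure
dominates.  The implementation is the standard SVD of the matrix of
standardized residuals; principal coordinates are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codon_metrics import RSCUVector
from .genetic_code import FAMILIES, INFORMATIVE_CODONS, MULTI_FAMILIES

logger = logging.getLogger(__name__)


@dataclass
class CAResult:
    row_coords: pd.DataFrame  # genomes x axes, principal coordinates
    col_coords: pd.DataFrame  # codons x axes, principal coordinates
    singular_values: np.ndarray
    total_inertia: float
    inertia_fractions: np.ndarray


def build_rscu_matrix(vectors: list[RSCUVector]) -> pd.DataFrame:
    """Assemble the genomes x 59-codon RSCU matrix for CA.

    Rows follow input order.  A family a genome never uses (rare at genome
    scale) leaves missing RSCU entries; these are imputed with the
    no-preference value 1.0 and logged.
    """
    if len(vectors) < 2:
        raise ValueError("correspondence analysis needs at least 2 genomes")
    rows = []
    for vec in vectors:
        row = {}
        for codon in INFORMATIVE_CODONS:
            row[codon] = vec.rscu.get(codon, np.nan)
        if vec.missing_families:
            logger.warning(
                "genome %s: families with zero usage imputed as RSCU=1.0: %s",
                vec.unit_id, sorted(vec.missing_families),
            )
        rows.append(row)
    mat = pd.DataFrame(rows, index=[v.unit_id for v in vectors],
                       columns=list(INFORMATIVE_CODONS))
    return mat.fillna(1.0)


def correspondence_analysis(matrix: pd.DataFrame, n_axes: int = 2) -> CAResult:
    """Run CA on a nonnegative matrix; returns principal coordinates.

    The axis sign is fixed by orienting each axis so the column (codon) with
    the largest |coordinate| is positive, making results deterministic under
    SVD sign ambiguity.  An all-equal (rank-1) matrix has zero inertia and
    zero coordinates.
    """
    X = np.asarray(matrix, dtype=float)
    if (X < 0).any():
        raise ValueError("matrix must be nonnegative")
    grand = X.sum()
    if grand <= 0:
        raise ValueError("matrix grand total must be positive")
    P = X / grand
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    if (r == 0).any() or (c == 0).any():
        raise ValueError("zero row or column margins")
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, s, Vt = np.linalg.svd(S, full_matrices=False)
    # drop numerically-zero axes (centering removes the trivial dimension)
    keep = s > max(s[0], 1.0) * 1e-12 if s.size else np.array([], bool)
    if keep.any():
        U, s, Vt = U[:, keep], s[keep], Vt[keep, :]
        total_inertia = float((s ** 2).sum())
    else:
        # all-equal (rank-1) matrix: zero inertia, zero coordinates
        total_inertia = 0.0
        s = np.zeros(min(n_axes, s.size))
        U = np.zeros((X.shape[0], s.size))
        Vt = np.zeros((s.size, X.shape[1]))
    k = min(n_axes, s.size)
    U, s, Vt = U[:, :k], s[:k], Vt[:k, :]
    row = (U * s) / np.sqrt(r)[:, None]
    col = (Vt.T * s) / np.sqrt(c)[:, None]
    for a in range(k):
        j = int(np.argmax(np.abs(col[:, a])))
        if col[j, a] < 0:
            col[:, a] *= -1
            row[:, a] *= -1
    axes = [f"axis{i + 1}" for i in range(k)]
    fractions = (s ** 2) / total_inertia if total_inertia > 0 else np.zeros(k)
    return CAResult(
        row_coords=pd.DataFrame(row, index=matrix.index, columns=axes),
        col_coords=pd.DataFrame(col, index=matrix.columns, columns=axes),
        singular_values=s,
        total_inertia=total_inertia,
        inertia_fractions=fractions,
    )


def gc_ending(codon: str) -> int:
    """1 if the codon ends in G or C, else 0."""
    return int(codon[2] in "GC")


def axis_report(
    result: CAResult, genome_classes: dict[str, str] | None = None
) -> pd.DataFrame:
    """Per-axis summary: inertia fraction and correlation of codon
    coordinates with the G/C-ending indicator; genome rows labeled by
    thermal class when provided.

    With zero inertia every correlation is undefined (NaN).  Unknown genome
    labels in ``genome_classes`` raise ``ValueError``.
    """
    if genome_classes is not None:
        unknown = set(genome_classes) - set(result.row_coords.index)
        if unknown:
            raise ValueError(f"unknown genome labels: {sorted(unknown)}")
    indicator = np.array([gc_ending(c) for c in result.col_coords.index], dtype=float)
    rows = []
    for i, axis in enumerate(result.col_coords.columns):
        coords = result.col_coords[axis].to_numpy()
        if result.total_inertia == 0 or np.std(coords) == 0 or np.std(indicator) == 0:
            corr = np.nan
        else:
            corr = float(np.corrcoef(coords, indicator)[0, 1])
        rows.append({
            "axis": axis,
            "inertia_fraction": float(result.inertia_fractions[i]),
            "gc_ending_correlation": corr,
        })
    return pd.DataFrame(rows)


def genome_class_table(
    result: CAResult, genome_classes: dict[str, str] | None = None
) -> pd.DataFrame:
    """Row (genome) coordinates with an optional thermal-class column."""
    out = result.row_coords.copy()
    if genome_classes is not None:
        unknown = set(genome_classes) - set(out.index)
        if unknown:
            raise ValueError(f"unknown genome labels: {sorted(unknown)}")
        out["class"] = [genome_classes.get(g, "") for g in out.index]
    return out.reset_index(names="genome")
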