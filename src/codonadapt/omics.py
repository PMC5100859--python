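"""Transcript/protein differential-expression filtering and correlation.

Differentially expressed genes (DEGs) are called on transcript P values
(P <= 0.001 by default); differentially expressed proteins (DEPs) on iTRAQ
fold changes, symmetrically in direction (max(FC, 1/FC) > 1.5), after an
eligibility gate of FDR < 0.01 and >= 2 unique peptides.  Correlations are
Spearman, so the log transform applied to fold changes before reporting is
cosmetic for the statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .optimal_codons import spearman

TRANSCRIPT_COLUMNS = {"gene", "fpkm_reference", "fold_change", "p_value"}
PROTEIN_COLUMNS = {"gene", "fold_change", "unique_peptides", "fdr"}


def _require(df: pd.DataFrame, cols: set[str], what: str) -> None:
    missing = cols - set(df.columns)
    if missing:
        raise ValueError(f"{what} table missing columns: {sorted(missing)}")


def filter_deg(
    transcripts: pd.DataFrame, p_cutoff: float = 0.001
) -> tuple[pd.DataFrame, int, int]:
    """DEG subset plus up/down counts: DEG iff P <= cutoff (inclusive).

    Direction is fold change vs 1.  Records with missing P values are
    skipped with a warning.
    """
    _require(transcripts, {"gene", "fold_change", "p_value"}, "transcript")
    df = transcripts.copy()
    na = df["p_value"].isna()
    if na.any():
        import warnings

        warnings.warn(f"{int(na.sum())} transcript records lack a P value; skipped",
                      stacklevel=2)
        df = df[~na]
    deg = df[df["p_value"] <= p_cutoff].copy()
    deg["direction"] = np.where(deg["fold_change"] > 1, "up",
                                np.where(deg["fold_change"] < 1, "down", "flat"))
    return deg, int((deg["direction"] == "up").sum()), int((deg["direction"] == "down").sum())


def filter_dep(
    proteins: pd.DataFrame,
    fc_cutoff: float = 1.5,
    min_unique_peptides: int = 2,
    fdr_cutoff: float = 0.01,
) -> pd.DataFrame:
    """DEP subset: eligible iff FDR < cutoff and unique peptides >= minimum;
    DEP iff max(FC, 1/FC) strictly exceeds the fold-change cutoff.

    Non-positive fold changes raise ``ValueError`` (ratios must be > 0).
    """
    _require(proteins, PROTEIN_COLUMNS, "protein")
    df = proteins.copy()
    if (df["fold_change"] <= 0).any():
        bad = df.loc[df["fold_change"] <= 0, "gene"].tolist()
        raise ValueError(f"non-positive protein fold changes for: {bad}")
    eligible = df[(df["fdr"] < fdr_cutoff) & (df["unique_peptides"] >= min_unique_peptides)]
    sym = np.maximum(eligible["fold_change"], 1.0 / eligible["fold_change"])
    dep = eligible[sym > fc_cutoff].copy()
    dep["direction"] = np.where(dep["fold_change"] > 1, "up", "down")
    return dep


def match_tables(
    transcripts: pd.DataFrame, proteins: pd.DataFrame
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Inner-join transcript and protein tables on gene id.

    Returns the matched frame plus the unmatched gene lists from each side
    (reported, never silently dropped).
    """
    merged = transcripts.merge(proteins, on="gene", suffixes=("_t", "_p"))
    matched = set(merged["gene"])
    unmatched_t = sorted(set(transcripts["gene"]) - matched)
    unmatched_p = sorted(set(proteins["gene"]) - matched)
    return merged, unmatched_t, unmatched_p


def level_vs_change_correlation(
    transcripts: pd.DataFrame, proteins: pd.DataFrame
) -> dict:
    """Spearman correlation of reference-condition transcript level (FPKM)
    with protein fold change over matched genes."""
    _require(transcripts, {"gene", "fpkm_reference"}, "transcript")
    _require(proteins, {"gene", "fold_change"}, "protein")
    merged, _, _ = match_tables(
        transcripts[["gene", "fpkm_reference"]], proteins[["gene", "fold_change"]]
    )
    n = len(merged)
    if n < 3:
        return {"scope": "global", "rho": float("nan"), "p_value": float("nan"),
                "n": n, "flag": "too few matched genes"}
    rho, p = spearman(merged["fpkm_reference"].to_numpy(),
                      merged["fold_change"].to_numpy())
    return {"scope": "global", "rho": rho, "p_value": p, "n": n, "flag": ""}


def pathway_correlations(
    transcripts: pd.DataFrame,
    proteins: pd.DataFrame,
    pathways: pd.DataFrame,
    min_n: int = 3,
) -> pd.DataFrame:
    """Per-pathway Spearman correlation between log transcript and log
    protein fold changes, plus a global record.

    ``pathways`` maps pathway_id -> gene_id (one row per membership; genes
    may appear in several pathways).  Pathways with fewer than ``min_n``
    matched genes are reported with NaN correlation and their n.
    """
    _require(transcripts, {"gene", "fold_change"}, "transcript")
    _require(proteins, {"gene", "fold_change"}, "protein")
    _require(pathways, {"pathway_id", "gene_id"}, "pathway")
    merged, _, _ = match_tables(
        transcripts[["gene", "fold_change"]], proteins[["gene", "fold_change"]]
    )
    merged["log_t"] = np.log2(merged["fold_change_t"])
    merged["log_p"] = np.log2(merged["fold_change_p"])
    rows = []

    def record(scope: str, sub: pd.DataFrame) -> dict:
        n = len(sub)
        if n < min_n:
            return {"scope": scope, "rho": float("nan"), "p_value": float("nan"), "n": n}
        rho, p = spearman(sub["log_t"].to_numpy(), sub["log_p"].to_numpy())
        return {"scope": scope, "rho": rho, "p_value": p, "n": n}

    rows.append(record("global", merged))
    for pid, members in pathways.groupby("pathway_id")["gene_id"]:
        sub = merged[merged["gene"].isin(set(members))]
        rows.append(record(str(pid), sub))
    return pd.DataFrame(rows)
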