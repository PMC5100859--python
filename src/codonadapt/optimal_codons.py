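"""Optimal-codon identification from codon-usage vs Nc correlations.

A codon is "optimal" for its synonymous family when its within-family
relative frequency rises as gene-level codon bias strengthens, i.e. shows
the strongest significantly *negative* Spearman correlation with Nc (or
Nc'), at a family-wise Bonferroni threshold of alpha/n where n is the
family size.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import inf

import numpy as np
import pandas as pd
from scipy import stats

from .codon_metrics import CodonCounts
from .genetic_code import CODON_TO_AA, FAMILIES, MULTI_FAMILIES


@dataclass
class OptimalCodon:
    amino_acid: str
    family_size: int
    codon: str | None
    rho: float | None
    p_value: float | None
    threshold: float


def per_gene_codon_frequencies(
    counts: CodonCounts, min_family_count: int = 1
) -> dict[str, float]:
    """Within-family relative codon frequencies for one gene.

    Families whose total usage falls below ``min_family_count`` contribute
    missing values (NaN) for all their codons; raw counts are never used
    downstream because they confound gene length.
    """
    freqs: dict[str, float] = {}
    for aa in MULTI_FAMILIES:
        fam = FAMILIES[aa]
        x = counts.family_counts(aa)
        t = x.sum()
        if t < max(min_family_count, 1):
            for codon in fam:
                freqs[codon] = np.nan
        else:
            for codon, xi in zip(fam, x):
                freqs[codon] = xi / t
    return freqs


def frequency_table(
    per_gene_counts: list[CodonCounts], min_family_count: int = 1
) -> pd.DataFrame:
    """Genes x codons table of within-family frequencies (NaN = family absent)."""
    rows = {c.unit_id: per_gene_codon_frequencies(c, min_family_count)
            for c in per_gene_counts}
    return pd.DataFrame.from_dict(rows, orient="index")


def spearman(
    x: np.ndarray, y: np.ndarray, method: str = "approx"
) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided P value.

    Ties get average ranks; rho is the Pearson correlation of the ranks.
    ``method="approx"`` uses the t approximation with n-2 degrees of
    freedom; ``method="exact"`` enumerates all permutations (n <= 7 only)
    and reports the fraction with |rho| at least as extreme.  Constant
    inputs return ``(nan, nan)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    n = x.size
    if n < 3:
        return float("nan"), float("nan")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if method == "exact":
        if n > 7:
            raise ValueError("exact permutation P limited to n <= 7")
        count = 0
        total = 0
        for perm in permutations(ry):
            r = np.corrcoef(rx, np.asarray(perm))[0, 1]
            count += abs(r) >= abs(rho) - 1e-12
            total += 1
        return rho, count / total
    if method != "approx":
        raise ValueError(f"unknown method {method!r}")
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(p)


def codon_correlations(
    freq: pd.DataFrame, bias: pd.Series, method: str = "approx"
) -> pd.DataFrame:
    """Per-codon Spearman correlation between within-family frequency and bias.

    ``freq`` is the genes x codons frequency table; ``bias`` is per-gene Nc
    or Nc' indexed by gene.  Genes missing either value drop out pairwise.
    """
    bias = bias.dropna()
    common = freq.index.intersection(bias.index)
    freq = freq.loc[common]
    bias = bias.loc[common]
    rows = []
    for codon in freq.columns:
        f = freq[codon].to_numpy(dtype=float)
        b = bias.to_numpy(dtype=float)
        mask = ~np.isnan(f)
        n = int(mask.sum())
        rho, p = spearman(f[mask], b[mask], method=method) if n >= 3 else (np.nan, np.nan)
        rows.append({
            "codon": codon, "amino_acid": CODON_TO_AA[codon],
            "family_size": len(FAMILIES[CODON_TO_AA[codon]]),
            "rho": rho, "p_value": p, "n_genes": n,
        })
    return pd.DataFrame(rows)


def identify_optimal_codons(
    freq: pd.DataFrame,
    bias: pd.Series,
    alpha: float = 0.05,
    method: str = "approx",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call at most one optimal codon per family.

    Eligibility: rho < 0 and P <= alpha / family size.  Within a family the
    most negative rho wins; ties break by smaller P, then lexicographic
    codon order.  Returns ``(correlation table, optimal-codon table)``.
    """
    if len(freq) < 10:
        import warnings

        warnings.warn("fewer than 10 genes: optimal-codon calls are unreliable",
                      stacklevel=2)
    corr = codon_correlations(freq, bias, method=method)
    calls = []
    for aa in MULTI_FAMILIES:
        fam = corr[corr["amino_acid"] == aa]
        k = len(FAMILIES[aa])
        threshold = alpha / k
        eligible = fam[(fam["rho"] < 0) & (fam["p_value"] <= threshold)].dropna(
            subset=["rho", "p_value"]
        )
        if eligible.empty:
            calls.append(OptimalCodon(aa, k, None, None, None, threshold))
            continue
        best = eligible.sort_values(
            by=["rho", "p_value", "codon"], ascending=[True, True, True]
        ).iloc[0]
        calls.append(OptimalCodon(aa, k, best["codon"], float(best["rho"]),
                                  float(best["p_value"]), threshold))
    optimal = pd.DataFrame(
        [{"amino_acid": c.amino_acid, "family_size": c.family_size,
          "optimal_codon": c.codon if c.codon else "none",
          "rho": c.rho, "p_value": c.p_value, "threshold": c.threshold}
         for c in calls]
    )
    return corr, optimal
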