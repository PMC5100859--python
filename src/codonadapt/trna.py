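"""tRNA anticodon decoding and optimal-codon / copy-number concordance.

Only exact Watson-Crick cognates are counted (no wobble expansion): the
cognate codon of an anticodon is its reverse complement read back into DNA.
Concordance asks whether, within each synonymous family, the optimal codon
is served by the largest tRNA gene copy number.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .genetic_code import CODON_TO_AA, CODONS, normalize_aa

_RNA_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass
class ConcordanceRow:
    amino_acid: str
    optimal_codon: str
    optimal_copies: int
    family_max_copies: int
    concordant: bool


def anticodon_to_codon(anticodon: str) -> str:
    """Watson-Crick cognate codon (DNA) of an RNA anticodon triplet.

    The anticodon pairs antiparallel with the codon, so the codon is the
    reverse complement; e.g. anticodon UCC decodes codon GGA (Gly).
    """
    ac = anticodon.strip().upper().replace("T", "U")
    if len(ac) != 3 or any(b not in _RNA_COMPLEMENT for b in ac):
        raise ValueError(f"invalid anticodon {anticodon!r}")
    codon_rna = "".join(_RNA_COMPLEMENT[b] for b in reversed(ac))
    return codon_rna.replace("U", "T")


def read_inventory(path) -> pd.DataFrame:
    """Read a tRNA inventory TSV with columns amino_acid, anticodon, copies."""
    df = pd.read_csv(path, sep="\t")
    required = {"amino_acid", "anticodon", "copies"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"tRNA inventory missing columns: {sorted(missing)}")
    return df


def codon_copy_numbers(inventory: pd.DataFrame) -> tuple[dict[str, int], pd.DataFrame]:
    """Map each codon to its cognate tRNA gene copy number.

    Copies of identical anticodons are summed; codons with no cognate tRNA
    get 0.  Records whose stated amino acid disagrees with the decoded
    codon's amino acid are excluded and returned as the flagged table.
    """
    copies = {c: 0 for c in CODONS}
    flagged_rows = []
    for _, rec in inventory.iterrows():
        codon = anticodon_to_codon(str(rec["anticodon"]))
        decoded_aa = CODON_TO_AA[codon]
        try:
            stated = normalize_aa(str(rec["amino_acid"]))
        except ValueError:
            stated = None
        if stated != decoded_aa:
            flagged_rows.append({**rec.to_dict(), "decoded_codon": codon,
                                 "decoded_aa": decoded_aa})
            continue
        copies[codon] += int(rec["copies"])
    return copies, pd.DataFrame(flagged_rows)


def concordance(
    optimal: pd.DataFrame, inventory: pd.DataFrame
) -> tuple[pd.DataFrame, float]:
    """Per-family concordance between optimal codons and tRNA copy numbers.

    A family is concordant when its optimal codon's cognate copy count
    equals the family maximum (ties count as concordant).  Families without
    an optimal codon are skipped.  Returns the per-family report and the
    fraction concordant.
    """
    from .genetic_code import FAMILIES

    copies, _ = codon_copy_numbers(inventory)
    rows = []
    for _, rec in optimal.iterrows():
        codon = rec["optimal_codon"]
        if not isinstance(codon, str) or codon == "none":
            continue
        aa = rec["amino_acid"]
        fam_copies = {c: copies[c] for c in FAMILIES[aa]}
        fam_max = max(fam_copies.values())
        rows.append(ConcordanceRow(
            amino_acid=aa, optimal_codon=codon,
            optimal_copies=fam_copies[codon],
            family_max_copies=fam_max,
            concordant=fam_copies[codon] == fam_max,
        ))
    report = pd.DataFrame(
        [{"amino_acid": r.amino_acid, "optimal_codon": r.optimal_codon,
          "optimal_copies": r.optimal_copies,
          "family_max_copies": r.family_max_copies,
          "concordant": r.concordant} for r in rows]
    )
    fraction = float(report["concordant"].mean()) if len(report) else float("nan")
    return report, fraction
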