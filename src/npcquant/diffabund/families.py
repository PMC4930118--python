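"""Translation-machinery family classification from gene symbols.

Pattern rules cover the canonical families — eukaryotic initiation
factors (EIF*), elongation factors (EEF*) and cytosolic ribosomal
proteins (RPL*/RPS*, including RPLP* and RPSA) — plus an explicit
override list for symbols conventionally grouped with these families in
published tables despite falling outside the patterns.  The overrides
record table membership, not a claim of biological correctness.
"""

from __future__ import annotations

INITIATION = "initiation_factor"
ELONGATION = "elongation_factor"
RIBOSOMAL = "ribosomal"
OTHER = "other"

FAMILY_LABELS = (INITIATION, ELONGATION, RIBOSOMAL, OTHER)

#: Symbols forced into a family irrespective of the pattern rules.
OVERRIDES: dict[str, str] = {
    "RPN": RIBOSOMAL,
    "RPN2": RIBOSOMAL,
    "RPA3": RIBOSOMAL,
    "PRPS1": RIBOSOMAL,
    "ELAV": INITIATION,
}


def classify_family(gene_symbol: str) -> str:
    """Map a gene symbol to its translation-machinery family (or 'other')."""
    if not gene_symbol:
        raise ValueError("empty gene symbol")
    symbol = gene_symbol.strip().upper()
    if symbol in OVERRIDES:
        return OVERRIDES[symbol]
    if symbol.startswith("EIF"):
        return INITIATION
    if symbol.startswith("EEF"):
        return ELONGATION
    if symbol.startswith(("RPL", "RPS")):
        return RIBOSOMAL
    return OTHER


def is_translation_machinery(gene_symbol: str) -> bool:
    return classify_family(gene_symbol) != OTHER
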