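"""Canonical amino-acid alphabet shared across the package."""

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def is_valid_sequence(seq: str) -> bool:
    """True if *seq* is non-empty and uses only canonical residues."""
    return bool(seq) and all(c in AA_INDEX for c in seq)
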