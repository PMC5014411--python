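"""Independent brute-force oracles used to freeze expected values.

These deliberately avoid the package's own code paths: digestion is done
by enumerating cleavage points positionally, fragment masses by summing
over explicit substrings, and combination counting by a per-individual
scan over a plain genotype matrix.
"""

from __future__ import annotations

from gvpid.masses import PROTON, WATER, peptide_neutral_mass


def oracle_digest(sequence: str, max_missed: int) -> set[tuple[str, int, int]]:
    """All tryptic peptides as (sequence, start, end) with 1-based
    inclusive spans: cut after K/R except before P, union of at most
    max_missed + 1 adjacent fragments."""
    cuts = [0]
    for i, aa in enumerate(sequence[:-1]):
        if aa in "KR" and sequence[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(len(sequence))
    out = set()
    for a in range(len(cuts) - 1):
        for b in range(a + 1, min(a + 2 + max_missed, len(cuts))):
            lo, hi = cuts[a], cuts[b]
            out.add((sequence[lo:hi], lo + 1, hi))
    return out


def oracle_b_ion(peptide: str, i: int) -> float:
    """Singly charged b_i via the neutral-mass routine on the prefix."""
    return peptide_neutral_mass(peptide[:i]) - WATER + PROTON


def oracle_y_ion(peptide: str, i: int) -> float:
    """Singly charged y_i via the neutral-mass routine on the suffix."""
    return peptide_neutral_mass(peptide[len(peptide) - i :]) + PROTON


def oracle_count(
    genotypes: dict[str, dict[str, tuple[str, str] | None]],
    combination: list[tuple[str, str]],
) -> tuple[int, int]:
    """(x, n) by scanning a plain {individual: {rs: allele pair or None}}
    matrix: n = complete cases at the combination's loci, x = those whose
    pairs contain every requested allele."""
    loci = sorted({rs for rs, _ in combination})
    x = n = 0
    for _, calls in sorted(genotypes.items()):
        pairs = {rs: calls.get(rs) for rs in loci}
        if any(p is None for p in pairs.values()):
            continue
        n += 1
        if all(nuc in pairs[rs] for rs, nuc in combination):
            x += 1
    return x, n
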