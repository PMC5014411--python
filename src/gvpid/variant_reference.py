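"""Variant protein reference construction and GVP catalog enumeration.

Builds the search database (reference proteins plus one variant copy per
protein carrying every common single-amino-acid polymorphism), digests
sequences in silico with trypsin, and enumerates the allele-specific
tryptic peptides (GVPs) with uniqueness and chemical-confusability
annotations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ProteinRecord",
    "SnpRecord",
    "GvpCatalogEntry",
    "Peptide",
    "CANONICAL_RESIDUES",
    "DEFAULT_CONFUSABLE_PAIRS",
    "VARIANT_SUFFIX",
    "build_variant_database",
    "digest",
    "enumerate_gvps",
    "uniqueness_screen",
    "confusable_sap_screen",
]

#: The 20 canonical amino-acid one-letter codes.
CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Ambiguity / non-standard codes rejected by default.
NONCANONICAL_RESIDUES = frozenset("BJOUXZ")

#: Substitutions indistinguishable from common chemical modification:
#: Met->Phe (oxidation-related), Asn->Asp (deamidation), Gln->Glu
#: (deamidation), Cys->Ser (alkylation artifacts).
DEFAULT_CONFUSABLE_PAIRS = frozenset(
    {("M", "F"), ("N", "D"), ("Q", "E"), ("C", "S")}
)

#: Accession suffix of the variant copy in the search database.
VARIANT_SUFFIX = "|var"


class VariantReferenceError(ValueError):
    """Raised on inconsistencies between SNP annotations and the proteome."""


def _validate_sequence(sequence: str, *, allow_noncanonical: bool = False) -> str:
    if not sequence:
        raise VariantReferenceError("protein sequence must be non-empty")
    seq = sequence.upper()
    bad = set(seq) - CANONICAL_RESIDUES
    if bad and not allow_noncanonical:
        raise VariantReferenceError(
            f"non-canonical residues {sorted(bad)} in sequence "
            "(set allow_noncanonical=True to accept)"
        )
    if bad - NONCANONICAL_RESIDUES - CANONICAL_RESIDUES:
        raise VariantReferenceError(f"unknown residue codes {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its accession and gene symbol."""

    accession: str
    gene: str
    sequence: str
    allow_noncanonical: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "sequence",
            _validate_sequence(self.sequence, allow_noncanonical=self.allow_noncanonical),
        )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SnpRecord:
    """A non-synonymous SNP annotated at protein coordinates.

    ``protein_position`` is 1-based. ``pop_counts`` maps population id to
    ``(x, n)`` carrier counts; ``allele_freq`` maps population id to the
    alternative-allele frequency in [0, 1].
    """

    rs_id: str
    gene: str
    protein_accession: str
    protein_position: int
    ref_aa: str
    alt_aa: str
    ref_nuc: str
    alt_nuc: str
    pop_counts: Mapping[str, tuple[int, int]] = field(default_factory=dict)
    allele_freq: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.protein_position < 1:
            raise VariantReferenceError(
                f"{self.rs_id}: protein_position must be >= 1"
            )
        for name in ("ref_aa", "alt_aa"):
            aa = getattr(self, name)
            if len(aa) != 1 or aa not in CANONICAL_RESIDUES:
                raise VariantReferenceError(f"{self.rs_id}: bad {name} {aa!r}")
        if self.ref_aa == self.alt_aa:
            raise VariantReferenceError(f"{self.rs_id}: ref_aa equals alt_aa")
        for pop, f in self.allele_freq.items():
            if not 0.0 <= f <= 1.0:
                raise VariantReferenceError(
                    f"{self.rs_id}: frequency {f} for {pop} outside [0, 1]"
                )

    def check_against(self, protein: ProteinRecord) -> None:
        """Validate position and reference residue against the protein."""
        if self.protein_position > len(protein):
            raise VariantReferenceError(
                f"{self.rs_id}: position {self.protein_position} beyond end of "
                f"{protein.accession} (length {len(protein)})"
            )
        found = protein.sequence[self.protein_position - 1]
        if found != self.ref_aa:
            raise VariantReferenceError(
                f"{self.rs_id}: reference residue mismatch at "
                f"{protein.accession}:{self.protein_position} "
                f"(annotation {self.ref_aa}, sequence {found})"
            )


@dataclass(frozen=True)
class Peptide:
    """A tryptic peptide with its 1-based inclusive span."""

    sequence: str
    start: int
    end: int
    missed_cleavages: int

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("span inconsistent with sequence length")


@dataclass(frozen=True)
class GvpCatalogEntry:
    """One allele-specific tryptic peptide tied to its gene and loci.

    ``alleles`` lists ``(rs_id, nucleotide, amino_acid)`` for every SNP
    position covered by the peptide span; ``allele_class`` is "variant" if
    any covered allele is the alternative one, else "reference".
    """

    peptide: str
    gene: str
    protein_accession: str
    rs_ids: tuple[str, ...]
    alleles: tuple[tuple[str, str, str], ...]
    start: int
    end: int
    allele_class: str
    missed_cleavages: int
    unique: bool = True
    matched_genes: tuple[str, ...] = ()
    confusable: bool = False
    confusable_pair: tuple[str, str] | None = None

    @property
    def key(self) -> tuple:
        return (self.gene, self.peptide, self.start, self.end, self.alleles)

    def allele_set(self) -> frozenset[tuple[str, str]]:
        """The (rs_id, nucleotide) pairs this peptide imputes."""
        return frozenset((rs, nuc) for rs, nuc, _ in self.alleles)


# ---------------------------------------------------------------------------
# Digestion


def cleavage_sites(sequence: str) -> list[int]:
    """0-based positions i such that trypsin cleaves between i and i+1.

    Cleavage C-terminal to K or R, suppressed when the next residue is P.
    """
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def digest(sequence: str, max_missed: int = 2) -> list[Peptide]:
    """In-silico tryptic digestion with up to ``max_missed`` missed cleavages.

    Returns peptides with 1-based inclusive spans, ordered by start then
    length. The zero-missed-cleavage peptides partition the sequence.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    seq = _validate_sequence(sequence)
    sites = cleavage_sites(seq)
    # fragment boundaries as 0-based half-open [b, e)
    bounds = [0] + [s + 1 for s in sites] + [len(seq)]
    fragments = list(zip(bounds[:-1], bounds[1:]))
    peptides: list[Peptide] = []
    for i in range(len(fragments)):
        for m in range(max_missed + 1):
            j = i + m
            if j >= len(fragments):
                break
            b, e = fragments[i][0], fragments[j][1]
            peptides.append(
                Peptide(sequence=seq[b:e], start=b + 1, end=e, missed_cleavages=m)
            )
    peptides.sort(key=lambda p: (p.start, len(p.sequence)))
    return peptides


# ---------------------------------------------------------------------------
# Variant database


def _snps_by_protein(
    proteome: Sequence[ProteinRecord], snps: Iterable[SnpRecord]
) -> dict[str, list[SnpRecord]]:
    by_acc = {p.accession: p for p in proteome}
    grouped: dict[str, list[SnpRecord]] = {}
    for snp in snps:
        protein = by_acc.get(snp.protein_accession)
        if protein is None:
            raise VariantReferenceError(
                f"{snp.rs_id}: unknown protein accession {snp.protein_accession}"
            )
        snp.check_against(protein)
        grouped.setdefault(snp.protein_accession, []).append(snp)
    for acc, group in grouped.items():
        seen: dict[int, str] = {}
        for snp in group:
            other = seen.get(snp.protein_position)
            if other is not None:
                raise VariantReferenceError(
                    f"co-positional SAPs {other} and {snp.rs_id} on {acc} "
                    f"at position {snp.protein_position}"
                )
            seen[snp.protein_position] = snp.rs_id
    return grouped


def snp_passes_frequency(snp: SnpRecord, freq_threshold: float) -> bool:
    """Keep a SAP if its allele frequency reaches the threshold in any
    population (exclude-if-below-everywhere)."""
    if not snp.allele_freq:
        return False
    return any(f >= freq_threshold for f in snp.allele_freq.values())


def substitute(sequence: str, substitutions: Mapping[int, str]) -> str:
    """Apply {1-based position: residue} substitutions to a sequence."""
    chars = list(sequence)
    for pos, aa in substitutions.items():
        chars[pos - 1] = aa
    return "".join(chars)


def build_variant_database(
    proteome: Sequence[ProteinRecord],
    snps: Iterable[SnpRecord],
    freq_threshold: float = 0.004,
) -> list[ProteinRecord]:
    """Reference proteome plus one variant copy per protein with >= 1
    passing SAP, carrying all passing SAPs simultaneously.

    The variant copy's accession is the reference accession plus "|var".
    """
    if not 0.0 <= freq_threshold <= 1.0:
        raise ValueError("freq_threshold must be in [0, 1]")
    grouped = _snps_by_protein(proteome, snps)
    out = list(proteome)
    for protein in proteome:
        passing = [
            s
            for s in grouped.get(protein.accession, [])
            if snp_passes_frequency(s, freq_threshold)
        ]
        if not passing:
            continue
        variant_seq = substitute(
            protein.sequence, {s.protein_position: s.alt_aa for s in passing}
        )
        out.append(
            ProteinRecord(
                accession=protein.accession + VARIANT_SUFFIX,
                gene=protein.gene,
                sequence=variant_seq,
            )
        )
    return out


# ---------------------------------------------------------------------------
# GVP enumeration


def _covering_peptides(
    sequence: str, positions: set[int], max_missed: int
) -> list[Peptide]:
    return [
        p for p in digest(sequence, max_missed) if any(p.start <= q <= p.end for q in positions)
    ]


def _cluster_snps(
    protein: ProteinRecord, group: list[SnpRecord], max_missed: int
) -> list[list[SnpRecord]]:
    """Partition a protein's SNPs into clusters that can share a tryptic
    peptide under some allele background.

    Runs to a fixed point: whenever a peptide covering one cluster's SNP
    also spans another SNP's position (under any allele combination of the
    current cluster), the clusters are merged.
    """
    parent = list(range(len(group)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    pos_to_idx = {s.protein_position: i for i, s in enumerate(group)}
    changed = True
    while changed:
        changed = False
        clusters: dict[int, list[int]] = {}
        for i in range(len(group)):
            clusters.setdefault(find(i), []).append(i)
        for members in clusters.values():
            cluster_snps = [group[i] for i in members]
            if len(cluster_snps) > 12:
                raise VariantReferenceError(
                    f"{protein.accession}: SAP cluster of size "
                    f"{len(cluster_snps)} exceeds enumeration limit"
                )
            positions = {s.protein_position for s in cluster_snps}
            for combo in itertools.product(
                *(((s.ref_aa, s.alt_aa)) for s in cluster_snps)
            ):
                seq = substitute(
                    protein.sequence,
                    {s.protein_position: aa for s, aa in zip(cluster_snps, combo)},
                )
                for pep in _covering_peptides(seq, positions, max_missed):
                    for pos, idx in pos_to_idx.items():
                        if pep.start <= pos <= pep.end and find(idx) != find(members[0]):
                            union(idx, members[0])
                            changed = True
    clusters = {}
    for i in range(len(group)):
        clusters.setdefault(find(i), []).append(i)
    return [[group[i] for i in members] for members in clusters.values()]


def enumerate_gvps(
    proteome: Sequence[ProteinRecord],
    snps: Iterable[SnpRecord],
    max_missed: int = 2,
    exclusion_pairs: frozenset[tuple[str, str]] = DEFAULT_CONFUSABLE_PAIRS,
) -> list[GvpCatalogEntry]:
    """Enumerate allele-specific tryptic peptides covering each SNP.

    Digestion runs on the allele-substituted sequence, so SAPs that create
    or destroy K/R cleavage sites produce different peptide sets per
    allele. SNPs close enough to share a peptide are enumerated jointly
    over all allele combinations; each emitted entry annotates every SNP
    position inside its span.
    """
    grouped = _snps_by_protein(proteome, snps)
    entries: dict[tuple, GvpCatalogEntry] = {}
    for protein in proteome:
        group = grouped.get(protein.accession, [])
        if not group:
            continue
        for cluster in _cluster_snps(protein, group, max_missed):
            positions = {s.protein_position: s for s in cluster}
            for combo in itertools.product(
                *(((s.ref_aa, s.alt_aa)) for s in cluster)
            ):
                chosen = {s.rs_id: aa for s, aa in zip(cluster, combo)}
                seq = substitute(
                    protein.sequence,
                    {s.protein_position: aa for s, aa in zip(cluster, combo)},
                )
                for pep in _covering_peptides(seq, set(positions), max_missed):
                    covered = [
                        s
                        for pos, s in sorted(positions.items())
                        if pep.start <= pos <= pep.end
                    ]
                    alleles = tuple(
                        (
                            s.rs_id,
                            s.alt_nuc if chosen[s.rs_id] == s.alt_aa else s.ref_nuc,
                            chosen[s.rs_id],
                        )
                        for s in covered
                    )
                    allele_class = (
                        "variant"
                        if any(chosen[s.rs_id] == s.alt_aa for s in covered)
                        else "reference"
                    )
                    confusable_pair = next(
                        (
                            (s.ref_aa, s.alt_aa)
                            for s in covered
                            if confusable_sap_screen(s.ref_aa, s.alt_aa, exclusion_pairs)
                        ),
                        None,
                    )
                    entry = GvpCatalogEntry(
                        peptide=pep.sequence,
                        gene=protein.gene,
                        protein_accession=protein.accession,
                        rs_ids=tuple(s.rs_id for s in covered),
                        alleles=alleles,
                        start=pep.start,
                        end=pep.end,
                        allele_class=allele_class,
                        missed_cleavages=pep.missed_cleavages,
                        confusable=confusable_pair is not None,
                        confusable_pair=confusable_pair,
                    )
                    entries.setdefault(entry.key, entry)
    return sorted(
        entries.values(), key=lambda e: (e.gene, e.start, e.end, e.alleles)
    )


# ---------------------------------------------------------------------------
# Screens


def uniqueness_screen(
    peptide: str, search_space: Sequence[ProteinRecord]
) -> tuple[bool, list[str]]:
    """True iff the peptide maps to at most one gene's products.

    Exact substring matching, I/L distinct. A gene's reference sequence
    and its own variant copy count as a single gene. A peptide absent
    from the whole space is unique with an empty gene list.
    """
    genes = sorted({p.gene for p in search_space if peptide in p.sequence})
    return len(genes) <= 1, genes


def annotate_catalog(
    catalog: Sequence[GvpCatalogEntry], search_space: Sequence[ProteinRecord]
) -> list[GvpCatalogEntry]:
    """Fill the ``unique``/``matched_genes`` fields against a search space."""
    from dataclasses import replace

    cache: dict[str, tuple[bool, list[str]]] = {}
    out = []
    for entry in catalog:
        if entry.peptide not in cache:
            cache[entry.peptide] = uniqueness_screen(entry.peptide, search_space)
        unique, genes = cache[entry.peptide]
        out.append(replace(entry, unique=unique, matched_genes=tuple(genes)))
    return out


def confusable_sap_screen(
    ref_aa: str,
    alt_aa: str,
    exclusion_pairs: frozenset[tuple[str, str]] = DEFAULT_CONFUSABLE_PAIRS,
) -> bool:
    """True (exclude) iff the ordered substitution is chemically confusable."""
    for aa in (ref_aa, alt_aa):
        if len(aa) != 1 or aa not in CANONICAL_RESIDUES:
            raise VariantReferenceError(f"non-canonical residue {aa!r}")
    return (ref_aa, alt_aa) in exclusion_pairs
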