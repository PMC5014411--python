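"""Readers and writers for the pipeline's external formats.

PSM tables, genotype panels (VCF or individual-by-locus TSV), truth
genotypes, the SNP annotation table, FASTA proteomes, the GVP catalog,
and deterministic JSON results. All text writes are byte-deterministic
for fixed inputs.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .variant_reference import GvpCatalogEntry, ProteinRecord, SnpRecord

logger = logging.getLogger(__name__)

__all__ = [
    "PsmRecord",
    "GenotypeCall",
    "PopulationPanel",
    "FormatError",
    "read_psm_table",
    "write_psm_table",
    "read_genotype_panel",
    "read_truth_genotypes",
    "write_truth_genotypes",
    "read_proteome_fasta",
    "write_proteome_fasta",
    "read_snp_table",
    "write_snp_table",
    "read_catalog",
    "write_catalog",
    "write_json",
]

ENGINES = {"xtandem", "mascot"}


class FormatError(ValueError):
    """Raised on malformed input files."""


@dataclass(frozen=True)
class PsmRecord:
    """One peptide-spectrum match row.

    ``score`` is log10(e) for X!Tandem and a linear expectation value for
    Mascot; no conversion between the two is ever applied.
    """

    subject_id: str
    sample_id: str
    peptide: str
    engine: str
    score: float
    observed_mass: float
    theoretical_mass: float
    modifications: tuple[tuple[int, float, str], ...] = ()
    fragment_mzs: tuple[float, ...] | None = None
    protein_accessions: tuple[str, ...] = ()
    decoy_rule: str | None = None  # hidden audit column; pipeline ignores it

    def __post_init__(self) -> None:
        if self.engine not in ENGINES:
            raise FormatError(f"unknown engine {self.engine!r}")
        if self.observed_mass <= 0 or self.theoretical_mass <= 0:
            raise FormatError("masses must be positive")
        for pos, _, name in self.modifications:
            if not 1 <= pos <= len(self.peptide):
                raise FormatError(
                    f"modification {name} position {pos} outside peptide"
                )


@dataclass(frozen=True)
class GenotypeCall:
    """A diploid genotype call; ``alleles`` is an unordered nucleotide pair
    (stored sorted) or None when missing/failed."""

    individual_id: str
    rs_id: str
    alleles: tuple[str, str] | None
    missing: bool = False

    def __post_init__(self) -> None:
        if self.alleles is None and not self.missing:
            raise FormatError("non-missing call requires alleles")
        if self.alleles is not None:
            object.__setattr__(self, "alleles", tuple(sorted(self.alleles)))

    def carries(self, nucleotide: str) -> bool:
        return self.alleles is not None and nucleotide in self.alleles


@dataclass
class PopulationPanel:
    """Per-individual diploid genotypes at catalogued loci for one
    population. ``calls[individual][rs_id]`` holds the GenotypeCall."""

    population_id: str
    calls: dict[str, dict[str, GenotypeCall]] = field(default_factory=dict)
    loci: tuple[str, ...] = ()
    uncounted_loci: tuple[str, ...] = ()

    @property
    def individuals(self) -> list[str]:
        return sorted(self.calls)

    def genotype(self, individual: str, rs_id: str) -> GenotypeCall | None:
        return self.calls.get(individual, {}).get(rs_id)


# ---------------------------------------------------------------------------
# PSM tables

_PSM_REQUIRED = ["subject", "sample", "peptide", "engine", "score", "obs_mass", "theo_mass"]
_PSM_OPTIONAL = ["mods", "fragments", "proteins", "decoy_rule"]


def _parse_mods(text: str) -> tuple[tuple[int, float, str], ...]:
    if not text:
        return ()
    out = []
    for item in text.split(";"):
        pos, delta, name = item.split(":")
        out.append((int(pos), float(delta), name))
    return tuple(out)


def _format_mods(mods: Sequence[tuple[int, float, str]]) -> str:
    return ";".join(f"{p}:{d!r}:{n}" for p, d, n in mods)


def read_psm_table(path: str | Path, *, permissive: bool = False) -> list[PsmRecord]:
    """Read a PSM TSV. Under ``permissive`` mode malformed rows are logged
    with their line number and skipped; otherwise they raise FormatError."""
    path = Path(path)
    records: list[PsmRecord] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in _PSM_REQUIRED if c not in header]
        if missing:
            raise FormatError(f"{path}: missing required columns {missing}")
        for lineno, row in enumerate(reader, start=2):
            try:
                fragments = row.get("fragments") or ""
                records.append(
                    PsmRecord(
                        subject_id=row["subject"],
                        sample_id=row["sample"],
                        peptide=row["peptide"],
                        engine=row["engine"],
                        score=float(row["score"]),
                        observed_mass=float(row["obs_mass"]),
                        theoretical_mass=float(row["theo_mass"]),
                        modifications=_parse_mods(row.get("mods") or ""),
                        fragment_mzs=tuple(float(x) for x in fragments.split(","))
                        if fragments
                        else None,
                        protein_accessions=tuple(
                            p for p in (row.get("proteins") or "").split(",") if p
                        ),
                        decoy_rule=(row.get("decoy_rule") or None),
                    )
                )
            except (ValueError, KeyError) as exc:
                if not permissive:
                    raise FormatError(f"{path}:{lineno}: {exc}") from exc
                logger.warning("%s:%d: skipping malformed row (%s)", path, lineno, exc)
    return records


def write_psm_table(records: Iterable[PsmRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_PSM_REQUIRED + _PSM_OPTIONAL)
        for r in records:
            writer.writerow(
                [
                    r.subject_id,
                    r.sample_id,
                    r.peptide,
                    r.engine,
                    repr(r.score),
                    repr(r.observed_mass),
                    repr(r.theoretical_mass),
                    _format_mods(r.modifications),
                    ",".join(repr(m) for m in r.fragment_mzs)
                    if r.fragment_mzs is not None
                    else "",
                    ",".join(r.protein_accessions),
                    r.decoy_rule or "",
                ]
            )


# ---------------------------------------------------------------------------
# Genotype panels

_MISSING_TOKENS = {"", ".", "./.", ".|.", "NA", "FAILED", "failed"}


def _parse_genotype(
    individual: str, rs_id: str, text: str, valid: set[str] | None
) -> GenotypeCall:
    text = text.strip()
    if text in _MISSING_TOKENS:
        return GenotypeCall(individual, rs_id, None, missing=True)
    sep = "|" if "|" in text else "/"
    parts = text.split(sep)
    if len(parts) != 2:
        raise FormatError(f"{individual}/{rs_id}: non-diploid genotype {text!r}")
    if valid is not None:
        bad = set(parts) - valid
        if bad:
            raise FormatError(
                f"{individual}/{rs_id}: alleles {sorted(bad)} not in {sorted(valid)}"
            )
    return GenotypeCall(individual, rs_id, (parts[0], parts[1]))


def _read_panel_tsv(
    path: Path, loci: Sequence[SnpRecord], population_id: str
) -> PopulationPanel:
    by_rs = {s.rs_id: s for s in loci}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        if not header or header[0] != "individual":
            raise FormatError(f"{path}: first column must be 'individual'")
        present = [rs for rs in header[1:] if rs in by_rs]
        calls: dict[str, dict[str, GenotypeCall]] = {}
        for row in reader:
            ind = row["individual"]
            calls[ind] = {}
            for rs in present:
                snp = by_rs[rs]
                calls[ind][rs] = _parse_genotype(
                    ind, rs, row[rs], {snp.ref_nuc, snp.alt_nuc}
                )
    uncounted = tuple(sorted(set(by_rs) - set(present)))
    for rs in uncounted:
        logger.warning("%s: locus %s absent from panel; marked uncounted", path, rs)
    return PopulationPanel(
        population_id=population_id,
        calls=calls,
        loci=tuple(sorted(present)),
        uncounted_loci=uncounted,
    )


def _read_panel_vcf(
    path: Path, loci: Sequence[SnpRecord], population_id: str
) -> PopulationPanel:
    from cyvcf2 import VCF

    by_rs = {s.rs_id: s for s in loci}
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    calls: dict[str, dict[str, GenotypeCall]] = {s: {} for s in samples}
    seen: set[str] = set()
    for variant in vcf:
        rs = variant.ID
        if rs is None or rs not in by_rs:
            continue
        if rs in seen:
            raise FormatError(f"{path}: duplicated locus ID {rs}")
        seen.add(rs)
        alleles = [variant.REF] + list(variant.ALT)
        for sample, gt in zip(samples, variant.genotypes):
            # cyvcf2 genotype rows are [allele_idx..., phased]; diploid -> 3
            idx = gt[:-1]
            if len(idx) != 2:
                raise FormatError(
                    f"{path}: non-diploid genotype for {sample} at {rs}"
                )
            if idx[0] < 0 or idx[1] < 0:
                calls[sample][rs] = GenotypeCall(sample, rs, None, missing=True)
            else:
                calls[sample][rs] = GenotypeCall(
                    sample, rs, (alleles[idx[0]], alleles[idx[1]])
                )
    uncounted = tuple(sorted(set(by_rs) - seen))
    for rs in uncounted:
        logger.warning("%s: locus %s absent from VCF; marked uncounted", path, rs)
    return PopulationPanel(
        population_id=population_id,
        calls=calls,
        loci=tuple(sorted(seen)),
        uncounted_loci=uncounted,
    )


def read_genotype_panel(
    path: str | Path, loci: Sequence[SnpRecord], population_id: str = "panel"
) -> PopulationPanel:
    """Read a population genotype panel from VCF or individual-by-locus TSV.

    Loci are matched by rs ID, never by position. Phase is ignored.
    """
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
    if first.startswith("##fileformat=VCF"):
        return _read_panel_vcf(path, loci, population_id)
    return _read_panel_tsv(path, loci, population_id)


# ---------------------------------------------------------------------------
# Truth genotypes


def read_truth_genotypes(path: str | Path) -> list[GenotypeCall]:
    """Read Sanger truth genotypes: TSV columns subject, rs_id, genotype.

    "FAILED", "." and "./." all mark a call as missing (excluded from
    confusion counting downstream).
    """
    path = Path(path)
    calls: list[GenotypeCall] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for col in ("subject", "rs_id", "genotype"):
            if col not in header:
                raise FormatError(f"{path}: missing column {col!r}")
        for row in reader:
            calls.append(
                _parse_genotype(row["subject"], row["rs_id"], row["genotype"], None)
            )
    return calls


def write_truth_genotypes(calls: Iterable[GenotypeCall], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["subject", "rs_id", "genotype"])
        for c in calls:
            gt = "FAILED" if c.alleles is None else "/".join(c.alleles)
            writer.writerow([c.individual_id, c.rs_id, gt])


# ---------------------------------------------------------------------------
# Proteome FASTA


def read_proteome_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read proteins from FASTA with headers ">accession GN=gene"."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        gene = rec.id
        for token in rec.description.split():
            if token.startswith("GN="):
                gene = token[3:]
        records.append(ProteinRecord(accession=rec.id, gene=gene, sequence=str(rec.seq)))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def write_proteome_fasta(proteins: Iterable[ProteinRecord], path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(p.sequence), id=p.accession, description=f"GN={p.gene}")
        for p in proteins
    ]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# SNP annotation table


def read_snp_table(path: str | Path) -> list[SnpRecord]:
    """Read the nsSNP annotation TSV.

    Fixed columns: rs_id, gene, accession, pos, ref_aa, alt_aa, ref_nuc,
    alt_nuc. Each additional population contributes three columns:
    ``<pop>_count``, ``<pop>_size``, ``<pop>_freq``.
    """
    path = Path(path)
    snps = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        fixed = ["rs_id", "gene", "accession", "pos", "ref_aa", "alt_aa", "ref_nuc", "alt_nuc"]
        missing = [c for c in fixed if c not in header]
        if missing:
            raise FormatError(f"{path}: missing columns {missing}")
        pops = sorted(
            {c[: -len("_freq")] for c in header if c.endswith("_freq")}
        )
        for row in reader:
            pop_counts = {}
            allele_freq = {}
            for pop in pops:
                if row.get(f"{pop}_count", "") != "" and row.get(f"{pop}_size", "") != "":
                    pop_counts[pop] = (int(row[f"{pop}_count"]), int(row[f"{pop}_size"]))
                if row.get(f"{pop}_freq", "") != "":
                    allele_freq[pop] = float(row[f"{pop}_freq"])
            snps.append(
                SnpRecord(
                    rs_id=row["rs_id"],
                    gene=row["gene"],
                    protein_accession=row["accession"],
                    protein_position=int(row["pos"]),
                    ref_aa=row["ref_aa"],
                    alt_aa=row["alt_aa"],
                    ref_nuc=row["ref_nuc"],
                    alt_nuc=row["alt_nuc"],
                    pop_counts=pop_counts,
                    allele_freq=allele_freq,
                )
            )
    return snps


def write_snp_table(snps: Sequence[SnpRecord], path: str | Path) -> None:
    pops = sorted({p for s in snps for p in s.allele_freq})
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        header = ["rs_id", "gene", "accession", "pos", "ref_aa", "alt_aa", "ref_nuc", "alt_nuc"]
        for pop in pops:
            header += [f"{pop}_count", f"{pop}_size", f"{pop}_freq"]
        writer.writerow(header)
        for s in snps:
            row = [
                s.rs_id, s.gene, s.protein_accession, s.protein_position,
                s.ref_aa, s.alt_aa, s.ref_nuc, s.alt_nuc,
            ]
            for pop in pops:
                x_n = s.pop_counts.get(pop)
                row += [x_n[0] if x_n else "", x_n[1] if x_n else ""]
                f = s.allele_freq.get(pop)
                row.append(repr(f) if f is not None else "")
            writer.writerow(row)


# ---------------------------------------------------------------------------
# GVP catalog TSV


def write_catalog(catalog: Sequence[GvpCatalogEntry], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "peptide", "gene", "accession", "rs_ids", "alleles", "start",
                "end", "allele_class", "missed_cleavages", "unique",
                "matched_genes", "confusable", "confusable_pair",
            ]
        )
        for e in catalog:
            writer.writerow(
                [
                    e.peptide, e.gene, e.protein_accession, ",".join(e.rs_ids),
                    ",".join(f"{rs}:{nuc}:{aa}" for rs, nuc, aa in e.alleles),
                    e.start, e.end, e.allele_class, e.missed_cleavages,
                    int(e.unique), ",".join(e.matched_genes), int(e.confusable),
                    "".join(e.confusable_pair) if e.confusable_pair else "",
                ]
            )


def read_catalog(path: str | Path) -> list[GvpCatalogEntry]:
    path = Path(path)
    entries = []
    with path.open(newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            alleles = tuple(
                tuple(item.split(":")) for item in row["alleles"].split(",") if item
            )
            pair = row["confusable_pair"]
            entries.append(
                GvpCatalogEntry(
                    peptide=row["peptide"],
                    gene=row["gene"],
                    protein_accession=row["accession"],
                    rs_ids=tuple(r for r in row["rs_ids"].split(",") if r),
                    alleles=alleles,  # type: ignore[arg-type]
                    start=int(row["start"]),
                    end=int(row["end"]),
                    allele_class=row["allele_class"],
                    missed_cleavages=int(row["missed_cleavages"]),
                    unique=bool(int(row["unique"])),
                    matched_genes=tuple(g for g in row["matched_genes"].split(",") if g),
                    confusable=bool(int(row["confusable"])),
                    confusable_pair=(pair[0], pair[1]) if pair else None,
                )
            )
    return entries


# ---------------------------------------------------------------------------
# JSON results


def _round_floats(obj, sig: int):
    if isinstance(obj, float):
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    return obj


def write_json(obj, path: str | Path, *, sig_digits: int = 12) -> None:
    """Byte-deterministic JSON: sorted keys, floats at 12 significant digits."""
    path = Path(path)
    with path.open("w") as fh:
        json.dump(_round_floats(obj, sig_digits), fh, indent=2, sort_keys=True)
        fh.write("\n")
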