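"""Collate filtered GVP detections into per-subject nsSNP allele profiles
and validate them against truth genotypes (confusion matrix, sensitivity,
PPV, FDR per GVP allele and overall).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import GenotypeCall, PsmRecord
from .variant_reference import GvpCatalogEntry, SnpRecord

__all__ = [
    "SubjectProfile",
    "ConfusionCounts",
    "collate_profile",
    "classify_calls",
    "metrics_table",
    "profile_matrix",
]


@dataclass
class SubjectProfile:
    """Per subject: gene -> set of imputed (rs_id, allele nucleotide).

    Within a gene each allele is recorded at most once regardless of how
    many PSMs support it; the set within one gene is the "allele
    combination" used for population counting.
    """

    subject_id: str
    gene_profiles: dict[str, set[tuple[str, str]]] = field(default_factory=dict)

    def add(self, gene: str, alleles: Iterable[tuple[str, str]]) -> None:
        self.gene_profiles.setdefault(gene, set()).update(alleles)

    def all_alleles(self) -> set[tuple[str, str, str]]:
        """Flattened (gene, rs_id, nucleotide) triples."""
        return {
            (gene, rs, nuc)
            for gene, combo in self.gene_profiles.items()
            for rs, nuc in combo
        }


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def evaluable(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def ppv(self) -> float | None:
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def fdr(self) -> float | None:
        d = self.tp + self.fp
        return self.fp / d if d else None

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.fn + other.fn, self.tn + other.tn,
        )


def collate_profile(
    detections: Sequence[tuple[PsmRecord, GvpCatalogEntry]],
    catalog: Sequence[GvpCatalogEntry] | None = None,
) -> list[SubjectProfile]:
    """Union the alleles implied by each subject's filtered detections.

    A multi-SNP peptide contributes all covered alleles jointly to its
    gene's combination; duplicate support collapses to one observation.
    Detections referencing non-unique catalog entries are a hard error —
    they must have been removed upstream by the uniqueness rule.
    """
    profiles: dict[str, SubjectProfile] = {}
    for psm, entry in detections:
        if not entry.unique:
            raise ValueError(
                f"detection of non-unique peptide {entry.peptide} reached "
                "collate_profile; run the uniqueness filter first"
            )
        profile = profiles.setdefault(psm.subject_id, SubjectProfile(psm.subject_id))
        profile.add(entry.gene, entry.allele_set())
    return [profiles[s] for s in sorted(profiles)]


def _truth_index(
    truth: Sequence[GenotypeCall],
) -> dict[tuple[str, str], GenotypeCall]:
    return {(c.individual_id, c.rs_id): c for c in truth}


def classify_calls(
    profiles: Sequence[SubjectProfile],
    truth: Sequence[GenotypeCall],
    catalog: Sequence[GvpCatalogEntry],
) -> tuple[dict[tuple[str, str, str], ConfusionCounts], ConfusionCounts]:
    """Score imputed alleles against truth genotypes.

    The evaluable universe is every (subject, gene, rs, allele) cell where
    the catalog contains a unique, non-confusable peptide for the allele
    and the subject has a non-failed truth call at the rs. Cells:
    detected & allele in genotype -> TP; detected & absent -> FP; absent &
    present -> FN; absent & absent -> TN. Returns per-GVP-allele counts
    keyed by (gene, rs_id, nucleotide) plus the overall sum.
    """
    evaluable_alleles = sorted(
        {
            (entry.gene, rs, nuc)
            for entry in catalog
            if entry.unique and not entry.confusable
            for rs, nuc in entry.allele_set()
        }
    )
    truth_by_key = _truth_index(truth)
    truth_subjects = {c.individual_id for c in truth}
    per_gvp: dict[tuple[str, str, str], ConfusionCounts] = {
        k: ConfusionCounts() for k in evaluable_alleles
    }
    for profile in profiles:
        if profile.subject_id not in truth_subjects:
            import logging

            logging.getLogger(__name__).warning(
                "subject %s absent from truth set; excluded", profile.subject_id
            )
    subjects = sorted({p.subject_id for p in profiles} & truth_subjects)
    by_subject = {p.subject_id: p for p in profiles}
    for subject in subjects:
        detected = by_subject[subject].all_alleles()
        for gene, rs, nuc in evaluable_alleles:
            call = truth_by_key.get((subject, rs))
            if call is None or call.missing:
                continue  # failed Sanger determination: not evaluable
            is_detected = (gene, rs, nuc) in detected
            is_carrier = call.carries(nuc)
            counts = per_gvp[(gene, rs, nuc)]
            if is_detected and is_carrier:
                delta = ConfusionCounts(tp=1)
            elif is_detected:
                delta = ConfusionCounts(fp=1)
            elif is_carrier:
                delta = ConfusionCounts(fn=1)
            else:
                delta = ConfusionCounts(tn=1)
            per_gvp[(gene, rs, nuc)] = counts + delta
    overall = sum(per_gvp.values(), ConfusionCounts())
    return per_gvp, overall


def metrics_table(
    per_gvp: Mapping[tuple[str, str, str], ConfusionCounts],
    snps: Sequence[SnpRecord] = (),
    population: str | None = None,
) -> pd.DataFrame:
    """Per-GVP sensitivity/PPV table, sorted by ascending minor-allele
    frequency (loci without a known frequency sort last). Undefined
    ratios (zero denominators) are NA, never 0 or 100."""
    freq_by_rs: dict[str, float] = {}
    for s in snps:
        if population is not None:
            if population in s.allele_freq:
                freq_by_rs[s.rs_id] = min(
                    s.allele_freq[population], 1 - s.allele_freq[population]
                )
        elif s.allele_freq:
            f = min(s.allele_freq.values())
            freq_by_rs[s.rs_id] = min(f, 1 - f)
    rows = []
    for (gene, rs, nuc), c in per_gvp.items():
        rows.append(
            {
                "gene": gene,
                "rs_id": rs,
                "allele": nuc,
                "maf": freq_by_rs.get(rs),
                "tp": c.tp,
                "fp": c.fp,
                "fn": c.fn,
                "tn": c.tn,
                "sensitivity_pct": None if c.sensitivity is None else 100 * c.sensitivity,
                "ppv_pct": None if c.ppv is None else 100 * c.ppv,
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(
            ["maf", "gene", "rs_id", "allele"], na_position="last"
        ).reset_index(drop=True)
    return df


def profile_matrix(profiles: Sequence[SubjectProfile]) -> pd.DataFrame:
    """Subjects x gene-allele 0/1 indicator matrix (one column per
    (gene, rs, nucleotide); at most one observation per cell)."""
    columns = sorted({a for p in profiles for a in p.all_alleles()})
    data = {
        f"{g}:{rs}:{nuc}": [int((g, rs, nuc) in p.all_alleles()) for p in profiles]
        for g, rs, nuc in columns
    }
    return pd.DataFrame(data, index=[p.subject_id for p in profiles])
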