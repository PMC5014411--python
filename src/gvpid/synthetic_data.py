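"""Simulation of every pipeline input with known ground truth.

Generates a toy proteome with embedded SAP loci, diploid genotype panels
under Hardy-Weinberg equilibrium (optionally with explicit within-gene
haplotype frequencies), subject truth genotypes, and a binary
peptide-detection process with configurable per-GVP sensitivity and
false-positive rate. Decoy PSMs crafted to violate exactly one named
exclusion rule support filter audits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import masses
from .gvp_filter import FilterConfig, alternative_peptides
from .io_formats import GenotypeCall, PopulationPanel, PsmRecord
from .variant_reference import (
    DEFAULT_CONFUSABLE_PAIRS,
    GvpCatalogEntry,
    ProteinRecord,
    SnpRecord,
    annotate_catalog,
    build_variant_database,
    enumerate_gvps,
)

__all__ = [
    "SimLocus",
    "SimConfig",
    "Study",
    "default_config",
    "build_study",
    "simulate_panel",
    "simulate_subjects",
    "simulate_detections",
    "make_decoys",
    "panel_to_vcf",
    "panel_to_tsv",
]

# Residues safe for SAP embedding: canonical, non-cleavage (K/R), not P,
# and chosen to avoid the default chemically confusable pairs.
_SAP_RESIDUES = "ADEFGHILMNQSTVWY"
_NUCS = "ACGT"


@dataclass(frozen=True)
class SimLocus:
    gene: str
    rs_id: str
    ref_aa: str
    alt_aa: str
    ref_nuc: str
    alt_nuc: str
    alt_freq: Mapping[str, float]
    protein_position: int = 0  # assigned during proteome construction
    role: str = "normal"  # normal | rare | confusable | shared


@dataclass(frozen=True)
class SimConfig:
    loci: tuple[SimLocus, ...]
    panel_sizes: Mapping[str, int]
    n_subjects: int
    detection_sensitivity: float
    false_positive_rate: float
    seed: int
    max_missed: int = 2
    haplotypes: Mapping[str, Sequence[tuple[Mapping[str, str], float]]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        for rate in (self.detection_sensitivity, self.false_positive_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        for locus in self.loci:
            for q in locus.alt_freq.values():
                if not 0.0 <= q <= 1.0:
                    raise ValueError(f"{locus.rs_id}: frequency {q} outside [0, 1]")


@dataclass
class Study:
    """A fully materialized toy study: reference proteome, SNP records,
    search space (with variant copies), and annotated GVP catalog."""

    config: SimConfig
    proteome: list[ProteinRecord]
    snps: list[SnpRecord]
    search_space: list[ProteinRecord]
    catalog: list[GvpCatalogEntry]


def default_config(
    seed: int,
    n_genes: int = 8,
    n_loci: int = 12,
    panel_sizes: Mapping[str, int] | None = None,
    n_subjects: int = 20,
    detection_sensitivity: float = 0.8,
    false_positive_rate: float = 0.02,
    with_decoy_loci: bool = False,
) -> SimConfig:
    """Toy-study configuration: ``n_loci`` loci spread over ``n_genes``
    genes with population-specific alternative-allele frequencies.

    ``with_decoy_loci`` appends one rare, one chemically confusable, and
    one shared-peptide locus, each designed to trip exactly one
    catalog-level exclusion rule.
    """
    if n_loci < n_genes:
        raise ValueError("need at least one locus per gene")
    panel_sizes = dict(panel_sizes or {"EUR": 400, "AFR": 250})
    rng = np.random.default_rng(seed)
    pops = sorted(panel_sizes)
    loci: list[SimLocus] = []
    for i in range(n_loci):
        gene = f"GENE{i % n_genes + 1}"
        ref_aa, alt_aa = rng.choice(list(_SAP_RESIDUES), size=2, replace=False)
        ref_nuc, alt_nuc = rng.choice(list(_NUCS), size=2, replace=False)
        freqs = {pop: float(rng.uniform(0.05, 0.5)) for pop in pops}
        loci.append(
            SimLocus(
                gene=gene,
                rs_id=f"rs{1000 + i}",
                ref_aa=str(ref_aa),
                alt_aa=str(alt_aa),
                ref_nuc=str(ref_nuc),
                alt_nuc=str(alt_nuc),
                alt_freq=freqs,
            )
        )
    if with_decoy_loci:
        loci.append(
            SimLocus(
                gene="GRARE", rs_id="rs9001", ref_aa="A", alt_aa="V",
                ref_nuc="C", alt_nuc="T",
                alt_freq={pop: 0.001 for pop in pops}, role="rare",
            )
        )
        loci.append(
            SimLocus(
                gene="GCONF", rs_id="rs9002", ref_aa="N", alt_aa="D",
                ref_nuc="A", alt_nuc="G",
                alt_freq={pop: 0.2 for pop in pops}, role="confusable",
            )
        )
        loci.append(
            SimLocus(
                gene="GSHARE", rs_id="rs9003", ref_aa="S", alt_aa="G",
                ref_nuc="A", alt_nuc="G",
                alt_freq={pop: 0.2 for pop in pops}, role="shared",
            )
        )
    return SimConfig(
        loci=tuple(loci),
        panel_sizes=panel_sizes,
        n_subjects=n_subjects,
        detection_sensitivity=detection_sensitivity,
        false_positive_rate=false_positive_rate,
        seed=seed,
    )


def _random_gene_sequence(rng: np.random.Generator, length: int) -> list[str]:
    """Random sequence with a K/R every 8th residue so tryptic peptides
    stay short (<= 24 residues at 2 missed cleavages) and SAP loci 30+
    residues apart never share a peptide."""
    alphabet = list("ACDEFGHILMNQSTVWY")  # no K/R/P in random fill
    seq = [str(a) for a in rng.choice(alphabet, size=length)]
    for i in range(7, length - 1, 8):
        seq[i] = "K" if rng.random() < 0.5 else "R"
    return seq


def build_study(config: SimConfig, freq_threshold: float = 0.004) -> Study:
    """Materialize the proteome, SNP annotations, search space, and
    annotated GVP catalog for a simulation configuration."""
    rng = np.random.default_rng(config.seed)
    by_gene: dict[str, list[SimLocus]] = {}
    for locus in config.loci:
        by_gene.setdefault(locus.gene, []).append(locus)
    proteome: list[ProteinRecord] = []
    snps: list[SnpRecord] = []
    placed: dict[str, SimLocus] = {}
    shared_window: str | None = None
    for gene in sorted(by_gene):
        group = by_gene[gene]
        length = 40 * (len(group) + 1)
        seq = _random_gene_sequence(rng, length)
        for k, locus in enumerate(group):
            # 1-based, >= 30 residues apart, never on the 8-periodic K/R grid
            pos = 40 * (k + 1) + 4
            seq[pos - 1] = locus.ref_aa
            placed[locus.rs_id] = replace(locus, protein_position=pos)
        accession = f"P_{gene}"
        protein = ProteinRecord(accession=accession, gene=gene, sequence="".join(seq))
        proteome.append(protein)
        for locus in group:
            p = placed[locus.rs_id]
            snps.append(
                SnpRecord(
                    rs_id=p.rs_id,
                    gene=gene,
                    protein_accession=accession,
                    protein_position=p.protein_position,
                    ref_aa=p.ref_aa,
                    alt_aa=p.alt_aa,
                    ref_nuc=p.ref_nuc,
                    alt_nuc=p.alt_nuc,
                    allele_freq=dict(p.alt_freq),
                )
            )
            if locus.role == "shared":
                # window around the locus spanning whole tryptic fragments,
                # with the ALT residue, to be duplicated into a second gene
                pos0 = p.protein_position - 1
                start = max(0, pos0 - 16)
                end = min(len(seq), pos0 + 16)
                window = list(seq[start:end])
                window[pos0 - start] = p.alt_aa
                shared_window = "".join(window)
    if shared_window is not None:
        filler = _random_gene_sequence(rng, 40)
        proteome.append(
            ProteinRecord(
                accession="P_GSHARE2",
                gene="GSHARE2",
                sequence="".join(filler) + shared_window,
            )
        )
    search_space = build_variant_database(proteome, snps, freq_threshold)
    catalog = annotate_catalog(
        enumerate_gvps(proteome, snps, config.max_missed), search_space
    )
    return Study(
        config=config,
        proteome=proteome,
        snps=snps,
        search_space=search_space,
        catalog=catalog,
    )


# ---------------------------------------------------------------------------
# Genotype simulation


def _draw_gene_genotypes(
    rng: np.random.Generator,
    individual: str,
    gene_loci: Sequence[SnpRecord],
    q_by_rs: Mapping[str, float],
    haplotypes: Sequence[tuple[Mapping[str, str], float]] | None,
) -> list[GenotypeCall]:
    if haplotypes:
        weights = np.array([w for _, w in haplotypes], dtype=float)
        weights = weights / weights.sum()
        picks = rng.choice(len(haplotypes), size=2, p=weights)
        calls = []
        for snp in gene_loci:
            pair = tuple(
                haplotypes[h][0].get(snp.rs_id, snp.ref_nuc) for h in picks
            )
            calls.append(GenotypeCall(individual, snp.rs_id, pair))  # type: ignore[arg-type]
        return calls
    calls = []
    for snp in gene_loci:
        q = q_by_rs[snp.rs_id]
        pair = tuple(
            snp.alt_nuc if rng.random() < q else snp.ref_nuc for _ in range(2)
        )
        calls.append(GenotypeCall(individual, snp.rs_id, pair))  # type: ignore[arg-type]
    return calls


def _simulate_individuals(
    config: SimConfig,
    snps: Sequence[SnpRecord],
    population: str,
    ids: Sequence[str],
    rng: np.random.Generator,
) -> dict[str, dict[str, GenotypeCall]]:
    by_gene: dict[str, list[SnpRecord]] = {}
    for snp in snps:
        by_gene.setdefault(snp.gene, []).append(snp)
    q_by_rs = {
        locus.rs_id: locus.alt_freq.get(population, 0.0) for locus in config.loci
    }
    calls: dict[str, dict[str, GenotypeCall]] = {}
    for individual in ids:
        calls[individual] = {}
        for gene in sorted(by_gene):
            gene_calls = _draw_gene_genotypes(
                rng, individual, by_gene[gene], q_by_rs,
                config.haplotypes.get(gene),
            )
            for c in gene_calls:
                calls[individual][c.rs_id] = c
    return calls


def simulate_panel(
    config: SimConfig,
    snps: Sequence[SnpRecord],
    population: str,
    rng: np.random.Generator | None = None,
) -> PopulationPanel:
    """Draw a diploid HWE panel: genotype classes {(1-q)^2, 2q(1-q), q^2}
    independently per locus (or per-gene haplotype draws when
    ``config.haplotypes`` covers the gene)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.panel_sizes[population]
    ids = [f"{population}_{i:04d}" for i in range(n)]
    calls = _simulate_individuals(config, snps, population, ids, rng)
    return PopulationPanel(
        population_id=population,
        calls=calls,
        loci=tuple(sorted({s.rs_id for s in snps})),
    )


def simulate_subjects(
    config: SimConfig,
    snps: Sequence[SnpRecord],
    population: str = "EUR",
    rng: np.random.Generator | None = None,
) -> list[GenotypeCall]:
    """Truth genotypes for the study subjects, drawn under the same
    generative law as the panel."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    ids = [f"S{i:03d}" for i in range(config.n_subjects)]
    calls = _simulate_individuals(config, snps, population, ids, rng)
    return [
        calls[ind][rs] for ind in ids for rs in sorted(calls[ind])
    ]


# ---------------------------------------------------------------------------
# Detection simulation


def detectable_alleles(
    study: Study, freq_threshold: float = 0.004
) -> dict[tuple[str, str, str], GvpCatalogEntry]:
    """Map each imputable (gene, rs, nucleotide) to a single-locus,
    unique, non-confusable, frequency-passing catalog entry (fewest
    missed cleavages)."""
    passing_rs = {
        s.rs_id
        for s in study.snps
        if any(f >= freq_threshold for f in s.allele_freq.values())
    }
    best: dict[tuple[str, str, str], GvpCatalogEntry] = {}
    for entry in study.catalog:
        if not entry.unique or entry.confusable or len(entry.alleles) != 1:
            continue
        rs, nuc, _ = entry.alleles[0]
        if rs not in passing_rs:
            continue
        key = (entry.gene, rs, nuc)
        if key not in best or entry.missed_cleavages < best[key].missed_cleavages:
            best[key] = entry
    return best


def _passing_psm(
    subject: str, entry: GvpCatalogEntry, decoy_rule: str | None = None
) -> PsmRecord:
    mass = masses.peptide_neutral_mass(entry.peptide)
    return PsmRecord(
        subject_id=subject,
        sample_id=f"{subject}_hair",
        peptide=entry.peptide,
        engine="xtandem",
        score=-5.0,
        observed_mass=mass,
        theoretical_mass=mass,
        protein_accessions=(entry.protein_accession,),
        decoy_rule=decoy_rule,
    )


def simulate_detections(
    truth: Sequence[GenotypeCall],
    study: Study,
    config: SimConfig | None = None,
    rng: np.random.Generator | None = None,
    include_decoys: bool = False,
    filter_config: FilterConfig | None = None,
) -> list[PsmRecord]:
    """Binary detection process over the imputable allele universe.

    For every allele a subject carries, a filter-passing PSM is emitted
    with probability ``detection_sensitivity``; for every allele the
    subject lacks, with probability ``false_positive_rate``. Optional
    decoy PSMs each violate exactly one named exclusion rule and carry
    it in the hidden ``decoy_rule`` column.
    """
    config = config if config is not None else study.config
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    universe = detectable_alleles(study)
    truth_by_subject: dict[str, dict[str, GenotypeCall]] = {}
    for call in truth:
        truth_by_subject.setdefault(call.individual_id, {})[call.rs_id] = call
    psms: list[PsmRecord] = []
    for subject in sorted(truth_by_subject):
        calls = truth_by_subject[subject]
        for (gene, rs, nuc), entry in sorted(universe.items()):
            call = calls.get(rs)
            if call is None or call.missing:
                continue
            p = (
                config.detection_sensitivity
                if call.carries(nuc)
                else config.false_positive_rate
            )
            if rng.random() < p:
                psms.append(_passing_psm(subject, entry))
    if include_decoys:
        psms.extend(
            make_decoys(study, filter_config or FilterConfig(), subject="DECOY")
        )
    return psms


def make_decoys(
    study: Study, filter_config: FilterConfig, subject: str = "DECOY"
) -> list[PsmRecord]:
    """One PSM per exclusion rule, each violating exactly that rule."""
    universe = detectable_alleles(study)
    if not universe:
        raise ValueError("no detectable alleles to build decoys from")
    clean = universe[sorted(universe)[0]]
    mass = masses.peptide_neutral_mass(clean.peptide)
    decoys = [
        replace(_passing_psm(subject, clean, "score"), score=-1.0),
        replace(
            _passing_psm(subject, clean, "precursor_mass"),
            observed_mass=mass + filter_config.precursor_tol_da + 0.3,
        ),
        replace(
            _passing_psm(subject, clean, "ptm"),
            modifications=((1, 79.96633, "phospho"),),
        ),
    ]
    by_role: dict[str, GvpCatalogEntry] = {}
    roles = {l.rs_id: l.role for l in study.config.loci}
    for entry in study.catalog:
        if len(entry.alleles) != 1:
            continue
        rs, nuc, _ = entry.alleles[0]
        role = roles.get(rs, "normal")
        if role == "rare" and entry.unique and not entry.confusable:
            by_role.setdefault("frequency", entry)
        if role == "confusable" and entry.unique and entry.confusable:
            by_role.setdefault("confusable", entry)
        if role == "shared" and not entry.unique and entry.allele_class == "variant":
            by_role.setdefault("uniqueness", entry)
    for rule in ("frequency", "confusable", "uniqueness"):
        if rule in by_role:
            decoys.append(_passing_psm(subject, by_role[rule], rule))
    alt_decoy = _alt_fragment_decoy(study, filter_config, subject)
    if alt_decoy is not None:
        decoys.append(alt_decoy)
    return decoys


def _alt_fragment_decoy(
    study: Study, filter_config: FilterConfig, subject: str
) -> PsmRecord | None:
    universe = detectable_alleles(study)
    tol = filter_config.fragment_tol_da
    for key in sorted(universe):
        entry = universe[key]
        own = masses.fragment_ladder(entry.peptide)
        for alt_pep in alternative_peptides(entry, study.catalog):
            diagnostic = [
                m
                for m in masses.fragment_ladder(alt_pep)
                if not any(abs(m - o) <= tol for o in own)
            ]
            if diagnostic:
                return replace(
                    _passing_psm(subject, entry, "alt_fragment"),
                    fragment_mzs=(round(diagnostic[0], 5),),
                )
    return None


# ---------------------------------------------------------------------------
# File emission


def panel_to_vcf(
    panel: PopulationPanel, snps: Sequence[SnpRecord], path: str | Path
) -> None:
    """Write the panel as a minimal uncompressed VCF 4.2 (GT only)."""
    samples = panel.individuals
    snps_in = [s for s in snps if s.rs_id in set(panel.loci)]
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=1>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for pos, snp in enumerate(sorted(snps_in, key=lambda s: s.rs_id), start=1):
        gts = []
        for sample in samples:
            call = panel.genotype(sample, snp.rs_id)
            if call is None or call.missing:
                gts.append("./.")
            else:
                idx = ["1" if a == snp.alt_nuc else "0" for a in call.alleles]
                gts.append("/".join(idx))
        lines.append(
            f"1\t{pos}\t{snp.rs_id}\t{snp.ref_nuc}\t{snp.alt_nuc}\t.\tPASS\t.\tGT\t"
            + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def panel_to_tsv(panel: PopulationPanel, path: str | Path) -> None:
    """Write the panel as an individual-by-locus genotype TSV."""
    loci = list(panel.loci)
    lines = ["individual\t" + "\t".join(loci)]
    for individual in panel.individuals:
        row = [individual]
        for rs in loci:
            call = panel.genotype(individual, rs)
            row.append(
                "./." if call is None or call.missing else "/".join(call.alleles)
            )
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")
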