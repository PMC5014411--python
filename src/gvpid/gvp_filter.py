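"""Exclusion rules for candidate GVP detections.

Seven pure, order-independent rules: engine score, precursor mass
deviation, population frequency, biological PTMs, chemically confusable
SAPs, peptide uniqueness, and alternative-allele fragment evidence. Each
returns a FilterDecision naming the rules that failed; ``apply_all``
conjoins them and produces a per-rule audit table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import masses
from .io_formats import PsmRecord
from .variant_reference import (
    DEFAULT_CONFUSABLE_PAIRS,
    GvpCatalogEntry,
)

__all__ = [
    "FilterConfig",
    "FilterDecision",
    "RULES",
    "score_filter",
    "precursor_mass_filter",
    "frequency_filter",
    "ptm_filter",
    "confusable_filter",
    "uniqueness_filter",
    "alt_allele_fragment_filter",
    "apply_all",
    "alternative_peptides",
]

RULES = (
    "score",
    "precursor_mass",
    "frequency",
    "ptm",
    "confusable",
    "uniqueness",
    "alt_fragment",
)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for every exclusion rule.

    Boundary values pass: the printed inequalities are strict on the
    exclusion side (reject Mascot expectation > 0.05, reject mass
    deviation > 0.2 Da, reject frequency < the threshold).
    """

    xtandem_loge_max: float = -2.0
    mascot_expect_max: float = 0.05
    precursor_tol_da: float = 0.2
    freq_threshold: float = 0.004
    fragment_tol_da: float = 0.02
    biological_mods: frozenset[str] = frozenset({"phospho"})
    exclusion_pairs: frozenset[tuple[str, str]] = DEFAULT_CONFUSABLE_PAIRS
    populations: tuple[str, ...] = ()  # empty -> all populations with a frequency

    def __post_init__(self) -> None:
        if self.precursor_tol_da <= 0 or self.fragment_tol_da <= 0:
            raise ValueError("tolerances must be positive")
        for v in (self.xtandem_loge_max, self.mascot_expect_max, self.freq_threshold):
            if not math.isfinite(v):
                raise ValueError("thresholds must be finite")


@dataclass(frozen=True)
class FilterDecision:
    psm: PsmRecord
    failed_rules: tuple[str, ...] = ()
    flags: tuple[str, ...] = ()

    @property
    def passed(self) -> bool:
        return not self.failed_rules


def _fail(psm: PsmRecord, rule: str) -> FilterDecision:
    return FilterDecision(psm=psm, failed_rules=(rule,))


def _pass(psm: PsmRecord, *flags: str) -> FilterDecision:
    return FilterDecision(psm=psm, flags=tuple(flags))


def score_filter(psm: PsmRecord, config: FilterConfig) -> FilterDecision:
    """Keep X!Tandem PSMs with log10(e) <= -2; Mascot with expectation <= 0.05."""
    if psm.engine == "xtandem":
        ok = psm.score <= config.xtandem_loge_max
    elif psm.engine == "mascot":
        ok = psm.score <= config.mascot_expect_max
    else:  # pragma: no cover - PsmRecord already validates
        raise ValueError(f"unknown engine {psm.engine!r}")
    return _pass(psm) if ok else _fail(psm, "score")


def precursor_mass_filter(psm: PsmRecord, config: FilterConfig) -> FilterDecision:
    """Reject when |observed - theoretical| exceeds the tolerance (strict)."""
    delta = abs(psm.observed_mass - psm.theoretical_mass)
    return _pass(psm) if delta <= config.precursor_tol_da else _fail(psm, "precursor_mass")


def frequency_filter(
    psm: PsmRecord, entry: GvpCatalogEntry, config: FilterConfig,
    freqs: Mapping[str, Mapping[str, float]],
) -> FilterDecision:
    """Reject loci rarer than the threshold in every reference population.

    ``freqs`` maps rs_id -> population -> alternative-allele frequency.
    A locus passes if its frequency reaches the threshold in at least one
    configured population; a multi-locus peptide must pass at every
    covered locus. Missing frequencies fail closed with their own rule
    name.
    """
    for rs in entry.rs_ids:
        pop_freqs = freqs.get(rs, {})
        pops = config.populations or tuple(pop_freqs)
        values = [pop_freqs[p] for p in pops if p in pop_freqs]
        if not values:
            return _fail(psm, "frequency_missing")
        if all(v < config.freq_threshold for v in values):
            return _fail(psm, "frequency")
    return _pass(psm)


def ptm_filter(psm: PsmRecord, config: FilterConfig) -> FilterDecision:
    """Reject PSMs whose assignment incorporates a biological PTM.

    Sample-preparation and search-artifact modifications
    (carbamidomethyl, oxidation, deamidation) never trigger this rule.
    """
    for _, _, name in psm.modifications:
        if name.lower() in config.biological_mods:
            return _fail(psm, "ptm")
    return _pass(psm)


def confusable_filter(
    psm: PsmRecord, entry: GvpCatalogEntry, config: FilterConfig
) -> FilterDecision:
    """Reject SAPs attributable to chemical modification or conversion."""
    if entry.confusable and entry.confusable_pair in config.exclusion_pairs:
        return _fail(psm, "confusable")
    return _pass(psm)


def uniqueness_filter(
    psm: PsmRecord, entry: GvpCatalogEntry, config: FilterConfig
) -> FilterDecision:
    """Reject peptides matching more than one gene product."""
    return _pass(psm) if entry.unique else _fail(psm, "uniqueness")


def alternative_peptides(
    entry: GvpCatalogEntry, catalog: Sequence[GvpCatalogEntry]
) -> list[str]:
    """Peptides the same locus would produce under the other allele.

    For each rs covered by ``entry``, catalog entries from the same gene
    that cover that rs with a different nucleotide are counterparts. For
    cleavage-site SAPs the counterpart has a different tryptic span; the
    full counterpart peptide is returned either way.
    """
    own = {(rs, nuc) for rs, nuc, _ in entry.alleles}
    out: list[str] = []
    for other in catalog:
        if other.gene != entry.gene or other.peptide == entry.peptide:
            continue
        other_alleles = {(rs, nuc) for rs, nuc, _ in other.alleles}
        shared_rs = {rs for rs, _ in own} & {rs for rs, _ in other_alleles}
        if shared_rs and any(
            (rs, nuc) not in own for rs, nuc in other_alleles if rs in shared_rs
        ):
            out.append(other.peptide)
    return sorted(set(out))


def alt_allele_fragment_filter(
    psm: PsmRecord,
    entry: GvpCatalogEntry,
    config: FilterConfig,
    catalog: Sequence[GvpCatalogEntry] = (),
) -> FilterDecision:
    """Reject spectra containing fragment masses diagnostic of the
    alternative allele.

    Diagnostic ions are singly charged b/y ions of an alternative-allele
    peptide absent from the detected peptide's own ladder (compared
    within the fragment tolerance). PSMs without a fragment list pass
    with a "not-evaluated" flag.
    """
    if psm.fragment_mzs is None:
        return _pass(psm, "alt_fragment:not-evaluated")
    own_ladder = masses.fragment_ladder(entry.peptide)
    tol = config.fragment_tol_da
    for alt_peptide in alternative_peptides(entry, catalog):
        diagnostic = [
            m
            for m in masses.fragment_ladder(alt_peptide)
            if not any(abs(m - o) <= tol for o in own_ladder)
        ]
        for observed in psm.fragment_mzs:
            if any(abs(observed - d) <= tol for d in diagnostic):
                return _fail(psm, "alt_fragment")
    return _pass(psm)


# ---------------------------------------------------------------------------


def _merge(psm: PsmRecord, decisions: Iterable[FilterDecision]) -> FilterDecision:
    failed: list[str] = []
    flags: list[str] = []
    for d in decisions:
        failed.extend(d.failed_rules)
        flags.extend(d.flags)
    return FilterDecision(psm=psm, failed_rules=tuple(sorted(set(failed))),
                          flags=tuple(sorted(set(flags))))


def evaluate_psm(
    psm: PsmRecord,
    entry: GvpCatalogEntry,
    config: FilterConfig,
    freqs: Mapping[str, Mapping[str, float]],
    catalog: Sequence[GvpCatalogEntry] = (),
) -> FilterDecision:
    """Run every exclusion rule on one PSM/catalog-entry pair."""
    return _merge(
        psm,
        [
            score_filter(psm, config),
            precursor_mass_filter(psm, config),
            frequency_filter(psm, entry, config, freqs),
            ptm_filter(psm, config),
            confusable_filter(psm, entry, config),
            uniqueness_filter(psm, entry, config),
            alt_allele_fragment_filter(psm, entry, config, catalog),
        ],
    )


def evaluable_catalog(
    catalog: Sequence[GvpCatalogEntry],
    config: FilterConfig,
    freqs: Mapping[str, Mapping[str, float]],
) -> list[GvpCatalogEntry]:
    """Entries passing the catalog-level rules (uniqueness, confusable
    SAP, population frequency) — the imputable allele universe used for
    validation."""

    def _freq_ok(entry: GvpCatalogEntry) -> bool:
        for rs in entry.rs_ids:
            pop_freqs = freqs.get(rs, {})
            pops = config.populations or tuple(pop_freqs)
            values = [pop_freqs[p] for p in pops if p in pop_freqs]
            if not values or all(v < config.freq_threshold for v in values):
                return False
        return True

    return [
        e for e in catalog if e.unique and not e.confusable and _freq_ok(e)
    ]


def apply_all(
    psms: Sequence[PsmRecord],
    catalog: Sequence[GvpCatalogEntry],
    config: FilterConfig,
    freqs: Mapping[str, Mapping[str, float]],
) -> tuple[list[tuple[PsmRecord, GvpCatalogEntry]], list[FilterDecision], pd.DataFrame]:
    """Filter PSMs against the catalog.

    Returns (passing detections as (psm, entry) pairs, all decisions, and
    a per-rule audit table of failure counts). PSMs whose peptide is not
    in the catalog are dropped with a "no_catalog_match" decision.
    """
    by_peptide: dict[str, list[GvpCatalogEntry]] = {}
    for e in catalog:
        by_peptide.setdefault(e.peptide, []).append(e)
    detections: list[tuple[PsmRecord, GvpCatalogEntry]] = []
    decisions: list[FilterDecision] = []
    for psm in psms:
        entries = by_peptide.get(psm.peptide)
        if not entries:
            decisions.append(_fail(psm, "no_catalog_match"))
            continue
        for entry in entries:
            decision = evaluate_psm(psm, entry, config, freqs, catalog)
            decisions.append(decision)
            if decision.passed:
                detections.append((psm, entry))
    counts: dict[str, int] = {rule: 0 for rule in RULES}
    for d in decisions:
        for rule in d.failed_rules:
            counts[rule] = counts.get(rule, 0) + 1
    audit = pd.DataFrame(
        sorted(counts.items()), columns=["rule", "n_failed"]
    )
    return detections, decisions, audit
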