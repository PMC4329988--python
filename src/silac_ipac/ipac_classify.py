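"""Cross-experiment iPAC classification.

Parallel affinity capture purifies one doubly-tagged bait with two (or
more) different resins.  A genuine partner is enriched with *every* resin;
a protein enriched with one resin but sitting at ratio ~ 1 with the other
is a tag-specific artefact — the false-positive class that single-tag
pull-downs cannot detect; proteins near ratio 1 everywhere are
non-specific resin binders.  This module aggregates per-experiment
significance calls into per-resin evidence, applies that decision table,
and ranks genuine partners high/medium/low by replicate, reciprocal-label
and cross-tag reproducibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .quant_io import ProteinGroupRecord, StudyDesign
from .ratio_model import (
    CallStatus,
    InsufficientDataError,
    OrientedRatio,
    RatioDistributionStats,
    SignificanceCall,
    call_significance,
    distribution_stats,
    orient_ratio,
    quantification_filter,
)

__all__ = [
    "ClassifierConfig",
    "ResinEvidence",
    "InteractionVerdict",
    "VERDICT_ORDER",
    "CONFIDENCE_ORDER",
    "summarize_resin",
    "classify_protein",
    "rank_confidence",
    "overlap_report",
    "beadome_flag",
    "classify_dataset",
    "sort_verdicts",
    "evidence_to_jsonable",
    "evidence_from_jsonable",
]

#: Verdict classes, in report order.
VERDICT_ORDER = ("bait", "genuine", "tag_specific_artefact", "non_specific",
                 "insufficient_data")
#: Confidence ranks, strongest first.
CONFIDENCE_ORDER = ("high", "medium", "low", "not_applicable")

_SUPPORTING = (CallStatus.SIGNIFICANT_ENRICHED, CallStatus.EXCLUSIVE_TAGGED)


@dataclass(frozen=True)
class ClassifierConfig:
    """Tunable thresholds of the full classification pipeline.

    ``k`` is the significance threshold in dispersion units (1 for the
    permissive call, 2 for the strict call).  ``min_sig_per_resin`` is the
    number of supporting (enriched or exclusive-tagged) experiments a resin
    must contribute before it counts towards a genuine verdict; the
    ``consistent`` mode raises it to a majority of that resin's observed
    experiments.  ``frac_high``/``frac_medium`` are the reproducibility
    fractions separating high/medium/low confidence.
    """

    k: float = 1.0
    min_peptides: int = 2
    exclusive_min_peptides: int = 2
    min_stats_n: int = 10
    robust: bool = False
    min_sig_per_resin: int = 1
    consistent: bool = False
    frac_high: float = 0.75
    frac_medium: float = 0.5


@dataclass(frozen=True)
class ResinEvidence:
    """Counts of call outcomes for one protein across one resin's experiments.

    ``n_significant`` counts supporting calls (significant-enriched or
    exclusive-tagged).  ``n_near_one`` counts quantified, not-significant
    calls; significantly *depleted* calls are tracked separately but are
    treated as near-one by the artefact logic (only enrichment in the tagged
    channel is specific).
    """

    resin: str
    n_experiments: int
    n_significant: int
    n_near_one: int
    n_depleted: int
    n_exclusive_control: int
    n_unobserved: int
    orientations_supporting: frozenset[str]
    mean_log2_enrichment: float | None

    def __post_init__(self) -> None:
        total = (self.n_significant + self.n_near_one + self.n_depleted
                 + self.n_exclusive_control + self.n_unobserved)
        if total != self.n_experiments:
            raise ValueError(
                f"resin {self.resin!r}: outcome counts sum to {total}, "
                f"expected {self.n_experiments}"
            )

    @property
    def n_observed(self) -> int:
        return self.n_experiments - self.n_unobserved

    @property
    def n_quantified(self) -> int:
        """Experiments with a usable ratio (enriched calls may be exclusive,
        hence are not counted here; near-one and depleted always are)."""
        return self.n_near_one + self.n_depleted

    @property
    def n_near_one_like(self) -> int:
        """Near-one evidence for the artefact rule (includes depleted)."""
        return self.n_near_one + self.n_depleted


def empty_evidence(resin: str, n_experiments: int) -> ResinEvidence:
    """Evidence for a resin in which the protein was never observed."""
    return ResinEvidence(
        resin=resin,
        n_experiments=n_experiments,
        n_significant=0,
        n_near_one=0,
        n_depleted=0,
        n_exclusive_control=0,
        n_unobserved=n_experiments,
        orientations_supporting=frozenset(),
        mean_log2_enrichment=None,
    )


@dataclass(frozen=True)
class InteractionVerdict:
    """Final cross-resin classification of one protein."""

    protein: str
    verdict: str
    confidence: str
    per_resin: Mapping[str, ResinEvidence]
    in_beadome: bool = False

    def __post_init__(self) -> None:
        if self.verdict not in VERDICT_ORDER:
            raise ValueError(f"unknown verdict {self.verdict!r}")
        if self.confidence not in CONFIDENCE_ORDER:
            raise ValueError(f"unknown confidence {self.confidence!r}")


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def summarize_resin(
    calls: Sequence[SignificanceCall],
    design: StudyDesign,
    *,
    n_experiments: int | None = None,
) -> ResinEvidence:
    """Aggregate one protein's calls across one resin's experiments.

    ``n_experiments`` defaults to the number of (non-control) experiments
    the design holds for the resin; experiments with no call at all count
    as unobserved, as do calls with the unquantified status.
    """
    if not calls:
        raise ValueError("summarize_resin needs at least one call")
    proteins = {c.protein for c in calls}
    if len(proteins) != 1:
        raise ValueError(f"calls span multiple proteins: {sorted(proteins)!r}")
    resins = {design[c.experiment_id].resin for c in calls}
    if len(resins) != 1:
        raise ValueError(f"calls span multiple resins: {sorted(resins)!r}")
    (resin,) = resins
    if n_experiments is None:
        n_experiments = len(design.experiments_for(resin))
    if len(calls) > n_experiments:
        raise ValueError(
            f"{len(calls)} calls for resin {resin!r} exceed its "
            f"{n_experiments} experiments"
        )

    n_sig = sum(c.status in _SUPPORTING for c in calls)
    n_near = sum(c.status is CallStatus.NOT_SIGNIFICANT for c in calls)
    n_dep = sum(c.status is CallStatus.SIGNIFICANT_DEPLETED for c in calls)
    n_exc = sum(c.status is CallStatus.EXCLUSIVE_CONTROL for c in calls)
    n_unq = sum(c.status is CallStatus.UNQUANTIFIED for c in calls)
    quantified = [
        c.log2_enrichment
        for c in calls
        if c.status in (CallStatus.SIGNIFICANT_ENRICHED,
                        CallStatus.SIGNIFICANT_DEPLETED,
                        CallStatus.NOT_SIGNIFICANT)
    ]
    return ResinEvidence(
        resin=resin,
        n_experiments=n_experiments,
        n_significant=n_sig,
        n_near_one=n_near,
        n_depleted=n_dep,
        n_exclusive_control=n_exc,
        n_unobserved=n_experiments - len(calls) + n_unq,
        orientations_supporting=frozenset(
            design[c.experiment_id].orientation
            for c in calls
            if c.status in _SUPPORTING
        ),
        mean_log2_enrichment=(
            float(np.mean(quantified)) if quantified else None
        ),
    )


# ---------------------------------------------------------------------------
# decision table
# ---------------------------------------------------------------------------

def _required_support(evidence: ResinEvidence, config: ClassifierConfig) -> int:
    base = max(1, config.min_sig_per_resin)
    if config.consistent and evidence.n_observed > 0:
        return max(base, evidence.n_observed // 2 + 1)
    return base


def classify_protein(
    protein: str,
    per_resin: Mapping[str, ResinEvidence],
    config: ClassifierConfig = ClassifierConfig(),
    *,
    bait_accessions: Iterable[str] = (),
) -> InteractionVerdict:
    """Apply the iPAC decision table to one protein's per-resin evidence.

    Decision order: declared bait; genuine (supported by >= 2 resins);
    tag-specific artefact (supported by one resin, near-1 with another);
    non-specific (quantified somewhere, supported nowhere); otherwise
    insufficient data (e.g. only a single resin ever saw the protein).
    A protein supported by two resins and near-1 with a third is still
    genuine — multi-resin support dominates — with a warning.
    """
    if not per_resin:
        raise ValueError(f"protein {protein!r}: no resin evidence")
    evs = list(per_resin.values())

    artefact_pattern = any(e.n_significant >= 1 for e in evs) and any(
        e.n_significant == 0 and e.n_near_one_like >= 1 for e in evs
    )

    if protein in set(bait_accessions):
        verdict = "bait"
    elif sum(e.n_significant >= _required_support(e, config) for e in evs) >= 2:
        verdict = "genuine"
        if artefact_pattern:
            warnings.warn(
                f"{protein}: supported by >=2 resins but near-1 with another; "
                "multi-resin support dominates, classifying as genuine",
                stacklevel=2,
            )
    elif artefact_pattern:
        verdict = "tag_specific_artefact"
    elif (all(e.n_significant == 0 for e in evs)
          and sum(e.n_quantified for e in evs) >= 1):
        verdict = "non_specific"
    else:
        verdict = "insufficient_data"

    out = InteractionVerdict(
        protein=protein,
        verdict=verdict,
        confidence="not_applicable",
        per_resin=dict(per_resin),
    )
    if verdict == "genuine":
        out = replace(out, confidence=rank_confidence(out, config))
    return out


def rank_confidence(
    verdict: InteractionVerdict,
    config: ClassifierConfig = ClassifierConfig(),
) -> str:
    """High/medium/low rank of a genuine partner by reproducibility.

    High: supported in at least ``frac_high`` of the observed experiments of
    *every* resin, with both labelling orientations supporting in at least
    one resin.  Medium: at least ``frac_medium`` reproducibility in every
    resin (e.g. consistent ratios but single-orientation support).  Low:
    meets the genuine floor only — e.g. supported in 4/4 experiments of one
    resin but only 1/4 of the other.
    """
    if verdict.verdict != "genuine":
        return "not_applicable"
    observed = [e for e in verdict.per_resin.values() if e.n_observed > 0]
    if not observed:
        return "low"
    eps = 1e-9

    def frac_ok(threshold: float) -> bool:
        return all(
            e.n_significant >= threshold * e.n_observed - eps for e in observed
        )

    both_orientations = any(
        len(e.orientations_supporting) == 2 for e in observed
    )
    if frac_ok(config.frac_high) and both_orientations:
        return "high"
    if frac_ok(config.frac_medium):
        return "medium"
    return "low"


# ---------------------------------------------------------------------------
# set overlaps and beadome annotation
# ---------------------------------------------------------------------------

def overlap_report(sets: Mapping[str, Iterable]) -> pd.DataFrame:
    """Venn-style region table for two or more named identifier sets.

    Returns one row per non-empty combination of membership (2^n - 1
    regions) with the exclusive count and its percentage of the union;
    region order follows ascending membership masks in input-name order, so
    repeated runs are identical.  The union size is stored in
    ``df.attrs["union"]``.
    """
    names = list(sets)
    if len(names) < 2:
        raise ValueError("overlap_report needs at least two named sets")
    materialized = {name: set(sets[name]) for name in names}
    union: set = set().union(*materialized.values())
    rows = []
    for mask in range(1, 2 ** len(names)):
        inside = [names[i] for i in range(len(names)) if mask >> i & 1]
        outside = [n for n in names if n not in inside]
        region: set = set.intersection(*(materialized[n] for n in inside))
        for n in outside:
            region -= materialized[n]
        rows.append(
            {
                "region": "&".join(inside),
                "count": len(region),
                "percent_of_union": (
                    100.0 * len(region) / len(union) if union else 0.0
                ),
            }
        )
    df = pd.DataFrame(rows, columns=("region", "count", "percent_of_union"))
    df.attrs["union"] = len(union)
    return df


def beadome_flag(
    verdicts: Iterable[InteractionVerdict],
    beadome: Iterable,
    *,
    match: str = "accession",
    gene_of: Mapping[str, str] | None = None,
) -> list[InteractionVerdict]:
    """Annotate verdicts whose protein appears in a beadome (sticky-protein)
    list.  Annotation only — the verdict class is never vetoed.

    ``beadome`` may hold accession strings or objects with an ``accession``
    attribute.  With ``match="gene"`` both sides are mapped through
    ``gene_of`` before comparison.
    """
    if match not in ("accession", "gene"):
        raise ValueError(f"unknown match mode {match!r}")
    members = {getattr(e, "accession", e) for e in beadome}
    if match == "gene":
        gene_of = gene_of or {}
        members = {gene_of.get(m, m) for m in members}

    out = []
    for v in verdicts:
        key = v.protein
        if match == "gene":
            key = (gene_of or {}).get(key, key)
        out.append(replace(v, in_beadome=key in members))
    return out


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def classify_dataset(
    records: Sequence[ProteinGroupRecord],
    design: StudyDesign,
    config: ClassifierConfig = ClassifierConfig(),
    *,
    beadome: Iterable | None = None,
) -> tuple[list[InteractionVerdict], dict[str, RatioDistributionStats]]:
    """Run the full per-experiment -> per-resin -> verdict pipeline.

    Steps: peptide-count filter, ratio orientation, per-experiment
    distribution statistics, significance calls, per-resin aggregation,
    decision table, confidence ranking and (optionally) beadome annotation.
    Returns the verdicts together with each experiment's distribution
    statistics.  Raises :class:`InsufficientDataError` if any experiment
    has too few quantified proteins.
    """
    records = quantification_filter(records, config.min_peptides)
    analysis_ids = {e.experiment_id for e in design.analysis_entries}

    by_experiment: dict[str, list[OrientedRatio]] = {}
    for rec in records:
        if rec.experiment_id not in analysis_ids:
            continue
        oriented = orient_ratio(
            rec, design[rec.experiment_id],
            exclusive_min_peptides=config.exclusive_min_peptides,
        )
        by_experiment.setdefault(rec.experiment_id, []).append(oriented)

    stats: dict[str, RatioDistributionStats] = {}
    calls_by_protein: dict[str, dict[str, list[SignificanceCall]]] = {}
    for experiment_id, oriented_list in by_experiment.items():
        stats[experiment_id] = distribution_stats(
            oriented_list, min_stats_n=config.min_stats_n
        )
        resin = design[experiment_id].resin
        for oriented in oriented_list:
            call = call_significance(
                oriented, stats[experiment_id], config.k, robust=config.robust
            )
            calls_by_protein.setdefault(call.protein, {}).setdefault(
                resin, []
            ).append(call)

    resin_sizes = {r: len(design.experiments_for(r)) for r in design.resins}
    verdicts = []
    for protein in sorted(calls_by_protein):
        per_resin = {}
        for resin, n_exp in resin_sizes.items():
            calls = calls_by_protein[protein].get(resin)
            per_resin[resin] = (
                summarize_resin(calls, design, n_experiments=n_exp)
                if calls
                else empty_evidence(resin, n_exp)
            )
        verdicts.append(
            classify_protein(
                protein, per_resin, config,
                bait_accessions=design.bait_accessions,
            )
        )
    if beadome is not None:
        verdicts = beadome_flag(verdicts, beadome)
    return sort_verdicts(verdicts), stats


def sort_verdicts(verdicts: Iterable[InteractionVerdict]) -> list[InteractionVerdict]:
    """Deterministic report order: class, descending confidence, accession."""
    return sorted(
        verdicts,
        key=lambda v: (
            VERDICT_ORDER.index(v.verdict),
            CONFIDENCE_ORDER.index(v.confidence),
            v.protein,
        ),
    )


# ---------------------------------------------------------------------------
# (de)serialization helpers for verdict reports
# ---------------------------------------------------------------------------

def evidence_to_jsonable(per_resin: Mapping[str, ResinEvidence]) -> dict:
    return {
        resin: {
            "n_experiments": e.n_experiments,
            "n_significant": e.n_significant,
            "n_near_one": e.n_near_one,
            "n_depleted": e.n_depleted,
            "n_exclusive_control": e.n_exclusive_control,
            "n_unobserved": e.n_unobserved,
            "orientations_supporting": sorted(e.orientations_supporting),
            "mean_log2_enrichment": e.mean_log2_enrichment,
        }
        for resin, e in per_resin.items()
    }


def evidence_from_jsonable(data: Mapping[str, Mapping]) -> dict[str, ResinEvidence]:
    return {
        resin: ResinEvidence(
            resin=resin,
            n_experiments=d["n_experiments"],
            n_significant=d["n_significant"],
            n_near_one=d["n_near_one"],
            n_depleted=d["n_depleted"],
            n_exclusive_control=d["n_exclusive_control"],
            n_unobserved=d["n_unobserved"],
            orientations_supporting=frozenset(d["orientations_supporting"]),
            mean_log2_enrichment=d["mean_log2_enrichment"],
        )
        for resin, d in data.items()
    }
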