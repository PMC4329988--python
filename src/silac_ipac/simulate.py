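"""Seeded generator of synthetic SILAC parallel-capture datasets.

The generator plants four protein classes with the ratio structure the
classification scheme is built to resolve:

* the bait, strongly enriched with every resin;
* genuine partners, enriched (tagged/control = ``2**e``) with every resin;
* tag-specific artefacts, enriched or exclusive with exactly one "sticky"
  resin and at ratio ~ 1 with the others;
* non-specific binders at ratio 1 everywhere.

Observed ratios receive log-normal multiplicative noise; the SILAC channel
assignment follows the labelling orientation of each experiment; incomplete
heavy-isotope incorporation leaks part of the heavy-grown cells' signal
into the light channel, shrinking apparent enrichments toward 1; detection
of a protein in an experiment is Bernoulli with a logistic probability in
the log total eluate signal, so faint proteins go missing at random.  The
same seed always yields bit-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .ipac_classify import InteractionVerdict
from .quant_io import (
    DesignEntry,
    ProteinGroupRecord,
    StudyDesign,
    write_design,
    write_protein_groups,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "ScoreSummary",
    "simulate_dataset",
    "simulate_design",
    "score_against_truth",
    "write_dataset",
    "read_truth",
]

_INTENSITY_SCALE = 100.0  # arbitrary MS-intensity units per abundance unit


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror a two-tag parallel capture with reciprocal labelling
    and duplicate replicates (2 resins x 2 orientations x 2 replicates = 8
    experiments), ~500 detectable protein groups per pull-down, planted
    genuine partners at 4-fold enrichment and per-experiment log2 ratio
    noise of 0.5, with 98% heavy-isotope incorporation.
    """

    seed: int = 0
    n_proteins: int = 500
    n_true_interactors: int = 20
    n_tag_artefacts_per_resin: int = 5
    resins: tuple[str, ...] = ("FLAG", "TALON")
    replicates_per_orientation: int = 2
    log2_enrichment_mean: float = 2.0
    log2_enrichment_sd: float = 0.0
    noise_sd: float = 0.5
    abundance_mu: float = 8.0
    abundance_sigma: float = 1.0
    detection_slope: float = 2.0
    detection_midpoint: float | None = None  # defaults to mu - 2.5*sigma
    incorporation: float = 0.98
    exclusive_rate: float = 0.05
    bait_accession: str = "SIMBAIT001"

    def __post_init__(self) -> None:
        planted = (self.n_true_interactors
                   + self.n_tag_artefacts_per_resin * len(self.resins) + 1)
        if planted > self.n_proteins:
            raise ValueError(
                f"{planted} planted proteins exceed n_proteins={self.n_proteins}"
            )
        if len(self.resins) < 2:
            raise ValueError("parallel capture needs at least two resins")
        if not 0 < self.incorporation <= 1:
            raise ValueError("incorporation must be in (0, 1]")
        for name in ("log2_enrichment_sd", "noise_sd", "abundance_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.exclusive_rate <= 1:
            raise ValueError("exclusive_rate must be in [0, 1]")
        if self.replicates_per_orientation < 1:
            raise ValueError("replicates_per_orientation must be >= 1")

    @property
    def midpoint(self) -> float:
        if self.detection_midpoint is not None:
            return self.detection_midpoint
        return self.abundance_mu - 2.5 * self.abundance_sigma


@dataclass(frozen=True)
class GroundTruth:
    """Planted class, enrichment and sticky resin for every simulated protein."""

    classes: Mapping[str, str]
    log2_enrichment: Mapping[str, float]
    sticky_resin: Mapping[str, str]

    @property
    def proteins(self) -> list[str]:
        return sorted(self.classes)

    def of_class(self, cls: str) -> list[str]:
        return sorted(p for p, c in self.classes.items() if c == cls)


def simulate_design(config: SimulationConfig) -> StudyDesign:
    """Experiment design implied by the configuration (no control-only rows)."""
    entries = []
    for resin in config.resins:
        for orientation, tag in (("tagged_heavy", "H"), ("tagged_light", "L")):
            for rep in range(1, config.replicates_per_orientation + 1):
                entries.append(
                    DesignEntry(
                        experiment_id=f"{resin}_{tag}{rep}",
                        resin=resin,
                        orientation=orientation,
                        replicate=rep,
                        bait_accession=config.bait_accession,
                    )
                )
    return StudyDesign(entries)


def _plant_classes(config: SimulationConfig, rng: np.random.Generator):
    classes: dict[str, str] = {config.bait_accession: "bait"}
    sticky: dict[str, str] = {}
    enrichment: dict[str, float] = {}

    names = [f"SIMP{i:05d}" for i in range(1, config.n_proteins)]
    cursor = 0
    for _ in range(config.n_true_interactors):
        classes[names[cursor]] = "genuine"
        cursor += 1
    for resin in config.resins:
        for _ in range(config.n_tag_artefacts_per_resin):
            classes[names[cursor]] = "tag_specific_artefact"
            sticky[names[cursor]] = resin
            cursor += 1
    for name in names[cursor:]:
        classes[name] = "non_specific"

    for protein, cls in classes.items():
        if cls == "bait":
            # the bait itself is the most enriched species in its pull-down
            enrichment[protein] = config.log2_enrichment_mean + 2.0
        elif cls in ("genuine", "tag_specific_artefact"):
            e = config.log2_enrichment_mean
            if config.log2_enrichment_sd > 0:
                e += config.log2_enrichment_sd * rng.standard_normal()
            enrichment[protein] = max(e, 0.1)
        else:
            enrichment[protein] = 0.0
    return classes, sticky, enrichment


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[list[ProteinGroupRecord], StudyDesign, GroundTruth]:
    """Generate protein-group records, a design and the ground-truth ledger."""
    rng = np.random.default_rng(config.seed)
    design = simulate_design(config)
    classes, sticky, enrichment = _plant_classes(config, rng)
    proteins = sorted(classes)

    abundance = {
        p: math.exp(
            config.abundance_mu + config.abundance_sigma * rng.standard_normal()
        )
        for p in proteins
    }
    # digestible-length proxy driving per-experiment peptide counts
    length = {p: rng.lognormal(math.log(350.0), 0.5) for p in proteins}
    # per-protein loss of the control channel for strongly enriched species
    exclusive = {
        p: (classes[p] != "non_specific"
            and rng.random() < config.exclusive_rate)
        for p in proteins
    }

    i = config.incorporation
    records: list[ProteinGroupRecord] = []
    for entry in design:
        for protein in proteins:
            cls = classes[protein]
            enriched_here = (
                cls in ("bait", "genuine")
                or (cls == "tag_specific_artefact"
                    and sticky[protein] == entry.resin)
            )
            true_ratio = 2.0 ** enrichment[protein] if enriched_here else 1.0
            observed_ratio = true_ratio * 2.0 ** rng.normal(0.0, config.noise_sd)

            base = abundance[protein] * _INTENSITY_SCALE
            tagged = base * observed_ratio
            control = 0.0 if (enriched_here and exclusive[protein]) else base

            if entry.orientation == "tagged_heavy":
                # heavy-grown tagged cells: (1 - i) of their signal leaks light
                intensity_h = i * tagged
                intensity_l = control + (1.0 - i) * tagged
            else:
                intensity_h = i * control
                intensity_l = tagged + (1.0 - i) * control

            signal = (intensity_h + intensity_l) / 2.0 / _INTENSITY_SCALE
            logit = config.detection_slope * (math.log(signal) - config.midpoint)
            p_detect = 1.0 if cls == "bait" else 1.0 / (1.0 + math.exp(-logit))
            if rng.random() >= p_detect:
                continue

            peptides = 1 + int(rng.poisson(length[protein] / 50.0))
            ratio = (
                intensity_h / intensity_l
                if intensity_h > 0 and intensity_l > 0
                else None
            )
            records.append(
                ProteinGroupRecord(
                    group_id=protein,
                    accessions=(protein,),
                    unique_razor_peptides=peptides,
                    experiment_id=entry.experiment_id,
                    ratio_hl=ratio,
                    intensity_h=round(intensity_h, 4),
                    intensity_l=round(intensity_l, 4),
                )
            )

    truth = GroundTruth(
        classes=classes, log2_enrichment=enrichment, sticky_resin=sticky
    )
    return records, design, truth


# ---------------------------------------------------------------------------
# scoring against the planted truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoreSummary:
    """Confusion of planted classes against verdicts.

    ``sensitivity`` is the recall of planted genuine partners;
    ``specificity`` the fraction of planted non-genuine (non-specific plus
    artefact) proteins *not* called genuine; ``false_genuine_rate`` the
    genuine-call rate among planted non-specifics only;
    ``artefact_detection_rate`` the recall of planted tag artefacts.
    Proteins without a verdict (never detected) count as insufficient_data.
    """

    confusion: Mapping[str, Mapping[str, int]]
    sensitivity: float
    specificity: float
    false_genuine_rate: float
    artefact_detection_rate: float


def score_against_truth(
    verdicts: Iterable[InteractionVerdict],
    truth: GroundTruth,
) -> ScoreSummary:
    by_protein = {v.protein: v.verdict for v in verdicts}
    confusion: dict[str, dict[str, int]] = {}
    for protein, planted in truth.classes.items():
        called = by_protein.get(protein, "insufficient_data")
        confusion.setdefault(planted, {}).setdefault(called, 0)
        confusion[planted][called] += 1

    def rate(planted_classes: tuple[str, ...], called: str) -> float:
        total = hits = 0
        for cls in planted_classes:
            for verdict, n in confusion.get(cls, {}).items():
                total += n
                if verdict == called:
                    hits += n
        return hits / total if total else float("nan")

    false_genuine = rate(("non_specific",), "genuine")
    genuine_among_nongenuine = rate(
        ("non_specific", "tag_specific_artefact"), "genuine"
    )
    return ScoreSummary(
        confusion={k: dict(v) for k, v in confusion.items()},
        sensitivity=rate(("genuine",), "genuine"),
        specificity=1.0 - genuine_among_nongenuine,
        false_genuine_rate=false_genuine,
        artefact_detection_rate=rate(
            ("tag_specific_artefact",), "tag_specific_artefact"
        ),
    )


# ---------------------------------------------------------------------------
# on-disk datasets (self-hosting fixtures)
# ---------------------------------------------------------------------------

def write_dataset(
    records: Sequence[ProteinGroupRecord],
    design: StudyDesign,
    truth: GroundTruth,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the dataset through the standard table writers.

    Produces ``protein_groups.tsv`` (long-form MaxQuant-like dialect),
    ``design.tsv`` and ``ground_truth.tsv`` in ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "protein_groups": out_dir / "protein_groups.tsv",
        "design": out_dir / "design.tsv",
        "ground_truth": out_dir / "ground_truth.tsv",
    }
    write_protein_groups(records, paths["protein_groups"])
    write_design(design, paths["design"])
    with open(paths["ground_truth"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("protein\tclass\tlog2_enrichment\tsticky_resin\n")
        for protein in truth.proteins:
            fh.write(
                f"{protein}\t{truth.classes[protein]}\t"
                f"{truth.log2_enrichment[protein]!r}\t"
                f"{truth.sticky_resin.get(protein, '')}\n"
            )
    return paths


def read_truth(path: str | Path) -> GroundTruth:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return GroundTruth(
        classes=dict(zip(df["protein"], df["class"])),
        log2_enrichment={
            p: float(e) for p, e in zip(df["protein"], df["log2_enrichment"])
        },
        sticky_resin={
            p: r for p, r in zip(df["protein"], df["sticky_resin"]) if r
        },
    )
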