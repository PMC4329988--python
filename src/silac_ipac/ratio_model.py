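"""Per-experiment SILAC ratio model.

The statistical core of the scheme: each pull-down experiment mixes lysate
from tagged (bait-expressing) and untagged control cells labelled in
opposite SILAC channels.  Non-specific resin binders come equally from both
cell lines and sit at H/L ~ 1; bait and genuine partners are enriched in the
tagged channel.  Operations here

* orient each H/L ratio onto a common tagged/control axis (so that a
  reciprocal labelling flips sign before orientation and agrees after),
* characterise each experiment's log2 ratio distribution (median, SD, MAD),
* call per-protein significance at ``k`` standard deviations from the
  median, with exclusive (single-channel) detections handled by
  presence/absence logic.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .quant_io import DesignEntry, ProteinGroupRecord

__all__ = [
    "CallStatus",
    "OrientedRatio",
    "RatioDistributionStats",
    "SignificanceCall",
    "InsufficientDataError",
    "orient_ratio",
    "quantification_filter",
    "distribution_stats",
    "call_significance",
]

logger = logging.getLogger(__name__)

MAD_TO_SD = 1.4826  # consistency factor for a normal distribution


class InsufficientDataError(ValueError):
    """Too few quantified proteins to characterise a ratio distribution."""


class CallStatus(str, Enum):
    SIGNIFICANT_ENRICHED = "significant_enriched"
    SIGNIFICANT_DEPLETED = "significant_depleted"
    NOT_SIGNIFICANT = "not_significant"
    EXCLUSIVE_TAGGED = "exclusive_tagged"
    EXCLUSIVE_CONTROL = "exclusive_control"
    UNQUANTIFIED = "unquantified"


@dataclass(frozen=True)
class OrientedRatio:
    """A protein's enrichment in one experiment on the tagged/control axis.

    ``log2_enrichment`` is NaN unless ``quantified``; the exclusive flags are
    mutually exclusive and imply ``quantified`` is False.
    """

    protein: str
    experiment_id: str
    log2_enrichment: float
    quantified: bool
    exclusive_tagged: bool
    exclusive_control: bool
    peptides: int

    def __post_init__(self) -> None:
        if self.quantified and not math.isfinite(self.log2_enrichment):
            raise ValueError("quantified ratio must have finite log2 enrichment")
        if self.exclusive_tagged and self.exclusive_control:
            raise ValueError("exclusive flags are mutually exclusive")
        if (self.exclusive_tagged or self.exclusive_control) and self.quantified:
            raise ValueError("exclusive detection cannot be quantified")


@dataclass(frozen=True)
class RatioDistributionStats:
    """Location/scale summary of one experiment's log2 ratio distribution."""

    experiment_id: str
    n_quantified: int
    median_log2: float
    sd_log2: float
    mad_log2: float

    def scale(self, robust: bool = False) -> float:
        """Dispersion used for calling: sample SD, or 1.4826*MAD if robust."""
        return MAD_TO_SD * self.mad_log2 if robust else self.sd_log2


@dataclass(frozen=True)
class SignificanceCall:
    """Outcome of the +/- k*SD-from-median test for one protein/experiment."""

    protein: str
    experiment_id: str
    status: CallStatus
    z_distance: float | None
    k_used: float
    log2_enrichment: float  # NaN when not quantified


def orient_ratio(
    record: ProteinGroupRecord,
    entry: DesignEntry,
    *,
    exclusive_min_peptides: int = 2,
) -> OrientedRatio:
    """Map one H/L ratio onto the tagged/control axis.

    When the tagged cells were grown heavy, tagged/control = H/L; when grown
    light, tagged/control = L/H, i.e. the log2 enrichment changes sign.  An
    absent ratio with signal only in the tagged channel (and at least
    ``exclusive_min_peptides`` peptides) is an exclusive-tagged detection;
    signal only in the control channel is exclusive-control; anything else
    is unquantified.
    """
    if record.experiment_id != entry.experiment_id:
        raise ValueError(
            f"record experiment {record.experiment_id!r} does not match "
            f"design entry {entry.experiment_id!r}"
        )
    tagged_heavy = entry.orientation == "tagged_heavy"
    if record.ratio_hl is not None:
        log2e = math.log2(record.ratio_hl)
        if not tagged_heavy:
            log2e = -log2e
        return OrientedRatio(
            protein=record.representative,
            experiment_id=record.experiment_id,
            log2_enrichment=log2e,
            quantified=True,
            exclusive_tagged=False,
            exclusive_control=False,
            peptides=record.unique_razor_peptides,
        )
    tagged_int = record.intensity_h if tagged_heavy else record.intensity_l
    control_int = record.intensity_l if tagged_heavy else record.intensity_h
    enough = record.unique_razor_peptides >= exclusive_min_peptides
    exclusive_tagged = enough and tagged_int > 0 and control_int == 0
    exclusive_control = enough and control_int > 0 and tagged_int == 0
    return OrientedRatio(
        protein=record.representative,
        experiment_id=record.experiment_id,
        log2_enrichment=math.nan,
        quantified=False,
        exclusive_tagged=exclusive_tagged,
        exclusive_control=exclusive_control,
        peptides=record.unique_razor_peptides,
    )


def quantification_filter(
    records: Iterable[ProteinGroupRecord],
    min_peptides: int = 2,
) -> list[ProteinGroupRecord]:
    """Keep records with at least ``min_peptides`` unique+razor peptides.

    The conventional floor of two peptides guards against one-hit-wonder
    quantifications.  Dropped records are logged with the reason.
    """
    kept: list[ProteinGroupRecord] = []
    for rec in records:
        if rec.unique_razor_peptides >= min_peptides:
            kept.append(rec)
        else:
            logger.info(
                "dropping group %s in %s: %d unique+razor peptides < %d",
                rec.group_id, rec.experiment_id,
                rec.unique_razor_peptides, min_peptides,
            )
    return kept


def distribution_stats(
    oriented: Sequence[OrientedRatio],
    *,
    min_stats_n: int = 10,
    ddof: int = 1,
) -> RatioDistributionStats:
    """Median, SD and MAD of the quantified log2 enrichments of one experiment.

    The dispersion defaults to the sample standard deviation (``ddof=1``);
    ``ddof=0`` yields the population SD.  Requires at least ``min_stats_n``
    quantified proteins — a pull-down with fewer cannot support a
    distribution-based significance threshold.
    """
    experiments = {o.experiment_id for o in oriented}
    if len(experiments) != 1:
        raise ValueError(f"expected one experiment, got {sorted(experiments)!r}")
    (experiment_id,) = experiments
    values = np.array([o.log2_enrichment for o in oriented if o.quantified])
    if values.size < min_stats_n:
        raise InsufficientDataError(
            f"experiment {experiment_id!r}: {values.size} quantified proteins "
            f"< required {min_stats_n}"
        )
    median = float(np.median(values))
    sd = float(np.std(values, ddof=ddof))
    mad = float(np.median(np.abs(values - median)))
    if sd == 0:
        warnings.warn(
            f"experiment {experiment_id!r}: zero ratio dispersion; "
            "significance calling is impossible",
            stacklevel=2,
        )
    return RatioDistributionStats(
        experiment_id=experiment_id,
        n_quantified=int(values.size),
        median_log2=median,
        sd_log2=sd,
        mad_log2=mad,
    )


def call_significance(
    oriented: OrientedRatio,
    stats: RatioDistributionStats,
    k: float = 1.0,
    *,
    robust: bool = False,
) -> SignificanceCall:
    """Call one protein against its experiment's ratio distribution.

    A quantified protein is significant when its log2 enrichment lies more
    than ``k`` dispersion units from the experiment median (two-sided;
    direction recorded as enriched/depleted).  Exclusive detections pass
    through to their own statuses and carry no z-distance.
    """
    if oriented.experiment_id != stats.experiment_id:
        raise ValueError(
            f"call for {oriented.experiment_id!r} against stats of "
            f"{stats.experiment_id!r}"
        )
    if k <= 0:
        raise ValueError("significance threshold k must be > 0")
    if oriented.exclusive_tagged:
        status, z = CallStatus.EXCLUSIVE_TAGGED, None
    elif oriented.exclusive_control:
        status, z = CallStatus.EXCLUSIVE_CONTROL, None
    elif not oriented.quantified:
        status, z = CallStatus.UNQUANTIFIED, None
    else:
        scale = stats.scale(robust)
        if scale == 0:
            status, z = CallStatus.NOT_SIGNIFICANT, None
        else:
            z = abs(oriented.log2_enrichment - stats.median_log2) / scale
            if z > k:
                status = (
                    CallStatus.SIGNIFICANT_ENRICHED
                    if oriented.log2_enrichment > stats.median_log2
                    else CallStatus.SIGNIFICANT_DEPLETED
                )
            else:
                status = CallStatus.NOT_SIGNIFICANT
    return SignificanceCall(
        protein=oriented.protein,
        experiment_id=oriented.experiment_id,
        status=status,
        z_distance=z,
        k_used=k,
        log2_enrichment=oriented.log2_enrichment,
    )
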