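"""Relative transcript abundance by the 2^-ddCt method.

For each (sample, tissue, target) the replicate cycle thresholds are
averaged, dCt = Ct_target - Ct_reference is formed per tissue against a
housekeeping reference gene (RPL13a by default), ddCt subtracts the
calibrator tissue's dCt (legs by default), and the relative quantity is
RQ = 2^(-ddCt). The calibrator's RQ is exactly 1 for every target by
construction; one cycle of target advantage doubles RQ.

Censoring: an "Undetermined" well is a Ct beyond the instrument's last
cycle (40 by default). Censored replicates are excluded from means; a
group whose replicates are all censored is censored as a whole and any
quantity depending on it is flagged not-quantifiable rather than imputed.
Replicate scatter is reported as the ddCt standard deviation propagated
in quadrature over the four mean Cts involved.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

MAX_CYCLES = 40.0


@dataclass(frozen=True)
class CtRecord:
    """Replicate Ct measurements for one (sample, tissue, target) well group."""

    sample_id: str
    tissue: str
    target_gene: str
    replicate_cts: tuple[Optional[float], ...]  # None marks a censored well
    is_nrt_control: bool = False

    def __post_init__(self) -> None:
        if not self.replicate_cts:
            raise ValueError(
                f"{self.sample_id}/{self.tissue}/{self.target_gene}: no replicates"
            )
        for ct in self.replicate_cts:
            if ct is not None and not (0 < ct <= MAX_CYCLES):
                raise ValueError(
                    f"{self.sample_id}/{self.tissue}/{self.target_gene}: "
                    f"Ct {ct} outside (0, {MAX_CYCLES}]"
                )


@dataclass(frozen=True)
class MeanCt:
    sample_id: str
    tissue: str
    target_gene: str
    mean_ct: Optional[float]  # None when all replicates were censored
    sd: float
    n_replicates: int
    is_nrt_control: bool = False

    @property
    def censored(self) -> bool:
        return self.mean_ct is None


@dataclass(frozen=True)
class RelativeQuantity:
    """2^-ddCt relative abundance of one target in one tissue."""

    sample_id: str
    tissue: str
    target_gene: str
    delta_ct: Optional[float]
    delta_delta_ct: Optional[float]
    rq: Optional[float]
    sd_delta_delta_ct: Optional[float] = None

    @property
    def quantifiable(self) -> bool:
        return self.rq is not None


def aggregate_replicates(records: Sequence[CtRecord]) -> list[MeanCt]:
    """Mean Ct per (sample, tissue, target) over non-censored replicates.

    NRT controls aggregate separately (they are reported, never folded into
    sample means); mixing NRT and sample wells under one key is an error.
    """
    grouped: dict[tuple[str, str, str, bool], list[CtRecord]] = defaultdict(list)
    keys_seen: dict[tuple[str, str, str], set[bool]] = defaultdict(set)
    for rec in records:
        grouped[(rec.sample_id, rec.tissue, rec.target_gene, rec.is_nrt_control)].append(rec)
        keys_seen[(rec.sample_id, rec.tissue, rec.target_gene)].add(rec.is_nrt_control)

    means = []
    for (sample_id, tissue, target, is_nrt), recs in sorted(grouped.items()):
        cts = [ct for rec in recs for ct in rec.replicate_cts]
        observed = [ct for ct in cts if ct is not None]
        if observed:
            mean = sum(observed) / len(observed)
            sd = (
                math.sqrt(sum((c - mean) ** 2 for c in observed) / (len(observed) - 1))
                if len(observed) > 1
                else 0.0
            )
        else:
            mean, sd = None, 0.0
        means.append(
            MeanCt(
                sample_id=sample_id,
                tissue=tissue,
                target_gene=target,
                mean_ct=mean,
                sd=sd,
                n_replicates=len(cts),
                is_nrt_control=is_nrt,
            )
        )
    return means


def ddct(
    target_ct: Optional[float],
    reference_ct: Optional[float],
    calibrator_target_ct: Optional[float],
    calibrator_reference_ct: Optional[float],
    sds: Optional[tuple[float, float, float, float]] = None,
    sample_id: str = "",
    tissue: str = "",
    target_gene: str = "",
) -> RelativeQuantity:
    """Form dCt, ddCt and RQ = 2^(-ddCt) from four mean Cts.

    Any censored input (None) yields a not-quantifiable result with no
    numeric RQ. ``sds`` optionally carries the four mean-Ct standard
    deviations (target, reference, calibrator target, calibrator
    reference) for quadrature propagation.
    """
    inputs = (target_ct, reference_ct, calibrator_target_ct, calibrator_reference_ct)
    if any(v is None for v in inputs):
        return RelativeQuantity(sample_id, tissue, target_gene, None, None, None)
    delta = target_ct - reference_ct
    delta_calibrator = calibrator_target_ct - calibrator_reference_ct
    delta_delta = delta - delta_calibrator
    sd_dd = math.sqrt(sum(s * s for s in sds)) if sds is not None else None
    return RelativeQuantity(
        sample_id=sample_id,
        tissue=tissue,
        target_gene=target_gene,
        delta_ct=delta,
        delta_delta_ct=delta_delta,
        rq=2.0 ** (-delta_delta),
        sd_delta_delta_ct=sd_dd,
    )


def relative_quantities(
    records: Sequence[CtRecord],
    reference_gene: str = "RPL13a",
    calibrator_tissue: str = "legs",
) -> list[RelativeQuantity]:
    """Full 2^-ddCt pipeline: aggregate replicates, then RQ per
    (sample, tissue, target) against the reference gene and calibrator
    tissue of the same sample. NRT controls are excluded."""
    means = aggregate_replicates([r for r in records if not r.is_nrt_control])
    lookup: dict[tuple[str, str, str], MeanCt] = {
        (m.sample_id, m.tissue, m.target_gene): m for m in means
    }
    results = []
    for m in means:
        if m.target_gene == reference_gene:
            continue
        reference = lookup.get((m.sample_id, m.tissue, reference_gene))
        cal_target = lookup.get((m.sample_id, calibrator_tissue, m.target_gene))
        cal_reference = lookup.get((m.sample_id, calibrator_tissue, reference_gene))
        parts = (m, reference, cal_target, cal_reference)
        results.append(
            ddct(
                *(p.mean_ct if p is not None else None for p in parts),
                sds=tuple(p.sd if p is not None else 0.0 for p in parts),
                sample_id=m.sample_id,
                tissue=m.tissue,
                target_gene=m.target_gene,
            )
            if all(p is not None for p in parts)
            else RelativeQuantity(m.sample_id, m.tissue, m.target_gene, None, None, None)
        )
    return results


def rank_glands(
    quantities: Sequence[RelativeQuantity],
    silk_gland_tissues: Optional[Sequence[str]] = None,
) -> list[str]:
    """Order tissues by descending RQ for one target (stable under ties).

    ``silk_gland_tissues`` optionally restricts and pre-orders the panel.
    The top tissue can feed class assignment as expression evidence.
    Raises when no tissue is quantifiable.
    """
    pool = [q for q in quantities if q.quantifiable]
    if silk_gland_tissues is not None:
        allowed = set(silk_gland_tissues)
        order = {t: i for i, t in enumerate(silk_gland_tissues)}
        pool = sorted(
            (q for q in pool if q.tissue in allowed), key=lambda q: order[q.tissue]
        )
    if not pool:
        raise ValueError("no quantifiable tissue for ranking")
    ranked = sorted(pool, key=lambda q: -q.rq)  # sort is stable: ties keep input order
    return [q.tissue for q in ranked]
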