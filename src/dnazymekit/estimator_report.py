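"""Relative kinetics estimation, candidate filtering/ranking, and reports.

When a designed DNAzyme targets a recognition site embedded in a sequence
context different from the one in which the DNAzyme was originally
characterized, its rate and yield are only estimable relative to the
reported data. Three relative figures are emitted, each on a percent scale:

* RRk — relative reported k_obs: 100 * k_obs(matched context) / k_obs(original).
* RRY — relative reported yield: 100 * yield(matched) / yield(original).
* RCY — relative calculated yield: the matched context's own reported
  yield, or — when no characterized context matches — the mean yield over
  contexts within a small Hamming distance of the observed window.

The ``basis`` field records which route produced the numbers so every
estimate is auditable: ``original_context`` (RRk = RRY = 100 by
definition), ``reported_mutant_context``, ``model`` (nearest-context
average), or ``unavailable``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple, Union

from .designer import DesignResult, diagram
from .errors import FilterSpecificationError
from .knowledgebase import ContextEntry, DnazymeRecord, ReactionType
from .scanner import SiteMatch, iupac_match


class EstimateBasis(str, Enum):
    ORIGINAL_CONTEXT = "original_context"
    REPORTED_MUTANT_CONTEXT = "reported_mutant_context"
    MODEL = "model"
    UNAVAILABLE = "unavailable"


@dataclass(frozen=True)
class Estimates:
    rrk_percent: Optional[float]
    rry_percent: Optional[float]
    rcy_percent: Optional[float]
    basis: EstimateBasis
    model_distance: Optional[int] = None  # Hamming threshold used when basis=model


def _ratio(num: Optional[float], den: Optional[float]) -> Optional[float]:
    if num is None or den is None or den <= 0:
        return None
    return 100.0 * num / den


def _context_distance(pattern: str, observed: str) -> Optional[int]:
    """Positions of ``observed`` not matching ``pattern`` (None if lengths differ)."""
    if len(pattern) != len(observed):
        return None
    return sum(0 if iupac_match(p, s) else 1 for p, s in zip(pattern, observed))


def estimate(
    site: SiteMatch, record: DnazymeRecord, model_distance: int = 1
) -> Estimates:
    """Relative rate/yield estimates for a context-classified site.

    A site matching the originally characterized context gets RRk = RRY =
    100 and RCY = that context's yield. A site matching another reported
    context gets ratios to the original. An unmatched site falls back to
    the nearest-context model: RCY is the mean reported yield over the
    record's contexts differing from the observed window at <=
    ``model_distance`` positions (None when none qualify). Records with no
    contexts yield basis=unavailable.
    """
    if not record.contexts:
        return Estimates(None, None, None, EstimateBasis.UNAVAILABLE)
    original = record.original_context()
    matched = site.matched_context
    if matched is not None and matched.is_original:
        return Estimates(
            rrk_percent=100.0,
            rry_percent=100.0,
            rcy_percent=matched.yield_percent,
            basis=EstimateBasis.ORIGINAL_CONTEXT,
        )
    if matched is not None:
        return Estimates(
            rrk_percent=_ratio(matched.k_obs, original.k_obs if original else None),
            rry_percent=_ratio(
                matched.yield_percent, original.yield_percent if original else None
            ),
            rcy_percent=matched.yield_percent,
            basis=EstimateBasis.REPORTED_MUTANT_CONTEXT,
        )
    yields = []
    for ctx in record.contexts:
        d = _context_distance(ctx.context_pattern, site.context_observed)
        if d is not None and d <= model_distance and ctx.yield_percent is not None:
            yields.append(ctx.yield_percent)
    rcy = sum(yields) / len(yields) if yields else None
    return Estimates(
        rrk_percent=None,
        rry_percent=None,
        rcy_percent=rcy,
        basis=EstimateBasis.MODEL,
        model_distance=model_distance,
    )


def attach_estimates(result: DesignResult, model_distance: int = 1) -> DesignResult:
    """Return the design with estimates computed and provenance noted."""
    est = estimate(result.site, result.record, model_distance=model_distance)
    notes = list(result.notes)
    if est.basis is EstimateBasis.MODEL:
        notes.append(
            f"estimates from nearest-context model (Hamming distance <= "
            f"{model_distance})"
        )
    from dataclasses import replace

    return replace(result, estimates=est, notes=tuple(notes))


# ---------------------------------------------------------------------------
# filtering and ranking

class SortKey(str, Enum):
    K_OBS = "k_obs"       # descending, nulls last (default)
    TM = "tm"             # mean arm Tm, descending
    POSITION = "position"  # cleavage position, ascending


@dataclass(frozen=True)
class FilterSpec:
    """User constraints on the candidate list; None means unconstrained."""

    region: Optional[Tuple[int, int]] = None      # cleavage position interval
    arm_length_min: Optional[int] = None
    arm_length_max: Optional[int] = None
    tm_min: Optional[float] = None
    tm_max: Optional[float] = None
    mechanism: Optional[ReactionType] = None
    cofactors: Optional[Tuple[str, ...]] = None
    ph_min: Optional[float] = None
    ph_max: Optional[float] = None
    dnazyme_names: Optional[Tuple[str, ...]] = None
    sort_key: SortKey = SortKey.K_OBS
    max_results: Optional[int] = None


def result_k_obs(result: DesignResult) -> Optional[float]:
    """The k_obs the result is ranked/reported by: matched context first."""
    site = result.site
    if site.matched_context is not None and site.matched_context.k_obs is not None:
        return site.matched_context.k_obs
    original = result.record.original_context()
    return original.k_obs if original else None


def _validate_spec(spec: FilterSpec) -> None:
    def ordered(lo, hi, what):
        if lo is not None and hi is not None and lo > hi:
            raise FilterSpecificationError(f"{what}: min {lo} > max {hi}")

    ordered(spec.tm_min, spec.tm_max, "Tm range")
    ordered(spec.ph_min, spec.ph_max, "pH range")
    ordered(spec.arm_length_min, spec.arm_length_max, "arm length range")
    if spec.region is not None:
        ordered(spec.region[0], spec.region[1], "region")
    if spec.max_results is not None and spec.max_results < 0:
        raise FilterSpecificationError("max_results must be >= 0")


def _passes(result: DesignResult, spec: FilterSpec) -> bool:
    rec = result.record
    arms = result.arms
    if spec.region is not None:
        lo, hi = spec.region
        if not lo <= result.site.cleavage_position <= hi:
            return False
    lengths = (len(arms.arm1), len(arms.arm2))
    if spec.arm_length_min is not None and min(lengths) < spec.arm_length_min:
        return False
    if spec.arm_length_max is not None and max(lengths) > spec.arm_length_max:
        return False
    if spec.tm_min is not None and min(arms.tm1_C, arms.tm2_C) < spec.tm_min:
        return False
    if spec.tm_max is not None and max(arms.tm1_C, arms.tm2_C) > spec.tm_max:
        return False
    if spec.mechanism is not None and rec.reaction_type is not spec.mechanism:
        return False
    if spec.cofactors is not None:
        allowed = {c.lower() for c in spec.cofactors}
        if not any(c.name.lower() in allowed for c in rec.cofactors):
            return False
    if spec.ph_min is not None or spec.ph_max is not None:
        # record's pH window must intersect the requested one
        lo = spec.ph_min if spec.ph_min is not None else float("-inf")
        hi = spec.ph_max if spec.ph_max is not None else float("inf")
        rlo = rec.ph_min if rec.ph_min is not None else float("-inf")
        rhi = rec.ph_max if rec.ph_max is not None else float("inf")
        if rlo > hi or rhi < lo:
            return False
    if spec.dnazyme_names is not None and rec.name not in spec.dnazyme_names:
        return False
    return True


def _tiebreak(result: DesignResult) -> Tuple[str, str, int]:
    return (result.record.name, result.record.variant_id, result.site.rss)


def apply_filters(
    results: Sequence[DesignResult], spec: Optional[FilterSpec] = None
) -> List[DesignResult]:
    """Filter, rank, and truncate one run's design results.

    Every present constraint must hold (the Tm constraint applies to both
    arms; a cofactor constraint passes if any of the record's cofactors is
    allowed; a pH constraint passes if the record's window intersects the
    requested one). Ranking follows ``sort_key`` with nulls last and the
    deterministic tie-break (name, variant, RSS).
    """
    spec = spec or FilterSpec()
    _validate_spec(spec)
    kept = [r for r in results if _passes(r, spec)]

    if spec.sort_key is SortKey.K_OBS:
        def key(r):
            k = result_k_obs(r)
            return (k is None, -(k or 0.0), _tiebreak(r))
    elif spec.sort_key is SortKey.TM:
        def key(r):
            return (-(r.arms.tm1_C + r.arms.tm2_C) / 2.0, _tiebreak(r))
    else:
        def key(r):
            return (r.site.cleavage_position, _tiebreak(r))

    kept.sort(key=key)
    if spec.max_results is not None:
        kept = kept[: spec.max_results]
    return kept


# ---------------------------------------------------------------------------
# reports

SUMMARY_COLUMNS = (
    "name",
    "variant_id",
    "cleavage_position",
    "cofactors",
    "k_obs_per_min",
    "tm_arm1_C",
    "tm_arm2_C",
    "rrk_percent",
    "rry_percent",
    "rcy_percent",
)


def _summary_row(result: DesignResult) -> dict:
    est = result.estimates
    return {
        "name": result.record.name,
        "variant_id": result.record.variant_id,
        "cleavage_position": result.site.cleavage_position,
        "cofactors": ";".join(c.name for c in result.record.cofactors),
        "k_obs_per_min": result_k_obs(result),
        "tm_arm1_C": result.arms.tm1_C,
        "tm_arm2_C": result.arms.tm2_C,
        "rrk_percent": est.rrk_percent if est else None,
        "rry_percent": est.rry_percent if est else None,
        "rcy_percent": est.rcy_percent if est else None,
    }


def write_summary(
    results: Sequence[DesignResult],
    path: Union[str, Path],
    format: str = "csv",
) -> None:
    """Write the candidate table as RFC-4180 CSV or as JSON (same fields)."""
    path = Path(path)
    rows = [_summary_row(r) for r in results]
    fmt = format.lower()
    if fmt == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=SUMMARY_COLUMNS)
            writer.writeheader()
            for row in rows:
                writer.writerow({k: ("" if v is None else v) for k, v in row.items()})
    elif fmt == "json":
        path.write_text(json.dumps(rows, indent=1, sort_keys=True), encoding="utf-8")
    else:
        raise FilterSpecificationError(f"unknown summary format {format!r}")


def detail_document(result: DesignResult) -> dict:
    """The full per-design report as a JSON-serializable document."""
    site = result.site
    rec = result.record
    est = result.estimates
    substrate_seq = result.product_5p.sequence + result.product_3p.sequence
    return {
        "dnazyme": {"name": rec.name, "variant_id": rec.variant_id,
                    "citation": rec.citation},
        "substrate": {
            "sequence": substrate_seq,
            "highlight": {
                "arm1_window": list(result.arms.arm1_window),
                "arm2_window": list(result.arms.arm2_window),
                "rs_start": site.rss,
                "rs_end": site.rss + len(rec.rs_pattern) - 1,
                "cleavage_position": site.cleavage_position,
            },
        },
        "assembly": {
            "full_sequence": result.full_sequence,
            "components": [
                {"label": label, "start": start, "end": end}
                for label, start, end in result.components
            ],
        },
        "products": {
            "product_5p": {"sequence": result.product_5p.sequence,
                           "end5": result.product_5p.end5,
                           "end3": result.product_5p.end3},
            "product_3p": {"sequence": result.product_3p.sequence,
                           "end5": result.product_3p.end5,
                           "end3": result.product_3p.end3},
        },
        "diagram": diagram(result),
        "conditions": result.conditions,
        "kinetics": {
            "k_obs_per_min": result_k_obs(result),
            "matched_context": (
                site.matched_context.context_pattern if site.matched_context else None
            ),
            "context_observed": site.context_observed,
        },
        "estimates": {
            "rrk_percent": est.rrk_percent if est else None,
            "rry_percent": est.rry_percent if est else None,
            "rcy_percent": est.rcy_percent if est else None,
            "basis": est.basis.value if est else None,
            "model_distance": est.model_distance if est else None,
        },
        "notes": list(result.notes),
    }


def write_detail(result: DesignResult, path: Union[str, Path]) -> None:
    """Write one design's detail report as JSON."""
    Path(path).write_text(
        json.dumps(detail_document(result), indent=1, sort_keys=True),
        encoding="utf-8",
    )
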