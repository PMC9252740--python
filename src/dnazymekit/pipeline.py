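"""End-to-end run: read -> sanitize -> scan -> design -> estimate -> report.

`run_pipeline` is the single entry point the CLI wraps; library users can
call it directly with a :class:`RunConfig`. Every run writes a summary
table (CSV and/or JSON), one detail JSON per design, and a run manifest
with the configuration and the counts at each stage, so identical inputs
produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple, Union

from . import __version__
from .designer import ArmSpec, DesignResult, design_site
from .errors import DesignInfeasibleError, DnazymekitError
from .estimator_report import (
    FilterSpec,
    apply_filters,
    attach_estimates,
    write_detail,
    write_summary,
)
from .knowledgebase import KnowledgeBase, load_db
from .scanner import scan_all
from .seqio import (
    SeqFormat,
    SubstrateType,
    convert_type,
    read_sequence,
    reverse_complement,
    sanitize,
)

logger = logging.getLogger("dnazymekit")


@dataclass
class RunConfig:
    """Everything one design run needs; substrate type defaults to DNA."""

    substrate: str                                  # path or literal sequence text
    db_path: Union[str, Path, None] = None
    db: Optional[KnowledgeBase] = None              # takes precedence over db_path
    format_hint: Optional[SeqFormat] = None
    substrate_type: SubstrateType = SubstrateType.DNA
    revcomp: bool = False
    convert_to: Optional[SubstrateType] = None
    arm_spec: Optional[ArmSpec] = None
    filter_spec: Optional[FilterSpec] = None
    model_distance: int = 1
    out_dir: Union[str, Path] = "dnazymekit_out"
    out_formats: Tuple[str, ...] = ("csv", "json")
    write_details: bool = True


@dataclass
class RunOutcome:
    results: List[DesignResult]
    manifest: dict
    summary_paths: List[Path] = field(default_factory=list)
    detail_paths: List[Path] = field(default_factory=list)


def run_pipeline(config: RunConfig) -> RunOutcome:
    """Execute the full design pipeline and write all reports.

    Zero results is a normal outcome (reported, not an error); input,
    database, and configuration problems raise :class:`DnazymekitError`
    subclasses with single-line reasons.
    """
    if config.db is not None:
        db = config.db
    elif config.db_path is not None:
        db = load_db(config.db_path)
    else:
        raise DnazymekitError("a knowledge base (db or db_path) is required")

    stype = SubstrateType(config.substrate_type)
    convert_to = SubstrateType(config.convert_to) if config.convert_to else None
    raw = read_sequence(config.substrate, config.format_hint)
    substrate = sanitize(raw, stype)
    if config.revcomp:
        substrate = reverse_complement(substrate)
    if convert_to is not None:
        substrate = convert_type(substrate, convert_to)

    sites = scan_all(substrate, db)
    results: List[DesignResult] = []
    infeasible = 0
    for site in sites:
        try:
            result = design_site(substrate, site, config.arm_spec)
        except DesignInfeasibleError as exc:
            logger.info("site at RSS %d (%s) infeasible: %s",
                        site.rss, site.record.name, exc)
            infeasible += 1
            continue
        results.append(attach_estimates(result, config.model_distance))

    filtered = apply_filters(results, config.filter_spec)

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outcome = RunOutcome(results=filtered, manifest={})
    for fmt in config.out_formats:
        path = out_dir / f"summary.{fmt.lower()}"
        write_summary(filtered, path, fmt)
        outcome.summary_paths.append(path)
    if config.write_details:
        for i, result in enumerate(filtered, start=1):
            path = out_dir / (
                f"detail_{i:03d}_{result.record.name}_rss{result.site.rss}.json"
            )
            write_detail(result, path)
            outcome.detail_paths.append(path)

    manifest = {
        "tool": "dnazymekit",
        "tool_version": __version__,
        "db_version": db.version,
        "db_source": db.source,
        "substrate_id": substrate.id,
        "substrate_length": substrate.length,
        "substrate_type": substrate.substrate_type.value,
        "removed_characters": len(substrate.removed),
        "config": {
            "revcomp": config.revcomp,
            "convert_to": convert_to.value if convert_to else None,
            "arm_spec": {
                "length": config.arm_spec.length if config.arm_spec else None,
                "target_tm": config.arm_spec.target_tm if config.arm_spec else None,
            },
            "model_distance": config.model_distance,
        },
        "counts": {
            "db_records": len(db),
            "sites_scanned": len(sites),
            "designs": len(results),
            "design_infeasible": infeasible,
            "after_filters": len(filtered),
        },
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True), encoding="utf-8"
    )
    outcome.manifest = manifest
    return outcome
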