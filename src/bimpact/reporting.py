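"""Report writers: published-table-style CSV, JSON result documents, manifests.

All monetary cells in reports are integer QAR (unit-cost tables keep two
decimals); the CSV layout mirrors a published BIA table — year, N, per-arm
costs, scenario totals, incremental, per-patient, affordability — with a
final cumulative line, so side-by-side diffing against a printed table is
trivial.
"""

from __future__ import annotations

import datetime
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from . import __version__
from .engine import BudgetImpactResult
from .model import ModelSpec, convert_currency
from .sensitivity import SpiderDataset, spider_series

log = logging.getLogger("bimpact")


def result_frame_with_total(result: BudgetImpactResult) -> pd.DataFrame:
    frame = result.to_frame()
    total = {col: "" for col in frame.columns}
    total.update(year="cumulative", incremental=round(result.cumulative))
    return pd.concat([frame, pd.DataFrame([total])], ignore_index=True)


def result_to_json_doc(result: BudgetImpactResult, spec: ModelSpec) -> dict:
    """JSON-ready result document, including the USD cumulative figure."""
    return {
        "spec_digest": result.spec_digest,
        "currency": spec.currency.reporting_currency,
        "rows": [
            {
                "year": r.year,
                "n": r.n,
                "arm_costs": {a: round(c) for a, c in r.arm_costs.items()},
                "projected_total": round(r.projected_total),
                "baseline_total": round(r.baseline_total),
                "incremental": round(r.incremental),
                "per_patient": r.per_patient,
                "affordability": r.affordability.value,
            }
            for r in result.rows
        ],
        "cumulative": round(result.cumulative),
        "cumulative_usd": convert_currency(result.cumulative, spec.currency),
        "threshold": spec.threshold.effective,
    }


def write_result(
    result: BudgetImpactResult,
    spec: ModelSpec,
    output_dir: Path,
    stem: str = "budget_impact",
) -> List[Path]:
    output_dir.mkdir(parents=True, exist_ok=True)
    csv_path = output_dir / f"{stem}.csv"
    json_path = output_dir / f"{stem}.json"
    result_frame_with_total(result).to_csv(csv_path, index=False)
    json_path.write_text(
        json.dumps(result_to_json_doc(result, spec), indent=2) + "\n",
        encoding="utf-8",
    )
    log.info("wrote %s and %s", csv_path, json_path)
    return [csv_path, json_path]


def write_spider(
    dataset: SpiderDataset, output_dir: Path, stem: str = "sensitivity"
) -> List[Path]:
    """Long-format spider CSV: (axis_id, level, year|'cumulative', value_qar)."""
    output_dir.mkdir(parents=True, exist_ok=True)
    frame = pd.concat(
        [spider_series(dataset, "cumulative"), spider_series(dataset, "by_year")],
        ignore_index=True,
    )
    frame["value_qar"] = frame["value_qar"].round().astype("int64")
    path = output_dir / f"{stem}.csv"
    frame.to_csv(path, index=False)
    log.info("wrote %s", path)
    return [path]


def write_manifest(
    output_dir: Path,
    subcommand: str,
    outputs: List[Path],
    spec_path: Optional[Path] = None,
    spec_digest: str = "",
) -> Path:
    manifest = {
        "tool": "bimpact",
        "version": __version__,
        "subcommand": subcommand,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "spec_path": str(spec_path) if spec_path else None,
        "spec_digest": spec_digest,
        "outputs": [str(p) for p in outputs],
    }
    path = output_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return path
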