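"""Batch screening of candidate networks and ranking-table reports.

A screen runs the full phenotype-query battery over a family of networks
(an edge template's admissible subnetworks, or an explicit list) and
produces one row per network with the four prevalence percentages used to
rank switching robustness: full/partial path x resettable bistability /
hysteresis.  Screens are deterministic and checkpointed, so an
interrupted batch resumes without recomputation.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .network import RegulatoryNetwork, enumerate_template_subnetworks, NetworkTemplate, validate_network
from .queries import PhenotypeConfig, compute_prevalence

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1

#: Fixed column order of screen CSVs.
COLUMNS = [
    "network_id",
    "edges",
    "query_node",
    "orientation",
    "n_copies",
    "n_full_paths",
    "n_partial_paths",
    "resettable_full_pct",
    "resettable_partial_pct",
    "hysteresis_full_pct",
    "hysteresis_partial_pct",
    "resettable_full_pct_by_copy",
    "resettable_partial_pct_by_copy",
    "hysteresis_full_pct_by_copy",
    "hysteresis_partial_pct_by_copy",
    "error",
    "runtime_s",
]


@dataclass
class ScreenConfig:
    """What to screen and how.

    Exactly one of ``template`` / ``networks`` must be given.  The
    normalization recorded in the ``*_pct`` columns is selected by
    ``normalization`` ("by_pair" or "by_copy"); both are always computed.
    """

    phenotype: PhenotypeConfig
    template: NetworkTemplate | None = None
    networks: dict[str, RegulatoryNetwork] | None = None
    normalization: str = "by_pair"
    output_dir: Path | None = None
    checkpoint: bool = True

    def __post_init__(self):
        if (self.template is None) == (self.networks is None):
            raise ValueError("exactly one of template / networks must be set")

    def network_items(self) -> list[tuple[str, RegulatoryNetwork]]:
        if self.networks is not None:
            return list(self.networks.items())
        subs = enumerate_template_subnetworks(self.template)
        width = len(str(len(subs) - 1))
        return [(f"net{i:0{width}d}", n) for i, n in enumerate(subs)]


def _row_for(name: str, net: RegulatoryNetwork, cfg: ScreenConfig) -> dict:
    t0 = time.perf_counter()
    row = {c: None for c in COLUMNS}
    row["network_id"] = name
    row["edges"] = " ".join(str(e) for e in net.edges)
    problems = validate_network(net)
    if problems:
        row["error"] = "; ".join(problems)
        row["runtime_s"] = round(time.perf_counter() - t0, 4)
        return row
    try:
        rep = compute_prevalence(net, cfg.phenotype, name=name)
    except Exception as exc:  # a per-network failure never aborts the batch
        row["error"] = f"{type(exc).__name__}: {exc}"
        row["runtime_s"] = round(time.perf_counter() - t0, 4)
        return row
    row["query_node"] = rep.query_node
    row["orientation"] = rep.orientation
    row["n_copies"] = rep.n_copies
    row["n_full_paths"] = rep.n_full_paths
    row["n_partial_paths"] = rep.n_partial_paths
    for norm, suffix in (("by_pair", ""), ("by_copy", "_by_copy")):
        row[f"resettable_full_pct{suffix}"] = rep.percentage("resettable_qs", "full", norm)
        row[f"resettable_partial_pct{suffix}"] = rep.percentage("resettable_qs", "partial", norm)
        row[f"hysteresis_full_pct{suffix}"] = rep.percentage("hysteresis", "full", norm)
        row[f"hysteresis_partial_pct{suffix}"] = rep.percentage("hysteresis", "partial", norm)
    if cfg.normalization == "by_copy":
        for col in ("resettable_full_pct", "resettable_partial_pct",
                    "hysteresis_full_pct", "hysteresis_partial_pct"):
            row[col] = row[col + "_by_copy"]
    row["error"] = ""
    row["runtime_s"] = round(time.perf_counter() - t0, 4)
    return row


def run_screen(cfg: ScreenConfig) -> pd.DataFrame:
    """One row per network; deterministic content, checkpointed.

    The checkpoint file (``screen_checkpoint.json`` under the output
    directory) stores finished rows keyed by network id; reruns skip them.
    """
    items = cfg.network_items()
    done: dict[str, dict] = {}
    ckpt_path = None
    if cfg.output_dir is not None and cfg.checkpoint:
        cfg.output_dir = Path(cfg.output_dir)
        cfg.output_dir.mkdir(parents=True, exist_ok=True)
        ckpt_path = cfg.output_dir / "screen_checkpoint.json"
        if ckpt_path.exists():
            done = json.loads(ckpt_path.read_text())
            log.info("resuming screen: %d rows from checkpoint", len(done))
    rows = []
    for name, net in items:
        if name in done:
            rows.append(done[name])
            continue
        log.info("screening %s", name)
        row = _row_for(name, net, cfg)
        log.info("%s done in %.2fs", name, row["runtime_s"])
        rows.append(row)
        done[name] = row
        if ckpt_path is not None:
            ckpt_path.write_text(json.dumps(done, indent=1))
    return pd.DataFrame(rows, columns=COLUMNS)


def write_reports(rows: pd.DataFrame, output_dir, formats=("csv", "json")) -> list[Path]:
    """Write the screen table as CSV and schema-versioned JSON, plus the
    prevalence-bin histogram summary."""
    if rows.empty:
        raise ValueError("no rows to report")
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    written = []
    if "csv" in formats:
        p = output_dir / "screen.csv"
        rows.to_csv(p, index=False)
        written.append(p)
    if "json" in formats:
        p = output_dir / "screen.json"
        payload = {"schema_version": SCHEMA_VERSION, "rows": rows.to_dict(orient="records")}
        p.write_text(json.dumps(payload, indent=1))
        written.append(p)
    p = output_dir / "histograms.csv"
    histogram_summary(rows).to_csv(p, index=False)
    written.append(p)
    return written


def read_report_json(path) -> pd.DataFrame:
    payload = json.loads(Path(path).read_text())
    return pd.DataFrame(payload["rows"], columns=COLUMNS)


def histogram_summary(rows: pd.DataFrame, bin_width: float = 10.0) -> pd.DataFrame:
    """Counts of networks per prevalence bin for each of the four queries."""
    out = []
    edges = [i * bin_width for i in range(int(100 / bin_width) + 1)]
    for col in ("hysteresis_full_pct", "hysteresis_partial_pct",
                "resettable_full_pct", "resettable_partial_pct"):
        vals = rows[col].dropna()
        positive = vals[vals > 0]
        record = {"query": col, "n_networks": len(vals), "n_positive": int((vals > 0).sum())}
        for lo, hi in zip(edges[:-1], edges[1:]):
            n = int(((positive > lo) & (positive <= hi)).sum())
            record[f"({lo:g},{hi:g}]"] = n
        out.append(record)
    return pd.DataFrame(out)
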