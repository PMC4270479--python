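"""End-to-end analysis pipeline: decompose → trajectories → (optional) ordering.

All thresholds default to the analysis conventions of the spectral-tuning
study: per-step gradualness at |Δλ| < 25 nm, variance split at Δλ > 30 nm,
and a 5-nm cutoff for reporting large interaction terms.  Every report embeds
the configuration (and its hash), so two runs with identical configs produce
identical numerical content.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

from . import io as sio
from .landscape import (
    attach_uncertainty,
    bit_count,
    decompose,
    Landscape,
)
from .ordering import (
    CharacterMatrix,
    TimedTree,
    linear_extensions,
    partial_orders,
    place_substitutions,
)
from .trajectories import (
    BRUTE_FORCE_LIMIT,
    classify_by_step,
    constrained_paths,
    count_accessible,
    enumerate_trajectories,
    path_variance_distribution,
)

logger = logging.getLogger("spectune")


@dataclass
class RunConfig:
    """Inputs, thresholds and provenance for one pipeline run."""

    landscape_path: Optional[str] = None
    tree_path: Optional[str] = None
    characters_path: Optional[str] = None
    focal_tip: str = "human"
    step_threshold_nm: float = 25.0
    split_threshold_nm: float = 30.0
    theta_report_cutoff_nm: float = 5.0
    pop_variance: bool = False        # population (n) instead of sample (n−1)
    bh_adjust: bool = False
    seed: int = 0
    outdir: str = "results"

    def __post_init__(self) -> None:
        for name in ("step_threshold_nm", "split_threshold_nm",
                     "theta_report_cutoff_nm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @property
    def ddof(self) -> int:
        return 0 if self.pop_variance else 1

    def as_dict(self) -> Dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        payload = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(config: RunConfig,
                 landscape: Optional[Landscape] = None) -> Dict:
    """Run the full analysis and write the report bundle to ``config.outdir``.

    Emits effects.tsv, trajectories.tsv and summary.json.  Returns the summary
    dict.  A landscape object may be passed directly instead of a path.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if landscape is None:
        if config.landscape_path is None:
            raise ValueError("run_pipeline needs a landscape (path or object)")
        logger.info("parsing landscape from %s", config.landscape_path)
        landscape = sio.parse_landscape(config.landscape_path)

    sites = landscape.sites
    logger.info("decomposing %d-site landscape (%d genotypes, %d nonfunctional)",
                sites.L, len(landscape.records), landscape.n_nonfunctional())
    effects, completed = decompose(landscape)
    attach_uncertainty(effects, completed, bh_adjust=config.bh_adjust)
    sio.write_effect_table(effects, outdir / "effects.tsv")

    big_interactions = sorted(
        ("+".join(sites.labels_of(m)) for m in effects.theta
         if bit_count(m) >= 2
         and abs(effects.theta[m]) >= config.theta_report_cutoff_nm),
    )

    summary = count_accessible(landscape, threshold_nm=config.step_threshold_nm,
                               ddof=config.ddof)
    logger.info("trajectories: %d total, %d accessible (%.2f%%)",
                summary.total, summary.accessible,
                100 * summary.fraction_accessible)

    report = {
        "config": config.as_dict(),
        "config_hash": config.digest(),
        "seed": config.seed,
        "sites": list(sites.labels),
        "lambda_anc_nm": landscape.lambda_anc,
        "n_genotypes": len(landscape.records),
        "n_nonfunctional": landscape.n_nonfunctional(),
        "trajectories": {
            "total": summary.total,
            "accessible": summary.accessible,
            "terminated": summary.terminated,
            "fraction_accessible": summary.fraction_accessible,
            "per_first_mutation": summary.per_first_mutation,
            "step_class_counts": summary.step_class_counts,
        },
        "interactions_ge_cutoff": big_interactions,
        "n_interactions_ge_cutoff": len(big_interactions),
    }

    if sites.L <= BRUTE_FORCE_LIMIT:
        paths = list(enumerate_trajectories(landscape, ddof=config.ddof))
        sio.write_trajectory_report(paths, outdir / "trajectories.tsv")
        split = path_variance_distribution(
            landscape, split_threshold_nm=config.split_threshold_nm,
            ddof=config.ddof)
        report["variance_split"] = {
            "threshold_nm": config.split_threshold_nm,
            "n_without_large_step": int(split.without_large_step.size),
            "n_with_large_step": int(split.with_large_step.size),
            "mean_var_without": (float(split.without_large_step.mean())
                                 if split.without_large_step.size else None),
            "mean_var_with": (float(split.with_large_step.mean())
                              if split.with_large_step.size else None),
        }

    if config.tree_path and config.characters_path:
        logger.info("ordering substitutions on %s", config.tree_path)
        tree = TimedTree.from_newick(
            Path(config.tree_path).read_text(encoding="utf-8"),
            focal_tip=config.focal_tip)
        chars = CharacterMatrix.from_csv(config.characters_path)
        placement = place_substitutions(tree, chars)
        orders = partial_orders(placement)
        report["ordering"] = {
            "placements": {s: list(b) for s, b in placement.branches.items()},
            "notes": placement.notes,
            "partial_orders": [[sorted(g) for g in po.groups] for po in orders],
            "n_consistent_orderings": [linear_extensions(po) for po in orders],
        }
        if len(orders) == 1:
            cpaths = constrained_paths(landscape, orders[0], effects=effects,
                                       ddof=config.ddof)
            sio.write_trajectory_report(
                [(c.trajectory, c.profile) for c in cpaths],
                outdir / "constrained_paths.tsv")
            report["ordering"]["n_constrained_paths"] = len(cpaths)

    sio.write_json(report, outdir / "summary.json")
    return report


def setup_logging(debug: bool = False) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if debug else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )
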