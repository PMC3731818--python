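"""TSV report writers tying the pipeline stages together.

Every report starts with ``#``-prefixed metadata lines (tool version, seed,
configuration) so a run is reproducible bit-for-bit from its own header.
"""

from __future__ import annotations

import logging
from pathlib import Path

from . import __version__
from .cluster import HoxCluster, HoxValidationError, cluster_stats
from .mutants import Scenario, classify_scenario, packaged_scenarios, _scenario_from_row
from .noise import NoiseSpec, compare_organisms

__all__ = ["run_table1", "run_table2_style", "run_scenarios"]

logger = logging.getLogger(__name__)


def _header(**meta) -> list[str]:
    lines = [f"# hoxphys {__version__}"]
    lines += [f"# {key} = {value}" for key, value in meta.items()]
    return lines


def run_table1(clusters: list[HoxCluster]) -> str:
    """Distance statistics (total/mean/population variance) per cluster."""
    if not clusters:
        raise HoxValidationError("no clusters supplied")
    lines = _header(report="cluster-stats")
    lines.append("organism\tn_genes\tn_distances\ttotal_kbp\tmean_kbp\tvariance_kbp2")
    for cluster in clusters:
        stats = cluster_stats(cluster)
        lines.append(
            f"{cluster.organism}\t{len(cluster.genes)}\t"
            f"{len(cluster.distances_kbp)}\t{stats.total_kbp:g}\t"
            f"{stats.mean_kbp:.3f}\t{stats.variance_kbp2:.3f}"
        )
    return "\n".join(lines) + "\n"


def run_table2_style(
    clusters: list[HoxCluster],
    noise: NoiseSpec,
    l: float = 100.0,
) -> str:
    """Noise-experiment report: pooled stats, closed-form oracle, ranking.

    The header records the noise model and notes that only the variance
    ordering across cluster geometries — not any particular printed variance
    value — is the reproducible claim: the noise amplitude calibration is a
    free choice.
    """
    comparison = compare_organisms(list(clusters), l, noise)
    lines = _header(
        report="fpr-noise",
        model=noise.model,
        level=noise.level,
        realizations=noise.realizations_R,
        seed=noise.seed,
        ideal_length_l=l,
        note=(
            "only the variance ordering across cluster geometries is "
            "contractual; absolute variances depend on the noise-amplitude "
            "calibration"
        ),
    )
    lines.append(
        "organism\tn_segments\ttotal_kbp\tpooled_mean\tpooled_variance\t"
        "theoretical_variance"
    )
    for row in comparison.rows:
        lines.append(
            f"{row['organism']}\t{row['n_segments']}\t{row['total_kbp']:g}\t"
            f"{row['pooled_mean']:.3f}\t{row['pooled_variance']:.3f}\t"
            f"{row['theoretical_variance']:.3f}"
        )
    lines.append("# variance ranking (low to high): " + " < ".join(comparison.ranking))
    return "\n".join(lines) + "\n"


def run_scenarios(
    cluster: HoxCluster, scenario_path: str | Path | None = None
) -> tuple[str, int]:
    """Run manipulation scenarios; returns (TSV report, mismatch count).

    Malformed scenario rows are logged with their line number and skipped;
    the run continues.
    """
    import csv

    if scenario_path is None:
        scenarios: list[tuple[int, Scenario | None, str]] = [
            (i + 1, s, "") for i, s in enumerate(packaged_scenarios())
        ]
    else:
        scenarios = []
        with open(scenario_path, newline="") as fh:
            visible = [
                (i + 1, line)
                for i, line in enumerate(fh)
                if line.strip() and not line.startswith("#")
            ]
        if visible:
            reader = csv.DictReader(
                (line for _, line in visible), delimiter="\t"
            )
            for (lineno, _), row in zip(visible[1:], reader):
                try:
                    scenarios.append((lineno, _scenario_from_row(row), ""))
                except (HoxValidationError, KeyError, ValueError) as exc:
                    logger.warning("scenario line %d skipped: %s", lineno, exc)
                    scenarios.append((lineno, None, str(exc)))

    lines = _header(report="mutant-predict", cluster=cluster.organism)
    lines.append(
        "scenario_id\tprobe\texpected\tcomputed\tsecondary\tmatch\trationale"
    )
    mismatches = 0
    for lineno, scenario, err in scenarios:
        if scenario is None:
            continue
        outcome = classify_scenario(cluster, scenario)
        match = outcome.matches(
            scenario.expected_verdict, scenario.expected_secondary
        )
        if not match:
            mismatches += 1
        expected = scenario.expected_verdict.value + (
            f"+{scenario.expected_secondary.value}"
            if scenario.expected_secondary
            else ""
        )
        computed = outcome.verdict.value
        lines.append(
            f"{scenario.scenario_id}\t{scenario.probe}\t{expected}\t{computed}\t"
            f"{outcome.secondary.value if outcome.secondary else ''}\t"
            f"{'yes' if match else 'NO'}\t{outcome.rationale}"
        )
    return "\n".join(lines) + "\n", mismatches
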