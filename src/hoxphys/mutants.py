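"""Cluster-manipulation algebra and qualitative mutant-expression verdicts.

Deletions, duplications and splittings act on the fiber bookkeeping of a
cluster: a deletion removes Kbp (and hence charge N, which is spread over
the whole cluster), a tandem duplication adds it, and a posterior split
removes the anchored 5' end of the elastic-spring analogue.  The verdicts
are qualitative — the experimental claims being modeled are qualitative —
and each classifier records the comparison that decided it.

For anterior deletions the decisive comparison is between the mutant
extruded fiber length E (driven by the reduced force F_c on the
post-deletion elasticity profile) and the naively shortened wild-type
length L - D:

* |E - (L-D)| small      -> case 1, expression unchanged;
* E > (L-D)              -> case 2, premature anteriorization — with a
  marked expression gain when the overshoot is large, because the probe can
  retreat toward the CT/ICD border where activation peaks;
* E < (L-D)              -> case 3, the probe stays inside the chromosome
  territory and is silenced (for the most posterior gene no compensating
  posteriorization is available).

Posterior edits follow the F = P·N compensation logic directly: a deletion
lowers N, so P (hence position/time) must rise — delayed posteriorization;
a duplication raises N, anteriorizing the probe while pushing it past the
transcription factory — downregulation.  Removing the fixed end leaves the
spring loose at both ends, so the remaining genes anteriorize; an inversion
sparing the small anchor region between Evx2 and Hoxd13 leaves expression
unchanged.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from enum import Enum
from importlib import resources

from .biophysics import ElasticityProfile
from .cluster import HoxCluster, HoxGene, HoxValidationError, cluster_span

__all__ = [
    "Verdict",
    "Manipulation",
    "Outcome",
    "Scenario",
    "DEFAULT_I_KBP",
    "SCENARIO_PROFILES",
    "apply_manipulation",
    "deletion_extent",
    "classify_anterior_deletion",
    "classify_posterior_edit",
    "classify_split",
    "packaged_scenarios",
    "run_packaged_scenarios",
    "anterior_deletion_case",
]

logger = logging.getLogger(__name__)

# Length of the named intergenic region "i" between genes 4 and 8 (Kbp).
# Its true extent is not part of the packaged distance tables; it is modeled
# as the stretch immediately anterior to gene 8.
DEFAULT_I_KBP = 10.0


class Verdict(str, Enum):
    UNCHANGED = "UNCHANGED"
    ANTERIORIZED = "ANTERIORIZED"
    ANTERIORIZED_WITH_GAIN = "ANTERIORIZED_WITH_GAIN"
    POSTERIORIZED_DELAYED = "POSTERIORIZED_DELAYED"
    SILENCED = "SILENCED"
    DOWNREGULATED = "DOWNREGULATED"


@dataclass(frozen=True)
class Manipulation:
    """A cluster edit: deletion, duplication or split/inversion.

    ``gene_start``/``gene_end`` bound the edited gene range (inclusive);
    ``include_i`` adds the named intergenic region "i" (between genes 4 and
    8) to a deletion; a pure del(i) has no gene range at all.
    """

    kind: str  # deletion | duplication | split_inversion
    gene_start: int | None = None
    gene_end: int | None = None
    include_i: bool = False
    removes_fixed_end: bool = False
    includes_evx2_boundary: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("deletion", "duplication", "split_inversion"):
            raise HoxValidationError(f"unknown manipulation kind {self.kind!r}")
        if (self.gene_start is None) != (self.gene_end is None):
            raise HoxValidationError("gene_start and gene_end must come together")
        if self.gene_start is not None and self.gene_end < self.gene_start:
            raise HoxValidationError("gene_end must be >= gene_start")
        if self.kind == "deletion" and self.gene_start is None and not self.include_i:
            raise HoxValidationError("a deletion needs a gene range and/or region i")
        if self.kind == "duplication" and self.gene_start is None:
            raise HoxValidationError("a duplication needs a gene range")


@dataclass(frozen=True)
class Outcome:
    verdict: Verdict
    case_label: str  # case1 | case2 | case3 | posterior_rule | split_rule | none
    rationale: str
    secondary: Verdict | None = None
    probe: int | None = None

    def matches(self, verdict: Verdict, secondary: Verdict | None = None) -> bool:
        return self.verdict is verdict and self.secondary is secondary


# ---------------------------------------------------------------------------
# Fiber bookkeeping
# ---------------------------------------------------------------------------

def _gene_index(cluster: HoxCluster, number: int) -> int:
    for i, g in enumerate(cluster.genes):
        if g.number == number:
            return i
    raise HoxValidationError(f"gene {number} not in cluster {cluster.organism!r}")


def _i_region_interval(cluster: HoxCluster, i_kbp: float) -> tuple[float, float]:
    """Fiber interval of the named region "i": just anterior to gene 8."""
    numbers = cluster.gene_numbers
    if 4 not in numbers or 8 not in numbers:
        raise HoxValidationError("region i needs genes 4 and 8 in the cluster")
    i4, i8 = _gene_index(cluster, 4), _gene_index(cluster, 8)
    if i8 != i4 + 1:
        raise HoxValidationError("region i lies between adjacent genes 4 and 8")
    if cluster.distances_kbp[i4] <= i_kbp:
        raise HoxValidationError(
            f"region i ({i_kbp} Kbp) does not fit inside d(4,8)="
            f"{cluster.distances_kbp[i4]} Kbp"
        )
    end = cluster.gene_position_kbp(8)
    return end - i_kbp, end


def deletion_extent(
    cluster: HoxCluster, m: Manipulation, i_kbp: float = DEFAULT_I_KBP
) -> tuple[float, float]:
    """Fiber interval [start, end] removed by a deletion (Kbp coordinates)."""
    if m.kind != "deletion":
        raise HoxValidationError("deletion_extent applies to deletions only")
    if m.gene_start is None:
        return _i_region_interval(cluster, i_kbp)
    start = cluster.gene_position_kbp(m.gene_start)
    end = cluster.gene_position_kbp(m.gene_end)
    end += cluster.genes[_gene_index(cluster, m.gene_end)].length_kbp
    if m.include_i:
        i_lo, i_hi = _i_region_interval(cluster, i_kbp)
        if not (i_hi <= start or abs(i_hi - start) < 1e-9):
            raise HoxValidationError("region i must be adjacent-anterior to the range")
        start = i_lo
    return start, end


def apply_manipulation(
    cluster: HoxCluster, m: Manipulation, i_kbp: float = DEFAULT_I_KBP
) -> HoxCluster:
    """Return the mutant cluster with its fiber bookkeeping updated.

    Deletions remove the region's Kbp and merge flanking distances, so the
    charge N of the mutant follows the reduced span.  Duplications insert a
    tandem copy adjacent to the original (zero-length junction), increasing
    the span by the copied extent; deleting the copy restores the original.
    A split/inversion that removes the fixed end unsets the 5' anchor and
    leaves the span unchanged.
    """
    if m.kind == "split_inversion":
        removes = m.removes_fixed_end or m.includes_evx2_boundary
        return cluster.with_fixed_end(cluster.fixed_posterior_end and not removes)

    if m.kind == "deletion":
        genes = list(cluster.genes)
        distances = list(cluster.distances_kbp)
        if m.gene_start is not None:
            lo, hi = _gene_index(cluster, m.gene_start), _gene_index(cluster, m.gene_end)
            if lo == 0 or hi == len(genes) - 1:
                # flanking merge needs a surviving gene on both sides
                raise HoxValidationError(
                    "deletion must leave genes on both sides of the region"
                )
            merged = distances[lo - 1] + distances[hi]
            genes[lo : hi + 1] = []
            distances[lo - 1 : hi + 1] = [merged]
        if m.include_i or m.gene_start is None:
            mutant_numbers = [g.number for g in genes]
            if 4 not in mutant_numbers:
                raise HoxValidationError("region i needs gene 4 to survive")
            i4 = mutant_numbers.index(4)
            if distances[i4] <= i_kbp:
                raise HoxValidationError("region i exceeds the remaining stretch")
            distances[i4] -= i_kbp
        return replace(
            cluster,
            genes=tuple(genes),
            distances_kbp=tuple(distances),
            relaxed=True,
        )

    # duplication: tandem copy of genes a..b inserted right after b
    lo, hi = _gene_index(cluster, m.gene_start), _gene_index(cluster, m.gene_end)
    genes = list(cluster.genes)
    distances = list(cluster.distances_kbp)
    copy = [
        HoxGene(number=g.number, label=g.label + "'", length_kbp=g.length_kbp)
        for g in genes[lo : hi + 1]
    ]
    internal = list(distances[lo:hi])
    genes[hi + 1 : hi + 1] = copy
    # zero-length junction between the original b and the copied a
    distances[hi:hi] = [0.0] + internal
    return replace(
        cluster, genes=tuple(genes), distances_kbp=tuple(distances), relaxed=True
    )


# ---------------------------------------------------------------------------
# Classifiers
# ---------------------------------------------------------------------------

def anterior_deletion_case(
    E: float, L: float, D: float, eta: float = 0.05, gain_eta: float = 0.10
) -> tuple[str, Verdict]:
    """Decide the anterior-deletion case from E vs (L - D).

    The partition is exhaustive and mutually exclusive for any eta > 0; the
    boundary |E-(L-D)| = eta*L counts as case 1.
    """
    if eta <= 0 or gain_eta <= eta:
        raise HoxValidationError("need 0 < eta < gain_eta")
    diff = E - (L - D)
    if abs(diff) <= eta * L:
        return "case1", Verdict.UNCHANGED
    if diff > 0:
        if diff > gain_eta * L:
            return "case2", Verdict.ANTERIORIZED_WITH_GAIN
        return "case2", Verdict.ANTERIORIZED
    return "case3", Verdict.SILENCED


def classify_anterior_deletion(
    wt: HoxCluster,
    m: Manipulation,
    probe: int,
    profile: ElasticityProfile,
    eta: float = 0.05,
    gain_eta: float = 0.10,
    i_kbp: float = DEFAULT_I_KBP,
) -> Outcome:
    """Classify an anterior deletion's effect on ``probe`` expression.

    The wild-type force is calibrated as the quasi-static work needed to
    extrude the fiber to the probe (L) on the wild-type profile; the mutant
    force F_c is that force scaled by the charge ratio (span-D)/span, and E
    is the extrusion F_c achieves on the post-deletion profile.
    """
    if m.kind != "deletion":
        raise HoxValidationError("classify_anterior_deletion needs a deletion")
    start, end = deletion_extent(wt, m, i_kbp)
    L = wt.gene_position_kbp(probe)
    if end > L + 1e-9:
        raise HoxValidationError(
            f"deleted region [{start:g}, {end:g}] is not anterior to probe "
            f"gene {probe} at {L:g} Kbp"
        )
    D = end - start
    span = cluster_span(wt)
    F_wt = float(profile.work(L))
    charge_ratio = (span - D) / span
    F_c = charge_ratio * F_wt
    mutant_profile = profile.excise(start, end)
    E = float(mutant_profile.extrusion(F_c))
    case, verdict = anterior_deletion_case(E, L, D, eta, gain_eta)
    posterior_most = probe == wt.gene_numbers[-1]
    rationale = (
        f"L={L:g}, D={D:g}, charge ratio {charge_ratio:.4f} reduces the "
        f"calibrated force {F_wt:g} to F_c={F_c:g}; mutant extrusion E={E:.3f} "
        f"vs L-D={L - D:g} (tolerance {eta:g}*L={eta * L:g}) -> {case}"
    )
    if case == "case3" and not posterior_most:
        rationale += (
            "; probe is not the most posterior gene, so a compensating "
            "posteriorization could in principle relocate it to the ICD"
        )
    return Outcome(
        verdict=verdict, case_label=case, rationale=rationale, probe=probe
    )


def classify_posterior_edit(
    wt: HoxCluster, m: Manipulation, probe: int
) -> Outcome:
    """Classify a posterior deletion/duplication via F = P·N compensation."""
    if m.kind not in ("deletion", "duplication"):
        raise HoxValidationError("posterior edits are deletions or duplications")
    if m.gene_start is None or m.include_i:
        raise HoxValidationError("posterior edits use a gene range (region i is anterior)")
    probe_pos = wt.gene_position_kbp(probe)
    start_pos = wt.gene_position_kbp(m.gene_start)
    if start_pos <= probe_pos:
        raise HoxValidationError(
            f"edited range starting at gene {m.gene_start} is not posterior to "
            f"probe gene {probe}"
        )
    lo, hi = _gene_index(wt, m.gene_start), _gene_index(wt, m.gene_end)
    extent = sum(wt.distances_kbp[lo:hi]) + sum(
        g.length_kbp for g in wt.genes[lo : hi + 1]
    )
    if extent == 0:
        return Outcome(
            verdict=Verdict.UNCHANGED,
            case_label="posterior_rule",
            rationale="edit of zero fiber extent: N unchanged, F unchanged",
            probe=probe,
        )
    if m.kind == "deletion":
        return Outcome(
            verdict=Verdict.POSTERIORIZED_DELAYED,
            case_label="posterior_rule",
            rationale=(
                f"deleting {extent:g} Kbp posterior to the probe lowers N; by "
                "F = P*N the pulling capacity P must rise to restore the "
                "extruding force, so probe expression is delayed and "
                "posteriorized"
            ),
            probe=probe,
        )
    return Outcome(
        verdict=Verdict.ANTERIORIZED,
        secondary=Verdict.DOWNREGULATED,
        case_label="posterior_rule",
        rationale=(
            f"duplicating {extent:g} Kbp posterior to the probe raises N and "
            "hence F: the probe extrudes prematurely (anteriorization) and is "
            "carried past the CT/ICD border away from the transcription "
            "factory, downregulating its expression (quantitative "
            "collinearity)"
        ),
        probe=probe,
    )


def classify_split(
    wt: HoxCluster, m: Manipulation, probes: list[int]
) -> list[Outcome]:
    """Classify a posterior split/inversion for each probe gene."""
    if m.kind != "split_inversion":
        raise HoxValidationError("classify_split needs a split_inversion")
    removes = m.removes_fixed_end or m.includes_evx2_boundary
    outcomes = []
    for probe in probes:
        wt.gene_position_kbp(probe)  # existence check
        if removes:
            outcome = Outcome(
                verdict=Verdict.ANTERIORIZED,
                case_label="split_rule",
                rationale=(
                    "the split removes the fixed 5' end: the spring is loose "
                    "at both ends and decondenses with abnormally smaller "
                    "forces, so expression is prematurely anteriorized"
                ),
                probe=probe,
            )
        else:
            outcome = Outcome(
                verdict=Verdict.UNCHANGED,
                case_label="split_rule",
                rationale=(
                    "the anchor region between Evx2 and Hoxd13 (fixed end of "
                    "the spring) remains intact, so extrusion mechanics and "
                    "expression match the wild type"
                ),
                probe=probe,
            )
        outcomes.append(outcome)
    return outcomes


# ---------------------------------------------------------------------------
# Packaged scenario presets
# ---------------------------------------------------------------------------

# Declared per-scenario elasticity profiles over the 94-Kbp mouse HoxD fiber.
# The qualitative outcomes hinge on unobserved local elasticity, so each
# scenario names the profile that realizes its reported case; the profiles
# are data, not hidden constants.
SCENARIO_PROFILES: dict[str, ElasticityProfile] = {
    # homogeneous fiber: deletions shorten extrusion one-for-one (case 1)
    "uniform": ElasticityProfile(edges=(0.0, 94.0), stiffness=(1.0,)),
    # the deleted block [i-8-10] is stiff: removing it frees a soft fiber,
    # so the reduced force overshoots L-D by far (case 2 with gain)
    "stiff_deleted_block": ElasticityProfile(
        edges=(0.0, 47.0, 73.0, 94.0), stiffness=(1.0, 2.0, 1.0)
    ),
    # only the region i is (mildly) stiff: a modest overshoot (plain case 2)
    "stiff_region_i": ElasticityProfile(
        edges=(0.0, 47.0, 57.0, 94.0), stiffness=(1.0, 1.5, 1.0)
    ),
    # soft fiber with a stiff belt between genes 12 and 13: after del(9-12)
    # the weakened force stalls in the belt short of L-D (case 3)
    "posterior_stiff_belt": ElasticityProfile(
        edges=(0.0, 88.0, 89.0, 94.0), stiffness=(0.05, 100.0, 0.05)
    ),
}


@dataclass(frozen=True)
class Scenario:
    scenario_id: str
    manipulation: Manipulation
    probe: int
    profile_ref: str
    expected_verdict: Verdict
    expected_secondary: Verdict | None = None

    @property
    def profile(self) -> ElasticityProfile | None:
        return SCENARIO_PROFILES.get(self.profile_ref)


def _parse_region(text: str) -> dict:
    """Parse a region spec like '8-10', 'i-8-10', 'i' or '12-13'."""
    parts = [p for p in text.strip().split("-") if p]
    include_i = False
    if parts and parts[0] == "i":
        include_i = True
        parts = parts[1:]
    if not parts:
        return {"gene_start": None, "gene_end": None, "include_i": include_i}
    if len(parts) == 1:
        lo = hi = int(parts[0])
    elif len(parts) == 2:
        lo, hi = int(parts[0]), int(parts[1])
    else:
        raise HoxValidationError(f"cannot parse region {text!r}")
    return {"gene_start": lo, "gene_end": hi, "include_i": include_i}


def _scenario_from_row(row: dict) -> Scenario:
    kind = row["kind"].strip()
    region = _parse_region(row.get("region", "") or "")
    manipulation = Manipulation(
        kind=kind,
        removes_fixed_end=row.get("removes_fixed_end", "0").strip() in ("1", "true"),
        includes_evx2_boundary=row.get("includes_evx2_boundary", "0").strip()
        in ("1", "true"),
        **(region if kind != "split_inversion" else
           {"gene_start": None, "gene_end": None, "include_i": False}),
    )
    secondary = (row.get("expected_secondary") or "").strip()
    return Scenario(
        scenario_id=row["scenario_id"].strip(),
        manipulation=manipulation,
        probe=int(row["probe"]),
        profile_ref=(row.get("profile_ref") or "").strip(),
        expected_verdict=Verdict(row["expected_verdict"].strip()),
        expected_secondary=Verdict(secondary) if secondary else None,
    )


def packaged_scenarios() -> list[Scenario]:
    """The nine packaged manipulation scenarios with expected verdicts."""
    ref = resources.files("hoxphys.data").joinpath("scenarios.tsv")
    with resources.as_file(ref) as path, open(path, newline="") as fh:
        rows = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        )
        return [_scenario_from_row(row) for row in rows]


def classify_scenario(
    cluster: HoxCluster, scenario: Scenario, i_kbp: float = DEFAULT_I_KBP
) -> Outcome:
    """Route one scenario through the appropriate classifier."""
    m = scenario.manipulation
    if m.kind == "split_inversion":
        return classify_split(cluster, m, [scenario.probe])[0]
    probe_pos = cluster.gene_position_kbp(scenario.probe)
    if m.gene_start is not None:
        start_pos = cluster.gene_position_kbp(m.gene_start)
        anterior = start_pos < probe_pos
    else:
        anterior = True  # region i lies anterior to gene 8
    if m.kind == "deletion" and anterior:
        profile = scenario.profile
        if profile is None:
            raise HoxValidationError(
                f"scenario {scenario.scenario_id!r} names unknown profile "
                f"{scenario.profile_ref!r}"
            )
        return classify_anterior_deletion(
            cluster, m, scenario.probe, profile, i_kbp=i_kbp
        )
    if m.kind == "duplication" and anterior:
        # anterior duplications: delayed, posteriorized probe expression
        # (the extruded fiber lengthens ahead of the probe); weakly
        # constrained compared to the other rules
        return Outcome(
            verdict=Verdict.POSTERIORIZED_DELAYED,
            case_label="none",
            rationale=(
                "anterior duplication lengthens the fiber anterior to the "
                "probe: extra extrusion work delays the probe's exit from "
                "the chromosome territory (delayed, posteriorized)"
            ),
            probe=scenario.probe,
        )
    return classify_posterior_edit(cluster, m, scenario.probe)


def run_packaged_scenarios(
    cluster: HoxCluster | None = None,
) -> list[tuple[Scenario, Outcome, bool]]:
    """Run every packaged scenario; returns (scenario, outcome, match) rows."""
    from .cluster import load_mouse_hoxd

    if cluster is None:
        cluster = load_mouse_hoxd()
    results = []
    for scenario in packaged_scenarios():
        outcome = classify_scenario(cluster, scenario)
        match = outcome.matches(scenario.expected_verdict, scenario.expected_secondary)
        results.append((scenario, outcome, match))
    return results
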