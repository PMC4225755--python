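"""Plan evaluation: the S_D quality score, DVH metric extraction, and the
paired one-tailed Wilcoxon signed-rank cohort comparison.

S_D sums the violations of required dose ranges over the evaluated DVH
points (Boost D_mean/D_99%/D_95%/D_1% and PTV-Boost D_99%/D_95% by
default): an achieved value A below its lower limit contributes
R_lo - A, one above its upper limit contributes A - R_up, and a value
inside the range contributes nothing.  A plan fulfilling every
requirement has S_D = 0; the score is in Gy.

The Wilcoxon test is exact by default (full distribution of the positive
rank sum over sign assignments, midranks for ties, zeros dropped); the
Gaussian approximation with tie-corrected variance is reported alongside,
since published cohort p-values are usually of that flavour.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .dose import DVH, DoseEngine, DoseGrid
from .geometry import StructureSet

logger = logging.getLogger(__name__)


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# requirements and the S_D score
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DoseRequirement:
    """A required dose range for one SOI metric (limits in Gy; a missing
    side makes the requirement one-sided)."""

    label: str                   # e.g. "Boost D99%"
    structure: str
    metric: str                  # "Dmean", "D99%", ...
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        if self.lower is None and self.upper is None:
            raise EvaluationError(f"{self.label}: requirement needs a limit")
        if (self.lower is not None and self.upper is not None
                and self.lower > self.upper):
            raise EvaluationError(f"{self.label}: lower limit above upper limit")

    def penalty(self, achieved: float) -> float:
        if self.lower is not None and achieved < self.lower:
            return self.lower - achieved
        if self.upper is not None and achieved > self.upper:
            return achieved - self.upper
        return 0.0


def default_requirements() -> list[DoseRequirement]:
    """The SIB prostate protocol requirement set: Boost 74 Gy +- 2% with a
    76.2 Gy mean (+- 1%) and D_1% < 80 Gy; PTV-Boost 60.1 Gy +- 2% with
    D_99% > 56 Gy."""
    return [
        DoseRequirement("Boost Dmean", "Boost", "Dmean", 75.4, 77.0),
        DoseRequirement("Boost D99%", "Boost", "D99%", 70.0, None),
        DoseRequirement("Boost D95%", "Boost", "D95%", 72.5, 75.5),
        DoseRequirement("Boost D1%", "Boost", "D1%", None, 80.0),
        DoseRequirement("PTV-Boost D99%", "PTV-Boost", "D99%", 56.0, None),
        DoseRequirement("PTV-Boost D95%", "PTV-Boost", "D95%", 58.9, 61.3),
    ]


@dataclass
class PlanScore:
    """Per-requirement achieved values and penalties, the net S_D, and the
    auxiliary rectum / CTV metrics when computed from a dose grid."""

    achieved: dict[str, float | None]
    penalties: dict[str, float]
    s_d: float
    rectum_v: dict[str, float] = field(default_factory=dict)   # "V95%" -> cm^3
    ctv_d99: float | None = None

    def as_frame(self) -> pd.DataFrame:
        rows = [(k, self.achieved.get(k), self.penalties.get(k, 0.0))
                for k in self.achieved]
        return pd.DataFrame(rows, columns=["requirement", "achieved", "S_D"])


def s_d_score(achieved: dict[str, float | None],
              requirements: list[DoseRequirement]) -> PlanScore:
    """Apply the violation-sum score to achieved metric values.

    ``achieved`` maps requirement labels to values in Gy; a value of
    ``None`` marks a metric not reported for this plan and is skipped.  A
    missing key is an error (every requirement must be accounted for).
    """
    penalties: dict[str, float] = {}
    for req in requirements:
        if req.label not in achieved:
            raise EvaluationError(f"no achieved value for {req.label!r}")
        val = achieved[req.label]
        if val is None:
            continue
        penalties[req.label] = req.penalty(float(val))
    net = float(sum(penalties.values()))
    return PlanScore(dict(achieved), penalties, round(net, 10))


def evaluate_plan(dose: DoseGrid, ss: StructureSet,
                  requirements: list[DoseRequirement] | None = None,
                  reference_dose: float = 76.2,
                  engine: DoseEngine | None = None) -> PlanScore:
    """Extract the protocol DVH metrics from a dose grid and score them.

    Besides the S_D requirements this reports the CTV D_99% and the
    absolute rectum volumes inside the 50%, 80% and 95% isodoses of
    ``reference_dose`` (default 76.2 Gy, making V_95% the volume above
    72.4 Gy).
    """
    requirements = requirements or default_requirements()
    engine = engine or DoseEngine(ss)
    dvhs: dict[str, DVH] = {}

    def dvh_of(structure: str) -> DVH:
        if structure not in dvhs:
            mask = engine.mask(structure)
            if not mask.any():
                raise EvaluationError(f"SOI {structure!r} absent or empty")
            dvhs[structure] = DVH.from_dose(dose, mask, structure)
        return dvhs[structure]

    achieved: dict[str, float | None] = {}
    for req in requirements:
        d = dvh_of(req.structure)
        if req.metric == "Dmean":
            achieved[req.label] = d.mean
        elif req.metric.startswith("D") and req.metric.endswith("%"):
            achieved[req.label] = d.d_at(float(req.metric[1:-1]))
        else:
            raise EvaluationError(f"unsupported metric {req.metric!r}")
    score = s_d_score(achieved, requirements)

    if "Rectum" in ss.structures:
        rect = dvh_of("Rectum")
        score.rectum_v = {f"V{p:g}%": rect.v_at(p, reference_dose)
                          for p in (50.0, 80.0, 95.0)}
    if "CTV" in ss.structures:
        score.ctv_d99 = dvh_of("CTV").d_at(99.0)
    return score


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test (one-tailed)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WilcoxonResult:
    w_plus: float
    n_nonzero: int
    p_exact: float
    p_normal: float
    all_zero: bool = False


def _signed_ranks(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Midranks of |d| and the signs, zeros already removed."""
    absd = np.abs(diffs)
    order = np.argsort(absd, kind="stable")
    ranks = np.empty(len(diffs), dtype=float)
    sorted_abs = absd[order]
    i = 0
    while i < len(diffs):
        j = i
        while j + 1 < len(diffs) and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks, np.sign(diffs)


def _exact_cdf_w_plus(ranks: np.ndarray, w_obs: float) -> float:
    """P(W+ <= w_obs) under the null, by the exact distribution of the
    positive rank sum over all sign assignments (dynamic program over
    doubled ranks, which are integers even with midranks)."""
    r2 = np.rint(2.0 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:total + 1 - r]
        counts = counts + shifted
    w2 = int(math.floor(2.0 * w_obs + 1e-9))
    return float(counts[:w2 + 1].sum() / counts.sum())


def brute_force_wilcoxon_p(diffs: list[float], w_obs: float) -> float:
    """Independent oracle: enumerate all 2^m sign assignments (m <= 20)."""
    d = np.asarray([x for x in diffs if x != 0.0], dtype=float)
    if len(d) > 20:
        raise EvaluationError("brute force limited to m <= 20")
    ranks, _ = _signed_ranks(d)
    count = 0
    for signs in itertools.product((0, 1), repeat=len(d)):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w <= w_obs + 1e-9:
            count += 1
    return count / 2 ** len(d)


def wilcoxon_signed_rank_1tail(pairs: list[tuple[float, float]],
                               alternative: str = "less") -> WilcoxonResult:
    """One-tailed Wilcoxon signed-rank test on paired values (a, b).

    ``alternative="less"`` tests a < b (the p-value is the null
    probability of a positive rank sum W+ at most as large as observed,
    with d = a - b); ``"greater"`` mirrors the differences.  Zero
    differences are dropped; ties share midranks.  Both the exact
    p-value and the tie-corrected Gaussian approximation are returned.
    """
    if alternative not in ("less", "greater"):
        raise EvaluationError("alternative must be 'less' or 'greater'")
    if not pairs:
        raise EvaluationError("need at least one pair")
    d = np.asarray([a - b for a, b in pairs], dtype=float)
    if alternative == "greater":
        d = -d
    d = d[d != 0.0]
    if len(d) == 0:
        logger.warning("all paired differences are zero; p = 1")
        return WilcoxonResult(0.0, 0, 1.0, 1.0, all_zero=True)
    ranks, signs = _signed_ranks(d)
    w_plus = float(ranks[signs > 0].sum())
    m = len(d)
    p_exact = _exact_cdf_w_plus(ranks, w_plus)

    mean = m * (m + 1) / 4.0
    var = m * (m + 1) * (2 * m + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= float(np.sum(tie_counts ** 3 - tie_counts)) / 48.0
    z = (w_plus - mean) / math.sqrt(var) if var > 0 else 0.0
    p_normal = float(norm.cdf(z))
    return WilcoxonResult(w_plus, m, p_exact, p_normal)


# ---------------------------------------------------------------------------
# cohort comparison
# ---------------------------------------------------------------------------

_COMPARISONS = [("adapted", "relocated"), ("native", "adapted"),
                ("native", "relocated")]


def compare_cohort(s_d: dict[str, list[float]],
                   v95: dict[str, list[float]],
                   alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise one-tailed comparisons between plan groups.

    ``s_d`` and ``v95`` map the group names (relocated / native / adapted)
    to per-case values in identical case order.  For each of the three
    standard comparisons (adapted vs relocated, native vs adapted, native
    vs relocated) the test asks whether the first group improves on
    (is lower than) the second, on S_D and on rectum V_95%; the returned
    table carries exact and approximate p-values and a significance flag
    at ``alpha``.
    """
    for metric in (s_d, v95):
        ns = {len(v) for v in metric.values()}
        if len(ns) != 1:
            raise EvaluationError("groups must contain the same cases")
    rows = []
    for first, second in _COMPARISONS:
        row: dict[str, object] = {"comparison": f"{first} against {second}"}
        for name, metric in (("S_D", s_d), ("V95%", v95)):
            res = wilcoxon_signed_rank_1tail(
                list(zip(metric[first], metric[second])), alternative="less")
            row[f"p_exact {name}"] = res.p_exact
            row[f"p_normal {name}"] = res.p_normal
            row[f"significant {name}"] = res.p_exact < alpha
        rows.append(row)
    return pd.DataFrame(rows)


__all__ = [
    "DoseRequirement", "EvaluationError", "PlanScore", "WilcoxonResult",
    "brute_force_wilcoxon_p", "compare_cohort", "default_requirements",
    "evaluate_plan", "s_d_score", "wilcoxon_signed_rank_1tail",
]
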