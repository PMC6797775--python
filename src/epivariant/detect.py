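"""Per-case outlier (epi-mutation) calling against a control panel.

This is the pipeline's central statistic. For every eligible peak and
every case sample, the case's normalized coverage q is compared with every
control:

* an UP call requires q_case >= 5, q_case >= 1.5 x q_c for every control
  c, and a one-tailed normal-model p-value below 0.01;
* a DOWN call requires every control q_c >= 5, q_case <= 0.5 x q_c for
  every control, and the lower-tail p-value below 0.01.

The nominal p is the tail probability of the case value under a normal
distribution fitted to the controls (mean, unbiased SD). Peaks dominated
by low-MAPQ reads (fraction >= 0.75) or with low cohort-mean coverage
(< 2.5) are excluded before testing. The fold thresholds are inclusive,
matching the "at least"/"at most" rule they implement; all comparisons
are exact (no epsilon).

Because a call requires the case to beat *every* control, the rule favors
specificity: under a homogeneous cohort the per-case call rate is well
below 1% of eligible peaks at default thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io import SampleSheet

__all__ = [
    "DetectionThresholds",
    "OutlierCall",
    "DetectionResult",
    "RecurrenceSummary",
    "eligible_peaks",
    "nominal_p",
    "detect_outliers",
    "summarize_recurrence",
    "sample_correlation",
    "flag_subgroups",
]

UP = "up"
DOWN = "down"


@dataclass(frozen=True)
class DetectionThresholds:
    """Thresholds of the outlier rule; defaults are the published operating point."""

    up_fold: float = 1.5
    down_fold: float = 0.5
    min_case_cov_up: float = 5.0
    min_ctrl_cov_down: float = 5.0
    nominal_p_max: float = 0.01
    low_cov_exclude: float = 2.5
    mapq_frac_exclude: float = 0.75
    gene_link_dist: int = 2000

    def __post_init__(self) -> None:
        if not self.up_fold > 1:
            raise ValueError("up_fold must exceed 1")
        if not 0 < self.down_fold < 1:
            raise ValueError("down_fold must be in (0, 1)")
        if not 0 < self.nominal_p_max < 1:
            raise ValueError("nominal_p_max must be in (0, 1)")


@dataclass(frozen=True)
class OutlierCall:
    peak_id: str
    sample_id: str
    direction: str  # "up" or "down"
    extreme_fold: float  # worst-case fold vs controls: min for up, max for down
    nominal_p: float
    control_mean: float
    control_sd: float


@dataclass
class DetectionResult:
    calls: List[OutlierCall]
    eligibility: pd.DataFrame  # per peak: eligible flag + excluded_reason
    thresholds: DetectionThresholds

    def calls_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "peak_id": c.peak_id,
                    "sample_id": c.sample_id,
                    "direction": c.direction,
                    "extreme_fold": c.extreme_fold,
                    "nominal_p": c.nominal_p,
                    "control_mean": c.control_mean,
                    "control_sd": c.control_sd,
                }
                for c in self.calls
            ],
            columns=[
                "peak_id",
                "sample_id",
                "direction",
                "extreme_fold",
                "nominal_p",
                "control_mean",
                "control_sd",
            ],
        )


def eligible_peaks(
    matrix: pd.DataFrame,
    mapq_summary: pd.Series | Mapping[str, float] | None,
    thresholds: DetectionThresholds = DetectionThresholds(),
) -> pd.DataFrame:
    """Locus filters applied before any testing.

    A peak is excluded iff its pooled low-MAPQ fraction is present and
    >= 0.75, or the cohort mean of q across all samples is < 2.5.
    Returns a frame indexed like the matrix with boolean ``eligible`` and a
    string ``excluded_reason`` ("" when testable).
    """
    mean_q = matrix.mean(axis=1)
    low_cov = mean_q < thresholds.low_cov_exclude
    if mapq_summary is None:
        bad_mapq = pd.Series(False, index=matrix.index)
    else:
        frac = pd.Series(mapq_summary, dtype=float).reindex(matrix.index)
        bad_mapq = frac.notna() & (frac >= thresholds.mapq_frac_exclude)
    reason = pd.Series("", index=matrix.index, dtype=object)
    reason[low_cov] = "low_coverage"
    reason[bad_mapq] = "low_mapq"  # mappability reason wins when both apply
    return pd.DataFrame(
        {"eligible": ~(low_cov | bad_mapq), "excluded_reason": reason}
    )


def nominal_p(q_case: float, control_values: Sequence[float], direction: str) -> float:
    """Tail probability of the case value under Normal(mean, sd) of the controls.

    sd is the unbiased (n-1) sample standard deviation. With sd = 0 the
    normal degenerates to a point mass: p is 0 when the case differs from
    the control mean in the tested direction, else 1.
    """
    controls = np.asarray(control_values, dtype=float)
    if controls.size < 2:
        raise ValueError("nominal_p requires at least 2 control values")
    if direction not in (UP, DOWN):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    mu = float(controls.mean())
    sd = float(controls.std(ddof=1))
    if sd == 0.0:
        if direction == UP:
            return 0.0 if q_case > mu else 1.0
        return 0.0 if q_case < mu else 1.0
    if direction == UP:
        return float(norm.sf(q_case, loc=mu, scale=sd))
    return float(norm.cdf(q_case, loc=mu, scale=sd))


def detect_outliers(
    matrix: pd.DataFrame,
    sample_sheet: SampleSheet,
    mapq_summary: pd.Series | Mapping[str, float] | None = None,
    thresholds: DetectionThresholds = DetectionThresholds(),
    case_subset: Sequence[str] | None = None,
) -> DetectionResult:
    """Call per-case up/down outlier peaks against the full control panel.

    ``case_subset`` restricts which case samples are tested (subgroup
    analyses); controls are always the sheet's full control panel. Calls
    are ordered by (peak position in the matrix, case sample order).
    """
    sample_sheet.validate_for_detection()
    missing = [s for s in matrix.columns if s not in sample_sheet.sample_ids]
    if missing:
        raise ValueError(f"matrix samples absent from sample sheet: {missing}")
    cases = [s for s in sample_sheet.cases if s in matrix.columns]
    controls = [s for s in sample_sheet.controls if s in matrix.columns]
    if case_subset is not None:
        unknown = [s for s in case_subset if s not in cases]
        if unknown:
            raise ValueError(f"case subset contains non-case samples: {unknown}")
        cases = [s for s in cases if s in set(case_subset)]
    if len(controls) < 2:
        raise ValueError("need at least 2 controls present in the matrix")

    elig = eligible_peaks(matrix, mapq_summary, thresholds)
    mask = elig["eligible"].to_numpy()
    peak_ids = matrix.index.to_numpy()

    C = matrix[controls].to_numpy(dtype=float)  # peaks x controls
    mu = C.mean(axis=1)
    sd = C.std(axis=1, ddof=1)
    cmax = C.max(axis=1)
    cmin = C.min(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        p_up_norm = norm.sf(
            (matrix[cases].to_numpy(dtype=float) - mu[:, None])
            / np.where(sd > 0, sd, np.nan)[:, None]
        )
        p_dn_norm = norm.cdf(
            (matrix[cases].to_numpy(dtype=float) - mu[:, None])
            / np.where(sd > 0, sd, np.nan)[:, None]
        )
    Q = matrix[cases].to_numpy(dtype=float)
    degenerate = sd == 0
    # point-mass rule for sd == 0
    p_up = np.where(
        degenerate[:, None], np.where(Q > mu[:, None], 0.0, 1.0), p_up_norm
    )
    p_dn = np.where(
        degenerate[:, None], np.where(Q < mu[:, None], 0.0, 1.0), p_dn_norm
    )

    up_ok = (
        mask[:, None]
        & (Q >= thresholds.min_case_cov_up)
        & (Q >= thresholds.up_fold * cmax[:, None])
        & (p_up < thresholds.nominal_p_max)
    )
    down_ok = (
        mask[:, None]
        & (cmin >= thresholds.min_ctrl_cov_down)[:, None]
        & (Q <= thresholds.down_fold * cmin[:, None])
        & (p_dn < thresholds.nominal_p_max)
    )

    calls: List[OutlierCall] = []
    for i in np.nonzero(up_ok.any(axis=1) | down_ok.any(axis=1))[0]:
        for j, sample in enumerate(cases):
            if up_ok[i, j]:
                with np.errstate(divide="ignore"):
                    fold = Q[i, j] / cmax[i] if cmax[i] > 0 else np.inf
                calls.append(
                    OutlierCall(
                        str(peak_ids[i]), sample, UP, float(fold),
                        float(p_up[i, j]), float(mu[i]), float(sd[i]),
                    )
                )
            if down_ok[i, j]:
                calls.append(
                    OutlierCall(
                        str(peak_ids[i]), sample, DOWN, float(Q[i, j] / cmin[i]),
                        float(p_dn[i, j]), float(mu[i]), float(sd[i]),
                    )
                )
    return DetectionResult(calls, elig, thresholds)


@dataclass
class RecurrenceSummary:
    """How often each altered locus recurs across case samples.

    The primary grouping is (peak, direction); a per-peak any-direction
    view is kept alongside because the two differ when one locus is up in
    one case and down in another.
    """

    by_locus_direction: pd.DataFrame  # peak_id, direction, n_samples, samples
    by_peak: pd.DataFrame  # peak_id, n_samples
    singleton_fraction: float  # NaN when there are no calls
    singleton_fraction_by_peak: float

    @property
    def multi(self) -> pd.DataFrame:
        """Loci (peak, direction) altered in at least two case samples."""
        return self.by_locus_direction[self.by_locus_direction["n_samples"] >= 2]


def summarize_recurrence(calls: Sequence[OutlierCall]) -> RecurrenceSummary:
    if not calls:
        empty = pd.DataFrame(columns=["peak_id", "direction", "n_samples", "samples"])
        return RecurrenceSummary(
            empty, pd.DataFrame(columns=["peak_id", "n_samples"]), float("nan"), float("nan")
        )
    df = pd.DataFrame(
        {"peak_id": [c.peak_id for c in calls],
         "direction": [c.direction for c in calls],
         "sample_id": [c.sample_id for c in calls]}
    )
    by_ld = (
        df.groupby(["peak_id", "direction"], sort=True)["sample_id"]
        .agg(n_samples="nunique", samples=lambda s: ",".join(sorted(set(s))))
        .reset_index()
    )
    by_peak = (
        df.groupby("peak_id", sort=True)["sample_id"].nunique().rename("n_samples").reset_index()
    )
    singleton = float((by_ld["n_samples"] == 1).mean())
    singleton_peak = float((by_peak["n_samples"] == 1).mean())
    return RecurrenceSummary(by_ld, by_peak, singleton, singleton_peak)


def sample_correlation(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between samples over their per-peak q vectors.

    Diagonal is 1 by definition; pairs involving a zero-variance sample
    are reported missing (NaN).
    """
    if matrix.shape[0] < 2:
        raise ValueError("sample correlation needs at least 2 peaks")
    X = matrix.to_numpy(dtype=float)
    sd = X.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        pcc = np.corrcoef(X, rowvar=False)
    pcc = np.atleast_2d(pcc)
    zero = sd == 0
    pcc[zero, :] = np.nan
    pcc[:, zero] = np.nan
    np.fill_diagonal(pcc, 1.0)
    return pd.DataFrame(pcc, index=matrix.columns, columns=matrix.columns)


def flag_subgroups(
    pcc: pd.DataFrame,
    case_ids: Sequence[str],
    delta: float = 0.05,
) -> Dict[str, List[List[str]]]:
    """Partition case samples into a main group and mutually-correlated subgroups.

    A pair of cases is a subgroup candidate when their mutual PCC exceeds
    each member's mean PCC to all samples outside the pair by at least
    ``delta``. Candidate pairs are closed into connected components, and a
    component is kept only if every within-component pair still clears the
    margin against the members' mean PCC to all non-component samples.
    Deterministic: components are ordered by their sorted member lists.

    This operationalizes the screen for globally divergent but mutually
    similar case pairs (e.g., two cases at mutual PCC 0.97 against a 0.89
    cohort mean stand out at the default 0.05 margin).
    """
    samples = list(pcc.index)
    case_ids = [c for c in case_ids if c in samples]

    def mean_to_rest(member: str, cluster: Sequence[str]) -> float:
        rest = [s for s in samples if s != member and s not in cluster]
        vals = pcc.loc[member, rest].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        return float(vals.mean()) if vals.size else float("nan")

    def pair_ok(a: str, b: str, cluster: Sequence[str]) -> bool:
        mutual = float(pcc.loc[a, b])
        if np.isnan(mutual):
            return False
        for member in (a, b):
            base = mean_to_rest(member, cluster)
            if np.isnan(base) or mutual - base < delta:
                return False
        return True

    # candidate edges between case samples
    edges = [
        (a, b)
        for i, a in enumerate(case_ids)
        for b in case_ids[i + 1:]
        if pair_ok(a, b, (a, b))
    ]
    # connected components over candidate edges
    parent = {c: c for c in case_ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        parent[find(a)] = find(b)
    comps: Dict[str, List[str]] = {}
    for c in case_ids:
        comps.setdefault(find(c), []).append(c)
    flagged: List[List[str]] = []
    for comp in sorted((sorted(v) for v in comps.values() if len(v) >= 2)):
        if all(
            pair_ok(a, b, comp)
            for i, a in enumerate(comp)
            for b in comp[i + 1:]
        ):
            flagged.append(comp)
    in_flagged = {s for grp in flagged for s in grp}
    main = [c for c in case_ids if c not in in_flagged]
    return {"main": [main], "flagged": flagged}
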