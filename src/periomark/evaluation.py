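"""Evaluation statistics: matching scores, one-sample t tests, degree
census, and batched resorption errors.

The per-edge matching score compares a ground-truth curve G with an
automatically fitted curve A over the overlap of their y-ranges::

    ms_e = sum_{i=Y_m}^{Y_M} (X_Gi - X_Ai)^2 / (Y_M - Y_m)

The denominator is Y_M - Y_m exactly as defined even though the sum has
Y_M - Y_m + 1 terms; rms_e = sqrt(ms_e) is reported alongside since
summary deviations are quoted in pixels (linear units).

Per-edge deviations x_e = X_Gi - X_Ai feed a one-sample Student t test
of mean zero with df = L_e - 1 (L_e = Y_M - Y_m). Percentage errors
E = A - G are grouped into batches and t-tested per batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .edge_description import EdgeGroup, PolynomialFit, select_degree
from .errors import EvaluationError


@dataclass
class EdgeMatch:
    y_m: int
    y_M: int
    x_e: np.ndarray            # X_Gi - X_Ai at integer y in [y_m, y_M]
    ms_e: float
    rms_e: float

    @property
    def L_e(self) -> int:
        return self.y_M - self.y_m

    @property
    def df(self) -> int:
        return self.L_e - 1


@dataclass
class EvaluationSummary:
    n_edges: int = 0
    m_e: float = float("nan")       # mean per-edge rms deviation, px
    sigma_e: float = float("nan")   # std of per-edge rms deviations, px
    p_p: float = float("nan")       # mean per-edge t-test p value
    sigma_p: float = float("nan")   # mean per-edge estimated std-dev, px
    pct_H0_not_rejected: float = float("nan")
    degree_census: dict[int, tuple[int, int]] = field(default_factory=dict)
    p_b: float = float("nan")       # batch-averaged p value on E = A - G
    m_b: float = float("nan")       # batch-averaged mean |E|
    sigma_b: float = float("nan")   # batch-averaged std of E
    critical_point_mean_error_px: float = float("nan")
    n_pairs_used: int = 0

    def to_dict(self) -> dict:
        return {
            "n_edges": self.n_edges,
            "m_e": self.m_e,
            "sigma_e": self.sigma_e,
            "p_p": self.p_p,
            "sigma_p": self.sigma_p,
            "pct_H0_not_rejected": self.pct_H0_not_rejected,
            "degree_census": {
                str(d): {"count": c, "pct": p}
                for d, (c, p) in sorted(self.degree_census.items())
            },
            "p_b": self.p_b,
            "m_b": self.m_b,
            "sigma_b": self.sigma_b,
            "critical_point_mean_error_px": self.critical_point_mean_error_px,
            "n_pairs_used": self.n_pairs_used,
        }


def matching_score(
    G: PolynomialFit,
    A: PolynomialFit,
    y_range_G: tuple[float, float],
    y_range_A: tuple[float, float],
) -> EdgeMatch:
    """Evaluate both fits at every integer y in the overlap of their
    ranges and form the matching score."""
    y_m = int(np.ceil(max(y_range_G[0], y_range_A[0])))
    y_M = int(np.floor(min(y_range_G[1], y_range_A[1])))
    if y_M - y_m < 2:
        raise EvaluationError("y ranges overlap by less than 2 px")
    ys = np.arange(y_m, y_M + 1, dtype=float)
    x_e = np.asarray(G(ys), dtype=float) - np.asarray(A(ys), dtype=float)
    ms_e = float(np.sum(x_e ** 2) / (y_M - y_m))
    return EdgeMatch(y_m=y_m, y_M=y_M, x_e=x_e, ms_e=ms_e, rms_e=float(np.sqrt(ms_e)))


def one_sample_t_test(x) -> tuple[float, int, float]:
    """t = mean / (sd / sqrt(n)) with the sample sd (n-1 denominator);
    two-sided p from Student's t with df = n - 1."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise EvaluationError("t test needs n >= 2")
    sd = float(x.std(ddof=1))
    if sd == 0:
        raise EvaluationError("degenerate sample: zero variance")
    t = float(x.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    return t, n - 1, p


def edge_fit_evaluation(
    matches: list[EdgeMatch], alpha: float = 0.05
) -> EvaluationSummary:
    """Aggregate matching scores and per-edge t tests.

    m_e / sigma_e summarize the per-edge rms deviations in pixels;
    p_p / sigma_p are the mean p value and mean estimated std-dev over
    edges; pct_H0_not_rejected is the share of edges whose deviation
    from zero is not rejected at level alpha.
    """
    if not matches:
        raise EvaluationError("edge_fit_evaluation needs >= 1 match")
    rms = np.array([m.rms_e for m in matches])
    p_values, sds = [], []
    for m in matches:
        sd = float(m.x_e.std(ddof=1)) if len(m.x_e) > 1 else 0.0
        sds.append(sd)
        if sd == 0:
            # perfect match: the null of zero mean deviation stands
            p_values.append(1.0)
        else:
            p_values.append(one_sample_t_test(m.x_e)[2])
    p_values = np.array(p_values)
    return EvaluationSummary(
        n_edges=len(matches),
        m_e=float(rms.mean()),
        sigma_e=float(rms.std(ddof=0)) if len(matches) > 1 else 0.0,
        p_p=float(p_values.mean()),
        sigma_p=float(np.mean(sds)),
        pct_H0_not_rejected=float(100.0 * np.mean(p_values >= alpha)),
    )


def census_percentages(counts: dict[int, int]) -> dict[int, tuple[int, int]]:
    """{degree: (count, integer percentage of the total)}."""
    total = sum(counts.values())
    if total == 0:
        raise EvaluationError("empty census")
    return {
        d: (c, int(round(100.0 * c / total))) for d, c in sorted(counts.items())
    }


def degree_census(groups: list[EdgeGroup]) -> dict[int, tuple[int, int]]:
    """Run the minimum-MSE degree selection on every group and tabulate
    counts and integer percentages per selected degree."""
    if not groups:
        raise EvaluationError("degree_census needs >= 1 group")
    counts: dict[int, int] = {}
    for g in groups:
        d = select_degree(g).degree
        counts[d] = counts.get(d, 0) + 1
    return census_percentages(counts)


def resorption_error_batches(
    results: list[tuple[float | None, float]],
    n_batches: int = 10,
    alpha: float = 0.05,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """(p_b, m_b, sigma_b) over contiguous batches of E = A - G.

    Pairs whose automatic percentage is None (significant point not
    detected) are excluded before batching. Batches follow input order
    unless ``seed`` requests a deterministic shuffle. p_b averages the
    per-batch two-sided p values (batches with zero variance are
    skipped in that average), m_b the per-batch mean |E| and sigma_b
    the per-batch std of E.
    """
    errors = np.array([a - g for a, g in results if a is not None], dtype=float)
    if len(errors) < n_batches:
        raise EvaluationError("fewer usable pairs than batches")
    if seed is not None:
        errors = errors[np.random.default_rng(seed).permutation(len(errors))]
    p_vals, m_vals, s_vals = [], [], []
    for batch in np.array_split(errors, n_batches):
        m_vals.append(float(np.abs(batch).mean()))
        s_vals.append(float(batch.std(ddof=1)) if len(batch) > 1 else 0.0)
        try:
            p_vals.append(one_sample_t_test(batch)[2])
        except EvaluationError:
            pass
    p_b = float(np.mean(p_vals)) if p_vals else float("nan")
    return p_b, float(np.mean(m_vals)), float(np.mean(s_vals))


# ---------------------------------------------------------------------------
# suite-level evaluation (predict and compare against ground truth)
# ---------------------------------------------------------------------------

def evaluate_suite(items, config=None, n_batches: int | None = None):
    """Run the pipeline over (radiograph, detections, truth-edge list)
    triples and aggregate every evaluation statistic.

    Truth edges must expose ``implant``, ``side``, ``curve()``,
    ``domain``, ``critical`` and ``resorption_pct`` (phantom truth does;
    annotation sets are adapted by the CLI). Predicted edges match truth
    edges on (implant, side). Returns (EvaluationSummary, details dict).
    """
    from .config import DEFAULT_CONFIG
    from .critical_points import STATUS_BOTH, STATUS_NONE
    from .errors import DescriptionError, GatingError, ScanError
    from .pipeline import analyze

    config = config or DEFAULT_CONFIG
    matches: list[EdgeMatch] = []
    cp_errors: list[float] = []
    pct_pairs: list[tuple[float | None, float]] = []
    groups = []
    zero_truth_total = zero_truth_none = 0
    excluded = 0

    for radiograph, detections, truth_edges in items:
        try:
            _, art = analyze(radiograph, detections, config)
        except (GatingError, DescriptionError, ScanError):
            excluded += 1
            continue
        predicted = {}
        for edge, pair in zip(art.edges, art.pairs):
            key = (edge.implant_id, edge.side)
            if key not in predicted or edge.group.size > predicted[key][0].group.size:
                predicted[key] = (edge, pair)
        for t in truth_edges:
            hit = predicted.get((t.implant, t.side))
            if hit is None:
                if t.resorption_pct is not None:
                    pct_pairs.append((None, t.resorption_pct))
                continue
            edge, pair = hit
            groups.append(edge.group)
            try:
                matches.append(matching_score(
                    t.curve(), edge.curve, t.domain,
                    (edge.group.y_min, edge.group.y_max),
                ))
            except EvaluationError:
                pass
            if t.resorption_pct is None:
                zero_truth_total += 1
                if pair.status == STATUS_NONE:
                    zero_truth_none += 1
                continue
            if pair.status == STATUS_BOTH and len(t.critical) == 2:
                for detected, true in zip((pair.first, pair.second), t.critical):
                    cp_errors.append(float(np.hypot(
                        detected[0] - true[0], detected[1] - true[1]
                    )))
            from .resorption import resorption_percentage
            if pair.status == STATUS_BOTH:
                pct, _ = resorption_percentage(edge, pair)
                pct_pairs.append((pct, t.resorption_pct))
            else:
                pct_pairs.append((None, t.resorption_pct))

    if not matches:
        raise EvaluationError("no evaluable edges in the suite")
    summary = edge_fit_evaluation(matches, alpha=config.alpha)
    summary.degree_census = degree_census(groups)
    summary.critical_point_mean_error_px = (
        float(np.mean(cp_errors)) if cp_errors else float("nan")
    )
    nb = n_batches if n_batches is not None else config.n_batches
    usable = [p for p in pct_pairs if p[0] is not None]
    summary.n_pairs_used = len(usable)
    if len(usable) >= nb:
        summary.p_b, summary.m_b, summary.sigma_b = resorption_error_batches(
            pct_pairs, n_batches=nb, alpha=config.alpha
        )
    details = {
        "critical_point_errors_px": cp_errors,
        "pct_pairs": pct_pairs,
        "zero_defect_edges": zero_truth_total,
        "zero_defect_none": zero_truth_none,
        "excluded_images": excluded,
    }
    return summary, details
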