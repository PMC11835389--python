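"""Visual homogeneity: a distance-to-center decision variable.

Visual homogeneity (VH) of a display is the Euclidean distance of its
predicted response vector from a single center point in perceptual space.
Homogeneous displays (target-absent arrays, symmetric objects) lie far from
the center; heterogeneous displays (target-present arrays, asymmetric
objects) are pulled inward by response averaging.  If observers read out VH
against a decision boundary, response times are slowest near the boundary,
which predicts a *positive* RT-VH correlation in one group (present /
asymmetric) and a *negative* one in the other (absent / symmetric) — and a
near-zero correlation when the groups are pooled.

The center is a free parameter (k coordinates), fitted by maximizing
r_groupA - r_groupB with multi-start derivative-free optimization inside box
bounds.  Everything here is invariant to jointly rotating / translating the
embedding and the center, since only distances enter the objective.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import mannwhitneyu

from ._utils import UndefinedCorrelationError, pearson, rng_for, spearman
from .display_model import GROUP_A_LABELS, GROUP_B_LABELS


def split_groups(labels) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks for group A (present/asymmetric) and B (absent/symmetric)."""
    labels = np.asarray(labels)
    in_a = np.isin(labels, sorted(GROUP_A_LABELS))
    in_b = np.isin(labels, sorted(GROUP_B_LABELS))
    unknown = ~(in_a | in_b)
    if unknown.any():
        raise ValueError(f"unknown display labels: {sorted(set(labels[unknown]))}")
    return in_a, in_b


def visual_homogeneity(responses: np.ndarray, center: np.ndarray) -> np.ndarray:
    """Euclidean distance of each response vector to the center."""
    responses = np.atleast_2d(np.asarray(responses, dtype=float))
    center = np.asarray(center, dtype=float)
    if responses.shape[1] != center.shape[0]:
        raise ValueError(
            f"dimension mismatch: responses are {responses.shape[1]}-D, "
            f"center is {center.shape[0]}-D"
        )
    return np.sqrt(((responses - center) ** 2).sum(axis=1))


def objective(
    center: np.ndarray,
    responses: np.ndarray,
    rts: np.ndarray,
    labels,
    *,
    method: str = "pearson",
) -> float:
    """r(VH, RT | group A) - r(VH, RT | group B) for a candidate center.

    The quantity maximized by :func:`fit_center`; ranges over [-2, 2] and
    reaches 2 only when VH orders RTs perfectly (and oppositely) in the two
    groups.
    """
    in_a, in_b = split_groups(labels)
    rts = np.asarray(rts, dtype=float)
    if in_a.sum() < 3 or in_b.sum() < 3:
        raise ValueError("need at least 3 displays per group")
    vh = visual_homogeneity(responses, center)
    corr = pearson if method == "pearson" else spearman
    r_a = corr(vh[in_a], rts[in_a], context="group A (present/asymmetric)")
    r_b = corr(vh[in_b], rts[in_b], context="group B (absent/symmetric)")
    return r_a - r_b


@dataclass
class VHModelFit:
    """Fitted center and per-display visual homogeneity."""

    center: np.ndarray
    vh: np.ndarray
    r_group_a: float
    r_group_b: float
    objective: float
    restart_objectives: list[float] = field(default_factory=list)
    converged: bool = True
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "center": [float(c) for c in self.center],
            "vh": [float(v) for v in self.vh],
            "r_group_a": self.r_group_a,
            "r_group_b": self.r_group_b,
            "objective": self.objective,
            "restart_objectives": self.restart_objectives,
            "converged": self.converged,
            "seed": self.seed,
        }


def default_bounds(responses: np.ndarray, expand: float = 0.5) -> np.ndarray:
    """Box bounds: the response bounding box expanded by ``expand`` per side."""
    responses = np.atleast_2d(responses)
    lo = responses.min(axis=0)
    hi = responses.max(axis=0)
    span = np.maximum(hi - lo, 1e-9)
    return np.column_stack([lo - expand * span, hi + expand * span])


def _project_to_span(center: np.ndarray, responses: np.ndarray) -> np.ndarray:
    """Project the center onto the affine span of the responses.

    When the responses span fewer than k dimensions the fitted center has
    weakly identified out-of-span components; projecting gives a canonical
    representative.  Note the projection is not objective-preserving in
    general (an out-of-span offset h maps in-span distances d to
    sqrt(d^2 + h^2), a nonlinear transform), so it is opt-in.
    """
    mu = responses.mean(axis=0)
    x = responses - mu
    # orthonormal basis of the data span
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    rank = int((s > s.max() * 1e-10).sum()) if s.size and s.max() > 0 else 0
    basis = vt[:rank]
    offset = center - mu
    return mu + basis.T @ (basis @ offset)


def fit_center(
    responses: np.ndarray,
    rts: np.ndarray,
    labels,
    *,
    bounds: np.ndarray | None = None,
    n_restarts: int = 20,
    seed: int = 0,
    method: str = "pearson",
    xatol: float = 1e-6,
    fatol: float = 1e-10,
    extra_starts: np.ndarray | None = None,
    project_center: bool = False,
) -> VHModelFit:
    """Fit the VH center by multi-start Nelder-Mead within box bounds.

    Starts: the response centroid, any ``extra_starts`` (e.g. a warm start
    from a previous fit), and ``n_restarts`` uniform draws inside the bounds.
    The best restart wins; among restarts within 1e-9 of the best objective
    the smallest-norm center is reported, and all restart optima are kept for
    stability audits.
    """
    responses = np.atleast_2d(np.asarray(responses, dtype=float))
    rts = np.asarray(rts, dtype=float)
    in_a, in_b = split_groups(labels)
    if in_a.sum() < 3 or in_b.sum() < 3:
        raise ValueError("need at least 3 displays per group")
    if bounds is None:
        bounds = default_bounds(responses)
    bounds = np.asarray(bounds, dtype=float)
    if not np.all(np.isfinite(bounds)):
        raise ValueError("bounds must be finite")

    rt_a = rts[in_a] - rts[in_a].mean()
    rt_b = rts[in_b] - rts[in_b].mean()
    na = np.sqrt((rt_a**2).sum())
    nb = np.sqrt((rt_b**2).sum())
    if na == 0:
        raise UndefinedCorrelationError("zero RT variance in group A (present/asymmetric)")
    if nb == 0:
        raise UndefinedCorrelationError("zero RT variance in group B (absent/symmetric)")
    resp_a, resp_b = responses[in_a], responses[in_b]

    if method == "pearson":

        def neg_obj(c: np.ndarray) -> float:
            va = np.sqrt(((resp_a - c) ** 2).sum(axis=1))
            vb = np.sqrt(((resp_b - c) ** 2).sum(axis=1))
            va = va - va.mean()
            vb = vb - vb.mean()
            da = np.sqrt((va**2).sum())
            db = np.sqrt((vb**2).sum())
            if da == 0 or db == 0:
                return np.inf
            return -((va @ rt_a) / (da * na) - (vb @ rt_b) / (db * nb))

    else:

        def neg_obj(c: np.ndarray) -> float:
            vh = visual_homogeneity(responses, c)
            try:
                return -(
                    spearman(vh[in_a], rts[in_a]) - spearman(vh[in_b], rts[in_b])
                )
            except UndefinedCorrelationError:
                return np.inf

    rng = rng_for(seed, 11)
    starts = [responses.mean(axis=0)]
    if extra_starts is not None:
        starts.extend(np.atleast_2d(extra_starts))
    k = responses.shape[1]
    if n_restarts > 0:
        draws = rng.uniform(bounds[:, 0], bounds[:, 1], size=(n_restarts, k))
        starts.extend(draws)

    results = []
    failures = []
    for x0 in starts:
        x0 = np.clip(x0, bounds[:, 0], bounds[:, 1])
        try:
            res = minimize(
                neg_obj,
                x0,
                method="Nelder-Mead",
                bounds=bounds,
                options={"xatol": xatol, "fatol": fatol, "maxiter": 2000 * k},
            )
            results.append(res)
        except Exception as exc:  # pragma: no cover - defensive
            failures.append(str(exc))
    if not results:
        raise RuntimeError(f"all restarts failed: {failures}")

    objs = np.array([-r.fun for r in results])
    best = objs.max()
    near = [r for r, o in zip(results, objs) if o >= best - 1e-9]
    winner = min(near, key=lambda r: float(np.linalg.norm(r.x)))
    center = winner.x
    if project_center:
        center = _project_to_span(center, responses)
    vh = visual_homogeneity(responses, center)
    corr = pearson if method == "pearson" else spearman
    r_a = corr(vh[in_a], rts[in_a], context="group A")
    r_b = corr(vh[in_b], rts[in_b], context="group B")
    return VHModelFit(
        center=center,
        vh=vh,
        r_group_a=r_a,
        r_group_b=r_b,
        objective=r_a - r_b,
        restart_objectives=sorted((float(o) for o in objs), reverse=True),
        converged=bool(winner.success),
        seed=seed,
    )


@dataclass
class LOOCVResult:
    """Leave-one-image-out cross-validated VH predictions."""

    vh_pred: np.ndarray
    r_group_a: float
    r_group_b: float
    n_folds: int
    skipped_folds: list = field(default_factory=list)


def loocv_fit(
    responses: np.ndarray,
    rts: np.ndarray,
    labels,
    display_objects,
    *,
    bounds: np.ndarray | None = None,
    n_restarts: int = 2,
    seed: int = 0,
    warm_start: np.ndarray | None = None,
    **fit_kwargs,
) -> LOOCVResult:
    """Leave-one-image-out validation of the center fit.

    For each object, all displays involving it are held out, the center is
    refit on the rest (warm-started at the full-data center unless another
    ``warm_start`` is given), and VH of the held-out displays is computed
    under the refit center.  Group correlations are reported on the assembled
    out-of-fold predictions.
    """
    responses = np.atleast_2d(np.asarray(responses, dtype=float))
    rts = np.asarray(rts, dtype=float)
    labels = np.asarray(labels)
    in_a, in_b = split_groups(labels)
    if bounds is None:
        bounds = default_bounds(responses)
    if warm_start is None:
        warm_start = fit_center(
            responses, rts, labels, bounds=bounds, n_restarts=max(n_restarts, 5),
            seed=seed, **fit_kwargs,
        ).center

    objects = sorted({obj for objs in display_objects for obj in objs})
    involves = {
        obj: np.array([obj in objs for objs in display_objects]) for obj in objects
    }
    vh_pred = np.full(len(rts), np.nan)
    skipped = []
    for fold, obj in enumerate(objects):
        held = involves[obj]
        keep = ~held
        if (in_a & keep).sum() < 3 or (in_b & keep).sum() < 3:
            skipped.append(obj)
            warnings.warn(f"LOOCV fold for object {obj!r} degenerate; skipped")
            continue
        fit = fit_center(
            responses[keep], rts[keep], labels[keep],
            bounds=bounds, n_restarts=n_restarts, seed=seed + 1000 + fold,
            extra_starts=warm_start, **fit_kwargs,
        )
        vh_pred[held] = visual_homogeneity(responses[held], fit.center)

    have = ~np.isnan(vh_pred)
    r_a = pearson(vh_pred[in_a & have], rts[in_a & have], context="LOOCV group A")
    r_b = pearson(vh_pred[in_b & have], rts[in_b & have], context="LOOCV group B")
    return LOOCVResult(
        vh_pred=vh_pred,
        r_group_a=r_a,
        r_group_b=r_b,
        n_folds=len(objects) - len(skipped),
        skipped_folds=skipped,
    )


@dataclass
class WeightSweepResult:
    table: pd.DataFrame
    w_best: float


def weight_sweep(
    emb,
    displays,
    rts: np.ndarray,
    labels,
    w_grid=None,
    *,
    n_restarts: int = 5,
    seed: int = 0,
    **fit_kwargs,
) -> WeightSweepResult:
    """Refit the center for a grid of target/distractor summation weights.

    For each target weight w the oddball-array responses are rebuilt as
    w*target + (1-w)*distractor, the center refit, and the objective
    recorded; the argmax locates the summation rule best supported by the
    RTs (equal weights = plain averaging).
    """
    from .display_model import build_display_responses

    if w_grid is None:
        w_grid = np.round(np.arange(0.0, 1.0001, 0.05), 10)
    rows = []
    for w in w_grid:
        responses = build_display_responses(emb, displays, w_target=float(w))
        fit = fit_center(
            responses, rts, labels, n_restarts=n_restarts, seed=seed, **fit_kwargs
        )
        rows.append(
            {"w_target": float(w), "objective": fit.objective,
             "r_group_a": fit.r_group_a, "r_group_b": fit.r_group_b}
        )
    table = pd.DataFrame(rows)
    w_best = float(table.loc[table["objective"].idxmax(), "w_target"])
    return WeightSweepResult(table=table, w_best=w_best)


def vh_group_summary(vh: np.ndarray, labels) -> dict:
    """Group means/SDs of VH and a two-sided Wilcoxon rank-sum p-value.

    The exact null distribution is used when there are no ties; with ties the
    normal approximation (tie-corrected) is used instead.
    """
    vh = np.asarray(vh, dtype=float)
    in_a, in_b = split_groups(labels)
    a, b = vh[in_a], vh[in_b]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    out = {
        "group_a": {"n": int(a.size), "mean": float(a.mean()),
                    "sd": float(a.std(ddof=1)) if a.size > 1 else float("nan")},
        "group_b": {"n": int(b.size), "mean": float(b.mean()),
                    "sd": float(b.std(ddof=1)) if b.size > 1 else float("nan")},
    }
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "asymptotic" if has_ties else "exact"
    stat, p = mannwhitneyu(a, b, alternative="two-sided", method=method)
    out["ranksum"] = {"u": float(stat), "p": float(min(p, 1.0)), "method": method}
    return out
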