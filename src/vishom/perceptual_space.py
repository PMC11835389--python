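"""Perceptual space from oddball-search reaction times.

The reciprocal of the average oddball-search time for a pair of images is a
measure of their perceptual dissimilarity (units 1/s): hard searches mean
similar items.  Pooling all trials of a pair (both target/distractor roles,
all participants), taking 1/mean(RT), and embedding the resulting symmetric
dissimilarity matrix by multidimensional scaling yields coordinates whose
dimensions can be read as the responses of individual artificial neurons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.manifold import smacof

from ._utils import UndefinedCorrelationError, condensed_upper, pearson

TRIAL_COLUMNS = ["participant", "target_id", "distractor_id", "label", "rt_seconds", "correct"]


class MissingPairError(ValueError):
    """Raised when some object pair has no surviving trial."""


@dataclass
class DissimilarityMatrix:
    """Symmetric object-by-object perceptual distances, in 1/s.

    Off-diagonal entries are strictly positive; the diagonal is fixed at 0 and
    carries no information (there is no self-search).
    """

    objects: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.objects)
        if self.d.shape != (n, n):
            raise ValueError("dissimilarity matrix shape does not match object list")
        if not np.allclose(self.d, self.d.T, equal_nan=True):
            raise ValueError("dissimilarity matrix must be symmetric")

    @property
    def n_objects(self) -> int:
        return len(self.objects)

    def condensed(self) -> np.ndarray:
        return condensed_upper(self.d)


@dataclass
class PerceptualEmbedding:
    """MDS coordinates for objects, plus fit diagnostics.

    ``stress`` is Kruskal stress-1, sqrt(sum (dhat-d)^2 / sum d^2); ``fit_r``
    is the Pearson correlation between embedded and observed dissimilarities
    (NaN when the observed dissimilarities have zero variance).  Coordinates
    are centered on their centroid; orientation is arbitrary, and every
    downstream quantity is invariant to orthogonal transforms.
    """

    objects: list[str]
    coords: np.ndarray
    k: int
    stress: float
    fit_r: float
    criterion: str = "metric_stress"
    seed: int | None = None

    def distances(self) -> np.ndarray:
        from scipy.spatial.distance import squareform, pdist

        return squareform(pdist(self.coords))


@dataclass
class SplitHalfResult:
    r: float
    n_pairs: int
    n_excluded: int


def _pair_key(frame: pd.DataFrame) -> pd.Series:
    a = frame["target_id"].astype(str)
    b = frame["distractor_id"].astype(str)
    lo = a.where(a <= b, b)
    hi = b.where(a <= b, a)
    return lo + "\x1f" + hi


def filter_trials(
    trials: pd.DataFrame,
    min_rt: float = 0.3,
    max_rt: float = 3.0,
    min_accuracy: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Remove implausible and incorrect trials.

    Keeps correct trials with ``min_rt <= rt <= max_rt``.  When
    ``min_accuracy`` is given, additionally drops *all* of a participant's
    trials involving any object on which that participant's accuracy (over
    their unfiltered trials involving the object, as target or distractor)
    falls below the threshold.  Returns the surviving trials and a report
    with the fraction removed by each rule.
    """
    if not min_rt < max_rt:
        raise ValueError("min_rt must be smaller than max_rt")
    n0 = len(trials)
    if n0 == 0:
        raise ValueError("empty trial table")
    df = trials.copy()

    report: dict = {"n_input": n0}
    if min_accuracy is not None:
        long = pd.concat(
            [
                df[["participant", "correct"]].assign(object=df["target_id"].astype(str)),
                df[["participant", "correct"]].assign(object=df["distractor_id"].astype(str)),
            ]
        )
        acc = long.groupby(["participant", "object"])["correct"].mean()
        bad = set(acc[acc < min_accuracy].index)
        if bad:
            tkey = list(zip(df["participant"], df["target_id"].astype(str)))
            dkey = list(zip(df["participant"], df["distractor_id"].astype(str)))
            drop = np.array([t in bad or d in bad for t, d in zip(tkey, dkey)])
        else:
            drop = np.zeros(len(df), dtype=bool)
        report["n_low_accuracy"] = int(drop.sum())
        df = df[~drop]
    else:
        report["n_low_accuracy"] = 0

    rt = df["rt_seconds"].to_numpy(dtype=float)
    in_bounds = (rt >= min_rt) & (rt <= max_rt)
    report["n_rt_out_of_bounds"] = int((~in_bounds).sum())
    df = df[in_bounds]
    correct = df["correct"].astype(bool)
    report["n_incorrect"] = int((~correct).sum())
    df = df[correct.to_numpy()]

    report["n_output"] = len(df)
    report["fraction_removed"] = 1.0 - len(df) / n0
    if len(df) == 0:
        culprit = max(
            ("n_low_accuracy", "n_rt_out_of_bounds", "n_incorrect"),
            key=lambda key: report[key],
        )
        raise ValueError(f"all trials removed; dominant filter: {culprit}")
    return df.reset_index(drop=True), report


def dissimilarity_from_trials(
    trials: pd.DataFrame, objects: list[str] | None = None
) -> DissimilarityMatrix:
    """Pairwise dissimilarity d(i,j) = 1 / mean RT over all trials of pair {i,j}.

    Both target/distractor orderings of a pair are pooled before averaging
    (so d is symmetric by construction).  Every unordered pair of the object
    set must have at least one trial.
    """
    df = trials
    if objects is None:
        objects = sorted(
            set(df["target_id"].astype(str)) | set(df["distractor_id"].astype(str))
        )
    idx = {obj: i for i, obj in enumerate(objects)}
    n = len(objects)
    mean_rt = df.groupby(_pair_key(df))["rt_seconds"].mean()

    d = np.zeros((n, n))
    missing = []
    for i in range(n):
        for j in range(i + 1, n):
            key = "\x1f".join(sorted((objects[i], objects[j])))
            if key not in mean_rt.index:
                missing.append((objects[i], objects[j]))
                continue
            d[i, j] = d[j, i] = 1.0 / mean_rt[key]
    if missing:
        raise MissingPairError(
            f"{len(missing)} object pair(s) have no surviving trials, e.g. {missing[:5]}"
        )
    return DissimilarityMatrix(objects=list(objects), d=d)


def split_half_consistency(trials: pd.DataFrame) -> SplitHalfResult:
    """Correlation of per-pair mean RTs between even- and odd-numbered participants.

    Participants are numbered 1..P in sorted order; the halves are the odd and
    even ranks.  Pairs missing from either half are excluded and counted.
    """
    participants = sorted(trials["participant"].unique())
    if len(participants) < 2:
        raise ValueError("split-half consistency needs at least 2 participants")
    odd = {p for i, p in enumerate(participants, start=1) if i % 2 == 1}
    df = trials.copy()
    df["_pair"] = _pair_key(df)
    df["_half"] = np.where(df["participant"].isin(odd), "odd", "even")
    means = df.groupby(["_half", "_pair"])["rt_seconds"].mean().unstack("_half")
    complete = means.dropna()
    n_excluded = len(means) - len(complete)
    if n_excluded:
        warnings.warn(f"{n_excluded} pair(s) missing from one half; excluded")
    r = pearson(
        complete["odd"].to_numpy(),
        complete["even"].to_numpy(),
        context="split-half per-pair mean RTs",
    )
    return SplitHalfResult(r=r, n_pairs=len(complete), n_excluded=n_excluded)


def classical_mds(d: np.ndarray, k: int) -> np.ndarray:
    """Classical (Torgerson) scaling: exact for Euclidean distance matrices."""
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    vals, vecs = vals[order], vecs[:, order]
    coords = vecs * np.sqrt(np.clip(vals, 0.0, None))
    return coords


def embed_mds(
    d: DissimilarityMatrix,
    k: int,
    criterion: str = "metric_stress",
    n_init: int = 10,
    seed: int = 0,
    max_iter: int = 300,
    eps: float = 1e-10,
) -> PerceptualEmbedding:
    """Embed a dissimilarity matrix into k dimensions by SMACOF MDS.

    Best of ``n_init`` runs: the first is initialized from classical scaling
    (exact when the dissimilarities are Euclidean), the rest from perturbed
    copies of it.  ``criterion`` is ``metric_stress`` (default) or
    ``nonmetric_stress`` (Kruskal's nonmetric variant).
    """
    if criterion not in ("metric_stress", "nonmetric_stress"):
        raise ValueError(f"unknown MDS criterion {criterion!r}")
    n = d.n_objects
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    delta = np.asarray(d.d, dtype=float)
    if not np.all(np.isfinite(delta)):
        raise ValueError("dissimilarities must be finite")

    rng = np.random.default_rng(seed)
    init0 = classical_mds(delta, k)
    scale = float(np.sqrt((init0**2).mean())) or 1.0
    metric = criterion == "metric_stress"

    best_coords, best_raw = None, np.inf
    for i in range(max(1, n_init)):
        init = init0 if i == 0 else init0 + rng.normal(scale=0.1 * scale, size=init0.shape)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coords, raw_stress = smacof(
                delta,
                metric=metric,
                n_components=k,
                init=init,
                n_init=1,
                max_iter=max_iter,
                eps=eps,
                normalized_stress=False,
            )
        if raw_stress < best_raw:
            best_raw, best_coords = raw_stress, coords
    coords = best_coords - best_coords.mean(axis=0)

    from scipy.spatial.distance import pdist

    dhat = pdist(coords)
    dobs = condensed_upper(delta)
    denom = (dobs**2).sum()
    stress1 = float(np.sqrt(((dhat - dobs) ** 2).sum() / denom)) if denom > 0 else 0.0
    try:
        fit_r = pearson(dhat, dobs, context="embedded vs observed dissimilarities")
    except UndefinedCorrelationError:
        fit_r = float("nan")
        warnings.warn("observed dissimilarities have zero variance; fit_r undefined")
    return PerceptualEmbedding(
        objects=list(d.objects),
        coords=coords,
        k=k,
        stress=stress1,
        fit_r=fit_r,
        criterion=criterion,
        seed=seed,
    )


@dataclass
class DimensionSweepResult:
    table: pd.DataFrame = field(repr=False)
    selected_k: int = 0
    plateau_tol: float = 0.05


def dimension_sweep(
    trials: pd.DataFrame,
    displays,
    rts: np.ndarray,
    labels,
    k_range,
    *,
    criterion: str = "metric_stress",
    n_init: int = 4,
    seed: int = 0,
    use_loocv: bool = True,
    plateau_tol: float = 0.05,
    fit_kwargs: dict | None = None,
) -> DimensionSweepResult:
    """Sweep embedding dimensionality, scoring each k by |r_A| + |r_B| under
    leave-one-image-out cross-validation of the VH center fit.

    Returns the per-k table and the smallest k whose score is within
    ``plateau_tol`` of the sweep maximum (the start of the plateau).
    """
    from . import vh_model
    from .display_model import build_display_responses

    fit_kwargs = dict(fit_kwargs or {})
    d = dissimilarity_from_trials(trials)
    rows = []
    for k in k_range:
        emb = embed_mds(d, k=k, criterion=criterion, n_init=n_init, seed=seed)
        responses = build_display_responses(emb, displays)
        if use_loocv:
            res = vh_model.loocv_fit(
                responses, rts, labels,
                display_objects=[spec.object_ids for spec in displays],
                seed=seed, **fit_kwargs,
            )
            r_a, r_b = res.r_group_a, res.r_group_b
        else:
            fit = vh_model.fit_center(responses, rts, labels, seed=seed, **fit_kwargs)
            r_a, r_b = fit.r_group_a, fit.r_group_b
        rows.append({"k": int(k), "r_group_a": r_a, "r_group_b": r_b,
                     "score": abs(r_a) + abs(r_b)})
    table = pd.DataFrame(rows)
    best = table["score"].max()
    ok = table[table["score"] >= best - plateau_tol]
    return DimensionSweepResult(table=table, selected_k=int(ok["k"].min()),
                                plateau_tol=plateau_tol)
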