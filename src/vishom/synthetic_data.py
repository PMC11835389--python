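"""Synthetic behavioral and voxel data with the structure the analysis assumes.

Everything downstream of this module can be validated against a known ground
truth: objects live at known coordinates in a latent k-dimensional space;
oddball-search RTs are the reciprocal of inter-object distance plus noise;
present/absent (or symmetric/asymmetric) decision RTs follow a
distance-from-boundary law on the visual-homogeneity axis (slowest near the
boundary, hence opposite-sign correlations within the two groups and a
near-zero pooled correlation); and voxel volumes carry a planted
VH-encoding region, a planted RT-encoding region, and noise elsewhere.

Defaults mirror the study conditions: 32 objects, 5 latent dimensions, 16
participants, 2 search repetitions per pair (992 correct trials each),
~98% accuracy, a 0.05 s physical floor on RTs.  All draws are seeded, and
random streams are split per operation so enlarging one table never
perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._utils import rng_for
from .display_model import DisplaySpec, build_display_responses
from .searchlight import VoxelDataset, VoxelLayout
from .vh_model import visual_homogeneity

RT_FLOOR = 0.05  # seconds; truncation keeps simulated RTs physical


@dataclass(frozen=True)
class RTLink:
    """Linear distance-from-boundary RT law: rt = t_max - beta*|VH - b| + noise."""

    t_max: float = 1.8  # seconds, RT at the decision boundary
    beta: float = 0.4  # seconds of speed-up per unit VH away from the boundary
    sigma: float = 0.0  # trial noise SD, seconds

    def __post_init__(self) -> None:
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    """Latent geometry and RT laws behind one synthetic study."""

    embedding: np.ndarray  # (n_objects, k)
    center: np.ndarray  # (k,)
    boundary: float  # decision boundary on the VH axis
    rt_link: RTLink = field(default_factory=RTLink)
    search_noise_sigma: float = 0.1  # seconds, SD of search-RT trial noise
    seed: int = 0

    def __post_init__(self) -> None:
        emb = np.atleast_2d(np.asarray(self.embedding, dtype=float))
        object.__setattr__(self, "embedding", emb)
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.n_objects < 3:
            raise ValueError("need at least 3 objects")
        if self.center.shape != (self.k,):
            raise ValueError("center dimension must match embedding")

    @property
    def n_objects(self) -> int:
        return self.embedding.shape[0]

    @property
    def k(self) -> int:
        return self.embedding.shape[1]

    @property
    def objects(self) -> list[str]:
        return [f"obj{i:02d}" for i in range(self.n_objects)]

    @property
    def coords(self) -> np.ndarray:  # duck-types as a PerceptualEmbedding
        return self.embedding


def gen_embedding(n_objects: int, k: int, spread: float = 0.55, seed: int = 0) -> np.ndarray:
    """Draw object coordinates i.i.d. from an isotropic Gaussian N(0, spread^2 I).

    With the default spread, pairwise distances for 32 objects in 5
    dimensions land mostly in ~[0.7, 3] 1/s, i.e. noiseless search RTs of
    roughly 0.3-1.5 s — the plausible range for oddball search.
    """
    if n_objects < 3:
        raise ValueError("n_objects must be >= 3")
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = rng_for(seed, 1)
    return spread * rng.standard_normal((n_objects, k))


def gen_search_trials(
    gt: GroundTruth,
    trials_per_pair: int = 2,
    n_participants: int = 16,
    seed: int | None = None,
    accuracy: float = 0.98,
    rt_floor: float = RT_FLOOR,
) -> pd.DataFrame:
    """Oddball-search trial table: per-trial RT = 1/distance + truncated noise.

    Each participant contributes ``trials_per_pair`` trials per unordered
    object pair, alternating which item plays target.  Incorrect trials
    (Bernoulli with rate 1-``accuracy``) are flagged, not removed, so the
    filtering stage is exercised downstream.
    """
    if trials_per_pair < 1:
        raise ValueError("trials_per_pair must be >= 1")
    seed = gt.seed if seed is None else seed
    rng = rng_for(seed, 2)
    objs = gt.objects
    emb = gt.embedding
    n = gt.n_objects
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    dists = np.array([np.linalg.norm(emb[i] - emb[j]) for i, j in pairs])
    if gt.search_noise_sigma == 0 and np.any(dists == 0):
        raise ValueError(
            "zero inter-object distance with zero noise gives infinite RT; "
            "perturb the embedding or add noise"
        )

    rows = {k: [] for k in ("participant", "target_id", "distractor_id")}
    base = []
    for (i, j), d in zip(pairs, dists):
        for p in range(1, n_participants + 1):
            for t in range(trials_per_pair):
                tgt, dst = (i, j) if t % 2 == 0 else (j, i)
                rows["participant"].append(p)
                rows["target_id"].append(objs[tgt])
                rows["distractor_id"].append(objs[dst])
                base.append(np.inf if d == 0 else 1.0 / d)
    base = np.array(base)
    noise = rng.normal(scale=gt.search_noise_sigma, size=base.size)
    rt = np.maximum(base + noise, rt_floor)
    correct = rng.random(base.size) < accuracy
    return pd.DataFrame(
        {
            "participant": rows["participant"],
            "target_id": rows["target_id"],
            "distractor_id": rows["distractor_id"],
            "label": "search",
            "rt_seconds": rt,
            "correct": correct.astype(int),
        }
    )


def decision_rt_noiseless(vh: np.ndarray, boundary: float, link: RTLink) -> np.ndarray:
    """Deterministic part of the decision-RT law."""
    return link.t_max - link.beta * np.abs(np.asarray(vh) - boundary)


def gen_decision_trials(
    gt: GroundTruth,
    displays: list[DisplaySpec],
    seed: int | None = None,
    *,
    w_target: float = 0.5,
    n_participants: int = 16,
    reps: int = 1,
    accuracy: float = 0.95,
    label_mode: str = "displays",
    group_a_label: str = "present",
    group_b_label: str = "absent",
    rt_floor: float = RT_FLOOR,
) -> pd.DataFrame:
    """Decision trial table from the boundary RT law.

    Per display, VH_true = ||response - center_true|| with responses built by
    weighted averaging (``w_target`` for oddball arrays), and per-trial
    RT = t_max - beta*|VH_true - boundary| + noise, truncated at the floor.
    With ``label_mode='boundary'`` labels are assigned by which side of the
    boundary VH_true falls on (group A below, group B above); the default
    keeps the labels carried by the display specs, which allows the
    overlapping VH ranges seen in real data.
    """
    seed = gt.seed if seed is None else seed
    rng = rng_for(seed, 3)
    responses = build_display_responses(gt, displays, w_target=w_target)
    vh_true = visual_homogeneity(responses, gt.center)
    link = gt.rt_link
    base = decision_rt_noiseless(vh_true, gt.boundary, link)
    if np.any(base <= 0):
        import warnings

        warnings.warn("RT law yields negative pre-truncation RTs for some displays")

    if label_mode == "boundary":
        labels = np.where(vh_true < gt.boundary, group_a_label, group_b_label)
    elif label_mode == "displays":
        labels = np.array([d.label for d in displays])
    else:
        raise ValueError(f"unknown label_mode {label_mode!r}")

    n_disp = len(displays)
    rows = []
    for p in range(1, n_participants + 1):
        for rep in range(reps):
            rows.append(
                pd.DataFrame(
                    {
                        "participant": p,
                        "display_id": [d.display_id for d in displays],
                        "target_id": [d.target_id for d in displays],
                        "distractor_id": [
                            d.distractor_id if d.distractor_id is not None else d.target_id
                            for d in displays
                        ],
                        "label": labels,
                        "rt_seconds": np.maximum(
                            base + rng.normal(scale=link.sigma, size=n_disp), rt_floor
                        ),
                        "correct": (rng.random(n_disp) < accuracy).astype(int),
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def mean_decision_rts(trials: pd.DataFrame, displays: list[DisplaySpec]) -> np.ndarray:
    """Mean RT per display (correct trials only), aligned to the display list."""
    ok = trials[trials["correct"].astype(bool)]
    means = ok.groupby("display_id")["rt_seconds"].mean()
    return np.array([means[d.display_id] for d in displays])


def make_search_displays(
    gt: GroundTruth, n_present: int | None = None, seed: int | None = None
) -> list[DisplaySpec]:
    """Standard present/absent display set: one absent (singleton) display per
    object plus ``n_present`` oddball arrays with every object appearing
    equally often as target."""
    seed = gt.seed if seed is None else seed
    rng = rng_for(seed, 4)
    objs = gt.objects
    n = len(objs)
    n_present = n if n_present is None else n_present
    displays = [
        DisplaySpec(kind="singleton", target_id=o, label="absent") for o in objs
    ]
    targets = [objs[i % n] for i in range(n_present)]
    for tgt in targets:
        others = [o for o in objs if o != tgt]
        dst = others[int(rng.integers(len(others)))]
        displays.append(
            DisplaySpec(kind="oddball_array", target_id=tgt, distractor_id=dst,
                        label="present")
        )
    return displays


def _embedding_in_band(
    n_objects: int, k: int, spread: float, seed: int,
    min_dist: float, max_dist: float, max_tries: int = 200,
) -> np.ndarray:
    """Isotropic-Gaussian embedding, resampled until all pairwise distances
    lie in [min_dist, max_dist].

    Emulates stimulus-set curation: experimenters pick objects that are
    neither indistinguishable nor trivially different, which is what keeps
    real search RTs almost entirely inside the plausible 0.3-3 s window.
    """
    for attempt in range(max_tries):
        rng = rng_for(seed, 1, attempt)
        pts: list[np.ndarray] = []
        for _ in range(n_objects):
            for _ in range(2000):
                p = spread * rng.standard_normal(k)
                if not pts:
                    pts.append(p)
                    break
                d = np.linalg.norm(np.asarray(pts) - p, axis=1)
                if d.min() >= min_dist and d.max() <= max_dist:
                    pts.append(p)
                    break
            else:
                break  # stuck; restart with a fresh stream
        if len(pts) == n_objects:
            return np.asarray(pts)
    raise RuntimeError(
        f"could not draw an embedding with distances in [{min_dist}, {max_dist}] "
        f"after {max_tries} tries; widen the band or change spread"
    )


def make_ground_truth(
    n_objects: int = 32,
    k: int = 5,
    spread: float = 0.55,
    seed: int = 0,
    *,
    search_noise_sigma: float = 0.1,
    rt_noise_frac: float = 0.1,
    t_max: float = 1.8,
    beta: float | None = None,
    displays: list[DisplaySpec] | None = None,
    dist_band: tuple[float, float] = (0.4, 3.0),
) -> tuple[GroundTruth, list[DisplaySpec]]:
    """Assemble a full synthetic study: geometry, center, boundary, RT laws.

    The true center is the object centroid; the boundary is the midpoint of
    the mean VH of the present-group and absent-group displays; ``beta`` is
    chosen so the noiseless decision RTs span ~0.5 s, and the trial noise SD
    is ``rt_noise_frac`` of that noiseless RT range (0.1 by default).
    Pairwise distances are constrained to ``dist_band`` (1/s) so noiseless
    search RTs stay within the 0.3-3 s plausibility window.
    """
    emb = _embedding_in_band(n_objects, k, spread, seed, *dist_band)
    center = emb.mean(axis=0)
    gt = GroundTruth(
        embedding=emb, center=center, boundary=0.0,
        rt_link=RTLink(t_max=t_max, beta=1.0, sigma=0.0),
        search_noise_sigma=search_noise_sigma, seed=seed,
    )
    if displays is None:
        displays = make_search_displays(gt, seed=seed)
    responses = build_display_responses(gt, displays)
    vh = visual_homogeneity(responses, center)
    labels = np.array([d.label for d in displays])
    from .vh_model import split_groups

    in_a, in_b = split_groups(labels)
    boundary = 0.5 * (vh[in_a].mean() + vh[in_b].mean())
    if beta is None:
        span = np.abs(vh - boundary).max()
        beta = 0.5 / span if span > 0 else 1.0
    rt_range = beta * (np.abs(vh - boundary).max() - np.abs(vh - boundary).min())
    link = RTLink(t_max=t_max, beta=float(beta), sigma=float(rt_noise_frac * rt_range))
    return replace(gt, boundary=float(boundary), rt_link=link), displays


def make_symmetric_design(
    n_per_group: int = 32,
    k: int = 5,
    boundary: float = 1.0,
    delta_range: tuple[float, float] = (0.1, 0.5),
    seed: int = 0,
    *,
    t_max: float = 1.8,
    beta: float = 0.4,
    rt_noise_frac: float = 0.1,
    min_separation: float = 0.36,
    group_a_label: str = "asymmetric",
    group_b_label: str = "symmetric",
) -> tuple[GroundTruth, list[DisplaySpec]]:
    """A design whose two VH distributions mirror each other about the boundary.

    Objects are singleton displays placed on random directions at radii
    boundary -/+ delta (group A / group B) from the true center, with matched
    deltas, so the pooled population correlation between VH and RT is exactly
    zero while the within-group correlations are +/-1 before noise.  Noise SD
    is ``rt_noise_frac`` of the noiseless RT range.  Directions are drawn
    sequentially, rejecting any point closer than ``min_separation`` to an
    earlier one, which keeps all noiseless search RTs below the 3 s filter.
    """
    rng = rng_for(seed, 5)
    deltas = np.sort(rng.uniform(*delta_range, size=n_per_group))
    radii = np.concatenate([boundary - deltas, boundary + deltas])
    emb = np.empty((2 * n_per_group, k))
    for i, radius in enumerate(radii):
        for _ in range(10_000):
            v = rng.standard_normal(k)
            pt = radius * v / np.linalg.norm(v)
            if i == 0 or np.linalg.norm(emb[:i] - pt, axis=1).min() >= min_separation:
                emb[i] = pt
                break
        else:
            raise RuntimeError(
                "could not place objects with the requested minimum separation; "
                "reduce n_per_group or min_separation"
            )
    labels = [group_a_label] * n_per_group + [group_b_label] * n_per_group
    rt_range = beta * (deltas.max() - deltas.min())
    gt = GroundTruth(
        embedding=emb, center=np.zeros(k), boundary=boundary,
        rt_link=RTLink(t_max=t_max, beta=beta, sigma=float(rt_noise_frac * rt_range)),
        seed=seed,
    )
    displays = [
        DisplaySpec(kind="singleton", target_id=obj, label=lab)
        for obj, lab in zip(gt.objects, labels)
    ]
    return gt, displays


def make_layout(
    grid_shape: tuple[int, int, int] = (20, 20, 20),
    vh_corner: tuple[int, int, int] = (3, 3, 3),
    rt_corner: tuple[int, int, int] = (13, 13, 13),
    region_shape: tuple[int, int, int] = (4, 4, 4),
    noise_sigma: float = 1.0,
    mask: np.ndarray | None = None,
) -> VoxelLayout:
    """Full-grid mask with two disjoint planted cuboid regions."""
    if mask is None:
        mask = np.ones(grid_shape, dtype=bool)
    vh_region = np.zeros(grid_shape, dtype=bool)
    rt_region = np.zeros(grid_shape, dtype=bool)
    sl = lambda c: tuple(slice(a, a + b) for a, b in zip(c, region_shape))
    vh_region[sl(vh_corner)] = True
    rt_region[sl(rt_corner)] = True
    return VoxelLayout(grid_shape=grid_shape, mask=mask, vh_region=vh_region,
                       rt_region=rt_region, noise_sigma=noise_sigma)


def gen_voxel_data(
    layout: VoxelLayout,
    vh: np.ndarray,
    rt: np.ndarray,
    seed: int = 0,
    *,
    conditions: list[str] | None = None,
    gain_vh: float = 1.0,
    gain_rt: float = 1.0,
    baseline: float = 0.0,
    n_subjects: int = 1,
) -> VoxelDataset:
    """Per-condition activation volumes with planted VH and RT codes.

    Inside the VH region, activation(condition) = baseline + gain_vh *
    vh(condition) + noise; inside the RT region the same with RT; everywhere
    else in the mask, pure noise.  ``n_subjects`` > 1 yields per-subject
    volumes (independent noise) whose mean populates ``betas``.
    """
    vh = np.asarray(vh, dtype=float)
    rt = np.asarray(rt, dtype=float)
    if vh.shape != rt.shape:
        raise ValueError("vh and rt must be indexed by the same condition list")
    n_cond = vh.size
    if conditions is None:
        conditions = [f"cond{i:03d}" for i in range(n_cond)]
    rng = rng_for(seed, 6)
    shape = layout.grid_shape
    signal = np.zeros((n_cond,) + tuple(shape))
    signal[:, layout.vh_region] = baseline + gain_vh * vh[:, None]
    signal[:, layout.rt_region] = baseline + gain_rt * rt[:, None]
    subj = signal[None] + rng.normal(
        scale=layout.noise_sigma, size=(n_subjects, n_cond) + tuple(shape)
    )
    subj *= layout.mask[None, None]
    betas = subj.mean(axis=0)
    return VoxelDataset(
        mask=layout.mask, conditions=list(conditions), betas=betas,
        subject_betas=subj if n_subjects > 1 else None,
    )
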