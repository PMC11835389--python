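"""Predicted responses to search displays via multiple-object averaging.

Under divisive normalization in high-level visual cortex, the population
response to several simultaneously presented objects is (approximately) the
average of the single-object responses.  Two consequences drive everything
downstream:

* a homogeneous (target-absent) array of identical items evokes the same
  response as the single item, and
* an oddball (target-present) array evokes a response on the line segment
  joining the target and distractor responses — a convex combination with
  weights that default to equal (plain averaging) but may be swept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: display labels whose RTs are expected to correlate positively with VH
GROUP_A_LABELS = frozenset({"present", "asymmetric"})
#: display labels whose RTs are expected to correlate negatively with VH
GROUP_B_LABELS = frozenset({"absent", "symmetric"})


@dataclass(frozen=True)
class DisplaySpec:
    """A stimulus display: a single item, or an oddball array of two identities.

    ``oddball_array`` displays carry a distinct target and distractor id;
    ``singleton`` displays carry one object id (``distractor_id`` is None).
    """

    kind: str  # "singleton" | "oddball_array"
    target_id: str
    distractor_id: str | None = None
    label: str = ""
    display_id: str = field(default="")

    def __post_init__(self) -> None:
        if self.kind not in ("singleton", "oddball_array"):
            raise ValueError(f"unknown display kind {self.kind!r}")
        if self.kind == "oddball_array":
            if self.distractor_id is None:
                raise ValueError("oddball_array requires a distractor_id")
        if not self.display_id:
            object.__setattr__(self, "display_id", self._default_id())

    def _default_id(self) -> str:
        if self.kind == "singleton":
            return f"{self.label or 'single'}:{self.target_id}"
        return f"{self.label or 'array'}:{self.target_id}|{self.distractor_id}"

    @property
    def object_ids(self) -> tuple[str, ...]:
        if self.kind == "singleton" or self.distractor_id == self.target_id:
            return (self.target_id,)
        return (self.target_id, self.distractor_id)


def _object_index(emb) -> dict:
    return {obj: i for i, obj in enumerate(emb.objects)}


def singleton_response(emb, object_id: str) -> np.ndarray:
    """Response vector to a single item (= its embedding coordinates).

    A target-absent array of identical items evokes this same vector, so this
    function also serves as the absent-array response.
    """
    try:
        row = _object_index(emb)[object_id]
    except KeyError:
        raise KeyError(f"object {object_id!r} not in embedding") from None
    return np.asarray(emb.coords[row], dtype=float).copy()


def array_response(
    emb,
    target_id: str,
    distractor_id: str,
    w_target: float = 0.5,
    w_distractor: float = 0.5,
) -> np.ndarray:
    """Response to an oddball array: weighted average of target and distractor.

    Weights are normalized to sum to 1 on entry, making the weighted variant a
    one-parameter family; (0.5, 0.5) is plain multiple-object averaging.
    """
    if w_target < 0 or w_distractor < 0:
        raise ValueError("summation weights must be non-negative")
    total = w_target + w_distractor
    if total == 0:
        raise ValueError("at least one summation weight must be positive")
    wt, wd = w_target / total, w_distractor / total
    return wt * singleton_response(emb, target_id) + wd * singleton_response(
        emb, distractor_id
    )


def build_display_responses(
    emb,
    displays: Sequence[DisplaySpec],
    w_target: float = 0.5,
) -> np.ndarray:
    """Stack response vectors for a display list, order preserved.

    Returns an (n_displays, k) array.  ``w_target`` applies to oddball arrays
    only; the distractor weight is ``1 - w_target`` after normalization.
    """
    rows = []
    for spec in displays:
        if spec.kind == "singleton":
            rows.append(singleton_response(emb, spec.target_id))
        else:
            rows.append(
                array_response(emb, spec.target_id, spec.distractor_id, w_target, 1.0 - w_target)
            )
    if not rows:
        return np.empty((0, emb.coords.shape[1]))
    return np.vstack(rows)


def displays_to_frame(displays: Iterable[DisplaySpec]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "display_id": d.display_id,
                "kind": d.kind,
                "target_id": d.target_id,
                "distractor_id": "" if d.distractor_id is None else d.distractor_id,
                "label": d.label,
            }
            for d in displays
        ]
    )


def displays_from_frame(frame: pd.DataFrame) -> list[DisplaySpec]:
    out = []
    for row in frame.itertuples(index=False):
        distractor = getattr(row, "distractor_id", "")
        distractor = None if distractor in ("", None) or pd.isna(distractor) else str(distractor)
        out.append(
            DisplaySpec(
                kind=str(row.kind),
                target_id=str(row.target_id),
                distractor_id=distractor,
                label=str(row.label),
                display_id=str(row.display_id),
            )
        )
    return out
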