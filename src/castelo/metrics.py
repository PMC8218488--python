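"""Comparison metrics and ranking of atom subtypes.

Each atom subtype's per-frame cluster-size series C_{t,A} is compared against
the whole-molecule reference series C_{t,S} with two metrics:

* cosine similarity  CosSim = Σ_t A_t S_t / (‖A‖ ‖S‖), in (0, 1] for positive
  size series — low values mean the subtype's clustering departs from the
  whole-molecule behaviour;
* average difference AvgDiff = Σ_t (A_t − S_t) / T, negative when the subtype
  is less stable (smaller clusters) than the whole molecule.

Both are mean-centred over the subtypes present in the ligand (nCosSim,
nAvgDiff), averaged over the CVAE ensemble (the std across ensemble members
is an agreement score), and combined into a final rank with rank 1 the most
"malicious" subtype — the prime candidate for chemical modification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, UndefinedValueError

__all__ = [
    "SubtypeMetrics",
    "cosine_similarity",
    "average_difference",
    "normalize",
    "aggregate_ensemble",
    "rank_subtypes",
]


@dataclass
class SubtypeMetrics:
    """Ensemble-aggregated comparison metrics for one atom subtype."""

    subtype_id: int
    cos_sim: float
    avg_diff: float
    cos_sim_std: float = 0.0
    avg_diff_std: float = 0.0
    n_cos_sim: float = float("nan")
    n_avg_diff: float = float("nan")


def _as_aligned(a, s) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(getattr(a, "sizes", a), dtype=float)
    s = np.asarray(getattr(s, "sizes", s), dtype=float)
    if a.shape != s.shape or a.ndim != 1:
        raise AlignmentError(
            f"series must be 1-D and equal length, got shapes {a.shape} and {s.shape}"
        )
    if a.size == 0:
        raise AlignmentError("series must have at least one frame")
    return a, s


def cosine_similarity(a, s) -> float:
    """CosSim between a subtype size series and the reference series.

    Accepts ``ClusterSizeSeries`` or plain 1-D arrays. Raises
    :class:`UndefinedValueError` if either series is all-zero.
    """
    a, s = _as_aligned(a, s)
    na, ns = np.linalg.norm(a), np.linalg.norm(s)
    if na == 0.0 or ns == 0.0:
        raise UndefinedValueError("cosine similarity undefined for all-zero series")
    return float(np.dot(a, s) / (na * ns))


def average_difference(a, s) -> float:
    """AvgDiff: mean over frames of (A_t − S_t), in frames."""
    a, s = _as_aligned(a, s)
    return float(np.mean(a - s))


def normalize(values) -> np.ndarray:
    """Centre per-subtype metric values by their unweighted mean."""
    values = np.asarray(values, dtype=float)
    return values - values.mean()


def aggregate_ensemble(per_model_values) -> tuple[np.ndarray, np.ndarray]:
    """Mean and population std over ensemble members.

    ``per_model_values`` has shape (n_models, n_subtypes) (or (n_models,) for
    a single subtype). A single model gives std 0.
    """
    v = np.atleast_2d(np.asarray(per_model_values, dtype=float))
    return v.mean(axis=0), v.std(axis=0)


def rank_subtypes(
    metrics: list[SubtypeMetrics],
    stable: bool = True,
) -> pd.DataFrame:
    """Rank subtypes from most to least "malicious".

    Each subtype is ranked separately by ascending nCosSim and ascending
    nAvgDiff; the final rank orders subtypes by the mean of those two ranks,
    ties broken by ascending subtype id. The nCosSim/nAvgDiff columns are
    (re)computed here by mean-centring the ensemble means, so the invariant
    mean(nCosSim) = mean(nAvgDiff) = 0 holds over the returned table.

    If ``stable`` is false the simulation has no persistent binding mode and
    low metric values cannot be read as malicious atoms; a prominent warning
    is emitted but ranks are still returned.
    """
    if not metrics:
        raise ValueError("need at least one subtype")
    if not stable:
        warnings.warn(
            "Reference clustering is NOT stable: ranking is returned but the "
            "malicious-atom interpretation is invalid (the method requires a "
            "stable whole-molecule binding mode).",
            stacklevel=2,
        )
    ids = np.array([m.subtype_id for m in metrics])
    n_cos = normalize([m.cos_sim for m in metrics])
    n_avg = normalize([m.avg_diff for m in metrics])

    def _rank(values: np.ndarray) -> np.ndarray:
        # competition-free dense ordering: ties share their average rank
        from scipy.stats import rankdata

        return rankdata(values, method="average")

    r_cos = _rank(n_cos)
    r_avg = _rank(n_avg)
    composite = (r_cos + r_avg) / 2.0
    order = np.lexsort((ids, composite))
    final = np.empty(len(ids), dtype=int)
    final[order] = np.arange(1, len(ids) + 1)
    df = pd.DataFrame(
        {
            "subtype_id": ids,
            "n_cos_sim": n_cos,
            "n_avg_diff": n_avg,
            "cos_sim": [m.cos_sim for m in metrics],
            "avg_diff": [m.avg_diff for m in metrics],
            "agreement_std_cos_sim": [m.cos_sim_std for m in metrics],
            "agreement_std_avg_diff": [m.avg_diff_std for m in metrics],
            "rank_cos_sim": r_cos,
            "rank_avg_diff": r_avg,
            "rank": final,
        }
    )
    return df.sort_values("rank", kind="stable").reset_index(drop=True)
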