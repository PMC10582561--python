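"""Cell-level phenotype prediction by weighted plurality voting over pixel
predictions, with the exact theoretical voting accuracy.

Each pixel of a cell casts a vote for its argmax class, weighted by

    W(x) = alpha * (Morpho(x) - beta(x))**gamma + C

where ``beta`` is the substrate height (0 by convention).  The defaults
alpha = 0, gamma = 0, C = 1 make every weight 1, i.e. simple plurality
voting free of empirical tuning.

If pixel predictions were independent with per-pixel probability ``p0`` of
the correct class (and ``p1``, ``p2`` for the two wrong classes), the
probability that the correct class wins a strict plurality among ``m``
pixels is an exact sum of multinomial probabilities over the outcomes
(r, w1, w2), r + w1 + w2 = m, with r > max(w1, w2).  Ties are counted as
failures, a conservative convention.  Real pixel predictions are spatially
correlated, so this is an idealised bound, but it explains why even modest
per-pixel accuracy (~75 %) yields near-certain cell classification once a
cell spans a few dozen pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import lgamma, log
from typing import Callable, Sequence

import numpy as np

from .classifier import CLASSES

__all__ = [
    "WeightParams",
    "VotingOutcome",
    "vote_weight",
    "vote_cell",
    "vote_cells",
    "theoretical_voting_accuracy",
    "accuracy_curve",
    "min_pixels_for_accuracy",
    "even_split",
]


@dataclass(frozen=True)
class WeightParams:
    """Parameters of the polynomial voting-weight function.

    ``beta`` may be a constant or a callable of the Morpho value's pixel;
    the default constant 0 encodes the substrate-at-0 height convention.
    """

    alpha: float = 0.0
    gamma: float = 0.0
    C: float = 1.0
    beta: float = 0.0


def vote_weight(morpho, params: WeightParams = WeightParams()):
    """Voting weight W = alpha * (morpho - beta)**gamma + C.

    With the default parameters every pixel weighs 1.  ``0**0`` is taken
    as 1, so gamma = 0 gives a flat alpha + C regardless of height.
    """
    base = np.asarray(morpho, dtype=float) - params.beta
    if params.gamma != int(params.gamma) and np.any(base < 0):
        raise ValueError("morpho < beta with non-integer gamma")
    w = params.alpha * base**params.gamma + params.C
    if not np.all(np.isfinite(w)):
        raise ValueError("non-finite voting weight")
    return float(w) if np.isscalar(morpho) else w


@dataclass
class VotingOutcome:
    """Weighted tallies, winner and per-pixel votes for one cell."""

    tallies: dict[str, float]
    predicted: str
    tie_flag: bool
    pixel_votes: np.ndarray = field(default_factory=lambda: np.array([]))
    cell_id: str = ""
    label: str = "unknown"


def vote_cell(
    probs: np.ndarray,
    weights: np.ndarray | None = None,
    classes: Sequence[str] = CLASSES,
    cell_id: str = "",
    label: str = "unknown",
) -> VotingOutcome:
    """Aggregate per-pixel softmax probabilities into one cell phenotype.

    ``probs`` is (m, k); each pixel votes for its argmax class with its
    weight.  An exact tally tie sets ``tie_flag`` and is broken by the
    summed weighted probability, then by lowest class index, keeping the
    pipeline deterministic.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 2 or len(probs) == 0:
        raise ValueError("need a non-empty (m, k) probability array")
    m, k = probs.shape
    weights = np.ones(m) if weights is None else np.asarray(weights, dtype=float)
    votes = probs.argmax(axis=1)
    tallies = np.zeros(k)
    np.add.at(tallies, votes, weights)
    top = tallies.max()
    winners = np.nonzero(tallies == top)[0]
    tie = len(winners) > 1
    if tie:
        soft = weights @ probs
        soft_winners = winners[soft[winners] == soft[winners].max()]
        winner = int(soft_winners[0])
    else:
        winner = int(winners[0])
    return VotingOutcome(
        tallies={classes[i]: float(tallies[i]) for i in range(k)},
        predicted=classes[winner],
        tie_flag=tie,
        pixel_votes=votes,
        cell_id=cell_id,
        label=label,
    )


def vote_cells(
    predictions,
    classes: Sequence[str] = CLASSES,
    weight_params: WeightParams = WeightParams(),
) -> list[VotingOutcome]:
    """Vote every cell of a pixel-prediction table (grouped by cell_id).

    ``predictions`` is the output of
    :func:`nanovote.classifier.predict_pixels` and must carry ``cell_id``,
    ``Morpho`` (raw, nm, for the weight function) and the ``p_<class>``
    probability columns.
    """
    prob_cols = [f"p_{c}" for c in classes]
    outcomes = []
    for cell_id, group in predictions.groupby("cell_id", sort=True):
        probs = group[prob_cols].to_numpy()
        weights = vote_weight(group["Morpho"].to_numpy(), weight_params)
        weights = np.broadcast_to(np.asarray(weights, dtype=float), (len(group),))
        label = group["Category"].iloc[0] if "Category" in group else "unknown"
        outcomes.append(
            vote_cell(probs, weights, classes, cell_id=str(cell_id), label=label)
        )
    return outcomes


#: display colours of the pixel-vote map: M0 red, M1 green, M2 blue
VOTE_COLORS = np.array(
    [[220, 50, 47], [60, 170, 60], [50, 90, 220]], dtype=np.uint8
)


def vote_map_rgb(
    vote_grid: np.ndarray, mask: np.ndarray | None = None
) -> np.ndarray:
    """Render a per-pixel argmax-class grid as an RGB image (uint8).

    ``vote_grid`` holds class indices; pixels outside ``mask`` (or with a
    negative index) are black.  Save with ``imageio.imwrite`` or
    ``tifffile.imwrite`` as PNG/TIFF.
    """
    grid = np.asarray(vote_grid, dtype=int)
    rgb = np.zeros(grid.shape + (3,), dtype=np.uint8)
    ok = grid >= 0
    if mask is not None:
        ok &= mask
    rgb[ok] = VOTE_COLORS[grid[ok] % len(VOTE_COLORS)]
    return rgb


def _validate_probs(p0: float, p1: float, p2: float) -> None:
    if min(p0, p1, p2) < 0 or abs(p0 + p1 + p2 - 1.0) > 1e-9:
        raise ValueError(f"invalid probability vector ({p0}, {p1}, {p2})")


def theoretical_voting_accuracy(m: int, p0: float, p1: float, p2: float) -> float:
    """Exact probability that strict plurality voting over ``m``
    independent pixels picks the correct class.

    Sums the multinomial probabilities of every outcome (r, w1, w2) with
    r + w1 + w2 = m in which the correct-class count r strictly exceeds
    both wrong-class counts; ties count as failures.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    _validate_probs(p0, p1, p2)
    log_p = [log(p) if p > 0 else -np.inf for p in (p0, p1, p2)]
    lg = lgamma
    total = 0.0
    for r in range(m, -1, -1):
        if r <= m // 3:  # r cannot beat both wrong classes below m/3
            break
        if p0 == 0.0 and r > 0:
            continue
        base = lg(m + 1) - lg(r + 1) + r * (log_p[0] if r else 0.0)
        rem = m - r
        for w1 in range(min(rem, r - 1) + 1):
            w2 = rem - w1
            if w2 >= r:
                continue
            if (p1 == 0.0 and w1 > 0) or (p2 == 0.0 and w2 > 0):
                continue
            lt = base - lg(w1 + 1) - lg(w2 + 1)
            if w1:
                lt += w1 * log_p[1]
            if w2:
                lt += w2 * log_p[2]
            total += np.exp(lt)
    return min(float(total), 1.0)


def even_split(p0: float) -> tuple[float, float, float]:
    """Probability vector with the error mass split evenly between the two
    wrong classes: (p0, (1-p0)/2, (1-p0)/2).

    Helper for theory checks when only the diagonal (per-class accuracy)
    of a confusion matrix is known.
    """
    q = (1.0 - p0) / 2.0
    return p0, q, q


def accuracy_curve(
    p0: float, p1: float, p2: float, m_values: Sequence[int]
) -> np.ndarray:
    """Theoretical voting accuracy at each pixel count in ``m_values``."""
    return np.array([theoretical_voting_accuracy(m, p0, p1, p2) for m in m_values])


def min_pixels_for_accuracy(
    p0: float,
    p1: float,
    p2: float,
    threshold: float,
    m_max: int = 2000,
    on_dip: Callable[[int, float], None] | None = None,
) -> int:
    """Smallest pixel count whose theoretical voting accuracy reaches
    ``threshold``.

    Returns the first crossing; because plurality accuracy can oscillate
    with the parity of m, any later dip back below the threshold (up to
    a short lookahead) is reported through ``on_dip(m, accuracy)``.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    _validate_probs(p0, p1, p2)
    first = None
    for m in range(1, m_max + 1):
        acc = theoretical_voting_accuracy(m, p0, p1, p2)
        if first is None and acc >= threshold:
            first = m
        elif first is not None:
            if acc < threshold and on_dip is not None:
                on_dip(m, acc)
            if m >= first + 8:
                break
    if first is None:
        raise ValueError(
            f"voting accuracy never reaches {threshold} up to m = {m_max}; "
            "the correct class must dominate for the limit to be 1"
        )
    return first
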