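"""z-score event-based progression model.

The model describes disease progression as an ordered sequence of *events*,
where an event is a biomarker (regional atrophy z-score) crossing a z
threshold ("waypoint", default z = 1, 2, 3).  A *trajectory* is a permutation
of all events that respects the per-biomarker threshold order; a subject's
*stage* is the number of events that have occurred.  Between its event
positions each biomarker's expected z-score rises piecewise-linearly from 0
through its thresholds up to ``z_max`` at the final stage.

The subject likelihood marginalizes a Gaussian observation model over a
uniform stage prior; a mixture of trajectories with fractions ``f_c`` gives
the subtype model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "EventSet",
    "SubtypeModel",
    "build_event_set",
    "validate_ordering",
    "expected_trajectory",
    "stage_likelihoods",
    "subject_loglik",
    "mixture_loglik",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class EventSet:
    """Shared event definition: biomarkers, per-biomarker z thresholds, z_max.

    Events are indexed 0..E-1 in (biomarker, threshold) lexicographic order;
    ``event_biomarker[e]`` and ``event_threshold[e]`` resolve an event id.
    """

    biomarkers: tuple
    thresholds: tuple  # tuple of tuples, one per biomarker, strictly increasing
    z_max: float = 5.0
    # derived (filled in __post_init__)
    event_biomarker: np.ndarray = field(default=None, repr=False, compare=False)
    event_threshold: np.ndarray = field(default=None, repr=False, compare=False)
    event_rank: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        bi, zt, rk = [], [], []
        for b, ths in enumerate(self.thresholds):
            for t, z in enumerate(ths):
                bi.append(b)
                zt.append(float(z))
                rk.append(t)
        object.__setattr__(self, "event_biomarker", np.asarray(bi, dtype=np.intp))
        object.__setattr__(self, "event_threshold", np.asarray(zt, dtype=float))
        object.__setattr__(self, "event_rank", np.asarray(rk, dtype=np.intp))

    @property
    def n_biomarkers(self) -> int:
        return len(self.biomarkers)

    @property
    def n_events(self) -> int:
        return int(self.event_biomarker.size)

    @property
    def n_stages(self) -> int:
        return self.n_events + 1


def build_event_set(biomarkers, thresholds=(1.0, 2.0, 3.0), z_max=5.0) -> EventSet:
    """Create a validated :class:`EventSet`.

    ``thresholds`` is either one sequence applied to every biomarker or a
    mapping biomarker-name -> sequence.
    """
    biomarkers = tuple(biomarkers)
    if len(biomarkers) == 0:
        raise ValueError("need at least one biomarker")
    if len(set(biomarkers)) != len(biomarkers):
        raise ValueError("duplicate biomarker names")
    if isinstance(thresholds, dict):
        per = tuple(tuple(float(z) for z in thresholds[b]) for b in biomarkers)
    else:
        shared = tuple(float(z) for z in thresholds)
        per = tuple(shared for _ in biomarkers)
    for b, ths in zip(biomarkers, per):
        if len(ths) == 0:
            raise ValueError(f"biomarker {b!r} has no thresholds")
        if any(z2 <= z1 for z1, z2 in zip(ths, ths[1:])):
            raise ValueError(f"thresholds for {b!r} must be strictly increasing")
        if ths[-1] >= z_max:
            raise ValueError(f"thresholds for {b!r} must lie below z_max={z_max}")
    return EventSet(biomarkers=biomarkers, thresholds=per, z_max=float(z_max))


def validate_ordering(order: np.ndarray, es: EventSet) -> np.ndarray:
    """Check that ``order`` is a permutation of the event ids respecting the
    per-biomarker threshold order; return it as an int array."""
    order = np.asarray(order, dtype=np.intp)
    E = es.n_events
    if order.shape != (E,) or not np.array_equal(np.sort(order), np.arange(E)):
        raise ValueError("ordering must be a permutation of the event ids")
    pos = np.empty(E, dtype=np.intp)
    pos[order] = np.arange(E)
    for b in range(es.n_biomarkers):
        p = pos[es.event_biomarker == b]
        if np.any(np.diff(p) <= 0):
            raise ValueError(
                f"ordering violates threshold order for biomarker "
                f"{es.biomarkers[b]!r}"
            )
    return order


def _positions_matrix(order: np.ndarray, es: EventSet) -> np.ndarray:
    """(B, T_max) 1-based positions of each biomarker's events in threshold
    order, NaN-padded when threshold counts differ."""
    E = es.n_events
    pos = np.empty(E, dtype=float)
    pos[order] = np.arange(1, E + 1)
    t_max = max(len(t) for t in es.thresholds)
    P = np.full((es.n_biomarkers, t_max), np.nan)
    P[es.event_biomarker, es.event_rank] = pos
    return P


def _trajectory_from_positions(P: np.ndarray, es: EventSet) -> np.ndarray:
    """Piecewise-linear expected z ``g[b, k]`` for stages k = 0..E given the
    1-based event positions ``P`` (as from :func:`_positions_matrix`).

    Anchors per biomarker: (0, 0), (p_t, z_t) for each threshold, and
    (E, z_max).  When the last event sits at position E the threshold anchor
    takes precedence over the z_max anchor.
    """
    B, t_max = P.shape
    E = es.n_events
    K = E + 1
    # anchor x/y with a sentinel segment beyond E so the search never
    # overruns; padded (NaN) thresholds repeat the previous anchor.
    xp = np.empty((B, t_max + 2))
    yp = np.empty((B, t_max + 2))
    xp[:, 0] = 0.0
    yp[:, 0] = 0.0
    for t in range(t_max):
        col = P[:, t]
        prev = xp[:, t]
        filled = np.where(np.isnan(col), prev, col)
        xp[:, t + 1] = filled
        z_col = np.array(
            [ths[t] if t < len(ths) else ths[-1] for ths in es.thresholds]
        )
        yp[:, t + 1] = np.where(np.isnan(col), yp[:, t], z_col)
    last = xp[:, t_max]
    # final anchor at (E, z_max); if an event already sits at E, push the
    # sentinel to E+1 so interpolation up to stage E ends on the threshold.
    xp[:, -1] = np.where(last >= E, E + 1.0, float(E))
    yp[:, -1] = es.z_max
    # guard zero-length duplicate segments from NaN padding
    seg = np.diff(xp, axis=1)
    seg[seg == 0] = 1.0
    k = np.arange(K, dtype=float)
    idx = (xp[:, None, :] <= k[None, :, None]).sum(axis=2) - 1
    idx = np.clip(idx, 0, t_max)
    rows = np.arange(B)[:, None]
    x0 = xp[rows, idx]
    y0 = yp[rows, idx]
    y1 = yp[rows, idx + 1]
    d = seg[rows, idx]
    g = y0 + (k[None, :] - x0) * (y1 - y0) / d
    return g


def expected_trajectory(order: np.ndarray, es: EventSet) -> np.ndarray:
    """Expected z-score matrix ``g[b, k]`` (biomarkers x stages 0..E) for a
    valid event ordering."""
    order = validate_ordering(order, es)
    return _trajectory_from_positions(_positions_matrix(order, es), es)


def _check_sigma(sigma, es: EventSet) -> np.ndarray:
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), (es.n_biomarkers,))
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    return sigma


def _stage_logdens(Z: np.ndarray, g: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """log Π_b N(z_jb; g_bk, σ_b) for every subject j and stage k.

    Expanded as a matrix product so fitting can evaluate thousands of
    candidate orderings per second.
    """
    w = 1.0 / sigma**2
    const = -0.5 * g.shape[0] * _LOG_2PI - np.log(sigma).sum()
    zq = (Z**2 * w).sum(axis=1)  # (n,)
    gq = (g.T**2 * w).sum(axis=1)  # (K,)
    cross = (Z * w) @ g  # (n, K)
    return const - 0.5 * (zq[:, None] - 2.0 * cross + gq[None, :])


def stage_likelihoods(z_row, order, es: EventSet, sigma=1.0):
    """Per-stage log-likelihoods and the normalized stage posterior for one
    subject under a uniform stage prior.

    Returns ``(log_dens, posterior)``, both of length E+1.
    """
    z_row = np.asarray(z_row, dtype=float)
    if z_row.shape != (es.n_biomarkers,):
        raise ValueError("z_row length must equal the number of biomarkers")
    if not np.all(np.isfinite(z_row)):
        raise ValueError("z_row must be finite")
    sigma = _check_sigma(sigma, es)
    g = expected_trajectory(order, es)
    ld = _stage_logdens(z_row[None, :], g, sigma)[0]
    post = np.exp(ld - logsumexp(ld))
    return ld, post


def subject_loglik(z_row, order, es: EventSet, sigma=1.0) -> float:
    """Stage-marginal log-likelihood log[(1/(E+1)) Σ_k Π_b φ(z_b; g_bk, σ_b)]."""
    ld, _ = stage_likelihoods(z_row, order, es, sigma)
    return float(logsumexp(ld) - np.log(es.n_stages))


@dataclass
class SubtypeModel:
    """A fitted mixture of event orderings.

    Attributes
    ----------
    event_set : EventSet
    orderings : list of int arrays, the ML trajectory of each subtype
    fractions : (C,) mixture fractions, non-negative, summing to 1
    sigma : (B,) per-biomarker observation noise sd (default 1: inputs are
        normative z-scores)
    loglik : total data log-likelihood at the fit (NaN before fitting)
    mcmc : McmcSamples or None, ordering-uncertainty samples
    """

    event_set: EventSet
    orderings: list
    fractions: np.ndarray
    sigma: np.ndarray = None
    loglik: float = float("nan")
    mcmc: object = None

    def __post_init__(self):
        if len(self.orderings) == 0:
            raise ValueError("model must contain at least one subtype")
        self.orderings = [
            validate_ordering(o, self.event_set) for o in self.orderings
        ]
        f = np.asarray(self.fractions, dtype=float)
        if f.shape != (len(self.orderings),) or np.any(f < 0) or not np.isclose(
            f.sum(), 1.0
        ):
            raise ValueError("fractions must be non-negative and sum to 1")
        self.fractions = f / f.sum()
        self.sigma = _check_sigma(
            1.0 if self.sigma is None else self.sigma, self.event_set
        )

    @property
    def n_subtypes(self) -> int:
        return len(self.orderings)


def _marginal_logliks(Z: np.ndarray, orderings, es: EventSet, sigma) -> np.ndarray:
    """(n, C) stage-marginal log-likelihood of every subject under every
    subtype ordering."""
    cols = []
    logK = np.log(es.n_stages)
    for order in orderings:
        g = _trajectory_from_positions(_positions_matrix(order, es), es)
        ld = _stage_logdens(Z, g, sigma)
        cols.append(logsumexp(ld, axis=1) - logK)
    return np.column_stack(cols)


def mixture_loglik(Z, model: SubtypeModel):
    """Total mixture log-likelihood and per-subject subtype posteriors.

    Returns ``(total, posteriors)`` where ``posteriors`` is (n, C) with rows
    summing to 1.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[1] != model.event_set.n_biomarkers:
        raise ValueError("Z must be (subjects x biomarkers) for this event set")
    L = _marginal_logliks(Z, model.orderings, model.event_set, model.sigma)
    with np.errstate(divide="ignore"):
        lw = L + np.log(model.fractions)[None, :]
    per_subject = logsumexp(lw, axis=1)
    post = np.exp(lw - per_subject[:, None])
    return float(per_subject.sum()), post
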