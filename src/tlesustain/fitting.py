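"""Fitting the subtype-and-stage model.

The maximum-likelihood trajectory for one subtype is found by multi-start
greedy hill-climbing over event relocations; a mixture of ``k`` trajectories
is built hierarchically by candidate-splitting each cluster of the ``k-1``
solution (random bipartitions refined by hard expectation-maximization).
Ordering uncertainty is quantified by Metropolis MCMC over valid event
relocations with mixture fractions held fixed, and the number of subtypes is
chosen by the cross-validation information criterion (CVIC; lower is
better).  Subjects are assigned a maximum-a-posteriori trajectory and stage;
subjects with no modelled z-score above 1 are staged 0 and labelled
"normal".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import logsumexp
from scipy.stats import spearmanr

from .progression import (
    EventSet,
    SubtypeModel,
    _check_sigma,
    _positions_matrix,
    _stage_logdens,
    _trajectory_from_positions,
    mixture_loglik,
    validate_ordering,
)

__all__ = [
    "FitConfig",
    "McmcSamples",
    "CvicReport",
    "SubjectAssignment",
    "greedy_fit_single",
    "mcmc_sample",
    "fit_subtypes",
    "select_model_order",
    "assign_individuals",
    "positional_variance",
    "assignment_consistency",
]

NORMAL_LABEL = "normal"

try:  # numba accelerates the inner likelihood loops ~4x
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    def _njit(*a, **k):
        def deco(f):
            return f
        return deco if not a or not callable(a[0]) else a[0]


@_njit(cache=True)
def _g_kernel(P, TH, E, z_max):
    """Piecewise-linear trajectory g (B, E+1) from NaN-padded 1-based event
    positions P (B, T) and thresholds TH (B, T)."""
    B, T = P.shape
    K = E + 1
    g = np.zeros((B, K))
    xs = np.empty(T + 2)
    ys = np.empty(T + 2)
    for b in range(B):
        na = 1
        xs[0] = 0.0
        ys[0] = 0.0
        for t in range(T):
            if not np.isnan(P[b, t]):
                xs[na] = P[b, t]
                ys[na] = TH[b, t]
                na += 1
        if xs[na - 1] >= E:  # last event at the final stage: threshold anchor wins
            xs[na] = E + 1.0
        else:
            xs[na] = float(E)
        ys[na] = z_max
        na += 1
        seg = 1
        for k in range(K):
            while seg < na - 1 and xs[seg] <= k:
                seg += 1
            x0, x1 = xs[seg - 1], xs[seg]
            y0, y1 = ys[seg - 1], ys[seg]
            g[b, k] = y0 + (k - x0) * (y1 - y0) / (x1 - x0)
    return g


@_njit(cache=True)
def _marg_kernel(cross, g, w, zq, const, logK):
    """Per-subject stage-marginal log-likelihood from the cross-product
    matrix ``cross = (Z*w) @ g``."""
    n, K = cross.shape
    B = g.shape[0]
    gq = np.empty(K)
    for k in range(K):
        s = 0.0
        for b in range(B):
            s += w[b] * g[b, k] * g[b, k]
        gq[k] = s
    out = np.empty(n)
    for j in range(n):
        m = -np.inf
        for k in range(K):
            v = cross[j, k] - 0.5 * gq[k]
            if v > m:
                m = v
        s = 0.0
        for k in range(K):
            s += np.exp(cross[j, k] - 0.5 * gq[k] - m)
        out[j] = const - 0.5 * zq[j] + m + np.log(s) - logK
    return out


@dataclass
class FitConfig:
    """Iteration budgets.  Reference runs use 25 greedy starts and long MCMC
    chains; the test profile scales these down (results at test scale are
    property-checked, not value-matched)."""

    n_starts: int = 25
    n_iter_mcmc: int = 100_000
    thin: int = 10
    n_bipartitions: int = None  # per-cluster split candidates; default n_starts
    n_starts_split: int = 1  # greedy starts per bipartition half
    em_max_iter: int = 25
    n_residual_views: int = 3  # residual-guided split seeds (raw/PCA-1/PCA-2)
    refit_passes: int = None  # hill-climb passes per EM refit (None: converge)
    polish_em_iter: int = 12  # full-refit EM iterations on each kept solution
    n_iter_mcmc_cv: int = 2_000  # chain length inside cross-validation
    max_cv_samples: int = 50  # MCMC samples averaged for out-of-sample loglik
    sigma: object = 1.0

    def bipartitions(self) -> int:
        return self.n_bipartitions if self.n_bipartitions is not None \
            else self.n_starts


#: scaled-down profile used by the test suite and the demo config
TEST_PROFILE = FitConfig(n_starts=2, n_iter_mcmc=10_000, n_bipartitions=2,
                         em_max_iter=6, refit_passes=1,
                         n_iter_mcmc_cv=1_500, max_cv_samples=40)

#: lighter profile for the cross-validated model-order search
CV_PROFILE = FitConfig(n_starts=2, n_bipartitions=1, em_max_iter=5,
                       n_residual_views=1, refit_passes=1, polish_em_iter=6,
                       n_iter_mcmc_cv=1_500, max_cv_samples=40)


@dataclass
class McmcSamples:
    """Thinned MCMC store: ``orderings[c]`` is (n_stored, E) for subtype c."""

    orderings: list
    loglik_trace: np.ndarray
    acceptance_rate: float
    seed: int
    ml_orderings: list = None
    ml_loglik: float = float("nan")

    @property
    def n_stored(self) -> int:
        return int(self.loglik_trace.size)


@dataclass
class CvicReport:
    k_values: list
    cvic: np.ndarray  # per k
    mean_oos_loglik: np.ndarray  # per k
    fold_oos_loglik: np.ndarray  # (k, folds)
    selected_k: int
    n_folds: int


@dataclass
class SubjectAssignment:
    """Per-subject subtype posterior, MAP trajectory label and MAP stage.

    ``table`` columns: label (trajectory_1.. / normal), stage, and one
    posterior column per trajectory.
    """

    table: pd.DataFrame
    posteriors: np.ndarray

    @property
    def labels(self) -> pd.Series:
        return self.table["label"]

    @property
    def stages(self) -> pd.Series:
        return self.table["stage"]


# ---------------------------------------------------------------------------
# likelihood plumbing


class _Evaluator:
    """Cached dataset log-likelihood machinery for one (Z, event set, sigma).

    Precomputes the weighted data products so each candidate ordering costs
    one trajectory build, one BLAS product and one fused logsumexp kernel.
    """

    def __init__(self, Z, es: EventSet, sigma):
        self.Z = np.ascontiguousarray(np.asarray(Z, dtype=float))
        if self.Z.ndim != 2 or self.Z.shape[1] != es.n_biomarkers:
            raise ValueError("Z must be subjects x biomarkers for the event set")
        self.es = es
        self.sigma = _check_sigma(sigma, es)
        self.logK = float(np.log(es.n_stages))
        self.w = 1.0 / self.sigma**2
        self.Zw = self.Z * self.w
        self.zq = (self.Z * self.Zw).sum(axis=1)
        self.const = float(-0.5 * es.n_biomarkers * np.log(2 * np.pi)
                           - np.log(self.sigma).sum())
        t_max = max(len(t) for t in es.thresholds)
        TH = np.full((es.n_biomarkers, t_max), np.nan)
        TH[es.event_biomarker, es.event_rank] = es.event_threshold
        self.TH = TH

    def _g(self, order) -> np.ndarray:
        return _g_kernel(_positions_matrix(order, self.es), self.TH,
                         self.es.n_events, self.es.z_max)

    def marginals(self, order, rows=None) -> np.ndarray:
        """Per-subject stage-marginal log-likelihood under one ordering."""
        g = self._g(order)
        Zw = self.Zw if rows is None else self.Zw[rows]
        zq = self.zq if rows is None else self.zq[rows]
        return _marg_kernel(Zw @ g, g, self.w, zq, self.const, self.logK)

    def total(self, order, rows=None) -> float:
        return float(self.marginals(order, rows).sum())


def _valid_insertions(seq, i, es: EventSet):
    """Insertion index range (lo, hi), inclusive, in removed-list coordinates
    for relocating the event at ``seq[i]``: it must land after its lower and
    before its upper same-biomarker threshold sibling."""
    e = seq[i]
    b = es.event_biomarker[e]
    r = es.event_rank[e]
    lo, hi = 0, len(seq) - 1
    for m, other in enumerate(seq):
        if m == i or es.event_biomarker[other] != b:
            continue
        mm = m if m < i else m - 1  # index once seq[i] is removed
        rr = es.event_rank[other]
        if rr == r - 1:
            lo = mm + 1
        elif rr == r + 1:
            hi = mm
    return lo, hi


def _relocate(seq, i, j):
    return np.insert(np.delete(seq, i), j, seq[i])


def _random_valid_start(es: EventSet, rng) -> np.ndarray:
    keys = np.empty(es.n_events)
    for b in range(es.n_biomarkers):
        m = es.event_biomarker == b
        keys[m] = np.sort(rng.random(int(m.sum())))
    return np.argsort(keys, kind="stable")


def _hill_climb(ev: _Evaluator, seq, rng, rows=None, max_passes=None):
    """Best-improvement relocation passes until no move improves (or the
    pass budget runs out)."""
    seq = np.asarray(seq, dtype=np.intp).copy()
    es = ev.es
    cur = ev.total(seq, rows)
    improved = True
    n_pass = 0
    while improved and (max_passes is None or n_pass < max_passes):
        improved = False
        n_pass += 1
        for i in rng.permutation(len(seq)):
            lo, hi = _valid_insertions(seq, int(i), es)
            best_j, best_ll = None, cur
            for j in range(lo, hi + 1):
                if j == i:
                    continue
                ll = ev.total(_relocate(seq, int(i), j), rows)
                if ll > best_ll + 1e-9:
                    best_j, best_ll = j, ll
            if best_j is not None:
                seq = _relocate(seq, int(i), best_j)
                cur = best_ll
                improved = True
    return seq, cur


def greedy_fit_single(Z, es: EventSet, n_starts: int = 25, seed: int = 0,
                      sigma=1.0, rows=None):
    """Multi-start greedy fit of a single trajectory.

    From each random valid start, hill-climb by trying every valid
    relocation of every event, taking the best improvement until none
    exists; returns the best ``(ordering, loglik)`` across starts.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    ev = Z if isinstance(Z, _Evaluator) else _Evaluator(Z, es, sigma)
    rng = np.random.default_rng(seed)
    best = (None, -np.inf)
    for _ in range(n_starts):
        seq, ll = _hill_climb(ev, _random_valid_start(ev.es, rng), rng, rows)
        if ll > best[1]:
            best = (seq, ll)
    return best


# ---------------------------------------------------------------------------
# MCMC


def mcmc_sample(Z, init: SubtypeModel, n_iter: int, seed: int = 0,
                thin: int = 10) -> McmcSamples:
    """Metropolis sampling over valid event relocations.

    Each iteration picks one subtype uniformly, proposes relocating one
    uniformly chosen event to a uniformly chosen valid position, and accepts
    with min(1, exp(delta log-likelihood)); mixture fractions stay fixed so
    the chain is a pure ordering sampler.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    es = init.event_set
    ev = _Evaluator(Z, es, init.sigma)
    rng = np.random.default_rng(seed)
    C = init.n_subtypes
    seqs = [o.copy() for o in init.orderings]
    logf = np.log(np.maximum(init.fractions, 1e-300))
    Lm = np.column_stack([ev.marginals(s) for s in seqs])

    def total(L):
        return float(logsumexp(L + logf[None, :], axis=1).sum())

    cur = total(Lm)
    stores = [[] for _ in range(C)]
    trace = []
    best = (cur, [s.copy() for s in seqs])
    n_acc = 0
    for it in range(n_iter):
        c = int(rng.integers(C))
        i = int(rng.integers(es.n_events))
        lo, hi = _valid_insertions(seqs[c], i, es)
        if hi < lo:
            continue
        j = int(rng.integers(lo, hi + 1))
        cand = _relocate(seqs[c], i, j)
        if np.array_equal(cand, seqs[c]):
            new_col, new_tot = None, cur
        else:
            new_col = ev.marginals(cand)
            L2 = Lm.copy()
            L2[:, c] = new_col
            new_tot = total(L2)
        if np.log(rng.random()) < new_tot - cur:
            if new_col is not None:
                seqs[c] = cand
                Lm[:, c] = new_col
                cur = new_tot
                n_acc += 1
                if cur > best[0]:
                    best = (cur, [s.copy() for s in seqs])
        if (it + 1) % thin == 0:
            for c2 in range(C):
                stores[c2].append(seqs[c2].copy())
            trace.append(cur)
    return McmcSamples(
        orderings=[np.array(s, dtype=np.intp) for s in stores],
        loglik_trace=np.asarray(trace),
        acceptance_rate=n_acc / n_iter,
        seed=seed,
        ml_orderings=best[1],
        ml_loglik=best[0],
    )


# ---------------------------------------------------------------------------
# hierarchical mixture fitting


def _hard_em(ev: _Evaluator, seqs, rng, max_iter=25, refit_passes=None,
             subset=None):
    """Alternate hard reassignment and per-cluster refits (hill-climb from
    the current orderings) until the assignment is stable.

    ``subset`` restricts the EM to a row subset (used when refining a
    2-mixture inside one cluster before the global pass).  Returns
    (seqs, fractions, assignment, classification-loglik trace).
    """
    subset = np.arange(ev.Z.shape[0]) if subset is None else subset
    n = subset.size
    C = len(seqs)
    f = np.full(C, 1.0 / C)
    assign = None
    trace = []
    for _ in range(max_iter):
        Lm = np.column_stack([ev.marginals(s, rows=subset) for s in seqs])
        with np.errstate(divide="ignore"):
            scores = Lm + np.log(f)[None, :]
        new_assign = scores.argmax(axis=1)
        trace.append(float(scores.max(axis=1).sum()))
        if assign is not None and np.array_equal(new_assign, assign):
            break
        assign = new_assign
        f = np.bincount(assign, minlength=C) / n
        for c in range(C):
            rows = subset[assign == c]
            if rows.size == 0:
                continue
            seqs[c], _ = _hill_climb(ev, seqs[c], rng, rows, refit_passes)
    return seqs, f, assign, np.asarray(trace)


def _residual_bipartitions(ev: _Evaluator, members, order, rng, n_views=3):
    """Structured split seeds: 2-means on the members' residuals from the
    parent trajectory at their MAP stage, on the raw residuals and on their
    leading principal components.  A subtype with a different event ordering
    leaves a coherent residual direction, so these seeds isolate minority
    subtypes far more reliably than chance bipartitions (which are kept as
    additional candidates)."""
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    g = ev._g(order)
    ld = _stage_logdens(ev.Z[members], g, ev.sigma)
    resid = ev.Z[members] - g[:, ld.argmax(axis=1)].T
    views = [resid]
    for npc in (1, 2):
        if min(resid.shape) > npc:
            views.append(PCA(n_components=npc).fit_transform(resid))
    if n_views == 1 and len(views) > 1:
        views = [views[1]]  # the PCA-1 view is the strongest denoised seed
    else:
        views = views[:max(1, n_views)]
    out = []
    for view in views:
        lab = KMeans(n_clusters=2, n_init=5,
                     random_state=int(rng.integers(2**31))).fit_predict(view)
        out.append((members[lab == 0], members[lab == 1]))
    return out


def _split_cluster(ev, seqs, members, cluster, cfg: FitConfig, rng):
    """Split one cluster: try a residual-guided bipartition of its members
    plus random bipartitions, fit each half, refine all clusters by hard EM;
    return the best candidate model."""
    candidates = []
    if members.size >= 4:
        for a, b in _residual_bipartitions(ev, members, seqs[cluster], rng,
                                           cfg.n_residual_views):
            if a.size >= 2 and b.size >= 2:
                candidates.append((a, b))
    for _ in range(cfg.bipartitions()):
        perm = rng.permutation(members)
        half = max(1, members.size // 2)
        candidates.append((perm[:half], perm[half:]))
    best = None
    for parts in candidates:
        if parts[1].size == 0:
            continue
        pair = [greedy_fit_single(ev, ev.es, cfg.n_starts_split,
                                  seed=int(rng.integers(2**31)), rows=rows)[0]
                for rows in parts]
        # refine the 2-mixture on this cluster's members alone first, so the
        # split is not washed out by the other clusters' subjects
        pair, _, _, _ = _hard_em(ev, pair, rng, cfg.em_max_iter,
                                 cfg.refit_passes, subset=members)
        new_seqs = [s.copy() for i, s in enumerate(seqs)
                    if i != cluster] + pair
        new_seqs, f, assign, _ = _hard_em(ev, new_seqs, rng, cfg.em_max_iter,
                                          cfg.refit_passes)
        Lm = np.column_stack([ev.marginals(s) for s in new_seqs])
        with np.errstate(divide="ignore"):
            ll = float(logsumexp(Lm + np.log(np.maximum(f, 1e-300))[None, :],
                                 axis=1).sum())
        if best is None or ll > best[0]:
            best = (ll, new_seqs, f)
    return best


def _fit_hierarchy(Z, es: EventSet, k_max: int, cfg: FitConfig, seed: int):
    """Greedy hierarchical construction; returns {k: SubtypeModel} for
    k = 1..k_max (without MCMC attached)."""
    ev = Z if isinstance(Z, _Evaluator) else _Evaluator(Z, es, cfg.sigma)
    n = ev.Z.shape[0]
    if k_max > n:
        raise ValueError("more subtypes than subjects")
    rng = np.random.default_rng(seed)
    seq, ll = greedy_fit_single(ev, es, cfg.n_starts,
                                seed=int(rng.integers(2**31)))
    models = {1: SubtypeModel(event_set=es, orderings=[seq],
                              fractions=np.array([1.0]), sigma=ev.sigma,
                              loglik=ll)}
    seqs, fracs = [seq], np.array([1.0])
    for k in range(2, k_max + 1):
        Lm = np.column_stack([ev.marginals(s) for s in seqs])
        with np.errstate(divide="ignore"):
            assign = (Lm + np.log(np.maximum(fracs, 1e-300))).argmax(axis=1)
        best = None
        for c in range(len(seqs)):
            members = np.flatnonzero(assign == c)
            if members.size < 2:
                continue
            cand = _split_cluster(ev, seqs, members, c, cfg, rng)
            if cand is not None and (best is None or cand[0] > best[0]):
                best = cand
        if best is None:
            raise ValueError(f"no cluster of the {k - 1}-subtype solution "
                             "can be split further")
        ll, seqs, fracs = best
        if cfg.polish_em_iter:  # converge the kept solution fully
            seqs, fracs, _, _ = _hard_em(ev, seqs, rng, cfg.polish_em_iter,
                                         refit_passes=None)
            Lp = np.column_stack([ev.marginals(s) for s in seqs])
            with np.errstate(divide="ignore"):
                ll = float(logsumexp(
                    Lp + np.log(np.maximum(fracs, 1e-300))[None, :],
                    axis=1).sum())
        keep = fracs > 0
        if not keep.all():  # an emptied cluster cannot carry mixture mass
            seqs = [s for s, kp in zip(seqs, keep) if kp]
            fracs = fracs[keep] / fracs[keep].sum()
        models[k] = SubtypeModel(event_set=es, orderings=[s.copy() for s in seqs],
                                 fractions=fracs.copy(), sigma=ev.sigma,
                                 loglik=ll)
    return models


def fit_subtypes(Z, es: EventSet, k: int, config: FitConfig | None = None,
                 seed: int = 0) -> SubtypeModel:
    """Fit a ``k``-subtype model: hierarchical greedy construction followed
    by MCMC for ordering uncertainty; the returned model carries the ML
    orderings over the chain, the converged mixture fractions and the sample
    store."""
    if k < 1:
        raise ValueError("k must be >= 1")
    cfg = config or FitConfig()
    ev = _Evaluator(Z, es, cfg.sigma)
    models = _fit_hierarchy(ev, es, k, cfg, seed)
    model = models[k]
    samples = mcmc_sample(ev.Z, model, cfg.n_iter_mcmc,
                          seed=seed + 1, thin=cfg.thin)
    seqs = [validate_ordering(o, es) for o in samples.ml_orderings]
    if cfg.polish_em_iter and k > 1:
        # the chain's ML state can leave the EM fixed point; re-converge
        rng = np.random.default_rng(seed + 2)
        seqs, fracs, _, _ = _hard_em(ev, seqs, rng, cfg.polish_em_iter)
        keep = fracs > 0
        seqs = [s for s, kp in zip(seqs, keep) if kp]
        fracs = fracs[keep] / fracs[keep].sum()
        model.fractions = fracs
    model.orderings = seqs
    Lf = np.column_stack([ev.marginals(s) for s in model.orderings])
    with np.errstate(divide="ignore"):
        model.loglik = float(logsumexp(
            Lf + np.log(np.maximum(model.fractions, 1e-300))[None, :],
            axis=1).sum())
    model.mcmc = samples
    return model


def select_model_order(Z, es: EventSet, k_range, n_folds: int = 3,
                       seed: int = 0, config: FitConfig | None = None
                       ) -> CvicReport:
    """Choose the number of subtypes by CVIC.

    Plain (stratification-free) fold split; for every fold and k the model
    is fitted on the training folds and the held-out log-likelihood is
    averaged over MCMC ordering samples.  CVIC(k) = sum over folds of
    -2 x out-of-sample log-likelihood; the selected k minimizes CVIC.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    cfg = config or FitConfig()
    k_range = sorted(int(k) for k in k_range)
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0]
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    folds = np.array_split(idx, n_folds)
    if min(f.size for f in folds) < max(k_range):
        raise ValueError("a fold has fewer subjects than the largest k")
    oos = np.zeros((len(k_range), n_folds))
    for fi, test in enumerate(folds):
        train = np.setdiff1d(idx, test)
        ev = _Evaluator(Z[train], es, cfg.sigma)
        models = _fit_hierarchy(ev, es, max(k_range), cfg,
                                seed=int(rng.integers(2**31)))
        for ki, k in enumerate(k_range):
            model = models[k]
            samples = mcmc_sample(Z[train], model, cfg.n_iter_mcmc_cv,
                                  seed=int(rng.integers(2**31)), thin=cfg.thin)
            stored = samples.n_stored
            take = np.linspace(0, stored - 1,
                               min(cfg.max_cv_samples, stored)).astype(int)
            lls = []
            for s in take:
                m = SubtypeModel(
                    event_set=es,
                    orderings=[samples.orderings[c][s] for c in
                               range(model.n_subtypes)],
                    fractions=model.fractions, sigma=model.sigma)
                ll, _ = mixture_loglik(Z[test], m)
                lls.append(ll)
            oos[ki, fi] = float(np.mean(lls))
    mean_oos = oos.mean(axis=1)
    cvic = (-2.0 * oos).sum(axis=1)
    return CvicReport(k_values=list(k_range), cvic=cvic,
                      mean_oos_loglik=mean_oos, fold_oos_loglik=oos,
                      selected_k=int(k_range[int(np.argmin(cvic))]),
                      n_folds=n_folds)


# ---------------------------------------------------------------------------
# assignment & diagnostics


def assign_individuals(model: SubtypeModel, Z, subject_ids=None,
                       normal_threshold: float = 1.0) -> SubjectAssignment:
    """MAP subtype and stage per subject, with the "normal" rule.

    A subject whose modelled z-scores are all below ``normal_threshold`` is
    staged 0; any subject at stage 0 carries the label "normal", otherwise
    the MAP trajectory label.
    """
    Z = np.asarray(Z, dtype=float)
    es = model.event_set
    if Z.ndim != 2 or Z.shape[1] != es.n_biomarkers:
        raise ValueError("Z columns must match the model's biomarkers")
    n = Z.shape[0]
    if subject_ids is None:
        subject_ids = list(range(n))
    _, post = mixture_loglik(Z, model)
    ml_subtype = post.argmax(axis=1)
    stages = np.zeros(n, dtype=int)
    G = [_trajectory_from_positions(_positions_matrix(o, es), es)
         for o in model.orderings]
    for c in range(model.n_subtypes):
        rows = np.flatnonzero(ml_subtype == c)
        if rows.size == 0:
            continue
        ld = _stage_logdens(Z[rows], G[c], model.sigma)
        stages[rows] = ld.argmax(axis=1)
    stages[(Z < normal_threshold).all(axis=1)] = 0
    labels = np.where(stages == 0, NORMAL_LABEL,
                      [f"trajectory_{c + 1}" for c in ml_subtype])
    table = pd.DataFrame({
        "label": labels,
        "ml_subtype": ml_subtype + 1,
        "stage": stages,
    }, index=pd.Index(subject_ids, name="subject_id"))
    for c in range(model.n_subtypes):
        table[f"p_trajectory_{c + 1}"] = post[:, c]
    return SubjectAssignment(table=table, posteriors=post)


def positional_variance(samples: McmcSamples, subtype: int) -> np.ndarray:
    """(event, position) MCMC frequency matrix; rows sum to 1."""
    store = samples.orderings[subtype]
    if store.size == 0:
        raise ValueError("empty MCMC sample store")
    S, E = store.shape
    pvd = np.zeros((E, E))
    pos = np.empty_like(store)
    ar = np.arange(E)
    for s in range(S):
        pos[s, store[s]] = ar
    for e in range(E):
        pvd[e] = np.bincount(pos[:, e], minlength=E) / S
    return pvd


def assignment_consistency(a: SubjectAssignment, b: SubjectAssignment):
    """Percent identical final labels after maximum-agreement label matching
    (subtype indices are arbitrary), and the Spearman correlation of stages.
    """
    if list(a.table.index) != list(b.table.index):
        raise ValueError("assignments cover different subjects")
    la = a.labels.to_numpy()
    lb = b.labels.to_numpy()
    cats_a = sorted(set(la))
    cats_b = sorted(set(lb))
    conf = np.zeros((len(cats_a), len(cats_b)))
    ia = {c: i for i, c in enumerate(cats_a)}
    ib = {c: i for i, c in enumerate(cats_b)}
    for x, y in zip(la, lb):
        conf[ia[x], ib[y]] += 1
    r, c = linear_sum_assignment(conf, maximize=True)
    agreement = 100.0 * conf[r, c].sum() / la.size
    sa = a.stages.to_numpy()
    sb = b.stages.to_numpy()
    if np.all(sa == sa[0]) or np.all(sb == sb[0]):
        rho = np.nan
        warnings.warn("constant stages: rank correlation undefined")
    else:
        rho = float(spearmanr(sa, sb).statistic)
    return float(agreement), rho
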