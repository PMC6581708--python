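"""Polarity-invariant topographic clustering and model selection.

The segmentation engine is a modified k-means over scalp maps: maps are
assigned to the template with the highest *squared* spatial correlation
(so a map and its sign-flip behave identically), and each template is
re-estimated as the dominant eigenvector of its members' scatter matrix
— the polarity-invariant analogue of the cluster mean.  Solutions are
scored by global explained variance (GEV), the GFP-weighted fraction of
topographic variance captured by the assigned templates.

The number of clusters is chosen by a meta-criterion: seven standard
cluster-validity indices each vote for one k and the median vote wins.
A two-step procedure mirrors group studies: per-subject clustering of
GFP-peak maps first, then clustering of the pooled individual templates
into group-level classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

from .core import (
    Recording,
    TemplateSet,
    correlation_matrix,
    gfp_of_maps,
    normalize_maps,
    spatial_correlation,
)
from .gfp import compute_gfp, find_gfp_peaks, peak_maps

__all__ = [
    "ClusterRunResult",
    "ModelSelection",
    "spatial_correlation",
    "modified_kmeans",
    "gev_of_assignment",
    "select_k_metacriterion",
    "individual_clustering",
    "group_clustering",
]

DEFAULT_K_RANGE = (2, 10)
DEFAULT_RESTARTS = 50


class InsufficientDataError(ValueError):
    """Too few GFP-peak maps for a stable clustering."""


@dataclass
class ClusterRunResult:
    templates: TemplateSet
    assignment: np.ndarray  # per-map class index
    gev: float
    n_restarts: int
    seed: int | None


@dataclass
class ModelSelection:
    k_range: tuple[int, int]
    criterion_table: pd.DataFrame  # one row per k, one column per criterion
    votes: dict[str, int]
    chosen_k: int
    runs: dict[int, ClusterRunResult] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# GEV


def gev_of_assignment(
    maps: np.ndarray,
    templates: np.ndarray,
    assignment: np.ndarray,
    gfp_weights: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Global explained variance of a labeling of maps.

    ``GEV = sum_t (w_t * C_t)^2 / sum_t w_t^2`` with ``C_t`` the spatial
    correlation between map t and its assigned template and ``w_t`` its
    GFP weight (the maps' own GFP when not given).  Returns the total
    and the per-class decomposition (which sums to the total).
    """
    maps = np.atleast_2d(maps)
    templates = np.atleast_2d(templates)
    assignment = np.asarray(assignment, dtype=int)
    if gfp_weights is None:
        gfp_weights = gfp_of_maps(maps)
    w = np.asarray(gfp_weights, dtype=float)
    denom = float(np.sum(w**2))
    if denom == 0:
        raise ValueError("all-zero GFP weights: GEV undefined")
    c = correlation_matrix(maps, templates)
    c_own = c[np.arange(maps.shape[0]), assignment]
    contrib = (w * c_own) ** 2
    per_class = np.array(
        [contrib[assignment == k].sum() for k in range(templates.shape[0])]
    )
    return float(contrib.sum() / denom), per_class / denom


# ---------------------------------------------------------------------------
# modified k-means


def _eigen_template(members: np.ndarray, warm: np.ndarray | None = None, iters: int = 3) -> np.ndarray:
    """Dominant eigenvector of the members' scatter matrix.

    This maximizes the summed squared projection over members — the
    polarity-invariant mean, which plain averaging would break when
    members carry opposite signs.  Members are zero-mean across
    channels, so the eigenvector is too.  Computed by power iteration on
    ``M^T M``, warm-started from the current template when available
    (the outer k-means loop supplies the remaining convergence).
    """
    if warm is None:
        _, _, vt = np.linalg.svd(members, full_matrices=False)
        return vt[0]
    v = warm
    for _ in range(iters):
        v = members.T @ (members @ v)
        nrm = np.linalg.norm(v)
        if nrm == 0:  # degenerate warm start orthogonal to all members
            _, _, vt = np.linalg.svd(members, full_matrices=False)
            return vt[0]
        v = v / nrm
    return v


def _normalize_template_rows(maps: np.ndarray) -> np.ndarray:
    return normalize_maps(maps, canonical=True)


def modified_kmeans(
    maps: np.ndarray,
    k: int,
    n_restarts: int = DEFAULT_RESTARTS,
    seed: int | None = None,
    gfp_weights: np.ndarray | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> ClusterRunResult:
    """Polarity-invariant k-means over topographies.

    Assignment is purely topographic (argmax squared spatial
    correlation on unit-normalized maps); the template update takes the
    dominant eigenvector of the sum of outer products of the member
    maps *at their original amplitudes*, which makes each sweep exact
    coordinate ascent on the GFP-weighted GEV (an amplitude-blind
    update would not be).  Iterations run until assignments stabilize
    (then templates are polished with an exact eigensolve) or the
    relative GEV change drops below ``tol``.  Empty clusters are
    reseeded from the worst-fit map.  The best restart by GEV wins;
    deterministic given ``seed``.
    """
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    n = maps.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of maps ({n})")
    if gfp_weights is None:
        gfp_weights = gfp_of_maps(maps)
    norm_maps = normalize_maps(maps, canonical=False)
    rng = np.random.default_rng(seed)
    n_ch = norm_maps.shape[1]
    w2 = np.asarray(gfp_weights, dtype=float) ** 2
    w2_sum = float(w2.sum())
    if w2_sum == 0:
        raise ValueError("all-zero GFP weights")

    # members enter the scatter at their original amplitude (GFP weight)
    weighted_maps = norm_maps * np.asarray(gfp_weights, dtype=float)[:, None]

    # when there are fewer distinct k-subsets of seeds than restarts,
    # enumerate them all instead of sampling (guarantees basin coverage
    # on small instances)
    from itertools import combinations
    from math import comb

    if comb(n, k) <= max(1, n_restarts):
        inits = [np.array(c) for c in combinations(range(n), k)]
    else:
        inits = [rng.choice(n, size=k, replace=False) for _ in range(max(1, n_restarts))]

    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for init in inits:
        templates = norm_maps[init].copy()
        prev_assign = None
        prev_gev = -np.inf
        for _ in range(max_iter):
            # unit-GFP rows: correlation = dot product / N
            c2 = (norm_maps @ templates.T / n_ch) ** 2
            assign = np.argmax(c2, axis=1)
            # reseed empty clusters from the worst-fitting map
            best_c2 = c2[np.arange(n), assign]
            for cls in range(k):
                if not np.any(assign == cls):
                    worst = int(np.argmin(best_c2))
                    assign[worst] = cls
                    best_c2[worst] = np.inf
            gev = float(np.sum(w2 * np.minimum(best_c2, 1.0)) / w2_sum)
            if prev_assign is not None and np.array_equal(assign, prev_assign):
                # converged: polish templates with the exact eigensolve
                # for this partition and re-score the same assignment
                for cls in range(k):
                    templates[cls] = _eigen_template(weighted_maps[assign == cls])
                templates = normalize_maps(templates, canonical=False)
                c2 = (norm_maps @ templates.T / n_ch) ** 2
                own = np.minimum(c2[np.arange(n), assign], 1.0)
                gev = float(np.sum(w2 * own) / w2_sum)
                break
            if prev_gev > -np.inf and abs(gev - prev_gev) < tol * max(prev_gev, tol):
                break
            prev_assign, prev_gev = assign, gev
            for cls in range(k):
                templates[cls] = _eigen_template(
                    weighted_maps[assign == cls], warm=templates[cls]
                )
            templates = normalize_maps(templates, canonical=False)
        if best is None or gev > best[0]:
            best = (gev, templates.copy(), assign.copy())

    gev, templates, assign = best
    # canonical polarity changes neither correlations nor the assignment
    templates = _normalize_template_rows(templates)
    return ClusterRunResult(
        templates=TemplateSet(maps=templates, gev_total=gev),
        assignment=assign,
        gev=float(gev),
        n_restarts=n_restarts,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# cluster-validity criteria (meta-criterion battery)


def _within_dispersion(c2_own: np.ndarray) -> float:
    """W_k = sum over maps of d^2 = 1 - C^2 to the own template."""
    return float(np.sum(1.0 - c2_own))


def _criterion_votes(
    norm_maps: np.ndarray,
    runs: dict[int, ClusterRunResult],
    k_min: int,
    k_max: int,
    rng: np.random.Generator,
    n_restarts_ref: int = 5,
    n_ref_sets: int = 3,
    max_ref_maps: int = 200,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Evaluate the seven validity criteria and collect one vote each.

    All criteria operate on the polarity-invariant dissimilarity
    ``d^2 = 1 - C^2``.  Criteria that are undefined on an instance (zero
    dispersion, degenerate partitions) abstain.
    """
    n, n_ch = norm_maps.shape
    p = n_ch - 1  # topographies live in the zero-mean subspace
    ks = sorted(k for k in runs if k_min <= k <= k_max)

    c2_own: dict[int, np.ndarray] = {}
    w_k: dict[int, float] = {}
    for k, run in runs.items():
        c = correlation_matrix(norm_maps, run.templates.maps)
        c2_own[k] = c[np.arange(n), run.assignment] ** 2
        w_k[k] = _within_dispersion(c2_own[k])

    # total dispersion around the single global template
    if 1 in runs:
        t_disp = w_k[1]
    else:
        global_t = _eigen_template(norm_maps)
        t_disp = float(np.sum(1.0 - (norm_maps @ global_t) ** 2 / np.sum(global_t**2)))

    table = pd.DataFrame(index=ks, dtype=float)
    votes: dict[str, int] = {}

    def vote(name: str, series: dict[int, float], maximize: bool) -> None:
        vals = {k: v for k, v in series.items() if np.isfinite(v)}
        table[name] = pd.Series(series)
        if vals:
            pick = max(vals, key=vals.get) if maximize else min(vals, key=vals.get)
            votes[name] = int(pick)

    # 1. Krzanowski-Lai
    diff = {
        k: (k - 1) ** (2.0 / p) * w_k[k - 1] - k ** (2.0 / p) * w_k[k]
        for k in runs
        if (k - 1) in w_k
    }
    kl = {}
    for k in ks:
        if k in diff and (k + 1) in diff and abs(diff[k + 1]) > 1e-12:
            kl[k] = abs(diff[k]) / abs(diff[k + 1])
        else:
            kl[k] = np.nan
    vote("krzanowski_lai", kl, maximize=True)

    # 2. Calinski-Harabasz
    ch = {}
    for k in ks:
        if k > 1 and n > k and w_k[k] > 1e-12:
            ch[k] = ((t_disp - w_k[k]) / (k - 1)) / (w_k[k] / (n - k))
        else:
            ch[k] = np.nan
    vote("calinski_harabasz", ch, maximize=True)

    # 3. silhouette on d = sqrt(1 - C^2)
    c_all = correlation_matrix(norm_maps, norm_maps)
    d_full = np.sqrt(np.clip(1.0 - c_all**2, 0.0, None))
    np.fill_diagonal(d_full, 0.0)
    sil = {}
    for k in ks:
        labels = runs[k].assignment
        if 1 < len(np.unique(labels)) < n:
            try:
                sil[k] = float(silhouette_score(d_full, labels, metric="precomputed"))
            except ValueError:
                sil[k] = np.nan
        else:
            sil[k] = np.nan
    vote("silhouette", sil, maximize=True)

    # 4. Davies-Bouldin (smaller is better)
    db = {}
    for k in ks:
        run = runs[k]
        labels = run.assignment
        t_maps = run.templates.maps
        c_map_t = correlation_matrix(norm_maps, t_maps)
        s = np.array(
            [
                np.mean(np.sqrt(np.clip(1 - c_map_t[labels == i, i] ** 2, 0, None)))
                if np.any(labels == i)
                else np.nan
                for i in range(k)
            ]
        )
        c_tt = correlation_matrix(t_maps, t_maps)
        m = np.sqrt(np.clip(1.0 - c_tt**2, 0.0, None))
        ratios = np.full((k, k), np.nan)
        for i in range(k):
            for j in range(k):
                if i != j and m[i, j] > 1e-12:
                    ratios[i, j] = (s[i] + s[j]) / m[i, j]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            db[k] = float(np.nanmean(np.nanmax(ratios, axis=1))) if k > 1 else np.nan
    vote("davies_bouldin", db, maximize=False)

    # 5. cross-validation criterion: residual variance with a dof penalty
    cv = {}
    for k in ks:
        if n - 1 - k > 0:
            sigma2 = w_k[k] / (n * (n_ch - 1))
            cv[k] = sigma2 * ((n - 1) / (n - 1 - k)) ** 2
        else:
            cv[k] = np.nan
    vote("cross_validation", cv, maximize=False)

    # 6. gap-style dispersion ratio against unstructured reference maps
    sub = np.arange(n)
    if n > max_ref_maps:
        sub = rng.choice(n, size=max_ref_maps, replace=False)
    data_sub = norm_maps[sub]
    n_sub = data_sub.shape[0]
    log_w_data, log_w_ref, s_ref = {}, {}, {}
    ref_sets = [
        normalize_maps(rng.standard_normal((n_sub, n_ch)), canonical=False)
        for _ in range(n_ref_sets)
    ]
    gap_ks = [k for k in ks if k < n_sub]
    for k in gap_ks:
        run = modified_kmeans(
            data_sub, k, n_restarts=n_restarts_ref, seed=int(rng.integers(2**31))
        )
        c2 = correlation_matrix(data_sub, run.templates.maps)
        own = c2[np.arange(n_sub), run.assignment] ** 2
        log_w_data[k] = np.log(max(_within_dispersion(own), 1e-12))
        logs = []
        for ref in ref_sets:
            rrun = modified_kmeans(
                ref, k, n_restarts=max(3, n_restarts_ref // 2),
                seed=int(rng.integers(2**31)),
            )
            cr = correlation_matrix(ref, rrun.templates.maps)
            ro = cr[np.arange(n_sub), rrun.assignment] ** 2
            logs.append(np.log(max(_within_dispersion(ro), 1e-12)))
        log_w_ref[k] = float(np.mean(logs))
        s_ref[k] = float(np.std(logs) * np.sqrt(1 + 1.0 / n_ref_sets))
    gap = {k: log_w_ref[k] - log_w_data[k] for k in gap_ks}
    table["gap"] = pd.Series({k: gap.get(k, np.nan) for k in ks})
    gap_vote = None
    for k in gap_ks:
        if (k + 1) in gap and gap[k] >= gap[k + 1] - s_ref[k + 1]:
            gap_vote = k
            break
    if gap_vote is None and gap:
        gap_vote = max(gap, key=gap.get)
    if gap_vote is not None:
        votes["gap"] = int(gap_vote)

    # 7. GEV-elbow: most concave point of the GEV(k) curve
    gev_curve = {k: runs[k].gev for k in runs}
    elbow = {}
    for k in ks:
        if (k - 1) in gev_curve and (k + 1) in gev_curve:
            d2 = gev_curve[k - 1] + gev_curve[k + 1] - 2 * gev_curve[k]
            elbow[k] = -d2  # concavity: positive where the curve bends
        else:
            elbow[k] = np.nan
    if all(not np.isfinite(v) or abs(v) < 1e-15 for v in elbow.values()):
        elbow = {k: np.nan for k in ks}
    vote("gev_elbow", elbow, maximize=True)

    table["gev"] = pd.Series({k: runs[k].gev for k in ks})
    return table, votes


def select_k_metacriterion(
    maps: np.ndarray,
    k_min: int = DEFAULT_K_RANGE[0],
    k_max: int = DEFAULT_K_RANGE[1],
    seed: int | None = None,
    n_restarts: int = DEFAULT_RESTARTS,
    gfp_weights: np.ndarray | None = None,
) -> ModelSelection:
    """Choose the number of template maps by a seven-criterion vote.

    Runs the modified k-means for every k in the (possibly shrunk)
    range, evaluates the validity battery, lets each defined criterion
    vote for one k, and takes the lower median of the votes (ties favor
    fewer clusters).  With no usable votes — e.g. all maps identical —
    the floor ``k_min`` is returned.
    """
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    n = maps.shape[0]
    if k_min < 1:
        raise ValueError("k_min must be >= 1")
    if k_max < k_min:
        raise ValueError("k_max must be >= k_min")
    if k_max >= n:
        warnings.warn(
            f"only {n} maps: shrinking k range from {k_min}-{k_max} to "
            f"{k_min}-{n - 1}",
            stacklevel=2,
        )
        k_max = n - 1
        k_min = min(k_min, k_max)
    if gfp_weights is None:
        gfp_weights = gfp_of_maps(maps)
    rng = np.random.default_rng(seed)
    norm_maps = normalize_maps(maps, canonical=False)

    runs: dict[int, ClusterRunResult] = {}
    lo = max(1, k_min - 1)
    hi = min(n, k_max + 1)
    for k in range(lo, hi + 1):
        runs[k] = modified_kmeans(
            maps,
            k,
            n_restarts=n_restarts,
            seed=int(rng.integers(2**31)),
            gfp_weights=gfp_weights,
        )

    table, votes = _criterion_votes(norm_maps, runs, k_min, k_max, rng)
    if votes:
        ordered = sorted(votes.values())
        chosen = int(ordered[(len(ordered) - 1) // 2])  # lower median
    else:
        chosen = int(k_min)
    chosen = int(np.clip(chosen, k_min, k_max))
    return ModelSelection(
        k_range=(k_min, k_max),
        criterion_table=table,
        votes=votes,
        chosen_k=chosen,
        runs={k: v for k, v in runs.items() if k_min <= k <= k_max},
    )


# ---------------------------------------------------------------------------
# two-step procedure


def individual_clustering(
    rec: Recording,
    k_min: int = DEFAULT_K_RANGE[0],
    k_max: int = DEFAULT_K_RANGE[1],
    seed: int | None = None,
    n_restarts: int = DEFAULT_RESTARTS,
    min_peaks_per_k: int = 10,
) -> tuple[TemplateSet, ModelSelection]:
    """Per-subject template maps from the GFP-peak maps of a recording."""
    series = compute_gfp(rec)
    peaks = find_gfp_peaks(series)
    if peaks.size < min_peaks_per_k * k_max:
        raise InsufficientDataError(
            f"{peaks.size} GFP peaks < {min_peaks_per_k * k_max} required"
        )
    maps = peak_maps(rec, peaks)
    sel = select_k_metacriterion(
        maps, k_min=k_min, k_max=k_max, seed=seed, n_restarts=n_restarts
    )
    run = sel.runs[sel.chosen_k]
    templates = TemplateSet(
        maps=run.templates.maps, level="individual", gev_total=run.gev
    )
    return templates, sel


CANONICAL_CLASS_NAMES = ("A", "B", "C", "D", "E", "F", "G", "H", "I", "J")


def group_clustering(
    individual_sets: list[TemplateSet],
    k_min: int = DEFAULT_K_RANGE[0],
    k_max: int = DEFAULT_K_RANGE[1],
    seed: int | None = None,
    n_restarts: int = DEFAULT_RESTARTS,
    reference_maps: np.ndarray | None = None,
) -> tuple[TemplateSet, ModelSelection]:
    """Pool every subject's templates and cluster them into group classes.

    Each individual template enters with unit weight (GFP weight 1), so
    subjects contribute proportionally to their number of templates.
    Classes are ordered by descending explained-variance share over the
    pooled maps; if ``reference_maps`` is given, classes are instead
    greedily matched (best |r| first) to those canonical maps and named
    after them — a purely cosmetic relabeling.
    """
    if len(individual_sets) < 2:
        raise ValueError("group clustering needs at least 2 subjects")
    pooled = np.vstack([s.maps for s in individual_sets])
    if pooled.shape[0] == 0:
        raise ValueError("empty template pool")
    weights = np.ones(pooled.shape[0])
    sel = select_k_metacriterion(
        pooled,
        k_min=k_min,
        k_max=k_max,
        seed=seed,
        n_restarts=n_restarts,
        gfp_weights=weights,
    )
    run = sel.runs[sel.chosen_k]
    maps = run.templates.maps
    # provisional backfit of the pooled maps for the ordering
    _, per_class = gev_of_assignment(pooled, maps, run.assignment, weights)
    order = np.argsort(-per_class)
    maps = maps[order]
    names = None
    if reference_maps is not None:
        ref = np.atleast_2d(reference_maps)
        c = np.abs(correlation_matrix(maps, ref))
        perm = np.full(maps.shape[0], -1)
        used: set[int] = set()
        for _ in range(min(maps.shape[0], ref.shape[0])):
            i, j = np.unravel_index(np.argmax(c), c.shape)
            perm[i] = j
            used.add(int(j))
            c[i, :] = -1
            c[:, j] = -1
        names = tuple(
            CANONICAL_CLASS_NAMES[j] if j >= 0 else f"X{i}"
            for i, j in enumerate(perm)
        )
    templates = TemplateSet(maps=maps, level="group", names=names, gev_total=run.gev)
    return templates, sel


def match_templates(estimated: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Greedy one-to-one matching of estimated to reference maps.

    Returns ``(perm, abs_r)`` where ``perm[i]`` is the reference index
    matched to estimated map i and ``abs_r[i]`` the |correlation| of the
    pair.  Used to score template recovery on synthetic data.
    """
    est = np.atleast_2d(estimated)
    ref = np.atleast_2d(truth)
    c = np.abs(correlation_matrix(est, ref))
    perm = np.full(est.shape[0], -1)
    scores = np.zeros(est.shape[0])
    work = c.copy()
    for _ in range(min(est.shape[0], ref.shape[0])):
        i, j = np.unravel_index(np.argmax(work), work.shape)
        perm[i] = j
        scores[i] = c[i, j]
        work[i, :] = -1
        work[:, j] = -1
    return perm, scores
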