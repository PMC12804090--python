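"""Joint hidden Markov random field for nuclear spatial-localization states.

Genomic bins are nodes of per-cell-type graphs (linear adjacency plus
significant long-range contacts); each node carries a vector of
nuclear-position observations (TSA-seq-like, DamID-like) and a hidden
spatial state shared across cell types.  The model is

    P(H, O)  ~  prod_c  prod_i P(O_i^c | H_i^c)  prod_(i,j) in E^c psi(H_i^c, H_j^c)

with Gaussian emissions shared across cell types and a symmetric state
compatibility matrix psi.  Inference is hard-EM: iterated conditional
modes (ICM) over the hidden states alternating with closed-form updates
of the emission and compatibility parameters.  The reported
pseudo-log-likelihood is the Laplace-penalized complete-data objective,
under which both steps are exact coordinate ascent, so it is
non-decreasing at every iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import networkx as nx

from .contact import ContactMatrix, observed_over_expected

__all__ = [
    "SpinModel",
    "stable_bins",
    "normalize_tracks",
    "build_graph",
    "fit_spin",
    "select_K",
    "state_enrichment",
    "carna_enrichment",
]


@dataclass
class SpinModel:
    K: int
    means: np.ndarray                     # (K, d)
    variances: np.ndarray                 # (K, d) diagonal covariances
    log_psi: np.ndarray                   # (K, K) symmetric log compatibility
    assignments: list[np.ndarray]         # per cell type, ints in 0..K-1
    pseudo_log_likelihood: float = np.nan
    history: list[float] = field(default_factory=list)
    converged: bool = False


def stable_bins(interchrom_corr: np.ndarray, top_frac: float = 0.25) -> np.ndarray:
    """Spatially conserved bins: top 25% by mean interchromosomal
    contact-profile correlation across cell types.  Ties resolved by bin
    order (earlier bin wins), making the selection deterministic."""
    corr = np.asarray(interchrom_corr, dtype=float)
    if corr.size == 0:
        raise ValueError("empty correlation vector")
    k = max(1, int(round(top_frac * corr.size)))
    # stable sort descending; ties keep original order
    order = np.argsort(-corr, kind="stable")
    return np.sort(order[:k])


def normalize_tracks(
    tracks: np.ndarray, stable: np.ndarray
) -> np.ndarray:
    """Yeo-Johnson power transform fitted on spatially stable bins.

    `tracks` is (n_bins, d); for each column the transform parameters
    (lambda, centre, scale) are fitted on the stable-bin values and then
    applied genome-wide.  Constant tracks are rejected.
    """
    from sklearn.preprocessing import PowerTransformer

    tracks = np.asarray(tracks, dtype=float)
    if tracks.ndim == 1:
        tracks = tracks[:, None]
    out = np.empty_like(tracks)
    for j in range(tracks.shape[1]):
        col = tracks[:, j]
        ref = col[stable]
        if np.std(ref) == 0:
            raise ValueError(f"track {j} is constant on the stable bins")
        pt = PowerTransformer(method="yeo-johnson", standardize=True)
        pt.fit(ref[:, None])
        out[:, j] = pt.transform(col[:, None])[:, 0]
    return out


def build_graph(
    cm: ContactMatrix,
    oe_zscore_threshold: float = 3.0,
    include_adjacency: bool = True,
    balanced: bool = False,
) -> np.ndarray:
    """Edge list (m, 2) for one cell type.

    Edges are the linear-adjacency pairs (i, i+1) within chromosomes plus
    all cis pairs whose O/E z-score within their distance stratum exceeds
    the threshold (significant long-range interactions).
    """
    if oe_zscore_threshold < 0:
        raise ValueError("threshold must be non-negative")
    layout = cm.layout
    oe = observed_over_expected(cm, balanced=balanced)
    edges = []
    for chrom in layout.chroms:
        sl = layout.chrom_slice(chrom)
        if include_adjacency:
            for i in range(sl.start, sl.stop - 1):
                edges.append((i, i + 1))
        sub = oe[sl, sl]
        m = sub.shape[0]
        for d in range(2, m):
            v = np.diagonal(sub, offset=d)
            fin = np.isfinite(v)
            if fin.sum() < 3:
                continue
            mu, sd = v[fin].mean(), v[fin].std()
            if sd == 0:
                continue
            z = (v - mu) / sd
            for i in np.flatnonzero(fin & (z > oe_zscore_threshold)):
                edges.append((sl.start + i, sl.start + i + d))
    return np.asarray(edges, dtype=int).reshape(-1, 2)


def _emission_loglik(obs: np.ndarray, means: np.ndarray, var: np.ndarray) -> np.ndarray:
    """(n, K) Gaussian diagonal-covariance log densities."""
    n, d = obs.shape
    ll = np.empty((n, means.shape[0]))
    for k in range(means.shape[0]):
        z2 = ((obs - means[k]) ** 2) / var[k]
        ll[:, k] = -0.5 * (z2 + np.log(2 * np.pi * var[k])).sum(axis=1)
    return ll


def _color_classes(n: int, edges: np.ndarray) -> list[np.ndarray]:
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(map(tuple, edges))
    coloring = nx.coloring.greedy_color(g, strategy="largest_first")
    colors: dict[int, list[int]] = {}
    for node, c in coloring.items():
        colors.setdefault(c, []).append(node)
    return [np.asarray(sorted(v)) for _, v in sorted(colors.items())]


def fit_spin(
    observations: list[np.ndarray],
    edges: list[np.ndarray],
    K: int,
    seed: int = 0,
    max_iter: int = 50,
    tol: float = 1e-4,
    psi_alpha: float = 0.1,
    var_floor: float = 1e-6,
    n_restarts: int = 1,
) -> SpinModel:
    """Hard-EM fit of the joint HMRF.

    E-step: exact dynamic programming over every chain of
    consecutive-bin edges (long-range edges contribute unary terms at
    their partners' current states; the move is kept only if the full
    objective does not decrease), followed by graph-coloured ICM sweeps
    -- nodes of one colour class share no edge, so their simultaneous
    update is exact coordinate ascent given the parameters.  M-step:
    pooled Gaussian mean/variance per state and Laplace-smoothed
    transition-style compatibility from neighbour state pairs (exact
    maximizer of the penalized objective).  Iterates until the
    label-change fraction drops below `tol` or `max_iter`.  With
    `n_restarts` > 1, the restart with the best final objective wins.
    """
    from sklearn.cluster import KMeans

    if K < 1:
        raise ValueError("K must be >= 1")
    if n_restarts > 1:
        fits = [
            fit_spin(observations, edges, K, seed=seed + 7919 * r, max_iter=max_iter,
                     tol=tol, psi_alpha=psi_alpha, var_floor=var_floor, n_restarts=1)
            for r in range(n_restarts)
        ]
        return max(fits, key=lambda m: m.pseudo_log_likelihood)
    n_ct = len(observations)
    if len(edges) != n_ct:
        raise ValueError("one edge list per cell type required")
    obs = [np.asarray(o, dtype=float) for o in observations]
    n, d = obs[0].shape
    pooled = np.vstack(obs)
    km = KMeans(n_clusters=K, n_init=1, random_state=seed).fit(pooled)
    H = [km.labels_[c * n : (c + 1) * n].copy() for c in range(n_ct)]

    from scipy import sparse

    adj = []
    for e in edges:
        if len(e):
            data = np.ones(2 * len(e))
            rows = np.concatenate([e[:, 0], e[:, 1]])
            cols = np.concatenate([e[:, 1], e[:, 0]])
            a = sparse.csr_matrix((data, (rows, cols)), shape=(n, n))
        else:
            a = sparse.csr_matrix((n, n))
        adj.append(a)
    color_classes = [_color_classes(n, e) for e in edges]
    adj_by_class = [
        [adj[c][cls] for cls in color_classes[c]] for c in range(len(edges))
    ]

    def m_step():
        means = np.empty((K, d))
        var = np.empty((K, d))
        allh = np.concatenate(H)
        for k in range(K):
            sel = pooled[allh == k]
            if len(sel) == 0:
                # re-seed an empty state from the farthest point
                far = np.argmax(((pooled - pooled.mean(0)) ** 2).sum(1))
                sel = pooled[far : far + 1]
            means[k] = sel.mean(axis=0)
            var[k] = np.maximum(sel.var(axis=0), var_floor)
        counts = np.full((K, K), 0.0)
        for c in range(n_ct):
            e = edges[c]
            if len(e):
                np.add.at(counts, (H[c][e[:, 0]], H[c][e[:, 1]]), 1.0)
        counts = counts + counts.T
        # transition-style compatibility: row-normalized conditional with
        # Laplace smoothing; the symmetrized log matrix enters the ICM
        # scores and the objective
        row = counts.sum(axis=1, keepdims=True)
        q = (counts + psi_alpha) / (row + psi_alpha * K)
        log_q = np.log(q)
        log_psi = 0.5 * (log_q + log_q.T)
        return means, var, log_psi, log_q

    def objective(ll_list, log_psi, log_q) -> float:
        total = 0.0
        for c in range(n_ct):
            total += ll_list[c][np.arange(n), H[c]].sum()
            e = edges[c]
            if len(e):
                total += log_psi[H[c][e[:, 0]], H[c][e[:, 1]]].sum()
        # Laplace penalty under which the conditional M-step is exact
        total += 0.5 * psi_alpha * log_q.sum()
        return float(total)

    # split each edge set into chain runs (consecutive-bin edges, solvable
    # exactly by dynamic programming) and extra long-range edges
    chains: list[list[np.ndarray]] = []
    extra_adj = []
    for e in edges:
        is_chain = (np.abs(e[:, 0] - e[:, 1]) == 1) if len(e) else np.zeros(0, bool)
        nxt = np.full(n, -1, dtype=int)
        for a, b in e[is_chain]:
            lo, hi = min(a, b), max(a, b)
            nxt[lo] = hi
        runs = []
        seen = np.zeros(n, dtype=bool)
        starts = set(np.arange(n)[nxt >= 0]) - set(nxt[nxt >= 0])
        for s0 in sorted(starts):
            run = [s0]
            while nxt[run[-1]] >= 0:
                run.append(nxt[run[-1]])
            runs.append(np.asarray(run))
            seen[run] = True
        chains.append(runs)
        ee = e[~is_chain]
        if len(ee):
            data = np.ones(2 * len(ee))
            rows = np.concatenate([ee[:, 0], ee[:, 1]])
            cols = np.concatenate([ee[:, 1], ee[:, 0]])
            extra_adj.append(sparse.csr_matrix((data, (rows, cols)), shape=(n, n)))
        else:
            extra_adj.append(sparse.csr_matrix((n, n)))

    def _viterbi(unary: np.ndarray, log_pair: np.ndarray) -> np.ndarray:
        m = unary.shape[0]
        bt = np.zeros((m, K), dtype=int)
        dp = unary[0].copy()
        for i in range(1, m):
            sc = dp[:, None] + log_pair
            bt[i] = np.argmax(sc, axis=0)
            dp = unary[i] + sc[bt[i], np.arange(K)]
        h = np.zeros(m, dtype=int)
        h[-1] = int(np.argmax(dp))
        for i in range(m - 1, 0, -1):
            h[i - 1] = bt[i][h[i]]
        return h

    def icm_sweeps(c: int, ll: np.ndarray, log_psi: np.ndarray, n_sweeps: int = 3) -> int:
        changed = 0
        onehot = np.zeros((n, K))
        onehot[np.arange(n), H[c]] = 1.0
        for _ in range(n_sweeps):
            sweep_changed = 0
            for cls, a_cls in zip(color_classes[c], adj_by_class[c]):
                nb = a_cls @ onehot
                score = ll[cls] + nb @ log_psi
                new = np.argmax(score, axis=1)
                sweep_changed += int((new != H[c][cls]).sum())
                onehot[cls] = 0.0
                onehot[cls, new] = 1.0
                H[c][cls] = new
            changed += sweep_changed
            if sweep_changed == 0:
                break
        return changed

    means, var, log_psi, log_q = m_step()
    ll_list = [_emission_loglik(obs[c], means, var) for c in range(n_ct)]
    history = [objective(ll_list, log_psi, log_q)]
    converged = False
    for _ in range(max_iter):
        changed = 0
        # E-step part 1: exact DP over each chain run, long-range edge terms
        # entering as unary contributions at the partners' current states;
        # the move is accepted only if the full objective does not decrease
        obj_before = objective(ll_list, log_psi, log_q)
        H_backup = [h.copy() for h in H]
        for c in range(n_ct):
            onehot = np.zeros((n, K))
            onehot[np.arange(n), H[c]] = 1.0
            unary_extra = (extra_adj[c] @ onehot) @ log_psi
            unary = ll_list[c] + unary_extra
            for run in chains[c]:
                newh = _viterbi(unary[run], log_psi)
                changed += int((newh != H[c][run]).sum())
                H[c][run] = newh
        if objective(ll_list, log_psi, log_q) < obj_before:
            H = [h.copy() for h in H_backup]
            changed = 0
        # E-step part 2: ICM sweeps (exact coordinate ascent, polishes the
        # long-range edges and any bins outside chain runs)
        for c in range(n_ct):
            changed += icm_sweeps(c, ll_list[c], log_psi)
        means, var, log_psi, log_q = m_step()
        ll_list = [_emission_loglik(obs[c], means, var) for c in range(n_ct)]
        history.append(objective(ll_list, log_psi, log_q))
        if changed / (n_ct * n) < tol:
            converged = True
            break
    return SpinModel(
        K=K,
        means=means,
        variances=var,
        log_psi=log_psi,
        assignments=H,
        pseudo_log_likelihood=history[-1],
        history=history,
        converged=converged,
    )


def select_K(
    observations: list[np.ndarray],
    edges: list[np.ndarray],
    K_range: range | list[int],
    seed: int = 0,
    **fit_kwargs,
):
    """Elbow curve (k-means WCSS) plus AIC/BIC table over candidate K.

    AIC = 2p - 2 PL and BIC = p ln(n_obs) - 2 PL with the HMRF
    pseudo-log-likelihood PL and p = K d (means) + K d (variances) + K^2
    (compatibility).
    """
    from sklearn.cluster import KMeans

    pooled = np.vstack([np.asarray(o) for o in observations])
    n_obs, d = pooled.shape
    rows = []
    for K in K_range:
        km = KMeans(n_clusters=K, n_init=1, random_state=seed).fit(pooled)
        model = fit_spin(observations, edges, K, seed=seed, **fit_kwargs)
        p = K * d + K * d + K * K
        pl = model.pseudo_log_likelihood
        rows.append(
            {
                "K": K,
                "wcss": float(km.inertia_),
                "pseudo_logL": pl,
                "AIC": 2 * p - 2 * pl,
                "BIC": p * np.log(n_obs) - 2 * pl,
            }
        )
    import pandas as pd

    return pd.DataFrame(rows)


def state_enrichment(states: np.ndarray, track: np.ndarray) -> np.ndarray:
    """log2 of mean track signal per state over the genome-wide mean.

    Empty states yield NaN.
    """
    states = np.asarray(states)
    track = np.asarray(track, dtype=float)
    overall = np.nanmean(track)
    K = int(states.max()) + 1
    out = np.full(K, np.nan)
    for k in range(K):
        m = states == k
        if m.any():
            with np.errstate(divide="ignore"):
                out[k] = np.log2(np.nanmean(track[m]) / overall)
    return out


def carna_enrichment(
    rna_class: np.ndarray,
    dna_state: np.ndarray,
    rna_chrom: np.ndarray | None = None,
    dna_chrom: np.ndarray | None = None,
):
    """Repeat-class x spatial-state log2 observed/expected for RNA-DNA pairs.

    Expected counts are total pairs times the product of the marginal
    class and state abundances.  Only interchromosomal pairs are used
    when chromosome labels are supplied; dropped cis pairs are counted.
    Zero observed with nonzero expected yields -inf (flagged).
    """
    import pandas as pd

    rna_class = np.asarray(rna_class)
    dna_state = np.asarray(dna_state)
    n_dropped = 0
    if rna_chrom is not None and dna_chrom is not None:
        keep = np.asarray(rna_chrom) != np.asarray(dna_chrom)
        n_dropped = int((~keep).sum())
        rna_class = rna_class[keep]
        dna_state = dna_state[keep]
    obs = pd.crosstab(pd.Series(rna_class, name="class"), pd.Series(dna_state, name="state"))
    total = obs.to_numpy().sum()
    p_class = obs.sum(axis=1) / total
    p_state = obs.sum(axis=0) / total
    expected = np.outer(p_class, p_state) * total
    with np.errstate(divide="ignore"):
        log2fc = np.log2(obs.to_numpy() / expected)
    df = pd.DataFrame(log2fc, index=obs.index, columns=obs.columns)
    return {"log2fc": df, "observed": obs, "expected": pd.DataFrame(expected, index=obs.index, columns=obs.columns), "n_cis_dropped": n_dropped}
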