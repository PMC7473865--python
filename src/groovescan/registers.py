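"""Register deconvolution: PSSM window scanning and Gibbs motif clustering.

Two routes assign each peptide its 9mer (or 13mer) binding core:

* **PSSM scanning** (libraries with a designed register): the log2-enrichment
  PSSM scores every candidate window; peptides whose best-scoring window is
  shifted from the designed register are out-of-register, regardless of score.
* **Gibbs clustering** (13mer libraries and external peptide sets): an
  annealed Gibbs sampler over (cluster, offset) assignments maximizes the
  summed Kullback-Leibler information of cluster log-odds matrices against a
  data-derived background; the cluster number is chosen by maximum mean KLD,
  and peptides whose best log-odds score falls below a trash threshold are
  flagged as outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .designs import AA_ORDER
from .enrichment import EnrichmentMatrix
from .simulate import encode_peptides

#: effective pseudocount mass added to cluster residue counts
GIBBS_BETA = 50.0


@dataclass
class PSSM:
    """9-position x 20-residue additive scoring matrix of log2 enrichments."""

    scores: pd.DataFrame
    source_round: int | None = None

    def __post_init__(self) -> None:
        if self.scores.shape != (9, 20):
            raise ValueError("PSSM requires 9 positions")
        if not np.isfinite(self.scores.to_numpy()).all():
            raise ValueError("PSSM entries must be finite")

    @property
    def matrix(self) -> np.ndarray:
        return self.scores.to_numpy(dtype=float)


@dataclass
class RegisterAssignment:
    peptide: str
    best_offset: int
    score: float
    in_register: bool


@dataclass
class GibbsSolution:
    """Result of Gibbs register deconvolution at the KLD-selected cluster count."""

    assignments: dict[str, tuple[int, int]]  # peptide -> (cluster, offset)
    cluster_pssms: dict[int, pd.DataFrame]   # cluster -> log-odds matrix
    kld_by_k: dict[int, float]
    chosen_k: int
    outliers: set[str] = field(default_factory=set)
    trash_threshold: float | None = None
    background: pd.Series | None = None


def build_pssm(enrich: EnrichmentMatrix) -> PSSM:
    """PSSM from a 9-position enrichment matrix (direct value transfer)."""
    if enrich.log2fc.shape[0] != 9:
        raise ValueError("PSSM requires 9 positions")
    return PSSM(scores=enrich.log2fc.copy(), source_round=enrich.round)


def score_windows(peptide: str, pssm: PSSM) -> np.ndarray:
    """PSSM score of every 9mer window of the peptide (len - 8 windows)."""
    if len(peptide) < 9:
        raise ValueError("too short for core: peptide must be >= 9 residues")
    idx = encode_peptides([peptide])[0]
    if (idx >= 20).any():
        raise ValueError("peptide contains non-standard residues")
    m = pssm.matrix
    n_win = len(peptide) - 8
    return np.array([m[np.arange(9), idx[o:o + 9]].sum() for o in range(n_win)])


def assign_register(peptide: str, pssm: PSSM, expected_offset: int,
                    ) -> RegisterAssignment:
    """Best-scoring 9mer register; ties prefer the designed offset, then lowest."""
    scores = score_windows(peptide, pssm)
    best = float(scores.max())
    tied = np.flatnonzero(scores == best)
    if expected_offset in tied:
        off = expected_offset
    else:
        off = int(tied[0])
    return RegisterAssignment(peptide=peptide, best_offset=off, score=best,
                              in_register=(off == expected_offset))


def assign_registers(peptides, pssm: PSSM, expected_offset: int) -> pd.DataFrame:
    """Vectorized register assignment over a same-length peptide set."""
    peptides = list(peptides)
    if not peptides:
        return pd.DataFrame(columns=["peptide", "offset", "score", "in_register"])
    idx = encode_peptides(peptides)
    L = idx.shape[1]
    if L < 9:
        raise ValueError("too short for core: peptides must be >= 9 residues")
    m = np.hstack([pssm.matrix, np.full((9, 1), -np.inf)])  # sentinel col for stops
    n_win = L - 8
    all_scores = np.empty((len(peptides), n_win))
    for o in range(n_win):
        all_scores[:, o] = m[np.arange(9)[None, :], idx[:, o:o + 9]].sum(axis=1)
    best = all_scores.max(axis=1)
    # tie policy: designed offset wins ties, else lowest offset
    is_tied_expected = all_scores[:, expected_offset] == best
    first = all_scores.argmax(axis=1)
    offs = np.where(is_tied_expected, expected_offset, first)
    return pd.DataFrame({
        "peptide": peptides,
        "offset": offs.astype(int),
        "score": best,
        "in_register": offs == expected_offset,
    })


def _data_background(idx: np.ndarray) -> np.ndarray:
    counts = np.bincount(idx.ravel(), minlength=20).astype(float)
    counts += 1.0  # avoid zero background cells
    return counts / counts.sum()


def _cluster_log_odds(counts: np.ndarray, n_members: float,
                      bg: np.ndarray) -> np.ndarray:
    """Pseudocount-regularized log2-odds matrix of one cluster."""
    f = (counts + GIBBS_BETA * bg[None, :]) / (n_members + GIBBS_BETA)
    return np.log2(f / bg[None, :])


def _system_kld(counts_by_k: np.ndarray, sizes: np.ndarray, bg: np.ndarray) -> float:
    """Size-weighted mean KL information over clusters, shrunk for small clusters.

    Each cluster's contribution carries an extra factor n_k / (n_k + beta)
    (the same pseudocount mass used for the log-odds matrices). Without it
    the objective is near-monotone in the cluster count — splitting a few
    stray peptides off raises the weighted mean by a hair — and the
    argmax-over-k model selection becomes unstable.
    """
    total = sizes.sum()
    if total == 0:
        return 0.0
    kld = 0.0
    for k in range(counts_by_k.shape[0]):
        if sizes[k] == 0:
            continue
        f = (counts_by_k[k] + GIBBS_BETA * bg[None, :]) / (sizes[k] + GIBBS_BETA)
        info = float((f * np.log2(f / bg[None, :])).sum())
        kld += (sizes[k] / total) * (sizes[k] / (sizes[k] + GIBBS_BETA)) * info
    return kld


def _gibbs_once(idx: np.ndarray, motif_len: int, n_clusters: int,
                iters: int, t_start: float, rng: np.random.Generator,
                bg: np.ndarray):
    """One annealed Gibbs run; returns (assignments, counts, sizes, kld)."""
    n, L = idx.shape
    n_off = L - motif_len + 1
    clus = rng.integers(0, n_clusters, size=n)
    offs = rng.integers(0, n_off, size=n)

    counts = np.zeros((n_clusters, motif_len, 20))
    sizes = np.zeros(n_clusters)
    pos = np.arange(motif_len)
    for i in range(n):
        counts[clus[i], pos, idx[i, offs[i]:offs[i] + motif_len]] += 1
        sizes[clus[i]] += 1

    lo_cache = [_cluster_log_odds(counts[k], sizes[k], bg) for k in range(n_clusters)]
    all_windows = np.lib.stride_tricks.sliding_window_view(idx, motif_len, axis=1)

    temps = np.linspace(t_start, 0.0, iters)  # linear decay; final sweeps greedy
    order = np.arange(n)
    for it in range(iters):
        T = temps[it]
        rng.shuffle(order)
        for i in order:
            c0, o0 = clus[i], offs[i]
            counts[c0, pos, idx[i, o0:o0 + motif_len]] -= 1
            sizes[c0] -= 1
            lo_cache[c0] = _cluster_log_odds(counts[c0], sizes[c0], bg)
            # score all (cluster, offset) options
            windows = all_windows[i]
            scores = np.empty((n_clusters, n_off))
            for k in range(n_clusters):
                scores[k] = lo_cache[k][pos[None, :], windows].sum(axis=1)
            flat = scores.ravel()
            if T > 1e-9:
                w = flat - flat.max()
                w = np.exp(w / T)
                choice = rng.choice(flat.size, p=w / w.sum())
            else:
                choice = int(flat.argmax())
            c1, o1 = divmod(int(choice), n_off)
            clus[i], offs[i] = c1, o1
            counts[c1, pos, idx[i, o1:o1 + motif_len]] += 1
            sizes[c1] += 1
            lo_cache[c1] = _cluster_log_odds(counts[c1], sizes[c1], bg)
    return clus, offs, counts, sizes, _system_kld(counts, sizes, bg)


def gibbs_cluster(peptides, motif_len: int = 9,
                  k_range=range(1, 7), n_seeds: int = 5, iters: int = 60,
                  t_start: float = 1.0, trash_threshold: float | None = 0.0,
                  seed: int = 0) -> GibbsSolution:
    """Gibbs-sampling register deconvolution with KLD-selected cluster number.

    For each candidate cluster count the sampler is restarted ``n_seeds``
    times with annealing from ``t_start`` to zero, keeping the restart with
    the best final KLD; ``chosen_k`` maximizes mean KLD over ``k_range``.
    With ``trash_threshold`` set, peptides whose best log-odds score falls
    below it are flagged as outliers (and excluded from the cluster matrices
    in a final refinement pass).
    """
    peptides = list(dict.fromkeys(peptides))
    if len(peptides) < 20:
        raise ValueError("need at least 20 peptides for clustering")
    if motif_len > min(len(p) for p in peptides):
        raise ValueError("motif longer than peptides")
    lens = {len(p) for p in peptides}
    if len(lens) != 1:
        raise ValueError("ragged peptide set: peptides differ in length")
    idx = encode_peptides(peptides)
    if (idx >= 20).any():
        raise ValueError("peptides contain non-standard residues")
    bg = _data_background(idx)
    ss = np.random.SeedSequence(seed)

    best_by_k = {}
    for k in k_range:
        best = None
        for child in ss.spawn(n_seeds):
            rng = np.random.default_rng(child)
            res = _gibbs_once(idx, motif_len, k, iters, t_start, rng, bg)
            if best is None or res[4] > best[4]:
                best = res
        best_by_k[k] = best
    kld_by_k = {k: v[4] for k, v in best_by_k.items()}
    chosen_k = max(kld_by_k, key=kld_by_k.get)
    clus, offs, counts, sizes, _ = best_by_k[chosen_k]

    pos = np.arange(motif_len)
    # best log-odds score of each peptide under its assigned cluster
    def _best_scores(counts, sizes):
        scores = np.empty(len(peptides))
        for i in range(len(peptides)):
            lo = _cluster_log_odds(counts[clus[i]], sizes[clus[i]], bg)
            scores[i] = lo[pos, idx[i, offs[i]:offs[i] + motif_len]].sum()
        return scores

    outliers: set[str] = set()
    if trash_threshold is not None:
        scores = _best_scores(counts, sizes)
        out_mask = scores < trash_threshold
        outliers = {peptides[i] for i in np.flatnonzero(out_mask)}
        if out_mask.any():  # refinement: rebuild matrices without outliers
            for i in np.flatnonzero(out_mask):
                counts[clus[i], pos, idx[i, offs[i]:offs[i] + motif_len]] -= 1
                sizes[clus[i]] -= 1

    assignments = {peptides[i]: (int(clus[i]), int(offs[i]))
                   for i in range(len(peptides)) if peptides[i] not in outliers}
    labels = [f"pos{j}" for j in range(motif_len)]
    cluster_pssms = {
        int(k): pd.DataFrame(_cluster_log_odds(counts[k], sizes[k], bg),
                             index=labels, columns=list(AA_ORDER))
        for k in range(chosen_k)
    }
    return GibbsSolution(
        assignments=assignments, cluster_pssms=cluster_pssms,
        kld_by_k={int(k): float(v) for k, v in kld_by_k.items()},
        chosen_k=int(chosen_k), outliers=outliers,
        trash_threshold=trash_threshold,
        background=pd.Series(bg, index=list(AA_ORDER)),
    )


def flag_outliers(solution: GibbsSolution, peptides) -> tuple[float, set[str]]:
    """Outlier fraction and set over an input peptide collection."""
    if solution.trash_threshold is None:
        raise ValueError("solution was computed without a trash threshold")
    peptides = list(dict.fromkeys(peptides))
    out = {p for p in peptides if p in solution.outliers}
    frac = len(out) / len(peptides) if peptides else 0.0
    return frac, out
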