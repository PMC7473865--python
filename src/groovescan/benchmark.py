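"""Benchmark construction and scoring: minimal epitopes, tiled decoys, AUC, PPV.

Decoy peptides are generated by tiling the source proteins of the positive
set with lengths drawn from the positives' length distribution (consecutive
tiles overlap by 8 residues), then sampled to the requested positive:decoy
ratio while rejecting any tile that shares a 9mer substring with a positive
or an already-chosen decoy. AUC is computed at 1:1 with the Mann-Whitney rank
statistic (ties counted half); PPV at 1:19 is the fraction of positives in
the top 5% of predictions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest, rankdata
from sklearn.metrics import roc_curve

from .designs import AA_ORDER
from .enrichment import position_labels

_RATIOS = {"1:1": 1, "1:19": 19}


@dataclass
class BenchmarkSet:
    positives: list[str]
    decoys: list[str]
    ratio: str
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.ratio not in _RATIOS:
            raise ValueError(f"ratio must be one of {sorted(_RATIOS)}")


@dataclass
class BenchmarkResult:
    auc: float
    roc_points: list[tuple[float, float]]
    scores: pd.DataFrame
    ppv: float | None = None


def _ninemers(peptide: str):
    return {peptide[i:i + 9] for i in range(max(0, len(peptide) - 8))}


def minimal_epitopes(peptides, exclusion=()) -> set[str]:
    """Collapse nested peptide sets to their minimal members.

    A peptide is dropped if another retained peptide is a proper substring of
    it (nested-set rule: the group's innermost member is kept), or if it
    contains any exclusion-list substring (stand-in for Ig/HLA mapping).
    """
    peps = sorted(set(peptides), key=lambda p: (len(p), p))
    peps = [p for p in peps if not any(x in p for x in exclusion)]
    kept: list[str] = []
    for p in peps:  # ascending length: any container of a kept peptide drops
        if any(q in p and q != p for q in kept):
            continue
        kept.append(p)
    return set(kept)


def tile_protein(sequence: str, lengths, rng: np.random.Generator,
                 overlap: int = 8) -> list[str]:
    """Tile one protein with lengths drawn from ``lengths``; step = length - overlap.

    Tiles start at the first residue; if a tile would overrun the protein end,
    its start is shifted back so the tile lies within the protein.
    """
    lengths = np.asarray(lengths)
    tiles: list[str] = []
    start = 0
    seen_starts = set()
    while start < len(sequence):
        L = int(rng.choice(lengths))
        if start + L > len(sequence):
            shifted = len(sequence) - L
            if shifted >= 0 and shifted not in seen_starts:
                tiles.append(sequence[shifted:shifted + L])
            break
        if start not in seen_starts:
            tiles.append(sequence[start:start + L])
            seen_starts.add(start)
        step = L - overlap
        if step < 1:
            step = 1
        start += step
    return tiles


def generate_decoys(proteome: dict[str, str], positives, ratio: str = "1:1",
                    seed: int = 0, provenance: str = "") -> BenchmarkSet:
    """Length-matched tiled decoys at the requested positive:decoy ratio.

    ``proteome`` maps protein id -> sequence (the source proteins of the
    positives). Decoys are drawn per positive-length stratum and any tile
    sharing a 9mer with a positive or a chosen decoy is rejected.
    """
    positives = list(dict.fromkeys(positives))
    if not proteome or not positives:
        raise ValueError("proteome and positives must be nonempty")
    rng = np.random.default_rng(seed)
    pos_lengths = np.array([len(p) for p in positives])

    pool: list[str] = []
    for _pid, seq in sorted(proteome.items()):
        pool.extend(tile_protein(seq, pos_lengths, rng))
    rng.shuffle(pool)

    forbidden = set()
    for p in positives:
        forbidden |= _ninemers(p)

    n_per = _RATIOS[ratio]
    need = {}
    for L, cnt in zip(*np.unique(pos_lengths, return_counts=True)):
        need[int(L)] = int(cnt) * n_per
    decoys: list[str] = []
    chosen = set()
    for tile in pool:
        L = len(tile)
        if need.get(L, 0) <= 0 or tile in chosen:
            continue
        nm = _ninemers(tile)
        if nm & forbidden:
            continue
        decoys.append(tile)
        chosen.add(tile)
        forbidden |= nm
        need[L] -= 1
    short = sum(v for v in need.values() if v > 0)
    if short:
        raise ValueError(f"decoy pool exhausted: short {short} decoys "
                         f"(by length: { {k: v for k, v in need.items() if v > 0} })")
    return BenchmarkSet(positives=positives, decoys=decoys, ratio=ratio,
                        provenance=provenance)


def _check_scored(bench: BenchmarkSet, scores: dict[str, float]) -> None:
    missing = [p for p in bench.positives + bench.decoys if p not in scores]
    if missing:
        raise ValueError(f"unscored peptides: {len(missing)} missing from scores")


def roc_auc(bench: BenchmarkSet, scores: dict[str, float]) -> BenchmarkResult:
    """ROC curve and AUC on a 1:1 benchmark set.

    AUC via the Mann-Whitney rank statistic (ties counted half); ROC points
    at every score threshold, whose trapezoidal integral equals the AUC.
    """
    _check_scored(bench, scores)
    y = np.array([1] * len(bench.positives) + [0] * len(bench.decoys))
    s = np.array([scores[p] for p in bench.positives + bench.decoys])
    ranks = rankdata(s)  # average ranks: ties count half in the U statistic
    n_pos, n_neg = y.sum(), (1 - y).sum()
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    fpr, tpr, _ = roc_curve(y, s)
    points = list(zip(fpr.tolist(), tpr.tolist()))
    df = pd.DataFrame({"peptide": bench.positives + bench.decoys,
                       "label": y, "score": s})
    return BenchmarkResult(auc=float(auc), roc_points=points, scores=df)


def ppv_top5(bench: BenchmarkSet, scores: dict[str, float]) -> float:
    """Fraction of positives in the top 5% of predictions on a 1:19 set.

    The top ``ceil(0.05 * N)`` peptides are taken after a stable descending
    sort (ties keep input order: positives first, then decoys, each in the
    order supplied).
    """
    if bench.ratio != "1:19":
        raise ValueError("PPV requires 1:19 composition")
    _check_scored(bench, scores)
    peptides = bench.positives + bench.decoys
    labels = np.array([1] * len(bench.positives) + [0] * len(bench.decoys))
    s = np.array([scores[p] for p in peptides])
    order = np.argsort(-s, kind="stable")
    k = math.ceil(0.05 * len(peptides))
    top = labels[order[:k]]
    return float(top.sum() / k)


def compare_predictors(scoresA: dict[str, tuple[float, int]],
                       scoresB: dict[str, tuple[float, int]],
                       percentile: float = 90.0) -> dict[str, pd.DataFrame]:
    """Positional comparison of two predictors on a common scored peptide set.

    Peptides in the top ``percentile`` of only one predictor are compared,
    core position by residue, against those in the top percentile of both
    (two-sided binomial tests, Bonferroni over 9 x 20 cells). Returns, per
    predictor, a signed significance table: ``sign(f_only - f_both) *
    -log10(p_adj)``, zeros where not significant at 0.05.
    """
    common = sorted(set(scoresA) & set(scoresB))
    if not common:
        raise ValueError("no shared peptides between predictors")
    vA = np.array([scoresA[p][0] for p in common])
    vB = np.array([scoresB[p][0] for p in common])
    thrA = np.percentile(vA, percentile)
    thrB = np.percentile(vB, percentile)
    topA = {p for p, v in zip(common, vA) if v >= thrA}
    topB = {p for p, v in zip(common, vB) if v >= thrB}
    both = topA & topB
    if not both:
        raise ValueError("no shared top peptides")

    def cores(pepset, src):
        return [p[src[p][1]:src[p][1] + 9] for p in sorted(pepset)]

    def freq_counts(core_list):
        from .simulate import encode_peptides
        idx = encode_peptides(core_list)
        counts = np.zeros((9, 20), dtype=int)
        for pos in range(9):
            counts[pos] = np.bincount(idx[:, pos], minlength=20)
        return counts

    both_counts_A = freq_counts(cores(both, scoresA))
    both_counts_B = freq_counts(cores(both, scoresB))
    out = {}
    for name, only, src, base_counts in (
        ("A", topA - topB, scoresA, both_counts_A),
        ("B", topB - topA, scoresB, both_counts_B),
    ):
        table = np.zeros((9, 20))
        if only:
            oc = freq_counts(cores(only, src))
            n_only = len(only)
            base_f = (base_counts / base_counts.sum(axis=1, keepdims=True)).clip(1e-12, 1 - 1e-12)
            factor = 9 * 20
            for pos in range(9):
                for a in range(20):
                    pv = binomtest(int(oc[pos, a]), n_only, base_f[pos, a],
                                   alternative="two-sided").pvalue
                    padj = min(1.0, pv * factor)
                    if padj < 0.05:
                        sgn = np.sign(oc[pos, a] / n_only - base_f[pos, a])
                        table[pos, a] = sgn * -np.log10(max(padj, 1e-300))
        out[name] = pd.DataFrame(table, index=position_labels(9),
                                 columns=list(AA_ORDER))
    return out
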