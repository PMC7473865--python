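"""Positional frequencies, log2-fold enrichment, significance, and KL motifs.

All matrices are pandas DataFrames with positions as rows (labelled P1..P9
for 9-position matrices, P(-2)..P11 for 13-position ones) and the 20 residues
in fixed alphabetical order as columns. Frequencies are percentages
(rows sum to 100); each unique peptide counts once ("unweighted").
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .designs import AA_ORDER
from .simulate import encode_peptides

#: default pseudocount (percentage points) applied to both sides of the ratio
DEFAULT_PSEUDO = 0.1


def position_labels(n_positions: int) -> list[str]:
    """P1..P9 for a 9mer core; P(-2)..P11 for the diversified 13mer window."""
    if n_positions == 9:
        return [f"P{i}" for i in range(1, 10)]
    if n_positions == 13:
        return [f"P{i}" if i >= 1 else f"P({i})" for i in range(-2, 11) if i != 0] + ["P11"]
    return [f"pos{i}" for i in range(n_positions)]


def uniprot_background() -> pd.Series:
    """UniProt-average residue frequencies (sums to 1, alphabetical order)."""
    path = resources.files("groovescan.data") / "uniprot_freqs.tsv"
    df = pd.read_csv(path, sep="\t").set_index("residue")
    bg = df["frequency"].reindex(list(AA_ORDER))
    return bg / bg.sum()


@dataclass
class FrequencyMatrix:
    """Position x residue percentages over a unique-peptide set."""

    freq: pd.DataFrame
    n_peptides: int
    weighting: str = "unweighted"

    @property
    def n_positions(self) -> int:
        return self.freq.shape[0]


@dataclass
class EnrichmentMatrix:
    """log2-fold enrichments of a selected round vs the unselected library."""

    log2fc: pd.DataFrame
    reference: FrequencyMatrix
    round: int | None = None
    pvals: pd.DataFrame | None = None


@dataclass
class KLLogo:
    """Kullback-Leibler motif: per-position information and signed letter heights.

    ``heights[p, a] = f(a) * log2(f(a) / bg(a))`` so enriched residues get
    positive heights, depleted residues negative ones, and the signed heights
    at a position sum exactly to its KL information (which is >= 0).
    """

    info: pd.Series
    heights: pd.DataFrame
    background: pd.Series


def positional_frequencies(peptides, start: int = 0,
                           length: int | None = None) -> FrequencyMatrix:
    """Unweighted positional residue percentages over a unique peptide set.

    ``start``/``length`` select the window of interest (e.g. the randomized
    positions of a design); by default the full peptide length is used.
    """
    peptides = list(dict.fromkeys(peptides))  # unique, order-preserving
    if not peptides:
        raise ValueError("no peptides")
    lens = {len(p) for p in peptides}
    if len(lens) != 1:
        raise ValueError("ragged peptide set: peptides differ in length")
    L = lens.pop()
    if length is None:
        length = L - start
    idx = encode_peptides(peptides)[:, start:start + length]
    if (idx >= 20).any():
        raise ValueError("peptides contain non-standard residues")
    counts = np.zeros((length, 20))
    for p in range(length):
        counts[p] = np.bincount(idx[:, p], minlength=20)
    freq = 100.0 * counts / len(peptides)
    df = pd.DataFrame(freq, index=position_labels(length), columns=list(AA_ORDER))
    return FrequencyMatrix(freq=df, n_peptides=len(peptides))


def log2_enrichment(selected: FrequencyMatrix, naive: FrequencyMatrix,
                    pseudo: float = DEFAULT_PSEUDO, round: int | None = None,
                    ) -> EnrichmentMatrix:
    """log2((selected + pseudo) / (naive + pseudo)), entrywise, in percent units."""
    if selected.freq.shape != naive.freq.shape:
        raise ValueError("matrix shape error: selected and naive dimensions differ")
    log2fc = np.log2((selected.freq + pseudo) / (naive.freq.values + pseudo))
    return EnrichmentMatrix(log2fc=log2fc, reference=naive, round=round)


def positional_significance(peptides, naive: FrequencyMatrix,
                            n_sample: int = 10_000, seed: int = 0,
                            start: int = 0, length: int | None = None,
                            ) -> pd.DataFrame:
    """Bonferroni-adjusted two-sided binomial tests vs the unselected library.

    For each position/residue, the count among ``min(n_sample, n)`` sampled
    peptides is tested against the naive frequency as the null probability;
    the Bonferroni factor is positions x 20.
    """
    peptides = list(dict.fromkeys(peptides))
    if not peptides:
        raise ValueError("no peptides")
    rng = np.random.default_rng(seed)
    if len(peptides) > n_sample:
        pick = rng.choice(len(peptides), size=n_sample, replace=False)
        peptides = [peptides[i] for i in pick]
    n = len(peptides)
    if length is None:
        length = len(peptides[0]) - start
    idx = encode_peptides(peptides)[:, start:start + length]
    factor = length * 20
    null = (naive.freq.values / 100.0).clip(1e-12, 1 - 1e-12)
    if naive.freq.shape[0] != length:
        raise ValueError("matrix shape error: naive matrix does not match window")
    pvals = np.ones((length, 20))
    for p in range(length):
        counts = np.bincount(idx[:, p], minlength=20)
        for a in range(20):
            pv = binomtest(int(counts[a]), n, null[p, a], alternative="two-sided").pvalue
            pvals[p, a] = min(1.0, pv * factor)
    return pd.DataFrame(pvals, index=position_labels(length), columns=list(AA_ORDER))


def kl_logo(freqs: FrequencyMatrix, background: pd.Series) -> KLLogo:
    """KL relative-entropy motif of a frequency matrix against a background."""
    bg = background.reindex(list(AA_ORDER)).to_numpy(dtype=float)
    if np.any(bg <= 0):
        raise ValueError("degenerate background: zero or negative frequency")
    bg = bg / bg.sum()
    f = (freqs.freq.to_numpy(dtype=float) / 100.0).clip(0, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = f * np.log2(f / bg[None, :])
    h[f == 0] = 0.0  # lim f->0 of f log f
    heights = pd.DataFrame(h, index=freqs.freq.index, columns=freqs.freq.columns)
    info = heights.sum(axis=1)
    return KLLogo(info=info, heights=heights,
                  background=pd.Series(bg, index=list(AA_ORDER)))


def random_peptides(n: int, length: int, background: pd.Series, seed: int,
                    unique: bool = True) -> list[str]:
    """Seeded background-frequency random peptides (the calibration/motif set)."""
    rng = np.random.default_rng(seed)
    bg = background.reindex(list(AA_ORDER))
    p = (bg / bg.sum()).to_numpy()
    aas = np.frombuffer(AA_ORDER.encode(), dtype=np.uint8)
    out: list[str] = []
    seen = set()
    while len(out) < n:
        draw = aas[rng.choice(20, size=(n - len(out), length), p=p)]
        for row in draw.view(f"S{length}").ravel():
            s = row.decode()
            if unique:
                if s in seen:
                    continue
                seen.add(s)
            out.append(s)
            if len(out) == n:
                break
    return out


def algorithm_motif(scores: dict[str, tuple[float, int]], rule,
                    background: pd.Series | None = None) -> KLLogo:
    """KL motif of the predicted 9mer cores of peptides passing a binder rule.

    ``scores`` maps peptide -> (predicted value, predicted core offset);
    ``rule`` is a predicate on the predicted value (e.g. IC50 < 500 nM, or a
    rank cutoff). Background defaults to the packaged UniProt averages.
    """
    if background is None:
        background = uniprot_background()
    cores = [pep[off:off + 9] for pep, (val, off) in scores.items() if rule(val)]
    if not cores:
        raise ValueError("empty motif: no peptide passes the binder rule")
    freqs = positional_frequencies(cores)
    return kl_logo(freqs, background)


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
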