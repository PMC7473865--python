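"""Synthetic NNK selection libraries with a planted ground-truth binding model.

Emulates the data-generating process of a yeast-display MHC-II selection:

* naive library reads drawn codon-wise from NNK (N = any base, K = G/T), fixed
  flank residues encoded by one canonical codon each;
* iterative rounds of selection in which each displayed peptide is retained
  with probability ``logistic(stringency * (core_score - threshold))``, the
  core score being the planted PSSM evaluated at the design's expected
  register (or at a mixture-drawn register for 13mer designs);
* PCR/sequencing substitution errors with a two-valued Phred-33 quality model
  (above/below Q20, the only quality boundary the downstream filters use).

Every emitted read is tracked in a truth map (dna -> peptide, core offset,
binder flag) so downstream stages can be scored against known answers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .designs import AA_INDEX, AA_ORDER, LibraryDesign

_HIGH_Q = "?"  # Phred 30
_LOW_Q = "0"   # Phred 15

_NT = np.frombuffer(b"ACGT", dtype=np.uint8)
_NT_INDEX = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _NT_INDEX[_b] = _i

# codon index (16*a + 4*b + c over ACGT digits) -> residue byte, '*' for stops
from .designs import GENETIC_CODE  # noqa: E402

_CODON_AA = np.zeros(64, dtype=np.uint8)
for _codon, _aa in GENETIC_CODE.items():
    _idx = 16 * _NT_INDEX[ord(_codon[0])] + 4 * _NT_INDEX[ord(_codon[1])] + _NT_INDEX[ord(_codon[2])]
    _CODON_AA[_idx] = ord(_aa)

_AA_TO_IDX = np.full(256, 20, dtype=np.int64)  # 20 = sentinel (stop / unknown)
for _a, _i in AA_INDEX.items():
    _AA_TO_IDX[ord(_a)] = _i


def encode_peptides(peptides) -> np.ndarray:
    """Encode residue strings as an (n, L) int matrix; stops/unknowns map to 20."""
    arr = np.frombuffer("".join(peptides).encode(), dtype=np.uint8)
    return _AA_TO_IDX[arr].reshape(len(peptides), -1)


def translate_codons(dna_matrix: np.ndarray) -> np.ndarray:
    """Translate an (n, 3L) uint8 nucleotide matrix to an (n, L) residue byte matrix."""
    idx = _NT_INDEX[dna_matrix]
    codons = 16 * idx[:, 0::3] + 4 * idx[:, 1::3] + idx[:, 2::3]
    return _CODON_AA[codons]


@dataclass
class GroundTruthModel:
    """Planted binding model: a 9mer-core PSSM plus a logistic selection rule.

    ``pssm`` is (9 positions x 20 residues) on a log2-enrichment-like scale.
    ``stringency_by_round[r-1]`` is the logistic slope applied in round r;
    later rounds are at least as stringent. ``register_mixture`` (13mer
    designs) gives the probability of each permissible core offset.
    """

    pssm: np.ndarray
    stringency_by_round: tuple[float, ...]
    score_threshold: float
    register_mixture: dict[int, float] | None = None

    def __post_init__(self) -> None:
        self.pssm = np.asarray(self.pssm, dtype=float)
        if self.pssm.shape != (9, 20):
            raise ValueError("planted PSSM must be 9 positions x 20 residues")
        s = np.asarray(self.stringency_by_round, dtype=float)
        if np.any(s <= 0) or np.any(np.diff(s) < 0):
            raise ValueError("stringency must be positive and non-decreasing")
        if self.register_mixture is not None:
            total = sum(self.register_mixture.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError("register_mixture must sum to 1")

    def score_cores(self, pep_idx: np.ndarray, offsets: np.ndarray) -> np.ndarray:
        """PSSM score of the 9mer core starting at ``offsets`` for each row."""
        padded = np.hstack([self.pssm, np.full((9, 1), -1e3)])  # col 20: stop sentinel
        pos = offsets[:, None] + np.arange(9)[None, :]
        cols = np.take_along_axis(pep_idx, pos, axis=1)
        return padded[np.arange(9)[None, :], cols].sum(axis=1)

    def to_json(self, path) -> None:
        d = {
            "pssm": self.pssm.tolist(),
            "stringency_by_round": list(self.stringency_by_round),
            "score_threshold": self.score_threshold,
            "register_mixture": (None if self.register_mixture is None
                                 else {str(k): v for k, v in self.register_mixture.items()}),
        }
        with open(path, "w") as fh:
            json.dump(d, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruthModel":
        with open(path) as fh:
            d = json.load(fh)
        mix = d["register_mixture"]
        if mix is not None:
            mix = {int(k): v for k, v in mix.items()}
        return cls(np.array(d["pssm"]), tuple(d["stringency_by_round"]),
                   d["score_threshold"], mix)


@dataclass
class SimulatedReadSet:
    """Reads of one round, with the truth map covering every emitted record."""

    round: int
    records: list[tuple[str, str]]
    truth: dict[str, tuple[str, int, bool]]
    parent_of: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)


def _nnk_frequencies() -> np.ndarray:
    from .designs import NNK_CODON_COUNT
    f = np.array([NNK_CODON_COUNT.get(a, 0) for a in AA_ORDER], dtype=float)
    return f / f.sum()


def _planted_pssm() -> np.ndarray:
    """A DR401-like planted motif on the log2-enrichment scale.

    Built as log2(target / NNK) where ``target`` is a plausible enriched-round
    frequency profile: anchor positions P1/P4/P6/P9 concentrate probability
    mass on their favored residues (proportionally within the favored set),
    P7 carries a mild auxiliary preference, and P2-Pro / non-P1 Trp are
    depleted. Planting on this scale makes the ground truth the same kind of
    object the pipeline recovers (a log2-enrichment matrix), including the
    depletion structure that enrichment at anchors necessarily implies.
    """
    nnk = _nnk_frequencies()
    targets = np.tile(nnk, (9, 1))

    def concentrate(pos: int, residues: str, mass: float) -> None:
        idx = np.array([AA_INDEX[a] for a in residues])
        rest = np.ones(20, dtype=bool)
        rest[idx] = False
        t = np.empty(20)
        t[idx] = mass * nnk[idx] / nnk[idx].sum()
        t[rest] = (1 - mass) * nnk[rest] / nnk[rest].sum()
        targets[pos] = t

    concentrate(0, "FILMVWY", 0.75)   # P1: large hydrophobics
    concentrate(3, "DE", 0.60)        # P4: acidic
    concentrate(5, "STND", 0.55)      # P6: polar
    concentrate(8, "AGSC", 0.55)      # P9: small (+ Cys)
    concentrate(6, "PN", 0.35)        # P7: auxiliary
    targets[1, AA_INDEX["P"]] *= 0.2  # strong P2 Pro depletion
    for pos in range(1, 9):
        targets[pos, AA_INDEX["W"]] *= 0.5  # W depleted outside P1
    targets /= targets.sum(axis=1, keepdims=True)
    return np.log2(targets / nnk[None, :])


def default_ground_truth(design: LibraryDesign,
                         stringency_by_round: tuple[float, ...] = (1.0, 1.2, 1.4, 1.6, 1.8),
                         threshold_quantile: float = 0.90) -> GroundTruthModel:
    """Default planted model for a design.

    The logistic midpoint is placed at the ``threshold_quantile`` of the null
    core-score distribution (NNK residue frequencies, estimated once from a
    fixed internal sample), so a defined naive fraction is selectable.
    """
    pssm = _planted_pssm()
    rng = np.random.default_rng(20_000)  # fixed internal sample: threshold is part of the model definition
    from .designs import NNK_CODON_COUNT
    aas = [a for a in AA_ORDER]
    probs = np.array([NNK_CODON_COUNT.get(a, 0) for a in aas], dtype=float)
    probs /= probs.sum()
    sample = rng.choice(20, size=(10_000, 9), p=probs)
    scores = pssm[np.arange(9)[None, :], sample].sum(axis=1)
    threshold = float(np.quantile(scores, threshold_quantile))

    mixture = None
    if design.n_random == 13:
        c = design.expected_core_offset
        lo, hi = 0, design.peptide_length - 9
        raw = {c: 0.70, c - 1: 0.10, c + 1: 0.10, c - 2: 0.05, c + 2: 0.05}
        mixture = {o: p for o, p in raw.items() if lo <= o <= hi}
        total = sum(mixture.values())
        mixture = {o: p / total for o, p in mixture.items()}
    return GroundTruthModel(pssm, stringency_by_round, threshold, mixture)


def sample_naive(design: LibraryDesign, n: int, seed: int) -> SimulatedReadSet:
    """Draw ``n`` naive (round 0) reads with NNK-randomized codons.

    Randomized codons sample N uniformly from ACGT and K from G/T, so codon
    usage carries natural NNK redundancy (e.g. Leu has 3 NNK codons, Met 1).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    k = design.n_random
    L_pep = design.peptide_length

    rand = np.empty((n, 3 * k), dtype=np.uint8)
    rand[:, 0::3] = _NT[rng.integers(0, 4, size=(n, k))]
    rand[:, 1::3] = _NT[rng.integers(0, 4, size=(n, k))]
    rand[:, 2::3] = _NT[2 + rng.integers(0, 2, size=(n, k))]  # G or T

    f5_dna, f3_dna = design.flank_dna()
    prefix = (design.barcode_by_round[0] + design.constant5_dna + f5_dna).encode()
    suffix = (f3_dna + design.constant3_dna).encode()
    L = len(prefix) + 3 * k + len(suffix)
    reads = np.empty((n, L), dtype=np.uint8)
    reads[:, : len(prefix)] = np.frombuffer(prefix, dtype=np.uint8)
    reads[:, len(prefix): len(prefix) + 3 * k] = rand
    reads[:, len(prefix) + 3 * k:] = np.frombuffer(suffix, dtype=np.uint8)

    rand_aa = translate_codons(rand)
    pep_bytes = np.empty((n, L_pep), dtype=np.uint8)
    pep_bytes[:, : len(design.flank5_aa)] = np.frombuffer(design.flank5_aa.encode(), dtype=np.uint8)
    pep_bytes[:, design.randomized_slice] = rand_aa
    pep_bytes[:, len(design.flank5_aa) + k:] = np.frombuffer(design.flank3_aa.encode(), dtype=np.uint8)

    dnas = [b.decode() for b in reads.view(f"S{L}").ravel()]
    peptides = [b.decode() for b in pep_bytes.view(f"S{L_pep}").ravel()]
    qual = _HIGH_Q * L
    records = [(d, qual) for d in dnas]
    truth: dict[str, tuple[str, int, bool]] = {}
    # offsets and binder flags are attached by annotate_truth (needs the model);
    # until then record the designed register and binder=False placeholder
    for d, p in zip(dnas, peptides):
        truth.setdefault(d, (p, design.expected_core_offset, False))
    rs = SimulatedReadSet(round=0, records=records, truth=truth)
    return rs


def annotate_truth(reads: SimulatedReadSet, design: LibraryDesign,
                   model: GroundTruthModel, seed: int) -> None:
    """Fill in each truth entry's core offset (mixture-drawn for 13mers) and binder flag."""
    rng = np.random.default_rng(seed)
    dnas = list(reads.truth.keys())
    peptides = [reads.truth[d][0] for d in dnas]
    pep_idx = encode_peptides(peptides)
    n = len(dnas)
    if model.register_mixture is None:
        offsets = np.full(n, design.expected_core_offset)
    else:
        opts = np.array(sorted(model.register_mixture))
        probs = np.array([model.register_mixture[o] for o in opts])
        offsets = opts[rng.choice(len(opts), size=n, p=probs)]
    scores = model.score_cores(pep_idx, offsets)
    binder = scores >= model.score_threshold
    for d, o, b in zip(dnas, offsets, binder):
        pep = reads.truth[d][0]
        reads.truth[d] = (pep, int(o), bool(b))


def simulate_selection(naive: SimulatedReadSet, model: GroundTruthModel,
                       n_rounds: int, carryover: int = 100_000,
                       seed: int = 0, design: LibraryDesign | None = None,
                       ) -> list[SimulatedReadSet]:
    """Simulate ``n_rounds`` of selection from the naive library.

    Each round applies independent Bernoulli retention with probability
    ``logistic(stringency_r * (core_score - threshold))`` to every read of the
    previous round, then resamples the survivors (with replacement) to
    ``carryover`` reads. Peptides in round r+1 always existed in round r.

    When ``design`` is given, emitted reads carry the inline barcode of their
    round (the barcode prefix is swapped; the rest of the read is unchanged).
    """
    if len(naive.records) == 0:
        raise ValueError("no peptides to select")
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    rng = np.random.default_rng(seed)

    # score every unique dna once, at its truth-map register
    dnas = list(naive.truth.keys())
    peptides = [naive.truth[d][0] for d in dnas]
    offsets = np.array([naive.truth[d][1] for d in dnas])
    scores = model.score_cores(encode_peptides(peptides), offsets)
    score_of = dict(zip(dnas, scores))

    # counts representation of the current pool
    from collections import Counter
    pool = Counter(d for d, _ in naive.records)

    rounds_out: list[SimulatedReadSet] = []
    L = len(naive.records[0][0])
    qual = _HIGH_Q * L
    strs = model.stringency_by_round
    for r in range(1, n_rounds + 1):
        s = strs[min(r - 1, len(strs) - 1)]
        uniq = list(pool.keys())
        counts = np.array([pool[d] for d in uniq])
        sc = np.array([score_of[d] for d in uniq])
        with np.errstate(over="ignore"):
            p = expit(s * (sc - model.score_threshold))
        survivors = rng.binomial(counts, p)
        total = survivors.sum()
        if total == 0:
            raise RuntimeError(f"selection eliminated all peptides at round {r}")
        drawn = rng.multinomial(carryover, survivors / total)
        new_pool = Counter()
        for d, c in zip(uniq, drawn):
            if c:
                new_pool[d] = int(c)
        if design is not None:
            bc = design.barcode_by_round[r]
            bl = len(bc)
            emit = {d: bc + d[bl:] for d in new_pool}
        else:
            emit = {d: d for d in new_pool}
        records = [(emit[d], qual) for d, c in new_pool.items() for _ in range(c)]
        truth = {emit[d]: naive.truth[d] for d in new_pool}
        rounds_out.append(SimulatedReadSet(round=r, records=records, truth=truth))
        pool = new_pool
    return rounds_out


def inject_errors(reads: SimulatedReadSet, sub_rate: float,
                  low_q_fraction: float, seed: int) -> SimulatedReadSet:
    """Apply per-base substitution errors and a two-valued Phred quality model.

    Each base substitutes with probability ``sub_rate`` (uniform over the three
    alternatives); a ``low_q_fraction`` of bases get Phred < 20 (Q15), the rest
    Q30. The truth map gains entries mapping each corrupted read to its
    error-free parent's annotation, and ``parent_of`` records the parent dna.
    """
    if not 0 <= sub_rate <= 1 or not 0 <= low_q_fraction <= 1:
        raise ValueError("rates must be in [0, 1]")
    if not reads.records:
        return SimulatedReadSet(reads.round, [], dict(reads.truth), dict(reads.parent_of))
    rng = np.random.default_rng(seed)
    dnas = [d for d, _ in reads.records]
    n = len(dnas)
    L = len(dnas[0])
    arr = np.frombuffer("".join(dnas).encode(), dtype=np.uint8).reshape(n, L).copy()

    sub_mask = rng.random((n, L)) < sub_rate
    if sub_mask.any():
        idx = _NT_INDEX[arr[sub_mask]]
        shift = rng.integers(1, 4, size=idx.shape)
        arr[sub_mask] = _NT[(idx + shift) % 4]

    low_mask = rng.random((n, L)) < low_q_fraction
    quals = np.where(low_mask, ord(_LOW_Q), ord(_HIGH_Q)).astype(np.uint8)

    new_dnas = [b.decode() for b in arr.view(f"S{L}").ravel()]
    new_quals = [b.decode() for b in quals.view(f"S{L}").ravel()]
    records = [(d, q) for d, q in zip(new_dnas, new_quals)]

    truth = dict(reads.truth)
    parent_of = dict(reads.parent_of)
    changed = sub_mask.any(axis=1)
    for i in np.flatnonzero(changed):
        parent, child = dnas[i], new_dnas[i]
        if child not in truth:
            truth[child] = truth[parent]
            parent_of[child] = parent
    return SimulatedReadSet(reads.round, records, truth, parent_of)


def write_fastq(reads: SimulatedReadSet, path) -> None:
    """Write standard 4-line Phred-33 FASTQ."""
    with open(path, "w") as fh:
        for i, (dna, qual) in enumerate(reads.records):
            fh.write(f"@sim_r{reads.round}_{i}\n{dna}\n+\n{qual}\n")


def write_truth(reads: SimulatedReadSet, path) -> None:
    """Write the truth map as TSV: dna, peptide, core_offset, binder."""
    with open(path, "w") as fh:
        fh.write("dna\tpeptide\tcore_offset\tbinder\n")
        for dna, (pep, off, binder) in reads.truth.items():
            fh.write(f"{dna}\t{pep}\t{off}\t{int(binder)}\n")
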